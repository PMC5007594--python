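"""Sequence-based feature groups.

Three feature blocks are computed directly from nucleotide sequence:

* **Group I — DNA structural properties.** Each property is a lookup table
  over di- or tri-nucleotides (helical twist, bendability and the like);
  the feature value is the mean of the table over all sliding windows of
  the region.

* **Group II — TF binding motif occurrence.** For each position weight
  matrix (PWM) the expected occupancy of the whole region is computed with
  the TRAP biophysical model: every window on both strands contributes a
  saturating Boltzmann term ``R0·e^{-E} / (1 + R0·e^{-E})`` where ``E`` is
  the mismatch energy of the window relative to the PWM consensus,

      E = (1/λ) · Σ_j ln( (c_max,j + p) / (c_obs,j + p) ),

  with λ the mismatch scale, ``p`` a pseudocount, ``c_max,j`` the column
  maximum count and ``c_obs,j`` the count of the observed base. The
  per-motif equilibrium constant defaults to ``R0 = exp(0.584·W − 5.66)``
  for a matrix of width W. Defaults follow the published TRAP parameters
  (λ = 0.7, pseudocount 1) and are all overridable.

* **Group III — k-mer composition.** Exact overlapping occurrence counts
  of a fixed k-mer list (k = 1..6), normalised by the number of windows;
  no reverse-complement collapsing.

Windows containing N are skipped (Groups I, III) or contribute zero
occupancy (Group II); unknown bases never fabricate signal.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genomic_io import PWM

__all__ = [
    "PropertyScale",
    "TrapParameters",
    "KmerList",
    "load_property_scales",
    "default_property_scales",
    "all_kmers",
    "load_kmer_list",
    "dna_property_features",
    "trap_mismatch_energy",
    "trap_affinity",
    "trap_feature_vector",
    "kmer_composition",
    "gc_content",
    "reverse_complement",
    "DnaPropertyFeaturizer",
    "TrapFeaturizer",
    "KmerFeaturizer",
]

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3, N (or anything else) = 4."""
    out = np.full(len(seq), 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


@dataclass(frozen=True)
class PropertyScale:
    """A structural property lookup table over all k-mers (k = 2 or 3)."""

    name: str
    k: int
    table: dict[str, float]

    def __post_init__(self):
        if self.k not in (2, 3):
            raise ValueError(f"{self.name}: window width must be 2 or 3")
        if len(self.table) != 4**self.k:
            raise ValueError(
                f"{self.name}: expected {4 ** self.k} table entries, "
                f"got {len(self.table)}"
            )


@dataclass(frozen=True)
class TrapParameters:
    """Parameters of the TRAP occupancy model."""

    lam: float = 0.7
    lnR0_slope: float = 0.584
    lnR0_intercept: float = -5.66
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    def r0(self, width: int) -> float:
        return math.exp(self.lnR0_slope * width + self.lnR0_intercept)


@dataclass(frozen=True)
class KmerList:
    """An ordered, duplicate-free list of k-mers with lengths 1..6."""

    kmers: tuple[str, ...]

    def __init__(self, kmers):
        kmers = tuple(str(k).upper() for k in kmers)
        if len(set(kmers)) != len(kmers):
            raise ValueError("duplicate k-mers in list")
        for km in kmers:
            if not (1 <= len(km) <= 6) or any(b not in "ACGT" for b in km):
                raise ValueError(f"invalid k-mer {km!r} (length 1-6 over ACGT)")
        object.__setattr__(self, "kmers", kmers)

    def __len__(self):
        return len(self.kmers)

    def __iter__(self):
        return iter(self.kmers)


def all_kmers(max_k: int = 3) -> KmerList:
    """All k-mers for k ≤ max_k, lexicographic within each k (fallback list)."""
    if not 1 <= max_k <= 6:
        raise ValueError("max_k must be in 1..6")
    kmers = []
    for k in range(1, max_k + 1):
        kmers.extend("".join(t) for t in itertools.product("ACGT", repeat=k))
    return KmerList(kmers)


def load_kmer_list(path) -> KmerList:
    with open(path) as fh:
        return KmerList([ln.strip() for ln in fh if ln.strip()])


def load_property_scales(path) -> list[PropertyScale]:
    """Read scales from TSV rows: name, k, then 4^k ``kmer:value`` pairs."""
    scales = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, k = fields[0], int(fields[1])
            table = {}
            for pair in fields[2:]:
                km, _, val = pair.partition(":")
                table[km.upper()] = float(val)
            scales.append(PropertyScale(name, k, table))
    if not scales:
        raise ValueError(f"no property scales in {path}")
    return scales


def default_property_scales() -> list[PropertyScale]:
    """The packaged default set of 23 di-/tri-nucleotide property scales.

    These are synthetic stand-in tables with realistic dynamic range, not
    measured structural parameters; substitute a measured table via
    :func:`load_property_scales` for real analyses.
    """
    ref = resources.files("enhanseq") / "data" / "property_scales.synthetic.tsv"
    with resources.as_file(ref) as path:
        return load_property_scales(path)


# ---------------------------------------------------------------------------
# Group I


def dna_property_features(seq: str, scales) -> np.ndarray:
    """Mean structural-property value over all windows, one value per scale.

    Windows containing a base outside ACGT are skipped; if every window is
    skipped the feature is 0 and a warning is logged.
    """
    seq = seq.upper()
    scales = list(scales)
    if not scales:
        raise ValueError("no property scales supplied")
    max_k = max(s.k for s in scales)
    if len(seq) < max_k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={max_k}")
    out = np.zeros(len(scales))
    for i, scale in enumerate(scales):
        vals = [
            scale.table[seq[j : j + scale.k]]
            for j in range(len(seq) - scale.k + 1)
            if seq[j : j + scale.k] in scale.table
        ]
        if vals:
            out[i] = float(np.mean(vals))
        else:
            logger.warning(
                "all %d-mer windows contain N; property %s set to 0",
                scale.k,
                scale.name,
            )
    return out


# ---------------------------------------------------------------------------
# Group II (TRAP)


def _log_penalties(pwm: PWM, params: TrapParameters) -> np.ndarray:
    """(5, W) array: row b = ln((c_obs+p)/(c_max+p)) for base b; row 4 = -inf (N)."""
    counts = pwm.effective_counts()
    p = params.pseudocount
    cmax = counts.max(axis=0)
    with np.errstate(divide="ignore"):
        pen = np.log(counts + p) - np.log(cmax + p)  # <= 0
    return np.vstack([pen, np.full((1, pwm.width), -np.inf)])


def trap_mismatch_energy(window: str, pwm: PWM, params: TrapParameters | None = None) -> float:
    """Mismatch energy E of a single window against a PWM (0 at consensus)."""
    params = params or TrapParameters()
    window = window.upper()
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM width {pwm.width}"
        )
    enc = _encode(window)
    if (enc == 4).any():
        raise ValueError("window contains a base outside ACGT")
    pen = _log_penalties(pwm, params)
    return float(-(pen[enc, np.arange(pwm.width)].sum()) / params.lam)


def _strand_occupancies(enc: np.ndarray, pen: np.ndarray, lam: float, r0: float) -> np.ndarray:
    """Occupancy terms for all windows of one strand; N windows give 0."""
    w = pen.shape[1]
    n_win = enc.size - w + 1
    if n_win <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    logsum = pen[windows, np.arange(w)].sum(axis=1)  # = -λ·E, is -inf for N windows
    boltz = r0 * np.exp(logsum / lam)
    with np.errstate(invalid="ignore"):
        occ = boltz / (1.0 + boltz)
    return np.nan_to_num(occ, nan=0.0)


def trap_affinity(
    seq: str,
    pwm: PWM,
    params: TrapParameters | None = None,
    r0: float | None = None,
    log1p: bool = False,
) -> float:
    """TRAP occupancy of a sequence: sum over both strands and all offsets.

    The reverse-strand term at each offset uses the energy of the
    reverse-complemented window. Windows containing N contribute 0. The raw
    occupancy sum is returned by default; ``log1p=True`` applies log(1+x).
    """
    params = params or TrapParameters()
    seq = seq.upper()
    if len(seq) < pwm.width:
        raise ValueError(
            f"sequence length {len(seq)} shorter than PWM width {pwm.width}"
        )
    if r0 is None:
        r0 = params.r0(pwm.width)
    pen = _log_penalties(pwm, params)
    enc_fwd = _encode(seq)
    enc_rev = _encode(reverse_complement(seq))
    total = float(
        _strand_occupancies(enc_fwd, pen, params.lam, r0).sum()
        + _strand_occupancies(enc_rev, pen, params.lam, r0).sum()
    )
    return math.log1p(total) if log1p else total


def trap_feature_vector(
    seq: str, pwms, params: TrapParameters | None = None, log1p: bool = False
) -> np.ndarray:
    """One TRAP occupancy per PWM, in PWM-list order.

    PWMs wider than the sequence yield 0 with a warning rather than an
    error, so one short region does not abort a whole matrix build.
    """
    pwms = list(pwms)
    if not pwms:
        raise ValueError("empty PWM list")
    out = np.zeros(len(pwms))
    for i, pwm in enumerate(pwms):
        if len(seq) < pwm.width:
            logger.warning(
                "sequence shorter than PWM %s (W=%d); score set to 0",
                pwm.id,
                pwm.width,
            )
            continue
        out[i] = trap_affinity(seq, pwm, params, log1p=log1p)
    return out


# ---------------------------------------------------------------------------
# Group III and GC


def kmer_composition(seq: str, kmer_list: KmerList) -> np.ndarray:
    """Normalised exact occurrence counts of each k-mer.

    For a k-mer of length k the value is (overlapping occurrences among the
    L−k+1 windows, N windows never matching) / max(L−k+1, 1).
    """
    seq = seq.upper()
    if len(seq) < 1:
        raise ValueError("empty sequence")
    out = np.zeros(len(kmer_list))
    for i, km in enumerate(kmer_list):
        k = len(km)
        n_win = len(seq) - k + 1
        if n_win < 1:
            continue
        c = 0
        start = 0
        while True:
            j = seq.find(km, start)
            if j < 0:
                break
            c += 1
            start = j + 1
        out[i] = c / n_win
    return out


def gc_content(seq: str) -> float:
    """(G + C) / non-N bases; 0 for an all-N sequence."""
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    denom = sum(1 for b in seq if b != "N")
    if denom == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / denom


# ---------------------------------------------------------------------------
# sklearn-style featurizers (operate on lists of sequences)


class _SequenceFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless transformer base: fit is a no-op, transform maps sequences."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.vstack([self._featurize(seq) for seq in X])


class DnaPropertyFeaturizer(_SequenceFeaturizer):
    """Group I transformer: one mean structural-property value per scale."""

    group = "I"

    def __init__(self, scales=None):
        self.scales = scales

    def _resolved(self):
        return list(self.scales) if self.scales is not None else default_property_scales()

    def _featurize(self, seq):
        return dna_property_features(seq, self._resolved())

    def get_feature_names_out(self, input_features=None):
        return np.array([f"prop_{s.name}" for s in self._resolved()])


class TrapFeaturizer(_SequenceFeaturizer):
    """Group II transformer: one TRAP occupancy per PWM."""

    group = "II"

    def __init__(self, pwms=None, params=None, log1p=False):
        self.pwms = pwms
        self.params = params
        self.log1p = log1p

    def _featurize(self, seq):
        return trap_feature_vector(seq, self.pwms, self.params, log1p=self.log1p)

    def get_feature_names_out(self, input_features=None):
        return np.array([f"trap_{p.id}" for p in self.pwms])


class KmerFeaturizer(_SequenceFeaturizer):
    """Group III transformer: normalised k-mer composition."""

    group = "III"

    def __init__(self, kmer_list=None):
        self.kmer_list = kmer_list

    def _resolved(self):
        return self.kmer_list if self.kmer_list is not None else all_kmers(3)

    def _featurize(self, seq):
        return kmer_composition(seq, self._resolved())

    def get_feature_names_out(self, input_features=None):
        return np.array([f"kmer_{k}" for k in self._resolved()])
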