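"""Readers and writers for the external formats the toolkit consumes.

All interval arithmetic is BED-style: 0-based, half-open ``[start, end)``.
Region length is ``end - start`` and equals the length of the extracted
sequence. Strand columns in BED input are ignored (enhancer and control
regions are treated as unstranded).

Position weight matrices (PWMs) are stored as 4×W count matrices with rows
ordered A, C, G, T. Matrices supplied as column-normalised frequencies are
accepted and flagged; downstream affinity scoring rescales flagged matrices
by 100 so a single count-based energy model applies everywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicRegion",
    "Genome",
    "PWM",
    "PeakSet",
    "RegionReadCounts",
    "FeatureMatrix",
    "read_fasta",
    "read_bed",
    "read_pwms",
    "read_peaks",
    "read_region_counts",
    "write_feature_matrix",
    "read_feature_matrix",
    "write_bed",
    "write_fasta",
]

LABELS = ("positive", "negative", "unlabeled")

_NON_ACGTN = re.compile(r"[^ACGTN]")
_BASE_ORDER = "ACGT"


@dataclass(frozen=True)
class GenomicRegion:
    """A labelled half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    label: str = "unlabeled"
    id: str = ""

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


class Genome:
    """In-memory genome: chromosome name -> uppercase sequence over ACGTN."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = dict(sequences)
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Extract ``[start, end)``; out-of-bounds lookups are errors."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start >= end:
            raise ValueError(
                f"window {chrom}:{start}-{end} outside chromosome of "
                f"length {self.lengths[chrom]}"
            )
        return self.sequences[chrom][start:end]

    def region_sequence(self, region: GenomicRegion) -> str:
        return self.fetch(region.chrom, region.start, region.end)

    def __eq__(self, other):
        return isinstance(other, Genome) and self.sequences == other.sequences


@dataclass
class PWM:
    """Nucleotide count matrix of shape (4, W), rows ordered A, C, G, T."""

    id: str
    counts: np.ndarray
    from_frequencies: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"PWM {self.id}: counts must be 4xW")
        if self.counts.shape[1] < 1:
            raise ValueError(f"PWM {self.id}: width must be >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"PWM {self.id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"PWM {self.id}: column of all zeros")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def effective_counts(self) -> np.ndarray:
        """Counts for the energy model; frequency matrices are scaled by 100."""
        if self.from_frequencies:
            return self.counts * 100.0
        return self.counts

    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.counts.argmax(axis=0))


class PeakSet:
    """A named peak track; intervals stored sorted by (chrom, start).

    Overlap queries use a running-max-of-ends index per chromosome so
    membership tests stay O(log n) even when stored intervals overlap
    each other (they are retained as-is, never merged).
    """

    def __init__(self, name: str, intervals):
        self.name = name
        self.intervals = sorted(
            (str(c), int(s), int(e)) for c, s, e in intervals
        )
        for c, s, e in self.intervals:
            if s < 0 or s >= e:
                raise ValueError(f"peak track {name}: invalid interval {c}:{s}-{e}")
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in self.intervals:
            by_chrom.setdefault(c, []).append((s, e))
        for c, pairs in by_chrom.items():
            starts = np.array([p[0] for p in pairs])
            ends = np.array([p[1] for p in pairs])
            self._index[c] = (starts, np.maximum.accumulate(ends))

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff some stored interval intersects ``[start, end)`` by >= 1 bp."""
        if chrom not in self._index:
            return False
        starts, max_ends = self._index[chrom]
        k = int(np.searchsorted(starts, end, side="left"))  # intervals with start < end
        return k > 0 and max_ends[k - 1] > start

    def contains_within(self, chrom: str, start: int, end: int) -> bool:
        """True iff some stored interval lies entirely inside ``[start, end)``."""
        if chrom not in self._index:
            return False
        return any(
            c == chrom and s >= start and e <= end for c, s, e in self.intervals
        )


@dataclass
class RegionReadCounts:
    """Per-region read counts for one sequencing library."""

    track_name: str
    counts: dict[str, float]
    total_mapped: int

    def __post_init__(self):
        if self.total_mapped <= 0:
            raise ValueError(f"{self.track_name}: total_mapped must be positive")
        for rid, c in self.counts.items():
            if c < 0:
                raise ValueError(f"{self.track_name}: negative count for {rid}")
        if self.counts and self.total_mapped < max(self.counts.values()):
            raise ValueError(
                f"{self.track_name}: total_mapped smaller than a region count"
            )


class FeatureMatrix:
    """Regions × named features, with class labels and per-feature group tags.

    Groups follow the five-block feature taxonomy: I DNA structural
    properties, II TF motif occurrence (TRAP), III k-mer composition,
    IV chromatin state, V TF RPM densities.
    """

    GROUPS = ("I", "II", "III", "IV", "V")

    def __init__(self, region_ids, feature_names, values, labels, group_tags):
        self.region_ids = list(region_ids)
        self.feature_names = list(feature_names)
        self.values = np.asarray(values, dtype=float)
        if self.values.size == 0:
            self.values = self.values.reshape(len(self.region_ids), len(self.feature_names))
        self.labels = dict(labels)
        self.group_tags = dict(group_tags)
        self._validate()

    def _validate(self):
        n, p = self.values.shape
        if n != len(self.region_ids) or p != len(self.feature_names):
            raise ValueError("values shape inconsistent with ids/feature names")
        if len(set(self.region_ids)) != n:
            raise ValueError("duplicate region ids")
        if len(set(self.feature_names)) != p:
            raise ValueError("duplicate feature names")
        if p and not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")
        for rid in self.region_ids:
            if rid not in self.labels:
                raise ValueError(f"missing label for region {rid}")
        for name in self.feature_names:
            tag = self.group_tags.get(name)
            if tag not in self.GROUPS:
                raise ValueError(f"feature {name!r} has no valid group tag")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def y(self) -> np.ndarray:
        """Binary response: 1 for positive regions, 0 otherwise."""
        return np.array(
            [1 if self.labels[rid] == "positive" else 0 for rid in self.region_ids]
        )

    def subset(self, feature_names) -> "FeatureMatrix":
        keep = list(feature_names)
        idx = [self.feature_names.index(f) for f in keep]
        return FeatureMatrix(
            self.region_ids,
            keep,
            self.values[:, idx] if idx else np.empty((self.n_regions, 0)),
            self.labels,
            {f: self.group_tags[f] for f in keep},
        )

    def exclude(self, patterns) -> "FeatureMatrix":
        """Drop features whose name matches any of the given regexes."""
        regs = [re.compile(p) for p in patterns]
        keep = [f for f in self.feature_names if not any(r.search(f) for r in regs)]
        if not keep:
            raise ValueError("exclusion patterns removed every feature")
        return self.subset(keep)

    @staticmethod
    def concat(blocks) -> "FeatureMatrix":
        """Column-wise concatenation of blocks sharing the same region order."""
        blocks = list(blocks)
        if not blocks:
            raise ValueError("no feature blocks to concatenate")
        first = blocks[0]
        names, tags, mats = [], {}, []
        for b in blocks:
            if b.region_ids != first.region_ids:
                raise ValueError("region-id mismatch between feature sources")
            names.extend(b.feature_names)
            tags.update(b.group_tags)
            mats.append(b.values)
        return FeatureMatrix(
            first.region_ids, names, np.hstack(mats), first.labels, tags
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", [self.labels[r] for r in self.region_ids])
        df.insert(0, "region_id", self.region_ids)
        return df

    def __eq__(self, other):
        return (
            isinstance(other, FeatureMatrix)
            and self.region_ids == other.region_ids
            and self.feature_names == other.feature_names
            and self.labels == other.labels
            and self.group_tags == other.group_tags
            and np.allclose(self.values, other.values, rtol=0, atol=0)
        )


# ---------------------------------------------------------------------------
# readers


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome`.

    Sequences are uppercased; any character outside ACGTN (ambiguity codes
    included) is mapped to N. Multi-line records are concatenated.
    """
    sequences: dict[str, str] = {}
    with open(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise ValueError(f"duplicate sequence name {record.id!r}")
            seq = _NON_ACGTN.sub("N", str(record.seq).upper())
            sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(sequences)


def _bed_rows(path):
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            yield ln, fields[0], start, end, fields


def read_bed(path, default_label: str = "unlabeled") -> list[GenomicRegion]:
    """Read BED (3+ columns) into labelled regions.

    Column 4, when present and non-empty, is used as the region id;
    otherwise the id is ``chrom:start-end``. Coordinates are kept verbatim
    (0-based half-open). track/browser/comment lines are skipped.
    """
    regions = []
    seen = set()
    for ln, chrom, start, end, fields in _bed_rows(path):
        if start >= end:
            raise ValueError(f"{path}:{ln}: empty or inverted interval")
        rid = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
        if rid in seen:
            raise ValueError(f"{path}:{ln}: duplicate region id {rid!r}")
        seen.add(rid)
        regions.append(GenomicRegion(chrom, start, end, default_label, rid))
    return regions


def write_bed(regions, path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\n")


def write_fasta(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_peaks(path, name: str) -> PeakSet:
    """Read a BED/narrowPeak track (first 3 columns) into a sorted PeakSet."""
    intervals = []
    for ln, chrom, start, end, _ in _bed_rows(path):
        if start >= end:
            raise ValueError(f"{path}:{ln}: empty or inverted interval")
        intervals.append((chrom, start, end))
    return PeakSet(name, intervals)


def read_region_counts(path) -> RegionReadCounts:
    """Read a per-region count table.

    Format: a header line ``#total_mapped=<int>`` followed by
    ``region_id<TAB>count`` rows.
    """
    total_mapped = None
    counts: dict[str, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*total_mapped\s*=\s*(\d+)", line)
                if m:
                    total_mapped = int(m.group(1))
                continue
            rid, _, val = line.partition("\t")
            if not val:
                raise ValueError(f"{path}:{ln}: expected region_id<TAB>count")
            if rid in counts:
                raise ValueError(f"{path}:{ln}: duplicate region id {rid!r}")
            c = float(val)
            if c < 0:
                raise ValueError(f"{path}:{ln}: negative count")
            counts[rid] = c
    if total_mapped is None:
        raise ValueError(f"{path}: missing '#total_mapped=' header")
    import os

    name = os.path.splitext(os.path.basename(str(path)))[0]
    return RegionReadCounts(name, counts, total_mapped)


# ---------------------------------------------------------------------------
# PWM dialects

_NUMROW = re.compile(r"^[\s0-9eE+.\-]+$")


def _finalise_pwm(pid: str, rows: list[list[float]], by_base: bool) -> PWM:
    if by_base:
        counts = np.array(rows, dtype=float)  # 4 rows of length W
    else:
        arr = np.array(rows, dtype=float)  # W rows of 4
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError(f"PWM {pid}: expected 4 values per position")
        counts = arr.T
    col_sums = counts.sum(axis=0)
    from_freq = bool(np.all(np.abs(col_sums - 1.0) < 1e-3))
    return PWM(pid, counts, from_frequencies=from_freq)


def _parse_tsv_pwms(lines) -> list[PWM]:
    pwms, pid, rows = [], None, []
    for line in lines:
        s = line.strip()
        if not s:
            continue
        parts = s.replace(",", " ").split()
        if _NUMROW.match(s) and len(parts) == 4:
            if pid is None:
                raise ValueError("matrix row before any motif id")
            rows.append([float(x) for x in parts])
        else:
            if pid is not None:
                pwms.append(_finalise_pwm(pid, rows, by_base=False))
            pid, rows = s.lstrip(">"), []
    if pid is not None:
        pwms.append(_finalise_pwm(pid, rows, by_base=False))
    return pwms


def _parse_jaspar_pwms(lines) -> list[PWM]:
    pwms, pid, rows = [], None, {}

    def flush():
        if pid is None:
            return
        if sorted(rows) != list("ACGT"):
            raise ValueError(f"PWM {pid}: need exactly 4 labelled rows A/C/G/T")
        lens = {len(v) for v in rows.values()}
        if len(lens) != 1:
            raise ValueError(f"PWM {pid}: rows of unequal length")
        pwms.append(_finalise_pwm(pid, [rows[b] for b in "ACGT"], by_base=True))

    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith(">"):
            flush()
            pid, rows = s[1:].split()[0], {}
        else:
            m = re.match(r"^([ACGTacgt])\s*[:|\[]?\s*(.*?)\s*\]?\s*$", s)
            if not m:
                raise ValueError(f"unparseable JASPAR row: {s!r}")
            rows[m.group(1).upper()] = [float(x) for x in m.group(2).split()]
    flush()
    return pwms


def _parse_transfac_pwms(lines) -> list[PWM]:
    pwms, pid, rows = [], None, []
    in_matrix = False
    for line in lines:
        s = line.rstrip()
        if s.startswith("ID"):
            pid, rows, in_matrix = s.split(None, 1)[1].strip(), [], False
        elif s.startswith(("P0", "PO")):
            in_matrix = True
        elif s.startswith("//"):
            if pid is not None and rows:
                pwms.append(_finalise_pwm(pid, rows, by_base=False))
            pid, rows, in_matrix = None, [], False
        elif in_matrix and re.match(r"^\d+\s", s):
            parts = s.split()
            rows.append([float(x) for x in parts[1:5]])
    if pid is not None and rows:
        pwms.append(_finalise_pwm(pid, rows, by_base=False))
    return pwms


def read_pwms(path, dialect: str = "tsv") -> list[PWM]:
    """Read a PWM collection in one of three dialects.

    ``tsv``: id line then W rows of 4 numbers (A C G T). ``jaspar``:
    ``>id`` followed by 4 labelled base rows. ``transfac``: ID/P0…//
    blocks. Counts are stored as given; matrices whose columns all sum to
    ≈1 are flagged as frequency matrices.
    """
    parsers = {
        "tsv": _parse_tsv_pwms,
        "jaspar": _parse_jaspar_pwms,
        "transfac": _parse_transfac_pwms,
    }
    if dialect not in parsers:
        raise ValueError(f"unknown PWM dialect {dialect!r}")
    with open(path) as fh:
        pwms = parsers[dialect](fh.readlines())
    if not pwms:
        raise ValueError(f"no PWMs found in {path}")
    return pwms


def write_pwms(pwms, path) -> None:
    """Write PWMs in the tsv dialect (round-trips with read_pwms)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id}\n")
            for col in p.counts.T:
                fh.write("\t".join(f"{v:g}" for v in col) + "\n")


# ---------------------------------------------------------------------------
# feature-matrix TSV


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    """Write a feature matrix as TSV with a group-tag header.

    Layout: ``#group<TAB>name<TAB>tag`` header lines, then a header row
    ``region_id  label  <features...>`` and one row per region. Round-trips
    losslessly with :func:`read_feature_matrix`.
    """
    for name in m.feature_names:
        if "\t" in name or "\n" in name:
            raise ValueError(f"feature name {name!r} contains a tab/newline")
    with open(path, "w") as fh:
        for name in m.feature_names:
            fh.write(f"#group\t{name}\t{m.group_tags[name]}\n")
        fh.write("\t".join(["region_id", "label", *m.feature_names]) + "\n")
        for i, rid in enumerate(m.region_ids):
            vals = "\t".join(repr(float(v)) for v in m.values[i])
            row = f"{rid}\t{m.labels[rid]}"
            fh.write(row + ("\t" + vals if vals else "") + "\n")


def read_feature_matrix(path) -> FeatureMatrix:
    group_tags: dict[str, str] = {}
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#group\t"):
                _, name, tag = line.split("\t")
                group_tags[name] = tag
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: empty feature matrix file")
    feature_names = header[2:]
    region_ids = [r[0] for r in rows]
    labels = {r[0]: r[1] for r in rows}
    values = np.array(
        [[float(x) for x in r[2:]] for r in rows], dtype=float
    ).reshape(len(rows), len(feature_names))
    return FeatureMatrix(region_ids, feature_names, values, labels, group_tags)
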