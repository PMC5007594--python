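"""Self-contained synthetic fixtures for the whole pipeline.

The generator emulates the statistical structure of an enhancer study on a
toy genome: uniform-background chromosomes; "enhancer" regions with
consensus instances of a few high-information PWMs planted at Poisson rate
into the background; length-matched negative controls produced by random
shifts on the same chromosome; peak tracks covering positives and
negatives with configurable probabilities; and Poisson read counts with
fold-enrichment of the TF library over its input in positive regions.

Every generator is deterministic for a fixed seed (one master seed,
spawned per stage). Defaults: 300 enhancers of 500 bp, 5 planted among 50
PWMs with ~3 insertions per enhancer, 64 peak tracks at 0.9/0.1
positive/negative coverage, and 4-fold TF read enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import Genome, GenomicRegion, PWM, PeakSet, RegionReadCounts

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "make_genome",
    "make_pwm_collection",
    "plant_enhancers",
    "shift_controls",
    "make_peaks",
    "make_read_counts",
    "simulate",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticConfig:
    n_chroms: int = 4
    chrom_length: int = 200_000
    n_enhancers: int = 300
    region_length: int = 500
    n_planted_pwms: int = 5
    decoy_pwms: int = 45
    plant_rate: float = 3.0
    plant_mode: str = "consensus"  # or "sample": draw bases from the PWM
    peak_tracks: int = 64
    p_peak_pos: float = 0.9
    p_peak_neg: float = 0.1
    tf_tracks: int = 5
    read_depth: float = 200.0  # mean input reads per kb of region
    enrichment: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_peak_neg <= 1 and 0 <= self.p_peak_pos <= 1):
            raise ValueError("peak probabilities must be in [0, 1]")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        for name in (
            "n_chroms",
            "chrom_length",
            "n_enhancers",
            "region_length",
            "n_planted_pwms",
            "peak_tracks",
            "tf_tracks",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.decoy_pwms < self.n_planted_pwms:
            raise ValueError("need at least as many decoys as planted PWMs")
        if self.plant_mode not in ("consensus", "sample"):
            raise ValueError("plant_mode must be 'consensus' or 'sample'")


def _rng(cfg: SyntheticConfig, stage: int) -> np.random.Generator:
    # one spawned child per generation stage, so stages are independent
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(6)[stage])


def make_genome(cfg: SyntheticConfig) -> Genome:
    """i.i.d. uniform A/C/G/T background chromosomes (chr1..chrN)."""
    rng = _rng(cfg, 0)
    seqs = {}
    for i in range(cfg.n_chroms):
        draws = rng.integers(0, 4, size=cfg.chrom_length)
        seqs[f"chr{i + 1}"] = _BASES[draws].tobytes().decode()
    return Genome(seqs)


def make_pwm_collection(cfg: SyntheticConfig) -> list[PWM]:
    """Planted (high-information) plus decoy (near-uniform) PWMs.

    Planted matrices have one dominant base per column (count 85 of 100)
    and widths 6–10; decoys draw column counts from a flat Dirichlet with
    high concentration, keeping per-column information well under 0.5 bits.
    Ids are prefixed ``planted_`` / ``decoy_``.
    """
    rng = _rng(cfg, 1)
    pwms = []
    for i in range(cfg.n_planted_pwms):
        width = int(rng.integers(6, 11))
        counts = np.full((4, width), 5.0)
        dominant = rng.integers(0, 4, size=width)
        counts[dominant, np.arange(width)] = 85.0
        pwms.append(PWM(f"planted_{i + 1:02d}", counts))
    for i in range(cfg.decoy_pwms):
        width = int(rng.integers(6, 11))
        probs = rng.dirichlet(np.full(4, 50.0), size=width).T
        counts = np.round(probs * 100) + 1.0
        pwms.append(PWM(f"decoy_{i + 1:02d}", counts))
    return pwms


def _place_regions(cfg: SyntheticConfig, rng, genome: Genome):
    """Rejection-sample non-overlapping region placements."""
    chroms = sorted(genome.lengths)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out = []
    attempts = 0
    L = cfg.region_length
    while len(out) < cfg.n_enhancers:
        attempts += 1
        if attempts > 1000 * cfg.n_enhancers:
            raise ValueError("genome too small for the requested regions")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, genome.lengths[chrom] - L + 1))
        if any(start < e and s < start + L for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, start + L))
        out.append((chrom, start, start + L))
    return out


def plant_enhancers(
    genome: Genome, cfg: SyntheticConfig, pwms: list[PWM] | None = None
) -> tuple[Genome, list[GenomicRegion]]:
    """Place enhancer regions and plant motif instances into them.

    Each region receives Poisson(plant_rate) insertions; each insertion
    picks a planted PWM uniformly, a random offset and strand, and
    overwrites the background with the consensus (default) or a sequence
    sampled column-wise from the PWM (``plant_mode="sample"``).
    """
    rng = _rng(cfg, 2)
    if pwms is None:
        pwms = make_pwm_collection(cfg)
    planted = [p for p in pwms if p.id.startswith("planted_")]
    if not planted:
        raise ValueError("PWM collection has no planted_ matrices")
    if cfg.region_length > min(genome.lengths.values()):
        raise ValueError("regions longer than the shortest chromosome")
    placements = _place_regions(cfg, rng, genome)

    seqs = {c: list(s) for c, s in genome.sequences.items()}
    regions = []
    from .sequence_features import reverse_complement

    for i, (chrom, start, end) in enumerate(placements):
        n_ins = int(rng.poisson(cfg.plant_rate))
        for _ in range(n_ins):
            pwm = planted[int(rng.integers(0, len(planted)))]
            if cfg.plant_mode == "consensus":
                ins = pwm.consensus()
            else:
                probs = pwm.counts / pwm.counts.sum(axis=0)
                ins = "".join(
                    "ACGT"[rng.choice(4, p=probs[:, j])] for j in range(pwm.width)
                )
            if rng.integers(0, 2):
                ins = reverse_complement(ins)
            offset = int(rng.integers(0, cfg.region_length - pwm.width + 1))
            seqs[chrom][start + offset : start + offset + pwm.width] = list(ins)
        regions.append(
            GenomicRegion(chrom, start, end, "positive", f"enh_{i + 1:04d}")
        )
    new_genome = Genome({c: "".join(s) for c, s in seqs.items()})
    return new_genome, regions


def shift_controls(
    positives: list[GenomicRegion], genome: Genome, seed: int | None = None
) -> list[GenomicRegion]:
    """One same-chromosome, length-matched, shifted control per positive.

    New starts are drawn uniformly over the chromosome and rejected while
    they overlap any positive region; 1000 attempts per control before
    giving up with an error.
    """
    rng = np.random.default_rng(seed)
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for p in positives:
        by_chrom.setdefault(p.chrom, []).append(p)
    controls = []
    for i, p in enumerate(positives):
        length = p.length
        hi = genome.lengths[p.chrom] - length
        if hi < 0:
            raise ValueError(f"chromosome {p.chrom} shorter than region {p.id}")
        for attempt in range(1000):
            start = int(rng.integers(0, hi + 1))
            end = start + length
            if not any(
                start < q.end and q.start < end for q in by_chrom[p.chrom]
            ):
                controls.append(
                    GenomicRegion(p.chrom, start, end, "negative", f"ctrl_{i + 1:04d}")
                )
                break
        else:
            raise ValueError(
                f"could not place a control for {p.id} in 1000 attempts"
            )
    return controls


def make_peaks(regions: list[GenomicRegion], cfg: SyntheticConfig) -> list[PeakSet]:
    """Peak tracks covering positives/negatives with the configured rates.

    A covering peak is the region interval itself jittered by up to 50 bp
    on each side (clipped at zero).
    """
    rng = _rng(cfg, 3)
    tracks = []
    for t in range(cfg.peak_tracks):
        intervals = []
        for r in regions:
            p = cfg.p_peak_pos if r.label == "positive" else cfg.p_peak_neg
            if rng.random() < p:
                j1, j2 = rng.integers(0, 51, size=2)
                intervals.append((r.chrom, max(0, r.start - int(j1)), r.end + int(j2)))
        tracks.append(PeakSet(f"mark_{t + 1:02d}", intervals))
    return tracks


def make_read_counts(
    regions: list[GenomicRegion], cfg: SyntheticConfig
) -> list[tuple[RegionReadCounts, RegionReadCounts]]:
    """(TF, input) Poisson count-table pairs with positive-region enrichment.

    Input counts ~ Poisson(read_depth · length / 1 kb); TF counts use the
    same mean times ``enrichment`` in positive regions. ``total_mapped`` is
    the track's count sum plus a constant 1e6 genomic background.
    """
    rng = _rng(cfg, 4)
    pairs = []
    for t in range(cfg.tf_tracks):
        tf_counts, in_counts = {}, {}
        for r in regions:
            base = cfg.read_depth * r.length / 1000.0
            in_counts[r.id] = float(rng.poisson(base))
            mean = base * (cfg.enrichment if r.label == "positive" else 1.0)
            tf_counts[r.id] = float(rng.poisson(mean))
        pairs.append(
            (
                RegionReadCounts(
                    f"tf_{t + 1:02d}", tf_counts, int(sum(tf_counts.values()) + 1e6)
                ),
                RegionReadCounts(
                    f"tf_{t + 1:02d}_input",
                    in_counts,
                    int(sum(in_counts.values()) + 1e6),
                ),
            )
        )
    return pairs


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, generated from one config."""

    genome: Genome
    pwms: list
    positives: list
    negatives: list
    peaks: list
    read_counts: list

    @property
    def regions(self) -> list[GenomicRegion]:
        return list(self.positives) + list(self.negatives)


def simulate(cfg: SyntheticConfig | None = None) -> SyntheticDataset:
    """Run every generator stage under one master seed."""
    cfg = cfg or SyntheticConfig()
    background = make_genome(cfg)
    pwms = make_pwm_collection(cfg)
    genome, positives = plant_enhancers(background, cfg, pwms)
    ctrl_seed = int(np.random.SeedSequence(cfg.seed).spawn(6)[5].generate_state(1)[0])
    negatives = shift_controls(positives, genome, seed=ctrl_seed)
    regions = positives + negatives
    peaks = make_peaks(regions, cfg)
    counts = make_read_counts(regions, cfg)
    return SyntheticDataset(genome, pwms, positives, negatives, peaks, counts)


def write_fixtures(dataset: SyntheticDataset, outdir) -> None:
    """Write genome.fa, pos.bed, neg.bed, pwms.txt, peaks/, counts/."""
    import os

    from .genomic_io import write_bed, write_fasta, write_pwms

    os.makedirs(outdir, exist_ok=True)
    write_fasta(dataset.genome, os.path.join(outdir, "genome.fa"))
    write_bed(dataset.positives, os.path.join(outdir, "pos.bed"))
    write_bed(dataset.negatives, os.path.join(outdir, "neg.bed"))
    write_pwms(dataset.pwms, os.path.join(outdir, "pwms.txt"))
    peak_dir = os.path.join(outdir, "peaks")
    os.makedirs(peak_dir, exist_ok=True)
    for ps in dataset.peaks:
        with open(os.path.join(peak_dir, f"{ps.name}.bed"), "w") as fh:
            for c, s, e in ps.intervals:
                fh.write(f"{c}\t{s}\t{e}\n")
    count_dir = os.path.join(outdir, "counts")
    os.makedirs(count_dir, exist_ok=True)
    for tf, ctrl in dataset.read_counts:
        names = {id(tf): f"{tf.track_name}.tsv", id(ctrl): f"{tf.track_name}.input.tsv"}
        for track in (tf, ctrl):
            with open(os.path.join(count_dir, names[id(track)]), "w") as fh:
                fh.write(f"#total_mapped={track.total_mapped}\n")
                for rid, c in track.counts.items():
                    fh.write(f"{rid}\t{c:g}\n")
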