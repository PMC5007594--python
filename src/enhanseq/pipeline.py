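"""End-to-end orchestration: build feature groups, select, evaluate, report.

A single :class:`PipelineConfig` (optionally loaded from YAML) names the
inputs, the feature groups to assemble (any subset of I–V), and the
selection / cross-validation / importance settings. :func:`run_pipeline`
executes build → (optional) recursive feature elimination →
cross-validation → permutation importance and writes four artifacts into
the run directory: ``report.json``, ``trace.json``, ``importance.tsv`` and
``roc.tsv``. Outputs carry no timestamps, so two runs with the same config
and seed are byte-identical.

Feature selection runs once on the full matrix before cross-validation by
default, mirroring the original study protocol; note this leaks label
information into the CV estimate. ``nested=true`` instead reruns the
elimination inside every training fold for a leakage-free estimate.
"""

from __future__ import annotations

import glob
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .chip_features import ChromatinStateFeaturizer, RpmFeaturizer
from .evaluation import EvalReport, _report_from_scores, cross_validate, stratified_folds
from .genomic_io import (
    FeatureMatrix,
    read_bed,
    read_fasta,
    read_peaks,
    read_pwms,
    read_region_counts,
    write_feature_matrix,
)
from .rf_selection import (
    EnhancerForest,
    RFConfig,
    SelectionTrace,
    VarSelRF,
    permutation_importance,
    varselrf_select,
)
from .sequence_features import (
    DnaPropertyFeaturizer,
    KmerFeaturizer,
    TrapFeaturizer,
    TrapParameters,
    all_kmers,
    load_kmer_list,
    load_property_scales,
)

__all__ = ["PipelineConfig", "build_matrix", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str | None = None
    positive_regions: str | None = None
    negative_regions: str | None = None
    pwms: str | None = None
    pwm_dialect: str = "tsv"
    property_scales: str | None = None  # None -> packaged default table
    kmers: str | None = None  # None -> all k-mers up to kmer_max_k
    kmer_max_k: int = 3
    peaks_dir: str | None = None
    counts_dir: str | None = None
    feature_groups: tuple = ("II",)
    exclusions: tuple = ()
    selection: bool = True
    drop_fraction: float = 0.1
    c_sd: float = 1.0
    nested: bool = False
    cv_folds: int = 10
    seed: int = 1
    threshold: float = 0.5
    ntree: int = 5000
    ntree_iterat: int = 2000
    mtry: int | str = "sqrt"
    n_jobs: int = 1
    importance: bool = True
    n_perm: int = 100
    trap_lambda: float = 0.7
    trap_log1p: bool = False
    outdir: str = "enhanseq_run"

    def __post_init__(self):
        self.feature_groups = tuple(self.feature_groups)
        self.exclusions = tuple(self.exclusions)
        if not self.feature_groups:
            raise ValueError("at least one feature group must be enabled")
        bad = set(self.feature_groups) - set(FeatureMatrix.GROUPS)
        if bad:
            raise ValueError(f"unknown feature groups {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def rf_config(self, seed: int | None = None) -> RFConfig:
        return RFConfig(
            ntree=self.ntree,
            ntree_iterat=self.ntree_iterat,
            mtry=self.mtry,
            seed=self.seed if seed is None else seed,
            n_jobs=self.n_jobs,
        )


def _tagged_block(regions, labels, featurizer, inputs, group) -> FeatureMatrix:
    values = featurizer.transform(inputs)
    names = list(featurizer.get_feature_names_out())
    return FeatureMatrix(
        [r.id for r in regions], names, values, labels, {n: group for n in names}
    )


def _paired_count_tracks(counts_dir):
    """Pair <name>.tsv with <name>.input.tsv inside a directory."""
    pairs = []
    for path in sorted(glob.glob(os.path.join(counts_dir, "*.tsv"))):
        base = os.path.basename(path)
        if base.endswith(".input.tsv"):
            continue
        input_path = path[: -len(".tsv")] + ".input.tsv"
        if not os.path.exists(input_path):
            raise FileNotFoundError(f"no matched input track for {path}")
        pairs.append((read_region_counts(path), read_region_counts(input_path)))
    if not pairs:
        raise ValueError(f"no count-table pairs under {counts_dir}")
    return pairs


def build_matrix(cfg: PipelineConfig) -> FeatureMatrix:
    """Assemble the requested feature-group blocks column-wise."""
    regions = []
    if cfg.positive_regions:
        regions += read_bed(cfg.positive_regions, "positive")
    if cfg.negative_regions:
        regions += read_bed(cfg.negative_regions, "negative")
    if not regions:
        raise ValueError("no input regions")
    labels = {r.id: r.label for r in regions}

    needs_seq = {"I", "II", "III"} & set(cfg.feature_groups)
    seqs = None
    if needs_seq:
        genome = read_fasta(cfg.genome)
        seqs = [genome.region_sequence(r) for r in regions]

    blocks = []
    for group in cfg.feature_groups:
        if group == "I":
            scales = (
                load_property_scales(cfg.property_scales)
                if cfg.property_scales
                else None
            )
            feat = DnaPropertyFeaturizer(scales)
            blocks.append(_tagged_block(regions, labels, feat, seqs, "I"))
        elif group == "II":
            pwms = read_pwms(cfg.pwms, cfg.pwm_dialect)
            params = TrapParameters(lam=cfg.trap_lambda)
            feat = TrapFeaturizer(pwms, params, log1p=cfg.trap_log1p)
            blocks.append(_tagged_block(regions, labels, feat, seqs, "II"))
        elif group == "III":
            kl = load_kmer_list(cfg.kmers) if cfg.kmers else all_kmers(cfg.kmer_max_k)
            feat = KmerFeaturizer(kl)
            blocks.append(_tagged_block(regions, labels, feat, seqs, "III"))
        elif group == "IV":
            paths = sorted(
                glob.glob(os.path.join(cfg.peaks_dir, "*.bed"))
                + glob.glob(os.path.join(cfg.peaks_dir, "*.narrowPeak"))
            )
            if not paths:
                raise ValueError(f"no peak tracks under {cfg.peaks_dir}")
            peak_sets = [
                read_peaks(p, os.path.splitext(os.path.basename(p))[0])
                for p in paths
            ]
            feat = ChromatinStateFeaturizer(peak_sets)
            blocks.append(_tagged_block(regions, labels, feat, regions, "IV"))
        elif group == "V":
            pairs = _paired_count_tracks(cfg.counts_dir)
            feat = RpmFeaturizer(pairs)
            blocks.append(_tagged_block(regions, labels, feat, regions, "V"))
        logger.info(
            "group %s: %d features for %d regions",
            group,
            blocks[-1].n_features,
            blocks[-1].n_regions,
        )
    matrix = FeatureMatrix.concat(blocks)
    if cfg.exclusions:
        matrix = matrix.exclude(cfg.exclusions)
    return matrix


def _nested_cross_validate(m: FeatureMatrix, cfg: PipelineConfig) -> EvalReport:
    """CV with the elimination rerun inside every training fold."""
    ss = np.random.SeedSequence(cfg.seed)
    fold_ss, *fit_seeds = ss.spawn(cfg.cv_folds + 1)
    folds = stratified_folds(
        m.labels, cfg.cv_folds, seed=int(fold_ss.generate_state(1)[0] % (2**31))
    )
    y = m.y()
    idx_of = {rid: i for i, rid in enumerate(m.region_ids)}
    pooled = np.empty(m.n_regions)
    per_fold = []
    for k in range(1, cfg.cv_folds + 1):
        tr = np.array([idx_of[r] for r in m.region_ids if folds[r] != k])
        te = np.array([idx_of[r] for r in m.region_ids if folds[r] == k])
        seed_k = int(fit_seeds[k - 1].generate_state(1)[0] % (2**31))
        sel = VarSelRF(
            drop_fraction=cfg.drop_fraction,
            c_sd=cfg.c_sd,
            ntree=cfg.ntree,
            ntree_iterat=cfg.ntree_iterat,
            mtry=cfg.mtry,
            seed=seed_k,
            n_jobs=cfg.n_jobs,
        ).fit(m.values[tr], y[tr], feature_names=m.feature_names)
        cols = np.flatnonzero(sel.support_)
        forest = EnhancerForest(
            ntree=cfg.ntree,
            mtry=cfg.mtry,
            seed=seed_k,
            compute_importance=False,
            n_jobs=cfg.n_jobs,
        ).fit(m.values[np.ix_(tr, cols)], y[tr])
        s = forest.predict_score(m.values[np.ix_(te, cols)])
        pooled[te] = s
        per_fold.append(_report_from_scores(y[te], s, cfg.threshold))
    report = _report_from_scores(y, pooled, cfg.threshold)
    report.per_fold = per_fold
    return report


def run_pipeline(cfg: PipelineConfig, matrix: FeatureMatrix | None = None):
    """Execute build → select → cross-validate → importance; write artifacts.

    Returns ``(report, trace, importance_frame)``. A prebuilt matrix may be
    passed to skip the build stage (used by tests and the CLI on cached
    matrices).
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    t0 = time.time()
    if matrix is None:
        matrix = build_matrix(cfg)
        write_feature_matrix(matrix, os.path.join(cfg.outdir, "features.tsv"))
    logger.info(
        "stage=build n_regions=%d n_features=%d elapsed=%.1fs",
        matrix.n_regions,
        matrix.n_features,
        time.time() - t0,
    )

    t0 = time.time()
    if cfg.selection and not cfg.nested:
        trace = varselrf_select(
            matrix, cfg.rf_config(), cfg.drop_fraction, cfg.c_sd
        )
        selected = matrix.subset(trace.selected)
    else:
        full = (tuple(matrix.feature_names), None, None)
        trace = SelectionTrace(
            iterations=[full],
            selected=list(matrix.feature_names),
            drop_fraction=cfg.drop_fraction,
            c_sd=cfg.c_sd,
        )
        selected = matrix
    logger.info(
        "stage=select n_selected=%d elapsed=%.1fs",
        len(trace.selected),
        time.time() - t0,
    )

    t0 = time.time()
    if cfg.nested:
        report = _nested_cross_validate(matrix, cfg)
    else:
        report = cross_validate(
            selected,
            cfg.rf_config(),
            K=cfg.cv_folds,
            seed=cfg.seed,
            threshold=cfg.threshold,
        )
    logger.info(
        "stage=evaluate auc=%.4f acc=%.4f elapsed=%.1fs",
        report.auc,
        report.acc,
        time.time() - t0,
    )

    t0 = time.time()
    imp = None
    if cfg.importance:
        imp = permutation_importance(selected, cfg.rf_config(), n_perm=cfg.n_perm)
        logger.info("stage=importance n_perm=%d elapsed=%.1fs", cfg.n_perm, time.time() - t0)

    _write_artifacts(cfg, report, trace, imp)
    return report, trace, imp


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _write_artifacts(cfg, report, trace, imp):
    _json_dump(report.to_dict(), os.path.join(cfg.outdir, "report.json"))
    _json_dump(trace.to_dict(), os.path.join(cfg.outdir, "trace.json"))
    with open(os.path.join(cfg.outdir, "roc.tsv"), "w") as fh:
        fh.write("fpr\ttpr\n")
        for f, t in report.roc:
            fh.write(f"{f:.6g}\t{t:.6g}\n")
    if imp is not None:
        imp.to_csv(os.path.join(cfg.outdir, "importance.tsv"), sep="\t", index=False)
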