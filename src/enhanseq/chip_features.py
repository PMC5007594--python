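"""ChIP-Seq-based feature groups.

Group IV (chromatin state): for each histone-modification peak track a
binary indicator of whether the region overlaps a peak, plus a summary
feature equal to the number of overlapping tracks — so 64 tracks yield 65
features. "Contains a peak" is read as >= 1 bp half-open overlap by
default; a strict containment mode (peak entirely inside the region) is
available via ``mode="containment"``.

Group V (TF RPM): reads-per-million-mapped-reads per base pair, with the
matched input (control) library subtracted:

    rpm = count / (total_mapped / 1e6) / region_length
    density = rpm(TF) − rpm(input)

The subtraction is TF − input so that enrichment is positive; values may
be negative where the input exceeds the TF signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .genomic_io import GenomicRegion, PeakSet, RegionReadCounts

__all__ = [
    "ChromatinStateVector",
    "chromatin_state_features",
    "rpm_density",
    "tf_rpm_features",
    "ChromatinStateFeaturizer",
    "RpmFeaturizer",
]


@dataclass(frozen=True)
class ChromatinStateVector:
    """Per-track 0/1 overlap indicators plus their sum."""

    indicators: tuple[int, ...]
    summary: int

    def __post_init__(self):
        if any(i not in (0, 1) for i in self.indicators):
            raise ValueError("indicators must be 0/1")
        if self.summary != sum(self.indicators):
            raise ValueError("summary must equal the sum of indicators")

    def as_array(self) -> np.ndarray:
        return np.array([*self.indicators, self.summary], dtype=float)


def chromatin_state_features(
    region: GenomicRegion, peak_sets, mode: str = "overlap"
) -> ChromatinStateVector:
    """Group IV features for one region: |tracks| indicators + summary."""
    if mode not in ("overlap", "containment"):
        raise ValueError(f"unknown mode {mode!r}")
    indicators = []
    for ps in peak_sets:
        if mode == "overlap":
            hit = ps.overlaps(region.chrom, region.start, region.end)
        else:
            hit = ps.contains_within(region.chrom, region.start, region.end)
        indicators.append(1 if hit else 0)
    return ChromatinStateVector(tuple(indicators), sum(indicators))


def _rpm(count: float, total_mapped: int, length: int) -> float:
    return count / (total_mapped / 1e6) / length


def rpm_density(
    region: GenomicRegion, tf: RegionReadCounts, input_ctrl: RegionReadCounts
) -> float:
    """Input-subtracted RPM-per-bp density of one TF track over a region."""
    for track in (tf, input_ctrl):
        if region.id not in track.counts:
            raise KeyError(f"region {region.id!r} missing from track {track.track_name}")
        if track.total_mapped <= 0:
            raise ValueError(f"track {track.track_name}: zero total_mapped")
    return _rpm(tf.counts[region.id], tf.total_mapped, region.length) - _rpm(
        input_ctrl.counts[region.id], input_ctrl.total_mapped, region.length
    )


def tf_rpm_features(region: GenomicRegion, tf_tracks) -> np.ndarray:
    """Group V vector: one input-subtracted RPM density per (TF, input) pair."""
    tf_tracks = list(tf_tracks)
    if not tf_tracks:
        raise ValueError("empty TF track list")
    return np.array([rpm_density(region, tf, ctrl) for tf, ctrl in tf_tracks])


class ChromatinStateFeaturizer(TransformerMixin, BaseEstimator):
    """Group IV transformer over regions; output width = |tracks| + 1."""

    group = "IV"

    def __init__(self, peak_sets=None, mode="overlap"):
        self.peak_sets = peak_sets
        self.mode = mode

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.vstack(
            [
                chromatin_state_features(r, self.peak_sets, self.mode).as_array()
                for r in X
            ]
        )

    def get_feature_names_out(self, input_features=None):
        names = [f"chrom_{ps.name}" for ps in self.peak_sets]
        return np.array([*names, "chrom_state_summary"])


class RpmFeaturizer(TransformerMixin, BaseEstimator):
    """Group V transformer over regions."""

    group = "V"

    def __init__(self, tf_tracks=None):
        self.tf_tracks = tf_tracks

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.vstack([tf_rpm_features(r, self.tf_tracks) for r in X])

    def get_feature_names_out(self, input_features=None):
        return np.array([f"rpm_{tf.track_name}" for tf, _ in self.tf_tracks])
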