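import numpy as np
import pytest

import enhanseq as e


@pytest.fixture(scope="session")
def small_dataset():
    """A quick synthetic dataset shared by read-only tests."""
    cfg = e.SyntheticConfig(n_enhancers=60, peak_tracks=8, tf_tracks=3, seed=7)
    return cfg, e.simulate(cfg)


@pytest.fixture(scope="session")
def small_group2_matrix(small_dataset):
    """Group II (TRAP) feature matrix for the small dataset."""
    _, ds = small_dataset
    seqs = [ds.genome.region_sequence(r) for r in ds.regions]
    feat = e.TrapFeaturizer(ds.pwms)
    names = [str(n) for n in feat.get_feature_names_out()]
    return e.FeatureMatrix(
        [r.id for r in ds.regions],
        names,
        feat.transform(seqs),
        {r.id: r.label for r in ds.regions},
        {n: "II" for n in names},
    )


def separable_matrix(n=200, n_noise=0, seed=0, flip=0.0):
    """Balanced labels with one feature equal to the label (+ optional noise)."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    cols = [y + rng.normal(0, 0.05, n)]
    names = ["signal"]
    for i in range(n_noise):
        cols.append(rng.normal(0, 1, n))
        names.append(f"noise_{i:02d}")
    ids = [f"r{i:04d}" for i in range(n)]
    labels = {rid: ("positive" if yy else "negative") for rid, yy in zip(ids, y)}
    return e.FeatureMatrix(ids, names, np.column_stack(cols), labels, {n_: "II" for n_ in names})


def noise_matrix(n=200, p=5, seed=0):
    """Balanced labels with pure-noise features."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    ids = [f"r{i:04d}" for i in range(n)]
    labels = {rid: ("positive" if yy else "negative") for rid, yy in zip(ids, y)}
    names = [f"noise_{i:02d}" for i in range(p)]
    return e.FeatureMatrix(ids, names, rng.normal(0, 1, (n, p)), labels, {n_: "II" for n_ in names})
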