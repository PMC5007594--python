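"""Random-forest training, recursive feature elimination and permutation
importance.

The classifier is a standard random forest (scikit-learn trees under the
hood). What this module adds on top:

* **Out-of-bag mean-decrease-accuracy importance.** For every tree, the
  accuracy on its out-of-bag (OOB) samples is compared with the accuracy
  after permuting one feature's values among those samples; the importance
  of the feature is the mean accuracy drop over trees (unscaled).

* **Recursive feature elimination** in the varSelRF style: fit the full
  model once, rank features by the initial importance (never recomputed),
  then repeatedly drop the least-important ``drop_fraction`` of the current
  set (rounded, minimum 1) and refit, recording OOB error ± SE, down to
  2 features. The selected set is the smallest one whose OOB error is
  within ``c_sd`` standard errors of the minimum observed error.

* **Label-permutation importance** in the rfPermute style: the forest is
  refit on ``n_perm`` seeded permutations of the response, building a null
  distribution of each feature's importance; the p-value is
  ``(b + 1) / (B + 1)`` where ``b`` counts null values >= observed.

All randomness flows from one master seed through ``numpy`` seed-sequence
spawning: child 0 seeds the forest, child 1 the importance permutations,
and each elimination refit / label permutation draws its own child, so
every stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .genomic_io import FeatureMatrix

__all__ = [
    "RFConfig",
    "SelectionTrace",
    "EnhancerForest",
    "VarSelRF",
    "RFPermuteImportance",
    "train_rf",
    "oob_se",
    "varselrf_select",
    "permutation_importance",
]


@dataclass
class RFConfig:
    """Forest hyperparameters shared across the pipeline.

    ``ntree`` trees are grown for the initial/final fits; elimination
    refits use the cheaper ``ntree_iterat``. ``mtry`` is the number of
    candidate features per split ("sqrt" = floor(sqrt(p)))."""

    ntree: int = 5000
    mtry: int | str = "sqrt"
    seed: int = 0
    compute_importance: bool = True
    ntree_iterat: int = 2000
    n_jobs: int = 1

    def __post_init__(self):
        if self.ntree < 1 or self.ntree_iterat < 1:
            raise ValueError("tree counts must be >= 1")


@dataclass
class SelectionTrace:
    """Per-iteration record of a recursive-elimination run."""

    iterations: list  # (feature_names tuple, oob_error, oob_se)
    selected: list
    drop_fraction: float
    c_sd: float

    def __post_init__(self):
        sizes = [len(feats) for feats, _, _ in self.iterations]
        if any(s2 >= s1 for s1, s2 in zip(sizes, sizes[1:])):
            raise ValueError("iteration feature sets must strictly shrink")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")
        if set(self.selected) not in [set(f) for f, _, _ in self.iterations]:
            raise ValueError("selected set must be one of the iterations")

    def to_dict(self) -> dict:
        return {
            "drop_fraction": self.drop_fraction,
            "c_sd": self.c_sd,
            "selected": list(self.selected),
            "iterations": [
                {
                    "n_features": len(feats),
                    "features": list(feats),
                    "oob_error": err,
                    "oob_se": se,
                }
                for feats, err, se in self.iterations
            ],
        }


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    # sklearn wants an int; keep it under 2^31
    return int(seed_seq.generate_state(1)[0] % (2**31))


def oob_se(err: float, n: int) -> float:
    """Binomial standard error of an OOB error rate over n samples."""
    if not 0 <= err <= 1:
        raise ValueError("error rate outside [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.sqrt(err * (1.0 - err) / n)


class EnhancerForest(ClassifierMixin, BaseEstimator):
    """Random-forest classifier with OOB error and OOB permutation importance.

    Fitted attributes: ``classes_``, ``oob_error_``, ``oob_se_``,
    ``feature_importances_`` (unscaled mean decrease in OOB accuracy; only
    when ``compute_importance``), ``n_features_in_``.
    """

    def __init__(
        self,
        ntree: int = 5000,
        mtry="sqrt",
        seed: int | None = 0,
        compute_importance: bool = True,
        n_jobs: int = 1,
    ):
        self.ntree = ntree
        self.mtry = mtry
        self.seed = seed
        self.compute_importance = compute_importance
        self.n_jobs = n_jobs

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one feature")
        if not np.isfinite(X).all():
            raise ValueError("X contains NaN or infinite values")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes in y")
        ss = np.random.SeedSequence(self.seed)
        forest_ss, imp_ss = ss.spawn(2)
        self._rf = RandomForestClassifier(
            n_estimators=self.ntree,
            max_features=self.mtry,
            oob_score=True,
            bootstrap=True,
            random_state=_seed_int(forest_ss),
            n_jobs=self.n_jobs,
        )
        self._rf.fit(X, y)
        self.classes_ = self._rf.classes_
        self.n_features_in_ = X.shape[1]
        self.oob_error_ = 1.0 - float(self._rf.oob_score_)
        self.oob_se_ = oob_se(self.oob_error_, X.shape[0])
        if self.compute_importance:
            self.feature_importances_ = self._oob_mda(
                X, y, np.random.default_rng(imp_ss)
            )
        return self

    def _oob_mda(self, X, y, rng) -> np.ndarray:
        """Unscaled OOB mean-decrease-accuracy, one pass per tree."""
        n, p = X.shape
        y_enc = np.searchsorted(self._rf.classes_, y).astype(float)
        imp = np.zeros(p)
        for tree, sampled in zip(self._rf.estimators_, self._rf.estimators_samples_):
            mask = np.ones(n, dtype=bool)
            mask[sampled] = False
            oob = np.flatnonzero(mask)
            if oob.size == 0:
                continue
            X_oob = X[oob].copy()
            y_oob = y_enc[oob]
            base = (tree.predict(X_oob) == y_oob).mean()
            for f in range(p):
                saved = X_oob[:, f].copy()
                X_oob[:, f] = saved[rng.permutation(oob.size)]
                perm = (tree.predict(X_oob) == y_oob).mean()
                X_oob[:, f] = saved
                imp[f] += base - perm
        return imp / len(self._rf.estimators_)

    def predict_proba(self, X):
        check_is_fitted(self, "_rf")
        return self._rf.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        check_is_fitted(self, "_rf")
        return self._rf.predict(np.asarray(X, dtype=float))

    def predict_score(self, X) -> np.ndarray:
        """Positive-class vote fraction in [0, 1] (class ``1`` / max label)."""
        proba = self.predict_proba(X)
        pos = int(np.argmax(self.classes_))
        if 1 in self.classes_:
            pos = int(np.flatnonzero(self.classes_ == 1)[0])
        return proba[:, pos]


class VarSelRF(SelectorMixin, BaseEstimator):
    """Recursive feature elimination driven by OOB error.

    Fitted attributes: ``trace_`` (:class:`SelectionTrace`), ``support_``,
    ``selected_features_`` and ``feature_names_in_``.
    """

    def __init__(
        self,
        drop_fraction: float = 0.1,
        c_sd: float = 1.0,
        ntree: int = 5000,
        ntree_iterat: int = 2000,
        mtry="sqrt",
        seed: int | None = 0,
        n_jobs: int = 1,
    ):
        self.drop_fraction = drop_fraction
        self.c_sd = c_sd
        self.ntree = ntree
        self.ntree_iterat = ntree_iterat
        self.mtry = mtry
        self.seed = seed
        self.n_jobs = n_jobs

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, p = X.shape
        if p < 2:
            raise ValueError("need at least 2 features for elimination")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must be in (0, 1)")
        if feature_names is None:
            feature_names = [f"f{i:05d}" for i in range(p)]
        feature_names = list(feature_names)
        self.feature_names_in_ = np.array(feature_names, dtype=object)

        ss = np.random.SeedSequence(self.seed)
        seeds = iter(ss.spawn(1 + _n_iterations(p, self.drop_fraction)))

        full = EnhancerForest(
            ntree=self.ntree,
            mtry=self.mtry,
            seed=_seed_int(next(seeds)),
            compute_importance=True,
            n_jobs=self.n_jobs,
        ).fit(X, y)
        # rank once on the initial importance; ties break lexicographically
        order = sorted(
            range(p),
            key=lambda i: (-full.feature_importances_[i], feature_names[i]),
        )  # most important first
        iterations = [(tuple(feature_names), full.oob_error_, full.oob_se_)]

        current = list(order)
        while len(current) > 2:
            n_drop = max(1, round(self.drop_fraction * len(current)))
            current = current[: max(2, len(current) - n_drop)]
            fit = EnhancerForest(
                ntree=self.ntree_iterat,
                mtry=self.mtry,
                seed=_seed_int(next(seeds)),
                compute_importance=False,
                n_jobs=self.n_jobs,
            ).fit(X[:, current], y)
            iterations.append(
                (
                    tuple(feature_names[i] for i in sorted(current)),
                    fit.oob_error_,
                    fit.oob_se_,
                )
            )

        errs = [err for _, err, _ in iterations]
        min_err = min(errs)
        threshold = min_err + self.c_sd * oob_se(min_err, n)
        candidates = [it for it in iterations if it[1] <= threshold]
        selected = min(candidates, key=lambda it: len(it[0]))[0]

        self.trace_ = SelectionTrace(
            iterations=iterations,
            selected=list(selected),
            drop_fraction=self.drop_fraction,
            c_sd=self.c_sd,
        )
        self.selected_features_ = list(selected)
        sel = set(selected)
        self.support_ = np.array([f in sel for f in feature_names])
        self.n_features_in_ = p
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _n_iterations(p: int, drop_fraction: float) -> int:
    count, size = 0, p
    while size > 2:
        size -= max(1, round(drop_fraction * size))
        size = max(2, size)
        count += 1
    return count + 2


class RFPermuteImportance(BaseEstimator):
    """Null-calibrated feature importance via response permutation.

    Fitted attributes: ``observed_``, ``null_mean_``, ``null_sd_``,
    ``p_values_`` (each one entry per feature) and ``null_`` with the raw
    (n_perm × p) null importances.
    """

    def __init__(
        self,
        n_perm: int = 100,
        ntree: int = 5000,
        mtry="sqrt",
        seed: int | None = 0,
        n_jobs: int = 1,
    ):
        self.n_perm = n_perm
        self.ntree = ntree
        self.mtry = mtry
        self.seed = seed
        self.n_jobs = n_jobs

    def fit(self, X, y):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(2 * self.n_perm + 1)
        observed = EnhancerForest(
            ntree=self.ntree,
            mtry=self.mtry,
            seed=_seed_int(children[0]),
            compute_importance=True,
            n_jobs=self.n_jobs,
        ).fit(X, y)
        self.observed_ = observed.feature_importances_
        null = np.empty((self.n_perm, X.shape[1]))
        for b in range(self.n_perm):
            rng = np.random.default_rng(children[1 + 2 * b])
            y_perm = rng.permutation(y)
            fit = EnhancerForest(
                ntree=self.ntree,
                mtry=self.mtry,
                seed=_seed_int(children[2 + 2 * b]),
                compute_importance=True,
                n_jobs=self.n_jobs,
            ).fit(X, y_perm)
            null[b] = fit.feature_importances_
        self.null_ = null
        self.null_mean_ = null.mean(axis=0)
        self.null_sd_ = null.std(axis=0, ddof=1) if self.n_perm > 1 else np.zeros(
            X.shape[1]
        )
        b_ge = (null >= self.observed_[None, :]).sum(axis=0)
        self.p_values_ = (b_ge + 1) / (self.n_perm + 1)
        return self


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimators


def train_rf(m: FeatureMatrix, cfg: RFConfig | None = None) -> EnhancerForest:
    """Fit a forest on a feature matrix; labels positive=1, else 0."""
    cfg = cfg or RFConfig()
    forest = EnhancerForest(
        ntree=cfg.ntree,
        mtry=cfg.mtry,
        seed=cfg.seed,
        compute_importance=cfg.compute_importance,
        n_jobs=cfg.n_jobs,
    )
    forest.fit(m.values, m.y())
    forest.feature_names_ = list(m.feature_names)
    return forest


def varselrf_select(
    m: FeatureMatrix,
    cfg: RFConfig | None = None,
    drop_fraction: float = 0.1,
    c_sd: float = 1.0,
) -> SelectionTrace:
    """Run recursive elimination on a feature matrix; returns the trace."""
    cfg = cfg or RFConfig()
    sel = VarSelRF(
        drop_fraction=drop_fraction,
        c_sd=c_sd,
        ntree=cfg.ntree,
        ntree_iterat=cfg.ntree_iterat,
        mtry=cfg.mtry,
        seed=cfg.seed,
        n_jobs=cfg.n_jobs,
    )
    sel.fit(m.values, m.y(), feature_names=m.feature_names)
    return sel.trace_


def permutation_importance(
    m: FeatureMatrix, cfg: RFConfig | None = None, n_perm: int = 100
) -> pd.DataFrame:
    """rfPermute-style importance report as a DataFrame (one row per feature)."""
    cfg = cfg or RFConfig()
    est = RFPermuteImportance(
        n_perm=n_perm,
        ntree=cfg.ntree,
        mtry=cfg.mtry,
        seed=cfg.seed,
        n_jobs=cfg.n_jobs,
    ).fit(m.values, m.y())
    return pd.DataFrame(
        {
            "feature": m.feature_names,
            "observed": est.observed_,
            "null_mean": est.null_mean_,
            "null_sd": est.null_sd_,
            "p_value": est.p_values_,
        }
    )
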