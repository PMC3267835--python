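"""Leave-one-out meta-classifier evaluation of the fusion schemes.

The protocol mirrors the motivating study: for each held-out sample, the
remaining ``n - 1`` samples drive *everything* — univariate t-test pruning of
the x-view, ridge selection, fitting the fusion model, building the
metaspace and training the classifier — and the held-out sample is then
projected into the training metaspace and classified.  Accuracy is the
fraction of correctly classified held-out samples.

Schemes: ``pca``, ``plsr``, ``cca`` (no ridge), ``rcca`` (unsupervised
leave-one-out ridge selection) and ``srcca-tt`` / ``srcca-wrst`` /
``srcca-wlt`` (supervised ridge selection).  Classifiers: ``knn1`` (an
internal 1-nearest-neighbor with deterministic tie-breaking) and ``rf50``
(a 50-tree random forest, seeded per fold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier

from . import cca
from .baselines import pca_embed, plsr_embed
from .data import MultimodalDataset, prune_features_ttest
from .metaspace import MetaspaceConfig, build_metaspace
from .selection import RegularizationGrid, select_parameters

__all__ = [
    "SCHEMES",
    "CLASSIFIERS",
    "EvaluationResult",
    "SweepResult",
    "PairedTestResult",
    "loo_evaluate",
    "sweep",
    "paired_accuracy_ttest",
    "count_factorizations",
]

SCHEMES = ("pca", "plsr", "cca", "rcca", "srcca-tt", "srcca-wrst", "srcca-wlt")
CLASSIFIERS = ("knn1", "rf50")

_SCHEME_CRITERION = {"rcca": "rcca-loo", "srcca-tt": "tt", "srcca-wrst": "wrst", "srcca-wlt": "wlt"}


@dataclass(frozen=True)
class EvaluationResult:
    """Per-fold LOO predictions and accuracy for one evaluation cell."""

    scheme: str
    classifier: str
    d: int
    per_fold: tuple[dict, ...]
    accuracy: float

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)


@dataclass(frozen=True)
class SweepResult:
    """All evaluation cells of a (pairs × schemes × classifiers × d) sweep."""

    cells: dict
    summaries: dict

    def accuracies(self, scheme: str, classifier: str) -> np.ndarray:
        return np.array(
            [r.accuracy for key, r in sorted(self.cells.items()) if key[0] == scheme and key[1] == classifier]
        )


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired Student t-test on per-cell accuracy differences."""

    t_statistic: float
    p_value: float
    n_pairs: int


def _knn1_predict(train: np.ndarray, train_labels: np.ndarray, test: np.ndarray) -> int:
    """1-NN with Euclidean distance; exact ties go to the lowest train index."""
    d2 = np.sum((train - test.ravel()) ** 2, axis=1)
    return int(train_labels[int(np.argmin(d2))])


def _fit_and_project(ds_train: MultimodalDataset, x_test: np.ndarray, y_test: np.ndarray,
                     scheme: str, d: int, grid: RegularizationGrid | None,
                     lambda0: float, score_view: str,
                     selection_cache: dict | None = None, fold: int | None = None):
    """Fit one fusion scheme on the training fold; embed train + test.

    Returns (train_embedding, test_embedding, selected ridge pair or None).
    ``selection_cache`` memoizes the (deterministic) per-fold ridge selection
    across sweep cells that share the training fold but differ in d or
    classifier.
    """
    xtr, ytr, labels = ds_train.x_view, ds_train.y_view, ds_train.labels
    if scheme == "pca":
        emb, model = pca_embed(xtr, ytr, d)
        test_emb = model.transform(np.hstack([x_test, y_test]), d)
        return emb, test_emb, None
    if scheme == "plsr":
        emb, model = plsr_embed(xtr, ytr, d)
        test_emb = model.transform(x_test, d)
        return emb, test_emb, None
    if scheme == "cca":
        lx = ly = 0.0
        selected = None
    else:
        key = (scheme, fold)
        if selection_cache is not None and key in selection_cache:
            lx, ly = selection_cache[key]
        else:
            criterion = _SCHEME_CRITERION[scheme]
            sel = select_parameters(
                xtr, ytr,
                labels if criterion != "rcca-loo" else None,
                grid, criterion, score_view=score_view,
            )
            lx, ly = sel.lambda_x, sel.lambda_y
            if selection_cache is not None:
                selection_cache[key] = (lx, ly)
        selected = (lx, ly)
    cov = cca.compute_covariances(xtr, ytr)
    model = cca.solve_rcca(cov, lx, ly, d=min(d, model_phi(cov)))
    ms = build_metaspace(xtr, ytr, model, MetaspaceConfig(d=d, lambda0=lambda0, view=score_view))
    test_values = x_test if score_view == "x" else y_test
    test_emb = cca.project(test_values, model, score_view, ms.d)
    return ms.embedding, test_emb, selected


def model_phi(cov: cca.CovarianceTriple) -> int:
    return min(cov.c_xx.shape[0], cov.c_yy.shape[0])


def loo_evaluate(
    ds: MultimodalDataset,
    scheme: str,
    classifier: str = "knn1",
    d: int = 3,
    grid: RegularizationGrid | None = None,
    prune_k: int | None = None,
    prune_alpha: float = 0.05,
    lambda0: float = 0.0,
    seed: int = 0,
    score_view: str = "x",
    _selection_cache: dict | None = None,
) -> EvaluationResult:
    """Leave-one-out evaluation of one (scheme, classifier, d) cell.

    ``prune_k`` enables within-fold t-test pruning of the x-view to at most
    ``prune_k`` features (two-sided p < ``prune_alpha``); ``None`` skips
    pruning (for inputs already at panel scale).  ``grid`` is required for
    the ridge-selecting schemes.  ``seed`` only feeds the random-forest
    classifier (seeded per fold as ``seed + fold_index``); everything else
    is deterministic.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    if classifier not in CLASSIFIERS:
        raise ValueError(f"classifier must be one of {CLASSIFIERS}")
    if scheme in _SCHEME_CRITERION and grid is None:
        raise ValueError(f"scheme {scheme!r} requires a regularization grid")
    n = ds.n_samples
    if n < 3:
        raise ValueError("leave-one-out evaluation needs n >= 3")

    per_fold = []
    correct = 0
    for i in range(n):
        keep = np.r_[0:i, i + 1 : n]
        if len(np.unique(ds.labels.labels[keep])) < 2:
            raise ValueError(f"training fold {i} lost one class entirely")
        train = ds.subset_samples(keep)
        x_test = ds.x_view.values[i : i + 1]
        y_test = ds.y_view.values[i : i + 1]

        if prune_k is not None:
            pruned = prune_features_ttest(train.x_view, train.labels, prune_k, prune_alpha)
            train = MultimodalDataset(pruned, train.y_view, train.labels)
            test_view = ds.x_view.subset_samples([i]).restrict_to_features(pruned.feature_ids)
            x_test = test_view.values

        emb_train, emb_test, selected = _fit_and_project(
            train, x_test, y_test, scheme, d, grid, lambda0, score_view,
            selection_cache=_selection_cache, fold=i,
        )
        train_labels = train.labels.labels
        if classifier == "knn1":
            pred = _knn1_predict(emb_train, train_labels, emb_test)
        else:
            rf = RandomForestClassifier(n_estimators=50, random_state=seed + i)
            rf.fit(emb_train, train_labels)
            pred = int(rf.predict(emb_test)[0])
        true = int(ds.labels.labels[i])
        correct += pred == true
        per_fold.append(
            {
                "sample_id": ds.labels.sample_ids[i],
                "true": true,
                "predicted": pred,
                "selected": selected,
            }
        )
    return EvaluationResult(
        scheme=scheme,
        classifier=classifier,
        d=d,
        per_fold=tuple(per_fold),
        accuracy=correct / n,
    )


def sweep(
    pairs: list[MultimodalDataset],
    schemes=SCHEMES,
    classifiers=CLASSIFIERS,
    d_values=tuple(range(1, 11)),
    grid: RegularizationGrid | None = None,
    seed: int = 0,
    pair_names: list[str] | None = None,
    **loo_kwargs,
) -> SweepResult:
    """Evaluate every (scheme, classifier, d, pair) cell and summarize.

    Summaries hold the max and median accuracy per scheme × classifier over
    all (pair, d) cells, as in the study's dimensionality sweep.
    """
    if not pairs:
        raise ValueError("at least one view pair is required")
    if pair_names is None:
        pair_names = [f"pair{k + 1}" for k in range(len(pairs))]
    cells = {}
    # ridge selection is per (pair, scheme, fold) and deterministic: memoize
    # it across the d x classifier cells that share a training fold
    caches = {name: {} for name in pair_names}
    for scheme in schemes:
        for clf in classifiers:
            for d in d_values:
                for name, ds in zip(pair_names, pairs):
                    cells[(scheme, clf, d, name)] = loo_evaluate(
                        ds, scheme, clf, d, grid=grid, seed=seed,
                        _selection_cache=caches[name], **loo_kwargs
                    )
    summaries = {}
    for scheme in schemes:
        for clf in classifiers:
            acc = [r.accuracy for key, r in cells.items() if key[0] == scheme and key[1] == clf]
            summaries[(scheme, clf)] = {
                "max": float(np.max(acc)),
                "median": float(np.median(acc)),
                "n_cells": len(acc),
            }
    return SweepResult(cells=cells, summaries=summaries)


def paired_accuracy_ttest(a1, a2) -> PairedTestResult:
    """Two-sided paired Student t-test on matched accuracy vectors.

    Identical vectors give (t=0, p=1).  A constant non-zero difference has
    zero variance, where the t statistic diverges; this degenerate case
    returns a signed infinite t with a p-value sentinel just above 0, with a
    warning.
    """
    a1 = np.asarray(a1, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 1:
        raise ValueError("accuracy vectors must be 1-D and of equal length")
    if a1.size < 2:
        raise ValueError("need at least 2 paired observations")
    diff = a1 - a2
    if np.all(diff == 0.0):
        return PairedTestResult(0.0, 1.0, a1.size)
    # constant differences up to float rounding: the t statistic diverges
    if np.std(diff) <= 1e-9 * np.abs(diff).mean():
        warnings.warn(
            "zero-variance non-zero differences: t diverges, p reported as ~0",
            stacklevel=2,
        )
        t = float(np.sign(diff.mean()) * np.inf)
        return PairedTestResult(t, float(np.finfo(float).tiny), a1.size)
    res = sp_stats.ttest_rel(a1, a2)
    return PairedTestResult(float(res.statistic), float(res.pvalue), a1.size)


def count_factorizations(grid: RegularizationGrid, n: int, method: str) -> int:
    """Predicted number of CCA factorizations a selection run performs.

    The supervised criteria need one solve per grid point; the unsupervised
    leave-one-out criterion needs ``n`` per grid point.  The selection
    routine's instrumented counter matches these predictions exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method not in ("rcca", "srcca"):
        raise ValueError("method must be 'rcca' or 'srcca'")
    base = grid.n_points
    return base * n if method == "rcca" else base
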