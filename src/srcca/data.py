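"""Containers and preprocessing for two-view sample × feature tables.

A *view* is one modality's measurement table (samples in rows, features in
columns) carrying sample and feature identifiers.  Two views plus a binary
outcome vector form a :class:`MultimodalDataset`, the input to every fusion
scheme in this package.

Preprocessing mirrors the standard proteomics chain: quantile normalization
across samples, log2 transformation, per-feature standardization, and
univariate t-test pruning to a small panel of class-associated features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ViewMatrix",
    "LabelVector",
    "MultimodalDataset",
    "read_view_table",
    "write_view_table",
    "read_labels",
    "write_labels",
    "align_views",
    "quantile_normalize",
    "log2_transform",
    "standardize_features",
    "welch_t_statistics",
    "prune_features_ttest",
]


@dataclass(frozen=True)
class ViewMatrix:
    """One modality's samples × features table.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Real-valued measurements.
    sample_ids, feature_ids : sequence of str
        Unique, ordered identifiers for rows and columns.
    modality_tag : str
        Free-text tag naming the modality (e.g. ``"P"`` for proteomic,
        ``"H"`` for histologic).
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]
    modality_tag: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = values.shape
        if n < 1:
            raise ValueError("a view needs at least one sample")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.feature_ids) != m:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != m:
            raise ValueError("duplicate feature ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, index: Sequence[int]) -> "ViewMatrix":
        """Return a view restricted to the given row positions (in order)."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index],
            sample_ids=tuple(self.sample_ids[i] for i in index),
        )

    def subset_features(self, index: Sequence[int]) -> "ViewMatrix":
        """Return a view restricted to the given column positions (in order)."""
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[:, index],
            feature_ids=tuple(self.feature_ids[i] for i in index),
        )

    def restrict_to_features(self, feature_ids: Sequence[str]) -> "ViewMatrix":
        """Return a view with exactly the named features, in the given order."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in pos]
        if missing:
            raise KeyError(f"features not present in view: {missing}")
        return self.subset_features([pos[f] for f in feature_ids])


@dataclass(frozen=True)
class LabelVector:
    """Binary class label per sample (two classes, W1 and W2)."""

    labels: np.ndarray
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if len(self.sample_ids) != labels.size:
            raise ValueError("label / sample-id length mismatch")
        if len(set(self.sample_ids)) != labels.size:
            raise ValueError("duplicate sample ids")
        if len(np.unique(labels)) != 2:
            raise ValueError("exactly two classes must be present")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    @property
    def class_counts(self) -> tuple[int, int]:
        c = self.classes
        return int(np.sum(self.labels == c[0])), int(np.sum(self.labels == c[1]))

    def subset_samples(self, index: Sequence[int]) -> "LabelVector":
        index = np.asarray(index)
        return LabelVector(
            labels=self.labels[index],
            sample_ids=tuple(self.sample_ids[i] for i in index),
        )


@dataclass(frozen=True)
class MultimodalDataset:
    """Two row-aligned views plus the outcome labels."""

    x_view: ViewMatrix
    y_view: ViewMatrix
    labels: LabelVector

    def __post_init__(self) -> None:
        ids = self.x_view.sample_ids
        if self.y_view.sample_ids != ids or self.labels.sample_ids != ids:
            raise ValueError("x_view, y_view and labels must share identical, ordered sample ids")

    @property
    def n_samples(self) -> int:
        return self.x_view.n_samples

    def subset_samples(self, index: Sequence[int]) -> "MultimodalDataset":
        return MultimodalDataset(
            x_view=self.x_view.subset_samples(index),
            y_view=self.y_view.subset_samples(index),
            labels=self.labels.subset_samples(index),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_view_table(path: str | Path, modality_tag: str = "", sep: str = ",") -> ViewMatrix:
    """Read a delimited samples × features table.

    The first column holds sample ids; the header row holds feature ids.
    Row and column order are preserved.  Duplicate ids or non-numeric cells
    raise ``ValueError``.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    sample_ids = [str(s) for s in df.index]
    feature_ids = [str(f) for f in df.columns]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample ids")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(f"{path}: duplicate feature ids")
    values = np.empty(df.shape, dtype=float)
    # cell-wise float() keeps the conversion exact (bit-level round-trip)
    for j, col in enumerate(df.columns):
        for i, (sid, cell) in enumerate(zip(df.index, df[col])):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell at row {sid!r}, column {col!r}"
                ) from None
            if not np.isfinite(values[i, j]):
                raise ValueError(
                    f"{path}: missing or non-finite cell at row {sid!r}, column {col!r}"
                )
    return ViewMatrix(values, tuple(sample_ids), tuple(feature_ids), modality_tag)


def write_view_table(view: ViewMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a view so that :func:`read_view_table` round-trips it bit-exactly.

    Values are written with ``repr``-faithful precision (17 significant
    digits), which reparses to the identical float64.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id" + sep + sep.join(view.feature_ids) + "\n")
        for sid, row in zip(view.sample_ids, view.values):
            fh.write(sid + sep + sep.join(repr(float(v)) for v in row) + "\n")


def read_labels(path: str | Path, sep: str = ",") -> LabelVector:
    """Read a two-column (sample_id, label) table with a header row."""
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    ids = [str(s) for s in df.iloc[:, 0]]
    labels = df.iloc[:, 1].astype(int).to_numpy()
    return LabelVector(labels, tuple(ids))


def write_labels(labels: LabelVector, path: str | Path, sep: str = ",") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id" + sep + "label\n")
        for sid, lab in zip(labels.sample_ids, labels.labels):
            fh.write(f"{sid}{sep}{int(lab)}\n")


def align_views(x: ViewMatrix, y: ViewMatrix, labels: LabelVector) -> MultimodalDataset:
    """Reorder the three inputs to a common canonical sample order.

    The canonical order is sorted sample id.  The three id sets must be
    identical; otherwise the symmetric difference is reported.
    """
    sx, sy, sl = set(x.sample_ids), set(y.sample_ids), set(labels.sample_ids)
    if not (sx == sy == sl):
        diff = sorted((sx ^ sy) | (sx ^ sl) | (sy ^ sl))
        raise ValueError(f"sample-id sets differ; symmetric difference: {diff}")
    order = sorted(sx)
    ix = {s: i for i, s in enumerate(x.sample_ids)}
    iy = {s: i for i, s in enumerate(y.sample_ids)}
    il = {s: i for i, s in enumerate(labels.sample_ids)}
    return MultimodalDataset(
        x_view=x.subset_samples([ix[s] for s in order]),
        y_view=y.subset_samples([iy[s] for s in order]),
        labels=labels.subset_samples([il[s] for s in order]),
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def quantile_normalize(view: ViewMatrix) -> ViewMatrix:
    """Quantile-normalize so every sample (row) shares one value distribution.

    The reference distribution is the per-rank mean across samples: sort each
    row, average the sorted rows, and assign each cell the reference value at
    its within-row rank.  Ties within a row receive the mean of the reference
    values over the tied rank positions.
    """
    v = view.values
    if not np.all(np.isfinite(v)):
        raise ValueError("quantile_normalize requires finite input")
    n, m = v.shape
    reference = np.sort(v, axis=1).mean(axis=0)
    out = np.empty_like(v)
    for i in range(n):
        row = v[i]
        order = np.argsort(row, kind="stable")
        ranked = np.empty(m)
        ranked[order] = reference
        # midrank tie handling: average reference values over tied positions
        uniq, inverse, counts = np.unique(row, return_inverse=True, return_counts=True)
        if uniq.size != m:
            sums = np.zeros(uniq.size)
            np.add.at(sums, inverse, ranked)
            ranked = (sums / counts)[inverse]
        out[i] = ranked
    return replace(view, values=out)


def log2_transform(view: ViewMatrix, offset: float = 0.0) -> ViewMatrix:
    """Elementwise log2, optionally after adding a positive offset."""
    v = view.values + offset
    if np.any(v <= 0):
        raise ValueError("log2 of non-positive value; configure an offset")
    return replace(view, values=np.log2(v))


def standardize_features(view: ViewMatrix) -> ViewMatrix:
    """Center each feature to mean 0 and scale to unit sample sd (ddof=1).

    Zero-variance features are set to all-zeros with a warning.
    """
    v = view.values
    if not np.all(np.isfinite(v)):
        raise ValueError("standardize_features requires finite input")
    mean = v.mean(axis=0)
    if v.shape[0] > 1:
        sd = v.std(axis=0, ddof=1)
    else:
        sd = np.zeros(v.shape[1])
    constant = sd == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} zero-variance feature(s) set to zeros",
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    out = (v - mean) / safe_sd
    out[:, constant] = 0.0
    return replace(view, values=out)


def welch_t_statistics(
    view: ViewMatrix, labels: LabelVector
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature Welch t statistic and two-sided p-value between the classes.

    Uses (n-1)-denominator variances and the Welch–Satterthwaite degrees of
    freedom.  Features with zero variance in both classes get t=0 (equal
    means) or +inf (distinct means) with p-values 1 and 0 respectively.
    """
    c = labels.classes
    g1 = view.values[labels.labels == c[0]]
    g2 = view.values[labels.labels == c[1]]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical groups trigger a precision-loss RuntimeWarning that we
        # resolve explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(g1, g2, axis=0, equal_var=False)
        t = np.abs(np.asarray(res.statistic, dtype=float))
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(t)
    if np.any(degenerate):
        equal = np.isclose(g1.mean(0), g2.mean(0))
        t[degenerate & equal] = 0.0
        p[degenerate & equal] = 1.0
        t[degenerate & ~equal] = np.inf
        p[degenerate & ~equal] = 0.0
    return t, p


def prune_features_ttest(
    view: ViewMatrix,
    labels: LabelVector,
    k: int = 25,
    alpha: float = 0.05,
) -> ViewMatrix:
    """Keep the top-``k`` features ranked by |Welch t| with two-sided p < alpha.

    Rank ties are broken by feature order.  Raises if no feature passes the
    significance cutoff.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    n1, n2 = labels.class_counts
    if min(n1, n2) < 2:
        raise ValueError("each class needs at least 2 samples for the t-test")
    t, p = welch_t_statistics(view, labels)
    passing = np.flatnonzero(p < alpha)
    if passing.size == 0:
        raise ValueError(
            f"no feature passes the p < {alpha} cutoff; relax alpha or inspect the data"
        )
    # stable sort on -|t| keeps feature order among exact ties
    order = passing[np.argsort(-t[passing], kind="stable")]
    return view.subset_features(order[:k])
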