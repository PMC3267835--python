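"""Ridge-parameter selection for regularized CCA.

Two families of criteria choose the ridge pair ``(lambda_x, lambda_y)`` on a
grid:

* the unsupervised RCCA criterion: a leave-one-out stability objective that
  refits CCA ``n`` times per grid point and maximizes the Pearson correlation
  of the held-out paired scores;
* the supervised SRCCA criteria: a single fit per grid point, scored by how
  well the first canonical component separates the two classes — Welch
  t-score (maximized), Wilcoxon rank-sum statistic (maximized), or Wilks
  lambda (minimized).

Because the supervised criteria need one factorization per grid point instead
of ``n``, SRCCA selection is an order of ``n`` times cheaper than the RCCA
leave-one-out search; :mod:`srcca.evaluation` verifies the counts exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from . import cca
from .data import LabelVector, ViewMatrix

__all__ = [
    "RegularizationGrid",
    "GroupStats",
    "SelectionResult",
    "make_grid",
    "rcca_loo_objective",
    "tscore",
    "wrst_score",
    "wilks_lambda",
    "select_parameters",
    "CRITERIA",
]

CRITERIA = ("rcca-loo", "tt", "wrst", "wlt")


@dataclass(frozen=True)
class RegularizationGrid:
    """Evenly spaced ridge grid on ``[theta1, theta2]`` with ``v`` points.

    ``mode="coupled"`` traverses the ``v`` diagonal pairs ``lambda_x =
    lambda_y``; ``mode="full-pairs"`` traverses all ``v**2`` ordered pairs.
    """

    theta1: float
    theta2: float
    v: int
    mode: str = "coupled"

    def __post_init__(self) -> None:
        if self.theta1 < 0 or self.theta1 > self.theta2:
            raise ValueError("need 0 <= theta1 <= theta2")
        if self.v < 1:
            raise ValueError("v must be >= 1")
        if self.mode not in ("coupled", "full-pairs"):
            raise ValueError("mode must be 'coupled' or 'full-pairs'")

    @property
    def values(self) -> np.ndarray:
        if self.v == 1:
            return np.array([self.theta1])
        return np.linspace(self.theta1, self.theta2, self.v)

    def pairs(self) -> Iterator[tuple[float, float]]:
        """Grid pairs in lexicographic order (ties in selection break here)."""
        vals = self.values
        if self.mode == "coupled":
            for lam in vals:
                yield float(lam), float(lam)
        else:
            for lx in vals:
                for ly in vals:
                    yield float(lx), float(ly)

    @property
    def n_points(self) -> int:
        return self.v if self.mode == "coupled" else self.v**2


def make_grid(theta1: float, theta2: float, v: int, mode: str = "coupled") -> RegularizationGrid:
    """Build an inclusive, evenly spaced ridge grid (``v=1`` gives ``theta1``)."""
    return RegularizationGrid(theta1, theta2, v, mode)


# ---------------------------------------------------------------------------
# class-separation statistics of a 1-D embedding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupStats:
    """Per-class summary of a 1-D embedding: means, (n-1)-variances, sizes."""

    mu1: float
    mu2: float
    var1: float
    var2: float
    n1: int
    n2: int

    @classmethod
    def from_embedding(cls, values: np.ndarray, labels: LabelVector) -> "GroupStats":
        values = np.asarray(values, dtype=float).ravel()
        c = labels.classes
        g1 = values[labels.labels == c[0]]
        g2 = values[labels.labels == c[1]]
        return cls(
            mu1=float(g1.mean()),
            mu2=float(g2.mean()),
            var1=float(g1.var(ddof=1)) if g1.size > 1 else 0.0,
            var2=float(g2.var(ddof=1)) if g2.size > 1 else 0.0,
            n1=g1.size,
            n2=g2.size,
        )


def tscore(g: GroupStats) -> float:
    """Welch t-score ``|mu1 - mu2| / sqrt(var1/n1 + var2/n2)``.

    Returns 0 when both variances vanish with equal means, and +inf (perfect
    separation sentinel) when both vanish with distinct means.
    """
    if g.n1 < 2 or g.n2 < 2:
        raise ValueError("tscore needs at least 2 samples per class")
    num = abs(g.mu1 - g.mu2)
    den = np.sqrt(g.var1 / g.n1 + g.var2 / g.n2)
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return float(num / den)


def wrst_score(values: np.ndarray, labels: LabelVector) -> float:
    """Wilcoxon rank-sum separation score with midranks for ties.

    Computes the Mann-Whitney ``U = sum of class-2 ranks - n2(n2+1)/2`` and
    returns ``max(U, n1*n2 - U)``, i.e. the larger of the two one-sided
    statistics.  All-identical values give the null center ``n1*n2/2``.
    """
    values = np.asarray(values, dtype=float).ravel()
    ranks = stats.rankdata(values)
    c = labels.classes
    mask2 = labels.labels == c[1]
    n2 = int(mask2.sum())
    n1 = values.size - n2
    u = float(ranks[mask2].sum() - n2 * (n2 + 1) / 2)
    return max(u, n1 * n2 - u)


def wilks_lambda(g: GroupStats) -> float:
    """Wilks lambda: within-class sum of squares over total sum of squares.

    Uses population-form variances (denominators ``n1``, ``n2``, ``n``), so
    the ratio is the SS decomposition ``SS_within / SS_total`` and lies in
    [0, 1]; smaller means better class separation.
    """
    n = g.n1 + g.n2
    ss_within = (g.n1 - 1) * g.var1 + (g.n2 - 1) * g.var2
    grand = (g.n1 * g.mu1 + g.n2 * g.mu2) / n
    ss_between = g.n1 * (g.mu1 - grand) ** 2 + g.n2 * (g.mu2 - grand) ** 2
    ss_total = ss_within + ss_between
    if ss_total == 0.0:
        raise ValueError("degenerate embedding: total variance is zero")
    return float(ss_within / ss_total)


# ---------------------------------------------------------------------------
# the RCCA leave-one-out objective
# ---------------------------------------------------------------------------


def rcca_loo_objective(
    x: ViewMatrix,
    y: ViewMatrix,
    lambda_x: float,
    lambda_y: float,
) -> float:
    """Leave-one-out stability objective for one ridge pair.

    For each sample ``i``, refit single-component RCCA on the other ``n-1``
    samples and score the held-out sample on both views (centered with the
    training means).  The objective is the Pearson correlation of the two
    held-out score vectors; it is high when the weights are stable under
    sample deletion.
    """
    n = x.n_samples
    if n < 3:
        raise ValueError("the leave-one-out objective needs n >= 3")
    u = np.empty(n)
    v = np.empty(n)
    for i in range(n):
        keep = np.r_[0:i, i + 1 : n]
        cov = cca.compute_covariances(x.subset_samples(keep), y.subset_samples(keep))
        model = cca.solve_rcca(cov, lambda_x, lambda_y, d=1)
        u[i] = cca.project(x.values[i], model, "x", 1)[0, 0]
        v[i] = cca.project(y.values[i], model, "y", 1)[0, 0]
    if np.std(u) == 0.0 or np.std(v) == 0.0:
        warnings.warn("zero-variance LOO score vector; objective defined as 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(u, v)[0, 1])


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionResult:
    """Chosen ridge pair with the full criterion surface and solve count."""

    lambda_x: float
    lambda_y: float
    criterion: str
    criterion_surface: tuple[tuple[float, float, float], ...]
    factorizations: int

    def to_dict(self) -> dict:
        return {
            "lambda_x": self.lambda_x,
            "lambda_y": self.lambda_y,
            "criterion": self.criterion,
            "criterion_surface": [list(t) for t in self.criterion_surface],
            "factorizations": self.factorizations,
        }


def select_parameters(
    x: ViewMatrix,
    y: ViewMatrix,
    labels: LabelVector | None,
    grid: RegularizationGrid,
    criterion: str,
    score_view: str = "x",
) -> SelectionResult:
    """Grid-search the ridge pair under the given criterion.

    ``criterion`` is one of ``rcca-loo`` (unsupervised; labels must be
    absent), ``tt``, ``wrst`` or ``wlt`` (supervised; labels required).
    Supervised scores are
    computed on the first canonical component of ``score_view``.  Wilks
    lambda is minimized; the others are maximized.  Ties break toward the
    lexicographically smallest ``(lambda_x, lambda_y)``.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"criterion must be one of {CRITERIA}")
    supervised = criterion != "rcca-loo"
    if supervised and labels is None:
        raise ValueError(f"criterion {criterion!r} requires labels")
    if not supervised and labels is not None:
        raise ValueError("the rcca-loo criterion is unsupervised; pass labels=None")
    if score_view not in ("x", "y"):
        raise ValueError("score_view must be 'x' or 'y'")
    if grid.n_points < 1:
        raise ValueError("empty grid")

    minimize = criterion == "wlt"
    count_before = cca.solve_count()
    cov = cca.compute_covariances(x, y) if supervised else None

    surface: list[tuple[float, float, float]] = []
    best: tuple[float, float, float] | None = None
    for lx, ly in grid.pairs():
        if supervised:
            model = cca.solve_rcca(cov, lx, ly, d=1)
            view = x if score_view == "x" else y
            emb = cca.project(view, model, score_view, 1)[:, 0]
            if criterion == "tt":
                score = tscore(GroupStats.from_embedding(emb, labels))
            elif criterion == "wrst":
                score = wrst_score(emb, labels)
            else:
                score = wilks_lambda(GroupStats.from_embedding(emb, labels))
        else:
            score = rcca_loo_objective(x, y, lx, ly)
        surface.append((lx, ly, float(score)))
        key = -score if minimize else score
        if best is None or key > best[0]:
            best = (key, lx, ly)

    return SelectionResult(
        lambda_x=best[1],
        lambda_y=best[2],
        criterion=criterion,
        criterion_surface=tuple(surface),
        factorizations=cca.solve_count() - count_before,
    )
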