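"""Comparator embeddings: PCA on the concatenated views and NIPALS PLSR.

Both baselines consume the same row-aligned view pair as the CCA family and
emit an n × d embedding plus a fitted model able to project held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ViewMatrix

__all__ = ["PCAModel", "PLSRModel", "pca_embed", "plsr_embed"]


@dataclass(frozen=True)
class PCAModel:
    """Principal components of the concatenated two-view matrix Z = [X Y].

    ``components`` holds orthonormal loading vectors as columns;
    ``eigenvalues`` the explained variances (singular values squared over
    n-1), non-increasing.  ``centering`` is the vector subtracted before
    projection (per-feature means by default).
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    centering: np.ndarray
    row_centered: bool = False

    def transform(self, z: np.ndarray, d: int | None = None) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        if self.row_centered:
            zc = z - z.mean(axis=1, keepdims=True)
        else:
            zc = z - self.centering
        d = self.components.shape[1] if d is None else d
        return zc @ self.components[:, :d]


@dataclass(frozen=True)
class PLSRModel:
    """NIPALS partial-least-squares model X = T P' + E, Y = T C' + F.

    ``scores`` (T, n×l) are the predictor latent scores; ``x_loadings`` (P),
    ``y_loadings`` (C) the loading matrices; ``x_residual`` / ``y_residual``
    the residual blocks after l deflations.  ``rotations`` maps centered
    predictor rows to scores for held-out samples: T = X_c W (P' W)^-1.
    """

    scores: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_residual: np.ndarray
    y_residual: np.ndarray
    n_components: int
    x_mean: np.ndarray
    y_mean: np.ndarray
    rotations: np.ndarray

    def transform(self, x: np.ndarray, d: int | None = None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        d = self.n_components if d is None else d
        return (x - self.x_mean) @ self.rotations[:, :d]


def pca_embed(
    x: ViewMatrix,
    y: ViewMatrix,
    d: int,
    center: str = "columns",
) -> tuple[np.ndarray, PCAModel]:
    """PCA of the concatenated matrix Z = [X Y]; returns top-d scores.

    ``center="columns"`` (default) removes per-feature means, the standard
    convention; ``center="rows"`` removes per-sample means instead, matching
    a literal row-mean-centering reading of the concatenated-PCA recipe.
    """
    if x.sample_ids != y.sample_ids:
        raise ValueError("views must be row-aligned")
    if center not in ("columns", "rows"):
        raise ValueError("center must be 'columns' or 'rows'")
    z = np.hstack([x.values, y.values])
    n, m = z.shape
    if d < 1 or d > min(n - 1, m):
        raise ValueError(f"d must lie in [1, min(n-1, p+q)] = [1, {min(n - 1, m)}]")
    if center == "columns":
        mu = z.mean(axis=0)
        zc = z - mu
        row_centered = False
    else:
        mu = np.zeros(m)
        zc = z - z.mean(axis=1, keepdims=True)
        row_centered = True
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    # deterministic sign: largest-|entry| of each loading vector positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    model = PCAModel(
        components=vt.T,
        eigenvalues=s**2 / (n - 1),
        centering=mu,
        row_centered=row_centered,
    )
    return u[:, :d] * s[:d], model


def plsr_embed(
    x: ViewMatrix,
    y: ViewMatrix,
    d: int,
) -> tuple[np.ndarray, PLSRModel]:
    """PLS2 regression of the y-view on the x-view; returns the predictor
    scores T (n × d) as the embedding.

    Each component's weight vector is the dominant left singular vector of
    the deflated cross-product ``E^T F`` — the exact fixed point that the
    classic NIPALS inner loop power-iterates toward, computed directly so
    that near-tied singular values (routine in deep components of small-n
    data) cannot stall the extraction.  Both blocks are then deflated with
    the predictor scores (regression-mode deflation).
    """
    if x.sample_ids != y.sample_ids:
        raise ValueError("views must be row-aligned")
    n, p = x.values.shape
    q = y.values.shape[1]
    if d < 1 or d > min(n - 1, p):
        raise ValueError(f"d must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    x_mean = x.values.mean(axis=0)
    y_mean = y.values.mean(axis=0)
    e = x.values - x_mean
    f = y.values - y_mean

    scores = np.empty((n, d))
    weights = np.empty((p, d))
    x_loadings = np.empty((p, d))
    y_loadings = np.empty((q, d))

    for comp in range(d):
        m = e.T @ f
        u_m, s_m, _ = np.linalg.svd(m, full_matrices=False)
        if s_m[0] <= np.finfo(float).eps * max(e.shape):
            raise np.linalg.LinAlgError(
                f"PLSR component {comp + 1}: cross-covariance exhausted"
            )
        w = u_m[:, 0]
        t = e @ w
        c = f.T @ t / (t @ t)
        # deterministic sign: largest-|entry| of w positive
        i = np.argmax(np.abs(w))
        if w[i] < 0:
            w, t, c = -w, -t, -c
        pload = e.T @ t / (t @ t)
        e = e - np.outer(t, pload)
        f = f - np.outer(t, c)
        scores[:, comp] = t
        weights[:, comp] = w
        x_loadings[:, comp] = pload
        y_loadings[:, comp] = c

    rotations = weights @ np.linalg.pinv(x_loadings.T @ weights)
    model = PLSRModel(
        scores=scores,
        x_weights=weights,
        x_loadings=x_loadings,
        y_loadings=y_loadings,
        x_residual=e,
        y_residual=f,
        n_components=d,
        x_mean=x_mean,
        y_mean=y_mean,
        rotations=rotations,
    )
    return scores, model
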