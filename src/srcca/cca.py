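"""Covariance computation and the (regularized) canonical-correlation eigenproblem.

Canonical correlation analysis (CCA) finds weight vectors ``w_x``, ``w_y``
maximizing the Pearson correlation of the projections ``X w_x`` and ``Y w_y``.
The solution is a generalized eigenproblem on the cross- and auto-covariance
matrices; ridge regularization adds ``lambda_x I`` / ``lambda_y I`` to the
auto-covariances, which is essential whenever ``n < p + q + 1`` and the
auto-covariances are singular.

Two solver branches are used:

* **positive-definite branch** (any ridge > 0, or well-conditioned data):
  Cholesky whitening of the regularized auto-covariances followed by an SVD
  of the whitened cross-covariance — numerically stable and algebraically
  equivalent to the generalized eigenproblem.
* **singular branch** (ridge = 0 with rank-deficient auto-covariance): the
  generalized eigenproblem is solved literally, with pseudo-inverses standing
  in for the inverses of the singular auto-covariances and a non-symmetric
  eigendecomposition.  This deliberately mirrors how plain CCA behaves on
  such data — the returned directions are numerically unreliable and the
  embedding components come out strongly mutually correlated, which is the
  failure mode regularization exists to fix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .data import ViewMatrix

__all__ = [
    "CovarianceTriple",
    "CanonicalModel",
    "compute_covariances",
    "solve_rcca",
    "project",
    "solve_count",
]

# module-level instrumentation: incremented once per solve_rcca call so the
# selection routines can report exact factorization counts.
_SOLVE_COUNT = 0


def solve_count() -> int:
    """Total number of CCA factorizations performed so far in this process."""
    return _SOLVE_COUNT


@dataclass(frozen=True)
class CovarianceTriple:
    """Centered auto- and cross-covariances of two row-aligned views.

    ``c_xx`` (p×p) and ``c_yy`` (q×q) are the auto-covariances, ``c_xy``
    (p×q) the cross-covariance, all with denominator ``n - 1``.  The column
    means used for centering are retained so held-out samples can be
    projected consistently.
    """

    c_xx: np.ndarray
    c_yy: np.ndarray
    c_xy: np.ndarray
    n: int
    column_means_x: np.ndarray
    column_means_y: np.ndarray


@dataclass(frozen=True)
class CanonicalModel:
    """Fitted (regularized) CCA: paired weights, correlations and ridges.

    ``w_x`` (p×d) and ``w_y`` (q×d) hold the canonical weight vectors,
    ``correlations`` the d canonical correlations sorted non-increasing and
    clamped to [0, 1].  ``phi`` is min(p, q), the maximum number of canonical
    components.  Weight columns are normalized so that
    ``w_x^T (C_xx + lambda_x I) w_x = 1`` per component (and likewise for y)
    whenever the normalization is numerically meaningful.
    """

    w_x: np.ndarray
    w_y: np.ndarray
    correlations: np.ndarray
    lambda_x: float
    lambda_y: float
    phi: int
    column_means_x: np.ndarray
    column_means_y: np.ndarray
    degenerate: bool = False

    @property
    def d(self) -> int:
        return self.w_x.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "w_x": self.w_x.tolist(),
            "w_y": self.w_y.tolist(),
            "correlations": self.correlations.tolist(),
            "lambda_x": self.lambda_x,
            "lambda_y": self.lambda_y,
            "phi": self.phi,
            "column_means_x": self.column_means_x.tolist(),
            "column_means_y": self.column_means_y.tolist(),
            "degenerate": self.degenerate,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CanonicalModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            w_x=np.asarray(payload["w_x"], dtype=float),
            w_y=np.asarray(payload["w_y"], dtype=float),
            correlations=np.asarray(payload["correlations"], dtype=float),
            lambda_x=float(payload["lambda_x"]),
            lambda_y=float(payload["lambda_y"]),
            phi=int(payload["phi"]),
            column_means_x=np.asarray(payload["column_means_x"], dtype=float),
            column_means_y=np.asarray(payload["column_means_y"], dtype=float),
            degenerate=bool(payload["degenerate"]),
        )


def compute_covariances(x: ViewMatrix, y: ViewMatrix) -> CovarianceTriple:
    """Column-centered covariances with denominator ``n - 1``."""
    if x.sample_ids != y.sample_ids:
        raise ValueError("views must be row-aligned (identical ordered sample ids)")
    n = x.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to estimate covariances")
    mx = x.values.mean(axis=0)
    my = y.values.mean(axis=0)
    xc = x.values - mx
    yc = y.values - my
    return CovarianceTriple(
        c_xx=xc.T @ xc / (n - 1),
        c_yy=yc.T @ yc / (n - 1),
        c_xy=xc.T @ yc / (n - 1),
        n=n,
        column_means_x=mx,
        column_means_y=my,
    )


def _fix_signs(w_x: np.ndarray, w_y: np.ndarray, c_xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention.

    Each ``w_x`` column's largest-magnitude entry is made positive; each
    ``w_y`` column's sign is then chosen so the in-sample correlation of the
    paired projections (whose sign equals that of ``w_x^T C_xy w_y``) is
    non-negative.
    """
    w_x = w_x.copy()
    w_y = w_y.copy()
    for j in range(w_x.shape[1]):
        i = np.argmax(np.abs(w_x[:, j]))
        if w_x[i, j] < 0:
            w_x[:, j] = -w_x[:, j]
        num = w_x[:, j] @ c_xy @ w_y[:, j]
        if num < 0:
            w_y[:, j] = -w_y[:, j]
    return w_x, w_y


def _solve_pd(a_xx: np.ndarray, a_yy: np.ndarray, c_xy: np.ndarray, d: int):
    """Cholesky-whitening + SVD branch; raises LinAlgError if not PD."""
    lx = linalg.cholesky(a_xx, lower=True)
    ly = linalg.cholesky(a_yy, lower=True)
    k = linalg.solve_triangular(lx, c_xy, lower=True)
    k = linalg.solve_triangular(ly, k.T, lower=True).T
    u, s, vt = np.linalg.svd(k, full_matrices=False)
    w_x = linalg.solve_triangular(lx.T, u[:, :d], lower=False)
    w_y = linalg.solve_triangular(ly.T, vt[:d].T, lower=False)
    return w_x, w_y, s[:d]


def _solve_degenerate(a_xx: np.ndarray, a_yy: np.ndarray, c_xy: np.ndarray, d: int,
                      rtol: float = 1e-10):
    """Literal generalized-eigenproblem branch for singular auto-covariances.

    Forms ``pinv(C_xx) C_xy pinv(C_yy) C_yx`` and takes the real parts of its
    leading eigenvectors (sorted by eigenvalue real part).  On rank-deficient
    data the eigenvalues cluster degenerately and the recovered directions
    are unreliable — intentionally so; see the module docstring.
    """
    p_xx = np.linalg.pinv(a_xx, rcond=rtol)
    p_yy = np.linalg.pinv(a_yy, rcond=rtol)
    m = p_xx @ c_xy @ p_yy @ c_xy.T
    ev, vec = linalg.eig(m)
    order = np.argsort(-ev.real, kind="stable")[:d]
    eigenvalues = ev.real[order]
    w_x = vec.real[:, order]
    # pair w_y to w_x through the second half of the eigen equations
    w_y = p_yy @ c_xy.T @ w_x
    # normalize in the (possibly singular) covariance metric where meaningful
    for w, a in ((w_x, a_xx), (w_y, a_yy)):
        norms = np.sqrt(np.maximum(np.einsum("ij,jk,ki->i", w.T, a, w), 0.0))
        good = norms > 1e-12
        w[:, good] /= norms[good]
    s = np.sqrt(np.clip(eigenvalues, 0.0, None))
    return w_x, w_y, s


def solve_rcca(
    cov: CovarianceTriple,
    lambda_x: float = 0.0,
    lambda_y: float = 0.0,
    d: int | None = None,
) -> CanonicalModel:
    """Solve the (regularized) canonical-correlation problem.

    Returns the top-``d`` components of the generalized eigenproblem

    ``C_xy (C_yy + lambda_y I)^(-1) C_yx w_x = rho^2 (C_xx + lambda_x I) w_x``

    (and symmetrically for ``w_y``).  The reported correlations are the
    square roots of the eigenvalues of the whitened operator, sorted
    non-increasing and clamped to [0, 1].  With zero ridges and singular
    auto-covariances, pseudo-inverses are used — reproducing plain CCA's
    ill-conditioned behavior on ``n < p + q + 1`` data.
    """
    global _SOLVE_COUNT
    if lambda_x < 0 or lambda_y < 0:
        raise ValueError("ridge parameters must be >= 0")
    p = cov.c_xx.shape[0]
    q = cov.c_yy.shape[0]
    phi = min(p, q)
    if d is None:
        d = phi
    if d < 1 or d > phi:
        raise ValueError(f"d must lie in [1, min(p, q)] = [1, {phi}]")
    a_xx = cov.c_xx + lambda_x * np.eye(p)
    a_yy = cov.c_yy + lambda_y * np.eye(q)
    _SOLVE_COUNT += 1
    degenerate = False
    try:
        w_x, w_y, s = _solve_pd(a_xx, a_yy, cov.c_xy, d)
    except linalg.LinAlgError:
        degenerate = True
        w_x, w_y, s = _solve_degenerate(a_xx, a_yy, cov.c_xy, d)
    if degenerate:
        # the singular branch is numerically unreliable by construction;
        # clamp whatever it produced into [0, 1]
        s = np.clip(s, 0.0, 1.0)
    else:
        excess = s.max(initial=0.0) - 1.0
        if excess > 1e-10:
            raise linalg.LinAlgError(
                f"canonical correlation exceeds 1 by {excess:.3e}; covariances inconsistent"
            )
        s = np.clip(s, 0.0, 1.0)
    order = np.argsort(-s, kind="stable")
    w_x, w_y, s = w_x[:, order], w_y[:, order], s[order]
    w_x, w_y = _fix_signs(w_x, w_y, cov.c_xy)
    return CanonicalModel(
        w_x=w_x,
        w_y=w_y,
        correlations=s,
        lambda_x=float(lambda_x),
        lambda_y=float(lambda_y),
        phi=phi,
        column_means_x=cov.column_means_x,
        column_means_y=cov.column_means_y,
        degenerate=degenerate,
    )


def project(
    v: ViewMatrix | np.ndarray,
    model: CanonicalModel,
    view: str = "x",
    d: int | None = None,
) -> np.ndarray:
    """Project samples into the canonical space of one view.

    Columns are centered with the model's stored training means, then
    multiplied by the first ``d`` weight columns.  Works for training data
    and for held-out samples alike.
    """
    if view not in ("x", "y"):
        raise ValueError("view must be 'x' or 'y'")
    w = model.w_x if view == "x" else model.w_y
    means = model.column_means_x if view == "x" else model.column_means_y
    values = v.values if isinstance(v, ViewMatrix) else np.atleast_2d(np.asarray(v, dtype=float))
    if values.shape[1] != w.shape[0]:
        raise ValueError(
            f"feature count {values.shape[1]} does not match view '{view}' weights ({w.shape[0]})"
        )
    if d is None:
        d = model.d
    if d > model.d:
        raise ValueError(f"d={d} exceeds the model's {model.d} components")
    return (values - means) @ w[:, :d]
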