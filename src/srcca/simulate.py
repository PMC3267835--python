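"""Two-view synthetic data with known shared-latent, class-informative structure.

The generator draws ``n_latent`` shared Gaussian factors; the first factor's
mean is shifted between the two classes by ``class_shift`` standard
deviations, so all class signal lives in the shared latent space.  Each view
receives its own noisy copy of the factors (calibrated so the *population*
canonical correlation per factor equals ``latent_corr`` after the additive
feature noise), mapped into feature space through random orthonormal loading
matrices, plus i.i.d. Gaussian feature noise — the exact noise structure the
ridge-regularized CCA model assumes.

``generate_study_like`` emits three view pairs shaped like the motivating
prostate-cancer cohort: a 19 × 953 positive-valued expression view (suitable
for the quantile/log2/standardize preprocessing chain and downstream t-test
pruning to 25 features) paired with 19 × 100, 19 × 51 and 19 × 151
morphology-, architecture- and histology-sized views, with a 10/9 class
split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabelVector, MultimodalDataset, ViewMatrix

__all__ = ["SyntheticSpec", "generate_two_view", "generate_study_like"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    Defaults emulate the motivating study's conditions at the post-pruning
    scale: n=19 samples split 10/9, a 25-feature x-view against a 51-feature
    y-view, three shared latent factors with cross-view canonical correlation
    0.9, a 1.5-sd class shift on the first factor, and feature noise sd 0.2.
    """

    n: int = 19
    p: int = 25
    q: int = 51
    n_latent: int = 3
    latent_corr: float = 0.9
    class_shift: float = 1.5
    noise_sd_x: float = 0.2
    noise_sd_y: float = 0.2
    class_balance: tuple[int, int] = (10, 9)

    def __post_init__(self) -> None:
        if self.n_latent > min(self.p, self.q):
            raise ValueError("n_latent must not exceed min(p, q)")
        if not (0.0 <= self.latent_corr <= 1.0):
            raise ValueError("latent_corr must lie in [0, 1]")
        if sum(self.class_balance) != self.n:
            raise ValueError("class_balance must sum to n")
        if min(self.class_balance) < 1:
            raise ValueError("both classes need at least one sample")
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ValueError("noise scales must be >= 0")


def _attainable_corr(noise_sd_x: float, noise_sd_y: float) -> float:
    """Largest canonical correlation reachable given the feature noise."""
    return 1.0 / np.sqrt((1 + noise_sd_x**2) * (1 + noise_sd_y**2))


def generate_two_view(spec: SyntheticSpec, seed: int) -> MultimodalDataset:
    """Draw one two-view dataset; deterministic given ``seed``.

    Per latent factor k, both views observe ``sqrt(c) z_k`` plus independent
    factor noise with ``c`` chosen so that, after the i.i.d. feature noise,
    the population canonical correlation equals ``latent_corr``.  Raises if
    the requested correlation exceeds the attainable bound for the given
    noise scales.
    """
    bound = _attainable_corr(spec.noise_sd_x, spec.noise_sd_y)
    if spec.latent_corr > bound + 1e-12:
        raise ValueError(
            f"latent_corr={spec.latent_corr} is unattainable with noise "
            f"({spec.noise_sd_x}, {spec.noise_sd_y}); bound is {bound:.4f}"
        )
    rng = np.random.default_rng(seed)
    n1, n2 = spec.class_balance
    labels = np.array([0] * n1 + [1] * n2)

    z = rng.standard_normal((spec.n, spec.n_latent))
    z[:, 0] = z[:, 0] + spec.class_shift * labels

    c = min(spec.latent_corr / bound, 1.0)
    fx = np.sqrt(c) * z + np.sqrt(1 - c) * rng.standard_normal((spec.n, spec.n_latent))
    fy = np.sqrt(c) * z + np.sqrt(1 - c) * rng.standard_normal((spec.n, spec.n_latent))

    ax, _ = np.linalg.qr(rng.standard_normal((spec.p, spec.n_latent)))
    ay, _ = np.linalg.qr(rng.standard_normal((spec.q, spec.n_latent)))

    x = fx @ ax.T + spec.noise_sd_x * rng.standard_normal((spec.n, spec.p))
    y = fy @ ay.T + spec.noise_sd_y * rng.standard_normal((spec.n, spec.q))

    sample_ids = tuple(f"S{i + 1:03d}" for i in range(spec.n))
    x_view = ViewMatrix(x, sample_ids, tuple(f"xf{j + 1}" for j in range(spec.p)), "X")
    y_view = ViewMatrix(y, sample_ids, tuple(f"yf{j + 1}" for j in range(spec.q)), "Y")
    return MultimodalDataset(x_view, y_view, LabelVector(labels, sample_ids))


def generate_study_like(seed: int) -> list[MultimodalDataset]:
    """Three study-shaped view pairs sharing one expression view and latent.

    Returns pairs shaped (19×953, 19×100), (19×953, 19×51) and
    (19×953, 19×151) with class balance 10/9.  The x-view is emitted on a
    positive scale (``2**(value + 8)``) so the proteomic preprocessing chain
    (quantile normalization, log2, per-feature standardization) is exercised
    meaningfully before pruning.
    """
    n, p = 19, 953
    q_views = {"M": 100, "A": 51, "H": 151}
    n_latent = 3
    spec = SyntheticSpec()  # defaults: corr 0.9, shift 1.5, noise 0.2, 10/9
    bound = _attainable_corr(spec.noise_sd_x, spec.noise_sd_y)
    c = min(spec.latent_corr / bound, 1.0)

    rng = np.random.default_rng(seed)
    labels = np.array([0] * 10 + [1] * 9)
    z = rng.standard_normal((n, n_latent))
    z[:, 0] = z[:, 0] + spec.class_shift * labels
    fx = np.sqrt(c) * z + np.sqrt(1 - c) * rng.standard_normal((n, n_latent))
    ax, _ = np.linalg.qr(rng.standard_normal((p, n_latent)))
    x_raw = fx @ ax.T + spec.noise_sd_x * rng.standard_normal((n, p))
    x_pos = 2.0 ** (x_raw + 8.0)

    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    x_view = ViewMatrix(x_pos, sample_ids, tuple(f"prot{j + 1}" for j in range(p)), "P")
    label_vec = LabelVector(labels, sample_ids)

    pairs = []
    for tag, q in q_views.items():
        fy = np.sqrt(c) * z + np.sqrt(1 - c) * rng.standard_normal((n, n_latent))
        ay, _ = np.linalg.qr(rng.standard_normal((q, n_latent)))
        y = fy @ ay.T + spec.noise_sd_y * rng.standard_normal((n, q))
        y_view = ViewMatrix(y, sample_ids, tuple(f"{tag.lower()}f{j + 1}" for j in range(q)), tag)
        pairs.append(MultimodalDataset(x_view, y_view, label_vec))
    return pairs
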