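"""Fused low-dimensional metaspace built from a fitted canonical model.

When the paired projections ``X w_x`` and ``Y w_y`` are highly correlated,
either one can represent both modalities; the metaspace is the chosen view's
projection onto the top canonical components, optionally truncated at a
correlation threshold ``lambda0`` so that only components whose canonical
correlation reaches the threshold contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cca import CanonicalModel, project
from .data import ViewMatrix

__all__ = ["MetaspaceConfig", "Metaspace", "build_metaspace", "write_metaspace"]


@dataclass(frozen=True)
class MetaspaceConfig:
    """Requested dimensionality ``d``, correlation threshold and source view."""

    d: int
    lambda0: float = 0.0
    view: str = "x"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if not (0.0 <= self.lambda0 <= 1.0):
            raise ValueError("lambda0 must lie in [0, 1]")
        if self.view not in ("x", "y"):
            raise ValueError("view must be 'x' or 'y'")


@dataclass(frozen=True)
class Metaspace:
    """n × d' fused embedding with the correlations of the kept components."""

    embedding: np.ndarray
    kept_correlations: np.ndarray
    source_view: str
    config: MetaspaceConfig
    sample_ids: tuple[str, ...]

    @property
    def d(self) -> int:
        return self.embedding.shape[1]


def build_metaspace(
    x: ViewMatrix,
    y: ViewMatrix,
    model: CanonicalModel,
    config: MetaspaceConfig,
) -> Metaspace:
    """Project the configured view onto the kept canonical components.

    Components are taken in order of decreasing canonical correlation and
    truncated at the first one below ``lambda0`` (prefix truncation — the
    correlations are sorted, so this equals filtering), then capped at
    ``config.d``.  Raises if no component reaches the threshold.
    """
    corr = model.correlations
    below = np.flatnonzero(corr < config.lambda0)
    n_pass = int(below[0]) if below.size else corr.size
    if n_pass == 0:
        raise ValueError(
            f"no component meets lambda0={config.lambda0}; "
            f"highest available correlation is {corr.max(initial=0.0):.6f}"
        )
    d_kept = min(config.d, n_pass, model.d)
    view = x if config.view == "x" else y
    emb = project(view, model, config.view, d_kept)
    return Metaspace(
        embedding=emb,
        kept_correlations=corr[:d_kept].copy(),
        source_view=config.view,
        config=config,
        sample_ids=view.sample_ids,
    )


def write_metaspace(ms: Metaspace, path: str | Path, sep: str = ",") -> None:
    """Write the metaspace as a (sample_id, comp_1..comp_d) delimited table."""
    with open(path, "w", encoding="utf-8") as fh:
        header = ["sample_id"] + [f"comp_{j + 1}" for j in range(ms.d)]
        fh.write(sep.join(header) + "\n")
        for sid, row in zip(ms.sample_ids, ms.embedding):
            fh.write(sid + sep + sep.join(repr(float(v)) for v in row) + "\n")
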