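"""Gaussian-mixture center-bias prior.

Human observers fixate disproportionately near the image centre regardless of
content. The prior models this as a sum of N axis-aligned (diagonal
covariance) Gaussian bumps

    B(x, y) = Σᵢ αᵢ · exp(−(x−μx,i)²/(2σx,i²) − (y−μy,i)²/(2σy,i²)),

evaluated at pixel centres with 0-based coordinates (x = column, y = row).
In the full trained system the component parameters are learned; here they
are explicit, serialisable inputs so the prior is testable standalone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


import numpy as np

#: Default number of mixture components.
DEFAULT_N_COMPONENTS = 16


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: amplitude, mean (px) and per-axis scale (px)."""

    alpha: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be nonnegative, got {self.alpha}")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("component sigmas must be positive")


@dataclass(frozen=True)
class GaussianPrior:
    """A centre-bias prior as a list of Gaussian components."""

    components: tuple[GaussianComponent, ...]

    def __post_init__(self) -> None:
        comps = tuple(
            c if isinstance(c, GaussianComponent) else GaussianComponent(**c)
            for c in self.components
        )
        if len(comps) < 1:
            raise ValueError("prior needs at least one Gaussian component")
        object.__setattr__(self, "components", comps)

    @property
    def n(self) -> int:
        return len(self.components)

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialise as a JSON list of component dicts."""
        payload = json.dumps([vars(c) for c in self.components], indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "GaussianPrior":
        text = Path(source).read_text() if Path(str(source)).is_file() else str(source)
        return cls(tuple(GaussianComponent(**d) for d in json.loads(text)))


def build_center_bias(prior: GaussianPrior, height: int, width: int) -> np.ndarray:
    """Evaluate the mixture on an ``height×width`` pixel grid.

    Returns a nonnegative ``H×W`` raster bounded above by the sum of the
    component amplitudes.
    """
    if height < 1 or width < 1:
        raise ValueError("grid dimensions must be at least 1×1")
    y = np.arange(height, dtype=np.float64)[:, None]
    x = np.arange(width, dtype=np.float64)[None, :]
    bias = np.zeros((height, width), dtype=np.float64)
    for c in prior.components:
        bias += c.alpha * np.exp(
            -((x - c.mu_x) ** 2) / (2.0 * c.sigma_x**2)
            - ((y - c.mu_y) ** 2) / (2.0 * c.sigma_y**2)
        )
    return bias


def central_prior(height: int, width: int, sigma_frac: float = 0.25) -> GaussianPrior:
    """A single isotropic Gaussian at the grid centre (scale as a fraction of
    the smaller image side). Convenience constructor for tests and baselines."""
    sigma = sigma_frac * min(height, width)
    return GaussianPrior(
        (
            GaussianComponent(
                alpha=1.0,
                mu_x=(width - 1) / 2.0,
                mu_y=(height - 1) / 2.0,
                sigma_x=sigma,
                sigma_y=sigma,
            ),
        )
    )


def sample_default_prior(
    n: int, height: int, width: int, seed: int
) -> GaussianPrior:
    """Draw a seeded random prior standing in for learned parameters.

    Component means fall in the central third of the grid, per-axis scales in
    ``[0.1, 0.4]·min(H, W)`` and amplitudes in ``(0, 1]``; the draw is
    deterministic for a given seed.
    """
    if n < 1:
        raise ValueError(f"need at least one component, got n={n}")
    rng = np.random.default_rng(seed)
    lo_x, hi_x = width / 3.0, 2.0 * width / 3.0
    lo_y, hi_y = height / 3.0, 2.0 * height / 3.0
    s_lo, s_hi = 0.1 * min(height, width), 0.4 * min(height, width)
    comps = tuple(
        GaussianComponent(
            alpha=1.0 - rng.uniform(0.0, 1.0),  # in (0, 1]
            mu_x=rng.uniform(lo_x, hi_x),
            mu_y=rng.uniform(lo_y, hi_y),
            sigma_x=rng.uniform(s_lo, s_hi),
            sigma_y=rng.uniform(s_lo, s_hi),
        )
        for _ in range(n)
    )
    return GaussianPrior(comps)
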