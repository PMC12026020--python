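"""Multi-scale centre-surround bottom-up saliency baseline.

A deterministic difference-of-Gaussians detector in the Itti–Koch tradition:
for an intensity channel and two colour-opponent channels (R−G and
B−(R+G)/2), the absolute centre-surround response |Gσc∗X − Gσs∗X| is
computed at several (σc, σs) scale pairs, each map is normalised to unit
range, and all maps are averaged. It stands in for external bottom-up models
in the original-vs-retina comparison protocol, which only requires a
deterministic bottom-up map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .retina import LuminanceImage, gaussian_lowpass

#: Default (centre, surround) Gaussian scale pairs in pixels.
DEFAULT_SCALES: tuple[tuple[float, float], ...] = ((1.0, 4.0), (2.0, 8.0), (4.0, 16.0))

NORM_STATES = ("raw", "unit_range", "unit_mass", "zscore")


@dataclass(frozen=True)
class SaliencyMap:
    """A nonnegative saliency raster with an explicit normalisation state."""

    values: np.ndarray
    norm_state: str = "raw"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError(f"saliency map must be H×W, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("saliency map contains non-finite values")
        if self.norm_state not in NORM_STATES:
            raise ValueError(
                f"norm_state must be one of {NORM_STATES}, got {self.norm_state!r}"
            )
        if self.norm_state != "zscore" and values.min() < 0:
            raise ValueError("saliency map must be nonnegative")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_unit_range(self) -> "SaliencyMap":
        """Affinely rescale to [0, 1]; a constant map maps to all zeros."""
        v = self.values
        span = v.max() - v.min()
        if span == 0.0:
            return SaliencyMap(np.zeros_like(v), "raw")
        return SaliencyMap((v - v.min()) / span, "unit_range")

    def to_unit_mass(self) -> "SaliencyMap":
        """Normalise to sum 1 (a probability distribution over pixels)."""
        v = self.values - min(self.values.min(), 0.0)
        total = v.sum()
        if total == 0.0:
            v = np.full_like(v, 1.0 / v.size)
        else:
            v = v / total
        return SaliencyMap(v, "unit_mass")

    def to_zscore(self) -> "SaliencyMap":
        """Standardise to mean 0, population std 1; constant maps to zeros."""
        v = self.values
        std = v.std()
        if std == 0.0:
            return SaliencyMap(np.zeros_like(v), "zscore")
        return SaliencyMap((v - v.mean()) / std, "zscore")


def _opponent_channels(img: LuminanceImage) -> list[np.ndarray]:
    """Intensity plus (for colour input) R−G and B−(R+G)/2 opponents."""
    channels = [img.luminance()]
    if img.is_color:
        r, g, b = (img.values[..., i] for i in range(3))
        channels.append(r - g)
        channels.append(b - (r + g) / 2.0)
    return channels


def center_surround_saliency(
    img: LuminanceImage,
    scales: Sequence[tuple[float, float]] = DEFAULT_SCALES,
    smooth_sigma: float | None = None,
) -> SaliencyMap:
    """Multi-scale centre-surround saliency of an image.

    Each per-channel, per-scale map ``|Gσc∗X − Gσs∗X|`` is normalised to unit
    range before averaging so no single channel dominates. The averaged map
    is smoothed with a final Gaussian (default scale ``min(H, W)/32`` px, the
    customary output blur of fixation-prediction models, which fills in the
    contour rings the rectified band-pass leaves at object centres) and
    normalised to unit range. A featureless (uniform) image yields an
    all-zero map in the ``raw`` state. Pass ``smooth_sigma=0`` to disable
    the output blur.
    """
    scales = tuple(scales)
    if len(scales) == 0:
        raise ValueError("need at least one (center, surround) scale pair")
    for sc, ss in scales:
        if not 0 < sc < ss:
            raise ValueError(
                f"each scale pair needs 0 < center < surround, got ({sc}, {ss})"
            )
    if smooth_sigma is None:
        smooth_sigma = min(img.values.shape[:2]) / 32.0

    maps = []
    for channel in _opponent_channels(img):
        for sc, ss in scales:
            response = np.abs(
                gaussian_lowpass(channel, sc) - gaussian_lowpass(channel, ss)
            )
            maps.append(SaliencyMap(response).to_unit_range().values)
    combined = np.mean(maps, axis=0)
    if smooth_sigma > 0:
        combined = gaussian_lowpass(combined, smooth_sigma)
    return SaliencyMap(combined).to_unit_range()


def apply_prior(smap: SaliencyMap, bias: np.ndarray) -> SaliencyMap:
    """Modulate a saliency map by a spatial prior (elementwise product).

    The product is renormalised to unit range, mirroring how a centre-bias
    map multiplies a feature map before the final normalisation.
    """
    bias = np.asarray(bias, dtype=np.float64)
    if bias.shape != smap.values.shape:
        raise ValueError(
            f"prior shape {bias.shape} does not match map shape {smap.values.shape}"
        )
    if bias.min() < 0:
        raise ValueError("prior must be nonnegative")
    return SaliencyMap(smap.values * bias).to_unit_range()
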