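"""Parvocellular retina-imitation filter.

The filter chains four biologically motivated stages:

1. **Photoreceptor adaptation** — a Michaelis–Menten gain control driven by
   the local luminance of each photoreceptor's neighbourhood, which compresses
   dynamic range and recovers detail in both dark and bright image regions.
2. **OPL band-pass** — the outer plexiform layer, modelled (in its static,
   zero-temporal-frequency form) as the difference between the photoreceptor
   network low-pass and the horizontal-cell network low-pass, i.e. a
   centre-surround difference of Gaussians that rejects the DC component.
3. **Bipolar ON/OFF segregation** — half-wave rectification of the signed OPL
   signal into disjoint ON (positive) and OFF (negative) channels.
4. **IPL ganglion compression** — a second Michaelis–Menten stage applied to
   each bipolar channel independently, enhancing local contour information.

All spatial filters are unit-mass Gaussians with reflective boundary handling
and kernels truncated at 4 standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

#: Gaussian kernels are truncated at this many standard deviations.
TRUNCATE = 4.0

#: Rec. 601 luma weights used to reduce colour input to a luminance channel.
REC601 = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class LuminanceImage:
    """A validated raster of received luminances in ``[0, vmax]``.

    Parameters
    ----------
    values
        ``H×W`` (grayscale) or ``H×W×3`` (colour) array of finite,
        nonnegative luminances.
    vmax
        The luminance ceiling. Conventionally 255 for 8-bit input and
        1.0 for float input.
    """

    values: np.ndarray
    vmax: float = 255.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim not in (2, 3) or (values.ndim == 3 and values.shape[2] != 3):
            raise ValueError(
                f"expected H×W or H×W×3 raster, got shape {values.shape}"
            )
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("image must have at least one row and one column")
        if not (np.isfinite(self.vmax) and self.vmax > 0):
            raise ValueError(f"vmax must be positive and finite, got {self.vmax}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite pixels")
        if values.min() < 0 or values.max() > self.vmax:
            raise ValueError(
                f"pixel values must lie in [0, {self.vmax}]; "
                f"got range [{values.min()}, {values.max()}]"
            )
        object.__setattr__(self, "values", values)

    @property
    def is_color(self) -> bool:
        return self.values.ndim == 3

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def luminance(self) -> np.ndarray:
        """Rec. 601 luminance channel (identity for grayscale input)."""
        if self.is_color:
            return self.values @ REC601
        return self.values


@dataclass(frozen=True)
class RetinaParams:
    """Constants of the Parvocellular pipeline.

    Parameters
    ----------
    v0_photo
        Photoreceptor adaptation strength ``V0`` in ``(0, 1)``; larger values
        couple the compression point more tightly to the local luminance.
    v0_ganglion
        Michaelis–Menten strength of the IPL ganglion stage, in ``(0, 1)``.
    sigma_lum
        Gaussian scale (px) of the neighbourhood over which the local
        luminance ``Lp`` is pooled.
    sigma_ph
        Low-pass scale (px) of the photoreceptor network (OPL centre).
    sigma_h
        Low-pass scale (px) of the horizontal-cell network (OPL surround);
        must exceed ``sigma_ph``.
    vmax
        Luminance ceiling the parameters assume. ``None`` inherits the
        ceiling of the image being processed.
    literal_adaptation
        If True, use the literal reading of the adaptation formula
        ``Ap = Rp/(Rp+Rp0)·Vmax + Rp0`` (clipped to the ceiling, which it
        otherwise exceeds on bright input) instead of the range-preserving
        ``Ap = Rp/(Rp+Rp0)·(Vmax+Rp0)``. Provided for comparison only.
    """

    v0_photo: float = 0.90
    v0_ganglion: float = 0.90
    sigma_lum: float = 8.0
    sigma_ph: float = 1.0
    sigma_h: float = 4.0
    vmax: Optional[float] = None
    literal_adaptation: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.v0_photo < 1.0:
            raise ValueError(f"v0_photo must be in (0, 1), got {self.v0_photo}")
        if not 0.0 < self.v0_ganglion < 1.0:
            raise ValueError(f"v0_ganglion must be in (0, 1), got {self.v0_ganglion}")
        if not self.sigma_lum > 0:
            raise ValueError(f"sigma_lum must be positive, got {self.sigma_lum}")
        if not 0 < self.sigma_ph < self.sigma_h:
            raise ValueError(
                "filter scales must satisfy 0 < sigma_ph < sigma_h, "
                f"got sigma_ph={self.sigma_ph}, sigma_h={self.sigma_h}"
            )
        if self.vmax is not None and not self.vmax > 0:
            raise ValueError(f"vmax must be positive, got {self.vmax}")

    def resolve_vmax(self, img: LuminanceImage) -> float:
        return float(self.vmax) if self.vmax is not None else img.vmax


@dataclass(frozen=True)
class ParvoResponse:
    """Staged outputs of the Parvocellular pipeline."""

    adapted: LuminanceImage
    opl: np.ndarray
    bip_on: np.ndarray
    bip_off: np.ndarray
    parvo: LuminanceImage


def _kernel_radius(sigma: float) -> int:
    return int(TRUNCATE * sigma + 0.5)


def gaussian_lowpass(arr: np.ndarray, sigma: float) -> np.ndarray:
    """Unit-mass (mean-preserving) Gaussian low-pass with reflective padding.

    Colour input (``H×W×3``) is filtered per channel. Kernels whose truncated
    radius falls below one pixel are rejected: such a "filter" degenerates to
    the identity and signals a misconfigured scale.
    """
    if _kernel_radius(sigma) < 1:
        raise ValueError(
            f"sigma={sigma} truncates to a kernel radius below 1 px; "
            "increase the scale"
        )
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:
        return ndimage.gaussian_filter(
            arr, sigma, axes=(0, 1), mode="reflect", truncate=TRUNCATE
        )
    return ndimage.gaussian_filter(arr, sigma, mode="reflect", truncate=TRUNCATE)


def local_luminance(img: LuminanceImage, sigma_lum: float) -> np.ndarray:
    """Local luminance ``Lp``: Gaussian pooling of the luminance channel.

    Colour input is first reduced to a single Rec. 601 luminance channel, so
    one shared neighbourhood luminance drives the adaptation of all three
    colour channels. The unit-normalised kernel makes the pooling
    mean-preserving, hence the output stays within ``[0, vmax]``.
    """
    if not sigma_lum > 0:
        raise ValueError(f"sigma_lum must be positive, got {sigma_lum}")
    return gaussian_lowpass(img.luminance(), sigma_lum)


def michaelis_menten(
    x: np.ndarray, lp: np.ndarray, v0: float, vmax: float
) -> np.ndarray:
    """Luminance-adapted Michaelis–Menten compression.

    Computes ``x / (x + R0) · (Vmax + R0)`` with the half-saturation constant
    ``R0 = V0·Lp + Vmax·(1 − V0)`` set by the local luminance ``Lp``. For
    ``V0 < 1`` the constant satisfies ``R0 ≥ Vmax(1 − V0) > 0``, so the
    denominator never vanishes; the map sends ``[0, Vmax]`` into itself and is
    strictly increasing in ``x`` at fixed ``Lp``.
    """
    r0 = v0 * lp + vmax * (1.0 - v0)
    return x / (x + r0) * (vmax + r0)


def photoreceptor_adapt(
    img: LuminanceImage, lp: np.ndarray, params: RetinaParams
) -> LuminanceImage:
    """Photoreceptor stage: adapt each pixel to its neighbourhood luminance.

    Dark neighbourhoods (small ``Lp``) lower the half-saturation constant and
    boost local gain; bright neighbourhoods compress it, so detail survives at
    both ends of the luminance range. The same shared ``Lp`` drives all three
    channels of colour input, preserving colour contrast.
    """
    lp = np.asarray(lp, dtype=np.float64)
    if lp.shape != img.values.shape[:2]:
        raise ValueError(
            f"local luminance shape {lp.shape} does not match image "
            f"{img.values.shape[:2]}"
        )
    vmax = params.resolve_vmax(img)
    lp_b = lp[..., None] if img.is_color else lp
    if params.literal_adaptation:
        r0 = params.v0_photo * lp_b + vmax * (1.0 - params.v0_photo)
        adapted = np.clip(img.values / (img.values + r0) * vmax + r0, 0.0, vmax)
    else:
        adapted = michaelis_menten(img.values, lp_b, params.v0_photo, vmax)
    return LuminanceImage(adapted, vmax)


def opl_bandpass(adapted: LuminanceImage, params: RetinaParams) -> np.ndarray:
    """OPL stage: centre-surround band-pass (static transfer ``Fph·(1−Fh)``).

    Realised as ``Gph∗X − Gh∗(Gph∗X)``: the photoreceptor-network low-pass
    minus its horizontal-cell smoothing. Both kernels have unit mass, so any
    constant image maps to exactly zero (DC rejection). Colour channels are
    filtered independently. The output is signed and zero-mean band-pass.
    """
    centre = gaussian_lowpass(adapted.values, params.sigma_ph)
    surround = gaussian_lowpass(centre, params.sigma_h)
    return centre - surround


def bipolar_split(opl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bipolar stage: half-wave rectify the OPL signal into ON/OFF channels.

    ``bip_on − bip_off`` reconstructs the OPL signal exactly and the two
    channels have disjoint support (their elementwise product is zero).
    """
    opl = np.asarray(opl, dtype=np.float64)
    if not np.all(np.isfinite(opl)):
        raise ValueError("OPL signal contains non-finite values")
    return np.maximum(opl, 0.0), np.maximum(-opl, 0.0)


def ganglion_compress(
    channel: np.ndarray,
    params: RetinaParams,
    vmax: float = 255.0,
) -> np.ndarray:
    """IPL ganglion stage: Michaelis–Menten contour enhancement of a channel.

    The nonnegative bipolar channel is rescaled to ``[0, vmax]`` and
    compressed with its own Gaussian-pooled local mean (scale ``sigma_lum``)
    acting as the adapting luminance, which locally amplifies weak contours.
    A channel with no signal — identically zero, or nothing beyond the
    floating-point residue the band-pass leaves on constant input — is
    returned unchanged rather than rescaled into spurious full-range output.
    """
    channel = np.asarray(channel, dtype=np.float64)
    if channel.min() < 0:
        raise ValueError("ganglion input channel must be nonnegative")
    peak = channel.max()
    if peak <= 1e-12 * vmax:
        return channel.copy()
    scaled = channel * (vmax / peak)
    lp = gaussian_lowpass(scaled, params.sigma_lum)
    return michaelis_menten(scaled, lp, params.v0_ganglion, vmax)


def parvo_process(img: LuminanceImage, params: RetinaParams | None = None) -> ParvoResponse:
    """Run the full Parvocellular pipeline on an image.

    Chains local-luminance pooling, photoreceptor adaptation, OPL band-pass,
    bipolar ON/OFF segregation and per-channel ganglion compression, then
    recombines the compressed ON and OFF channels into a display-range output:
    the signed difference ``C(ON) − C(OFF)`` is affinely mapped to
    ``[0, vmax]`` with its zero level at ``vmax/2``. The whole pipeline is
    deterministic.
    """
    if params is None:
        params = RetinaParams()
    vmax = params.resolve_vmax(img)
    if params.vmax is not None and img.vmax != params.vmax:
        img = LuminanceImage(np.clip(img.values, 0.0, vmax), vmax)

    lp = local_luminance(img, params.sigma_lum)
    adapted = photoreceptor_adapt(img, lp, params)
    opl = opl_bandpass(adapted, params)
    bip_on, bip_off = bipolar_split(opl)

    if opl.ndim == 3:
        comp_on = np.stack(
            [ganglion_compress(bip_on[..., c], params, vmax) for c in range(3)],
            axis=-1,
        )
        comp_off = np.stack(
            [ganglion_compress(bip_off[..., c], params, vmax) for c in range(3)],
            axis=-1,
        )
    else:
        comp_on = ganglion_compress(bip_on, params, vmax)
        comp_off = ganglion_compress(bip_off, params, vmax)

    diff = comp_on - comp_off
    span = np.abs(diff).max()
    # below the float residue of the band-pass there is no signal to stretch
    if span <= 1e-9 * vmax:
        parvo_values = np.full_like(diff, vmax / 2.0)
    else:
        parvo_values = np.clip(vmax / 2.0 + diff * (vmax / (2.0 * span)), 0.0, vmax)

    return ParvoResponse(
        adapted=adapted,
        opl=opl,
        bip_on=bip_on,
        bip_off=bip_off,
        parvo=LuminanceImage(parvo_values, vmax),
    )
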