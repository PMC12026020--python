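# Methods

## The Parvocellular retina filter

The filter emulates the static (Parvocellular) pathway of the primate
retina as a chain of four stages, each operating on rasters normalised to a
luminance ceiling `Vmax` (255 for 8-bit input, 1.0 for float input).

**Photoreceptor adaptation.** Each pixel's received luminance `R` is
compressed with a Michaelis–Menten gain control whose half-saturation point
tracks the local neighbourhood luminance `L` (a Gaussian pooling at scale
`sigma_lum`, default 8 px):

    R0 = V0·L + Vmax·(1 − V0),          V0 = 0.90
    A  = R / (R + R0) · (Vmax + R0)

With `V0 < 1` the constant satisfies `R0 ≥ Vmax(1 − V0) > 0`, so the map is
well defined, sends `[0, Vmax]` into itself, and is strictly increasing in
`R` at fixed `L`. Dark neighbourhoods lower `R0` and hence raise local gain;
bright ones compress. A widely reproduced typographical variant of this
formula reads `A = R/(R+R0)·Vmax + R0`; that form exceeds the ceiling on
bright uniform input (at `R = L = Vmax` it yields `3/2·Vmax`) and is
therefore not used by default, but it is available for comparison via
`RetinaParams(literal_adaptation=True)` (clipped to the ceiling). For colour
input one shared `L`, pooled from the Rec. 601 luminance channel, drives all
three channels, which preserves colour contrast.

**OPL band-pass.** The outer plexiform layer couples the photoreceptor
network (a low-pass, scale `sigma_ph`) with the inhibitory horizontal-cell
network (a broader low-pass, scale `sigma_h > sigma_ph`). Its transfer
function is `F_opl = F_ph · (1 − F_h)`; we realise the static
(zero-temporal-frequency) case as

    opl = G_ph ∗ A  −  G_h ∗ (G_ph ∗ A)

with unit-mass Gaussian kernels, so any constant image maps to exactly zero
(DC rejection). The neither-network scale is constrained by physiology only
qualitatively; defaults `sigma_ph = 1`, `sigma_h = 4` px are the smallest
pair giving a clear centre-surround band-pass, and all scales are
YAML-configurable.

**Bipolar ON/OFF segregation.** The signed band-pass signal is half-wave
rectified into `bip_on = max(opl, 0)` and `bip_off = max(−opl, 0)`. The two
channels have disjoint support and reconstruct `opl` exactly.

**IPL ganglion compression.** Each bipolar channel is rescaled to
`[0, Vmax]` and passed through the same Michaelis–Menten form with its own
strength `v0_ganglion = 0.90` and its own Gaussian-pooled local mean as the
adapting signal. This saturates strong contours and amplifies weak ones —
local contour enhancement. A channel whose maximum is below `1e-12·Vmax`
(i.e. nothing beyond the floating-point residue the band-pass leaves on
constant input) is passed through unchanged; rescaling such a channel would
stretch numerical dust to full range.

**Recombination.** The compressed channels are recombined as
`d = C(on) − C(off)` and affinely mapped to display range with the zero
level at mid-grey: `parvo = clip(Vmax/2 + d·Vmax/(2·max|d|))`. The max is
taken over all colour channels jointly so relative colour contrast
survives. If `max|d| ≤ 1e-9·Vmax` the output is uniform mid-grey. The whole
pipeline is deterministic and bit-stable.

All Gaussian filtering uses reflective boundary handling and kernels
truncated at 4σ; scales that truncate to a kernel radius below one pixel
are rejected as misconfiguration. 1×1 images are legal; every filter then
degenerates to the identity (and the band-pass to zero).

## Centre-bias prior

The spatial prior is a sum of `N` axis-aligned Gaussians (default `N = 16`)
evaluated at 0-based pixel centres (`x` = column, `y` = row):

    B(x, y) = Σᵢ αᵢ exp(−(x−μx,i)²/(2σx,i²) − (y−μy,i)²/(2σy,i²))

In a trained saliency network these parameters are learned; here they are
explicit inputs (JSON-serialisable) so the prior is testable standalone,
with a seeded sampler (`sample_default_prior`) standing in for learned
values: means in the central third, scales in `[0.1, 0.4]·min(H, W)`,
amplitudes in `(0, 1]`.

## Centre-surround baseline detector

The harness needs a deterministic bottom-up saliency method to compare
original against retina-processed inputs; we use a difference-of-Gaussians
detector in the Itti–Koch tradition. For the intensity channel and two
colour opponents (R−G, B−(R+G)/2), `|G_c ∗ X − G_s ∗ X|` is computed at
scale pairs (1, 4), (2, 8), (4, 16) px, each map normalised to unit range,
averaged, smoothed with a final Gaussian of scale `min(H, W)/32`, and
normalised to unit range. The output smoothing is the customary final blur
of fixation-prediction models; mechanically it matters here because the
rectified band-pass leaves ring-shaped responses with a dip exactly at blob
centres, where fixation density peaks. It is applied identically to both
variants and can be disabled (`smooth_sigma=0`).

## Evaluation metrics

Eight standard fixation-prediction metrics. Conventions the literature
leaves open are fixed as follows (all configurable):

- **KL divergence**: direction `KL(ground-truth density ‖ prediction)`,
  natural log; `1e-12` is added to the prediction before renormalisation.
- **EMD**: exact optimal transport (Euclidean ground distance) after a
  mass-preserving block-sum downsampling to at most `grid×grid` cells,
  reported in downsampled-cell units. The LP is solved with HiGHS via
  `scipy.optimize.linprog` on the sparse marginal constraints, with one
  (linearly dependent) marginal row dropped for numerical stability. The
  standalone default grid is 32 (≈40 s for two dense 32×32 distributions on
  one core); the comparison harness uses 16 so a 20-scene protocol stays
  interactive.
- **NSS**: population (not sample) standard deviation in the z-scoring.
- **AUC-Judd**: thresholds at the fixations' saliency values; TP rate over
  fixations, FP rate over all non-fixated pixels, trapezoidal area through
  (0, 0) and (1, 1). With few fixations this classical construction is
  biased high relative to the pairwise-comparison (Mann–Whitney) area by
  roughly `1/(2·n_fix)`; the oracle tests therefore use enough fixations
  for the two to converge.
- **AUC-Borji**: negatives are uniformly random non-fixated pixels
  (`n_neg` = number of fixations by default), 100 splits, seeded; each
  split's ROC uses thresholds at every observed value, giving ties half
  credit.
- **Shuffled AUC**: as Borji, but negatives are drawn from fixation
  locations pooled from *other* images, which neutralises centre bias.
- **Degenerate (constant) maps** score their chance level by convention:
  CC 0, NSS 0, AUCs 0.5.

## Synthetic data generator

The generator emulates the statistical structure of free-viewing data on
low-light natural scenes, not their appearance.

- **Scenes** follow a reflectance × illumination model: background
  reflectance `1 − target_contrast`, Gaussian-profile target blobs
  (scale `min(H, W)/24`) rising to reflectance 1, multiplied by an
  illumination field (uniform, linear gradient, or a radial dark-corner
  ramp from 0.15 to 0.90 of the ceiling), plus additive Gaussian sensor
  noise (`noise_sd = 0.02`). Every target therefore has the same Weber
  contrast while its absolute contrast scales with local illumination —
  dark-region targets are nearly invisible to a detector operating on raw
  intensities, which is precisely the regime luminance adaptation
  addresses. The dark-corner floor of 0.15 keeps the darkest region above
  the noise floor: recoverable detail must exist for a test of detail
  recovery to be meaningful. At least one target is always placed in the
  darkest third; placement is rejection-sampled to avoid overlap
  (centres ≥ 6 blob-scales apart, 3 from borders).
- **Fixations** are drawn categorically over the pixel grid (no sub-pixel
  positions, keeping metric oracles exact) from a mixture of a
  target-anchored density (the blurred target mask) and a central Gaussian
  prior with weight 0.3, emulating the human centre bias. Default 80
  fixations per scene, the order of real per-image fixation counts.
- **Ground-truth densities** are built exactly as real ones: a delta per
  fixation, Gaussian blur with a fixed kernel (default `width/16`,
  standing in for an eye-tracker-noise kernel), renormalised to unit mass.

Default scene size is 96×128 with 3 targets; 20 scenes score in ~20 s on
one core, which sets the problem size used by the comparison protocol and
the acceptance script. What passing tests on these scenes shows is that the
retina filter improves contrast-based saliency detection *when salient
content hides in poorly illuminated regions and ground truth knows about
it*; it does not show anything about semantic saliency (faces, text),
photographic clutter, or dataset-specific centre-bias strength.

## Comparison protocol

For each scene the baseline detector runs on the original image and on
`parvo_process(image).parvo`; both maps are scored with all eight metrics,
shuffled-AUC negatives pooled from the other scenes' fixations (with a
single scene the metric is reported missing). A (metric, dataset-mean)
cell counts as improved when the retina variant is strictly better in the
metric's own direction — ties are not improvements, matching how
comparison tables bold only strictly better scores. The improvement
fraction is the share of improved cells; per-image scores are also
retained and the CSV round-trips losslessly.

## Known limitations

- The temporal dimension of the OPL transfer function (and the whole
  Magnocellular/motion pathway) is not modelled; the filter is static.
- The EMD at the standalone grid default is exact but slow (linear program
  with ~10⁶ variables); use a coarser grid for batch work.
- The centre-bias prior is an input, not learned; nothing in the package
  fits its parameters to data.
- The focal loss extends to soft (blurred-density) targets by linear
  interpolation of the two binary terms per pixel, `t·FL(p,1) +
  (1−t)·FL(p,0)` — the natural reduction, but one of several possible.
- The improvement fraction is a stochastic quantity of the generated
  scenes; across seeds it typically lands at 75–90% with seven of the
  eight metric cells improving (shuffled AUC is the usual holdout, as
  expected for a protocol whose scenes share one centre-bias strength).
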