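# Methods

This note records the models, conventions and numerical choices behind
`melanotherm`, and what the synthetic-data results do and do not establish
about real photographs.

## Lightness standardization

Illumination intensity acts multiplicatively on recorded lightness, so the
correction is a gain, not an offset: every pixel's HLS lightness is
multiplied by `g = L̄_ref(baseline) / L̄_ref(frame)`, where `L̄_ref` is the
mean lightness of the in-frame grayscale standard and the baseline is the
individual's first frame. Corrected lightness is clipped to [0, 1] and the
number of clipped pixels is logged — clipping is information loss and a
large count is a QC signal. The transform is idempotent (after one pass the
reference already matches, so `g = 1`), and for a frame whose lightness is a
global multiple of another's the two standardized outputs agree pixelwise
(the gains cancel the scale exactly, absent clipping).

Standardization is within-individual only. A baseline fitted on one animal
refuses to transform another's frames unless explicitly overridden, because
the gain anchors all frames to an arbitrary per-individual exposure;
luminance is therefore comparable across time within an animal, never across
animals.

Conversions use the hexcone HLS model (`L = (max+min)/2`,
`S = (max−min)/(1−|2L−1|)`, hue by sector) implemented in double precision;
the round-trip error is below 1e-9 (tested against stdlib `colorsys`).
Luminance is the weighted channel sum with Rec.601 weights
(0.299, 0.587, 0.114) by default; the weights are a parameter, so Rec.709 is
a one-line change.

## Foreground and segmentation

Foreground = ROI ∩ {lightness below a background threshold, default 0.92},
suiting a pale (white-Teflon-like) arena. For standardized frames the
threshold is additionally applied to the pre-standardization lightness
`L/g`: a background that overexposed at capture clips to pure white, and a
gain below one would otherwise drag it under the threshold even though the
pixel carries no recoverable information. Without this rule, frames shot
under >~5% excess illumination flip the two k-means clusters from
spot-vs-base to animal-vs-background.

Clustering is k-means on raw RGB triples of foreground pixels: k-means++
seeding (first center uniform, subsequent centers with probability
proportional to squared distance to the nearest chosen center), Lloyd
iterations with convergence when the maximum center movement falls below
`tol = 1e-4` (RGB units) or after 100 sweeps, an emptied cluster re-seeded
at the point farthest from its center, and a single initialization by
default (`n_init` is configurable). Inertia is asserted non-increasing at
every sweep. "Hierarchical" clustering is bisecting recursion: each cluster
is re-split to `max_depth` levels; the default depth 1 with k = 2 is one
binary split, deliberately conservative so melanin is not overestimated by
fragmenting the light class.

The melanistic class is the cluster whose center has the lower luminance.
If the darkest and lightest centers differ by less than 10/255 luminance
units the frame has no separable pattern: it is flagged `low_contrast` and
scored proportion 0 — the correct reading for near-patternless animals, and
the tie-break when both centers coincide. Shadow-induced misclustering is
handled the way a field workflow handles it: a QC overlay plus an editable
accept/reject flag file per image; rejected frames are excluded downstream
and counted, with no extra shadow modelling.

## Quantification conventions

- Melanistic proportion = melanistic pixels / dorsal foreground pixels, per
  image; per-individual summaries use the mean, the sample SD (ddof = 1) and
  the natural log of the mean (flagged undefined at 0). Natural log is used
  for every log transform.
- Body temperature = mean of the two eye readings; if exactly one eye is
  unusable the snout reading substitutes with a warning (the eye average and
  snout track each other closely); a record with neither is excluded.
- Datalogger readings of exactly 0 °C are dead-battery artifacts: set
  invalid and counted; a timepoint with any invalid logger reading has no
  valid three-logger average.
- The 15 timepoints map to five blocks of three (start plateau, cooling
  transition, cold plateau, heating transition, end plateau); the mapping is
  a configurable schedule since block boundaries are experiment metadata.
- Cooling rate = block-1 mean − block-3 mean; heating rate = block-5 mean −
  block-3 mean; both positive magnitudes under the intended 25 → 15 → 25 °C
  profile, and start–end change = heating − cooling by construction. Logs
  are taken only of positive rates; non-positive rates are flagged and the
  individual excluded from log-rate models with a warning.

## Statistical battery

Paired block contrasts gate on Shapiro–Wilk normality of the differences at
α = 0.05: normal → paired *t* (`t = d̄/(s_d/√n)`, df = n−1), otherwise
Wilcoxon signed-rank with the conventions of the common R implementation:
V = sum of ranks of positive differences, zero differences dropped, midranks
for tied magnitudes, exact two-sided p from the full 2ⁿ null distribution
for tie-free n ≤ 25, else a normal approximation with continuity and tie
corrections. All tests are two-sided and no multiple-testing correction is
applied (none is appropriate to the mirrored design). Correlation output
always reports r, r² and (for models) adjusted R² as distinct quantities;
adjusted R² can legitimately be negative and is reported as such.

OLS models go through statsmodels with Wilkinson formulas; sex is a
two-level factor with treatment contrasts; the luminance-change models fit
main effects plus interaction (`Δlum ~ log p × ΔT`), separately per segment
class (melanistic / non-melanistic) and block pair (1–3, 3–5, 1–5). Every
fit carries hat-matrix leverages and Cook's distances
`D_i = e_i² h_ii / (p s² (1−h_ii)²)` (equal to the leave-one-out refit
definition; verified to 1e-10); individuals with D > 1 are flagged. A
numerically perfect fit has no influence to measure and returns all-zero D
rather than 0/0. Degenerate sub-analyses inside the full battery (constant
humidity, identical paired luminances, a constant temperature-change
column) are recorded as undefined rather than aborting the whole report.

## Synthetic study conditions

The image generator renders an ellipse-chain body (head/trunk/tail) on a
pale background (level 0.97) with a gray reference patch (0.5) outside the
ROI, yellowish base skin (0.80, 0.70, 0.30), near-black spots
(0.10, 0.10, 0.08), per-pixel Gaussian noise (σ = 0.01), and a smooth
multiplicative shading gradient across the body (amplitude 0.05) — shadows
on the animal are the documented failure mode of unsupervised clustering,
while the arena itself stays clean. Spots are dart-thrown inside the body
(overlap allowed) until coverage reaches the target, with the last spot
shrunk by bisection so the realized coverage lands within ±0.01. A series
fixes the spot layout and re-poses the animal by affine jitter (rotation
±12°, translation ±8 px, shear ±0.08); frame 1 is the baseline reference
shot at gain 1.0 — the setup shot a photographer exposes correctly — and
later frames draw gains from U[0.7, 1.3].

The thermal generator follows block targets (25, 20, 15, 20, 25) °C with a
per-individual offset (SD 0.2), per-timepoint latent noise (SD 0.3), per-eye
reading noise (SD 0.1), substrate tracking the schedule with a +0.3 °C
offset (IR substrate reads slightly warm), three in-terrarium loggers with
characteristic offsets, an outside (atmospheric) logger, and humidity
uncorrelated with temperature (41 ± 3%). Individual heating magnitudes vary
(SD 0.8 °C), which is what makes the proportion × ΔT interaction
identifiable at all. True proportions default to the study-shaped spectrum:
nine animals spanning 0.01–0.11 plus 0.16, 0.22 and 0.41; per-image measured
proportions add noise of SD 0.035 (the observed image-to-image variability
of the measurement chain at study scale). Two random IR frames are dropped
and one logger reading zeroed by default, so the 178/179/180 filter
arithmetic is exercised end to end.

Effects are injected exactly: heating magnitude multiplied by
`exp(slope · log p)`, and the blocks 3→5 non-melanistic luminance change set
to `b₁·log p + b₂·ΔT + b₃·log p·ΔT` with ΔT computed from the same eye
readings the analysis averages — with all noise at zero, OLS recovers the
injected coefficients to machine precision, which pins the full
generator→analysis chain. The power scenario injects an interaction of
0.012 luminance units per (log-unit·°C) — about four times the null standard
error of that coefficient (≈0.003, measured on null cohorts), the standard
~90%-power design point — together with a main-effect slope of −0.11 that
keeps luminance changes inside the unit gamut at the ~10 °C reference
temperature change (an uncompensated interaction of that size would imply
out-of-range luminances and clip).

## What the synthetic results do not show

The generator's animals are rigid ellipse unions with circular spots,
shading is a smooth gradient rather than cast shadow with penumbra, pose
variation is affine rather than articulated, and background is uniform.
Passing recovery suites therefore demonstrates the correctness of the
measurement chain (color math, gain standardization, clustering, filter
plumbing, inference), not robustness to articulated postures, specular
highlights, soft shadows crossing the pattern, or miscropped ROIs — those
failure modes are exactly what the human QC step exists for. Statistics on
12 individuals inherit all small-sample caveats; the Cook's-distance flag is
reported, not remediated.

## Problem sizes

Default tests and the acceptance script use 200×260 px frames, 15-frame
series, 21-image coverage sweeps, and 100-replicate cohort calibrations —
sizes at which the full suite completes in a few minutes on one CPU while
every statistical check retains its designed resolution.
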