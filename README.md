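# melanotherm

Quantifying stable melanistic color pattern and physiological color change
from repeat photographs of a freely moving animal, and testing whether that
pattern matters for thermoregulation.

Many ectotherms — the motivating case is a crepuscular gecko with dark spots
on a yellowish dorsum — are photographed repeatedly over a temperature
experiment while their body temperature is tracked by infrared thermography.
Two questions follow: does the *proportion* of stable melanistic pattern
influence heating and cooling rates, and does the skin's *luminance*
(physiological color change via melanosome movement) respond to temperature,
possibly differently in melanistic and non-melanistic skin?  `melanotherm`
provides the full measurement-and-inference chain for that design:

1. **Lightness standardization** (`melanotherm.imaging`). Each frame is
   converted to HLS; the lightness channel is multiplied by the gain
   `g = L̄_ref(first frame) / L̄_ref(current frame)` computed on an in-frame
   grayscale standard, so illumination drift cancels within an individual.
   Cross-individual comparison of luminance is refused at the API level —
   gains anchored to different baselines are not comparable.
2. **Pattern segmentation** (`melanotherm.segmentation`). Animal pixels
   (inside the user's dorsal ROI, below a background-lightness threshold)
   are clustered in RGB space by k-means with k-means++ seeding
   (`PatternKMeans`, a scikit-learn-style clusterer supporting bisecting
   recursion). The cluster with the lower Rec.601 luminance center is the
   melanistic class; near-uniform animals are flagged `low_contrast` and get
   proportion 0 rather than a spurious split.
3. **Quantification** (`melanotherm.quantification`). Melanistic proportion
   `p = |melanistic| / |dorsal foreground|` and mean segment luminances per
   image; body temperature as the mean of the two eye readings (snout
   fallback); per-block means over the five-block 25 → 15 → 25 °C profile;
   cooling rate `T̄₁ − T̄₃` and heating rate `T̄₅ − T̄₃` per individual.
4. **Statistics** (`melanotherm.stats`). Pearson/Spearman correlations,
   Shapiro–Wilk-gated paired contrasts (paired *t* or Wilcoxon signed-rank
   with R-style conventions: V = sum of positive ranks, zero-drop, midranks,
   exact p for tie-free n ≤ 25), OLS models — log rates ~ mass/SVL/sex,
   log proportion ~ SVL × sex, and luminance change ~ log proportion ×
   temperature change — with Cook's distance influence flags (D > 1).
5. **Synthetic studies** (`melanotherm.synthetic`). Generators render
   spotted animals with known coverage, illumination drift and on-body
   shadows, and emit thermal cohorts with injectable ground-truth effects,
   so every stage is testable without the original photographs.

## Worked example

```python
import numpy as np
import melanotherm as mt
from melanotherm.quantification import prepare_thermal_table

# measure one individual's 15-frame photo series (22% true spot coverage)
series = mt.generate_image_series(
    mt.ImageGenParams(target_proportion=0.22, seed=5), T=15, individual_id="G01")
baseline = mt.LightnessStandardizer().fit(series[0].record)
props = []
for frame in series:
    rec = baseline.transform(frame.record)
    seg = mt.segment_pattern(rec, mt.SegmentationConfig(seed=0))
    props.append(seg.melanistic_proportion)
print(f"recovered proportion: {np.mean(props):.3f} +/- {np.std(props, ddof=1):.4f} "
      f"(truth {series[0].true_proportion:.3f})")

# run the statistical battery on a 12-animal cohort
cohort = mt.generate_thermal_cohort(mt.ThermalGenParams(seed=1))
report = mt.run_analysis(mt.StudyDataset(
    thermal=prepare_thermal_table(cohort.thermal),
    metrics=cohort.metrics, individuals=cohort.individuals))
print(report.counts)
corr = report.correlations.set_index("comparison")
print(f"body vs substrate: r = {corr.loc['body vs IR substrate', 'r']:.3f}")
row = report.contrasts.query("variable=='mean_body_temp' and phase=='heating'").iloc[0]
print(f"heating contrast (blocks 3-5): {row.test}, statistic = {row.statistic:.1f}, "
      f"p = {row.p:.2e}")
m = report.luminance_models["lum_nonmel_heating"]
print(f"luminance ~ log-proportion x dT (heating, non-melanistic): "
      f"t = {m.tvalues['log_prop:temp_change']:.2f}, "
      f"p = {m.pvalues['log_prop:temp_change']:.2f}, adj R2 = {m.adjusted_r2:.2f}")
```

prints

```
recovered proportion: 0.220 +/- 0.0008 (truth 0.220)
{'n_individuals': 12, 'n_visible_points': 180, 'n_ir_points': 178, 'n_logger_points': 179, 'n_logger_invalid': 1}
body vs substrate: r = 0.987
heating contrast (blocks 3-5): t, statistic = -83.3, p = 9.28e-17
luminance ~ log-proportion x dT (heating, non-melanistic): t = -0.41, p = 0.69, adj R2 = 0.13
```

The proportion is recovered to a fraction of a percentage point despite
per-frame illumination gains spanning 0.7–1.3; the cohort counts reflect the
built-in data blemishes (two unusable IR frames → 178 IR points; one
dead-logger zero reading → 179 valid logger averages out of 180 scheduled);
body temperature tracks the substrate closely; the blocks 3→5 contrast shows
the ~10 °C rewarming; and with no injected melanism effect the interaction
term is, correctly, non-significant.

A `melanotherm` console command wraps the same pipeline
(`simulate` / `extract` / `analyze`); `melanotherm simulate --out study/
--with-images` writes a complete ready-to-run synthetic study.

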