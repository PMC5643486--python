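# fadyn — video fluorescein angiography dynamics

`fadyn` quantifies dye-transit dynamics in video fluorescein angiography of
retinal and superficial cortical vasculature, the kind of recording used to
ask whether the blood-retinal barrier can stand in for the blood-brain
barrier when probing vascular leakage. It is aimed at researchers analysing
rodent fundus-camera videos (30 frames/s, ~1 min, with a pre-bolus baseline)
and at anyone who wants a fully synthetic, ground-truthed test bed for such
pipelines.

## What it computes

After rigid registration, every pixel's time-intensity curve I(t) is
baseline-normalized,

    v(t) = 100 · (I(t) − Ī_base) / (I_peak − Ī_base)   [% of peak above baseline],

and reduced to three indices:

* **half-rise** t₅₀↑ — first time after bolus onset with v(t) ≥ 50% on the way
  up (fill timing; arteries fill before capillaries, veins last);
* **half-fall** t₅₀↓ — first time after the peak with v(t) < 50% (washout);
  curves that never fall back are censored, not extrapolated;
* **offset** — mean v(t) over the final seconds of the recording (remnant
  fluorescence, % of peak): the leakage indicator.

Group statistics mirror the barrier-disruption experiment: per-animal medians
and IQRs; control medians bootstrapped (animals resampled with replacement,
1,000×) for 95% confidence limits; and the **index of injury** — the
percentage of a treated animal's pixels strictly above the pooled control
75th percentile. For pixels distributed like the controls the expected index
is 25%, the null reference level.

A seedable simulator (`fadyn.synthetic`) renders whole recordings with known
ground truth: per-pixel gamma-variate bolus transit
K·((t−t₀)/αβ)^α·e^(α−(t−t₀)/β) plus a saturating leakage plateau, retinal
spoke or cortical curvilinear vessel layouts, camera noise, rigid frame drift
and digitizer quantization.

## Worked example

```python
import numpy as np
from fadyn import SceneConfig, render_video, estimate_shifts, apply_shifts
from fadyn import AnalysisConfig, compute_maps

scene = SceneConfig(layout="retina", seed=1, motion_amplitude_px=3.0)
video, truth = render_video(scene)              # 1800 frames, 64x64, 30 fps

est = estimate_shifts(video)                    # rigid drift, sub-pixel
print(f"max drift error: {np.abs(est.shifts - truth.shifts).max():.2f} px")
aligned, valid = apply_shifts(video, est)

maps = compute_maps(aligned, AnalysisConfig(), label_map=truth.label_map,
                    invalid_mask=~valid)
for cls, code in (("artery", 1), ("vein", 2), ("capillary", 3)):
    sel = truth.labels == code
    print(f"{cls:10s} median half-rise {np.nanmedian(maps.half_rise[sel]):.2f} s "
          f"(truth {np.nanmedian(truth.half_rise[sel]):.2f} s), "
          f"offset {np.nanmedian(maps.offset[sel]):.1f} %")
```

prints

```
max drift error: 0.24 px
artery     median half-rise 6.62 s (truth 6.59 s), offset 13.2 %
vein       median half-rise 7.57 s (truth 7.55 s), offset 16.0 %
capillary  median half-rise 6.80 s (truth 6.79 s), offset 11.3 %
```

— arteries fill first and veins last, and the dim-background retina keeps a
low residual offset; a disruption scenario
(`make_disruption_scenario(scene, 0.3)`) raises every compartment's offset
while leaving fill timing untouched.

The same workflow is scriptable from the shell:

```sh
fadyn simulate --config scene.yaml --out sim/
fadyn analyze --video sim/video.tif --meta sim/video.json \
      --mask sim/labels.tif --out maps/
fadyn run --config study.yaml --seed 1 --out study/   # full control-vs-treated study
```

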