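# Methods

## The measurement

Video fluorescein angiography records the first pass of an intravenous dye
bolus through retinal or superficial cortical vessels: fluorescence rises as
dye arrives, decays as the bolus washes out, and — when the blood-neural
barrier leaks — settles on an elevated residual plateau instead of returning
to baseline. `fadyn` reduces every pixel's time course to three indices
(half-rise, half-fall, offset), summarizes them per vessel compartment, and
compares treated animals with controls through an injury index. All analysis
time is measured from bolus onset; the recording's pre-bolus segment
(default 5 s at 30 frames/s) provides the normalization baseline, which also
cancels constant pseudofluorescence.

## Pipeline stages and their assumptions

**Registration** (`fadyn.registration`). Translation-only: the preparations
are head-fixed, so drift is a few pixels of slow rigid motion and rotation
and warping are out of scope. Each frame is mean-subtracted, Hann-windowed
and aligned to a reference by Fourier cross-correlation with upsampled-DFT
sub-pixel refinement. The reference is the mean of the pre-bolus frames,
*after* aligning them to the first frame — baseline frames drift too, and an
unaligned average would be blurred and anchored at the average baseline
position rather than the recording start. Spectral-whitening ("phase")
normalization is deliberately not used: on these smooth, low-frequency scenes
it amplifies noise and fails, while plain windowed cross-correlation recovers
3 px drifts to ≲0.25 px at realistic noise. Frames whose aligned Pearson
correlation with the reference falls below 0.2 are flagged invalid rather
than force-aligned (blinks/occlusions); pixels that entered the field of view
during alignment are excluded downstream. Sub-pixel resampling necessarily
perturbs individual vessel-edge pixels (a ~0.1 px spurious correction can
move one pixel's shallow half-fall crossing substantially); class-level
summaries move by well under one histogram bin, and that is the level at
which registration neutrality is guaranteed and tested.

**Curve normalization and indices** (`fadyn.dynamics`). Peak location and the
50% crossings are found on a centered moving average (default 0.5 s, 15
samples at 30 fps) to suppress frame noise; crossings are linearly
interpolated between samples. The offset averages the *raw* normalized
samples over the plateau window so the plateau level is not biased by
smoothing. Defaults, with rationale:

| parameter | default | why |
|---|---|---|
| `smoothing_width_s` | 0.5 s | suppresses single-frame noise; shifts gamma-variate crossings by <0.01 s |
| `plateau_window_s` | final 5 s | the first pass has washed out and the leakage term has saturated by then |
| `snr_k` | 3 | a pixel needs peak > baseline + 3·SD to count as perfused; pigment-dark background has no transit |
| `half_level` | 50 % | threshold of peak-above-baseline, symmetric for rise and fall |
| half-fall reference | % of peak, not peak-minus-plateau | the simplest reading of "time to 50% decay"; with strong leakage the curve may never fall below 50% and is then *censored*, reported but excluded from half-fall summaries |

Invalid pixels carry exactly one reason code
(`background / saturated / no_peak / censored_half_fall / low_snr`); pixels
clipped by registration or whose peak falls inside the plateau window are
coded `low_snr` (the fixed code set has no dedicated value for them).

**Vessel classification** (`fadyn.classify`). Manual label masks always take
precedence. The automatic mode segments large vessels on the peak image with
a three-class Otsu threshold (background / diffuse capillary bed / vessels;
a single or hierarchical Otsu mis-splits this three-mode histogram), removes
8-connected components under 20 px, then splits vessel pixels into two
1-D k-means clusters of half-rise seeded at the 10th/90th percentiles — the
earlier-filling cluster is arterial. Remaining pixels with a valid transit
are capillary/extravascular. Classification is per-pixel, deterministic and
orientation-stable.

**Group statistics** (`fadyn.stats`). Linear-interpolation quantiles
everywhere. Histograms normalize counts to the class pixel total (%), with
censored pixels excluded from numerator and denominator and reported
separately; default bins are 0.1 s (timing) and 1% (offset). The control
reference pools pixels across control animals per site/class/parameter and
takes the 75th percentile as the injury cutoff; the injury index is the
percentage of an animal's pixels *strictly above* the cutoff ("beyond" is
one-sided upper for all three indices, since slower filling, slower decay
and higher residual fluorescence are all the pathological direction). By
construction, control pixels exceed their own pooled cutoff 25% of the time,
so 25% is the null reference level for group means. Confidence limits
resample *animals* (their medians), never pixels — pixels within an animal
are strongly dependent — 1,000 times, taking the 2.5th/97.5th percentiles of
the resampled statistic. The default statistic is the **median** of the
per-animal medians: in simulation with 10-animal normal groups its percentile
interval covers the true central value at a near-nominal rate (within the
90–98% band), whereas the mean-of-medians interval undercovers (below 90% at
nominal 95%); `statistic="mean"` is available. Group comparisons use the Mann–Whitney U test (exact enumeration
for combined n ≤ 12 without ties, normal approximation with tie correction
otherwise).

## The synthetic-data generator

`fadyn.synthetic` renders recordings under the study's acquisition
conditions: 30 frames/s, 60 s, bolus onset 5 s after recording start. Each
pixel's noiseless curve is a gamma-variate indicator-dilution transit plus a
saturating leakage term,

    I(t) = b + A·((t−t₀)/αβ)^α·e^(α−(t−t₀)/β) + f·A·(1−e^(−(t−t₀)/τ)),  t > t₀,

chosen because the gamma-variate is the standard dye-dilution model and has a
closed-form peak time (t₀ + αβ) usable as an oracle. Note the leakage term
already contributes at the first-pass peak, so the asymptotic normalized
offset is 100·f/(1 + f·(1−e^(−αβ/τ))), slightly below 100·f.

Class parameter defaults were set so the rendered class medians land near
measured values for rat retina (half-rise ≈ 6.5/6.7/7.4 s, half-fall ≈
10.8/10.8/13.0 s, offset ≈ 13/10/16 % for artery/capillary/vein) and cortex
(faster transit, offsets ≈ 34–41%), with arteries always arriving before
capillaries before veins. Between-animal variability is a *shared* arrival
delay (SD 0.25 s) and leakage shift (SD 0.02) added to every class mean —
systemic factors (injection timing, circulation) dominate between-animal
differences, which keeps the fill-timing ordering intact within each animal —
plus per-pixel jitter within classes. The retina layout is a spoke pattern of
eight alternating artery/vein radials around a central disc over a dim
(pigment-blocked) background; the cortex layout has four larger curvilinear
vessels over a bright diffuse parenchyma labelled capillary/extravascular.
Vessels span ~5–6 px, emulating a cropped field at native-like camera
sampling where a vessel covers many pixels; substantially thinner vessels
would make every vessel pixel an edge pixel whose recorded curve mixes with
the neighbouring bed under motion, which misrepresents the instrument.
Baselines carry a smooth multiplicative texture (fundus/parenchyma
reflectance structure) so pre-bolus frames contain registration features, as
real reflectance images do.

Noise is additive Gaussian (SD 2 counts) plus an intensity-proportional term
(1%); motion is a smooth random walk anchored at zero (the preparation starts
aligned) with configurable amplitude; quantization is applied last (8-bit,
gain 1; or 16-bit, gain 256 so the extra depth is actually used) with
saturation clipping. All randomness flows from the single scene seed;
identical configurations render bit-identical stacks. A disruption scenario
raises every compartment's mean leakage fraction by a fixed shift and changes
nothing else — leakage without altered filling, the signature of systemic
barrier disruption.

What the simulator does **not** emulate: hemodynamic flow coupling between
compartments, choroidal two-compartment kinetics, photobleaching, pulsatile
or non-rigid motion, and spatially correlated noise. Passing tests therefore
demonstrate that the pipeline recovers known transit/leakage structure under
realistic sampling, noise, motion and quantization — not that the gamma-variate
is the true functional form of any real recording.

## Problem sizes and numerical choices

Default scenes are 64×64 px × 1800 frames — small enough that a full 10+10
animal study renders and analyses in a few minutes, while every class still
contains hundreds-to-thousands of pixels. Analytic ground-truth indices are
computed on a 1/120 s grid of the continuous noiseless model (crossings
linearly interpolated), an order of magnitude finer than the 1/30 s
acquisition grid the pipeline sees; test oracles use an independent 1 ms
grid. Bulk curve evaluation uses float32 (≤1e-4-count rounding, far below
camera noise); statistics are float64. Ties in crossing detection resolve to
the earliest qualifying sample; an exactly flat baseline with no signal is
`no_peak`, a noisy sub-threshold pixel `low_snr`.

## Known limitations

* Registration accuracy degrades near the bolus peak, where frame content
  differs most from the baseline reference (bias up to ~0.24 px at 3 px
  drift); a content-adaptive reference could reduce this.
* The injury index's 25% null holds exactly only when animals contribute
  equal valid-pixel counts to the pooled cutoff; unequal counts shift it
  slightly.
* Censoring ties half-fall availability to leakage: under strong disruption
  most half-fall values are censored, so treated half-fall summaries describe
  a selected subpopulation.
* Auto-classification assumes exactly two timing clusters among large-vessel
  pixels and will mislabel arteriovenous anastomoses or pathological shunts.
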