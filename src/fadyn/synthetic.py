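"""Seedable synthetic dye-transit videos with known ground truth.

The simulator emulates video fluorescein angiography of the rat retina
(through the pupil) and of superficial cortical vessels (through a thinned
skull): 30 frames/s for 60 s, recording started 5 s before bolus infusion.

Each pixel's noiseless time course is an indicator-dilution gamma-variate
first-pass bolus plus a saturating leakage plateau::

    I(t) = baseline                                          for t <= t0
    I(t) = baseline
           + amplitude * ((t-t0)/(alpha*beta))**alpha * exp(alpha - (t-t0)/beta)
           + leak_frac * amplitude * (1 - exp(-(t-t0)/tau_leak))   otherwise

The gamma-variate term is normalized so it peaks at exactly ``amplitude`` at
``t0 + alpha*beta``; ``leak_frac`` sets the late residual-fluorescence plateau
as a fraction of that peak, the quantity that rises when the blood-neural
barrier leaks. Arrival times are earliest in arteries, later in the
capillary/extravascular bed and latest in veins, and the cortical transit is
faster than the retinal one. The rendered video adds camera noise (additive
Gaussian plus an intensity-proportional term), rigid smooth-random-walk frame
motion and final integer quantization with saturation.

All randomness flows from a single seed in :class:`SceneConfig`; identical
configurations render bit-identical videos.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import ConfigError, ParameterError
from .io import (
    LABEL_ARTERY,
    LABEL_BACKGROUND,
    LABEL_CAPILLARY,
    LABEL_NAMES,
    LABEL_VEIN,
    NAME_TO_LABEL,
    VESSEL_CLASSES,
    VesselLabelMap,
    VideoStack,
)

__all__ = [
    "CurveParams",
    "ClassCurveModel",
    "SceneConfig",
    "GroundTruth",
    "simulate_pixel_curve",
    "render_video",
    "make_disruption_scenario",
    "analytic_curve_features",
]


# ---------------------------------------------------------------------------
# Single-pixel transit curve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one pixel's noiseless transit curve.

    t0 : bolus-arrival delay (s, relative to infusion onset)
    alpha, beta : gamma-variate shape (–) and time scale (s); the first-pass
        peak occurs ``alpha * beta`` seconds after arrival
    amplitude : peak fluorescence above baseline (camera counts)
    leak_frac : late residual plateau as a fraction of the peak, in [0, 1)
    tau_leak : leakage rise time constant (s)
    baseline : pre-bolus intensity (camera counts)
    """

    t0: float
    alpha: float
    beta: float
    amplitude: float
    leak_frac: float = 0.0
    tau_leak: float = 10.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.tau_leak <= 0:
            raise ParameterError("alpha, beta and tau_leak must be positive")
        if self.amplitude <= 0:
            raise ParameterError("amplitude must be positive")
        if not 0.0 <= self.leak_frac < 1.0:
            raise ParameterError("leak_frac must lie in [0, 1)")
        if self.baseline < 0:
            raise ParameterError("baseline must be non-negative")

    @property
    def gamma_peak_time(self) -> float:
        """Time of the first-pass maximum for a pure (leak-free) curve."""
        return self.t0 + self.alpha * self.beta


def _gamma_variate(s: np.ndarray, alpha, beta) -> np.ndarray:
    """Unit-peak gamma-variate evaluated at time-since-arrival ``s`` (0 for s<=0)."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    pos = s > 0
    sp = s[pos]
    a = np.broadcast_to(np.asarray(alpha, dtype=float), sp.shape) if np.ndim(alpha) else alpha
    b = np.broadcast_to(np.asarray(beta, dtype=float), sp.shape) if np.ndim(beta) else beta
    # computed in log space for numerical stability at large s/beta
    out[pos] = np.exp(a * np.log(sp / (a * b)) + a - sp / b)
    return out


def simulate_pixel_curve(params: CurveParams, times) -> np.ndarray:
    """Noiseless intensity at each time point (times in s after infusion onset).

    Deterministic; equals ``baseline`` for every ``t < t0``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ParameterError("times must be a non-empty 1-D sequence")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ParameterError("times must be strictly increasing")
    s = times - params.t0
    curve = params.amplitude * _gamma_variate(s, params.alpha, params.beta)
    leak = params.leak_frac * params.amplitude * -np.expm1(
        -np.clip(s, 0.0, None) / params.tau_leak
    )
    return params.baseline + curve + leak


def _render_curves(
    p: dict[str, np.ndarray], times: np.ndarray, dtype=np.float32
) -> np.ndarray:
    """Vectorized noiseless curves: parameter field arrays (N,) -> (T, N).

    float32 by default: the 1e-4-count rounding is far below camera noise and
    quantization, and single precision roughly halves render time and memory.
    """
    s = (times[:, None] - p["t0"][None, :]).astype(dtype)
    np.maximum(s, 0.0, out=s)
    pos = s > 0
    a = p["alpha"].astype(dtype)[None, :]
    b = p["beta"].astype(dtype)[None, :]
    with np.errstate(divide="ignore"):
        logg = a * np.log(s / (a * b)) + a - s / b
    g = np.exp(logg, where=pos, out=np.zeros_like(s))
    leak = p["leak_frac"].astype(dtype)[None, :] * -np.expm1(
        -s / p["tau_leak"].astype(dtype)[None, :]
    )
    out = g
    out += leak
    out *= p["amplitude"].astype(dtype)[None, :]
    out += p["baseline"].astype(dtype)[None, :]
    return out


# ---------------------------------------------------------------------------
# Scene configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassCurveModel:
    """Distribution of curve parameters within one vessel compartment.

    ``t0_sd``, ``amplitude_sd`` and ``leak_frac_sd`` are per-pixel spreads
    within an animal; between-animal spreads are configured once per scene
    (:attr:`SceneConfig.animal_t0_sd`, :attr:`SceneConfig.animal_leak_sd`).
    """

    t0_mean: float
    t0_sd: float
    alpha: float
    beta: float
    amplitude_mean: float
    amplitude_sd: float
    leak_frac_mean: float
    leak_frac_sd: float
    tau_leak: float = 10.0
    baseline: float = 16.0


def _retina_classes() -> dict[str, ClassCurveModel]:
    # Arrival times, transit widths and leakage plateaus chosen to land the
    # class medians near the measured retinal values (half-rise ~6.5/6.7/7.4 s,
    # half-fall ~10.8/10.8/13.0 s, offset ~13/10/16 %) for artery/capillary/vein.
    return {
        "artery": ClassCurveModel(5.04, 0.15, 3.0, 1.05, 160.0, 10.0, 0.126, 0.030, 10.0, 22.0),
        "capillary_extravascular": ClassCurveModel(
            5.34, 0.18, 3.0, 0.98, 60.0, 8.0, 0.100, 0.030, 10.0, 16.0
        ),
        "vein": ClassCurveModel(5.57, 0.15, 3.0, 1.355, 160.0, 10.0, 0.159, 0.035, 10.0, 22.0),
    }


def _cortex_classes() -> dict[str, ClassCurveModel]:
    # Faster transit and much higher residual fluorescence than the retina;
    # the diffuse parenchyma (capillary/extravascular) is bright.
    return {
        "artery": ClassCurveModel(4.02, 0.15, 3.0, 1.137, 150.0, 10.0, 0.347, 0.040, 10.0, 30.0),
        "capillary_extravascular": ClassCurveModel(
            4.19, 0.20, 3.0, 1.161, 70.0, 8.0, 0.414, 0.050, 10.0, 40.0
        ),
        "vein": ClassCurveModel(4.52, 0.15, 3.0, 1.21, 150.0, 10.0, 0.336, 0.040, 10.0, 30.0),
    }


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic angiography recording."""

    layout: str = "retina"  # "retina" (spoke vasculature) or "cortex"
    shape: tuple[int, int] = (64, 64)
    frame_rate: float = 30.0
    duration_s: float = 60.0
    bolus_onset_s: float = 5.0
    classes: Mapping[str, ClassCurveModel] | None = None
    background_baseline: float | None = None
    texture_amp: float = 0.25  # relative spatial modulation of the baseline
    noise_sigma: float = 2.0  # additive Gaussian camera noise (counts)
    noise_gain: float = 0.01  # intensity-proportional noise coefficient
    motion_amplitude_px: float = 0.0
    animal_t0_sd: float = 0.25  # between-animal shared arrival-delay spread (s)
    animal_leak_sd: float = 0.02  # between-animal shared leak_frac spread
    bit_depth: int = 8
    gain: float | None = None  # digitizer counts per scene count; None = 1 (8-bit) or 256 (16-bit)
    seed: int = 0

    def __post_init__(self):
        if self.layout not in ("retina", "cortex"):
            raise ConfigError(f"unknown layout {self.layout!r}")
        if self.duration_s <= self.bolus_onset_s:
            raise ConfigError("duration_s must exceed bolus_onset_s")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.bit_depth not in (8, 16):
            raise ConfigError("bit_depth must be 8 or 16")
        if self.gain is None:
            object.__setattr__(self, "gain", 1.0 if self.bit_depth == 8 else 256.0)
        if self.gain <= 0:
            raise ConfigError("gain must be positive")
        if self.classes is None:
            object.__setattr__(
                self,
                "classes",
                _retina_classes() if self.layout == "retina" else _cortex_classes(),
            )
        if self.background_baseline is None:
            object.__setattr__(
                self, "background_baseline", 10.0 if self.layout == "retina" else 35.0
            )
        missing = set(VESSEL_CLASSES) - set(self.classes)
        if missing:
            raise ConfigError(f"classes missing compartments {sorted(missing)}")
        art = self.classes["artery"].t0_mean
        cap = self.classes["capillary_extravascular"].t0_mean
        vein = self.classes["vein"].t0_mean
        if not art < cap < vein:
            raise ConfigError(
                "mean arrival times must be ordered artery < capillary < vein, got "
                f"{art}, {cap}, {vein}"
            )
        for name, m in self.classes.items():
            if not 0.0 <= m.leak_frac_mean < 1.0:
                raise ParameterError(f"{name}: leak_frac_mean out of [0, 1)")

    @property
    def site(self) -> str:
        return "retina" if self.layout == "retina" else "brain"

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = {k: dataclasses.asdict(v) for k, v in self.classes.items()}
        return d


def scene_from_dict(d: Mapping) -> SceneConfig:
    """Build a SceneConfig from a plain dict (e.g. parsed YAML), rejecting unknown keys."""
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SceneConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown scene config fields {sorted(unknown)}")
    if "classes" in d and d["classes"] is not None:
        cls_known = {f.name for f in dataclasses.fields(ClassCurveModel)}
        classes = {}
        for name, cd in dict(d["classes"]).items():
            bad = set(cd) - cls_known
            if bad:
                raise ConfigError(f"unknown class model fields {sorted(bad)} for {name!r}")
            classes[name] = ClassCurveModel(**cd)
        d["classes"] = classes
    if "shape" in d:
        d["shape"] = tuple(d["shape"])
    return SceneConfig(**d)


def make_disruption_scenario(base: SceneConfig, offset_shift: float) -> SceneConfig:
    """Scene with every compartment's mean leakage plateau raised by ``offset_shift``.

    Models systemic barrier disruption: the residual-fluorescence plateau rises
    in every compartment while arrival and decay timing are left untouched.
    """
    new_classes = {}
    for name, m in base.classes.items():
        new_leak = m.leak_frac_mean + offset_shift
        if not 0.0 <= new_leak < 1.0:
            raise ParameterError(
                f"{name}: shifted leak_frac {new_leak:.3f} outside [0, 1)"
            )
        new_classes[name] = dataclasses.replace(m, leak_frac_mean=new_leak)
    return dataclasses.replace(base, classes=new_classes)


# ---------------------------------------------------------------------------
# Vessel layouts
# ---------------------------------------------------------------------------


def _retina_labels(shape: tuple[int, int]) -> np.ndarray:
    """Spoke pattern: alternating artery/vein radial vessels around a central disc."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(rr - cy, cc - cx)
    theta = np.arctan2(rr - cy, cc - cx)
    ext = min(h, w)
    field_r = 0.48 * ext
    disc_r = 0.10 * ext
    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[(r <= field_r) & (r > disc_r)] = LABEL_CAPILLARY
    n_spokes = 8
    # ~5 px wide spokes: a cropped field at native-like sampling, where real
    # retinal vessels span several pixels, so edge pixels are a minority
    half_width_px = 2.5
    for k in range(n_spokes):
        ang = -np.pi + (k + 0.5) * 2 * np.pi / n_spokes
        d = np.angle(np.exp(1j * (theta - ang)))
        vessel = (np.abs(d) * np.maximum(r, 1.0) <= half_width_px) & (r > disc_r) & (
            r <= field_r
        )
        labels[vessel] = LABEL_ARTERY if k % 2 == 0 else LABEL_VEIN
    return labels


def _cortex_labels(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Few large curvilinear vessels over a diffuse bright parenchyma."""
    h, w = shape
    labels = np.full(shape, LABEL_CAPILLARY, dtype=np.uint8)
    margin = max(1, min(h, w) // 32)
    labels[:margin, :] = LABEL_BACKGROUND
    labels[-margin:, :] = LABEL_BACKGROUND
    labels[:, :margin] = LABEL_BACKGROUND
    labels[:, -margin:] = LABEL_BACKGROUND
    rr, cc = np.mgrid[0:h, 0:w]
    n_vessels = 4
    half_width = max(3.0, 0.05 * h)  # cortical surface vessels are larger
    for i in range(n_vessels):
        base_row = h * (i + 1) / (n_vessels + 1)
        amp = rng.uniform(0.03, 0.08) * h
        freq = rng.uniform(1.0, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        center = base_row + amp * np.sin(2 * np.pi * freq * cc / w + phase)
        vessel = np.abs(rr - center) <= half_width
        vessel &= labels == LABEL_CAPILLARY
        labels[vessel] = LABEL_ARTERY if i % 2 == 0 else LABEL_VEIN
    return labels


# ---------------------------------------------------------------------------
# Ground truth & analytic dynamics
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Everything the renderer knows that the pipeline must recover."""

    labels: np.ndarray  # (H, W) uint8 compartment labels
    params: dict[str, np.ndarray]  # per-pixel curve parameter fields (H, W)
    shifts: np.ndarray  # (T, 2) applied rigid shift per frame (dy, dx), px
    half_rise: np.ndarray  # analytic indices on the noiseless curve (s, s, %)
    half_fall: np.ndarray
    offset: np.ndarray

    @property
    def label_map(self) -> VesselLabelMap:
        return VesselLabelMap(self.labels)

    def class_median(self, class_name: str, parameter: str) -> float:
        vals = getattr(self, parameter)[self.labels == NAME_TO_LABEL[class_name]]
        return float(np.nanmedian(vals))


def analytic_curve_features(
    params: dict[str, np.ndarray],
    t_end: float,
    plateau_window_s: float = 5.0,
    dt: float = 1.0 / 120.0,
    level: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-rise, half-fall and offset of noiseless continuous curves.

    Evaluates each parameter vector's curve on a fine regular grid over
    ``[0, t_end]`` (analysis time, s after infusion onset), normalizes to
    peak-above-baseline = 100 and finds the 50% crossings by linear
    interpolation; the offset is the mean normalized value over the final
    ``plateau_window_s`` seconds. Pixels with zero amplitude return NaN;
    half-fall is NaN (censored) when the curve never falls back through the
    threshold before ``t_end``.
    """
    flat = {k: np.asarray(v, dtype=float).ravel() for k, v in params.items()}
    n = flat["t0"].size
    tg = np.arange(0.0, t_end + dt / 2, dt)
    plateau = tg >= t_end - plateau_window_s
    half_rise = np.full(n, np.nan)
    half_fall = np.full(n, np.nan)
    offset = np.full(n, np.nan)
    live = flat["amplitude"] > 0
    idx_live = np.flatnonzero(live)
    chunk = max(1, int(4e6 / max(tg.size, 1)))
    for start in range(0, idx_live.size, chunk):
        sel = idx_live[start : start + chunk]
        sub = {k: v[sel] for k, v in flat.items()}
        curves = _render_curves(sub, tg) - sub["baseline"][None, :]
        pk = np.argmax(curves, axis=0)
        pkval = curves[pk, np.arange(sel.size)]
        v = curves / pkval[None, :] * 100.0
        cols = np.arange(sel.size)
        # rising crossing at or before the peak
        rise_cond = (v >= level) & (np.arange(tg.size)[:, None] <= pk[None, :])
        i = rise_cond.argmax(axis=0)
        i0 = np.maximum(i - 1, 0)
        v1, v0 = v[i, cols], v[i0, cols]
        frac = np.where(v1 > v0, (level - v0) / np.where(v1 > v0, v1 - v0, 1.0), 0.0)
        half_rise[sel] = tg[i0] + frac * (tg[i] - tg[i0])
        # falling crossing strictly after the peak
        fall_cond = (v < level) & (np.arange(tg.size)[:, None] > pk[None, :])
        has_fall = fall_cond.any(axis=0)
        j = fall_cond.argmax(axis=0)
        j0 = np.maximum(j - 1, 0)
        v1, v0 = v[j, cols], v[j0, cols]
        frac = np.where(v0 > v1, (v0 - level) / np.where(v0 > v1, v0 - v1, 1.0), 0.0)
        hf = tg[j0] + frac * (tg[j] - tg[j0])
        half_fall[sel] = np.where(has_fall, hf, np.nan)
        offset[sel] = np.clip(v[plateau].mean(axis=0), 0.0, 100.0)
    shape = np.asarray(params["t0"]).shape
    return half_rise.reshape(shape), half_fall.reshape(shape), offset.reshape(shape)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _sample_parameter_fields(
    config: SceneConfig, labels: np.ndarray, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    shape = labels.shape
    fields = {
        "t0": np.zeros(shape),
        "alpha": np.ones(shape),
        "beta": np.ones(shape),
        "amplitude": np.zeros(shape),
        "leak_frac": np.zeros(shape),
        "tau_leak": np.full(shape, 10.0),
        "baseline": np.full(shape, float(config.background_baseline)),
    }
    # shared per-animal systemic effects (injection timing, circulation, dose)
    dt0 = rng.normal(0.0, config.animal_t0_sd) if config.animal_t0_sd > 0 else 0.0
    dleak = rng.normal(0.0, config.animal_leak_sd) if config.animal_leak_sd > 0 else 0.0
    for name in VESSEL_CLASSES:
        m = config.classes[name]
        sel = labels == NAME_TO_LABEL[name]
        n = int(sel.sum())
        if n == 0:
            continue
        fields["t0"][sel] = np.clip(rng.normal(m.t0_mean + dt0, m.t0_sd, n), 0.05, None)
        fields["alpha"][sel] = m.alpha
        fields["beta"][sel] = m.beta
        fields["amplitude"][sel] = np.clip(
            rng.normal(m.amplitude_mean, m.amplitude_sd, n), 1.0, None
        )
        fields["leak_frac"][sel] = np.clip(
            rng.normal(m.leak_frac_mean + dleak, m.leak_frac_sd, n), 0.0, 0.95
        )
        fields["tau_leak"][sel] = m.tau_leak
        fields["baseline"][sel] = m.baseline
    # smooth multiplicative texture so the baseline image has registration
    # features (fundus/parenchyma reflectance structure)
    if config.texture_amp > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
        sd = tex.std()
        if sd > 0:
            tex = np.clip(tex / sd * config.texture_amp, -0.6, 0.6)
        fields["baseline"] = np.clip(fields["baseline"] * (1.0 + tex), 0.0, None)
    return fields


def _motion_shifts(config: SceneConfig, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    if config.motion_amplitude_px <= 0:
        return np.zeros((n_frames, 2))
    # smooth random walk anchored at zero: the preparation starts aligned and
    # drifts away from its initial position over the recording
    steps = rng.standard_normal((n_frames, 2))
    walk = np.cumsum(steps, axis=0)
    walk = ndimage.gaussian_filter1d(walk, sigma=config.frame_rate, axis=0, mode="nearest")
    walk -= walk[0]
    peak = np.abs(walk).max()
    if peak == 0:
        return np.zeros((n_frames, 2))
    return walk / peak * config.motion_amplitude_px


def render_video(config: SceneConfig) -> tuple[VideoStack, GroundTruth]:
    """Render a synthetic angiography recording and its ground truth.

    Returns the quantized noisy video plus a :class:`GroundTruth` with the
    label map, per-pixel curve parameters, the applied per-frame shifts and
    the analytic half-rise/half-fall/offset of the noiseless curves.
    Deterministic: the same config (including seed) renders identical stacks.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.shape
    pad = int(np.ceil(config.motion_amplitude_px)) + 2 if config.motion_amplitude_px > 0 else 0
    hp, wp = h + 2 * pad, w + 2 * pad
    if config.layout == "retina":
        labels_p = _retina_labels((hp, wp))
    else:
        labels_p = _cortex_labels((hp, wp), rng)
    fields = _sample_parameter_fields(config, labels_p, rng)
    n_frames = config.n_frames
    shifts = _motion_shifts(config, n_frames, rng)

    t_analysis = np.arange(n_frames) / config.frame_rate - config.bolus_onset_s
    flat = {k: v.ravel() for k, v in fields.items()}
    clean = _render_curves(flat, t_analysis).reshape(n_frames, hp, wp)

    maxval = 2**config.bit_depth - 1
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    video = np.empty((n_frames, h, w), dtype=dtype)
    crop = (slice(pad, pad + h), slice(pad, pad + w)) if pad else (slice(None), slice(None))
    for k in range(n_frames):
        frame = clean[k]
        dy, dx = shifts[k]
        if dy != 0.0 or dx != 0.0:
            frame = ndimage.shift(frame, (dy, dx), order=1, mode="nearest")
        frame = frame[crop]
        if config.noise_sigma > 0 or config.noise_gain > 0:
            sd = config.noise_sigma + config.noise_gain * frame
            frame = frame + rng.standard_normal(frame.shape) * sd
        video[k] = np.rint(np.clip(frame * config.gain, 0, maxval)).astype(dtype)

    labels = labels_p[crop].copy()
    params = {k: v[crop].copy() for k, v in fields.items()}
    hr, hf, off = analytic_curve_features(
        params, t_end=config.duration_s - config.bolus_onset_s
    )
    bg = labels == LABEL_BACKGROUND
    for arr in (hr, hf, off):
        arr[bg] = np.nan
    stack = VideoStack(
        frames=video,
        frame_rate=config.frame_rate,
        bolus_onset_s=config.bolus_onset_s,
        site=config.site,
    )
    truth = GroundTruth(
        labels=labels, params=params, shifts=shifts, half_rise=hr, half_fall=hf, offset=off
    )
    return stack, truth
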