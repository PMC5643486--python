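"""Per-pixel time-intensity curve indices: half-rise, half-fall, offset.

Every pixel's registered time course is normalized to its pre-bolus baseline
(baseline ≡ 0%, smoothed peak-above-baseline ≡ 100%), which also cancels any
constant pseudofluorescence. Three indices summarize the transit:

half-rise
    first time (s after bolus onset) the normalized curve reaches 50% on the
    way up to its peak, linearly interpolated between samples;
half-fall
    first time after the peak it falls back through 50%; curves that never do
    before the recording ends are *censored*, not extrapolated;
offset
    remnant fluorescence late in the recording, the mean normalized value
    over a plateau window (default: the final 5 s), in % of peak — the
    leakage indicator.

Peak location and the 50% crossings are detected on a lightly smoothed curve
(centered moving average, default 0.5 s) to suppress frame noise; the offset
averages the raw normalized samples so the plateau level is unbiased.
Pixels without a resolvable transit (peak below ``baseline + k·sd``) are
flagged, never zero-filled.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, FadynError, NoPeakError, WindowError
from .io import LABEL_BACKGROUND, VesselLabelMap, VideoStack, NAME_TO_LABEL

__all__ = [
    "AnalysisConfig",
    "NormalizedCurve",
    "DynamicsMaps",
    "normalize_curve",
    "compute_half_rise",
    "compute_half_fall",
    "compute_offset",
    "compute_maps",
    "REASON_NAMES",
]

REASON_OK = 0
REASON_BACKGROUND = 1
REASON_SATURATED = 2
REASON_NO_PEAK = 3
REASON_CENSORED_HALF_FALL = 4
REASON_LOW_SNR = 5

REASON_NAMES = {
    REASON_OK: "ok",
    REASON_BACKGROUND: "background",
    REASON_SATURATED: "saturated",
    REASON_NO_PEAK: "no_peak",
    REASON_CENSORED_HALF_FALL: "censored_half_fall",
    REASON_LOW_SNR: "low_snr",
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-pixel dynamics analysis.

    smoothing_width_s : width of the centered moving average used for peak
        location and crossing detection (s).
    plateau_window_s : length of the end-of-recording window averaged for the
        offset (s).
    snr_k : a pixel needs ``peak > baseline_mean + snr_k * baseline_sd`` to
        count as having a transit signal.
    half_level : crossing threshold in % of peak-above-baseline.
    saturation_value : digitizer full scale; ``None`` = infer from the stack
        dtype (255 for 8-bit, 65535 for 16-bit, none for float).
    baseline_window_s : ``(lo, hi)`` in analysis time (both ≤ 0); ``None``
        uses every pre-bolus frame.
    """

    smoothing_width_s: float = 0.5
    plateau_window_s: float = 5.0
    snr_k: float = 3.0
    half_level: float = 50.0
    saturation_value: float | None = None
    baseline_window_s: tuple[float, float] | None = None

    def __post_init__(self):
        if self.smoothing_width_s < 0:
            raise ConfigError("smoothing_width_s must be >= 0")
        if self.plateau_window_s <= 0:
            raise ConfigError("plateau_window_s must be positive")
        if self.snr_k < 0:
            raise ConfigError("snr_k must be >= 0")

    def smoothing_samples(self, frame_rate: float) -> int:
        return max(1, int(round(self.smoothing_width_s * frame_rate)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def analysis_from_dict(d) -> AnalysisConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown analysis config fields {sorted(unknown)}")
    if d.get("baseline_window_s") is not None:
        d["baseline_window_s"] = tuple(d["baseline_window_s"])
    return AnalysisConfig(**d)


# ---------------------------------------------------------------------------
# Single-curve operations
# ---------------------------------------------------------------------------


@dataclass
class NormalizedCurve:
    """A pixel time course scaled to baseline = 0, smoothed peak = 100."""

    times: np.ndarray  # s, relative to bolus onset
    values: np.ndarray  # smoothed normalized curve (% of peak-above-baseline)
    raw_values: np.ndarray  # unsmoothed normalized curve (same scale)
    peak_index: int
    peak_time: float
    baseline_mean: float  # raw units
    baseline_sd: float  # raw units
    saturated: bool = False


def _smooth(raw: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return raw.astype(np.float64)
    return ndimage.uniform_filter1d(raw.astype(np.float64), size=width, axis=0, mode="nearest")


def normalize_curve(
    raw,
    times,
    baseline_window: tuple[float, float] | None = None,
    smoothing_width: int = 15,
    snr_k: float = 3.0,
    saturation_value: float | None = None,
) -> NormalizedCurve:
    """Baseline-subtract and peak-normalize one raw intensity sequence.

    ``times`` are analysis times (s, 0 at bolus onset). ``smoothing_width``
    is in samples (≥ 1; 1 disables smoothing). Raises
    :class:`~fadyn.errors.NoPeakError` when the smoothed peak does not exceed
    ``baseline_mean + snr_k * baseline_sd``; a saturated sample only sets the
    ``saturated`` flag, the curve is still returned.
    """
    raw = np.asarray(raw, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if raw.shape != times.shape or raw.ndim != 1:
        raise WindowError("raw and times must be matching 1-D sequences")
    if smoothing_width < 1:
        raise WindowError("smoothing width must be at least 1 sample")
    if baseline_window is None:
        base_sel = times < 0
    else:
        lo, hi = baseline_window
        if hi > 0:
            raise WindowError("baseline window must lie wholly before bolus onset")
        base_sel = (times >= lo) & (times < hi)
    if not base_sel.any():
        raise WindowError("no samples in the baseline window")
    post = times >= 0
    if not post.any():
        raise WindowError("no samples after bolus onset")
    base_mean = float(raw[base_sel].mean())
    base_sd = float(raw[base_sel].std())
    smoothed = _smooth(raw, smoothing_width)
    post_idx = np.flatnonzero(post)
    peak_index = int(post_idx[np.argmax(smoothed[post_idx])])
    peak_val = float(smoothed[peak_index])
    if peak_val <= base_mean + snr_k * base_sd:
        raise NoPeakError(
            f"smoothed peak {peak_val:.3g} not above baseline "
            f"{base_mean:.3g} + {snr_k}*{base_sd:.3g}"
        )
    scale = 100.0 / (peak_val - base_mean)
    saturated = saturation_value is not None and bool(np.any(raw >= saturation_value))
    return NormalizedCurve(
        times=times,
        values=(smoothed - base_mean) * scale,
        raw_values=(raw - base_mean) * scale,
        peak_index=peak_index,
        peak_time=float(times[peak_index]),
        baseline_mean=base_mean,
        baseline_sd=base_sd,
        saturated=saturated,
    )


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def compute_half_rise(curve: NormalizedCurve, level: float = 50.0) -> float:
    """First time at or before the peak where the curve crosses ``level`` rising."""
    v = curve.values
    post = np.flatnonzero(curve.times >= 0)
    start = int(post[0])
    for i in range(start, curve.peak_index + 1):
        if v[i] >= level:
            if i == start or v[i - 1] >= level:
                return float(curve.times[i])
            return _interp_crossing(
                curve.times[i - 1], curve.times[i], v[i - 1], v[i], level
            )
    raise FadynError("normalized curve never reached the rise threshold before its peak")


def compute_half_fall(curve: NormalizedCurve, level: float = 50.0) -> float | None:
    """First time after the peak the curve falls through ``level``; None = censored."""
    v = curve.values
    for j in range(curve.peak_index + 1, v.size):
        if v[j] < level:
            return _interp_crossing(
                curve.times[j - 1], curve.times[j], v[j - 1], v[j], level
            )
    return None


def compute_offset(
    curve: NormalizedCurve, plateau_window: tuple[float, float] | None = None
) -> float:
    """Mean raw normalized value over the plateau window, clamped to [0, 100]."""
    t = curve.times
    if plateau_window is None:
        plateau_window = (t[-1] - 5.0, t[-1])
    lo, hi = plateau_window
    eps = 1e-9
    if hi > t[-1] + eps or lo < t[0] - eps:
        raise WindowError("plateau window must lie within the recording")
    if lo <= curve.peak_time:
        raise WindowError("plateau window must start after the curve peak")
    sel = (t >= lo - eps) & (t <= hi + eps)
    if not sel.any():
        raise WindowError("no samples in the plateau window")
    return float(np.clip(curve.raw_values[sel].mean(), 0.0, 100.0))


# ---------------------------------------------------------------------------
# Whole-image maps
# ---------------------------------------------------------------------------


@dataclass
class DynamicsMaps:
    """Per-pixel half-rise (s), half-fall (s) and offset (%) maps.

    Invalid pixels are NaN in the parameter maps and carry exactly one reason
    code in ``reason`` (see :data:`REASON_NAMES`). Pixels censored for
    half-fall keep their half-rise and offset values. ``peak_raw`` is the
    per-pixel maximum of the (registered) raw stack, the image used for
    vessel segmentation.
    """

    half_rise: np.ndarray
    half_fall: np.ndarray
    offset: np.ndarray
    reason: np.ndarray
    frame_rate: float
    bolus_onset_s: float
    peak_raw: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.reason.shape

    def valid_mask(self, parameter: str) -> np.ndarray:
        ok = self.reason == REASON_OK
        if parameter in ("half_rise", "offset"):
            return ok | (self.reason == REASON_CENSORED_HALF_FALL)
        if parameter == "half_fall":
            return ok
        raise KeyError(parameter)

    def values(
        self,
        parameter: str,
        label_map: VesselLabelMap | None = None,
        vessel_class: str | None = None,
    ) -> np.ndarray:
        """Finite values of one parameter, optionally restricted to one class."""
        sel = self.valid_mask(parameter)
        if vessel_class is not None:
            if label_map is None:
                raise ValueError("label_map required to select a vessel class")
            sel = sel & (label_map.labels == NAME_TO_LABEL[vessel_class])
        vals = getattr(self, parameter)[sel]
        return vals[np.isfinite(vals)]

    def n_censored(
        self, label_map: VesselLabelMap | None = None, vessel_class: str | None = None
    ) -> int:
        sel = self.reason == REASON_CENSORED_HALF_FALL
        if vessel_class is not None and label_map is not None:
            sel = sel & (label_map.labels == NAME_TO_LABEL[vessel_class])
        return int(sel.sum())


def compute_maps(
    stack: VideoStack,
    config: AnalysisConfig = AnalysisConfig(),
    label_map: VesselLabelMap | None = None,
    invalid_mask: np.ndarray | None = None,
) -> DynamicsMaps:
    """Apply normalize / half-rise / half-fall / offset to every pixel.

    ``label_map`` (optional) marks background pixels; ``invalid_mask``
    (optional, True = unusable, e.g. registration border pixels) marks pixels
    to exclude. Per-pixel failures become reason codes, never exceptions.
    Deterministic and vectorized over pixels.
    """
    t = stack.analysis_times()
    n_frames, h, w = stack.frames.shape
    n_pix = h * w
    X = stack.frames.reshape(n_frames, n_pix).astype(np.float64)

    if config.baseline_window_s is None:
        base_sel = t < 0
    else:
        lo, hi = config.baseline_window_s
        if hi > 0:
            raise WindowError("baseline window must lie wholly before bolus onset")
        base_sel = (t >= lo) & (t < hi)
    if not base_sel.any():
        raise WindowError("no baseline samples before bolus onset")
    post = t >= 0

    base_mean = X[base_sel].mean(axis=0)
    base_sd = X[base_sel].std(axis=0)

    width = config.smoothing_samples(stack.frame_rate)
    S = _smooth(X, width)

    post_idx = np.flatnonzero(post)
    pk_rel = np.argmax(S[post_idx], axis=0)
    peak_idx = post_idx[pk_rel]
    cols = np.arange(n_pix)
    peak_val = S[peak_idx, cols]
    signal = peak_val - base_mean

    sat_val = config.saturation_value
    if sat_val is None:
        sat_val = stack.saturation_value
    saturated = (
        (X >= sat_val).any(axis=0) if sat_val is not None else np.zeros(n_pix, dtype=bool)
    )

    weak = signal <= config.snr_k * base_sd
    flat_base = base_sd == 0

    reason = np.zeros(n_pix, dtype=np.uint8)
    reason[weak] = REASON_LOW_SNR
    reason[weak & flat_base] = REASON_NO_PEAK
    reason[saturated] = REASON_SATURATED
    if invalid_mask is not None:
        reason[np.asarray(invalid_mask, dtype=bool).ravel()] = REASON_LOW_SNR
    if label_map is not None:
        if label_map.shape != (h, w):
            raise WindowError("label map dimensions do not match the video frames")
        reason[(label_map.labels == LABEL_BACKGROUND).ravel()] = REASON_BACKGROUND

    live = reason == REASON_OK
    safe_signal = np.where(signal > 0, signal, 1.0)
    V = (S - base_mean) / safe_signal * 100.0
    level = config.half_level
    frame_no = np.arange(n_frames)[:, None]

    # --- half-rise: first post-onset sample at/above level, at or before peak
    rise_cond = (V >= level) & (frame_no <= peak_idx[None, :]) & post[:, None]
    i = rise_cond.argmax(axis=0)
    i0 = np.maximum(i - 1, 0)
    v1 = V[i, cols]
    v0 = V[i0, cols]
    first_post = post_idx[0]
    denom = np.where(v1 > v0, v1 - v0, 1.0)
    frac = np.where((i > first_post) & (v1 > v0) & (v0 < level), (level - v0) / denom, 0.0)
    half_rise = t[i0] + frac * (t[i] - t[i0])
    half_rise = np.where(
        (i > first_post) & (v0 < level), half_rise, t[i]
    )

    # --- half-fall: first sample strictly after peak below level
    fall_cond = (V < level) & (frame_no > peak_idx[None, :])
    has_fall = fall_cond.any(axis=0)
    j = fall_cond.argmax(axis=0)
    j0 = np.maximum(j - 1, 0)
    v1 = V[j, cols]
    v0 = V[j0, cols]
    denom = np.where(v0 > v1, v0 - v1, 1.0)
    frac = np.where(v0 > v1, (v0 - level) / denom, 0.0)
    half_fall = t[j0] + frac * (t[j] - t[j0])
    half_fall = np.where(has_fall, half_fall, np.nan)

    # --- offset: mean of raw normalized values over the end plateau
    plateau_lo = t[-1] - config.plateau_window_s
    plateau = t >= plateau_lo - 1e-9
    R = (X[plateau] - base_mean) / safe_signal * 100.0
    offset = np.clip(R.mean(axis=0), 0.0, 100.0)

    # a peak inside the plateau window means there is no resolved transit
    peak_in_plateau = live & (t[peak_idx] >= plateau_lo)
    reason[peak_in_plateau] = REASON_LOW_SNR
    live = reason == REASON_OK
    reason[live & ~has_fall] = REASON_CENSORED_HALF_FALL

    rise_ok = (reason == REASON_OK) | (reason == REASON_CENSORED_HALF_FALL)
    half_rise = np.where(rise_ok, half_rise, np.nan)
    offset = np.where(rise_ok, offset, np.nan)
    half_fall = np.where(reason == REASON_OK, half_fall, np.nan)

    peak_raw = stack.frames.max(axis=0).astype(np.float64)
    return DynamicsMaps(
        half_rise=half_rise.reshape(h, w),
        half_fall=half_fall.reshape(h, w),
        offset=offset.reshape(h, w),
        reason=reason.reshape(h, w),
        frame_rate=stack.frame_rate,
        bolus_onset_s=stack.bolus_onset_s,
        peak_raw=peak_raw,
        attrs={"analysis_config": config.to_dict()},
    )
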