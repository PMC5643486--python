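"""Rigid (translation-only) frame alignment.

Per-pixel time-course analysis requires every frame to sample the same tissue
location, but head-fixed preparations still drift by a few pixels over a
minute. Each frame's translation relative to a reference image is estimated
by cross-correlation in the Fourier domain with upsampled-DFT sub-pixel
refinement (``skimage.registration.phase_cross_correlation``); frames and the
reference are mean-subtracted and Hann-windowed first so the estimate is
insensitive to the large global intensity swing of the dye bolus and to
edge effects. The reference defaults to the mean of the pre-bolus baseline
frames, which are motion-representative and independent of the bolus.

Rotation and warping are deliberately not modelled: the preparations are
rigidly fixed, and a translation-only contract keeps recovery testable
against ground-truth shifts. Frames whose aligned correlation with the
reference falls below a threshold are flagged invalid rather than
force-aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import RegistrationError
from .io import VideoStack

__all__ = ["ShiftEstimate", "estimate_shifts", "apply_shifts", "baseline_reference"]


@dataclass
class ShiftEstimate:
    """Per-frame rigid displacement relative to the reference image.

    ``shifts[k] = (dy, dx)`` is the displacement the frame content has
    undergone relative to the reference (sub-pixel, in pixels); applying the
    negated shift re-aligns the frame. ``scores`` are Pearson correlations of
    the aligned frame with the reference, clipped to [0, 1]; frames with
    ``valid = False`` (undefined shift or score below threshold) should be
    treated as unaligned.
    """

    shifts: np.ndarray  # (T, 2) as (dy, dx)
    scores: np.ndarray  # (T,)
    valid: np.ndarray  # (T,) bool
    min_score: float = 0.2

    @property
    def n_frames(self) -> int:
        return self.shifts.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "dx": self.shifts[:, 1],
                "dy": self.shifts[:, 0],
                "score": self.scores,
                "valid": self.valid,
            }
        )

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def baseline_reference(stack: VideoStack, upsample_factor: int = 50) -> np.ndarray:
    """Mean of the pre-bolus baseline frames, anchored at the first frame.

    Baseline frames drift too; averaging them as-is would blur the reference
    and anchor it at the *average* baseline position. Each baseline frame is
    therefore first aligned to the first frame, so the reference is sharp and
    all reported shifts are relative to the recording start.
    """
    base = stack.baseline_frames().astype(np.float64)
    if base.shape[0] == 0:
        raise RegistrationError("stack has no pre-bolus baseline frames")
    first = base[0]
    if np.ptp(first) == 0 or base.shape[0] == 1:
        return base.mean(axis=0)
    win = _hann2d(first.shape)
    first_p = _prepare(first, win)
    acc = first.copy()
    count = 1
    for frame in base[1:]:
        if np.ptp(frame) == 0:
            continue
        res, _, _ = phase_cross_correlation(
            first_p, _prepare(frame, win), upsample_factor=upsample_factor,
            normalization=None,
        )
        acc += ndimage.shift(frame, res, order=1, mode="nearest")
        count += 1
    return acc / count


def _prepare(img: np.ndarray, window: np.ndarray) -> np.ndarray:
    img = img.astype(np.float64)
    return (img - img.mean()) * window


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    return np.hanning(shape[0])[:, None] * np.hanning(shape[1])[None, :]


def estimate_shifts(
    stack: VideoStack,
    reference: np.ndarray | None = None,
    upsample_factor: int = 50,
    min_score: float = 0.2,
) -> ShiftEstimate:
    """Estimate each frame's translation relative to ``reference``.

    Deterministic. A frame with zero intensity variation has no defined
    shift; it is flagged (shift NaN, score 0, ``valid=False``) rather than
    guessed.
    """
    if reference is None:
        reference = baseline_reference(stack)
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape != stack.image_shape:
        raise RegistrationError(
            f"reference shape {reference.shape} != frame shape {stack.image_shape}"
        )
    if np.ptp(reference) == 0:
        raise RegistrationError("reference image is constant; cannot register")
    win = _hann2d(reference.shape)
    ref_p = _prepare(reference, win)
    n = stack.n_frames
    shifts = np.zeros((n, 2))
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for k in range(n):
        frame = stack.frames[k]
        if np.ptp(frame) == 0:
            shifts[k] = np.nan
            scores[k] = 0.0
            valid[k] = False
            continue
        res, _, _ = phase_cross_correlation(
            ref_p, _prepare(frame, win), upsample_factor=upsample_factor,
            normalization=None,
        )
        disp = -np.asarray(res, dtype=float)  # displacement of frame vs reference
        shifts[k] = disp
        scores[k] = _alignment_score(reference, frame, disp)
        valid[k] = scores[k] >= min_score
    return ShiftEstimate(shifts=shifts, scores=scores, valid=valid, min_score=min_score)


def _alignment_score(reference: np.ndarray, frame: np.ndarray, disp: np.ndarray) -> float:
    """Pearson correlation of the re-aligned frame with the reference, in [0, 1]."""
    aligned = ndimage.shift(frame.astype(np.float64), -disp, order=1, mode="nearest")
    b = int(np.ceil(np.max(np.abs(disp)))) + 1
    h, w = reference.shape
    if 2 * b >= min(h, w):
        return 0.0
    a = aligned[b : h - b, b : w - b].ravel()
    r = reference[b : h - b, b : w - b].astype(np.float64).ravel()
    sa, sr = a.std(), r.std()
    if sa == 0 or sr == 0:
        return 0.0
    rho = float(np.dot(a - a.mean(), r - r.mean()) / (a.size * sa * sr))
    return float(np.clip(rho, 0.0, 1.0))


def apply_shifts(
    stack: VideoStack, est: ShiftEstimate
) -> tuple[VideoStack, np.ndarray]:
    """Resample every frame by its negated shift (linear interpolation).

    Returns the aligned stack and a 2-D boolean mask of pixels that stayed
    inside the frame for every valid shift; pixels that entered from outside
    the field of view at any frame are ``False`` and must be excluded from
    per-pixel analysis. Flagged frames (undefined shift or low score) are
    passed through unshifted rather than force-aligned with an untrusted
    estimate. If every shift is exactly zero the input frames are returned
    unchanged (bit-exact).
    """
    shifts = np.where(
        np.isfinite(est.shifts) & est.valid[:, None], est.shifts, 0.0
    )
    if shifts.shape[0] != stack.n_frames:
        raise RegistrationError("one shift per frame required")
    h, w = stack.image_shape
    valid_mask = np.ones((h, w), dtype=bool)
    if not np.any(shifts):
        return stack, valid_mask
    out = np.empty((stack.n_frames, h, w), dtype=np.float64)
    for k in range(stack.n_frames):
        dy, dx = shifts[k]
        frame = stack.frames[k].astype(np.float64)
        if dy == 0.0 and dx == 0.0:
            out[k] = frame
        else:
            out[k] = ndimage.shift(frame, (-dy, -dx), order=1, mode="nearest")
    # pixel (r, c) of the aligned frame sampled source (r + dy, c + dx)
    dy_max, dx_max = shifts.max(axis=0)
    dy_min, dx_min = shifts.min(axis=0)
    top = int(np.ceil(max(-dy_min, 0.0)))
    bottom = int(np.ceil(max(dy_max, 0.0)))
    left = int(np.ceil(max(-dx_min, 0.0)))
    right = int(np.ceil(max(dx_max, 0.0)))
    if top:
        valid_mask[:top, :] = False
    if bottom:
        valid_mask[h - bottom :, :] = False
    if left:
        valid_mask[:, :left] = False
    if right:
        valid_mask[:, w - right :] = False
    aligned = VideoStack(
        frames=out,
        frame_rate=stack.frame_rate,
        bolus_onset_s=stack.bolus_onset_s,
        animal_id=stack.animal_id,
        site=stack.site,
    )
    return aligned, valid_mask
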