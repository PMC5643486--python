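"""Artery/vein/capillary labelling from fill timing.

Manually drawn label masks are first-class inputs and always take precedence;
the automatic mode exists so fully synthetic studies run unattended. It works
in two steps: (1) segment the large vessels on the peak image (per-pixel
maximum of the registered stack) with a three-class Otsu threshold — the peak
histogram has background, diffuse capillary/extravascular and large-vessel
modes, and the top class is the vessels — plus removal of small connected
components; (2) split the large-vessel pixels into
two clusters of half-rise time with a deterministic 1-D 2-means
(initialized at the 10th/90th percentiles): the earlier-filling cluster is
arterial, the later venous. Remaining foreground pixels with a valid transit
are capillary/extravascular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import remove_small_objects

from .errors import ClassificationError, InsufficientDataError, SegmentationError
from .io import (
    LABEL_ARTERY,
    LABEL_BACKGROUND,
    LABEL_CAPILLARY,
    LABEL_VEIN,
    VesselLabelMap,
)

__all__ = ["ClassificationResult", "segment_vessels", "classify_by_timing"]


@dataclass
class ClassificationResult:
    label_map: VesselLabelMap
    counts: dict[str, int]
    method: str  # "manual" | "auto_timing"
    quality: float  # silhouette-style separation of the half-rise clusters

    def __post_init__(self):
        non_bg = sum(v for k, v in self.counts.items() if k != "background")
        total = int(np.count_nonzero(self.label_map.labels != LABEL_BACKGROUND))
        if non_bg != total:
            raise ClassificationError("class counts do not sum to non-background pixels")


def segment_vessels(peak_image: np.ndarray, min_size: int = 20) -> np.ndarray:
    """Binary large-vessel mask from the peak (per-pixel maximum) image.

    Three-class Otsu: the peak histogram carries a dark background mode, a
    diffuse capillary/extravascular mode and a bright large-vessel mode; the
    upper threshold isolates the vessels. 8-connected components smaller than
    ``min_size`` pixels are removed.
    """
    img = np.asarray(peak_image, dtype=np.float64)
    if img.ndim != 2:
        raise SegmentationError("peak image must be 2-D")
    if np.ptp(img) == 0:
        raise SegmentationError("peak image is uniform; nothing to segment")
    try:
        thr = threshold_multiotsu(img, classes=3)[-1]
    except ValueError:  # fewer than 3 distinct grey levels
        thr = threshold_otsu(img)
    vessels = img > thr
    if not vessels.any():
        raise SegmentationError("no foreground above the Otsu threshold")
    vessels = remove_small_objects(vessels, max_size=min_size - 1, connectivity=2)
    if not vessels.any():
        raise SegmentationError("no vessel component of at least "
                                f"{min_size} pixels survived cleanup")
    return vessels


def _two_means_1d(x: np.ndarray, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means, k=2, centers seeded at the 10th/90th percentiles."""
    centers = np.percentile(x, [10.0, 90.0]).astype(np.float64)
    if centers[0] == centers[1]:
        raise ClassificationError("half-rise values are degenerate; cannot split clusters")
    labels = np.zeros(x.size, dtype=np.int8)
    for _ in range(max_iter):
        # nearest-center assignment reduces to a midpoint threshold in 1-D
        mid = centers.mean()
        new_labels = (x > mid).astype(np.int8)
        if new_labels.all() or not new_labels.any():
            break
        new_centers = np.array([x[new_labels == 0].mean(), x[new_labels == 1].mean()])
        if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
            break
        labels, centers = new_labels, new_centers
    if labels.all() or not labels.any():
        raise ClassificationError("fill-timing clusters collapsed to one group")
    return labels, centers


def _separation_score(x: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette-style cluster separation in [0, 1] (1 = perfectly split)."""
    a, b = x[labels == 0], x[labels == 1]
    spread = (a.std() + b.std()) / 2.0
    gap = abs(b.mean() - a.mean())
    if gap == 0:
        return 0.0
    return float(np.clip(gap / (gap + 2.0 * spread), 0.0, 1.0))


def classify_by_timing(
    half_rise: np.ndarray,
    vessel_mask: np.ndarray,
    min_coverage: float = 0.5,
) -> ClassificationResult:
    """Label pixels by fill timing: early large vessels are arteries, late veins.

    ``half_rise`` is the per-pixel half-rise map (NaN where invalid);
    ``vessel_mask`` the binary large-vessel mask. Requires a valid half-rise
    on at least ``min_coverage`` of the vessel mask. Deterministic and
    independent of pixel order.
    """
    half_rise = np.asarray(half_rise, dtype=np.float64)
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if half_rise.shape != vessel_mask.shape:
        raise ClassificationError("half-rise map and vessel mask shapes differ")
    valid = np.isfinite(half_rise)
    vm_valid = vessel_mask & valid
    n_mask = int(vessel_mask.sum())
    if n_mask == 0:
        raise InsufficientDataError("empty vessel mask")
    if vm_valid.sum() < min_coverage * n_mask:
        raise InsufficientDataError(
            "half-rise valid on "
            f"{vm_valid.sum()}/{n_mask} vessel pixels (< {min_coverage:.0%})"
        )
    x = half_rise[vm_valid]
    cl, centers = _two_means_1d(x)
    early_is_artery = centers[0] <= centers[1]

    labels = np.full(half_rise.shape, LABEL_BACKGROUND, dtype=np.uint8)
    rr, cc = np.nonzero(vm_valid)
    art = cl == (0 if early_is_artery else 1)
    labels[rr[art], cc[art]] = LABEL_ARTERY
    labels[rr[~art], cc[~art]] = LABEL_VEIN
    labels[valid & ~vessel_mask] = LABEL_CAPILLARY

    lm = VesselLabelMap(labels)
    result = ClassificationResult(
        label_map=lm,
        counts=lm.counts(),
        method="auto_timing",
        quality=_separation_score(x, cl),
    )
    # fill-timing semantics: arteries must not fill later than veins
    med_a = np.median(half_rise[lm.mask("artery")])
    med_v = np.median(half_rise[lm.mask("vein")])
    if med_a > med_v:
        raise ClassificationError("artery cluster fills later than vein cluster")
    return result
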