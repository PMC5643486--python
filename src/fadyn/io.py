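"""Reading and writing video stacks, vessel label masks, parameter maps and manifests.

Conventions used everywhere in the package:

* pixel coordinates are 0-based ``(row, column)``;
* the frame (time) axis comes first in every stack array;
* *recording time* is 0 at the first frame; *analysis time* is 0 at bolus
  onset, so the pre-bolus baseline segment carries negative analysis times;
* vessel labels are small integers: 0 = background, 1 = artery, 2 = vein,
  3 = capillary / extravascular space.

Video stacks are stored as multi-page TIFF with a JSON metadata sidecar
(``frame_rate``, ``bolus_onset_s``, optionally ``animal_id`` and ``site``);
label masks as single-page integer TIFF or PNG; parameter maps as one
floating-point TIFF per parameter plus a validity mask and a JSON provenance
record; group manifests as CSV with a fixed header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError

LABEL_BACKGROUND = 0
LABEL_ARTERY = 1
LABEL_VEIN = 2
LABEL_CAPILLARY = 3

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_ARTERY: "artery",
    LABEL_VEIN: "vein",
    LABEL_CAPILLARY: "capillary_extravascular",
}
NAME_TO_LABEL = {v: k for k, v in LABEL_NAMES.items()}

#: Vessel compartments carrying a transit signal (everything but background).
VESSEL_CLASSES = ("artery", "vein", "capillary_extravascular")

#: The three dynamics indices computed per pixel.
PARAMETERS = ("half_rise", "half_fall", "offset")

SITES = ("retina", "brain")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Video stacks
# ---------------------------------------------------------------------------


@dataclass
class VideoStack:
    """An ordered stack of grayscale frames with its acquisition metadata.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, height, width)``, non-negative intensities.
    frame_rate:
        Acquisition rate in frames per second.
    bolus_onset_s:
        Seconds between recording start and the start of dye infusion; the
        frames before this instant form the normalization baseline.
    """

    frames: np.ndarray
    frame_rate: float
    bolus_onset_s: float
    animal_id: str = ""
    site: str = "retina"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be 3-D (time, row, col), got {self.frames.ndim}-D")
        if self.frames.size == 0:
            raise FormatError("empty video stack")
        if np.issubdtype(self.frames.dtype, np.floating) and not np.all(
            np.isfinite(self.frames)
        ):
            raise FormatError("non-finite intensities in video stack")
        if self.frames.min() < 0:
            raise FormatError("negative intensities in video stack")
        if self.frame_rate <= 0:
            raise FormatError("frame_rate must be positive")
        if self.bolus_onset_s < 0:
            raise FormatError("bolus_onset_s must be non-negative")
        if self.site not in SITES:
            raise FormatError(f"site must be one of {SITES}, got {self.site!r}")
        # a baseline segment and at least one post-bolus frame must exist
        if self.n_frames <= self.frame_rate * self.bolus_onset_s:
            raise FormatError(
                f"stack of {self.n_frames} frames at {self.frame_rate} fps contains "
                f"no data after the bolus onset at {self.bolus_onset_s} s"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def saturation_value(self) -> float | None:
        """Digitizer full-scale value inferred from the dtype (None for floats)."""
        if np.issubdtype(self.frames.dtype, np.integer):
            return float(np.iinfo(self.frames.dtype).max)
        return None

    def times(self) -> np.ndarray:
        """Recording times of each frame (s, 0 at first frame)."""
        return np.arange(self.n_frames) / self.frame_rate

    def analysis_times(self) -> np.ndarray:
        """Frame times relative to bolus onset (s; negative = baseline)."""
        return self.times() - self.bolus_onset_s

    def baseline_frames(self) -> np.ndarray:
        """The pre-bolus frames used for normalization."""
        return self.frames[self.analysis_times() < 0]

    def metadata(self) -> dict:
        return {
            "frame_rate": self.frame_rate,
            "bolus_onset_s": self.bolus_onset_s,
            "animal_id": self.animal_id,
            "site": self.site,
        }


def read_stack(video_path, metadata_path) -> VideoStack:
    """Load a multi-page TIFF video and its JSON metadata sidecar.

    Intensities are returned exactly as stored (no rescaling). Truncated or
    inconsistent files raise :class:`~fadyn.errors.FormatError` rather than
    returning partial data.
    """
    video_path, metadata_path = Path(video_path), Path(metadata_path)
    try:
        with open(metadata_path) as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read metadata {metadata_path}: {exc}") from exc
    for key in ("frame_rate", "bolus_onset_s"):
        if key not in meta:
            raise FormatError(f"metadata {metadata_path} missing required key {key!r}")
    try:
        with tifffile.TiffFile(video_path) as tf:
            series = tf.series[0]
            # a truncated file keeps the declared series shape but loses pages;
            # reject it instead of returning zero-filled frames
            n_expected = series.shape[0] if len(series.shape) == 3 else 1
            if len(tf.pages) < n_expected:
                raise FormatError(
                    f"{video_path}: truncated stack "
                    f"({len(tf.pages)} pages, {n_expected} declared)"
                )
            frames = series.asarray()
    except FormatError:
        raise
    except (OSError, ValueError, IndexError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read video {video_path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim not in (2, 3) or frames.dtype == object:
        raise FormatError(f"{video_path}: pages do not form a uniform (time, row, col) stack")
    return VideoStack(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        bolus_onset_s=float(meta["bolus_onset_s"]),
        animal_id=str(meta.get("animal_id", "")),
        site=str(meta.get("site", "retina")),
    )


def write_stack(stack: VideoStack, video_path, metadata_path=None) -> None:
    """Write a stack as frame-major multi-page TIFF plus JSON sidecar."""
    video_path = Path(video_path)
    video_path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(video_path, stack.frames)
    if metadata_path is None:
        metadata_path = video_path.with_suffix(".json")
    with open(metadata_path, "w") as fh:
        json.dump(stack.metadata(), fh, indent=1)


# ---------------------------------------------------------------------------
# Vessel label maps
# ---------------------------------------------------------------------------


@dataclass
class VesselLabelMap:
    """Per-pixel compartment labels (background/artery/vein/capillary)."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label map must be a single 2-D image")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if np.any(self.labels != np.round(self.labels)):
                raise FormatError("label map must be integer-valued")
            self.labels = self.labels.astype(np.uint8)
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise FormatError(f"label map contains undefined values {sorted(bad)}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, class_name: str) -> np.ndarray:
        return self.labels == NAME_TO_LABEL[class_name]

    def counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == code))
            for code, name in LABEL_NAMES.items()
        }


def read_label_map(path) -> VesselLabelMap:
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            img = iio.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read label map {path}: {exc}") from exc
    return VesselLabelMap(np.asarray(img))


def write_label_map(label_map: VesselLabelMap, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, label_map.labels.astype(np.uint8))


# ---------------------------------------------------------------------------
# Dynamics maps (one float TIFF per parameter + validity + provenance)
# ---------------------------------------------------------------------------

_MAP_FILES = {
    "half_rise": "half_rise.tif",
    "half_fall": "half_fall.tif",
    "offset": "offset.tif",
    "peak_raw": "peak.tif",
}


def write_maps(maps, out_dir, provenance: dict | None = None) -> dict[str, Path]:
    """Write a :class:`~fadyn.dynamics.DynamicsMaps` bundle to ``out_dir``.

    One float32 TIFF per parameter (NaN where invalid), a ``validity.tif``
    with reason codes, and ``provenance.json`` recording acquisition metadata,
    the reason-code table and any caller-supplied provenance (config hash,
    seed).
    """
    from .dynamics import REASON_NAMES

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, fname in _MAP_FILES.items():
        arr = getattr(maps, name)
        if arr is None:
            continue
        p = out_dir / fname
        tifffile.imwrite(p, arr.astype(np.float32))
        written[name] = p
    p = out_dir / "validity.tif"
    tifffile.imwrite(p, maps.reason.astype(np.uint8))
    written["reason"] = p
    prov = {
        "frame_rate": maps.frame_rate,
        "bolus_onset_s": maps.bolus_onset_s,
        "reason_codes": {str(k): v for k, v in REASON_NAMES.items()},
    }
    prov.update(maps.attrs)
    prov.update(provenance or {})
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, default=str)
    written["provenance"] = out_dir / "provenance.json"
    return written


def read_maps(out_dir):
    """Read back a map bundle written by :func:`write_maps`."""
    from .dynamics import DynamicsMaps

    out_dir = Path(out_dir)
    try:
        with open(out_dir / "provenance.json") as fh:
            prov = json.load(fh)
        arrays = {}
        for name, fname in _MAP_FILES.items():
            p = out_dir / fname
            arrays[name] = tifffile.imread(p).astype(np.float64) if p.exists() else None
        reason = tifffile.imread(out_dir / "validity.tif").astype(np.uint8)
    except (OSError, ValueError, tifffile.TiffFileError, json.JSONDecodeError) as exc:
        raise FormatError(f"cannot read maps bundle in {out_dir}: {exc}") from exc
    attrs = {
        k: v
        for k, v in prov.items()
        if k not in ("frame_rate", "bolus_onset_s", "reason_codes")
    }
    return DynamicsMaps(
        half_rise=arrays["half_rise"],
        half_fall=arrays["half_fall"],
        offset=arrays["offset"],
        reason=reason,
        frame_rate=float(prov["frame_rate"]),
        bolus_onset_s=float(prov["bolus_onset_s"]),
        peak_raw=arrays["peak_raw"],
        attrs=attrs,
    )


# ---------------------------------------------------------------------------
# Group manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("animal_id", "site", "group", "time_point", "video", "meta", "mask")
GROUPS = ("control", "treated")
TIME_POINTS = ("baseline", "6h", "24h")


@dataclass
class ManifestEntry:
    animal_id: str
    site: str
    group: str
    time_point: str
    video: Path
    meta: Path
    mask: Path | None = None


def read_manifest(path) -> list[ManifestEntry]:
    """Read a CSV group manifest; paths are resolved relative to the CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} missing columns {sorted(missing)}")
    base = path.parent
    entries: list[ManifestEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for _, row in df.iterrows():
        key = (row["animal_id"], row["site"], row["time_point"])
        if key in seen:
            raise FormatError(f"duplicate animal_id {key} in manifest {path}")
        seen.add(key)
        if row["site"] not in SITES:
            raise FormatError(f"manifest {path}: unknown site {row['site']!r}")
        if row["group"] not in GROUPS:
            raise FormatError(f"manifest {path}: unknown group {row['group']!r}")
        entry = ManifestEntry(
            animal_id=row["animal_id"],
            site=row["site"],
            group=row["group"],
            time_point=row["time_point"],
            video=base / row["video"],
            meta=base / row["meta"],
            mask=(base / row["mask"]) if row["mask"] else None,
        )
        for p in (entry.video, entry.meta) + ((entry.mask,) if entry.mask else ()):
            if not Path(p).exists():
                raise FormatError(f"manifest {path}: missing file {p}")
        entries.append(entry)
    return entries


def write_manifest(entries: list[ManifestEntry], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = path.parent
    rows = []
    for e in entries:
        rows.append(
            {
                "animal_id": e.animal_id,
                "site": e.site,
                "group": e.group,
                "time_point": e.time_point,
                "video": _relpath(e.video, base),
                "meta": _relpath(e.meta, base),
                "mask": _relpath(e.mask, base) if e.mask else "",
            }
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)


def _relpath(p, base) -> str:
    try:
        return str(Path(p).relative_to(base))
    except ValueError:
        return str(p)
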