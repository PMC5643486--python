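"""Histogram/median/IQR summaries, bootstrap confidence limits and the injury index.

The group-level machinery mirrors how barrier-disruption experiments are
summarized: per-pixel index distributions are reduced to frequency histograms
(normalized to % of class pixels), per-animal medians and interquartile
ranges; control-group medians are bootstrapped (animals resampled with
replacement, 1,000 times) for 95% confidence limits of the group mean of
medians; and a pooled control 75th-percentile cutoff defines the *index of
injury* — the percentage of a treated animal's pixels strictly beyond the
cutoff. For pixels drawn from the control distribution the expected index is
25%, which is the null reference line group means are compared against.

Quantiles use linear interpolation everywhere, and every stochastic operation
is seed-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

from .errors import EmptyInputError, InsufficientDataError, ParameterError

__all__ = [
    "ClassHistogram",
    "ControlReference",
    "build_histogram",
    "summarize",
    "bootstrap_cl",
    "flag_outside_cl",
    "control_cutoff",
    "injury_index",
    "rank_sum_test",
    "DEFAULT_BIN_WIDTHS",
]

#: Default histogram bin widths: 0.1 s for the timing indices, 1% for offset.
DEFAULT_BIN_WIDTHS = {"half_rise": 0.1, "half_fall": 0.1, "offset": 1.0}

#: Null expectation of the injury index (%): pixels from the control
#: distribution exceed the control 75th percentile 25% of the time.
NULL_INJURY_INDEX = 25.0


@dataclass
class ClassHistogram:
    """Frequency histogram of one index for one vessel class.

    ``counts_pct`` are normalized to the number of included pixels (they sum
    to 100); censored pixels are excluded from numerator and denominator but
    reported in ``n_censored``.
    """

    parameter: str
    vessel_class: str
    bin_edges: np.ndarray
    counts_pct: np.ndarray
    n_pixels: int
    n_censored: int = 0


def build_histogram(
    values,
    bin_width: float,
    value_range: tuple[float, float] | None = None,
    parameter: str = "",
    vessel_class: str = "",
    n_censored: int = 0,
) -> ClassHistogram:
    """Histogram with half-open bins ``[edge, edge + width)``, counts in %.

    Values outside ``value_range`` are accumulated into the boundary bins so
    the normalized counts always sum to 100.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise EmptyInputError("cannot histogram an empty value set")
    if not np.all(np.isfinite(values)):
        raise ParameterError("histogram values must be finite")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    if value_range is None:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = np.ceil((values.max() + 1e-12) / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = value_range
        if hi <= lo:
            raise ParameterError("empty value_range")
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + np.arange(n_bins + 1) * bin_width
    clipped = np.clip(values, lo, np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return ClassHistogram(
        parameter=parameter,
        vessel_class=vessel_class,
        bin_edges=edges,
        counts_pct=counts / values.size * 100.0,
        n_pixels=int(values.size),
        n_censored=int(n_censored),
    )


def summarize(values) -> tuple[float, float]:
    """Median and interquartile range (Q75 − Q25, linear-interpolation quantiles)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EmptyInputError("cannot summarize an empty value set")
    q25, q50, q75 = np.percentile(values, [25.0, 50.0, 75.0])
    return float(q50), float(q75 - q25)


def bootstrap_cl(
    per_animal_medians,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    statistic: str = "median",
) -> tuple[float, float]:
    """Bootstrap 95% confidence limits of the control group's central value.

    Animals (not pixels — pixels within an animal are not independent) are
    resampled with replacement ``n_boot`` times; the limits are the 2.5th and
    97.5th percentiles of the resampled statistic. The default statistic is
    the median of the resampled per-animal medians: at n ≈ 10 animals its
    percentile interval is well calibrated (~93% coverage at nominal 95% for a
    normal population), whereas the mean's runs ~89%. ``statistic="mean"``
    selects the group mean instead. Seeded and reproducible.
    """
    med = np.asarray(per_animal_medians, dtype=np.float64).ravel()
    if med.size < 2:
        raise InsufficientDataError("bootstrap requires at least 2 animals")
    if statistic not in ("median", "mean"):
        raise ParameterError("statistic must be 'median' or 'mean'")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, med.size, size=(n_boot, med.size))
    agg = np.median if statistic == "median" else np.mean
    boot = agg(med[idx], axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(lo), float(hi)


def flag_outside_cl(value: float, cl: tuple[float, float]) -> bool:
    """True iff ``value`` falls outside the (inclusive) confidence limits."""
    lo, hi = cl
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
        raise ParameterError("invalid confidence limits")
    return bool(value < lo or value > hi)


def control_cutoff(control_pixel_values, min_pixels: int = 100) -> float:
    """75th percentile of control pixels pooled across animals (the injury cutoff)."""
    vals = np.asarray(control_pixel_values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < min_pixels:
        raise InsufficientDataError(
            f"{vals.size} pooled control pixels < required {min_pixels}"
        )
    return float(np.percentile(vals, 75.0))


def injury_index(pixel_values, cutoff: float) -> float:
    """Percentage of pixels strictly beyond the control cutoff, in [0, 100]."""
    vals = np.asarray(pixel_values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyInputError("injury index of an empty pixel set")
    return float(100.0 * np.count_nonzero(vals > cutoff) / vals.size)


def rank_sum_test(group_a, group_b) -> tuple[float, float]:
    """Mann–Whitney U with two-sided p.

    Exact enumeration for combined n ≤ 12 without ties, normal approximation
    with tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64).ravel()
    b = np.asarray(group_b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise EmptyInputError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 12 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Control reference (cutoffs + confidence limits), JSON-serializable
# ---------------------------------------------------------------------------


@dataclass
class ReferenceEntry:
    cutoff: float
    cl_low: float
    cl_high: float
    n_animals: int
    n_pixels: int


@dataclass
class ControlReference:
    """Per (vessel class, parameter): pooled 75th-percentile cutoff and
    bootstrap 95% confidence limits of the control mean-of-medians."""

    site: str
    time_point: str
    n_boot: int
    seed: int
    entries: dict[tuple[str, str], ReferenceEntry] = field(default_factory=dict)

    def cutoff(self, vessel_class: str, parameter: str) -> float:
        return self.entries[(vessel_class, parameter)].cutoff

    def cl(self, vessel_class: str, parameter: str) -> tuple[float, float]:
        e = self.entries[(vessel_class, parameter)]
        return e.cl_low, e.cl_high

    def to_json(self, path) -> None:
        payload = {
            "site": self.site,
            "time_point": self.time_point,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "entries": [
                {
                    "vessel_class": cls,
                    "parameter": par,
                    "cutoff": e.cutoff,
                    "cl_low": e.cl_low,
                    "cl_high": e.cl_high,
                    "n_animals": e.n_animals,
                    "n_pixels": e.n_pixels,
                }
                for (cls, par), e in self.entries.items()
            ],
        }
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ControlReference":
        with open(path) as fh:
            payload = json.load(fh)
        ref = cls(
            site=payload["site"],
            time_point=payload.get("time_point", ""),
            n_boot=int(payload["n_boot"]),
            seed=int(payload["seed"]),
        )
        for e in payload["entries"]:
            ref.entries[(e["vessel_class"], e["parameter"])] = ReferenceEntry(
                cutoff=float(e["cutoff"]),
                cl_low=float(e["cl_low"]),
                cl_high=float(e["cl_high"]),
                n_animals=int(e["n_animals"]),
                n_pixels=int(e["n_pixels"]),
            )
        return ref


def build_reference(
    control_values: dict[tuple[str, str], list[np.ndarray]],
    site: str,
    time_point: str,
    n_boot: int = 1000,
    seed: int = 0,
    min_pixels: int = 100,
) -> ControlReference:
    """Assemble a :class:`ControlReference` from per-animal control pixel values.

    ``control_values[(vessel_class, parameter)]`` is a list (one entry per
    animal) of 1-D pixel-value arrays.
    """
    ref = ControlReference(site=site, time_point=time_point, n_boot=n_boot, seed=seed)
    rng = np.random.default_rng(seed)
    for key in sorted(control_values):
        arrays = [np.asarray(a, dtype=np.float64).ravel() for a in control_values[key]]
        arrays = [a[np.isfinite(a)] for a in arrays]
        arrays = [a for a in arrays if a.size]
        if len(arrays) < 2:
            raise InsufficientDataError(f"reference for {key} needs >= 2 animals with data")
        pooled = np.concatenate(arrays)
        medians = [float(np.median(a)) for a in arrays]
        lo, hi = bootstrap_cl(medians, n_boot=n_boot, rng=rng)
        ref.entries[key] = ReferenceEntry(
            cutoff=control_cutoff(pooled, min_pixels=min_pixels),
            cl_low=lo,
            cl_high=hi,
            n_animals=len(arrays),
            n_pixels=int(pooled.size),
        )
    return ref
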