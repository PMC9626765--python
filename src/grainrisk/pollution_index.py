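"""Single-factor pollution index, grading, exceedance and category binning.

The single-factor pollution index Pi = Ci/Si compares a crop's mean Cd
concentration Ci to the Chinese regulatory maximum level Si (GB 2762-2017:
rice 0.2, corn and wheat 0.1 mg/kg).  Grades: Pi <= 0.7 excellent quality,
0.7 < Pi <= 1 safe, 1 < Pi <= 2 slight pollution, Pi > 2 pollution.

Category binning summarises the concentration distribution per crop: Cd
categories follow the Pi grade cuts applied to concentration — boundaries
at (0.35, 0.7, 1, 2) x Si, the excellent band split equally in two — while
F, having no food-safety limit, is split into equal-frequency quintiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import EmptyGroupError, ParameterError
from .io_config import SampleRecord, subset

GRADES = ("excellent", "safe", "slight_pollution", "pollution")


@dataclass(frozen=True)
class PiResult:
    crop: str
    element: str
    mean_c: float
    si_limit: float
    pi: float
    grade: str


@dataclass(frozen=True)
class BinSummary:
    """Per-category summary: count and observed range/median/mean."""

    n: int
    obs_min: float | None
    obs_max: float | None
    median: float | None
    mean: float | None


@dataclass(frozen=True)
class CategoryBinning:
    crop: str
    element: str
    boundaries: tuple[float, float, float, float]
    per_category: tuple[BinSummary, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (b[0] < b[1] < b[2] < b[3]):
            raise ParameterError(f"bin boundaries must be strictly ascending: {b}")


def compute_pi(mean_c: float, si: float) -> float:
    """Pi = mean concentration / regulatory limit."""
    if si <= 0:
        raise ParameterError(f"regulatory limit si must be positive, got {si}")
    if mean_c < 0:
        raise ParameterError(f"mean concentration must be non-negative, got {mean_c}")
    return mean_c / si


def grade_pi(pi: float) -> str:
    """Grade a pollution index; each band is closed on its upper cut."""
    if pi < 0:
        raise ParameterError(f"pollution index must be non-negative, got {pi}")
    if pi <= 0.7:
        return "excellent"
    if pi <= 1.0:
        return "safe"
    if pi <= 2.0:
        return "slight_pollution"
    return "pollution"


def pi_for_crop(records: Iterable[SampleRecord], crop: str, si: float) -> PiResult:
    values = [r.cd_mgkg for r in subset(records, crop)]
    if not values:
        raise EmptyGroupError(f"no records for crop {crop!r}")
    mean_c = float(np.mean(values))
    pi = compute_pi(mean_c, si)
    return PiResult(crop=crop, element="Cd", mean_c=mean_c, si_limit=si,
                    pi=pi, grade=grade_pi(pi))


def exceedance_ratio(records: Iterable[SampleRecord], crop: str, limit: float,
                     element: str = "Cd") -> float:
    """Percent of the crop's samples strictly above the limit.

    A value exactly at the limit is compliant (strict ``>``), per the
    GB 2762-2017 reading of a maximum level.
    """
    values = [r.concentration(element) for r in subset(records, crop)]
    if not values:
        raise EmptyGroupError(f"no records for crop {crop!r}")
    exceed = sum(v > limit for v in values)
    return 100.0 * exceed / len(values)


def _bin_summaries(values: np.ndarray, assignments: np.ndarray,
                   n_bins: int = 5) -> tuple[BinSummary, ...]:
    out = []
    for b in range(n_bins):
        vals = values[assignments == b]
        if vals.size == 0:
            out.append(BinSummary(n=0, obs_min=None, obs_max=None,
                                  median=None, mean=None))
        else:
            out.append(
                BinSummary(
                    n=int(vals.size),
                    obs_min=float(vals.min()),
                    obs_max=float(vals.max()),
                    median=float(np.median(vals)),
                    mean=float(vals.mean()),
                )
            )
    return tuple(out)


def bin_cd_categories(records: Iterable[SampleRecord], crop: str,
                      si: float) -> CategoryBinning:
    """Five Cd categories at concentration cuts (0.35, 0.7, 1, 2) x Si.

    These are the Pi grade thresholds mapped to concentration, with the
    excellent band (Pi <= 0.7) split equally in two.  Intervals are closed
    on the right (a value exactly at a cut falls in the lower category),
    matching the grade convention.  Reported ranges are observed extremes
    within each theoretical bin.
    """
    if si <= 0:
        raise ParameterError(f"regulatory limit si must be positive, got {si}")
    values = np.array([r.cd_mgkg for r in subset(records, crop)], dtype=float)
    if values.size == 0:
        raise EmptyGroupError(f"no records for crop {crop!r}")
    boundaries = (0.35 * si, 0.7 * si, 1.0 * si, 2.0 * si)
    # right-closed: index = number of boundaries strictly below the value;
    # the relative nudge keeps a value at a cut in the lower bin despite
    # binary representation noise in 0.35*si / 0.7*si
    eff = np.asarray(boundaries) * (1 + 1e-12)
    assignments = np.searchsorted(eff, values, side="left")
    return CategoryBinning(
        crop=crop,
        element="Cd",
        boundaries=boundaries,
        per_category=_bin_summaries(values, assignments),
    )


def quintile_slices(n: int, n_bins: int = 5) -> list[tuple[int, int]]:
    """Sort-position slices for equal-frequency bins; sizes differ by <= 1."""
    return [(b * n // n_bins, (b + 1) * n // n_bins) for b in range(n_bins)]


def bin_f_categories(records: Iterable[SampleRecord], crop: str) -> CategoryBinning:
    """Equal-frequency (quintile) F categories on observed values.

    F has no current food-safety limit, so the distribution is split into
    five rank-based categories of (near-)equal size.  Boundaries reported
    are the upper observed value of the first four bins.
    """
    values = np.array([r.f_mgkg for r in subset(records, crop)], dtype=float)
    n = values.size
    if n < 5:
        raise EmptyGroupError(f"need >= 5 records for quintile binning, got {n}")
    order = np.argsort(values, kind="stable")
    assignments = np.empty(n, dtype=int)
    slices = quintile_slices(n)
    for b, (lo, hi) in enumerate(slices):
        assignments[order[lo:hi]] = b
    sorted_vals = values[order]
    boundaries = tuple(float(sorted_vals[hi - 1]) for _, hi in slices[:4])
    return CategoryBinning(
        crop=crop,
        element="F",
        boundaries=boundaries,  # type: ignore[arg-type]
        per_category=_bin_summaries(values, assignments),
    )
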