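"""Incidence age ranges, the years-per-step statistic, and their analyses.

The incidence age range of a stratum is the interval from the start of
its first nonzero-incidence bin to the end of its last one (after the
same >= 80-year truncation rule used in the multistep fit).  Dividing
the range width by the fitted step count gives years/step — the average
time for one rate-limiting step to occur — which groups the diseases
into tiers (slow stem diseases, intermediate trunk diseases, fast crown
diseases).  The step count is inversely related to the range width: a
disease needing more steps has a narrower onset window, captured by the
steps-versus-range regression.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io import IncidenceDataset
from .multistep import (
    TRUNCATION_AGE,
    TRUNCATION_MIN_POINTS,
    MultistepFit,
)


@dataclasses.dataclass(frozen=True)
class AgeRangeSummary:
    """Onset age range and years/step for one stratum.

    ``n_steps``/``years_per_step`` are None for strata without a valid
    multistep fit (e.g. the non-monotone control); such strata still
    contribute their range to the shared-age-range analysis.
    """

    label: str
    age_min: float
    age_max: float
    n_steps: int | None = None
    years_per_step: float | None = None
    passes_linearity: bool = False

    @property
    def range_width(self) -> float:
        return self.age_max - self.age_min


def incidence_age_range(
    datasets: Sequence[IncidenceDataset],
    *,
    truncation: bool = True,
    truncation_age: float = TRUNCATION_AGE,
    min_points_after: int = TRUNCATION_MIN_POINTS,
    use_midpoints: bool = False,
) -> tuple[float, float]:
    """Onset age range (age_min, age_max) across one stratum's datasets.

    Uses bin edges by default (first nonzero bin's start to last nonzero
    bin's end, unioned over studies); ``use_midpoints=True`` switches to
    midpoint semantics.  The >= 80-year truncation mirrors the fit: bins
    with midpoint at or above the cutoff are ignored provided at least
    ``min_points_after`` nonzero bins remain.
    """
    bins = [b for ds in datasets for b in ds.bins if b.incidence > 0]
    if not bins:
        raise ValueError("all-zero incidence: no observable onset range")
    if truncation:
        kept = [b for b in bins if b.midpoint < truncation_age]
        if len(kept) >= min_points_after and len(kept) < len(bins):
            bins = kept
    if use_midpoints:
        return min(b.midpoint for b in bins), max(b.midpoint for b in bins)
    return min(b.age_start for b in bins), max(b.age_end for b in bins)


def years_per_step(range_width: float, n_steps: int) -> float:
    """Average years for one step: range width divided by step count."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if range_width < 0:
        raise ValueError("range_width must be >= 0")
    return range_width / n_steps


def summarize_stratum(
    label: str,
    datasets: Sequence[IncidenceDataset],
    fit: MultistepFit | None,
    *,
    truncation: bool = True,
) -> AgeRangeSummary:
    """Combine a stratum's age range with its multistep fit (if gated in)."""
    lo, hi = incidence_age_range(datasets, truncation=truncation)
    if fit is not None and fit.passes_linearity:
        return AgeRangeSummary(
            label=label,
            age_min=lo,
            age_max=hi,
            n_steps=fit.n_steps,
            years_per_step=years_per_step(hi - lo, fit.n_steps),
            passes_linearity=True,
        )
    return AgeRangeSummary(label=label, age_min=lo, age_max=hi)


@dataclasses.dataclass(frozen=True)
class StepsRangeRegression:
    """OLS of step count on incidence age-range width (slope in steps/year)."""

    slope: float
    intercept: float
    r_squared: float
    n_strata: int

    def summary(self) -> str:
        direction = "inverse" if self.slope < 0 else "direct"
        return (
            f"Steps vs. age-range regression over {self.n_strata} strata\n"
            f"  slope     {self.slope:>10.4f} steps/year ({direction} relation)\n"
            f"  intercept {self.intercept:>10.4f} steps\n"
            f"  R^2       {self.r_squared:>10.4f}"
        )


def fit_steps_vs_range(summaries: Sequence[AgeRangeSummary]) -> StepsRangeRegression:
    """Regress n_steps on range width over gate-passing strata (>= 3)."""
    usable = [s for s in summaries if s.passes_linearity and s.n_steps is not None]
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 strata passing the linearity gate, got {len(usable)}"
        )
    x = np.asarray([s.range_width for s in usable], dtype=float)
    y = np.asarray([float(s.n_steps) for s in usable], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate range variance: all strata share one width")
    res = stats.linregress(x, y)
    return StepsRangeRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_strata=len(usable),
    )


def shared_age_bins(
    summaries: Sequence[AgeRangeSummary], bin_width: float = 2.0
) -> pd.DataFrame:
    """Count strata whose onset range covers each age bin.

    The overall age axis (min age_min to max age_max) is partitioned into
    bins of ``bin_width`` years anchored at the overall minimum; a
    stratum counts toward a bin only if its [age_min, age_max] covers the
    whole bin.  Returns a DataFrame with columns ``age_start, age_end,
    n_strata, strata``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not summaries:
        return pd.DataFrame(columns=["age_start", "age_end", "n_strata", "strata"])
    lo = min(s.age_min for s in summaries)
    hi = max(s.age_max for s in summaries)
    n_bins = max(1, math.ceil((hi - lo) / bin_width - 1e-9))
    rows = []
    for k in range(n_bins):
        b0, b1 = lo + k * bin_width, lo + (k + 1) * bin_width
        covering = sorted(
            s.label for s in summaries if s.age_min <= b0 and s.age_max >= b1
        )
        rows.append(
            {
                "age_start": b0,
                "age_end": b1,
                "n_strata": len(covering),
                "strata": ";".join(covering),
            }
        )
    return pd.DataFrame(rows)


def max_shared_interval(shared: pd.DataFrame) -> tuple[float, float, int]:
    """Longest contiguous run of bins attaining the maximum stratum count.

    Returns (age_start, age_end, count).
    """
    if shared.empty:
        raise ValueError("no shared-age bins")
    top = int(shared["n_strata"].max())
    best: tuple[float, float] | None = None
    run_start = None
    prev_end = None
    for _, row in shared.iterrows():
        if row["n_strata"] == top:
            if run_start is None or row["age_start"] != prev_end:
                run_start = row["age_start"]
            prev_end = row["age_end"]
            if best is None or prev_end - run_start > best[1] - best[0]:
                best = (run_start, prev_end)
        else:
            run_start = None
            prev_end = None
    assert best is not None
    return best[0], best[1], top


def cluster_years_per_step(
    summaries: Sequence[AgeRangeSummary], n_clusters: int = 3
) -> dict[str, int]:
    """Single-linkage grouping of strata by years/step.

    Returns label -> cluster id, ids ordered by increasing mean
    years/step (1 = fastest tier).  Strata without a years/step value are
    omitted.
    """
    usable = [s for s in summaries if s.years_per_step is not None]
    if len(usable) < n_clusters:
        raise ValueError("fewer usable strata than requested clusters")
    vals = np.asarray([[s.years_per_step] for s in usable], dtype=float)
    assignment = fcluster(linkage(vals, method="single"), n_clusters, criterion="maxclust")
    means = {
        c: float(np.mean([v[0] for v, a in zip(vals, assignment) if a == c]))
        for c in set(assignment)
    }
    order = {c: rank + 1 for rank, c in enumerate(sorted(means, key=means.get))}
    return {s.label: order[a] for s, a in zip(usable, assignment)}


def summaries_to_frame(summaries: Sequence[AgeRangeSummary]) -> pd.DataFrame:
    """Tabulate summaries (one row per stratum, label-sorted)."""
    rows = [
        {
            "stratum": s.label,
            "age_min": s.age_min,
            "age_max": s.age_max,
            "range_width": s.range_width,
            "n_steps": s.n_steps,
            "years_per_step": s.years_per_step,
            "passes_linearity": s.passes_linearity,
        }
        for s in sorted(summaries, key=lambda s: s.label)
    ]
    return pd.DataFrame(rows)


def fits_to_frame(fits: Mapping[str, MultistepFit]) -> pd.DataFrame:
    """Tabulate multistep fits (one row per stratum, label-sorted)."""
    rows = [
        {
            "stratum": f.label,
            "slope_m": f.slope_m,
            "intercept_c_natural": f.intercept_c_natural,
            "n_steps": f.n_steps,
            "background_risk_u": f.background_risk_u,
            "geom_mean_risk_mu": f.geom_mean_risk_mu,
            "r_squared": f.r_squared,
            "n_points": f.n_points,
            "truncated": f.truncated,
            "passes_linearity": f.passes_linearity,
        }
        for f in sorted(fits.values(), key=lambda f: f.label)
    ]
    return pd.DataFrame(rows)
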