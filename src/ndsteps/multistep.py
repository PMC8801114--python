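"""The multistep (Armitage-Doll-type) incidence-age model for one stratum.

A disease requiring ``n`` sequential rate-limiting steps has incidence

    i(t) = u1 * u2 * ... * un * t**(n-1) = u * t**(n-1)

so ``log(i) = (n - 1) * log(t) + c`` is a straight line in log-log
coordinates with slope ``m = n - 1`` and intercept ``c = log(u)``.  The
number of steps is recovered as ``n = round(m + 1)``, the aggregate
background risk as ``u = e**c`` (natural-log intercept), and the
per-step geometric-mean risk as ``mu = u**(1/n)``.

:class:`MultistepModel` wraps the ordinary least-squares fit of
log10(incidence) on log10(age) for the pooled bins of one stratum;
:meth:`MultistepModel.fit` returns a :class:`MultistepFit` results object
with the estimates, fit quality, and a linearity gate deciding whether
the stratum behaves like a multistep disease at all (slope must be
positive and R^2 at least ``gate_r2``; the MS-like control fails this).

Data preparation follows two fixed conventions: the representative age
of a bin is its midpoint, and bins with midpoint at 80 years or above
are discarded provided at least 4 points remain afterwards (late-age
incidence estimates are unreliable: survivor depletion, under-ascertainment).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy import stats

from .io import IncidenceDataset

#: Age (years) at and above which bin midpoints are dropped before fitting.
TRUNCATION_AGE = 80.0
#: Minimum number of points that must survive truncation for it to apply.
TRUNCATION_MIN_POINTS = 4
#: Default linearity-gate R^2 threshold.
DEFAULT_GATE_R2 = 0.8


class FitInfeasibleError(ValueError):
    """Fewer than 2 usable points, or degenerate age variance."""


@dataclasses.dataclass(frozen=True)
class LogLogPoints:
    """Pooled log10-log10 points for one stratum.

    ``log_age`` / ``log_incidence`` are log10 of bin-midpoint age (years)
    and of incidence (per 100,000 person-years).  Zero-incidence bins are
    excluded before the transform; ``truncated`` records whether the
    >= 80-year rule removed any bins.
    """

    label: str
    log_age: tuple[float, ...]
    log_incidence: tuple[float, ...]
    source_study_ids: tuple[str, ...]
    truncated: bool

    def __len__(self) -> int:
        return len(self.log_age)


def prepare_points(
    datasets: Sequence[IncidenceDataset],
    *,
    truncation: bool = True,
    truncation_age: float = TRUNCATION_AGE,
    min_points_after: int = TRUNCATION_MIN_POINTS,
) -> LogLogPoints:
    """Pool one stratum's bins across studies into log-log points.

    Bins contribute their midpoint age; zero-incidence bins are dropped
    (log undefined).  Bins with midpoint >= ``truncation_age`` are then
    removed, but only if at least ``min_points_after`` points remain;
    otherwise no truncation is applied.
    """
    if not datasets:
        raise FitInfeasibleError("no datasets supplied")
    labels = {ds.label for ds in datasets}
    if len(labels) != 1:
        raise ValueError(f"datasets span multiple strata: {sorted(labels)}")
    label = labels.pop()

    ages: list[float] = []
    incidences: list[float] = []
    for ds in datasets:
        for b in ds.bins:
            if b.incidence > 0:
                ages.append(b.midpoint)
                incidences.append(b.incidence)
    ages_arr = np.asarray(ages)
    inc_arr = np.asarray(incidences)

    truncated = False
    if truncation:
        keep = ages_arr < truncation_age
        if keep.sum() >= min_points_after and keep.sum() < len(ages_arr):
            ages_arr, inc_arr = ages_arr[keep], inc_arr[keep]
            truncated = True
    if len(ages_arr) < 2:
        raise FitInfeasibleError(
            f"stratum {label}: only {len(ages_arr)} usable points (need >= 2)"
        )
    order = np.argsort(ages_arr)
    return LogLogPoints(
        label=label,
        log_age=tuple(np.log10(ages_arr[order])),
        log_incidence=tuple(np.log10(inc_arr[order])),
        source_study_ids=tuple(sorted({ds.study_id for ds in datasets})),
        truncated=truncated,
    )


def steps_from_slope(slope_m: float) -> int:
    """Number of steps from the log-log slope: ``n = round(m + 1)``.

    Rounding is half-up (2.5 -> 3), with a floor of 1 step.  A slope of
    4.8 or 4.6 therefore maps to a six-step disease.  Slopes at or below
    -1 admit no valid step count.
    """
    if slope_m <= -1:
        raise ValueError(f"slope {slope_m} <= -1 admits no valid step count")
    n = int(math.floor(slope_m + 1.0 + 0.5))  # half-up, also for negatives
    return max(n, 1)


def risk_parameters(intercept_c_natural: float, n_steps: int) -> tuple[float, float]:
    """Background risk ``u = e**c`` and per-step geometric mean ``mu = u**(1/n)``."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    u = math.exp(intercept_c_natural)
    mu = u ** (1.0 / n_steps)
    return u, mu


@dataclasses.dataclass(frozen=True)
class MultistepFit:
    """Results of the log-log incidence-age fit for one stratum.

    Attributes
    ----------
    slope_m
        OLS slope of log10(incidence) on log10(age); dimensionless.
    intercept_c_log10, intercept_c_natural
        Intercept in log10 and natural-log scale (``u = e**c`` uses the
        natural-log value).
    n_steps
        ``round(slope_m + 1)``, half-up, minimum 1.
    background_risk_u, geom_mean_risk_mu
        ``u = e**c`` and ``mu = u**(1/n)``.
    r_squared, n_points, truncated
        Fit diagnostics.
    passes_linearity
        True when ``r_squared >= gate_r2`` and the slope is positive; the
        stratum is treated as following a multistep model only then.
    """

    label: str
    slope_m: float
    intercept_c_log10: float
    intercept_c_natural: float
    n_steps: int
    background_risk_u: float
    geom_mean_risk_mu: float
    r_squared: float
    n_points: int
    truncated: bool
    gate_r2: float
    passes_linearity: bool

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        gate = "pass" if self.passes_linearity else "FAIL"
        lines = [
            f"Multistep incidence-age fit: {self.label}",
            "=" * 44,
            f"  points (pooled bins)     {self.n_points:>12d}",
            f"  >=80y truncation applied {str(self.truncated):>12s}",
            f"  slope m                  {self.slope_m:>12.4f}",
            f"  intercept c (log10)      {self.intercept_c_log10:>12.4f}",
            f"  steps n = round(m + 1)   {self.n_steps:>12d}",
            f"  background risk u = e^c  {self.background_risk_u:>12.4e}",
            f"  per-step risk mu=u^(1/n) {self.geom_mean_risk_mu:>12.4e}",
            f"  R^2                      {self.r_squared:>12.4f}",
            f"  linearity gate (R^2>={self.gate_r2:.2f}) {gate:>10s}",
        ]
        return "\n".join(lines)


class MultistepModel:
    """OLS multistep model for one stratum's pooled log-log points.

    Build from prepared points or directly from datasets; ``fit()``
    returns a :class:`MultistepFit`.

    Examples
    --------
    >>> from ndsteps.simulate import DiseaseSpec, generate_dataset
    >>> spec = DiseaseSpec("ALS", "pooled", 6, 1e-9, 45, 80, noise_sigma=0)
    >>> res = MultistepModel.from_datasets([generate_dataset(spec)]).fit()
    >>> res.n_steps
    6
    """

    def __init__(self, points: LogLogPoints, *, gate_r2: float = DEFAULT_GATE_R2):
        if len(points) < 2:
            raise FitInfeasibleError(f"stratum {points.label}: need >= 2 points")
        self.points = points
        self.gate_r2 = gate_r2

    @classmethod
    def from_datasets(
        cls,
        datasets: Sequence[IncidenceDataset],
        *,
        gate_r2: float = DEFAULT_GATE_R2,
        truncation: bool = True,
    ) -> "MultistepModel":
        return cls(prepare_points(datasets, truncation=truncation), gate_r2=gate_r2)

    def fit(self) -> MultistepFit:
        x = np.asarray(self.points.log_age)
        y = np.asarray(self.points.log_incidence)
        if np.ptp(x) == 0:
            raise FitInfeasibleError(
                f"stratum {self.points.label}: all points share one age "
                "(degenerate x-variance)"
            )
        res = stats.linregress(x, y)
        slope = float(res.slope)
        intercept_log10 = float(res.intercept)
        # r_squared: 1 for a 2-point fit by construction (rvalue is +-1)
        r2 = float(res.rvalue) ** 2
        intercept_natural = intercept_log10 * math.log(10.0)
        try:
            n_steps = steps_from_slope(slope)
        except ValueError:
            n_steps = 1  # steeply falling incidence; gate fails below anyway
        u, mu = risk_parameters(intercept_natural, n_steps)
        return MultistepFit(
            label=self.points.label,
            slope_m=slope,
            intercept_c_log10=intercept_log10,
            intercept_c_natural=intercept_natural,
            n_steps=n_steps,
            background_risk_u=u,
            geom_mean_risk_mu=mu,
            r_squared=r2,
            n_points=len(self.points),
            truncated=self.points.truncated,
            gate_r2=self.gate_r2,
            passes_linearity=(r2 >= self.gate_r2 and slope > 0),
        )


def fit_multistep(
    points: LogLogPoints, *, gate_r2: float = DEFAULT_GATE_R2
) -> MultistepFit:
    """Functional wrapper: fit prepared points, return the results object."""
    return MultistepModel(points, gate_r2=gate_r2).fit()


def fit_panel(
    datasets_by_stratum: dict[str, Sequence[IncidenceDataset]],
    *,
    gate_r2: float = DEFAULT_GATE_R2,
    truncation: bool = True,
) -> dict[str, MultistepFit]:
    """Fit every stratum of a grouped panel; returns label -> fit."""
    return {
        label: MultistepModel.from_datasets(
            dsets, gate_r2=gate_r2, truncation=truncation
        ).fit()
        for label, dsets in datasets_by_stratum.items()
    }
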