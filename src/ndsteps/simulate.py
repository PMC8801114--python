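"""Synthetic age-stratified incidence panels with known ground truth.

The simulator emulates the structure of a multi-study incidence
collection: each disease/sex stratum is described by a
:class:`DiseaseSpec` carrying the true step count ``n``, the background
risk ``u`` (so that incidence follows the multistep power law
``i(t) = u * t**(n-1)``), the designed age range of incidence, the
age-bin scheme, a multiplicative log-normal noise level, and the number
of independent studies.  One spec per stratum uses a non-monotone
(unimodal, MS-like) incidence curve instead, serving as the negative
control for the log-log linearity of the multistep model.

All randomness is driven by a single integer seed; identical
``(specs, seed)`` produce byte-identical panels.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import SEXES, AgeBin, IncidenceDataset, StratumLabel

MULTISTEP = "multistep"
NONMONOTONE_CONTROL = "nonmonotone_control"


@dataclasses.dataclass(frozen=True)
class DiseaseSpec:
    """Ground-truth description of one simulated disease/sex stratum.

    Parameters
    ----------
    disease_code, sex
        Stratum identity; rendered labels follow the f/m/uppercase
        convention of :mod:`ndsteps.io`.
    n_true
        True number of rate-limiting steps (``>= 1``).  Incidence grows as
        ``t**(n_true - 1)``.
    background_risk_u
        Product of per-step background risks; the multiplicative constant
        of the power law, in (cases per 100,000 person-years) / years**(n-1).
    age_min, age_max
        Designed incidence age range in years; bins tile ``[age_min, age_max)``.
    bin_width
        Age-bin width in years.
    noise_sigma
        Standard deviation of the multiplicative log-normal noise: observed
        incidence is the curve times ``exp(eps)``, ``eps ~ N(0, sigma^2)``.
    n_studies
        Number of independent studies generated for this stratum.
    model
        ``"multistep"`` or ``"nonmonotone_control"``.
    peak_age, peak_incidence, shape
        Parameters of the control curve (ignored for multistep): a
        Gamma-density-like unimodal curve
        ``i(t) = peak_incidence * (t/peak_age)**shape * exp(shape*(1 - t/peak_age))``
        peaking at ``peak_age`` with sharpness ``shape``.
    """

    disease_code: str
    sex: str
    n_true: int
    background_risk_u: float
    age_min: float
    age_max: float
    bin_width: float = 5.0
    noise_sigma: float = 0.1
    n_studies: int = 3
    model: str = MULTISTEP
    peak_age: float = 30.0
    peak_incidence: float = 6.0
    shape: float = 12.0

    def __post_init__(self) -> None:
        StratumLabel(self.disease_code, self.sex)  # validates identity
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if self.n_true < 1:
            raise ValueError("n_true must be >= 1")
        if self.background_risk_u <= 0:
            raise ValueError("background_risk_u must be positive")
        if self.age_min <= 0:
            raise ValueError("age_min must be positive (log of age is taken)")
        if not self.age_min < self.age_max:
            raise ValueError("age_min must be < age_max")
        if self.bin_width <= 0 or self.bin_width >= self.age_max - self.age_min:
            raise ValueError("bin_width must be in (0, age_max - age_min)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.model not in (MULTISTEP, NONMONOTONE_CONTROL):
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def label(self) -> str:
        return StratumLabel(self.disease_code, self.sex).render()

    def true_incidence(self, age: float | np.ndarray) -> float | np.ndarray:
        """Noise-free incidence curve at ``age`` (years)."""
        age = np.asarray(age, dtype=float)
        if self.model == MULTISTEP:
            return self.background_risk_u * age ** (self.n_true - 1)
        r = age / self.peak_age
        return self.peak_incidence * r**self.shape * np.exp(self.shape * (1.0 - r))


def u_from_incidence_at(incidence: float, age: float, n_steps: int) -> float:
    """Background risk ``u`` giving a target incidence at a reference age.

    Convenience inversion of ``i = u * t**(n-1)``; handy for designing
    specs from real-world incidence magnitudes.
    """
    if incidence <= 0 or age <= 0 or n_steps < 1:
        raise ValueError("need incidence > 0, age > 0, n_steps >= 1")
    return incidence / age ** (n_steps - 1)


def _study_rng(spec: DiseaseSpec, study_index: int, seed: int) -> np.random.Generator:
    # crc32 keeps the stream stable across processes (no PYTHONHASHSEED issues)
    tag = zlib.crc32(f"{spec.disease_code}|{spec.sex}".encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, study_index, tag])


def generate_dataset(
    spec: DiseaseSpec,
    study_index: int = 0,
    seed: int = 0,
    *,
    bin_jitter: float = 0.0,
) -> IncidenceDataset:
    """Generate one study's incidence table for a spec.

    Bins tile ``[age_min, age_max)`` at ``bin_width`` (a final short bin is
    kept if the range is not an exact multiple).  With ``bin_jitter > 0``
    all bin edges are shifted down by a uniform draw in ``[0, bin_jitter]``
    years, emulating heterogeneous study bin schemes.  Incidence at each
    bin midpoint is the spec's curve times log-normal noise; all values
    are strictly positive.
    """
    rng = _study_rng(spec, study_index, seed)
    offset = float(rng.uniform(0.0, bin_jitter)) if bin_jitter > 0 else 0.0
    lo = spec.age_min - offset
    if lo <= 0:
        raise ValueError(
            f"bin jitter pushed age_min to {lo} <= 0 for {spec.label}"
        )
    edges = np.arange(lo, spec.age_max - offset - 1e-9, spec.bin_width)
    edges = np.append(edges, spec.age_max - offset)
    mids = 0.5 * (edges[:-1] + edges[1:])
    base = np.asarray(spec.true_incidence(mids), dtype=float)
    eps = rng.normal(0.0, spec.noise_sigma, size=mids.size) if spec.noise_sigma > 0 else 0.0
    values = base * np.exp(eps)
    bins = tuple(
        AgeBin(float(s), float(e), float(v))
        for s, e, v in zip(edges[:-1], edges[1:], values)
    )
    return IncidenceDataset(
        disease_code=spec.disease_code,
        sex=spec.sex,
        study_id=f"{spec.label}-S{study_index:02d}",
        bins=bins,
    )


def generate_panel(
    specs: Sequence[DiseaseSpec],
    seed: int = 0,
    *,
    bin_jitter: float = 2.0,
) -> list[IncidenceDataset]:
    """Generate ``n_studies`` independent datasets per spec.

    Disease/sex pairs must be unique across specs.  Per-study bin-scheme
    jitter (edges shifted by up to ``bin_jitter`` years) is on by default
    to exercise the spline harmonization downstream.  Deterministic under
    a fixed seed.
    """
    pairs = [(s.disease_code, s.sex) for s in specs]
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise ValueError(f"duplicate disease/sex pairs in specs: {dupes}")
    panel: list[IncidenceDataset] = []
    for spec in specs:
        for j in range(spec.n_studies):
            panel.append(generate_dataset(spec, j, seed, bin_jitter=bin_jitter))
    triples = [(d.disease_code, d.sex, d.study_id) for d in panel]
    assert len(set(triples)) == len(triples)
    return panel


def default_specs(
    *,
    sex: str = "pooled",
    noise_sigma: float = 0.1,
    n_studies: int = 3,
) -> list[DiseaseSpec]:
    """The default simulated study conditions: ten multistep strata plus
    one MS-like non-monotone control.

    Step counts span the stem (2), trunk-level (6) and crown (8-13) tiers;
    incidence age ranges are designed inversely to the step counts and all
    overlap on 60-78 years; background risks are anchored to realistic
    incidence magnitudes (cases per 100,000 person-years) at age 70.
    Resulting years-per-step values fall in three tiers: ~32.5 (stem),
    ~7.5-9 (trunk), ~2-3 (crown).
    """
    # (code, n_true, incidence at age 70, age_min, age_max, bin_width)
    design = [
        ("HD",   2,   0.6, 15.0, 80.0, 5.0),
        ("ALS",  6,   5.0, 30.0, 80.0, 5.0),
        ("PD",   6, 150.0, 35.0, 80.0, 5.0),
        ("CJD",  6,   2.0, 32.0, 80.0, 4.0),
        ("FTD",  6,  15.0, 26.0, 80.0, 6.0),
        ("PDM",  8, 200.0, 56.0, 80.0, 4.0),
        ("PDD",  9, 100.0, 53.0, 80.0, 3.0),
        ("DLB", 11,  80.0, 56.0, 78.0, 2.0),
        ("AD",  12, 800.0, 56.0, 80.0, 4.0),
        ("PSP", 13,  15.0, 52.0, 78.0, 2.0),
    ]
    specs = [
        DiseaseSpec(
            disease_code=code,
            sex=sex,
            n_true=n,
            background_risk_u=u_from_incidence_at(i70, 70.0, n),
            age_min=lo,
            age_max=hi,
            bin_width=bw,
            noise_sigma=noise_sigma,
            n_studies=n_studies,
        )
        for code, n, i70, lo, hi, bw in design
    ]
    # MS-like control: early-adult incidence peak, steep decline with age,
    # so onset past 75 is vanishingly rare and log-log is far from linear.
    specs.append(
        DiseaseSpec(
            disease_code="MS",
            sex=sex,
            n_true=1,
            background_risk_u=1.0,
            age_min=15.0,
            age_max=80.0,
            bin_width=5.0,
            noise_sigma=noise_sigma,
            n_studies=n_studies,
            model=NONMONOTONE_CONTROL,
            peak_age=30.0,
            peak_incidence=6.0,
            shape=12.0,
        )
    )
    return specs


def default_panel(seed: int = 0, **kwargs) -> list[IncidenceDataset]:
    """Generate the default panel (see :func:`default_specs`)."""
    return generate_panel(default_specs(**kwargs), seed=seed)


def write_manifest(specs: Sequence[DiseaseSpec], seed: int, path: str | Path) -> Path:
    """Write a JSON provenance manifest (specs + seed) for a panel."""
    path = Path(path)
    payload = {
        "seed": seed,
        "specs": [dataclasses.asdict(s) for s in specs],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def true_years_per_step(spec: DiseaseSpec) -> float:
    """Designed years-per-step of a spec: range width over true steps."""
    if spec.model != MULTISTEP:
        return math.nan
    return (spec.age_max - spec.age_min) / spec.n_true
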