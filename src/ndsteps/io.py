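"""Reading and writing age-stratified incidence tables.

The on-disk dialect is a plain CSV with mandatory header columns
``disease, sex, study_id, age_start, age_end, incidence``.  Age bins are
half-open intervals ``[age_start, age_end)`` in years; incidence is in
cases per 100,000 person-years.  Lines starting with ``#`` are comments.

Stratum labels follow the epidemiological naming convention used
throughout the package: a disease code ending in a lowercase ``f`` is the
female stratum, a lowercase ``m`` the male stratum, and an all-uppercase
code the pool of both sexes (e.g. ``ADf``, ``ADm``, ``AD``).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female", "pooled")

#: Registry exclusion list: pooled Alzheimer's disease datasets removed from
#: the source collection before refitting the shared-step model.  Applied
#: only when these study IDs actually occur in the input.
DEFAULT_EXCLUDED_STUDY_IDS = frozenset(
    {"AD-60", "AD-61", "AD-62", "AD-68", "AD-71", "AD-78", "AD-82"}
)

_REQUIRED_COLUMNS = ["disease", "sex", "study_id", "age_start", "age_end", "incidence"]


class IncidenceTableError(ValueError):
    """Raised for malformed incidence tables (with row diagnostics)."""


@dataclasses.dataclass(frozen=True)
class StratumLabel:
    """One disease/sex combination.

    ``render()`` produces the conventional short label: ``<CODE>f`` for
    female, ``<CODE>m`` for male, and the bare all-uppercase code for the
    pooled stratum.
    """

    disease_code: str
    sex: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (self.disease_code.isalpha() and self.disease_code.isupper()):
            raise ValueError(
                f"disease code must be non-empty uppercase letters, got "
                f"{self.disease_code!r}"
            )

    def render(self) -> str:
        suffix = {"female": "f", "male": "m", "pooled": ""}[self.sex]
        return self.disease_code + suffix

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_stratum_label(label: str) -> StratumLabel:
    """Parse a short stratum label into (disease code, sex).

    ``"ADm"`` -> (AD, male); ``"ADf"`` -> (AD, female); ``"AD"`` -> (AD,
    pooled).  Anything that is neither all-uppercase nor uppercase plus a
    single trailing ``f``/``m`` is rejected.
    """
    if not label:
        raise ValueError("empty stratum label")
    if label.isupper():
        return StratumLabel(label, "pooled")
    head, tail = label[:-1], label[-1]
    if head and head.isupper() and tail in ("f", "m"):
        return StratumLabel(head, "female" if tail == "f" else "male")
    raise ValueError(
        f"malformed stratum label {label!r}: expected all-uppercase or "
        "uppercase code with a single trailing 'f' or 'm'"
    )


@dataclasses.dataclass(frozen=True)
class AgeBin:
    """Half-open age bin ``[age_start, age_end)`` with its incidence."""

    age_start: float
    age_end: float
    incidence: float

    def __post_init__(self) -> None:
        if not self.age_start < self.age_end:
            raise ValueError(
                f"age_start must be < age_end, got [{self.age_start}, {self.age_end})"
            )
        if self.incidence < 0:
            raise ValueError(f"incidence must be >= 0, got {self.incidence}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_start + self.age_end)

    @property
    def width(self) -> float:
        return self.age_end - self.age_start


@dataclasses.dataclass(frozen=True)
class IncidenceDataset:
    """One study's age-stratified incidence for one disease/sex stratum.

    Bins are kept sorted by ``age_start`` and must not overlap; incidence
    is in cases per 100,000 person-years.
    """

    disease_code: str
    sex: str
    study_id: str
    bins: tuple[AgeBin, ...]

    def __post_init__(self) -> None:
        bins = tuple(sorted(self.bins, key=lambda b: b.age_start))
        object.__setattr__(self, "bins", bins)
        if len(bins) < 2:
            raise ValueError(
                f"dataset {self.study_id!r} needs at least 2 age bins, got {len(bins)}"
            )
        for prev, cur in zip(bins, bins[1:]):
            if cur.age_start < prev.age_end:
                raise ValueError(
                    f"dataset {self.study_id!r}: overlapping bins "
                    f"[{prev.age_start}, {prev.age_end}) and "
                    f"[{cur.age_start}, {cur.age_end})"
                )
        # validates disease_code/sex
        StratumLabel(self.disease_code, self.sex)

    @property
    def stratum(self) -> StratumLabel:
        return StratumLabel(self.disease_code, self.sex)

    @property
    def label(self) -> str:
        return self.stratum.render()

    @property
    def age_min(self) -> float:
        return self.bins[0].age_start

    @property
    def age_max(self) -> float:
        return self.bins[-1].age_end

    def midpoints(self) -> list[float]:
        return [b.midpoint for b in self.bins]

    def incidences(self) -> list[float]:
        return [b.incidence for b in self.bins]


def read_incidence_table(path: str | Path) -> list[IncidenceDataset]:
    """Read an incidence CSV into datasets grouped by (disease, sex, study).

    Validation failures (missing columns, negative incidence, overlapping
    bins) raise :class:`IncidenceTableError` naming the offending rows.
    CSV row numbers in diagnostics count the header as row 1.
    """
    path = Path(path)
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise IncidenceTableError(f"{path}: missing columns {missing}")
    # +2: header line plus 1-based indexing
    frame = frame.reset_index(drop=True)
    frame["_row"] = frame.index + 2

    bad = frame[frame["incidence"] < 0]
    if not bad.empty:
        rows = bad["_row"].tolist()
        raise IncidenceTableError(f"{path}: negative incidence at rows {rows}")
    bad = frame[~(frame["age_start"] < frame["age_end"])]
    if not bad.empty:
        rows = bad["_row"].tolist()
        raise IncidenceTableError(f"{path}: age_start >= age_end at rows {rows}")

    datasets: list[IncidenceDataset] = []
    for (disease, sex, study), grp in frame.groupby(
        ["disease", "sex", "study_id"], sort=True
    ):
        grp = grp.sort_values("age_start")
        starts = grp["age_start"].to_numpy()
        ends = grp["age_end"].to_numpy()
        rows = grp["_row"].to_numpy()
        for i in range(len(grp) - 1):
            if starts[i + 1] < ends[i]:
                raise IncidenceTableError(
                    f"{path}: overlapping bins for {disease}/{sex}/{study} "
                    f"at rows {rows[i]} and {rows[i + 1]}: "
                    f"[{starts[i]}, {ends[i]}) and [{starts[i + 1]}, {ends[i + 1]})"
                )
        bins = tuple(
            AgeBin(float(s), float(e), float(v))
            for s, e, v in zip(starts, ends, grp["incidence"])
        )
        try:
            datasets.append(IncidenceDataset(str(disease), str(sex), str(study), bins))
        except ValueError as exc:
            raise IncidenceTableError(f"{path}: {exc}") from exc
    return datasets


def write_incidence_table(
    datasets: Iterable[IncidenceDataset], path: str | Path, header_comment: str | None = None
) -> Path:
    """Write datasets to the incidence CSV dialect (UTF-8, sorted rows)."""
    path = Path(path)
    rows = []
    for ds in datasets:
        for b in ds.bins:
            rows.append(
                {
                    "disease": ds.disease_code,
                    "sex": ds.sex,
                    "study_id": ds.study_id,
                    "age_start": b.age_start,
                    "age_end": b.age_end,
                    "incidence": b.incidence,
                }
            )
    frame = pd.DataFrame(rows, columns=_REQUIRED_COLUMNS)
    frame = frame.sort_values(["disease", "sex", "study_id", "age_start"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
    return path


def group_by_stratum(
    datasets: Iterable[IncidenceDataset],
) -> dict[str, list[IncidenceDataset]]:
    """Group datasets by rendered stratum label, label-sorted."""
    out: dict[str, list[IncidenceDataset]] = {}
    for ds in sorted(datasets, key=lambda d: (d.label, d.study_id)):
        out.setdefault(ds.label, []).append(ds)
    return out


def filter_registry(
    datasets: Sequence[IncidenceDataset],
    *,
    counterpart_rule: bool = True,
    excluded_study_ids: frozenset[str] | set[str] = DEFAULT_EXCLUDED_STUDY_IDS,
) -> list[IncidenceDataset]:
    """Drop redundant pooled-sex datasets from a collection.

    A pooled-sex dataset is removed when the same study contributes both a
    male and a female dataset for the same disease (the pooled entry is
    then double counting).  Additionally, any dataset whose study ID is on
    ``excluded_study_ids`` is dropped.  Sex-annotated datasets are never
    removed by the counterpart rule.  Removals are logged with reasons.
    """
    sexed = {
        (ds.disease_code, ds.study_id, ds.sex)
        for ds in datasets
        if ds.sex in ("male", "female")
    }
    kept: list[IncidenceDataset] = []
    for ds in datasets:
        if ds.study_id in excluded_study_ids:
            logger.info(
                "filter_registry: dropping %s/%s/%s (registry exclusion list)",
                ds.disease_code, ds.sex, ds.study_id,
            )
            continue
        if (
            counterpart_rule
            and ds.sex == "pooled"
            and (ds.disease_code, ds.study_id, "male") in sexed
            and (ds.disease_code, ds.study_id, "female") in sexed
        ):
            logger.info(
                "filter_registry: dropping pooled %s/%s (male and female "
                "counterparts present)", ds.disease_code, ds.study_id,
            )
            continue
        kept.append(ds)
    return kept
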