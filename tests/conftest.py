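import pytest

from ndsteps import age_range as ar
from ndsteps import io as ndio
from ndsteps import multistep as ms
from ndsteps import simulate as sim


@pytest.fixture(scope="session")
def panel():
    """Default synthetic panel (10 multistep strata + MS-like control), seed 0."""
    return sim.default_panel(seed=0)


@pytest.fixture(scope="session")
def grouped(panel):
    return ndio.group_by_stratum(panel)


@pytest.fixture(scope="session")
def fits(grouped):
    return ms.fit_panel(grouped)


@pytest.fixture(scope="session")
def summaries(grouped, fits):
    return [
        ar.summarize_stratum(label, dsets, fits.get(label))
        for label, dsets in grouped.items()
    ]


def make_dataset(bins, disease="XX", sex="pooled", study="XX-S00"):
    """Small helper: dataset from (start, end, incidence) triples."""
    return ndio.IncidenceDataset(
        disease_code=disease,
        sex=sex,
        study_id=study,
        bins=tuple(ndio.AgeBin(*b) for b in bins),
    )
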