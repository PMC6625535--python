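import itertools

import pytest

from jjdq.records import CaseRecord, DecisionPoint, Extract, Phase, ResponseValue

_TOKEN_TO_VALUE = {
    "yes": ResponseValue.YES,
    "no": ResponseValue.NO,
    "missing": ResponseValue.MISSING,
}

_COUNTER = itertools.count()


def make_case(
    diverted="no",
    detained="no",
    petitioned="no",
    adjudicated="no",
    probation="no",
    confined="no",
    waived="no",
    **kwargs,
):
    """Build a CaseRecord from yes/no/missing point tokens (test shorthand)."""
    tokens = {
        DecisionPoint.DIVERTED: diverted,
        DecisionPoint.DETAINED: detained,
        DecisionPoint.PETITIONED: petitioned,
        DecisionPoint.ADJUDICATED: adjudicated,
        DecisionPoint.PROBATION: probation,
        DecisionPoint.CONFINED: confined,
        DecisionPoint.WAIVED: waived,
    }
    defaults = dict(
        case_id=f"case-{next(_COUNTER):06d}",
        youth_id="youth-00000",
        cms_id="CMS1",
        county_id="CMS1-C1",
        extraction_phase=Phase.PRE,
        gender="male",
        race_ethnicity="White",
        age_years=15,
        charge_severity="Misdemeanor A",
    )
    defaults.update(kwargs)
    return CaseRecord(points={p: _TOKEN_TO_VALUE[t] for p, t in tokens.items()}, **defaults)


def make_extract(*cases, provenance="test"):
    return Extract(records=list(cases), provenance=provenance)


@pytest.fixture
def simple_extract():
    """Four clean cases across two CMSs (no flags, no missingness)."""
    return make_extract(
        make_case(diverted="yes"),
        make_case(petitioned="yes", adjudicated="yes", probation="yes"),
        make_case(petitioned="yes", adjudicated="yes", confined="yes", cms_id="CMS2"),
        make_case(petitioned="yes", cms_id="CMS2", gender="female"),
    )
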