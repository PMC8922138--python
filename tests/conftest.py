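from __future__ import annotations

from datetime import datetime, timedelta

import pytest
from hypothesis import settings

from wellsauto.cli_io import score_cohort
from wellsauto.lexicon import build_dvt_lexicon, build_hemoptysis_lexicon
from wellsauto.models import COMPONENT_NAMES, Encounter
from wellsauto.scoring import Component, WellsComponents
from wellsauto.synth import paper_mode_cohort

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

INDEX_TIME = datetime(2019, 5, 20, 12, 0)


@pytest.fixture(scope="session")
def dvt_lexicon():
    return build_dvt_lexicon()


@pytest.fixture(scope="session")
def hemoptysis_lexicon():
    return build_hemoptysis_lexicon()


@pytest.fixture(scope="session")
def paper_cohort():
    return paper_mode_cohort(seed=1)


@pytest.fixture(scope="session")
def paper_scores(paper_cohort):
    encounters, _ = paper_cohort
    return score_cohort(encounters)


def make_encounter(**kwargs) -> Encounter:
    kwargs.setdefault("encounter_id", "e1")
    kwargs.setdefault("index_order_time", INDEX_TIME)
    return Encounter(**kwargs)


def make_components(**values: bool) -> WellsComponents:
    values.setdefault("gestalt", True)
    return WellsComponents(
        components=tuple(
            Component(name=n, value=values.get(n, False)) for n in COMPONENT_NAMES
        )
    )


def hours(h: float) -> datetime:
    return INDEX_TIME + timedelta(hours=h)


def days(d: float) -> datetime:
    return INDEX_TIME + timedelta(days=d)
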