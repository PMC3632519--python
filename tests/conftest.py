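import numpy as np
import pandas as pd
import pytest

from addinter import (
    Cohort,
    ParticipantRecord,
    classify_and_derive,
    generate_cohort,
    paper_default_config,
)


def make_record(**kw) -> ParticipantRecord:
    """A reference-class participant; override fields per test."""
    base = dict(
        id="p1",
        sex="male",
        selfreport_diabetes="no",
        fasting_glucose=5.2,
        antidiabetic_medication="no",
        mother_diabetes="no",
        father_diabetes="no",
        sibling_diabetes="no",
        smoking="never",
        leisure_pa=2,
        work_sedentary=2,
        height=178.0,
        weight=80.0,
        waist=95.0,
        hip=100.0,
        sad=21.0,
    )
    base.update(kw)
    return ParticipantRecord(**base)


@pytest.fixture(scope="session")
def default_config():
    return paper_default_config()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """A seeded 4232-record synthetic cohort (the default study size)."""
    return generate_cohort(default_config, seed=20240101)


@pytest.fixture(scope="session")
def small_study(small_cohort):
    return classify_and_derive(small_cohort)


@pytest.fixture
def csv_cohort(tmp_path):
    """Write a tiny 3-row well-formed cohort CSV and return its path."""
    rows = [
        "id,sex,selfreport_diabetes,fasting_glucose,antidiabetic_medication,"
        "mother_diabetes,father_diabetes,sibling_diabetes,smoking,leisure_pa,"
        "work_sedentary,height,weight,waist,hip,sad",
        "a1,male,no,5.1,no,no,no,no,never,2,1,178,80,95,100,21.0",
        "a2,female,no,6.5,no,yes,no,no,current,1,2,165,70,88,104,19.5",
        "a3,male,yes,8.2,yes,no,yes,no,ex,3,4,180,95,105,103,24.0",
    ]
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join(rows) + "\n")
    return path
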