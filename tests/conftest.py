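"""Shared fixtures and dataset-construction helpers."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from phenoclaims.data_model import (
    ADJUDICATION_COLUMNS,
    CLAIM_COLUMNS,
    ENROLLMENT_COLUMNS,
    MEMBER_COLUMNS,
    ClaimsDataset,
)


def member(member_id: str, sex: str = "F", birth_year: int = 1950) -> dict:
    return {"member_id": member_id, "sex": sex, "birth_year": birth_year}


def span(member_id: str, start: str, end: str) -> dict:
    return {
        "member_id": member_id,
        "start_date": pd.Timestamp(start),
        "end_date": pd.Timestamp(end),
    }


def claim(
    claim_id: str,
    member_id: str,
    date: str,
    setting: str = "outpatient",
    codes: tuple[str, ...] = ("1820",),
    provider: str | None = None,
    principal: bool | None = None,
) -> dict:
    return {
        "claim_id": claim_id,
        "member_id": member_id,
        "service_date": pd.Timestamp(date),
        "setting": setting,
        "provider_id": provider,
        "principal_dx_flag": principal,
        "dx_codes": tuple(codes),
    }


def adjudication(member_id: str, reviewer_id: str, label: str, alternative: str | None = None) -> dict:
    return {
        "member_id": member_id,
        "reviewer_id": reviewer_id,
        "label": label,
        "alternative_dx": alternative,
    }


def make_dataset(members, spans=(), claims=(), adjudications=()) -> ClaimsDataset:
    """Build a validated dataset from row dicts (see helpers above)."""
    return ClaimsDataset(
        members=pd.DataFrame(list(members), columns=MEMBER_COLUMNS),
        enrollment=pd.DataFrame(list(spans), columns=ENROLLMENT_COLUMNS),
        claims=pd.DataFrame(list(claims), columns=CLAIM_COLUMNS),
        adjudication=pd.DataFrame(list(adjudications), columns=ADJUDICATION_COLUMNS),
    ).validate()


@pytest.fixture
def simple_case_dataset() -> ClaimsDataset:
    """One qualifying outpatient case with clean baseline, one background member."""
    return make_dataset(
        members=[member("A", birth_year=1950), member("B", birth_year=1960)],
        spans=[span("A", "2009-01-01", "2013-12-31"), span("B", "2010-01-01", "2012-12-31")],
        claims=[
            claim("c1", "A", "2011-05-10", provider="O1"),
            claim("c2", "A", "2011-05-20", provider="O1"),
            claim("c3", "B", "2011-06-01", codes=("4019",)),
        ],
    )


@pytest.fixture(scope="session")
def default_window() -> tuple[dt.date, dt.date]:
    return (dt.date(2010, 1, 1), dt.date(2014, 8, 31))
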