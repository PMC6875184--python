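"""Seeded synthetic claims generator with planted ground truth.

Emulates a commercially insured female population for end-to-end testing of
the case-identification algorithm and its validation workflow:

* *true cases* — members with genuine endometrial adenocarcinoma, coded
  182.xx via one inpatient stay or two distinct-day outpatient visits;
* *mimics* — members with another condition (uterine sarcoma, endometrial
  hyperplasia, ovarian cancer, ...) that nonetheless received 182.xx codes,
  the source of algorithm false positives;
* *single-outpatient leaks* — true cases truncated to one outpatient claim,
  which the algorithm by design cannot capture;
* *background* — members with only non-cancer utilization noise.

Chart adjudication labels derive from the planted truth (true case ->
confirmed, mimic -> not-endometrial), with a configurable fraction of
non-evaluable charts overriding either. Each member draws from its own
counter-keyed random stream, so a member's output is invariant to
population size, and identical seeds give byte-identical CSVs.
"""

from __future__ import annotations

import datetime as dt
import math
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .data_model import (
    ADJUDICATION_COLUMNS,
    CLAIM_COLUMNS,
    ENROLLMENT_COLUMNS,
    MEMBER_COLUMNS,
    ClaimsDataset,
    write_dataset,
)

ONE_DAY = pd.Timedelta(days=1)

TRUTH_COLUMNS = ["member_id", "true_status", "mimic_dx", "chart_evaluable", "planted_route"]

#: Alternative diagnoses observed among false positives, with sampling
#: weights proportional to their reported shares (renormalized).
MIMIC_DIAGNOSES: dict[str, float] = {
    "endometrial_hyperplasia": 0.17,
    "endometrial_stromal_sarcoma": 0.07,
    "ovarian_cancer": 0.07,
    "rhabdomyosarcoma_uterus": 0.03,
    "fallopian_tube_cancer": 0.03,
    "leiomyosarcoma": 0.03,
    "colon_cancer": 0.03,
    "none_identified": 0.34,
}

#: Target-category subcodes planted on cases/mimics (corpus uteri).
TARGET_SUBCODES = ("1820", "1821", "1828")
TARGET_SUBCODE_WEIGHTS = (0.90, 0.05, 0.05)

#: Non-cancer utilization noise (hypertension, diabetes, URI, back pain,
#: chest pain, general exam, hyperlipidemia, UTI) — deliberately outside
#: both the target category and the 140-209 washout chapter.
BACKGROUND_CODES = ("4019", "25000", "4659", "7242", "78650", "V700", "2720", "5990")

#: Washout-chapter code (colon cancer) used for opt-in baseline contamination.
CONTAMINATION_CODE = "1539"


class SimulationConfig(BaseModel):
    """Knobs of the synthetic population; defaults emulate the validation study.

    ``true_case_fraction`` and ``mimic_fraction`` default to 286 and 29 per
    2,000 members, reproducing the evaluable confirmed:not ratio of the
    validation sample; ``non_evaluable_fraction`` is 15/330. The outpatient
    inter-diagnosis gap is a shifted log-normal (1 + LogNormal) with median
    ``gap_median_days`` and log-scale ``gap_sigma``; the defaults give a
    heavy right tail with median ~10.5 d and mean ~50 d. Age at index is
    truncated normal (63.4, 10.3) on [30, 95).
    """

    n_members: int = Field(2000, ge=1)
    study_window: tuple[dt.date, dt.date] = (dt.date(2010, 1, 1), dt.date(2014, 8, 31))
    true_case_fraction: float = Field(0.143, ge=0, le=1)
    mimic_fraction: float = Field(0.0145, ge=0, le=1)
    non_evaluable_fraction: float = Field(15 / 330, ge=0, le=1)
    single_outpatient_fraction: float = Field(0.043, ge=0, le=1)
    inpatient_route_fraction: float = Field(44 / 330, ge=0, le=1)
    enrollment_gap_rate: float = Field(0.10, ge=0, le=1)
    gap_median_days: float = Field(10.5, gt=1)
    gap_sigma: float = Field(1.8, gt=0)
    age_mean: float = 63.4
    age_sd: float = Field(10.3, gt=0)
    age_min: int = 30
    age_max: int = 94
    baseline_contamination_fraction: float = Field(0.0, ge=0, le=1)
    reviewer_disagreement_rate: float = Field(0.0, ge=0, le=1)
    background_claims_per_year: float = Field(2.0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "SimulationConfig":
        if self.true_case_fraction + self.mimic_fraction > 1:
            raise ValueError("true_case_fraction + mimic_fraction must be <= 1")
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study_window must span at least two days")
        if self.age_min >= self.age_max:
            raise ValueError("age_min must be < age_max")
        return self


# ---------------------------------------------------------------------------
# low-level draws


def _draw_gap_days(rng: np.random.Generator, config: SimulationConfig) -> int:
    """Shifted log-normal gap: 1 + LogNormal(log(median-1), sigma), rounded."""
    mu = math.log(config.gap_median_days - 1)
    return max(1, int(round(1 + rng.lognormal(mu, config.gap_sigma))))


def _draw_age(rng: np.random.Generator, config: SimulationConfig) -> int:
    while True:  # truncated normal by rejection
        age = rng.normal(config.age_mean, config.age_sd)
        if config.age_min <= age <= config.age_max:
            return int(age)


def plant_case(
    member_id: str,
    route: str,
    window: tuple[pd.Timestamp, pd.Timestamp],
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
) -> list[dict]:
    """Plant the 182.xx claim pattern for one case.

    ``inpatient`` yields one inpatient claim with the target code principal;
    ``outpatient`` yields two outpatient claims on distinct dates at the
    same office, separated by a draw from the gap distribution;
    ``single_outpatient`` yields exactly one outpatient claim. Out-of-window
    draws are redrawn internally; no claim is ever emitted outside the window.
    """
    config = config or SimulationConfig()
    start, end = window
    horizon = (end - start).days
    code = lambda: str(rng.choice(TARGET_SUBCODES, p=TARGET_SUBCODE_WEIGHTS))  # noqa: E731

    def claim(k: int, date: pd.Timestamp, setting: str, provider: str, principal: bool | None):
        return {
            "claim_id": f"{member_id}-{k:03d}",
            "member_id": member_id,
            "service_date": date,
            "setting": setting,
            "provider_id": provider,
            "principal_dx_flag": principal,
            "dx_codes": (code(),),
        }

    if route == "inpatient":
        date = start + ONE_DAY * int(rng.integers(0, horizon + 1))
        return [claim(0, date, "inpatient", f"{member_id}-H1", True)]
    if route == "single_outpatient":
        date = start + ONE_DAY * int(rng.integers(0, horizon + 1))
        return [claim(0, date, "outpatient", f"{member_id}-O1", None)]
    if route == "outpatient":
        office = f"{member_id}-O1"
        for _ in range(200):
            first = int(rng.integers(0, horizon + 1))
            gap = _draw_gap_days(rng, config)
            if first + gap <= horizon:
                d1 = start + ONE_DAY * first
                return [
                    claim(0, d1, "outpatient", office, None),
                    claim(1, d1 + ONE_DAY * gap, "outpatient", office, None),
                ]
        # pathological window/gap combination: clamp to guaranteed-fit values
        d1 = start
        return [
            claim(0, d1, "outpatient", office, None),
            claim(1, d1 + ONE_DAY * max(1, min(_draw_gap_days(rng, config), horizon)),
                  "outpatient", office, None),
        ]
    raise ValueError(f"unknown route {route!r}")


def _sample_dates_in_spans(
    spans: list[tuple[pd.Timestamp, pd.Timestamp]], n: int, rng: np.random.Generator
) -> list[pd.Timestamp]:
    lengths = np.array([(e - s).days + 1 for s, e in spans])
    if lengths.sum() == 0 or n == 0:
        return []
    dates = []
    for _ in range(n):
        i = int(rng.choice(len(spans), p=lengths / lengths.sum()))
        offset = int(rng.integers(0, lengths[i]))
        dates.append(spans[i][0] + ONE_DAY * offset)
    return dates


# ---------------------------------------------------------------------------
# per-member generation


def _generate_member(index: int, config: SimulationConfig):
    rng = np.random.default_rng([abs(config.seed), index])
    member_id = f"M{index:06d}"
    start, end = (pd.Timestamp(d) for d in config.study_window)

    u = rng.uniform()
    if u < config.true_case_fraction:
        status = "true_case"
    elif u < config.true_case_fraction + config.mimic_fraction:
        status = "mimic"
    else:
        status = "background"

    claims: list[dict] = []
    adjudication: list[dict] = []

    if status == "background":
        anchor = start + ONE_DAY * int(rng.integers(0, (end - start).days + 1))
        spans = _background_spans(anchor, rng, config)
        age = _draw_age(rng, config)
        birth_year = anchor.year - age
        truth = {
            "member_id": member_id,
            "true_status": "background",
            "mimic_dx": None,
            "chart_evaluable": True,
            "planted_route": "none",
        }
    else:
        if status == "true_case" and rng.uniform() < config.single_outpatient_fraction:
            route = "single_outpatient"
        elif rng.uniform() < config.inpatient_route_fraction:
            route = "inpatient"
        else:
            route = "outpatient"
        planted = plant_case(member_id, route, (start, end), rng, config)
        claims.extend(planted)
        anchor = min(c["service_date"] for c in planted)  # planted index date
        spans = _case_spans(anchor, rng, config)
        age = _draw_age(rng, config)
        birth_year = anchor.year - age

        if rng.uniform() < config.baseline_contamination_fraction:
            claims.append(
                {
                    "claim_id": f"{member_id}-CN0",
                    "member_id": member_id,
                    "service_date": anchor - ONE_DAY * int(rng.integers(30, 300)),
                    "setting": "outpatient",
                    "provider_id": f"{member_id}-O9",
                    "principal_dx_flag": None,
                    "dx_codes": (CONTAMINATION_CODE,),
                }
            )

        mimic_dx = None
        if status == "mimic":
            names = list(MIMIC_DIAGNOSES)
            weights = np.array(list(MIMIC_DIAGNOSES.values()))
            mimic_dx = str(rng.choice(names, p=weights / weights.sum()))
        chart_evaluable = bool(rng.uniform() >= config.non_evaluable_fraction)
        truth = {
            "member_id": member_id,
            "true_status": status,
            "mimic_dx": mimic_dx,
            "chart_evaluable": chart_evaluable,
            "planted_route": route,
        }
        adjudication = _adjudication_rows(member_id, status, mimic_dx, chart_evaluable, rng, config)

    claims.extend(_noise_claims(member_id, spans, rng, config, start_index=len(claims) + 10))

    member = {"member_id": member_id, "sex": "F", "birth_year": birth_year}
    span_rows = [
        {"member_id": member_id, "start_date": s, "end_date": e} for s, e in spans
    ]
    return member, span_rows, claims, adjudication, truth


def _case_spans(index_date, rng, config):
    """Coverage around a planted index; any gap sits strictly before baseline."""
    extra_pre = int(rng.integers(120, 500))
    post = int(rng.integers(30, 400))
    span_start = index_date - ONE_DAY * (365 + extra_pre)
    span_end = index_date + ONE_DAY * post
    if rng.uniform() < config.enrollment_gap_rate:
        gap_len = int(rng.integers(5, 60))
        hi = extra_pre - gap_len - 5
        if hi > 6:
            gap_start = span_start + ONE_DAY * int(rng.integers(5, hi))
            gap_end = gap_start + ONE_DAY * (gap_len - 1)
            return [(span_start, gap_start - ONE_DAY), (gap_end + ONE_DAY, span_end)]
    return [(span_start, span_end)]


def _background_spans(anchor, rng, config):
    span_start = anchor - ONE_DAY * int(rng.integers(100, 1500))
    span_end = anchor + ONE_DAY * int(rng.integers(30, 700))
    if rng.uniform() < config.enrollment_gap_rate:
        total = (span_end - span_start).days
        if total > 90:
            gap_start = span_start + ONE_DAY * int(rng.integers(20, total - 60))
            gap_len = int(rng.integers(5, 40))
            gap_end = gap_start + ONE_DAY * (gap_len - 1)
            if gap_end < span_end - ONE_DAY:
                return [(span_start, gap_start - ONE_DAY), (gap_end + ONE_DAY, span_end)]
    return [(span_start, span_end)]


def _noise_claims(member_id, spans, rng, config, start_index):
    covered_years = sum((e - s).days + 1 for s, e in spans) / 365.25
    n = int(rng.poisson(config.background_claims_per_year * covered_years))
    out = []
    for k, date in enumerate(_sample_dates_in_spans(spans, n, rng)):
        setting = "inpatient" if rng.uniform() < 0.05 else "outpatient"
        out.append(
            {
                "claim_id": f"{member_id}-{start_index + k:03d}",
                "member_id": member_id,
                "service_date": date,
                "setting": setting,
                "provider_id": f"{member_id}-N{int(rng.integers(1, 4))}",
                "principal_dx_flag": None,
                "dx_codes": (str(rng.choice(BACKGROUND_CODES)),),
            }
        )
    return out


def _adjudication_rows(member_id, status, mimic_dx, chart_evaluable, rng, config):
    if not chart_evaluable:
        base = "non_evaluable"
    elif status == "true_case":
        base = "confirmed"
    else:
        base = "not_endometrial"
    alt = mimic_dx if (base == "not_endometrial" and mimic_dx != "none_identified") else None
    rows = []
    for reviewer in ("R1", "R2"):
        label = base
        if reviewer == "R2" and rng.uniform() < config.reviewer_disagreement_rate:
            others = [l for l in ("confirmed", "not_endometrial", "non_evaluable") if l != base]
            label = str(rng.choice(others))
        rows.append(
            {
                "member_id": member_id,
                "reviewer_id": reviewer,
                "label": label,
                "alternative_dx": alt if label == "not_endometrial" else None,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# population generation


def generate(config: SimulationConfig) -> tuple[ClaimsDataset, pd.DataFrame]:
    """Generate a full population and its ground-truth ledger.

    Returns a validated :class:`ClaimsDataset` plus a truth table with one
    row per member (member_id, true_status, mimic_dx, chart_evaluable,
    planted_route). Identical configs (including seed) give identical output.
    """
    members, spans, claims, adjudication, truth = [], [], [], [], []
    for i in range(config.n_members):
        m, s, c, a, t = _generate_member(i, config)
        members.append(m)
        spans.extend(s)
        claims.extend(c)
        adjudication.extend(a)
        truth.append(t)

    dataset = ClaimsDataset(
        members=pd.DataFrame(members, columns=MEMBER_COLUMNS),
        enrollment=pd.DataFrame(spans, columns=ENROLLMENT_COLUMNS),
        claims=pd.DataFrame(claims, columns=CLAIM_COLUMNS),
        adjudication=pd.DataFrame(adjudication, columns=ADJUDICATION_COLUMNS),
    ).validate()
    return dataset, pd.DataFrame(truth, columns=TRUTH_COLUMNS)


def write_simulation(dataset: ClaimsDataset, truth: pd.DataFrame, directory: Path | str) -> dict:
    """Write the four dataset CSVs plus truth.csv to a directory."""
    directory = Path(directory)
    written = write_dataset(dataset, directory)
    out = truth.copy()
    out["mimic_dx"] = out["mimic_dx"].map(lambda v: "" if v is None else v)
    out["chart_evaluable"] = out["chart_evaluable"].map(lambda v: "true" if v else "false")
    path = directory / "truth.csv"
    out.to_csv(path, index=False, lineterminator="\n")
    written["truth"] = path
    return written


def read_truth(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["mimic_dx"] = df["mimic_dx"].replace("", None)
    df["chart_evaluable"] = df["chart_evaluable"].map(lambda v: v == "true")
    return df[TRUTH_COLUMNS]
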