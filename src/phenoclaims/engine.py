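"""Case-identification engine.

Implements the claims-based algorithm for incident endometrial
adenocarcinoma: a member qualifies with at least one inpatient diagnosis of
uterine cancer (ICD-9-CM category 182) or at least two outpatient diagnoses
on distinct service dates, all within the study window. The index date is
the earliest qualifying diagnosis date. Qualifying members are then screened
for 12 months of continuous enrollment before index and a cancer-free
baseline (no ICD-9-CM 140-209 diagnosis in the half-open year before index);
the survivors form the analyzable cohort.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .codes import code_matches, in_washout_range, normalize_dx_code  # noqa: F401 (re-export)
from .data_model import ClaimsDataset, merge_enrollment_spans

ONE_DAY = pd.Timedelta(days=1)

DEFAULT_STUDY_WINDOW = (dt.date(2010, 1, 1), dt.date(2014, 8, 31))


class AlgorithmConfig(BaseModel):
    """All rule constants of the case-identification algorithm.

    ``excluded_prefixes`` lists categories deliberately NOT used for
    qualification (the nonspecific 179 "uterus, part unspecified" category is
    excluded by default: it trades sensitivity for specificity). The washout
    range 140-209 is the malignant-neoplasm chapter used for the
    cancer-history screen.
    """

    target_code_prefixes: frozenset[str] = frozenset({"182"})
    excluded_prefixes: frozenset[str] = frozenset({"179"})
    washout_range: tuple[int, int] = (140, 209)
    study_window: tuple[dt.date, dt.date] = DEFAULT_STUDY_WINDOW
    baseline_days: int = Field(365, ge=1)
    enrollment_gap_tolerance_days: int = Field(0, ge=0)
    min_inpatient: int = Field(1, ge=1)
    min_outpatient: int = Field(2, ge=1)

    @field_validator("target_code_prefixes", "excluded_prefixes", mode="after")
    @classmethod
    def _prefixes_are_dotfree_digits(cls, value: frozenset[str]) -> frozenset[str]:
        for p in value:
            if not p or "." in p or not p.replace("V", "").replace("E", "").isdigit():
                raise ValueError(f"invalid code prefix: {p!r}")
        return value

    @model_validator(mode="after")
    def _ranges_well_ordered(self) -> "AlgorithmConfig":
        if self.washout_range[0] > self.washout_range[1]:
            raise ValueError("washout_range must be (low, high) with low <= high")
        if self.study_window[0] > self.study_window[1]:
            raise ValueError("study_window must be (start, end) with start <= end")
        return self

    def is_target(self, code: str) -> bool:
        return code_matches(code, self.target_code_prefixes) and not code_matches(
            code, self.excluded_prefixes
        )


@dataclass
class QualificationResult:
    qualified: bool
    route: Optional[str] = None  # "inpatient" | "outpatient"
    index_date: Optional[pd.Timestamp] = None
    qualifying_claim_ids: tuple[str, ...] = ()


COHORT_COLUMNS = [
    "member_id",
    "index_date",
    "route",
    "age_at_index",
    "qualifying_claim_ids",
    "excluded",
    "exclusion_reason",
]

EXCLUSION_REASONS = ("not_female", "insufficient_enrollment", "baseline_cancer")


def qualify(claims: pd.DataFrame, config: AlgorithmConfig) -> QualificationResult:
    """Apply the qualification rule to one member's claims.

    Returns route, index date and the claim ids backing each met criterion.
    The two-outpatient criterion counts distinct service dates (two claims
    on one day never qualify). A member meeting both criteria is routed to
    ``inpatient`` when the first inpatient diagnosis is on or before the day
    the second distinct outpatient diagnosis occurs, else ``outpatient``;
    the index date is the earliest diagnosis date among met criteria.
    """
    start, end = (pd.Timestamp(d) for d in config.study_window)
    target = claims[
        claims["service_date"].between(start, end)
        & claims["dx_codes"].map(lambda codes: any(config.is_target(c) for c in codes))
    ]
    inpat = target[target["setting"] == "inpatient"]
    outpat = target[target["setting"] == "outpatient"]
    outpat_dates = sorted(outpat["service_date"].unique())

    inpat_met = len(inpat) >= config.min_inpatient
    outpat_met = len(outpat_dates) >= config.min_outpatient
    if not inpat_met and not outpat_met:
        return QualificationResult(qualified=False)

    candidates: list[pd.Timestamp] = []
    qualifying = []
    if inpat_met:
        candidates.append(inpat["service_date"].min())
        qualifying.append(inpat)
    if outpat_met:
        candidates.append(pd.Timestamp(outpat_dates[0]))
        qualifying.append(outpat)

    if inpat_met and (
        not outpat_met
        or inpat["service_date"].min() <= pd.Timestamp(outpat_dates[config.min_outpatient - 1])
    ):
        route = "inpatient"
    else:
        route = "outpatient"

    backing = pd.concat(qualifying).sort_values(["service_date", "claim_id"])
    return QualificationResult(
        qualified=True,
        route=route,
        index_date=min(candidates),
        qualifying_claim_ids=tuple(backing["claim_id"].unique()),
    )


def continuously_enrolled(
    spans: pd.DataFrame,
    index_date: pd.Timestamp,
    baseline_days: int = 365,
    gap_tolerance_days: int = 0,
) -> bool:
    """True iff the half-open window [index - baseline_days, index) is covered.

    ``spans`` must be merged (disjoint) spans for one member; at most
    ``gap_tolerance_days`` uncovered days are tolerated. A window extending
    before all recorded coverage counts the missing days as uncovered.
    """
    index_date = pd.Timestamp(index_date)
    window_start = index_date - pd.Timedelta(days=baseline_days)
    covered = 0
    for start, end in zip(spans["start_date"], spans["end_date"]):
        lo = max(start, window_start)
        hi = min(end + ONE_DAY, index_date)  # end inclusive -> half-open
        if hi > lo:
            covered += (hi - lo).days
    return baseline_days - covered <= gap_tolerance_days


def cancer_free_baseline(
    claims: pd.DataFrame,
    index_date: pd.Timestamp,
    baseline_days: int = 365,
    washout_range: tuple[int, int] = (140, 209),
) -> bool:
    """True iff no washout-range diagnosis falls in [index - baseline_days, index).

    The window is half-open on the right: the index-date diagnosis itself is
    not baseline history (it would otherwise self-exclude every case).
    """
    index_date = pd.Timestamp(index_date)
    window_start = index_date - pd.Timedelta(days=baseline_days)
    in_window = claims[
        (claims["service_date"] >= window_start) & (claims["service_date"] < index_date)
    ]
    low, high = washout_range
    return not any(
        in_washout_range(code, low, high)
        for codes in in_window["dx_codes"]
        for code in codes
    )


def build_cohort(
    dataset: ClaimsDataset, config: AlgorithmConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Run the full selection cascade and return (cohort table, attrition report).

    The cohort has one row per member who meets the qualification rule, with
    exclusion flags applied in fixed order: not_female, then
    insufficient_enrollment, then baseline_cancer. The attrition report
    counts members entering and surviving each stage; the included cohort is
    the rows with ``excluded == False``.
    """
    config = config or AlgorithmConfig()
    attrition = {
        "members_total": len(dataset.members),
        "algorithm_qualified": 0,
        "female": 0,
        "enrolled_baseline": 0,
        "cancer_free_baseline": 0,
        "included": 0,
    }

    # Pre-filter to members with at least one target-coded claim.
    has_target = dataset.claims["dx_codes"].map(
        lambda codes: any(config.is_target(c) for c in codes)
    )
    candidates = set(dataset.claims.loc[has_target, "member_id"])

    sex_by_member = dict(zip(dataset.members["member_id"], dataset.members["sex"]))
    birth_by_member = dict(zip(dataset.members["member_id"], dataset.members["birth_year"]))
    claims_by_member = dict(tuple(dataset.claims.groupby("member_id", sort=False)))
    # continuously_enrolled requires disjoint spans; merge defensively in case
    # the dataset was hand-built rather than loaded through read_dataset
    merged_spans = merge_enrollment_spans(dataset.enrollment)
    spans_by_member = dict(tuple(merged_spans.groupby("member_id", sort=False)))
    empty_spans = merged_spans.iloc[0:0]

    rows = []
    for member_id in sorted(candidates):
        member_claims = claims_by_member[member_id]
        result = qualify(member_claims, config)
        if not result.qualified:
            continue
        attrition["algorithm_qualified"] += 1

        reason = None
        if sex_by_member[member_id] != "F":
            reason = "not_female"
        else:
            attrition["female"] += 1
            spans = spans_by_member.get(member_id, empty_spans)
            if not continuously_enrolled(
                spans,
                result.index_date,
                config.baseline_days,
                config.enrollment_gap_tolerance_days,
            ):
                reason = "insufficient_enrollment"
            else:
                attrition["enrolled_baseline"] += 1
                if not cancer_free_baseline(
                    member_claims, result.index_date, config.baseline_days, config.washout_range
                ):
                    reason = "baseline_cancer"
                else:
                    attrition["cancer_free_baseline"] += 1

        rows.append(
            {
                "member_id": member_id,
                "index_date": result.index_date,
                "route": result.route,
                "age_at_index": int(result.index_date.year) - int(birth_by_member[member_id]),
                "qualifying_claim_ids": result.qualifying_claim_ids,
                "excluded": reason is not None,
                "exclusion_reason": reason,
            }
        )

    attrition["included"] = attrition["cancer_free_baseline"]
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return cohort, attrition


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (qualifying_claim_ids semicolon-joined)."""
    out = cohort.copy()
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d") if len(out) else out["index_date"]
    out["qualifying_claim_ids"] = out["qualifying_claim_ids"].map(";".join)
    out["excluded"] = out["excluded"].map(lambda v: "true" if v else "false")
    out["exclusion_reason"] = out["exclusion_reason"].map(lambda v: "" if v is None else v)
    out.to_csv(path, index=False, lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["index_date"] = pd.to_datetime(df["index_date"], format="%Y-%m-%d")
    df["age_at_index"] = df["age_at_index"].astype(int)
    df["qualifying_claim_ids"] = df["qualifying_claim_ids"].map(
        lambda s: tuple(p for p in s.split(";") if p)
    )
    df["excluded"] = df["excluded"].map(lambda v: v == "true")
    df["exclusion_reason"] = df["exclusion_reason"].replace("", None)
    return df[COHORT_COLUMNS]


def sample_for_adjudication(cohort: pd.DataFrame, n: int, seed: int) -> list[str]:
    """Uniform without-replacement sample of cohort member_ids, reproducible by seed."""
    ids = sorted(cohort["member_id"])
    if n > len(ids):
        raise ValueError(f"sample size {n} exceeds cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    return list(rng.choice(np.array(ids, dtype=object), size=n, replace=False))
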