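"""Validation statistics for claims-based phenotyping.

Positive predictive value (PPV) with binomial confidence intervals,
stratified estimates, two-reviewer consensus adjudication, Cohen's kappa
inter-rater agreement, and descriptive statistics of the gap between the
two qualifying outpatient diagnoses.

PPV is the proportion of algorithm-identified members confirmed as true
cases on chart review; charts found insufficient to determine case status
(non-evaluable) are excluded from both numerator and denominator. The
default interval is the Wald normal approximation
``p ± z_{1-a/2} * sqrt(p(1-p)/n)`` truncated to [0, 1]; Wilson and
Clopper-Pearson intervals are available as better-behaved alternatives near
the boundaries.
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Mapping
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .data_model import ADJUDICATION_LABELS
from .engine import AlgorithmConfig
from .errors import UndefinedEstimateError

logger = logging.getLogger(__name__)

CI_METHODS = ("wald", "wilson", "clopper_pearson")

CONSENSUS_POLICIES = ("conservative", "either_confirms", "adjudicator_tiebreak")


def round_half_up(value: float | Fraction, ndigits: int = 1) -> float:
    """Decimal half-up rounding (display contract; internal math stays exact)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(str(float(value)))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def percent(value: float | Fraction, ndigits: int = 1) -> float:
    """Proportion -> percent with half-up display rounding (0.9079... -> 90.8)."""
    return round_half_up(Fraction(value) * 100 if isinstance(value, Fraction) else value * 100,
                         ndigits)


# ---------------------------------------------------------------------------
# point estimate and intervals


def compute_ppv(n_confirmed: int, n_not: int) -> Fraction:
    """Exact PPV as a rational: confirmed / (confirmed + not-endometrial)."""
    if n_confirmed + n_not < 1:
        raise UndefinedEstimateError("PPV undefined on empty denominator")
    return Fraction(n_confirmed, n_confirmed + n_not)


def binomial_ci(
    k: int, n: int, alpha: float = 0.05, method: str = "wald"
) -> tuple[float, float]:
    """Two-sided (1-alpha) binomial CI for k successes in n trials.

    ``wald``: normal approximation, truncated to [0, 1].
    ``wilson``: score interval. ``clopper_pearson``: exact beta interval.
    """
    if n < 1:
        raise ValueError("binomial_ci requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if method == "wald":
        p = k / n
        z = sps.norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(p * (1 - p) / n)
        return (max(0.0, p - half), min(1.0, p + half))
    if method == "wilson":
        return proportion_confint(k, n, alpha=alpha, method="wilson")
    if method == "clopper_pearson":
        return proportion_confint(k, n, alpha=alpha, method="beta")
    raise ValueError(f"unknown CI method {method!r}; choose from {CI_METHODS}")


# ---------------------------------------------------------------------------
# consensus adjudication


def adjudicate_consensus(
    adjudication: pd.DataFrame,
    policy: str = "conservative",
    tiebreaks: Mapping[str, str] | None = None,
) -> pd.Series:
    """Collapse per-reviewer labels into one final label per member.

    Agreeing reviewers keep their label; a single-reviewer member keeps that
    reviewer's label. Disagreements resolve by ``policy``:

    * ``conservative`` (default): non_evaluable if either reviewer says so,
      confirmed only if both confirm, otherwise not_endometrial.
    * ``either_confirms``: confirmed if either confirms; else
      not_endometrial if either says so; else non_evaluable.
    * ``adjudicator_tiebreak``: a third-party label from ``tiebreaks`` keyed
      by member_id decides.

    Returns a Series indexed by member_id.
    """
    if policy not in CONSENSUS_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {CONSENSUS_POLICIES}")
    counts = adjudication.groupby("member_id")["reviewer_id"].nunique()
    if (counts > 2).any():
        offenders = sorted(counts[counts > 2].index)
        raise ValueError(f"more than two reviewers for member(s): {offenders}")

    final: dict[str, str] = {}
    for member_id, group in adjudication.groupby("member_id", sort=True):
        labels = list(group["label"])
        if len(labels) == 1 or labels[0] == labels[1]:
            final[member_id] = labels[0]
        elif policy == "conservative":
            if "non_evaluable" in labels:
                final[member_id] = "non_evaluable"
            else:  # one confirmed, one not_endometrial
                final[member_id] = "not_endometrial"
        elif policy == "either_confirms":
            if "confirmed" in labels:
                final[member_id] = "confirmed"
            elif "not_endometrial" in labels:
                final[member_id] = "not_endometrial"
            else:
                final[member_id] = "non_evaluable"
        else:  # adjudicator_tiebreak
            if tiebreaks is None or member_id not in tiebreaks:
                raise ValueError(
                    f"adjudicator_tiebreak policy needs a tiebreak label for {member_id!r}"
                )
            final[member_id] = tiebreaks[member_id]
    return pd.Series(final, name="final_label", dtype=object)


# ---------------------------------------------------------------------------
# stratified PPV


@dataclass
class PpvEstimate:
    """PPV point estimate with CI and counts for one validation stratum."""

    stratum_label: str
    n_confirmed: int
    n_not: int
    n_non_evaluable: int
    ppv: Optional[Fraction]
    ci_low: Optional[float]
    ci_high: Optional[float]
    ci_method: str = "wald"
    alpha: float = 0.05

    @property
    def defined(self) -> bool:
        return self.ppv is not None

    @property
    def ppv_pct(self) -> Optional[float]:
        return None if self.ppv is None else percent(self.ppv)

    @property
    def ci_pct(self) -> Optional[tuple[float, float]]:
        if self.ci_low is None:
            return None
        return (percent(self.ci_low), percent(self.ci_high))


def ppv_estimate(
    stratum_label: str,
    n_confirmed: int,
    n_not: int,
    n_non_evaluable: int = 0,
    alpha: float = 0.05,
    method: str = "wald",
) -> PpvEstimate:
    """Build a :class:`PpvEstimate`; an empty denominator yields a flagged row."""
    if n_confirmed + n_not == 0:
        return PpvEstimate(stratum_label, n_confirmed, n_not, n_non_evaluable,
                           None, None, None, method, alpha)
    p = compute_ppv(n_confirmed, n_not)
    low, high = binomial_ci(n_confirmed, n_confirmed + n_not, alpha=alpha, method=method)
    return PpvEstimate(stratum_label, n_confirmed, n_not, n_non_evaluable,
                       p, low, high, method, alpha)


AGE_BANDS = ("30-44", "45-64", "65+")


def age_band(age: int) -> str:
    """Age stratum at index: 30-44, 45-64, 65+; anything else is 'other'."""
    if 30 <= age <= 44:
        return "30-44"
    if 45 <= age <= 64:
        return "45-64"
    if age >= 65:
        return "65+"
    return "other"


def default_stratifiers() -> dict[str, Callable[[pd.Series], str]]:
    return {
        "setting": lambda row: row["route"],
        "age": lambda row: age_band(row["age_at_index"]),
    }


def stratified_ppv(
    validation: pd.DataFrame,
    stratifiers: Mapping[str, Callable[[pd.Series], str]] | None = None,
    alpha: float = 0.05,
    method: str = "wald",
) -> list[PpvEstimate]:
    """Overall and per-stratum PPV estimates from a validation frame.

    ``validation`` needs one row per adjudicated member with a
    ``final_label`` column plus whatever columns the stratifiers read
    (``route`` and ``age_at_index`` for the defaults). Stratum counts within
    each stratifier sum to the overall counts; zero-evaluable strata are
    flagged, not dropped.
    """
    if stratifiers is None:
        stratifiers = default_stratifiers()

    def counts(df: pd.DataFrame) -> tuple[int, int, int]:
        vc = df["final_label"].value_counts()
        return (int(vc.get("confirmed", 0)), int(vc.get("not_endometrial", 0)),
                int(vc.get("non_evaluable", 0)))

    out = [ppv_estimate("overall", *counts(validation), alpha=alpha, method=method)]
    for name, fn in stratifiers.items():
        if validation.empty:
            continue
        values = validation.apply(fn, axis=1)
        for value in sorted(values.unique()):
            sub = validation[values == value]
            out.append(
                ppv_estimate(f"{name}:{value}", *counts(sub), alpha=alpha, method=method)
            )
    return out


def ppv_table(estimates: list[PpvEstimate]) -> pd.DataFrame:
    """Render estimates as a display table (percents rounded half-up, 1 dp)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "stratum": e.stratum_label,
                "confirmed": e.n_confirmed,
                "not_endometrial": e.n_not,
                "non_evaluable": e.n_non_evaluable,
                "ppv_pct": e.ppv_pct,
                "ci_low_pct": None if e.ci_low is None else percent(e.ci_low),
                "ci_high_pct": None if e.ci_high is None else percent(e.ci_high),
                "ci_method": e.ci_method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inter-rater agreement


@dataclass
class AgreementResult:
    """Crude agreement and Cohen's kappa for two paired raters."""

    crude_agreement: float
    kappa: float  # NaN when chance agreement is 1 (both raters constant, identical)
    n_pairs: int
    category_table: pd.DataFrame


def cohen_kappa(labels_a, labels_b, categories: tuple[str, ...] | None = None) -> AgreementResult:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_o`` is the observed agreement proportion and ``p_e`` the expected
    agreement under independent raters with the observed marginals. With
    identical constant raters p_e = 1 and kappa is undefined (NaN).
    """
    a = pd.Series(list(labels_a), dtype=object)
    b = pd.Series(list(labels_b), dtype=object)
    if len(a) != len(b):
        raise ValueError("paired label vectors must have equal length")
    if len(a) == 0:
        raise ValueError("need at least one label pair")
    if categories is None:
        observed = set(a) | set(b)
        if observed <= set(ADJUDICATION_LABELS):
            categories = ADJUDICATION_LABELS
        else:
            categories = tuple(sorted(observed))

    table = pd.crosstab(
        pd.Categorical(a, categories=categories),
        pd.Categorical(b, categories=categories),
        dropna=False,
    ).reindex(index=categories, columns=categories, fill_value=0)
    n = len(a)
    p_o = float(np.trace(table.to_numpy())) / n
    marg_a = table.sum(axis=1).to_numpy() / n
    marg_b = table.sum(axis=0).to_numpy() / n
    p_e = float(marg_a @ marg_b)
    if p_e == 1.0:
        logger.warning("kappa undefined: both raters constant and identical")
        kappa = float("nan")
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return AgreementResult(crude_agreement=p_o, kappa=kappa, n_pairs=n, category_table=table)


# ---------------------------------------------------------------------------
# outpatient inter-diagnosis gap


@dataclass
class GapStats:
    """Days between the first two distinct outpatient target diagnoses."""

    n: int
    mean: Optional[float]
    sd: Optional[float]  # sample SD (n-1); None when n < 2
    median: Optional[float]

    @property
    def empty(self) -> bool:
        return self.n == 0


def outpatient_gap_stats(
    cohort: pd.DataFrame, claims: pd.DataFrame, config: AlgorithmConfig | None = None
) -> GapStats:
    """Gap statistics over included outpatient-route cohort members."""
    config = config or AlgorithmConfig()
    start, end = (pd.Timestamp(d) for d in config.study_window)
    members = cohort[(cohort["route"] == "outpatient") & (~cohort["excluded"])]["member_id"]
    target = claims[
        claims["member_id"].isin(set(members))
        & (claims["setting"] == "outpatient")
        & claims["service_date"].between(start, end)
        & claims["dx_codes"].map(lambda codes: any(config.is_target(c) for c in codes))
    ]
    gaps = []
    for _, group in target.groupby("member_id"):
        dates = sorted(group["service_date"].unique())
        if len(dates) >= 2:
            gaps.append((pd.Timestamp(dates[1]) - pd.Timestamp(dates[0])).days)
    if not gaps:
        return GapStats(n=0, mean=None, sd=None, median=None)
    arr = np.asarray(gaps, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) >= 2 else None
    return GapStats(n=len(arr), mean=float(arr.mean()), sd=sd, median=float(np.median(arr)))


def paired_reviewer_labels(adjudication: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Aligned label vectors over members reviewed by exactly two reviewers.

    Reviewer roles are assigned by sorted reviewer_id within each member, so
    the pairing is deterministic. Single-reviewer members are skipped.
    """
    a, b = [], []
    for _, group in adjudication.groupby("member_id", sort=True):
        group = group.sort_values("reviewer_id")
        if len(group) == 2:
            a.append(group["label"].iloc[0])
            b.append(group["label"].iloc[1])
    return a, b


# ---------------------------------------------------------------------------
# validation-frame assembly


def build_validation_frame(
    cohort: pd.DataFrame,
    adjudication: pd.DataFrame,
    policy: str = "conservative",
    tiebreaks: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join consensus labels onto included cohort entries.

    Included cohort members with no adjudication record are dropped from the
    validation set with a logged warning (their charts were never reviewed).
    """
    included = cohort[~cohort["excluded"]].copy()
    final = adjudicate_consensus(adjudication, policy=policy, tiebreaks=tiebreaks)
    missing = sorted(set(included["member_id"]) - set(final.index))
    if missing:
        logger.warning(
            "%d cohort member(s) lack adjudication records and are excluded "
            "from validation (first few: %s)", len(missing), missing[:5],
        )
    merged = included.merge(
        final.rename_axis("member_id").reset_index(), on="member_id", how="inner"
    )
    return merged
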