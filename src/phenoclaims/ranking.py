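"""Record-source ranking for chart retrieval.

For each algorithm-identified member, candidate medical-record sources are
ranked to maximize the chance an abstractable chart is obtained:

tier 1 — a hospitalization where uterine cancer was the principal diagnosis;
tier 2 — physician offices with more than one uterine-cancer visit, ordered
         by decreasing number of such visits.

A "visit" is a distinct service date at a provider with at least one
target-coded claim; multiple claim lines on one date count once. Ties within
a tier break lexicographically on provider_id, so output is deterministic
and invariant to claim row order.
"""

from __future__ import annotations

import pandas as pd

from .engine import AlgorithmConfig

RECORD_SOURCE_COLUMNS = ["member_id", "provider_id", "tier", "target_visit_count", "rank"]


def rank_sources(claims: pd.DataFrame, config: AlgorithmConfig | None = None) -> pd.DataFrame:
    """Rank candidate record sources for one member's claims.

    Returns a DataFrame with columns member_id, provider_id, tier (1 or 2),
    target_visit_count and rank (1-based). Inpatient claims lacking a
    principal-diagnosis flag are ineligible for tier 1; offices need at
    least two distinct target-coded service dates to be listed. A member
    with no rankable source yields an empty frame.
    """
    config = config or AlgorithmConfig()
    if claims.empty:
        return pd.DataFrame(columns=RECORD_SOURCE_COLUMNS)
    member_id = claims["member_id"].iloc[0]

    target = claims[claims["dx_codes"].map(lambda codes: any(config.is_target(c) for c in codes))]
    target = target[target["provider_id"].notna()]

    rows = []

    # Tier 1: hospitalizations with a principal target diagnosis (first-listed
    # code is principal when the flag is set).
    inpat = target[
        (target["setting"] == "inpatient")
        & target["principal_dx_flag"].map(lambda v: v is True)
        & target["dx_codes"].map(lambda codes: config.is_target(codes[0]))
    ]
    for provider_id, group in inpat.groupby("provider_id", sort=True):
        rows.append((member_id, provider_id, 1, group["service_date"].nunique()))

    # Tier 2: offices with >1 distinct target-coded visit date.
    outpat = target[target["setting"] == "outpatient"]
    for provider_id, group in outpat.groupby("provider_id", sort=True):
        n_visits = group["service_date"].nunique()
        if n_visits > 1:
            rows.append((member_id, provider_id, 2, n_visits))

    df = pd.DataFrame(rows, columns=RECORD_SOURCE_COLUMNS[:4])
    df = df.sort_values(
        ["tier", "target_visit_count", "provider_id"],
        ascending=[True, False, True],
        ignore_index=True,
    )
    df["rank"] = df.index + 1
    return df


def rank_all_sources(
    claims: pd.DataFrame, member_ids: list[str], config: AlgorithmConfig | None = None
) -> pd.DataFrame:
    """Concatenate :func:`rank_sources` over the given members."""
    config = config or AlgorithmConfig()
    parts = []
    grouped = dict(tuple(claims.groupby("member_id", sort=False)))
    for member_id in sorted(member_ids):
        if member_id in grouped:
            parts.append(rank_sources(grouped[member_id], config))
    if not parts:
        return pd.DataFrame(columns=RECORD_SOURCE_COLUMNS)
    return pd.concat(parts, ignore_index=True)
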