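"""Independent brute-force oracles, kept deliberately literal and slow.

These re-derive the selection rules from first principles (explicit day
sets, claim-subset reasoning) without reusing any engine code paths beyond
the shared data model, so they can serve as a cross-check for the
vectorized implementation.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

from phenoclaims.data_model import ClaimsDataset


def _is_target(code: str) -> bool:
    return code.isdigit() and code[:3] == "182"


def _is_washout(code: str) -> bool:
    return code.isdigit() and len(code) >= 3 and 140 <= int(code[:3]) <= 209


def brute_force_cohort(
    dataset: ClaimsDataset,
    window: tuple[dt.date, dt.date] = (dt.date(2010, 1, 1), dt.date(2014, 8, 31)),
    baseline_days: int = 365,
) -> list[dict]:
    """Literal re-derivation of the selection cascade.

    One inpatient 182-category diagnosis OR two outpatient diagnoses on
    distinct days, inside the window; index = earliest date among met
    criteria; inpatient route wins when its first date is on or before the
    second distinct outpatient date; then every day of the half-open year
    before index must be enrolled, and no 140-209 code may appear in it.
    """
    start, end = (pd.Timestamp(d) for d in window)
    rows = []
    for _, m in dataset.members.sort_values("member_id").iterrows():
        claims = dataset.claims[dataset.claims["member_id"] == m["member_id"]]
        inpat_dates, outpat_dates = set(), set()
        for _, c in claims.iterrows():
            if not (start <= c["service_date"] <= end):
                continue
            if any(_is_target(code) for code in c["dx_codes"]):
                (inpat_dates if c["setting"] == "inpatient" else outpat_dates).add(
                    c["service_date"]
                )
        inpat_met = len(inpat_dates) >= 1
        outpat_met = len(outpat_dates) >= 2
        if not (inpat_met or outpat_met):
            continue

        candidates = []
        if inpat_met:
            candidates.append(min(inpat_dates))
        if outpat_met:
            candidates.append(min(outpat_dates))
        index_date = min(candidates)
        if inpat_met and (not outpat_met or min(inpat_dates) <= sorted(outpat_dates)[1]):
            route = "inpatient"
        else:
            route = "outpatient"

        reason = None
        if m["sex"] != "F":
            reason = "not_female"
        else:
            covered = set()
            spans = dataset.enrollment[dataset.enrollment["member_id"] == m["member_id"]]
            for _, s in spans.iterrows():
                day = s["start_date"]
                while day <= s["end_date"]:
                    covered.add(day)
                    day += pd.Timedelta(days=1)
            baseline = [
                index_date - pd.Timedelta(days=k) for k in range(1, baseline_days + 1)
            ]
            if not all(day in covered for day in baseline):
                reason = "insufficient_enrollment"
            else:
                dirty = False
                for _, c in claims.iterrows():
                    if index_date - pd.Timedelta(days=baseline_days) <= c["service_date"] < index_date:
                        if any(_is_washout(code) for code in c["dx_codes"]):
                            dirty = True
                if dirty:
                    reason = "baseline_cancer"

        rows.append(
            {
                "member_id": m["member_id"],
                "index_date": index_date,
                "route": route,
                "excluded": reason is not None,
                "exclusion_reason": reason,
            }
        )
    return rows


def random_micro_dataset(rng, max_members: int = 5, max_claims: int = 8) -> ClaimsDataset:
    """Small random dataset exercising window edges, codes, settings, spans."""
    from conftest import claim, make_dataset, member, span

    code_pool = ["1820", "1821", "1828", "179", "1799", "1539", "2390", "4019", "V103", "183"]
    n_members = int(rng.integers(1, max_members + 1))
    members, spans, claims = [], [], []
    for i in range(n_members):
        mid = f"m{i}"
        sex = "F" if rng.uniform() < 0.85 else "M"
        members.append(member(mid, sex=sex, birth_year=int(rng.integers(1930, 1985))))
        for _ in range(int(rng.integers(0, 3))):
            s = pd.Timestamp("2008-01-01") + pd.Timedelta(days=int(rng.integers(0, 2600)))
            e = s + pd.Timedelta(days=int(rng.integers(0, 1200)))
            spans.append(span(mid, str(s.date()), str(e.date())))
    n_claims = int(rng.integers(0, max_claims + 1))
    for j in range(n_claims):
        mid = f"m{int(rng.integers(0, n_members))}"
        date = pd.Timestamp("2009-06-01") + pd.Timedelta(days=int(rng.integers(0, 2200)))
        codes = tuple(
            str(rng.choice(code_pool)) for _ in range(int(rng.integers(1, 3)))
        )
        claims.append(
            claim(
                f"c{j}", mid, str(date.date()),
                setting="inpatient" if rng.uniform() < 0.3 else "outpatient",
                codes=codes,
                provider=f"p{int(rng.integers(0, 3))}",
                principal=bool(rng.uniform() < 0.5) if rng.uniform() < 0.5 else None,
            )
        )
    return make_dataset(members, spans, claims)
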