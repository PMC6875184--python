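"""PPV, binomial intervals, consensus adjudication, kappa, gap statistics."""

from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import adjudication, claim, make_dataset, member
from phenoclaims.engine import AlgorithmConfig
from phenoclaims.errors import UndefinedEstimateError
from phenoclaims.stats import (
    adjudicate_consensus,
    binomial_ci,
    build_validation_frame,
    cohen_kappa,
    compute_ppv,
    outpatient_gap_stats,
    paired_reviewer_labels,
    percent,
    ppv_estimate,
    round_half_up,
    stratified_ppv,
)


class TestPpvPoint:
    def test_exact_rational(self):
        assert compute_ppv(286, 29) == Fraction(286, 315)

    @pytest.mark.parametrize("k,n_not,pct", [(0, 5, 0.0), (5, 0, 100.0)])
    def test_boundaries(self, k, n_not, pct):
        assert percent(compute_ppv(k, n_not)) == pct

    def test_empty_denominator_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            compute_ppv(0, 0)

    def test_display_rounding_is_half_up(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(0.24, 1) == 0.2
        assert percent(Fraction(1, 16), 2) == 6.25


class TestBinomialCi:
    def test_wald_truncates_to_unit_interval(self):
        # near-boundary: the untruncated upper limit for 8/9 exceeds 1
        low, high = binomial_ci(8, 9, method="wald")
        assert high == 1.0 and 0 < low < 8 / 9
        # at the boundary Wald degenerates to zero width (known pathology)
        assert binomial_ci(9, 9, method="wald") == (1.0, 1.0)
        assert binomial_ci(0, 9, method="wald") == (0.0, 0.0)

    @pytest.mark.parametrize("method", ["wald", "wilson", "clopper_pearson"])
    @pytest.mark.parametrize("k,n", [(0, 10), (3, 10), (10, 10), (35, 41)])
    def test_interval_contains_point_estimate(self, method, k, n):
        low, high = binomial_ci(k, n, method=method)
        assert low <= k / n <= high

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(1, 0)
        with pytest.raises(ValueError):
            binomial_ci(5, 4)
        with pytest.raises(ValueError):
            binomial_ci(1, 4, method="bayes")

    def test_wald_empirical_coverage_matches_exact_enumeration(self):
        """Simulated Wald coverage at p=0.9, n=315 lies within 3 points of
        the benchmark computed by exact binomial tail sums."""
        p, n = 0.9, 315
        ks = np.arange(n + 1)
        pmf = sps.binom.pmf(ks, n, p)
        covers = np.array(
            [binomial_ci(int(k), n, method="wald")[0] <= p <= binomial_ci(int(k), n, method="wald")[1]
             for k in ks]
        )
        exact_coverage = float(pmf @ covers)
        rng = np.random.default_rng(20240901)
        draws = rng.binomial(n, p, size=2000)
        empirical = np.mean(
            [binomial_ci(int(k), n)[0] <= p <= binomial_ci(int(k), n)[1] for k in draws]
        )
        assert abs(empirical - exact_coverage) < 0.03

    def test_clopper_pearson_coverage_at_least_nominal(self):
        """Exact enumeration: CP coverage >= 95% for all small n."""
        for n in (5, 20, 50):
            for p in (0.1, 0.5, 0.9):
                ks = np.arange(n + 1)
                pmf = sps.binom.pmf(ks, n, p)
                covers = np.array(
                    [binomial_ci(int(k), n, method="clopper_pearson")[0] - 1e-12 <= p
                     <= binomial_ci(int(k), n, method="clopper_pearson")[1] + 1e-12
                     for k in ks]
                )
                assert pmf @ covers >= 0.95 - 1e-9


LABELS = ("confirmed", "not_endometrial", "non_evaluable")


class TestConsensus:
    @pytest.mark.parametrize("a,b", list(product(LABELS, LABELS)))
    def test_conservative_policy_table(self, a, b):
        """Full enumeration against the policy definition: non_evaluable if
        either says so, confirmed only if both confirm."""
        records = pd.DataFrame(
            [adjudication("A", "R1", a), adjudication("A", "R2", b)]
        )
        final = adjudicate_consensus(records)["A"]
        if "non_evaluable" in (a, b):
            expected = "non_evaluable" if a != b or a == "non_evaluable" else a
        elif a == b:
            expected = a
        else:
            expected = "not_endometrial"
        assert final == expected

    def test_either_confirms_policy(self):
        records = pd.DataFrame(
            [adjudication("A", "R1", "confirmed"), adjudication("A", "R2", "not_endometrial")]
        )
        assert adjudicate_consensus(records, policy="either_confirms")["A"] == "confirmed"

    def test_single_reviewer_keeps_label(self):
        records = pd.DataFrame([adjudication("A", "R1", "not_endometrial")])
        assert adjudicate_consensus(records)["A"] == "not_endometrial"

    def test_tiebreak_policy_requires_tiebreak(self):
        records = pd.DataFrame(
            [adjudication("A", "R1", "confirmed"), adjudication("A", "R2", "not_endometrial")]
        )
        with pytest.raises(ValueError, match="tiebreak"):
            adjudicate_consensus(records, policy="adjudicator_tiebreak")
        final = adjudicate_consensus(
            records, policy="adjudicator_tiebreak", tiebreaks={"A": "confirmed"}
        )
        assert final["A"] == "confirmed"

    def test_three_reviewers_rejected(self):
        records = pd.DataFrame(
            [adjudication("A", f"R{i}", "confirmed") for i in (1, 2, 3)]
        )
        with pytest.raises(ValueError):
            adjudicate_consensus(records)


class TestKappa:
    def test_identical_vectors(self):
        result = cohen_kappa(["confirmed", "not_endometrial"] * 5,
                             ["confirmed", "not_endometrial"] * 5)
        assert result.kappa == 1.0 and result.crude_agreement == 1.0

    def test_perfect_disagreement_on_balanced_binary_input(self):
        a = ["x", "y"] * 10
        b = ["y", "x"] * 10
        assert cohen_kappa(a, b).kappa == pytest.approx(-1.0)

    def test_hand_computed_two_by_two(self):
        # cross-tab [[40, 5], [5, 50]]: p_o = 0.9,
        # p_e = 0.45*0.45 + 0.55*0.55 = 0.505, kappa = 0.395/0.495
        a = ["x"] * 45 + ["y"] * 55
        b = ["x"] * 40 + ["y"] * 5 + ["x"] * 5 + ["y"] * 50
        result = cohen_kappa(a, b)
        assert result.crude_agreement == pytest.approx(0.9)
        assert result.kappa == pytest.approx(0.395 / 0.495)
        assert result.category_table.to_numpy().tolist() == [[40, 5], [5, 50]]

    def test_matches_sklearn_on_random_labels(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        a = rng.choice(LABELS, size=200, p=[0.7, 0.2, 0.1])
        b = np.where(rng.uniform(size=200) < 0.8, a, rng.choice(LABELS, size=200))
        ours = cohen_kappa(list(a), list(b)).kappa
        theirs = sklearn_metrics.cohen_kappa_score(a, b)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_kappa_is_one_iff_no_offdiagonal_mass(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            a = list(rng.choice(["x", "y", "z"], size=40))
            b = [
                v if rng.uniform() < 0.9 else str(rng.choice(["x", "y", "z"]))
                for v in a
            ]
            result = cohen_kappa(a, b)
            off_diag = result.category_table.to_numpy().sum() - np.trace(
                result.category_table.to_numpy()
            )
            if not np.isnan(result.kappa):
                assert (result.kappa == 1.0) == (off_diag == 0)

    def test_constant_identical_raters_flagged_undefined(self):
        result = cohen_kappa(["x"] * 5, ["x"] * 5)
        assert np.isnan(result.kappa)
        assert result.crude_agreement == 1.0

    def test_paired_labels_alignment(self):
        records = pd.DataFrame([
            adjudication("A", "R2", "confirmed"),
            adjudication("A", "R1", "not_endometrial"),
            adjudication("B", "R1", "confirmed"),  # single reviewer: skipped
        ])
        a, b = paired_reviewer_labels(records)
        assert a == ["not_endometrial"] and b == ["confirmed"]


class TestStratifiedPpv:
    def _validation(self, rows):
        return pd.DataFrame(rows, columns=["member_id", "final_label", "route", "age_at_index"])

    def test_stratum_counts_sum_to_overall(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"m{i}", str(rng.choice(LABELS, p=[0.85, 0.1, 0.05])),
             str(rng.choice(["inpatient", "outpatient"])), int(rng.integers(30, 90)))
            for i in range(200)
        ]
        estimates = stratified_ppv(self._validation(rows))
        overall = estimates[0]
        by_group: dict[str, list] = {}
        for e in estimates[1:]:
            by_group.setdefault(e.stratum_label.split(":")[0], []).append(e)
        for group, parts in by_group.items():
            assert sum(e.n_confirmed for e in parts) == overall.n_confirmed, group
            assert sum(e.n_not for e in parts) == overall.n_not, group
            assert sum(e.n_non_evaluable for e in parts) == overall.n_non_evaluable, group

    def test_single_stratum_equals_overall(self):
        rows = [(f"m{i}", "confirmed", "outpatient", 70) for i in range(9)]
        rows.append(("m9", "not_endometrial", "outpatient", 71))
        estimates = stratified_ppv(self._validation(rows))
        overall = estimates[0]
        setting = [e for e in estimates if e.stratum_label == "setting:outpatient"][0]
        assert (setting.n_confirmed, setting.n_not, setting.ppv) == (
            overall.n_confirmed, overall.n_not, overall.ppv
        )

    def test_zero_evaluable_stratum_flagged_not_dropped(self):
        rows = [
            ("m0", "confirmed", "outpatient", 70),
            ("m1", "non_evaluable", "inpatient", 50),
        ]
        estimates = stratified_ppv(self._validation(rows))
        inpat = [e for e in estimates if e.stratum_label == "setting:inpatient"][0]
        assert not inpat.defined
        assert inpat.n_non_evaluable == 1

    def test_non_evaluable_never_enters_denominator(self):
        e = ppv_estimate("s", 9, 1, 90)
        assert e.ppv == Fraction(9, 10)
        assert e.n_confirmed + e.n_not + e.n_non_evaluable == 100


class TestGapStats:
    def _setup(self, gap_pairs):
        members_, claims_, cohort_rows = [], [], []
        for i, (d1, d2) in enumerate(gap_pairs):
            mid = f"m{i}"
            members_.append(member(mid))
            claims_.append(claim(f"c{i}a", mid, d1, provider="O1"))
            claims_.append(claim(f"c{i}b", mid, d2, provider="O1"))
            cohort_rows.append(
                {"member_id": mid, "route": "outpatient", "excluded": False}
            )
        ds = make_dataset(members_, claims=claims_)
        return pd.DataFrame(cohort_rows), ds.claims

    def test_equal_gaps(self):
        cohort, claims = self._setup([("2011-01-01", "2011-01-11"),
                                      ("2012-01-01", "2012-01-11")])
        g = outpatient_gap_stats(cohort, claims)
        assert (g.mean, g.sd, g.median) == (10.0, 0.0, 10.0)

    def test_skewed_gaps(self):
        cohort, claims = self._setup([
            ("2011-01-01", "2011-01-02"),
            ("2011-02-01", "2011-02-11"),
            ("2011-03-01", "2011-06-09"),
        ])
        g = outpatient_gap_stats(cohort, claims)
        assert g.mean == pytest.approx(37.0)
        assert g.median == 10.0

    def test_no_outpatient_members_flagged_empty(self):
        g = outpatient_gap_stats(
            pd.DataFrame(columns=["member_id", "route", "excluded"]),
            make_dataset([member("A")]).claims,
        )
        assert g.empty


class TestValidationFrame:
    def test_members_without_adjudication_dropped_with_warning(self, caplog):
        cohort = pd.DataFrame(
            [
                {"member_id": "A", "route": "outpatient", "age_at_index": 60,
                 "excluded": False, "exclusion_reason": None},
                {"member_id": "B", "route": "outpatient", "age_at_index": 61,
                 "excluded": False, "exclusion_reason": None},
            ]
        )
        records = pd.DataFrame([adjudication("A", "R1", "confirmed")])
        with caplog.at_level("WARNING"):
            frame = build_validation_frame(cohort, records)
        assert list(frame["member_id"]) == ["A"]
        assert "lack adjudication" in caplog.text
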