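"""Sibling-recurrence machinery: selection uniformity, matching contracts,
the logistic OR against its closed-form 2x2 oracle, and Wald comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from fpe_famkit.famsim import LiabilityParams, simulate_registry
from fpe_famkit.registry import (
    DegenerateTableError,
    IndexCriteria,
    MatchingError,
    RecurrenceResult,
    compare_or,
    fit_recurrence,
    fit_recurrence_counts,
    match_controls,
    p_vs_null,
    recurrence_by_sibling_sex,
    run_recurrence_analysis,
    se_log_or_from_ci,
    select_index_case,
    select_sibling,
)
from fpe_famkit.reference import REPORTED_SIBLING_ORS


def _toy_family(**overrides):
    base = pd.DataFrame(
        {
            "iid": [1, 2, 3, 4],
            "fid": [10, 10, 10, 10],
            "father": [100, 100, 100, 100],
            "mother": [101, 101, 101, 101],
            "sex": ["M", "F", "M", "F"],
            "birth_year": [1990, 1992, 1994, 1996],
            "role": ["offspring"] * 4,
            "dx_asd": [True, True, False, False],
            "dx_id": [False, False, False, False],
        }
    )
    base["dgroup"] = np.where(base["dx_asd"], "ASDnoID", "none")
    for col, vals in overrides.items():
        base[col] = vals
    return base


class TestSelection:
    def test_singleton_eligible(self, rng):
        fam = _toy_family()
        got = select_index_case(fam, IndexCriteria("M", "ASDnoID"), rng)
        assert got == 1

    def test_no_eligible_returns_none(self, rng):
        fam = _toy_family(dx_asd=[False] * 4, dgroup=["none"] * 4)
        assert select_index_case(fam, IndexCriteria("F", "ASDnoID"), rng) is None

    def test_two_eligible_uniform(self, rng):
        fam = _toy_family(sex=["M", "M", "M", "F"], dx_asd=[True, True, False, False],
                          dgroup=["ASDnoID", "ASDnoID", "none", "none"])
        picks = [select_index_case(fam, IndexCriteria("M", "ASDnoID"), rng) for _ in range(10_000)]
        freq = np.mean(np.array(picks) == 1)
        assert abs(freq - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_sibling_window_and_none(self, rng):
        fam = _toy_family(birth_year=[1990, 1975, 1979, 1978])
        assert select_sibling(fam, 1, (1981, 2005), rng) is None

    def test_sibling_unknown_index_raises(self, rng):
        with pytest.raises(ValueError):
            select_sibling(_toy_family(), 999, (1981, 2005), rng)

    def test_sibling_selection_not_diagnosis_dependent(self, rng):
        # one affected (iid 2) and one unaffected (iid 3) sibling of index 1
        fam = _toy_family()
        picks = np.array([select_sibling(fam, 1, (1981, 2005), rng) for _ in range(10_000)])
        freq_affected = np.mean(picks == 2)
        assert abs(freq_affected - 1 / 3) < 3 * math.sqrt((1 / 3) * (2 / 3) / 10_000)


class TestMatching:
    def _population(self, n=50):
        return pd.DataFrame(
            {
                "iid": np.arange(1000, 1000 + n),
                "fid": np.arange(2000, 2000 + n),
                "sex": ["F"] * n,
                "birth_year": [1990] * n,
                "role": ["offspring"] * n,
            }
        )

    def test_contract(self, rng):
        sib = pd.Series({"iid": 5, "sex": "F", "birth_year": 1990})
        got = match_controls(sib, self._population(), 2, set(), rng)
        assert len(got) == len(set(got)) == 2

    def test_insufficient_pool_raises(self, rng):
        sib = pd.Series({"iid": 5, "sex": "F", "birth_year": 1990})
        with pytest.raises(MatchingError, match="1990"):
            match_controls(sib, self._population(n=1), 2, set(), rng)

    def test_exclusions_respected(self, rng):
        sib = pd.Series({"iid": 5, "sex": "F", "birth_year": 1990})
        pop = self._population(n=3)
        with pytest.raises(MatchingError):
            match_controls(sib, pop, 2, set(pop["iid"].tolist()[:2]), rng)


class TestFitRecurrence:
    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(5, 400, size=4)
            res = fit_recurrence_counts(int(a), int(a + b), int(c), int(c + d))
            oracle_or = (a * d) / (b * c)
            oracle_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            assert res.odds_ratio == pytest.approx(oracle_or, rel=1e-6)
            assert res.se_log_or == pytest.approx(oracle_se, rel=1e-6)

    def test_matches_statsmodels_glm(self):
        """Independent route: ungrouped logistic regression via statsmodels."""
        for a, n1, c, n0 in [(150, 1707, 45, 3414), (30, 300, 20, 600), (8, 50, 40, 100)]:
            res = fit_recurrence_counts(a, n1, c, n0)
            y = np.r_[np.ones(a), np.zeros(n1 - a), np.ones(c), np.zeros(n0 - c)]
            x = sm.add_constant(np.r_[np.ones(n1), np.zeros(n0)])
            fit = sm.GLM(y, x, family=sm.families.Binomial()).fit()
            assert res.odds_ratio == pytest.approx(math.exp(fit.params[1]), rel=1e-6)
            assert res.se_log_or == pytest.approx(fit.bse[1], rel=1e-6)

    def test_printed_scale_example(self):
        # counts chosen to mimic the published female-index cell
        res = fit_recurrence_counts(150, 1707, 45, 3414)
        assert res.odds_ratio == pytest.approx(7.21, abs=0.005)
        assert res.ci_low == pytest.approx(5.14, abs=0.005)
        assert res.ci_high == pytest.approx(10.12, abs=0.005)

    def test_equal_rates_gives_or_one(self):
        res = fit_recurrence_counts(30, 300, 60, 600)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_zero_cell_flagged_degenerate(self):
        res = fit_recurrence_counts(10, 100, 0, 200)
        assert res.degenerate
        assert math.isfinite(res.odds_ratio)

    def test_fit_from_cohort_ids(self, registry_cohort):
        ch = registry_cohort.children()
        sibs = ch["iid"].to_numpy()[:400].tolist()
        ctls = ch["iid"].to_numpy()[400:1200].tolist()
        res = fit_recurrence(sibs, ctls, "ASDnoID", registry_cohort)
        a = (ch.iloc[:400]["dgroup"].astype(str) == "ASDnoID").sum()
        assert res.a == a
        with pytest.raises(ValueError):
            fit_recurrence(sibs, sibs, "ASDnoID", registry_cohort)


class TestCompareOR:
    def test_published_or_pair_below_printed_bound(self):
        f = RecurrenceResult.from_or_ci(*REPORTED_SIBLING_ORS[("F", "ASDnoID", "ASDnoID")])
        m = RecurrenceResult.from_or_ci(*REPORTED_SIBLING_ORS[("M", "ASDnoID", "ASDnoID")])
        comp = compare_or(f, m)
        assert comp.p_value == pytest.approx(0.00118, abs=1e-4)
        assert comp.p_value < 0.01

    def test_identical_results_p_one(self):
        r = RecurrenceResult.from_or_ci(2.0, 1.5, 2.67)
        comp = compare_or(r, r)
        assert comp.z == 0.0
        assert comp.p_value == pytest.approx(1.0)

    @given(
        or_a=st.floats(0.2, 8.0), or_b=st.floats(0.2, 8.0),
        se_a=st.floats(0.02, 1.0), se_b=st.floats(0.02, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, or_a, or_b, se_a, se_b):
        def mk(o, s):
            return RecurrenceResult(
                outcome="x", odds_ratio=o,
                ci_low=o * math.exp(-1.96 * s), ci_high=o * math.exp(1.96 * s),
                p_value=0.5, se_log_or=s,
            )
        ab = compare_or(mk(or_a, se_a), mk(or_b, se_b))
        ba = compare_or(mk(or_b, se_b), mk(or_a, se_a))
        assert ab.log_or_difference == pytest.approx(-ba.log_or_difference, rel=1e-12)
        assert ab.p_value == pytest.approx(ba.p_value, rel=1e-12)

    def test_degenerate_inputs_raise(self):
        r = RecurrenceResult.from_or_ci(2.0, 1.5, 2.67)
        d = fit_recurrence_counts(10, 100, 0, 200)
        with pytest.raises(DegenerateTableError):
            compare_or(r, d)

    def test_se_reconstruction_from_ci(self):
        res = fit_recurrence_counts(150, 1707, 45, 3414)
        assert se_log_or_from_ci(res.ci_low, res.ci_high) == pytest.approx(
            res.se_log_or, rel=1e-9
        )

    def test_published_ors_individually_significant(self):
        for key in (("F", "ASDnoID", "ASDnoID"), ("M", "ASDnoID", "ASDnoID")):
            r = RecurrenceResult.from_or_ci(*REPORTED_SIBLING_ORS[key])
            assert p_vs_null(r) < 1.34e-4


class TestFullAnalysis:
    def test_empty_criteria_empty_tables(self, registry_cohort):
        res, comp = run_recurrence_analysis(registry_cohort, criteria=(), seed=1)
        assert res.empty and comp.empty

    def test_matching_validity(self, registry_cohort):
        res, comp, assignments = run_recurrence_analysis(
            registry_cohort,
            criteria=(IndexCriteria("M", "ASDnoID"),),
            outcomes=("ASDnoID",),
            seed=3,
            return_assignments=True,
        )
        assign = assignments["M:ASDnoID"]["pairs"]
        index_iids = set(assignments["M:ASDnoID"]["index_cases"]["iid"])
        index_fids = set(assignments["M:ASDnoID"]["index_cases"]["fid"])
        df = registry_cohort.df
        sib = df.loc[assign["sibling_iid"]]
        ctl = df.loc[assign["control_iid"]]
        # exact sex and birth-year matching
        assert (sib["sex"].astype(str).to_numpy() == ctl["sex"].astype(str).to_numpy()).all()
        assert (sib["birth_year"].to_numpy() == ctl["birth_year"].to_numpy()).all()
        # no control reused; 2:1 ratio
        assert not assign["control_iid"].duplicated().any()
        assert len(assign) == 2 * assign["sibling_iid"].nunique()
        # no sibling of any index case serves as a control: the only members of
        # index families eligible for the pool are the index cases themselves
        in_index_fam = ctl[ctl["fid"].isin(index_fids)]
        assert set(in_index_fam["iid"]).issubset(index_iids)

    def test_wald_test_type_one_error_on_null_tables(self):
        """On truly null data (both arms at the same rate) the Wald OR test
        rejects at the nominal 5% level within 3 binomial SEs."""
        rng = np.random.default_rng(2024)
        n_reps, hits, kept = 1000, 0, 0
        for _ in range(n_reps):
            a = int(rng.binomial(500, 0.08))
            c = int(rng.binomial(1000, 0.08))
            res = fit_recurrence_counts(a, 500, c, 1000)
            if res.degenerate:
                continue
            kept += 1
            if res.p_value < 0.05:
                hits += 1
        frac = hits / kept
        se = math.sqrt(0.05 * 0.95 / kept)
        assert abs(frac - 0.05) < 3 * se

    def test_null_simulator_index_conditioning_baseline(self):
        """With family-once ascertainment (one index per family, chosen among
        the affected) and no familial clustering, the same-phenotype sibling
        rate is E[(X-1)/(k-1) | X>=1], strictly below the population rate p —
        so the design's null OR sits below 1, not at it.  The simulated rate
        must match this closed-form truncation oracle."""
        p = 0.12
        prevalence = {("ASD", "M"): p, ("ASD", "F"): p, ("ID", "M"): p, ("ID", "F"): p}
        params = LiabilityParams(h2_common=0.0, dnv_rate=0.0, prevalence=prevalence, seed=0)
        cohort = simulate_registry(
            params, 30_000, birth_year_range=(1990, 1999), seed=123
        )
        res, _ = run_recurrence_analysis(
            cohort, criteria=(IndexCriteria("any", "ASD-any"),),
            outcomes=("ASD-any",), seed=123,
        )
        row = res.iloc[0]
        sib_rate = row["a"] / row["n_siblings"]

        from fpe_famkit.famsim import DEFAULT_CHILDREN_DIST

        num = den = 0.0
        for k, w in DEFAULT_CHILDREN_DIST.items():
            p_any = 1 - (1 - p) ** k
            rate_k = (k * p / p_any - 1) / (k - 1)
            num += w * p_any * rate_k
            den += w * p_any
        oracle = num / den
        se = math.sqrt(oracle * (1 - oracle) / row["n_siblings"])
        assert abs(sib_rate - oracle) < 3 * se
        assert row["odds_ratio"] < 1.0

    def test_sibling_sex_strata_consistent(self, registry_cohort):
        res, comp = recurrence_by_sibling_sex(registry_cohort, seed=5)
        res = res.set_index("stratum")
        for stratum in ("sibling_M", "sibling_F"):
            assert res.loc[stratum, "n_siblings"] > 0
        # each stratum uses its own sex-matched controls, so the familial ORs
        # estimate the same quantity: their 95% CIs overlap
        lo = max(res["ci_low"])
        hi = min(res["ci_high"])
        assert lo <= hi

    def test_no_female_siblings_flagged(self, default_params):
        cohort = simulate_registry(default_params, 300, seed=9)
        cohort.df["sex"] = pd.Categorical(
            np.where(cohort.df["role"] == "founder",
                     cohort.df["sex"].astype(str), "M"),
            categories=["M", "F"],
        )
        cohort.df["dgroup"] = pd.Categorical(
            np.select(
                [cohort.df["dx_asd"] & cohort.df["dx_id"],
                 cohort.df["dx_asd"], cohort.df["dx_id"]],
                ["ASDandID", "ASDnoID", "IDnoASD"], default="none",
            ),
            categories=["ASDnoID", "ASDandID", "IDnoASD", "none"],
        )
        res, comp = recurrence_by_sibling_sex(cohort, seed=9)
        res = res.set_index("stratum")
        assert res.loc["sibling_F", "n_siblings"] == 0
        assert comp.empty
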