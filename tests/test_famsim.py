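"""Generative-model checks: threshold calibration, variance structure,
Mendelian transmission, ascertainment machinery, and diagnosis grouping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fpe_famkit.famsim import (
    AscertainmentError,
    LiabilityParams,
    ParameterError,
    assign_diagnosis_group,
    calibrate_thresholds,
    simulate_registry,
    simulate_trio_cohort,
    trios_from_cohort,
)


class TestCalibrateThresholds:
    @pytest.mark.parametrize(
        "prevalence,expected",
        [(0.02275, 2.0), (0.5, 0.0), (stats.norm.sf(1.0), 1.0)],
    )
    def test_inverse_normal_tail(self, prevalence, expected):
        t = calibrate_thresholds({"M": prevalence})["M"]
        assert t == pytest.approx(expected, abs=1e-3)

    def test_equal_prevalence_equal_thresholds(self):
        t = calibrate_thresholds({"M": 0.01, "F": 0.01})
        assert t["M"] == t["F"]

    def test_female_protection_orders_thresholds(self):
        t = calibrate_thresholds({"M": 0.02, "F": 0.0055})
        assert t["F"] > t["M"]

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_prevalence(self, bad):
        with pytest.raises(ParameterError):
            calibrate_thresholds({"M": bad})

    @given(p=st.floats(min_value=1e-6, max_value=0.999999))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, p):
        t = calibrate_thresholds({"M": p})["M"]
        assert stats.norm.sf(t) == pytest.approx(p, rel=1e-9)


class TestDiagnosisGroup:
    @pytest.mark.parametrize(
        "diags,expected",
        [
            ({"ASD"}, "ASDnoID"),
            ({"ASD", "ID"}, "ASDandID"),
            ({"ID"}, "IDnoASD"),
            (set(), "none"),
        ],
    )
    def test_total_mapping(self, diags, expected):
        assert assign_diagnosis_group(diags) == expected

    def test_row_input(self, registry_cohort):
        row = registry_cohort.df.iloc[0]
        assert assign_diagnosis_group(row) == str(row["dgroup"])


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"h2_common": 1.2},
            {"h2_common": -0.1},
            {"dnv_rate": 1.5},
            {"rg_asd_id": 1.5},
            {"prevalence": {("ASD", "M"): 0.0, ("ASD", "F"): 0.01,
                            ("ID", "M"): 0.01, ("ID", "F"): 0.01}},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            LiabilityParams(**kwargs)


class TestRegistrySimulation:
    def test_determinism_same_seed(self, default_params):
        a = simulate_registry(default_params, 500, seed=7)
        b = simulate_registry(default_params, 500, seed=7)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_founder_liability_standard_normal(self, registry_cohort):
        liab = registry_cohort.founders()["liab_asd"].to_numpy()
        n = liab.size
        assert n >= 1e5
        assert abs(liab.mean()) < 3 / math.sqrt(n)
        assert abs(liab.var(ddof=1) - 1.0) < 3 * math.sqrt(2.0 / n)

    def test_prevalence_recovery(self):
        # de-novo-free model: liability is exactly standard normal in children
        params = LiabilityParams(dnv_rate=0.0, seed=3)
        cohort = simulate_registry(params, 40_000, seed=3)
        ch = cohort.children()
        for pheno, col in (("ASD", "dx_asd"), ("ID", "dx_id")):
            for sex in ("M", "F"):
                sub = ch[ch["sex"].astype(str) == sex]
                target = params.prevalence[(pheno, sex)]
                se = math.sqrt(target * (1 - target) / len(sub))
                assert abs(sub[col].mean() - target) < 3 * se, (pheno, sex)

    def test_parent_offspring_regression_slope_half(self, registry_cohort):
        ch = registry_cohort.children()
        father_pgs = registry_cohort.df["pgs_true"].loc[ch["father"]].to_numpy()
        child_pgs = ch["pgs_true"].to_numpy()
        res = stats.linregress(father_pgs, child_pgs)
        assert abs(res.slope - 0.5) < 3 * res.stderr

    def test_pedigree_consistency(self, registry_cohort):
        df = registry_cohort.df
        ch = registry_cohort.children()
        assert ch["father"].isin(df["iid"]).all()
        assert ch["mother"].isin(df["iid"]).all()
        assert (df.loc[ch["father"], "sex"].astype(str) == "M").all()
        assert (df.loc[ch["mother"], "sex"].astype(str) == "F").all()

    def test_diagnosis_consistent_with_threshold(self, registry_cohort):
        df = registry_cohort.df
        t = registry_cohort.params.threshold_map()
        thr = np.where(df["sex"].astype(str) == "M", t[("ASD", "M")], t[("ASD", "F")])
        np.testing.assert_array_equal(df["dx_asd"].to_numpy(), df["liab_asd"].to_numpy() > thr)

    def test_null_model_breaks_parent_child_score_link(self):
        params = LiabilityParams(h2_common=0.0, dnv_rate=0.0, score_noise_sd=1.0, seed=5)
        cohort = simulate_registry(params, 2_000, seed=5)
        assert cohort.children()["pgs_true"].abs().max() == 0.0


class TestTrioCohort:
    def test_structure_and_screening(self, quad_cohort):
        ch = quad_cohort.children()
        par = quad_cohort.founders()
        by_fam = ch.groupby("fid")
        assert (by_fam["dx_asd"].any()).all()  # >=1 affected child
        assert not par["dx_asd"].any()  # screened parents
        assert by_fam["is_proband"].sum().eq(1).all()
        assert by_fam["is_designated_sibling"].sum().eq(1).all()
        # proband affected, designee unaffected
        assert ch.loc[ch["is_proband"], "dx_asd"].all()
        assert not ch.loc[ch["is_designated_sibling"], "dx_asd"].any()

    def test_designated_sibling_is_oldest_unaffected(self, quad_cohort):
        ch = quad_cohort.children()
        unaff = ch[~ch["dx_asd"]]
        oldest = unaff.loc[unaff.groupby("fid")["birth_year"].idxmin()]
        designated = ch[ch["is_designated_sibling"]]
        assert set(designated["iid"]) == set(oldest["iid"])

    def test_empty_cohort(self, default_params):
        cohort = simulate_trio_cohort(default_params, 0, seed=1)
        assert len(cohort) == 0

    def test_infeasible_ascertainment_raises(self):
        thresholds = {(p, s): -math.inf for p in ("ASD", "ID") for s in ("M", "F")}
        params = LiabilityParams(thresholds=thresholds, seed=1)
        with pytest.raises(AscertainmentError, match="unaffected parents"):
            simulate_trio_cohort(
                params, 5, require_unaffected_parents=True, max_candidates=50_000, seed=1
            )

    def test_fpe_maternal_polygenic_excess(self, default_params):
        """With a higher female threshold, ascertained mothers out-carry fathers."""
        gaps = []
        for r in range(20):
            cohort = simulate_trio_cohort(default_params, 1_000, seed=1000 + r)
            par = cohort.founders()
            sex = par["sex"].astype(str)
            gaps.append(
                par.loc[sex == "F", "pgs_true"].mean() - par.loc[sex == "M", "pgs_true"].mean()
            )
        gaps = np.asarray(gaps)
        assert gaps.mean() > 0
        assert (gaps > 0).sum() > 10

    def test_dnv_enrichment_in_female_cases(self, quad_cohort):
        pro = quad_cohort.children().query("is_proband")
        sex = pro["sex"].astype(str)
        assert pro.loc[sex == "F", "dnv"].mean() > pro.loc[sex == "M", "dnv"].mean()

    def test_trios_from_cohort_shapes(self, quad_cohort):
        pro = trios_from_cohort(quad_cohort, members="probands")
        sib = trios_from_cohort(quad_cohort, members="designated_siblings")
        assert len(pro) == len(sib) == quad_cohort.meta["n_families"]
        assert pro["affected"].all()
        assert not sib["affected"].any()
        with pytest.raises(ValueError):
            trios_from_cohort(quad_cohort, members="nonsense")
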