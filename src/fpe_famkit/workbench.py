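"""Scenario orchestration, fixtures, and end-to-end diagnostics.

This module wires the simulator to the three analysis stages (sibling
recurrence, score contrasts, pTDT) behind a single seeded configuration so a
whole qualitative study — "does a sex-specific-threshold model produce
female-index excess recurrence, a maternal polygenic excess, and the pTDT
gradient?" — runs from one config file, deterministically, and leaves an
audit trail of tables and per-stage seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from ._rng import substream
from .famsim import (
    Cohort,
    LiabilityParams,
    simulate_registry,
    simulate_trio_cohort,
    simulate_unascertained_trios,
    trios_from_cohort,
)
from .prs import compare_groups, standardize
from .ptdt import ptdt_deviations, ptdt_test, run_ptdt_analysis
from .registry import IndexCriteria, run_recurrence_analysis

__all__ = [
    "RunConfig",
    "run_scenario",
    "make_fixtures",
    "fpe_replicates",
    "ptdt_null_rejection_rate",
]


@dataclass
class RunConfig:
    """One end-to-end scenario: simulator parameters plus analysis options."""

    seed: int = 1
    params: LiabilityParams = field(default_factory=LiabilityParams)
    n_registry_families: int = 50_000
    n_trio_families: int = 2_000
    ratio: int = 2
    k_pcs: int = 15
    scale: str | float = "from-data"

    def validate(self) -> None:
        if self.n_registry_families < 1 or self.n_trio_families < 0:
            raise ValueError("family counts must be positive")
        if self.ratio < 1:
            raise ValueError("control ratio must be >= 1")
        if self.scale != "from-data" and not float(self.scale) > 0:
            raise ValueError("scale must be 'from-data' or a positive number")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = fio._params_to_dict(self.params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "params" in d and d["params"] is not None:
            d["params"] = fio._params_from_dict(d["params"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _bar(value: float, scale: float = 4.0, width: int = 40) -> str:
    n = int(round(min(abs(value) * scale, width)))
    return "#" * n


def run_scenario(config: RunConfig, outdir) -> dict:
    """Simulate, analyze, and write all tables plus a human-readable summary.

    Deterministic given ``config.seed``: every stage pulls a named substream
    from the root seed, and the per-stage parameters are logged to
    ``run_log.yaml``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = dataclasses.replace(config.params, seed=config.seed)

    registry_cohort = simulate_registry(params, config.n_registry_families, seed=config.seed)
    recurrence, comparisons = run_recurrence_analysis(
        registry_cohort, ratio=config.ratio, seed=config.seed
    )
    fio._tsv(recurrence, outdir / "recurrence.tsv")
    fio._tsv(comparisons, outdir / "recurrence_comparisons.tsv")

    trio_cohort = simulate_trio_cohort(
        params, config.n_trio_families, require_unaffected_parents=True,
        require_unaffected_sibling=True, seed=config.seed,
    )
    proband_trios = trios_from_cohort(trio_cohort, members="probands")
    sibling_trios = trios_from_cohort(trio_cohort, members="designated_siblings")
    fio.write_trios(proband_trios, outdir / "proband_trios.tsv")
    fio.write_trios(sibling_trios, outdir / "sibling_trios.tsv")

    ptdt_res, ptdt_comp = run_ptdt_analysis(proband_trios, strata="affected_by_sex_dnv",
                                            scale=config.scale)
    sib_res, _ = run_ptdt_analysis(
        pd.concat([proband_trios, sibling_trios], ignore_index=True),
        strata="unaffected_by_sex", scale=config.scale,
    )
    fio._tsv(ptdt_res, outdir / "ptdt_probands.tsv")
    fio._tsv(ptdt_comp, outdir / "ptdt_comparisons.tsv")
    fio._tsv(sib_res, outdir / "ptdt_siblings.tsv")

    # parental score gap on the observed score, standardized to an
    # unascertained population reference drawn from the registry cohort
    parents = trio_cohort.founders()
    reference = registry_cohort.founders()["pgs_obs"]
    std = standardize(parents["pgs_obs"], reference)
    is_mother = (parents["sex"].astype(str) == "F").astype(int)
    gap = compare_groups(std, is_mother)
    parent_tbl = pd.DataFrame(
        [{
            "contrast": "mothers_minus_fathers",
            "difference_sd": gap.difference,
            "standard_error": gap.standard_error,
            "p_value": gap.p_value,
            "n_mothers": gap.n1,
            "n_fathers": gap.n0,
        }]
    )
    fio._tsv(parent_tbl, outdir / "parent_score_gap.tsv")

    summary = _summarize(recurrence, comparisons, ptdt_res, sib_res, parent_tbl)
    (outdir / "summary.txt").write_text(summary)
    log = {
        "config": config.to_dict(),
        "stages": {
            "registry-sim": {"n_families": config.n_registry_families},
            "recurrence": {"ratio": config.ratio},
            "trio-sim": {
                "n_families": config.n_trio_families,
                "candidates_tried": int(trio_cohort.meta.get("candidates_tried", 0)),
            },
            "ptdt": {"scale": config.scale},
        },
    }
    (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=True))
    return {
        "recurrence": recurrence,
        "comparisons": comparisons,
        "ptdt_probands": ptdt_res,
        "ptdt_siblings": sib_res,
        "parent_gap": parent_tbl,
        "summary": summary,
    }


def _summarize(recurrence, comparisons, ptdt_res, sib_res, parent_tbl) -> str:
    lines = ["FPE scenario summary", "=" * 60, "", "Sibling recurrence (OR vs matched controls)"]
    for _, r in recurrence.iterrows():
        flag = " (degenerate)" if r["degenerate"] else ""
        lines.append(
            f"  index {r['criteria_sex']} {r['criteria_group']:>8} -> {r['outcome']:>8}: "
            f"OR {r['odds_ratio']:6.2f} [{r['ci_low']:.2f}, {r['ci_high']:.2f}]"
            f" {_bar(np.log(max(r['odds_ratio'], 1e-9)))}{flag}"
        )
    lines.append("")
    lines.append("Female-vs-male index OR comparisons (gated)")
    for _, r in comparisons.iterrows():
        if r["tested"]:
            lines.append(
                f"  {r['criteria_group']:>8} -> {r['outcome']:>8}: "
                f"dlogOR {r['log_or_difference']:+.3f}, p {r['p_value']:.3g}"
            )
        else:
            lines.append(f"  {r['criteria_group']:>8} -> {r['outcome']:>8}: not tested")
    lines.append("")
    lines.append("pTDT, affected probands (mid-parent-SD units)")
    for _, r in ptdt_res.iterrows():
        lines.append(
            f"  {r['stratum']:>14}: {r['mean_deviation']:+.3f} (n={r['n']}) "
            f"{_bar(r['mean_deviation'], scale=40)}"
        )
    lines.append("")
    lines.append("pTDT, unaffected siblings")
    for _, r in sib_res.iterrows():
        lines.append(f"  {r['stratum']:>14}: {r['mean_deviation']:+.3f} (n={r['n']})")
    lines.append("")
    g = parent_tbl.iloc[0]
    lines.append(
        f"Parental observed-score gap (mothers - fathers): {g['difference_sd']:+.3f} SD, "
        f"p {g['p_value']:.3g}"
    )
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# fixtures

_FIXTURE_SIZES = {"tiny": (8, 5), "small": (500, 200), "medium": (5000, 1000)}


def make_fixtures(size: str, seed: int, outdir) -> Path:
    """Write a self-consistent fixture directory exercising every reader.

    Emits pedigree (FAM), score, covariate, diagnosis, trio, and annotated
    variant tables from one seeded simulation.  ``tiny`` is hand-checkable
    (8 families); ``medium`` is large enough for estimable recurrence ORs.
    """
    if size not in _FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(_FIXTURE_SIZES)}")
    n_reg, n_trio = _FIXTURE_SIZES[size]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = LiabilityParams(seed=seed)
    cohort = simulate_registry(params, n_reg, seed=seed)
    fio.save_cohort(cohort, outdir)

    trio_cohort = simulate_trio_cohort(params, n_trio, seed=seed)
    trios = trios_from_cohort(trio_cohort, members="probands")
    fio.write_trios(trios, outdir / "trios.tsv")

    rng = substream(seed, "fixtures")
    k = 15
    covars = pd.DataFrame(
        rng.standard_normal((len(cohort.df), k)),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    covars.insert(0, "IID", cohort.df["iid"].to_numpy())
    fio.write_covariates(covars, outdir / "covariates.tsv")

    fio.write_variants(_synthesize_variants(trio_cohort, rng), outdir / "variants.tsv")
    return outdir


def _synthesize_variants(trio_cohort: Cohort, rng: np.random.Generator) -> pd.DataFrame:
    """Annotated variant table consistent with the cohort's carrier flags.

    Each simulated de novo carrier gets one qualifying high-impact record;
    everyone may also get benign or inherited records, so the classifier's
    thresholds are actually exercised.
    """
    rows = []
    ch = trio_cohort.children()
    for iid, carrier in zip(ch["iid"], ch["dnv"]):
        sid = str(iid)
        if carrier:
            kind = rng.choice(["PTV", "missense", "CNV-del"])
            if kind == "PTV":
                rows.append(dict(sample_id=sid, gene=f"G{rng.integers(1000)}",
                                 var_class="PTV", de_novo=True,
                                 pli=float(rng.uniform(0.91, 1.0)),
                                 mpc=np.nan, constrained_genes_hit=np.nan))
            elif kind == "missense":
                rows.append(dict(sample_id=sid, gene=f"G{rng.integers(1000)}",
                                 var_class="missense", de_novo=True, pli=np.nan,
                                 mpc=float(rng.uniform(2.0, 4.0)),
                                 constrained_genes_hit=np.nan))
            else:
                rows.append(dict(sample_id=sid, gene=f"G{rng.integers(1000)}",
                                 var_class="CNV-del", de_novo=True, pli=np.nan,
                                 mpc=np.nan, constrained_genes_hit=int(rng.integers(1, 4))))
        if rng.random() < 0.3:  # benign de novo missense
            rows.append(dict(sample_id=sid, gene=f"G{rng.integers(1000)}",
                             var_class="missense", de_novo=True, pli=np.nan,
                             mpc=float(rng.uniform(0.0, 1.9)), constrained_genes_hit=np.nan))
        if rng.random() < 0.2:  # inherited PTV in a constrained gene: never qualifies
            rows.append(dict(sample_id=sid, gene=f"G{rng.integers(1000)}",
                             var_class="PTV", de_novo=False,
                             pli=float(rng.uniform(0.91, 1.0)),
                             mpc=np.nan, constrained_genes_hit=np.nan))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# replicate diagnostics


def fpe_replicates(
    params: LiabilityParams | None = None,
    n_replicates: int = 20,
    n_registry_families: int = 400_000,
    n_trio_families: int = 12_000,
    seed: int = 1,
    score: str = "pgs_true",
) -> pd.DataFrame:
    """Replicate-level FPE diagnostics under the generative model.

    For each replicate: a registry cohort is simulated and the female- and
    male-index ASDnoID sibling-recurrence ORs are estimated; an ascertained
    quad cohort (affected child, unaffected parents, unaffected sibling) is
    simulated and the parental polygenic gap, the proband pTDT strata
    (sex x de novo carrier) and the unaffected-sibling pTDT strata are
    computed on the chosen score column.  One row per replicate.
    """
    params = params or LiabilityParams()
    rows = []
    for r in range(n_replicates):
        rep_seed = int(substream(seed, f"fpe-rep-{r}").integers(2**31))
        reg = simulate_registry(params, n_registry_families, seed=rep_seed)
        criteria = (IndexCriteria("F", "ASDnoID"), IndexCriteria("M", "ASDnoID"))
        res, _ = run_recurrence_analysis(
            reg, criteria=criteria, outcomes=("ASDnoID",), seed=rep_seed
        )
        res = res.set_index("criteria_sex")
        or_f = float(res.loc["F", "odds_ratio"])
        or_m = float(res.loc["M", "odds_ratio"])
        del reg

        quads = simulate_trio_cohort(
            params, n_trio_families, require_unaffected_parents=True,
            require_unaffected_sibling=True, seed=rep_seed,
        )
        parents = quads.founders()
        mother_mean = float(parents.loc[parents["sex"].astype(str) == "F", score].mean())
        father_mean = float(parents.loc[parents["sex"].astype(str) == "M", score].mean())

        probands = trios_from_cohort(quads, members="probands", score=score)
        siblings = trios_from_cohort(quads, members="designated_siblings", score=score)
        all_trios = pd.concat([probands, siblings], ignore_index=True)
        mp_scale = "from-data"
        dev_all = ptdt_deviations(all_trios, scale_sd=mp_scale)
        scale_value = float(
            np.std(0.5 * (all_trios["mother_score"] + all_trios["father_score"]), ddof=1)
        )

        strata_res, _ = run_ptdt_analysis(
            all_trios, strata="affected_by_sex_dnv", scale=scale_value, comparisons=[]
        )
        strata = strata_res.set_index("stratum")["mean_deviation"]
        sib_res, _ = run_ptdt_analysis(
            all_trios, strata="unaffected_by_sex", scale=scale_value, comparisons=[]
        )
        sibs = sib_res.set_index("stratum")["mean_deviation"]

        proband_dev = ptdt_test(
            dev_all[all_trios["affected"].to_numpy()].to_numpy(), "probands"
        )
        ordering_ok = bool(
            strata.idxmin() == "male_dnv" and strata.idxmax() == "female_no_dnv"
        )
        rows.append(
            {
                "replicate": r,
                "seed": rep_seed,
                "or_female_index": or_f,
                "or_male_index": or_m,
                "mother_mean": mother_mean,
                "father_mean": father_mean,
                "proband_dev_mean": proband_dev.mean_deviation,
                "male_sibling_dev_mean": float(sibs.get("male_sibling", np.nan)),
                "female_sibling_dev_mean": float(sibs.get("female_sibling", np.nan)),
                "dev_male_dnv": float(strata.get("male_dnv", np.nan)),
                "dev_male_no_dnv": float(strata.get("male_no_dnv", np.nan)),
                "dev_female_dnv": float(strata.get("female_dnv", np.nan)),
                "dev_female_no_dnv": float(strata.get("female_no_dnv", np.nan)),
                "ordering_ok": ordering_ok,
            }
        )
    return pd.DataFrame(rows)


def ptdt_null_rejection_rate(
    params: LiabilityParams | None = None,
    n_replicates: int = 5000,
    n_trios: int = 100,
    alpha: float = 0.05,
    seed: int = 1,
) -> float:
    """Fraction of unascertained-trio replicates where the pTDT rejects.

    Under no ascertainment the deviations are exactly mean-zero normal, so
    the one-sample t-test should reject at the nominal rate.
    """
    params = params or LiabilityParams()
    rng = substream(seed, "ptdt-null")
    rejections = 0
    for r in range(n_replicates):
        trios = simulate_unascertained_trios(
            params, n_trios, seed=int(rng.integers(2**31))
        )
        dev = ptdt_deviations(trios, scale_sd="from-data")
        if ptdt_test(dev.to_numpy()).p_value < alpha:
            rejections += 1
    return rejections / n_replicates
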