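# fpe-famkit

Family-based analyses of the **female protective effect (FPE)** in autism
spectrum disorder, built on a liability-threshold family simulator.

Autism is diagnosed three to four times more often in males than in females.
The FPE hypothesis holds that females require a greater total liability than
males before meeting diagnostic criteria, so ascertained female cases — and
their relatives, who share their inherited risk — should carry more genetic
risk than male cases and their relatives. This package implements the three
family-based designs used to probe that prediction, together with a
generative model that lets every stage run, end to end, on synthetic data:

- **`famsim`** — a liability-threshold family simulator with sex-specific
  thresholds. Liability is `L = g + e (+ δ·β_dnv)` with `g` the transmitted
  polygenic component (`Var(g) = h²`), `e` an independent residual, and `δ`
  an untransmitted high-impact de novo shock. A child inherits
  `g_child ~ N((g_mat + g_pat)/2, h²/2)`. A person is diagnosed when
  `L > T_sex`, where `T_sex = Φ⁻¹(1 − K_sex)` encodes the sex-specific
  prevalence `K_sex`; the FPE is exactly `T_F > T_M`.
- **`registry`** — registry-style sibling recurrence: one randomly chosen
  index case per family (six cells: sex × {ASDnoID, ASDandID, IDnoASD}), one
  random full sibling, 2:1 age- and sex-matched population controls, a
  sibling-indicator logistic regression per outcome (`OR = e^β`, 95% Wald
  CI), and Wald comparisons of female-index vs male-index ORs, gated on both
  ORs being individually significant.
- **`prs`** — polygenic-score plumbing: linear scoring
  (`score = Σ w_v · dosage_v`), standardization to a reference-population SD,
  and OLS group contrasts controlling for ancestry principal components
  (`score ~ group + PC1..15`), including the female-vs-male proband contrast
  adjusted for comorbid intellectual disability.
- **`ptdt`** — the polygenic transmission disequilibrium test: the
  standardized deviation `d = (score_child − (score_mat + score_pat)/2) / SD(midparent)`
  has expectation 0 in random trios; ascertainment (affected child, screened
  unaffected parents) breaks this. One-sample t-tests per stratum, Welch
  two-sample tests between strata.
- **`dnv`** — high-impact de novo classification: protein-truncating variants
  in constrained genes (pLI > 0.9, strict), CNVs hitting ≥ 1 constrained
  gene, and missense variants with MPC ≥ 2; inherited variants never qualify.
- **`workbench`** — seeded end-to-end scenarios, fixtures, and replicate
  diagnostics, exposed through the `fpe-famkit` CLI.

Intended users: statistical geneticists and epidemiologists who want a
tested, reusable implementation of these designs — and a sandbox in which
their joint behaviour under an explicit generative model can be studied
before touching access-restricted cohort data.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
and write tidy tables under `results/`. For example, the pTDT gradient on
12,000 ascertained quad families (affected child, screened unaffected
parents, unaffected sibling), using the noisy observed score:

```text
$ python analysis/04_ptdt_gradient.py --seed 1
pTDT on pgs_obs over 12000 families (mid-parent-SD units, scale from data):

affected probands by sex x de novo carrier:
        male_dnv: +0.129 (SE 0.049, n = 1297, p = 0.0083)
      female_dnv: +0.252 (SE 0.067, n = 649, p = 0.00018)
     male_no_dnv: +0.321 (SE 0.019, n = 8054, p = 7.9e-62)
   female_no_dnv: +0.381 (SE 0.038, n = 2000, p = 2.2e-23)

  female_no_dnv vs male_dnv: diff +0.252, p = 4.7e-05

unaffected siblings by sex:
    male_sibling: -0.030 (SE 0.022, n = 5821, p = 0.19)
  female_sibling: +0.030 (SE 0.022, n = 6179, p = 0.16)
```

Reading this: every case stratum over-inherits polygenic risk relative to
the mid-parent expectation, least for male de novo carriers (the de novo
shock fills most of their liability gap) and most for female non-carriers
(who must reach the higher female threshold with common variation alone) —
with unaffected male siblings pulled below their mid-parent expectation.
That is the FPE signature. The companion scripts show the other two arms:
`02_sibling_recurrence.py` (female-index ASD recurrence OR ≈ 5.0 vs
male-index ≈ 2.6, Wald p ≈ 0.002 on 200,000 simulated families) and
`03_parental_polygenic_scores.py` (case parents +0.18 SD vs population;
mothers +0.05 SD vs fathers, p ≈ 2e-4).

`05_published_or_wald_tests.py` takes published registry odds ratios with
their confidence intervals as *inputs*, reconstructs the log-OR standard
errors from the printed intervals, and reruns the same gated Wald
machinery: the female- vs male-index ASD recurrence comparison gives
p ≈ 0.0012, and the cross-disorder cells are correctly left untested.

The same operations are available as a CLI for file-based workflows:

```bash
fpe-famkit simulate --kind registry --n-families 50000 --seed 1 --out cohort/
fpe-famkit recurrence --cohort cohort/ --ratio 2 --seed 1 --out recurrence.tsv
fpe-famkit ptdt --trios trios.tsv --strata affected_by_sex_dnv --out ptdt.tsv
fpe-famkit classify-dnv --variants variants.tsv --out carriers.tsv
```

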