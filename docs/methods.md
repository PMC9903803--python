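# Methods

## The generative model

Each person carries two latent liabilities, one per phenotype (ASD and
intellectual disability, ID). For phenotype `p`:

    L_p = g_p + e_p + δ · β_dnv

- `g = (g_ASD, g_ID)` is the common, transmitted polygenic component. In
  founders it is bivariate normal with `Var(g_p) = h²` and
  `Corr(g_ASD, g_ID) = r_g`. A child draws
  `g_child = (g_mat + g_pat)/2 + s`, with the Mendelian segregation
  deviation `s` bivariate normal with variance `h²/2` and the same
  correlation — the standard additive decomposition, which keeps
  `Var(g) = h²` in every generation under random mating.
- `e_p` is an independent residual with variance `1 − h²`, independent
  across phenotypes. Founder liability is therefore exactly standard
  normal.
- `δ` is a Bernoulli(`dnv_rate`) high-impact de novo indicator, drawn per
  child, never transmitted, and excluded from the founder variance
  normalization (founders carry none). The shock `β_dnv` hits **both**
  liabilities, reflecting the shared rare-variant influences of the two
  diagnoses; it adds variance on top of 1 for offspring, which is the point
  — de novo events add risk beyond the inherited distribution.

Diagnosis: `L_p > T_{p,sex}`, with `T = Φ⁻¹(1 − K)` calibrated from the
sex-specific prevalence `K`. A higher female threshold *is* the female
protective effect; no other sex difference exists anywhere in the model.
The observed polygenic score is `ĝ = g_ASD + ε`, `ε ~ N(0, σ²)`, emulating
a weak real-world PRS.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| `h2_common` | 0.65 | mid-range of family/twin additive heritability estimates for ASD liability (commonly cited 0.5–0.8) |
| ASD prevalence | M 2.0%, F 0.55% | ≈3.6:1 male:female diagnosis ratio |
| ID prevalence | M 1.5%, F 1.0% | registry cumulative-incidence scale for ID, milder male excess |
| `rg_asd_id` | 0 | the estimated genetic correlation between the common variants of ASD and ID is near zero; comorbidity in the model arises from shared de novo shocks |
| `dnv_rate` | 0.01 | with `β_dnv`, chosen so ~12% of male and ~20% of female cases carry a high-impact de novo, the carrier excess in female cases reported by exome studies |
| `β_dnv` | 1.5 liability SD | see above; a carrier's odds of diagnosis rise ~14-fold at the male threshold |
| `σ` (score noise) | sets `R²(ĝ, g) = 0.05` | the real ASD PRS explains under 3% of liability-scale variance; `h² × 0.05 ≈ 3%` matches that regime |
| birth years | uniform 1981–2005 | the registry follow-up window emulated |
| children per family | {2: .55, 3: .30, 4: .11, 5: .04} | registry analyses condition on two-plus-child families |

All defaults are conventions of this package: the designs themselves do not
prescribe them, and every qualitative conclusion tested is a sign or
ordering, not a magnitude.

Seeding: one root seed; every stage (registry simulation, trio rejection
sampling, index selection, matching, fixtures) draws from a named substream
(`SeedSequence(root, spawn_key=crc32(name))`), so any stage is reproducible
in isolation and a run log plus seed reproduces any table byte for byte.

## The analysis stages

**Sibling recurrence.** Per analysis cell (index sex × diagnosis group),
one index case is chosen uniformly among each family's eligible children;
families without one are dropped. One full sibling per index case is chosen
uniformly (never by diagnosis) within the birth-year window, and matched to
two controls on exact birth year and sex, sampled without replacement from
the population minus all siblings of index cases. Index cases themselves
remain control-eligible: controls are population-representative and may
carry diagnoses at the population rate. The per-outcome model is the
intercept + sibling-indicator logistic regression, fit by IRLS on the
grouped 2×2 counts (convergence `max |Δβ| < 1e-10`, ≤ 50 iterations); for
this saturated model the MLE equals the closed-form cross-product ratio,
which the tests exploit as an independent oracle (statsmodels GLM provides
a second, ungrouped route). A table with an empty cell is reported with the
Haldane–Anscombe 0.5 correction and flagged `degenerate`, never silently.
Female-index vs male-index ORs are compared with
`z = (log OR_F − log OR_M)/√(SE_F² + SE_M²)`, only when both 95% CIs
exclude 1 (interaction only in the presence of main effects); the two fits
are treated as independent, an approximation since both draw controls from
one population. When only printed CIs are available, the SE is
reconstructed as `(log hi − log lo)/(2·1.96)`.

**A deliberate property of the recurrence design.** Because each family
enters once and the index case is removed, the same-phenotype rate among
selected siblings under the *null* (no familial clustering) is
`E[(X−1)/(k−1) | X ≥ 1]` for `X ~ Bin(k, p)` — about `p/(2−p)` in two-child
families, i.e. roughly half the population rate — so the design's null OR
sits below 1, not at it. The test suite verifies the simulated null against
this closed-form truncation baseline. The bias is shared by female- and
male-index cells, leaving their comparison valid, and it is conservative
for recurrence itself; the Wald test's own type-I error is verified
separately on truly null 2×2 data.

**Score contrasts.** OLS of the standardized score on a group indicator
plus principal components (taken as input columns; PCA is upstream).
Standardization centers at the reference mean and divides by the reference
sample SD (n−1): coefficient scaling is identical either way, centering is
for interpretability. With no covariates the contrast equals the difference
of group means exactly, which the tests assert. Rank-deficient designs are
rejected with the collinear columns named.

**pTDT.** Deviations `(child − midparent)/SD(midparent)`; the scaling SD is
computed over *all* trios passed to a run, before stratification, or
supplied as an explicit constant to mirror an external convention. The
one-sample test is the exact t-test (df `n−1`); stratum comparisons use
Welch's unequal-variance t by default (`equal_var=True` restores the pooled
form). Strata with fewer than two trios are omitted with a warning. Each
child contributes one trio record (multiplex families are not
deduplicated); for simulated quads, the designated unaffected sibling is
the oldest unaffected child.

**De novo classification.** Strictly as printed thresholds: PTV with
pLI > 0.9 (strict), CNV hitting ≥ 1 constrained gene, missense with
MPC ≥ 2 (inclusive); inherited variants never qualify. Annotations are
inputs; supplying an annotation on the wrong variant class (MPC on a PTV)
is a validation error. Carrier status is "at least one qualifying record",
monotone in the record set.

## Problem sizes

Desk-scale runs are sized by power analysis, not by the emulated studies'
exact ns: the acceptance battery uses 20 replicates of 400,000 registry
families (the female-index ASDnoID cell then holds ~2,900 index cases,
putting the female-vs-male log-OR contrast near z ≈ 3 per replicate) and
12,000 ascertained quad families (mother−father polygenic gap near z ≈ 6
per replicate). The pTDT null calibration uses 5,000 replicates of 100
unascertained trios; the oracle check 1,000 random 2×2 tables; threshold
recovery ~100,000 children. The replicate FPE checks are computed on the
latent polygenic component `g`, the quantity the hypotheses are about;
analysis scripts show the same signs on the noisy observed score, where
weaker strata (unaffected siblings) attenuate toward zero as expected of a
weak score.

## What the simulator does and does not emulate

It emulates: sex-differential thresholds on a shared liability scale,
Mendelian transmission of a polygenic component, untransmitted de novo
shocks shared across the two phenotypes, registry-style multi-child family
structure with birth years, trio/quad ascertainment with parental
screening, and a weak noisy score. It does **not** emulate: genotypes (no
SNPs, LD, or allele frequencies — the polygenic component lives directly on
the liability scale), ancestry structure (fixture PCs are pure noise),
case-enriched registry sampling designs, diagnostic-bias mechanisms
(masking, evaluator bias, later female diagnosis), secular trends in
diagnostic practice, assortative mating, or shared-environment effects.
Passing tests therefore show that the *designs recover the generative
signal they target under their own assumptions* — not that real cohorts
satisfy those assumptions.

## Known limitations

- The liability-scale magnitudes of simulated contrasts depend on
  conventions (`h²`, prevalences, score noise); only signs, orderings, and
  calibration properties are asserted.
- The OR-comparison treats the two cells' fits as independent although
  their control draws come from one population (disjoint by construction,
  but correlated with the population composition).
- Exact birth-year matching is a design choice; real studies may use age
  calipers. It is configurable only in the sense that the window is; no
  caliper matching is implemented.
- The trio rejection sampler reports non-convergence against an
  acceptance-probability floor (default 1e-6) rather than proving
  infeasibility.
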