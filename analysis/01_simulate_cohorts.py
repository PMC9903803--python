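#!/usr/bin/env python
"""Simulate the two study populations and report their composition.

Simulates a registry-style population of multi-child families and an
ascertained quad cohort (affected child, screened unaffected parents,
unaffected sibling) under the default liability-threshold parameters, then
prints the realized prevalences, case sex ratio, and de novo carrier rates
so the generative model can be eyeballed against the epidemiology it is
meant to emulate.  A small composition table goes to results/; the full
cohort tables (tens of MB) go to scratch/.
"""

import argparse
from pathlib import Path

import pandas as pd

from fpe_famkit import io as fio
from fpe_famkit.famsim import LiabilityParams, simulate_registry, simulate_trio_cohort

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-registry", type=int, default=50_000)
parser.add_argument("--n-trios", type=int, default=3_000)
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--scratch", type=Path, default=Path("scratch/cohorts"),
                    help="Where the full cohort tables are written.")
args = parser.parse_args()

params = LiabilityParams(seed=args.seed)
print("thresholds:", {f"{p}:{s}": round(t, 3) for (p, s), t in params.threshold_map().items()})

registry = simulate_registry(params, args.n_registry, seed=args.seed)
fio.save_cohort(registry, args.scratch / "registry")
ch = registry.children()
rows = []
print(f"\nregistry: {args.n_registry} families, {len(ch)} children")
for sex in ("M", "F"):
    sub = ch[ch["sex"].astype(str) == sex]
    rows.append({"cohort": "registry", "sex": sex, "n_children": len(sub),
                 "asd_prevalence": sub["dx_asd"].mean(),
                 "id_prevalence": sub["dx_id"].mean()})
    print(
        f"  {sex}: ASD {sub['dx_asd'].mean():.4f}  ID {sub['dx_id'].mean():.4f}  (n={len(sub)})"
    )

quads = simulate_trio_cohort(
    params, args.n_trios, require_unaffected_parents=True,
    require_unaffected_sibling=True, seed=args.seed,
)
fio.save_cohort(quads, args.scratch / "quads")
pro = quads.children().query("is_proband")
sex = pro["sex"].astype(str)
print(f"\nquads: {args.n_trios} ascertained families "
      f"({quads.meta['candidates_tried']} candidates)")
print(f"  proband sex ratio M:F = {(sex == 'M').sum()}:{(sex == 'F').sum()}")
print(f"  high-impact de novo carriers: "
      f"{pro.loc[sex == 'M', 'dnv'].mean():.3f} of male cases, "
      f"{pro.loc[sex == 'F', 'dnv'].mean():.3f} of female cases")
for s in ("M", "F"):
    sub = pro[sex == s]
    rows.append({"cohort": "quad_probands", "sex": s, "n_children": len(sub),
                 "asd_prevalence": 1.0, "id_prevalence": sub["dx_id"].mean(),
                 "dnv_carrier_rate": sub["dnv"].mean()})

args.out.mkdir(parents=True, exist_ok=True)
fio._tsv(pd.DataFrame(rows), args.out / "cohort_composition.tsv")
print(f"\nwrote {args.out}/cohort_composition.tsv; full cohorts under {args.scratch}/")
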