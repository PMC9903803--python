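"""Readers and writers for the pipeline's plain-text interchange formats.

Pedigrees use the PLINK FAM dialect (FID IID PAT MAT SEX PHENO,
whitespace-delimited, no header, SEX 1=male/2=female, PHENO 1=unaffected/
2=affected/-9=missing); everything else is tab-separated text with a header
row (scores, covariates, long-format diagnoses, annotated variants, trio
score tables).  Simulation parameters and run configs round-trip through
YAML (TOML is accepted on read).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .famsim import Cohort, LiabilityParams

__all__ = [
    "write_fam", "read_fam",
    "write_scores", "read_scores",
    "write_covariates", "read_covariates",
    "write_diagnoses", "read_diagnoses",
    "write_variants", "read_variants",
    "write_trios", "read_trios",
    "save_cohort", "load_cohort",
    "save_params", "load_params",
]

_FLOAT_FMT = "%.10g"


def _tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_fam(cohort: Cohort | pd.DataFrame, path, phenotype: str = "ASD") -> None:
    """Write a FAM-dialect pedigree; PHENO encodes the given phenotype."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    dx = df["dx_asd"] if phenotype == "ASD" else df["dx_id"]
    out = pd.DataFrame(
        {
            "FID": df["fid"].to_numpy(),
            "IID": df["iid"].to_numpy(),
            "PAT": np.where(df["father"].to_numpy() < 0, 0, df["father"].to_numpy()),
            "MAT": np.where(df["mother"].to_numpy() < 0, 0, df["mother"].to_numpy()),
            "SEX": np.where(df["sex"].astype(str) == "M", 1, 2),
            "PHENO": np.where(dx.to_numpy(), 2, 1),
        }
    )
    out.to_csv(path, sep=" ", index=False, header=False)


def read_fam(path) -> pd.DataFrame:
    fam = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["FID", "IID", "PAT", "MAT", "SEX", "PHENO"],
    )
    return fam


def write_scores(df: pd.DataFrame, path, score_col: str = "pgs_obs") -> None:
    """Score table in PLINK .profile spirit: FID, IID, SCORE."""
    _tsv(
        pd.DataFrame(
            {"FID": df["fid"].to_numpy(), "IID": df["iid"].to_numpy(),
             "SCORE": df[score_col].to_numpy()}
        ),
        path,
    )


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_covariates(df: pd.DataFrame, path) -> None:
    """Covariate table: IID then PC1..PCk columns."""
    _tsv(df, path)


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_diagnoses(cohort: Cohort | pd.DataFrame, path) -> None:
    """Long-format diagnoses: one (IID, diagnosis) row per diagnosis."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    rows = []
    for pheno, col in (("ASD", "dx_asd"), ("ID", "dx_id")):
        sub = df[df[col]]
        rows.append(pd.DataFrame({"IID": sub["iid"].to_numpy(), "diagnosis": pheno}))
    _tsv(pd.concat(rows, ignore_index=True), path)


def read_diagnoses(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_variants(df: pd.DataFrame, path) -> None:
    _tsv(df, path)


def read_variants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trios(trios: pd.DataFrame, path) -> None:
    _tsv(trios, path)


def read_trios(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# params / cohort persistence


def _params_to_dict(params: LiabilityParams) -> dict:
    d = dataclasses.asdict(params)
    d["prevalence"] = {f"{p}:{s}": v for (p, s), v in params.prevalence.items()}
    if params.thresholds is not None:
        d["thresholds"] = {f"{p}:{s}": v for (p, s), v in params.thresholds.items()}
    return d


def _params_from_dict(d: dict) -> LiabilityParams:
    d = dict(d)
    if "prevalence" in d and d["prevalence"] is not None:
        d["prevalence"] = {
            tuple(k.split(":")): float(v) for k, v in d["prevalence"].items()
        }
    if d.get("thresholds") is not None:
        d["thresholds"] = {
            tuple(k.split(":")): float(v) for k, v in d["thresholds"].items()
        }
    return LiabilityParams(**d)


def save_params(params: LiabilityParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(_params_to_dict(params), sort_keys=True))


def load_params(path) -> LiabilityParams:
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        d = tomllib.loads(path.read_text())
    else:
        d = yaml.safe_load(path.read_text())
    return _params_from_dict(d)


_COHORT_DTYPES = {
    "iid": np.int64, "fid": np.int64, "father": np.int64, "mother": np.int64,
    "birth_year": np.int32,
    "pgs_true": float, "pgs_true_id": float, "pgs_obs": float,
    "liab_asd": float, "liab_id": float,
    "dnv": bool, "dx_asd": bool, "dx_id": bool,
}


def save_cohort(cohort: Cohort, directory) -> None:
    """Persist a cohort as plain text: full table, params, FAM, scores, diagnoses."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _tsv(cohort.df, directory / "cohort.tsv")
    save_params(cohort.params, directory / "params.yaml")
    meta = dict(cohort.meta, seed=cohort.seed)
    (directory / "meta.yaml").write_text(yaml.safe_dump(_jsonable(meta), sort_keys=True))
    write_fam(cohort, directory / "pedigree.fam")
    write_scores(cohort.df, directory / "scores.tsv")
    write_diagnoses(cohort, directory / "diagnoses.tsv")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def load_cohort(directory) -> Cohort:
    directory = Path(directory)
    df = pd.read_csv(directory / "cohort.tsv", sep="\t", dtype=_COHORT_DTYPES)
    for col, cats in (("sex", ["M", "F"]), ("role", ["founder", "offspring"]),
                      ("dgroup", ["ASDnoID", "ASDandID", "IDnoASD", "none"])):
        df[col] = pd.Categorical(df[col], categories=cats)
    df.index = pd.Index(df["iid"].to_numpy(), name="iid_index")
    params = load_params(directory / "params.yaml")
    meta = yaml.safe_load((directory / "meta.yaml").read_text()) or {}
    seed = meta.pop("seed", params.seed)
    if "birth_year_range" in meta and meta["birth_year_range"] is not None:
        meta["birth_year_range"] = tuple(meta["birth_year_range"])
    return Cohort(df, params, seed, meta)
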