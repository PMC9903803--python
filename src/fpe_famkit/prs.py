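"""Polygenic-score plumbing and covariate-adjusted group contrasts.

Raw scores are weighted dosage sums; interpretability comes from scaling to
the score SD of an external reference population (the convention of scaling
case-cohort differences by a general-population control SD).  Group
contrasts are ordinary least squares of the standardized score on a group
indicator plus ancestry principal components, so with no covariates the
contrast is exactly a difference of group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "GroupDiff",
    "score_samples",
    "standardize",
    "compare_groups",
    "proband_sex_comparison",
]


@dataclass
class GroupDiff:
    """A covariate-adjusted between-group score difference.

    ``difference`` is the coefficient of the group-coded-1 indicator, i.e.
    group-1 minus group-0, in whatever units the scores were supplied
    (reference-SD units after :func:`standardize`).
    """

    difference: float
    standard_error: float
    p_value: float
    n0: int
    n1: int
    n_covariates: int


def score_samples(dosages: pd.DataFrame, weights) -> pd.Series:
    """Linear scoring: score(sample) = sum over variants of weight x dosage.

    ``dosages`` is samples x variants in [0, 2]; ``weights`` maps variant id
    to effect size.  Variants missing from the weights are ignored (a count
    is logged); an empty intersection is an error.
    """
    w = pd.Series(weights, dtype=float)
    common = dosages.columns.intersection(w.index)
    ignored = len(dosages.columns) - len(common)
    if len(common) == 0:
        raise ValueError("no variants in common between dosages and weights")
    if ignored:
        logger.info("score_samples: ignored %d variants absent from weights", ignored)
    if dosages[common].isna().any().any():
        raise ValueError("missing dosages are not allowed; impute upstream")
    scores = dosages[common].to_numpy() @ w.loc[common].to_numpy()
    return pd.Series(scores, index=dosages.index, name="score")


def standardize(scores: pd.Series, reference: pd.Series) -> pd.Series:
    """Scale scores to reference-population SD units.

    Centers at the reference mean and divides by the reference sample SD
    (n-1 denominator), so the reference cohort itself maps to mean 0, SD 1.
    """
    if len(reference) < 2:
        raise ValueError("reference must contain at least two scores")
    sd = float(reference.std(ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("reference SD must be positive and finite")
    return (scores - float(reference.mean())) / sd


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        suspects = []
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[col]).to_numpy()) == rank:
                suspects.append(str(col))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {suspects}")


def _ols_indicator(
    scores: pd.Series,
    design: pd.DataFrame,
    indicator: str,
) -> tuple[float, float, float]:
    X = sm.add_constant(design, has_constant="add")
    _check_rank(X)
    fit = sm.OLS(scores.astype(float), X).fit()
    return float(fit.params[indicator]), float(fit.bse[indicator]), float(fit.pvalues[indicator])


def _aligned(scores: pd.Series, *others) -> list:
    idx = scores.index
    out = []
    for o in others:
        if o is None:
            out.append(None)
            continue
        o = o.reindex(idx)
        if o.isna().to_numpy().any():
            raise ValueError("samples missing from an input table")
        out.append(o)
    return out


def compare_groups(
    scores: pd.Series,
    group_indicator: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> GroupDiff:
    """OLS contrast of scores between two groups, controlling for PCs.

    ``group_indicator`` codes membership 0/1; ``covariates`` (optional) holds
    one principal component per column.  With no covariates the returned
    difference equals the difference of group means exactly.
    """
    group_indicator, covariates = _aligned(scores, group_indicator, covariates)
    g = group_indicator.astype(float)
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both groups must be nonempty")
    if n0 + n1 != len(g):
        raise ValueError("group_indicator must be coded 0/1")
    design = pd.DataFrame({"group": g})
    k = 0
    if covariates is not None:
        design = pd.concat([design, covariates.astype(float)], axis=1)
        k = covariates.shape[1]
    diff, se, p = _ols_indicator(scores, design, "group")
    return GroupDiff(difference=diff, standard_error=se, p_value=p, n0=n0, n1=n1, n_covariates=k)


def proband_sex_comparison(
    scores: pd.Series,
    sex: pd.Series,
    id_status: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> GroupDiff:
    """Female-minus-male score contrast among probands, controlling for ID.

    Because comorbid intellectual disability is more frequent in female
    cases and is associated with lower polygenic load, the ID indicator
    enters the model alongside the female indicator and the PCs.
    """
    sex, id_status, covariates = _aligned(scores, sex, id_status, covariates)
    female = sex.astype(str).map({"F": 1.0, "M": 0.0})
    if female.isna().any():
        raise ValueError("sex must be coded 'M'/'F' for every sample")
    n1 = int((female == 1).sum())
    n0 = int((female == 0).sum())
    if n0 == 0 or n1 == 0:
        raise ValueError("both sexes must be present among probands")
    design = pd.DataFrame({"female": female, "id_status": id_status.astype(float)})
    k = 0
    if covariates is not None:
        design = pd.concat([design, covariates.astype(float)], axis=1)
        k = covariates.shape[1]
    diff, se, p = _ols_indicator(scores, design, "female")
    return GroupDiff(difference=diff, standard_error=se, p_value=p, n0=n0, n1=n1, n_covariates=k)
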