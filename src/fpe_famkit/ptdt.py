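"""The polygenic transmission disequilibrium test (pTDT).

In a random trio the child's expected polygenic score is the mid-parent mean
(the average of the mother's and father's scores), so the standardized
deviation

    d_i = (child_i - midparent_i) / SD(midparent)

has expectation zero.  Ascertaining for a phenotypic deviation between child
and parents (an affected child with screened-unaffected parents) breaks that
expectation; the test is a two-sided one-sample t-test of the deviations
against zero, and strata are compared with a two-sample Welch t-test.

Within-family deviations are immune to population stratification, so unlike
the case-control score contrasts no ancestry covariates are needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TRIO_COLUMNS",
    "PTDTResult",
    "PTDTComparison",
    "DegenerateInputError",
    "midparent",
    "ptdt_deviations",
    "ptdt_test",
    "ptdt_group_compare",
    "run_ptdt_analysis",
]

TRIO_COLUMNS = (
    "fid", "child_iid", "mother_iid", "father_iid",
    "child_score", "mother_score", "father_score",
    "sex", "affected", "dnv",
)


class DegenerateInputError(ValueError):
    """Too few trios or zero variance: the t-test is undefined."""


@dataclass
class PTDTResult:
    """One-sample pTDT result for one stratum."""

    stratum: str
    n: int
    mean_deviation: float
    standard_error: float
    t: float
    df: int
    p_value: float


@dataclass
class PTDTComparison:
    """Two-sample comparison of deviation distributions between strata."""

    labels: tuple[str, str]
    difference: float
    t: float
    df: float
    p_value: float


def midparent(mother_score, father_score):
    """Mid-parent value: the Mendelian expectation for the child's score."""
    m = np.asarray(mother_score, dtype=float)
    f = np.asarray(father_score, dtype=float)
    if np.any(~np.isfinite(m)) or np.any(~np.isfinite(f)):
        raise ValueError("trio incomplete: missing or non-finite parental score")
    out = 0.5 * (m + f)
    return float(out) if out.ndim == 0 else out


def ptdt_deviations(trios: pd.DataFrame, scale_sd="from-data") -> pd.Series:
    """Standardized child-minus-midparent deviations.

    ``scale_sd`` is either a positive constant (to reproduce an externally
    fixed scaling convention) or ``"from-data"``, in which case the SD of the
    mid-parent values over all supplied trios is used.
    """
    mp = midparent(trios["mother_score"], trios["father_score"])
    if scale_sd == "from-data":
        scale = float(np.std(mp, ddof=1)) if len(mp) > 1 else 0.0
    else:
        scale = float(scale_sd)
    if not (scale > 0):
        raise ValueError("scale SD must be positive")
    dev = (trios["child_score"].to_numpy(dtype=float) - mp) / scale
    return pd.Series(dev, index=trios.index, name="ptdt_deviation")


def ptdt_test(deviations, stratum: str = "") -> PTDTResult:
    """Two-sided one-sample t-test of the mean deviation against zero."""
    d = np.asarray(deviations, dtype=float)
    n = d.size
    if n < 2:
        raise DegenerateInputError(f"stratum {stratum!r}: need at least 2 trios, got {n}")
    sd = d.std(ddof=1)
    if sd == 0 or np.ptp(d) == 0:  # ptp catches all-equal inputs exactly
        raise DegenerateInputError(f"stratum {stratum!r}: zero variance in deviations")
    se = sd / np.sqrt(n)
    t = d.mean() / se
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PTDTResult(
        stratum=stratum, n=n, mean_deviation=float(d.mean()),
        standard_error=float(se), t=float(t), df=n - 1, p_value=float(p),
    )


def ptdt_group_compare(dev_a, dev_b, labels=("a", "b"), equal_var: bool = False) -> PTDTComparison:
    """Two-sample t-test between two deviation distributions.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled-variance test.
    """
    a = np.asarray(dev_a, dtype=float)
    b = np.asarray(dev_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("both groups need at least 2 trios")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DegenerateInputError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return PTDTComparison(
        labels=tuple(labels),
        difference=float(a.mean() - b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
    )


def _strata_labels(trios: pd.DataFrame, strata) -> pd.Series:
    """Resolve a strata selector into one label per trio ('' = excluded)."""
    if isinstance(strata, pd.Series):
        return strata.reindex(trios.index).fillna("")
    sex = trios["sex"].astype(str).map({"M": "male", "F": "female"})
    if strata == "affected_by_sex_dnv":
        lab = sex + np.where(trios["dnv"], "_dnv", "_no_dnv")
        return pd.Series(np.where(trios["affected"], lab, ""), index=trios.index)
    if strata == "unaffected_by_sex":
        lab = sex + "_sibling"
        return pd.Series(np.where(~trios["affected"].astype(bool), lab, ""), index=trios.index)
    raise ValueError(f"unknown strata selector {strata!r}")


def run_ptdt_analysis(
    trios: pd.DataFrame,
    strata="affected_by_sex_dnv",
    scale="from-data",
    comparisons: list[tuple[str, str]] | str = "all-pairs",
    equal_var: bool = False,
):
    """pTDT per stratum plus pairwise stratum comparisons.

    The scaling SD is computed over *all* supplied trios (before any
    stratification) when ``scale="from-data"``, so every stratum is expressed
    on the same mid-parent-SD scale.  Empty or singleton strata are omitted
    with a warning.  Returns (results table, comparisons table).
    """
    dev = ptdt_deviations(trios, scale_sd=scale)
    labels = _strata_labels(trios, strata)
    results = []
    devs: dict[str, np.ndarray] = {}
    for lab in pd.unique(labels):
        if lab == "":
            continue
        d = dev[labels == lab].to_numpy()
        if d.size < 2:
            warnings.warn(f"stratum {lab!r} has {d.size} trios; omitted", stacklevel=2)
            continue
        devs[lab] = d
        results.append(ptdt_test(d, stratum=lab))
    results_df = pd.DataFrame(
        [
            {
                "stratum": r.stratum, "n": r.n, "mean_deviation": r.mean_deviation,
                "standard_error": r.standard_error, "t": r.t, "df": r.df,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
    if comparisons == "all-pairs":
        labs = sorted(devs)
        pairs = [(x, y) for i, x in enumerate(labs) for y in labs[i + 1:]]
    else:
        pairs = list(comparisons)
    comp_rows = []
    for x, y in pairs:
        if x not in devs or y not in devs:
            raise ValueError(f"unknown stratum label in comparison: {(x, y)}")
        comp = ptdt_group_compare(devs[x], devs[y], labels=(x, y), equal_var=equal_var)
        comp_rows.append(
            {
                "stratum_a": x, "stratum_b": y, "difference": comp.difference,
                "t": comp.t, "df": comp.df, "p_value": comp.p_value,
            }
        )
    return results_df, pd.DataFrame(comp_rows)
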