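"""Registry-style sibling recurrence analysis.

Implements the matched case-control sibling-recurrence design: per family,
one randomly selected diagnosed index case (a sex x diagnosis-group cell),
one randomly selected full sibling born inside the study window, 2:1 age- and
sex-matched population controls (all children of index-case families removed
from the control pool), a sibling-indicator logistic regression per outcome,
and Wald comparisons of the resulting odds ratios between female-index and
male-index cells.  With no covariates the logistic OR equals the 2x2
cross-product ratio, which serves as an independent oracle in the tests.

Comparisons between two odds ratios are gated the way the source design
prescribes: only computed when both ORs are individually significantly
different from 1 (both 95% CIs exclude 1), akin to testing an interaction
only in the presence of main effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .famsim import Cohort
from ._rng import substream

__all__ = [
    "Z95",
    "IndexCriteria",
    "SIX_CELLS",
    "RecurrenceResult",
    "ORComparison",
    "MatchingError",
    "DegenerateTableError",
    "select_index_case",
    "select_sibling",
    "match_controls",
    "fit_recurrence",
    "fit_recurrence_counts",
    "compare_or",
    "p_vs_null",
    "se_log_or_from_ci",
    "run_recurrence_analysis",
    "recurrence_by_sibling_sex",
]

Z95 = 1.96  # normal quantile used for the 95% Wald interval

OUTCOME_GROUPS = ("ASDnoID", "ASDandID", "IDnoASD")


class MatchingError(RuntimeError):
    """Not enough eligible controls in a (sex, birth-year) stratum."""


class DegenerateTableError(ValueError):
    """A 2x2 cell is empty; the odds ratio is not finite."""


@dataclass(frozen=True)
class IndexCriteria:
    """Index-case eligibility: sex ('M'/'F'/'any') x diagnosis group."""

    sex: str = "any"
    group: str = "ASDnoID"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "any"):
            raise ValueError(f"sex must be 'M', 'F' or 'any', got {self.sex!r}")
        if self.group not in OUTCOME_GROUPS + ("ASD-any",):
            raise ValueError(f"unknown index group {self.group!r}")

    @property
    def label(self) -> str:
        return f"{self.sex}:{self.group}"


#: The six analysis cells: (sex M/F) x (ASDnoID, ASDandID, IDnoASD).
SIX_CELLS = tuple(
    IndexCriteria(sex=s, group=g) for g in OUTCOME_GROUPS for s in ("F", "M")
)


@dataclass
class RecurrenceResult:
    """A sibling-vs-matched-control odds ratio for one outcome."""

    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    se_log_or: float
    a: int | None = None  # affected siblings
    b: int | None = None  # unaffected siblings
    c: int | None = None  # affected controls
    d: int | None = None  # unaffected controls
    n_siblings: int | None = None
    n_controls: int | None = None
    degenerate: bool = False
    label: str = ""

    @property
    def log_odds_ratio(self) -> float:
        return math.log(self.odds_ratio)

    @classmethod
    def from_or_ci(
        cls, odds_ratio: float, ci_low: float, ci_high: float,
        outcome: str = "", label: str = "",
    ) -> "RecurrenceResult":
        """Reconstruct a result from a published OR and its 95% CI."""
        se = se_log_or_from_ci(ci_low, ci_high)
        z = abs(math.log(odds_ratio)) / se
        return cls(
            outcome=outcome, odds_ratio=odds_ratio, ci_low=ci_low, ci_high=ci_high,
            p_value=2.0 * norm.sf(z), se_log_or=se, label=label,
        )


@dataclass
class ORComparison:
    """Wald comparison of two odds ratios on the log scale."""

    log_or_difference: float
    standard_error: float
    z: float
    p_value: float
    labels: tuple[str, str] = field(default=("a", "b"))


def se_log_or_from_ci(ci_low: float, ci_high: float, z: float = Z95) -> float:
    """Standard error of the log OR implied by a symmetric Wald 95% CI."""
    if not (0 < ci_low <= ci_high):
        raise ValueError("need 0 < ci_low <= ci_high")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


def p_vs_null(result: RecurrenceResult) -> float:
    """Two-sided Wald p-value for OR != 1."""
    return 2.0 * norm.sf(abs(result.log_odds_ratio) / result.se_log_or)


# ---------------------------------------------------------------------------
# selection and matching


def _children(family: pd.DataFrame) -> pd.DataFrame:
    if "role" in family.columns:
        return family[family["role"] == "offspring"]
    return family


def select_index_case(family: pd.DataFrame, criteria: IndexCriteria, rng: np.random.Generator):
    """Uniformly select one eligible child as the index case, or None."""
    ch = _children(family)
    if criteria.group == "ASD-any":
        mask = ch["dx_asd"].to_numpy()
    else:
        mask = (ch["dgroup"].astype(str) == criteria.group).to_numpy()
    if criteria.sex != "any":
        mask &= (ch["sex"].astype(str) == criteria.sex).to_numpy()
    eligible = ch["iid"].to_numpy()[mask]
    if eligible.size == 0:
        return None
    return int(eligible[rng.integers(eligible.size)])


def select_sibling(
    family: pd.DataFrame,
    index_id: int,
    birth_year_window: tuple[int, int],
    rng: np.random.Generator,
):
    """Uniformly select one full sibling of the index case born in-window.

    Selection is never diagnosis dependent: affected and unaffected siblings
    are equally likely to be chosen.
    """
    ch = _children(family)
    idx = ch[ch["iid"] == index_id]
    if idx.empty:
        raise ValueError(f"index case {index_id} not found among family offspring")
    father = idx["father"].iloc[0]
    mother = idx["mother"].iloc[0]
    y0, y1 = birth_year_window
    sibs = ch[
        (ch["father"] == father)
        & (ch["mother"] == mother)
        & (ch["iid"] != index_id)
        & ch["birth_year"].between(y0, y1)
    ]
    if sibs.empty:
        return None
    iids = sibs["iid"].to_numpy()
    return int(iids[rng.integers(iids.size)])


def match_controls(
    sibling: pd.Series,
    population: Cohort | pd.DataFrame,
    ratio: int,
    exclusions: set,
    rng: np.random.Generator,
) -> list[int]:
    """Sample ``ratio`` same-sex, same-birth-year controls without replacement."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    pop = population.children() if isinstance(population, Cohort) else _children(population)
    sex = str(sibling["sex"])
    year = int(sibling["birth_year"])
    pool = pop[
        (pop["sex"].astype(str) == sex)
        & (pop["birth_year"] == year)
        & (pop["iid"] != sibling["iid"])
    ]
    iids = pool["iid"].to_numpy()
    if exclusions:
        iids = iids[~np.isin(iids, np.fromiter(exclusions, dtype=np.int64, count=len(exclusions)))]
    if iids.size < ratio:
        raise MatchingError(
            f"stratum sex={sex}, birth_year={year}: {iids.size} eligible controls, need {ratio}"
        )
    return [int(i) for i in rng.choice(iids, size=ratio, replace=False)]


# ---------------------------------------------------------------------------
# logistic odds ratios


def _irls_2x2(a: float, n1: float, c: float, n0: float, tol: float = 1e-10, maxiter: int = 50):
    """IRLS fit of logit P(affected) = b0 + b1 * sibling on grouped counts.

    Returns (beta, cov).  For this saturated 2x2 model the MLE equals the
    closed-form cross-product ratio; IRLS converges quadratically.
    """
    X = np.array([[1.0, 0.0], [1.0, 1.0]])
    s = np.array([c, a], dtype=float)
    n = np.array([n0, n1], dtype=float)
    beta = np.zeros(2)
    XtWX = None
    for _ in range(maxiter):
        eta = X @ beta
        mu = expit(eta)
        w = n * mu * (1.0 - mu)
        z = eta + (s - n * mu) / w
        XtW = X.T * w
        XtWX = XtW @ X
        new = np.linalg.solve(XtWX, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    eta = X @ beta
    mu = expit(eta)
    w = n * mu * (1.0 - mu)
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    return beta, cov


def fit_recurrence_counts(
    a: int, n_siblings: int, c: int, n_controls: int,
    outcome: str = "", label: str = "",
) -> RecurrenceResult:
    """Sibling-indicator logistic regression from aggregated 2x2 counts.

    ``a`` affected among ``n_siblings`` siblings, ``c`` affected among
    ``n_controls`` matched controls.  Zero cells are reported with the
    Haldane-Anscombe 0.5 correction and flagged ``degenerate``.
    """
    b = n_siblings - a
    d = n_controls - c
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    degenerate = min(a, b, c, d) == 0
    if degenerate:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        log_or = math.log(aa * dd / (bb * cc))
        se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    else:
        beta, cov = _irls_2x2(a, n_siblings, c, n_controls)
        log_or = float(beta[1])
        se = float(math.sqrt(cov[1, 1]))
    return RecurrenceResult(
        outcome=outcome,
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p_value=2.0 * norm.sf(abs(log_or) / se),
        se_log_or=se,
        a=a, b=b, c=c, d=d,
        n_siblings=n_siblings, n_controls=n_controls,
        degenerate=degenerate, label=label,
    )


def _affected_mask(df: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome in OUTCOME_GROUPS:
        return (df["dgroup"].astype(str) == outcome).to_numpy()
    if outcome == "ASD-any":
        return df["dx_asd"].to_numpy()
    if outcome == "ID-any":
        return df["dx_id"].to_numpy()
    raise ValueError(f"unknown outcome {outcome!r}")


def fit_recurrence(
    siblings: list[int],
    controls: list[int],
    outcome: str,
    cohort: Cohort,
    label: str = "",
) -> RecurrenceResult:
    """Fit the sibling-vs-control logistic OR for one outcome."""
    if set(siblings) & set(controls):
        raise ValueError("siblings and controls overlap")
    sib = cohort.df.loc[list(siblings)]
    ctl = cohort.df.loc[list(controls)]
    a = int(_affected_mask(sib, outcome).sum())
    c = int(_affected_mask(ctl, outcome).sum())
    return fit_recurrence_counts(a, len(sib), c, len(ctl), outcome=outcome, label=label)


def compare_or(a: RecurrenceResult, b: RecurrenceResult) -> ORComparison:
    """Wald test of log OR_a - log OR_b, treating the two fits as independent."""
    if a.degenerate or b.degenerate:
        raise DegenerateTableError("cannot compare degenerate odds ratios")
    diff = a.log_odds_ratio - b.log_odds_ratio
    se = math.hypot(a.se_log_or, b.se_log_or)
    z = diff / se
    return ORComparison(
        log_or_difference=diff,
        standard_error=se,
        z=z,
        p_value=2.0 * norm.sf(abs(z)),
        labels=(a.label, b.label),
    )


# ---------------------------------------------------------------------------
# cohort-level orchestration


def _uniform_one_per_family(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Pick one row per fid, each row of a family equally likely."""
    if df.empty:
        return df
    perm = rng.permutation(len(df))
    return df.iloc[perm].drop_duplicates("fid")


def _bulk_match(
    siblings: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int,
    rng: np.random.Generator,
    label: str,
) -> np.ndarray:
    """Match ``ratio`` controls per sibling on exact sex x birth year.

    Controls are drawn without replacement within the whole analysis, so no
    control is reused across siblings.
    """
    chosen: list[np.ndarray] = []
    pool_groups = pool.groupby(["sex", "birth_year"], observed=True).indices
    pool_iids = pool["iid"].to_numpy()
    for (sex, year), idx in siblings.groupby(["sex", "birth_year"], observed=True).indices.items():
        need = ratio * len(idx)
        avail = pool_groups.get((sex, year))
        if avail is None or len(avail) < need:
            have = 0 if avail is None else len(avail)
            raise MatchingError(
                f"{label}: stratum sex={sex}, birth_year={year}: "
                f"{have} eligible controls, need {need}"
            )
        pick = rng.choice(avail, size=need, replace=False)
        chosen.append(pool_iids[pick])
    return np.concatenate(chosen) if chosen else np.array([], dtype=np.int64)


def _result_row(crit_sex: str, crit_group: str, res: RecurrenceResult, stratum: str = "") -> dict:
    return {
        "criteria_sex": crit_sex,
        "criteria_group": crit_group,
        "stratum": stratum,
        "outcome": res.outcome,
        "odds_ratio": res.odds_ratio,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p_value": res.p_value,
        "se_log_or": res.se_log_or,
        "n_siblings": res.n_siblings,
        "n_controls": res.n_controls,
        "a": res.a, "b": res.b, "c": res.c, "d": res.d,
        "degenerate": res.degenerate,
    }


def _run_cell(
    children: pd.DataFrame,
    criteria: IndexCriteria,
    outcomes: tuple[str, ...],
    ratio: int,
    window: tuple[int, int],
    rng: np.random.Generator,
):
    """One analysis cell: index selection, sibling selection, matching, fits."""
    if criteria.group == "ASD-any":
        mask = children["dx_asd"].to_numpy()
    else:
        mask = (children["dgroup"].astype(str) == criteria.group).to_numpy()
    if criteria.sex != "any":
        mask &= (children["sex"].astype(str) == criteria.sex).to_numpy()
    eligible = children[mask]
    index_cases = _uniform_one_per_family(eligible, rng)
    if index_cases.empty:
        return [], None, None

    index_fids = index_cases["fid"].to_numpy()
    fam_children = children[children["fid"].isin(index_fids)]
    # full siblings of the index case, in-window, excluding the index itself
    merged = fam_children.merge(
        index_cases[["fid", "iid", "father", "mother"]].rename(
            columns={"iid": "_index_iid", "father": "_ifather", "mother": "_imother"}
        ),
        on="fid",
    )
    y0, y1 = window
    sib_pool = merged[
        (merged["iid"] != merged["_index_iid"])
        & (merged["father"] == merged["_ifather"])
        & (merged["mother"] == merged["_imother"])
        & merged["birth_year"].between(y0, y1)
    ]
    siblings = _uniform_one_per_family(sib_pool, rng)
    if siblings.empty:
        return [], None, None

    # control pool: population children minus all siblings of index cases
    # (index cases themselves stay eligible: controls are population
    # representative and may carry diagnoses at the population rate)
    in_window = children["birth_year"].between(y0, y1).to_numpy()
    is_index_sibling = (
        children["fid"].isin(index_fids).to_numpy()
        & ~children["iid"].isin(index_cases["iid"]).to_numpy()
    )
    pool = children[in_window & ~is_index_sibling]
    control_iids = _bulk_match(
        siblings.reset_index(drop=True), pool.reset_index(drop=True),
        ratio, rng, criteria.label,
    )
    sib_iids = siblings["iid"].to_numpy()

    sib_rows = children[children["iid"].isin(sib_iids)]
    ctl_rows = children[children["iid"].isin(control_iids)]
    results = []
    for outcome in outcomes:
        a = int(_affected_mask(sib_rows, outcome).sum())
        c = int(_affected_mask(ctl_rows, outcome).sum())
        results.append(
            fit_recurrence_counts(
                a, len(sib_rows), c, len(ctl_rows),
                outcome=outcome, label=criteria.label,
            )
        )
    # assignment table: sibling -> its matched controls (strata-ordered)
    assignments = _assignment_table(siblings, control_iids, ratio)
    return results, assignments, index_cases[["fid", "iid"]]


def _assignment_table(siblings: pd.DataFrame, control_iids: np.ndarray, ratio: int) -> pd.DataFrame:
    """Pair each sibling with its ``ratio`` controls, stratum by stratum."""
    rows = []
    offset = 0
    for (_, _), idx in siblings.groupby(["sex", "birth_year"], observed=True).indices.items():
        sib_ids = siblings.iloc[idx]["iid"].to_numpy()
        block = control_iids[offset: offset + ratio * len(sib_ids)]
        offset += ratio * len(sib_ids)
        for j, sid in enumerate(sib_ids):
            for k in range(ratio):
                rows.append({"sibling_iid": int(sid), "control_iid": int(block[j * ratio + k])})
    return pd.DataFrame(rows)


def run_recurrence_analysis(
    cohort: Cohort,
    criteria: tuple[IndexCriteria, ...] = SIX_CELLS,
    outcomes: tuple[str, ...] = OUTCOME_GROUPS,
    ratio: int = 2,
    birth_year_window: tuple[int, int] | None = None,
    seed: int = 0,
    return_assignments: bool = False,
):
    """Run the full matched sibling-recurrence analysis.

    Each criteria cell is an independent analysis (own index-case selection,
    sibling selection and control draw).  Returns a tidy results table and a
    table of gated female-vs-male OR comparisons; with
    ``return_assignments=True`` also a mapping cell label -> sibling/control
    assignment table (for matching audits).
    """
    window = birth_year_window or cohort.meta.get("birth_year_range", (1981, 2005))
    children = cohort.children().reset_index(drop=True)
    rng = substream(seed, "recurrence")

    rows: list[dict] = []
    fitted: dict[tuple[str, str, str], RecurrenceResult] = {}
    assignments: dict[str, pd.DataFrame] = {}
    for crit in criteria:
        results, assign, index_cases = _run_cell(children, crit, tuple(outcomes), ratio, window, rng)
        if assign is not None:
            assignments[crit.label] = {"pairs": assign, "index_cases": index_cases}
        for res in results:
            rows.append(_result_row(crit.sex, crit.group, res))
            fitted[(crit.sex, crit.group, res.outcome)] = res

    results_df = pd.DataFrame(rows)
    comp_rows: list[dict] = []
    groups = {c.group for c in criteria if c.sex in ("M", "F")}
    for group in sorted(groups):
        for outcome in outcomes:
            fa = fitted.get(("F", group, outcome))
            ma = fitted.get(("M", group, outcome))
            if fa is None or ma is None:
                continue
            both_elevated = (
                not fa.degenerate and not ma.degenerate
                and fa.ci_low > 1.0 and ma.ci_low > 1.0
            )
            row = {
                "criteria_group": group,
                "outcome": outcome,
                "tested": both_elevated,
            }
            if both_elevated:
                comp = compare_or(fa, ma)
                row.update(
                    log_or_difference=comp.log_or_difference,
                    standard_error=comp.standard_error,
                    z=comp.z,
                    p_value=comp.p_value,
                )
            else:
                row.update(
                    log_or_difference=np.nan, standard_error=np.nan,
                    z=np.nan, p_value=np.nan,
                )
            comp_rows.append(row)
    comparisons_df = pd.DataFrame(comp_rows)
    if return_assignments:
        return results_df, comparisons_df, assignments
    return results_df, comparisons_df


def recurrence_by_sibling_sex(
    cohort: Cohort,
    ratio: int = 2,
    birth_year_window: tuple[int, int] | None = None,
    seed: int = 0,
    outcome: str = "ASD-any",
):
    """Recurrence stratified by the *sibling's* sex.

    The index case is any ASD-diagnosed child regardless of sex or comorbid
    ID.  Selected siblings are split by sex and each stratum is compared with
    its own sex-matched controls, so the implicit population rate is
    sex-specific.  Returns (results table, comparison table); empty strata
    are flagged with n = 0 rows.
    """
    window = birth_year_window or cohort.meta.get("birth_year_range", (1981, 2005))
    children = cohort.children().reset_index(drop=True)
    rng = substream(seed, "recurrence-sibling-sex")
    crit = IndexCriteria(sex="any", group="ASD-any")

    # reuse the cell machinery to select index cases + siblings + controls
    mask = children["dx_asd"].to_numpy()
    eligible = children[mask]
    index_cases = _uniform_one_per_family(eligible, rng)
    rows: list[dict] = []
    fitted: dict[str, RecurrenceResult] = {}
    if not index_cases.empty:
        index_fids = index_cases["fid"].to_numpy()
        fam_children = children[children["fid"].isin(index_fids)]
        merged = fam_children.merge(
            index_cases[["fid", "iid", "father", "mother"]].rename(
                columns={"iid": "_index_iid", "father": "_ifather", "mother": "_imother"}
            ),
            on="fid",
        )
        y0, y1 = window
        sib_pool = merged[
            (merged["iid"] != merged["_index_iid"])
            & (merged["father"] == merged["_ifather"])
            & (merged["mother"] == merged["_imother"])
            & merged["birth_year"].between(y0, y1)
        ]
        siblings = _uniform_one_per_family(sib_pool, rng)
        in_window = children["birth_year"].between(y0, y1).to_numpy()
        is_index_sibling = (
            children["fid"].isin(index_fids).to_numpy()
            & ~children["iid"].isin(index_cases["iid"]).to_numpy()
        )
        pool = children[in_window & ~is_index_sibling]
        for sex in ("M", "F"):
            strat = siblings[siblings["sex"].astype(str) == sex]
            if strat.empty:
                rows.append(
                    {
                        "criteria_sex": "any", "criteria_group": "ASD-any",
                        "stratum": f"sibling_{sex}", "outcome": outcome,
                        "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                        "p_value": np.nan, "se_log_or": np.nan,
                        "n_siblings": 0, "n_controls": 0,
                        "a": 0, "b": 0, "c": 0, "d": 0, "degenerate": True,
                    }
                )
                continue
            control_iids = _bulk_match(
                strat.reset_index(drop=True), pool.reset_index(drop=True),
                ratio, rng, f"sibling_{sex}",
            )
            sib_rows = children[children["iid"].isin(strat["iid"].to_numpy())]
            ctl_rows = children[children["iid"].isin(control_iids)]
            a = int(_affected_mask(sib_rows, outcome).sum())
            c = int(_affected_mask(ctl_rows, outcome).sum())
            res = fit_recurrence_counts(
                a, len(sib_rows), c, len(ctl_rows),
                outcome=outcome, label=f"sibling_{sex}",
            )
            fitted[sex] = res
            rows.append(_result_row("any", crit.group, res, stratum=f"sibling_{sex}"))
    results_df = pd.DataFrame(rows)
    comp_rows = []
    if "M" in fitted and "F" in fitted:
        fa, ma = fitted["F"], fitted["M"]
        tested = (not fa.degenerate and not ma.degenerate
                  and fa.ci_low > 1.0 and ma.ci_low > 1.0)
        row = {"comparison": "sibling_F_vs_M", "outcome": outcome, "tested": tested}
        if tested:
            comp = compare_or(fa, ma)
            row.update(
                log_or_difference=comp.log_or_difference,
                standard_error=comp.standard_error,
                z=comp.z, p_value=comp.p_value,
            )
        else:
            row.update(log_or_difference=np.nan, standard_error=np.nan, z=np.nan, p_value=np.nan)
        comp_rows.append(row)
    return results_df, pd.DataFrame(comp_rows)
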