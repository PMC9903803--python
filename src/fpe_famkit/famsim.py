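"""Liability-threshold family simulator with sex-specific diagnostic thresholds.

The generative model is the classical additive liability-threshold model of
quantitative genetics.  Each person carries, for each phenotype (ASD and ID),
a latent liability

    L = g + e (+ d * dnv_effect)

where ``g`` is the common (transmitted) polygenic component, ``e`` is an
independent residual, and ``d`` indicates a high-impact de novo variant that
arises in offspring only and is not transmitted.  In founders the liability is
standard normal: Var(g) = h2_common and Var(e) = 1 - h2_common.  A child's
polygenic component is the mid-parent value plus an independent Mendelian
segregation deviation with variance h2_common / 2, which keeps Var(g) =
h2_common in every generation under random mating.

A person is diagnosed when their liability exceeds a sex-specific threshold.
The female-protective effect is encoded entirely as a higher female threshold
(equivalently, a lower female prevalence): females must accumulate more total
liability than males before meeting diagnostic criteria.

The ASD and ID liabilities share nothing by default except de novo shocks,
which hit both: their common polygenic components are correlated ``rg_asd_id``
(default 0, reflecting the near-zero estimated genetic correlation between the
common variants underlying the two diagnoses), and their residuals are
independent.

An observed polygenic score is emitted as the true ASD common component plus
independent Gaussian noise, mimicking a weak real-world PRS; by default the
noise is sized so the score explains 5% of the variance of the common
component (and therefore under 3% of liability variance).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream

__all__ = [
    "SEXES",
    "PHENOTYPES",
    "DIAGNOSIS_GROUPS",
    "DEFAULT_PREVALENCE",
    "ParameterError",
    "AscertainmentError",
    "LiabilityParams",
    "Individual",
    "Cohort",
    "calibrate_thresholds",
    "assign_diagnosis_group",
    "diagnosis_groups",
    "simulate_registry",
    "simulate_trio_cohort",
    "simulate_unascertained_trios",
    "trios_from_cohort",
]

SEXES = ("M", "F")
PHENOTYPES = ("ASD", "ID")
DIAGNOSIS_GROUPS = ("ASDnoID", "ASDandID", "IDnoASD", "none")

#: Default lifetime diagnosis fractions per (phenotype, sex).  The ASD values
#: encode a ~3.6:1 male:female ratio; the ID values a milder male excess.
DEFAULT_PREVALENCE: Mapping[tuple[str, str], float] = {
    ("ASD", "M"): 0.02,
    ("ASD", "F"): 0.0055,
    ("ID", "M"): 0.015,
    ("ID", "F"): 0.010,
}

#: Variance of the true common component explained by the observed score.
DEFAULT_SCORE_R2 = 0.05

#: Default distribution of children per family (two or more, registry-style).
DEFAULT_CHILDREN_DIST: Mapping[int, float] = {2: 0.55, 3: 0.30, 4: 0.11, 5: 0.04}

DEFAULT_BIRTH_YEARS = (1981, 2005)


class ParameterError(ValueError):
    """Invalid simulation parameters."""


class AscertainmentError(RuntimeError):
    """Rejection sampling cannot satisfy the requested family constraints."""


def calibrate_thresholds(prevalence_by_sex: Mapping[str, float]) -> dict[str, float]:
    """Map per-sex prevalences to liability thresholds.

    The threshold ``T`` for a sex with prevalence ``K`` satisfies
    ``P(Z > T) = K`` for standard-normal ``Z``; lower prevalence means a
    higher threshold, which is how a female-protective effect is encoded.
    """
    out: dict[str, float] = {}
    for sex, prev in prevalence_by_sex.items():
        if not (0.0 < prev < 1.0):
            raise ParameterError(f"prevalence for sex {sex!r} must be in (0, 1), got {prev}")
        out[sex] = float(stats.norm.isf(prev))
    return out


@dataclass(frozen=True)
class LiabilityParams:
    """Parameters of the liability-threshold family model.

    Parameters
    ----------
    h2_common:
        Fraction of founder liability variance from the common (transmitted)
        polygenic component.  Default 0.65, mid-range of family/twin additive
        heritability estimates for ASD liability.
    dnv_rate:
        Per-child probability of carrying a high-impact de novo variant.
    dnv_effect:
        Liability shift (in liability SD units) added to both phenotypes for
        de novo carriers.  The default pair (0.01, 1.5) yields roughly one in
        eight male cases and one in five female cases carrying such a variant,
        in line with published exome studies of autism cohorts.
    rg_asd_id:
        Correlation between the ASD and ID common polygenic components.
    prevalence:
        Mapping (phenotype, sex) -> lifetime diagnosis fraction; converted to
        thresholds via :func:`calibrate_thresholds` unless explicit
        ``thresholds`` are supplied.
    thresholds:
        Optional explicit mapping (phenotype, sex) -> liability threshold.
    score_noise_sd:
        SD of the observation noise added to the true common component to form
        the observed score.  ``None`` sizes it so that the score explains
        ``DEFAULT_SCORE_R2`` of the common-component variance.
    seed:
        Root seed; every stage derives a named substream from it.
    """

    h2_common: float = 0.65
    dnv_rate: float = 0.01
    dnv_effect: float = 1.5
    rg_asd_id: float = 0.0
    prevalence: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    thresholds: Mapping[tuple[str, str], float] | None = None
    score_noise_sd: float | None = None
    seed: int = 1234

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_common <= 1.0):
            raise ParameterError(f"h2_common must be in [0, 1], got {self.h2_common}")
        if not (0.0 <= self.dnv_rate <= 1.0):
            raise ParameterError(f"dnv_rate must be in [0, 1], got {self.dnv_rate}")
        if not abs(self.rg_asd_id) <= 1.0:
            raise ParameterError(f"|rg_asd_id| must be <= 1, got {self.rg_asd_id}")
        if self.thresholds is None:
            for (pheno, sex), prev in self.prevalence.items():
                if not (0.0 < prev < 1.0):
                    raise ParameterError(
                        f"prevalence[{pheno}, {sex}] must be in (0, 1), got {prev}"
                    )
        else:
            for key, thr in self.thresholds.items():
                if math.isnan(thr):
                    raise ParameterError(f"threshold {key} is NaN")
        if self.score_noise_sd is not None and self.score_noise_sd < 0:
            raise ParameterError("score_noise_sd must be >= 0")

    def threshold_map(self) -> dict[tuple[str, str], float]:
        """Liability thresholds per (phenotype, sex)."""
        if self.thresholds is not None:
            return dict(self.thresholds)
        out: dict[tuple[str, str], float] = {}
        for pheno in PHENOTYPES:
            by_sex = {s: self.prevalence[(pheno, s)] for s in SEXES}
            for s, t in calibrate_thresholds(by_sex).items():
                out[(pheno, s)] = t
        return out

    def noise_sd(self) -> float:
        """Observation-noise SD for the observed polygenic score."""
        if self.score_noise_sd is not None:
            return float(self.score_noise_sd)
        if self.h2_common == 0:
            return 1.0
        return float(np.sqrt(self.h2_common * (1.0 / DEFAULT_SCORE_R2 - 1.0)))


@dataclass(frozen=True)
class Individual:
    """A single simulated person (convenience view onto a cohort row)."""

    iid: int
    fid: int
    father: int | None
    mother: int | None
    sex: str
    birth_year: int
    role: str
    pgs_true: float
    pgs_obs: float
    dnv_carrier: bool
    liab_asd: float
    liab_id: float
    diagnoses: frozenset[str]


class Cohort:
    """A simulated population: individuals plus a family index.

    The table is indexed by individual id and holds, per person: family links,
    sex, birth year, role, the true and observed polygenic scores, de novo
    carrier status, both liabilities, both diagnoses, and the derived
    mutually exclusive diagnosis group.
    """

    def __init__(self, df: pd.DataFrame, params: LiabilityParams, seed: int, meta: dict | None = None):
        self.df = df
        self.params = params
        self.seed = seed
        self.meta = dict(meta or {})
        self._family_index: dict | None = None

    def __len__(self) -> int:
        return len(self.df)

    def children(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "offspring"]

    def founders(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "founder"]

    @property
    def family_index(self) -> dict:
        """fid -> integer positions of all members of that family."""
        if self._family_index is None:
            self._family_index = self.df.groupby("fid", sort=False).indices
        return self._family_index

    def family_members(self, fid: int) -> pd.DataFrame:
        return self.df.iloc[self.family_index[fid]]

    def individual(self, iid: int) -> Individual:
        row = self.df.loc[iid]
        diags = frozenset(
            p for p, flag in (("ASD", row["dx_asd"]), ("ID", row["dx_id"])) if flag
        )
        father = int(row["father"]) if row["father"] >= 0 else None
        mother = int(row["mother"]) if row["mother"] >= 0 else None
        return Individual(
            iid=int(row["iid"]),
            fid=int(row["fid"]),
            father=father,
            mother=mother,
            sex=str(row["sex"]),
            birth_year=int(row["birth_year"]),
            role=str(row["role"]),
            pgs_true=float(row["pgs_true"]),
            pgs_obs=float(row["pgs_obs"]),
            dnv_carrier=bool(row["dnv"]),
            liab_asd=float(row["liab_asd"]),
            liab_id=float(row["liab_id"]),
            diagnoses=diags,
        )


def assign_diagnosis_group(x) -> str:
    """Collapse a diagnosis set into one of the four outcome classes.

    Accepts a set of diagnosis names, an :class:`Individual`, or a cohort row
    carrying ``dx_asd`` / ``dx_id`` flags.
    """
    if isinstance(x, Individual):
        diags = x.diagnoses
    elif isinstance(x, (set, frozenset)):
        diags = x
    else:  # pandas row
        diags = {p for p, flag in (("ASD", x["dx_asd"]), ("ID", x["dx_id"])) if flag}
    has_asd = "ASD" in diags
    has_id = "ID" in diags
    if has_asd and has_id:
        return "ASDandID"
    if has_asd:
        return "ASDnoID"
    if has_id:
        return "IDnoASD"
    return "none"


def diagnosis_groups(df: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`assign_diagnosis_group` over a cohort table."""
    asd = df["dx_asd"].to_numpy()
    idd = df["dx_id"].to_numpy()
    return np.select(
        [asd & idd, asd & ~idd, ~asd & idd],
        ["ASDandID", "ASDnoID", "IDnoASD"],
        default="none",
    )


def _common_chol(rg: float) -> np.ndarray:
    """Cholesky-like factor of the 2x2 correlation of the common components."""
    if abs(rg) >= 1.0:
        return np.array([[1.0, 0.0], [rg, 0.0]])
    return np.linalg.cholesky(np.array([[1.0, rg], [rg, 1.0]]))


def _thresholds_by_sex(params: LiabilityParams, male: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = params.threshold_map()
    t_asd = np.where(male, t[("ASD", "M")], t[("ASD", "F")])
    t_id = np.where(male, t[("ID", "M")], t[("ID", "F")])
    return t_asd, t_id


_COLUMNS = [
    "iid", "fid", "father", "mother", "sex", "birth_year", "role",
    "pgs_true", "pgs_true_id", "pgs_obs", "dnv",
    "liab_asd", "liab_id", "dx_asd", "dx_id", "dgroup",
]


def _assemble(
    params: LiabilityParams,
    *,
    iid, fid, father, mother, male, birth_year, role,
    g, e, dnv,
) -> pd.DataFrame:
    liab = g + e
    liab[:, 0] += dnv * params.dnv_effect
    liab[:, 1] += dnv * params.dnv_effect
    t_asd, t_id = _thresholds_by_sex(params, male)
    dx_asd = liab[:, 0] > t_asd
    dx_id = liab[:, 1] > t_id
    df = pd.DataFrame(
        {
            "iid": iid.astype(np.int64),
            "fid": fid.astype(np.int64),
            "father": father.astype(np.int64),
            "mother": mother.astype(np.int64),
            "sex": pd.Categorical(np.where(male, "M", "F"), categories=list(SEXES)),
            "birth_year": birth_year.astype(np.int32),
            "role": pd.Categorical(role, categories=["founder", "offspring"]),
            "pgs_true": g[:, 0],
            "pgs_true_id": g[:, 1],
            "pgs_obs": np.nan,  # filled by caller after pooling
            "dnv": dnv.astype(bool),
            "liab_asd": liab[:, 0],
            "liab_id": liab[:, 1],
            "dx_asd": dx_asd,
            "dx_id": dx_id,
        }
    )
    df["dgroup"] = pd.Categorical(diagnosis_groups(df), categories=list(DIAGNOSIS_GROUPS))
    return df


def _draw_families(
    params: LiabilityParams,
    n_families: int,
    sizes: np.ndarray,
    rng: np.random.Generator,
    birth_year_range: tuple[int, int],
    fid_offset: int = 0,
    iid_offset: int = 0,
) -> pd.DataFrame:
    """Draw founder couples and their children, vectorized.

    Fathers get iids ``offset + 2k``, mothers ``offset + 2k + 1``; children
    follow after all founders.
    """
    h2 = params.h2_common
    L = _common_chol(params.rg_asd_id)
    nf = 2 * n_families
    nc = int(sizes.sum())

    g_f = math.sqrt(h2) * rng.standard_normal((nf, 2)) @ L.T
    e_f = math.sqrt(1.0 - h2) * rng.standard_normal((nf, 2))

    fam = np.arange(n_families)
    rep = np.repeat(fam, sizes)
    g_dad = g_f[0::2]
    g_mom = g_f[1::2]
    midparent = 0.5 * (g_dad + g_mom)
    seg = math.sqrt(h2 / 2.0) * rng.standard_normal((nc, 2)) @ L.T
    g_c = midparent[rep] + seg
    e_c = math.sqrt(1.0 - h2) * rng.standard_normal((nc, 2))
    dnv_c = rng.random(nc) < params.dnv_rate

    y0, y1 = birth_year_range
    child_years = rng.integers(y0, y1 + 1, size=nc)
    founder_years = rng.integers(y0 - 40, y0 - 19, size=nf)

    # ids start at 1: 0 is the FAM-dialect "missing parent" code
    founder_iid = 1 + iid_offset + np.arange(nf)
    child_iid = 1 + iid_offset + nf + np.arange(nc)
    father_iid = founder_iid[0::2]
    mother_iid = founder_iid[1::2]

    founders = _assemble(
        params,
        iid=founder_iid,
        fid=fid_offset + np.repeat(fam, 2),
        father=np.full(nf, -1),
        mother=np.full(nf, -1),
        male=np.tile([True, False], n_families),
        birth_year=founder_years,
        role=np.full(nf, "founder"),
        g=g_f,
        e=e_f,
        dnv=np.zeros(nf, dtype=bool),
    )
    children = _assemble(
        params,
        iid=child_iid,
        fid=fid_offset + rep,
        father=father_iid[rep],
        mother=mother_iid[rep],
        male=rng.random(nc) < 0.5,
        birth_year=child_years,
        role=np.full(nc, "offspring"),
        g=g_c,
        e=e_c,
        dnv=dnv_c,
    )
    df = pd.concat([founders, children], ignore_index=True)
    return df


def _finalize(df: pd.DataFrame, params: LiabilityParams, seed: int, rng: np.random.Generator, meta: dict) -> Cohort:
    df = df.reset_index(drop=True)
    df["pgs_obs"] = df["pgs_true"].to_numpy() + params.noise_sd() * rng.standard_normal(len(df))
    df.index = pd.Index(df["iid"].to_numpy(), name="iid_index")
    return Cohort(df, params, seed, meta)


def simulate_registry(
    params: LiabilityParams,
    n_families: int,
    birth_year_range: tuple[int, int] = DEFAULT_BIRTH_YEARS,
    children_dist: Mapping[int, float] | None = None,
    seed: int | None = None,
) -> Cohort:
    """Simulate a registry-style population of multi-child families.

    Every family is a founder couple plus children drawn from
    ``children_dist`` (default: two to five children, registry-style
    two-plus-sibling families).  Children's birth years are uniform over
    ``birth_year_range``.  Deterministic given the seed.
    """
    if n_families < 1:
        raise ParameterError("n_families must be >= 1")
    dist = dict(children_dist or DEFAULT_CHILDREN_DIST)
    ks = np.array(list(dist.keys()))
    ps = np.array(list(dist.values()), dtype=float)
    if np.any(ps < 0) or not math.isclose(ps.sum(), 1.0, rel_tol=1e-9):
        raise ParameterError("children_dist probabilities must be nonnegative and sum to 1")
    root = params.seed if seed is None else seed
    rng = substream(root, "registry")
    sizes = rng.choice(ks, p=ps, size=n_families)
    df = _draw_families(params, n_families, sizes, rng, birth_year_range)
    meta = {"kind": "registry", "n_families": n_families, "birth_year_range": birth_year_range}
    return _finalize(df, params, root, rng, meta)


def simulate_trio_cohort(
    params: LiabilityParams,
    n_families: int,
    children_per_family: int = 2,
    require_unaffected_parents: bool = True,
    require_unaffected_sibling: bool = False,
    ascertainment_floor: float = 1e-6,
    max_candidates: int | None = None,
    birth_year_range: tuple[int, int] = DEFAULT_BIRTH_YEARS,
    seed: int | None = None,
) -> Cohort:
    """Rejection-sample an ascertained trio/quad cohort.

    Families are kept when they contain at least one ASD-affected child and
    satisfy the requested screening constraints (unaffected parents, an
    unaffected sibling).  Among each kept family's affected children one is
    marked as the designated proband (``is_proband``, uniform at random); the
    oldest unaffected child, if any, is marked ``is_designated_sibling``.

    Raises :class:`AscertainmentError` when the empirical acceptance
    probability falls below ``ascertainment_floor``.
    """
    root = params.seed if seed is None else seed
    rng = substream(root, "trios")
    k = int(children_per_family)
    if k < 1:
        raise ParameterError("children_per_family must be >= 1")
    if require_unaffected_sibling and k < 2:
        raise ParameterError("require_unaffected_sibling needs >= 2 children per family")

    meta = {
        "kind": "trio",
        "n_families": n_families,
        "children_per_family": k,
        "require_unaffected_parents": require_unaffected_parents,
        "require_unaffected_sibling": require_unaffected_sibling,
    }
    empty_meta = dict(meta, candidates_tried=0)
    if n_families == 0:
        df = _draw_families(params, 1, np.array([k]), rng, birth_year_range).iloc[0:0]
        return _finalize(df, params, root, rng, empty_meta)

    if max_candidates is None:
        max_candidates = max(1_000_000, 500 * n_families)

    kept: list[pd.DataFrame] = []
    accepted = 0
    tried = 0
    chunk = min(max(20_000, 5 * n_families), 250_000)
    fid_offset = 0
    iid_offset = 0
    while accepted < n_families:
        m = min(chunk, max_candidates - tried)
        if m <= 0:
            _raise_ascertainment(meta, accepted, tried)
        sizes = np.full(m, k)
        df = _draw_families(
            params, m, sizes, rng, birth_year_range,
            fid_offset=fid_offset, iid_offset=iid_offset,
        )
        fid_offset += m
        iid_offset += m * (2 + k)
        tried += m

        ch = df[df["role"] == "offspring"]
        aff = ch["dx_asd"].to_numpy().reshape(m, k)
        ok = aff.any(axis=1)
        if require_unaffected_sibling:
            ok &= (~aff).any(axis=1)
        if require_unaffected_parents:
            par_aff = df[df["role"] == "founder"]["dx_asd"].to_numpy().reshape(m, 2)
            ok &= ~par_aff.any(axis=1)
        good = np.flatnonzero(ok)
        if good.size:
            take = good[: n_families - accepted]
            # proband: uniform among affected children; designee: oldest unaffected
            years = ch["birth_year"].to_numpy().reshape(m, k)
            u = rng.random((m, k))
            prob_idx = np.argmax(aff.astype(float) * 2.0 + u, axis=1)
            sib_key = np.where(~aff, (3000.0 - years) + u, -np.inf)
            sib_idx = np.argmax(sib_key, axis=1)
            has_unaff = (~aff).any(axis=1)

            child_iids = ch["iid"].to_numpy().reshape(m, k)
            proband_iids = child_iids[take, prob_idx[take]]
            sib_take = take[has_unaff[take]]
            sib_iids = child_iids[sib_take, sib_idx[sib_take]]

            keep_fids = take + (fid_offset - m)
            sub = df[np.isin(df["fid"].to_numpy(), keep_fids)].copy()
            sub["is_proband"] = sub["iid"].isin(proband_iids)
            sub["is_designated_sibling"] = sub["iid"].isin(sib_iids)
            kept.append(sub)
            accepted += take.size
        if tried >= max_candidates and accepted < n_families:
            _raise_ascertainment(meta, accepted, tried)
        if tried >= 200_000 and accepted / tried < ascertainment_floor:
            _raise_ascertainment(meta, accepted, tried)

    df = pd.concat(kept, ignore_index=True)
    meta = dict(meta, candidates_tried=tried)
    return _finalize(df, params, root, rng, meta)


def _raise_ascertainment(meta: dict, accepted: int, tried: int) -> None:
    constraints = ["at least one ASD-affected child"]
    if meta["require_unaffected_parents"]:
        constraints.append("two unaffected parents")
    if meta["require_unaffected_sibling"]:
        constraints.append("an unaffected sibling")
    raise AscertainmentError(
        f"ascertainment did not converge: {accepted} families accepted out of "
        f"{tried} candidates under constraints: {', '.join(constraints)}"
    )


TRIO_COLUMNS = [
    "fid", "child_iid", "mother_iid", "father_iid",
    "child_score", "mother_score", "father_score",
    "sex", "affected", "dnv",
]


def trios_from_cohort(
    cohort: Cohort,
    members: str = "probands",
    score: str = "pgs_obs",
) -> pd.DataFrame:
    """Build a trio score table (one row per child) from a family cohort.

    ``members`` selects which children become trio rows: ``"probands"``
    (designated affected child per family), ``"designated_siblings"`` (oldest
    unaffected child), or ``"all_children"``.  ``score`` names the cohort
    column used as the polygenic score for all three members.
    """
    df = cohort.df
    ch = df[df["role"] == "offspring"]
    if members == "probands":
        if "is_proband" in ch.columns:
            ch = ch[ch["is_proband"]]
        else:
            ch = ch[ch["dx_asd"]]
    elif members == "designated_siblings":
        if "is_designated_sibling" not in ch.columns:
            raise ValueError("cohort has no designated siblings (not an ascertained trio cohort)")
        ch = ch[ch["is_designated_sibling"]]
    elif members != "all_children":
        raise ValueError(f"unknown members selector: {members!r}")
    score_by_iid = df[score]
    out = pd.DataFrame(
        {
            "fid": ch["fid"].to_numpy(),
            "child_iid": ch["iid"].to_numpy(),
            "mother_iid": ch["mother"].to_numpy(),
            "father_iid": ch["father"].to_numpy(),
            "child_score": ch[score].to_numpy(),
            "mother_score": score_by_iid.loc[ch["mother"]].to_numpy(),
            "father_score": score_by_iid.loc[ch["father"]].to_numpy(),
            "sex": ch["sex"].astype(str).to_numpy(),
            "affected": ch["dx_asd"].to_numpy(),
            "dnv": ch["dnv"].to_numpy(),
        }
    )
    return out


def simulate_unascertained_trios(
    params: LiabilityParams,
    n_trios: int,
    seed: int | None = None,
    score: str = "observed",
) -> pd.DataFrame:
    """Simulate parent-child trios with no ascertainment whatsoever.

    Under this null the child's score deviation from the mid-parent mean has
    expectation exactly zero; used for transmission-test calibration.
    """
    root = params.seed if seed is None else seed
    rng = substream(root, "null-trios")
    h2 = params.h2_common
    L = _common_chol(params.rg_asd_id)
    g_dad = math.sqrt(h2) * rng.standard_normal((n_trios, 2)) @ L.T
    g_mom = math.sqrt(h2) * rng.standard_normal((n_trios, 2)) @ L.T
    g_child = 0.5 * (g_dad + g_mom) + math.sqrt(h2 / 2.0) * rng.standard_normal((n_trios, 2)) @ L.T
    e_child = math.sqrt(1.0 - h2) * rng.standard_normal(n_trios)
    dnv = rng.random(n_trios) < params.dnv_rate
    male = rng.random(n_trios) < 0.5
    liab = g_child[:, 0] + e_child + dnv * params.dnv_effect
    t_asd, _ = _thresholds_by_sex(params, male)
    noise = params.noise_sd()
    if score == "observed":
        obs = lambda g: g + noise * rng.standard_normal(n_trios)  # noqa: E731
    elif score == "true":
        obs = lambda g: g  # noqa: E731
    else:
        raise ValueError("score must be 'observed' or 'true'")
    return pd.DataFrame(
        {
            "fid": np.arange(n_trios),
            "child_iid": np.arange(n_trios),
            "mother_iid": -np.ones(n_trios, dtype=int),
            "father_iid": -np.ones(n_trios, dtype=int),
            "child_score": obs(g_child[:, 0]),
            "mother_score": obs(g_mom[:, 0]),
            "father_score": obs(g_dad[:, 0]),
            "sex": np.where(male, "M", "F"),
            "affected": liab > t_asd,
            "dnv": dnv,
        }
    )
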