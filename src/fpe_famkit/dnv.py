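"""High-impact de novo variant classification.

A de novo variant counts as high impact when it falls in one of three
classes: (1) a protein-truncating variant (PTV) in a gene intolerant of
heterozygous loss of function (pLI strictly greater than 0.9); (2) a copy
number variant (deletion or duplication) affecting at least one such
constrained gene; (3) a missense variant with an MPC score of at least 2.
Inherited variants never qualify.  Constraint annotations (pLI, MPC,
constrained-gene overlap counts) are inputs; no gene database is consulted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_CLASSES",
    "ValidationError",
    "VariantRecord",
    "is_high_impact",
    "classify_variants",
    "flag_carriers",
]

VARIANT_CLASSES = ("PTV", "missense", "CNV-del", "CNV-dup", "other")

PLI_THRESHOLD = 0.9  # strict: pLI must exceed this
MPC_THRESHOLD = 2.0  # inclusive: MPC >= 2 qualifies


class ValidationError(ValueError):
    """Malformed variant record."""


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant carried by one sample.

    ``mpc`` is meaningful for missense variants only and
    ``constrained_genes_hit`` for CNVs only; supplying either on the wrong
    class is a validation error rather than silently ignored annotation.
    """

    sample_id: str
    gene: str
    var_class: str
    de_novo: bool
    pli: float | None = None
    mpc: float | None = None
    constrained_genes_hit: int | None = None

    def __post_init__(self) -> None:
        if self.var_class not in VARIANT_CLASSES:
            raise ValidationError(f"unknown variant class {self.var_class!r}")
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValidationError(f"pLI must be in [0, 1], got {self.pli}")
        if self.mpc is not None:
            if self.var_class != "missense":
                raise ValidationError("MPC score is only defined for missense variants")
            if self.mpc < 0:
                raise ValidationError(f"MPC must be >= 0, got {self.mpc}")
        if self.constrained_genes_hit is not None:
            if self.var_class not in ("CNV-del", "CNV-dup"):
                raise ValidationError("constrained_genes_hit is only defined for CNVs")
            if self.constrained_genes_hit < 0:
                raise ValidationError("constrained_genes_hit must be >= 0")


def is_high_impact(v: VariantRecord) -> bool:
    """True iff the variant is de novo and falls in a high-impact class."""
    if not v.de_novo:
        return False
    if v.var_class == "PTV":
        return v.pli is not None and v.pli > PLI_THRESHOLD
    if v.var_class in ("CNV-del", "CNV-dup"):
        return v.constrained_genes_hit is not None and v.constrained_genes_hit >= 1
    if v.var_class == "missense":
        return v.mpc is not None and v.mpc >= MPC_THRESHOLD
    return False


def _records_from_table(df: pd.DataFrame) -> list[VariantRecord]:
    def opt(v):
        return None if pd.isna(v) else v

    return [
        VariantRecord(
            sample_id=str(r["sample_id"]),
            gene=str(r["gene"]),
            var_class=str(r["var_class"]),
            de_novo=bool(r["de_novo"]),
            pli=opt(r.get("pli")),
            mpc=opt(r.get("mpc")),
            constrained_genes_hit=(
                None if pd.isna(r.get("constrained_genes_hit"))
                else int(r["constrained_genes_hit"])
            ),
        )
        for _, r in df.iterrows()
    ]


def classify_variants(variants: pd.DataFrame | Iterable[VariantRecord]) -> pd.Series:
    """High-impact flag per variant (order-preserving, deterministic)."""
    if isinstance(variants, pd.DataFrame):
        records = _records_from_table(variants)
        return pd.Series(
            [is_high_impact(v) for v in records], index=variants.index, name="high_impact"
        )
    return pd.Series([is_high_impact(v) for v in variants], name="high_impact")


def flag_carriers(
    variants: pd.DataFrame | Iterable[VariantRecord],
    samples: Sequence[str],
) -> pd.Series:
    """Carrier flag per sample: at least one high-impact de novo variant.

    Samples with no variant records are non-carriers; extra records never
    un-flag a carrier (monotone in the record set).
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("sample ids must be unique")
    if isinstance(variants, pd.DataFrame):
        hits = variants.loc[classify_variants(variants).to_numpy(), "sample_id"].astype(str)
        carrier_ids = set(hits)
    else:
        carrier_ids = {v.sample_id for v in variants if is_high_impact(v)}
    return pd.Series(
        np.array([s in carrier_ids for s in samples]),
        index=pd.Index(samples, name="sample_id"),
        name="carrier",
    )
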