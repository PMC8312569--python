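"""Instrument selection (significance filter + LD clumping) and strength
diagnostics (per-variant F statistics and variance explained)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .harmonize import HarmonizedVariant
from .sumstats_io import LDMatrix

logger = logging.getLogger("ivmr")

GENOME_WIDE_SIGNIFICANCE = 5e-8
DEFAULT_R2_MAX = 0.01
DEFAULT_WINDOW_BP = 500_000


def significance_filter(variants: Sequence, threshold: float = GENOME_WIDE_SIGNIFICANCE):
    """Retain exactly the variants with p-value strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValidationError(f"p-value threshold {threshold} outside (0, 1]")
    kept = [v for v in variants if v.pval < threshold]
    logger.info(
        "significance_filter: %d/%d variants at p < %g", len(kept), len(variants), threshold
    )
    return kept


def clump(
    variants: Sequence,
    ld: LDMatrix,
    r2_max: float = DEFAULT_R2_MAX,
    window_bp: int = DEFAULT_WINDOW_BP,
):
    """Greedy LD clumping: keep the most significant variant per region.

    Repeatedly accept the remaining variant with the smallest p-value (ties
    broken by ascending chrom, pos) as an index variant, then discard every
    remaining variant on the same chromosome within ±``window_bp`` whose
    squared correlation with the index is >= ``r2_max``; retained pairs
    therefore satisfy r² < r2_max within the window. Cross-chromosome LD is
    ignored. Output preserves genomic order.

    Works on any records exposing ``variant_id, chrom, pos, pval``
    (pre-harmonization associations or harmonized variants alike). A variant
    absent from ``ld``, or a within-window LD entry that is NaN, is an error.
    """
    for v in variants:
        if v.variant_id not in ld:
            raise ValidationError(f"variant {v.variant_id!r} absent from LD matrix")

    remaining = sorted(variants, key=lambda v: (v.pval, str(v.chrom), v.pos))
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for v in remaining:
            if v.chrom == index.chrom and abs(v.pos - index.pos) <= window_bp:
                r = ld.correlation(index.variant_id, v.variant_id)
                if math.isnan(r):
                    raise ValidationError(
                        f"missing LD entry for {index.variant_id!r}/{v.variant_id!r} "
                        "within the clumping window"
                    )
                if r * r >= r2_max:
                    continue
            survivors.append(v)
        remaining = survivors
    kept.sort(key=lambda v: (str(v.chrom), v.pos))
    logger.info("clump: %d index variant(s) from %d", len(kept), len(variants))
    return kept


def _effect_and_se(v) -> tuple[float, float]:
    if isinstance(v, HarmonizedVariant):
        return v.gamma, v.se_x
    return v.beta, v.se


def f_statistic(v) -> float:
    """Per-variant instrument strength F_j = (γ_j/σ_Xj)², the squared z."""
    beta, se = _effect_and_se(v)
    if se <= 0:
        raise ValidationError(f"non-positive SE for {v.variant_id!r}")
    return (beta / se) ** 2


def variance_explained(v, formula: str = "auto") -> float:
    """Fraction of trait variance explained by one variant.

    Formula ``"eaf"`` (valid for a trait standardized to unit variance):
    r²_j = 2·eaf·(1−eaf)·γ_j². Formula ``"f"`` (fallback when no frequency
    is available, e.g. a liability-scale binary trait): r²_j = F_j/(F_j+n−2).
    ``"auto"`` prefers the frequency formula, falling back to the F-based
    one; an error is raised only when neither is computable.
    """
    beta, _ = _effect_and_se(v)
    eaf = getattr(v, "eaf", None)
    n = getattr(v, "n", math.nan)
    has_eaf = eaf is not None and not (isinstance(eaf, float) and math.isnan(eaf))
    has_n = n is not None and not math.isnan(n) and n > 2
    if formula == "eaf" or (formula == "auto" and has_eaf):
        if not has_eaf:
            raise ValidationError(f"no eaf for {v.variant_id!r}; cannot use eaf formula")
        return 2.0 * eaf * (1.0 - eaf) * beta * beta
    if formula in ("f", "auto"):
        if not has_n:
            raise ValidationError(
                f"variant {v.variant_id!r}: neither eaf nor usable n available"
            )
        f = f_statistic(v)
        return f / (f + n - 2.0)
    raise ValidationError(f"unknown variance_explained formula {formula!r}")


@dataclass
class InstrumentSet:
    """Selected instruments with per-variant strength diagnostics."""

    variants: list[HarmonizedVariant]
    f_stats: np.ndarray
    r2: np.ndarray
    total_r2: float = field(init=False)

    def __post_init__(self) -> None:
        self.f_stats = np.asarray(self.f_stats, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.total_r2 = float(np.sum(self.r2))

    def __len__(self) -> int:
        return len(self.variants)


def build_instrument_set(variants: Sequence[HarmonizedVariant]) -> InstrumentSet:
    f = np.array([f_statistic(v) for v in variants])
    r2 = np.array([variance_explained(v) for v in variants])
    return InstrumentSet(variants=list(variants), f_stats=f, r2=r2)


def diagnostics_table(variants: Sequence[HarmonizedVariant]) -> pd.DataFrame:
    """Per-variant diagnostics: p, F, and both variance-explained formulas."""
    rows = []
    for v in variants:
        try:
            r2_a = variance_explained(v, formula="eaf")
        except ValidationError:
            r2_a = math.nan
        try:
            r2_b = variance_explained(v, formula="f")
        except ValidationError:
            r2_b = math.nan
        rows.append(
            {
                "variant_id": v.variant_id,
                "pval": v.pval,
                "F": f_statistic(v),
                "r2_formula_A": r2_a,
                "r2_formula_B": r2_b,
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "pval", "F", "r2_formula_A", "r2_formula_B"]
    )
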