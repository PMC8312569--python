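"""Allele harmonization of exposure and outcome associations.

Two-sample MR needs, for every shared variant j, the pair of effects
(γ_j ± σ_Xj on the exposure, Γ_j ± σ_Yj on the outcome) expressed for the
*same* effect allele. The outcome study may report the other allele, the
opposite strand, or both; harmonization detects the orientation from the
allele labels (and, for palindromic A/T and C/G variants, from allele
frequencies) and flips the outcome beta where needed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .exceptions import ValidationError
from .sumstats_io import VariantAssociation

logger = logging.getLogger("ivmr")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PalindromicPolicy = Literal["drop", "infer_by_eaf"]

#: EAF band within which a palindromic variant's strand cannot be inferred
DEFAULT_AMBIGUITY_BAND: tuple[float, float] = (0.42, 0.58)


@dataclass
class HarmonizedVariant:
    """An exposure/outcome effect pair aligned to a common effect allele.

    ``gamma``/``se_x`` are the variant-exposure effect and SE, ``Gamma``/
    ``se_y`` the variant-outcome ones. ``pval`` and ``n`` are carried over
    from the exposure record (instrument selection and strength diagnostics
    need them); ``eaf`` is the shared effect-allele frequency.
    """

    variant_id: str
    gamma: float
    se_x: float
    Gamma: float
    se_y: float
    chrom: str = ""
    pos: int = 0
    pval: float = math.nan
    n: float = math.nan
    eaf: float | None = None
    palindromic: bool = False


def _complement_allele(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in allele)
    except KeyError:
        return None


def is_palindromic(ea: str, oa: str) -> bool:
    """True for single-base variants whose alleles are strand-complementary."""
    return len(ea) == 1 == len(oa) and _COMPLEMENT.get(ea) == oa


def _check_unique(records: Sequence[VariantAssociation], label: str) -> dict:
    by_id: dict[str, VariantAssociation] = {}
    for r in records:
        if r.variant_id in by_id:
            raise ValidationError(
                f"duplicate variant_id {r.variant_id!r} in {label} input"
            )
        by_id[r.variant_id] = r
    return by_id


def _orient_nonpalindromic(exp: VariantAssociation, out: VariantAssociation):
    """Return +1 (same allele), -1 (swapped) or None (incompatible).

    Tries the labels as given, then their strand complement; exactly one
    orientation can match because the variant is not palindromic.
    """
    pairs = [(out.effect_allele, out.other_allele)]
    cea, coa = _complement_allele(out.effect_allele), _complement_allele(out.other_allele)
    if cea is not None and coa is not None:
        pairs.append((cea, coa))
    for ea, oa in pairs:
        if (ea, oa) == (exp.effect_allele, exp.other_allele):
            return 1
        if (ea, oa) == (exp.other_allele, exp.effect_allele):
            return -1
    return None


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindromic_policy: PalindromicPolicy = "infer_by_eaf",
    ambiguity_band: tuple[float, float] = DEFAULT_AMBIGUITY_BAND,
) -> tuple[list[HarmonizedVariant], list[tuple[str, str]]]:
    """Align outcome effects to the exposure's effect alleles.

    Returns the harmonized variants (in exposure order) and an exclusion
    report of ``(variant_id, reason)`` pairs covering every exposure variant
    that was not harmonized. Reasons: ``missing_in_outcome``,
    ``allele_mismatch``, ``palindromic``, ``palindromic_ambiguous``,
    ``indel_mismatch``.

    Palindromic (A/T, C/G) variants cannot be oriented from labels. Under
    ``policy="drop"`` they are always excluded; under ``"infer_by_eaf"`` they
    are aligned by comparing allele frequencies, provided both frequencies
    are known and fall outside ``ambiguity_band``. Indels are matched on
    exact or swapped labels only (no strand logic).
    """
    exp_by_id = _check_unique(exposure, "exposure")
    out_by_id = _check_unique(outcome, "outcome")
    lo, hi = ambiguity_band

    harmonized: list[HarmonizedVariant] = []
    excluded: list[tuple[str, str]] = []
    for vid, exp in exp_by_id.items():
        out = out_by_id.get(vid)
        if out is None:
            excluded.append((vid, "missing_in_outcome"))
            continue

        if exp.is_indel or out.is_indel:
            if (out.effect_allele, out.other_allele) == (
                exp.effect_allele,
                exp.other_allele,
            ):
                sign = 1
            elif (out.effect_allele, out.other_allele) == (
                exp.other_allele,
                exp.effect_allele,
            ):
                sign = -1
            else:
                excluded.append((vid, "indel_mismatch"))
                continue
            harmonized.append(_build(exp, out, sign, palindromic=False))
            continue

        if is_palindromic(exp.effect_allele, exp.other_allele):
            if palindromic_policy == "drop":
                excluded.append((vid, "palindromic"))
                continue
            # labels are uninformative: A/T on one strand reads T/A on the
            # other, so orientation must come from the frequencies.
            if exp.eaf is None or out.eaf is None:
                excluded.append((vid, "palindromic_ambiguous"))
                continue
            if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
                excluded.append((vid, "palindromic_ambiguous"))
                continue
            same_side = (exp.eaf < 0.5) == (out.eaf < 0.5)
            sign = 1 if same_side else -1
            harmonized.append(_build(exp, out, sign, palindromic=True))
            continue

        sign = _orient_nonpalindromic(exp, out)
        if sign is None:
            excluded.append((vid, "allele_mismatch"))
            continue
        harmonized.append(_build(exp, out, sign, palindromic=False))

    if excluded:
        logger.info("harmonize: %d variant(s) excluded", len(excluded))
    return harmonized, excluded


def _build(
    exp: VariantAssociation, out: VariantAssociation, sign: int, palindromic: bool
) -> HarmonizedVariant:
    return HarmonizedVariant(
        variant_id=exp.variant_id,
        gamma=exp.beta,
        se_x=exp.se,
        Gamma=sign * out.beta,
        se_y=out.se,
        chrom=exp.chrom,
        pos=exp.pos,
        pval=exp.pval,
        n=exp.n,
        eaf=exp.eaf,
        palindromic=palindromic,
    )


def wald_ratios(
    variants: Sequence[HarmonizedVariant],
) -> tuple[np.ndarray, np.ndarray, list[HarmonizedVariant], list[tuple[str, str]]]:
    """Per-variant ratio estimates θ̂_j = Γ_j/γ_j with first-order SEs.

    The SE is the leading-order delta approximation s_j = σ_Yj/|γ_j|, which
    treats γ_j as known — the same approximation the IVW weights imply.
    Variants with γ_j = 0 are excluded and reported.

    Returns ``(theta, se, kept_variants, excluded)`` with ``theta``/``se``
    aligned to ``kept_variants``.
    """
    kept: list[HarmonizedVariant] = []
    excluded: list[tuple[str, str]] = []
    theta: list[float] = []
    se: list[float] = []
    for v in variants:
        if v.gamma == 0:
            excluded.append((v.variant_id, "zero_exposure_effect"))
            continue
        kept.append(v)
        theta.append(v.Gamma / v.gamma)
        se.append(v.se_y / abs(v.gamma))
    return np.asarray(theta), np.asarray(se), kept, excluded


def flip_variant(v: HarmonizedVariant) -> HarmonizedVariant:
    """Simultaneous sign-flip of (γ, Γ): re-expresses v for the other allele."""
    return replace(
        v,
        gamma=-v.gamma,
        Gamma=-v.Gamma,
        eaf=None if v.eaf is None else 1 - v.eaf,
    )
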