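"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
continuous exposure GWAS (effects in SD units) in one sample and a
case-control outcome GWAS (effects on the log-odds scale) in a second,
non-overlapping sample, with

* minor-allele frequencies uniform on ``maf_range``;
* true variant-exposure effects with magnitude |N(0, gamma_sd²)|, every
  effect allele coded as the exposure-increasing allele (standard GWAS
  reporting orientation; it is also what makes *directional* pleiotropy
  directional rather than self-cancelling);
* per-variant horizontal pleiotropy α_j — zero for valid instruments,
  N(μ_p, τ_p²) for the invalid fraction (μ_p = 0 under the ``balanced``
  regime) — entering the outcome as Γ_j = θ·γ_j + α_j;
* summary-statistic sampling noise with the standard large-sample SEs
  σ_Xj = 1/sqrt(2 p_j (1−p_j) n_exp) and, for the case-control outcome,
  σ_Yj = 1/sqrt(2 p_j (1−p_j) n_out K(1−K));
* optional block LD: within a block the *sampling errors* are correlated
  with the block's constant r (true effects stay independent across
  variants).

Defaults mirror an African-ancestry two-sample design: exposure GWAS of
~77 000 participants and a stroke case-control GWAS of 3 734 cases and
18 317 controls (K ≈ 0.169). ``gamma_sd = 0.08`` makes most candidate
variants reach genome-wide significance at that exposure sample size with
selected-instrument F statistics in the tens-to-hundreds, the regime of a
well-powered lipid/T2D GWAS.

An individual-level simulator (:func:`empirical_power`) is included as the
oracle for the closed-form power calculation; it is deliberately slower and
independent of the summary-level generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats, special

from .exceptions import ValidationError
from .harmonize import HarmonizedVariant
from .sumstats_io import LDMatrix, VariantAssociation

#: allele pairs that are never palindromic and never complementary-ambiguous
_SAFE_ALLELES = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

_PVAL_FLOOR = 1e-300


@dataclass
class SimScenario:
    """Generative parameters for one synthetic two-sample dataset.

    ``noise`` scales the sampling noise added to the true effects (the
    reported SEs are unaffected); ``noise = 0`` yields observed effects equal
    to the truth, useful for exact-identity tests. ``ld_blocks`` is a list of
    ``(block_size, within_block_r)`` pairs summing to J; ``None`` means all
    variants independent. ``shuffle_alleles`` randomizes the outcome file's
    allele orientation so harmonization is exercised end to end.
    """

    theta: float = 0.2
    J: int = 50
    prop_invalid: float = 0.0
    pleiotropy: Literal["none", "balanced", "directional"] = "none"
    mu_p: float = 0.0
    tau_p: float = 0.02
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma_sd: float = 0.08
    n_exp: float = 77_000
    n_out: float = 22_051
    case_fraction: float = 0.169
    ld_blocks: list[tuple[int, float]] | None = None
    noise: float = 1.0
    shuffle_alleles: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.prop_invalid <= 1:
            raise ValidationError("prop_invalid outside [0, 1]")
        if self.n_exp <= 0 or self.n_out <= 0:
            raise ValidationError("sample sizes must be positive")
        if not 0 < self.case_fraction < 1:
            raise ValidationError("case_fraction outside (0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValidationError("maf_range must lie in (0, 0.5]")
        if self.ld_blocks is not None and sum(b for b, _ in self.ld_blocks) != self.J:
            raise ValidationError("ld_blocks sizes must sum to J")


@dataclass
class SimTruth:
    """Latent values behind one simulated dataset."""

    variant_ids: list[str]
    maf: np.ndarray
    gamma_true: np.ndarray
    alpha_pleio: np.ndarray
    Gamma_true: np.ndarray
    valid: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "maf": self.maf,
                "gamma_true": self.gamma_true,
                "alpha_pleio": self.alpha_pleio,
                "Gamma_true": self.Gamma_true,
                "valid": self.valid.astype(int),
            }
        )


def make_ld_blocks(
    blocks: Sequence[tuple[int, float]], variant_ids: Sequence[str]
) -> LDMatrix:
    """Block-diagonal equicorrelation LD matrix.

    Within each block every pair has the same correlation r; blocks are
    independent. Positive definiteness requires −1/(m−1) < r < 1 for a block
    of size m.
    """
    j = sum(b for b, _ in blocks)
    if j != len(variant_ids):
        raise ValidationError("block sizes do not sum to number of variants")
    r_full = np.zeros((j, j))
    start = 0
    for size, r in blocks:
        if size > 1 and not -1.0 / (size - 1) < r < 1.0:
            raise ValidationError(
                f"equicorrelation r={r} not positive definite for block size {size}"
            )
        r_full[start : start + size, start : start + size] = r
        start += size
    np.fill_diagonal(r_full, 1.0)
    return LDMatrix(variant_ids=list(variant_ids), r=r_full)


def _block_cholesky(blocks: Sequence[tuple[int, float]] | None, j: int):
    """Per-block Cholesky factors for correlated sampling noise."""
    if blocks is None:
        return None
    factors = []
    for size, r in blocks:
        c = np.full((size, size), r)
        np.fill_diagonal(c, 1.0)
        factors.append(np.linalg.cholesky(c))
    return factors


def _correlated_noise(rng, factors, j: int) -> np.ndarray:
    if factors is None:
        return rng.standard_normal(j)
    out = []
    for l in factors:
        out.append(l @ rng.standard_normal(l.shape[0]))
    return np.concatenate(out)


def _pvalue(z: np.ndarray) -> np.ndarray:
    return np.maximum(2 * stats.norm.sf(np.abs(z)), _PVAL_FLOOR)


def _draw_truth(scn: SimScenario, rng: np.random.Generator) -> SimTruth:
    j = scn.J
    maf = rng.uniform(scn.maf_range[0], scn.maf_range[1], size=j)
    gamma = np.abs(rng.normal(0.0, scn.gamma_sd, size=j))
    n_invalid = int(round(scn.prop_invalid * j))
    valid = np.ones(j, dtype=bool)
    if n_invalid > 0:
        invalid_idx = rng.choice(j, size=n_invalid, replace=False)
        valid[invalid_idx] = False
    alpha = np.zeros(j)
    if scn.pleiotropy == "balanced":
        alpha[~valid] = rng.normal(0.0, scn.tau_p, size=n_invalid)
    elif scn.pleiotropy == "directional":
        alpha[~valid] = rng.normal(scn.mu_p, scn.tau_p, size=n_invalid)
    elif scn.pleiotropy != "none" and n_invalid > 0:
        raise ValidationError(f"unknown pleiotropy regime {scn.pleiotropy!r}")
    big_gamma = scn.theta * gamma + alpha
    ids = [f"rs{i + 1}" for i in range(j)]
    return SimTruth(ids, maf, gamma, alpha, big_gamma, valid)


def _positions(scn: SimScenario) -> tuple[list[str], list[int]]:
    """Place variants on chromosome 1: blocks 10 Mb apart, members 10 kb
    apart, so clumping windows contain exactly one block."""
    blocks = scn.ld_blocks if scn.ld_blocks is not None else [(1, 0.0)] * scn.J
    chroms, pos = [], []
    p0 = 10_000_000
    for size, _ in blocks:
        for k in range(size):
            chroms.append("1")
            pos.append(p0 + k * 10_000)
        p0 += 10_000_000
    return chroms, pos


def simulate_harmonized(
    scn: SimScenario,
) -> tuple[list[HarmonizedVariant], LDMatrix, SimTruth]:
    """Fast path: simulate directly to harmonized (allele-aligned) variants.

    Equivalent to :func:`simulate_two_sample` followed by a perfect
    harmonization; used by simulation studies that do not need the file
    dialects.
    """
    scn.validate()
    rng = np.random.default_rng(scn.seed)
    truth = _draw_truth(scn, rng)
    se_x = 1.0 / np.sqrt(2 * truth.maf * (1 - truth.maf) * scn.n_exp)
    k = scn.case_fraction
    se_y = 1.0 / np.sqrt(2 * truth.maf * (1 - truth.maf) * scn.n_out * k * (1 - k))
    factors = _block_cholesky(scn.ld_blocks, scn.J)
    beta_x = truth.gamma_true + scn.noise * se_x * _correlated_noise(rng, factors, scn.J)
    beta_y = truth.Gamma_true + scn.noise * se_y * _correlated_noise(rng, factors, scn.J)
    chroms, pos = _positions(scn)
    pvals = _pvalue(beta_x / se_x)
    ld = make_ld_blocks(
        scn.ld_blocks if scn.ld_blocks is not None else [(1, 0.0)] * scn.J,
        truth.variant_ids,
    )
    variants = [
        HarmonizedVariant(
            variant_id=truth.variant_ids[i],
            gamma=float(beta_x[i]),
            se_x=float(se_x[i]),
            Gamma=float(beta_y[i]),
            se_y=float(se_y[i]),
            chrom=chroms[i],
            pos=pos[i],
            pval=float(pvals[i]),
            n=scn.n_exp,
            eaf=float(truth.maf[i]),
        )
        for i in range(scn.J)
    ]
    return variants, ld, truth


def simulate_two_sample(
    scn: SimScenario,
) -> tuple[list[VariantAssociation], list[VariantAssociation], LDMatrix, SimTruth]:
    """Simulate exposure and outcome summary statistics plus their LD matrix.

    The two files share variants and alleles; when ``shuffle_alleles`` is on,
    each outcome record is re-expressed for the other allele with probability
    1/2 (beta negated, EAF complemented), so downstream harmonization is
    exercised rather than assumed.
    """
    scn.validate()
    harmonized, ld, truth = simulate_harmonized(scn)
    rng = np.random.default_rng([scn.seed, 7])  # allele bookkeeping stream
    exposure: list[VariantAssociation] = []
    outcome: list[VariantAssociation] = []
    for v, maf in zip(harmonized, truth.maf):
        ea, oa = _SAFE_ALLELES[rng.integers(len(_SAFE_ALLELES))]
        eaf = float(maf)
        exposure.append(
            VariantAssociation(
                variant_id=v.variant_id,
                chrom=v.chrom,
                pos=v.pos,
                effect_allele=ea,
                other_allele=oa,
                beta=v.gamma,
                se=v.se_x,
                pval=v.pval,
                n=scn.n_exp,
                eaf=eaf,
            )
        )
        out_beta, out_ea, out_oa, out_eaf = v.Gamma, ea, oa, eaf
        if scn.shuffle_alleles and rng.random() < 0.5:
            out_beta, out_ea, out_oa, out_eaf = -v.Gamma, oa, ea, 1 - eaf
        z = out_beta / v.se_y
        outcome.append(
            VariantAssociation(
                variant_id=v.variant_id,
                chrom=v.chrom,
                pos=v.pos,
                effect_allele=out_ea,
                other_allele=out_oa,
                beta=out_beta,
                se=v.se_y,
                pval=float(_pvalue(np.array([z]))[0]),
                n=scn.n_out,
                eaf=out_eaf,
            )
        )
    return exposure, outcome, ld, truth


def empirical_power(
    or_value: float,
    n_out: float,
    total_r2: float,
    case_fraction: float,
    n_exp: float = 77_000,
    n_reps: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Individual-level rejection rate for a single-instrument MR design.

    Simulates, per replicate, (i) an exposure sample of ``n_exp`` people with
    a standardized genetic score G explaining ``total_r2`` of the exposure,
    and (ii) an independent outcome sample of ``n_out`` people whose disease
    log-odds are logit(K) + log(OR) · sqrt(R²)·G — the causal effect acting
    on the genetically proxied exposure component, the exact structural model
    behind the closed-form power formula. The variant-outcome association is
    tested with the logistic score test; the replicate rejects when the
    two-sided ratio-estimate z exceeds the normal critical value.
    """
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    log_or = math.log(or_value)
    b_g = log_or * math.sqrt(total_r2)  # outcome log-odds per SD of G
    intercept = special.logit(case_fraction)
    n_exp_i, n_out_i = int(n_exp), int(n_out)
    rejections = 0
    for _ in range(n_reps):
        # exposure sample: gamma-hat from OLS of X on G
        g = rng.standard_normal(n_exp_i)
        x = math.sqrt(total_r2) * g + math.sqrt(1 - total_r2) * rng.standard_normal(n_exp_i)
        gg = float(g @ g)
        gamma_hat = float(g @ x) / gg
        # outcome sample: logistic score test of Y on G
        g2 = rng.standard_normal(n_out_i)
        p_case = special.expit(intercept + b_g * g2)
        y = (rng.random(n_out_i) < p_case).astype(float)
        ybar = float(y.mean())
        if ybar in (0.0, 1.0):
            continue
        g2c = g2 - g2.mean()
        sgg = float(g2c @ g2c)
        info = ybar * (1 - ybar) * sgg
        gamma_out = float(g2c @ (y - ybar)) / info  # one-step logistic slope
        se_out = info**-0.5
        z = (gamma_out / gamma_hat) / (se_out / abs(gamma_hat))
        if abs(z) >= z_crit:
            rejections += 1
    return rejections / n_reps


def scenario_with_seed(scn: SimScenario, seed: int) -> SimScenario:
    return replace(scn, seed=seed)
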