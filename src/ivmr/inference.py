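"""Power diagnostics, effect-scale transforms, and the cross-ancestry
difference test.

The minimum detectable odds ratio follows the standard closed-form power
approximation for summary-data MR with a binary outcome: the IVW estimate of
the causal log-OR is treated as normal with variance 1/(N·R²·K(1−K)), where
N is the relevant GWAS sample size, R² the total variance of the exposure
explained by the instruments, and K the case fraction. At two-sided level α
and target power 1−β the smallest detectable effect is then

    |log OR| = (z_{1−α/2} + z_{1−β}) / sqrt(N · R² · K(1−K)).

Which N to plug in (exposure or outcome GWAS) is a caller choice surfaced in
:class:`PowerSpec`; the variance formula itself is driven by the outcome
study in the underlying derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd
from scipy import stats

from .estimators import MREstimate
from .exceptions import ValidationError

LN2 = math.log(2.0)


@dataclass
class PowerSpec:
    """Inputs for the minimum-detectable-OR calculation."""

    n: float
    total_r2: float
    case_fraction: float
    alpha: float = 0.05
    power: float = 0.8

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha {self.alpha} outside (0,1)")
        if not 0 < self.power < 1:
            raise ValidationError(f"power {self.power} outside (0,1)")
        if not 0 < self.total_r2 < 1:
            raise ValidationError(f"total_r2 {self.total_r2} outside (0,1)")
        if not 0 < self.case_fraction < 1:
            raise ValidationError(f"case_fraction {self.case_fraction} outside (0,1)")
        if self.n <= 0:
            raise ValidationError(f"sample size {self.n} must be positive")


@dataclass
class ComparisonResult:
    """Difference between two strata's MR estimates for one method."""

    method: str
    diff: float
    se_diff: float
    z: float
    pval: float


def min_detectable_or(spec: PowerSpec) -> float:
    """Smallest odds ratio detectable at the spec's power and level.

    Monotone decreasing in n, total_r2 and K(1−K); always > 1.
    """
    spec.validate()
    z_alpha = stats.norm.ppf(1 - spec.alpha / 2)
    z_power = stats.norm.ppf(spec.power)
    k = spec.case_fraction
    denom = math.sqrt(spec.n * spec.total_r2 * k * (1 - k))
    return math.exp((z_alpha + z_power) / denom)


def compare_ancestries(est_a: MREstimate, est_b: MREstimate) -> ComparisonResult:
    """Propagation-of-error test of the difference between two MR estimates.

    diff = β_a − β_b, SE(diff) = sqrt(SE_a² + SE_b²), two-sided normal p.
    The estimates must be expressed on the same exposure scale.
    """
    if est_a.exposure_scale != est_b.exposure_scale:
        raise ValidationError(
            f"exposure scales differ: {est_a.exposure_scale!r} vs "
            f"{est_b.exposure_scale!r}"
        )
    diff = est_a.beta - est_b.beta
    se_diff = math.sqrt(est_a.se**2 + est_b.se**2)
    z = diff / se_diff
    pval = float(2 * stats.norm.sf(abs(z)))
    method = est_a.method if est_a.method == est_b.method else f"{est_a.method}|{est_b.method}"
    return ComparisonResult(method=method, diff=diff, se_diff=se_diff, z=z, pval=pval)


def per_doubling_of_odds(est: MREstimate) -> MREstimate:
    """Rescale a binary-liability-exposure estimate to 'per doubling of odds'.

    The causal log-OR per unit change in exposure log-odds is multiplied by
    ln 2 (and the SE and CI with it); z-ratios and p-values are unchanged.
    Applying this to a continuous (per-SD) exposure is an error.
    """
    if est.exposure_scale != "log_odds":
        raise ValidationError(
            "per-doubling transform applies only to a binary (log-odds scale) "
            f"exposure; estimate is on scale {est.exposure_scale!r}"
        )
    return replace(
        est,
        beta=est.beta * LN2,
        se=est.se * LN2,
        ci_low=est.ci_low * LN2,
        ci_high=est.ci_high * LN2,
        ci_set=None
        if est.ci_set is None
        else [(lo * LN2, hi * LN2) for lo, hi in est.ci_set],
        exposure_scale="doubling_of_odds",
    )


def power_report(rows: list[dict]) -> pd.DataFrame:
    """Tabulate minimum detectable ORs for a set of exposures.

    Each input dict needs ``exposure`` plus the PowerSpec fields; the output
    mirrors a power-calculation summary table.
    """
    out = []
    for row in rows:
        spec = PowerSpec(
            n=row["n"],
            total_r2=row["total_r2"],
            case_fraction=row["case_fraction"],
            alpha=row.get("alpha", 0.05),
            power=row.get("power", 0.8),
        )
        out.append(
            {
                "exposure": row["exposure"],
                "n": spec.n,
                "total_r2": spec.total_r2,
                "case_fraction": spec.case_fraction,
                "alpha": spec.alpha,
                "power": spec.power,
                "min_detectable_or": min_detectable_or(spec),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "exposure",
            "n",
            "total_r2",
            "case_fraction",
            "alpha",
            "power",
            "min_detectable_or",
        ],
    )
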