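"""End-to-end orchestration: per-stratum analysis and cross-stratum
comparison, with self-documenting run logs.

The per-stratum sequence is: significance filter -> intersect/harmonize with
the outcome -> LD clump -> strength diagnostics -> all applicable MR
estimators. Every threshold, seed and default is echoed into the run log so
a run can be reproduced from its own output directory; no wall-clock
information is written, so identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from scipy import stats

from . import estimators as est
from .exceptions import ConfigurationError, NoInstrumentsError
from .harmonize import HarmonizedVariant, harmonize
from .inference import ComparisonResult, PowerSpec, compare_ancestries, min_detectable_or, per_doubling_of_odds
from .instruments import (
    DEFAULT_R2_MAX,
    DEFAULT_WINDOW_BP,
    GENOME_WIDE_SIGNIFICANCE,
    clump,
    diagnostics_table,
    significance_filter,
)
from .sumstats_io import (
    LDMatrix,
    VariantAssociation,
    read_ld_matrix,
    read_sumstats,
    write_estimates,
)

logger = logging.getLogger("ivmr")

_Z975 = stats.norm.ppf(0.975)

ALL_METHODS = tuple(est.METHOD_REGISTRY)


@dataclass
class AnalysisSettings:
    """Tunable knobs of a stratum analysis, with field-standard defaults."""

    p_threshold: float = GENOME_WIDE_SIGNIFICANCE
    r2_max: float = DEFAULT_R2_MAX
    window_bp: int = DEFAULT_WINDOW_BP
    palindromic_policy: str = "infer_by_eaf"
    n_boot: int = 1000
    seed: int = 0
    psi: float | None = None
    bandwidth_factor: float = 1.0
    clump_before_intersect: bool = False
    exposure_scale: str = "sd"
    methods: Sequence[str] = ALL_METHODS

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d


@dataclass
class StratumResult:
    estimates: list[est.MREstimate]
    instruments: list[HarmonizedVariant]
    diagnostics: pd.DataFrame
    exclusions: list[tuple[str, str]]
    total_r2: float
    skipped: dict[str, str] = field(default_factory=dict)

    def by_method(self) -> dict[str, est.MREstimate]:
        return {e.method: e for e in self.estimates}


def _total_r2(diag: pd.DataFrame) -> float:
    r2 = diag["r2_formula_A"].where(diag["r2_formula_A"].notna(), diag["r2_formula_B"])
    return float(r2.sum())


def analyze_stratum(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    ld: LDMatrix,
    settings: AnalysisSettings | None = None,
) -> StratumResult:
    """Run the full per-stratum analysis on in-memory records.

    Every exposure variant ends up either in the instrument set or in the
    exclusion report (reasons: ``not_significant``, harmonization reasons,
    ``clumped``). Zero surviving instruments raises
    :class:`NoInstrumentsError` rather than returning empty output.
    """
    settings = settings or AnalysisSettings()
    exclusions: list[tuple[str, str]] = []

    significant = significance_filter(exposure, settings.p_threshold)
    sig_ids = {v.variant_id for v in significant}
    exclusions += [
        (v.variant_id, "not_significant") for v in exposure if v.variant_id not in sig_ids
    ]

    if settings.clump_before_intersect:
        clumped = clump(significant, ld, settings.r2_max, settings.window_bp)
        kept_ids = {v.variant_id for v in clumped}
        exclusions += [
            (v.variant_id, "clumped") for v in significant if v.variant_id not in kept_ids
        ]
        instruments, harm_excl = harmonize(
            clumped, list(outcome), settings.palindromic_policy
        )
        exclusions += harm_excl
    else:
        harmonized, harm_excl = harmonize(
            significant, list(outcome), settings.palindromic_policy
        )
        exclusions += harm_excl
        instruments = clump(harmonized, ld, settings.r2_max, settings.window_bp)
        kept_ids = {v.variant_id for v in instruments}
        exclusions += [
            (v.variant_id, "clumped")
            for v in harmonized
            if v.variant_id not in kept_ids
        ]

    if not instruments:
        raise NoInstrumentsError(
            "no instruments remain after filtering, harmonization and clumping"
        )

    diagnostics = diagnostics_table(instruments)
    total_r2 = _total_r2(diagnostics)

    results: list[est.MREstimate] = []
    skipped: dict[str, str] = {}
    for method in settings.methods:
        fn, minimum = est.METHOD_REGISTRY[method]
        if len(instruments) < minimum:
            reason = f"needs >= {minimum} instruments, have {len(instruments)}"
            skipped[method] = reason
            logger.warning("skipping %s: %s", method, reason)
            continue
        if method == "weighted_median":
            e = fn(instruments, n_boot=settings.n_boot, seed=settings.seed)
        elif method == "weighted_mode":
            e = fn(
                instruments,
                bandwidth_factor=settings.bandwidth_factor,
                n_boot=settings.n_boot,
                seed=settings.seed,
            )
        elif method == "contamination_mixture":
            e = fn(instruments, psi=settings.psi)
        else:
            e = fn(instruments)
        e.exposure_scale = settings.exposure_scale
        results.append(e)

    return StratumResult(
        estimates=results,
        instruments=list(instruments),
        diagnostics=diagnostics,
        exclusions=exclusions,
        total_r2=total_r2,
        skipped=skipped,
    )


@dataclass
class StratumPaths:
    exposure: str
    outcome: str
    ld: str


@dataclass
class RunConfig:
    """Everything one `ivmr run` needs; loadable from a YAML file."""

    strata: dict[str, StratumPaths]
    out_dir: str = "ivmr_out"
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    power: dict | None = None  # n, case_fraction, alpha, power; total_r2 optional

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not raw or "strata" not in raw:
            raise ConfigurationError(f"config {path} lacks a 'strata' section")
        strata = {
            label: StratumPaths(**paths) for label, paths in raw["strata"].items()
        }
        settings = AnalysisSettings(**raw.get("settings", {}))
        return cls(
            strata=strata,
            out_dir=raw.get("out_dir", "ivmr_out"),
            settings=settings,
            power=raw.get("power"),
        )

    def validate_paths(self) -> None:
        for label, p in self.strata.items():
            for role in ("exposure", "outcome", "ld"):
                path = getattr(p, role)
                if not Path(path).exists():
                    raise ConfigurationError(
                        f"stratum {label!r}: {role} file {path!r} does not exist"
                    )


def run_stratum(cfg: RunConfig, stratum: str) -> StratumResult:
    """File-level wrapper: read inputs, analyze, write all reports."""
    if stratum not in cfg.strata:
        raise ConfigurationError(f"unknown stratum {stratum!r}")
    paths = cfg.strata[stratum]
    exposure = read_sumstats(paths.exposure)
    outcome = read_sumstats(paths.outcome)
    ld = read_ld_matrix(paths.ld)
    result = analyze_stratum(exposure, outcome, ld, cfg.settings)

    out = Path(cfg.out_dir) / stratum
    out.mkdir(parents=True, exist_ok=True)
    write_estimates(result.estimates, out / "estimates.tsv")
    result.diagnostics.to_csv(
        out / "diagnostics.tsv", sep="\t", index=False, float_format="%.12g"
    )
    pd.DataFrame(result.exclusions, columns=["variant_id", "reason"]).to_csv(
        out / "exclusions.tsv", sep="\t", index=False
    )

    run_log: dict = {
        "stratum": stratum,
        "inputs": dataclasses.asdict(paths),
        "settings": cfg.settings.as_dict(),
        "n_instruments": len(result.instruments),
        "total_r2": result.total_r2,
        "skipped_methods": result.skipped,
    }
    if cfg.power:
        spec = PowerSpec(
            n=cfg.power["n"],
            total_r2=cfg.power.get("total_r2") or result.total_r2,
            case_fraction=cfg.power["case_fraction"],
            alpha=cfg.power.get("alpha", 0.05),
            power=cfg.power.get("power", 0.8),
        )
        run_log["power"] = {
            **dataclasses.asdict(spec),
            "min_detectable_or": min_detectable_or(spec),
        }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)
    logger.info("run_stratum(%s): wrote results to %s", stratum, out)
    return result


def run_comparison(
    results_a: Sequence[est.MREstimate] | Mapping[str, est.MREstimate],
    results_b: Sequence[est.MREstimate] | Mapping[str, est.MREstimate],
) -> list[ComparisonResult]:
    """Propagation-of-error difference test per method shared by two strata.

    Methods present in only one stratum are skipped with a warning.
    """
    map_a = results_a if isinstance(results_a, Mapping) else {e.method: e for e in results_a}
    map_b = results_b if isinstance(results_b, Mapping) else {e.method: e for e in results_b}
    out: list[ComparisonResult] = []
    for method in map_a:
        if method not in map_b:
            logger.warning("run_comparison: method %r missing in second stratum", method)
            continue
        a, b = map_a[method], map_b[method]
        if not (a.se > 0 and b.se > 0):
            logger.warning("run_comparison: method %r lacks usable SEs", method)
            continue
        out.append(compare_ancestries(a, b))
    for method in map_b:
        if method not in map_a:
            logger.warning("run_comparison: method %r missing in first stratum", method)
    return out


def comparison_table(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": c.method,
                "diff": c.diff,
                "se_diff": c.se_diff,
                "z": c.z,
                "pval": c.pval,
            }
            for c in comparisons
        ],
        columns=["method", "diff", "se_diff", "z", "pval"],
    )


def format_or_ci(beta: float, ci_low: float, ci_high: float) -> str:
    return f"{math.exp(beta):.2f} [{math.exp(ci_low):.2f}, {math.exp(ci_high):.2f}]"


def render_forest_table(
    estimates: Mapping[tuple[str, str], Sequence[est.MREstimate]],
) -> pd.DataFrame:
    """Forest-plot table: one row per exposure x ancestry x method.

    Keys of ``estimates`` are ``(exposure, ancestry)`` pairs. ORs and CI
    bounds are formatted to 2 decimals; an empty mapping yields a
    header-only table.
    """
    rows = []
    for (exposure, ancestry), ests in estimates.items():
        for e in ests:
            rows.append(
                {
                    "exposure": exposure,
                    "ancestry": ancestry,
                    "method": e.method,
                    "n_variants": e.n_variants,
                    "or_95ci": format_or_ci(e.beta, e.ci_low, e.ci_high),
                    "pval": e.pval,
                }
            )
    return pd.DataFrame(
        rows, columns=["exposure", "ancestry", "method", "n_variants", "or_95ci", "pval"]
    )


def rescale_binary_exposure(result: StratumResult) -> StratumResult:
    """Re-express every estimate of a binary-liability exposure per doubling
    of odds (multiplies β and SE by ln 2)."""
    return dataclasses.replace(
        result, estimates=[per_doubling_of_odds(e) for e in result.estimates]
    )
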