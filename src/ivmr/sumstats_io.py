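"""Reading and writing GWAS summary statistics, LD matrices and MR estimates.

All on-disk formats are plain tab-separated text:

* summary statistics — one variant per row, header row, columns named by a
  *dialect* (a mapping from canonical field names to the file's column
  headers). The default dialect is
  ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n``.
* LD matrix — square table of pairwise correlations ``r``; the first column
  and the header row both carry the variant IDs.
* estimates — one MR method per row (see :func:`write_estimates`).

Records failing their invariants are dropped on read, counted, and reported
through the ``ivmr`` logger; reading never fails on a bad *row*, only on a
bad *file*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyInputError, FormatError

logger = logging.getLogger("ivmr")

#: canonical field name -> default column header
DEFAULT_DIALECT: dict[str, str] = {
    "variant_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

_MANDATORY = [k for k in DEFAULT_DIALECT if k != "eaf"]
_BASES = frozenset("ACGT")


@dataclass
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (SD units for a
    continuous trait, log-odds for a binary one); ``eaf`` is the
    effect-allele frequency and may be missing (``None``). Coordinates are
    1-based, following GWAS summary-statistic convention.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: float
    eaf: float | None = None

    @property
    def is_indel(self) -> bool:
        return len(self.effect_allele) > 1 or len(self.other_allele) > 1

    def is_valid(self) -> bool:
        if self.effect_allele == self.other_allele:
            return False
        if not (set(self.effect_allele) <= _BASES and set(self.other_allele) <= _BASES):
            return False
        if not (self.se > 0 and 0 < self.pval <= 1 and self.n > 0):
            return False
        if self.eaf is not None and not (0 < self.eaf < 1):
            return False
        return True


@dataclass
class LDMatrix:
    """Symmetric pairwise-correlation matrix over an ordered variant list."""

    variant_ids: list[str]
    r: np.ndarray
    positions: dict[str, tuple[str, int]] | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.variant_ids)
        if self.r.shape != (n, n):
            raise FormatError(
                f"LD matrix dimension {self.r.shape} does not match "
                f"{n} variant IDs"
            )
        self._index = {v: i for i, v in enumerate(self.variant_ids)}
        if len(self._index) != n:
            raise FormatError("duplicate variant IDs in LD matrix")

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def correlation(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def r2(self, a: str, b: str) -> float:
        return self.correlation(a, b) ** 2


def _column_map(dialect: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect field(s): {sorted(unknown)}")
        cols.update(dialect)
    return cols


def read_sumstats(
    path, dialect: Mapping[str, str] | None = None
) -> list[VariantAssociation]:
    """Read a summary-statistics TSV into validated records.

    Rows violating record invariants (``se <= 0``, identical alleles,
    out-of-range ``eaf`` or ``pval`` ...) are dropped and counted; the drop
    count is reported via logging. A missing mandatory column raises
    :class:`ConfigurationError` naming the column; a file without data rows
    raises :class:`EmptyInputError`.
    """
    cols = _column_map(dialect)
    try:
        df = pd.read_csv(path, sep="\t", dtype={cols["chrom"]: str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data in {path}") from None
    for fieldname in _MANDATORY:
        if cols[fieldname] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cols[fieldname]!r} (field {fieldname!r}) "
                f"missing from {path}"
            )
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")

    has_eaf = cols["eaf"] in df.columns
    records: list[VariantAssociation] = []
    n_dropped = 0
    n_indels = 0
    for row in df.itertuples(index=False):
        get = lambda f: getattr(row, cols[f])  # noqa: E731
        try:
            eaf = float(get("eaf")) if has_eaf else math.nan
            rec = VariantAssociation(
                variant_id=str(get("variant_id")),
                chrom=str(get("chrom")),
                pos=int(get("pos")),
                effect_allele=str(get("effect_allele")).upper(),
                other_allele=str(get("other_allele")).upper(),
                beta=float(get("beta")),
                se=float(get("se")),
                pval=float(get("pval")),
                n=float(get("n")),
                eaf=None if math.isnan(eaf) else eaf,
            )
        except (TypeError, ValueError):
            n_dropped += 1
            continue
        if not rec.is_valid():
            n_dropped += 1
            continue
        if rec.is_indel:
            n_indels += 1
        records.append(rec)
    if n_dropped:
        logger.warning("read_sumstats(%s): dropped %d invalid row(s)", path, n_dropped)
    if n_indels:
        logger.info("read_sumstats(%s): %d indel record(s) flagged", path, n_indels)
    logger.info("read_sumstats(%s): %d records read", path, len(records))
    return records


def write_sumstats(
    records: Iterable[VariantAssociation], path, dialect: Mapping[str, str] | None = None
) -> None:
    """Write records as a summary-statistics TSV (inverse of read_sumstats)."""
    cols = _column_map(dialect)
    rows = [
        {
            cols["variant_id"]: r.variant_id,
            cols["chrom"]: r.chrom,
            cols["pos"]: r.pos,
            cols["effect_allele"]: r.effect_allele,
            cols["other_allele"]: r.other_allele,
            cols["eaf"]: math.nan if r.eaf is None else r.eaf,
            cols["beta"]: r.beta,
            cols["se"]: r.se,
            cols["pval"]: r.pval,
            cols["n"]: r.n,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=[cols[f] for f in DEFAULT_DIALECT])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_ld_matrix(path) -> LDMatrix:
    """Read a square LD (pairwise r) TSV with IDs in the first row/column.

    Asymmetries beyond 1e-8 and any ``|r| > 1`` entry are format errors; the
    matrix is exactly symmetrized on return and the diagonal set to 1.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data in {path}") from None
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"LD matrix in {path} is not square: {df.shape}")
    ids_row = [str(c) for c in df.columns]
    ids_col = [str(i) for i in df.index]
    if ids_row != ids_col:
        raise FormatError(f"LD matrix row/column IDs disagree in {path}")
    r = df.to_numpy(dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise FormatError(f"LD matrix in {path} has |r| > 1")
    if np.max(np.abs(r - r.T)) > 1e-8:
        raise FormatError(f"LD matrix in {path} asymmetric beyond 1e-8")
    if np.max(np.abs(np.diag(r) - 1.0)) > 1e-8:
        raise FormatError(f"LD matrix in {path} has non-unit diagonal")
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variant_ids=ids_row, r=r)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    df = pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


ESTIMATE_COLUMNS = [
    "method",
    "n_variants",
    "beta",
    "se",
    "or",
    "ci_low",
    "ci_high",
    "pval",
    "q_stat",
    "intercept",
    "intercept_se",
]


def write_estimates(estimates: Sequence, path) -> None:
    """Serialize MR estimates as a TSV; odds ratios are ``exp(beta)``.

    Accepts any objects with the MREstimate attribute surface. An empty list
    yields a header-only file. A contamination-mixture confidence set, when
    present, is flattened to its outer bounds in ``ci_low``/``ci_high`` (the
    full set is serialized by the pipeline's own report).
    """
    rows = []
    for e in estimates:
        rows.append(
            {
                "method": e.method,
                "n_variants": e.n_variants,
                "beta": e.beta,
                "se": e.se,
                "or": math.exp(e.beta),
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "q_stat": e.q_stat,
                "intercept": e.intercept,
                "intercept_se": e.intercept_se,
            }
        )
    df = pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def read_estimates(path) -> pd.DataFrame:
    """Read an estimates TSV back as a DataFrame (used by `ivmr compare`)."""
    try:
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data in {path}") from None
    missing = set(ESTIMATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"estimates file {path} lacks columns {sorted(missing)}")
    return df
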