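"""GWAS summary-statistics containers, I/O, and per-variant instrument strength.

A :class:`GwasDataset` wraps a tidy :class:`pandas.DataFrame` with one row per
variant and canonical columns ``snp_id, chrom, pos, effect_allele,
other_allele, eaf, beta, se, pval, n``.  Effects are per effect-allele: log
odds ratios for binary traits, trait-SD units for standardized continuous
traits.  Datasets whose source tables carry only a Z-score are standardized on
ingestion with :func:`standardize_effects`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_VALID_ALLELES = frozenset("ACGT")


class ConfigurationError(ValueError):
    """A column mapping or study configuration is unusable."""


class InputError(ValueError):
    """An input table is empty or structurally broken."""


@dataclass
class GwasDataset:
    """Summary statistics for one trait.

    Parameters
    ----------
    trait_name
        Human-readable label, e.g. ``"smoking_initiation"``.
    trait_type
        ``"binary"`` (betas are log odds) or ``"continuous"`` (betas in SD
        units).
    table
        Canonical per-variant table; ``snp_id`` must be unique.
    ancestry_label
        Free-text metadata, e.g. ``"EUR"``.
    """

    trait_name: str
    trait_type: str = "continuous"
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    ancestry_label: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ConfigurationError(
                f"trait_type must be 'binary' or 'continuous', got {self.trait_type!r}"
            )
        if self.table.empty and len(self.table.columns) == 0:
            self.table = pd.DataFrame(columns=CANONICAL_COLUMNS)
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"dataset table missing columns: {missing}")
        if self.table["snp_id"].duplicated().any():
            dups = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"]
            raise InputError(f"duplicate snp_id values: {sorted(set(dups))[:5]}")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def subset(self, snp_ids) -> "GwasDataset":
        """Rows for *snp_ids*, silently skipping absent identifiers."""
        keep = self.table["snp_id"].isin(set(snp_ids))
        return GwasDataset(
            self.trait_name, self.trait_type, self.table.loc[keep].copy(), self.ancestry_label
        )

    def lookup(self, snp_id: str) -> pd.Series:
        rows = self.table.loc[self.table["snp_id"] == snp_id]
        if rows.empty:
            raise KeyError(snp_id)
        return rows.iloc[0]


def standardize_effects(zscore, eaf, n):
    """Standardize a Z-score into (beta, se) on the per-SD-of-trait scale.

    Uses the summary-statistic standardization

    .. math:: \\beta = z / \\sqrt{2 f (1-f) (n + z^2)}, \\qquad
              se = 1 / \\sqrt{2 f (1-f) (n + z^2)}

    where ``f`` is the allele frequency.  The product ``f(1-f)`` makes the
    choice between the effect-allele frequency and the folded MAF immaterial.
    By construction ``beta/se == z`` exactly.

    Returns ``(beta, se)`` (arrays for array input).
    """
    zscore = np.asarray(zscore, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((eaf <= 0.0) | (eaf >= 1.0)):
        raise ValueError("eaf must lie strictly inside (0, 1)")
    if np.any(n < 1):
        raise ValueError("sample size must be >= 1")
    denom = np.sqrt(2.0 * eaf * (1.0 - eaf) * (n + zscore**2))
    se = 1.0 / denom
    beta = zscore * se
    if beta.ndim == 0:
        return float(beta), float(se)
    return beta, se


def variance_explained(beta, se, n):
    """Proportion of trait variance explained by one variant.

    The MAF-bearing form ``2f(1-f)β² / (2f(1-f)β² + 2f(1-f)·n·se²)``
    cancels its frequency factors, leaving ``r² = β² / (β² + n·se²)``,
    which is what is computed here (the identity is asserted in tests).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if np.any(n < 1):
        raise ValueError("sample size must be >= 1")
    r2 = beta**2 / (beta**2 + n * se**2)
    return float(r2) if r2.ndim == 0 else r2


def f_statistic(r2, n):
    """Single-instrument F statistic, ``F = r²(n-2)/(1-r²)``.

    Values above 10 are the conventional screen against weak instruments.
    """
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((r2 < 0) | (r2 >= 1)):
        raise ValueError("r2 must lie in [0, 1)")
    if np.any(n <= 2):
        raise ValueError("sample size must exceed 2")
    f = r2 * (n - 2.0) / (1.0 - r2)
    return float(f) if f.ndim == 0 else f


def _validate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating record invariants; return (clean, n_dropped)."""
    df = df.copy()
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper().str.strip()
    ok = pd.Series(True, index=df.index)
    ok &= df["snp_id"].notna()
    ok &= df["effect_allele"].isin(_VALID_ALLELES)
    ok &= df["other_allele"].isin(_VALID_ALLELES)
    ok &= df["effect_allele"] != df["other_allele"]
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    ok &= eaf.isna() | ((eaf > 0) & (eaf < 1))
    se = pd.to_numeric(df["se"], errors="coerce")
    ok &= se > 0
    pval = pd.to_numeric(df["pval"], errors="coerce")
    ok &= (pval > 0) & (pval <= 1)
    nn = pd.to_numeric(df["n"], errors="coerce")
    ok &= nn.isna() | (nn >= 1)
    clean = df.loc[ok].copy()
    n_dropped = int((~ok).sum())

    # soft check: |beta/se| should reproduce the p-value within ~10%
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(
            pd.to_numeric(clean["beta"], errors="coerce")
            / pd.to_numeric(clean["se"], errors="coerce")
        )
        implied = 2.0 * stats.norm.sf(z)
        p = pd.to_numeric(clean["pval"], errors="coerce").to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(implied - p) / np.maximum(p, 1e-300)
    n_inconsistent = int(np.sum((rel > 0.10) & (p > 1e-250)))
    if n_inconsistent:
        logger.warning(
            "%d rows have p-values inconsistent with |beta/se| beyond 10%% "
            "(normal approximation); retained",
            n_inconsistent,
        )
    return clean, n_dropped


def read_sumstats(
    path,
    dialect: dict[str, str] | None = None,
    trait_name: str = "",
    trait_type: str = "continuous",
    ancestry_label: str = "",
    sep: str = "\t",
) -> GwasDataset:
    """Read a delimited summary-statistics table into a :class:`GwasDataset`.

    ``dialect`` maps canonical field names to the file's column names, e.g.
    ``{"snp_id": "SNP", "beta": "BETA", ...}``.  The mapping must cover
    ``snp_id``, ``effect_allele``, ``other_allele`` and either ``(beta, se)``
    or ``(zscore, eaf, n)``; in the Z-only case effects are populated with
    :func:`standardize_effects`.  Rows violating record invariants are
    dropped with a logged count.  Gzip input is accepted transparently.
    """
    dialect = dict(dialect or {c: c for c in CANONICAL_COLUMNS})
    raw = pd.read_csv(path, sep=sep)
    if raw.empty:
        raise InputError(f"no data rows in {path}")

    mandatory = ["snp_id", "effect_allele", "other_allele"]
    missing = [k for k in mandatory if dialect.get(k) not in raw.columns]
    if missing:
        raise ConfigurationError(f"dialect does not resolve mandatory fields: {missing}")
    has_beta = dialect.get("beta") in raw.columns and dialect.get("se") in raw.columns
    has_z = all(dialect.get(k) in raw.columns for k in ("zscore", "eaf", "n"))
    if not (has_beta or has_z):
        raise ConfigurationError(
            "dialect must resolve either (beta, se) or (zscore, eaf, n)"
        )

    df = pd.DataFrame()
    for canon in CANONICAL_COLUMNS:
        src = dialect.get(canon)
        df[canon] = raw[src] if src in raw.columns else np.nan
    # chromosome labels are strings ("1", "X"), whatever the file's dtype
    df["chrom"] = df["chrom"].map(lambda v: str(v) if pd.notna(v) else v)
    if not has_beta:
        z = pd.to_numeric(raw[dialect["zscore"]], errors="coerce").to_numpy()
        f = pd.to_numeric(raw[dialect["eaf"]], errors="coerce").to_numpy()
        n = pd.to_numeric(raw[dialect["n"]], errors="coerce").to_numpy()
        beta, se = standardize_effects(z, f, n)
        df["beta"], df["se"] = beta, se
        if df["pval"].isna().all():
            df["pval"] = 2.0 * stats.norm.sf(np.abs(z))

    clean, n_dropped = _validate_table(df)
    if n_dropped:
        logger.warning("dropped %d invalid rows while reading %s", n_dropped, path)
    return GwasDataset(trait_name or str(path), trait_type, clean, ancestry_label)


def write_sumstats(dataset: GwasDataset, path) -> None:
    """Write the canonical tab-separated table; round-trips with
    :func:`read_sumstats` field-for-field."""
    dataset.table[CANONICAL_COLUMNS].to_csv(path, sep="\t", index=False)
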