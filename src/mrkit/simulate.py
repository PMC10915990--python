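"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works entirely at the summary level: per-variant true exposure
effects are scaled to a target heritability, outcome effects are
``slope × exposure effect + pleiotropy``, and observed effects add sampling
noise with the standard-error model ``se = 1/sqrt(2f(1-f)·N)`` implied by
standardized traits.  Binary traits are emulated directly on the log-odds
scale.  Every draw is seeded, so datasets are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LdMatrix
from .sumstats import CANONICAL_COLUMNS, GwasDataset

# non-strand-ambiguous allele pairs only, so harmonization is exercised
# without the palindromic filter removing simulated instruments
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


@dataclass
class SimConfig:
    """Generative parameters for a two-sample (or mediation-triplet) scenario.

    Defaults emulate a well-powered behavioural-trait GWAS feeding a
    case-control outcome: ~100 independent instruments explaining ~2% of
    exposure variance at biobank sample sizes.
    """

    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_exp: int = 300_000
    n_out: int = 100_000
    n_med: int = 100_000
    true_slope: float = 0.0
    exposure_h2: float = 0.02
    pleiotropy: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_corr: float = 0.0  # instrument-strength coupling (InSIDE violation)
    invalid_fraction: float = 0.0
    mediation: tuple[float, float, float] | None = None  # (a, b, c')
    ld_blocks: list[int] | None = None
    ld_block_r2: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must lie inside (0, 1)")
        for n in (self.n_exp, self.n_out, self.n_med):
            if n < 1:
                raise ValueError("sample sizes must be >= 1")
        if self.pleiotropy not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy regime {self.pleiotropy!r}")


@dataclass
class SimTruth:
    """Per-variant ground truth aligned with the emitted datasets."""

    table: pd.DataFrame  # snp_id, beta_exp_true, pleiotropy, valid
    true_slope: float
    mediation: tuple[float, float, float] | None = None

    @property
    def true_indirect(self) -> float | None:
        if self.mediation is None:
            return None
        a, b, _ = self.mediation
        return a * b

    @property
    def true_total(self) -> float | None:
        if self.mediation is None:
            return None
        a, b, c = self.mediation
        return c + a * b


def _scaled_effects(rng, maf: np.ndarray, h2: float) -> np.ndarray:
    """True per-allele effects with Σ 2f(1-f)β² = h2."""
    raw = rng.normal(size=maf.size)
    var = np.sum(2.0 * maf * (1.0 - maf) * raw**2)
    return raw * np.sqrt(h2 / var) if var > 0 else raw


def _pleiotropic_effects(rng, cfg: SimConfig, beta_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(pleiotropy per variant, validity flag)."""
    k = beta_true.size
    alpha = np.zeros(k)
    valid = np.ones(k, dtype=bool)
    if cfg.pleiotropy == "none" or cfg.invalid_fraction == 0:
        return alpha, valid
    n_invalid = int(round(cfg.invalid_fraction * k))
    idx = rng.choice(k, size=n_invalid, replace=False)
    valid[idx] = False
    if cfg.pleiotropy == "balanced":
        alpha[idx] = rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
    elif cfg.pleiotropy == "directional":
        alpha[idx] = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_invalid)
    else:  # inside_violating: pleiotropy correlated with instrument strength
        r = cfg.pleiotropy_corr
        sd_b = np.std(beta_true[idx]) or 1.0
        noise = rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
        alpha[idx] = (
            cfg.pleiotropy_mean
            + r * (cfg.pleiotropy_sd / sd_b) * beta_true[idx]
            + np.sqrt(max(0.0, 1 - r**2)) * noise
        )
    return alpha, valid


def _observe(rng, snp_ids, chrom, pos, ea, oa, maf, beta_true, n) -> pd.DataFrame:
    """Observed summary row per variant under the standardized-trait SE model."""
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta_hat = beta_true + rng.normal(0.0, se)
    z = beta_hat / se
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": maf,
            "beta": beta_hat,
            "se": se,
            "pval": pval,
            "n": float(n),
        },
        columns=CANONICAL_COLUMNS,
    )


def _variant_frame(rng, n_snps: int, maf_range, prefix: str = "rs"):
    maf = rng.uniform(*maf_range, size=n_snps)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    ids = np.array([f"{prefix}{i + 1}" for i in range(n_snps)])
    chrom = np.array(["1"] * n_snps)
    pos = (1 + np.arange(n_snps)) * 20_000_000.0  # far apart: unlinked by distance
    return ids, chrom, pos, ea, oa, maf


def simulate_gwas_pair(config: SimConfig) -> tuple[GwasDataset, GwasDataset, SimTruth]:
    """One exposure/outcome two-sample pair with known causal slope.

    True outcome effects are ``true_slope × beta_exp + pleiotropy``; the two
    samples are independent (separate noise draws), matching the two-sample
    design.  Emitted p-values are exactly consistent with beta/se.
    """
    rng = np.random.default_rng(config.seed)
    ids, chrom, pos, ea, oa, maf = _variant_frame(rng, config.n_snps, config.maf_range)
    beta_true = _scaled_effects(rng, maf, config.exposure_h2)
    alpha, valid = _pleiotropic_effects(rng, config, beta_true)
    # pleiotropic effects are expressed per exposure-increasing allele, so a
    # directional mean survives orientation (as in Egger-intercept estimation)
    orient = np.where(beta_true >= 0, 1.0, -1.0)
    bout_true = config.true_slope * beta_true + alpha * orient

    exp_df = _observe(rng, ids, chrom, pos, ea, oa, maf, beta_true, config.n_exp)
    out_df = _observe(rng, ids, chrom, pos, ea, oa, maf, bout_true, config.n_out)
    truth = SimTruth(
        pd.DataFrame(
            {"snp_id": ids, "beta_exp_true": beta_true, "pleiotropy": alpha, "valid": valid}
        ),
        true_slope=config.true_slope,
    )
    exposure = GwasDataset("sim_exposure", "continuous", exp_df)
    outcome = GwasDataset("sim_outcome", "binary", out_df)
    return exposure, outcome, truth


def simulate_mediation_triplet(
    config: SimConfig,
) -> tuple[GwasDataset, GwasDataset, GwasDataset, SimTruth]:
    """Exposure → mediator → outcome chain with distinct instrument sets.

    Exposure instruments carry effects ``beta_x`` on the exposure,
    ``a·beta_x`` on the mediator and ``(c' + a·b)·beta_x`` on the outcome;
    mediator instruments carry ``beta_m`` on the mediator and ``b·beta_m``
    on the outcome and nothing on the exposure.  True indirect = a·b,
    true total = c' + a·b.
    """
    if config.mediation is None:
        raise ValueError("config.mediation (a, b, c') must be set")
    a, b, c_prime = config.mediation
    rng = np.random.default_rng(config.seed)
    k = config.n_snps

    ids_x, chrom_x, pos_x, ea_x, oa_x, maf_x = _variant_frame(rng, k, config.maf_range, "rsX")
    ids_m, chrom_m, pos_m, ea_m, oa_m, maf_m = _variant_frame(rng, k, config.maf_range, "rsM")
    pos_m = pos_m + 1e10  # mediator instruments live elsewhere in the genome
    beta_x = _scaled_effects(rng, maf_x, config.exposure_h2)
    beta_m = _scaled_effects(rng, maf_m, config.exposure_h2)

    ids = np.concatenate([ids_x, ids_m])
    chrom = np.concatenate([chrom_x, chrom_m])
    pos = np.concatenate([pos_x, pos_m])
    ea = np.concatenate([ea_x, ea_m])
    oa = np.concatenate([oa_x, oa_m])
    maf = np.concatenate([maf_x, maf_m])

    on_exp = np.concatenate([beta_x, np.zeros(k)])
    on_med = np.concatenate([a * beta_x, beta_m])
    on_out = np.concatenate([(c_prime + a * b) * beta_x, b * beta_m])

    exp_df = _observe(rng, ids, chrom, pos, ea, oa, maf, on_exp, config.n_exp)
    med_df = _observe(rng, ids, chrom, pos, ea, oa, maf, on_med, config.n_med)
    out_df = _observe(rng, ids, chrom, pos, ea, oa, maf, on_out, config.n_out)
    truth = SimTruth(
        pd.DataFrame(
            {
                "snp_id": ids,
                "beta_exp_true": on_exp,
                "pleiotropy": np.zeros(2 * k),
                "valid": np.ones(2 * k, dtype=bool),
            }
        ),
        true_slope=c_prime + a * b,
        mediation=(a, b, c_prime),
    )
    return (
        GwasDataset("sim_exposure", "continuous", exp_df),
        GwasDataset("sim_mediator", "binary", med_df),
        GwasDataset("sim_outcome", "binary", out_df),
        truth,
    )


def simulate_ld_matrix(config: SimConfig, snp_ids=None) -> LdMatrix:
    """Block-diagonal r² matrix: within-block ``ld_block_r2``, zero between.

    ``snp_ids`` defaults to the identifiers :func:`simulate_gwas_pair`
    assigns (``rs1..rsK``); block sizes come from ``config.ld_blocks`` and
    must sum to at most the number of identifiers.
    """
    if config.ld_blocks is None:
        raise ValueError("config.ld_blocks must be set")
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(config.n_snps)]
    snp_ids = list(snp_ids)
    if sum(config.ld_blocks) > len(snp_ids):
        raise ValueError("ld_blocks exceed the number of variants")
    k = len(snp_ids)
    r2 = np.zeros((k, k))
    start = 0
    for size in config.ld_blocks:
        r2[start : start + size, start : start + size] = config.ld_block_r2
        start += size
    np.fill_diagonal(r2, 1.0)
    sign = np.ones((k, k))
    return LdMatrix(snp_ids, r2, sign)
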