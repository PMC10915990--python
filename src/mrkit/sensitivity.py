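"""Pleiotropy and robustness diagnostics.

Four checks: the MR-Egger intercept test for directional pleiotropy, the
simulation-based residual-sum-of-squares (MR-PRESSO) global/outlier/
distortion tests, leave-one-out influence analysis, and exclusion of
instruments associated with known confounders at a Bonferroni-corrected
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MrEstimate, ivw, wald_ratios
from .instruments import HarmonizedData

logger = logging.getLogger(__name__)


def egger_intercept_test(egger_fit: MrEstimate, alpha: float = 0.05) -> dict:
    """Directional-pleiotropy verdict from the MR-Egger intercept.

    An intercept deviating from zero (two-sided p < *alpha*) is evidence
    that the average pleiotropic effect of the instruments is directional.
    """
    if egger_fit.intercept is None:
        raise ValueError("estimate does not carry intercept fields (not an Egger fit?)")
    p = egger_fit.intercept_pval
    return {
        "intercept": egger_fit.intercept,
        "se": egger_fit.intercept_se,
        "p": p,
        "verdict": "directional pleiotropy" if p < alpha else "no directional pleiotropy",
    }


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_p: float
    outlier_ids: list[str]
    outlier_pvals: dict[str, float]
    distortion_p: float | None
    corrected_estimate: MrEstimate | None
    n_sim: int
    seed: int | None


def _loo_slopes(ratio: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every variant, vectorized."""
    sw, swr = np.sum(w), np.sum(w * ratio)
    return (swr - w * ratio) / (sw - w)


def mr_presso(
    data: HarmonizedData,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """Pleiotropy residual sum and outlier test.

    The observed statistic is the weighted residual sum of squares of each
    variant about its leave-one-out IVW fit.  Its null distribution comes
    from *n_sim* parametric simulations of the outcome effects under the
    fitted no-pleiotropy model (``beta_out_j ~ Normal(slope^{(-j)}·beta_exp_j,
    se_out_j)``), with add-one smoothing so p is never 0.  When the global
    test rejects, variants whose own residual exceeds its simulated
    distribution (Bonferroni-corrected) are flagged as outliers, the
    IVW estimate is recomputed without them, and a distortion test compares
    the observed estimate shift with shifts from removing random subsets of
    the same size.
    """
    j = data.n_snps
    if j < 4:
        raise ValueError(f"MR-PRESSO needs >= 4 instruments, got {j}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    wr = wald_ratios(data)
    ratio, w = wr.ratio, wr.weight
    ids = list(wr.snp_ids)
    bexp = data.table["beta_exp"].to_numpy(dtype=float)
    seout = data.table["se_out"].to_numpy(dtype=float)

    loo = _loo_slopes(ratio, w)
    obs_resid = w * (ratio - loo) ** 2  # = (beta_out - loo*beta_exp)^2/se_out^2
    obs_rss = float(np.sum(obs_resid))

    # parametric null: simulate beta_out under the per-variant LOO fit
    sim_bout = rng.normal(loo * bexp, seout, size=(n_sim, j))
    sim_ratio = sim_bout / bexp
    sw = np.sum(w)
    swr = sim_ratio @ w
    sim_loo = (swr[:, None] - w[None, :] * sim_ratio) / (sw - w[None, :])
    sim_resid = w[None, :] * (sim_ratio - sim_loo) ** 2
    sim_rss = sim_resid.sum(axis=1)

    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))

    outlier_ids: list[str] = []
    outlier_pvals: dict[str, float] = {}
    distortion_p: float | None = None
    corrected: MrEstimate | None = None
    if global_p < alpha:
        per_snp_p = (1 + np.sum(sim_resid >= obs_resid[None, :], axis=0)) / (n_sim + 1)
        adj = np.minimum(per_snp_p * j, 1.0)  # Bonferroni over variants
        flagged = adj < alpha
        outlier_ids = [ids[k] for k in np.flatnonzero(flagged)]
        outlier_pvals = {ids[k]: float(adj[k]) for k in np.flatnonzero(flagged)}
        if outlier_ids and j - len(outlier_ids) >= 2:
            keep = ~data.table["snp_id"].isin(outlier_ids).to_numpy()
            corrected = ivw(HarmonizedData(data.table.loc[keep], data.dropped))
            beta_all = float(np.sum(w * ratio) / sw)
            obs_shift = corrected.beta - beta_all
            k_out = len(outlier_ids)
            shifts = np.empty(n_sim)
            for s in range(n_sim):
                drop = rng.choice(j, size=k_out, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                shifts[s] = np.sum(w[mask] * ratio[mask]) / np.sum(w[mask]) - beta_all
            distortion_p = float(
                (1 + np.sum(np.abs(shifts) >= abs(obs_shift))) / (n_sim + 1)
            )
    return PressoResult(
        global_rss=obs_rss,
        global_p=global_p,
        outlier_ids=outlier_ids,
        outlier_pvals=outlier_pvals,
        distortion_p=distortion_p,
        corrected_estimate=corrected,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(
    data: HarmonizedData, p_threshold: float = 0.05, model: str = "multiplicative-random"
) -> pd.DataFrame:
    """IVW re-estimated J times, omitting one variant each.

    A variant is flagged influential when its omission moves the IVW p-value
    across *p_threshold* (in either direction) relative to the full-set fit.
    """
    j = data.n_snps
    if j < 3:
        raise ValueError(f"leave-one-out needs >= 3 instruments, got {j}")
    full = ivw(data, model=model)
    rows = []
    for k in range(j):
        sub = HarmonizedData(data.table.drop(index=data.table.index[k]), data.dropped)
        est = ivw(sub, model=model)
        rows.append(
            {
                "snp_id": data.table.iloc[k]["snp_id"],
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "influential": (est.pval < p_threshold) != (full.pval < p_threshold),
            }
        )
    return pd.DataFrame(rows)


def confounder_filter(
    iv_ids,
    confounder_assoc: pd.DataFrame,
    n_risk_factors: int,
    alpha: float = 0.05,
) -> tuple[list[str], float]:
    """Exclude instruments associated with known confounders.

    The association table has columns ``snp_id, risk_factor, pval``.  The
    Bonferroni threshold is ``alpha / (n_instruments × n_risk_factors)``;
    any instrument with any confounder association below it is removed.
    Instruments absent from the table are treated as non-associated.
    Returns ``(retained_ids, threshold)``.
    """
    if n_risk_factors < 1:
        raise ValueError("n_risk_factors must be >= 1")
    iv_ids = sorted(set(iv_ids))
    if not len(iv_ids):
        return [], float("nan")
    threshold = alpha / (len(iv_ids) * n_risk_factors)
    if confounder_assoc is None or confounder_assoc.empty:
        logger.warning("empty confounder association table; no instruments removed")
        return iv_ids, threshold
    assoc = confounder_assoc.loc[confounder_assoc["snp_id"].isin(iv_ids)]
    bad = set(assoc.loc[pd.to_numeric(assoc["pval"]) < threshold, "snp_id"])
    return [s for s in iv_ids if s not in bad], threshold
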