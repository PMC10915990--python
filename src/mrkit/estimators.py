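"""Causal-effect estimators on harmonized exposure/outcome effect pairs.

All five methods operate on per-variant Wald ratios (outcome effect over
exposure effect).  The inverse-variance-weighted (IVW) average is the primary
estimator; MR-Egger, the weighted median, the weighted mode and the robust
adjusted profile score (RAPS) relax the no-pleiotropy assumption in different
directions.  Estimates are returned with normal-theory (or bootstrap)
standard errors and on the odds-ratio scale for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .instruments import HarmonizedData


class EstimationError(RuntimeError):
    """Too few instruments, or an iterative fit failed to converge."""


@dataclass
class WaldRatioSet:
    """Per-variant causal-effect ratios with first- or second-order SEs."""

    snp_ids: np.ndarray
    ratio: np.ndarray
    ratio_se: np.ndarray

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / self.ratio_se**2

    def __len__(self) -> int:
        return len(self.ratio)


@dataclass
class MrEstimate:
    """One method's causal estimate on the log-effect and odds-ratio scales."""

    method: str
    beta: float
    se: float
    pval: float
    or_value: float
    ci_low: float
    ci_high: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "pval": self.pval,
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_snp": self.n_snp,
        }
        if self.intercept is not None:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_pval=self.intercept_pval,
            )
        return d


def to_odds_ratio(beta: float, se: float, level: float = 0.95):
    """Exponentiate a log-scale estimate: ``(OR, ci_low, ci_high)``."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))


def _two_sided_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _finish(method: str, beta: float, se: float, n_snp: int, level: float = 0.95, **kw) -> MrEstimate:
    orv, lo, hi = to_odds_ratio(beta, se, level)
    return MrEstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        pval=_two_sided_p(beta, se),
        or_value=orv,
        ci_low=lo,
        ci_high=hi,
        n_snp=int(n_snp),
        **kw,
    )


def _arrays(data: HarmonizedData):
    df = data.table
    return (
        df["beta_exp"].to_numpy(dtype=float),
        df["se_exp"].to_numpy(dtype=float),
        df["beta_out"].to_numpy(dtype=float),
        df["se_out"].to_numpy(dtype=float),
    )


def wald_ratios(data: HarmonizedData, order: int = 1) -> WaldRatioSet:
    """Per-variant ratio ``beta_out/beta_exp``.

    ``order=1`` gives the usual first-order SE ``se_out/|beta_exp|``;
    ``order=2`` adds the exposure-uncertainty term.  Variants with a zero
    exposure effect cannot form a ratio and are excluded.
    """
    bexp, seexp, bout, seout = _arrays(data)
    ids = data.table["snp_id"].to_numpy()
    keep = bexp != 0
    bexp, seexp, bout, seout, ids = bexp[keep], seexp[keep], bout[keep], seout[keep], ids[keep]
    ratio = bout / bexp
    if order == 1:
        se = seout / np.abs(bexp)
    elif order == 2:
        se = np.sqrt(seout**2 / bexp**2 + bout**2 * seexp**2 / bexp**4)
    else:
        raise ValueError("order must be 1 or 2")
    return WaldRatioSet(ids, ratio, se)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

def ivw(data: HarmonizedData, model: str = "multiplicative-random", level: float = 0.95) -> MrEstimate:
    """Inverse-variance-weighted average of the Wald ratios.

    Identical to the zero-intercept weighted least-squares slope of the
    outcome effects on the exposure effects with weights ``1/se_out²``.  The
    default multiplicative-random-effects model inflates the fixed-effect SE
    by ``sqrt(Q/(J-1))`` when heterogeneity exceeds its expectation (floor at
    1); ``model="fixed"`` disables the inflation.
    """
    if model not in ("fixed", "multiplicative-random"):
        raise ValueError(f"unknown IVW model {model!r}")
    wr = wald_ratios(data)
    j = len(wr)
    if j < 2:
        raise EstimationError(f"IVW needs >= 2 instruments, got {j}")
    w = wr.weight
    beta = float(np.sum(w * wr.ratio) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (wr.ratio - beta) ** 2))
    if model == "multiplicative-random":
        se *= max(1.0, np.sqrt(q / (j - 1)))
    return _finish("IVW", beta, se, j, level, diagnostics={"Q": q, "model": model})


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------

def egger(data: HarmonizedData, level: float = 0.95, use_t: bool = False) -> MrEstimate:
    """MR-Egger regression: weighted least squares with a pleiotropy intercept.

    Exposure effects are oriented non-negative (outcome signs follow) so the
    intercept has a consistent direction; weights are ``1/se_out²``.  A
    non-zero intercept is the average directional pleiotropic effect.
    P-values use the normal reference by default (``use_t`` switches to the
    t reference with J-2 df).
    """
    bexp, _, bout, seout = _arrays(data)
    j = len(bexp)
    if j < 3:
        raise EstimationError(f"MR-Egger needs >= 3 instruments, got {j}")
    flip = np.sign(bexp)
    flip[flip == 0] = 1.0
    x, y = bexp * flip, bout * flip
    res = sm.WLS(y, sm.add_constant(x), weights=1.0 / seout**2).fit()
    inter, slope = float(res.params[0]), float(res.params[1])
    se_inter, se_slope = float(res.bse[0]), float(res.bse[1])
    if use_t:
        pf = lambda b, s: float(2.0 * stats.t.sf(abs(b) / s, df=j - 2)) if s > 0 else 0.0
        p_slope, p_inter = pf(slope, se_slope), pf(inter, se_inter)
    else:
        p_slope, p_inter = _two_sided_p(slope, se_slope), _two_sided_p(inter, se_inter)
    est = _finish(
        "MR-Egger",
        slope,
        se_slope,
        j,
        level,
        intercept=inter,
        intercept_se=se_inter,
        intercept_pval=p_inter,
    )
    est.pval = p_slope
    return est


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio, kind="mergesort")
    r, w = ratio[order], weight[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(
    data: HarmonizedData, n_boot: int = 1000, seed: int | None = None, level: float = 0.95
) -> MrEstimate:
    """Weighted median of the Wald ratios.

    Consistent when at least half of the total weight comes from valid
    instruments.  The point estimate interpolates the ordered ratios at
    mid-cumulative weight 0.5; the SE is a seeded parametric bootstrap
    (each ratio resampled from ``Normal(ratio_j, ratio_se_j)``).
    """
    wr = wald_ratios(data)
    j = len(wr)
    if j < 3:
        raise EstimationError(f"weighted median needs >= 3 instruments, got {j}")
    beta = _weighted_median(wr.ratio, wr.weight)
    rng = np.random.default_rng(seed)
    draws = rng.normal(wr.ratio, wr.ratio_se, size=(n_boot, j))
    boots = np.array([_weighted_median(d, wr.weight) for d in draws])
    se = float(np.std(boots, ddof=1))
    return _finish("weighted-median", beta, se, j, level)


# ---------------------------------------------------------------------------
# weighted mode
# ---------------------------------------------------------------------------

def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    # modified Silverman rule on the ratio set
    s = np.std(ratio, ddof=1)
    iqr = np.subtract(*np.percentile(ratio, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    h = phi * 0.9 * spread * len(ratio) ** (-0.2)
    return float(h)


def _kde_argmax(ratio: np.ndarray, weight: np.ndarray, h: float, n_grid: int = 10_000) -> float:
    if h <= 0 or not np.isfinite(h):
        # degenerate spread: the mode is the (weighted) majority value
        return _weighted_median(ratio, weight)
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2) @ weight
    return float(grid[np.argmax(dens)])


def weighted_mode(
    data: HarmonizedData,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> MrEstimate:
    """Mode-based estimate: the causal effect of the largest cluster of ratios.

    A weighted normal-kernel density over the Wald ratios (bandwidth =
    *phi* × modified Silverman rule) is maximized over a 10,000-point grid
    spanning the ratio range ± 3 bandwidths.  Unbiased when the variants in
    the largest cluster are valid.  SE by seeded parametric bootstrap.
    """
    wr = wald_ratios(data)
    j = len(wr)
    if j < 3:
        raise EstimationError(f"weighted mode needs >= 3 instruments, got {j}")
    h = _mode_bandwidth(wr.ratio, phi)
    beta = _kde_argmax(wr.ratio, wr.weight, h)
    rng = np.random.default_rng(seed)
    draws = rng.normal(wr.ratio, wr.ratio_se, size=(n_boot, j))
    boots = np.array(
        [_kde_argmax(d, wr.weight, _mode_bandwidth(d, phi), n_grid=2000) for d in draws]
    )
    se = float(np.std(boots, ddof=1))
    return _finish("weighted-mode", beta, se, j, level)


# ---------------------------------------------------------------------------
# MR-RAPS
# ---------------------------------------------------------------------------

def _psi_rho(loss: str):
    """(psi, delta) for the chosen robust loss; delta = E[psi(Z)·Z], Z~N(0,1)."""
    if loss == "l2":
        return (lambda t: t), 1.0
    if loss == "huber":
        c = 1.345

        def psi(t):
            return np.clip(t, -c, c)
    elif loss == "tukey":
        c = 4.685

        def psi(t):
            u = t / c
            out = t * (1 - u**2) ** 2
            return np.where(np.abs(t) <= c, out, 0.0)
    else:
        raise ValueError(f"unknown loss {loss!r}")
    zs, wq = np.polynomial.hermite_e.hermegauss(80)
    delta = float(np.sum(wq * psi(zs) * zs) / np.sqrt(2 * np.pi))
    return psi, delta


def mr_raps(
    data: HarmonizedData,
    loss: str = "l2",
    overdispersion: bool = False,
    level: float = 0.95,
) -> MrEstimate:
    """Robust adjusted profile score estimator.

    Solves the profile estimating equation for the slope β (and an
    overdispersion variance τ² when enabled): with standardized residuals
    ``t_j = (beta_out_j − β·beta_exp_j)/sqrt(se_out_j² + β²·se_exp_j² + τ²)``
    the slope solves ``Σ ψ(t_j)·beta_exp_j/sqrt(·) = 0`` and τ² solves
    ``Σ (ψ(t_j)·t_j − δ) = 0``.  ψ is identity (l2), Huber (c=1.345) or
    Tukey biweight (c=4.685); δ = E[ψ(Z)Z] keeps τ² unbiased under
    normality.  SEs are sandwich-type.  Accounts for many weak instruments
    (both-sample uncertainty enters the residual) and, via ψ/τ², for
    idiosyncratic and systematic pleiotropy.
    """
    bexp, seexp, bout, seout = _arrays(data)
    j = len(bexp)
    if j < 3:
        raise EstimationError(f"MR-RAPS needs >= 3 instruments, got {j}")
    psi, delta = _psi_rho(loss)

    def resid(beta, tau2):
        s = np.sqrt(seout**2 + beta**2 * seexp**2 + tau2)
        return (bout - beta * bexp) / s, s

    def score_beta(beta, tau2):
        t, s = resid(beta, tau2)
        return float(np.sum(psi(t) * bexp / s))

    def solve_beta(tau2, x0):
        # bracket the root around a ratio-based pilot
        lo, hi = x0 - 1.0, x0 + 1.0
        for _ in range(60):
            if score_beta(lo, tau2) * score_beta(hi, tau2) <= 0:
                break
            lo, hi = lo - (hi - lo), hi + (hi - lo)
        else:
            raise EstimationError("MR-RAPS: could not bracket the score root")
        return float(optimize.brentq(lambda b: score_beta(b, tau2), lo, hi, xtol=1e-12))

    w0 = bexp**2 / seout**2
    pilot = float(np.sum(w0 * (bout / bexp)) / np.sum(w0))
    tau2 = 0.0
    beta = solve_beta(tau2, pilot)
    if overdispersion:
        for _ in range(100):
            def moment(t2):
                t, _ = resid(beta, t2)
                return float(np.sum(psi(t) * t - delta))

            hi = np.var(bout - beta * bexp) + np.max(seout**2) + 1.0
            tau2_new = 0.0 if moment(0.0) <= 0 else float(
                optimize.brentq(moment, 0.0, hi, xtol=1e-12)
            )
            beta_new = solve_beta(tau2_new, beta)
            if abs(beta_new - beta) < 1e-10 and abs(tau2_new - tau2) < 1e-10:
                beta, tau2 = beta_new, tau2_new
                break
            beta, tau2 = beta_new, tau2_new
        else:
            raise EstimationError("MR-RAPS: overdispersion iteration did not converge")

    # sandwich variance: Var(beta) = B / A^2
    eps = 1e-6 * max(1.0, abs(beta))
    a = (score_beta(beta + eps, tau2) - score_beta(beta - eps, tau2)) / (2 * eps)
    t, s = resid(beta, tau2)
    b = float(np.sum(psi(t) ** 2 * bexp**2 / s**2))
    if a == 0:
        raise EstimationError("MR-RAPS: singular score derivative")
    se = float(np.sqrt(b) / abs(a))
    return _finish(
        "MR-RAPS",
        beta,
        se,
        j,
        level,
        diagnostics={"loss": loss, "tau2": tau2, "overdispersion": overdispersion},
    )


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------

def heterogeneity(data: HarmonizedData) -> dict:
    """Cochran's Q about the IVW fit and Rücker's Q about the Egger fit.

    Both use first-order weights ``beta_exp²/se_out²`` in ratio space
    (equivalently ``1/se_out²`` in effect space).  Rücker's Q is never
    larger than Cochran's: the Egger intercept absorbs heterogeneity.
    """
    out: dict = {}
    wr = wald_ratios(data)
    j = len(wr)
    if j >= 2:
        w = wr.weight
        beta = float(np.sum(w * wr.ratio) / np.sum(w))
        q = float(np.sum(w * (wr.ratio - beta) ** 2))
        out["cochran_q"] = {"Q": q, "df": j - 1, "p": float(stats.chi2.sf(q, j - 1))}
    else:
        out["cochran_q"] = None
    if j >= 3:
        bexp, _, bout, seout = _arrays(data)
        flip = np.sign(bexp)
        flip[flip == 0] = 1.0
        x, y, w2 = bexp * flip, bout * flip, 1.0 / seout**2
        res = sm.WLS(y, sm.add_constant(x), weights=w2).fit()
        qr = float(np.sum(w2 * res.resid**2))
        out["rucker_q"] = {"Q": qr, "df": j - 2, "p": float(stats.chi2.sf(qr, j - 2))}
    else:
        out["rucker_q"] = None
    return out


ALL_METHODS = ("IVW", "MR-RAPS", "MR-Egger", "weighted-median", "weighted-mode")


def run_all_estimators(
    data: HarmonizedData, n_boot: int = 1000, seed: int | None = None
) -> list[MrEstimate]:
    """The five-method panel on one harmonized dataset (seeded bootstraps)."""
    ss = np.random.SeedSequence(seed)
    s_med, s_mode = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    return [
        ivw(data),
        mr_raps(data, overdispersion=True, loss="huber"),
        egger(data),
        weighted_median(data, n_boot=n_boot, seed=s_med),
        weighted_mode(data, n_boot=n_boot, seed=s_mode),
    ]
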