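"""Two-step MR mediation: product of coefficients with delta-method SEs.

Step 1 estimates the exposure→mediator effect (a), step 2 the
mediator→outcome effect (b); the indirect effect is a·b with first-order
delta SE sqrt(a²·se_b² + b²·se_a²), the direct effect is total − indirect,
and the mediated proportion is indirect/total on the log-effect scale.
Step estimates from non-overlapping samples are treated as independent, so
no covariance term enters the delta variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class Effect:
    beta: float
    se: float


@dataclass
class MediationResult:
    total: Effect
    step1: Effect
    step2: Effect
    indirect: Effect
    indirect_p: float
    indirect_ci: tuple[float, float]
    direct: Effect
    proportion_mediated: float
    proportion_ci: tuple[float, float]
    proportion_p: float
    unreliable_total: bool

    def as_dict(self) -> dict:
        return {
            "total_beta": self.total.beta,
            "total_se": self.total.se,
            "step1_beta": self.step1.beta,
            "step1_se": self.step1.se,
            "step2_beta": self.step2.beta,
            "step2_se": self.step2.se,
            "indirect_beta": self.indirect.beta,
            "indirect_se": self.indirect.se,
            "indirect_p": self.indirect_p,
            "indirect_ci_low": self.indirect_ci[0],
            "indirect_ci_high": self.indirect_ci[1],
            "direct_beta": self.direct.beta,
            "direct_se": self.direct.se,
            "proportion_mediated": self.proportion_mediated,
            "proportion_ci_low": self.proportion_ci[0],
            "proportion_ci_high": self.proportion_ci[1],
            "proportion_p": self.proportion_p,
            "unreliable_total": self.unreliable_total,
        }


def indirect_effect(step1: Effect, step2: Effect, level: float = 0.95) -> tuple[Effect, float, tuple[float, float]]:
    """Product-of-coefficients indirect effect with first-order delta SE.

    ``beta = a·b``, ``se = sqrt(a²·se_b² + b²·se_a²)``; p-value and CI from
    the normal reference.  Symmetric in the two steps.
    """
    if step1.se <= 0 or step2.se <= 0:
        raise ValueError("step standard errors must be positive")
    a, b = step1.beta, step2.beta
    beta = a * b
    se = float(np.sqrt(a**2 * step2.se**2 + b**2 * step1.se**2))
    if se == 0:
        p = 0.0 if beta != 0 else 1.0
        return Effect(beta, se), p, (beta, beta)
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = float(2.0 * stats.norm.sf(abs(beta) / se))
    return Effect(beta, se), p, (beta - z * se, beta + z * se)


def mediated_proportion(
    indirect: Effect, total: Effect, level: float = 0.95
) -> tuple[float, tuple[float, float], float, bool]:
    """Mediated proportion ``indirect/total`` with delta-method CI.

    The two estimates are treated as independent normals; the ratio SE is
    ``|R|·sqrt(se_i²/i² + se_t²/t²)``.  Flagged unreliable when the total
    effect is weak (``|total/se_total| < 2``), where the ratio delta
    approximation degrades.
    Returns ``(proportion, ci, p, unreliable)``.
    """
    if total.beta == 0:
        raise ValueError("total effect is zero; proportion undefined")
    prop = indirect.beta / total.beta
    unreliable = total.se > 0 and abs(total.beta / total.se) < 2
    if indirect.beta == 0:
        se = abs(indirect.se / total.beta)
    else:
        se = abs(prop) * np.sqrt(
            indirect.se**2 / indirect.beta**2 + total.se**2 / total.beta**2
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = float(2.0 * stats.norm.sf(abs(prop) / se)) if se > 0 else (0.0 if prop else 1.0)
    return float(prop), (float(prop - z * se), float(prop + z * se)), p, bool(unreliable)


def mediation_analysis(
    total: Effect, step1: Effect, step2: Effect, level: float = 0.95
) -> MediationResult:
    """Assemble the full mediation decomposition from the three MR fits."""
    ind, ind_p, ind_ci = indirect_effect(step1, step2, level)
    direct = Effect(total.beta - ind.beta, float(np.sqrt(total.se**2 + ind.se**2)))
    prop, prop_ci, prop_p, unreliable = mediated_proportion(ind, total, level)
    return MediationResult(
        total=total,
        step1=step1,
        step2=step2,
        indirect=ind,
        indirect_p=ind_p,
        indirect_ci=ind_ci,
        direct=direct,
        proportion_mediated=prop,
        proportion_ci=prop_ci,
        proportion_p=prop_p,
        unreliable_total=unreliable,
    )
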