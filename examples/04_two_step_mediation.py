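"""Two-step MR mediation on a synthetic exposure → mediator → outcome chain.

The chain is generated with a = 0.3 (exposure→mediator), b = 0.5
(mediator→outcome) and direct effect c' = 0.1, so the true indirect effect
is a·b = 0.15, the total is 0.25, and the mediated proportion is 60%.
Each path is estimated by IVW on that trait's own instruments, and the
indirect effect uses the product of coefficients with a delta-method SE.
"""

from mrkit import (
    Effect,
    SimConfig,
    harmonize,
    ivw,
    mediation_analysis,
    simulate_mediation_triplet,
)

cfg = SimConfig(
    n_snps=100,
    exposure_h2=0.1,
    n_exp=2_000_000,
    n_med=500_000,
    n_out=100_000,
    mediation=(0.3, 0.5, 0.1),
    seed=21,
)
exposure, mediator, outcome, truth = simulate_mediation_triplet(cfg)
xids = [i for i in exposure.table["snp_id"] if i.startswith("rsX")]
mids = [i for i in exposure.table["snp_id"] if i.startswith("rsM")]

total = ivw(harmonize(exposure, outcome, xids))
step1 = ivw(harmonize(exposure, mediator, xids))
step2 = ivw(harmonize(mediator, outcome, mids))
res = mediation_analysis(
    Effect(total.beta, total.se), Effect(step1.beta, step1.se), Effect(step2.beta, step2.se)
)

print(f"true indirect = {truth.true_indirect:.3f}, true total = {truth.true_total:.3f}")
print(f"step 1 (exposure->mediator): a = {res.step1.beta:.4f} +/- {res.step1.se:.4f}")
print(f"step 2 (mediator->outcome):  b = {res.step2.beta:.4f} +/- {res.step2.se:.4f}")
print(f"total effect:                {res.total.beta:.4f} +/- {res.total.se:.4f}")
print(
    f"indirect (a*b):              {res.indirect.beta:.4f} +/- {res.indirect.se:.4f} "
    f"(p = {res.indirect_p:.2e})"
)
print(f"direct (total - indirect):   {res.direct.beta:.4f}")
print(
    f"mediated proportion:         {100 * res.proportion_mediated:.1f}% "
    f"(95% CI {100 * res.proportion_ci[0]:.1f}%-{100 * res.proportion_ci[1]:.1f}%)"
)
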