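"""Simulate a two-sample GWAS pair with a known causal effect and run the
five-method estimator panel.

The generator plants a true exposure→outcome log-odds slope of 0.3 across
100 independent instruments; every estimator should land near it.  The
printed odds ratio is exp(slope): the multiplicative risk increase per SD
of genetically predicted exposure.
"""

from mrkit import SimConfig, harmonize, run_all_estimators, simulate_gwas_pair

cfg = SimConfig(
    n_snps=100,
    true_slope=0.3,
    exposure_h2=0.05,
    n_exp=500_000,
    n_out=100_000,
    seed=1,
)
exposure, outcome, truth = simulate_gwas_pair(cfg)
data = harmonize(exposure, outcome, list(exposure.table["snp_id"]))

print(f"true slope: {truth.true_slope:.3f}  (OR {2.718281828**truth.true_slope:.3f})")
print(f"{'method':16s} {'beta':>8s} {'se':>8s} {'OR':>6s} {'95% CI':>16s} {'p':>10s}")
for est in run_all_estimators(data, n_boot=500, seed=7):
    ci = f"({est.ci_low:.3f}, {est.ci_high:.3f})"
    print(
        f"{est.method:16s} {est.beta:8.4f} {est.se:8.4f} "
        f"{est.or_value:6.3f} {ci:>16s} {est.pval:10.2e}"
    )
print(
    "\nAll five methods agree because the simulated instruments are valid:\n"
    "no pleiotropy was planted, so IVW is unbiased and the robust methods\n"
    "pay only a small efficiency price."
)
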