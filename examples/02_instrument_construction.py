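"""Instrument construction stage by stage: significance filtering, LD
clumping, proxy substitution, harmonization and the post-harmonization
filters.

A block-diagonal LD matrix makes the clumping visible: each 3-variant block
collapses to its most significant member.  One retained variant is then
removed from the outcome dataset to show proxy substitution.
"""

import numpy as np

from mrkit import (
    GwasDataset,
    SimConfig,
    drop_palindromic,
    find_proxies,
    harmonize,
    ld_clump,
    radial_filter,
    select_instruments,
    simulate_gwas_pair,
    simulate_ld_matrix,
    steiger_filter,
)

cfg = SimConfig(
    n_snps=30,
    true_slope=0.25,
    exposure_h2=0.04,
    n_exp=500_000,
    n_out=100_000,
    ld_blocks=[3] * 10,
    ld_block_r2=0.9,
    seed=11,
)
exposure, outcome, _ = simulate_gwas_pair(cfg)
ld = simulate_ld_matrix(cfg)

# collapse positions so each LD block sits inside one clumping window
tbl = exposure.table.copy()
tbl["pos"] = 1e6 + np.arange(len(tbl)) * 1e3
exposure = GwasDataset(exposure.trait_name, exposure.trait_type, tbl)

candidates = select_instruments(exposure, 5e-8)
print(f"genome-wide significant candidates: {len(candidates)}")

clumped = ld_clump(candidates, exposure, ld, r2_threshold=0.001, window_kb=10_000)
print(f"after LD clumping (r2 > 0.001, 10,000 kb): {len(clumped)} (one per block)")

# drop one clumped variant from the outcome to force a proxy lookup
missing = clumped[0]
out_tbl = outcome.table.loc[outcome.table["snp_id"] != missing]
outcome = GwasDataset(outcome.trait_name, outcome.trait_type, out_tbl)
proxies = find_proxies([missing], ld, outcome, r2_min=0.8)
print(f"proxy for {missing}: {proxies.get(missing)}")

data = harmonize(exposure, outcome, clumped, proxies)
data = drop_palindromic(data)
data = radial_filter(data, alpha=0.05)
data = steiger_filter(data)
print(f"instruments surviving the full chain: {data.n_snps}")
print("dropped ledger:")
print(data.dropped.to_string(index=False) if len(data.dropped) else "  (nothing dropped)")
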