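import numpy as np
import pandas as pd
import pytest

from mrkit.instruments import HARMONIZED_COLUMNS, HarmonizedData


def _make_harmonized(beta_exp, beta_out, se_out, se_exp=None, **overrides):
    """Build a HarmonizedData from effect arrays with sensible defaults."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.broadcast_to(np.asarray(se_out, dtype=float), beta_exp.shape)
    if se_exp is None:
        se_exp = np.full_like(beta_exp, 0.01)
    else:
        se_exp = np.broadcast_to(np.asarray(se_exp, dtype=float), beta_exp.shape)
    k = len(beta_exp)
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1}" for i in range(k)],
            "chrom": "1",
            "pos": (1 + np.arange(k)) * 1e6,
            "effect_allele": "A",
            "other_allele": "G",
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "eaf_exp": 0.3,
            "n_exp": 100_000.0,
            "pval_exp": 1e-10,
            "beta_out": beta_out,
            "se_out": se_out,
            "eaf_out": 0.3,
            "n_out": 100_000.0,
            "proxy_id": None,
            "proxy_r2": np.nan,
            "flipped": False,
        },
        columns=HARMONIZED_COLUMNS,
    )
    for key, val in overrides.items():
        df[key] = val
    return HarmonizedData(df)


@pytest.fixture
def make_hd():
    return _make_harmonized
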