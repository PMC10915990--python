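import itertools

import numpy as np
import pandas as pd
import pytest

from mrkit.instruments import (
    HarmonizedData,
    LdMatrix,
    drop_palindromic,
    find_proxies,
    harmonize,
    ld_clump,
    radial_filter,
    select_instruments,
    steiger_filter,
)
from mrkit.simulate import SimConfig, simulate_gwas_pair
from mrkit.sumstats import CANONICAL_COLUMNS, GwasDataset


def _dataset(rows, name="exp"):
    return GwasDataset(name, "continuous", pd.DataFrame(rows, columns=CANONICAL_COLUMNS))


def _row(snp, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, pval=1e-9, n=10000.0, chrom="1", pos=1e6):
    return [snp, chrom, pos, ea, oa, eaf, beta, se, pval, n]


class TestLdMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
        with pytest.raises(ValueError):
            LdMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))  # diagonal != 1

    def test_absent_pairs_unlinked(self):
        ld = LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert ld.lookup_r2("a", "zzz") == 0.0

    def test_long_and_square_loaders_agree(self, tmp_path):
        sq = tmp_path / "sq.tsv"
        pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=["a", "b"], columns=["a", "b"]).to_csv(
            sq, sep="\t"
        )
        lg = tmp_path / "lg.tsv"
        pd.DataFrame({"id_a": ["a"], "id_b": ["b"], "r2": [0.7]}).to_csv(lg, sep="\t", index=False)
        m1, m2 = LdMatrix.from_square_tsv(sq), LdMatrix.from_long_tsv(lg)
        assert m1.lookup_r2("a", "b") == m2.lookup_r2("a", "b") == 0.7


class TestSelectInstruments:
    def test_strict_threshold(self):
        ds = _dataset([_row("rs1", pval=1e-9), _row("rs2", pval=1e-7)])
        assert select_instruments(ds, 5e-8) == ["rs1"]

    def test_threshold_one_keeps_all(self):
        ds = _dataset([_row("rs1", pval=0.5), _row("rs2", pval=0.99)])
        assert set(select_instruments(ds, 1.0)) == {"rs1", "rs2"}

    def test_simulated_causal_snps_recovered(self):
        # 90 null variants plus 10 strong ones at large n: all 10 selected
        rng = np.random.default_rng(42)
        from scipy import stats

        rows = []
        for i in range(100):
            beta_true = 0.05 if i < 10 else 0.0
            se = 0.004
            beta = beta_true + rng.normal(0, se)
            p = 2 * stats.norm.sf(abs(beta / se))
            rows.append(_row(f"rs{i}", beta=beta, se=se, pval=max(p, 5e-324)))
        sel = set(select_instruments(_dataset(rows), 5e-8))
        assert {f"rs{i}" for i in range(10)} <= sel


class TestLdClump:
    def _trio(self):
        return _dataset(
            [
                _row("rsA", pval=1e-20, pos=1_000_000),
                _row("rsB", pval=1e-10, pos=1_050_000),
                _row("rsC", pval=1e-9, pos=9_000_000),
            ]
        )

    def test_unlinked_all_kept(self):
        ld = LdMatrix(["rsA", "rsB", "rsC"], np.eye(3))
        assert set(ld_clump(["rsA", "rsB", "rsC"], self._trio(), ld, 0.001, 10_000)) == {
            "rsA",
            "rsB",
            "rsC",
        }

    def test_greedy_rule(self):
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        ld = LdMatrix(["rsA", "rsB", "rsC"], r2)
        assert set(ld_clump(["rsA", "rsB", "rsC"], self._trio(), ld, 0.001, 10_000)) == {"rsA", "rsC"}

    def test_window_rule(self):
        ds = _dataset(
            [_row("rsA", pval=1e-20, pos=1e6), _row("rsB", pval=1e-10, pos=1e6 + 2e10)]
        )
        r2 = np.array([[1.0, 0.5], [0.5, 1.0]])
        ld = LdMatrix(["rsA", "rsB"], r2)
        assert set(ld_clump(["rsA", "rsB"], ds, ld, 0.001, 10_000)) == {"rsA", "rsB"}

    def test_order_independent_and_no_linked_pair_kept(self):
        rng = np.random.default_rng(3)
        k = 8
        ids = [f"rs{i}" for i in range(k)]
        ds = _dataset(
            [_row(ids[i], pval=float(rng.uniform(1e-12, 1e-8)), pos=1e6 + i * 1e4) for i in range(k)]
        )
        a = rng.uniform(0, 1, (k, k))
        r2 = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        ld = LdMatrix(ids, r2)
        ref = ld_clump(ids, ds, ld, 0.2, 10_000)
        for perm in itertools.islice(itertools.permutations(ids), 20):
            assert ld_clump(list(perm), ds, ld, 0.2, 10_000) == ref
        for a_id, b_id in itertools.combinations(ref, 2):
            assert ld.lookup_r2(a_id, b_id) <= 0.2


class TestFindProxies:
    def _ld(self, r2ab, r2ac=0.0, sign=True):
        ids = ["rsA", "rsB", "rsC"]
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = r2ab
        r2[0, 2] = r2[2, 0] = r2ac
        return LdMatrix(ids, r2, np.ones((3, 3)) if sign else None)

    def _outcome(self):
        return _dataset([_row("rsB"), _row("rsC")], name="out")

    def test_strong_proxy_substituted(self):
        subs = find_proxies(["rsA"], self._ld(0.95), self._outcome())
        assert subs["rsA"][0] == "rsB"

    def test_weak_proxy_not_substituted(self):
        assert find_proxies(["rsA"], self._ld(0.6), self._outcome()) == {}

    def test_best_of_two_proxies_chosen(self):
        subs = find_proxies(["rsA"], self._ld(0.85, 0.92), self._outcome())
        assert subs["rsA"][0] == "rsC"
        assert subs["rsA"][1] == pytest.approx(0.92)

    def test_proxy_without_sign_dropped(self):
        assert find_proxies(["rsA"], self._ld(0.95, sign=False), self._outcome()) == {}


class TestHarmonize:
    def test_allele_truth_table(self):
        # enumerate allele-order x strand cases for an A/G exposure variant
        cases = [
            (("A", "G"), 0.05, 0.2, 0.05, 0.2, False),  # exact match
            (("G", "A"), -0.05, 0.8, 0.05, 0.2, True),  # swapped order
            (("T", "C"), 0.05, 0.2, 0.05, 0.2, False),  # strand complement
            (("C", "T"), -0.05, 0.8, 0.05, 0.2, True),  # complement + swap
        ]
        for (ea, oa), beta, eaf, want_beta, want_eaf, want_flip in cases:
            exp = _dataset([_row("rs1", "A", "G", beta=0.1, eaf=0.2)])
            out = _dataset([_row("rs1", ea, oa, beta=beta, eaf=eaf)], name="out")
            h = harmonize(exp, out, ["rs1"])
            assert h.n_snps == 1, (ea, oa)
            row = h.table.iloc[0]
            assert row["beta_out"] == pytest.approx(want_beta)
            assert row["eaf_out"] == pytest.approx(want_eaf)
            assert bool(row["flipped"]) is want_flip

    def test_incompatible_alleles_dropped_with_reason(self):
        exp = _dataset([_row("rs1", "A", "G")])
        out = _dataset([_row("rs1", "A", "C")], name="out")
        h = harmonize(exp, out, ["rs1"])
        assert h.n_snps == 0
        assert h.dropped.iloc[0]["reason"] == "incompatible_alleles"

    def test_conservation(self):
        exp = _dataset([_row("rs1"), _row("rs2"), _row("rs3", "A", "C")])
        out = _dataset([_row("rs1"), _row("rs3", "T", "G")], name="out")
        h = harmonize(exp, out, ["rs1", "rs2", "rs3"])
        seen = set(h.table["snp_id"]) | set(h.dropped["snp_id"])
        assert seen == {"rs1", "rs2", "rs3"}
        assert len(h.table) + len(h.dropped) == 3

    def test_involution_on_aligned_data(self):
        exp = _dataset([_row("rs1"), _row("rs2", beta=-0.2)])
        out = _dataset([_row("rs1", beta=0.04), _row("rs2", beta=-0.1)], name="out")
        h1 = harmonize(exp, out, ["rs1", "rs2"])
        assert not h1.table["flipped"].any()
        assert list(h1.table["beta_out"]) == [0.04, -0.1]

    def test_proxy_substitution_uses_ld_sign(self):
        exp = _dataset([_row("rs1", beta=0.1)])
        out = _dataset([_row("rs2", beta=0.07, eaf=0.25)], name="out")
        subs = {"rs1": ("rs2", 0.95, -1.0)}
        h = harmonize(exp, out, ["rs1"], proxies=subs)
        row = h.table.iloc[0]
        assert row["proxy_id"] == "rs2"
        assert row["beta_out"] == pytest.approx(-0.07)
        assert row["eaf_out"] == pytest.approx(0.75)


class TestDropPalindromic:
    def test_intermediate_frequency_removed(self):
        exp = _dataset([_row("rs1", "A", "T", eaf=0.5)])
        out = _dataset([_row("rs1", "A", "T", eaf=0.5)], name="out")
        h = drop_palindromic(harmonize(exp, out, ["rs1"]))
        assert h.n_snps == 0
        assert h.dropped.iloc[0]["reason"] == "palindromic_intermediate_eaf"

    def test_extreme_concordant_retained(self):
        exp = _dataset([_row("rs1", "A", "T", eaf=0.10)])
        out = _dataset([_row("rs1", "A", "T", eaf=0.12)], name="out")
        h = drop_palindromic(harmonize(exp, out, ["rs1"]))
        assert h.n_snps == 1
        assert not h.table.iloc[0]["flipped"]

    def test_discordant_frequency_flips_sign(self):
        exp = _dataset([_row("rs1", "C", "G", eaf=0.10, beta=0.1)])
        out = _dataset([_row("rs1", "C", "G", eaf=0.90, beta=0.05)], name="out")
        h = drop_palindromic(harmonize(exp, out, ["rs1"]))
        row = h.table.iloc[0]
        assert row["beta_out"] == pytest.approx(-0.05)
        assert row["eaf_out"] == pytest.approx(0.10)


class TestSteigerFilter:
    def _hd(self, beta_exp, beta_out, n_exp=10000.0, n_out=10000.0):
        exp = _dataset([_row("rs1", beta=beta_exp, se=0.01, n=n_exp)])
        out = _dataset([_row("rs1", beta=beta_out, se=0.01, n=n_out)], name="out")
        return harmonize(exp, out, ["rs1"])

    def test_exposure_stronger_retained(self):
        assert steiger_filter(self._hd(0.05, 0.02)).n_snps == 1

    def test_outcome_stronger_removed(self):
        h = steiger_filter(self._hd(0.02, 0.05))
        assert h.n_snps == 0
        assert h.dropped.iloc[0]["stage"] == "steiger"

    def test_forward_simulation_rarely_removed(self):
        # genome-wide-significant instruments of a causal exposure almost
        # always explain more exposure than outcome variance
        e, o, _ = simulate_gwas_pair(
            SimConfig(n_snps=200, true_slope=0.3, exposure_h2=0.05, n_exp=100_000, n_out=100_000, seed=8)
        )
        h = harmonize(e, o, select_instruments(e))
        kept = steiger_filter(h)
        assert (h.n_snps - kept.n_snps) / h.n_snps < 0.05

    def test_idempotent(self):
        e, o, _ = simulate_gwas_pair(
            SimConfig(n_snps=50, true_slope=0.3, exposure_h2=0.02, n_exp=50_000, n_out=200_000, seed=9)
        )
        h = steiger_filter(harmonize(e, o, list(e.table["snp_id"])))
        again = steiger_filter(h)
        assert list(again.table["snp_id"]) == list(h.table["snp_id"])


class TestRadialFilter:
    def test_identical_ratios_nothing_removed(self, make_hd):
        h = make_hd([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], 0.01)
        assert radial_filter(h).n_snps == 3

    def test_planted_outlier_removed(self, make_hd):
        bexp = np.full(11, 0.1)
        bout = np.full(11, 0.02)
        bout[-1] = 0.5  # ratio 5.0 against a tight 0.2 consensus
        h = make_hd(bexp, bout, 0.002)
        out = radial_filter(h, alpha=0.05)
        assert "rs11" not in set(out.table["snp_id"])
        assert out.n_snps == 10

    def test_alpha_zero_never_removes(self, make_hd):
        bexp = np.full(11, 0.1)
        bout = np.full(11, 0.02)
        bout[-1] = 0.5
        assert radial_filter(make_hd(bexp, bout, 0.002), alpha=0.0).n_snps == 11

    def test_pass_through_below_two(self, make_hd):
        h = make_hd([0.1], [0.05], 0.01)
        assert radial_filter(h).n_snps == 1

    def test_idempotent(self):
        e, o, _ = simulate_gwas_pair(
            SimConfig(
                n_snps=60,
                true_slope=0.2,
                exposure_h2=0.02,
                n_exp=300_000,
                n_out=100_000,
                pleiotropy="balanced",
                pleiotropy_sd=0.02,
                invalid_fraction=0.2,
                seed=10,
            )
        )
        h = radial_filter(harmonize(e, o, list(e.table["snp_id"])), alpha=0.05)
        again = radial_filter(h, alpha=0.05)
        assert list(again.table["snp_id"]) == list(h.table["snp_id"])
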