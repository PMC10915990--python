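"""Instrument construction: significance filtering, LD clumping, proxy
substitution, allele harmonization, palindromic removal, Steiger filtering
and radial-Q outlier removal.

All stages are pure functions from/to :class:`HarmonizedData` or identifier
sets, and every discarded variant is recorded in a dropped ledger so that the
pipeline can assert conservation: candidates = retained + dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import GwasDataset, variance_explained

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

HARMONIZED_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "eaf_exp",
    "n_exp",
    "pval_exp",
    "beta_out",
    "se_out",
    "eaf_out",
    "n_out",
    "proxy_id",
    "proxy_r2",
    "flipped",
]


@dataclass
class LdMatrix:
    """Pairwise squared correlations between variants.

    ``r2`` is symmetric with unit diagonal; ``sign`` (optional, same shape)
    gives the sign of the allelic correlation between the *effect-allele*
    dosages of each pair, and is required to phase-align proxy variants.
    """

    snp_ids: list[str]
    r2: np.ndarray
    sign: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError("r2 shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup_r2(self, a: str, b: str) -> float:
        """r² between two variants; absent pairs are unlinked (0)."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])

    def lookup_sign(self, a: str, b: str) -> float | None:
        if self.sign is None:
            return None
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(np.sign(self.sign[ia, ib]))

    @classmethod
    def from_square_tsv(cls, path) -> "LdMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    @classmethod
    def from_long_tsv(cls, path) -> "LdMatrix":
        """Long format: columns id_a, id_b, r2[, sign]; unlisted pairs are 0."""
        df = pd.read_csv(path, sep="\t")
        ids = sorted(set(df.iloc[:, 0].astype(str)) | set(df.iloc[:, 1].astype(str)))
        idx = {s: i for i, s in enumerate(ids)}
        k = len(ids)
        r2 = np.eye(k)
        sign = np.ones((k, k)) if df.shape[1] > 3 else None
        for row in df.itertuples(index=False):
            ia, ib = idx[str(row[0])], idx[str(row[1])]
            r2[ia, ib] = r2[ib, ia] = float(row[2])
            if sign is not None:
                sign[ia, ib] = sign[ib, ia] = float(row[3])
        return cls(ids, r2, sign)


@dataclass
class HarmonizedData:
    """Aligned exposure/outcome effect pairs — the unit of all estimation.

    ``table`` has one row per retained variant with exposure and outcome
    effects expressed for the same effect allele; ``dropped`` ledgers every
    variant discarded at any stage with the stage name and reason.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "stage", "reason"])
    )

    def __post_init__(self) -> None:
        missing = [c for c in HARMONIZED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"harmonized table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)
        self.dropped = self.dropped.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def drop(self, mask, stage: str, reason) -> "HarmonizedData":
        """New object without rows where *mask* is True, ledgering them."""
        mask = np.asarray(mask, dtype=bool)
        gone = self.table.loc[mask, ["snp_id"]].copy()
        gone["stage"] = stage
        gone["reason"] = np.asarray(reason)[mask] if np.ndim(reason) else reason
        return HarmonizedData(
            self.table.loc[~mask].copy(),
            pd.concat([self.dropped, gone], ignore_index=True),
        )


# ---------------------------------------------------------------------------
# stage 1: significance filtering and LD clumping
# ---------------------------------------------------------------------------

def select_instruments(exposure: GwasDataset, p_threshold: float = 5e-8) -> list[str]:
    """Variants associated with the exposure at ``p < p_threshold`` (strict)."""
    if not 0 < p_threshold <= 1:
        raise ValueError("p_threshold must lie in (0, 1]")
    sel = exposure.table.loc[exposure.table["pval"] < p_threshold, "snp_id"]
    ids = sorted(sel.astype(str))
    if not ids:
        logger.warning("no variants pass p < %g for %s", p_threshold, exposure.trait_name)
    return ids


def ld_clump(
    candidates,
    exposure: GwasDataset,
    ld: LdMatrix,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[str]:
    """Greedy LD clumping by ascending p-value.

    Keeps the most significant variant, then discards any candidate with
    r² > *r2_threshold* to an already-kept variant within *window_kb*
    (inclusive, same chromosome).  Ties on p are broken by position then
    identifier, so the result is independent of input ordering.  Variants
    absent from the LD matrix are treated as unlinked.
    """
    sub = exposure.table.loc[exposure.table["snp_id"].isin(set(candidates))]
    order = sub.sort_values(
        ["pval", "pos", "snp_id"], kind="mergesort"
    )[["snp_id", "chrom", "pos"]].to_numpy(dtype=object)
    kept: list[tuple[str, object, float]] = []
    window_bp = window_kb * 1000.0
    for snp, chrom, pos in order:
        linked = False
        for ksnp, kchrom, kpos in kept:
            if chrom != kchrom or pd.isna(pos) or pd.isna(kpos):
                continue
            if abs(float(pos) - float(kpos)) <= window_bp:
                if ld.lookup_r2(snp, ksnp) > r2_threshold:
                    linked = True
                    break
        if not linked:
            kept.append((snp, chrom, pos))
    return [k[0] for k in kept]


def find_proxies(
    missing,
    ld: LdMatrix,
    outcome: GwasDataset,
    r2_min: float = 0.8,
) -> dict[str, tuple[str, float, float]]:
    """Best proxy present in the outcome for each missing instrument.

    Returns ``{missing_id: (proxy_id, r2, sign)}``.  A proxy needs
    r² > *r2_min* and a known allelic-correlation sign (from ``ld.sign``);
    without a sign the pair cannot be phase-aligned and the instrument is
    dropped rather than guessed.
    """
    if not 0 < r2_min < 1:
        raise ValueError("r2_min must lie in (0, 1)")
    available = set(outcome.table["snp_id"].astype(str))
    subs: dict[str, tuple[str, float, float]] = {}
    for snp in sorted(set(missing)):
        best_id, best_r2 = None, r2_min
        for cand in ld.snp_ids:
            if cand == snp or cand not in available:
                continue
            r2 = ld.lookup_r2(snp, cand)
            if r2 > best_r2:
                best_id, best_r2 = cand, r2
        if best_id is None:
            logger.info("no proxy with r2 > %g for %s", r2_min, snp)
            continue
        sign = ld.lookup_sign(snp, best_id)
        if sign is None or sign == 0:
            logger.warning("proxy %s for %s lacks an alignment sign; dropped", best_id, snp)
            continue
        subs[snp] = (best_id, best_r2, sign)
    return subs


# ---------------------------------------------------------------------------
# stage 2: harmonization
# ---------------------------------------------------------------------------

def _align_outcome(ea_exp, oa_exp, ea_out, oa_out):
    """Classify an outcome allele pair against the exposure pair.

    Returns ``(flip, ok)``: *flip* means the outcome effect refers to the
    exposure's other allele (negate beta, mirror eaf); *ok* False means the
    pairs are incompatible.
    """
    comp_ea, comp_oa = _COMPLEMENT[ea_out], _COMPLEMENT[oa_out]
    if (ea_out, oa_out) == (ea_exp, oa_exp):
        return False, True
    if (ea_out, oa_out) == (oa_exp, ea_exp):
        return True, True
    if (comp_ea, comp_oa) == (ea_exp, oa_exp):
        return False, True
    if (comp_ea, comp_oa) == (oa_exp, ea_exp):
        return True, True
    return False, False


def harmonize(
    exposure: GwasDataset,
    outcome: GwasDataset,
    iv_ids,
    proxies: dict[str, tuple[str, float, float]] | None = None,
) -> HarmonizedData:
    """Align outcome effects to the exposure effect allele, variant by variant.

    Swapped allele order flips the outcome beta and mirrors its frequency;
    strand-complement pairs are complemented first; incompatible pairs are
    dropped with a reason.  Instruments missing from the outcome may be
    served by a proxy substitution map from :func:`find_proxies` — the proxy's
    outcome effect is oriented with the LD sign and reported under the
    original identifier.
    """
    proxies = proxies or {}
    out_idx = outcome.table.set_index(outcome.table["snp_id"].astype(str))
    rows, dropped = [], []
    for snp in sorted(set(iv_ids)):
        try:
            erec = exposure.lookup(snp)
        except KeyError:
            dropped.append((snp, "harmonize", "absent_from_exposure"))
            continue
        proxy_id, proxy_r2 = None, np.nan
        if snp in out_idx.index:
            orec = out_idx.loc[snp]
            beta_out, eaf_out = float(orec["beta"]), orec["eaf"]
            ea_out, oa_out = orec["effect_allele"], orec["other_allele"]
        elif snp in proxies:
            proxy_id, proxy_r2, sign = proxies[snp]
            orec = out_idx.loc[proxy_id]
            # orient the proxy effect onto the exposure SNP's effect allele
            beta_out = float(orec["beta"]) * sign
            eaf_out = orec["eaf"] if sign > 0 else (
                1.0 - orec["eaf"] if pd.notna(orec["eaf"]) else np.nan
            )
            ea_out, oa_out = erec["effect_allele"], erec["other_allele"]
        else:
            dropped.append((snp, "harmonize", "absent_from_outcome"))
            continue

        flip, ok = _align_outcome(
            erec["effect_allele"], erec["other_allele"], ea_out, oa_out
        )
        if not ok:
            dropped.append((snp, "harmonize", "incompatible_alleles"))
            continue
        if flip:
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if pd.notna(eaf_out) else np.nan
        rows.append(
            {
                "snp_id": snp,
                "chrom": erec["chrom"],
                "pos": erec["pos"],
                "effect_allele": erec["effect_allele"],
                "other_allele": erec["other_allele"],
                "beta_exp": float(erec["beta"]),
                "se_exp": float(erec["se"]),
                "eaf_exp": erec["eaf"],
                "n_exp": erec["n"],
                "pval_exp": erec["pval"],
                "beta_out": beta_out,
                "se_out": float(orec["se"]),
                "eaf_out": eaf_out,
                "n_out": orec["n"],
                "proxy_id": proxy_id,
                "proxy_r2": proxy_r2,
                "flipped": bool(flip),
            }
        )
    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    ledger = pd.DataFrame(dropped, columns=["snp_id", "stage", "reason"])
    return HarmonizedData(table, ledger)


# ---------------------------------------------------------------------------
# stage 3: post-harmonization filters
# ---------------------------------------------------------------------------

def drop_palindromic(
    data: HarmonizedData, ambiguity_window: tuple[float, float] = (0.42, 0.58)
) -> HarmonizedData:
    """Remove strand-ambiguous A/T and C/G variants at intermediate frequency.

    Palindromic variants with extreme frequencies are retained; when exposure
    and outcome frequencies fall on opposite sides of 0.5 the outcome record
    is assumed to be reported on the other strand and its sign is flipped.
    """
    lo, hi = ambiguity_window
    df = data.table
    pairs = df["effect_allele"].map(_COMPLEMENT.get) == df["other_allele"]
    eaf = pd.to_numeric(df["eaf_exp"], errors="coerce")
    ambiguous = pairs & ((eaf.isna()) | ((eaf > lo) & (eaf < hi)))
    out = data.drop(ambiguous.to_numpy(), "palindromic", "palindromic_intermediate_eaf")

    df = out.table
    pairs = df["effect_allele"].map(_COMPLEMENT.get) == df["other_allele"]
    eo = pd.to_numeric(df["eaf_out"], errors="coerce")
    ee = pd.to_numeric(df["eaf_exp"], errors="coerce")
    discordant = (pairs & eo.notna() & ee.notna() & ((ee - 0.5) * (eo - 0.5) < 0)).to_numpy()
    if discordant.any():
        tbl = df.copy()
        tbl.loc[discordant, "beta_out"] = -tbl.loc[discordant, "beta_out"]
        tbl.loc[discordant, "eaf_out"] = 1.0 - tbl.loc[discordant, "eaf_out"]
        tbl.loc[discordant, "flipped"] = True
        out = HarmonizedData(tbl, out.dropped)
    return out


def steiger_filter(data: HarmonizedData, significance: bool = False, alpha: float = 0.05) -> HarmonizedData:
    """Enforce causal direction: drop variants explaining more outcome than
    exposure variance.

    The default decision is the plain r² comparison.  With ``significance``
    the variant is only dropped when the difference is also significant under
    a Steiger z-test of the implied correlations.
    """
    df = data.table
    n_exp = pd.to_numeric(df["n_exp"], errors="coerce")
    n_out = pd.to_numeric(df["n_out"], errors="coerce")
    known = n_exp.notna() & n_out.notna()
    if (~known).any():
        logger.warning("%d variants lack sample sizes; retained by Steiger filter", int((~known).sum()))
    r2_exp = np.where(
        known, variance_explained(df["beta_exp"], df["se_exp"], n_exp.fillna(1.0)), 0.0
    )
    r2_out = np.where(
        known, variance_explained(df["beta_out"], df["se_out"], n_out.fillna(1.0)), 0.0
    )
    remove = known.to_numpy() & (r2_out > r2_exp)
    if significance:
        # Steiger z: compare Fisher-transformed correlations across samples
        r_exp, r_out = np.sqrt(r2_exp), np.sqrt(r2_out)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (np.arctanh(r_out) - np.arctanh(r_exp)) / np.sqrt(
                1.0 / np.maximum(n_out.fillna(3.0) - 3.0, 1.0)
                + 1.0 / np.maximum(n_exp.fillna(3.0) - 3.0, 1.0)
            )
        remove &= stats.norm.sf(z) < alpha
    return data.drop(remove, "steiger", "explains_more_outcome_variance")


def radial_filter(data: HarmonizedData, alpha: float = 0.05, max_iter: int = 50) -> HarmonizedData:
    """Iterative radial-regression outlier removal.

    Fits the inverse-variance-weighted slope in radial form (first-order
    weights w = beta_exp²/se_out²), refers each variant's contribution
    Q_j = w_j (ratio_j − slope)² to χ²(1), removes the worst variant with
    p < *alpha*, and refits until no outlier remains or fewer than 3
    variants would be left.  One-at-a-time removal keeps a single gross
    outlier from inflating every other variant's contribution.
    """
    out = data
    if out.n_snps < 2:
        logger.warning("radial filter needs >= 2 variants; passing through")
        return out
    for _ in range(max_iter):
        df = out.table
        bexp = df["beta_exp"].to_numpy(dtype=float)
        bout = df["beta_out"].to_numpy(dtype=float)
        seout = df["se_out"].to_numpy(dtype=float)
        ratio = bout / bexp
        w = bexp**2 / seout**2
        slope = float(np.sum(w * ratio) / np.sum(w))
        q = w * (ratio - slope) ** 2
        pvals = stats.chi2.sf(q, df=1)
        worst = int(np.argmax(q))
        if pvals[worst] >= alpha:
            break
        if out.n_snps - 1 < 3:
            logger.warning("radial filter stopped: < 3 variants would remain")
            break
        remove = np.zeros(out.n_snps, dtype=bool)
        remove[worst] = True
        out = out.drop(remove, "radial", "radial_q_outlier")
    return out
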