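"""End-to-end study orchestration.

One direction of analysis runs the full stage chain — instrument selection,
LD clumping, confounder exclusion, proxy substitution, harmonization,
palindromic removal, radial outlier removal, Steiger filtering — followed by
the five estimators, heterogeneity statistics, the Egger intercept test,
MR-PRESSO, and leave-one-out.  Bidirectional and two-step (mediation) designs
compose that chain.  Every stochastic stage is seeded from a master seed via
a fixed derivation, so a re-run of the same configuration reproduces its
reports byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as est
from . import instruments as ins
from . import sensitivity as sens
from .mediation import Effect, mediation_analysis
from .sumstats import ConfigurationError, GwasDataset, f_statistic, variance_explained

logger = logging.getLogger(__name__)

# fixed stage codes: adding a stage appends a code and never re-seeds others
_STAGE_CODES = {"median": 11, "mode": 12, "presso": 13}


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the master seed (< 2**31)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_STAGE_CODES[stage],))
    return int(ss.generate_state(1)[0] % 2**31)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


@dataclass
class StudyConfig:
    """All stage thresholds and seeds for one study.

    ``n_tests`` is the user-declared size of the test family for Bonferroni
    correction (the pipeline also records its own count of configured
    primary tests; the declared value wins).
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000.0
    proxy_r2: float = 0.8
    palindromic_window: tuple[float, float] = (0.42, 0.58)
    radial_alpha: float = 0.05
    alpha: float = 0.05
    n_tests: int = 1
    n_boot: int = 1000
    presso_n_sim: int = 1000
    ivw_model: str = "multiplicative-random"
    mediation_gate: str = "family"  # family | nominal
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ConfigurationError("n_tests must be >= 1")
        if self.mediation_gate not in ("family", "nominal"):
            raise ConfigurationError("mediation_gate must be 'family' or 'nominal'")

    @property
    def family_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_tests)


def _estimate_panel(data: ins.HarmonizedData, config: StudyConfig) -> list[dict]:
    """Run all five estimators, recording per-method failures instead of dying."""
    panel = []
    runners = [
        ("IVW", lambda: est.ivw(data, model=config.ivw_model)),
        ("MR-RAPS", lambda: est.mr_raps(data, loss="huber", overdispersion=True)),
        ("MR-Egger", lambda: est.egger(data)),
        (
            "weighted-median",
            lambda: est.weighted_median(
                data, n_boot=config.n_boot, seed=derive_seed(config.master_seed, "median")
            ),
        ),
        (
            "weighted-mode",
            lambda: est.weighted_mode(
                data, n_boot=config.n_boot, seed=derive_seed(config.master_seed, "mode")
            ),
        ),
    ]
    for name, run in runners:
        try:
            panel.append(run().as_dict())
        except (est.EstimationError, ValueError) as exc:
            logger.warning("%s failed: %s", name, exc)
            panel.append({"method": name, "error": str(exc)})
    return panel


def run_mr(
    exposure: GwasDataset,
    outcome: GwasDataset,
    config: StudyConfig,
    ld: ins.LdMatrix | None = None,
    confounder_assoc: pd.DataFrame | None = None,
    n_risk_factors: int = 0,
    label: str | None = None,
) -> dict:
    """One exposure→outcome MR analysis through the full stage chain.

    Returns a JSON-ready report: per-stage instrument counts, the dropped
    ledger, instrument-strength summaries, the five-method estimate panel,
    and the sensitivity suite.  A run ending with fewer than two instruments
    is marked not-estimable rather than raising.
    """
    label = label or f"{exposure.trait_name}->{outcome.trait_name}"
    report: dict = {"pair": label, "config": asdict(config)}
    counts: dict[str, int] = {}
    extra_dropped: list[tuple[str, str, str]] = []

    candidates = ins.select_instruments(exposure, config.p_threshold)
    counts["selected"] = len(candidates)

    if ld is not None:
        clumped = ins.ld_clump(candidates, exposure, ld, config.clump_r2, config.clump_window_kb)
        extra_dropped += [(s, "clump", "ld_linked") for s in set(candidates) - set(clumped)]
    else:
        clumped = candidates
    counts["clumped"] = len(clumped)

    if confounder_assoc is not None and n_risk_factors >= 1:
        kept, thr = sens.confounder_filter(clumped, confounder_assoc, n_risk_factors, config.alpha)
        extra_dropped += [(s, "confounder", "confounder_associated") for s in set(clumped) - set(kept)]
        report["confounder_threshold"] = thr
        clumped = kept
    counts["confounder_filtered"] = len(clumped)

    outcome_ids = set(outcome.table["snp_id"].astype(str))
    missing = [s for s in clumped if s not in outcome_ids]
    proxies = ins.find_proxies(missing, ld, outcome, config.proxy_r2) if (ld and missing) else {}
    data = ins.harmonize(exposure, outcome, clumped, proxies)
    counts["harmonized"] = data.n_snps
    data = ins.drop_palindromic(data, config.palindromic_window)
    counts["palindromic_filtered"] = data.n_snps
    data = ins.radial_filter(data, config.radial_alpha)
    counts["radial_filtered"] = data.n_snps
    data = ins.steiger_filter(data)
    counts["steiger_filtered"] = data.n_snps

    dropped = pd.concat(
        [
            data.dropped,
            pd.DataFrame(extra_dropped, columns=["snp_id", "stage", "reason"]),
        ],
        ignore_index=True,
    )
    report["counts"] = counts
    report["dropped"] = dropped.sort_values(["stage", "snp_id"]).to_dict(orient="records")
    report["n_retained"] = data.n_snps
    report["retained_ids"] = list(data.table["snp_id"])

    if data.n_snps < 2:
        report["status"] = "not_estimable"
        return report
    report["status"] = "ok"

    tbl = data.table
    n_exp = pd.to_numeric(tbl["n_exp"], errors="coerce")
    if n_exp.notna().all() and (n_exp > 2).all():
        r2 = variance_explained(tbl["beta_exp"], tbl["se_exp"], n_exp)
        f = f_statistic(r2, n_exp)
        report["instrument_strength"] = {
            "r2_total": float(np.sum(r2)),
            "f_mean": float(np.mean(f)),
            "f_min": float(np.min(f)),
            "all_f_above_10": bool(np.min(f) > 10),
        }

    report["estimates"] = _estimate_panel(data, config)
    report["heterogeneity"] = est.heterogeneity(data)
    try:
        report["egger_intercept"] = sens.egger_intercept_test(est.egger(data), config.alpha)
    except (est.EstimationError, ValueError) as exc:
        report["egger_intercept"] = {"error": str(exc)}
    try:
        presso = sens.mr_presso(
            data,
            n_sim=config.presso_n_sim,
            alpha=config.alpha,
            seed=derive_seed(config.master_seed, "presso"),
        )
        report["mr_presso"] = {
            "global_rss": presso.global_rss,
            "global_p": presso.global_p,
            "outlier_ids": presso.outlier_ids,
            "distortion_p": presso.distortion_p,
            "corrected_estimate": (
                presso.corrected_estimate.as_dict() if presso.corrected_estimate else None
            ),
            "n_sim": presso.n_sim,
        }
    except ValueError as exc:
        report["mr_presso"] = {"error": str(exc)}
    try:
        loo = sens.leave_one_out(data, config.family_threshold, model=config.ivw_model)
        report["leave_one_out"] = loo.to_dict(orient="records")
    except ValueError as exc:
        report["leave_one_out"] = {"error": str(exc)}

    report["scatter_data"] = tbl[
        ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out"]
    ].to_dict(orient="records")
    return report


def run_bidirectional_mr(
    config: StudyConfig,
    trait_a: GwasDataset,
    trait_b: GwasDataset,
    ld: ins.LdMatrix | None = None,
) -> dict:
    """Reciprocal MR between two traits: A→B and B→A, independently."""
    if trait_a.trait_name == trait_b.trait_name:
        raise ConfigurationError("bidirectional MR requires two distinct traits")
    return {
        "forward": run_mr(trait_a, trait_b, config, ld=ld),
        "reverse": run_mr(trait_b, trait_a, config, ld=ld),
        "family_threshold": config.family_threshold,
    }


def _ivw_effect(report: dict) -> tuple[Effect, float] | None:
    for e in report.get("estimates", []):
        if e.get("method") == "IVW" and "beta" in e:
            return Effect(e["beta"], e["se"]), e["pval"]
    return None


def run_mediation_analysis(
    config: StudyConfig,
    exposure: GwasDataset,
    mediator: GwasDataset,
    outcome: GwasDataset,
    ld: ins.LdMatrix | None = None,
) -> dict:
    """Two-step MR mediation through the full stage chain.

    Step 1 instruments the exposure against the mediator; step 2 instruments
    the mediator against the outcome; the total effect is the direct
    exposure→outcome MR.  The indirect effect (product of coefficients, delta
    SE) is only computed when both the total and step-1 effects pass the
    gate (family Bonferroni threshold by default, nominal alpha optionally);
    a failed gate is reported explicitly, never silently omitted.
    """
    total_rep = run_mr(exposure, outcome, config, ld=ld, label="exposure->outcome")
    step1_rep = run_mr(exposure, mediator, config, ld=ld, label="exposure->mediator")
    step2_rep = run_mr(mediator, outcome, config, ld=ld, label="mediator->outcome")
    report = {
        "total": total_rep,
        "step1": step1_rep,
        "step2": step2_rep,
        "family_threshold": config.family_threshold,
    }
    gate_p = config.family_threshold if config.mediation_gate == "family" else config.alpha
    total, step1, step2 = (_ivw_effect(r) for r in (total_rep, step1_rep, step2_rep))
    if total is None or step1 is None or step2 is None:
        report["mediation"] = {"assessed": False, "reason": "a step was not estimable"}
        return report
    if total[1] >= gate_p or step1[1] >= gate_p:
        report["mediation"] = {
            "assessed": False,
            "reason": f"gate failed (total p={total[1]:.3g}, step1 p={step1[1]:.3g}, gate {gate_p:.3g})",
        }
        return report
    med = mediation_analysis(total[0], step1[0], step2[0])
    report["mediation"] = {"assessed": True, **med.as_dict()}
    # Figure-style vocabulary for the mediation summary
    report["mediation"]["ACME"] = med.indirect.beta
    report["mediation"]["total_effect"] = med.total.beta
    return report


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _estimates_frame(results: dict) -> pd.DataFrame:
    rows = []

    def walk(node, pair):
        if isinstance(node, dict):
            pair = node.get("pair", pair)
            for e in node.get("estimates", []):
                rows.append({"pair": pair, **e})
            for v in node.values():
                walk(v, pair)
        elif isinstance(node, list):
            for v in node:
                walk(v, pair)

    walk(results, "")
    cols = ["pair", "method", "beta", "se", "pval", "or", "ci_low", "ci_high", "n_snp"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df[cols]


def write_report(results: dict, path) -> None:
    """Emit the study artifacts into *path*.

    * ``estimates.tsv`` — tidy one-row-per-method-per-pair table
    * ``report.json`` — full provenance (config, seeds, counts, dropped ledger)
    * ``scatter.tsv``, ``leave_one_out.tsv``, ``funnel.tsv`` — plot-data tables

    Re-running the same configuration and seeds reproduces every file
    byte-for-byte (no timestamps are written).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "report.json", "w") as fh:
        json.dump(_jsonify(results), fh, indent=2, sort_keys=True)
        fh.write("\n")
    _estimates_frame(results).to_csv(path / "estimates.tsv", sep="\t", index=False)

    scatter, loo, funnel = [], [], []

    def walk(node, pair):
        if isinstance(node, dict):
            pair = node.get("pair", pair)
            for r in node.get("scatter_data", []):
                scatter.append({"pair": pair, **r})
                if r["beta_exp"]:
                    ratio = r["beta_out"] / r["beta_exp"]
                    se = r["se_out"] / abs(r["beta_exp"])
                    funnel.append({"pair": pair, "snp_id": r["snp_id"], "ratio": ratio, "precision": 1.0 / se})
            lo = node.get("leave_one_out")
            if isinstance(lo, list):
                for r in lo:
                    loo.append({"pair": pair, **r})
            for v in node.values():
                walk(v, pair)
        elif isinstance(node, list):
            for v in node:
                walk(v, pair)

    walk(results, "")
    pd.DataFrame(scatter).to_csv(path / "scatter.tsv", sep="\t", index=False)
    pd.DataFrame(loo).to_csv(path / "leave_one_out.tsv", sep="\t", index=False)
    pd.DataFrame(funnel).to_csv(path / "funnel.tsv", sep="\t", index=False)
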