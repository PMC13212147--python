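"""End-to-end orchestration: simulate or ingest, fit, decompose, report.

A :class:`RunConfig` fixes everything a run depends on (input source,
outcome, mediator and covariate sets, stratifier, Monte Carlo repetitions,
seed), and every emitted artifact embeds the configuration hash and seed so
reports are reproducible byte-for-byte from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mediation import decompose_effects, monte_carlo_ci, summarize_proportions
from .mixedfx import total_effects_table
from .pathmodel import PathModel
from .pathspec import build_model_spec
from .scores import AssembleOptions, assemble_analysis_table
from .simulate import GeneratorConfig, simulate_trial

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_primary", "run_stratified", "run_variant",
           "prepare_model_frame", "DEFAULT_COVARIATES", "DEFAULT_MEDIATORS"]

WEALTH_DUMMIES = ["wealth_q2", "wealth_q3", "wealth_q4", "wealth_q5"]

DEFAULT_COVARIATES = [
    "religion_muslim", *WEALTH_DUMMIES, "log_homestead_land", "log_agri_land",
    "crop_richness_baseline", "market_score_baseline", "education",
    "emp_social_support", "emp_comm_husband", "emp_external_comm",
    "emp_decision", "emp_mobility", "emp_income", "dds_baseline",
]

DEFAULT_MEDIATORS = [
    "crop_richness", "garden_practices", "n_poultry", "n_eggs",
    "fg_knowledge", "dd_knowledge",
]

STRATIFIERS = {
    "religion": {
        "muslim": lambda t: t["religion_muslim"] == 1,
        "hindu": lambda t: t["religion_muslim"] == 0,
    },
    "wealth": {  # low = quintiles 1-2, high = quintiles 3-5
        "low": lambda t: t["wealth_quintile"] <= 2,
        "high": lambda t: t["wealth_quintile"] >= 3,
    },
    "education": {  # low = none/primary, high = at least partial secondary
        "low": lambda t: t["education"] <= 2,
        "high": lambda t: t["education"] >= 3,
    },
}
STRATIFIER_COVARIATES = {
    "religion": ["religion_muslim"],
    "wealth": WEALTH_DUMMIES,
    "education": ["education"],
}

VARIANTS = ("ramadan_sensitivity", "mdd_outcome", "empowerment_mediators")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    generator: GeneratorConfig | None = None     # synthetic input
    panel_csv: str | None = None                 # or CSV input
    baseline_csv: str | None = None
    outcome: str = "dds_mean"
    mediators: list = field(default_factory=lambda: list(DEFAULT_MEDIATORS))
    market: str = "market_score"
    covariates: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    drop_ramadan: bool = False
    mc_reps: int = 10_000
    seed: int = 0
    mode: str = "auto"
    min_stratum: int = 200
    small_sample_correction: bool = False
    compute_fit_indices: bool = True
    outdir: str | None = None

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = self.generator.raw
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def prepare_model_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Add wealth-quintile indicator columns to an analysis table."""
    frame = table.copy()
    if "wealth_quintile" in frame.columns:
        for q, col in zip((2, 3, 4, 5), WEALTH_DUMMIES):
            frame[col] = np.where(
                frame["wealth_quintile"].isna(), np.nan,
                (frame["wealth_quintile"] == q).astype(float),
            )
    return frame


def load_inputs(config: RunConfig, include_empowerment=False):
    if config.generator is not None:
        return simulate_trial(config.generator, config.seed,
                              include_empowerment=include_empowerment)
    if not (config.panel_csv and config.baseline_csv):
        raise ValueError("config needs either a generator or panel/baseline CSVs")
    return pd.read_csv(config.panel_csv), pd.read_csv(config.baseline_csv)


def _analyze(frame, config: RunConfig, covariates, extra_mediators=(),
             label="primary"):
    """Fit the path model on a prepared frame and decompose effects."""
    spec = build_model_spec(
        config.mediators, config.outcome, covariates, treatment="arm",
        market=config.market, extra_mediators=extra_mediators,
    )
    cols = (["woman_id", "cluster_id", "arm"] + spec.endogenous
            + [c for c in spec.exogenous if c != "arm"])
    model = PathModel(frame[list(dict.fromkeys(cols))], spec,
                      cluster="cluster_id", mode=config.mode)
    fit = model.fit(small_sample_correction=config.small_sample_correction)
    decomp = decompose_effects(
        fit, config.mediators + list(extra_mediators), outcome=config.outcome,
        treatment="arm", market=config.market,
        market_feeders=config.mediators,
    )
    monte_carlo_ci(fit, decomp, n_reps=config.mc_reps, seed=config.seed + 7919)
    proportions = summarize_proportions(decomp)
    indices = fit.fit_indices() if config.compute_fit_indices else None
    logger.info("[%s] n=%d, loglik=%.2f, converged=%s",
                label, fit.nobs, fit.loglik, fit.converged)
    return {"fit": fit, "decomposition": decomp, "proportions": proportions,
            "fit_indices": indices, "spec": spec}


def run_primary(config: RunConfig, include_empowerment=False,
                extra_mediators=()):
    """Full pipeline: data -> analysis table -> total effects -> path model
    -> decomposition with Monte Carlo CIs.  Returns a report bundle dict."""
    panel, baseline = load_inputs(config, include_empowerment)
    table, asm_log = assemble_analysis_table(
        panel, baseline,
        AssembleOptions(drop_ramadan=config.drop_ramadan,
                        extra_measures=tuple(extra_mediators)),
    )
    frame = prepare_model_frame(table)
    totals = total_effects_table(
        frame,
        indicators=[config.outcome] + config.mediators + [config.market],
    )
    res = _analyze(frame, config, config.covariates,
                   extra_mediators=extra_mediators)
    bundle = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_women": int(len(table)),
        "n_clusters": int(frame["cluster_id"].nunique()),
        "n_excluded_no_diet": len(asm_log.excluded_no_diet),
        "analysis_table": table,
        "total_effects": totals,
        **res,
    }
    if config.outdir:
        write_report(bundle, config)
    return bundle


def run_stratified(config: RunConfig, stratifier: str):
    """Independent model fits per stratum; no pooling across strata."""
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier {stratifier!r}; "
                         f"valid: {sorted(STRATIFIERS)}")
    panel, baseline = load_inputs(config)
    table, _ = assemble_analysis_table(
        panel, baseline, AssembleOptions(drop_ramadan=config.drop_ramadan)
    )
    frame = prepare_model_frame(table)
    covariates = [c for c in config.covariates
                  if c not in STRATIFIER_COVARIATES[stratifier]]
    bundles = {}
    for level, rule in STRATIFIERS[stratifier].items():
        sub = frame[rule(frame)].reset_index(drop=True)
        if len(sub) < config.min_stratum:
            warnings.warn(
                f"stratum {stratifier}={level} has {len(sub)} women "
                f"(< {config.min_stratum}); skipped"
            )
            continue
        res = _analyze(sub, config, covariates, label=f"{stratifier}={level}")
        bundles[level] = {
            "n_women": int(len(sub)),
            "config_hash": config.hash(),
            "seed": config.seed,
            **res,
        }
    comparison = pd.DataFrame({
        level: b["proportions"] for level, b in bundles.items()
    })
    return {"strata": bundles, "proportion_comparison": comparison,
            "stratifier": stratifier}


def run_variant(config: RunConfig, variant: str):
    """Sensitivity/variant runs sharing the primary machinery."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {list(VARIANTS)}")
    cfg = dataclasses.replace(config)
    if variant == "ramadan_sensitivity":
        cfg.drop_ramadan = True
        return run_primary(cfg)
    if variant == "mdd_outcome":
        cfg.outcome = "mdd_prop"
        return run_primary(cfg)
    # empowerment_mediators: extend the mediator set; no market legs for the
    # empowerment indicators, residual correlations among them allowed
    extra = []
    if cfg.generator is not None:
        extra = list(cfg.generator.raw.get("empowerment_mediators", {}))
    return run_primary(cfg, include_empowerment=True, extra_mediators=extra)


def simulation_replicates(generator: GeneratorConfig, seeds, mc_reps=2000,
                          effect="total_indirect", progress=False):
    """Repeatedly simulate, fit and decompose; one row per replicate.

    Used for parameter-recovery and interval-coverage evaluation of the
    whole pipeline (generation -> scores -> FIML fit -> cluster-robust
    variance -> Monte Carlo CI).  Returns a DataFrame with the replicate
    seed, the point estimate of ``effect``, its Monte Carlo CI and the
    convergence flag.
    """
    seeds = [int(s) for s in seeds]
    rows = []
    config = RunConfig(generator=generator, mc_reps=mc_reps,
                       compute_fit_indices=False)
    for seed in seeds:
        panel, baseline = simulate_trial(generator, seed)
        table, _ = assemble_analysis_table(panel, baseline, AssembleOptions())
        frame = prepare_model_frame(table)
        config.seed = int(seed)
        res = _analyze(frame, config, config.covariates,
                       label=f"replicate seed={seed}")
        d = res["decomposition"]
        rows.append({
            "seed": int(seed),
            "estimate": d.effects[effect],
            "ci_low": d.ci[effect][0],
            "ci_high": d.ci[effect][1],
            "converged": res["fit"].converged,
            "n_women": res["fit"].nobs,
        })
        if progress:
            print(f"  replicate {len(rows)}/{len(seeds)} "
                  f"(seed {seed}): {rows[-1]['estimate']:.3f}", flush=True)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def decomposition_frame(bundle) -> pd.DataFrame:
    """Table-style decomposition: effects, CIs, proportions mediated."""
    decomp = bundle["decomposition"]
    props = bundle["proportions"]
    rows = []
    order = (["total", "direct", "total_indirect"] + decomp.individual_names
             + decomp.domain_names)
    for name in order:
        lo, hi = decomp.ci.get(name, (np.nan, np.nan))
        rows.append({
            "effect": name,
            "estimate": decomp.effects[name],
            "ci_low": lo,
            "ci_high": hi,
            "proportion_mediated_pct": props.get(name, np.nan),
        })
    return pd.DataFrame(rows)


def report_json(bundle) -> str:
    """Machine-readable report; byte-identical given (config, seed)."""
    decomp = bundle["decomposition"]
    payload = {
        "config_hash": bundle["config_hash"],
        "seed": bundle["seed"],
        "n_women": bundle["n_women"],
        "n_clusters": bundle.get("n_clusters"),
        "converged": bundle["fit"].converged,
        "loglik": bundle["fit"].loglik,
        "fit_indices": (
            {k: (None if isinstance(v, float) and np.isnan(v) else v)
             for k, v in bundle["fit_indices"].items()}
            if bundle["fit_indices"] else None
        ),
        "effects": {
            name: {
                "estimate": decomp.effects[name],
                "ci_low": decomp.ci.get(name, (None, None))[0],
                "ci_high": decomp.ci.get(name, (None, None))[1],
            }
            for name in sorted(decomp.effects)
        },
        "proportions_mediated_pct": dict(sorted(bundle["proportions"].items())),
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def write_report(bundle, config: RunConfig):
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["analysis_table"].to_csv(outdir / "analysis_table.csv", index=False)
    bundle["total_effects"].round(4).to_csv(outdir / "total_effects.csv", index=False)
    dec = decomposition_frame(bundle)
    dec["proportion_mediated_pct"] = dec["proportion_mediated_pct"].round(1)
    dec.round({"estimate": 3, "ci_low": 3, "ci_high": 3}).to_csv(
        outdir / "decomposition.csv", index=False
    )
    bundle["fit"].param_table().to_csv(outdir / "parameters.csv", index=False)
    (outdir / "report.json").write_text(report_json(bundle))
    logger.info("report written to %s (config %s)", outdir, bundle["config_hash"])
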