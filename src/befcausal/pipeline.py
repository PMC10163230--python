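"""Orchestration: run every design on one panel and summarize, or Monte-Carlo it.

``run_pipeline`` executes the requested designs in order on a supplied CSV
panel or a named synthetic scenario, writes per-design JSON/CSV artifacts, a
combined design-comparison table (one row per design, plus one per extra
sensitivity pi), and a JSON-lines log with seed, drop accounting and timing.
``monte_carlo`` replicates simulate -> estimate and reports bias, RMSE and
confidence-interval coverage per design against the generator's ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import robustness
from .config import SimulationConfig, scenario
from .estimators import (
    LN_RICHNESS,
    EstimationResult,
    estimate_bivariate,
    estimate_common_design,
    estimate_main_design,
)
from .heterogeneity import equality_test, estimate_by_type
from .panel import PanelDataset, PanelError, TYPE_COLUMNS, build_panel
from .simulate import TruthRecord, simulate_panel

ALL_DESIGNS = (
    "bivariate",
    "common",
    "main",
    "iv",
    "ldv",
    "mechanism_block",
    "oster",
    "heterogeneity",
)


class PipelineError(RuntimeError):
    """Raised after the run when one or more designs failed."""


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run; unknown keys are rejected."""

    scenario: str | None = "confounded"
    input_path: str | None = None
    column_map: dict | None = None
    inclusion_min_years: int = 5
    cluster_level: str = "plot"
    covariates: tuple[str, ...] = ("cov_plot",)
    diversity_var: str = "ln_richness"
    rarity_cutoff: float = 0.05
    oster_pi: tuple[float, ...] = (-0.10, 0.10)
    oster_r_max: float = 1.0
    designs: tuple[str, ...] = ALL_DESIGNS
    instrument_col: str = "instrument"
    shade_col: str = "shade_lag"
    seed: int = 0
    output_dir: str | None = None
    simulation_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [d for d in self.designs if d not in ALL_DESIGNS]
        if unknown:
            raise ValueError(f"unknown design(s) {unknown}; choose from {ALL_DESIGNS}")
        if self.scenario is None and self.input_path is None:
            raise ValueError("either a scenario name or an input path is required")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown RunConfig key(s): {sorted(unknown)}")
        raw = dict(raw)
        for key in ("covariates", "oster_pi", "designs"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ReportBundle:
    combined: pd.DataFrame
    results: dict
    log: list[dict]
    truth: TruthRecord | None = None
    errors: dict = field(default_factory=dict)


def _resolve_panel(config: RunConfig) -> tuple[PanelDataset, TruthRecord | None]:
    if config.input_path is not None:
        raw = pd.read_csv(config.input_path)
        return (
            build_panel(
                raw,
                inclusion_min_years=config.inclusion_min_years,
                column_map=config.column_map,
            ),
            None,
        )
    sim = scenario(config.scenario, **config.simulation_overrides).replace(seed=config.seed)
    need_types = "heterogeneity" in config.designs and sim.beta_by_type is None
    panel, truth = simulate_panel(sim, include_cover=need_types)
    if need_types:
        # classify realized composition and attach per-type richness counts
        from .heterogeneity import classify_species, per_type_richness

        types = classify_species(panel.cover, cutoff=config.rarity_cutoff)
        counts = per_type_richness(panel.cover, types)
        panel.data = panel.data.drop(columns=list(TYPE_COLUMNS)).merge(
            counts, on=["site_id", "plot_id", "year"], how="left"
        )
        for c in TYPE_COLUMNS:
            panel.data[c] = panel.data[c].fillna(0).astype(int)
    return panel, truth


def _headline_row(design: str, res: EstimationResult, term: str = LN_RICHNESS) -> dict:
    ci = res.conf_int.loc[term]
    return {
        "design": design,
        "term": term,
        "estimate": float(res.params[term]),
        "se": float(res.se[term]),
        "ci_lower": float(ci["lower"]),
        "ci_upper": float(ci["upper"]),
        "n_obs": int(res.n_obs),
        "n_clusters": int(res.n_clusters),
    }


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the requested designs in declared order and bundle the report."""
    t0 = time.time()
    panel, truth = _resolve_panel(config)
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    log: list[dict] = [
        {
            "event": "panel_ready",
            "seed": config.seed,
            "scenario": config.scenario,
            "rows_in": len(panel) + len(panel.drop_log),
            "rows_used": len(panel),
            "rows_dropped": len(panel.drop_log),
            "drop_reasons": panel.drop_log["reason"].value_counts().to_dict()
            if len(panel.drop_log)
            else {},
        }
    ]
    results: dict = {}
    errors: dict = {}
    combined_rows: list[dict] = []

    main_res: EstimationResult | None = None

    for design in config.designs:
        t_design = time.time()
        try:
            if design == "bivariate":
                res = estimate_bivariate(panel, cluster=config.cluster_level)
                combined_rows.append(_headline_row(design, res))
            elif design == "common":
                res = estimate_common_design(
                    panel, covariates=config.covariates, cluster=config.cluster_level
                )
                combined_rows.append(_headline_row(design, res))
            elif design == "main":
                res = estimate_main_design(
                    panel,
                    cluster_level=config.cluster_level,
                    diversity_var=config.diversity_var,
                )
                main_res = res
                combined_rows.append(_headline_row(design, res))
            elif design == "iv":
                if config.instrument_col not in panel.data.columns:
                    raise PanelError(
                        f"IV design requested but instrument column "
                        f"{config.instrument_col!r} is not in the panel"
                    )
                res = robustness.two_stage_least_squares(
                    panel, instrument_col=config.instrument_col, cluster=config.cluster_level
                )
                combined_rows.append(
                    {
                        "design": design,
                        "term": LN_RICHNESS,
                        "estimate": res.beta,
                        "se": res.se,
                        "ci_lower": res.conf_int[0],
                        "ci_upper": res.conf_int[1],
                        "n_obs": res.n_obs,
                        "n_clusters": res.n_clusters,
                    }
                )
            elif design == "ldv":
                res = robustness.estimate_ldv(panel, cluster=config.cluster_level)
                combined_rows.append(_headline_row(design, res))
            elif design == "mechanism_block":
                res = robustness.mechanism_block(
                    panel, shade_col=config.shade_col, cluster=config.cluster_level
                )
                combined_rows.append(_headline_row(design, res))
            elif design == "oster":
                res = {}
                for pi in config.oster_pi:
                    inputs = robustness.oster_inputs_from_designs(
                        panel, pi=pi, r_max=config.oster_r_max
                    )
                    adj = robustness.oster_adjusted_beta(inputs, method="exact_root")
                    res[pi] = adj
                    combined_rows.append(
                        {
                            "design": f"oster(pi={pi:+.2f})",
                            "term": LN_RICHNESS,
                            "estimate": adj.beta_star,
                            "se": np.nan,
                            "ci_lower": adj.identified_set[0],
                            "ci_upper": adj.identified_set[1],
                            "n_obs": len(panel),
                            "n_clusters": panel.n_plots,
                        }
                    )
            elif design == "heterogeneity":
                res = estimate_by_type(panel, cluster=config.cluster_level)
                eq = equality_test(res)
                res.extra["equality_test"] = {
                    "statistic": eq.statistic,
                    "df": eq.df,
                    "p_value": eq.p_value,
                }
                combined_rows.append(
                    {
                        "design": design,
                        "term": "type_equality_chi2",
                        "estimate": eq.statistic,
                        "se": np.nan,
                        "ci_lower": np.nan,
                        "ci_upper": np.nan,
                        "n_obs": res.n_obs,
                        "n_clusters": res.n_clusters,
                    }
                )
            results[design] = res
            log.append(
                {
                    "event": "design_done",
                    "design": design,
                    "seconds": round(time.time() - t_design, 4),
                }
            )
            if out and isinstance(res, EstimationResult):
                res.to_json(out / f"{design}.json")
                res.table().to_csv(out / f"{design}.csv", index=False)
        except Exception as exc:  # noqa: BLE001 - collected and re-raised below
            errors[design] = f"{type(exc).__name__}: {exc}"
            log.append({"event": "design_failed", "design": design, "error": errors[design]})

    combined = pd.DataFrame(combined_rows)
    log.append({"event": "done", "seconds": round(time.time() - t0, 4)})
    if out:
        combined.to_csv(out / "combined_table.csv", index=False)
        with open(out / "run_log.jsonl", "w") as fh:
            for entry in log:
                fh.write(json.dumps(entry) + "\n")
    bundle = ReportBundle(
        combined=combined, results=results, log=log, truth=truth, errors=errors
    )
    if errors:
        raise PipelineError(f"design failure(s): {errors}")
    return bundle


# ---------------------------------------------------------------------------
# Monte Carlo
# ---------------------------------------------------------------------------

_MC_DESIGNS = ("bivariate", "common", "main", "iv", "ldv", "mechanism_block")


def _rep_seeds(seed: int, n_reps: int) -> np.ndarray:
    state = np.random.SeedSequence(seed).generate_state(n_reps, dtype=np.uint32)
    return (state % np.uint32(2**31)).astype(np.int64)


@dataclass
class MonteCarloSummary:
    per_design: pd.DataFrame
    per_rep: pd.DataFrame
    beta_true: float
    n_reps: int


def monte_carlo(
    sim_config: SimulationConfig,
    n_reps: int,
    designs: tuple[str, ...] = ("main",),
    covariates: tuple[str, ...] = ("cov_plot",),
    out_path=None,
) -> MonteCarloSummary:
    """Replicate simulate -> estimate and summarize recovery per design.

    Reports mean estimate, bias, RMSE, 95% CI coverage (where the design
    yields an interval) and the Monte-Carlo standard error of the mean.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    unknown = [d for d in designs if d not in _MC_DESIGNS]
    if unknown:
        raise ValueError(f"unsupported Monte-Carlo design(s): {unknown}")
    beta_true = sim_config.beta_true
    seeds = _rep_seeds(sim_config.seed, n_reps)
    rows = []
    for rep, s in enumerate(seeds):
        panel, _ = simulate_panel(sim_config.replace(seed=int(s)))
        for design in designs:
            if design == "bivariate":
                res = estimate_bivariate(panel)
                est, lo, hi = _extract(res)
            elif design == "common":
                res = estimate_common_design(panel, covariates=covariates)
                est, lo, hi = _extract(res)
            elif design == "main":
                res = estimate_main_design(panel)
                est, lo, hi = _extract(res)
            elif design == "iv":
                iv = robustness.two_stage_least_squares(panel)
                est, (lo, hi) = iv.beta, iv.conf_int
            elif design == "ldv":
                res = robustness.estimate_ldv(panel)
                est, lo, hi = _extract(res)
            else:
                res = robustness.mechanism_block(panel)
                est, lo, hi = _extract(res)
            rows.append(
                {
                    "rep": rep,
                    "design": design,
                    "estimate": est,
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "covered": lo <= beta_true <= hi,
                }
            )
    per_rep = pd.DataFrame(rows)
    if out_path is not None:
        per_rep.to_csv(out_path, index=False)
    g = per_rep.groupby("design")["estimate"]
    summary = pd.DataFrame(
        {
            "mean": g.mean(),
            "bias": g.mean() - beta_true,
            "rmse": np.sqrt(((per_rep.set_index("design")["estimate"] - beta_true) ** 2).groupby("design").mean()),
            "mc_se": g.std(ddof=1) / np.sqrt(n_reps),
            "coverage": per_rep.groupby("design")["covered"].mean(),
        }
    )
    return MonteCarloSummary(
        per_design=summary, per_rep=per_rep, beta_true=beta_true, n_reps=n_reps
    )


def _extract(res: EstimationResult) -> tuple[float, float, float]:
    ci = res.conf_int.loc[LN_RICHNESS]
    return float(res.params[LN_RICHNESS]), float(ci["lower"]), float(ci["upper"])
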