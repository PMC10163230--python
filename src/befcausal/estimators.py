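"""The bivariate, covariate-conditioning and two-way fixed-effects designs.

All designs estimate the elasticity of plot productivity with respect to
species richness from a ln-ln specification:

* bivariate: ``ln LiveMass ~ ln Richness`` with no controls;
* Common Design: the same regression with observed plot/site/site-year
  covariates entered directly -- the conditioning-on-observables strategy
  common in observational ecology;
* Main Design: plot fixed effects (absorbing everything time-invariant at
  plot or site level) plus site-by-year fixed effects (absorbing site-level
  shocks), identifying beta from within-plot deviations.

Inference is cluster-robust (CR1) with confidence intervals on a t
distribution with (clusters - 1) degrees of freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import lsq
from .panel import (
    BIOMASS,
    PLOT,
    RICHNESS,
    SITE,
    YEAR,
    FixedEffectsSpec,
    PanelError,
    absorb_fixed_effects,
    as_frame,
)

LN_RICHNESS = "ln_richness"
LN_BIOMASS = "ln_live_mass"


class IdentificationError(ValueError):
    """Raised when a design has no identifying variation left."""


class CollinearityError(ValueError):
    """Raised when a requested term is collinear with absorbed fixed effects."""


@dataclass(frozen=True)
class ClusterSpec:
    """Where to cluster the sandwich variance: plot (default) or site."""

    level: str = "plot"
    correction: str = "CR1"

    def ids(self, df: pd.DataFrame) -> pd.Series:
        if self.level == "plot":
            return df[PLOT]
        if self.level == "site":
            return df[SITE]
        raise PanelError(f"unknown cluster level {self.level!r}")


def _as_cluster(cluster) -> ClusterSpec:
    if isinstance(cluster, ClusterSpec):
        return cluster
    return ClusterSpec(level=str(cluster))


@dataclass
class EstimationResult:
    """Coefficients, cluster-robust covariance and confidence intervals."""

    design: str
    params: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_clusters: int
    cluster_level: str
    fixed_effects: tuple[str, ...] = ()
    df_absorbed: int = 0
    r2_within: float = np.nan
    r2_total: float = np.nan
    dropped: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index)

    @property
    def t_critical(self) -> float:
        return float(stats.t.ppf(0.975, df=self.n_clusters - 1))

    @property
    def conf_int(self) -> pd.DataFrame:
        half = self.t_critical * self.se
        return pd.DataFrame(
            {"lower": self.params - half, "upper": self.params + half}
        )

    def table(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "design": self.design,
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.se.to_numpy(),
                "ci_lower": ci["lower"].to_numpy(),
                "ci_upper": ci["upper"].to_numpy(),
                "n_obs": self.n_obs,
                "n_clusters": self.n_clusters,
            }
        )

    def elasticity_report(self, term: str = LN_RICHNESS) -> dict:
        """Report the effect as % change in productivity per 10% richness.

        Both the linearized form 10*beta (the conventional reading of a ln-ln
        elasticity) and the exact transform 100*(1.1^beta - 1) are returned.
        """
        beta = float(self.params[term])
        ci = self.conf_int.loc[term]
        return {
            "beta": beta,
            "se": float(self.se[term]),
            "pct_per_10pct_linear": 10.0 * beta,
            "pct_per_10pct_exact": 100.0 * (1.1**beta - 1.0),
            "ci_lower": float(ci["lower"]),
            "ci_upper": float(ci["upper"]),
        }

    def to_json(self, path) -> None:
        payload = {
            "design": self.design,
            "params": self.params.to_dict(),
            "se": self.se.to_dict(),
            "conf_int": {
                term: [float(r["lower"]), float(r["upper"])]
                for term, r in self.conf_int.iterrows()
            },
            "n_obs": int(self.n_obs),
            "n_clusters": int(self.n_clusters),
            "cluster_level": self.cluster_level,
            "fixed_effects": list(self.fixed_effects),
            "r2_within": None if np.isnan(self.r2_within) else float(self.r2_within),
            "r2_total": None if np.isnan(self.r2_total) else float(self.r2_total),
            "dropped": list(self.dropped),
            "extra": _jsonable(self.extra),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def cluster_fit(
    design: str,
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    cluster_ids,
    *,
    fixed_effects: tuple[str, ...] = (),
    df_absorbed: int = 0,
    tss_total: float | None = None,
    extra: dict | None = None,
) -> EstimationResult:
    """Shared OLS + CR1 + t(G-1) machinery behind every design."""
    fit = lsq.ols(y, X, names=list(names))
    codes, uniques = pd.factorize(np.asarray(cluster_ids))
    vcov = lsq.cluster_robust_vcov(
        fit.X, fit.residuals, np.asarray(cluster_ids), k_total=fit.rank + df_absorbed
    )
    yv = np.asarray(y, dtype=float)
    tss_within = float(((yv - yv.mean()) ** 2).sum())
    r2_within = 1.0 - fit.rss / tss_within if tss_within > 0 else np.nan
    r2_total = 1.0 - fit.rss / tss_total if tss_total else r2_within
    return EstimationResult(
        design=design,
        params=pd.Series(fit.coef, index=fit.names),
        vcov=pd.DataFrame(vcov, index=fit.names, columns=fit.names),
        n_obs=fit.n,
        n_clusters=len(uniques),
        cluster_level="",
        fixed_effects=fixed_effects,
        df_absorbed=df_absorbed,
        r2_within=r2_within,
        r2_total=r2_total,
        dropped=tuple(fit.dropped),
        extra=extra or {},
    )


# ---------------------------------------------------------------------------
# designs
# ---------------------------------------------------------------------------


def _base_columns(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    if (out[BIOMASS] <= 0).any():
        raise PanelError("non-positive biomass in ln-based design; filter via build_panel")
    out[LN_BIOMASS] = np.log(out[BIOMASS].to_numpy(dtype=float))
    out[LN_RICHNESS] = np.log(out[RICHNESS].to_numpy(dtype=float))
    return out


def estimate_bivariate(panel, cluster="plot") -> EstimationResult:
    """ln biomass on ln richness with an intercept and no controls."""
    df = _base_columns(as_frame(panel))
    if len(df) < 3:
        raise PanelError("bivariate design needs at least 3 observations")
    spec = _as_cluster(cluster)
    X = np.column_stack([df[LN_RICHNESS].to_numpy(), np.ones(len(df))])
    res = cluster_fit(
        "bivariate", df[LN_BIOMASS].to_numpy(), X, [LN_RICHNESS, "const"], spec.ids(df)
    )
    res.cluster_level = spec.level
    return res


def estimate_common_design(
    panel, covariates: Sequence[str], cluster="plot"
) -> EstimationResult:
    """Covariate-conditioning design: ln-ln regression with controls entered directly.

    Categorical covariates are expanded into indicator columns; rows with any
    missing covariate are deleted listwise (with the count recorded), which is
    how covariate-poor sites fall out of the sample.
    """
    df = as_frame(panel)
    missing_cols = [c for c in covariates if c not in df.columns]
    if missing_cols:
        raise PanelError(f"covariate column(s) absent: {missing_cols}")
    df = _base_columns(df)
    n_before = len(df)
    work = df[[LN_BIOMASS, LN_RICHNESS, *covariates]].copy()
    keep = work.notna().all(axis=1)
    work, df = work[keep], df[keep]
    n_deleted = n_before - len(work)

    blocks = [work[LN_RICHNESS].to_numpy()[:, None]]
    names = [LN_RICHNESS]
    for c in covariates:
        col = work[c]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
            names.append(c)
        else:
            dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
            blocks.append(dummies.to_numpy())
            names.extend(dummies.columns)
    blocks.append(np.ones((len(work), 1)))
    names.append("const")
    X = np.hstack(blocks)
    spec = _as_cluster(cluster)
    res = cluster_fit(
        "common",
        work[LN_BIOMASS].to_numpy(),
        X,
        names,
        spec.ids(df),
        extra={"n_listwise_deleted": n_deleted},
    )
    res.cluster_level = spec.level
    return res


_DIVERSITY_VARS = ("ln_richness", "ln_simpson", "richness", "richness_quadratic")


def _diversity_columns(df: pd.DataFrame, diversity_var: str) -> tuple[pd.DataFrame, list[str]]:
    if diversity_var == "ln_richness":
        return df, [LN_RICHNESS]
    if diversity_var == "ln_simpson":
        if "simpson_d" not in df.columns:
            raise PanelError("ln_simpson variant requires a simpson_d column")
        df = df.assign(ln_simpson=np.log(df["simpson_d"].to_numpy(dtype=float)))
        return df, ["ln_simpson"]
    if diversity_var == "richness":
        return df, [RICHNESS]
    if diversity_var == "richness_quadratic":
        df = df.assign(richness_sq=df[RICHNESS].to_numpy(dtype=float) ** 2)
        return df, [RICHNESS, "richness_sq"]
    raise PanelError(f"diversity_var must be one of {_DIVERSITY_VARS}")


def estimate_main_design(
    panel,
    cluster_level="plot",
    extra_covariates: Sequence[str] = (),
    diversity_var: str = "ln_richness",
    outcome: str = "ln",
    design_label: str = "main",
) -> EstimationResult:
    """Two-way fixed-effects estimator: plot FE plus site-by-year FE.

    Estimated by residualizing outcome and regressors on both sets of group
    means (alternating demeaning) and running least squares on the deviations,
    which is numerically identical to explicit-dummy least squares.
    """
    df = _base_columns(as_frame(panel))
    df, xnames = _diversity_columns(df, diversity_var)
    yname = LN_BIOMASS if outcome == "ln" else BIOMASS
    cols = [yname, *xnames, *extra_covariates]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise PanelError(f"column(s) absent: {missing_cols}")
    keep = df[cols].notna().all(axis=1)
    df = df[keep]
    years_per_plot = df.groupby(PLOT)[YEAR].transform("nunique")
    if (years_per_plot < 2).all():
        raise IdentificationError("no plot observed in 2+ years; within variation absent")

    spec = FixedEffectsSpec(("plot", "site_year"))
    work = df[cols].astype(float)
    demeaned, report = absorb_fixed_effects(work, spec.codes(df))
    for x in xnames:
        if float(demeaned[x].to_numpy().var()) <= 1e-24:
            raise IdentificationError(
                f"all within-plot variation in {x!r} absorbed by the fixed effects"
            )

    cl = _as_cluster(cluster_level)
    yv = df[yname].to_numpy(dtype=float)
    tss_total = float(((yv - yv.mean()) ** 2).sum())
    res = cluster_fit(
        design_label,
        demeaned[yname].to_numpy(),
        demeaned[[*xnames, *extra_covariates]].to_numpy(),
        [*xnames, *extra_covariates],
        cl.ids(df),
        fixed_effects=("plot", "site_year"),
        df_absorbed=report.absorbed_df,
        tss_total=tss_total,
        extra={"absorption_sweeps": report.n_iter},
    )
    res.cluster_level = cl.level
    return res


def estimate_first_difference(panel, cluster="plot") -> EstimationResult:
    """Year-over-year first differences with differenced site-year effects.

    On a two-year balanced panel this is algebraically the within estimator;
    it is provided as the differenced form of the Main Design.
    """
    df = _base_columns(as_frame(panel)).sort_values([PLOT, YEAR])
    lagged = df.groupby(PLOT)[[LN_BIOMASS, LN_RICHNESS, YEAR]].shift(1)
    ok = (df[YEAR] - lagged[YEAR]) == 1
    d = df[ok].copy()
    d["d_y"] = df[LN_BIOMASS] - lagged[LN_BIOMASS]
    d["d_x"] = df[LN_RICHNESS] - lagged[LN_RICHNESS]
    if d.empty:
        raise IdentificationError("no consecutive-year pairs for differencing")
    demeaned, report = absorb_fixed_effects(
        d[["d_y", "d_x"]], FixedEffectsSpec(("site_year",)).codes(d)
    )
    cl = _as_cluster(cluster)
    res = cluster_fit(
        "first_difference",
        demeaned["d_y"].to_numpy(),
        demeaned[["d_x"]].to_numpy(),
        [LN_RICHNESS],
        cl.ids(d),
        fixed_effects=("site_year",),
        df_absorbed=report.absorbed_df,
    )
    res.cluster_level = cl.level
    return res


def estimate_moderation(
    panel,
    moderator: str,
    coding: str = "continuous",
    cluster="plot",
    include_main_effect: bool = False,
) -> EstimationResult:
    """Main Design plus (ln richness x moderator) interaction terms.

    The moderator is a site-level variable; its main effect is absorbed by
    the plot fixed effects and must not be requested, only the interaction is
    identified.  A joint Wald test on the interaction block is reported in
    ``extra``.
    """
    if include_main_effect:
        raise CollinearityError(
            "the moderator main effect is collinear with the plot fixed effects; "
            "only the interaction with ln richness is identified"
        )
    df = _base_columns(as_frame(panel))
    if moderator not in df.columns:
        raise PanelError(f"moderator column {moderator!r} absent")

    inter_names: list[str] = []
    if coding == "continuous":
        m = df[moderator].astype(float)
        m = m - m.mean()
        name = f"{LN_RICHNESS}:{moderator}"
        df[name] = df[LN_RICHNESS] * m
        inter_names = [name]
    elif coding == "categorical":
        dummies = pd.get_dummies(df[moderator], prefix=moderator, drop_first=True, dtype=float)
        for c in dummies.columns:
            name = f"{LN_RICHNESS}:{c}"
            df[name] = df[LN_RICHNESS] * dummies[c]
            inter_names.append(name)
    else:
        raise PanelError("coding must be 'continuous' or 'categorical'")

    res = estimate_main_design(
        df,
        cluster_level=cluster,
        extra_covariates=inter_names,
        design_label="moderation",
    )
    present = [n for n in inter_names if n in res.params.index]
    b = res.params[present].to_numpy()
    V = res.vcov.loc[present, present].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    q = len(present)
    res.extra.update(
        {
            "moderator": moderator,
            "interaction_terms": present,
            "joint_wald": stat,
            "joint_df": q,
            "joint_p": float(stats.chi2.sf(stat, q)),
        }
    )
    return res
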