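"""Alternative-assumption designs: IV 2SLS, mechanism blocking, LDV, Oster bounds.

Each design relaxes a different assumption of the two-way fixed-effects Main
Design:

* **IV / 2SLS** uses an excluded shifter of richness (mean richness of
  neighboring nutrient-manipulated plots in the field study; a standard
  normal instrument in the generator) to handle reverse causality and
  time-varying plot-level confounding, at the price of precision.  Instrument
  strength is diagnosed with the effective F statistic, which with a single
  instrument is the cluster-robust Wald statistic of the first stage.
* **Mechanism blocking** adds the shading covariate to the Main Design,
  cutting the productivity -> shading -> richness feedback path.
* **LDV** replaces plot fixed effects with last year's ln biomass; together
  with the Main Design it brackets the true effect under either assumption
  set.
* **Oster/Altonji sensitivity bounds** extrapolate how much unobserved
  confounding, proportional to the observed movement between the uncontrolled
  and controlled coefficients, would be needed to overturn the sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import lsq
from .estimators import (
    LN_BIOMASS,
    LN_RICHNESS,
    EstimationResult,
    IdentificationError,
    _as_cluster,
    _base_columns,
    cluster_fit,
    estimate_bivariate,
    estimate_main_design,
)
from .panel import (
    PLOT,
    SITE,
    YEAR,
    FixedEffectsSpec,
    PanelError,
    absorb_fixed_effects,
    as_frame,
)

LAG_LN_BIOMASS = "ln_live_mass_lag"


# ---------------------------------------------------------------------------
# instrumental variables
# ---------------------------------------------------------------------------


@dataclass
class FirstStage:
    gamma: float
    var_robust: float
    var_classical: float
    n: int
    df_absorbed: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_robust))

    @property
    def f_classical(self) -> float:
        return self.gamma**2 / self.var_classical


@dataclass
class IVResult:
    beta: float
    se: float
    conf_int: tuple[float, float]
    first_stage: FirstStage
    effective_f: float
    n_obs: int
    n_clusters: int
    cluster_level: str
    n_dropped_missing_instrument: int = 0
    extra: dict = field(default_factory=dict)

    def elasticity_report(self) -> dict:
        return {
            "beta": self.beta,
            "se": self.se,
            "pct_per_10pct_linear": 10.0 * self.beta,
            "pct_per_10pct_exact": 100.0 * (1.1**self.beta - 1.0),
            "ci_lower": self.conf_int[0],
            "ci_upper": self.conf_int[1],
        }


def effective_f(first_stage: FirstStage) -> float:
    """Weak-instrument diagnostic for the single-instrument case.

    With one instrument the heteroskedasticity/cluster-robust effective F
    reduces to gamma^2 divided by the cluster-robust variance of gamma.
    """
    if first_stage.var_robust <= 0:
        raise ZeroDivisionError("robust first-stage variance is zero")
    return first_stage.gamma**2 / first_stage.var_robust


def two_stage_least_squares(
    panel,
    instrument_col: str = "instrument",
    fe: tuple[str, ...] = ("plot", "site_year"),
    cluster="plot",
) -> IVResult:
    """Just-identified 2SLS with the Main Design's fixed effects absorbed.

    Absorbs plot and site-by-year effects from outcome, regressor and
    instrument; the coefficient is the reduced-form / first-stage ratio.
    Standard errors use the conventional 2SLS residual (computed with the
    observed, not fitted, regressor), cluster-robust at the requested level.
    """
    df = as_frame(panel)
    if instrument_col not in df.columns:
        raise PanelError(f"instrument column {instrument_col!r} absent")
    df = _base_columns(df)
    n_missing = int(df[instrument_col].isna().sum())
    df = df[df[instrument_col].notna()]

    spec = FixedEffectsSpec(fe)
    work = df[[LN_BIOMASS, LN_RICHNESS, instrument_col]].astype(float)
    demeaned, report = absorb_fixed_effects(work, spec.codes(df))
    y = demeaned[LN_BIOMASS].to_numpy()
    x = demeaned[LN_RICHNESS].to_numpy()
    z = demeaned[instrument_col].to_numpy()
    n = len(y)
    if float(z.var()) <= 1e-24:
        raise IdentificationError("instrument has no variation after FE absorption")

    cl = _as_cluster(cluster)
    cluster_ids = cl.ids(df).to_numpy()
    k_total = 1 + report.absorbed_df

    # first stage: x on z
    zz = float(z @ z)
    gamma = float(z @ x) / zz
    u1 = x - gamma * z
    var_rob = float(
        lsq.cluster_robust_vcov(z[:, None], u1, cluster_ids, k_total=k_total)[0, 0]
    )
    s2 = float(u1 @ u1) / (n - k_total)
    fs = FirstStage(
        gamma=gamma,
        var_robust=var_rob,
        var_classical=s2 / zz,
        n=n,
        df_absorbed=report.absorbed_df,
    )
    # a perfect first stage (instrument == regressor) has zero residual
    # variance: report an infinitely strong instrument instead of failing
    eff_f = np.inf if var_rob <= 0 else effective_f(fs)

    # second stage via the just-identified ratio; residual uses observed x
    zx = float(z @ x)
    beta = float(z @ y) / zx
    u2 = y - beta * x
    codes, uniques = pd.factorize(cluster_ids)
    G = len(uniques)
    if G < 2:
        raise lsq.ClusterError("2SLS inference requires at least 2 clusters")
    S = np.zeros(G)
    np.add.at(S, codes, z * u2)
    c = (G / (G - 1)) * ((n - 1) / (n - k_total))
    var_beta = c * float(S @ S) / zx**2
    se = float(np.sqrt(var_beta))
    tcrit = float(stats.t.ppf(0.975, df=G - 1))
    return IVResult(
        beta=beta,
        se=se,
        conf_int=(beta - tcrit * se, beta + tcrit * se),
        first_stage=fs,
        effective_f=eff_f,
        n_obs=n,
        n_clusters=G,
        cluster_level=cl.level,
        n_dropped_missing_instrument=n_missing,
    )


def block_mean_instrument(
    df: pd.DataFrame, block_cols: tuple[str, ...], value_col: str
) -> pd.Series:
    """Leave-one-out mean of ``value_col`` within each block (neighbor mean)."""
    g = df.groupby(list(block_cols))[value_col]
    total = g.transform("sum")
    count = g.transform("count")
    if (count < 2).any():
        raise PanelError("every block needs at least 2 members for a neighbor mean")
    return (total - df[value_col]) / (count - 1)


# ---------------------------------------------------------------------------
# mechanism blocking and lagged-dependent-variable design
# ---------------------------------------------------------------------------


def mechanism_block(panel, shade_col: str = "shade_lag", cluster="plot") -> EstimationResult:
    """Main Design with the shading covariate added as a regressor.

    Shading (fraction of ground-level light intercepted) proxies the channel
    through which productivity can suppress richness; conditioning on it
    blocks that reverse path.  Because the generator lets richness respond to
    *last* year's shading, the default covariate is the lagged measure.
    """
    df = as_frame(panel)
    if shade_col not in df.columns:
        raise PanelError(f"shading column {shade_col!r} absent")
    res = estimate_main_design(
        df, cluster_level=cluster, extra_covariates=[shade_col], design_label="mechanism_block"
    )
    return res


def estimate_ldv(panel, cluster="plot") -> EstimationResult:
    """Lagged-dependent-variable design: ln biomass on ln richness and its own lag.

    Site-by-year effects are retained but plot fixed effects are dropped
    (combining a lagged outcome with unit fixed effects induces Nickell
    bias); each plot's first usable year is lost to lag construction and only
    consecutive-year pairs enter.
    """
    df = _base_columns(as_frame(panel)).sort_values([PLOT, YEAR])
    lagged = df.groupby(PLOT)[[LN_BIOMASS, YEAR]].shift(1)
    ok = (df[YEAR] - lagged[YEAR]) == 1
    d = df[ok].copy()
    if d.empty:
        raise IdentificationError("no consecutive-year pairs for the lag")
    d[LAG_LN_BIOMASS] = lagged.loc[ok, LN_BIOMASS]

    demeaned, report = absorb_fixed_effects(
        d[[LN_BIOMASS, LN_RICHNESS, LAG_LN_BIOMASS]],
        FixedEffectsSpec(("site_year",)).codes(d),
    )
    cl = _as_cluster(cluster)
    yv = d[LN_BIOMASS].to_numpy(dtype=float)
    res = cluster_fit(
        "ldv",
        demeaned[LN_BIOMASS].to_numpy(),
        demeaned[[LN_RICHNESS, LAG_LN_BIOMASS]].to_numpy(),
        [LN_RICHNESS, LAG_LN_BIOMASS],
        cl.ids(d),
        fixed_effects=("site_year",),
        df_absorbed=report.absorbed_df,
        tss_total=float(((yv - yv.mean()) ** 2).sum()),
        extra={"n_dropped_no_lag": int(len(df) - len(d))},
    )
    res.cluster_level = cl.level
    return res


@dataclass
class BracketResult:
    beta_main: float
    beta_ldv: float
    interval: tuple[float, float]
    sign_agreement: bool
    interpretation: str | None


def bracket(beta_main: float, beta_ldv: float) -> BracketResult:
    """Order the two estimates into the interval that brackets the true effect.

    Under either design's assumption set the true effect lies between the
    within estimate and the LDV estimate; an interpretation is offered only
    when the two agree in sign.
    """
    lo, hi = sorted((float(beta_main), float(beta_ldv)))
    agree = np.sign(beta_main) == np.sign(beta_ldv) and beta_main != 0 and beta_ldv != 0
    interp = None
    if agree:
        direction = "negative" if beta_main < 0 else "positive"
        interp = (
            f"both designs point the same way: the true effect is bracketed in "
            f"[{lo:.4g}, {hi:.4g}] and is {direction}"
        )
    return BracketResult(
        beta_main=float(beta_main),
        beta_ldv=float(beta_ldv),
        interval=(lo, hi),
        sign_agreement=bool(agree),
        interpretation=interp,
    )


# ---------------------------------------------------------------------------
# Oster / Altonji sensitivity bounds
# ---------------------------------------------------------------------------


@dataclass
class OsterInputs:
    """Moments feeding the proportional-selection bias adjustment.

    ``(beta_dot, r2_dot)`` come from the uncontrolled regression,
    ``(beta_tilde, r2_tilde)`` from the controlled one; ``pi`` is the
    proportional-selection coefficient (selection on unobservables relative
    to observables) and ``r_max`` the R-squared a hypothetical
    fully-controlled regression would reach.  The second moments
    ``sigma2_y``, ``sigma2_x`` and ``tau_x`` (variance of the treatment
    residualized on the controls) are only needed for the exact-root method.
    """

    beta_dot: float
    r2_dot: float
    beta_tilde: float
    r2_tilde: float
    pi: float
    r_max: float
    sigma2_y: float | None = None
    sigma2_x: float | None = None
    tau_x: float | None = None

    def validate(self) -> None:
        if not self.r2_dot <= self.r2_tilde + 1e-12:
            raise ValueError("r2_dot must not exceed r2_tilde")
        if not self.r2_tilde <= self.r_max <= 1.0 + 1e-12:
            raise ValueError("need r2_tilde <= r_max <= 1")
        if abs(self.r2_tilde - self.r2_dot) < 1e-14:
            raise ZeroDivisionError(
                "r2_tilde equals r2_dot: controls add nothing, adjustment undefined"
            )


@dataclass
class OsterResult:
    beta_star: float
    identified_set: tuple[float, float]
    method: str
    roots: tuple[float, ...] = ()


def _oster_cubic_coefficients(inp: OsterInputs) -> np.ndarray:
    """Coefficients (ascending) of the proportional-selection cubic in beta.

    Derived from the moment system of the selection model
    y = beta x + w1 + W2 + e with W2 orthogonal to the controls:

        s2x(b)  = (beta_tilde - b) tau_x
        s1x(b)  = (beta_dot - b) sigma2_x - s2x
        s11(b)  = (r2_tilde - r2_dot) sigma2_y - s2x^2/tau_x
                  + (beta_dot - b)^2 sigma2_x
        s22(b)  = (r_max - r2_tilde) sigma2_y + s2x^2/tau_x
        f(b)    = s2x s11 - pi s1x s22 = 0

    f is exactly cubic in b, so its coefficients are obtained by
    interpolation at four nodes.
    """
    bt, bd = inp.beta_tilde, inp.beta_dot
    sy, sx, tx = inp.sigma2_y, inp.sigma2_x, inp.tau_x
    rd, rt, rm, d = inp.r2_dot, inp.r2_tilde, inp.r_max, inp.pi

    def f(b):
        s2x = (bt - b) * tx
        s1x = (bd - b) * sx - s2x
        s11 = (rt - rd) * sy - s2x**2 / tx + (bd - b) ** 2 * sx
        s22 = (rm - rt) * sy + s2x**2 / tx
        return s2x * s11 - d * s1x * s22

    scale = max(1.0, abs(bt), abs(bd))
    nodes = np.array([0.0, 1.0, -1.0, 2.0]) * scale + bt
    vals = np.array([f(b) for b in nodes])
    # exact cubic through four nodes
    V = np.vander(nodes, 4, increasing=True)
    return np.linalg.solve(V, vals)


def oster_adjusted_beta(inputs: OsterInputs, method: str = "approximation") -> OsterResult:
    """Bias-adjusted coefficient under proportional selection on unobservables.

    ``approximation`` uses
    ``beta* = beta_tilde - pi (beta_dot - beta_tilde)(r_max - r2_tilde)/(r2_tilde - r2_dot)``;
    ``exact_root`` solves the selection model's cubic and picks the real root
    closest to the controlled coefficient.  Returns beta* together with the
    identified set [beta_tilde, beta*].
    """
    inputs.validate()
    if method == "approximation":
        beta_star = inputs.beta_tilde - inputs.pi * (
            inputs.beta_dot - inputs.beta_tilde
        ) * (inputs.r_max - inputs.r2_tilde) / (inputs.r2_tilde - inputs.r2_dot)
        roots: tuple[float, ...] = ()
    elif method == "exact_root":
        if None in (inputs.sigma2_y, inputs.sigma2_x, inputs.tau_x):
            raise ValueError(
                "exact_root needs sigma2_y, sigma2_x and tau_x; "
                "use oster_inputs_from_designs or supply them directly"
            )
        coefs = _oster_cubic_coefficients(inputs)
        all_roots = np.roots(coefs[::-1])
        scale = max(1.0, abs(inputs.beta_tilde), abs(inputs.beta_dot))
        real = [float(r.real) for r in all_roots if abs(r.imag) < 1e-8 * scale]
        if not real:
            raise ArithmeticError("selection cubic has no real root")
        roots = tuple(sorted(real))
        beta_star = min(real, key=lambda r: abs(r - inputs.beta_tilde))
    else:
        raise ValueError("method must be 'approximation' or 'exact_root'")
    lo, hi = sorted((float(inputs.beta_tilde), float(beta_star)))
    return OsterResult(
        beta_star=float(beta_star), identified_set=(lo, hi), method=method, roots=roots
    )


def oster_inputs_from_designs(
    panel, pi: float = -0.10, r_max: float = 1.0
) -> OsterInputs:
    """Assemble sensitivity inputs from the bivariate and Main Design fits.

    The uncontrolled regression is the bivariate ln-ln fit; the controlled
    one is the two-way fixed-effects Main Design (its R-squared counts the
    absorbed effects as controls); tau_x is the variance of ln richness after
    FE absorption.
    """
    df = _base_columns(as_frame(panel))
    short = estimate_bivariate(df)
    long = estimate_main_design(df)
    demeaned, _ = absorb_fixed_effects(
        df[[LN_RICHNESS]], FixedEffectsSpec(("plot", "site_year")).codes(df)
    )
    return OsterInputs(
        beta_dot=float(short.params[LN_RICHNESS]),
        r2_dot=float(short.r2_total),
        beta_tilde=float(long.params[LN_RICHNESS]),
        r2_tilde=float(long.r2_total),
        pi=pi,
        r_max=r_max,
        sigma2_y=float(np.var(df[LN_BIOMASS].to_numpy(), ddof=1)),
        sigma2_x=float(np.var(df[LN_RICHNESS].to_numpy(), ddof=1)),
        tau_x=float(np.var(demeaned[LN_RICHNESS].to_numpy(), ddof=1)),
    )
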