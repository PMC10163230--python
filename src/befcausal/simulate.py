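"""Synthetic longitudinal grassland panels with known causal ground truth.

The generator is recursive in time.  For plot p in site s at year t:

    lnR_pt = r0 + alpha_p + nu_st + a_pt + gamma Z_pt + lambda shade_{p,t-1} + u_pt
    R_pt   = clip(round(exp(lnR_pt)), 1, pool_size)        (observed richness)
    lnP_pt = p0 + beta ln R_pt + delta_p + mu_st + b_pt + eps_pt
    shade_pt = logistic((lnP_pt - midpoint) / scale)

where (alpha_p, delta_p), (nu_st, mu_st) and (a_pt, b_pt) are correlated
Gaussian loading pairs -- the confounders that hit richness and productivity
together -- Z is an excluded instrument, eps is an (optionally AR(1))
productivity-only error, and productivity is built from the *observed*
integer richness so that noiseless configurations recover beta exactly.
A burn-in year initializes the shading lag and the AR(1) state.

Community composition follows a geometric rank-abundance pool per site; a
plot-year with richness R holds R species drawn with abundance-proportional
(Gumbel top-k) sampling, so the marginal species at higher richness is
increasingly a rare, disproportionately non-native one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig, scenario
from .panel import (
    BIOMASS,
    COVER,
    ORIGIN,
    NATIVE,
    NON_NATIVE,
    PLOT,
    RICHNESS,
    SITE,
    SPECIES,
    YEAR,
    PanelDataset,
    SPECIES_TYPES,
    TYPE_COLUMNS,
)

FIRST_YEAR = 2007


@dataclass
class TruthRecord:
    """Everything the estimators are not allowed to see.

    One plot-year per row in ``plotyear``; regenerating with the same config
    reproduces every frame bit for bit.
    """

    config: SimulationConfig
    beta_true: float
    beta_by_type: tuple[float, float, float, float] | None
    plot_effects: pd.DataFrame  # plot_id, site_id, alpha, delta, site_group
    siteyear_effects: pd.DataFrame  # site_id, year, nu, mu
    plotyear: pd.DataFrame  # plot_id, year, a, b, z, u, eps, lnR_latent, lnP, included
    pools: pd.DataFrame | None = None  # site_id, species_id, rank, abundance, origin, rare

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "beta_true": self.beta_true,
            "beta_by_type": self.beta_by_type,
            "plot_effects": self.plot_effects.to_dict(orient="list"),
            "siteyear_effects": self.siteyear_effects.to_dict(orient="list"),
            "plotyear": self.plotyear.to_dict(orient="list"),
            "pools": None if self.pools is None else self.pools.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _bivariate_pairs(rng: np.random.Generator, n: int, sd: float, rho: float):
    """Correlated loading pair (one for lnR, one for lnP), each with sd ``sd``."""
    z = rng.standard_normal((n, 2))
    a = sd * z[:, 0]
    b = sd * (rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - rho**2)) * z[:, 1])
    return a, b


def _plot_layout(config: SimulationConfig):
    site_ids = [f"S{s:02d}" for s in range(config.n_sites)]
    cycle = config.plot_count_cycle
    plots, site_of_plot = [], []
    for s, sid in enumerate(site_ids):
        count = cycle[s % len(cycle)] if cycle else config.plots_per_site
        for j in range(count):
            plots.append(f"{sid}P{j}")
            site_of_plot.append(s)
    return site_ids, plots, np.asarray(site_of_plot)


def build_species_pools(rng: np.random.Generator, config: SimulationConfig, site_ids):
    """Geometric rank-abundance pool per site with origin and rarity labels.

    Relative abundance of rank k is proportional to decay^k; a species is
    (truly) rare when its pool relative abundance is below the rarity cutoff.
    Non-native labels are drawn with probability increasing linearly in rank,
    averaging ``frac_nonnative``, so the rare tail is disproportionately
    non-native.
    """
    S = config.pool_size
    ranks = np.arange(1, S + 1)
    abund = config.rank_abundance_decay ** (ranks - 1)
    abund = abund / abund.sum()
    rare = abund < config.rarity_cutoff
    frames = []
    for sid in site_ids:
        p_nonnative = np.clip(2.0 * config.frac_nonnative * ranks / S, 0.0, 1.0)
        nonnative = rng.random(S) < p_nonnative
        origin = np.where(nonnative, NON_NATIVE, NATIVE)
        stype = np.where(
            rare,
            np.where(nonnative, "rare_nonnative", "rare_native"),
            np.where(nonnative, "nonrare_nonnative", "nonrare_native"),
        )
        frames.append(
            pd.DataFrame(
                {
                    SITE: sid,
                    SPECIES: [f"{sid}_sp{k:02d}" for k in ranks],
                    "rank": ranks,
                    "abundance": abund,
                    ORIGIN: origin,
                    "rare": rare,
                    "species_type": stype,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sample_members(rng: np.random.Generator, log_abund: np.ndarray, richness: np.ndarray):
    """Abundance-weighted sampling without replacement via Gumbel top-k."""
    n = len(richness)
    gumbel = rng.gumbel(size=(n, len(log_abund)))
    order = np.argsort(-(log_abund[None, :] + gumbel), axis=1)
    return [order[i, : richness[i]] for i in range(n)]


def simulate_panel(
    config: SimulationConfig, include_cover: bool = False
) -> tuple[PanelDataset, TruthRecord]:
    """Generate a panel plus its ground truth.

    Returns the panel the estimators see (biomass, integer richness, shading,
    instrument, observed confounder proxies, and per-type richness columns
    when composition is simulated) and the :class:`TruthRecord` of latent
    draws.  Two independent random streams are spawned from the seed -- one
    for the panel, one for community composition -- so the panel realization
    is unchanged by whether cover is simulated.
    """
    rng, rng_cover = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(2)
    )
    site_ids, plot_ids, site_of_plot = _plot_layout(config)
    n_plots, n_sites = len(plot_ids), len(site_ids)
    T = config.n_years + 1  # index 0 is a burn-in year

    alpha, delta = _bivariate_pairs(rng, n_plots, config.sd_plot_confounder, config.rho_plot)
    nu_flat, mu_flat = _bivariate_pairs(
        rng, n_sites * T, config.sd_siteyear_confounder, config.rho_siteyear
    )
    nu = nu_flat.reshape(n_sites, T)
    mu = mu_flat.reshape(n_sites, T)
    a_flat, b_flat = _bivariate_pairs(
        rng, n_plots * T, config.sd_plotyear_confounder, config.rho_plotyear
    )
    a_pt = a_flat.reshape(n_plots, T)
    b_pt = b_flat.reshape(n_plots, T)
    z = rng.standard_normal((n_plots, T))
    u = config.sd_richness_noise * rng.standard_normal((n_plots, T))
    innov = rng.standard_normal((n_plots, T))
    cov_plot = delta + config.covariate_noise * rng.standard_normal(n_plots)
    cov_siteyear = mu + config.covariate_noise * rng.standard_normal((n_sites, T))
    if config.year_window is not None:
        lo, hi = config.year_window
        lo, hi = min(lo, config.n_years), min(hi, config.n_years)
        lengths = rng.integers(lo, hi + 1, size=n_plots)
        starts = np.array([rng.integers(0, config.n_years - L + 1) for L in lengths])
    else:
        lengths = np.full(n_plots, config.n_years)
        starts = np.zeros(n_plots, dtype=int)

    by_type = config.beta_by_type is not None
    need_cover = by_type or include_cover
    pools = build_species_pools(rng_cover, config, site_ids) if need_cover else None
    if need_cover:
        log_abund = np.log(
            pools[pools[SITE] == site_ids[0]]["abundance"].to_numpy()
        )  # identical across sites by construction
        type_index = {name: i for i, name in enumerate(SPECIES_TYPES)}
        pool_type_codes = {
            sid: np.array(
                [type_index[t] for t in pools.loc[pools[SITE] == sid, "species_type"]]
            )
            for sid in site_ids
        }
        pool_species = {
            sid: pools.loc[pools[SITE] == sid, SPECIES].to_numpy() for sid in site_ids
        }
        pool_origin = {
            sid: pools.loc[pools[SITE] == sid, ORIGIN].to_numpy() for sid in site_ids
        }

    site_group = (np.arange(n_sites) % 2).astype(int)
    beta_site = config.beta_true + config.beta_moderator * site_group

    shade_prev = np.full(n_plots, 0.5)
    eps_prev = np.zeros(n_plots)
    ar = config.ar1_noise
    rows: list[dict] = []
    truth_rows: list[dict] = []
    cover_rows: list[dict] = []

    for t in range(T):
        lnR = (
            config.baseline_log_richness
            + alpha
            + nu[site_of_plot, t]
            + a_pt[:, t]
            + config.instrument_strength * z[:, t]
            + config.reverse_lambda * shade_prev
            + u[:, t]
        )
        R = np.clip(np.rint(np.exp(lnR)), 1, config.pool_size).astype(int)
        ln_obs = np.log(R.astype(float))

        if t == 0:
            eps = config.sd_noise * innov[:, t]
        else:
            eps = ar * eps_prev + config.sd_noise * np.sqrt(1.0 - ar**2) * innov[:, t]

        type_counts = None
        members = None
        if need_cover:
            members = _sample_members(rng_cover, log_abund, R)
            type_counts = np.zeros((n_plots, 4), dtype=int)
            for i in range(n_plots):
                codes = pool_type_codes[site_ids[site_of_plot[i]]][members[i]]
                type_counts[i] = np.bincount(codes, minlength=4)

        if by_type:
            bt = np.asarray(config.beta_by_type)
            effect = np.arcsinh(type_counts) @ bt
        else:
            effect = beta_site[site_of_plot] * ln_obs

        lnP = (
            config.baseline_log_biomass
            + effect
            + delta
            + mu[site_of_plot, t]
            + b_pt[:, t]
            + eps
            + config.site_group_shift * site_group[site_of_plot]
        )
        shade = expit((lnP - config.shade_midpoint) / config.shade_scale)

        if t >= 1:
            year = FIRST_YEAR + (t - 1)
            included = (starts <= t - 1) & (t - 1 < starts + lengths)
            for i in range(n_plots):
                truth_rows.append(
                    {
                        PLOT: plot_ids[i],
                        YEAR: year,
                        "a": a_pt[i, t],
                        "b": b_pt[i, t],
                        "z": z[i, t],
                        "u": u[i, t],
                        "eps": eps[i],
                        "lnR_latent": lnR[i],
                        "lnP": lnP[i],
                        "included": bool(included[i]),
                    }
                )
                if not included[i]:
                    continue
                sid = site_ids[site_of_plot[i]]
                row = {
                    SITE: sid,
                    PLOT: plot_ids[i],
                    YEAR: year,
                    BIOMASS: float(np.exp(lnP[i])),
                    RICHNESS: int(R[i]),
                    "shade": float(shade[i]),
                    "shade_lag": float(shade_prev[i]),
                    "instrument": float(z[i, t]),
                    "cov_plot": float(cov_plot[i]),
                    "cov_siteyear": float(cov_siteyear[site_of_plot[i], t]),
                    "site_group": int(site_group[site_of_plot[i]]),
                }
                if need_cover:
                    for col, cnt in zip(TYPE_COLUMNS, type_counts[i]):
                        row[col] = int(cnt)
                if include_cover:
                    sp = pool_species[sid][members[i]]
                    og = pool_origin[sid][members[i]]
                    ab = np.exp(log_abund[members[i]])
                    shares = ab / ab.sum()
                    for s_id, s_origin, s_share in zip(sp, og, shares):
                        cover_rows.append(
                            {
                                SITE: sid,
                                PLOT: plot_ids[i],
                                YEAR: year,
                                SPECIES: s_id,
                                COVER: float(s_share),
                                ORIGIN: s_origin,
                            }
                        )
                rows.append(row)

        shade_prev = shade
        eps_prev = eps

    data = pd.DataFrame(rows).sort_values([SITE, PLOT, YEAR]).reset_index(drop=True)
    panel = PanelDataset(data, inclusion_min_years=0)
    if include_cover:
        panel.cover = (
            pd.DataFrame(cover_rows).sort_values([SITE, PLOT, YEAR, SPECIES]).reset_index(drop=True)
        )

    siteyear = pd.DataFrame(
        {
            SITE: np.repeat(site_ids, config.n_years),
            YEAR: np.tile(np.arange(FIRST_YEAR, FIRST_YEAR + config.n_years), n_sites),
            "nu": nu[:, 1:].ravel(),
            "mu": mu[:, 1:].ravel(),
        }
    )
    truth = TruthRecord(
        config=config,
        beta_true=config.beta_true,
        beta_by_type=config.beta_by_type,
        plot_effects=pd.DataFrame(
            {
                PLOT: plot_ids,
                SITE: [site_ids[s] for s in site_of_plot],
                "alpha": alpha,
                "delta": delta,
                "site_group": site_group[site_of_plot],
            }
        ),
        siteyear_effects=siteyear,
        plotyear=pd.DataFrame(truth_rows),
        pools=pools,
    )
    return panel, truth


def simulate_cover(config: SimulationConfig, richness: pd.DataFrame) -> pd.DataFrame:
    """Sample species composition for externally supplied richness values.

    ``richness`` must carry the panel key columns plus a ``richness`` column
    with values not exceeding the pool size.  Covers are the pool relative
    abundances of the drawn species, renormalized to sum to one per plot-year.
    """
    R = richness[RICHNESS].to_numpy()
    if (R > config.pool_size).any():
        raise ValueError("requested richness exceeds the species pool")
    rng_cover = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    site_ids = sorted(richness[SITE].unique())
    pools = build_species_pools(rng_cover, config, site_ids)
    log_abund = np.log(pools[pools[SITE] == site_ids[0]]["abundance"].to_numpy())
    by_site_species = {
        sid: pools.loc[pools[SITE] == sid, SPECIES].to_numpy() for sid in site_ids
    }
    by_site_origin = {
        sid: pools.loc[pools[SITE] == sid, ORIGIN].to_numpy() for sid in site_ids
    }
    members = _sample_members(rng_cover, log_abund, R.astype(int))
    rows = []
    for i, (_, rec) in enumerate(richness.iterrows()):
        sid = rec[SITE]
        idx = members[i]
        ab = np.exp(log_abund[idx])
        shares = ab / ab.sum()
        for j, k in enumerate(idx):
            rows.append(
                {
                    SITE: sid,
                    PLOT: rec[PLOT],
                    YEAR: int(rec[YEAR]),
                    SPECIES: by_site_species[sid][k],
                    COVER: float(shares[j]),
                    ORIGIN: by_site_origin[sid][k],
                }
            )
    return pd.DataFrame(rows)


def pooled_ovb_decomposition(panel, truth: TruthRecord) -> dict:
    """In-sample omitted-variable-bias accounting for the pooled ln-ln slope.

    With lnP = beta lnR + e, the pooled OLS slope (with intercept) equals
    beta + cov(lnR, e)/var(lnR) exactly on the realized draws.  Returns the
    true beta, the realized bias and the implied pooled slope.
    """
    if truth.beta_by_type is not None or truth.config.beta_moderator != 0.0:
        raise ValueError("decomposition defined for the homogeneous-effect DGP")
    from .panel import as_frame

    df = as_frame(panel).merge(
        truth.plot_effects.drop(columns=["site_group"]), on=[PLOT, SITE]
    )
    df = df.merge(truth.siteyear_effects, on=[SITE, YEAR])
    df = df.merge(
        truth.plotyear[[PLOT, YEAR, "b", "eps"]], on=[PLOT, YEAR]
    )
    lnR = np.log(df[RICHNESS].to_numpy(dtype=float))
    e = (
        df["delta"].to_numpy()
        + df["mu"].to_numpy()
        + df["b"].to_numpy()
        + df["eps"].to_numpy()
        + truth.config.site_group_shift * df["site_group"].to_numpy()
    )
    bias = float(np.cov(lnR, e, ddof=1)[0, 1] / np.var(lnR, ddof=1))
    return {
        "beta_true": truth.beta_true,
        "bias": bias,
        "expected_pooled_slope": truth.beta_true + bias,
    }


__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "scenario",
    "simulate_panel",
    "simulate_cover",
    "build_species_pools",
    "pooled_ovb_decomposition",
]
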