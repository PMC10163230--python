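"""Panel containers, validation, diversity metrics and fixed-effect transforms.

The central object is a long-format plot x site x year table of grassland
observations: aboveground live biomass (g/m^2), plot-level species richness,
and optional covariates (shading, an instrument, per-type richness counts).
Everything downstream -- the two-way fixed-effects estimator, the
instrumental-variable and lagged-dependent-variable designs, the
heterogeneity analysis -- consumes the validated :class:`PanelDataset`
produced by :func:`build_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SITE = "site_id"
PLOT = "plot_id"
YEAR = "year"
BIOMASS = "live_mass"
RICHNESS = "richness"
KEY_COLUMNS = (SITE, PLOT, YEAR)

SPECIES = "species_id"
COVER = "relative_cover"
ORIGIN = "origin"
NATIVE = "native"
NON_NATIVE = "non-native"

#: the four rarity-by-origin species types, in conventional order
SPECIES_TYPES = ("rare_native", "nonrare_native", "nonrare_nonnative", "rare_nonnative")
#: per-type richness column names carried by panels with composition data
TYPE_COLUMNS = tuple(f"R_{t}" for t in SPECIES_TYPES)


class PanelError(ValueError):
    """Raised when a raw table violates the panel contract."""


class ConvergenceError(RuntimeError):
    """Raised when alternating demeaning fails to converge."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PanelDataset:
    """A validated long-format panel of plot-year observations.

    ``data`` holds one row per (plot, year); plots are nested in sites.
    ``drop_log`` records every row removed during ingestion together with the
    reason, so that ``rows_in == rows_kept + len(drop_log)`` always
    reconciles.
    """

    data: pd.DataFrame
    drop_log: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=[*KEY_COLUMNS, "reason"])
    )
    inclusion_min_years: int = 5
    #: optional species-level relative-cover table aligned with ``data``
    cover: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_plots(self) -> int:
        return self.data[PLOT].nunique()

    @property
    def n_sites(self) -> int:
        return self.data[SITE].nunique()

    def require(self, columns: Iterable[str], context: str = "") -> None:
        missing = [c for c in columns if c not in self.data.columns]
        if missing:
            where = f" for {context}" if context else ""
            raise PanelError(f"panel is missing column(s) {missing}{where}")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def as_frame(panel) -> pd.DataFrame:
    """Accept a PanelDataset or a bare DataFrame and return the DataFrame."""
    if isinstance(panel, PanelDataset):
        return panel.data
    if isinstance(panel, pd.DataFrame):
        return panel
    raise TypeError(f"expected PanelDataset or DataFrame, got {type(panel)!r}")


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------


def build_panel(
    raw: pd.DataFrame,
    inclusion_min_years: int = 5,
    column_map: Mapping[str, str] | None = None,
) -> PanelDataset:
    """Validate a raw long-format table and apply the inclusion rule.

    Plots contributing fewer than ``inclusion_min_years`` observed years are
    dropped entirely (the study keeps plots with five or more years of data);
    rows with non-positive or missing biomass, or richness below one, are
    excluded individually.  Duplicate (plot, year) rows or a plot that appears
    under two sites are hard errors rather than silent fixes.
    """
    df = raw.rename(columns=dict(column_map or {})).copy()
    for col in KEY_COLUMNS:
        if col not in df.columns:
            raise PanelError(f"raw table lacks required column {col!r}")
    if df.empty:
        empty = df.head(0)
        return PanelDataset(empty, inclusion_min_years=inclusion_min_years)

    df[SITE] = df[SITE].astype(str)
    df[PLOT] = df[PLOT].astype(str)
    df[YEAR] = pd.to_numeric(df[YEAR], errors="raise").astype(int)

    dup = df.duplicated([PLOT, YEAR], keep=False)
    if dup.any():
        pairs = df.loc[dup, [PLOT, YEAR]].drop_duplicates().to_records(index=False)
        raise PanelError(f"duplicate (plot, year) rows: {list(pairs)[:5]}")
    sites_per_plot = df.groupby(PLOT)[SITE].nunique()
    multi = sites_per_plot[sites_per_plot > 1]
    if len(multi):
        raise PanelError(f"plot(s) mapped to more than one site: {list(multi.index)[:5]}")

    drops: list[pd.DataFrame] = []

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        if mask.any():
            gone = df.loc[mask, list(KEY_COLUMNS)].copy()
            gone["reason"] = reason
            drops.append(gone)
            df = df.loc[~mask]

    if BIOMASS in df.columns:
        mass = pd.to_numeric(df[BIOMASS], errors="coerce")
        df[BIOMASS] = mass
        _drop(~(mass > 0), "nonpositive_or_missing_biomass")
    if RICHNESS in df.columns:
        rich = pd.to_numeric(df[RICHNESS], errors="coerce")
        df[RICHNESS] = rich
        _drop(~(rich >= 1), "richness_below_one")
        df[RICHNESS] = df[RICHNESS].astype(int)

    years_per_plot = df.groupby(PLOT)[YEAR].transform("nunique")
    _drop(years_per_plot < inclusion_min_years, "below_min_years")

    drop_log = (
        pd.concat(drops, ignore_index=True)
        if drops
        else pd.DataFrame(columns=[*KEY_COLUMNS, "reason"])
    )
    df = df.sort_values([SITE, PLOT, YEAR]).reset_index(drop=True)
    return PanelDataset(df, drop_log=drop_log, inclusion_min_years=inclusion_min_years)


# ---------------------------------------------------------------------------
# diversity metrics
# ---------------------------------------------------------------------------


def diversity_metrics(cover: pd.DataFrame) -> pd.DataFrame:
    """Per plot-year richness, inverse Simpson's diversity and Pielou evenness.

    Shares are renormalized within each plot-year before computing
    ``simpson_d = 1 / sum(p_i^2)`` and ``evenness = -sum(p_i ln p_i) /
    ln(richness)``; evenness is missing (not zero) for single-species
    plot-years.
    """
    needed = [*KEY_COLUMNS, SPECIES, COVER]
    missing = [c for c in needed if c not in cover.columns]
    if missing:
        raise PanelError(f"cover table missing column(s) {missing}")
    df = cover[needed].copy()
    totals = df.groupby(list(KEY_COLUMNS))[COVER].transform("sum")
    if (totals <= 0).any():
        bad = df.loc[totals <= 0, list(KEY_COLUMNS)].drop_duplicates()
        raise PanelError(
            f"all-zero cover in plot-year(s): {bad.head().to_records(index=False).tolist()}"
        )
    df = df[df[COVER] > 0]
    p = df[COVER] / df.groupby(list(KEY_COLUMNS))[COVER].transform("sum")
    df = df.assign(_p2=p**2, _plogp=p * np.log(p))
    agg = df.groupby(list(KEY_COLUMNS)).agg(
        richness=(SPECIES, "size"), _p2=("_p2", "sum"), _plogp=("_plogp", "sum")
    )
    out = pd.DataFrame(index=agg.index)
    out[RICHNESS] = agg["richness"].astype(int)
    out["simpson_d"] = 1.0 / agg["_p2"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["evenness"] = np.where(
            out[RICHNESS] > 1, -agg["_plogp"] / np.log(out[RICHNESS]), np.nan
        )
    return out.reset_index()


def ihs(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2 + 1)).

    Log-like but defined at zero, which makes it the natural transform for
    per-type richness counts that can be absent from a plot-year.
    """
    return np.arcsinh(x)


# ---------------------------------------------------------------------------
# fixed-effect absorption
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedEffectsSpec:
    """Which group intercepts to absorb before least squares.

    Supported factors: ``"plot"`` (one intercept per plot, which subsumes all
    time-invariant site attributes because plots are nested in sites) and
    ``"site_year"`` (one intercept per site-by-year cell, absorbing
    site-level shocks such as weather).  Any plain column name is also
    accepted as a factor.
    """

    factors: tuple[str, ...] = ("plot", "site_year")

    def codes(self, df: pd.DataFrame) -> list[pd.Series]:
        out = []
        for f in self.factors:
            if f == "plot":
                out.append(df[PLOT])
            elif f == "site_year":
                out.append(df[SITE].astype(str) + "::" + df[YEAR].astype(str))
            elif f in df.columns:
                out.append(df[f])
            else:
                raise PanelError(f"unknown fixed-effect factor {f!r}")
        return out


@dataclass
class AbsorptionReport:
    n_iter: int
    max_change: float
    converged: bool
    absorbed_df: int
    n_levels: tuple[int, ...]
    singleton_groups: int


def _union_find_components(codes_a: np.ndarray, n_a: int, codes_b: np.ndarray, n_b: int) -> int:
    parent = np.arange(n_a + n_b)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in zip(codes_a, codes_b + n_a):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    return len({find(i) for i in range(n_a + n_b)})


def absorbed_degrees_of_freedom(codes_list: list[np.ndarray]) -> int:
    """Rank of the absorbed indicator space (intercept included).

    One factor: number of levels.  Two factors: levels_1 + levels_2 minus the
    number of connected components of the bipartite level graph (for plots
    nested in sites with site-year cells this equals the number of sites).
    """
    sizes = [int(c.max()) + 1 for c in codes_list]
    if len(codes_list) == 1:
        return sizes[0]
    if len(codes_list) == 2:
        comps = _union_find_components(codes_list[0], sizes[0], codes_list[1], sizes[1])
        return sizes[0] + sizes[1] - comps
    raise PanelError("absorption supports one or two factors")


def absorb_fixed_effects(
    columns: pd.DataFrame,
    factors: Sequence[pd.Series | np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[pd.DataFrame, AbsorptionReport]:
    """Residualize ``columns`` on group indicators by alternating demeaning.

    Sweeps subtract within-group means for each factor in turn until the
    largest adjustment in a full sweep falls below ``tol``; the result is the
    same projection as explicit-dummy least squares (checked against that
    oracle in the tests) but without materializing the dummy matrix.
    """
    if not len(factors):
        raise PanelError("at least one factor required")
    M = columns.to_numpy(dtype=float).copy()
    if np.isnan(M).any():
        raise PanelError("columns to absorb contain missing values")
    codes_list = [pd.factorize(np.asarray(f))[0] for f in factors]
    counts = [np.bincount(c).astype(float) for c in codes_list]
    singletons = sum(int((cnt == 1).sum()) for cnt in counts)

    converged = False
    it = 0
    max_change = np.inf
    for it in range(1, max_iter + 1):
        max_change = 0.0
        for codes, cnt in zip(codes_list, counts):
            gm = np.zeros((len(cnt), M.shape[1]))
            np.add.at(gm, codes, M)
            gm /= cnt[:, None]
            adj = gm[codes]
            M -= adj
            if adj.size:
                max_change = max(max_change, float(np.abs(adj).max()))
        if max_change < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"alternating demeaning did not converge in {max_iter} sweeps "
            f"(last change {max_change:.3e})"
        )
    report = AbsorptionReport(
        n_iter=it,
        max_change=max_change,
        converged=converged,
        absorbed_df=absorbed_degrees_of_freedom(codes_list),
        n_levels=tuple(len(c) for c in counts),
        singleton_groups=singletons,
    )
    out = pd.DataFrame(M, columns=columns.columns, index=columns.index)
    return out, report
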