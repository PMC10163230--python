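"""Species-type heterogeneity: rarity x origin classification and per-type effects.

Richness is a compound treatment: adding a dominant native species is a
different intervention from adding a rare or non-native one.  Species are
classified per site into four types -- rare native, non-rare native,
non-rare non-native, rare non-native -- by comparing their site-level mean
relative cover (or relative frequency) to a cutoff.  The Main Design is then
re-estimated with the four per-type richness counts, on the inverse
hyperbolic sine scale so that zero counts are admissible, and a Wald test
asks whether the four effects are equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EstimationResult,
    IdentificationError,
    _as_cluster,
    _base_columns,
    cluster_fit,
)
from .panel import (
    BIOMASS,
    COVER,
    KEY_COLUMNS,
    ORIGIN,
    NON_NATIVE,
    PLOT,
    RICHNESS,
    SITE,
    SPECIES,
    SPECIES_TYPES,
    TYPE_COLUMNS,
    YEAR,
    FixedEffectsSpec,
    PanelError,
    absorb_fixed_effects,
    as_frame,
    ihs,
)

IHS_TYPE_COLUMNS = tuple(f"ihs_{c}" for c in TYPE_COLUMNS)


@dataclass
class SpeciesTypeTable:
    """Per (site, species) rarity/origin classification.

    ``table`` has columns site_id, species_id, abundance, rare, origin,
    species_type; the four types partition every classified species.
    ``dropped_plots`` lists plots excluded for missing origin labels.
    """

    table: pd.DataFrame
    cutoff: float
    metric: str
    dropped_plots: tuple[str, ...] = ()


def classify_species(
    cover: pd.DataFrame, cutoff: float = 0.05, metric: str = "relative_cover"
) -> SpeciesTypeTable:
    """Classify species into the four rarity-by-origin types per site.

    Site-level abundance is the mean relative cover of the species across all
    of the site's plot-years (absences count as zero); with
    ``metric="relative_frequency"`` it is the share of plot-years in which
    the species occurs.  A species is rare iff its abundance is below
    ``cutoff``.  Plots containing species without an origin label are dropped
    (with a record) before classification.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0, 1)")
    if metric not in ("relative_cover", "relative_frequency"):
        raise ValueError("metric must be 'relative_cover' or 'relative_frequency'")
    df = cover.copy()
    bad_plots = tuple(sorted(df.loc[df[ORIGIN].isna(), PLOT].unique()))
    if bad_plots:
        df = df[~df[PLOT].isin(bad_plots)]
    if df.empty:
        raise PanelError("no cover rows with origin labels")

    origins = df.groupby([SITE, SPECIES])[ORIGIN].nunique()
    if (origins > 1).any():
        bad = origins[origins > 1].index.tolist()[:5]
        raise PanelError(f"origin label not constant within site for: {bad}")

    n_plot_years = df.groupby(SITE)[[PLOT, YEAR]].apply(
        lambda g: g.drop_duplicates().shape[0]
    )
    present = df[df[COVER] > 0]
    if metric == "relative_cover":
        mass = present.groupby([SITE, SPECIES])[COVER].sum()
    else:
        mass = present.groupby([SITE, SPECIES])[COVER].size().astype(float)
    abundance = mass / n_plot_years.reindex(mass.index.get_level_values(SITE)).to_numpy()

    table = abundance.rename("abundance").reset_index()
    origin_map = df.groupby([SITE, SPECIES])[ORIGIN].first()
    table[ORIGIN] = origin_map.reindex(
        pd.MultiIndex.from_frame(table[[SITE, SPECIES]])
    ).to_numpy()
    table["rare"] = table["abundance"] < cutoff
    nonnative = table[ORIGIN] == NON_NATIVE
    table["species_type"] = np.where(
        table["rare"],
        np.where(nonnative, "rare_nonnative", "rare_native"),
        np.where(nonnative, "nonrare_nonnative", "nonrare_native"),
    )
    return SpeciesTypeTable(
        table=table, cutoff=cutoff, metric=metric, dropped_plots=bad_plots
    )


def per_type_richness(cover: pd.DataFrame, types: SpeciesTypeTable) -> pd.DataFrame:
    """Per plot-year count of present species in each of the four types.

    The four columns partition total richness: their sum equals the number of
    species with positive cover in the plot-year.
    """
    df = cover[cover[COVER] > 0]
    if types.dropped_plots:
        df = df[~df[PLOT].isin(types.dropped_plots)]
    merged = df.merge(
        types.table[[SITE, SPECIES, "species_type"]], on=[SITE, SPECIES], how="left"
    )
    if merged["species_type"].isna().any():
        missing = merged.loc[merged["species_type"].isna(), SPECIES].unique()[:5]
        raise PanelError(f"species missing from the type table: {list(missing)}")
    counts = (
        merged.groupby([*KEY_COLUMNS, "species_type"])
        .size()
        .unstack("species_type", fill_value=0)
    )
    for t in SPECIES_TYPES:
        if t not in counts.columns:
            counts[t] = 0
    counts = counts[list(SPECIES_TYPES)]
    counts.columns = list(TYPE_COLUMNS)
    return counts.reset_index()


def estimate_by_type(
    panel, type_cols: tuple[str, ...] = TYPE_COLUMNS, cluster="plot"
) -> EstimationResult:
    """Main Design with ihs-transformed per-type richness replacing ln richness.

    Plot and site-by-year fixed effects are absorbed as usual.  A type whose
    count has no within variation left after absorption cannot be estimated;
    it is dropped from the regression and flagged in ``extra['unidentified']``.
    """
    df = _base_columns(as_frame(panel))
    missing = [c for c in type_cols if c not in df.columns]
    if missing:
        raise PanelError(f"per-type richness column(s) absent: {missing}")
    names = []
    for c in type_cols:
        df[f"ihs_{c}"] = ihs(df[c].to_numpy(dtype=float))
        names.append(f"ihs_{c}")

    from .estimators import LN_BIOMASS

    spec = FixedEffectsSpec(("plot", "site_year"))
    demeaned, report = absorb_fixed_effects(df[[LN_BIOMASS, *names]], spec.codes(df))
    unidentified = [
        n for n in names if float(demeaned[n].to_numpy().var()) <= 1e-24
    ]
    used = [n for n in names if n not in unidentified]
    if not used:
        raise IdentificationError("no per-type richness column has within variation")

    cl = _as_cluster(cluster)
    yv = df[LN_BIOMASS].to_numpy(dtype=float)
    res = cluster_fit(
        "by_type",
        demeaned[LN_BIOMASS].to_numpy(),
        demeaned[used].to_numpy(),
        used,
        cl.ids(df),
        fixed_effects=("plot", "site_year"),
        df_absorbed=report.absorbed_df,
        tss_total=float(((yv - yv.mean()) ** 2).sum()),
        extra={"unidentified": unidentified},
    )
    res.cluster_level = cl.level
    return res


@dataclass
class EqualityTest:
    statistic: float
    df: int
    p_value: float
    base: str


def equality_test(
    result: EstimationResult,
    coefs: tuple[str, ...] = IHS_TYPE_COLUMNS,
    base: int = 0,
) -> EqualityTest:
    """Wald test that the per-type effects are all equal.

    Uses the pairwise-difference contrast against the ``base`` coefficient;
    the statistic is invariant to which coefficient serves as base.  The
    reference distribution is chi-square with (len(coefs) - 1) degrees of
    freedom.
    """
    present = [c for c in coefs if c in result.params.index]
    if len(present) < 2:
        raise ValueError("equality test needs at least 2 estimated coefficients")
    b = result.params[present].to_numpy()
    V = result.vcov.loc[present, present].to_numpy()
    k = len(present)
    C = np.zeros((k - 1, k))
    others = [j for j in range(k) if j != base]
    for i, j in enumerate(others):
        C[i, base] = 1.0
        C[i, j] = -1.0
    diff = C @ b
    mid = C @ V @ C.T
    if np.linalg.matrix_rank(mid) < k - 1:
        raise np.linalg.LinAlgError("contrast covariance is singular")
    stat = float(diff @ np.linalg.solve(mid, diff))
    return EqualityTest(
        statistic=stat,
        df=k - 1,
        p_value=float(stats.chi2.sf(stat, k - 1)),
        base=present[base],
    )
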