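"""Survey harmonization: raw records -> site x 10 functional-group matrix.

The stages mirror how pooled multi-program reef surveys are made comparable:
species exclusions, extreme-count capping, allometric length-weight biomass,
multiplicative method calibration with a species -> family x trophic ->
global decision cascade, 300 m spatial aggregation, functional-group
profiles, and the fourth-root / centre / standardize transform used by the
clustering stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import shapiro

from .lookups import benthic_lookup, exclusion_list, species_lookup
from .synthetic import BENTHIC_COLUMNS, FISH_COLUMNS, GROUP_COLUMNS

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


# ---------------------------------------------------------------------------
# Biomass
# ---------------------------------------------------------------------------

def compute_biomass(obs: pd.DataFrame, params: pd.DataFrame | None = None) -> pd.DataFrame:
    """Attach allometric biomass W = a * TL^b (grams) to fish observations.

    Adds ``mass_g`` (a * TL^b * count) and ``density_g_m2`` (mass / area).
    ``params`` must provide columns (species, a, b); defaults to the packaged
    table. Species without parameters raise a KeyError naming them.
    """
    if params is None:
        params = species_lookup()[["species", "a", "b"]]
    merged = obs.merge(params[["species", "a", "b"]], on="species", how="left")
    missing = merged.loc[merged["a"].isna(), "species"].unique()
    if len(missing):
        raise KeyError(f"no length-weight parameters for species: {sorted(missing)}")
    out = obs.copy()
    out["mass_g"] = (
        merged["a"].to_numpy()
        * merged["length_cm"].to_numpy() ** merged["b"].to_numpy()
        * merged["count"].to_numpy()
    )
    out["density_g_m2"] = out["mass_g"] / out["area_m2"].to_numpy()
    return out


def filter_exclusions(
    obs: pd.DataFrame, exclusions: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Drop species whose life history makes visual counts unreliable
    (cryptic, nocturnal, pelagic-schooling taxa; manta rays)."""
    if exclusions is None:
        exclusions = exclusion_list()
    banned = set(exclusions["species"])
    keep = ~obs["species"].isin(banned)
    n_removed = int((~keep).sum())
    log.info("filter_exclusions removed %d of %d observations", n_removed, len(obs))
    return obs.loc[keep].reset_index(drop=True)


def cap_outliers(
    obs: pd.DataFrame,
    global_quantile: float = 0.999,
    species_quantile: float = 0.99,
    report: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-step extreme-count adjustment for schooling species.

    Step 1 flags observations above the global ``global_quantile`` of all
    individual counts; step 2 replaces, for each flagged species, counts above
    that species' ``species_quantile`` (computed on the pre-capping counts)
    with that quantile. Quantiles are linear-interpolation (type-7) empirical
    quantiles. Passing a previous ``report`` reuses its stored thresholds,
    making the operation idempotent.
    """
    if len(obs) == 0:
        raise ValueError("cap_outliers requires at least one observation")
    out = obs.copy()
    out["count"] = out["count"].astype(float)  # quantile caps are fractional
    counts = out["count"].to_numpy(dtype=float)
    if report is None:
        global_thr = float(np.quantile(counts, global_quantile))
        flagged_species = out.loc[counts > global_thr, "species"].unique()
        rows = []
        for sp in flagged_species:
            sp_counts = out.loc[out["species"] == sp, "count"].to_numpy(dtype=float)
            thr = float(np.quantile(sp_counts, species_quantile))
            rows.append({"species": sp, "threshold": thr, "global_threshold": global_thr})
        report = pd.DataFrame(rows, columns=["species", "threshold", "global_threshold"])
    n_adj = []
    for _, r in report.iterrows():
        mask = (out["species"] == r["species"]) & (out["count"] > r["threshold"])
        out.loc[mask, "count"] = r["threshold"]
        n_adj.append(int(mask.sum()))
    report = report.assign(n_adjusted=n_adj) if len(report) else report.assign(
        n_adjusted=pd.Series(dtype=int)
    )
    return out.reset_index(drop=True), report


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationDecision:
    scope: str  # "species" | "family_trophic" | "global"
    key: str
    factor: float
    model_form: str  # "linear" | "delta" | "log-linear"
    n_pairs: int


def _pairs_for(df: pd.DataFrame, key_col: str, key: str,
               source_method: str, target_method: str) -> pd.DataFrame:
    sub = df[df[key_col] == key]
    wide = (
        sub.pivot_table(index="site_id", columns="method",
                        values="density_g_m2", aggfunc="sum", fill_value=0.0)
        .reindex(columns=[source_method, target_method], fill_value=0.0)
    )
    wide = wide[(wide[source_method] > 0) | (wide[target_method] > 0)]
    return wide.rename(columns={source_method: "x", target_method: "y"})


def _fit_factor(pairs: pd.DataFrame) -> tuple[float, str] | None:
    """Multiplicative factor from paired densities, with the decision rules:
    zero-dominated pairs use a delta model (occurrence x abundance); linear
    through-origin fit otherwise; non-normal residuals fall back to the
    log-scale geometric-mean ratio."""
    x = pairs["x"].to_numpy(dtype=float)
    y = pairs["y"].to_numpy(dtype=float)
    if (x > 0).sum() == 0:
        return None
    zero_frac = np.mean((x == 0) | (y == 0))
    if zero_frac > 0.5:
        both = (x > 0) & (y > 0)
        occ_ratio = np.mean(y > 0) / np.mean(x > 0)
        if both.sum() == 0:
            return None
        abund = float(np.exp(np.mean(np.log(y[both]) - np.log(x[both]))))
        return occ_ratio * abund, "delta"
    slope = float(x @ y / (x @ x))
    resid = y - slope * x
    p_norm = shapiro(resid).pvalue if len(resid) >= 3 and np.ptp(resid) > 0 else 1.0
    if p_norm < 0.05:
        both = (x > 0) & (y > 0)
        if both.sum() == 0:
            return None
        return float(np.exp(np.mean(np.log(y[both]) - np.log(x[both])))), "log-linear"
    return slope, "linear"


def derive_calibration(
    paired: pd.DataFrame,
    target_method: str,
    source_method: str,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Calibration-factor table from paired same-site two-method surveys.

    Factors convert source-method densities onto the target-method scale.
    Species with at least ``min_pairs`` paired observations get a species
    factor; others defer to a pooled family x trophic factor, and failing
    that a single global method factor. ``paired`` needs columns (site_id,
    method, species, density_g_m2).
    """
    if len(paired) == 0:
        raise ValueError("no paired observations supplied")
    sp = species_lookup()[["species", "family", "trophic"]]
    df = paired.merge(sp, on="species", how="left")
    df["family_trophic"] = df["family"].fillna("?") + ":" + df["trophic"].fillna("?")

    decisions: list[CalibrationDecision] = []
    deferred: list[str] = []
    for species in sorted(df["species"].unique()):
        pairs = _pairs_for(df, "species", species, source_method, target_method)
        fit = _fit_factor(pairs) if len(pairs) >= min_pairs else None
        if fit is None:
            deferred.append(species)
            continue
        factor, form = fit
        decisions.append(
            CalibrationDecision("species", species, factor, form, len(pairs))
        )
    deferred_ft = df.loc[df["species"].isin(deferred), "family_trophic"].unique()
    ft_failed = False
    for ft in sorted(deferred_ft):
        pairs = _pairs_for(df, "family_trophic", ft, source_method, target_method)
        fit = _fit_factor(pairs) if len(pairs) >= min_pairs else None
        if fit is None:
            ft_failed = True
            continue
        factor, form = fit
        decisions.append(
            CalibrationDecision("family_trophic", ft, factor, form, len(pairs))
        )
    # global factor: always derivable from all pairs pooled; emitted whenever
    # any species or family x trophic cell could not be calibrated directly
    if ft_failed or not decisions:
        wide = (
            df.pivot_table(index="site_id", columns="method",
                           values="density_g_m2", aggfunc="sum", fill_value=0.0)
            .reindex(columns=[source_method, target_method], fill_value=0.0)
        )
        wide = wide.rename(columns={source_method: "x", target_method: "y"})
        fit = _fit_factor(wide)
        if fit is None:
            raise ValueError("global calibration could not be derived")
        factor, form = fit
        decisions.append(CalibrationDecision("global", source_method, factor, form, len(wide)))
    return pd.DataFrame([d.__dict__ for d in decisions])


def apply_calibration(
    obs: pd.DataFrame, factors: pd.DataFrame, source_method: str | None = None
) -> pd.DataFrame:
    """Multiply fish densities by the most specific applicable factor
    (species beats family x trophic beats global). Rows from methods other
    than ``source_method`` (when given) pass through unchanged; benthic data
    are never passed here. An observation matching no scope raises KeyError."""
    if len(factors) == 0:
        raise ValueError("empty calibration-factor table")
    sp = species_lookup()[["species", "family", "trophic"]]
    df = obs.merge(sp, on="species", how="left")
    df["family_trophic"] = df["family"].fillna("?") + ":" + df["trophic"].fillna("?")
    by_scope = {s: g.set_index("key")["factor"] for s, g in factors.groupby("scope")}
    species_f = by_scope.get("species", pd.Series(dtype=float))
    ft_f = by_scope.get("family_trophic", pd.Series(dtype=float))
    glob = by_scope.get("global", pd.Series(dtype=float))
    global_factor = float(glob.iloc[0]) if len(glob) else np.nan

    factor = df["species"].map(species_f)
    factor = factor.fillna(df["family_trophic"].map(ft_f))
    factor = factor.fillna(global_factor)
    apply_mask = np.ones(len(df), dtype=bool)
    if source_method is not None:
        apply_mask = (df["method"] == source_method).to_numpy()
    unresolved = df.loc[apply_mask & factor.isna(), "species"].unique()
    if len(unresolved):
        raise KeyError(f"no calibration factor at any scope for: {sorted(unresolved)}")
    out = obs.copy()
    mult = np.where(apply_mask, factor.to_numpy(dtype=float), 1.0)
    for col in ("density_g_m2", "mass_g"):
        if col in out:
            out[col] = out[col] * mult
    return out


# ---------------------------------------------------------------------------
# Spatial aggregation
# ---------------------------------------------------------------------------

def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in meters between decimal-degree coordinates."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def aggregate_spatial(
    sites: pd.DataFrame, radius_m: float = 300.0
) -> pd.DataFrame:
    """Average surveys within ``radius_m`` of each other (and across years).

    Groups are single-linkage clusters of great-circle distance cut at
    ``radius_m`` — deterministic and independent of row order. Numeric
    columns are averaged per group; the group coordinate is the member
    centroid; non-numeric metadata take the first member's value.
    """
    if sites[["lat", "lon"]].isna().to_numpy().any():
        raise ValueError("missing coordinates")
    n = len(sites)
    if n == 0:
        return sites.copy()
    lat = sites["lat"].to_numpy(dtype=float)
    lon = sites["lon"].to_numpy(dtype=float)
    if n == 1:
        groups = np.array([1])
    else:
        ii, jj = np.triu_indices(n, k=1)
        d = haversine_m(lat[ii], lon[ii], lat[jj], lon[jj])
        groups = fcluster(linkage(d, method="single"), t=radius_m, criterion="distance")
    df = sites.copy()
    df["_group"] = groups
    num_cols = [c for c in df.columns
                if c not in ("_group",) and pd.api.types.is_numeric_dtype(df[c])]
    other_cols = [c for c in df.columns if c not in num_cols + ["_group"]]
    agg = {c: "mean" for c in num_cols} | {c: "first" for c in other_cols}
    out = df.groupby("_group", as_index=False).agg(agg | {"_group": "size"})
    out = out.rename(columns={"_group": "n_members"})
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Profiles and transform
# ---------------------------------------------------------------------------

def build_profile_matrix(
    fish: pd.DataFrame,
    benthic: pd.DataFrame,
    species_map: pd.DataFrame | None = None,
    benthic_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Collapse calibrated observations to one 10-field profile per site.

    Fish densities (``density_g_m2``) sum within (site, year, group) and then
    average across years and methods; benthic percent cover likewise. Every
    species must map to exactly one fish group and every benthic category to
    one cover group; unmapped taxa raise with the offenders listed.
    """
    if species_map is None:
        species_map = species_lookup()[["species", "group"]]
    if benthic_map is None:
        benthic_map = benthic_lookup()
    f = fish.merge(species_map, on="species", how="left")
    bad = f.loc[f["group"].isna(), "species"].unique()
    if len(bad):
        raise KeyError(f"unmapped fish species: {sorted(bad)}")
    b = benthic.merge(benthic_map, on="category", how="left")
    bad = b.loc[b["group"].isna(), "category"].unique()
    if len(bad):
        raise KeyError(f"unmapped benthic categories: {sorted(bad)}")

    fkeys = [k for k in ("site_id", "year", "method") if k in f.columns]
    fsurv = f.groupby(fkeys + ["group"])["density_g_m2"].sum().reset_index()
    fsite = fsurv.groupby(["site_id", "group"])["density_g_m2"].mean().unstack(fill_value=0.0)
    bkeys = [k for k in ("site_id", "year", "method") if k in b.columns]
    bsurv = b.groupby(bkeys + ["group"])["percent_cover"].sum().reset_index()
    bsite = bsurv.groupby(["site_id", "group"])["percent_cover"].mean().unstack(fill_value=0.0)

    sites = sorted(set(fsite.index) | set(bsite.index))
    out = pd.DataFrame(index=pd.Index(sites, name="site_id"))
    for col in BENTHIC_COLUMNS:
        out[col] = bsite[col] if col in bsite else 0.0
    for col in FISH_COLUMNS:
        out[col] = fsite[col] if col in fsite else 0.0
    return out.fillna(0.0).reset_index()


@dataclass
class TransformState:
    """Per-column centre/scale recorded when fitting the fourth-root
    transform, so new observations and component means can be mapped both
    ways exactly."""

    columns: list[str]
    center: np.ndarray
    scale: np.ndarray

    def apply(self, raw: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = self._values(raw)
        if (X < 0).any():
            raise ValueError("negative values cannot be fourth-root transformed")
        return (X ** 0.25 - self.center) / self.scale

    def invert(self, transformed: np.ndarray | pd.DataFrame) -> np.ndarray:
        Z = self._values(transformed)
        return (Z * self.scale + self.center) ** 4

    def _values(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            return X[self.columns].to_numpy(dtype=float)
        return np.asarray(X, dtype=float)


def transform(
    matrix: pd.DataFrame | np.ndarray, columns: list[str] | None = None
) -> tuple[np.ndarray, TransformState]:
    """Fourth-root, centre, and standardize to unit (sample) SD per column.

    Constant columns keep scale 1. Returns the transformed array and the
    fitted :class:`TransformState`; ``inverse_transform`` restores the raw
    matrix to round-off."""
    if isinstance(matrix, pd.DataFrame):
        cols = columns or [c for c in GROUP_COLUMNS if c in matrix.columns]
        X = matrix[cols].to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        cols = columns or [f"v{i}" for i in range(X.shape[1])]
    if (X < 0).any():
        raise ValueError("negative values cannot be fourth-root transformed")
    T = X ** 0.25
    center = T.mean(axis=0)
    scale = T.std(axis=0, ddof=1)
    # constant columns (up to float jitter) keep scale 1
    tol = 1e-12 * np.maximum(np.abs(center), 1.0)
    scale = np.where(scale > tol, scale, 1.0)
    state = TransformState(columns=list(cols), center=center, scale=scale)
    return (T - center) / scale, state


def inverse_transform(matrix: np.ndarray, state: TransformState) -> np.ndarray:
    """Undo :func:`transform` exactly: unscale, uncentre, fourth power."""
    return state.invert(matrix)


def filter_depth(meta: pd.DataFrame, depth_min: float = 0.0, depth_max: float = 30.0) -> pd.DataFrame:
    """Depth-window sensitivity filter on site metadata (forereef 0-30 m by
    default; 0-20 and 5-20 m windows are the standard sensitivity checks)."""
    keep = (meta["depth_m"] >= depth_min) & (meta["depth_m"] <= depth_max)
    return meta.loc[keep].reset_index(drop=True)
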