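"""Descriptive and comparative community statistics across regimes.

Ordination (non-metric MDS on Bray-Curtis dissimilarity), multivariate
homogeneity of group dispersions, one-way ANOVA with Tukey HSD contrasts,
and the spatial/compositional regime summary tables. Ordination and
dispersion operate on the fourth-root (uncentred, unstandardized) matrix:
Bray-Curtis requires non-negative input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from sklearn.manifold import MDS
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .lookups import coral_traits


# ---------------------------------------------------------------------------
# Distances and ordination
# ---------------------------------------------------------------------------

def bray_curtis(matrix: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity d(u, v) = sum|u-v| / sum(u+v).

    Input rows are non-negative abundance/cover vectors (use the
    untransformed or fourth-root scale, not centred data). Two all-zero rows
    are at distance 0.
    """
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError(
            "Bray-Curtis requires non-negative entries; "
            "use an untransformed-scale matrix"
        )
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # (n, 2), centred
    stress: float  # Kruskal stress-1
    n_starts: int
    seed: int


def nmds(
    distances: np.ndarray,
    n_dims: int = 2,
    n_starts: int = 50,
    seed: int = 0,
    max_iter: int = 500,
) -> OrdinationResult:
    """Non-metric multidimensional scaling of a dissimilarity matrix.

    Runs ``n_starts`` random initializations of monotone-regression stress
    minimization and keeps the best; the reported stress is Kruskal
    stress-1. Coordinates are centred (solutions are defined only up to
    rotation/reflection/translation)."""
    D = np.asarray(distances, dtype=float)
    if D.shape[0] < 3:
        raise ValueError("nMDS needs at least 3 points")
    mds = MDS(
        n_components=n_dims,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        eps=1e-9,
        random_state=seed,
        normalized_stress=True,
        n_jobs=1,
    )
    coords = mds.fit_transform(D)
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(
        coordinates=coords, stress=float(mds.stress_), n_starts=n_starts, seed=seed
    )


# ---------------------------------------------------------------------------
# Multivariate dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    group_distances: pd.Series  # mean distance-to-centroid per group
    distances: np.ndarray  # per-observation distance to its group centroid
    f_statistic: float
    p_value: float
    n_perm: int


def _pcoa_axes(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding of a dissimilarity matrix, keeping
    positive- and negative-eigenvalue axes separately (the usual correction
    for semi-metric dissimilarities like Bray-Curtis)."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    keep = np.abs(vals) > 1e-10 * max(np.abs(vals).max(), 1.0)
    vals, vecs = vals[keep], vecs[:, keep]
    pos = vals > 0
    real_axes = vecs[:, pos] * np.sqrt(vals[pos])
    imag_axes = vecs[:, ~pos] * np.sqrt(-vals[~pos])
    return real_axes, imag_axes


def _centroid_distances(real, imag, groups_idx, labels) -> np.ndarray:
    """Distance of each point to its group centroid, with the imaginary-axis
    part subtracted in the squared distance (clamped at zero)."""
    d2 = np.empty(len(labels))
    for g in groups_idx:
        m = labels == g
        cr = real[m].mean(axis=0)
        ci = imag[m].mean(axis=0) if imag.shape[1] else np.zeros(0)
        dr = ((real[m] - cr) ** 2).sum(axis=1)
        di = ((imag[m] - ci) ** 2).sum(axis=1) if imag.shape[1] else 0.0
        d2[m] = np.maximum(dr - di, 0.0)
    return np.sqrt(d2)


def _anova_f(values: np.ndarray, labels: np.ndarray, groups) -> float:
    n = len(values)
    k = len(groups)
    grand = values.mean()
    ssb = ssw = 0.0
    for g in groups:
        v = values[labels == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    if ssw <= 0:
        return np.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def dispersion_test(
    distances: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions across groups.

    Embeds the dissimilarity matrix by principal coordinates, computes each
    observation's distance to its group centroid, and compares group mean
    distances with a one-way F statistic whose null distribution comes from
    permuting group labels. p = (1 + #{perm F >= observed F}) / (n_perm + 1).
    """
    D = np.asarray(distances, dtype=float)
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need at least 2 groups with at least 2 members each")
    real, imag = _pcoa_axes(D)
    d = _centroid_distances(real, imag, uniq, labels)
    f_obs = _anova_f(d, labels, uniq)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        dp = _centroid_distances(real, imag, uniq, perm)
        if _anova_f(dp, perm, uniq) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    group_means = pd.Series(
        {g: d[labels == g].mean() for g in uniq}, name="mean_distance_to_centroid"
    )
    return DispersionResult(
        group_distances=group_means, distances=d,
        f_statistic=float(f_obs), p_value=float(p), n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Univariate contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastResult:
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, diff, lower, upper, reject


def anova_tukey(response, groups, alpha: float = 0.05) -> ContrastResult:
    """One-way ANOVA across groups plus Tukey HSD pairwise contrasts with
    family-wise ``1 - alpha`` confidence intervals."""
    y = np.asarray(response, dtype=float)
    g = np.asarray(groups)
    uniq = np.unique(g)
    if len(uniq) < 2 or any((g == u).sum() < 2 for u in uniq):
        raise ValueError("need at least 2 groups with at least 2 observations each")
    arrays = [y[g == u] for u in uniq]
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(y) == 0:
        raise ValueError("constant response: F is undefined")
    F, p = f_oneway(*arrays)
    tk = pairwise_tukeyhsd(y, g, alpha=alpha)
    frame = pd.DataFrame(
        tk.summary().data[1:], columns=[c.strip() for c in tk.summary().data[0]]
    )
    pairwise = pd.DataFrame(
        {
            "group1": frame["group1"],
            "group2": frame["group2"],
            "diff": tk.meandiffs,
            "lower": tk.confint[:, 0],
            "upper": tk.confint[:, 1],
            "p_adj": tk.pvalues,
            "reject": tk.reject,
        }
    )
    df = (len(uniq) - 1, len(y) - len(uniq))
    return ContrastResult(float(F), df, float(p), pairwise)


# ---------------------------------------------------------------------------
# Regime summaries
# ---------------------------------------------------------------------------

def regime_summaries(
    assignments: pd.DataFrame,
    metadata: pd.DataFrame,
    coral_cover: pd.DataFrame | None = None,
    trait_lookup: pd.DataFrame | None = None,
    n_top_species: int = 4,
) -> dict[str, object]:
    """Ecological and spatial characterization of the fitted regimes.

    Returns a dict with: ``island_by_regime`` (per island, % of its sites in
    each regime), ``shore_by_regime`` (per regime, % of sites on N/E/S/W
    shores; rows sum to 100), ``depth_contrasts``/``complexity_contrasts``
    (ANOVA + Tukey across regimes, when the columns exist), and — when a
    per-site coral species cover table is given — ``coral_composition``
    (per-regime proportional cover of the ``n_top_species`` most abundant
    species) and ``trait_shares`` (per-regime share by life-history class).

    ``assignments`` needs (observation_id, regime); ``metadata`` is joined on
    site id. Sites that fail to join raise with the offenders listed.
    """
    a = assignments.rename(columns={"observation_id": "site_id"})[["site_id", "regime"]]
    merged = a.merge(metadata, on="site_id", how="left", indicator=True)
    missing = merged.loc[merged["_merge"] != "both", "site_id"].tolist()
    if missing:
        raise KeyError(f"sites missing from metadata: {missing}")
    merged = merged.drop(columns="_merge")
    out: dict[str, object] = {}

    if "island" in merged:
        tab = pd.crosstab(merged["island"], merged["regime"])
        out["island_by_regime"] = tab.div(tab.sum(axis=1), axis=0) * 100.0
    if "shore_direction" in merged:
        tab = pd.crosstab(merged["regime"], merged["shore_direction"])
        out["shore_by_regime"] = tab.div(tab.sum(axis=1), axis=0) * 100.0
    for col, key in (("depth_m", "depth_contrasts"), ("complexity", "complexity_contrasts")):
        if col in merged:
            out[key] = anova_tukey(merged[col].to_numpy(), merged["regime"].to_numpy())

    if coral_cover is not None:
        cc = coral_cover.merge(a, on="site_id")
        mean_cover = cc.groupby("species")["percent_cover"].mean().sort_values(ascending=False)
        top = list(mean_cover.index[:n_top_species])
        per_regime = cc.groupby(["regime", "species"])["percent_cover"].mean().unstack(fill_value=0.0)
        prop = per_regime.div(per_regime.sum(axis=1), axis=0)
        out["coral_composition"] = prop[top]
        traits = trait_lookup if trait_lookup is not None else coral_traits()
        tc = cc.merge(traits, on="species", how="left")
        tshare = tc.groupby(["regime", "trait_class"])["percent_cover"].sum().unstack(fill_value=0.0)
        out["trait_shares"] = tshare.div(tshare.sum(axis=1), axis=0)
    return out
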