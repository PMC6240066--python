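"""Regime dynamics: site-year sequences, transition matrices, driver models.

Per-site regime time series are built from high-confidence yearly
predictions (membership probability >= 0.95, at least 3 retained years per
site). Transitions between successive retained years are tabulated into a
K x K matrix with Wilson binomial intervals, and the probability of a given
transition is modelled as a function of a scaled driver (human population
density or degree heating weeks) with a Bayesian logistic model sampled by
an affine-invariant MCMC ensemble.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filtering and transition records
# ---------------------------------------------------------------------------

def filter_predictions(
    assignments: pd.DataFrame,
    min_prob: float = 0.95,
    min_years: int = 3,
) -> pd.DataFrame:
    """Retain confident site-year regime predictions.

    Drops site-years whose maximum membership probability is below
    ``min_prob`` (uncertainty > 1 - min_prob), then drops sites with fewer
    than ``min_years`` retained years. ``assignments`` needs (site_id, year,
    regime) plus either prob_* columns or ``uncertainty``.
    """
    df = assignments.copy()
    prob_cols = [c for c in df.columns if c.startswith("prob_")]
    if prob_cols:
        max_prob = df[prob_cols].to_numpy(dtype=float).max(axis=1)
    elif "uncertainty" in df:
        max_prob = 1.0 - df["uncertainty"].to_numpy(dtype=float)
    else:
        raise ValueError("assignments need prob_* columns or an uncertainty column")
    kept = df[max_prob >= min_prob]
    n_dropped_prob = len(df) - len(kept)
    year_counts = kept.groupby("site_id")["year"].nunique()
    good_sites = year_counts[year_counts >= min_years].index
    out = kept[kept["site_id"].isin(good_sites)].reset_index(drop=True)
    log.info(
        "filter_predictions: dropped %d low-probability site-years, "
        "%d site-years at sites with < %d years (retained %d)",
        n_dropped_prob, len(kept) - len(out), min_years, len(out),
    )
    return out


def transition_records(
    retained: pd.DataFrame, consecutive_only: bool = False
) -> pd.DataFrame:
    """One row per successive retained-year pair per site.

    By default transitions span gaps in the retained years; with
    ``consecutive_only`` only year pairs differing by exactly 1 are kept.
    Driver columns present in the input are carried along."""
    extra = [c for c in retained.columns
             if c not in ("site_id", "year", "regime")
             and not c.startswith(("prob_", "uncertainty"))]
    rows = []
    for sid, g in retained.sort_values("year").groupby("site_id"):
        years = g["year"].to_numpy()
        regs = g["regime"].to_numpy()
        for a, b in zip(range(len(years) - 1), range(1, len(years))):
            if consecutive_only and years[b] - years[a] != 1:
                continue
            row = {
                "site_id": sid,
                "year_t": years[a],
                "year_t1": years[b],
                "regime_t": regs[a],
                "regime_t1": regs[b],
            }
            for c in extra:
                row[c] = g[c].iloc[a]
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TransitionMatrix:
    counts: pd.DataFrame  # K x K, regime_t rows -> regime_t1 columns
    row_proportions: pd.DataFrame
    overall_proportions: pd.DataFrame
    wilson_lower: pd.DataFrame  # Wilson CI on the overall proportions
    wilson_upper: pd.DataFrame
    n_transitions: int


def build_transition_matrix(
    retained: pd.DataFrame,
    n_regimes: int | None = None,
    consecutive_only: bool = False,
    level: float = 0.95,
) -> TransitionMatrix:
    """Tabulate regime transitions with binomial uncertainty.

    Counts every successive retained-year pair per site, then reports
    row-conditional proportions, proportions of the total, and per-cell
    Wilson ``level`` intervals on the overall proportions."""
    recs = retained if "regime_t" in retained.columns else transition_records(
        retained, consecutive_only=consecutive_only
    )
    if len(recs) == 0:
        raise ValueError("no transitions available")
    K = n_regimes or int(max(recs["regime_t"].max(), recs["regime_t1"].max()))
    idx = pd.RangeIndex(1, K + 1)
    counts = (
        pd.crosstab(recs["regime_t"], recs["regime_t1"])
        .reindex(index=idx, columns=idx, fill_value=0)
        .astype(int)
    )
    counts.index.name, counts.columns.name = "regime_t", "regime_t1"
    n_total = int(counts.to_numpy().sum())
    row_tot = counts.sum(axis=1)
    row_props = counts.div(row_tot.where(row_tot > 0), axis=0)
    overall = counts / n_total
    lo, hi = wilson_ci(counts.to_numpy().ravel(), n_total, level=level)
    shape = counts.shape
    return TransitionMatrix(
        counts=counts,
        row_proportions=row_props,
        overall_proportions=overall,
        wilson_lower=pd.DataFrame(lo.reshape(shape), index=idx, columns=idx),
        wilson_upper=pd.DataFrame(hi.reshape(shape), index=idx, columns=idx),
        n_transitions=n_total,
    )


def wilson_ci(k, n, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a binomial proportion.

    Vectorized in ``k`` (and ``n``). The interval is contained in [0, 1] and
    always contains k/n; k = 0 gives a lower bound of exactly 0."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if (n < 1).any() or (k < 0).any() or (k > n).any():
        raise ValueError("require 0 <= k <= n and n >= 1")
    z = norm.ppf(1 - (1 - level) / 2)
    phat = k / n
    denom = 1 + z ** 2 / n
    centre = (phat + z ** 2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2))
    return np.maximum(centre - half, 0.0), np.minimum(centre + half, 1.0)


# ---------------------------------------------------------------------------
# Covariate-dependent transition probability
# ---------------------------------------------------------------------------

@dataclass
class DriverModelResult:
    transition: tuple[int, int]
    driver: str
    skipped: bool
    reason: str | None = None
    draws: pd.DataFrame | None = None  # columns alpha, beta
    beta_interval: tuple[float, float] | None = None
    alpha_interval: tuple[float, float] | None = None
    curve: pd.DataFrame | None = None  # x, p_median, p_lower, p_upper
    rhat: dict[str, float] | None = None
    n_occurrences: int = 0
    n_records: int = 0


def _log_posterior(theta: np.ndarray, x: np.ndarray, y: np.ndarray,
                   prior_sd: float) -> float:
    alpha, beta = theta
    eta = alpha + beta * x
    # log Bernoulli likelihood with logit link, numerically stable
    ll = -np.sum(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y))
    lp = -(alpha ** 2 + beta ** 2) / (2 * prior_sd ** 2)
    return ll + lp


def fit_driver_model(
    records: pd.DataFrame,
    transition: tuple[int, int],
    driver: str,
    min_occurrences: int = 4,
    prior_sd: float = 2.5,
    n_chains: int = 4,
    n_walkers: int = 16,
    n_steps: int = 1000,
    burn: int | None = None,
    seed: int = 0,
) -> DriverModelResult:
    """Bayesian logistic model of one transition's probability vs a driver.

    For records starting in regime i, the outcome is 1 when the next regime
    is j: logit p = alpha + beta * x with the driver x pre-scaled to [0, 1]
    and Normal(0, prior_sd^2) priors on both coefficients. Transitions with
    fewer than ``min_occurrences`` outcomes are skipped with an explicit
    reason. The posterior is sampled with ``n_chains`` independent
    affine-invariant ensembles initialized in a small ball around the MAP;
    the first half of each run is discarded as warm-up and split R-hat is
    computed across the pooled ensembles."""
    i, j = transition
    sub = records[records["regime_t"] == i]
    if driver not in sub.columns:
        raise KeyError(f"driver column {driver!r} not in records")
    y = (sub["regime_t1"] == j).to_numpy(dtype=float)
    x = sub[driver].to_numpy(dtype=float)
    n_occ = int(y.sum())
    if n_occ < min_occurrences:
        reason = (f"only {n_occ} occurrences of transition {i}->{j} "
                  f"(minimum {min_occurrences})")
        log.info("fit_driver_model skipped: %s", reason)
        return DriverModelResult(transition=transition, driver=driver,
                                 skipped=True, reason=reason,
                                 n_occurrences=n_occ, n_records=len(sub))
    if (x < 0).any() or (x > 1).any():
        raise ValueError(f"driver {driver!r} must be scaled to [0, 1]")

    if burn is None:
        burn = n_steps // 2
    theta_map = minimize(lambda t: -_log_posterior(t, x, y, prior_sd),
                         np.zeros(2)).x
    chains = []
    for c in range(n_chains):
        rs = np.random.default_rng((seed, c))
        p0 = theta_map + rs.normal(0.0, 0.1, size=(n_walkers, 2))
        sampler = emcee.EnsembleSampler(
            n_walkers, 2, _log_posterior, args=(x, y, prior_sd)
        )
        sampler.random_state = np.random.RandomState(
            (seed * 1009 + c) % (2 ** 31)
        ).get_state()
        sampler.run_mcmc(p0, n_steps, progress=False)
        # step-major flatten so split R-hat contrasts early vs late draws
        chains.append(sampler.get_chain(discard=burn).reshape(-1, 2))
    post = np.stack(chains)  # (chain, draw, 2)
    idata = az.from_dict(posterior={"alpha": post[:, :, 0], "beta": post[:, :, 1]})
    rhat_ds = az.rhat(idata)
    rhat = {v: float(rhat_ds[v].values) for v in ("alpha", "beta")}
    flat = post.reshape(-1, 2)
    draws = pd.DataFrame(flat, columns=["alpha", "beta"])
    b_lo, b_hi = np.quantile(flat[:, 1], [0.025, 0.975])
    a_lo, a_hi = np.quantile(flat[:, 0], [0.025, 0.975])
    grid = np.linspace(0.0, 1.0, 101)
    p_draws = expit(flat[:, [0]] + flat[:, [1]] * grid[None, :])
    curve = pd.DataFrame(
        {
            "x": grid,
            "p_median": np.median(p_draws, axis=0),
            "p_lower": np.quantile(p_draws, 0.025, axis=0),
            "p_upper": np.quantile(p_draws, 0.975, axis=0),
        }
    )
    return DriverModelResult(
        transition=transition,
        driver=driver,
        skipped=False,
        draws=draws,
        beta_interval=(float(b_lo), float(b_hi)),
        alpha_interval=(float(a_lo), float(a_hi)),
        curve=curve,
        rhat=rhat,
        n_occurrences=n_occ,
        n_records=len(sub),
    )
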