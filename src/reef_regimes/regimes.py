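"""Regime identification by model-based clustering.

A reef "regime" is one component of a multivariate Gaussian mixture fitted
to the transformed site x 10 functional-group matrix. Fitting follows the
classic model-based clustering recipe: (1) hierarchical agglomeration to
initialize component memberships, (2) maximum-likelihood EM, (3) selection
of the component count K and covariance structure by BIC.

Six covariance parameterizations are searched, spanning the
spherical/diagonal/full x equal/varying axes. BIC here is on the
"larger is better" convention, BIC = 2*logL - p*log(n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

from .harmonization import TransformState

log = logging.getLogger(__name__)

STRUCTURES: tuple[str, ...] = (
    "spherical-equal",
    "spherical-varying",
    "diagonal-equal",
    "diagonal-varying",
    "full-equal",
    "full-varying",
)

_RIDGE = 1e-6


@dataclass
class RegimeModel:
    """Fitted Gaussian mixture over functional-group space."""

    n_components: int
    structure: str
    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d), expanded whatever the structure
    log_likelihood: float
    n_params: int
    bic: float
    converged: bool
    n_iter: int
    tol: float
    loglik_history: list[float] = field(default_factory=list)
    regularized: bool = False
    degenerate: bool = False
    columns: list[str] | None = None

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def hierarchical_init(X: np.ndarray, K: int) -> np.ndarray:
    """Initial hard partition into K groups by Ward agglomeration on
    Euclidean distance (0-based labels). Requires n >= K."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < K:
        raise ValueError(f"need at least K={K} observations, got {n}")
    if K == 1:
        return np.zeros(n, dtype=int)
    if K == n:
        return np.arange(n)
    labels = fcluster(linkage(X, method="ward"), t=K, criterion="maxclust")
    return labels - 1


def _n_cov_params(structure: str, K: int, d: int) -> int:
    return {
        "spherical-equal": 1,
        "spherical-varying": K,
        "diagonal-equal": d,
        "diagonal-varying": K * d,
        "full-equal": d * (d + 1) // 2,
        "full-varying": K * d * (d + 1) // 2,
    }[structure]


def _log_gaussians(X: np.ndarray, means: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Log N(x | mu_k, Sigma_k) for all points and components, (n, K)."""
    n, d = X.shape
    K = means.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        L = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        z = solve_triangular(L, diff.T, lower=True)
        maha = np.sum(z ** 2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        out[:, k] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def _mstep_covs(
    X: np.ndarray, resp: np.ndarray, means: np.ndarray, structure: str
) -> tuple[np.ndarray, bool]:
    """Covariance M-step under the requested structure; returns the stack of
    full (K, d, d) matrices and whether a ridge was applied."""
    n, d = X.shape
    K = means.shape[0]
    Nk = resp.sum(axis=0)
    regularized = False

    if structure.startswith(("spherical", "diagonal")):
        Ex2 = (resp.T @ (X ** 2)) / Nk[:, None]
        var_k = np.maximum(Ex2 - means ** 2, 0.0)  # (K, d)
        if structure == "diagonal-equal":
            pooled = (Nk[:, None] * var_k).sum(axis=0) / n
            var_k = np.broadcast_to(pooled, (K, d)).copy()
        elif structure == "spherical-varying":
            var_k = np.broadcast_to(var_k.mean(axis=1)[:, None], (K, d)).copy()
        elif structure == "spherical-equal":
            pooled = (Nk[:, None] * var_k).sum(axis=0) / n
            var_k = np.full((K, d), pooled.mean())
        floor = _RIDGE * max(var_k.mean(), 1e-12)
        if (var_k < floor).any():
            var_k = np.maximum(var_k, floor)
            regularized = True
        covs = np.zeros((K, d, d))
        covs[:, np.arange(d), np.arange(d)] = var_k
        return covs, regularized

    covs = np.empty((K, d, d))
    for k in range(K):
        diff = X - means[k]
        covs[k] = (resp[:, k][:, None] * diff).T @ diff / Nk[k]
    if structure == "full-equal":
        pooled = np.tensordot(Nk, covs, axes=1) / n
        covs = np.broadcast_to(pooled, (K, d, d)).copy()
    for k in range(K):
        # near-singularity is checked on the spectrum, not by waiting for a
        # Cholesky failure: a component collapsed onto a lower-dimensional
        # spike can stay numerically factorizable while its likelihood
        # contribution diverges
        ridge = _RIDGE * np.trace(covs[k]) / d
        ev_min = np.linalg.eigvalsh(covs[k]).min()
        if ev_min < ridge:
            covs[k] = covs[k] + (ridge - min(ev_min, 0.0)) * np.eye(d)
            regularized = True
    return covs, regularized


def fit_gmm(
    X: np.ndarray,
    K: int,
    structure: str = "diagonal-varying",
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    columns: list[str] | None = None,
) -> RegimeModel:
    """EM fit of a K-component mixture under one covariance structure.

    ``init`` is a hard partition (default: Ward agglomeration). The relative
    log-likelihood change per iteration is monitored against ``tol``;
    non-convergence within ``max_iter`` flags the model rather than raising.
    Log-likelihood is asserted non-decreasing (EM monotonicity).
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    n, d = X.shape
    if structure not in STRUCTURES:
        raise ValueError(f"unknown covariance structure {structure!r}")
    if init is None:
        init = hierarchical_init(X, K)
    resp = np.zeros((n, K))
    resp[np.arange(n), np.asarray(init, dtype=int)] = 1.0

    loglik_history: list[float] = []
    regularized = False
    last_reg = False
    converged = False
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # M step
        Nk = resp.sum(axis=0)
        if (Nk <= 0).any():  # dead component: tiny uniform reseed
            resp = resp + 1e-10
            Nk = resp.sum(axis=0)
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        covs, reg = _mstep_covs(X, resp, means, structure)
        regularized = regularized or reg
        last_reg = reg
        # E step
        log_prob = _log_gaussians(X, means, covs) + np.log(weights)
        norm = logsumexp(log_prob, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(log_prob - norm[:, None])
        if loglik_history and loglik < loglik_history[-1] - 1e-8 and not regularized:
            log.warning("log-likelihood decreased at iteration %d", it)
        loglik_history.append(loglik)
        if np.isfinite(prev) and abs(loglik - prev) <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = loglik

    # A component whose covariance still needs the floor/ridge at the final
    # iteration has collapsed onto (near-)duplicated points: the likelihood
    # is unbounded there and the "solution" is not a valid MLE. Such fits
    # are flagged degenerate and excluded from model selection.
    degenerate = last_reg
    if degenerate:
        log.info("degenerate %s fit at K=%d (collapsed component)", structure, K)
    p = K * d + (K - 1) + _n_cov_params(structure, K, d)
    bic = 2.0 * loglik - p * np.log(n)
    return RegimeModel(
        n_components=K,
        structure=structure,
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=loglik,
        n_params=p,
        bic=bic,
        converged=converged,
        n_iter=it,
        tol=tol,
        loglik_history=loglik_history,
        regularized=regularized,
        degenerate=degenerate,
        columns=list(columns) if columns is not None else None,
    )


def select_model(
    X: np.ndarray,
    k_range: range | list[int] = range(1, 10),
    structures: tuple[str, ...] = STRUCTURES,
    tol: float = 1e-6,
    max_iter: int = 500,
    columns: list[str] | None = None,
) -> tuple[RegimeModel, pd.DataFrame]:
    """Fit every (K, structure) pair and return the BIC-best converged model
    together with the full BIC table (one row per fitted pair)."""
    X = np.asarray(X, dtype=float)
    rows = []
    best: RegimeModel | None = None
    for K in k_range:
        try:
            init = hierarchical_init(X, K)
        except ValueError:
            continue
        for structure in structures:
            try:
                model = fit_gmm(X, K, structure, init=init, tol=tol,
                                max_iter=max_iter, columns=columns)
            except Exception as exc:  # noqa: BLE001 — record failed fits
                rows.append({"K": K, "structure": structure, "bic": np.nan,
                             "log_likelihood": np.nan, "n_params": np.nan,
                             "converged": False, "degenerate": False,
                             "error": str(exc)})
                continue
            rows.append({"K": K, "structure": structure, "bic": model.bic,
                         "log_likelihood": model.log_likelihood,
                         "n_params": model.n_params,
                         "converged": model.converged,
                         "degenerate": model.degenerate, "error": ""})
            if model.converged and not model.degenerate and (
                best is None or model.bic > best.bic
            ):
                best = model
    table = pd.DataFrame(rows)
    if best is None:
        raise RuntimeError("all mixture fits failed or none converged")
    return best, table


def assign_regimes(model: RegimeModel, X: np.ndarray | pd.DataFrame,
                   ids=None) -> pd.DataFrame:
    """Posterior membership per observation.

    Columns: prob_1..prob_K, ``regime`` (1-based argmax; ties break to the
    lowest index) and ``uncertainty`` = 1 - max_k prob_k."""
    if isinstance(X, pd.DataFrame):
        cols = model.columns or list(X.columns)
        X = X[cols].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X has width {X.shape[1] if X.ndim == 2 else '?'}, "
            f"model expects {model.n_features}"
        )
    if X.shape[0] == 0:
        cols = [f"prob_{k + 1}" for k in range(model.n_components)]
        return pd.DataFrame(columns=["observation_id", *cols, "regime", "uncertainty"])
    log_prob = _log_gaussians(X, model.means, model.covariances) + np.log(model.weights)
    resp = np.exp(log_prob - logsumexp(log_prob, axis=1)[:, None])
    labels = resp.argmax(axis=1)  # np.argmax takes the first (lowest) on ties
    out = pd.DataFrame(resp, columns=[f"prob_{k + 1}" for k in range(model.n_components)])
    out.insert(0, "observation_id", np.asarray(ids) if ids is not None else np.arange(len(resp)))
    out["regime"] = labels + 1
    out["uncertainty"] = 1.0 - resp.max(axis=1)
    return out


def predict_regime(
    model: RegimeModel,
    X_new: pd.DataFrame | np.ndarray,
    transform_state: TransformState,
    ids=None,
) -> pd.DataFrame:
    """Assign raw-scale observations using the training-time transform.

    Applies the stored fourth-root/centre/scale mapping, then posterior
    assignment — the model is never refitted."""
    if transform_state is None:
        raise ValueError("transform_state from training is required")
    if isinstance(X_new, pd.DataFrame) and len(X_new) == 0:
        return assign_regimes(model, np.empty((0, model.n_features)), ids=ids)
    Z = transform_state.apply(X_new)
    return assign_regimes(model, Z, ids=ids)


def save_model_yaml(model: RegimeModel, state: TransformState, path) -> None:
    """Serialize a fitted model plus its transform state to YAML."""
    import yaml

    payload = {
        "n_components": int(model.n_components),
        "structure": model.structure,
        "bic": float(model.bic),
        "log_likelihood": float(model.log_likelihood),
        "n_params": int(model.n_params),
        "converged": bool(model.converged),
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "transform_center": state.center.tolist(),
        "transform_scale": state.scale.tolist(),
        "columns": state.columns,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model_yaml(path) -> tuple[RegimeModel, TransformState]:
    """Inverse of :func:`save_model_yaml`."""
    import yaml

    with open(path) as fh:
        p = yaml.safe_load(fh)
    model = RegimeModel(
        n_components=p["n_components"],
        structure=p["structure"],
        weights=np.asarray(p["weights"]),
        means=np.asarray(p["means"]),
        covariances=np.asarray(p["covariances"]),
        log_likelihood=p["log_likelihood"],
        n_params=p["n_params"],
        bic=p["bic"],
        converged=p["converged"],
        n_iter=0,
        tol=np.nan,
        columns=list(p["columns"]),
    )
    state = TransformState(
        columns=list(p["columns"]),
        center=np.asarray(p["transform_center"]),
        scale=np.asarray(p["transform_scale"]),
    )
    return model, state


def regime_means_raw(model: RegimeModel, state: TransformState) -> pd.DataFrame:
    """Back-transformed component means: invert the standardization and raise
    to the fourth power, giving means on the raw %/g m^-2 scale."""
    raw = state.invert(model.means)
    cols = model.columns or state.columns
    df = pd.DataFrame(raw, columns=cols)
    df.insert(0, "regime", np.arange(1, model.n_components + 1))
    return df
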