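"""Numerical kernels shared by all multiple-imputation procedures.

Three primitives:

* :func:`draw_bayesian_linear` — a proper posterior draw (beta*, sigma*)
  for a normal linear model, reflecting both residual noise and the
  sampling variation of the fitted line;
* :func:`pmm_impute` — Type-1 predictive mean matching: predictions for
  observed rows use the least-squares coefficients, predictions for missing
  rows a posterior draw, and each missing row copies the actual value of a
  donor with a nearby predicted mean;
* :func:`pan_gibbs_step` / :func:`pan_impute` — a conjugate Gibbs sampler
  for the two-level (random-intercept, homogeneous residual variance)
  linear model, and imputation from its posterior predictive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular


@dataclass
class LinearDraw:
    """Result of one Bayesian linear draw."""

    beta_hat: np.ndarray   # ridge-stabilized least squares
    beta_star: np.ndarray  # posterior draw
    sigma_star: float      # drawn residual SD (>= 0)


@dataclass
class GibbsPriors:
    """Weakly informative conjugate priors for the two-level sampler:
    inverse-gamma(a, b) on both variances, flat on the fixed effects."""

    a_eps: float = 0.001
    b_eps: float = 0.001
    a_u: float = 0.001
    b_u: float = 0.001


@dataclass
class MultilevelState:
    """Current state of the random-intercept Gibbs chain."""

    beta: np.ndarray    # fixed effects (intercept, TIME, covariates...)
    u: np.ndarray       # one random intercept per cluster
    sigma2_e: float     # residual variance (homogeneous across clusters)
    tau2: float         # random-intercept variance

    def copy(self) -> "MultilevelState":
        return MultilevelState(self.beta.copy(), self.u.copy(),
                               self.sigma2_e, self.tau2)


def _ridge_gram(X: np.ndarray, ridge: float) -> np.ndarray:
    XtX = X.T @ X
    q = X.shape[1]
    lam = ridge * max(np.trace(XtX) / q, 1.0)
    return XtX + lam * np.eye(q)


def draw_bayesian_linear(y_obs: np.ndarray, X_obs: np.ndarray,
                         ridge: float = 1e-5,
                         rng: np.random.Generator | None = None) -> LinearDraw:
    """Draw (beta*, sigma*) from the posterior of a normal linear model.

    beta_hat comes from ridge-stabilized least squares; sigma*^2 = RSS / g
    with g ~ chi-square(n - q); beta* = beta_hat + sigma* L^-T z with
    L L^T the Cholesky factor of the (ridged) Gram matrix, so that over
    draws Cov(beta*) is proportional to (X'X)^-1.  With RSS = 0 the draw
    degenerates exactly to (beta_hat, 0).
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y_obs, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X_obs, dtype=float))
    n, q = X.shape
    if len(y) != n:
        raise ValueError("y_obs and X_obs disagree on the number of rows")
    if n < q + 1:
        raise ValueError(
            f"only {n} observed rows for {q} predictors; reduce the predictor "
            "set (need at least one more row than columns)")
    S = _ridge_gram(X, ridge)
    L = np.linalg.cholesky(S)
    # point estimate without the ridge so an exact linear fit degenerates
    # to RSS = 0 exactly; the ridge stabilizes only the draw covariance
    beta_hat = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta_hat
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        rss = 0.0
    g = rng.chisquare(n - q)
    sigma_star = float(np.sqrt(rss / g)) if rss > 0 else 0.0
    z = rng.standard_normal(q)
    beta_star = beta_hat + sigma_star * solve_triangular(L.T, z, lower=False)
    return LinearDraw(beta_hat=beta_hat, beta_star=beta_star,
                      sigma_star=sigma_star)


def pmm_impute(y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray,
               donors: int = 5, rng: np.random.Generator | None = None,
               ridge: float = 1e-5) -> np.ndarray:
    """Type-1 predictive mean matching.

    Observed rows are scored with beta_hat, missing rows with a posterior
    draw beta* (the stochastic matching distance).  For each missing row the
    ``donors`` observed rows with the closest predicted mean are found and
    one is drawn uniformly; its *actual* y value is the imputation, so every
    imputed value is an element of ``y_obs``.  Ties in matching distance are
    broken uniformly at random.
    """
    if rng is None:
        rng = np.random.default_rng()
    y = np.asarray(y_obs, dtype=float).ravel()
    X_obs = np.atleast_2d(np.asarray(X_obs, dtype=float))
    X_mis = np.atleast_2d(np.asarray(X_mis, dtype=float))
    n_obs = len(y)
    if donors < 1:
        raise ValueError("donors must be >= 1")
    if donors > n_obs:
        raise ValueError(f"donors={donors} exceeds the {n_obs} observed rows")
    if X_mis.shape[0] == 0:
        return np.empty(0)

    draw = draw_bayesian_linear(y, X_obs, ridge=ridge, rng=rng)
    yhat_obs = X_obs @ draw.beta_hat
    yhat_mis = X_mis @ draw.beta_star
    return _match_donors(y, yhat_obs, yhat_mis, donors, rng)


def _pick_uniform_true(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Per row of a boolean matrix, the column index of one uniformly drawn
    True entry (each row must contain at least one)."""
    counts = mask.sum(axis=1)
    r = rng.integers(0, counts)
    cum = np.cumsum(mask, axis=1)
    return np.argmax(cum > r[:, None], axis=1)


def _match_donors(y: np.ndarray, yhat_obs: np.ndarray, yhat_mis: np.ndarray,
                  donors: int, rng: np.random.Generator) -> np.ndarray:
    """Draw one of the ``donors`` nearest-prediction donors per missing row.

    The k nearest predicted means lie in a window of width 2k around each
    row's insertion point into the sorted donor predictions, so only that
    window is scored.  Exact distance ties at the pool boundary are broken
    uniformly and independently per row: a donor strictly inside the pool is
    drawn with probability 1/k, and the remaining probability is spread
    uniformly over *all* donors tied at the k-th distance (scored globally,
    since ties can extend beyond the window).
    """
    n_obs = len(y)
    n_mis = len(yhat_mis)
    order = np.argsort(yhat_obs, kind="stable")
    yhat_sorted = yhat_obs[order]
    pos = np.searchsorted(yhat_sorted, yhat_mis)
    lo = np.clip(pos - donors, 0, max(n_obs - 2 * donors, 0))
    width = min(2 * donors, n_obs)
    offsets = lo[:, None] + np.arange(width)[None, :]
    dist = np.abs(yhat_sorted[offsets] - yhat_mis[:, None])
    kth = np.partition(dist, donors - 1, axis=1)[:, donors - 1]

    strict = dist < kth[:, None]
    n_strict = strict.sum(axis=1)
    r = rng.integers(0, donors, size=n_mis)
    take_strict = r < n_strict

    chosen = np.empty(n_mis, dtype=np.int64)
    if take_strict.any():
        rows = np.flatnonzero(take_strict)
        cols = _pick_uniform_true(strict[rows], rng)
        chosen[rows] = order[offsets[rows, cols]]
    if (~take_strict).any():
        rows = np.flatnonzero(~take_strict)
        # ties can reach beyond the window only if a window edge sits at
        # exactly the k-th distance; everything else stays on the fast path
        at_edge = (dist[rows, 0] == kth[rows]) | (dist[rows, -1] == kth[rows])
        if width == n_obs:
            at_edge[:] = False
        inner = rows[~at_edge]
        if inner.size:
            cols = _pick_uniform_true(dist[inner] == kth[inner, None], rng)
            chosen[inner] = order[offsets[inner, cols]]
        outer = rows[at_edge]
        if outer.size:
            ties = np.abs(yhat_obs[None, :] - yhat_mis[outer, None]) == \
                kth[outer, None]
            chosen[outer] = _pick_uniform_true(ties, rng)
    return y[chosen]


# ---------------------------------------------------------------------------
# two-level Gibbs sampler


def _init_state(y: np.ndarray, X: np.ndarray, n_clusters: int,
                ridge: float) -> MultilevelState:
    S = _ridge_gram(X, ridge)
    beta = np.linalg.solve(S, X.T @ y)
    resid = y - X @ beta
    sig2 = float(resid @ resid) / max(len(y) - X.shape[1], 1)
    sig2 = max(sig2, 1e-12)
    return MultilevelState(beta=beta, u=np.zeros(n_clusters),
                           sigma2_e=sig2, tau2=max(sig2 / 2.0, 1e-12))


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape))


def pan_gibbs_step(y: np.ndarray, X: np.ndarray, cluster_ids: np.ndarray,
                   state: MultilevelState, priors: GibbsPriors,
                   rng: np.random.Generator, ridge: float = 1e-5,
                   _cache: dict | None = None) -> MultilevelState:
    """One full conjugate sweep of the random-intercept sampler.

    Order: random intercepts u_c given (beta, variances); fixed effects
    beta given (u, sigma2_e) under a flat prior; sigma2_e from its
    inverse-gamma full conditional; tau2 likewise.  Clusters with zero rows
    get their u drawn from the prior N(0, tau2) — which the precision
    formula yields automatically when the cluster count is zero.
    """
    y = np.asarray(y, dtype=float).ravel()
    cluster_ids = np.asarray(cluster_ids)
    n = len(y)
    n_clusters = len(state.u)
    if _cache is None:
        _cache = {}
    if "L" not in _cache:
        _cache["L"] = np.linalg.cholesky(_ridge_gram(X, ridge))
        _cache["Xt"] = np.ascontiguousarray(X.T)
        _cache["counts"] = np.bincount(cluster_ids, minlength=n_clusters).astype(float)
    L = _cache["L"]
    Xt = _cache["Xt"]
    counts = _cache["counts"]

    # u | beta, sigma2, tau2
    resid = y - X @ state.beta
    sums = np.bincount(cluster_ids, weights=resid, minlength=n_clusters)
    prec = counts / state.sigma2_e + 1.0 / state.tau2
    mean = (sums / state.sigma2_e) / prec
    u = mean + rng.standard_normal(n_clusters) / np.sqrt(prec)

    # beta | u, sigma2 (flat prior)
    ytil = y - u[cluster_ids]
    half = solve_triangular(L, Xt @ ytil, lower=True, check_finite=False)
    beta_hat = solve_triangular(L.T, half, lower=False, check_finite=False)
    z = rng.standard_normal(X.shape[1])
    beta = beta_hat + np.sqrt(state.sigma2_e) * solve_triangular(
        L.T, z, lower=False, check_finite=False)

    # sigma2_e | beta, u
    resid = ytil - X @ beta
    rss = float(resid @ resid)
    sigma2_e = _inv_gamma(rng, priors.a_eps + n / 2.0, priors.b_eps + rss / 2.0)

    # tau2 | u
    ssu = float(u @ u)
    tau2 = _inv_gamma(rng, priors.a_u + n_clusters / 2.0, priors.b_u + ssu / 2.0)

    return MultilevelState(beta=beta, u=u, sigma2_e=max(sigma2_e, 1e-12),
                           tau2=max(tau2, 1e-12))


def run_pan_gibbs(y: np.ndarray, X: np.ndarray, cluster_ids: np.ndarray,
                  n_clusters: int | None = None, n_sweeps: int = 2000,
                  burn_in: int = 500,
                  rng: np.random.Generator | None = None,
                  priors: GibbsPriors | None = None, ridge: float = 1e-5
                  ) -> tuple[MultilevelState, dict]:
    """Run the sampler and return (final state, post-burn-in chains).

    The chain dict holds per-sweep arrays for ``beta``, ``sigma2_e`` and
    ``tau2`` after discarding ``burn_in`` sweeps — the basis for parameter
    recovery checks and convergence diagnostics.
    """
    if rng is None:
        rng = np.random.default_rng()
    priors = priors or GibbsPriors()
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cluster_ids = np.asarray(cluster_ids)
    if n_clusters is None:
        n_clusters = int(cluster_ids.max()) + 1
    if n_clusters < 2:
        raise ValueError("the multilevel sampler needs at least 2 clusters")
    if not 0 <= burn_in < n_sweeps:
        raise ValueError("need 0 <= burn_in < n_sweeps")

    state = _init_state(y, X, n_clusters, ridge)
    cache: dict = {}
    kept = n_sweeps - burn_in
    chains = {"beta": np.empty((kept, X.shape[1])),
              "sigma2_e": np.empty(kept), "tau2": np.empty(kept)}
    for t in range(n_sweeps):
        state = pan_gibbs_step(y, X, cluster_ids, state, priors, rng,
                               ridge=ridge, _cache=cache)
        if t >= burn_in:
            i = t - burn_in
            chains["beta"][i] = state.beta
            chains["sigma2_e"][i] = state.sigma2_e
            chains["tau2"][i] = state.tau2
    return state, chains


def pan_impute(y_with_missing: np.ndarray, X: np.ndarray,
               cluster_ids: np.ndarray, n_clusters: int | None = None,
               n_sweeps: int = 200,
               rng: np.random.Generator | None = None,
               priors: GibbsPriors | None = None, ridge: float = 1e-5
               ) -> tuple[np.ndarray, MultilevelState]:
    """Impute missing entries from the two-level model's posterior predictive.

    The sampler runs ``n_sweeps`` full sweeps on the observed rows; the
    final state is a (correlated) posterior draw, and each missing y is then
    drawn from N(x'beta + u_cluster, sigma2_e).  Clusters unseen among the
    observed rows keep a random intercept drawn from N(0, tau2), which the
    sweep produces for empty clusters by construction.
    """
    if rng is None:
        rng = np.random.default_rng()
    priors = priors or GibbsPriors()
    y = np.asarray(y_with_missing, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cluster_ids = np.asarray(cluster_ids)
    if n_clusters is None:
        n_clusters = int(cluster_ids.max()) + 1
    if np.isnan(X).any():
        raise ValueError("design matrix must be complete (impute predictors first)")
    mis = np.isnan(y)
    if mis.all():
        raise ValueError("all y values are missing; nothing to fit")
    if not mis.any():
        return y.copy(), _init_state(y, X, n_clusters, ridge)

    obs = ~mis
    state = _init_state(y[obs], X[obs], n_clusters, ridge)
    cache: dict = {}
    for _ in range(n_sweeps):
        state = pan_gibbs_step(y[obs], X[obs], cluster_ids[obs], state,
                               priors, rng, ridge=ridge, _cache=cache)

    out = y.copy()
    mu = X[mis] @ state.beta + state.u[cluster_ids[mis]]
    out[mis] = mu + np.sqrt(state.sigma2_e) * rng.standard_normal(int(mis.sum()))
    return out, state
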