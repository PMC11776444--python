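"""Generalized linear mixed models with one random intercept.

Supports the model families the rhythm analyses need — Poisson and
negative-binomial (NB2) counts with a log link and offset, Gamma with a
log link, and Gaussian — with a single grouping factor (individual
identity) entering as a random intercept u_g ~ N(0, sigma_u^2).

Estimation maximizes the Laplace-approximate marginal likelihood: the
random-effect integral is one-dimensional per group, its mode found by a
vectorized Newton iteration (the conditional log-density is concave in u
for every supported family), and the outer optimization over fixed effects,
log sigma_u, and any dispersion parameter uses L-BFGS-B. For the Gaussian
family the Laplace approximation is exact. When the variance estimate hits
its lower bound the fit degrades gracefully to the fixed-effects model
(flagged on the result).

Inference helpers: likelihood-ratio tests of nested fits, Wald contrasts
with Tukey-style single-step multivariate-normal adjustment (Holm
fallback), Pearson dispersion, and randomized quantile residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .errors import FittingError, ValidationError

__all__ = [
    "GLMMFit",
    "ContrastRow",
    "fit_glmm",
    "likelihood_ratio_test",
    "contrast_tests",
    "pearson_dispersion",
    "quantile_residual_normality",
]

_ETA_CLIP = 30.0


# ---------------------------------------------------------------- families

class _Poisson:
    name = "poisson"
    n_extra = 0

    @staticmethod
    def ll(y, eta, extra):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return y * eta - mu - gammaln(y + 1)

    @staticmethod
    def d1(y, eta, extra):
        return y - np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    @staticmethod
    def d2(y, eta, extra):
        return -np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    @staticmethod
    def variance(mu, extra):
        return mu


class _NegBin:
    """NB2: Var = mu + mu^2 / theta; extra parameter is log theta."""

    name = "negative-binomial"
    n_extra = 1

    @staticmethod
    def ll(y, eta, extra):
        theta = np.exp(extra[0])
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return (
            gammaln(y + theta) - gammaln(theta) - gammaln(y + 1)
            + theta * np.log(theta) + y * eta - (y + theta) * np.log(mu + theta)
        )

    @staticmethod
    def d1(y, eta, extra):
        theta = np.exp(extra[0])
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return (y - mu) * theta / (mu + theta)

    @staticmethod
    def d2(y, eta, extra):
        theta = np.exp(extra[0])
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return -mu * theta * (theta + y) / (mu + theta) ** 2

    @staticmethod
    def variance(mu, extra):
        theta = np.exp(extra[0])
        return mu + mu * mu / theta


class _Gamma:
    """Gamma with log link; extra parameter is log shape."""

    name = "gamma"
    n_extra = 1

    @staticmethod
    def ll(y, eta, extra):
        k = np.exp(extra[0])
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return k * np.log(k) - gammaln(k) + (k - 1) * np.log(y) - k * y / mu - k * eta

    @staticmethod
    def d1(y, eta, extra):
        k = np.exp(extra[0])
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return k * (y / mu - 1.0)

    @staticmethod
    def d2(y, eta, extra):
        k = np.exp(extra[0])
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return -k * y / mu

    @staticmethod
    def variance(mu, extra):
        return mu * mu / np.exp(extra[0])


class _Gaussian:
    """Identity link; extra parameter is log residual SD."""

    name = "gaussian"
    n_extra = 1

    @staticmethod
    def ll(y, eta, extra):
        s2 = np.exp(2 * extra[0])
        return -0.5 * (y - eta) ** 2 / s2 - extra[0] - 0.5 * np.log(2 * np.pi)

    @staticmethod
    def d1(y, eta, extra):
        return (y - eta) / np.exp(2 * extra[0])

    @staticmethod
    def d2(y, eta, extra):
        return -np.ones_like(eta) / np.exp(2 * extra[0])

    @staticmethod
    def variance(mu, extra):
        return np.full_like(mu, np.exp(2 * extra[0]))


_FAMILIES = {f.name: f for f in (_Poisson, _NegBin, _Gamma, _Gaussian)}
_LOG_SIGMA_U_MIN = np.log(1e-6)


# ---------------------------------------------------------------- fitting

@dataclass
class GLMMFit:
    family: str
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u: float
    extra: dict
    loglik: float
    n_params: int
    converged: bool
    u_hat: np.ndarray
    mu_hat: np.ndarray          # conditional mean including u_hat
    sigma_u_boundary: bool      # True: variance pinned at ~0, fixed-effects fit
    pinned: np.ndarray = None   # fixed effects at a box bound (separation)
    y: np.ndarray = field(repr=False, default=None)
    notes: list = field(default_factory=list)

    @property
    def se_beta(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0, None))


def _inner_modes(u, y, eta0, groups, n_groups, sigma2, fam, extra):
    """Newton iteration for the per-group random-effect modes (in place)."""
    for _ in range(100):
        eta = eta0 + u[groups]
        g1 = np.bincount(groups, fam.d1(y, eta, extra), n_groups) - u / sigma2
        g2 = np.bincount(groups, fam.d2(y, eta, extra), n_groups) - 1.0 / sigma2
        step = g1 / g2
        np.clip(step, -2.0, 2.0, out=step)
        u -= step
        if np.max(np.abs(step)) < 1e-11:
            break
    return u


def _laplace_nll(params, y, X, groups, n_groups, offset, fam, u_store):
    p = X.shape[1]
    beta = params[:p]
    sigma2 = np.exp(2.0 * params[p])
    extra = params[p + 1:]
    eta0 = X @ beta + offset
    # always start the mode search from zero: warm starts introduce
    # hysteresis (and thus finite-difference noise) when sigma_u is tiny
    u = _inner_modes(np.zeros(n_groups), y, eta0, groups, n_groups, sigma2, fam, extra)
    u_store[:] = u
    eta = eta0 + u[groups]
    neg_h2 = 1.0 / sigma2 - np.bincount(groups, fam.d2(y, eta, extra), n_groups)
    ll = (
        float(np.sum(fam.ll(y, eta, extra)))
        - 0.5 * float(np.sum(u * u)) / sigma2
        - 0.5 * float(np.sum(np.log(sigma2 * neg_h2)))
    )
    return -ll


def _numeric_hessian(fun, x, step=1e-4):
    n = x.size
    h = step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            f = (
                fun(x + ei + ej) - fun(x + ei - ej)
                - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = f
    return H


def fit_glmm(
    y,
    X,
    groups,
    family: str = "poisson",
    offset=None,
    beta0=None,
    maxiter: int = 300,
) -> GLMMFit:
    """Fit ``g(E[y]) = X beta + offset + u_group`` by Laplace-approximate ML.

    ``groups`` may be any label array; it is factorized internally, so the
    fit is invariant to relabeling. Raises :class:`FittingError` with the
    optimizer trace on non-convergence.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    offset = np.zeros_like(y) if offset is None else np.asarray(offset, dtype=float)
    try:
        fam = _FAMILIES[family]
    except KeyError:
        raise ValidationError(f"unknown family {family!r}") from None
    if fam is _Gamma and np.any(y <= 0):
        raise ValidationError("gamma family requires strictly positive responses")

    p = X.shape[1]
    if beta0 is None:
        if fam is _Gaussian:
            z = y
        else:
            z = np.log(np.maximum(y, 0.25 if fam is not _Gamma else y.min())) - offset
        beta0, *_ = np.linalg.lstsq(X, z, rcond=None)
    x0 = np.concatenate([
        np.asarray(beta0, dtype=float),
        [np.log(0.3)],
        _extra_init(fam, y, X, beta0, offset),
    ])
    bounds = (
        [(-_ETA_CLIP, _ETA_CLIP)] * p
        + [(_LOG_SIGMA_U_MIN, np.log(5.0))]
        + _extra_bounds(fam)
    )
    u_store = np.zeros(n_groups)
    args = (y, X, codes, n_groups, offset, fam, u_store)
    # finite-difference step must sit above the inner-solver noise floor
    res = optimize.minimize(
        _laplace_nll, x0, args=args, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6, "eps": 1e-6},
    )
    if not res.success:
        res2 = optimize.minimize(
            _laplace_nll, res.x, args=args, method="Nelder-Mead", bounds=bounds,
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res2.fun <= res.fun:
            res2.jac = np.zeros_like(res2.x)
            res = res2
    grad = np.abs(getattr(res, "jac", np.zeros(1)))
    if not res.success and np.max(grad) > 0.5:
        raise FittingError(f"GLMM ({family}) did not converge: {res.message}", res)

    xhat = res.x
    beta = xhat[:p]
    sigma_u = float(np.exp(xhat[p]))
    extra_vals = xhat[p + 1:]
    boundary = bool(xhat[p] <= _LOG_SIGMA_U_MIN + 1e-6)
    pinned = np.abs(np.abs(beta) - _ETA_CLIP) < 1e-3
    notes = []
    if boundary:
        notes.append(
            "random-intercept variance at lower bound; "
            "fit is effectively the fixed-effects model"
        )

    fresh = np.zeros(n_groups)
    nll = _laplace_nll(xhat, y, X, codes, n_groups, offset, fam, fresh)
    u_hat = fresh
    eta = X @ beta + offset + u_hat[codes]
    mu_hat = eta if fam is _Gaussian else np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

    def at(v):
        return _laplace_nll(v, y, X, codes, n_groups, offset, fam, u_hat.copy())

    H = _numeric_hessian(at, xhat)
    # a flat likelihood direction (curvature ~0) marks an unidentified
    # parameter: an all-zero cell whose mean drifts toward -inf, or a
    # dispersion pinned at its bound (e.g. theta -> inf for Poisson-like
    # counts). Invert on the well-curved subspace only, so flat directions
    # cannot contaminate the covariance of identified coefficients.
    keep = np.abs(np.diag(H)) >= 1e-2
    pinned |= ~keep[:p]
    cov = np.zeros_like(H)
    if keep.any():
        cov[np.ix_(keep, keep)] = _safe_inverse(H[np.ix_(keep, keep)])
    if pinned.any():
        notes.append(
            f"{int(pinned.sum())} fixed effect(s) unidentified (empty cell / "
            "complete separation); Wald tests involving them are degenerate"
        )
    extra = {}
    if fam is _NegBin:
        extra["theta"] = float(np.exp(extra_vals[0]))
    elif fam is _Gamma:
        extra["shape"] = float(np.exp(extra_vals[0]))
    elif fam is _Gaussian:
        extra["sigma_resid"] = float(np.exp(extra_vals[0]))
    return GLMMFit(
        family=family,
        beta=beta,
        cov_beta=cov[:p, :p],
        sigma_u=sigma_u,
        extra=extra,
        loglik=-float(nll),
        n_params=xhat.size,
        converged=bool(res.success),
        u_hat=u_hat,
        mu_hat=mu_hat,
        sigma_u_boundary=boundary,
        pinned=pinned,
        y=y,
        notes=notes,
    )


def _extra_init(fam, y, X, beta0, offset):
    if fam is _NegBin:
        return np.array([np.log(10.0)])
    if fam is _Gamma:
        mu = np.exp(np.clip(X @ np.asarray(beta0, float) + offset, -_ETA_CLIP, _ETA_CLIP))
        cv2 = max(np.var(y / mu), 1e-3)
        return np.array([np.log(1.0 / cv2)])
    if fam is _Gaussian:
        resid = y - X @ np.asarray(beta0, float) - offset
        return np.array([np.log(max(np.std(resid), 1e-6))])
    return np.array([])


def _extra_bounds(fam):
    if fam is _NegBin:
        return [(np.log(0.05), np.log(1e6))]
    if fam is _Gamma:
        return [(np.log(1e-3), np.log(1e8))]
    if fam is _Gaussian:
        return [(np.log(1e-9), np.log(1e6))]
    return []


def _safe_inverse(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------- inference

def likelihood_ratio_test(full: GLMMFit, null: GLMMFit) -> tuple[float, int, float]:
    """Chi-square, df, p for nested full-vs-null fits."""
    chisq = max(0.0, 2.0 * (full.loglik - null.loglik))
    df = full.n_params - null.n_params
    if df <= 0:
        raise ValidationError("full model must have more parameters than null")
    return chisq, df, float(stats.chi2.sf(chisq, df))


@dataclass(frozen=True)
class ContrastRow:
    contrast: str
    estimate: float
    se: float
    z: float
    p_adj: float
    adjustment: str


def _mvn_rectangle(q: float, corr: np.ndarray) -> float:
    """P(all |Z_i| <= q) under N(0, corr)."""
    k = corr.shape[0]
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=corr, allow_singular=True)
    return float(mvn.cdf(np.full(k, q), lower_limit=np.full(k, -q)))


def contrast_tests(fit: GLMMFit, L: np.ndarray, names: list[str]) -> list[ContrastRow]:
    """Wald z tests of linear contrasts L @ beta, single-step adjusted.

    The family-wise adjustment is the Tukey-style multivariate-normal
    single-step method over the supplied contrast family; if the
    multivariate quantile cannot be evaluated the Holm step-down procedure
    is used instead (recorded per row).
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    est = L @ fit.beta
    k = L.shape[0]
    # a contrast touching a bound-pinned coefficient (empty cell /
    # complete separation) has no defensible Wald distribution
    pinned = fit.pinned if fit.pinned is not None else np.zeros(fit.beta.size, bool)
    degenerate = (np.abs(L[:, pinned]) > 1e-12).any(axis=1)
    V = L @ fit.cov_beta @ L.T
    degenerate |= np.diag(V) <= 1e-10
    se = np.sqrt(np.clip(np.diag(V), 1e-16, None))
    z = np.where(degenerate, 0.0, est / se)
    ok = ~degenerate
    p_adj = np.ones(k)
    adjustment = np.where(degenerate, "wald-degenerate", "none").astype(object)
    n_ok = int(ok.sum())
    if n_ok == 1:
        p_adj[ok] = 2 * stats.norm.sf(np.abs(z[ok]))
    elif n_ok > 1:
        idx = np.flatnonzero(ok)
        Vok = V[np.ix_(idx, idx)]
        seok = se[idx]
        corr = Vok / np.outer(seok, seok)
        corr = np.clip((corr + corr.T) / 2, -1, 1)
        np.fill_diagonal(corr, 1.0)
        try:
            p_adj[idx] = np.clip(
                [1.0 - _mvn_rectangle(abs(z[j]), corr) for j in idx], 0.0, 1.0
            )
            adjustment[idx] = "tukey-mvn"
        except Exception:
            p_adj[idx] = _holm(2 * stats.norm.sf(np.abs(z[idx])))
            adjustment[idx] = "holm"
    return [
        ContrastRow(nm, float(e), float(s), float(zz), float(pp), str(adj))
        for nm, e, s, zz, pp, adj in zip(names, est, se, z, p_adj, adjustment)
    ]


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    k = p.size
    adj = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def pearson_dispersion(fit: GLMMFit) -> float:
    """Pearson chi-square / residual df of the conditional fit (~1 is good)."""
    fam = _FAMILIES[fit.family]
    extra_vals = np.log(np.array(list(fit.extra.values()))) if fit.extra else np.array([])
    v = fam.variance(fit.mu_hat, extra_vals)
    resid_df = max(fit.y.size - fit.n_params, 1)
    return float(np.sum((fit.y - fit.mu_hat) ** 2 / np.maximum(v, 1e-300)) / resid_df)


def quantile_residual_normality(fit: GLMMFit, seed: int = 0) -> tuple[float, float]:
    """Shapiro-Wilk (W, p) of randomized quantile residuals.

    For count families the residual is Phi^-1 of a uniform draw between
    F(y-1) and F(y) under the fitted conditional distribution; continuous
    families use plain probability-integral residuals.
    """
    rng = np.random.default_rng(seed)
    y, mu = fit.y, fit.mu_hat
    if fit.family == "poisson":
        lo = stats.poisson.cdf(y - 1, mu)
        hi = stats.poisson.cdf(y, mu)
    elif fit.family == "negative-binomial":
        theta = fit.extra["theta"]
        pnb = theta / (theta + mu)
        lo = stats.nbinom.cdf(y - 1, theta, pnb)
        hi = stats.nbinom.cdf(y, theta, pnb)
    elif fit.family == "gamma":
        k = fit.extra["shape"]
        lo = hi = stats.gamma.cdf(y, k, scale=mu / k)
    else:
        s = fit.extra["sigma_resid"]
        lo = hi = stats.norm.cdf(y, mu, s)
    u = lo + (hi - lo) * rng.uniform(size=y.size)
    q = stats.norm.ppf(np.clip(u, 1e-10, 1 - 1e-10))
    if q.size > 5000:  # Shapiro-Wilk p-values are unreliable beyond this
        q = rng.choice(q, 5000, replace=False)
    if q.size < 3 or np.ptp(q) < 1e-12:
        return np.nan, np.nan
    w, p = stats.shapiro(q)
    return float(w), float(p)
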