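"""Gaussian mixture decomposition of lab-value distributions.

The central modelling assumption: within one gender/age segment the healthy
subpopulation produces (multi)normally distributed values, while pathological
results overlay a second, wider and shifted component.  Fitting a K=2 mixture

    p(x) = sum_k a_k N(x | mu_k, Sigma_k)

and keeping the *principal* (healthy) component therefore separates the
healthy distribution from the pathological tail without diagnostic labels.
The weight of the non-principal mass estimates the pathological fraction.

Two fitters share one output contract: maximum-likelihood EM (canonical) and
a variational-Bayes mixture with a Dirichlet weight-concentration prior and
normal-Wishart component priors, which shrinks superfluous components.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import digamma

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "fit_mixture",
    "select_principal",
    "outlier_fraction",
    "merge_components",
    "healthy_component",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GaussianComponent:
    """One mixture component: weight, mean vector, covariance matrix (mg/dl)."""

    weight: float
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, float))
        cov = np.atleast_2d(np.asarray(self.covariance, float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        d = mean.size
        if cov.shape != (d, d):
            raise ValueError(f"covariance shape {cov.shape} does not match dim {d}")
        if not np.allclose(cov, cov.T, rtol=0, atol=1e-10 * max(1.0, np.abs(cov).max())):
            raise ValueError("covariance must be symmetric")
        if not 0.0 <= self.weight <= 1.0 + 1e-12:
            raise ValueError("weight must lie in [0, 1]")

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def sd(self) -> float:
        """Standard deviation; only defined for 1D components."""
        if self.dim != 1:
            raise ValueError("sd is defined for 1D components only")
        return float(np.sqrt(self.covariance[0, 0]))

    def to_dict(self) -> dict:
        return {
            "weight": float(self.weight),
            "mean": self.mean.tolist(),
            "covariance": self.covariance.ravel().tolist(),  # row-major
            "dim": self.dim,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianComponent":
        dim = int(d["dim"])
        cov = np.asarray(d["covariance"], float).reshape(dim, dim)
        return cls(weight=float(d["weight"]), mean=np.asarray(d["mean"], float), covariance=cov)


@dataclass
class MixtureModel:
    components: list[GaussianComponent]
    log_likelihood: float
    n_iter: int
    converged: bool
    method: str
    seed: int | None
    log_likelihood_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def to_json(self) -> str:
        return json.dumps(
            {
                "components": [c.to_dict() for c in self.components],
                "log_likelihood": self.log_likelihood,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "method": self.method,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MixtureModel":
        d = json.loads(text)
        return cls(
            components=[GaussianComponent.from_dict(c) for c in d["components"]],
            log_likelihood=float(d["log_likelihood"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            method=str(d["method"]),
            seed=d["seed"],
        )


def _as_matrix(values) -> np.ndarray:
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("values must be an (n,) or (n, d) array")
    if not np.all(np.isfinite(X)):
        raise ValueError("values must be finite")
    return X


def _log_mvnorm(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at the rows of X, via Cholesky."""
    d = mean.size
    if d == 1:
        var = cov[0, 0]
        dev = X[:, 0] - mean[0]
        return -0.5 * (_LOG_2PI + np.log(var) + dev * dev / var)
    L = np.linalg.cholesky(cov)
    z = solve_triangular(L, (X - mean).T, lower=True)
    maha = np.sum(z * z, axis=0)
    log_det = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG_2PI + log_det + maha)


def _row_logsumexp(a: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp; bare-metal variant of the scipy routine for the
    EM inner loop where the (n, k) array is small in k."""
    m = a.max(axis=1)
    return m + np.log(np.exp(a - m[:, None]).sum(axis=1))


def _hard_assignment_resp(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    resp = np.zeros((X.shape[0], centers.shape[0]))
    resp[np.arange(X.shape[0]), labels] = 1.0
    return resp


def _kmeanspp_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(axis=2), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def _initial_responsibilities(
    X: np.ndarray, k: int, rng: np.random.Generator, deterministic: bool
) -> np.ndarray:
    """First restart: quantile split (1D) / seeded k-means++ (dD); then random."""
    n, d = X.shape
    if deterministic and d == 1:
        # split the sorted sample into k equal-count groups (median split at k=2)
        order = np.argsort(X[:, 0], kind="stable")
        resp = np.zeros((n, k))
        for j, chunk in enumerate(np.array_split(order, k)):
            resp[chunk, j] = 1.0
        return resp
    centers = _kmeanspp_centers(X, k, rng)
    return _hard_assignment_resp(X, centers)


def _m_step(X: np.ndarray, resp: np.ndarray, reg: float):
    n, d = X.shape
    nk = resp.sum(axis=0)
    nk = np.maximum(nk, 10 * np.finfo(float).tiny)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((resp.shape[1], d, d))
    for j in range(resp.shape[1]):
        dev = X - means[j]
        covs[j] = (resp[:, j][:, None] * dev).T @ dev / nk[j]
        covs[j][np.diag_indices(d)] += reg
    return weights, means, covs


def _em_single(X, resp, tol, max_iter, reg):
    n, d = X.shape
    k = resp.shape[1]
    weights, means, covs = _m_step(X, resp, reg)
    trace = []
    converged = False
    it = 0
    prev = -np.inf
    for it in range(1, max_iter + 1):
        log_dens = np.empty((n, k))
        for j in range(k):
            log_dens[:, j] = np.log(max(weights[j], 1e-300)) + _log_mvnorm(X, means[j], covs[j])
        norm = _row_logsumexp(log_dens)
        ll = float(norm.mean())
        trace.append(ll)
        resp = np.exp(log_dens - norm[:, None])
        weights, means, covs = _m_step(X, resp, reg)
        if it > 1 and abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
    return weights, means, covs, np.asarray(trace), it, converged


def _vb_single(X, resp, tol, max_iter, reg):
    """Variational-Bayes mixture: Dirichlet(1/K) weights, normal-Wishart components.

    Priors are set from the data moments: mean prior at the sample mean with
    unit precision scale, Wishart with d degrees of freedom and expected
    precision equal to the inverse sample covariance.  Point estimates
    returned are the posterior-expected weights/means and Sigma_k =
    (nu_k W_k)^{-1}, the inverse of the posterior-expected precision.
    """
    n, d = X.shape
    k = resp.shape[1]
    alpha0 = 1.0 / k
    beta0 = 1.0
    m0 = X.mean(axis=0)
    nu0 = float(d)
    S = np.cov(X, rowvar=False).reshape(d, d) + reg * np.eye(d)
    w0_inv = S * nu0  # so that E[Lambda] under the prior = S^{-1}

    trace = []
    converged = False
    it = 0
    prev = -np.inf
    alpha = beta = m = w_inv = nu = None
    for it in range(1, max_iter + 1):
        nk = resp.sum(axis=0) + 10 * np.finfo(float).tiny
        xbar = (resp.T @ X) / nk[:, None]
        alpha = alpha0 + nk
        beta = beta0 + nk
        nu = nu0 + nk
        m = (beta0 * m0 + nk[:, None] * xbar) / beta[:, None]
        w_inv = np.empty((k, d, d))
        for j in range(k):
            dev = X - xbar[j]
            sk = (resp[:, j][:, None] * dev).T @ dev
            dm = (xbar[j] - m0)[:, None]
            w_inv[j] = w0_inv + sk + (beta0 * nk[j] / (beta0 + nk[j])) * (dm @ dm.T)

        # variational E-step
        log_resp = np.empty((n, k))
        e_log_pi = digamma(alpha) - digamma(alpha.sum())
        for j in range(k):
            chol = np.linalg.cholesky(w_inv[j])
            log_det_w = -2.0 * np.sum(np.log(np.diag(chol)))
            e_log_lam = (
                np.sum(digamma(0.5 * (nu[j] - np.arange(d)))) + d * np.log(2.0) + log_det_w
            )
            z = np.linalg.solve(chol, (X - m[j]).T)
            maha = nu[j] * np.sum(z * z, axis=0)
            log_resp[:, j] = (
                e_log_pi[j] + 0.5 * e_log_lam - 0.5 * d / beta[j] - 0.5 * maha - 0.5 * d * _LOG_2PI
            )
        norm = _row_logsumexp(log_resp)
        resp = np.exp(log_resp - norm[:, None])

        # convergence is monitored on the variational objective surrogate
        # (mean log normalizer of the responsibilities), which keeps moving
        # while superfluous components are being emptied
        bound = float(norm.mean())
        trace.append(bound)
        if it > 1 and abs(bound - prev) < tol:
            converged = True
            break
        prev = bound

    weights = alpha / alpha.sum()
    covs = np.empty((k, d, d))
    for j in range(k):
        covs[j] = np.linalg.inv(nu[j] * np.linalg.inv(w_inv[j]))
        covs[j] = 0.5 * (covs[j] + covs[j].T)
        covs[j][np.diag_indices(d)] += reg
    return weights, m, covs, np.asarray(trace), it, converged


def fit_mixture(
    values,
    k: int = 2,
    method: str = "em",
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    reg: float | None = None,
    n_init: int = 5,
) -> MixtureModel:
    """Fit a K-component Gaussian mixture to 1D or 2D (or d-D) values.

    Parameters
    ----------
    values
        ``(n,)`` or ``(n, d)`` array of finite readings.
    k
        Number of components; 2 by default (healthy + pathological tail).
    method
        ``"em"`` (maximum likelihood, canonical) or ``"variational"``
        (variational Bayes; shrinks superfluous components).
    tol
        Convergence threshold on the change of the mean per-point
        log-likelihood between iterations.
    reg
        Ridge added to every covariance diagonal each M-step; defaults to
        ``1e-6`` times the mean per-dimension sample variance (floored to
        stay positive on degenerate data).
    n_init
        Restarts; the first uses a deterministic quantile split (1D) or
        seeded k-means++ (d-D), the rest random seeding.  Best final
        log-likelihood wins.

    Notes
    -----
    The reported ``log_likelihood`` and its per-iteration trace are the mean
    per-point log-likelihood; under EM the trace is non-decreasing.
    """
    X = _as_matrix(values)
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k * (d + 1):
        raise ValueError(f"insufficient data: n={n} < k(d+1)={k * (d + 1)}")
    if method not in ("em", "variational"):
        raise ValueError("method must be 'em' or 'variational'")
    if reg is None:
        reg = 1e-6 * float(np.mean(np.var(X, axis=0)))
    reg = max(reg, 1e-12)

    rng = np.random.default_rng(seed)
    single = _em_single if method == "em" else _vb_single
    best = None
    for i in range(max(1, n_init)):
        resp0 = _initial_responsibilities(X, k, rng, deterministic=(i == 0))
        weights, means, covs, trace, n_iter, converged = single(X, resp0, tol, max_iter, reg)
        ll = trace[-1] if trace.size else -np.inf
        if best is None or ll > best[0]:
            best = (ll, weights, means, covs, trace, n_iter, converged)

    ll, weights, means, covs, trace, n_iter, converged = best
    weights = weights / weights.sum()
    # report the data log-likelihood of the final parameters (for the VB
    # path the trace holds the variational surrogate instead)
    log_dens = np.empty((n, k))
    for j in range(k):
        log_dens[:, j] = np.log(max(weights[j], 1e-300)) + _log_mvnorm(X, means[j], covs[j])
    ll = float(_row_logsumexp(log_dens).mean())
    components = [
        GaussianComponent(weight=float(weights[j]), mean=means[j], covariance=covs[j])
        for j in range(k)
    ]
    return MixtureModel(
        components=components,
        log_likelihood=float(ll),
        n_iter=int(n_iter),
        converged=bool(converged),
        method=method,
        seed=seed,
        log_likelihood_trace=trace,
    )


def select_principal(
    model: MixtureModel,
    rule: str = "largest_weight",
    reference: np.ndarray | float | None = None,
) -> int:
    """Index of the component designated as the healthy (principal) Gaussian.

    ``rule="largest_weight"`` (default): the heaviest component, ties broken
    toward the smaller generalized variance det(Sigma).
    ``rule="nearest_median"``: the component whose mean is closest to
    ``reference`` (typically the sample median vector).
    """
    if model.k < 1:
        raise ValueError("model has no components")
    if rule == "largest_weight":
        dets = [float(np.linalg.det(c.covariance)) for c in model.components]
        order = sorted(
            range(model.k), key=lambda j: (-model.components[j].weight, dets[j], j)
        )
        return order[0]
    if rule == "nearest_median":
        if reference is None:
            raise ValueError("rule 'nearest_median' requires a reference point")
        ref = np.atleast_1d(np.asarray(reference, float))
        dists = [float(np.linalg.norm(c.mean - ref)) for c in model.components]
        return int(np.argmin(dists))
    raise ValueError(f"unknown principal-selection rule {rule!r}")


def outlier_fraction(model: MixtureModel, principal: int | None = None) -> float:
    """Pathological fraction: total weight outside the principal component."""
    if principal is None:
        principal = select_principal(model)
    return float(1.0 - model.components[principal].weight)


def merge_components(components: list[GaussianComponent]) -> GaussianComponent:
    """Moment-matched Gaussian for a sub-mixture (weights renormalized)."""
    w = np.array([c.weight for c in components], float)
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot merge components with zero total weight")
    w = w / total
    d = components[0].dim
    mean = np.zeros(d)
    for wi, c in zip(w, components):
        mean += wi * c.mean
    cov = np.zeros((d, d))
    for wi, c in zip(w, components):
        dev = (c.mean - mean)[:, None]
        cov += wi * (c.covariance + dev @ dev.T)
    return GaussianComponent(weight=float(total), mean=mean, covariance=cov)


def healthy_component(
    model: MixtureModel,
    principal: int | None = None,
    merge_overlapping: bool = True,
    mean_sd_threshold: float = 2.0,
    sd_ratio_threshold: float = 1.5,
) -> GaussianComponent:
    """The effective healthy Gaussian: the principal component, re-absorbing
    secondary components that are not a genuine pathological tail.

    A K=2 decomposition of a segment with essentially no pathological mass is
    unidentifiable: the fitter splits the healthy mode into two overlapping
    pieces and the heavier piece alone under-covers the healthy population.
    A secondary component therefore counts as tail only when it is clearly
    shifted (mean further than ``mean_sd_threshold`` Mahalanobis-SDs from the
    principal mean) or clearly widened (generalized SD more than
    ``sd_ratio_threshold`` times the principal's); anything closer is merged
    back by moment matching.  The returned component's weight is the total
    healthy weight, so ``1 - weight`` remains the pathological fraction.
    """
    if principal is None:
        principal = select_principal(model)
    pc = model.components[principal]
    if not merge_overlapping or model.k == 1:
        return pc
    keep = [pc]
    prec = np.linalg.inv(pc.covariance)
    det_p = float(np.linalg.det(pc.covariance))
    for j, c in enumerate(model.components):
        if j == principal:
            continue
        dev = c.mean - pc.mean
        maha = float(dev @ prec @ dev)
        shifted = maha > mean_sd_threshold**2
        sd_ratio = (float(np.linalg.det(c.covariance)) / det_p) ** (1.0 / (2 * c.dim))
        widened = sd_ratio > sd_ratio_threshold
        if not (shifted or widened):
            keep.append(c)
    if len(keep) == 1:
        return pc
    return merge_components(keep)
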