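"""Balanced-design two-level confirmatory factor analysis by maximum likelihood.

For ``G`` clusters (persons) of common size ``c`` (occasions) the Gaussian
two-level model ``y_is = mu + u_i + e_is`` with ``u ~ N(0, Sigma_b)`` and
``e ~ N(0, Sigma_w)`` has sufficient statistics: the pooled within-cluster
covariance ``S_PW`` (divisor ``N - G``), the scaled between covariance of the
cluster means ``S_B = c * sum_i (ybar_i - ybar)(ybar_i - ybar)' / (G - 1)``
and the grand mean.  Writing ``Sigma_c = Sigma_w + c * Sigma_b``, the deviance
is

    -2 ln L = N p ln(2 pi)
              + (N - G) [ln|Sigma_w| + tr(Sigma_w^-1 S_PW)]
              + G ln|Sigma_c| + tr(Sigma_c^-1 (G-1) S_B)
              + G c (ybar - mu)' Sigma_c^-1 (ybar - mu).

Three models are fitted on these moments:

- *hypothesized*: one factor per level, marker loading fixed to 1, free
  factor variance and item residuals per level, saturated means (30 free
  parameters for p = 6);
- *saturated*: unrestricted ``Sigma_w`` with ``Sigma_b`` constrained
  positive semi-definite (closed form, see below);
- *baseline*: independence (diagonal) covariances at both levels with free
  means (closed form, between variances constrained non-negative).

Only the hypothesized model needs iteration; it is fitted by bounded
quasi-Newton (L-BFGS-B) with an analytic gradient, variances constrained to
be non-negative.  Because all three models keep ``Sigma_b`` in the PSD cone
they are properly nested (baseline within hypothesized within saturated), so
deviance differences are non-negative and share conventions.

The saturated solution: simultaneously diagonalise ``S_PW`` and
``(G-1)/G * S_B`` (generalized eigenproblem, eigenvalues ``phi_k``).  In
each eigendirection the problem is a univariate one-way ANOVA; directions
with ``phi_k >= 1`` take the unconstrained MLE, directions with
``phi_k < 1`` (between variance estimate negative) are pooled to a common
variance ``(N - G + G phi_k) / N`` — the multivariate analogue of
truncating a negative variance component at zero.  Without this truncation
the deviance-difference chi-square is badly inflated whenever the
population between covariance is singular, because the null model's
non-negativity bounds cannot chase between-level noise that an
unconstrained saturated model absorbs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import linalg, optimize

from .datagen import ILDDataset, UnbalancedDataError

__all__ = [
    "TwoLevelMoments",
    "ModelSpec",
    "ParamVector",
    "FitResult",
    "NotPositiveDefiniteError",
    "compute_moments",
    "implied_covariances",
    "minus2_log_likelihood",
    "fit_model",
    "model_df",
    "HYPOTHESIZED",
    "SATURATED",
    "BASELINE",
]

_LOG_2PI = np.log(2.0 * np.pi)


class NotPositiveDefiniteError(ValueError):
    """A covariance matrix required to be positive definite is not."""


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoLevelMoments:
    """Sufficient statistics of a balanced two-level Gaussian sample."""

    s_pw: np.ndarray  # pooled within covariance, divisor N - G
    s_b: np.ndarray   # c * cov of cluster means, divisor G - 1
    ybar: np.ndarray  # grand mean
    G: int            # cluster count
    c: int            # common cluster size

    @property
    def N(self) -> int:
        return self.G * self.c

    @property
    def p(self) -> int:
        return self.ybar.shape[0]

    def to_dict(self) -> dict:
        return {
            "s_pw": self.s_pw.tolist(),
            "s_b": self.s_b.tolist(),
            "ybar": self.ybar.tolist(),
            "G": self.G,
            "c": self.c,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoLevelMoments":
        return cls(np.asarray(d["s_pw"], float), np.asarray(d["s_b"], float),
                   np.asarray(d["ybar"], float), int(d["G"]), int(d["c"]))


def compute_moments(data, clusters=None) -> TwoLevelMoments:
    """Balanced within/between moment decomposition.

    Parameters
    ----------
    data : ILDDataset or (N, p) array
        Raw rows.  If an array, ``clusters`` must give the cluster label of
        each row.
    """
    if isinstance(data, ILDDataset):
        y = data.values()
        idx = data.person_index()
    else:
        if clusters is None:
            raise ValueError("clusters required when passing a raw array")
        y = np.asarray(data, float)
        if y.ndim == 1:
            y = y[:, None]
        _, idx = np.unique(np.asarray(clusters), return_inverse=True)
    G = int(idx.max()) + 1 if idx.size else 0
    if G < 2:
        raise UnbalancedDataError("need at least two clusters")
    counts = np.bincount(idx, minlength=G)
    if counts.min() != counts.max():
        raise UnbalancedDataError(
            f"unequal cluster sizes (min {counts.min()}, max {counts.max()}); "
            "this estimator handles balanced designs only")
    c = int(counts[0])
    if c < 2:
        raise UnbalancedDataError("need at least two rows per cluster")
    N, p = y.shape
    means = np.zeros((G, p))
    np.add.at(means, idx, y)
    means /= c
    dev_w = y - means[idx]
    s_pw = dev_w.T @ dev_w / (N - G)
    ybar = y.mean(axis=0)
    dev_b = means - ybar
    s_b = c * dev_b.T @ dev_b / (G - 1)
    return TwoLevelMoments(s_pw, s_b, ybar, G, c)


# ---------------------------------------------------------------------------
# model specification and parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Which two-level covariance structure is being fitted."""

    kind: str = "hypothesized"  # hypothesized | saturated | baseline
    p: int = 6
    marker: int = 0  # item whose loading is fixed to 1 at both levels

    def __post_init__(self) -> None:
        if self.kind not in ("hypothesized", "saturated", "baseline"):
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if not 0 <= self.marker < self.p:
            raise ValueError("marker index out of range")

    @property
    def n_free(self) -> int:
        p = self.p
        if self.kind == "hypothesized":
            # per level: (p-1) loadings + p residuals + 1 factor variance
            return 2 * (2 * p) + p
        if self.kind == "saturated":
            return 2 * (p * (p + 1) // 2) + p
        return 3 * p  # baseline: p variances per level + p means


def model_df(model: ModelSpec) -> int:
    """Degrees of freedom: sample moments minus free parameters."""
    p = model.p
    n_moments = 2 * (p * (p + 1) // 2) + p
    return n_moments - model.n_free


HYPOTHESIZED = ModelSpec("hypothesized")
SATURATED = ModelSpec("saturated")
BASELINE = ModelSpec("baseline")


@dataclass(frozen=True)
class ParamVector:
    """Parameters of the two-level one-factor model (marker loadings = 1)."""

    lambda_w: np.ndarray  # length p, marker entry 1
    theta_w: np.ndarray   # length p
    phi_w: float
    lambda_b: np.ndarray
    theta_b: np.ndarray
    phi_b: float
    mu: np.ndarray

    @property
    def p(self) -> int:
        return self.mu.shape[0]

    def pack(self, marker: int = 0) -> np.ndarray:
        """Free structural parameters (means excluded; they are profiled)."""
        free = [j for j in range(self.p) if j != marker]
        return np.concatenate([
            self.lambda_w[free], self.theta_w, [self.phi_w],
            self.lambda_b[free], self.theta_b, [self.phi_b],
        ])

    @classmethod
    def unpack(cls, x: np.ndarray, mu: np.ndarray, marker: int = 0
               ) -> "ParamVector":
        p = mu.shape[0]
        free = [j for j in range(p) if j != marker]
        lw = np.ones(p)
        lb = np.ones(p)
        lw[free] = x[0:p - 1]
        tw = np.asarray(x[p - 1:2 * p - 1], float)
        pw = float(x[2 * p - 1])
        lb[free] = x[2 * p:3 * p - 1]
        tb = np.asarray(x[3 * p - 1:4 * p - 1], float)
        pb = float(x[4 * p - 1])
        return cls(lw, tw, pw, lb, tb, pb, np.asarray(mu, float))

    def names(self, marker: int = 0) -> list[str]:
        free = [j for j in range(self.p) if j != marker]
        return ([f"lambda_w{j + 1}" for j in free]
                + [f"theta_w{j + 1}" for j in range(self.p)] + ["phi_w"]
                + [f"lambda_b{j + 1}" for j in free]
                + [f"theta_b{j + 1}" for j in range(self.p)] + ["phi_b"])


def implied_covariances(theta: ParamVector, model: ModelSpec = HYPOTHESIZED):
    """Model-implied ``(Sigma_w, Sigma_b, mu)`` for a parameter vector."""
    lw = np.asarray(theta.lambda_w, float)
    lb = np.asarray(theta.lambda_b, float)
    sigma_w = theta.phi_w * np.outer(lw, lw) + np.diag(theta.theta_w)
    sigma_b = theta.phi_b * np.outer(lb, lb) + np.diag(theta.theta_b)
    return sigma_w, sigma_b, np.asarray(theta.mu, float)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _chol_logdet_inv(a: np.ndarray):
    try:
        cf = linalg.cho_factor(a, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise NotPositiveDefiniteError(str(err)) from None
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    inv = linalg.cho_solve(cf, np.eye(a.shape[0]), check_finite=False)
    return logdet, inv


def minus2_log_likelihood(m: TwoLevelMoments, sigma_w: np.ndarray,
                          sigma_b: np.ndarray, mu: np.ndarray) -> float:
    """Deviance of a balanced two-level Gaussian model at given matrices.

    Raises :class:`NotPositiveDefiniteError` if ``Sigma_w`` or
    ``Sigma_c = Sigma_w + c Sigma_b`` is not positive definite.
    """
    G, c, N, p = m.G, m.c, m.N, m.p
    sigma_c = sigma_w + c * np.asarray(sigma_b, float)
    ld_w, inv_w = _chol_logdet_inv(np.asarray(sigma_w, float))
    ld_c, inv_c = _chol_logdet_inv(sigma_c)
    diff = m.ybar - np.asarray(mu, float)
    value = (N * p * _LOG_2PI
             + (N - G) * (ld_w + np.sum(inv_w * m.s_pw))
             + G * ld_c + (G - 1) * np.sum(inv_c * m.s_b)
             + G * c * diff @ inv_c @ diff)
    return float(value)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of fitting one model to one set of moments."""

    params: ParamVector | None
    sigma_w: np.ndarray
    sigma_b: np.ndarray
    mu: np.ndarray
    minus2ll: float
    converged: bool
    n_iter: int
    grad_norm: float
    model: ModelSpec
    moments: TwoLevelMoments
    between_indefinite: bool = False


def _fit_saturated(m: TwoLevelMoments, model: ModelSpec) -> FitResult:
    # PSD-constrained closed form via simultaneous diagonalisation; the
    # unconstrained MLE (Sigma_w = S_PW, Sigma_c = (G-1)/G * S_B) is
    # recovered whenever every generalized eigenvalue phi_k >= 1.
    sc_hat = (m.G - 1) / m.G * m.s_b
    phi, v = linalg.eigh(sc_hat, m.s_pw)  # v' S_PW v = I, v' sc_hat v = diag
    a = np.ones(m.p)
    b = phi.copy()
    pool = phi < 1.0
    pooled = (m.N - m.G + m.G * phi[pool]) / m.N
    a[pool] = pooled
    b[pool] = pooled
    v_inv = np.linalg.inv(v)
    sigma_w = v_inv.T @ (a[:, None] * v_inv)
    sigma_b = v_inv.T @ ((b - a)[:, None] * v_inv) / m.c
    sigma_w = 0.5 * (sigma_w + sigma_w.T)
    sigma_b = 0.5 * (sigma_b + sigma_b.T)
    ll = minus2_log_likelihood(m, sigma_w, sigma_b, m.ybar)
    return FitResult(None, sigma_w, sigma_b, m.ybar.copy(), ll, True, 0, 0.0,
                     model, m, between_indefinite=bool(pool.any()))


def _fit_baseline(m: TwoLevelMoments, model: ModelSpec) -> FitResult:
    # diagonal structure separates per item: the univariate version of the
    # saturated solution, between variances truncated at zero.
    var_w = np.diag(m.s_pw).copy()
    var_c = (m.G - 1) / m.G * np.diag(m.s_b)
    pool = var_c < var_w
    pooled = ((m.N - m.G) * var_w + m.G * var_c) / m.N
    var_w = np.where(pool, pooled, var_w)
    var_c = np.where(pool, pooled, var_c)
    var_b = (var_c - var_w) / m.c
    sigma_w = np.diag(var_w)
    sigma_b = np.diag(var_b)
    ll = minus2_log_likelihood(m, sigma_w, sigma_b, m.ybar)
    return FitResult(None, sigma_w, sigma_b, m.ybar.copy(), ll, True, 0, 0.0,
                     model, m, between_indefinite=bool(pool.any()))


def _objective(x: np.ndarray, m: TwoLevelMoments, marker: int):
    """Profiled deviance (mu = ybar) and analytic gradient for L-BFGS-B."""
    G, c, N, p = m.G, m.c, m.N, m.p
    theta = ParamVector.unpack(x, m.ybar, marker)
    sigma_w, sigma_b, _ = implied_covariances(theta)
    sigma_c = sigma_w + c * sigma_b
    try:
        ld_w, inv_w = _chol_logdet_inv(sigma_w)
        ld_c, inv_c = _chol_logdet_inv(sigma_c)
    except NotPositiveDefiniteError:
        return np.inf, np.zeros_like(x)
    f = ((N - G) * (ld_w + np.sum(inv_w * m.s_pw))
         + G * ld_c + (G - 1) * np.sum(inv_c * m.s_b))
    # d/dSigma [k ln|Sigma| + tr(Sigma^-1 M)] = k Sigma^-1 - Sigma^-1 M Sigma^-1
    a_w = (N - G) * (inv_w - inv_w @ m.s_pw @ inv_w)
    a_c = G * inv_c - (G - 1) * inv_c @ m.s_b @ inv_c
    within = a_w + a_c        # Sigma_w enters both blocks
    between = c * a_c
    free = [j for j in range(p) if j != marker]
    lw, lb = theta.lambda_w, theta.lambda_b
    grad = np.concatenate([
        (2.0 * theta.phi_w * within @ lw)[free],
        np.diag(within),
        [lw @ within @ lw],
        (2.0 * theta.phi_b * between @ lb)[free],
        np.diag(between),
        [lb @ between @ lb],
    ])
    return f, grad


def _start_values(m: TwoLevelMoments, marker: int) -> np.ndarray:
    """Deterministic moment-based start for the hypothesized model."""
    p = m.p
    free = [j for j in range(p) if j != marker]

    def level_start(s: np.ndarray):
        off = s[marker, :].copy()
        phi = float(np.median(np.abs(np.delete(off, marker))))
        phi = max(phi, 1e-3 * max(np.max(np.abs(np.diag(s))), 1e-8), 1e-8)
        lam = np.ones(p)
        lam[free] = np.clip(off[free] / phi, -5.0, 5.0)
        theta = np.maximum(np.diag(s) - phi * lam ** 2,
                           0.05 * np.maximum(np.diag(s), 1e-8))
        return lam, theta, phi

    lw, tw, pw = level_start(m.s_pw)
    sb_tilde = (m.s_b - m.s_pw) / m.c
    lb, tb, pb = level_start(sb_tilde)
    tb = np.maximum(tb, 0.0)
    pb = max(pb, 1e-8)
    return np.concatenate([lw[free], tw, [pw], lb[free], tb, [pb]])


def _projected_grad_norm(x: np.ndarray, g: np.ndarray,
                         lb: np.ndarray) -> float:
    pg = g.copy()
    pg[(x <= lb + 1e-12) & (g > 0)] = 0.0
    return float(np.max(np.abs(pg)))


def _rescale_params(theta: ParamVector, d: np.ndarray, marker: int
                    ) -> ParamVector:
    """Map parameters fitted on items scaled by 1/d back to the raw scale."""
    dm = d[marker]
    return ParamVector(
        lambda_w=theta.lambda_w * d / dm,
        theta_w=theta.theta_w * d ** 2,
        phi_w=theta.phi_w * dm ** 2,
        lambda_b=theta.lambda_b * d / dm,
        theta_b=theta.theta_b * d ** 2,
        phi_b=theta.phi_b * dm ** 2,
        mu=theta.mu * d,
    )


def _fit_hypothesized(m: TwoLevelMoments, model: ModelSpec,
                      start: Optional[ParamVector]) -> FitResult:
    p = m.p
    marker = model.marker
    # standardize items by the pooled-within SDs: the deviance-difference
    # chi-square is invariant and the optimisation is far better conditioned
    # than on the raw 0-100 response scale
    d = np.sqrt(np.diag(m.s_pw))
    if np.any(d <= 0):
        d = np.where(d > 0, d, 1.0)
    dd = np.outer(d, d)
    ms = TwoLevelMoments(m.s_pw / dd, m.s_b / dd, m.ybar / d, m.G, m.c)

    if start is not None:
        x0 = _rescale_params(start, 1.0 / d, marker).pack(marker)
    else:
        x0 = _start_values(ms, marker)
    floor = 1e-10
    lb = np.concatenate([
        np.full(p - 1, -np.inf), np.full(p, floor), [floor],
        np.full(p - 1, -np.inf), np.zeros(p), [0.0],
    ])
    x0 = np.maximum(x0, lb)
    bounds = list(zip(lb, np.full(lb.shape, np.inf)))
    options = {"maxiter": 2000, "ftol": 1e-16, "gtol": 1e-12, "maxcor": 30}

    n_total = 0
    res = None
    for attempt in range(4):
        cur = optimize.minimize(_objective, x0, args=(ms, marker),
                                method="L-BFGS-B", jac=True, bounds=bounds,
                                options=options)
        n_total += cur.nit
        if res is not None and cur.fun > res.fun:
            cur = res
        improved = res is None or res.fun - cur.fun > 1e-10
        res = cur
        x0 = res.x  # restart resets the Hessian approximation
        if not improved and attempt > 0:
            break
    pg = _projected_grad_norm(res.x, res.jac, lb)
    # the deviance (and hence its gradient) scales with N; require the
    # per-observation projected gradient to be ~0
    converged = bool(np.isfinite(res.fun)) and pg < 1e-6 * max(1.0, m.N)
    theta_s = ParamVector.unpack(res.x, ms.ybar, marker)
    theta = _rescale_params(theta_s, d, marker)
    sigma_w, sigma_b, mu = implied_covariances(theta)
    # deviance back on the raw scale: add the Jacobian of the row-wise
    # rescaling, 2 N sum(log d)
    ll = res.fun + 2.0 * m.N * float(np.sum(np.log(d))) + m.N * p * _LOG_2PI
    return FitResult(theta, sigma_w, sigma_b, mu, float(ll), converged,
                     n_total, pg, model, m)


def fit_model(m: TwoLevelMoments, model: ModelSpec = HYPOTHESIZED,
              start: Optional[ParamVector] = None) -> FitResult:
    """Fit a two-level covariance-structure model to balanced moments.

    The saturated and baseline models are solved in closed form; the
    hypothesized one-factor-per-level model is minimised by bounded
    quasi-Newton from a deterministic moment-based start, with one
    deterministic perturbed restart on non-convergence.  A non-converged fit
    is returned flagged, never raised.
    """
    if model.p != m.p:
        model = replace(model, p=m.p)
    if model.kind == "saturated":
        return _fit_saturated(m, model)
    if model.kind == "baseline":
        return _fit_baseline(m, model)
    return _fit_hypothesized(m, model, start)
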