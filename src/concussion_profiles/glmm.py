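"""Generalized linear mixed models with Laplace-approximated random intercepts.

Families: Bernoulli, binomial with k trials, Poisson, NB2, and zero-inflated
NB2 (ZINB).  Random intercepts are supported for any number of grouping
factors; "athletes nested within sport groups" is expressed as two factors
(``sport_group`` and the globally unique ``athlete_id``).  The marginal
likelihood integrates the random effects out with a Laplace approximation:
the penalized log-likelihood is maximized over the random-effect vector by
Newton iterations with a sparse-to-dense Hessian, and the log-determinant
correction is taken at the mode.  Outer parameters (fixed effects, log
variance components, log NB dispersion, zero-inflation logit) are optimized by
L-BFGS-B with finite-difference gradients, then polished with damped Newton
steps on a numerically differenced Hessian; the same Hessian supplies Wald
standard errors.

The ZINB density is ``P(y) = pi * 1[y=0] + (1 - pi) * NB2(y; mu, theta)`` with
a log link on ``mu`` and a logit-scale, intercept-only zero-inflation
component.  NB2 variance is ``mu + mu^2 / theta``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln, logit

from .design import DesignBuilder

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "ConditionalEffect",
    "EffectSize",
    "ConvergenceError",
    "fit_glmm",
    "predict_conditional",
    "contrast_between",
    "wald_term_test",
    "variance_explained",
    "cohens_d",
    "pearson_effect",
    "classify_magnitude",
]

_ETA_MAX = 30.0  # linear-predictor clamp for count means


class ConvergenceError(RuntimeError):
    """Raised when a fit fails to converge and the caller demands a usable fit."""


# ---------------------------------------------------------------------------
# Families: per-observation log-likelihood and derivatives w.r.t. eta
# ---------------------------------------------------------------------------


class _Family:
    name = ""
    extra_names: tuple[str, ...] = ()

    def loglik(self, y, eta, extra):  # pragma: no cover - interface
        raise NotImplementedError

    def d1(self, y, eta, extra):
        raise NotImplementedError

    def d2(self, y, eta, extra):
        raise NotImplementedError

    def mean_response(self, eta, extra):
        raise NotImplementedError

    def check_response(self, y, k):
        if np.any(y < 0) or np.any(y != np.floor(y)):
            raise ValueError(f"{self.name} response must be non-negative integers")

    def init_extra(self, y):
        return np.array([])


class _Bernoulli(_Family):
    name = "bernoulli"
    k = 1

    def check_response(self, y, k):
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("bernoulli response must be 0/1")

    def loglik(self, y, eta, extra):
        return y * eta - np.logaddexp(0.0, eta)

    def d1(self, y, eta, extra):
        return y - expit(eta)

    def d2(self, y, eta, extra):
        p = expit(eta)
        return -p * (1.0 - p)

    def mean_response(self, eta, extra):
        return expit(eta)


class _BinomialK(_Family):
    name = "binomial_k"

    def __init__(self, k: int):
        if k < 1:
            raise ValueError("binomial_k requires k >= 1")
        self.k = k

    def check_response(self, y, k):
        super().check_response(y, k)
        if np.any(y > self.k):
            raise ValueError(f"binomial_k response must be <= k = {self.k}")

    def loglik(self, y, eta, extra):
        k = self.k
        return (
            gammaln(k + 1)
            - gammaln(y + 1)
            - gammaln(k - y + 1)
            + y * eta
            - k * np.logaddexp(0.0, eta)
        )

    def d1(self, y, eta, extra):
        return y - self.k * expit(eta)

    def d2(self, y, eta, extra):
        p = expit(eta)
        return -self.k * p * (1.0 - p)

    def mean_response(self, eta, extra):
        return self.k * expit(eta)


class _Poisson(_Family):
    name = "poisson"

    def loglik(self, y, eta, extra):
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        return y * eta - np.exp(eta) - gammaln(y + 1)

    def d1(self, y, eta, extra):
        return y - np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def d2(self, y, eta, extra):
        return -np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))

    def mean_response(self, eta, extra):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


def _nb2_loglik(y, mu, theta):
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * (np.log(theta) - np.log(theta + mu))
        + y * (np.log(mu + 1e-300) - np.log(theta + mu))
    )


class _NB2(_Family):
    name = "nb2"
    extra_names = ("log_theta",)

    def init_extra(self, y):
        m, v = float(np.mean(y)), float(np.var(y))
        theta = m**2 / max(v - m, m / 2 + 1e-6) if m > 0 else 1.0
        return np.array([np.log(np.clip(theta, 0.05, 100.0))])

    def loglik(self, y, eta, extra):
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        return _nb2_loglik(y, mu, np.exp(extra[0]))

    def d1(self, y, eta, extra):
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        theta = np.exp(extra[0])
        return y - (y + theta) * mu / (mu + theta)

    def d2(self, y, eta, extra):
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        theta = np.exp(extra[0])
        return -(y + theta) * theta * mu / (mu + theta) ** 2

    def mean_response(self, eta, extra):
        return np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))


class _ZINB(_Family):
    name = "zinb"
    extra_names = ("log_theta", "zi_logit")

    def init_extra(self, y):
        pos = y[y > 0]
        m = float(np.mean(pos)) if len(pos) else 1.0
        v = float(np.var(pos)) if len(pos) > 1 else m * 2
        theta = m**2 / max(v - m, m / 2 + 1e-6)
        pi0 = np.clip(0.5 * float(np.mean(y == 0)), 0.02, 0.9)
        return np.array([np.log(np.clip(theta, 0.05, 100.0)), logit(pi0)])

    @staticmethod
    def _parts(y, eta, extra):
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        theta = np.exp(extra[0])
        pi = expit(extra[1])
        return mu, theta, pi

    def loglik(self, y, eta, extra):
        mu, theta, pi = self._parts(y, eta, extra)
        log_nb = _nb2_loglik(y, mu, theta)
        out = np.log1p(-pi) + log_nb
        zero = y == 0
        if zero.any():
            log_a = theta * (np.log(theta) - np.log(theta + mu[zero]))
            out_zero = np.logaddexp(
                np.log(pi + 1e-300), np.log1p(-pi) + log_a
            )
            out = np.where(zero, 0.0, out)
            out[zero] = out_zero
        return out

    def d1(self, y, eta, extra):
        mu, theta, pi = self._parts(y, eta, extra)
        d = y - (y + theta) * mu / (mu + theta)
        zero = y == 0
        if zero.any():
            mz = mu[zero]
            a = np.exp(theta * (np.log(theta) - np.log(theta + mz)))
            p0 = pi + (1.0 - pi) * a
            da = -a * theta * mz / (mz + theta)
            d = np.where(zero, 0.0, d)
            d[zero] = (1.0 - pi) * da / p0
        return d

    def d2(self, y, eta, extra):
        mu, theta, pi = self._parts(y, eta, extra)
        h = -(y + theta) * theta * mu / (mu + theta) ** 2
        zero = y == 0
        if zero.any():
            mz = mu[zero]
            a = np.exp(theta * (np.log(theta) - np.log(theta + mz)))
            p0 = pi + (1.0 - pi) * a
            da = -a * theta * mz / (mz + theta)
            d2a = a * theta**2 * mz * (mz - 1.0) / (mz + theta) ** 2
            g1 = (1.0 - pi) * da / p0
            h = np.where(zero, 0.0, h)
            h[zero] = (1.0 - pi) * d2a / p0 - g1**2
        return h

    def mean_response(self, eta, extra):
        mu = np.exp(np.clip(eta, -_ETA_MAX, _ETA_MAX))
        return (1.0 - expit(extra[1])) * mu


def _make_family(name: str, k: Optional[int]) -> _Family:
    if name == "bernoulli":
        return _Bernoulli()
    if name == "binomial_k":
        if k is None:
            raise ValueError("binomial_k family requires k_trials")
        return _BinomialK(k)
    if name == "poisson":
        return _Poisson()
    if name == "nb2":
        return _NB2()
    if name == "zinb":
        return _ZINB()
    raise ValueError(f"unknown family {name!r}")


# ---------------------------------------------------------------------------
# Model specification and fit container
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Declaration of one mixed model.

    ``terms`` use the design grammar of :mod:`concussion_profiles.design`;
    ``groups`` lists random-intercept grouping columns (nesting = list the
    outer factor and a globally unique inner factor).
    """

    response: str
    family: str
    terms: Sequence[str] = ()
    groups: Sequence[str] = ()
    k_trials: Optional[int] = None

    def __post_init__(self) -> None:
        _make_family(self.family, self.k_trials if self.family == "binomial_k" else 6)


@dataclass
class ConditionalEffect:
    """Predicted mean response with 95% CI over a covariate grid."""

    grid: pd.DataFrame
    estimate: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    eta: np.ndarray
    eta_se: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.estimate + 1e-12) and np.all(self.estimate <= self.upper + 1e-12)):
            raise ValueError("conditional-effect bounds must bracket the estimate")


@dataclass
class EffectSize:
    """Standardized effect size with its magnitude category.

    Categories (lower bound inclusive): for Cohen's d — nominal < 0.2,
    small 0.2-0.5, medium 0.5-0.8, large >= 0.8; for Pearson's r — nominal
    < 0.7, small 0.7-0.8, medium 0.8-0.9, large >= 0.9.
    """

    kind: str  # "cohens_d" | "pearson_r"
    value: float
    magnitude: str = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in ("cohens_d", "pearson_r"):
            raise ValueError(f"unknown effect-size kind {self.kind!r}")
        if self.kind == "pearson_r" and not -1.0 <= self.value <= 1.0:
            raise ValueError("pearson_r must be in [-1, 1]")
        v = abs(self.value)
        bands = (0.2, 0.5, 0.8) if self.kind == "cohens_d" else (0.7, 0.8, 0.9)
        labels = ("nominal", "small", "medium", "large")
        idx = int(np.searchsorted(bands, v, side="right"))
        object.__setattr__(self, "magnitude", labels[idx])


@dataclass
class MixedModelFit:
    """Fitted mixed model: coefficients, variance components, diagnostics."""

    spec: ModelSpec
    design: DesignBuilder
    coef: pd.Series
    se: pd.Series
    cov: np.ndarray  # covariance of all outer parameters
    variance_components: dict[str, float]
    theta: Optional[float]
    zi_prob: Optional[float]
    loglik: float
    converged: bool
    grad_norm: float
    n_obs: int
    message: str
    extra: np.ndarray
    group_levels: dict[str, int]

    @property
    def n_fixed(self) -> int:
        return len(self.coef)

    def cov_fixed(self) -> np.ndarray:
        p = self.n_fixed
        return self.cov[:p, :p]


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------


def _build_random_design(
    data: pd.DataFrame, groups: Sequence[str]
) -> tuple[sparse.csr_matrix, np.ndarray, list[str], dict[str, int]]:
    """Sparse indicator matrix Z plus a column->factor index map."""
    n = len(data)
    rows, cols, factor_of_col = [], [], []
    kept, levels = [], {}
    offset = 0
    for f_idx, name in enumerate(groups):
        codes, uniques = pd.factorize(data[name], sort=True)
        if len(uniques) < 2:
            warnings.warn(
                f"grouping factor {name!r} has fewer than 2 levels; "
                "random-intercept term dropped",
                stacklevel=3,
            )
            continue
        rows.extend(range(n))
        cols.extend(codes + offset)
        factor_of_col.extend([len(kept)] * len(uniques))
        kept.append(name)
        levels[name] = len(uniques)
        offset += len(uniques)
    if not kept:
        return sparse.csr_matrix((n, 0)), np.array([], dtype=int), [], {}
    Z = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, offset)
    )
    return Z, np.asarray(factor_of_col, dtype=int), kept, levels


def _inner_mode(y, Xbeta, Z, prec, fam, extra, b0, tol=1e-8, max_iter=100):
    """Newton maximization of the penalized log-likelihood over random effects."""
    b = b0.copy()
    Zt = Z.T.tocsr()

    def pen_ll(b_vec):
        eta = Xbeta + Z @ b_vec
        return float(fam.loglik(y, eta, extra).sum() - 0.5 * np.sum(prec * b_vec**2))

    current = pen_ll(b)
    lam = 0.0  # Levenberg damping, raised only when a step fails outright
    for _ in range(max_iter):
        eta = Xbeta + Z @ b
        g1 = fam.d1(y, eta, extra)
        grad = Zt @ g1 - prec * b
        if np.max(np.abs(grad)) < tol:
            break
        # |d2| is a positive-definite surrogate for the handful of
        # non-concave rows a ZINB zero component can produce
        w = np.clip(np.abs(fam.d2(y, eta, extra)), 1e-12, None)
        A = (Z.multiply(w[:, None]).T @ Z).toarray()
        A[np.diag_indices_from(A)] += prec + lam
        try:
            c = cho_factor(A, lower=True)
            step = cho_solve(c, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, grad, rcond=None)[0]
        t = 1.0
        improved = False
        for _ls in range(20):
            cand = b + t * step
            val = pen_ll(cand)
            if val > current + 1e-13:
                b, current = cand, val
                improved = True
                break
            t *= 0.5
        if improved:
            lam = 0.0 if lam < 1e-2 else lam / 10.0
        else:
            # no ascent found: done if the gradient is already negligible,
            # otherwise damp harder and retry once more
            if np.max(np.abs(grad)) < 1e-5 or lam >= 1e4:
                break
            lam = max(lam * 10.0, 1e-2)
    # true curvature at the mode (unclipped), for the Laplace determinant
    eta = Xbeta + Z @ b
    w_true = -fam.d2(y, eta, extra)
    A = (Z.multiply(w_true[:, None]).T @ Z).toarray()
    A[np.diag_indices_from(A)] += prec
    try:
        c = cho_factor(A, lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    except np.linalg.LinAlgError:
        sign, logdet = np.linalg.slogdet(A)
        if sign <= 0:
            w_safe = np.clip(w_true, 1e-10, None)
            A = (Z.multiply(w_safe[:, None]).T @ Z).toarray()
            A[np.diag_indices_from(A)] += prec
            logdet = np.linalg.slogdet(A)[1]
    return b, current, logdet


def _numeric_grad(f, x, h=1e-5):
    g = np.zeros_like(x)
    for i in range(len(x)):
        hi = h * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= hi
        g[i] = (f(xp) - f(xm)) / (2 * hi)
    return g


def _numeric_hess(f, x, h=1e-4):
    p = len(x)
    H = np.zeros((p, p))
    hs = np.array([h * max(1.0, abs(v)) for v in x])
    f0 = f(x)
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += hs[i]
        xm[i] -= hs[i]
        fp[i], fm[i] = f(xp), f(xm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / hs[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            xpp = x.copy()
            xpp[[i, j]] += [hs[i], hs[j]]
            xmm = x.copy()
            xmm[[i, j]] -= [hs[i], hs[j]]
            H[i, j] = H[j, i] = (
                f(xpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + f(xmm)
            ) / (2 * hs[i] * hs[j])
    return H


def _glm_start(y: np.ndarray, X: np.ndarray, family: str, k: Optional[int]) -> np.ndarray:
    """Starting fixed effects from a plain GLM (no random effects)."""
    import statsmodels.api as sm

    try:
        if family == "bernoulli":
            return sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        if family == "binomial_k":
            endog = np.column_stack([y, k - y])
            return sm.GLM(endog, X, family=sm.families.Binomial()).fit().params
        return sm.GLM(y, X, family=sm.families.Poisson()).fit().params
    except Exception:
        beta = np.zeros(X.shape[1])
        m = float(np.mean(y))
        if family in ("bernoulli", "binomial_k"):
            kk = 1 if family == "bernoulli" else k
            p = np.clip(m / kk, 1e-3, 1 - 1e-3)
            beta[0] = float(logit(p))
        else:
            beta[0] = float(np.log(m + 1e-3))
        return beta


def fit_glmm(
    spec: ModelSpec,
    data: pd.DataFrame,
    seed: int = 0,
    max_restarts: int = 2,
    require_convergence: bool = False,
) -> MixedModelFit:
    """Maximize the Laplace-approximated marginal likelihood of ``spec`` on ``data``.

    Deterministic given the data and seed (restarts jitter from a seeded RNG).
    Non-convergence is never silent: the fit carries ``converged`` and
    ``grad_norm`` diagnostics, and ``require_convergence=True`` raises
    :class:`ConvergenceError` instead.
    """
    fam = _make_family(spec.family, spec.k_trials)
    y = data[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"response {spec.response!r} contains missing values")
    fam.check_response(y, spec.k_trials)

    builder = DesignBuilder(spec.terms)
    X_raw = builder.fit(data)
    if np.linalg.matrix_rank(X_raw) < X_raw.shape[1]:
        raise ValueError(
            "fixed-effect design matrix is rank deficient; check for "
            f"collinear or constant terms among {builder.column_names}"
        )
    # standardize columns (intercept aside) so the outer optimization and its
    # finite-difference derivatives are well conditioned; undone on extraction
    col_scale = X_raw.std(axis=0)
    col_scale[0] = 1.0
    col_scale[col_scale < 1e-12] = 1.0
    X = X_raw / col_scale
    if spec.family == "bernoulli":
        p_hat = float(np.mean(y))
        if p_hat in (0.0, 1.0):
            raise ValueError("bernoulli response is constant; model inestimable")

    Z, factor_of_col, kept_groups, group_levels = _build_random_design(data, spec.groups)
    q = Z.shape[1]
    r = len(kept_groups)
    p = X.shape[1]

    beta0 = _glm_start(y, X, spec.family, spec.k_trials)
    extra0 = fam.init_extra(y)
    if spec.family == "zinb":
        # the mixture mean is (1 - pi) * mu: raise the count-mean intercept
        beta0 = beta0.copy()
        beta0[0] -= np.log1p(-expit(extra0[1]))
    theta0 = np.concatenate([beta0, np.full(r, np.log(0.1)), extra0])

    extra_bounds = {"nb2": [(-4.0, 10.0)], "zinb": [(-4.0, 10.0), (-20.0, 10.0)]}
    bounds = (
        [(None, None)] * p
        + [(-12.0, 6.0)] * r
        + extra_bounds.get(spec.family, [])
    )

    cache = {"b": np.zeros(q)}

    def nll(theta_vec: np.ndarray) -> float:
        beta = theta_vec[:p]
        log_vars = theta_vec[p : p + r]
        extra = theta_vec[p + r :]
        eta_fixed = X @ beta
        if q == 0:
            return -float(fam.loglik(y, eta_fixed, extra).sum())
        var_col = np.exp(log_vars)[factor_of_col]
        prec = 1.0 / var_col
        b_hat, pen, logdet = _inner_mode(
            y, eta_fixed, Z, prec, fam, extra, cache["b"]
        )
        cache["b"] = b_hat
        marg = pen - 0.5 * np.sum(np.log(var_col)) - 0.5 * logdet
        return -marg

    lb = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    ub = np.array([b[1] if b[1] is not None else np.inf for b in bounds])

    def projected(g: np.ndarray, x: np.ndarray) -> np.ndarray:
        # KKT projected gradient: bound-active components pushing outward
        # (e.g. log-theta at the Poisson limit) do not count against convergence
        g = g.copy()
        g[(x <= lb + 1e-2) & (g > 0)] = 0.0
        g[(x >= ub - 1e-2) & (g < 0)] = 0.0
        return g

    rng = np.random.default_rng(seed)
    best = None
    start = theta0
    message = ""
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            nll,
            start,
            method="L-BFGS-B",
            jac="3-point",  # central differences: robust to inner-solve noise
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-6, "finite_diff_rel_step": 1e-5},
        )
        x = res.x.copy()
        # Levenberg-damped Newton polish on the numerically differenced
        # Hessian (which may be indefinite near variance/dispersion bounds)
        tau = 0.0
        H = None
        for _round in range(8):
            g = projected(_numeric_grad(nll, x), x)
            # polish to a quarter of the convergence tolerance; chasing the
            # numerical-noise floor costs Hessians without changing inference
            f_here = nll(x)
            if np.max(np.abs(g)) < max(2.5e-4, 2.5e-5 * abs(f_here)):
                break
            if H is None:
                H = _numeric_hess(nll, x)
            f_cur = nll(x)
            improved = False
            for _trial in range(8):
                try:
                    step = np.linalg.solve(H + tau * np.eye(len(x)), g)
                except np.linalg.LinAlgError:
                    tau = max(10.0 * tau, 1e-4)
                    continue
                cand = np.clip(x - step, lb, ub)
                if nll(cand) < f_cur:
                    x, improved = cand, True
                    tau /= 10.0
                    break
                tau = max(10.0 * tau, 1e-4)
            if not improved:
                break
            H = None  # recompute at the new point
        g = projected(_numeric_grad(nll, x), x)
        grad_norm = float(np.max(np.abs(g)))
        val = nll(x)
        if best is None or val < best[1]:
            best = (x, val, grad_norm, res.message)
        # gradient tolerance on the inference scale: a residual gradient of
        # 1e-4 * |loglik| implies a likelihood shortfall far below the ~0.5
        # that corresponds to one standard error
        if grad_norm < max(1e-3, 1e-4 * abs(val)):
            break
        # jittered restart, seeded
        start = best[0] + rng.normal(0.0, 0.1, size=len(theta0))
        message = f"restart {attempt + 1} after grad norm {grad_norm:.2e}"

    x, val, grad_norm, opt_message = best
    converged = grad_norm < max(1e-3, 1e-4 * abs(val))
    if require_convergence and not converged:
        raise ConvergenceError(
            f"fit of {spec.response} ({spec.family}) did not converge: "
            f"gradient norm {grad_norm:.3e}; {opt_message}"
        )

    H = _numeric_hess(nll, x)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        cov_diag = np.abs(np.diag(cov))
        cov[np.diag_indices_from(cov)] = cov_diag

    # undo the column standardization on coefficients and covariance
    cov = cov.copy()
    cov[:p, :] /= col_scale[:, None]
    cov[:, :p] /= col_scale[None, :]
    names = builder.column_names
    beta = x[:p] / col_scale
    se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    vc = {name: float(np.exp(x[p + i])) for i, name in enumerate(kept_groups)}
    extra = x[p + r :]
    theta_hat = float(np.exp(extra[0])) if spec.family in ("nb2", "zinb") else None
    zi_hat = float(expit(extra[1])) if spec.family == "zinb" else None

    return MixedModelFit(
        spec=spec,
        design=builder,
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        cov=cov,
        variance_components=vc,
        theta=theta_hat,
        zi_prob=zi_hat,
        loglik=-val,
        converged=converged,
        grad_norm=grad_norm,
        n_obs=len(y),
        message=str(opt_message) + (f"; {message}" if message else ""),
        extra=extra,
        group_levels=group_levels,
    )


# ---------------------------------------------------------------------------
# Post-fit: prediction, contrasts, variance explained, effect sizes
# ---------------------------------------------------------------------------


def _fit_family(fit: MixedModelFit) -> _Family:
    return _make_family(fit.spec.family, fit.spec.k_trials)


def predict_conditional(
    fit: MixedModelFit, grid: pd.DataFrame, level: float = 0.95
) -> ConditionalEffect:
    """Population-level predicted mean with delta-method CI on the grid.

    Random effects are set to zero; the CI is computed on the linear-predictor
    scale and transformed through the (monotone) inverse link.  For the ZINB
    family the predicted mean includes the zero-inflation factor (1 - pi).
    """
    fam = _fit_family(fit)
    X = fit.design.transform(grid)
    beta = fit.coef.to_numpy()
    eta = X @ beta
    cov_b = fit.cov_fixed()
    eta_var = np.einsum("ij,jk,ik->i", X, cov_b, X)
    eta_se = np.sqrt(np.clip(eta_var, 0.0, None))
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    lo, hi = eta - z * eta_se, eta + z * eta_se
    return ConditionalEffect(
        grid=grid.reset_index(drop=True),
        estimate=fam.mean_response(eta, fit.extra),
        lower=fam.mean_response(lo, fit.extra),
        upper=fam.mean_response(hi, fit.extra),
        eta=eta,
        eta_se=eta_se,
    )


def contrast_between(
    fit: MixedModelFit, grid: pd.DataFrame, i: int, j: int
) -> dict[str, float]:
    """Wald contrast between grid rows ``i`` and ``j`` (delta method).

    Returns the response-scale difference, the linear-predictor difference
    with its SE, the z statistic and two-sided p-value.
    """
    from scipy.stats import norm

    fam = _fit_family(fit)
    X = fit.design.transform(grid)
    beta = fit.coef.to_numpy()
    d = X[i] - X[j]
    eta_diff = float(d @ beta)
    se = float(np.sqrt(max(d @ fit.cov_fixed() @ d, 0.0)))
    z = eta_diff / se if se > 0 else np.inf * np.sign(eta_diff)
    p = 2 * norm.sf(abs(z)) if np.isfinite(z) else 0.0
    mean_i = float(fam.mean_response(np.atleast_1d(X[i] @ beta), fit.extra)[0])
    mean_j = float(fam.mean_response(np.atleast_1d(X[j] @ beta), fit.extra)[0])
    return {
        "response_diff": mean_i - mean_j,
        "eta_diff": eta_diff,
        "se": se,
        "z": float(z),
        "p": float(p),
    }


def wald_term_test(fit: MixedModelFit, term: str) -> dict[str, float]:
    """Joint Wald chi-square test that all coefficients of ``term`` are zero."""
    from scipy.stats import chi2

    if term not in fit.design.term_slices:
        raise ValueError(
            f"term {term!r} not in model; available: {list(fit.design.term_slices)}"
        )
    sl = fit.design.term_slices[term]
    beta = fit.coef.to_numpy()[sl]
    cov = fit.cov_fixed()[sl, sl]
    stat = float(beta @ np.linalg.solve(cov, beta))
    df = len(beta)
    return {"chi2": stat, "df": df, "p": float(chi2.sf(stat, df))}


def variance_explained(fit: MixedModelFit, data: pd.DataFrame) -> dict[str, float]:
    """Nakagawa-style marginal and conditional coefficients of determination.

    On the linear-predictor scale: fixed-effect variance is the variance of
    X @ beta over the data; random-effect variance is the sum of the fitted
    variance components; the distribution-specific residual variance uses the
    logit-scale pi^2/3 for Bernoulli/binomial and the log-normal approximation
    ln(1 + 1/lambda) (+ 1/theta for NB2/ZINB) for count families.  Also
    reports the share of explained variance attributable to the random terms.
    """
    if not fit.converged:
        raise ConvergenceError("variance_explained is undefined for non-converged fits")
    X = fit.design.transform(data)
    var_f = float(np.var(X @ fit.coef.to_numpy()))
    var_r = float(sum(fit.variance_components.values()))
    family = fit.spec.family
    if family in ("bernoulli", "binomial_k"):
        var_d = np.pi**2 / 3
    else:
        eta = X @ fit.coef.to_numpy()
        lam = float(np.exp(np.mean(eta) + 0.5 * (var_f + var_r)))
        inv_theta = 1.0 / fit.theta if fit.theta is not None else 0.0
        var_d = float(np.log1p(1.0 / max(lam, 1e-8) + inv_theta))
    total = var_f + var_r + var_d
    explained = var_f + var_r
    return {
        "marginal_r2": var_f / total,
        "conditional_r2": explained / total,
        "random_share_of_explained": var_r / explained if explained > 0 else 0.0,
    }


def cohens_d(contrast: float, pooled_sd: float) -> EffectSize:
    """Cohen's d: a contrast standardized by a pooled dispersion."""
    if pooled_sd <= 0:
        raise ValueError("pooled_sd must be > 0 for Cohen's d")
    return EffectSize(kind="cohens_d", value=contrast / pooled_sd)


def pearson_effect(r: float) -> EffectSize:
    """Pearson-correlation effect size for continuous relationships."""
    return EffectSize(kind="pearson_r", value=r)


def classify_magnitude(effect: EffectSize) -> str:
    """Magnitude category of an effect size (computed at construction)."""
    return effect.magnitude
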