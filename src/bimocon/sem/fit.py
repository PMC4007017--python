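"""Maximum-likelihood estimation of observed-variable path models.

The model-implied covariance is Sigma(theta) = (I - A)^-1 Psi (I - A)^-T,
with A the path-coefficient matrix (column acts on row) and Psi the
disturbance covariance (diagonal unless covariances are freed).  Fitting
minimizes the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

by quasi-Newton descent on an unconstrained reparameterization (log
disturbance variances), starting from per-equation OLS regression values.
chi^2 = (N - 1) F_min, the convention of classical SEM programs paired
with the N - 1 sample covariance denominator.  Standard errors come from the observed information
(N - 1)/2 x Hessian of F at the solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import PathModel, SampleMoments


class SingularPathModelError(ValueError):
    """Raised when (I - A) is singular at the requested parameter point."""


class UnidentifiedModelError(ValueError):
    """Raised when the observed information matrix is rank deficient."""


def _find_unit_gain_cycle(model: PathModel, A: np.ndarray) -> str:
    import networkx as nx

    idx = model.index()
    g = nx.DiGraph()
    g.add_nodes_from(model.variables)
    for frm, to in model.paths:
        g.add_edge(frm, to)
    best, best_gain = None, 0.0
    for cycle in nx.simple_cycles(g):
        gain = 1.0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            gain *= A[idx[b], idx[a]]
        if abs(gain) > best_gain:
            best, best_gain = cycle, abs(gain)
    if best is None:
        return "no cycle found (numerical singularity)"
    return " -> ".join(best + [best[0]]) + f" (loop gain {best_gain:.3f})"


def _unpack(model: PathModel, params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parameter vector -> (A, Psi)."""
    params = np.asarray(params, dtype=float)
    if params.shape != (model.n_free,):
        raise ValueError(f"expected {model.n_free} parameters, got {params.shape}")
    p = model.p
    na = len(model.paths)
    A = np.zeros((p, p))
    for val, (i, j) in zip(params[:na], model.path_index_pairs()):
        A[i, j] = val
    psi = np.zeros((p, p))
    np.fill_diagonal(psi, params[na : na + p])
    for val, (i, j) in zip(params[na + p :], model.psi_cov_index_pairs()):
        psi[i, j] = val
        psi[j, i] = val
    return A, psi


def implied_covariance(model: PathModel, params: np.ndarray) -> np.ndarray:
    """Sigma(theta) = (I - A)^-1 Psi (I - A)^-T for a parameter vector."""
    A, psi = _unpack(model, params)
    if np.any(np.diag(psi) <= 0):
        raise ValueError("disturbance variances must be positive")
    B = np.eye(model.p) - A
    if abs(np.linalg.det(B)) < 1e-12:
        raise SingularPathModelError(
            "(I - A) is singular; offending cycle: " + _find_unit_gain_cycle(model, A)
        )
    Binv = np.linalg.inv(B)
    sigma = Binv @ psi @ Binv.T
    return (sigma + sigma.T) / 2.0


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p (zero iff Sigma = S)."""
    S = np.asarray(S, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if S.shape != sigma.shape:
        raise ValueError("S and Sigma must have the same shape")
    p = S.shape[0]
    for name, M in (("S", S), ("Sigma", sigma)):
        ev_min = float(np.linalg.eigvalsh(M).min())
        if ev_min <= 0:
            raise ValueError(
                f"{name} is not positive definite (smallest eigenvalue {ev_min:.3e})"
            )
    L = np.linalg.cholesky(sigma)
    logdet_sigma = 2.0 * np.log(np.diag(L)).sum()
    sign, logdet_s = np.linalg.slogdet(S)
    inv_s = np.linalg.solve(sigma, S)
    return float(logdet_sigma + np.trace(inv_s) - logdet_s - p)


@dataclass(frozen=True)
class SEMFit:
    """One fitted path model with estimates, tests and the fit battery."""

    model: PathModel
    moments: SampleMoments
    estimates: np.ndarray  # full parameter vector (paths, variances, covs)
    se: np.ndarray
    sigma_hat: np.ndarray
    f_min: float
    converged: bool
    n_iter: int
    baseline_chi2: float
    baseline_df: int

    @property
    def param_names(self) -> list[str]:
        return self.model.parameter_names()

    @property
    def df(self) -> int:
        return self.model.df

    @property
    def chi_square(self) -> float:
        return max((self.moments.N - 1) * self.f_min, 0.0)

    @property
    def p_chi(self) -> float:
        if self.df <= 0:
            return float("nan")
        return float(stats.chi2.sf(self.chi_square, self.df))

    @property
    def gfi(self) -> float:
        return gfi(self.moments.S, self.sigma_hat)

    @property
    def cfi(self) -> float:
        return cfi(self.chi_square, self.df, self.baseline_chi2, self.baseline_df)

    @property
    def rmsea(self) -> float:
        return rmsea(self.chi_square, self.df, self.moments.N)

    @property
    def aic(self) -> float:
        return information_criteria(self.chi_square, self.model.n_free, self.moments.N)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self.chi_square, self.model.n_free, self.moments.N)[1]

    def path_estimates(self) -> np.ndarray:
        return self.estimates[: len(self.model.paths)]

    def standardized(self) -> np.ndarray:
        """beta per path: coefficient x sd(source) / sd(outcome), sds from Sigma-hat."""
        sd = np.sqrt(np.diag(self.sigma_hat))
        idx = self.model.index()
        out = np.empty(len(self.model.paths))
        for k, (frm, to) in enumerate(self.model.paths):
            out[k] = self.estimates[k] * sd[idx[frm]] / sd[idx[to]]
        return out

    def path_table(self) -> pd.DataFrame:
        """Per-path estimate, se, z, two-sided p, standardized beta."""
        na = len(self.model.paths)
        est = self.estimates[:na]
        se = self.se[:na]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.inf * np.sign(est))
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "from": [f for f, _ in self.model.paths],
                "to": [t for _, t in self.model.paths],
                "estimate": est,
                "se": se,
                "z": z,
                "p": pvals,
                "beta": self.standardized(),
            }
        )

    def fit_summary(self) -> dict:
        return {
            "f_min": self.f_min,
            "chi_square": self.chi_square,
            "df": self.df,
            "p_chi": self.p_chi,
            "gfi": self.gfi,
            "cfi": self.cfi,
            "rmsea": self.rmsea,
            "aic": self.aic,
            "bic": self.bic,
            "n_free": self.model.n_free,
            "n_obs": self.moments.N,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }

    def meets_criteria(
        self,
        p_min: float = 0.05,
        gfi_min: float = 0.95,
        cfi_min: float = 0.95,
        rmsea_max: float = 0.05,
    ) -> bool:
        """Conventional acceptance battery: chi^2 ns, GFI/CFI high, RMSEA low."""
        r = self.rmsea
        return (
            self.converged
            and (self.df == 0 or self.p_chi > p_min)
            and self.gfi > gfi_min
            and self.cfi > cfi_min
            and (np.isnan(r) or r < rmsea_max)
        )


def start_values(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Per-equation OLS starting values (paths + residual variances)."""
    idx = model.index()
    na = len(model.paths)
    params = np.zeros(model.n_free)
    psi0 = np.diag(S).copy()
    for i, var in enumerate(model.variables):
        parents = model.parents(var)
        if not parents:
            continue
        J = [idx[v] for v in parents]
        try:
            a = np.linalg.solve(S[np.ix_(J, J)], S[J, idx[var]])
        except np.linalg.LinAlgError:
            continue
        resid = S[idx[var], idx[var]] - S[idx[var], J] @ a
        for k, (frm, to) in enumerate(model.paths):
            if to == var:
                params[k] = a[parents.index(frm)]
        psi0[i] = resid if resid > 1e-6 * S[i, i] else 0.05 * S[i, i]
    params[na : na + model.p] = psi0
    return params


def _objective_factory(model: PathModel, S: np.ndarray):
    """F and its analytic gradient on the (paths, log-variances, covs) scale."""
    p = model.p
    na = len(model.paths)
    pairs = model.path_index_pairs()
    cov_pairs = model.psi_cov_index_pairs()
    sign, logdet_s = np.linalg.slogdet(S)
    eye = np.eye(p)

    def unpack_t(theta):
        params = theta.copy()
        params[na : na + p] = np.exp(theta[na : na + p])
        return params

    def f_and_grad(theta):
        params = unpack_t(theta)
        A, psi = _unpack(model, params)
        B = eye - A
        try:
            Binv = np.linalg.inv(B)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        sigma = Binv @ psi @ Binv.T
        sigma = (sigma + sigma.T) / 2.0
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(theta)
        logdet_sigma = 2.0 * np.log(np.diag(L)).sum()
        sigma_inv = np.linalg.inv(sigma)
        F = logdet_sigma + float(np.sum(sigma_inv * S)) - logdet_s - p
        G = sigma_inv - sigma_inv @ S @ sigma_inv  # dF/dSigma
        M_a = 2.0 * (Binv.T @ G @ sigma)
        M_psi = Binv.T @ G @ Binv
        grad = np.empty_like(theta)
        for k, (i, j) in enumerate(pairs):
            grad[k] = M_a[i, j]
        # chain rule through psi = exp(u) for the log-variance block
        grad[na : na + p] = np.diag(M_psi) * params[na : na + p]
        for k, (i, j) in enumerate(cov_pairs):
            grad[na + p + k] = 2.0 * M_psi[i, j]
        return F, grad

    def grad_original(params):
        """Gradient on the original (paths, variances, covs) scale."""
        A, psi = _unpack(model, params)
        B = eye - A
        Binv = np.linalg.inv(B)
        sigma = Binv @ psi @ Binv.T
        sigma = (sigma + sigma.T) / 2.0
        sigma_inv = np.linalg.inv(sigma)
        G = sigma_inv - sigma_inv @ S @ sigma_inv
        M_a = 2.0 * (Binv.T @ G @ sigma)
        M_psi = Binv.T @ G @ Binv
        grad = np.empty(model.n_free)
        for k, (i, j) in enumerate(pairs):
            grad[k] = M_a[i, j]
        grad[na : na + p] = np.diag(M_psi)
        for k, (i, j) in enumerate(cov_pairs):
            grad[na + p + k] = 2.0 * M_psi[i, j]
        return grad

    return f_and_grad, grad_original, unpack_t


def _hessian_fd(grad_fn, params: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central finite differences of an analytic gradient."""
    t = len(params)
    H = np.empty((t, t))
    for k in range(t):
        h = rel_step * max(1.0, abs(params[k]))
        up = params.copy()
        dn = params.copy()
        up[k] += h
        dn[k] -= h
        H[:, k] = (grad_fn(up) - grad_fn(dn)) / (2.0 * h)
    return (H + H.T) / 2.0


def fit_baseline(moments: SampleMoments) -> tuple[float, int]:
    """Independence model (free variances, no paths): chi^2 and df.

    The ML solution is Sigma = diag(S) in closed form, so
    F_B = sum ln S_ii - ln|S|.
    """
    S = moments.S
    sign, logdet_s = np.linalg.slogdet(S)
    f_b = float(np.log(np.diag(S)).sum() - logdet_s)
    chi2_b = max((moments.N - 1) * f_b, 0.0)
    p = moments.p
    return chi2_b, p * (p - 1) // 2


def fit_ml(
    model: PathModel,
    moments: SampleMoments,
    start: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-6,
    check_identification: bool = True,
    low_n_warning: bool = True,
    stability_warning: bool = True,
    compute_se: bool = True,
) -> SEMFit:
    """Fit a path model to sample moments by maximum likelihood.

    ``start`` optionally overrides the OLS starting values (useful to warm
    start from a neighboring model during specification search).
    """
    if moments.variables != model.variables:
        if set(moments.variables) == set(model.variables):
            order = [moments.variables.index(v) for v in model.variables]
            S = moments.S[np.ix_(order, order)]
            moments = SampleMoments(S=S, N=moments.N, variables=model.variables)
        else:
            raise ValueError(
                f"moment variables {moments.variables} do not match model "
                f"variables {model.variables}"
            )
    ev_min = float(np.linalg.eigvalsh(moments.S).min())
    if ev_min <= 0:
        raise ValueError(
            f"sample covariance is not positive definite "
            f"(smallest eigenvalue {ev_min:.3e}); ML fitting requires N > p "
            "linearly independent observations"
        )
    if low_n_warning and moments.N < 2 * model.n_free:
        warnings.warn(
            f"N={moments.N} observations for t={model.n_free} free parameters; "
            "estimates and standard errors are unreliable at this sample size",
            stacklevel=2,
        )
    f_and_grad, grad_original, unpack_t = _objective_factory(model, moments.S)
    params0 = start_values(model, moments.S) if start is None else np.asarray(start, float)
    na = len(model.paths)
    # disturbance variances are kept inside [1e-4, 10] x the observed variance:
    # at small N, weakly identified (e.g. reciprocal) blocks otherwise drift
    # onto improper ridges with exploding variances
    s_ii = np.diag(moments.S)
    lo = np.log(1e-4 * s_ii)
    hi = np.log(10.0 * s_ii)
    theta0 = params0.copy()
    theta0[na : na + model.p] = np.clip(
        np.log(np.maximum(params0[na : na + model.p], 1e-8)), lo, hi
    )
    bounds = [(None, None)] * na + list(zip(lo, hi)) + [(None, None)] * len(
        model.psi_covariances
    )

    res = optimize.minimize(
        f_and_grad,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-9},
    )
    f_min = float(res.fun)
    theta = res.x
    grad = f_and_grad(theta)[1]
    # projected gradient: directions blocked by an active bound do not count
    eps = 1e-8
    for k in range(len(theta)):
        b_lo, b_hi = bounds[k]
        if b_lo is not None and theta[k] <= b_lo + eps and grad[k] > 0:
            grad[k] = 0.0
        if b_hi is not None and theta[k] >= b_hi - eps and grad[k] < 0:
            grad[k] = 0.0
    converged = bool(res.success or float(np.abs(grad).max()) < gtol)
    params = unpack_t(theta)
    at_bound = np.zeros(model.n_free, dtype=bool)
    at_bound[na : na + model.p] = (theta[na : na + model.p] <= lo + 1e-6) | (
        theta[na : na + model.p] >= hi - 1e-6
    )

    # observed information on the original scale
    se = np.full(model.n_free, np.nan)
    if not compute_se:
        chi2_b, df_b = fit_baseline(moments)
        return SEMFit(
            model=model,
            moments=moments,
            estimates=params,
            se=se,
            sigma_hat=implied_covariance(model, params),
            f_min=max(f_min, 0.0),
            converged=converged,
            n_iter=int(res.nit),
            baseline_chi2=chi2_b,
            baseline_df=df_b,
        )
    H = _hessian_fd(grad_original, params)
    scale = (moments.N - 1) / 2.0
    ev, vec = np.linalg.eigh(H)
    tol = 1e-8 * max(ev.max(), 1.0)
    if ev.min() > tol:
        cov = np.linalg.inv(H * scale)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    else:
        # flat directions confined to bound-active variances are tolerable
        # (a constrained improper solution); anything else is unidentified
        names = model.parameter_names()
        involved: set[int] = set()
        for k in np.where(ev <= tol)[0]:
            involved |= set(np.where(np.abs(vec[:, k]) > 0.3)[0])
        if check_identification and not all(at_bound[i] for i in involved):
            raise UnidentifiedModelError(
                "model is empirically unidentified at the solution; information "
                f"matrix null space involves: {[names[i] for i in sorted(involved)]}"
            )
        cov = np.linalg.pinv(H * scale, rcond=1e-8)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se[list(involved)] = np.nan

    A, _ = _unpack(model, params)
    radius = float(np.max(np.abs(np.linalg.eigvals(A))))
    if stability_warning and radius >= 1.0:
        warnings.warn(
            f"nonrecursive system is unstable at the solution "
            f"(spectral radius of A = {radius:.3f} >= 1)",
            stacklevel=2,
        )
    chi2_b, df_b = fit_baseline(moments)
    return SEMFit(
        model=model,
        moments=moments,
        estimates=params,
        se=se,
        sigma_hat=implied_covariance(model, params),
        f_min=max(f_min, 0.0),
        converged=converged,
        n_iter=int(res.nit),
        baseline_chi2=chi2_b,
        baseline_df=df_b,
    )


# -- fit indices --------------------------------------------------------------


def gfi(S: np.ndarray, sigma_hat: np.ndarray) -> float:
    """Joreskog's ML goodness-of-fit index."""
    W = np.linalg.solve(sigma_hat, S)
    p = S.shape[0]
    num = float(np.trace((W - np.eye(p)) @ (W - np.eye(p))))
    den = float(np.trace(W @ W))
    return 1.0 - num / den


def cfi(chi2_m: float, df_m: int, chi2_b: float, df_b: int) -> float:
    """Comparative fit index against the independence baseline."""
    lam_m = max(chi2_m - df_m, 0.0)
    lam_b = max(chi2_b - df_b, lam_m, 0.0)
    if lam_b == 0.0:
        return 1.0
    return 1.0 - lam_m / lam_b


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root-mean-square error of approximation (nan when df = 0)."""
    if df <= 0:
        return float("nan")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))


def information_criteria(chi2: float, t: int, n: int) -> tuple[float, float]:
    """chi^2-based AIC and BIC.

    AIC = chi^2 + 2 t and BIC = chi^2 + t ln N.  These differ from the
    likelihood-based forms by a constant shared across models fitted to the
    same moments, so only differences between candidate models are
    meaningful.
    """
    if n < 2:
        raise ValueError("need N >= 2")
    return float(chi2 + 2 * t), float(chi2 + t * np.log(n))
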