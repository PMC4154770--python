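"""Maximum-likelihood fitting of RAM path models to sample covariances.

The estimator minimizes the Wishart ML discrepancy

    F_ML(theta) = ln|Sigma(theta)| + tr(S Sigma(theta)^-1) - ln|S| - p

over the free parameters.  ``(N - 1) * F_ML(theta_hat)`` is the model
chi-square with ``p(p+1)/2 - t`` degrees of freedom; the overall model
p-value tests whether the sample and implied covariance matrices differ by
more than sampling error (p < alpha means the model structure does not fit).
Standard errors come from the curvature of the discrepancy at the optimum
scaled by 2/(N-1).

A negative estimated variance (Heywood case) marks the fit non-converged so
callers can fall back to an alternative parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .ram import RAMMatrices, build_ram, implied_covariance
from .semspec import SEMModelSpec

__all__ = [
    "SampleMoments",
    "FitResult",
    "ml_discrepancy",
    "fit_ml",
    "fit_indices",
    "standardize_solution",
    "moments_from_table",
    "apply_transforms",
]

_F_TOL = 1e-10
_DEFAULT_RESTARTS = 20


@dataclass(frozen=True)
class SampleMoments:
    """Sample covariance matrix S of the observed variables and its N."""

    variables: tuple[str, ...]
    S: np.ndarray
    N: int

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        p = len(self.variables)
        if S.shape != (p, p):
            raise ValueError("covariance matrix shape does not match variables")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        if np.any(np.diag(S) <= 0):
            raise ValueError("covariance matrix needs positive diagonal")
        if self.N <= p:
            raise ValueError(f"N={self.N} must exceed the number of variables p={p}")
        object.__setattr__(self, "S", (S + S.T) / 2.0)

    def reordered(self, variables: tuple[str, ...]) -> "SampleMoments":
        idx = [self.variables.index(v) for v in variables]
        return SampleMoments(tuple(variables), self.S[np.ix_(idx, idx)], self.N)


def apply_transforms(table: pd.DataFrame, transforms: dict[str, str]) -> pd.DataFrame:
    """Apply per-column transforms, then z-standardize every column.

    ``log1p`` is the default for biomass/abundance-like quantities whose
    distributions are right-skewed; richness and land-use indices stay on
    their original scale.  Standardization makes the ML solution's
    standardized and unstandardized coefficients coincide (up to fixed
    loadings), and is logged with every fit.
    """
    out = table.copy()
    for col, tag in transforms.items():
        if col not in out.columns:
            continue
        if tag == "log1p":
            out[col] = np.log1p(out[col])
        elif tag != "identity":
            raise ValueError(f"unknown transform {tag!r}")
    for col in out.columns:
        sd = out[col].std(ddof=1)
        if sd <= 0:
            raise ValueError(f"column {col!r} has zero variance after transform")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def moments_from_table(
    table: pd.DataFrame,
    variables: tuple[str, ...] | list[str],
    transforms: dict[str, str] | None = None,
) -> SampleMoments:
    """Transform, z-standardize and reduce a plot table to sample moments."""
    sub = table.loc[:, list(variables)].dropna()
    if transforms:
        sub = apply_transforms(sub, {k: v for k, v in transforms.items() if k in sub})
    else:
        sub = apply_transforms(sub, {})
    S = np.cov(sub.to_numpy(), rowvar=False, ddof=1)
    return SampleMoments(tuple(variables), S, len(sub))


def ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Wishart ML discrepancy between sample and implied covariances.

    Non-negative, and zero exactly when ``Sigma == S``.  Raises
    ``LinAlgError`` when either matrix is not positive definite.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    p = S.shape[0]
    c, low = linalg.cho_factor(Sigma, lower=True)
    logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(c))))
    cs, lows = linalg.cho_factor(S, lower=True)
    logdet_s = 2.0 * float(np.sum(np.log(np.diag(cs))))
    trace = float(np.trace(linalg.cho_solve((c, low), S)))
    return logdet_sigma + trace - logdet_s - p


@dataclass
class FitResult:
    """Estimates, fit statistics and the standardized solution of one fit."""

    spec: SEMModelSpec
    ram: RAMMatrices
    moments: SampleMoments
    theta: np.ndarray
    converged: bool
    f_ml: float
    chi_square: float
    df: int
    model_p_value: float
    gof_index: float
    aic: float
    aicc: float
    implied: np.ndarray
    params: pd.DataFrame = field(repr=False)
    n_restarts_used: int = 0
    message: str = ""

    @property
    def n_free(self) -> int:
        return self.ram.n_free

    def std_coefficient(self, source: str, target: str) -> float:
        """Standardized coefficient on the directed edge source → target."""
        rows = self.params[
            (self.params["source"] == source)
            & (self.params["target"] == target)
            & (self.params["kind"].isin(["path", "loading"]))
        ]
        if len(rows) != 1:
            raise KeyError(f"no directed coefficient {source!r} -> {target!r}")
        return float(rows["std_estimate"].iloc[0])


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _objective(ram: RAMMatrices, S: np.ndarray):
    obs = ram.obs_idx
    n = len(ram.variables)
    eye = np.eye(n)

    def f(theta: np.ndarray) -> float:
        A, P = ram.materialize(theta)
        try:
            B = np.linalg.solve(eye - A, eye)
            V = B @ P @ B.T
            Sigma = V[np.ix_(obs, obs)]
            return ml_discrepancy(S, Sigma)
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            return 1e12

    return f


def _objective_with_grad(ram: RAMMatrices, S: np.ndarray):
    """F_ML and its analytic gradient in the RAM parameterization.

    With B = (I-A)^-1 and M = Sigma^-1 - Sigma^-1 S Sigma^-1 (lifted to the
    full variable space as G), the derivative w.r.t. a directed coefficient
    A[i,j] is 2 (B P B^T G B)[j,i] and w.r.t. a covariance cell P[i,j] it is
    (B^T G B)[i,j] (doubled off-diagonal).
    """
    obs = ram.obs_idx
    n = len(ram.variables)
    eye = np.eye(n)
    p = len(obs)
    big = 1e12

    def fg(theta: np.ndarray) -> tuple[float, np.ndarray]:
        A, P = ram.materialize(theta)
        grad = np.zeros_like(theta)
        try:
            B = np.linalg.solve(eye - A, eye)
            V = B @ P @ B.T
            Sigma = V[np.ix_(obs, obs)]
            c, low = linalg.cho_factor(Sigma, lower=True)
            isig = linalg.cho_solve((c, low), np.eye(p))
            logdet_sigma = 2.0 * float(np.sum(np.log(np.diag(c))))
            sign, logdet_s = np.linalg.slogdet(S)
            fval = logdet_sigma + float(np.trace(isig @ S)) - logdet_s - p
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            return big, grad
        M = isig - isig @ S @ isig
        G = np.zeros((n, n))
        G[np.ix_(obs, obs)] = M
        K = V @ G @ B  # for A-cells
        T = B.T @ G @ B  # for P-cells
        for k, par in enumerate(ram.parameters):
            if par.matrix == "A":
                grad[k] = 2.0 * K[par.col, par.row]
            elif par.row == par.col:
                grad[k] = T[par.row, par.row]
            else:
                grad[k] = 2.0 * T[par.row, par.col]
        return fval, grad

    return fg


def _numeric_hessian(fg, x: np.ndarray, step: float = 1e-6) -> np.ndarray:
    """Hessian by central differences of the analytic gradient.

    The analytic gradient is free of the cancellation noise that limits
    finite differences of F_ML itself, so this is accurate enough both for
    Newton polishing and for standard errors.
    """
    k = len(x)
    H = np.empty((k, k))
    h = step * np.maximum(1.0, np.abs(x))
    for i in range(k):
        xp = x.copy(); xp[i] += h[i]
        xm = x.copy(); xm[i] -= h[i]
        H[i] = (fg(xp)[1] - fg(xm)[1]) / (2 * h[i])
    return (H + H.T) / 2.0


def _newton_polish(fg, x: np.ndarray, iterations: int = 3) -> np.ndarray:
    """A few damped Newton steps on the analytic gradient.

    Quasi-Newton stops once F_ML changes fall below its ~1e-16 noise floor,
    which leaves parameters accurate only to ~1e-8; the gradient itself is
    still informative there, so Newton steps recover full precision.
    """
    for _ in range(iterations):
        fval, g = fg(x)
        if fval >= 1e11 or not np.all(np.isfinite(g)):
            return x
        H = _numeric_hessian(fg, x)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return x
        if not np.all(np.isfinite(delta)) or np.linalg.norm(delta) > 1.0:
            return x
        candidate = x - delta
        if fg(candidate)[0] <= fval + 1e-12:
            x = candidate
        else:
            return x
    return x


def fit_ml(
    spec: SEMModelSpec,
    moments: SampleMoments,
    *,
    restarts: int = _DEFAULT_RESTARTS,
    seed: int = 0,
    compute_se: bool = True,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Fit a path model by maximum likelihood.

    Starts from zero paths / unit loadings / sample variances and runs a
    quasi-Newton minimizer; up to ``restarts`` seeded jittered restarts are
    tried before the fit is declared non-converged.  A Heywood case (negative
    estimated variance) also marks the fit non-converged, which callers treat
    as the trigger for the latent-to-correlation fallback.
    """
    ram = build_ram(spec)
    moments = moments.reordered(spec.observed)
    S = moments.S
    N = moments.N
    p = len(spec.observed)
    t = ram.n_free
    # Optimize on the correlation scale (F_ML is invariant under diagonal
    # rescaling) so wildly different variable units cannot ill-condition the
    # search; estimates are mapped back to the original scale afterwards.
    d_obs = np.sqrt(np.diag(S))
    R = S / np.outer(d_obs, d_obs)
    # Each latent is anchored by a loading fixed to 1, so switching the
    # indicators to correlation units implicitly rescales the latent by its
    # anchor's SD; fixed-variance latents keep unit scale on both sides.
    index = {v: i for i, v in enumerate(ram.variables)}
    s_full = np.ones(len(ram.variables))
    s_full[ram.obs_idx] = d_obs
    for lat in spec.latents:
        anchors = [l.indicator for l in spec.loadings if l.latent == lat and l.fixed is not None]
        s_full[index[lat]] = s_full[index[anchors[0]]] if anchors else 1.0
    scale = np.array(
        [
            s_full[par.row] / s_full[par.col]
            if par.matrix == "A"
            else s_full[par.row] * s_full[par.col]
            for par in ram.parameters
        ]
    )
    fg_orig = _objective_with_grad(ram, S)
    fg = _objective_with_grad(ram, R)
    rng = np.random.default_rng(seed)

    if x0 is None:
        x0_corr = ram.start_values(np.diag(R))
    else:
        x0_corr = np.asarray(x0, dtype=float) / scale
    best = None
    used = 0
    for attempt in range(restarts + 1):
        start = x0_corr if attempt == 0 else x0_corr + rng.normal(scale=0.1 + 0.05 * attempt, size=t)
        res = optimize.minimize(
            fg, start, jac=True, method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-11, "maxiter": 2000},
        )
        if res.fun < 1e11:
            x_polished = _newton_polish(fg, res.x)
            res.fun, res.x = fg(x_polished)[0], x_polished
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        used = attempt
        if best.fun < 1e12 and _is_admissible(ram, best.x):
            break
    theta = best.x * scale
    f_min = float(best.fun)

    heywood = not _is_admissible(ram, theta)
    converged = bool(f_min < 1e11 and not heywood)

    df = p * (p + 1) // 2 - t
    chi_square = max(0.0, (N - 1) * f_min) if converged else np.nan
    if converged:
        model_p = float(stats.chi2.sf(chi_square, df)) if df > 0 else 1.0
        Sigma = implied_covariance(ram, theta)
        gof = _gfi(S, Sigma)
        aic = chi_square + 2 * t
        aicc = aic + (2 * t * (t + 1)) / (N - t - 1) if N > t + 1 else np.nan
    else:
        model_p = np.nan
        Sigma = np.full((p, p), np.nan)
        gof = np.nan
        aic = np.nan
        aicc = np.nan

    params = _parameter_table(ram, theta, moments, fg_orig, compute_se=compute_se and converged)
    return FitResult(
        spec=spec,
        ram=ram,
        moments=moments,
        theta=theta,
        converged=converged,
        f_ml=f_min,
        chi_square=chi_square,
        df=df,
        model_p_value=model_p,
        gof_index=gof,
        aic=aic,
        aicc=aicc,
        implied=Sigma,
        params=params,
        n_restarts_used=used,
        message="heywood case" if heywood else best.message if isinstance(best.message, str) else "",
    )


def _is_admissible(ram: RAMMatrices, theta: np.ndarray) -> bool:
    """No Heywood case: every variance estimate is non-negative."""
    for par, value in zip(ram.parameters, theta):
        if par.kind == "variance" and value < 0:
            return False
    return True


def _gfi(S: np.ndarray, Sigma: np.ndarray) -> float:
    """Joreskog-Sorbom goodness-of-fit index (ML version)."""
    W = np.linalg.solve(Sigma, S)
    I = np.eye(S.shape[0])
    num = float(np.trace((W - I) @ (W - I)))
    den = float(np.trace(W @ W))
    return 1.0 - num / den


def fit_indices(fit: FitResult) -> tuple[float, float, float]:
    """(GoF index, AIC, AICc) of a converged fit."""
    if not fit.converged:
        raise ValueError("fit indices require a converged fit")
    return fit.gof_index, fit.aic, fit.aicc


def _parameter_table(
    ram: RAMMatrices,
    theta: np.ndarray,
    moments: SampleMoments,
    fg,
    *,
    compute_se: bool,
) -> pd.DataFrame:
    """Assemble the per-parameter table: estimates, SEs, z, p, stars, std."""
    se = np.full(ram.n_free, np.nan)
    if compute_se and ram.n_free:
        try:
            H = _numeric_hessian(fg, theta)
            cov = (2.0 / (moments.N - 1)) * np.linalg.pinv(H)
            d = np.diag(cov)
            se = np.where(d > 0, np.sqrt(np.clip(d, 0, None)), np.nan)
        except (np.linalg.LinAlgError, ValueError):
            pass
    z = theta / se
    pvals = 2 * stats.norm.sf(np.abs(z))
    std = standardize_solution(ram, theta)

    rows = []
    for k, par in enumerate(ram.parameters):
        rows.append(
            {
                "name": par.name,
                "kind": par.kind,
                "source": par.source,
                "target": par.target,
                "estimate": theta[k],
                "se": se[k],
                "z": z[k],
                "p_value": pvals[k],
                "stars": _stars(pvals[k]) if np.isfinite(pvals[k]) else "",
                "std_estimate": std[k],
                "fixed": False,
            }
        )
    # Fixed loadings are reported too: their unstandardized value is the
    # pinned constant but the standardized value generally is not 1.
    index = {v: i for i, v in enumerate(ram.variables)}
    try:
        V = implied_covariance(ram, theta, full=True)
        sds = np.sqrt(np.clip(np.diag(V), 1e-300, None))
    except np.linalg.LinAlgError:
        sds = np.full(len(ram.variables), np.nan)
    for l in ram.spec.loadings:
        if l.fixed is None:
            continue
        i, j = index[l.indicator], index[l.latent]
        rows.append(
            {
                "name": f"{l.latent}=~{l.indicator}",
                "kind": "loading",
                "source": l.latent,
                "target": l.indicator,
                "estimate": l.fixed,
                "se": np.nan,
                "z": np.nan,
                "p_value": np.nan,
                "stars": "",
                "std_estimate": l.fixed * sds[j] / sds[i] if np.all(np.isfinite(sds[[i, j]])) else np.nan,
                "fixed": True,
            }
        )
    return pd.DataFrame(rows)


def standardize_solution(ram: RAMMatrices, theta: np.ndarray) -> np.ndarray:
    """Standardized estimates for every free parameter.

    Directed coefficients are rescaled by SD(source)/SD(target) under the
    full implied covariance (latent SDs included); covariances become
    correlations; variances become shares of the variable's implied variance.
    """
    index = {v: i for i, v in enumerate(ram.variables)}
    try:
        V = implied_covariance(ram, theta, full=True)
    except np.linalg.LinAlgError:
        return np.full(ram.n_free, np.nan)
    d = np.diag(V)
    if np.any(d <= 0):
        return np.full(ram.n_free, np.nan)
    sds = np.sqrt(d)
    out = np.empty(ram.n_free)
    for k, par in enumerate(ram.parameters):
        if par.matrix == "A":
            i, j = index[par.target], index[par.source]
            out[k] = theta[k] * sds[j] / sds[i]
        elif par.kind == "covariance":
            i, j = index[par.source], index[par.target]
            out[k] = theta[k] / (sds[i] * sds[j])
        else:  # variance
            i = index[par.source]
            out[k] = theta[k] / d[i]
    return out
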