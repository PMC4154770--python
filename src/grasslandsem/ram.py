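"""Reticular-action-model (RAM) form of a path diagram.

Every path model reduces to three matrices over the full variable vector
(observed then latent): ``A`` holds directed coefficients (``A[i, j]`` is the
coefficient on the edge j → i), ``P`` holds variances and covariances of the
exogenous residuals, and the filter ``F`` selects the observed rows.  The
model-implied covariance of the observed variables is

    Sigma(theta) = F (I - A)^-1 P (I - A)^-T F^T

Free parameters live in a flat vector ``theta``; :class:`RAMMatrices` keeps a
map from parameter index to the matrix cells it fills (symmetric ``P`` cells
are filled in pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .semspec import SEMModelSpec, SpecificationError

__all__ = ["Parameter", "RAMMatrices", "build_ram", "implied_covariance"]


@dataclass(frozen=True)
class Parameter:
    """One free parameter: its label, kind and the cell it occupies."""

    name: str
    kind: str  # "loading" | "path" | "variance" | "covariance"
    matrix: str  # "A" | "P"
    row: int
    col: int
    source: str
    target: str


@dataclass
class RAMMatrices:
    """RAM matrices plus the free-parameter map for one model spec."""

    spec: SEMModelSpec
    variables: tuple[str, ...]
    obs_idx: np.ndarray  # indices of observed variables within `variables`
    a_fixed: np.ndarray  # constants (fixed loadings) baked into A
    p_fixed: np.ndarray  # constants (fixed latent variances) baked into P
    parameters: list[Parameter]

    @property
    def n_free(self) -> int:
        return len(self.parameters)

    @property
    def n_observed(self) -> int:
        return len(self.obs_idx)

    def materialize(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fill A and P from a parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"theta must have length {self.n_free}")
        A = self.a_fixed.copy()
        P = self.p_fixed.copy()
        for par, value in zip(self.parameters, theta):
            if par.matrix == "A":
                A[par.row, par.col] = value
            else:
                P[par.row, par.col] = value
                P[par.col, par.row] = value
        return A, P

    def start_values(self, sample_variances: np.ndarray | None = None) -> np.ndarray:
        """Default optimizer start: zero paths, unit loadings, sample variances."""
        theta = np.zeros(self.n_free)
        for k, par in enumerate(self.parameters):
            if par.kind == "loading":
                theta[k] = 1.0
            elif par.kind == "variance":
                if sample_variances is not None and par.row in self.obs_idx:
                    theta[k] = float(sample_variances[list(self.obs_idx).index(par.row)])
                else:
                    theta[k] = 1.0
        return theta

    def index_of(self, source: str, target: str) -> int:
        """Index of the free directed parameter on edge source → target."""
        for k, par in enumerate(self.parameters):
            if par.matrix == "A" and par.source == source and par.target == target:
                return k
        raise KeyError(f"no free directed parameter {source!r} -> {target!r}")


def build_ram(spec: SEMModelSpec) -> RAMMatrices:
    """Translate a validated spec into RAM matrices and a parameter map.

    Raises
    ------
    SpecificationError
        If the spec is invalid or has more free parameters than there are
        distinct observed moments p(p+1)/2 (not identifiable).
    """
    spec.validate()
    variables = spec.variables
    index = {v: i for i, v in enumerate(variables)}
    n = len(variables)
    a_fixed = np.zeros((n, n))
    p_fixed = np.zeros((n, n))
    params: list[Parameter] = []

    for l in spec.loadings:
        i, j = index[l.indicator], index[l.latent]
        if l.fixed is not None:
            a_fixed[i, j] = l.fixed
        else:
            params.append(
                Parameter(f"{l.latent}=~{l.indicator}", "loading", "A", i, j, l.latent, l.indicator)
            )
    for s, t in spec.paths:
        params.append(Parameter(f"{s}->{t}", "path", "A", index[t], index[s], s, t))
    # Variances: every observed variable gets a free (residual) variance;
    # latent variances are free when a loading anchors the scale, fixed at 1
    # when the latent itself is scaled by its variance.
    for v in spec.observed:
        i = index[v]
        params.append(Parameter(f"V[{v}]", "variance", "P", i, i, v, v))
    for lat in spec.latents:
        i = index[lat]
        if lat in spec.fixed_variance_latents:
            p_fixed[i, i] = 1.0
        else:
            params.append(Parameter(f"V[{lat}]", "variance", "P", i, i, lat, lat))
    for a, b in spec.covariances:
        i, j = index[a], index[b]
        params.append(Parameter(f"{a}~~{b}", "covariance", "P", i, j, a, b))

    p = len(spec.observed)
    if len(params) > p * (p + 1) // 2:
        raise SpecificationError(
            f"model has {len(params)} free parameters but only {p * (p + 1) // 2} moments"
        )
    return RAMMatrices(
        spec=spec,
        variables=variables,
        obs_idx=np.array([index[v] for v in spec.observed], dtype=int),
        a_fixed=a_fixed,
        p_fixed=p_fixed,
        parameters=params,
    )


def implied_covariance(
    ram: RAMMatrices, theta: np.ndarray, *, full: bool = False
) -> np.ndarray:
    """Model-implied covariance Sigma(theta) of the observed variables.

    With ``full=True`` the covariance of the complete variable vector
    (latents included) is returned, which standardization needs for the
    latent standard deviations.
    """
    A, P = ram.materialize(theta)
    n = A.shape[0]
    ima = np.eye(n) - A
    try:
        B = np.linalg.solve(ima, np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("I - A is singular at theta") from exc
    V = B @ P @ B.T
    V = (V + V.T) / 2.0
    if full:
        return V
    return V[np.ix_(ram.obs_idx, ram.obs_idx)]
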