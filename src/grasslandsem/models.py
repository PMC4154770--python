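"""Default model catalog, stepwise pruning, and total-effect decomposition.

Two concepts are shipped.  The Resource Heterogeneity model routes land-use
effects on consumers through resource *diversity*: a latent land-use
intensity drives mowing (anchor loading fixed at 1), fertilization and
grazing; the management modes shape plant biomass and plant diversity; plant
diversity feeds herbivore diversity which feeds predator diversity, with an
additional direct plant-diversity → predator-diversity arrow; days since the
last cut enter as an exogenous covariate on the arthropod variables.  The
Resource Abundance model adds the *quantity* route: plant biomass →
herbivore biomass → (herbivore diversity, predator biomass) and predator
biomass → predator diversity.

Standardized total effects between two variables are the sum, over every
directed simple path connecting them, of the product of standardized
coefficients along the path (loadings count as edges when the source is the
latent).  An algebraically independent check — the off-diagonal entries of
(I - A_std)^-1 - I — is used by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from .fit import FitResult, SampleMoments, fit_ml
from .semspec import Loading, SEMModelSpec, SpecificationError

__all__ = [
    "LATENT",
    "ModelCatalog",
    "PruneTrace",
    "EffectDecomposition",
    "default_rh_model",
    "default_ra_model",
    "default_catalog",
    "latent_fallback",
    "with_quadratic_grazing",
    "stepwise_prune",
    "enumerate_paths",
    "total_effect",
    "round_half_away",
]

LATENT = "land_use"

_MODES = ("mowing", "fertilization", "grazing")
_RH_OBSERVED = (
    "mowing",
    "fertilization",
    "grazing",
    "time_after_mowing",
    "plant_biomass",
    "plant_diversity",
    "herbivore_diversity",
    "predator_diversity",
)
_DEFAULT_TRANSFORMS = (
    ("grazing", "log1p"),
    ("fertilization", "log1p"),
    ("plant_biomass", "log1p"),
    ("herbivore_biomass", "log1p"),
    ("predator_biomass", "log1p"),
)


def default_rh_model() -> SEMModelSpec:
    """Resource Heterogeneity model: diversity-mediated land-use effects."""
    paths = []
    for mode in _MODES:
        paths.append((mode, "plant_biomass"))
        paths.append((mode, "plant_diversity"))
    paths += [
        ("plant_biomass", "plant_diversity"),
        ("plant_diversity", "herbivore_diversity"),
        ("herbivore_diversity", "predator_diversity"),
        ("plant_diversity", "predator_diversity"),
        ("time_after_mowing", "herbivore_diversity"),
        ("time_after_mowing", "predator_diversity"),
    ]
    return SEMModelSpec(
        name="rh",
        observed=_RH_OBSERVED,
        latents=(LATENT,),
        loadings=(
            Loading(LATENT, "mowing", 1.0),
            Loading(LATENT, "fertilization"),
            Loading(LATENT, "grazing"),
        ),
        paths=tuple(paths),
        transforms=tuple(t for t in _DEFAULT_TRANSFORMS if t[0] in _RH_OBSERVED),
    ).validate()


def default_ra_model() -> SEMModelSpec:
    """Resource Abundance model: RH plus the biomass-mediated route."""
    rh = default_rh_model()
    observed = rh.observed + ("herbivore_biomass", "predator_biomass")
    paths = rh.paths + (
        ("plant_biomass", "herbivore_biomass"),
        ("herbivore_biomass", "herbivore_diversity"),
        ("herbivore_biomass", "predator_biomass"),
        ("predator_biomass", "predator_diversity"),
        ("time_after_mowing", "herbivore_biomass"),
    )
    return replace(
        rh,
        name="ra",
        observed=observed,
        paths=paths,
        transforms=tuple(t for t in _DEFAULT_TRANSFORMS if t[0] in observed),
    ).validate()


@dataclass(frozen=True)
class ModelCatalog:
    """The two default concepts plus variant switches."""

    rh_spec: SEMModelSpec
    ra_spec: SEMModelSpec
    quadratic_grazing: bool = False
    abundance_instead_of_biomass: bool = False

    def validate(self) -> "ModelCatalog":
        # RA restricted to the RH variables must be the RH graph.
        rh_vars = set(self.rh_spec.observed) | set(self.rh_spec.latents)
        restricted = tuple(
            p for p in self.ra_spec.paths if p[0] in rh_vars and p[1] in rh_vars
        )
        if set(restricted) != set(self.rh_spec.paths):
            raise SpecificationError("RA model does not extend the RH model")
        if self.ra_spec.loadings != self.rh_spec.loadings:
            raise SpecificationError("RA and RH measurement models differ")
        return self


def default_catalog(**flags) -> ModelCatalog:
    return ModelCatalog(default_rh_model(), default_ra_model(), **flags).validate()


def latent_fallback(spec: SEMModelSpec) -> SEMModelSpec:
    """Replace every latent with free covariances among its indicators.

    Mirrors the convention used when a latent-variable fit does not converge:
    the anchor indicator (the one whose loading was fixed) is correlated with
    each remaining indicator, and the latent disappears.  Idempotent; a spec
    without latents is returned unchanged.
    """
    if not spec.latents:
        return spec
    covs = list(spec.covariances)
    for lat in spec.latents:
        own = [l for l in spec.loadings if l.latent == lat]
        anchors = [l.indicator for l in own if l.fixed is not None]
        anchor = anchors[0] if anchors else own[0].indicator
        for l in own:
            if l.indicator != anchor:
                covs.append((anchor, l.indicator))
    return replace(
        spec,
        name=spec.name + "_fallback",
        latents=(),
        loadings=(),
        fixed_variance_latents=(),
        covariances=tuple(covs),
    ).validate()


def with_quadratic_grazing(spec: SEMModelSpec) -> SEMModelSpec:
    """Variant adding squared grazing intensity as a further indicator.

    The squared term loads on the same latent and sends paths to the same
    targets as linear grazing; it is kept only if it lowers AICc.
    """
    if "grazing_sq" in spec.observed:
        return spec
    observed = spec.observed + ("grazing_sq",)
    loadings = spec.loadings
    if spec.latents:
        loadings = loadings + (Loading(spec.latents[0], "grazing_sq"),)
    extra = tuple(("grazing_sq", t) for (s, t) in spec.paths if s == "grazing")
    return replace(
        spec,
        name=spec.name + "_quad",
        observed=observed,
        loadings=loadings,
        paths=spec.paths + extra,
    ).validate()


# ---------------------------------------------------------------------------
# stepwise pruning


@dataclass
class PruneStep:
    deleted: tuple[str, str]
    aicc_before: float
    aicc_after: float
    p_after: float


@dataclass
class PruneTrace:
    """Audit record of a stepwise model-selection run."""

    steps: list[PruneStep]
    status: str  # "fit_adequate" | "gof_rescue" | "failed"
    used_fallback: bool = False

    @property
    def deleted_paths(self) -> list[tuple[str, str]]:
        return [s.deleted for s in self.steps]


def stepwise_prune(
    spec: SEMModelSpec,
    moments: SampleMoments,
    *,
    alpha_fit: float = 0.05,
    gof_floor: float = 0.75,
    seed: int = 0,
    trigger: str = "pvalue",
    max_steps: int = 50,
) -> tuple[FitResult, PruneTrace]:
    """Fit a model, backing off paths one at a time when the structure fails.

    With ``trigger="pvalue"`` (the default rule) deletion rounds run only
    while the overall model p-value is below ``alpha_fit``: every free
    directed path is removed in turn, each candidate refitted, and the
    deletion that most lowers AICc is accepted — if none lowers it, the
    procedure stops.  ``trigger="aicc"`` instead prunes while any single
    deletion improves AICc, which exercises the same selection machinery on
    well-fitting models.  Loadings, variances and covariances are never
    deletion candidates.  If the initial latent-variable fit does not
    converge, the latent is automatically replaced by indicator correlations
    before pruning starts.
    """
    if trigger not in ("pvalue", "aicc"):
        raise ValueError("trigger must be 'pvalue' or 'aicc'")
    current = spec
    fit = fit_ml(current, moments, seed=seed)
    used_fallback = False
    if not fit.converged and current.latents:
        current = latent_fallback(current)
        fit = fit_ml(current, moments, seed=seed)
        used_fallback = True

    steps: list[PruneStep] = []
    for _ in range(max_steps):
        if not fit.converged:
            break
        if trigger == "pvalue" and fit.model_p_value >= alpha_fit:
            break
        best = _best_single_deletion(current, moments, seed=seed, parent=fit)
        if best is None:
            break
        cand_spec, cand_fit, deleted = best
        if not (cand_fit.aicc < fit.aicc):
            break
        steps.append(
            PruneStep(deleted, fit.aicc, cand_fit.aicc, cand_fit.model_p_value)
        )
        current, fit = cand_spec, cand_fit
        if trigger == "pvalue" and fit.model_p_value >= alpha_fit:
            break

    if fit.converged and fit.model_p_value >= alpha_fit:
        status = "fit_adequate"
    elif fit.converged and fit.gof_index > gof_floor:
        status = "gof_rescue"
    else:
        status = "failed"
    return fit, PruneTrace(steps=steps, status=status, used_fallback=used_fallback)


def _best_single_deletion(
    spec: SEMModelSpec,
    moments: SampleMoments,
    *,
    seed: int,
    parent: FitResult | None = None,
):
    """Refit every single-path deletion; return the AICc-minimizing one.

    Candidate fits warm-start from the parent estimates with the deleted
    coefficient dropped.  Ties on AICc are broken toward the path with the
    smaller |z| in the parent fit, making the choice deterministic.
    """
    if parent is None:
        parent = fit_ml(spec, moments, seed=seed, compute_se=True)
    free = parent.params[~parent.params["fixed"]]
    est_by_name = dict(zip(free["name"], free["estimate"]))
    zmap = {
        (r["source"], r["target"]): abs(r["z"]) if np.isfinite(r["z"]) else np.inf
        for _, r in parent.params.iterrows()
        if r["kind"] == "path"
    }
    candidates = []
    for s, t in spec.paths:
        cand = spec.without_path(s, t)
        from .ram import build_ram  # local import avoids a cycle at module load

        cand_ram = build_ram(cand)
        x0 = np.array([est_by_name.get(p.name, 0.1) for p in cand_ram.parameters])
        fit = fit_ml(cand, moments, seed=seed, compute_se=False, x0=x0, restarts=5)
        if not fit.converged:
            continue
        candidates.append((round(fit.aicc, 10), zmap.get((s, t), np.inf), (s, t), cand, fit))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, deleted, cand, fit = candidates[0]
    return cand, fit, deleted


# ---------------------------------------------------------------------------
# total effects


@dataclass(frozen=True)
class EffectDecomposition:
    """All simple directed paths from source to target and their products."""

    source: str
    target: str
    paths: tuple[tuple[tuple[str, ...], float], ...]
    total: float

    @property
    def n_paths(self) -> int:
        return len(self.paths)


def enumerate_paths(
    spec_or_graph: SEMModelSpec | nx.DiGraph, source: str, target: str
) -> list[tuple[str, ...]]:
    """Every directed simple path from source to target, lexicographic order."""
    g = spec_or_graph.graph() if isinstance(spec_or_graph, SEMModelSpec) else spec_or_graph
    if source not in g or target not in g:
        raise KeyError(f"unknown node in ({source!r}, {target!r})")
    return sorted(tuple(p) for p in nx.all_simple_paths(g, source, target))


def total_effect_from_coefficients(
    coefficients: dict[tuple[str, str], float], source: str, target: str
) -> EffectDecomposition:
    """Total effect over an explicit edge → standardized-coefficient map.

    Useful for desk calculations from reported coefficients: the graph is
    the support of the mapping, and the total is the sum over all simple
    directed paths of the products along each path.
    """
    if source == target:
        raise ValueError("source and target must differ")
    g = nx.DiGraph()
    for (s, t), value in coefficients.items():
        g.add_edge(s, t, coefficient=value)
    if source not in g or target not in g:
        raise KeyError(f"unknown node in ({source!r}, {target!r})")
    decomposed = []
    for nodes in enumerate_paths(g, source, target):
        prod = 1.0
        for a, b in zip(nodes[:-1], nodes[1:]):
            prod *= coefficients[(a, b)]
        decomposed.append((nodes, prod))
    return EffectDecomposition(
        source=source,
        target=target,
        paths=tuple(decomposed),
        total=float(sum(p for _, p in decomposed)),
    )


def total_effect(fit: FitResult, source: str, target: str) -> EffectDecomposition:
    """Standardized total effect of source on target by path enumeration.

    Multiplies the standardized coefficients along every directed simple
    path from ``source`` to ``target`` and sums the products; loadings count
    as path edges, so latent sources are supported directly.
    """
    if source == target:
        raise ValueError("source and target must differ")
    node_paths = enumerate_paths(fit.spec, source, target)
    decomposed = []
    for nodes in node_paths:
        prod = 1.0
        for a, b in zip(nodes[:-1], nodes[1:]):
            prod *= fit.std_coefficient(a, b)
        decomposed.append((nodes, prod))
    return EffectDecomposition(
        source=source,
        target=target,
        paths=tuple(decomposed),
        total=float(sum(p for _, p in decomposed)),
    )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching the reported-table convention."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
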