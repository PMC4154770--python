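"""Declarative path-model specifications with optional latent variables.

A :class:`SEMModelSpec` is the in-memory form of a path diagram: a set of
observed variables, zero or more latent variables measured through loadings,
directed structural paths, and free covariances between exogenous variables.
Latents are identified by fixing exactly one loading (conventionally to 1) or
by fixing the latent variance; only the fixed-loading convention is used by
the shipped model catalog.

Specs serialize to a small line-oriented text format::

    model rh
    observed mowing fertilization grazing plant_biomass
    latent LandUse =~ mowing@1 + fertilization + grazing
    path mowing -> plant_biomass
    cov mowing ~~ fertilization
    transform plant_biomass log1p

``parse_spec(serialize_spec(spec)) == spec`` holds bit-exactly for canonical
text, which the result tables rely on for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "Loading",
    "SEMModelSpec",
    "SpecificationError",
    "parse_spec",
    "serialize_spec",
]

_TRANSFORMS = ("identity", "log1p")


class SpecificationError(ValueError):
    """Raised when a model specification is malformed or unidentifiable."""


@dataclass(frozen=True)
class Loading:
    """A latent → indicator measurement edge.

    ``fixed`` is ``None`` for a freely estimated loading, otherwise the
    constant the loading is pinned to (1.0 anchors the latent's scale).
    """

    latent: str
    indicator: str
    fixed: float | None = None


@dataclass(frozen=True)
class SEMModelSpec:
    """Immutable declarative path model.

    Parameters
    ----------
    name
        Identifier used in result tables and serialized specs.
    observed
        Observed variables in fitting order (the covariance-matrix order).
    latents
        Latent variable names, disjoint from ``observed``.
    loadings
        Measurement edges; each latent needs at least one loading and exactly
        one fixed loading unless its variance is fixed via
        ``fixed_variance_latents``.
    paths
        Directed structural edges ``(source, target)``; the structural graph
        must be acyclic.
    covariances
        Free covariances between pairs of variables (exogenous residuals).
    transforms
        Per-observed-variable transform tag (``identity`` or ``log1p``)
        applied before z-standardization and covariance computation.
    """

    name: str
    observed: tuple[str, ...]
    latents: tuple[str, ...] = ()
    loadings: tuple[Loading, ...] = ()
    paths: tuple[tuple[str, str], ...] = ()
    covariances: tuple[tuple[str, str], ...] = ()
    fixed_variance_latents: tuple[str, ...] = ()
    transforms: tuple[tuple[str, str], ...] = field(default=())

    # -- derived views ----------------------------------------------------

    @property
    def variables(self) -> tuple[str, ...]:
        """All variables, observed first, in fitting order."""
        return self.observed + self.latents

    def edges(self) -> list[tuple[str, str]]:
        """Directed edges of the path diagram (loadings then paths)."""
        return [(l.latent, l.indicator) for l in self.loadings] + list(self.paths)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges())
        return g

    def transform_of(self, var: str) -> str:
        return dict(self.transforms).get(var, "identity")

    def validate(self) -> "SEMModelSpec":
        """Check structural invariants; return self for chaining."""
        names = self.variables
        if len(set(names)) != len(names):
            raise SpecificationError("duplicate variable names")
        known = set(names)
        for l in self.loadings:
            if l.latent not in self.latents:
                raise SpecificationError(f"loading from unknown latent {l.latent!r}")
            if l.indicator not in known:
                raise SpecificationError(f"loading onto unknown variable {l.indicator!r}")
        for s, t in self.paths:
            if s not in known or t not in known:
                raise SpecificationError(f"path {s!r} -> {t!r} uses unknown variable")
        if len(set(self.paths)) != len(self.paths):
            raise SpecificationError("duplicate path declared")
        if len(set(self.covariances)) != len(self.covariances):
            raise SpecificationError("duplicate covariance declared")
        for a, b in self.covariances:
            if a not in known or b not in known:
                raise SpecificationError(f"covariance {a!r} ~~ {b!r} uses unknown variable")
            if a == b:
                raise SpecificationError("covariance must link two distinct variables")
        for var, tag in self.transforms:
            if var not in self.observed:
                raise SpecificationError(f"transform targets unknown variable {var!r}")
            if tag not in _TRANSFORMS:
                raise SpecificationError(f"unknown transform {tag!r}")
        # Latent scale: exactly one fixed loading, or the variance is fixed.
        for lat in self.latents:
            fixed = [l for l in self.loadings if l.latent == lat and l.fixed is not None]
            if lat in self.fixed_variance_latents:
                if fixed:
                    raise SpecificationError(
                        f"latent {lat!r} has both a fixed variance and a fixed loading"
                    )
            elif len(fixed) != 1:
                raise SpecificationError(
                    f"latent {lat!r} needs exactly one fixed loading or a fixed variance"
                )
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise SpecificationError("structural graph contains a cycle")
        return self

    # -- convenience edits -------------------------------------------------

    def without_path(self, source: str, target: str) -> "SEMModelSpec":
        if (source, target) not in self.paths:
            raise SpecificationError(f"no path {source!r} -> {target!r} to delete")
        return replace(
            self,
            paths=tuple(p for p in self.paths if p != (source, target)),
        )

    def with_name(self, name: str) -> "SEMModelSpec":
        return replace(self, name=name)


# ---------------------------------------------------------------------------
# text format


def serialize_spec(spec: SEMModelSpec) -> str:
    """Render a spec in the canonical line-oriented text format."""
    lines = [f"model {spec.name}", "observed " + " ".join(spec.observed)]
    for lat in spec.latents:
        terms = []
        for l in spec.loadings:
            if l.latent != lat:
                continue
            if l.fixed is None:
                terms.append(l.indicator)
            else:
                terms.append(f"{l.indicator}@{l.fixed:g}")
        lines.append(f"latent {lat} =~ " + " + ".join(terms))
    for lat in spec.fixed_variance_latents:
        lines.append(f"fixvar {lat}")
    for s, t in spec.paths:
        lines.append(f"path {s} -> {t}")
    for a, b in spec.covariances:
        lines.append(f"cov {a} ~~ {b}")
    for var, tag in spec.transforms:
        lines.append(f"transform {var} {tag}")
    return "\n".join(lines) + "\n"


def parse_spec(text: str) -> SEMModelSpec:
    """Parse the text format produced by :func:`serialize_spec`."""
    name = "model"
    observed: list[str] = []
    latents: list[str] = []
    loadings: list[Loading] = []
    fixvar: list[str] = []
    paths: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    transforms: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        head, _, rest = line.partition(" ")
        try:
            if head == "model":
                name = rest.strip()
            elif head == "observed":
                observed.extend(rest.split())
            elif head == "latent":
                lat, _, terms = rest.partition("=~")
                lat = lat.strip()
                latents.append(lat)
                for term in terms.split("+"):
                    term = term.strip()
                    if "@" in term:
                        ind, val = term.split("@")
                        loadings.append(Loading(lat, ind.strip(), float(val)))
                    else:
                        loadings.append(Loading(lat, term))
            elif head == "fixvar":
                fixvar.append(rest.strip())
            elif head == "path":
                s, _, t = rest.partition("->")
                paths.append((s.strip(), t.strip()))
            elif head == "cov":
                a, _, b = rest.partition("~~")
                covs.append((a.strip(), b.strip()))
            elif head == "transform":
                var, tag = rest.split()
                transforms.append((var, tag))
            else:
                raise SpecificationError(f"unknown directive {head!r}")
        except SpecificationError:
            raise
        except Exception as exc:  # malformed numeric literal etc.
            raise SpecificationError(f"line {lineno}: cannot parse {line!r}") from exc
    return SEMModelSpec(
        name=name,
        observed=tuple(observed),
        latents=tuple(latents),
        loadings=tuple(loadings),
        paths=tuple(paths),
        covariances=tuple(covs),
        fixed_variance_latents=tuple(fixvar),
        transforms=tuple(transforms),
    ).validate()
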