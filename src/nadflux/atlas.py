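"""Atom maps for NAD+ biosynthesis routes and expected isotopologue shifts.

The atlas encodes the metabolites and atom transitions of the three routes by
which mammalian tissues (and the gut microbiome) make NAD+:

* **de novo / kynurenine pathway** — tryptophan → N-formylkynurenine →
  kynurenine → 3-hydroxykynurenine → 3-hydroxyanthranilic acid → quinolinic
  acid → NAD+ (one carbon leaves as formate at the formamidase step, three as
  alanine at the kynureninase step, one as CO2 at the QPRT step);
* **salvage** — nicotinamide (NAM) → NAD+ via NAMPT (phosphorylated
  intermediates lumped), with the reverse NAD+ → NAM consumption step closing
  the recycling loop;
* **Preiss-Handler / microbial** — host-derived NAM is deamidated to nicotinic
  acid (NA) by bacterial PncA in the gut lumen, and NA feeds back into NAD+.

Given a tracer — uniformly 13C-labeled tryptophan (M+11) or 2,4,5,6-deuterated
nicotinamide (M+4) — the atlas predicts the nominal mass shift of every
downstream product by walking the transition graph and counting how many heavy
atoms survive each step.  The single chemistry-specific wrinkle is the
redox-active 4-position deuterium of the NAM tracer: it is lost exactly once,
at the incorporation of NAM into NAD+, so the M+4 tracer yields M+3 NAD+ and
recycled M+3 NAM, which keeps its remaining three deuteria through any further
salvage round.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TracerSpec",
    "MetaboliteSpec",
    "AtomTransition",
    "PathwayMap",
    "AtlasError",
    "UnknownMetaboliteError",
    "NoRouteError",
    "AmbiguousRouteError",
    "LabelState",
    "parse_formula",
    "expected_shift",
    "expected_shifts",
    "monitored_isotopologues",
    "validate_map",
    "default_map",
    "default_tracers",
    "path_shift_map",
    "write_atlas",
    "read_atlas",
]


class AtlasError(Exception):
    """Base class for atlas lookup failures."""


class UnknownMetaboliteError(AtlasError):
    """Metabolite id not in atlas."""


class NoRouteError(AtlasError):
    """Metabolite not reachable from the tracer's entry point."""


class AmbiguousRouteError(AtlasError):
    """Several routes reach the metabolite with different shifts."""


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C10H12N2O3`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"malformed formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"malformed formula {formula!r}")
    return counts


@dataclass(frozen=True)
class TracerSpec:
    """An infused labeled precursor.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"13C11-Trp"``.
    element : {"C", "H"}
        Element carrying the heavy label.
    n_heavy : int
        Heavy atoms in the intact infused molecule (11 for U-13C-Trp,
        4 for 2,4,5,6-2H-NAM).
    entry_metabolite : str
        Atlas id of the infused molecule.
    redox_site_loss : int
        Heavy atoms lost upon incorporation into NAD+ (1 for the d4-NAM
        tracer's redox-active 4-2H, 0 for 13C-Trp).
    purity : float
        Isotopic enrichment per heavy position, in (0, 1].
    """

    name: str
    element: str
    n_heavy: int
    entry_metabolite: str
    redox_site_loss: int = 0
    purity: float = 0.99

    def __post_init__(self) -> None:
        if self.element not in ("C", "H"):
            raise ValueError(f"tracer element must be C or H, got {self.element!r}")
        if not 0 <= self.redox_site_loss <= self.n_heavy:
            raise ValueError("redox_site_loss must be within [0, n_heavy]")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


@dataclass(frozen=True)
class MetaboliteSpec:
    id: str
    element_counts: Mapping[str, int]
    pathway_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.element_counts.values()):
            raise ValueError(f"{self.id}: negative element count")


@dataclass(frozen=True)
class AtomTransition:
    """One atom-mapped step: how many atoms of each element the product keeps."""

    substrate: str
    product: str
    atoms_retained: Mapping[str, int]
    route: str
    redox_incorporation: bool = False
    requires_prior_nad: bool = False


@dataclass
class PathwayMap:
    metabolites: dict[str, MetaboliteSpec]
    transitions: list[AtomTransition]
    tracers: dict[str, TracerSpec] = field(default_factory=dict)
    #: optional (tracer name, metabolite id) -> reported shift overrides, for
    #: metabolites whose conventionally reported shift differs from the
    #: structural atom count (e.g. 3HAA reported at M+6 with 7 retained carbons)
    overrides: dict[tuple[str, str], int] = field(default_factory=dict)

    def metabolite(self, met_id: str) -> MetaboliteSpec:
        try:
            return self.metabolites[met_id]
        except KeyError:
            raise UnknownMetaboliteError(f"{met_id!r} not in atlas") from None

    def transitions_from(self, met_id: str) -> list[AtomTransition]:
        return [t for t in self.transitions if t.substrate == met_id]


@dataclass(frozen=True)
class LabelState:
    """A labeled species during a graph walk.

    ``redox_intact`` records whether the tracer's redox-site heavy atom is
    still present; ``via_nad`` whether the path has passed through NAD+
    (host-recycled material), which gates the microbial NAM→NA step.
    """

    metabolite: str
    shift: int
    redox_intact: bool = True
    via_nad: bool = False

    def apply(self, t: AtomTransition, tracer: TracerSpec) -> "LabelState":
        shift = min(self.shift, t.atoms_retained.get(tracer.element, 0))
        redox = self.redox_intact
        if t.redox_incorporation and redox and tracer.redox_site_loss:
            shift = max(shift - tracer.redox_site_loss, 0)
            redox = False
        return LabelState(
            metabolite=t.product,
            shift=shift,
            redox_intact=redox,
            via_nad=self.via_nad or t.product == "NAD+",
        )


def _walk(tracer: TracerSpec, pmap: PathwayMap):
    """Enumerate reachable (metabolite, shift) pairs with their route paths.

    Returns dict metabolite -> dict shift -> route tuple (routes of the
    transitions along the first/shortest path that produced the shift).
    """
    pmap.metabolite(tracer.entry_metabolite)
    start = LabelState(tracer.entry_metabolite, tracer.n_heavy)
    reached: dict[str, dict[int, tuple[str, ...]]] = {
        start.metabolite: {start.shift: ()}
    }
    seen = {start}
    queue: deque[tuple[LabelState, tuple[str, ...]]] = deque([(start, ())])
    while queue:
        state, routes = queue.popleft()
        for t in pmap.transitions_from(state.metabolite):
            if t.requires_prior_nad and not state.via_nad:
                continue
            nxt = state.apply(t, tracer)
            if nxt in seen:
                continue
            seen.add(nxt)
            shifts = reached.setdefault(nxt.metabolite, {})
            shifts.setdefault(nxt.shift, routes + (t.route,))
            queue.append((nxt, routes + (t.route,)))
    return reached


def expected_shifts(
    tracer: TracerSpec, metabolite: str, pmap: PathwayMap
) -> dict[int, tuple[str, ...]]:
    """All nominal shifts of ``metabolite`` reachable from the tracer.

    Returns a mapping shift -> tuple of route labels traversed (empty tuple
    for the intact infused molecule itself).
    """
    pmap.metabolite(metabolite)
    reached = _walk(tracer, pmap)
    if metabolite not in reached:
        raise NoRouteError(
            f"no route from {tracer.entry_metabolite} to {metabolite} "
            f"for tracer {tracer.name}"
        )
    return dict(sorted(reached[metabolite].items()))


def expected_shift(
    tracer: TracerSpec,
    metabolite: str,
    pmap: PathwayMap,
    route: str | None = None,
) -> int:
    """Nominal mass shift of ``metabolite`` under ``tracer``.

    When several routes reach the metabolite with different shifts (e.g. NAM
    as intact infusate M+4 vs NAD+-recycled M+3), pass ``route`` to pick one:
    it matches any route label on the path, or ``"infusate"`` for the intact
    infused molecule.  Per-metabolite overrides on the map win over the
    structural count.
    """
    if (tracer.name, metabolite) in pmap.overrides:
        return pmap.overrides[(tracer.name, metabolite)]
    if tracer.n_heavy == 0:
        pmap.metabolite(metabolite)  # raises if unknown
        return 0
    shifts = expected_shifts(tracer, metabolite, pmap)
    if route is None:
        if metabolite == tracer.entry_metabolite:
            return tracer.n_heavy
        if len(shifts) == 1:
            return next(iter(shifts))
        raise AmbiguousRouteError(
            f"{metabolite} reachable with shifts {sorted(shifts)}; "
            "pass route= to disambiguate"
        )
    if route == "infusate":
        if metabolite != tracer.entry_metabolite:
            raise NoRouteError(f"{metabolite} is not the infused molecule")
        return tracer.n_heavy
    matching = {s for s, routes in shifts.items() if route in routes}
    if not matching:
        raise NoRouteError(f"no {route!r} route to {metabolite}")
    if len(matching) > 1:
        raise AmbiguousRouteError(
            f"route {route!r} reaches {metabolite} with shifts {sorted(matching)}"
        )
    return matching.pop()


def monitored_isotopologues(
    tracer: TracerSpec, pmap: PathwayMap
) -> dict[str, list[int]]:
    """Shifts the pipeline should extract for each reachable metabolite.

    Always includes M+0 alongside every expected labeled shift; drives both
    extraction and the simulator's labeled-species state space.
    """
    if not pmap.metabolites:
        return {}
    reached = _walk(tracer, pmap)
    return {
        met: sorted({0} | {s for s in shifts if s > 0})
        for met, shifts in sorted(reached.items())
    }


def validate_map(pmap: PathwayMap) -> list[str]:
    """Check atlas invariants; returns a list of human-readable violations."""
    problems: list[str] = []
    for met in pmap.metabolites.values():
        if any(v < 0 for v in met.element_counts.values()):
            problems.append(f"{met.id}: negative element count")
        if met.element_counts.get("C", 0) <= 0:
            problems.append(f"{met.id}: organic metabolite without carbon")
    for t in pmap.transitions:
        for end in (t.substrate, t.product):
            if end not in pmap.metabolites:
                problems.append(f"transition {t.substrate}->{t.product}: "
                                f"unknown metabolite {end!r}")
        for elem, n in t.atoms_retained.items():
            for end in (t.substrate, t.product):
                if end in pmap.metabolites:
                    have = pmap.metabolites[end].element_counts.get(elem, 0)
                    if n > have:
                        problems.append(
                            f"transition {t.substrate}->{t.product}: retains "
                            f"{n} {elem} but {end} has only {have}"
                        )
    # each named route must be acyclic on its own edge set
    for route in {t.route for t in pmap.transitions}:
        edges = [(t.substrate, t.product) for t in pmap.transitions
                 if t.route == route]
        if _has_cycle(edges):
            problems.append(f"route {route!r} contains a cycle")
    for tracer in pmap.tracers.values():
        if tracer.entry_metabolite not in pmap.metabolites:
            problems.append(
                f"tracer {tracer.name}: entry {tracer.entry_metabolite!r} "
                "not in atlas"
            )
    return problems


def _has_cycle(edges: Iterable[tuple[str, str]]) -> bool:
    adj: dict[str, list[str]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node: str) -> bool:
        color[node] = GRAY
        for nb in adj.get(node, ()):
            c = color.get(nb, WHITE)
            if c == GRAY or (c == WHITE and visit(nb)):
                return True
        color[node] = BLACK
        return False

    return any(color.get(n, WHITE) == WHITE and visit(n) for n in list(adj))


def path_shift_map(pmap: PathwayMap, substrate: str, product: str, route: str):
    """Composite label mapping along one named route from substrate to product.

    Returns ``f(shift, redox_intact) -> (shift, redox_intact)`` obtained by
    chaining the route's atom transitions, used by the simulator for lumped
    fluxes (e.g. Trp → Kyn across the formamidase step).  Raises NoRouteError
    if the route does not connect the two metabolites.
    """
    steps = _route_path(pmap, substrate, product, route)

    def apply(shift: int, redox_intact: bool, tracer: TracerSpec):
        state = LabelState(substrate, shift, redox_intact)
        for t in steps:
            state = state.apply(t, tracer)
        return state.shift, state.redox_intact

    return apply


def _route_path(
    pmap: PathwayMap, substrate: str, product: str, route: str
) -> list[AtomTransition]:
    queue: deque[tuple[str, list[AtomTransition]]] = deque([(substrate, [])])
    visited = {substrate}
    while queue:
        node, path = queue.popleft()
        if node == product:
            return path
        for t in pmap.transitions_from(node):
            if t.route == route and t.product not in visited:
                visited.add(t.product)
                queue.append((t.product, path + [t]))
    raise NoRouteError(f"no {route!r} path {substrate} -> {product}")


# ---------------------------------------------------------------------------
# shipped atlas


def _fmt_retained(retained: Mapping[str, int]) -> str:
    return ";".join(f"{e}={n}" for e, n in sorted(retained.items()))


def _parse_retained(text: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for part in text.split(";"):
        elem, _, n = part.partition("=")
        out[elem.strip()] = int(n)
    return out


def read_atlas(metabolites_path, transitions_path) -> PathwayMap:
    """Read an atlas from the two flat CSV tables (see ``write_atlas``)."""
    # keep_default_na: nicotinic acid's id "NA" must stay a string
    mets = pd.read_csv(metabolites_path, keep_default_na=False)
    trans = pd.read_csv(transitions_path, keep_default_na=False)
    metabolites = {
        row.id: MetaboliteSpec(
            id=row.id,
            element_counts=parse_formula(row.formula),
            pathway_tags=frozenset(str(row.pathway_tags).split(";")),
        )
        for row in mets.itertuples()
    }
    transitions = [
        AtomTransition(
            substrate=row.substrate,
            product=row.product,
            atoms_retained=_parse_retained(row.atoms_retained),
            route=row.route,
            redox_incorporation=str(row.redox_incorporation).lower() == "true",
            requires_prior_nad=str(row.requires_prior_nad).lower() == "true",
        )
        for row in trans.itertuples()
    ]
    return PathwayMap(metabolites=metabolites, transitions=transitions,
                      tracers=default_tracers())


def write_atlas(pmap: PathwayMap, metabolites_path, transitions_path) -> None:
    """Serialize an atlas to two flat UTF-8 CSV tables."""
    def fmt_formula(counts: Mapping[str, int]) -> str:
        order = ["C", "H"] + sorted(set(counts) - {"C", "H"})
        return "".join(
            f"{e}{counts[e] if counts[e] != 1 else ''}"
            for e in order if counts.get(e)
        )

    pd.DataFrame(
        {
            "id": [m.id for m in pmap.metabolites.values()],
            "formula": [fmt_formula(m.element_counts)
                        for m in pmap.metabolites.values()],
            "pathway_tags": [";".join(sorted(m.pathway_tags))
                             for m in pmap.metabolites.values()],
        }
    ).to_csv(metabolites_path, index=False)
    pd.DataFrame(
        {
            "substrate": [t.substrate for t in pmap.transitions],
            "product": [t.product for t in pmap.transitions],
            "route": [t.route for t in pmap.transitions],
            "atoms_retained": [_fmt_retained(t.atoms_retained)
                               for t in pmap.transitions],
            "redox_incorporation": [t.redox_incorporation
                                    for t in pmap.transitions],
            "requires_prior_nad": [t.requires_prior_nad
                                   for t in pmap.transitions],
        }
    ).to_csv(transitions_path, index=False)


def default_tracers() -> dict[str, TracerSpec]:
    """The two tracers of the infusion study."""
    return {
        "13C11-Trp": TracerSpec(
            name="13C11-Trp", element="C", n_heavy=11,
            entry_metabolite="Trp", redox_site_loss=0,
        ),
        "2H4-NAM": TracerSpec(
            name="2H4-NAM", element="H", n_heavy=4,
            entry_metabolite="NAM", redox_site_loss=1,
        ),
    }


def default_map() -> PathwayMap:
    """The shipped atlas (kynurenine, salvage, and microbial NA routes)."""
    data = resources.files("nadflux").joinpath("data")
    with resources.as_file(data.joinpath("atlas_metabolites.csv")) as mp, \
            resources.as_file(data.joinpath("atlas_transitions.csv")) as tp:
        return read_atlas(mp, tp)
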