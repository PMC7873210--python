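"""Icosahedral two-component architecture: building blocks, contact graph, species.

The I53 design family builds a 120-subunit icosahedral shell from 20 trimeric
(T3) and 12 pentameric (P5) building blocks joined by a single designed
trimer–pentamer interface.  The contact graph is the face–vertex incidence
structure of a regular icosahedron: faces are trimers (degree 3), vertices are
pentamers (degree 5), and the 60 edges are the heteromeric contacts.  Neither
trimer–trimer nor pentamer–pentamer contacts exist in the architecture.

The equilibrium model (see :mod:`nanocage.equilibrium`) is parameterized per
assembly species by its building-block composition (a trimers, b pentamers),
its contact count c (multiplier of the per-contact energy in the Boltzmann
factor) and its symmetry number s (rotational degeneracy divisor).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ComponentSpec",
    "ArchitectureSpec",
    "SpeciesSpec",
    "build_default_architecture",
    "default_species_table",
    "max_trimeric_voids",
    "species_table_to_dicts",
    "species_table_from_dicts",
]

MwClass = Literal["high", "low"]
Role = Literal["complete", "late_intermediate", "early_intermediate", "free"]


@dataclass(frozen=True)
class ComponentSpec:
    """One oligomeric building block of a two-component architecture.

    Parameters
    ----------
    name:
        Short label, conventionally ``"T"`` (trimer) or ``"P"`` (pentamer).
    oligomer_size:
        Monomers per building block (3 for a trimer, 5 for a pentamer).
    copies_complete:
        Building blocks per complete assembly (20 trimers / 12 pentamers).
    monomer_mw:
        Monomer molecular weight in kDa (used for mass-weighted fractions).
    extinction:
        Molar absorptivity at 280 nm per monomer, 1/(M cm).
    """

    name: str
    oligomer_size: int
    copies_complete: int
    monomer_mw: float = 0.0
    extinction: float = 1.0

    def __post_init__(self) -> None:
        if self.oligomer_size < 1:
            raise ValueError("oligomer_size must be >= 1")
        if self.copies_complete < 1:
            raise ValueError("copies_complete must be >= 1")
        if self.extinction <= 0:
            raise ValueError("extinction must be positive")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A complete two-component architecture and its heteromeric contact graph.

    ``contact_edges`` holds (trimer_index, pentamer_index) pairs; indices run
    over 0..copies_complete-1 for each component.
    """

    components: tuple[ComponentSpec, ComponentSpec]
    contact_edges: tuple[tuple[int, int], ...]

    @property
    def trimer(self) -> ComponentSpec:
        return self.components[0]

    @property
    def pentamer(self) -> ComponentSpec:
        return self.components[1]

    @property
    def total_contacts(self) -> int:
        return len(self.contact_edges)

    @property
    def total_monomers(self) -> int:
        t, p = self.components
        return t.oligomer_size * t.copies_complete + p.oligomer_size * p.copies_complete

    def trimer_degrees(self) -> dict[int, int]:
        deg = {i: 0 for i in range(self.trimer.copies_complete)}
        for t, _ in self.contact_edges:
            deg[t] += 1
        return deg

    def pentamer_degrees(self) -> dict[int, int]:
        deg = {i: 0 for i in range(self.pentamer.copies_complete)}
        for _, p in self.contact_edges:
            deg[p] += 1
        return deg

    def validate(self) -> None:
        """Check the regular incidence structure (degrees 3 and 5, connected)."""
        tdeg = self.trimer_degrees()
        pdeg = self.pentamer_degrees()
        if any(d != self.trimer.oligomer_size for d in tdeg.values()):
            raise ValueError("every trimer node must have exactly 3 contacts")
        if any(d != self.pentamer.oligomer_size for d in pdeg.values()):
            raise ValueError("every pentamer node must have exactly 5 contacts")
        if not _is_connected(self):
            raise ValueError("contact graph must be connected")

    def to_json(self) -> str:
        return json.dumps(
            {
                "components": [asdict(c) for c in self.components],
                "edges": [list(e) for e in self.contact_edges],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        obj = json.loads(text)
        comps = tuple(ComponentSpec(**c) for c in obj["components"])
        edges = tuple((int(t), int(p)) for t, p in obj["edges"])
        return cls(components=comps, contact_edges=edges)  # type: ignore[arg-type]


def _is_connected(arch: ArchitectureSpec) -> bool:
    # BFS over the bipartite contact graph
    nt = arch.trimer.copies_complete
    adj: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for t, p in arch.contact_edges:
        adj.setdefault(("t", t), []).append(("p", p))
        adj.setdefault(("p", p), []).append(("t", t))
    n_nodes = nt + arch.pentamer.copies_complete
    if not adj:
        return n_nodes <= 1
    seen = {next(iter(adj))}
    stack = list(seen)
    while stack:
        for nb in adj.get(stack.pop(), []):
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == n_nodes


@dataclass(frozen=True)
class SpeciesSpec:
    """One assembly species T_{3a}P_{5b} of the equilibrium model.

    ``n_trimers``/``n_pentamers`` count building blocks (not monomers); the
    conventional label uses monomer counts, e.g. the single-trimeric-void
    intermediate with 19 trimers and 12 pentamers is ``T57P60``.  ``contacts``
    is the number of trimer–pentamer contacts c present in the partial
    structure; ``symmetry`` is the rotational order s of the structure, used
    as a degeneracy divisor in its mass-action law.
    """

    species_id: str
    n_trimers: int
    n_pentamers: int
    contacts: int
    symmetry: int
    mw_class: MwClass
    role: Role = "late_intermediate"

    def __post_init__(self) -> None:
        if not (0 <= self.n_trimers <= 20 and 0 <= self.n_pentamers <= 12):
            raise ValueError("building-block counts outside the I53 range")
        if self.symmetry < 1:
            raise ValueError("symmetry must be >= 1")
        if self.n_trimers and self.n_pentamers:
            if self.contacts < max(self.n_trimers, self.n_pentamers) - 1:
                raise ValueError("too few contacts for a connected species")


# Default species set of the inclusive model: the complete cage, the three
# late (nearly complete) intermediates, and the five smallest early ones.
# Contact counts / symmetry numbers for T60P60, T57P60, T3P5 follow their
# published closed forms; the rest are the combinatorial values for the
# corresponding partial structures and can be overridden via configuration.
_DEFAULT_SPECIES: tuple[tuple[str, int, int, int, int, str, str], ...] = (
    ("T60P60", 20, 12, 60, 60, "high", "complete"),
    ("T60P55", 20, 11, 55, 5, "high", "late_intermediate"),
    ("T57P60", 19, 12, 57, 3, "high", "late_intermediate"),
    ("T54P60", 18, 12, 54, 1, "high", "late_intermediate"),
    ("T6P10", 2, 2, 3, 1, "low", "early_intermediate"),
    ("T6P5", 2, 1, 2, 1, "low", "early_intermediate"),
    ("T3P15", 1, 3, 3, 3, "low", "early_intermediate"),
    ("T3P10", 1, 2, 2, 1, "low", "early_intermediate"),
    ("T3P5", 1, 1, 1, 1, "low", "early_intermediate"),
)


def default_species_table(model: str = "inclusive") -> list[SpeciesSpec]:
    """Species set of the simplified or inclusive equilibrium model.

    ``simplified`` keeps only the complete T60P60 cage (plus free components,
    which are bookkept separately, not as species).  ``inclusive`` adds the
    three late and five early on-pathway intermediates.
    """
    if model not in ("simplified", "inclusive"):
        raise ValueError(f"unknown model {model!r}; use 'simplified' or 'inclusive'")
    rows = _DEFAULT_SPECIES[:1] if model == "simplified" else _DEFAULT_SPECIES
    return [SpeciesSpec(*row) for row in rows]  # type: ignore[arg-type]


def species_table_to_dicts(table: Sequence[SpeciesSpec]) -> list[dict]:
    return [asdict(s) for s in table]


def species_table_from_dicts(rows: Sequence[dict]) -> list[SpeciesSpec]:
    return [SpeciesSpec(**{k: v for k, v in row.items()}) for row in rows]


def _icosahedron_incidence() -> tuple[tuple[int, int], ...]:
    """Face–vertex incidence of the regular icosahedron.

    Vertices from the cyclic (0, ±1, ±phi) coordinates; edges join vertex
    pairs at the minimum distance; faces are the 3-cliques.  Returns
    (face_index, vertex_index) pairs in deterministic order.
    """
    phi = (1 + np.sqrt(5)) / 2
    verts = []
    for a, b in itertools.product((1.0, -1.0), repeat=2):
        verts.append((0.0, a, b * phi))
        verts.append((a, b * phi, 0.0))
        verts.append((a * phi, 0.0, b))
    v = np.array(verts)
    d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(-1)
    edge_len2 = np.min(d2[d2 > 1e-9])
    adj = (np.abs(d2 - edge_len2) < 1e-9)
    faces = []
    for i, j, k in itertools.combinations(range(12), 3):
        if adj[i, j] and adj[j, k] and adj[i, k]:
            faces.append((i, j, k))
    assert len(faces) == 20
    incidence = []
    for fi, face in enumerate(sorted(faces)):
        for vi in face:
            incidence.append((fi, vi))
    return tuple(incidence)


def build_default_architecture(
    monomer_mw_t: float = 0.0,
    monomer_mw_p: float = 0.0,
    extinction_t: float = 20_000.0,
    extinction_p: float = 15_000.0,
) -> ArchitectureSpec:
    """The I53 architecture: 20 trimers, 12 pentamers, 60 heteromeric contacts.

    The contact graph is realized combinatorially as the face–vertex incidence
    of a regular icosahedron; no 3D coordinates are retained.  The default
    extinction coefficients are synthetic placeholders (per-monomer, 1/(M cm))
    — real systems supply their own via configuration.
    """
    arch = ArchitectureSpec(
        components=(
            ComponentSpec("T", 3, 20, monomer_mw_t, extinction_t),
            ComponentSpec("P", 5, 12, monomer_mw_p, extinction_p),
        ),
        contact_edges=_icosahedron_incidence(),
    )
    arch.validate()
    return arch


def max_trimeric_voids(
    architecture: ArchitectureSpec, min_contacts: int
) -> tuple[int, tuple[int, ...]]:
    """Maximum number of trimers removable while every pentamer keeps contacts.

    Finds, by depth-first branch and bound over trimer subsets, the largest
    set of trimer nodes whose removal leaves every pentamer with at least
    ``min_contacts`` incident contact edges.  Returns the maximum count and
    one witness subset of trimer indices.

    With ``min_contacts=3`` on the default icosahedral graph the counting
    bound is floor(12*(5-3)/3) = 8, and 8 is attained (two vertex-disjoint
    tetrads of faces) — see the package documentation for how this relates
    to the topological void capacity of the architecture.
    """
    if not (0 <= min_contacts <= architecture.pentamer.oligomer_size):
        raise ValueError("min_contacts out of range")
    n_t = architecture.trimer.copies_complete
    n_p = architecture.pentamer.copies_complete
    # capacity[p]: contacts pentamer p may still lose
    pdeg = architecture.pentamer_degrees()
    base_capacity = [pdeg[p] - min_contacts for p in range(n_p)]
    if min(base_capacity) < 0:
        raise ValueError("architecture already violates min_contacts")
    touched = [tuple(p for t, p in architecture.contact_edges if t == ti) for ti in range(n_t)]

    best_count = 0
    best_subset: tuple[int, ...] = ()

    def dfs(start: int, capacity: list[int], chosen: list[int]) -> None:
        nonlocal best_count, best_subset
        if len(chosen) > best_count:
            best_count = len(chosen)
            best_subset = tuple(chosen)
        # bound: total remaining capacity limits further removals
        if len(chosen) + sum(capacity) // architecture.trimer.oligomer_size <= best_count:
            return
        for ti in range(start, n_t):
            ps = touched[ti]
            if all(capacity[p] >= 1 for p in ps):
                for p in ps:
                    capacity[p] -= 1
                chosen.append(ti)
                dfs(ti + 1, capacity, chosen)
                chosen.pop()
                for p in ps:
                    capacity[p] += 1

    dfs(0, list(base_capacity), [])
    return best_count, best_subset
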