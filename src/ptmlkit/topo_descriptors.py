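"""Topological indices: bond-based spectral moments and connectivity (chi) indices.

Two descriptor families are computed on the hydrogen-suppressed graph:

* **Spectral moments** ``SM(w)k``: the trace of the k-th power of the
  bond-adjacency matrix — the NB x NB matrix with 1 at (i, j) when bonds i
  and j share an atom and the physicochemical bond weight of scheme ``w``
  on the diagonal.  ``SM(w)0`` is NB itself.

* **Connectivity (chi) indices** by subgraph class and order: for each
  connected edge-subgraph of a given class (P path, C cluster, PC
  path-cluster, Ch chain/ring) and order m (number of edges), a term
  ``(prod x)^(-1/2)`` is accumulated, where x runs over the subgraph's
  vertex degrees (atom form, ``X``), valence deltas (valence form, ``Xv``)
  or edge degrees (bond form, ``e``), all taken in the parent graph.

Each raw index TI also has an NB-normalized companion NTI = TI / NB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .chem_graph import MolecularGraph, WeightScheme, assign_weights, builtin_scheme

__all__ = [
    "SubgraphClass",
    "TopoIndexSet",
    "bond_adjacency_matrix",
    "spectral_moment",
    "enumerate_subgraphs",
    "classify_subgraph",
    "chi_atom",
    "chi_bond",
    "descriptor_vector",
    "DescriptorConfig",
    "default_descriptor_names",
]

logger = logging.getLogger(__name__)


class SubgraphClass(str, Enum):
    """Connectivity-index subgraph taxonomy.

    P (path): acyclic, every vertex of subgraph-degree <= 2.
    C (cluster): acyclic tree with a branch vertex and no degree-2 vertex.
    PC (path-cluster): acyclic tree with both a branch vertex and a
    degree-2 (chain) vertex.
    Ch (chain/ring): contains a cycle.  An order-m chain subgraph is
    counted only when the cycle has exactly m edges, i.e. the subgraph is
    the m-ring itself.
    """

    P = "P"
    C = "C"
    PC = "PC"
    Ch = "Ch"


@dataclass
class TopoIndexSet:
    """Named TI/NTI values for one molecule, plus the NB used to normalize."""

    smiles: str
    nb: int
    values: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)


# ---------------------------------------------------------------------------
# Spectral moments
# ---------------------------------------------------------------------------


def bond_adjacency_matrix(graph: MolecularGraph, scheme_id: str) -> np.ndarray:
    """NB x NB bond-adjacency (line-graph) matrix with weights on the diagonal.

    Off-diagonal entry (i, j) is 1 when bonds i and j share an atom;
    diagonal entry (i, i) is the physicochemical weight of bond i under
    ``scheme_id``.  Requires :func:`ptmlkit.chem_graph.assign_weights` to
    have been called for that scheme.
    """
    weights = graph.weights(scheme_id)  # raises if unweighted
    nb = graph.nb
    m = np.zeros((nb, nb))
    for i, bi in enumerate(graph.bonds):
        m[i, i] = weights[i]
        for j in range(i + 1, nb):
            bj = graph.bonds[j]
            if len({bi.u, bi.v} & {bj.u, bj.v}) > 0:
                m[i, j] = m[j, i] = 1.0
    return m


def spectral_moment(graph: MolecularGraph, scheme_id: str, k: int) -> float:
    """Trace of the k-th power of the weighted bond-adjacency matrix.

    ``k = 0`` returns NB (trace of the identity).
    """
    if k < 0:
        raise ValueError(f"spectral-moment order must be >= 0, got {k}")
    if k == 0:
        return float(graph.nb)
    m = bond_adjacency_matrix(graph, scheme_id)
    return float(np.trace(np.linalg.matrix_power(m, k)))


# ---------------------------------------------------------------------------
# Connected edge-subgraph enumeration (ESU on the line graph)
# ---------------------------------------------------------------------------


def _line_graph_adjacency(graph: MolecularGraph) -> list[set[int]]:
    nb = graph.nb
    adj: list[set[int]] = [set() for _ in range(nb)]
    for i in range(nb):
        bi = graph.bonds[i]
        for j in range(i + 1, nb):
            bj = graph.bonds[j]
            if len({bi.u, bi.v} & {bj.u, bj.v}) > 0:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _connected_edge_subsets(graph: MolecularGraph, max_size: int) -> dict[int, list[frozenset[int]]]:
    """All connected edge subsets of size 1..max_size, each exactly once.

    ESU-style enumeration on the line graph: each subset is generated from
    its minimum-index edge, extending only with higher-indexed neighbours.
    """
    adj = _line_graph_adjacency(graph)
    out: dict[int, list[frozenset[int]]] = {m: [] for m in range(1, max_size + 1)}

    # Wernicke's ESU: neighbourhood holds the subset plus every neighbour of
    # it, so each extension vertex is reachable from exactly one parent.
    def extend(subset: list[int], extension: set[int],
               neighbourhood: set[int], seed: int) -> None:
        out[len(subset)].append(frozenset(subset))
        if len(subset) == max_size:
            return
        ext = sorted(extension)
        for idx, w in enumerate(ext):
            excl = {x for x in adj[w] if x > seed and x not in neighbourhood}
            subset.append(w)
            extend(subset, set(ext[idx + 1:]) | excl,
                   neighbourhood | excl | {w}, seed)
            subset.pop()

    for e in range(graph.nb):
        first_ext = {x for x in adj[e] if x > e}
        extend([e], first_ext, {e} | first_ext, e)
    return out


def classify_subgraph(graph: MolecularGraph, edges: Iterable[int]) -> SubgraphClass:
    """Classify a connected edge subset into P / C / PC / Ch.

    Degrees are taken within the subgraph.  A connected subset with as many
    vertices as edges (or fewer) contains a cycle and is Ch; among trees,
    max degree <= 2 gives P, no degree-2 vertex gives C, otherwise PC.
    """
    edge_list = [graph.bonds[e] for e in edges]
    deg: dict[int, int] = {}
    for b in edge_list:
        deg[b.u] = deg.get(b.u, 0) + 1
        deg[b.v] = deg.get(b.v, 0) + 1
    n_vertices = len(deg)
    n_edges = len(edge_list)
    if n_vertices <= n_edges:  # connected => cyclic
        return SubgraphClass.Ch
    degrees = list(deg.values())
    if max(degrees) <= 2:
        return SubgraphClass.P
    if 2 not in degrees:
        return SubgraphClass.C
    return SubgraphClass.PC


def _is_pure_cycle(graph: MolecularGraph, edges: Iterable[int]) -> bool:
    deg: dict[int, int] = {}
    for e in edges:
        b = graph.bonds[e]
        deg[b.u] = deg.get(b.u, 0) + 1
        deg[b.v] = deg.get(b.v, 0) + 1
    return all(d == 2 for d in deg.values())


def enumerate_subgraphs(
    graph: MolecularGraph, m: int, cls: SubgraphClass
) -> list[frozenset[int]]:
    """Connected edge subsets of ``graph`` with m edges classifying as ``cls``.

    Order m must lie in 1..6.  Chain subgraphs of order m are the m-edge
    cycles; cyclic subsets carrying pendant edges are not counted.
    """
    if not 1 <= m <= 6:
        raise ValueError(f"subgraph order must be in 1..6, got {m}")
    subsets = _connected_edge_subsets(graph, m)[m]
    out = []
    for s in subsets:
        c = classify_subgraph(graph, s)
        if c is not cls:
            continue
        if cls is SubgraphClass.Ch and not _is_pure_cycle(graph, s):
            continue
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Chi indices
# ---------------------------------------------------------------------------


def _subgraph_atoms(graph: MolecularGraph, edges: Iterable[int]) -> set[int]:
    atoms: set[int] = set()
    for e in edges:
        b = graph.bonds[e]
        atoms.add(b.u)
        atoms.add(b.v)
    return atoms


def _chi_from_subsets(
    graph: MolecularGraph,
    subsets: Sequence[frozenset[int]],
    kind: str,
) -> float:
    """Sum of reciprocal-square-root products over the given subgraphs.

    ``kind``: 'atom' uses parent-graph vertex degrees, 'valence' the
    valence deltas, 'bond' the edge degrees epsilon.  A zero factor (the
    epsilon = 0 single-bond degenerate case) contributes 0 with a warning.
    """
    total = 0.0
    for s in subsets:
        if kind == "bond":
            prod = 1.0
            for e in s:
                prod *= graph.bonds[e].edge_degree
        else:
            prod = 1.0
            for a in _subgraph_atoms(graph, s):
                atom = graph.atoms[a]
                prod *= atom.degree if kind == "atom" else atom.valence_delta
        if prod == 0.0:
            logger.warning(
                "zero degree product in %s chi term for %s; term contributes 0",
                kind,
                graph.smiles,
            )
            continue
        if prod < 0.0:
            # valence deltas can be negative only for exotic charged species;
            # such terms are undefined and excluded.
            logger.warning("negative degree product skipped for %s", graph.smiles)
            continue
        total += prod ** -0.5
    return total


def chi_atom(
    graph: MolecularGraph, m: int, cls: SubgraphClass, valence: bool = False
) -> float:
    """Atom (or valence) connectivity index of order m and class ``cls``."""
    subsets = enumerate_subgraphs(graph, m, cls)
    return _chi_from_subsets(graph, subsets, "valence" if valence else "atom")


def chi_bond(graph: MolecularGraph, m: int, cls: SubgraphClass) -> float:
    """Bond connectivity index of order m and class ``cls`` (edge degrees)."""
    subsets = enumerate_subgraphs(graph, m, cls)
    return _chi_from_subsets(graph, subsets, "bond")


# ---------------------------------------------------------------------------
# Full descriptor vector
# ---------------------------------------------------------------------------

#: chi orders exported per subgraph class: clusters need >= 3 edges,
#: path-clusters >= 4, rings >= 3.
_CLASS_ORDERS: dict[SubgraphClass, tuple[int, ...]] = {
    SubgraphClass.P: (1, 2, 3, 4, 5, 6),
    SubgraphClass.C: (3, 4, 5, 6),
    SubgraphClass.PC: (4, 5, 6),
    SubgraphClass.Ch: (3, 4, 5, 6),
}


@dataclass(frozen=True)
class DescriptorConfig:
    """Which TI families to compute.

    ``sm_orders`` are the spectral-moment orders k (1..15 supported, 1..6
    by default), computed for every scheme in ``schemes``; chi indices run
    over the class/order grid of the standard taxonomy up to order 6.
    """

    schemes: tuple[str, ...] = ("Hyd", "Psa", "Mol", "Gas", "Ato")
    sm_orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    max_chi_order: int = 6
    include_normalized: bool = True


def default_descriptor_names(config: DescriptorConfig | None = None) -> list[str]:
    """The symbolic descriptor grammar produced by :func:`descriptor_vector`."""
    config = config or DescriptorConfig()
    names: list[str] = []
    for w in config.schemes:
        for k in config.sm_orders:
            names.append(f"SM({w}){k}")
    for prefix in ("X", "Xv", "e"):
        for cls, orders in _CLASS_ORDERS.items():
            for m in orders:
                if m <= config.max_chi_order:
                    names.append(f"{prefix}({cls.value}){m}")
    if config.include_normalized:
        names.extend([f"N{n}" for n in names])
    return names


def descriptor_vector(
    graph: MolecularGraph,
    schemes: Sequence[WeightScheme] | None = None,
    config: DescriptorConfig | None = None,
) -> TopoIndexSet:
    """Compute all configured TIs and NTIs for one molecule.

    Subgraphs are enumerated once and shared across the three chi families;
    spectral moments reuse one bond-adjacency matrix per scheme.  The
    result is invariant to the atom ordering of the input SMILES.
    """
    config = config or DescriptorConfig()
    if schemes is None:
        schemes = [builtin_scheme(s) for s in config.schemes]
    assign_weights(graph, list(schemes))

    out = TopoIndexSet(smiles=graph.smiles, nb=graph.nb)
    nb = graph.nb

    for scheme in schemes:
        m = bond_adjacency_matrix(graph, scheme.scheme_id)
        power = np.eye(nb)
        k_max = max(config.sm_orders)
        traces = {}
        for k in range(1, k_max + 1):
            power = power @ m
            traces[k] = float(np.trace(power))
        for k in config.sm_orders:
            out.values[f"SM({scheme.scheme_id}){k}"] = traces[k]

    subsets_by_order = _connected_edge_subsets(graph, config.max_chi_order)
    by_key: dict[tuple[SubgraphClass, int], list[frozenset[int]]] = {}
    for m, subsets in subsets_by_order.items():
        for s in subsets:
            cls = classify_subgraph(graph, s)
            if cls is SubgraphClass.Ch and not _is_pure_cycle(graph, s):
                continue
            by_key.setdefault((cls, m), []).append(s)

    for prefix, kind in (("X", "atom"), ("Xv", "valence"), ("e", "bond")):
        for cls, orders in _CLASS_ORDERS.items():
            for m in orders:
                if m > config.max_chi_order:
                    continue
                subsets = by_key.get((cls, m), [])
                out.values[f"{prefix}({cls.value}){m}"] = _chi_from_subsets(
                    graph, subsets, kind
                )

    if config.include_normalized:
        for name in list(out.values):
            out.values[f"N{name}"] = out.values[name] / nb
    return out
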