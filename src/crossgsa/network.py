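"""Typed molecular networks and seed-set expansion.

A :class:`MolecularNetwork` holds protein-protein interactions (``pp``,
undirected), transcription-factor-to-target edges (``tf``, directed) and
miRNA-to-target edges (``mirna``, directed) for one species.  Nodes are
gene tokens except miRNA regulators, which live in a separate namespace:
they may be traversed (so two genes co-targeted by one miRNA are two
hops apart) but never enter a gene set, because gene-set statistics are
gene-based.

The navigator operations mirror interactive network exploration:
expanding a seed set along chosen relation types, partitioning seeds by
connectivity, trimming to an induced subgraph and exporting the
remaining gene nodes as a new private set.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import networkx as nx

from .core import CrossGsaError, GeneID, GeneSet, SpeciesMismatchError

__all__ = [
    "RELATION_TYPES",
    "MolecularNetwork",
    "ExpansionSpec",
    "expand",
    "seed_components",
    "induced_subgraph",
    "to_gene_set",
]

RELATION_TYPES = ("pp", "tf", "mirna")
_DIRECTED = {"tf", "mirna"}
_DIRECTIONS = ("downstream", "upstream", "both")


@dataclass(frozen=True)
class ExpansionSpec:
    """How to walk the network: which relations, how far, which way.

    ``hops=0`` is permitted and expands nothing — useful for pure
    adjacency/connectivity questions on the seed itself.  For directed
    relations, ``downstream`` follows regulator-to-target arrows,
    ``upstream`` follows them backwards, ``both`` ignores direction.
    """

    relations: tuple[str, ...] = ("pp",)
    hops: int = 1
    direction: str = "both"

    def __post_init__(self) -> None:
        if not self.relations:
            raise CrossGsaError("expansion requires at least one relation type")
        unknown = [r for r in self.relations if r not in RELATION_TYPES]
        if unknown:
            raise CrossGsaError(
                f"unknown relation types {unknown}; choose from {RELATION_TYPES}"
            )
        if self.hops < 0:
            raise CrossGsaError("hops must be >= 0")
        if self.direction not in _DIRECTIONS:
            raise CrossGsaError(
                f"direction must be one of {_DIRECTIONS}, got {self.direction!r}"
            )


class MolecularNetwork:
    """A typed interaction graph over one species' genes (and miRNAs)."""

    def __init__(self, species: str) -> None:
        self.species = species
        # MultiDiGraph keyed by relation type; pp edges stored once with
        # endpoints in canonical sorted order.
        self._g = nx.MultiDiGraph()

    # -- construction -------------------------------------------------

    def add_node(self, token: str, namespace: str = "gene") -> None:
        if namespace not in ("gene", "mirna"):
            raise CrossGsaError(f"unknown node namespace {namespace!r}")
        if token in self._g and self._g.nodes[token]["namespace"] != namespace:
            raise CrossGsaError(
                f"node {token!r} already present with namespace "
                f"{self._g.nodes[token]['namespace']!r}"
            )
        self._g.add_node(token, namespace=namespace)

    def add_edge(self, u: str, relation: str, v: str) -> bool:
        """Add a typed edge; returns False if it was already present.

        ``pp`` edges are canonicalized (endpoints sorted) so loading
        (a, pp, b) and (b, pp, a) yields one stored edge.  The first
        endpoint of a ``mirna`` edge is placed in the miRNA namespace.
        """
        if relation not in RELATION_TYPES:
            raise CrossGsaError(
                f"unknown relation {relation!r}; choose from {RELATION_TYPES}"
            )
        if relation == "pp" and u > v:
            u, v = v, u
        self.add_node(u, "mirna" if relation == "mirna" else "gene")
        self.add_node(v, "gene")
        if self._g.has_edge(u, v, key=relation):
            return False
        self._g.add_edge(u, v, key=relation, self_loop=(u == v))
        return True

    # -- queries ------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self._g.nodes))

    def namespace(self, token: str) -> str:
        return self._g.nodes[token]["namespace"]

    def gene_nodes(self) -> tuple[str, ...]:
        return tuple(
            t for t in self.nodes if self._g.nodes[t]["namespace"] == "gene"
        )

    def edges(self) -> list[tuple[str, str, str]]:
        """All edges as (u, relation, v), deterministically ordered."""
        return sorted((u, k, v) for u, v, k in self._g.edges(keys=True))

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, token: str) -> bool:
        return token in self._g

    def neighbors(self, token: str, spec: ExpansionSpec) -> frozenset[str]:
        """Nodes one step from ``token`` under the spec's relations."""
        if token not in self._g:
            return frozenset()
        out: set[str] = set()
        for rel in spec.relations:
            follow_out = rel == "pp" or spec.direction in ("downstream", "both")
            follow_in = rel == "pp" or spec.direction in ("upstream", "both")
            if follow_out:
                for _, v, k in self._g.out_edges(token, keys=True):
                    if k == rel:
                        out.add(v)
            if follow_in:
                for u, _, k in self._g.in_edges(token, keys=True):
                    if k == rel:
                        out.add(u)
        out.discard(token)
        return frozenset(out)


def _seed_tokens(seed: GeneSet, net: MolecularNetwork) -> list[str]:
    if seed.species != net.species:
        raise SpeciesMismatchError(
            f"seed species {seed.species!r} does not match network species "
            f"{net.species!r}"
        )
    return list(seed.tokens)


def _reachable(
    net: MolecularNetwork, start: Iterable[str], spec: ExpansionSpec
) -> set[str]:
    """Breadth-first reachable node set within ``spec.hops`` steps."""
    frontier = {t for t in start if t in net}
    visited = set(frontier)
    for _ in range(spec.hops):
        nxt: set[str] = set()
        for t in frontier:
            nxt.update(net.neighbors(t, spec))
        frontier = nxt - visited
        if not frontier:
            break
        visited.update(frontier)
    return visited


def expand(
    seed: GeneSet,
    net: MolecularNetwork,
    spec: ExpansionSpec = ExpansionSpec(),
    new_name: str | None = None,
) -> GeneSet:
    """Augment a seed set with network neighbors within ``spec.hops``.

    The result is the seed plus every reachable gene-namespace node;
    miRNA nodes are traversed but excluded.  Seed genes absent from the
    network are retained unchanged.
    """
    tokens = _seed_tokens(seed, net)
    reached = _reachable(net, tokens, spec)
    genes = {t for t in reached if net.namespace(t) == "gene"}
    genes.update(tokens)
    members = frozenset(GeneID(seed.species, t) for t in genes)
    return GeneSet(
        new_name or f"{seed.name}_expanded",
        seed.species,
        "private/network",
        members,
        seed.provenance
        + (
            f"expanded {spec.hops} hop(s) over {'+'.join(spec.relations)} "
            f"({spec.direction})",
        ),
    )


def _traversal_graph(net: MolecularNetwork, spec: ExpansionSpec) -> nx.Graph:
    """Undirected adjacency under the spec (u-v iff v is a neighbor of u)."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for token in net.nodes:
        for nb in net.neighbors(token, spec):
            g.add_edge(token, nb)
    return g


def seed_components(
    seed: GeneSet, net: MolecularNetwork, spec: ExpansionSpec = ExpansionSpec()
) -> list[frozenset[GeneID]]:
    """Partition seed genes into connectivity classes.

    Two seeds share a class iff they are connected in the subgraph
    induced on the seeds plus every node reachable from them within
    ``spec.hops`` — i.e. reached nodes act as intermediates.  With
    ``hops=0`` only direct seed-seed adjacency counts.  Singleton
    classes mark isolated seeds.
    """
    tokens = _seed_tokens(seed, net)
    allowed = set(tokens) | _reachable(net, tokens, spec)
    sub = _traversal_graph(net, spec).subgraph(allowed)
    classes: list[frozenset[GeneID]] = []
    assigned: set[str] = set()
    for comp in nx.connected_components(sub):
        in_comp = [t for t in tokens if t in comp]
        if in_comp:
            classes.append(frozenset(GeneID(seed.species, t) for t in in_comp))
            assigned.update(in_comp)
    for t in tokens:
        if t not in assigned:  # seed absent from the network entirely
            classes.append(frozenset({GeneID(seed.species, t)}))
    return sorted(classes, key=lambda c: min(g.token for g in c))


def induced_subgraph(nodes: GeneSet | Iterable[str], net: MolecularNetwork) -> MolecularNetwork:
    """Keep only edges with both endpoints in ``nodes``; types preserved."""
    if isinstance(nodes, GeneSet):
        if nodes.species != net.species:
            raise SpeciesMismatchError(
                f"node set species {nodes.species!r} does not match network "
                f"species {net.species!r}"
            )
        keep = set(nodes.tokens)
    else:
        keep = set(nodes)
    sub = MolecularNetwork(net.species)
    for t in keep:
        if t in net:
            sub.add_node(t, net.namespace(t))
    for u, rel, v in net.edges():
        if u in keep and v in keep:
            sub.add_edge(u, rel, v)
    return sub


def to_gene_set(
    net_or_nodes: MolecularNetwork | Iterable[GeneID],
    name: str,
    category: str = "private/network",
    species: str | None = None,
) -> GeneSet:
    """Export a network's gene-namespace nodes as a new private set."""
    if isinstance(net_or_nodes, MolecularNetwork):
        members = frozenset(
            GeneID(net_or_nodes.species, t) for t in net_or_nodes.gene_nodes()
        )
        species = net_or_nodes.species
    else:
        members = frozenset(net_or_nodes)
        if species is None:
            if not members:
                raise CrossGsaError(
                    "species must be given when exporting an empty gene collection"
                )
            species = next(iter(members)).species
    return GeneSet(name, species, category, members, ("exported from network",))
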