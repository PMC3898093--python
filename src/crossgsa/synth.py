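"""Seeded generators for synthetic corpora, orthology maps and networks.

Real annotation corpora (GO terms, model-organism phenotype sets),
ortholog-pair tables and interaction networks are external resources;
the generators here produce structurally faithful stand-ins so every
operation in the package can be exercised and power-tested offline.

Public set sizes are drawn log-uniformly between bounds, mimicking the
heavy right skew of real functional term sizes (many small terms, few
huge ones).  A *planted signal* builds a private input set with an
exact, known overlap k against one designated public target set, which
makes detection power measurable: the analysis should place the planted
target at rank 1.

All randomness flows from one integer seed through independent
`numpy` generator streams per artifact, so corpora, maps and networks
are individually reproducible and mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnnotationCorpus, CrossGsaError, GeneID, GeneSet
from .network import MolecularNetwork
from .orthology import OrthologyMap

__all__ = ["PlantedSignal", "SynthSpec", "gen_corpus", "plant_signal", "gen_ortho", "gen_network"]


@dataclass(frozen=True)
class PlantedSignal:
    """Geometry of the engineered private/target overlap.

    Defaults reproduce a small-GWAS-input scenario: 5 input genes, 3 of
    them inside a 22-gene annotation set.
    """

    input_size: int = 5
    overlap: int = 3
    target_size: int = 22
    target_name: str = "planted_target"

    def __post_init__(self) -> None:
        if self.input_size <= 0 or self.target_size <= 0:
            raise CrossGsaError("planted input and target sizes must be positive")
        if not 0 <= self.overlap <= min(self.input_size, self.target_size):
            raise CrossGsaError(
                "planted overlap must satisfy 0 <= k <= min(input, target size)"
            )


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic study instance."""

    seed: int
    species: tuple[str, str] = ("human", "mouse")
    inventory_sizes: tuple[int, int] = (10_000, 8_000)
    n_sets: int = 500
    set_size_range: tuple[int, int] = (10, 300)
    annotation_type: str = "phenotype"
    ortho_coverage: float = 0.6
    one_to_many_rate: float = 0.2
    n_edges: int = 2_000
    planted: PlantedSignal | None = field(default_factory=PlantedSignal)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise CrossGsaError("seed must be a non-negative integer")
        if min(self.inventory_sizes) <= 0 or self.n_sets <= 0 or self.n_edges < 0:
            raise CrossGsaError("all counts must be positive")
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise CrossGsaError("set size range must satisfy 1 <= min <= max")
        if hi > self.inventory_sizes[0]:
            raise CrossGsaError(
                f"requested set size {hi} exceeds inventory of "
                f"{self.inventory_sizes[0]} genes"
            )
        if not 0 <= self.ortho_coverage <= 1 or not 0 <= self.one_to_many_rate <= 1:
            raise CrossGsaError("fractions must lie in [0, 1]")
        if self.planted and self.planted.target_size > self.inventory_sizes[0]:
            raise CrossGsaError("planted target size exceeds inventory")


def _rng(spec: SynthSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _inventory(species: str, size: int) -> list[GeneID]:
    return [GeneID(species, str(i)) for i in range(1, size + 1)]


def gen_corpus(spec: SynthSpec) -> AnnotationCorpus:
    """Generate a public annotation corpus for both species.

    Each species gets ``n_sets`` public sets of the configured
    annotation type with log-uniform sizes, plus (for the first species,
    when a signal is planted) one target set of exactly the planted
    size.  Universes default to the union of set members.
    """
    corpus = AnnotationCorpus()
    lo, hi = spec.set_size_range
    for si, (species, inv_size) in enumerate(zip(spec.species, spec.inventory_sizes)):
        rng = _rng(spec, 10 + si)
        inventory = _inventory(species, inv_size)
        corpus.set_inventory(species, inventory)
        sizes = np.exp(
            rng.uniform(np.log(lo), np.log(hi + 1), size=spec.n_sets)
        ).astype(int)
        sizes = np.clip(sizes, lo, hi)
        for j, size in enumerate(sizes):
            idx = rng.choice(inv_size, size=int(size), replace=False)
            corpus.add_set(
                GeneSet(
                    f"{species}_set_{j:04d}",
                    species,
                    f"public/{spec.annotation_type}",
                    frozenset(inventory[i] for i in idx),
                )
            )
        if si == 0 and spec.planted is not None:
            idx = rng.choice(inv_size, size=spec.planted.target_size, replace=False)
            corpus.add_set(
                GeneSet(
                    spec.planted.target_name,
                    species,
                    f"public/{spec.annotation_type}",
                    frozenset(inventory[i] for i in idx),
                )
            )
    return corpus


def plant_signal(corpus: AnnotationCorpus, spec: SynthSpec) -> GeneSet:
    """Build the private input set with the engineered overlap.

    Exactly ``overlap`` members are drawn from the planted target set
    and ``input_size - overlap`` from the rest of the *annotated*
    universe, so the contingency table recovered downstream matches the
    planted (n, K, k) precisely under the default universe policy.
    """
    if spec.planted is None:
        raise CrossGsaError("spec has no planted signal")
    species = spec.species[0]
    target = None
    for s in corpus.sets_of(species, spec.annotation_type):
        if s.name == spec.planted.target_name:
            target = s
            break
    if target is None:
        raise CrossGsaError(
            f"target set {spec.planted.target_name!r} not found in corpus"
        )
    k, n = spec.planted.overlap, spec.planted.input_size
    if k > len(target):
        raise CrossGsaError("planted overlap exceeds target set size")
    universe = corpus.universe(species, spec.annotation_type)
    outside = sorted(universe - target.members, key=lambda g: int(g.token))
    if n - k > len(outside):
        raise CrossGsaError("not enough genes outside the target set")
    rng = _rng(spec, 20)
    inside = sorted(target.members, key=lambda g: int(g.token))
    pick_in = rng.choice(len(inside), size=k, replace=False)
    pick_out = rng.choice(len(outside), size=n - k, replace=False)
    members = frozenset(
        [inside[i] for i in pick_in] + [outside[i] for i in pick_out]
    )
    return GeneSet(
        "planted_input", species, "private/synthetic", members,
        (f"planted overlap k={k} against {target.name}",),
    )


def gen_ortho(spec: SynthSpec) -> OrthologyMap:
    """Generate an ortholog-pair map from the first species to the second.

    ``ortho_coverage`` of the source inventory receives at least one
    target; of those, ``one_to_many_rate`` receive a second distinct
    target (in-paralog expansion).  Coverage 0 yields an empty map.
    """
    rng = _rng(spec, 30)
    src_sp, tgt_sp = spec.species
    src_n, tgt_n = spec.inventory_sizes
    omap = OrthologyMap(src_sp, tgt_sp)
    n_mapped = int(round(spec.ortho_coverage * src_n))
    if n_mapped == 0:
        return omap
    sources = rng.choice(src_n, size=n_mapped, replace=False)
    targets = rng.integers(1, tgt_n + 1, size=n_mapped)
    expand_flags = rng.random(n_mapped) < spec.one_to_many_rate
    for s_idx, t_idx, two in zip(sources, targets, expand_flags):
        src = GeneID(src_sp, str(int(s_idx) + 1))
        omap.add_pair(src, GeneID(tgt_sp, str(int(t_idx))))
        if two:
            second = int(t_idx) % tgt_n + 1  # distinct from the first
            omap.add_pair(src, GeneID(tgt_sp, str(second)))
    return omap


def gen_network(spec: SynthSpec) -> MolecularNetwork:
    """Generate an undirected PPI network with exactly ``n_edges`` edges.

    Endpoints are drawn uniformly from the first species' inventory
    (an Erdős–Rényi-like degree profile); canonical duplicates and
    self-loops are rejected until the requested count is reached.
    """
    rng = _rng(spec, 40)
    species = spec.species[0]
    inv_size = spec.inventory_sizes[0]
    max_edges = inv_size * (inv_size - 1) // 2
    if spec.n_edges > max_edges:
        raise CrossGsaError(
            f"{spec.n_edges} edges requested but only {max_edges} possible"
        )
    net = MolecularNetwork(species)
    seen: set[tuple[str, str]] = set()
    while len(seen) < spec.n_edges:
        need = spec.n_edges - len(seen)
        pairs = rng.integers(1, inv_size + 1, size=(max(2 * need, 16), 2))
        for u_i, v_i in pairs:
            if u_i == v_i:
                continue
            u, v = str(int(u_i)), str(int(v_i))
            key = (u, v) if u < v else (v, u)
            if key in seen:
                continue
            seen.add(key)
            net.add_edge(u, "pp", v)
            if len(seen) == spec.n_edges:
                break
    return net
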