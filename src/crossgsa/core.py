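"""Core data model: genes, gene sets, identifier maps, annotation corpora.

Every downstream operation (orthology mapping, network expansion,
over-representation statistics) consumes and produces :class:`GeneSet`
objects.  Genes are species-scoped canonical identifiers following the
NCBI Entrez Gene convention: the token is an opaque string, usually
integer-like, and two genes are equal only if both species and token
match — identifiers never compare equal across species.

Gene sets live in a category tree whose root is either ``public``
(pre-compiled annotation sets) or ``private`` (user inputs and every
operation result).  Enrichment is always private-versus-public.
"""

from __future__ import annotations

from collections.abc import Collection, Iterable, Iterator, Mapping
from dataclasses import dataclass, field

__all__ = [
    "CrossGsaError",
    "SpeciesMismatchError",
    "GeneID",
    "GeneSet",
    "IdMap",
    "ConversionReport",
    "AnnotationCorpus",
    "SetLibrary",
    "convert_ids",
    "create_set",
    "set_operation",
    "restrict_to_universe",
    "token_sort_key",
]


class CrossGsaError(ValueError):
    """Base class for domain errors raised by this package."""


class SpeciesMismatchError(CrossGsaError):
    """An operation combined objects from different species."""


def token_sort_key(token: str) -> tuple[int, int, str]:
    """Canonical ordering for gene tokens: numeric tokens first, by value."""
    if token.isdigit():
        return (0, int(token), "")
    return (1, 0, token)


@dataclass(frozen=True, slots=True)
class GeneID:
    """A species-scoped canonical gene identifier."""

    species: str
    token: str

    def __post_init__(self) -> None:
        if not self.species:
            raise CrossGsaError("GeneID species must be non-empty")
        if not self.token:
            raise CrossGsaError("GeneID token must be non-empty")

    def __repr__(self) -> str:  # compact — GeneIDs appear in bulk in reports
        return f"{self.species}:{self.token}"


def _sorted_genes(genes: Iterable[GeneID]) -> tuple[GeneID, ...]:
    return tuple(sorted(genes, key=lambda g: token_sort_key(g.token)))


_CATEGORY_ROOTS = ("public", "private")


@dataclass(frozen=True)
class GeneSet:
    """A named, species-homogeneous, categorized collection of genes.

    ``category`` is a ``/``-separated path rooted at ``public`` or
    ``private``.  ``provenance`` is an append-only trail of operation
    descriptors, so any derived set can be traced back to its inputs.
    """

    name: str
    species: str
    category: str
    members: frozenset[GeneID]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise CrossGsaError("gene set name must be non-empty")
        root = self.category.split("/", 1)[0]
        if root not in _CATEGORY_ROOTS:
            raise CrossGsaError(
                f"category {self.category!r} must be rooted at 'public' or 'private'"
            )
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))
        offenders = sorted(
            {g.species for g in self.members if g.species != self.species}
        )
        if offenders:
            raise SpeciesMismatchError(
                f"set {self.name!r} is scoped to {self.species!r} but contains "
                f"genes from {offenders}"
            )

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[GeneID]:
        return iter(_sorted_genes(self.members))

    def __contains__(self, gene: GeneID) -> bool:
        return gene in self.members

    @property
    def tokens(self) -> tuple[str, ...]:
        """Member tokens in canonical order."""
        return tuple(g.token for g in self)

    def with_provenance(self, entry: str) -> "GeneSet":
        return GeneSet(
            self.name, self.species, self.category, self.members,
            self.provenance + (entry,),
        )


def create_set(
    name: str,
    genes: Collection[GeneID],
    species: str,
    category: str = "private/user",
) -> GeneSet:
    """Create a new gene set de novo.

    Duplicates are collapsed (membership is a set); genes from a species
    other than ``species`` raise :class:`SpeciesMismatchError` listing the
    offenders.  Empty sets are legal.
    """
    return GeneSet(name, species, category, frozenset(genes), ("created",))


class SetLibrary:
    """A category-keyed registry of gene sets.

    Enforces the platform rules that set names are unique within a
    category and that the ``public`` subtree is read-only at the user
    surface: only :meth:`_deposit_public` (used by corpus loaders) may
    place sets there.
    """

    def __init__(self) -> None:
        self._sets: dict[tuple[str, str], GeneSet] = {}

    def deposit(self, gene_set: GeneSet) -> GeneSet:
        if gene_set.category.split("/", 1)[0] == "public":
            raise CrossGsaError(
                "the 'public' category is read-only; deposit under 'private'"
            )
        return self._store(gene_set)

    def _deposit_public(self, gene_set: GeneSet) -> GeneSet:
        return self._store(gene_set)

    def _store(self, gene_set: GeneSet) -> GeneSet:
        key = (gene_set.category, gene_set.name)
        if key in self._sets:
            raise CrossGsaError(
                f"a set named {gene_set.name!r} already exists under "
                f"{gene_set.category!r}"
            )
        self._sets[key] = gene_set
        return gene_set

    def get(self, category: str, name: str) -> GeneSet:
        return self._sets[(category, name)]

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)


def _normalize_alias(alias: str) -> str:
    return alias.strip().casefold()


class IdMap:
    """Multimap from (namespace, alias) to canonical genes.

    Aliases are matched case-insensitively after whitespace trimming;
    canonical tokens themselves are case-sensitive.  An alias may map to
    several genes — ambiguity is representable, not an error.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], set[GeneID]] = {}
        self._species: set[str] = set()

    def add(self, namespace: str, alias: str, gene: GeneID) -> None:
        self._entries.setdefault((namespace, _normalize_alias(alias)), set()).add(gene)
        self._species.add(gene.species)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._species)

    def lookup(self, alias: str, species: str | None = None) -> frozenset[GeneID]:
        """All canonical genes matching ``alias`` across namespaces."""
        norm = _normalize_alias(alias)
        hits: set[GeneID] = set()
        for (_, a), genes in self._entries.items():
            if a == norm:
                hits.update(
                    g for g in genes if species is None or g.species == species
                )
        return frozenset(hits)

    def __len__(self) -> int:
        return len(self._entries)


@dataclass
class ConversionReport:
    """Outcome of an identifier conversion run."""

    mapped: int = 0
    unmapped: list[str] = field(default_factory=list)
    ambiguous: list[tuple[str, tuple[GeneID, ...]]] = field(default_factory=list)
    duplicates_collapsed: int = 0


def convert_ids(
    aliases: Iterable[str],
    id_map: IdMap,
    species: str,
    name: str = "converted",
    category: str = "private/imports",
) -> tuple[GeneSet, ConversionReport]:
    """Convert raw identifiers to a canonical gene set.

    Every candidate canonical gene of an ambiguous alias is included and
    the alias is flagged in the report: silently dropping genes would
    corrupt the effective input size of every downstream test.  Duplicate
    input aliases collapse silently but are counted.
    """
    aliases = list(aliases)
    if id_map.species and species not in id_map.species:
        raise CrossGsaError(
            f"unknown species {species!r}; identifier map covers "
            f"{sorted(id_map.species)}"
        )
    report = ConversionReport()
    seen: set[str] = set()
    members: set[GeneID] = set()
    for alias in aliases:
        norm = _normalize_alias(alias)
        if not norm:
            continue
        if norm in seen:
            report.duplicates_collapsed += 1
            continue
        seen.add(norm)
        hits = id_map.lookup(alias, species=species)
        if not hits:
            report.unmapped.append(alias)
        else:
            report.mapped += 1
            if len(hits) > 1:
                report.ambiguous.append((alias, _sorted_genes(hits)))
            members.update(hits)
    gene_set = GeneSet(
        name, species, category, frozenset(members), ("converted from aliases",)
    )
    return gene_set, report


_SET_OPS = ("union", "intersection", "difference")


def set_operation(op: str, a: GeneSet, b: GeneSet, name: str) -> GeneSet:
    """Union, intersection or difference of two preexisting gene sets.

    Both operands must share a species; combining sets across species
    requires orthology mapping first.  ``difference`` is ``a`` minus
    ``b``.  The result lands under the private category.
    """
    if op not in _SET_OPS:
        raise CrossGsaError(f"unknown set operation {op!r}; choose from {_SET_OPS}")
    if a.species != b.species:
        raise SpeciesMismatchError(
            f"cannot combine {a.species!r} and {b.species!r} sets; "
            "map one across species first"
        )
    if op == "union":
        members = a.members | b.members
    elif op == "intersection":
        members = a.members & b.members
    else:
        members = a.members - b.members
    return GeneSet(
        name, a.species, "private/derived", members,
        (f"{op}({a.name}, {b.name})",),
    )


def restrict_to_universe(
    s: GeneSet, universe: Collection[GeneID]
) -> tuple[GeneSet, list[GeneID]]:
    """Intersect a set with a background universe; report what was dropped."""
    universe = frozenset(universe)
    kept = s.members & universe
    dropped = [g for g in s if g not in universe]
    restricted = GeneSet(
        s.name, s.species, s.category, kept,
        s.provenance + (f"restricted to universe of {len(universe)}",),
    )
    return restricted, dropped


class AnnotationCorpus:
    """Per-species, per-annotation-type collections of public gene sets.

    Holds the public annotation sets keyed by (species, annotation type,
    name), optional explicit universes per (species, type), and the total
    gene inventory per species.  The annotation type of a set is the
    second component of its category path (``public/<type>/...``).
    """

    def __init__(self) -> None:
        self._sets: dict[tuple[str, str, str], GeneSet] = {}
        self._universes: dict[tuple[str, str], frozenset[GeneID]] = {}
        self._inventory: dict[str, frozenset[GeneID]] = {}

    # -- construction -------------------------------------------------

    def add_set(self, gene_set: GeneSet, annotation_type: str | None = None) -> None:
        if annotation_type is None:
            parts = gene_set.category.split("/")
            if len(parts) < 2 or parts[0] != "public":
                raise CrossGsaError(
                    f"cannot infer annotation type from category "
                    f"{gene_set.category!r}; expected 'public/<type>[/...]'"
                )
            annotation_type = parts[1]
        key = (gene_set.species, annotation_type, gene_set.name)
        if key in self._sets:
            raise CrossGsaError(
                f"duplicate public set {gene_set.name!r} for "
                f"({gene_set.species}, {annotation_type})"
            )
        inv = self._inventory.get(gene_set.species)
        if inv is not None and not gene_set.members <= inv:
            raise CrossGsaError(
                f"set {gene_set.name!r} contains genes outside the "
                f"{gene_set.species!r} inventory"
            )
        self._sets[key] = gene_set

    def set_inventory(self, species: str, genes: Iterable[GeneID]) -> None:
        self._inventory[species] = frozenset(genes)

    def set_universe(
        self, species: str, annotation_type: str, genes: Iterable[GeneID]
    ) -> None:
        universe = frozenset(genes)
        member_union = frozenset().union(
            *(s.members for s in self.sets_of(species, annotation_type)), frozenset()
        )
        if not member_union <= universe:
            raise CrossGsaError(
                "declared universe must contain every member of its "
                "annotation type's sets"
            )
        self._universes[(species, annotation_type)] = universe

    # -- queries ------------------------------------------------------

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self._inventory) | frozenset(k[0] for k in self._sets)

    def inventory(self, species: str) -> frozenset[GeneID]:
        try:
            return self._inventory[species]
        except KeyError:
            raise CrossGsaError(
                f"no gene inventory for species {species!r}; "
                f"known: {sorted(self._inventory)}"
            ) from None

    def annotation_types(self, species: str) -> tuple[str, ...]:
        return tuple(sorted({t for (sp, t, _) in self._sets if sp == species}))

    def sets_of(self, species: str, annotation_type: str) -> list[GeneSet]:
        return [
            s
            for (sp, t, _), s in sorted(self._sets.items())
            if sp == species and t == annotation_type
        ]

    def annotated_genes(
        self, species: str, annotation_type: str = "any"
    ) -> frozenset[GeneID]:
        """Genes of ``species`` appearing in at least one set of the type.

        ``"any"`` pools every annotation type.
        """
        if annotation_type == "any":
            types = self.annotation_types(species)
        else:
            if annotation_type not in self.annotation_types(species):
                raise CrossGsaError(
                    f"unknown annotation type {annotation_type!r} for "
                    f"{species!r}; available: "
                    f"{list(self.annotation_types(species))}"
                )
            types = (annotation_type,)
        genes: set[GeneID] = set()
        for t in types:
            for s in self.sets_of(species, t):
                genes.update(s.members)
        return frozenset(genes)

    def universe(self, species: str, annotation_type: str) -> frozenset[GeneID]:
        """Declared universe, falling back to the union of set members."""
        key = (species, annotation_type)
        if key in self._universes:
            return self._universes[key]
        return self.annotated_genes(species, annotation_type)
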