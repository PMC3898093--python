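"""Cross-species orthology mapping and the annotation-coverage survey.

Orthology relations between two species form a many-to-many bipartite
graph: a gene may have no counterpart, one counterpart, or several
(in-paralog expansion).  Mapping a gene set across species takes the
union of all counterparts of all mapped genes; genes without orthologs
are dropped, never passed through untranslated, so mapped sets stay
species-homogeneous.

The coverage survey quantifies how much annotation a poorly-annotated
species (typically human, whose phenotype annotation is sparse) gains by
borrowing annotation from model-organism orthologs: a target gene counts
as *gained* for an annotation type when it lacks native annotation of
that type but has at least one ortholog carrying it in a source species.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .core import (
    AnnotationCorpus,
    CrossGsaError,
    GeneID,
    GeneSet,
    SpeciesMismatchError,
    token_sort_key,
)

__all__ = [
    "OrthologyMap",
    "OrthologyReport",
    "CoverageStat",
    "GainStat",
    "map_set",
    "annotation_coverage",
    "orthology_gain",
    "coverage_percent",
]


def coverage_percent(annotated: int, total: int) -> float:
    """Percentage on the 0–100 scale, rounded half-up to one decimal.

    Half-up (not banker's) rounding matches the convention of printed
    coverage tables, e.g. 34710/42059 -> 82.5.
    """
    if total <= 0:
        raise CrossGsaError("total gene count must be positive")
    if not 0 <= annotated <= total:
        raise CrossGsaError("annotated count must satisfy 0 <= annotated <= total")
    pct = Decimal(100 * annotated) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


class OrthologyMap:
    """Many-to-many ortholog pairs between exactly two species."""

    def __init__(
        self,
        source_species: str,
        target_species: str,
        pairs: Iterable[tuple[GeneID, GeneID]] = (),
    ) -> None:
        if source_species == target_species:
            raise CrossGsaError("orthology map must span two distinct species")
        self.source_species = source_species
        self.target_species = target_species
        self._forward: dict[GeneID, set[GeneID]] = {}
        self._reverse: dict[GeneID, set[GeneID]] = {}
        self._n_pairs = 0
        for src, tgt in pairs:
            self.add_pair(src, tgt)

    def add_pair(self, source: GeneID, target: GeneID) -> None:
        if source.species != self.source_species:
            raise SpeciesMismatchError(
                f"pair source {source!r} is not a {self.source_species!r} gene"
            )
        if target.species != self.target_species:
            raise SpeciesMismatchError(
                f"pair target {target!r} is not a {self.target_species!r} gene"
            )
        bucket = self._forward.setdefault(source, set())
        if target not in bucket:
            bucket.add(target)
            self._reverse.setdefault(target, set()).add(source)
            self._n_pairs += 1

    def __len__(self) -> int:
        return self._n_pairs

    def pairs(self) -> list[tuple[GeneID, GeneID]]:
        """All ortholog pairs in canonical (source, target) token order."""
        key = lambda g: token_sort_key(g.token)  # noqa: E731
        return [
            (src, tgt)
            for src in sorted(self._forward, key=key)
            for tgt in sorted(self._forward[src], key=key)
        ]

    def targets_of(self, source: GeneID) -> frozenset[GeneID]:
        return frozenset(self._forward.get(source, ()))

    def sources_of(self, target: GeneID) -> frozenset[GeneID]:
        return frozenset(self._reverse.get(target, ()))


@dataclass
class OrthologyReport:
    """Accounting for one cross-species mapping run.

    ``mapped + len(unmapped)`` always equals the input set size.
    """

    mapped: int = 0
    unmapped: list[GeneID] = field(default_factory=list)
    expansions: list[tuple[GeneID, tuple[GeneID, ...]]] = field(default_factory=list)
    output_size: int = 0


def map_set(
    s: GeneSet,
    omap: OrthologyMap,
    new_name: str,
    policy: str = "all",
) -> tuple[GeneSet, OrthologyReport]:
    """Map a gene set to its orthologous set in another species.

    ``policy="all"`` keeps every ortholog of a one-to-many gene (the
    default: recall-maximizing, mirrors in-paralog expansion);
    ``policy="best-one"`` keeps the single ortholog that sorts first by
    token, for users needing size-preserving maps.  One-to-many genes
    expand, many-to-one genes dedupe; sources without any ortholog are
    dropped and listed in the report.
    """
    if policy not in ("all", "best-one"):
        raise CrossGsaError(f"unknown one-to-many policy {policy!r}")
    if s.species != omap.source_species:
        raise SpeciesMismatchError(
            f"set species {s.species!r} does not match map source "
            f"{omap.source_species!r}"
        )
    report = OrthologyReport()
    members: set[GeneID] = set()
    for gene in s:
        targets = sorted(omap.targets_of(gene), key=lambda g: token_sort_key(g.token))
        if not targets:
            report.unmapped.append(gene)
            continue
        report.mapped += 1
        if policy == "best-one":
            targets = targets[:1]
        elif len(targets) > 1:
            report.expansions.append((gene, tuple(targets)))
        members.update(targets)
    report.output_size = len(members)
    mapped = GeneSet(
        new_name,
        omap.target_species,
        "private/orthology",
        frozenset(members),
        s.provenance
        + (f"orthology-mapped from {s.name} ({s.species} -> {omap.target_species})",),
    )
    return mapped, report


@dataclass(frozen=True)
class CoverageStat:
    """Fraction of a species' inventory carrying some annotation type."""

    species: str
    annotation_type: str
    total_genes: int
    annotated_genes: int

    @property
    def percent(self) -> float:
        return coverage_percent(self.annotated_genes, self.total_genes)


def annotation_coverage(
    corpus: AnnotationCorpus, species: str, annotation_type: str = "any"
) -> CoverageStat:
    """Count inventory genes appearing in >=1 set of the given type.

    ``annotation_type="any"`` pools every type the corpus holds for the
    species.
    """
    inventory = corpus.inventory(species)
    annotated = corpus.annotated_genes(species, annotation_type) & inventory
    return CoverageStat(species, annotation_type, len(inventory), len(annotated))


@dataclass(frozen=True)
class GainStat:
    """Annotation gained for a target species by borrowing from orthologs.

    ``per_source`` holds, per source species, the target genes that lack
    native annotation of the type but have an annotated ortholog there.
    ``combined`` is the union over sources (a gene reachable from two
    model organisms is counted once); ``summed_count`` is the plain sum
    of per-source counts, reported alongside because the two coincide
    exactly when per-source contributions are disjoint.
    """

    target_species: str
    annotation_type: str
    total_genes: int
    per_source: dict[str, frozenset[GeneID]]
    combined: frozenset[GeneID]

    @property
    def combined_count(self) -> int:
        return len(self.combined)

    @property
    def summed_count(self) -> int:
        return sum(len(v) for v in self.per_source.values())

    @property
    def combined_percent(self) -> float:
        return coverage_percent(len(self.combined), self.total_genes)

    def source_percent(self, source_species: str) -> float:
        return coverage_percent(
            len(self.per_source[source_species]), self.total_genes
        )


def orthology_gain(
    corpus: AnnotationCorpus,
    maps: Sequence[OrthologyMap],
    target_species: str,
    annotation_type: str,
) -> GainStat:
    """Survey how much annotation orthology adds to a target species.

    For each source species *s*: gained(s) = target inventory genes that
    lack native annotation of ``annotation_type`` but have >=1 ortholog
    in *s* that carries it there.  The combined gain is the union over
    sources.  Gained genes are by construction disjoint from natively
    annotated genes.
    """
    if not maps:
        raise CrossGsaError("orthology_gain requires at least one orthology map")
    for omap in maps:
        if omap.target_species != target_species:
            raise SpeciesMismatchError(
                f"map {omap.source_species}->{omap.target_species} does not "
                f"target {target_species!r}"
            )
    inventory = corpus.inventory(target_species)
    native = corpus.annotated_genes(target_species, annotation_type) & inventory
    unannotated = inventory - native
    per_source: dict[str, frozenset[GeneID]] = {}
    for omap in maps:
        src_sp = omap.source_species
        if annotation_type in corpus.annotation_types(src_sp):
            src_annotated = corpus.annotated_genes(src_sp, annotation_type)
        else:
            src_annotated = frozenset()
        gained = frozenset(
            g
            for g in unannotated
            if any(o in src_annotated for o in omap.sources_of(g))
        )
        per_source[src_sp] = gained
    combined = frozenset().union(*per_source.values(), frozenset())
    return GainStat(
        target_species, annotation_type, len(inventory), per_source, combined
    )
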