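"""Reconstruction of the published seven-species coverage survey.

The published survey reports, per species, the total gene inventory,
how many genes carry any annotation, phenotype annotation, or a PPI
connection, and how many *human* genes gain inferred phenotype / PPI
annotation through orthologs in each model organism.  Only these counts
are public — the underlying gene memberships are the platform's hosted
content — so this module realizes the counts as a synthetic corpus:
inventories are integer token ranges and every annotated block is a
prefix/segment of them, sized exactly by the published numbers, with
ortholog pairs wired so that each model organism contributes precisely
its published gain block.

Feeding this reconstruction through :func:`~crossgsa.orthology.annotation_coverage`
and :func:`~crossgsa.orthology.orthology_gain` therefore reproduces the
published coverage and gain percentages from genuine set arithmetic,
which is what the survey's percentages are: counts, unions and
half-up-rounded ratios.

Gene memberships here are synthetic stand-ins; only the counts are real.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .core import AnnotationCorpus, GeneID, GeneSet
from .orthology import OrthologyMap

__all__ = ["SurveyCounts", "load_survey_counts", "build_survey"]

TARGET = "human"

#: token offsets for the human gain blocks (disjoint, outside every
#: natively annotated range)
_PHENOTYPE_GAIN_BASE = {"worm": 20000, "fly": 21000, "mouse": 22000, "yeast": 23000}
_PPI_GAIN_BASE = {
    "arabidopsis": 25000,
    "worm": 27000,
    "fly": 28500,
    "mouse": 30000,
    "yeast": 31000,
}


@dataclass(frozen=True)
class SurveyCounts:
    species: str
    total_genes: int
    all_annotated: int
    phenotype_annotated: int
    ppi_connected: int
    phenotype_gain_to_human: int
    ppi_gain_to_human: int


def load_survey_counts() -> dict[str, SurveyCounts]:
    """Load the published per-species survey counts shipped with the package."""
    text = (
        resources.files("crossgsa.data")
        .joinpath("annotation_survey_counts.tsv")
        .read_text(encoding="utf-8")
    )
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    out: dict[str, SurveyCounts] = {}
    for rec in csv.DictReader(lines, delimiter="\t"):
        out[rec["species"]] = SurveyCounts(
            species=rec["species"],
            total_genes=int(rec["total_genes"]),
            all_annotated=int(rec["all_annotated"]),
            phenotype_annotated=int(rec["phenotype_annotated"]),
            ppi_connected=int(rec["ppi_connected"]),
            phenotype_gain_to_human=int(rec["phenotype_gain_to_human"]),
            ppi_gain_to_human=int(rec["ppi_gain_to_human"]),
        )
    return out


def _range_set(species: str, start: int, count: int) -> frozenset[GeneID]:
    return frozenset(GeneID(species, str(i)) for i in range(start, start + count))


def build_survey() -> tuple[AnnotationCorpus, list[OrthologyMap]]:
    """Realize the survey counts as a corpus plus human-targeted maps.

    Layout per species (token ranges within the inventory 1..total):

    * ``general`` annotation: tokens ``1..all_annotated``;
    * ``phenotype``: tokens ``1..phenotype_annotated`` (for the human
      target nested inside the general block, so pooled coverage equals
      the general block);
    * ``ppi``: for human, nested in the general block; for model
      organisms, a segment disjoint from the phenotype block wherever
      the inventory allows, so that PPI-derived gains never leak into
      phenotype gains (for yeast, whose inventory forces an overlap,
      pairing below only uses its phenotype-free PPI segment).

    Each model organism's ortholog map pairs its published human gain
    block — human genes lacking the native annotation — with annotated
    source genes of the right type, and nothing else.
    """
    counts = load_survey_counts()
    corpus = AnnotationCorpus()
    for c in counts.values():
        sp = c.species
        corpus.set_inventory(sp, _range_set(sp, 1, c.total_genes))
        corpus.add_set(
            GeneSet(f"{sp}_general", sp, "public/general",
                    _range_set(sp, 1, c.all_annotated))
        )
        if c.phenotype_annotated:
            corpus.add_set(
                GeneSet(f"{sp}_phenotype", sp, "public/phenotype",
                        _range_set(sp, 1, c.phenotype_annotated))
            )
        if c.ppi_connected:
            if sp == TARGET or c.phenotype_annotated == 0:
                ppi = _range_set(sp, 1, c.ppi_connected)
            elif c.phenotype_annotated + c.ppi_connected <= c.total_genes:
                ppi = _range_set(sp, c.phenotype_annotated + 1, c.ppi_connected)
            else:
                # inventory too small for disjoint blocks: take every
                # phenotype-free gene, fill the rest from the front
                free = c.total_genes - c.phenotype_annotated
                ppi = _range_set(sp, c.phenotype_annotated + 1, free) | _range_set(
                    sp, 1, c.ppi_connected - free
                )
            corpus.add_set(GeneSet(f"{sp}_ppi", sp, "public/ppi", ppi))

    human = counts[TARGET]
    maps: list[OrthologyMap] = []
    for c in counts.values():
        if c.species == TARGET:
            continue
        omap = OrthologyMap(c.species, TARGET)
        if c.phenotype_gain_to_human:
            # phenotype-annotated, PPI-free source partners
            partners = [
                t
                for t in range(1, c.phenotype_annotated + 1)
                if not (c.phenotype_annotated + c.ppi_connected > c.total_genes
                        and t <= c.ppi_connected - (c.total_genes - c.phenotype_annotated))
            ]
            base = _PHENOTYPE_GAIN_BASE[c.species]
            for i in range(c.phenotype_gain_to_human):
                src = GeneID(c.species, str(partners[i % len(partners)]))
                omap.add_pair(src, GeneID(TARGET, str(base + i)))
        if c.ppi_gain_to_human:
            # PPI-connected, phenotype-free source partners
            lo = c.phenotype_annotated + 1
            hi = min(c.phenotype_annotated + c.ppi_connected, c.total_genes)
            if c.phenotype_annotated == 0:
                lo, hi = 1, c.ppi_connected
            partners = list(range(lo, hi + 1))
            base = _PPI_GAIN_BASE[c.species]
            for i in range(c.ppi_gain_to_human):
                src = GeneID(c.species, str(partners[i % len(partners)]))
                omap.add_pair(src, GeneID(TARGET, str(base + i)))
        maps.append(omap)

    # sanity: human gain blocks stay inside the inventory and clear of
    # the native annotation they are meant to augment
    assert all(
        base + counts_sp.phenotype_gain_to_human <= human.total_genes
        and base > human.phenotype_annotated
        for sp, base in _PHENOTYPE_GAIN_BASE.items()
        for counts_sp in (counts[sp],)
    )
    assert all(
        base + counts[sp].ppi_gain_to_human <= human.total_genes
        and base > human.ppi_connected
        for sp, base in _PPI_GAIN_BASE.items()
    )
    return corpus, maps
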