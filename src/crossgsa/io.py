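"""Readers and writers for the package's plain-text formats.

Formats are deliberately minimal and line-oriented:

* gene sets — GMT dialect: tab-separated, column 1 the set name,
  column 2 a ``category|species`` descriptor, columns 3+ gene tokens;
* alias tables — 3-column TSV (namespace, alias, canonical token),
  species given by the caller, ``#`` comment lines skipped;
* ortholog tables — 4-column TSV (source taxon, source token, target
  taxon, target token); one species pair per file, enforced;
* networks — 3-column edge TSV or SIF (node, relation, node(s)) with
  relation vocabulary ``pp`` / ``tf`` / ``mirna``; written as SIF for
  graph-viewer interoperability;
* enrichment results — TSV superset of the usual printed layout
  (rank / set size / overlap / p / q), with p and q in scientific
  notation at two significant digits.

All readers tolerate trailing whitespace, blank lines and ``#``
comments, and report malformed input with file name and line number.
Writers emit canonical order (sets by category then name, genes by
token), so write-then-read is the identity on canonical files.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from pathlib import Path

from .core import (
    AnnotationCorpus,
    CrossGsaError,
    GeneID,
    GeneSet,
    IdMap,
)
from .enrich import EnrichmentResult, EnrichmentRow, SetGraph
from .network import RELATION_TYPES, MolecularNetwork
from .orthology import OrthologyMap

__all__ = [
    "ParseError",
    "read_gmt",
    "write_gmt",
    "read_alias_tsv",
    "read_ortho",
    "write_ortho",
    "read_network",
    "write_sif",
    "write_results",
    "read_ranked_table",
    "write_set_graph",
    "read_gene_list",
    "corpus_from_sets",
]


class ParseError(CrossGsaError):
    """Malformed input, located by file and line number."""

    def __init__(self, path: str | Path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


# -- gene sets (GMT) ------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for lineno, line in _data_lines(path):
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) < 2:
            raise ParseError(path, lineno, "GMT lines need >=2 tab-separated columns")
        name, descr = cols[0], cols[1]
        if "|" not in descr:
            raise ParseError(
                path, lineno, f"descriptor {descr!r} must be 'category|species'"
            )
        category, species = descr.split("|", 1)
        tokens = [t for t in cols[2:] if t]
        try:
            sets.append(
                GeneSet(
                    name, species, category,
                    frozenset(GeneID(species, t) for t in tokens),
                )
            )
        except CrossGsaError as exc:
            raise ParseError(path, lineno, str(exc)) from exc
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    ordered = sorted(sets, key=lambda s: (s.category, s.name))
    with open(path, "w", encoding="utf-8") as fh:
        for s in ordered:
            cols = [s.name, f"{s.category}|{s.species}", *s.tokens]
            fh.write("\t".join(cols) + "\n")


def corpus_from_sets(
    sets: Iterable[GeneSet],
    inventories: dict[str, Iterable[GeneID]] | None = None,
) -> AnnotationCorpus:
    """Assemble a corpus from public GMT sets.

    Annotation types come from category paths (``public/<type>``).
    Missing inventories default to the union of the species' set members.
    """
    corpus = AnnotationCorpus()
    sets = list(sets)
    if inventories:
        for species, genes in inventories.items():
            corpus.set_inventory(species, genes)
    per_species: dict[str, set[GeneID]] = {}
    for s in sets:
        per_species.setdefault(s.species, set()).update(s.members)
    for species, genes in per_species.items():
        if not inventories or species not in inventories:
            corpus.set_inventory(species, genes)
    for s in sets:
        corpus.add_set(s)
    return corpus


# -- alias tables ---------------------------------------------------------


def read_alias_tsv(path: str | Path, species: str) -> IdMap:
    id_map = IdMap()
    for lineno, line in _data_lines(path):
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) != 3:
            raise ParseError(
                path, lineno, f"alias lines need 3 columns, got {len(cols)}"
            )
        namespace, alias, token = cols
        if not alias or not token:
            raise ParseError(path, lineno, "empty alias or canonical token")
        id_map.add(namespace, alias, GeneID(species, token))
    return id_map


# -- ortholog tables ------------------------------------------------------


def read_ortho(path: str | Path) -> OrthologyMap:
    omap: OrthologyMap | None = None
    for lineno, line in _data_lines(path):
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) != 4:
            raise ParseError(
                path, lineno, f"ortholog lines need 4 columns, got {len(cols)}"
            )
        src_sp, src_tok, tgt_sp, tgt_tok = cols
        if omap is None:
            if src_sp == tgt_sp:
                raise ParseError(path, lineno, "source and target species coincide")
            omap = OrthologyMap(src_sp, tgt_sp)
        elif (src_sp, tgt_sp) != (omap.source_species, omap.target_species):
            raise ParseError(
                path,
                lineno,
                f"species pair ({src_sp}, {tgt_sp}) differs from the file's "
                f"({omap.source_species}, {omap.target_species}); one pair "
                "per file",
            )
        omap.add_pair(GeneID(src_sp, src_tok), GeneID(tgt_sp, tgt_tok))
    if omap is None:
        raise ParseError(path, 0, "ortholog file contains no pairs")
    return omap


def write_ortho(omap: OrthologyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for src, tgt in omap.pairs():
            fh.write(
                f"{src.species}\t{src.token}\t{tgt.species}\t{tgt.token}\n"
            )


# -- networks -------------------------------------------------------------


def read_network(path: str | Path, species: str) -> MolecularNetwork:
    """Read a 3-column edge TSV or a SIF file (detected per line).

    SIF lines may carry several targets: ``node<TAB>relation<TAB>t1<TAB>t2…``.
    """
    net = MolecularNetwork(species)
    for lineno, line in _data_lines(path):
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) < 3:
            raise ParseError(
                path, lineno, f"edge lines need >=3 columns, got {len(cols)}"
            )
        u, relation, targets = cols[0], cols[1], cols[2:]
        if relation not in RELATION_TYPES:
            raise ParseError(
                path,
                lineno,
                f"unknown relation {relation!r}; expected one of "
                f"{RELATION_TYPES}",
            )
        for v in targets:
            if v:
                net.add_edge(u, relation, v)
    return net


def write_sif(net: MolecularNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, rel, v in net.edges():
            fh.write(f"{u}\t{rel}\t{v}\n")


# -- enrichment results ---------------------------------------------------

_RESULT_COLUMNS = (
    "rank", "private_set", "public_set", "annotation_type", "set_size",
    "overlap", "input_size", "universe_size", "p_value", "q_value",
    "kappa", "overlap_genes",
)


def _sci(x: float) -> str:
    return f"{x:.1E}"


def write_results(result: EnrichmentResult, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_RESULT_COLUMNS) + "\n")
        for row in result.rows():
            kap = "" if math.isnan(row.kappa) else f"{row.kappa:.3f}"
            fh.write(
                "\t".join(
                    [
                        str(row.rank),
                        row.private_set,
                        row.public_set,
                        row.annotation_type,
                        str(row.set_size),
                        str(row.overlap),
                        str(row.input_size),
                        str(row.universe_size),
                        _sci(row.p_value),
                        _sci(row.q_value),
                        kap,
                        "|".join(g.token for g in row.overlap_genes),
                    ]
                )
                + "\n"
            )


def _number(text: str, path: str | Path, lineno: int) -> float:
    # tolerate the "2.5.E-06" style of older printed tables
    cleaned = text.replace(".E", "E").replace(".e", "e")
    try:
        return float(cleaned)
    except ValueError:
        raise ParseError(path, lineno, f"cannot parse number {text!r}") from None


def read_ranked_table(
    path: str | Path,
    private_set: str = "input",
    annotation_type: str = "phenotype",
) -> list[EnrichmentRow]:
    """Read a published-style ranked table into enrichment rows.

    Expected columns: rank, set_size, overlap, p_value, q_value,
    annotation name.  Effective input and universe sizes are not part
    of this layout and are recorded as 0.
    """
    rows: list[EnrichmentRow] = []
    for lineno, line in _data_lines(path):
        cols = [c.strip() for c in line.split("\t")]
        if cols[0].lower() == "rank":
            continue
        if len(cols) < 6:
            raise ParseError(
                path, lineno, f"ranked tables need 6 columns, got {len(cols)}"
            )
        rows.append(
            EnrichmentRow(
                rank=int(cols[0]),
                private_set=private_set,
                public_set=cols[5],
                annotation_type=annotation_type,
                set_size=int(cols[1]),
                overlap=int(cols[2]),
                input_size=0,
                universe_size=0,
                p_value=_number(cols[3], path, lineno),
                q_value=_number(cols[4], path, lineno),
            )
        )
    return rows


def write_set_graph(
    sg: SetGraph, sif_path: str | Path, attrs_path: str | Path
) -> None:
    """Export the association graph as SIF plus an edge-attribute TSV."""
    with open(sif_path, "w", encoding="utf-8") as fh:
        for u, v, _ in sg.edges():
            fh.write(f"{u}\tassoc\t{v}\n")
    with open(attrs_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in sg.edges():
            fh.write(f"{u}\t{v}\t{w:.6g}\n")


# -- plain gene lists -----------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; '#' comments and blanks skipped."""
    return [line.strip() for _, line in _data_lines(path)]
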