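"""Over-representation statistics: hypergeometric test, kappa, BH, ranking.

Each private (user) gene set is tested against every public annotation
set of the selected annotation types.  With a background universe of N
genes, a public set covering K of them, and an input of n universe
genes overlapping the public set in k genes, the upper-tail
hypergeometric probability

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)

is the chance of seeing at least k overlaps when drawing n genes
without replacement.  Cohen's kappa measures chance-corrected agreement
between the two membership indicators over the universe.  Within one
private set, p-values are corrected across the whole family of public
sets tested (including zero-overlap sets) by the Benjamini-Hochberg
step-up procedure.

The universe N is a modelling choice that changes every p-value.  The
default policy ("annotated") takes the genes annotated in >=1 set of
the selected types — standard over-representation practice; the
alternatives are the full species inventory ("all-genes") or an
explicit custom collection.
"""

from __future__ import annotations

import math
from collections.abc import Collection, Iterable, Sequence
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .core import (
    AnnotationCorpus,
    CrossGsaError,
    GeneID,
    GeneSet,
    restrict_to_universe,
)

__all__ = [
    "P_FLOOR",
    "ContingencyTable",
    "EnrichmentRow",
    "EnrichmentResult",
    "SetGraph",
    "hypergeom_pvalue",
    "kappa",
    "bh_adjust",
    "run_gsa",
    "filter_rank",
    "set_graph",
]

#: Reported p-values are floored here to keep -log10 finite in exports.
P_FLOOR = 1e-300


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k].

    Computed in log space via scipy's survival function for numerical
    stability at extreme tails, then floored at :data:`P_FLOOR`.
    ``k = 0`` returns exactly 1 (the upper tail includes everything).
    """
    if not 0 <= K <= N:
        raise CrossGsaError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise CrossGsaError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise CrossGsaError(f"need 0 <= k <= min(n, K), got k={k}, n={n}, K={K}")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(1.0, max(p, P_FLOOR))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 classification of universe genes by two set memberships.

    ``a`` = in both, ``b`` = private only, ``c`` = public only,
    ``d`` = in neither; N = a+b+c+d.  In hypergeometric terms
    n = a+b (effective input size), K = a+c (public set size), k = a.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CrossGsaError("contingency cells must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_counts(cls, N: int, K: int, n: int, k: int) -> "ContingencyTable":
        return cls(a=k, b=n - k, c=K - k, d=N - n - K + k)

    @classmethod
    def from_sets(
        cls,
        private: Collection[GeneID],
        public: Collection[GeneID],
        universe: Collection[GeneID],
    ) -> "ContingencyTable":
        universe = frozenset(universe)
        pr = frozenset(private) & universe
        pu = frozenset(public) & universe
        a = len(pr & pu)
        return cls(a=a, b=len(pr) - a, c=len(pu) - a, d=len(universe - pr - pu))


def kappa(table: ContingencyTable) -> float:
    """Cohen's kappa between the two memberships; NaN when degenerate.

    kappa = (po - pe) / (1 - pe) with observed agreement
    po = (a+d)/N and chance agreement
    pe = [(a+b)(a+c) + (c+d)(b+d)] / N^2.  When pe = 1 (both sets empty
    or both equal to the universe) agreement beyond chance is undefined
    and NaN is returned.
    """
    N = table.N
    if N == 0:
        raise CrossGsaError("kappa requires a non-empty universe")
    a, b, c, d = table.a, table.b, table.c, table.d
    po = (a + d) / N
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
    if pe == 1.0:
        return math.nan
    return (po - pe) / (1.0 - pe)


def bh_adjust(pvalues: Sequence[float], m: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``m`` is the family size and may exceed ``len(pvalues)`` when some
    family members (e.g. zero-overlap tests with p = 1) are corrected
    for but not listed.  q_(i) = min_{j>=i} p_(j) * m / j on the
    ascending-sorted p's, clipped at 1, returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise CrossGsaError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise CrossGsaError("family size m must be >= number of p-values")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate((p[order] * m / ranks)[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    # p*m/m can round one ulp below p; dominance q >= p holds exactly
    q_sorted = np.maximum(q_sorted, p[order])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q.tolist()


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested (private set, public set) pair."""

    rank: int
    private_set: str
    public_set: str
    annotation_type: str
    set_size: int  # K: public set size within the universe
    overlap: int  # k
    input_size: int  # n: private set size within the universe
    universe_size: int  # N
    p_value: float
    q_value: float
    kappa: float = math.nan
    overlap_genes: tuple[GeneID, ...] = ()


@dataclass
class EnrichmentResult:
    """Ranked rows per private set plus the correction family sizes."""

    blocks: dict[str, list[EnrichmentRow]] = field(default_factory=dict)
    m: dict[str, int] = field(default_factory=dict)
    universe_policy: str = "annotated"
    dropped: dict[str, list[GeneID]] = field(default_factory=dict)

    def rows(self) -> list[EnrichmentRow]:
        out: list[EnrichmentRow] = []
        for name in sorted(self.blocks):
            out.extend(self.blocks[name])
        return out


def _row_order_key(row: EnrichmentRow) -> tuple:
    # total, reproducible order: best p first; larger overlap, then
    # smaller public set, then name break ties
    return (row.p_value, -row.overlap, row.set_size, row.public_set)


def _resolve_universe(
    corpus: AnnotationCorpus,
    species: str,
    annotation_types: Sequence[str],
    universe_policy: str | Collection[GeneID],
) -> tuple[frozenset[GeneID], str]:
    if isinstance(universe_policy, str):
        if universe_policy == "annotated":
            u: frozenset[GeneID] = frozenset()
            for t in annotation_types:
                u |= corpus.universe(species, t)
            return u, "annotated"
        if universe_policy == "all-genes":
            return corpus.inventory(species), "all-genes"
        raise CrossGsaError(
            f"unknown universe policy {universe_policy!r}; use 'annotated', "
            "'all-genes' or an explicit gene collection"
        )
    return frozenset(universe_policy), "custom"


def run_gsa(
    private_sets: Sequence[GeneSet],
    corpus: AnnotationCorpus,
    annotation_types: Sequence[str] | str,
    universe_policy: str | Collection[GeneID] = "annotated",
) -> EnrichmentResult:
    """Test each private set against every public set of the given types.

    For each private set the BH family is the full collection of public
    sets tested (zero-overlap rows count toward m but are excluded from
    the ranked report, since their p = 1 carries no signal).  Ranks are
    assigned by ascending p, then descending overlap, then ascending
    public set size, then set name — a total order, so identical inputs
    give identical tables.
    """
    if isinstance(annotation_types, str):
        annotation_types = (annotation_types,)
    if not private_sets:
        raise CrossGsaError("at least one private set is required")
    if not annotation_types:
        raise CrossGsaError("at least one public annotation type is required")
    species = private_sets[0].species
    for s in private_sets:
        if s.species != species:
            raise CrossGsaError(
                "all private sets in one analysis must share a species"
            )
    for t in annotation_types:
        if t not in corpus.annotation_types(species):
            raise CrossGsaError(
                f"no public sets of type {t!r} for {species!r}; available: "
                f"{list(corpus.annotation_types(species))}"
            )
    universe, policy_name = _resolve_universe(
        corpus, species, annotation_types, universe_policy
    )
    public = [
        (t, ps) for t in annotation_types for ps in corpus.sets_of(species, t)
    ]

    result = EnrichmentResult(universe_policy=policy_name)
    for s in private_sets:
        restricted, dropped = restrict_to_universe(s, universe)
        result.dropped[s.name] = dropped
        n = len(restricted)
        if n == 0:
            raise CrossGsaError(
                f"set {s.name!r} has no analyzable genes after restriction "
                f"to the {policy_name} universe"
            )
        N = len(universe)
        tested: list[tuple[str, GeneSet, int, int, float, float, tuple[GeneID, ...]]] = []
        for t, ps in public:
            in_universe = ps.members & universe
            K = len(in_universe)
            overlap_genes = tuple(
                g for g in restricted if g in in_universe
            )
            k = len(overlap_genes)
            p = hypergeom_pvalue(N, K, n, k)
            kap = kappa(ContingencyTable.from_counts(N, K, n, k))
            tested.append((t, ps, K, k, p, kap, overlap_genes))
        m = len(tested)
        qvals = bh_adjust([row[4] for row in tested], m=m)
        rows = [
            EnrichmentRow(
                rank=0,
                private_set=s.name,
                public_set=ps.name,
                annotation_type=t,
                set_size=K,
                overlap=k,
                input_size=n,
                universe_size=N,
                p_value=p,
                q_value=q,
                kappa=kap,
                overlap_genes=genes,
            )
            for (t, ps, K, k, p, kap, genes), q in zip(tested, qvals)
            if k > 0
        ]
        rows.sort(key=_row_order_key)
        result.blocks[s.name] = [
            EnrichmentRow(**{**row.__dict__, "rank": i + 1})
            for i, row in enumerate(rows)
        ]
        result.m[s.name] = m
    return result


def filter_rank(
    rows: Iterable[EnrichmentRow], q_threshold: float = 0.05
) -> list[EnrichmentRow]:
    """Keep rows with q below the cut-off; original ranks preserved."""
    if not 0 <= q_threshold <= 1:
        raise CrossGsaError("q threshold must lie in [0, 1]")
    return [r for r in rows if r.q_value < q_threshold]


@dataclass
class SetGraph:
    """Bipartite association graph between private and public sets.

    Edges connect a private set to each public set it is significantly
    associated with; the weight is -log10(q) (default) or kappa.
    """

    graph: nx.Graph
    weight_kind: str = "neglog10_q"

    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        )


def set_graph(
    result: EnrichmentResult,
    q_threshold: float = 0.05,
    weight: str = "neglog10_q",
) -> SetGraph:
    """Build the gene-set association graph from an enrichment result."""
    if weight not in ("neglog10_q", "kappa"):
        raise CrossGsaError("weight must be 'neglog10_q' or 'kappa'")
    g = nx.Graph()
    for row in result.rows():
        if not (row.q_value < q_threshold):
            continue
        g.add_node(row.private_set, kind="private")
        g.add_node(row.public_set, kind="public")
        w = (
            -math.log10(max(row.q_value, P_FLOOR))
            if weight == "neglog10_q"
            else row.kappa
        )
        g.add_edge(row.private_set, row.public_set, weight=w)
    return SetGraph(graph=g, weight_kind=weight)
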