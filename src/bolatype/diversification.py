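"""Association graphs between co-segregating MHC elements.

Haplotype catalogues are summarised as weighted bipartite association
graphs at four genomic levels: DQA/DQB alleles within DQ pairs, paired DQ
loci within duplicated-DQ haplotypes, DR/DQ haplotypes, and MHCI/DR
haplotypes.  Each edge (association) is classified descriptively:

* ``one_to_one`` — the two elements are only ever seen with each other;
* ``index`` — the highest-weight association of a multi-edge group;
* ``mu_gc`` — differs from its group's index only by same-allelic-group
  substitutions (a mutation / gene-conversion proxy);
* ``recombination`` — shares an element with the group but crosses allelic
  groups on the other side (a recombination proxy).

No parent/derived direction is inferred — the index is simply the most
frequent association, and the labels are descriptive relative to it.

Grouping is symmetric at the ``pair`` and ``dq_dup`` levels (edges join a
group by sharing an endpoint or, at ``pair`` level, an allelic-group
signature).  At the ``dr_dq`` and ``mhci_dr`` levels grouping is rooted on
the non-DR side: a DQ or MHCI haplotype associating with several DR
elements forms a group, while a DR element recurring across different DQ /
MHCI haplotypes does not by itself (the DR locus is the shared anchor
between the regions being compared).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Sequence

import networkx as nx

from .alleles import AlleleName
from .fixtures import Mhc2Row, cohort_rows
from .nomenclature import group_key

Level = Literal["pair", "dq_dup", "dr_dq", "mhci_dr"]
CLASSES = ("one_to_one", "index", "mu_gc", "recombination")


@dataclass(frozen=True)
class Edge:
    left: str
    right: str
    weight: int


@dataclass
class AssociationGraph:
    level: Level
    edges: list[Edge]
    classes: dict[tuple[str, str], str] = field(default_factory=dict)

    def class_of(self, left: str, right: str) -> str:
        return self.classes[(left, right)]


def _dq_token_group(token: str) -> str:
    return token[2:].split(".")[0]           # DQ12.3 -> "12"


def _dr_group(dr: str) -> str:
    return dr[2:].split(".")[0]              # DR27.3 -> "27"


def _allele_group(name: str) -> str:
    return "{}*{}".format(*group_key(AlleleName.parse(name.split("/")[0])))


def _hp_family(name: str) -> str:
    base = name[2:] if name.startswith("un") else name
    return base[len("HP1."):].rsplit(".", 1)[0]


GROUP_OF: Mapping[str, Callable[[str], str]] = {
    "allele": _allele_group,
    "dq_token": _dq_token_group,
    "dr": _dr_group,
    "hp": _hp_family,
    "dq_hap": lambda h: "|".join(_dq_token_group(t) for t in h.split("|")),
}


def build_graph(rows: Sequence[Mhc2Row], cohort: str, level: Level, *,
                include_presumed: bool = True,
                mhci_dr_pairs: Iterable[tuple[str, str, int]] | None = None) -> AssociationGraph:
    """Build the association graph for one cohort of the MHCII catalogue.

    ``pair`` joins DQA and DQB alleles within complete DQ pairs (orphan
    pairs with no DQA are excluded); ``dq_dup`` joins the two DQ-pair
    tokens of duplicated-DQ haplotypes; ``dr_dq`` joins DR tokens to DQ
    haplotypes.  ``mhci_dr`` requires explicit (mhci_haplotype, dr, weight)
    observations since the MHCII table does not carry class I data.
    """
    weights: Counter = Counter()
    if level == "mhci_dr":
        if mhci_dr_pairs is None:
            raise ValueError("mhci_dr level needs explicit MHCI/DR observations")
        for hp, dr, w in mhci_dr_pairs:
            weights[(hp, dr)] += w
    else:
        for r in cohort_rows(rows, cohort):
            w = r.count(cohort)
            if level == "pair":
                for (dqa, dqb), pres in zip(r.pairs, r.presumed_dqa):
                    if not include_presumed and pres:
                        continue
                    if dqa != "?":
                        weights[(dqa, dqb)] += w
            elif level == "dq_dup":
                if len(r.dq_tokens) == 2:
                    weights[tuple(sorted(r.dq_tokens))] += w
            elif level == "dr_dq":
                dq_hap = "|".join(sorted(r.dq_tokens))
                dr = r.base_name.split("|")[0]
                weights[(dq_hap, dr)] += w
            else:
                raise ValueError(f"unknown graph level {level!r}")
    edges = [Edge(l, r, w) for (l, r), w in sorted(weights.items())]
    return AssociationGraph(level=level, edges=edges)


_LEVEL_GROUPS: Mapping[Level, tuple[str, str]] = {
    "pair": ("allele", "allele"),
    "dq_dup": ("dq_token", "dq_token"),
    "dr_dq": ("dq_hap", "dr"),
    "mhci_dr": ("hp", "dr"),
}

#: levels where a group is rooted on the left (non-DR) element only
_ROOTED: frozenset = frozenset({"dr_dq", "mhci_dr"})


def classify_edges(graph: AssociationGraph,
                   group_of: tuple[Callable[[str], str], Callable[[str], str]] | None = None,
                   ) -> AssociationGraph:
    """Assign a class to every edge (see module docstring for the rules)."""
    if group_of is None:
        gl, gr = (GROUP_OF[k] for k in _LEVEL_GROUPS[graph.level])
    else:
        gl, gr = group_of
    edges = graph.edges
    g = nx.Graph()
    g.add_nodes_from(range(len(edges)))
    symmetric = graph.level not in _ROOTED
    for i, e in enumerate(edges):
        for j in range(i + 1, len(edges)):
            f = edges[j]
            share_left = e.left == f.left
            share_right = e.right == f.right
            same_signature = gl(e.left) == gl(f.left) and gr(e.right) == gr(f.right)
            if symmetric:
                if share_left or share_right or same_signature:
                    g.add_edge(i, j)
            else:
                if share_left:   # rooted on the non-DR element
                    g.add_edge(i, j)
    classes: dict[tuple[str, str], str] = {}
    for comp in nx.connected_components(g):
        comp_edges = sorted(comp, key=lambda i: (-edges[i].weight, edges[i].left, edges[i].right))
        if len(comp_edges) == 1:
            e = edges[comp_edges[0]]
            classes[(e.left, e.right)] = "one_to_one"
            continue
        index = edges[comp_edges[0]]
        classes[(index.left, index.right)] = "index"
        for i in comp_edges[1:]:
            e = edges[i]
            within_group = True
            differing = 0
            for side, grp in (("left", gl), ("right", gr)):
                a, b = getattr(e, side), getattr(index, side)
                if a == b:
                    continue
                differing += 1
                if grp(a) != grp(b):
                    within_group = False
            classes[(e.left, e.right)] = (
                "mu_gc" if within_group and differing > 0 else "recombination")
    graph.classes = classes
    return graph


@dataclass
class GraphSummary:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]
    promiscuity: dict[str, int]

    def percent(self, cls: str) -> float:
        return self.percentages.get(cls, 0.0)


def summarize(graph: AssociationGraph) -> GraphSummary:
    if not graph.classes:
        classify_edges(graph)
    counts = Counter(graph.classes.values())
    total = len(graph.edges)
    partners: dict[str, set] = defaultdict(set)
    for e in graph.edges:
        partners[e.left].add(e.right)
        partners[e.right].add(e.left)
    return GraphSummary(
        total=total,
        counts={c: counts.get(c, 0) for c in CLASSES},
        percentages={c: 100.0 * counts.get(c, 0) / total for c in CLASSES} if total else {},
        promiscuity={k: len(v) for k, v in sorted(partners.items())},
    )


def edges_to_tsv(graph: AssociationGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("level\tleft\tright\tweight\tclass\n")
        for e in graph.edges:
            cls = graph.classes.get((e.left, e.right), "")
            fh.write(f"{graph.level}\t{e.left}\t{e.right}\t{e.weight}\t{cls}\n")
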