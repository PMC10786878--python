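"""Assembly of PPI networks from per-dataset interactor calls.

Combination rules when pooling datasets: a protein significant in >=1
dataset is an interactor; a protein detected in >=1 dataset but significant
in none is a non-interactor; all index (bait) proteins of the contributing
datasets are excluded from both lists. Index-index edges (one bait called
significant in another bait's IP) are retained as edges so bait-bait links
survive, but index genes never enter the interactor or non-interactor lists
used as enrichment backgrounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import InteractorStats
from .io import ValidationError, canonical_edge

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["bait", "prey", "datasets", "known"]


@dataclass
class PPINetwork:
    """A bait-prey interaction network with enrichment backgrounds.

    ``edges`` has columns ``bait``, ``prey``, ``datasets`` (comma-joined
    supporting dataset ids) and ``known`` (reference-database flag, NaN
    until annotated). Interactor and non-interactor sets exclude all index
    proteins; every interactor is the prey of at least one edge.
    """

    scope: str
    index_proteins: set[str]
    edges: pd.DataFrame
    interactors: set[str]
    non_interactors: set[str]
    known_by_list: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interactors & self.non_interactors:
            raise ValidationError("interactors and non-interactors overlap")
        if self.index_proteins & (self.interactors | self.non_interactors):
            raise ValidationError("index proteins leaked into interactor lists")
        prey_with_edge = set(self.edges["prey"]) | set(self.edges["bait"])
        orphans = self.interactors - prey_with_edge
        if orphans:
            raise ValidationError(f"interactors without edges: {sorted(orphans)[:5]}")

    @property
    def edge_pairs(self) -> set[tuple[str, str]]:
        return {canonical_edge(b, p) for b, p in zip(self.edges["bait"], self.edges["prey"])}

    def copy(self) -> "PPINetwork":
        return replace(self, edges=self.edges.copy(),
                       index_proteins=set(self.index_proteins),
                       interactors=set(self.interactors),
                       non_interactors=set(self.non_interactors))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for gene in self.index_proteins:
            g.add_node(gene, role="index")
        for gene in self.interactors:
            g.add_node(gene, role="interactor")
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.bait, row.prey, datasets=row.datasets, known=row.known)
        return g


def build_network(datasets: Sequence[InteractorStats], scope: str = "combined",
                  require_qc: bool = True) -> PPINetwork:
    """Combine per-dataset calls into one network under the >=1-dataset rules."""
    if not datasets:
        raise ValidationError("no datasets supplied")
    if require_qc:
        bad = [d.dataset for d in datasets if d.qc_pass is False]
        if bad:
            raise ValidationError(f"datasets failed QC: {bad}")
    baits = {d.bait for d in datasets if d.bait is not None}
    significant: set[str] = set()
    detected: set[str] = set()
    edge_support: dict[tuple[str, str], list[str]] = {}
    for d in datasets:
        if d.bait is None:
            raise ValidationError(f"dataset {d.dataset}: bait gene not set")
        sig = d.significant
        detected |= d.detected
        significant |= sig
        for prey in sorted(sig):
            if prey == d.bait:
                continue  # self-loop: the bait enriching itself is a QC fact, not an edge
            edge_support.setdefault((d.bait, prey), []).append(d.dataset)
    interactors = significant - baits
    non_interactors = (detected - significant) - baits
    edges = pd.DataFrame(
        [(b, p, ",".join(ds), pd.NA) for (b, p), ds in sorted(edge_support.items())],
        columns=EDGE_COLUMNS,
    )
    return PPINetwork(scope, baits, edges, interactors, non_interactors)


def interactor_frequency(network: PPINetwork) -> tuple[pd.DataFrame, float]:
    """Number of distinct baits linked to each interactor, plus the fraction
    of interactors linked to more than one bait."""
    sub = network.edges[network.edges["prey"].isin(network.interactors)]
    freq = sub.groupby("prey")["bait"].nunique().rename("frequency")
    table = freq.reset_index().rename(columns={"prey": "gene"}).sort_values(
        ["frequency", "gene"], ascending=[False, True]).reset_index(drop=True)
    frac = float((table["frequency"] >= 2).mean()) if len(table) else 0.0
    return table, frac


def annotate_known_edges(
    network: PPINetwork,
    references: Mapping[str, set[tuple[str, str]]],
) -> tuple[PPINetwork, dict[str, float]]:
    """Flag each edge known iff its unordered gene pair appears in >=1
    reference edge list; returns the annotated network and per-list /
    any-list known fractions."""
    net = network.copy()
    canon = [canonical_edge(b, p) for b, p in zip(net.edges["bait"], net.edges["prey"])]
    ref_canon = {name: {canonical_edge(a, b) for a, b in ref}
                 for name, ref in references.items()}
    any_known = []
    summary: dict[str, float] = {}
    n_edges = len(canon)
    for name, ref in ref_canon.items():
        flags = [e in ref for e in canon]
        net.edges[f"known_{name}"] = flags
        summary[f"fraction_known_{name}"] = (sum(flags) / n_edges) if n_edges else 0.0
    for e in canon:
        any_known.append(any(e in ref for ref in ref_canon.values()))
    net.edges["known"] = any_known
    summary["fraction_known_any"] = (sum(any_known) / n_edges) if n_edges else 0.0
    net.known_by_list = ref_canon
    return net, summary


def celltype_partition(
    network_a: PPINetwork,
    network_b: PPINetwork,
    labels: tuple[str, str] = ("EC", "SMC"),
) -> dict[str, PPINetwork]:
    """Partition two cell-type networks into exclusive/shared interactor sets.

    Returns networks labelled ``"<A> only"``, ``"<B> only"``, ``"Intersect"``
    and ``"Union"``. The non-interactor background of each partition is the
    union of the contributing cell types' non-interactors minus that
    partition's interactors (and minus all index proteins).
    """
    la, lb = labels
    A, B = network_a.interactors, network_b.interactors
    baits = network_a.index_proteins | network_b.index_proteins
    parts = {
        f"{la} only": (A - B, (la,)),
        f"{lb} only": (B - A, (lb,)),
        "Intersect": (A & B, (la, lb)),
        "Union": (A | B, (la, lb)),
    }
    nets: dict[str, PPINetwork] = {}
    all_edges = pd.concat([network_a.edges.assign(cell_type=la),
                           network_b.edges.assign(cell_type=lb)], ignore_index=True)
    noni = {la: network_a.non_interactors, lb: network_b.non_interactors}
    for name, (inter, contribs) in parts.items():
        bg: set[str] = set().union(*(noni[c] for c in contribs))
        bg = (bg - inter) - baits
        keep = all_edges[all_edges["prey"].isin(inter)
                         | (all_edges["prey"].isin(baits) & all_edges["bait"].isin(baits))]
        nets[name] = PPINetwork(name, baits, keep.reset_index(drop=True), inter, bg)
    return nets


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_network(network: PPINetwork, edges_path: str | Path,
                  nodes_path: str | Path) -> None:
    """Serialize a network as an edge TSV plus a node TSV (deterministic
    order; round-trip safe via :func:`read_network`)."""
    edges = network.edges.sort_values(["bait", "prey"], kind="mergesort")
    edges.to_csv(edges_path, sep="\t", index=False, na_rep="NA")
    rows = (
        [(g, "index") for g in sorted(network.index_proteins)]
        + [(g, "interactor") for g in sorted(network.interactors)]
        + [(g, "non_interactor") for g in sorted(network.non_interactors)]
    )
    pd.DataFrame(rows, columns=["gene", "role"]).to_csv(nodes_path, sep="\t", index=False)


def read_network(edges_path: str | Path, nodes_path: str | Path,
                 scope: str = "combined") -> PPINetwork:
    edges = pd.read_csv(edges_path, sep="\t", na_values=["NA"], keep_default_na=False)
    nodes = pd.read_csv(nodes_path, sep="\t")
    roles = nodes.groupby("role")["gene"].apply(set).to_dict()
    return PPINetwork(
        scope,
        roles.get("index", set()),
        edges,
        roles.get("interactor", set()),
        roles.get("non_interactor", set()),
    )
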