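"""Protein interaction subnetworks, radiality centrality, TF identification,
the tripartite TF-lncRNA-gene network and generic hypergeometric enrichment.

Radiality of node v in a connected component with n >= 2 nodes and unweighted
diameter D is

    Crad(v) = sum over w != v of (D + 1 - dist(v, w)) / (n - 1),

computed per connected component (D and n taken from the component);
singleton components score 0. Nodes are ranked network-wide by descending
Crad, ties broken lexicographically by id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cis_targets import CisTargetLink
from .coexpression import CoexpressionPair

__all__ = [
    "CentralityResult",
    "TFRecord",
    "TripartiteNetwork",
    "build_subnetwork",
    "radiality",
    "identify_tfs",
    "assemble_tripartite",
    "hypergeom_enrich",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 0.7


def build_subnetwork(
    all_edges: pd.DataFrame,
    seed_nodes: set[str],
    min_score: float = DEFAULT_MIN_SCORE,
) -> nx.Graph:
    """Induced interaction subgraph on ``seed_nodes`` at score >= ``min_score``.

    ``all_edges`` needs columns gene_a, gene_b, score with scores in [0, 1]
    (validated). Self-loops are discarded, duplicate pairs keep the highest
    score, and seed nodes left without a qualifying edge are dropped.
    """
    required = {"gene_a", "gene_b", "score"}
    if not required.issubset(all_edges.columns):
        raise ValueError(f"edge table needs columns {sorted(required)}")
    s = all_edges["score"]
    if ((s < 0) | (s > 1)).any():
        bad = all_edges.loc[(s < 0) | (s > 1)].head(3)
        raise ValueError(f"interaction scores must lie in [0, 1]; offending:\n{bad}")
    g = nx.Graph(induced=True, min_score=min_score)
    for a, b, score in all_edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
        if a == b or a not in seed_nodes or b not in seed_nodes:
            continue
        if score < min_score:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(score))
        else:
            g.add_edge(a, b, score=float(score))
    if g.number_of_edges() == 0:
        log.warning("no interactions passed the %.2f score threshold", min_score)
    return g


@dataclass(frozen=True)
class CentralityResult:
    node: str
    component: int
    crad: float
    degree: int
    rank: int  # 1-based, descending Crad, lexicographic tie-break


def radiality(net: nx.Graph) -> list[CentralityResult]:
    """Radiality centrality per node, ranked network-wide.

    Raises ``ValueError`` on an empty graph.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("radiality needs a non-empty network")
    crad: dict[str, float] = {}
    comp_of: dict[str, int] = {}
    for ci, comp in enumerate(
        sorted(nx.connected_components(net), key=lambda c: sorted(c)[0])
    ):
        n = len(comp)
        if n == 1:
            (v,) = comp
            crad[v] = 0.0
            comp_of[v] = ci
            continue
        sub = net.subgraph(comp)
        ecc = nx.eccentricity(sub)
        diameter = max(ecc.values())
        for v in comp:
            dist = nx.single_source_shortest_path_length(sub, v)
            total = sum(diameter + 1 - d for w, d in dist.items() if w != v)
            crad[v] = total / (n - 1)
            comp_of[v] = ci
    order = sorted(crad, key=lambda v: (-crad[v], v))
    return [
        CentralityResult(
            node=v,
            component=comp_of[v],
            crad=crad[v],
            degree=net.degree[v],
            rank=i + 1,
        )
        for i, v in enumerate(order)
    ]


@dataclass(frozen=True)
class TFRecord:
    gene_id: str
    family: str
    is_fd_detf: bool


def identify_tfs(
    genes: set[str],
    tf_table: pd.Series | dict,
    fd_degs: set[str] | None = None,
) -> list[TFRecord]:
    """Look up which genes are transcription factors.

    ``tf_table`` maps gene id -> family label (the TF-database lookup that
    stands in for an HMM domain scan). ``is_fd_detf`` marks TFs that are also
    FD-DEGs. Results are sorted by gene id.
    """
    table = dict(tf_table)
    fd_degs = fd_degs or set()
    return [
        TFRecord(g, str(table[g]), g in fd_degs)
        for g in sorted(genes)
        if g in table
    ]


@dataclass
class TripartiteNetwork:
    """Directed lncRNA -> TF (cis) and TF -> gene (regulatory) network."""

    graph: nx.DiGraph

    def _nodes(self, kind: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == kind}

    @property
    def tf_nodes(self) -> set[str]:
        return self._nodes("TF")

    @property
    def lncrna_nodes(self) -> set[str]:
        return self._nodes("lncRNA")

    @property
    def gene_nodes(self) -> set[str]:
        return self._nodes("gene")

    def tf_out_degree(self) -> pd.Series:
        """Number of target genes per TF (descending)."""
        d = {tf: self.graph.out_degree(tf) for tf in self.tf_nodes}
        return pd.Series(d, dtype=int).sort_values(ascending=False)

    def tf_in_degree(self) -> pd.Series:
        """Number of lncRNAs targeting each TF (descending)."""
        d = {tf: self.graph.in_degree(tf) for tf in self.tf_nodes}
        return pd.Series(d, dtype=int).sort_values(ascending=False)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d["kind"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_kind"])


def assemble_tripartite(
    fd_detfs: set[str],
    cis_links: list[CisTargetLink],
    tf_deg_pairs: list[CoexpressionPair],
) -> TripartiteNetwork:
    """Assemble the TF-centred tripartite network.

    A lncRNA -> TF edge is added for every cis link whose gene is an FD-DETF;
    a TF -> gene edge for every selected TF-target pair. TFs left without any
    incident edge are excluded, so every node in the result is connected.
    """
    g = nx.DiGraph()
    for link in cis_links:
        if link.gene_id in fd_detfs:
            g.add_node(link.lncrna_id, kind="lncRNA")
            g.add_node(link.gene_id, kind="TF")
            g.add_edge(link.lncrna_id, link.gene_id, kind="cis")
    for p in tf_deg_pairs:
        if p.lncrna_id in fd_detfs:
            g.add_node(p.lncrna_id, kind="TF")
            g.add_node(p.gene_id, kind="gene")
            g.add_edge(p.lncrna_id, p.gene_id, kind="regulatory", r=p.r)
    isolated = [n for n in g.nodes if g.degree(n) == 0]
    g.remove_nodes_from(isolated)
    return TripartiteNetwork(graph=g)


def hypergeom_enrich(
    selected: set[str],
    universe: set[str],
    term_table: pd.DataFrame,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``selected`` within ``universe``.

    ``term_table`` needs columns term_id, gene_id (term_name optional). For a
    term with K universe members of which k are selected, p = P(X >= k) under
    Hypergeom(M=|universe|, K, n=|selected|); fold enrichment is
    (k/n)/(K/M). BH-adjusted p-values are reported; ``significant`` uses the
    raw p-value at ``p_cut``.
    """
    extra = selected - universe
    if extra:
        raise ValueError(f"selected ids outside the universe: {sorted(extra)[:10]}")
    required = {"term_id", "gene_id"}
    if not required.issubset(term_table.columns):
        raise ValueError(f"term table needs columns {sorted(required)}")
    tt = term_table[term_table["gene_id"].isin(universe)]
    M, n = len(universe), len(selected)
    names = (
        tt.drop_duplicates("term_id").set_index("term_id")["term_name"]
        if "term_name" in tt.columns
        else None
    )
    rows = []
    for term, sub in tt.groupby("term_id", sort=True):
        members = set(sub["gene_id"])
        K, k = len(members), len(members & selected)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if n else 1.0
        fold = (k / n) / (K / M) if n and K else 0.0
        if k == 0:
            fold = 0.0
        rows.append((term, K, k, fold, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "term_size", "n_selected", "fold_enrichment", "pvalue"]
    )
    if len(out):
        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["significant"] = out["pvalue"] < p_cut
        if names is not None:
            out.insert(1, "term_name", out["term_id"].map(names))
        out = out.sort_values(["pvalue", "term_id"]).reset_index(drop=True)
    return out
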