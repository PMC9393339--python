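"""End-to-end orchestration: lncRNA calling -> quantification/DE -> cis
targets -> FD intersection -> coexpression -> networks -> enrichment.

The pipeline is deterministic; all randomness lives in :mod:`lncfat.synthetic`.
Stage outputs are written as TSVs under the output directory and every count
in the run report is re-derivable from them.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as ann_mod
from . import cis_targets as cis_mod
from . import coexpression as coex_mod
from . import lncrna_id as lnc_mod
from . import networks as net_mod
from . import quant as quant_mod
from .synthetic import SyntheticDataset

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_inputs"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Input locations and every analysis threshold (defaults as published)."""

    # inputs (unused when an in-memory dataset is supplied)
    gtf: str | None = None
    counts: str | None = None
    effective_lengths: str | None = None
    samples: str | None = None  # TSV sample -> tissue
    votes: str | None = None
    reference_ids: str | None = None
    fd_genes: str | None = None
    tf_table: str | None = None
    binding_scores: str | None = None
    ppi_edges: str | None = None
    term_table: str | None = None
    outdir: str = "lncfat_out"
    # thresholds
    fpkm_threshold: float = 0.1
    fc_cut: float = 1.0
    p_cut: float = 0.05
    pseudocount: float = 1.0
    cis_window: int = 100_000
    ppi_min_score: float = 0.7
    key_r_cut: float = 0.9
    tf_r_cut: float = 0.8
    binding_score_cut: float = 3.0
    core_size: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Headline counts of every stage, mirroring the study's summary tables."""

    n_transcripts: int = 0
    n_lncrna_candidates: int = 0
    n_novel_lncrnas: int = 0
    n_known_lncrnas: int = 0
    n_expressed_features: int = 0
    n_dels: int = 0
    n_dels_up: int = 0
    n_dels_down: int = 0
    n_dels_st_specific: int = 0
    n_dels_lt_specific: int = 0
    n_demrs: int = 0
    n_demrs_up: int = 0
    n_demrs_down: int = 0
    n_degs: int = 0
    n_cis_links: int = 0
    n_fd_dels: int = 0
    fd_del_pct: float = 0.0
    n_fd_degs: int = 0
    fd_deg_pct: float = 0.0
    n_key_lncrnas: int = 0
    n_fd_detfs: int = 0
    ppi_nodes: int = 0
    ppi_edges: int = 0
    core_nodes: int = 0
    tripartite_tfs: int = 0
    tripartite_lncrnas: int = 0
    tripartite_genes: int = 0
    n_terms_significant: int = 0
    key_lncrnas: set[str] = field(default_factory=set)
    fd_detfs: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in asdict(self).items()
                if not isinstance(v, set)]
        return pd.DataFrame(rows, columns=["metric", "value"])

    def to_text(self) -> str:
        lines = ["lncfat run report", "=" * 40]
        for k, v in asdict(self).items():
            if isinstance(v, set):
                lines.append(f"{k:24s} {len(v)} ids")
            else:
                lines.append(f"{k:24s} {v}")
        return "\n".join(lines) + "\n"


def load_inputs(cfg: RunConfig) -> SyntheticDataset:
    """Read pipeline inputs from the paths in ``cfg`` into a dataset bundle."""
    from .synthetic import GeneratorConfig, GroundTruth

    transcripts = ann_mod.read_gtf(cfg.gtf)
    counts = pd.read_csv(cfg.counts, sep="\t", index_col=0)
    lengths = pd.read_csv(cfg.effective_lengths, sep="\t", index_col=0).iloc[:, 0]
    tissues = pd.read_csv(cfg.samples, sep="\t", index_col=0).iloc[:, 0]
    votes = lnc_mod.read_votes(cfg.votes)
    ref = set(Path(cfg.reference_ids).read_text().split()) if cfg.reference_ids else set()
    fd = set(Path(cfg.fd_genes).read_text().split())
    tf_table = pd.read_csv(cfg.tf_table, sep="\t", index_col=0).iloc[:, 0].to_dict()
    binding = pd.read_csv(cfg.binding_scores, sep="\t")
    ppi = pd.read_csv(cfg.ppi_edges, sep="\t")
    terms = pd.read_csv(cfg.term_table, sep="\t") if cfg.term_table else pd.DataFrame(
        columns=["term_id", "gene_id"])
    tx_of_gene: dict[str, str] = {}
    for t in transcripts:
        tx_of_gene.setdefault(t.gene_id, t.transcript_id)
    return SyntheticDataset(
        config=GeneratorConfig(seed=cfg.seed),
        transcripts=transcripts,
        counts=counts,
        effective_lengths=lengths,
        tissues=tissues,
        votes=votes,
        reference_ids=ref,
        fd_genes=fd,
        tf_table=tf_table,
        binding_scores=binding,
        ppi_edges=ppi,
        term_table=terms,
        truth=GroundTruth(pd.Series(dtype=object), [], set(), {}, set(), set()),
        tx_of_gene=tx_of_gene,
    )


def run_pipeline(cfg: RunConfig, data: SyntheticDataset | None = None
                 ) -> RunReport:
    """Execute every stage on ``data`` (or the inputs named in ``cfg``).

    Writes stage TSVs plus ``report.tsv``/``report.txt`` under ``cfg.outdir``
    and returns the :class:`RunReport`. A stage failure aborts with the stage
    name; outputs of completed stages are retained.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = load_inputs(cfg)
    report = RunReport(n_transcripts=len(data.transcripts))
    stage = "setup"
    t0 = time.time()

    def tick(name):
        nonlocal stage, t0
        log.info("stage %-14s done in %.2fs", stage, time.time() - t0)
        stage, t0 = name, time.time()

    try:
        # --- lncRNA identification -------------------------------------
        stage = "lncrna_id"
        consensus = lnc_mod.consensus_noncoding(data.votes, data.transcripts)
        candidates = consensus.candidates
        novelty = lnc_mod.flag_novel(candidates, data.reference_ids)
        report.n_lncrna_candidates = len(candidates)
        report.n_novel_lncrnas = sum(novelty.values())
        report.n_known_lncrnas = len(candidates) - report.n_novel_lncrnas
        lnc_mod.write_ids(candidates, out / "lncrna_candidates.txt")
        coding_tx = [t for t in data.transcripts if t.biotype == "protein_coding"]
        lncs = [t for t in data.transcripts if t.transcript_id in candidates]
        for t in lncs:
            t.novel = novelty[t.transcript_id]
            t.structural_class = ann_mod.classify_structure(t, coding_tx)
        if lncs:
            (out / "lncrna_summary.tsv").write_text(
                ann_mod.summarize(lncs).to_tsv())

        # --- quantification and differential screen --------------------
        tick("quant_de")
        matrix = quant_mod.compute_fpkm(
            data.counts, data.effective_lengths, data.tissues)
        matrix = quant_mod.filter_expressed(matrix, cfg.fpkm_threshold)
        report.n_expressed_features = len(matrix.features)
        de = quant_mod.differential_screen(
            matrix, cfg.fc_cut, cfg.p_cut, cfg.pseudocount)
        de.rename_axis("feature_id").to_csv(out / "differential.tsv", sep="\t")

        tx2gene = {t.transcript_id: t.gene_id for t in data.transcripts}
        is_lnc = de.index.isin(candidates)
        is_coding = de.index.map(
            lambda i: tx2gene.get(i) is not None and i not in candidates
            and i in {t.transcript_id for t in coding_tx})
        de_status = de["status"]
        dels = set(de.index[is_lnc & (de_status != "ns")])
        del_tab = de.loc[list(dels)]
        report.n_dels = len(dels)
        report.n_dels_up = int((del_tab["status"] == "up").sum())
        report.n_dels_down = int((del_tab["status"] == "down").sum())
        report.n_dels_st_specific = int(
            (del_tab["specificity"] == "ST_specific").sum())
        report.n_dels_lt_specific = int(
            (del_tab["specificity"] == "LT_specific").sum())
        demrs = set(de.index[pd.Series(list(is_coding), index=de.index)
                             & (de_status != "ns")])
        demr_tab = de.loc[list(demrs)]
        report.n_demrs = len(demrs)
        report.n_demrs_up = int((demr_tab["status"] == "up").sum())
        report.n_demrs_down = int((demr_tab["status"] == "down").sum())
        degs = {tx2gene[t] for t in demrs}
        report.n_degs = len(degs)

        # --- cis targets and FD intersection ---------------------------
        tick("cis_targets")
        spans = cis_mod.gene_spans(coding_tx)
        links = cis_mod.assign_cis_targets(
            [t for t in lncs], spans, cfg.cis_window)
        report.n_cis_links = len(links)
        cis_mod.links_to_frame(links).to_csv(
            out / "cis_links.tsv", sep="\t", index=False)
        fd_sets = cis_mod.intersect_fd(dels, degs, data.fd_genes, links)
        report.n_fd_dels = len(fd_sets.fd_dels)
        report.fd_del_pct = fd_sets.fd_del_pct
        report.n_fd_degs = len(fd_sets.fd_degs)
        report.fd_deg_pct = fd_sets.fd_deg_pct

        # --- coexpression: key lncRNAs ---------------------------------
        tick("coexpression")
        expressed = set(matrix.features)
        pair_links = [
            l for l in links
            if l.lncrna_id in fd_sets.fd_dels
            and l.gene_id in fd_sets.fd_degs
            and l.lncrna_id in expressed
            and data.tx_of_gene.get(l.gene_id) in expressed
        ]
        coex_pairs = coex_mod.pearson_pairs(
            matrix,
            [(l.lncrna_id, data.tx_of_gene[l.gene_id]) for l in pair_links],
            cfg.pseudocount,
        )
        # rewrite gene transcript ids back to gene ids for selection
        coex_pairs = [
            coex_mod.CoexpressionPair(p.lncrna_id, l.gene_id, p.r, p.n_samples)
            for p, l in zip(coex_pairs, pair_links)
        ]
        keys = coex_mod.select_key_lncrnas(
            coex_pairs, fd_sets.fd_dels, fd_sets.fd_degs, cfg.key_r_cut)
        report.n_key_lncrnas = len(keys)
        report.key_lncrnas = keys
        coex_mod.pairs_to_frame(coex_pairs, keys).to_csv(
            out / "key_lncrna_pairs.tsv", sep="\t", index=False)

        # --- PPI subnetwork and radiality core -------------------------
        tick("networks")
        ppi = net_mod.build_subnetwork(
            data.ppi_edges, fd_sets.fd_degs, cfg.ppi_min_score)
        report.ppi_nodes = ppi.number_of_nodes()
        report.ppi_edges = ppi.number_of_edges()
        if ppi.number_of_nodes():
            cent = net_mod.radiality(ppi)
            core = cent[: cfg.core_size]
            report.core_nodes = len(core)
            pd.DataFrame(
                [(c.node, c.component, c.crad, c.degree, c.rank) for c in cent],
                columns=["node", "component", "crad", "degree", "rank"],
            ).to_csv(out / "radiality.tsv", sep="\t", index=False)

        # --- TFs and the tripartite network ----------------------------
        tf_records = net_mod.identify_tfs(degs, data.tf_table, fd_sets.fd_degs)
        fd_detfs = {r.gene_id for r in tf_records if r.is_fd_detf}
        report.n_fd_detfs = len(fd_detfs)
        report.fd_detfs = fd_detfs
        # TFs cis-targeted by FD-DELs drive the regulatory-target analysis
        cis_tfs = {
            l.gene_id for l in links
            if l.lncrna_id in fd_sets.fd_dels and l.gene_id in fd_detfs
        }
        cand = data.binding_scores[
            data.binding_scores["tf_id"].isin(cis_tfs)
            & data.binding_scores["gene_id"].isin(fd_sets.fd_degs)
        ]
        tf_pairs_expr = [
            (tf, g) for tf, g in cand[["tf_id", "gene_id"]].itertuples(index=False)
            if data.tx_of_gene.get(tf) in expressed
            and data.tx_of_gene.get(g) in expressed and tf != g
        ]
        tf_coex = coex_mod.pearson_pairs(
            matrix,
            [(data.tx_of_gene[tf], data.tx_of_gene[g]) for tf, g in tf_pairs_expr],
            cfg.pseudocount,
        )
        tf_coex = [
            coex_mod.CoexpressionPair(tf, g, p.r, p.n_samples)
            for p, (tf, g) in zip(tf_coex, tf_pairs_expr)
        ]
        scores = {(r.tf_id, r.gene_id): r.score
                  for r in data.binding_scores.itertuples(index=False)}
        kept_pairs = coex_mod.select_tf_deg_pairs(
            tf_coex, scores, cfg.binding_score_cut, cfg.tf_r_cut)
        tri_links = [l for l in links
                     if l.lncrna_id in fd_sets.fd_dels and l.gene_id in cis_tfs]
        tri = net_mod.assemble_tripartite(cis_tfs, tri_links, kept_pairs)
        report.tripartite_tfs = len(tri.tf_nodes)
        report.tripartite_lncrnas = len(tri.lncrna_nodes)
        report.tripartite_genes = len(tri.gene_nodes)
        tri.to_edge_frame().to_csv(out / "tripartite_edges.tsv", sep="\t",
                                   index=False)

        # --- enrichment -------------------------------------------------
        tick("enrichment")
        if len(data.term_table):
            universe = {t.gene_id for t in coding_tx}
            enrich = net_mod.hypergeom_enrich(
                fd_sets.fd_degs & universe, universe, data.term_table, cfg.p_cut)
            report.n_terms_significant = int(enrich["significant"].sum()) if len(enrich) else 0
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        tick("done")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    (out / "report.txt").write_text(report.to_text())
    return report
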