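"""Synthetic two-muscle RNA-seq study with known ground truth.

Emulates the study design the pipeline targets: two tissues (LT and ST,
i.e. longissimus thoracis vs semitendinosus) with three replicates each,
negative-binomial fragment counts, planted differential features, planted
lncRNA-gene coexpression within the cis window, and toy versions of every
external table (coding-potential votes, fat-deposition gene list, TF family
table, TF binding scores, scored PPI edges, term-gene annotations).

Layout: every coding gene, and every "far" intergenic lncRNA, occupies its
own 400 kb block so that unrelated features are always separated by well over
the 100 kb cis window. Planted coexpressed lncRNAs are placed 1-80 kb from
their partner gene inside the partner's block; intronic / antisense /
sense-overlapping lncRNAs are hosted inside non-differential genes.

Counts for feature g in sample s are NegativeBinomial with mean
mu_g * 2^(+/-lfc) in ST for differential features and gene-wise log-normal
baselines mu_g; planted (lncRNA, gene) pairs additionally share a per-sample
log-normal latent factor whose variance is solved from the target pair
correlation after accounting for the shared tissue effect and the
NB measurement noise (at the defaults the tissue effect alone already
realises the 0.95 target, so the factor variance is ~0).

All randomness flows from ``GeneratorConfig.seed`` through per-stage child
seeds, so each generator function is individually deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .annotation import GenomicInterval, TranscriptModel, write_gtf
from .lncrna_id import CodingPotentialVote

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticDataset",
           "generate_annotation", "generate_counts", "generate_side_tables",
           "generate_dataset"]

_TF_FAMILIES = ("zf-C2H2", "bHLH", "Homeobox", "bZIP", "MYB", "ETS", "T-box")


@dataclass
class GeneratorConfig:
    """Study-design knobs; the defaults define the standard test conditions."""

    seed: int = 0
    # design
    n_coding_genes: int = 600
    n_lncrnas: int = 150
    replicates: int = 3
    n_chromosomes: int = 3
    block_bp: int = 400_000
    # differential structure
    frac_differential: float = 0.30
    planted_log2fc: float = 2.0
    # counts model
    dispersion: float = 0.02
    mean_scale: float = 500.0
    mean_sigma: float = 0.5
    stable_mean_floor: float = 200.0
    # planted coexpression
    n_planted_pairs: int = 25
    planted_r: float = 0.95
    # lncRNA structural-class mix (intergenic takes the remainder)
    frac_intronic: float = 0.44
    frac_antisense: float = 0.06
    frac_sense_overlapping: float = 0.10
    # tissue-specific (on/off) features among the decoy differential ones
    n_tissue_specific_lnc: int = 8
    n_tissue_specific_coding: int = 15
    # external-table structure
    frac_known: float = 0.20
    vote_error_rate: float = 0.01
    fd_coverage: float = 0.45
    n_fd_decoys: int = 200
    n_planted_tfs: int = 5
    lnc_per_tf: int = 2
    targets_per_tf: int = 4
    n_decoy_tfs: int = 15
    n_decoy_binding_pairs: int = 40
    ppi_core_size: int = 12
    ppi_background_density: float = 0.02
    n_terms: int = 12
    term_size_range: tuple[int, int] = (20, 60)

    def __post_init__(self) -> None:
        for name in ("frac_differential", "frac_intronic", "frac_antisense",
                     "frac_sense_overlapping", "frac_known", "vote_error_rate",
                     "fd_coverage", "ppi_background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_intronic + self.frac_antisense + self.frac_sense_overlapping > 1:
            raise ValueError("structural-class fractions exceed 1")
        if not 0.0 < self.planted_r < 1.0:
            raise ValueError("planted_r must lie in (0, 1)")

    def chromosome_lengths(self) -> dict[str, int]:
        n_blocks = self.n_coding_genes + self.n_lncrnas  # generous upper bound
        per_chrom = -(-n_blocks // self.n_chromosomes)
        return {f"chr{i + 1}": per_chrom * self.block_bp
                for i in range(self.n_chromosomes)}

    def _child_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed).spawn(4)[stage]
        )


@dataclass
class GroundTruth:
    """Everything the generator planted, for closing the loop in tests."""

    true_status: pd.Series  # per transcript: up / down / ns (ST vs LT)
    planted_pairs: list[tuple[str, str]]  # (lnc transcript id, gene id)
    planted_key_lncrnas: set[str]
    structural_class: dict[str, str]  # per lncRNA transcript id
    reference_known_ids: set[str]
    true_lncrna_ids: set[str]
    fd_genes: set[str] = field(default_factory=set)
    planted_tfs: set[str] = field(default_factory=set)
    planted_tf_pairs: list[tuple[str, str]] = field(default_factory=list)
    ppi_core: set[str] = field(default_factory=set)
    roles: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        pair_of = dict(self.planted_pairs)
        rows = []
        for fid, status in self.true_status.items():
            rows.append({
                "feature_id": fid,
                "true_status": status,
                "is_lncrna": fid in self.true_lncrna_ids,
                "structural_class": self.structural_class.get(fid, ""),
                "planted_key": fid in self.planted_key_lncrnas,
                "planted_partner": pair_of.get(fid, ""),
                "known": fid in self.reference_known_ids,
            })
        return pd.DataFrame(rows).set_index("feature_id")


@dataclass
class _Annotation:
    transcripts: list[TranscriptModel]
    reference_known_ids: set[str]
    truth: GroundTruth
    tx_of_gene: dict[str, str]


def _make_gene(rng, chrom, strand, start, n_exons, exon_rng=(120, 400),
               intron_rng=(800, 3000)) -> list[GenomicInterval]:
    exons, pos = [], start
    for i in range(n_exons):
        elen = int(rng.integers(*exon_rng))
        exons.append(GenomicInterval(chrom, pos, pos + elen - 1, strand))
        if i < n_exons - 1:
            pos += elen + int(rng.integers(*intron_rng))
        else:
            pos += elen
    return exons


def _make_lnc_exons(rng, chrom, strand, start, total_len, n_exons) -> list[GenomicInterval]:
    if n_exons == 1:
        return [GenomicInterval(chrom, start, start + total_len - 1, strand)]
    cuts = np.sort(rng.choice(np.arange(1, total_len), n_exons - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [total_len]]))
    exons, pos = [], start
    for s in sizes:
        exons.append(GenomicInterval(chrom, pos, pos + int(s) - 1, strand))
        pos += int(s) + int(rng.integers(300, 1500))
    return exons


def generate_annotation(cfg: GeneratorConfig) -> _Annotation:
    """Place coding genes and lncRNAs; returns transcripts + placement truth.

    Raises ``ValueError`` when the requested lncRNA mix cannot be packed into
    the available host genes (suggesting a larger design).
    """
    rng = cfg._child_rng(0)
    chroms = list(cfg.chromosome_lengths())

    n_int = round(cfg.frac_intronic * cfg.n_lncrnas)
    n_anti = round(cfg.frac_antisense * cfg.n_lncrnas)
    n_sense = round(cfg.frac_sense_overlapping * cfg.n_lncrnas)
    n_pairs = min(cfg.n_planted_pairs, cfg.n_lncrnas - n_int - n_anti - n_sense)
    if n_pairs < 0:
        raise ValueError("structural-class fractions leave no room for planted pairs")
    n_far = cfg.n_lncrnas - n_int - n_anti - n_sense - n_pairs

    # partner genes: the first n_planted_tfs get lnc_per_tf lncRNAs each
    tf_lncs = min(cfg.n_planted_tfs * cfg.lnc_per_tf, n_pairs)
    n_partner_genes = cfg.n_planted_tfs + (n_pairs - tf_lncs) if n_pairs else 0
    n_de_coding = round(cfg.frac_differential * cfg.n_coding_genes)
    n_targets = cfg.n_planted_tfs * cfg.targets_per_tf
    n_other_de = n_de_coding - n_partner_genes - n_targets
    if n_other_de < 0 or n_partner_genes + n_targets > cfg.n_coding_genes:
        raise ValueError("frac_differential too small for the planted structure")
    n_quiet = cfg.n_coding_genes - n_partner_genes - n_targets - max(n_other_de, 0)
    n_hosted = n_int + n_anti + n_sense
    if n_quiet < n_hosted:
        raise ValueError(
            f"not enough non-differential host genes ({n_quiet}) for {n_hosted} "
            "hosted lncRNAs; increase n_coding_genes or chromosome capacity"
        )

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_coding_genes)]
    partner_genes = gene_ids[:n_partner_genes]
    target_genes = gene_ids[n_partner_genes:n_partner_genes + n_targets]
    other_de = gene_ids[n_partner_genes + n_targets:
                        n_partner_genes + n_targets + n_other_de]
    quiet = gene_ids[n_partner_genes + n_targets + n_other_de:]
    host_ids = list(rng.permutation(quiet)[:n_hosted])

    # each partner gene's attached lncRNAs
    lnc_alloc: dict[str, int] = {}
    k = 0
    for gi, g in enumerate(partner_genes):
        want = cfg.lnc_per_tf if gi < cfg.n_planted_tfs else 1
        lnc_alloc[g] = min(want, n_pairs - k)
        k += lnc_alloc[g]

    transcripts: list[TranscriptModel] = []
    tx_of_gene: dict[str, str] = {}
    structural: dict[str, str] = {}
    planted_pairs: list[tuple[str, str]] = []
    lnc_counter = 0

    def new_lnc_id():
        nonlocal lnc_counter
        lnc_counter += 1
        return f"LNC{lnc_counter:04d}.t1"

    # assign blocks round-robin across chromosomes
    block_of: dict[str, tuple[str, int]] = {}
    next_block = {c: 0 for c in chroms}
    items = gene_ids + [f"FARBLOCK{i}" for i in range(n_far)]
    for i, item in enumerate(items):
        c = chroms[i % len(chroms)]
        block_of[item] = (c, next_block[c])
        next_block[c] += 1

    host_iter = iter(host_ids)
    hosts = {"intronic": [next(host_iter) for _ in range(n_int)],
             "antisense": [next(host_iter) for _ in range(n_anti)],
             "sense_overlapping": [next(host_iter) for _ in range(n_sense)]}
    host_role = {g: role for role, gs in hosts.items() for g in gs}

    for g in gene_ids:
        chrom, block = block_of[g]
        base = block * cfg.block_bp
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(3, 9))
        start = base + 150_000 + int(rng.integers(0, 5_000))
        exons = _make_gene(rng, chrom, strand, start, n_exons)
        tid = f"{g}.t1"
        transcripts.append(TranscriptModel(tid, g, exons, biotype="protein_coding"))
        tx_of_gene[g] = tid
        gene_start, gene_end = exons[0].start, exons[-1].end

        for _ in range(lnc_alloc.get(g, 0)):
            lid = new_lnc_id()
            upstream = rng.random() < 0.5
            length = int(rng.integers(400, 1500))
            gap = int(rng.integers(1_000, 80_000))
            lstrand = "+" if rng.random() < 0.5 else "-"
            if upstream:
                lend = gene_start - gap - 1
                lex = _make_lnc_exons(rng, chrom, lstrand, lend - length + 1,
                                      length, 1)
            else:
                lex = _make_lnc_exons(rng, chrom, lstrand, gene_end + gap + 1,
                                      length, 1)
            transcripts.append(TranscriptModel(lid, lid.split(".")[0], lex,
                                               biotype="lncRNA_candidate"))
            structural[lid] = "intergenic"
            planted_pairs.append((lid, g))

        role = host_role.get(g)
        if role == "intronic":
            introns = sorted(
                TranscriptModel(tid + "_tmp", g, exons).introns(),
                key=len, reverse=True)
            intron = introns[0]
            llen = min(int(rng.integers(250, 700)), len(intron) - 4)
            lid = new_lnc_id()
            lstrand = "+" if rng.random() < 0.5 else "-"
            lex = [GenomicInterval(chrom, intron.start + 2,
                                   intron.start + 1 + llen, lstrand)]
            transcripts.append(TranscriptModel(lid, lid.split(".")[0], lex,
                                               biotype="lncRNA_candidate"))
            structural[lid] = "intronic"
        elif role in ("antisense", "sense_overlapping"):
            ex = exons[int(rng.integers(0, len(exons)))]
            llen = int(rng.integers(300, 700))
            lid = new_lnc_id()
            lstrand = strand if role == "sense_overlapping" else ("-" if strand == "+" else "+")
            lex = [GenomicInterval(chrom, ex.start + 1, ex.start + llen, lstrand)]
            transcripts.append(TranscriptModel(lid, lid.split(".")[0], lex,
                                               biotype="lncRNA_candidate"))
            structural[lid] = role

    for i in range(n_far):
        chrom, block = block_of[f"FARBLOCK{i}"]
        base = block * cfg.block_bp
        lid = new_lnc_id()
        lstrand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(300, 2_000))
        n_exons = int(rng.integers(1, 4))
        lex = _make_lnc_exons(rng, chrom, lstrand, base + 200_000, length, n_exons)
        transcripts.append(TranscriptModel(lid, lid.split(".")[0], lex,
                                           biotype="lncRNA_candidate"))
        structural[lid] = "intergenic"

    lnc_ids = [t.transcript_id for t in transcripts
               if t.biotype == "lncRNA_candidate"]
    known = set(rng.permutation(lnc_ids)[:round(cfg.frac_known * len(lnc_ids))])

    truth = GroundTruth(
        true_status=pd.Series(dtype=object),
        planted_pairs=planted_pairs,
        planted_key_lncrnas={l for l, _ in planted_pairs},
        structural_class=structural,
        reference_known_ids=known,
        true_lncrna_ids=set(lnc_ids),
        roles={
            "partner_genes": partner_genes,
            "target_genes": target_genes,
            "other_de": other_de,
            "quiet": quiet,
            "far_lnc": lnc_ids[-n_far:] if n_far else [],
        },
    )
    return _Annotation(transcripts, known, truth, tx_of_gene)


def _noise_var_log2(mu: float, phi: float) -> float:
    # delta-method variance of log2 counts for NB(mean mu, dispersion phi)
    return (1.0 / max(mu, 1.0) + phi) / np.log(2.0) ** 2


def generate_counts(cfg: GeneratorConfig, ann: _Annotation
                    ) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """NB counts for the 2-tissue x replicate design; fills in true DE status.

    Returns (counts, effective_lengths, truth); sample ids are LT1..LTn,
    ST1..STn and effective length is the spliced transcript length.
    """
    rng = cfg._child_rng(1)
    roles = ann.truth.roles
    samples = ([f"LT{i + 1}" for i in range(cfg.replicates)] +
               [f"ST{i + 1}" for i in range(cfg.replicates)])
    st_mask = np.array([0] * cfg.replicates + [1] * cfg.replicates)

    feature_ids = [t.transcript_id for t in ann.transcripts]
    lengths = pd.Series({t.transcript_id: t.length for t in ann.transcripts},
                        name="effective_length").loc[feature_ids]

    de_coding = set(roles["partner_genes"]) | set(roles["target_genes"]) | set(roles["other_de"])
    far_lnc = list(roles["far_lnc"])
    n_decoy_de = max(0, round(cfg.frac_differential * cfg.n_lncrnas)
                     - len(ann.truth.planted_key_lncrnas))
    decoy_de_lnc = far_lnc[:min(n_decoy_de, len(far_lnc))]
    ts_lnc = set(decoy_de_lnc[:cfg.n_tissue_specific_lnc])
    ts_coding = set(roles["other_de"][:cfg.n_tissue_specific_coding])

    stable = ({g for g, _ in [(p, l) for l, p in ann.truth.planted_pairs]} |
              set(roles["partner_genes"]) | set(roles["target_genes"]))

    # per-feature baseline means and DE signs
    mu: dict[str, float] = {}
    sign: dict[str, int] = {}
    status: dict[str, str] = {}
    gene_sign: dict[str, int] = {}

    for g in sorted(de_coding):
        gene_sign[g] = 1 if rng.random() < 0.5 else -1

    for t in ann.transcripts:
        fid = t.transcript_id
        base = float(np.exp(rng.normal(np.log(cfg.mean_scale), cfg.mean_sigma)))
        gene = t.gene_id
        if gene in stable:
            base = max(base, cfg.stable_mean_floor)
        mu[fid] = base
        if t.biotype == "protein_coding" and gene in de_coding:
            sign[fid] = gene_sign[gene]
            status[fid] = "up" if sign[fid] > 0 else "down"
        else:
            sign[fid] = 0
            status[fid] = "ns"

    pair_partner = dict(ann.truth.planted_pairs)
    for lid in sorted(ann.truth.planted_key_lncrnas):
        mu[lid] = max(mu[lid], cfg.stable_mean_floor)
        s = gene_sign[pair_partner[lid]]
        sign[lid] = s
        status[lid] = "up" if s > 0 else "down"
    for lid in decoy_de_lnc:
        s = 1 if rng.random() < 0.5 else -1
        sign[lid] = s
        status[lid] = "up" if s > 0 else "down"

    fc = 2.0 ** cfg.planted_log2fc
    mean_mat = np.zeros((len(feature_ids), len(samples)))
    for i, fid in enumerate(feature_ids):
        m = np.full(len(samples), mu[fid])
        if sign[fid] > 0:
            m[st_mask == 1] *= fc
        elif sign[fid] < 0:
            m[st_mask == 1] /= fc
        if fid in ts_lnc or fid in ts_coding:
            off = (st_mask == 1) if sign[fid] < 0 else (st_mask == 0)
            m[off] = 0.0
        mean_mat[i] = m

    # shared latent factor per planted pair group, variance solved from target r
    idx = {fid: i for i, fid in enumerate(feature_ids)}
    groups: dict[str, list[str]] = {}
    for lid, g in ann.truth.planted_pairs:
        groups.setdefault(g, [ann.tx_of_gene[g]]).append(lid)
    for g, members in sorted(groups.items()):
        sn2 = float(np.mean([_noise_var_log2(mu[m], cfg.dispersion) for m in members]))
        tissue_var = cfg.planted_log2fc ** 2 / 4.0  # balanced +/- lfc/2 pattern
        sf2 = max(0.0, cfg.planted_r / (1.0 - cfg.planted_r) * sn2 - tissue_var)
        if sf2 > 0:
            factor = 2.0 ** rng.normal(0.0, np.sqrt(sf2), len(samples))
            for m in members:
                mean_mat[idx[m]] *= factor

    n_nb = 1.0 / cfg.dispersion
    counts = np.zeros_like(mean_mat, dtype=np.int64)
    pos = mean_mat > 0
    counts[pos] = rng.negative_binomial(n_nb, n_nb / (n_nb + mean_mat[pos]))

    truth = ann.truth
    truth.true_status = pd.Series(status).loc[feature_ids]
    counts_df = pd.DataFrame(counts, index=pd.Index(feature_ids, name="feature_id"),
                             columns=samples)
    return counts_df, lengths, truth


def generate_side_tables(cfg: GeneratorConfig, ann: _Annotation,
                         truth: GroundTruth) -> dict:
    """FD list, TF table, binding scores, PPI edges, votes and a term table."""
    rng = cfg._child_rng(2)
    roles = truth.roles
    gene_ids = sorted({t.gene_id for t in ann.transcripts
                       if t.biotype == "protein_coding"})

    # fat-deposition gene list: all planted structure + random coverage + decoys
    fd = set(roles["partner_genes"]) | set(roles["target_genes"])
    rest = [g for g in gene_ids if g not in fd]
    fd |= set(rng.permutation(rest)[:round(cfg.fd_coverage * len(rest))])
    fd |= {f"FDDECOY{i:04d}" for i in range(cfg.n_fd_decoys)}
    truth.fd_genes = fd

    # TF table: planted regulatory TFs (= the first partner genes) + quiet decoys
    planted_tfs = list(roles["partner_genes"][:cfg.n_planted_tfs])
    decoy_tfs = list(rng.permutation(roles["quiet"])[:cfg.n_decoy_tfs])
    tf_table = {g: _TF_FAMILIES[i % len(_TF_FAMILIES)]
                for i, g in enumerate(planted_tfs + decoy_tfs)}
    truth.planted_tfs = set(planted_tfs)

    # binding scores: planted TF->target pairs clear the >3 gate, decoys do not
    rows = []
    targets = list(roles["target_genes"])
    for i, tf in enumerate(planted_tfs):
        for g in targets[i * cfg.targets_per_tf:(i + 1) * cfg.targets_per_tf]:
            rows.append((tf, g, float(rng.uniform(3.2, 9.0))))
            truth.planted_tf_pairs.append((tf, g))
    all_tfs = planted_tfs + decoy_tfs
    for _ in range(cfg.n_decoy_binding_pairs):
        tf = all_tfs[int(rng.integers(0, len(all_tfs)))]
        g = gene_ids[int(rng.integers(0, len(gene_ids)))]
        if g != tf:
            rows.append((tf, g, float(rng.uniform(0.2, 3.0))))
    binding = pd.DataFrame(rows, columns=["tf_id", "gene_id", "score"])

    # PPI: a high-score planted core among FD differential genes + weak background
    de_fd = [g for g in roles["target_genes"] + roles["other_de"] if g in fd]
    core = de_fd[:cfg.ppi_core_size]
    truth.ppi_core = set(core)
    edges = []
    for i in range(len(core)):
        for j in range(i + 1, len(core)):
            edges.append((core[i], core[j], float(rng.uniform(0.75, 0.98))))
    n_bg = round(cfg.ppi_background_density * len(de_fd) * (len(de_fd) - 1) / 2)
    for _ in range(n_bg):
        a, b = rng.integers(0, len(de_fd), 2)
        if a != b:
            edges.append((de_fd[int(a)], de_fd[int(b)],
                          float(rng.beta(2.0, 8.0))))
    ppi = pd.DataFrame(edges, columns=["gene_a", "gene_b", "score"])

    # coding-potential votes with a configurable flip rate
    votes = []
    for t in ann.transcripts:
        true_call = ("noncoding" if t.biotype == "lncRNA_candidate" else "coding")
        for tool in ("CNCI", "CPC2", "PLEK"):
            call = true_call
            if rng.random() < cfg.vote_error_rate:
                call = "coding" if call == "noncoding" else "noncoding"
            votes.append(CodingPotentialVote(t.transcript_id, tool, call))

    # toy functional terms; the first two are enriched in FD differential genes
    lo, hi = cfg.term_size_range
    terms = []
    for ti in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        pool = de_fd if ti < 2 and len(de_fd) >= size else gene_ids
        for g in rng.permutation(pool)[:size]:
            terms.append((f"TERM{ti:03d}", f"toy term {ti}", g))
    term_table = pd.DataFrame(terms, columns=["term_id", "term_name", "gene_id"])

    return {"fd_genes": fd, "tf_table": tf_table, "binding_scores": binding,
            "ppi_edges": ppi, "votes": votes, "term_table": term_table}


def null_positive_rate(
    n_matrices: int = 1000,
    n_features: int = 200,
    dispersion: float = 0.1,
    replicates: int = 3,
    seed: int = 0,
    p_cut: float = 0.05,
    mean_scale: float = 500.0,
    mean_sigma: float = 0.5,
) -> float:
    """Fraction of null features called significant by the DE screen.

    Simulates matrices with no planted effects (both tissues share each
    feature's NB mean) and runs them through the full FPKM + Welch screen;
    a well-calibrated screen should report ~``p_cut``.
    """
    from .quant import compute_fpkm, differential_screen

    rng = np.random.default_rng(seed)
    samples = ([f"LT{i + 1}" for i in range(replicates)] +
               [f"ST{i + 1}" for i in range(replicates)])
    tissues = pd.Series({s: s[:2] for s in samples})
    n_nb = 1.0 / dispersion
    positives = total = 0
    for _ in range(n_matrices):
        mu = np.exp(rng.normal(np.log(mean_scale), mean_sigma, n_features))
        lam = np.repeat(mu[:, None], 2 * replicates, axis=1)
        counts = rng.negative_binomial(n_nb, n_nb / (n_nb + lam))
        cdf = pd.DataFrame(counts, index=[f"f{i}" for i in range(n_features)],
                           columns=samples)
        m = compute_fpkm(cdf, pd.Series(1000.0, index=cdf.index), tissues)
        de = differential_screen(m, p_cut=p_cut)
        positives += int((de["pvalue"] < p_cut).sum())
        total += n_features
    return positives / total


@dataclass
class SyntheticDataset:
    """All pipeline inputs plus the ground truth that produced them."""

    config: GeneratorConfig
    transcripts: list[TranscriptModel]
    counts: pd.DataFrame
    effective_lengths: pd.Series
    tissues: pd.Series
    votes: list[CodingPotentialVote]
    reference_ids: set[str]
    fd_genes: set[str]
    tf_table: dict[str, str]
    binding_scores: pd.DataFrame
    ppi_edges: pd.DataFrame
    term_table: pd.DataFrame
    truth: GroundTruth
    tx_of_gene: dict[str, str]

    def write(self, outdir) -> None:
        """Emit every input in the plain-text formats the pipeline consumes."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_gtf(self.transcripts, out / "annotation.gtf")
        self.counts.to_csv(out / "counts.tsv", sep="\t")
        self.effective_lengths.rename_axis("feature_id").to_csv(
            out / "effective_lengths.tsv", sep="\t")
        self.tissues.rename_axis("sample").rename("tissue").to_csv(
            out / "samples.tsv", sep="\t")
        pd.DataFrame([(v.transcript_id, v.tool, v.call) for v in self.votes],
                     columns=["transcript_id", "tool", "call"]).to_csv(
            out / "votes.tsv", sep="\t", index=False)
        for name, ids in (("reference_ids.txt", self.reference_ids),
                          ("fd_genes.txt", self.fd_genes)):
            (out / name).write_text("".join(f"{i}\n" for i in sorted(ids)))
        pd.Series(self.tf_table, name="family").rename_axis("gene_id").to_csv(
            out / "tf_table.tsv", sep="\t")
        self.binding_scores.to_csv(out / "binding_scores.tsv", sep="\t", index=False)
        self.ppi_edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False)
        self.term_table.to_csv(out / "term_table.tsv", sep="\t", index=False)
        self.truth.to_frame().to_csv(out / "ground_truth.tsv", sep="\t")
        cfg = asdict(self.config)
        cfg["term_size_range"] = list(cfg["term_size_range"])
        (out / "generator_config.yaml").write_text(yaml.safe_dump(cfg))


def generate_dataset(cfg: GeneratorConfig | None = None, seed: int | None = None
                     ) -> SyntheticDataset:
    """Generate the complete synthetic study for ``cfg`` (or default + seed)."""
    if cfg is None:
        cfg = GeneratorConfig(seed=0 if seed is None else seed)
    elif seed is not None:
        cfg = GeneratorConfig(**{**asdict(cfg), "seed": seed})
    ann = generate_annotation(cfg)
    counts, lengths, truth = generate_counts(cfg, ann)
    side = generate_side_tables(cfg, ann, truth)
    tissues = pd.Series({s: ("LT" if s.startswith("LT") else "ST")
                         for s in counts.columns})
    return SyntheticDataset(
        config=cfg,
        transcripts=ann.transcripts,
        counts=counts,
        effective_lengths=lengths,
        tissues=tissues,
        votes=side["votes"],
        reference_ids=ann.reference_known_ids,
        fd_genes=side["fd_genes"],
        tf_table=side["tf_table"],
        binding_scores=side["binding_scores"],
        ppi_edges=side["ppi_edges"],
        term_table=side["term_table"],
        truth=truth,
        tx_of_gene=ann.tx_of_gene,
    )
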