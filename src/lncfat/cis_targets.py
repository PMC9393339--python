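"""Cis-target assignment within a +/-100 kb window and fat-deposition intersections.

A protein-coding gene is a cis target of a lncRNA when both lie on the same
chromosome and the gap between their genomic spans is at most the window
(default 100,000 bp; overlap counts as distance 0). Gene spans run from the
minimum exon start to the maximum exon end over the gene's transcripts.
Inclusion ignores strand; the lncRNA's strand only labels the relation as
upstream/downstream/overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

__all__ = [
    "CisTargetLink",
    "FDLabelledSets",
    "gene_spans",
    "assign_cis_targets",
    "intersect_fd",
    "percent",
]

DEFAULT_WINDOW = 100_000


@dataclass(frozen=True)
class CisTargetLink:
    lncrna_id: str
    gene_id: str
    distance: int  # bp gap between spans; 0 if they overlap
    relation: str  # overlapping | upstream | downstream (lncRNA strand frame)


def gene_spans(transcripts: list[TranscriptModel]) -> pd.DataFrame:
    """Collapse transcripts to per-gene spans (min start, max end).

    Genes whose transcripts disagree on chromosome or strand are rejected.
    """
    rows: dict[str, list] = {}
    for t in transcripts:
        cur = rows.get(t.gene_id)
        if cur is None:
            rows[t.gene_id] = [t.chrom, t.start, t.end, t.strand]
        else:
            if cur[0] != t.chrom or cur[3] != t.strand:
                raise ValueError(
                    f"gene {t.gene_id}: transcripts on mixed chromosomes/strands"
                )
            cur[1] = min(cur[1], t.start)
            cur[2] = max(cur[2], t.end)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["chrom", "start", "end", "strand"]
    ).rename_axis("gene_id")


def _relation(lnc_start, lnc_end, lnc_strand, g_start, g_end) -> tuple[int, str]:
    if g_start <= lnc_end and lnc_start <= g_end:
        return 0, "overlapping"
    if g_start > lnc_end:  # gene 3' of lncRNA on + frame
        gap = g_start - lnc_end - 1
        rel = "downstream" if lnc_strand == "+" else "upstream"
    else:
        gap = lnc_start - g_end - 1
        rel = "upstream" if lnc_strand == "+" else "downstream"
    return gap, rel


def assign_cis_targets(
    lncs: list[TranscriptModel],
    genes: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> list[CisTargetLink]:
    """Link each lncRNA to protein-coding genes within ``window`` bp.

    ``genes`` is the :func:`gene_spans` frame. Candidate genes per chromosome
    are found by binary search on sorted span coordinates; each (lncRNA, gene)
    pair appears at most once.
    """
    links: list[CisTargetLink] = []
    by_chrom = {}
    for chrom, sub in genes.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        by_chrom[chrom] = (
            sub.index.to_numpy(),
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
        )
    for lnc in lncs:
        got = by_chrom.get(lnc.chrom)
        if got is None:
            continue
        ids, starts, ends = got
        # gene qualifies iff start <= lnc.end + window + 1 and end >= lnc.start - window - 1
        hi = np.searchsorted(starts, lnc.end + window + 1, side="right")
        cand = np.nonzero(ends[:hi] >= lnc.start - window - 1)[0]
        for j in cand:
            gap, rel = _relation(
                lnc.start, lnc.end, lnc.strand, int(starts[j]), int(ends[j])
            )
            if gap <= window:
                links.append(CisTargetLink(lnc.transcript_id, str(ids[j]), gap, rel))
    return links


@dataclass
class FDLabelledSets:
    """Fat-deposition intersections of DE lncRNAs, genes and cis targets."""

    fd_genes: set[str]
    fd_dels: set[str]  # DELs with >= 1 cis target in the FD list
    fd_degs: set[str]  # DEGs that are themselves FD genes
    fd_target_genes: set[str]  # cis targets of DELs that are FD genes
    fd_del_pct: float  # 100 * |fd_dels| / |DELs|, one decimal
    fd_deg_pct: float  # 100 * |fd_degs| / |DEGs|, one decimal


def percent(part: int, whole: int, decimals: int = 1) -> float:
    """Percentage rounded to ``decimals`` (0.0 for an empty denominator)."""
    return round(100.0 * part / whole, decimals) if whole else 0.0


def intersect_fd(
    dels: set[str],
    degs: set[str],
    fd_genes: set[str],
    links: list[CisTargetLink],
) -> FDLabelledSets:
    """Label FD-DELs, FD-DEGs and FD cis-target genes.

    An FD-DEL is a differentially expressed lncRNA with at least one cis
    target in the fat-deposition gene list; an FD-DEG is a differentially
    expressed gene that is itself in the list.
    """
    fd_target_genes: set[str] = set()
    fd_dels: set[str] = set()
    for link in links:
        if link.lncrna_id in dels and link.gene_id in fd_genes:
            fd_dels.add(link.lncrna_id)
            fd_target_genes.add(link.gene_id)
    fd_degs = degs & fd_genes
    return FDLabelledSets(
        fd_genes=set(fd_genes),
        fd_dels=fd_dels,
        fd_degs=fd_degs,
        fd_target_genes=fd_target_genes,
        fd_del_pct=percent(len(fd_dels), len(dels)),
        fd_deg_pct=percent(len(fd_degs), len(degs)),
    )


def links_to_frame(links: list[CisTargetLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.lncrna_id, l.gene_id, l.distance, l.relation) for l in links],
        columns=["lncrna_id", "gene_id", "distance", "relation"],
    )
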