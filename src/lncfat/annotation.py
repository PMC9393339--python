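"""Transcript models, GTF input/output and structural classification of lncRNAs.

Coordinates are 1-based and inclusive at both ends, matching GTF. A transcript
is an ordered chain of non-overlapping exons on a single chromosome and strand.
Long non-coding RNA candidates are classified relative to a protein-coding
reference annotation into one of four structural classes with the precedence

    sense_overlapping > antisense > intronic > intergenic

where sense_overlapping/antisense require at least 1 bp of exon-exon overlap
(same/opposite strand), intronic means the whole transcript span lies inside a
single intron of a reference transcript (either strand) without exonic
overlap, and everything else is intergenic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from gffutils.feature import feature_from_line

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSummary",
    "GtfParseError",
    "read_gtf",
    "write_gtf",
    "classify_structure",
    "summarize",
]

#: structural classes in classification precedence order
STRUCTURAL_CLASSES = ("sense_overlapping", "antisense", "intronic", "intergenic")

#: length histogram bin edges (bp); the last bin is open-ended
LENGTH_BINS = (0, 200, 500, 1000, 2000, 5000, 10000)


class GtfParseError(ValueError):
    """Raised when a GTF line cannot be parsed or fails validation."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript: exon chain plus biotype/novelty/structural annotations."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = "unknown"  # protein_coding | lncRNA_candidate | unknown
    novel: bool = False
    structural_class: str = "unset"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands "
                f"({sorted(chroms)}, {sorted(strands)}); fusion transcripts are "
                "not supported"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        if self.biotype == "lncRNA_candidate" and self.length <= 200:
            raise ValueError(
                f"{self.transcript_id}: lncRNA candidates must exceed 200 nt, "
                f"got {self.length}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        """Genomic span from first exon start to last exon end."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def length(self) -> int:
        """Spliced (exonic) transcript length in bp."""
        return sum(len(e) for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start - a.end > 1
        ]


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Exons are grouped by ``transcript_id``, sorted by start, and validated
    (single chromosome/strand, non-overlapping). The optional
    ``transcript_biotype`` attribute is carried into :attr:`TranscriptModel.biotype`.

    Raises
    ------
    GtfParseError
        On malformed lines or invalid coordinates, naming the line number.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    biotype_of: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            if feat.end < feat.start:
                raise GtfParseError(
                    f"{path}:{lineno}: exon end ({feat.end}) < start ({feat.start})"
                )
            attrs = feat.attributes
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise GtfParseError(
                    f"{path}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            tid = attrs["transcript_id"][0]
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            try:
                exons[tid].append(
                    GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
                )
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            gene_of[tid] = attrs["gene_id"][0]
            if "transcript_biotype" in attrs:
                biotype_of[tid] = attrs["transcript_biotype"][0]
    out = []
    for tid in order:
        try:
            out.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_of[tid],
                    exons=exons[tid],
                    biotype=biotype_of.get(tid, "unknown"),
                )
            )
        except ValueError as exc:
            raise GtfParseError(f"{path}: transcript {tid}: {exc}") from exc
    return out


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    """Write transcripts as GTF exon records (round-trips with :func:`read_gtf`)."""
    with open(path, "w") as fh:
        for t in transcripts:
            for i, e in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}"; transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    f"{e.chrom}\tlncfat\texon\t{e.start}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.chrom != b.chrom or not a.span.overlaps(b.span):
        return False
    for ea in a.exons:
        for eb in b.exons:
            if ea.start <= eb.end and eb.start <= ea.end:
                return True
    return False


def classify_structure(
    lnc: TranscriptModel, reference: list[TranscriptModel]
) -> str:
    """Classify a lncRNA candidate relative to protein-coding reference transcripts.

    Returns one of ``sense_overlapping``, ``antisense``, ``intronic`` or
    ``intergenic`` (precedence in that order); an empty reference (or none on
    the lncRNA's chromosome) yields ``intergenic``. The result is independent
    of the ordering of the reference list.
    """
    same = [r for r in reference if r.chrom == lnc.chrom]
    if any(_exonic_overlap(lnc, r) for r in same if r.strand == lnc.strand):
        return "sense_overlapping"
    if any(_exonic_overlap(lnc, r) for r in same if r.strand != lnc.strand):
        return "antisense"
    for r in same:
        for intron in r.introns():
            if intron.start <= lnc.start and lnc.end <= intron.end:
                return "intronic"
    return "intergenic"


@dataclass
class AnnotationSummary:
    """Descriptive statistics over a set of transcripts."""

    n_transcripts: int
    min_length: int
    max_length: int
    mean_length: float
    mean_exons: float
    min_exons: int
    max_exons: int
    class_counts: dict[str, int] = field(default_factory=dict)
    biotype_counts: dict[str, int] = field(default_factory=dict)
    chromosome_counts: dict[str, int] = field(default_factory=dict)
    length_histogram: dict[str, int] = field(default_factory=dict)
    exon_histogram: dict[int, int] = field(default_factory=dict)

    def to_tsv(self) -> str:
        rows = [("metric", "key", "value")]
        rows += [
            ("n_transcripts", "", str(self.n_transcripts)),
            ("min_length", "", str(self.min_length)),
            ("max_length", "", str(self.max_length)),
            ("mean_length", "", f"{self.mean_length:.1f}"),
            ("mean_exons", "", f"{self.mean_exons:.2f}"),
        ]
        for name, d in (
            ("structural_class", self.class_counts),
            ("biotype", self.biotype_counts),
            ("chromosome", self.chromosome_counts),
            ("length_bin", self.length_histogram),
            ("exon_count", self.exon_histogram),
        ):
            for k, v in d.items():
                rows.append((name, str(k), str(v)))
        return "\n".join("\t".join(r) for r in rows) + "\n"


def _length_bin(length: int) -> str:
    edges = LENGTH_BINS
    for lo, hi in zip(edges, edges[1:]):
        if lo < length <= hi:
            return f"({lo},{hi}]"
    return f">{edges[-1]}"


def summarize(transcripts: list[TranscriptModel]) -> AnnotationSummary:
    """Summarize lengths, exon counts and per-chromosome/class tallies.

    Raises ``ValueError("nothing to summarize")`` on an empty list.
    """
    if not transcripts:
        raise ValueError("nothing to summarize")
    lengths = [t.length for t in transcripts]
    exons = [t.n_exons for t in transcripts]
    return AnnotationSummary(
        n_transcripts=len(transcripts),
        min_length=min(lengths),
        max_length=max(lengths),
        mean_length=sum(lengths) / len(lengths),
        mean_exons=sum(exons) / len(exons),
        min_exons=min(exons),
        max_exons=max(exons),
        class_counts=dict(Counter(t.structural_class for t in transcripts)),
        biotype_counts=dict(Counter(t.biotype for t in transcripts)),
        chromosome_counts=dict(Counter(t.chrom for t in transcripts)),
        length_histogram=dict(
            Counter(_length_bin(length) for length in lengths)
        ),
        exon_histogram=dict(Counter(exons)),
    )
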