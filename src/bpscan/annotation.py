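"""Gene models, intron derivation and the analysed feature classes.

Nine feature classes are profiled for variant density: the two splice-site
classes, start and stop codons, the two UTR classes, exons, introns and the
intergenic complement. A derived ``coding`` class (exon ∪ start_codon ∪
stop_codon by default, reflecting a literal reading of "variants overlapping
exons, start codons and stop codons" as coding) and a ``genic`` class (union
of gene bodies) are carried alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils

from .genome import GenomeAssembly, GenomicInterval, merge_by_chrom, merge_intervals

log = logging.getLogger(__name__)

FEATURE_CLASSES = (
    "five_prime_ss",
    "three_prime_ss",
    "start_codon",
    "stop_codon",
    "five_prime_utr",
    "three_prime_utr",
    "exon",
    "intron",
    "intergenic",
)
DERIVED_CLASSES = ("coding", "genic")


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]] = field(default_factory=list)  # genomic order
    cds: List[Tuple[int, int]] = field(default_factory=list)
    five_prime_utr: List[Tuple[int, int]] = field(default_factory=list)
    three_prime_utr: List[Tuple[int, int]] = field(default_factory=list)
    start_codon: List[Tuple[int, int]] = field(default_factory=list)
    stop_codon: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    transcripts: List[Transcript] = field(default_factory=list)

    @property
    def span(self) -> Tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


@dataclass(frozen=True)
class IntronRecord:
    """An intron with strand-aware donor and acceptor dinucleotides.

    The donor (5' splice site) is the transcript-orientation first two intron
    bases and the acceptor (3' splice site) the last two; on the minus strand
    the donor therefore has the higher genomic coordinates.
    """

    chrom: str
    start: int  # 0-based half-open, genomic
    end: int
    strand: str
    gene_id: str

    def __post_init__(self):
        if self.end - self.start < 4:
            raise ValueError("intron shorter than its two splice dinucleotides")

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def donor(self) -> GenomicInterval:
        if self.strand == "-":
            return GenomicInterval(self.chrom, self.end - 2, self.end, self.strand)
        return GenomicInterval(self.chrom, self.start, self.start + 2, self.strand)

    @property
    def acceptor(self) -> GenomicInterval:
        if self.strand == "-":
            return GenomicInterval(self.chrom, self.start, self.start + 2, self.strand)
        return GenomicInterval(self.chrom, self.end - 2, self.end, self.strand)

    def sequence(self, genome: GenomeAssembly) -> str:
        """Intron sequence in transcript orientation (donor first)."""
        return genome.fetch(self.interval, oriented=True)

    def genomic_position(self, t_index: int) -> int:
        """0-based genomic coordinate of a transcript-orientation index."""
        if not 0 <= t_index < len(self):
            raise IndexError(t_index)
        if self.strand == "-":
            return self.end - 1 - t_index
        return self.start + t_index

    def first_bases(self, genome: GenomeAssembly, k: int) -> str:
        return self.sequence(genome)[:k]

    def last_bases(self, genome: GenomeAssembly, k: int) -> str:
        return self.sequence(genome)[-k:]


def parse_annotation(gtf_path: str, genome: GenomeAssembly) -> List[GeneModel]:
    """Read a GTF into gene models, skipping records on unknown chromosomes.

    Raises ValueError for unparseable GTF content or exons outside chromosome
    bounds; records on chromosomes absent from the assembly are skipped with
    a logged count.
    """
    with open(gtf_path) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        log.warning("GTF %s contains no records", gtf_path)
        return []
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a mix of exception types
        raise ValueError(f"unparseable GTF {gtf_path}: {exc}") from exc

    genes: Dict[str, GeneModel] = {}
    transcripts: Dict[str, Transcript] = {}
    skipped_unknown = 0

    def _attr(feat, key, default=""):
        vals = feat.attributes.get(key, [default])
        return vals[0] if vals else default

    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.seqid not in genome:
            skipped_unknown += 1
            continue
        ftype = feat.featuretype
        start, end = feat.start - 1, feat.end  # GTF is 1-based inclusive
        if end > genome.length(feat.seqid) or start < 0:
            raise ValueError(
                f"{ftype} [{feat.start},{feat.end}] outside chromosome "
                f"{feat.seqid} (length {genome.length(feat.seqid)})"
            )
        gene_id = _attr(feat, "gene_id")
        if ftype == "gene":
            genes.setdefault(
                gene_id,
                GeneModel(gene_id, feat.seqid, feat.strand,
                          _attr(feat, "gene_biotype", "protein_coding")),
            )
            continue
        tx_id = _attr(feat, "transcript_id")
        if not tx_id:
            continue
        if tx_id not in transcripts:
            transcripts[tx_id] = Transcript(tx_id, gene_id, feat.seqid, feat.strand)
        tx = transcripts[tx_id]
        if ftype == "exon":
            tx.exons.append((start, end))
        elif ftype == "CDS":
            tx.cds.append((start, end))
        elif ftype == "five_prime_utr":
            tx.five_prime_utr.append((start, end))
        elif ftype == "three_prime_utr":
            tx.three_prime_utr.append((start, end))
        elif ftype == "start_codon":
            tx.start_codon.append((start, end))
        elif ftype == "stop_codon":
            tx.stop_codon.append((start, end))

    for tx in transcripts.values():
        tx.exons.sort()
        tx.cds.sort()
        if tx.gene_id not in genes:
            genes[tx.gene_id] = GeneModel(tx.gene_id, tx.chrom, tx.strand)
        genes[tx.gene_id].transcripts.append(tx)

    if skipped_unknown:
        log.warning("skipped %d GTF records on unknown chromosomes", skipped_unknown)
    models = [g for g in genes.values() if g.transcripts]
    if not models:
        log.warning("no gene models parsed from %s", gtf_path)
    return models


def derive_introns(
    genes: Iterable[GeneModel], protein_coding_only: bool = True
) -> List[IntronRecord]:
    """Introns as gaps between consecutive exons, deduplicated across transcripts."""
    seen = {}
    for gene in genes:
        if protein_coding_only and gene.biotype != "protein_coding":
            continue
        for tx in gene.transcripts:
            exons = sorted(tx.exons)
            ok = all(exons[i][1] <= exons[i + 1][0] for i in range(len(exons) - 1))
            if not ok:
                log.warning("transcript %s has overlapping exons; skipped", tx.transcript_id)
                continue
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                key = (gene.chrom, e1, s2, gene.strand)
                if key not in seen and s2 - e1 >= 4:
                    seen[key] = IntronRecord(gene.chrom, e1, s2, gene.strand, gene.gene_id)
    return sorted(seen.values(), key=lambda r: (r.chrom, r.start, r.end, r.strand))


class FeatureCatalog:
    """Strand-aware interval sets for each analysed feature class."""

    def __init__(self, intervals: Dict[str, List[GenomicInterval]]):
        self._intervals = intervals
        self._merged: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}

    @property
    def classes(self) -> List[str]:
        return list(self._intervals)

    def intervals(self, cls: str) -> List[GenomicInterval]:
        return self._intervals[cls]

    def merged(self, cls: str) -> Dict[str, List[Tuple[int, int]]]:
        """Per-chromosome disjoint union of a class's intervals (cached)."""
        if cls not in self._merged:
            self._merged[cls] = merge_by_chrom(self._intervals[cls])
        return self._merged[cls]

    def effective_length(self, cls: str, genome: GenomeAssembly) -> int:
        return genome.effective_interval_length(self.merged(cls))

    def write_bed(self, cls: str, path: str) -> None:
        with open(path, "w") as fh:
            for iv in sorted(self._intervals[cls]):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{cls}\t0\t{iv.strand}\n")


def effective_length(
    intervals: Sequence[GenomicInterval], genome: GenomeAssembly
) -> int:
    """Non-N bases in the union of the intervals (union first, no double count)."""
    return genome.effective_interval_length(merge_by_chrom(intervals))


def build_feature_catalog(
    genes: Sequence[GeneModel],
    genome: GenomeAssembly,
    introns: Optional[Sequence[IntronRecord]] = None,
    coding_mode: str = "exon",
) -> FeatureCatalog:
    """Assemble the nine feature classes plus derived coding/genic classes.

    coding_mode 'exon' treats every exonic base (UTRs included) plus start and
    stop codons as coding; 'cds' restricts to CDS ∪ start_codon ∪ stop_codon.
    """
    if coding_mode not in ("exon", "cds"):
        raise ValueError(f"unknown coding_mode {coding_mode!r}")
    if introns is None:
        introns = derive_introns(genes)

    iv: Dict[str, List[GenomicInterval]] = {c: [] for c in FEATURE_CLASSES + DERIVED_CLASSES}

    for gene in genes:
        for tx in gene.transcripts:
            st = gene.strand
            for s, e in tx.exons:
                iv["exon"].append(GenomicInterval(gene.chrom, s, e, st))
            for s, e in tx.start_codon:
                iv["start_codon"].append(GenomicInterval(gene.chrom, s, e, st))
            for s, e in tx.stop_codon:
                iv["stop_codon"].append(GenomicInterval(gene.chrom, s, e, st))
            utr5, utr3 = tx.five_prime_utr, tx.three_prime_utr
            if not (utr5 or utr3) and tx.cds:
                utr5, utr3 = _derive_utrs(tx)
            for s, e in utr5:
                iv["five_prime_utr"].append(GenomicInterval(gene.chrom, s, e, st))
            for s, e in utr3:
                iv["three_prime_utr"].append(GenomicInterval(gene.chrom, s, e, st))
        s, e = gene.span
        iv["genic"].append(GenomicInterval(gene.chrom, s, e, gene.strand))

    for intron in introns:
        iv["intron"].append(intron.interval)
        iv["five_prime_ss"].append(intron.donor)
        iv["three_prime_ss"].append(intron.acceptor)

    # intergenic: complement of the union of gene bodies (any biotype)
    genic_by_chrom = merge_by_chrom(iv["genic"])
    for chrom in genome.chromosomes:
        pos = 0
        for s, e in genic_by_chrom.get(chrom, []):
            if s > pos:
                iv["intergenic"].append(GenomicInterval(chrom, pos, s))
            pos = max(pos, e)
        if pos < genome.length(chrom):
            iv["intergenic"].append(GenomicInterval(chrom, pos, genome.length(chrom)))

    if coding_mode == "exon":
        coding_src = iv["exon"] + iv["start_codon"] + iv["stop_codon"]
    else:
        coding_src = iv["start_codon"] + iv["stop_codon"]
        for gene in genes:
            for tx in gene.transcripts:
                coding_src.extend(
                    GenomicInterval(gene.chrom, s, e, gene.strand) for s, e in tx.cds
                )
    iv["coding"] = list(coding_src)
    return FeatureCatalog(iv)


def _derive_utrs(tx: Transcript):
    """UTRs from exon-vs-CDS when the GTF carries no explicit UTR records."""
    cds_lo = min(s for s, _ in tx.cds)
    cds_hi = max(e for _, e in tx.cds)
    left, right = [], []
    for s, e in tx.exons:
        if s < cds_lo:
            left.append((s, min(e, cds_lo)))
        if e > cds_hi:
            right.append((max(s, cds_hi), e))
    if tx.strand == "-":
        return right, left
    return left, right
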