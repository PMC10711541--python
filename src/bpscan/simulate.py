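"""Synthetic genomes, annotations and variant catalogues with known truth.

The generator emulates the statistical structure the downstream analyses
assume: multi-exon protein-coding genes on both strands, a branch point
heptamer planted in every intron at a drawn distance upstream of the 3'
splice site, per-feature-class constraint multipliers on the mutation rate
(splice sites and branch point positions 4/6 most depleted), a tunable
transition probability controlling Ti/Tv, N-masked intergenic blocks, and
two contamination modes mimicking exome-only and error-prone submission
batches in public archives.

Every output is a pure function of (config, seed): identical configs give
byte-identical FASTA/GTF/VCF/TSV files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import GeneModel, Transcript
from .genome import GenomeAssembly, GenomicInterval, merge_by_chrom
from .variants import VariantCatalog, VariantRecord

BASE_CHARS = np.frombuffer(b"ACGTN", dtype=np.uint8)

# per-base class codes, in increasing paint priority
CLS_INTERGENIC, CLS_INTRON, CLS_UTR, CLS_CODING, CLS_BPS_OTHER, CLS_BPS46, CLS_SPLICE = range(7)
CLASS_NAMES = {
    CLS_INTERGENIC: "intergenic",
    CLS_INTRON: "intron",
    CLS_UTR: "utr",
    CLS_CODING: "coding",
    CLS_BPS_OTHER: "bps_other",
    CLS_BPS46: "bps_pos4_6",
    CLS_SPLICE: "splice_site",
}


def default_bp_offset_distribution(
    lo: int = 9, hi: int = 150, median: float = 26.0, sigma: float = 0.55
) -> Dict[int, float]:
    """Log-normal-shaped discrete distance distribution, median near 26 bp."""
    d = np.arange(lo, hi + 1)
    dens = np.exp(-((np.log(d) - math.log(median)) ** 2) / (2 * sigma**2)) / d
    dens /= dens.sum()
    return {int(k): float(v) for k, v in zip(d, dens)}


def default_generative_pwm() -> np.ndarray:
    """Sharp planting PWM (consensus TTCTAAC; strong T at 4, strong A at 6).

    The matrix is deliberately information-rich so planted motifs are
    unambiguous against random intronic background; it is a generator
    setting, not an estimate of real branch point degeneracy.
    """
    return np.array(
        [
            [0.04, 0.04, 0.02, 0.90],
            [0.04, 0.04, 0.02, 0.90],
            [0.03, 0.92, 0.01, 0.04],
            [0.01, 0.02, 0.01, 0.96],
            [0.92, 0.02, 0.04, 0.02],
            [0.96, 0.01, 0.02, 0.01],
            [0.03, 0.92, 0.01, 0.04],
        ]
    )


def default_constraint_multipliers() -> Dict[str, float]:
    return {
        "splice_site": 0.02,
        "bps_pos4_6": 0.2,
        "bps_other": 0.85,
        "coding": 0.4,
        "utr": 0.7,
        "intron": 0.9,
        "intergenic": 1.2,
    }


@dataclass
class SimulationConfig:
    n_chromosomes: int = 2
    chrom_length: int = 1_500_000
    n_genes: int = 350
    exons_per_gene: Tuple[int, int] = (3, 6)
    exon_length: Tuple[int, int] = (100, 200)
    intron_length: Tuple[int, int] = (170, 400)
    utr_length: Tuple[int, int] = (30, 80)
    minus_strand_fraction: float = 0.5
    bp_offset_distribution: Dict[int, float] = field(
        default_factory=default_bp_offset_distribution
    )
    generative_pwm: np.ndarray = field(default_factory=default_generative_pwm)
    base_mutation_rate: float = 0.03
    transition_probability: float = 0.7
    constraint_multipliers: Dict[str, float] = field(
        default_factory=default_constraint_multipliers
    )
    n_fraction: float = 0.02
    min_gap: int = 150
    study_labels: Tuple[str, ...] = ("S1", "S2", "S3")
    seed: int = 1

    def validate(self) -> None:
        pwm = np.asarray(self.generative_pwm, dtype=float)
        if pwm.shape != (7, 4) or np.any(pwm < 0):
            raise ValueError("generative_pwm must be a non-negative 7x4 matrix")
        if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("generative_pwm rows must each sum to 1 (within 1e-9)")
        offs = self.bp_offset_distribution
        if not offs:
            raise ValueError("bp_offset_distribution is empty")
        if min(offs) < 9 or max(offs) > 150:
            raise ValueError(
                f"bp offset support [{min(offs)}, {max(offs)}] must lie within [9, 150]"
            )
        if not math.isclose(sum(offs.values()), 1.0, abs_tol=1e-6):
            raise ValueError("bp_offset_distribution must sum to 1")
        if any(p < 0 for p in offs.values()):
            raise ValueError("bp offset probabilities must be non-negative")
        d_max = max(offs)
        if self.intron_length[0] < d_max + 7:
            raise ValueError(
                f"intron_length min {self.intron_length[0]} cannot admit the "
                f"heptamer at max branch point offset {d_max} "
                f"(needs >= {d_max + 7})"
            )
        if self.exons_per_gene[0] < 2:
            raise ValueError("exons_per_gene min must be >= 2 to yield introns")
        if self.exon_length[0] < self.utr_length[1] + 6:
            raise ValueError(
                f"exon_length min {self.exon_length[0]} too short for UTR up to "
                f"{self.utr_length[1]} plus a codon (needs >= {self.utr_length[1] + 6})"
            )
        if any(m < 0 for m in self.constraint_multipliers.values()):
            raise ValueError("constraint multipliers must be >= 0")
        missing = set(CLASS_NAMES.values()) - set(self.constraint_multipliers)
        if missing:
            raise ValueError(f"constraint_multipliers missing classes {sorted(missing)}")
        if not 0.0 <= self.minus_strand_fraction <= 1.0:
            raise ValueError("minus_strand_fraction must be a probability")
        if not 0.0 <= self.transition_probability <= 1.0:
            raise ValueError("transition_probability must be a probability")
        max_span = (
            self.exons_per_gene[1] * self.exon_length[1]
            + (self.exons_per_gene[1] - 1) * self.intron_length[1]
        )
        per_chrom = -(-self.n_genes // self.n_chromosomes)
        need = per_chrom * max_span + (per_chrom + 1) * self.min_gap
        if need > self.chrom_length:
            raise ValueError(
                f"chrom_length {self.chrom_length} cannot fit {per_chrom} genes of "
                f"max span {max_span} plus gaps (needs >= {need})"
            )


@dataclass(frozen=True)
class PlantedBP:
    """Ground truth for one planted branch point heptamer."""

    chrom: str
    intron_start: int  # 0-based half-open, genomic
    intron_end: int
    strand: str
    bp_pos: int  # 1-based genomic position of the planted branch point
    distance: int  # rank of the branch point from the intron 3' end (last base = 1)
    heptamer: str  # transcript orientation; branch point is its 6th base


@dataclass
class SyntheticGenome:
    genome: GenomeAssembly
    genes: List[GeneModel]
    truth: List[PlantedBP]
    class_codes: Dict[str, np.ndarray]
    config: SimulationConfig

    def exonic_intervals(self) -> Dict[str, List[Tuple[int, int]]]:
        ivs = [
            GenomicInterval(g.chrom, s, e, g.strand)
            for g in self.genes
            for tx in g.transcripts
            for s, e in tx.exons
        ]
        return merge_by_chrom(ivs)

    def splice_site_intervals(self) -> Dict[str, List[Tuple[int, int]]]:
        ivs = []
        for g in self.genes:
            for tx in g.transcripts:
                exons = sorted(tx.exons)
                for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                    ivs.append(GenomicInterval(g.chrom, e1, e1 + 2))
                    ivs.append(GenomicInterval(g.chrom, s2 - 2, s2))
        return merge_by_chrom(ivs)

    def write_fasta(self, path: str) -> None:
        self.genome.write_fasta(path)

    def write_gtf(self, path: str) -> None:
        write_gtf(self.genes, path)

    def write_truth(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "chrom\tintron_start\tintron_end\tstrand\tbp_pos_1based\theptamer\tdistance\n"
            )
            for t in self.truth:
                fh.write(
                    f"{t.chrom}\t{t.intron_start + 1}\t{t.intron_end}\t{t.strand}\t"
                    f"{t.bp_pos}\t{t.heptamer}\t{t.distance}\n"
                )


def write_gtf(genes: Sequence[GeneModel], path: str) -> None:
    """Emit gene/transcript/exon/CDS/UTR/codon records, 1-based inclusive."""
    lines = []

    def rec(chrom, ftype, s, e, strand, gene_id, tx_id=None):
        attrs = f'gene_id "{gene_id}"; gene_biotype "protein_coding";'
        if tx_id:
            attrs = (
                f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                f'gene_biotype "protein_coding";'
            )
        lines.append(
            f"{chrom}\tbpscan_sim\t{ftype}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attrs}"
        )

    for gene in genes:
        gs, ge = gene.span
        rec(gene.chrom, "gene", gs, ge, gene.strand, gene.gene_id)
        for tx in gene.transcripts:
            ts, te = tx.span
            rec(gene.chrom, "transcript", ts, te, gene.strand, gene.gene_id, tx.transcript_id)
            for kind, ivs in (
                ("exon", tx.exons),
                ("CDS", tx.cds),
                ("five_prime_utr", tx.five_prime_utr),
                ("three_prime_utr", tx.three_prime_utr),
                ("start_codon", tx.start_codon),
                ("stop_codon", tx.stop_codon),
            ):
                for s, e in sorted(ivs):
                    rec(gene.chrom, kind, s, e, gene.strand, gene.gene_id, tx.transcript_id)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _draw_gene_layout(cfg: SimulationConfig, rng: np.random.Generator):
    """Transcript-local layout of one gene: exon/intron intervals and motifs."""
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
    intron_lens = rng.integers(
        cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1
    )
    u5 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    u3 = int(rng.integers(cfg.utr_length[0], cfg.utr_length[1] + 1))
    offsets = np.array(sorted(cfg.bp_offset_distribution))
    probs = np.array([cfg.bp_offset_distribution[int(d)] for d in offsets])
    probs = probs / probs.sum()
    pwm = np.asarray(cfg.generative_pwm, dtype=float)

    cursor = 0
    exons, introns, plants = [], [], []
    for i in range(n_ex):
        exons.append((cursor, cursor + int(exon_lens[i])))
        cursor += int(exon_lens[i])
        if i < n_ex - 1:
            il = int(intron_lens[i])
            d = int(rng.choice(offsets, p=probs))
            hept = np.array([rng.choice(4, p=pwm[k] / pwm[k].sum()) for k in range(7)],
                            dtype=np.uint8)
            introns.append((cursor, cursor + il))
            plants.append((cursor, il, d, hept))
            cursor += il
    return exons, introns, plants, u5, u3, cursor


def generate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Build the genome, gene annotation and planted branch point truth."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    seqs: Dict[str, np.ndarray] = {}
    cls: Dict[str, np.ndarray] = {}
    genes: List[GeneModel] = []
    truth: List[PlantedBP] = []

    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1

    gene_counter = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        arr = rng.integers(0, 4, size=cfg.chrom_length).astype(np.uint8)
        carr = np.zeros(cfg.chrom_length, dtype=np.uint8)

        layouts = [_draw_gene_layout(cfg, rng) for _ in range(per_chrom[ci])]
        spans = [lay[5] for lay in layouts]
        free = cfg.chrom_length - sum(spans)
        n_gaps = len(layouts) + 1
        if free < n_gaps * cfg.min_gap:
            raise ValueError(
                f"chromosome {chrom} cannot fit {len(layouts)} genes: needs "
                f"{sum(spans) + n_gaps * cfg.min_gap} bases, has {cfg.chrom_length}"
            )
        w = rng.random(n_gaps)
        extra = np.floor(w / w.sum() * (free - n_gaps * cfg.min_gap)).astype(int)
        gaps = extra + cfg.min_gap
        gaps[-1] += free - int(gaps.sum())  # make lengths exact

        gap_intervals = []
        pos = 0
        for gi, lay in enumerate(layouts):
            gap_intervals.append((pos, pos + int(gaps[gi])))
            pos += int(gaps[gi])
            g0 = pos
            gene_counter += 1
            minus = rng.random() < cfg.minus_strand_fraction
            _place_gene(
                arr, carr, chrom, g0, lay, minus, gene_counter, genes, truth
            )
            pos += lay[5]
        gap_intervals.append((pos, cfg.chrom_length))

        _mask_intergenic_n(arr, gap_intervals, cfg, rng)
        seqs[chrom] = arr
        cls[chrom] = carr

    genome = GenomeAssembly(
        {c: BASE_CHARS[a].tobytes().decode("ascii") for c, a in seqs.items()}
    )
    return SyntheticGenome(genome, genes, truth, cls, cfg)


def _place_gene(arr, carr, chrom, g0, layout, minus, gene_number, genes, truth):
    exons, introns, plants, u5, u3, span = layout
    g1 = g0 + span
    strand = "-" if minus else "+"

    def to_genomic(a: int, b: int) -> Tuple[int, int]:
        if minus:
            return g1 - b, g1 - a
        return g0 + a, g0 + b

    def write_bases(t0: int, codes: np.ndarray) -> None:
        if minus:
            lo = g1 - (t0 + len(codes))
            arr[lo : lo + len(codes)] = (3 - codes)[::-1]
        else:
            arr[g0 + t0 : g0 + t0 + len(codes)] = codes

    def paint(a: int, b: int, code: int) -> None:
        s, e = to_genomic(a, b)
        carr[s:e] = code

    # local exonic sub-intervals of a transcript-local range [a, b)
    def exonic_within(a: int, b: int) -> List[Tuple[int, int]]:
        out = []
        for s, e in exons:
            lo, hi = max(s, a), min(e, b)
            if lo < hi:
                out.append((lo, hi))
        return out

    # paint classes in increasing priority
    for s, e in introns:
        paint(s, e, CLS_INTRON)
    for s, e in exonic_within(0, u5):
        paint(s, e, CLS_UTR)
    for s, e in exonic_within(span - u3, span):
        paint(s, e, CLS_UTR)
    for s, e in exonic_within(u5, span - u3):
        paint(s, e, CLS_CODING)

    # splice dinucleotides and planted heptamers
    G, T, A, C = np.uint8(2), np.uint8(3), np.uint8(0), np.uint8(1)
    for (ls, il, d, hept) in plants:
        write_bases(ls, np.array([G, T], dtype=np.uint8))  # donor GT
        write_bases(ls + il - 2, np.array([A, G], dtype=np.uint8))  # acceptor AG
        hs = ls + il - d - 5
        write_bases(hs, hept)
        paint(hs, hs + 7, CLS_BPS_OTHER)
        paint(hs + 3, hs + 4, CLS_BPS46)
        paint(hs + 5, hs + 6, CLS_BPS46)
        paint(ls, ls + 2, CLS_SPLICE)
        paint(ls + il - 2, ls + il, CLS_SPLICE)

    write_bases(u5, np.array([A, T, G], dtype=np.uint8))  # start codon ATG
    write_bases(span - u3 - 3, np.array([T, A, A], dtype=np.uint8))  # stop codon TAA

    gene_id = f"g{gene_number}"
    tx = Transcript(f"{gene_id}.t1", gene_id, chrom, strand)
    tx.exons = sorted(to_genomic(s, e) for s, e in exons)
    tx.cds = sorted(to_genomic(s, e) for s, e in exonic_within(u5, span - u3 - 3))
    tx.five_prime_utr = sorted(to_genomic(s, e) for s, e in exonic_within(0, u5))
    tx.three_prime_utr = sorted(to_genomic(s, e) for s, e in exonic_within(span - u3, span))
    tx.start_codon = [to_genomic(u5, u5 + 3)]
    tx.stop_codon = [to_genomic(span - u3 - 3, span - u3)]
    gene = GeneModel(gene_id, chrom, strand, "protein_coding", [tx])
    genes.append(gene)

    base_chars = "ACGT"
    for (ls, il, d, hept) in plants:
        s, e = to_genomic(ls, ls + il)
        t_bp = ls + il - d
        bp_genomic = (g1 - 1 - t_bp) if minus else (g0 + t_bp)
        truth.append(
            PlantedBP(
                chrom=chrom,
                intron_start=s,
                intron_end=e,
                strand=strand,
                bp_pos=bp_genomic + 1,
                distance=d,
                heptamer="".join(base_chars[int(b)] for b in hept),
            )
        )


def _mask_intergenic_n(arr, gap_intervals, cfg: SimulationConfig, rng) -> None:
    """Carve N blocks out of intergenic gap centres up to the target fraction."""
    target = int(round(cfg.n_fraction * len(arr)))
    buffer = 50
    placed = 0
    for s, e in gap_intervals:
        if placed >= target:
            break
        room = (e - s) - 2 * buffer
        if room < 20:
            continue
        block = min(room, target - placed)
        mid = (s + e) // 2
        lo = max(s + buffer, mid - block // 2)
        arr[lo : lo + block] = 4
        placed += block


def simulate_variants(
    sim: SyntheticGenome, config: Optional[SimulationConfig] = None
) -> VariantCatalog:
    """Mutate each non-N base independently at rate x class multiplier.

    The alt allele is the transition partner with probability p_ts, else one
    of the two transversions uniformly. Each variant carries a single study
    id drawn from the configured labels.
    """
    cfg = config or sim.config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    mult = np.array(
        [cfg.constraint_multipliers[CLASS_NAMES[c]] for c in range(len(CLASS_NAMES))]
    )
    records: List[VariantRecord] = []
    base_chars = "ACGT"
    for chrom in sim.genome.chromosomes:
        codes = sim.genome.codes(chrom)
        carr = sim.class_codes[chrom]
        rate = cfg.base_mutation_rate * mult[carr]
        rate[codes == 4] = 0.0
        hits = np.nonzero(rng.random(len(codes)) < rate)[0]
        if len(hits) == 0:
            continue
        refs = codes[hits]
        is_ts = rng.random(len(hits)) < cfg.transition_probability
        coin = rng.integers(0, 2, size=len(hits))
        alts = np.where(is_ts, refs ^ 2, np.where(coin == 0, refs ^ 1, refs ^ 3))
        sids = rng.integers(0, len(cfg.study_labels), size=len(hits))
        for p, r, a, s in zip(hits, refs, alts, sids):
            records.append(
                VariantRecord(
                    chrom,
                    int(p) + 1,
                    base_chars[int(r)],
                    base_chars[int(a)],
                    frozenset({cfg.study_labels[int(s)]}),
                )
            )
    return VariantCatalog(records)


CONTAMINATION_MODES = ("exome_batch", "error_batch")


def inject_contamination(
    catalog: VariantCatalog,
    genome: GenomeAssembly,
    mode: str,
    n_added: int,
    study_id: str,
    seed: int,
    exome_intervals: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    regions: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    ts_prob: float = 0.7,
) -> VariantCatalog:
    """Add a contaminating submission batch to a catalogue.

    exome_batch samples sites uniformly from exonic non-N bases (alt allele
    transition with probability ts_prob, like genuine exome calls);
    error_batch samples uniformly from non-N bases genome-wide (optionally
    restricted to ``regions``) with the alt uniform over the three
    alternatives, giving the added subset an expected Ti/Tv of 0.5. Sites
    already present merge the new study id into their submission list.
    """
    if mode not in CONTAMINATION_MODES:
        raise ValueError(f"unknown contamination mode {mode!r}; expected {CONTAMINATION_MODES}")
    if n_added == 0:
        return catalog
    if mode == "exome_batch":
        if exome_intervals is None:
            raise ValueError("exome_batch requires exome_intervals")
        pool_ivs = exome_intervals
    else:
        pool_ivs = regions or {
            c: [(0, genome.length(c))] for c in genome.chromosomes
        }

    chroms, positions = [], []
    for chrom, ivs in pool_ivs.items():
        codes = genome.codes(chrom)
        for s, e in ivs:
            pos = np.arange(s, e)[codes[s:e] != 4]
            positions.append(pos)
            chroms.extend([chrom] * len(pos))
    pool_pos = np.concatenate(positions) if positions else np.empty(0, dtype=int)
    if n_added > len(pool_pos):
        raise ValueError(f"cannot add {n_added} variants from a pool of {len(pool_pos)}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(pool_pos), size=n_added, replace=False)

    existing = {(r.chrom, r.pos): i for i, r in enumerate(catalog.records)}
    new_records = list(catalog.records)
    base_chars = "ACGT"
    for k in pick:
        chrom, pos0 = chroms[int(k)], int(pool_pos[int(k)])
        key = (chrom, pos0 + 1)
        if key in existing:
            i = existing[key]
            old = new_records[i]
            new_records[i] = replace(old, study_ids=old.study_ids | {study_id})
            continue
        ref = genome.codes(chrom)[pos0]
        if mode == "error_batch":
            alt = ref ^ int(rng.integers(1, 4))  # uniform over the 3 alternatives
        else:
            if rng.random() < ts_prob:
                alt = ref ^ 2
            else:
                alt = ref ^ (1 if rng.integers(0, 2) == 0 else 3)
        new_records.append(
            VariantRecord(
                chrom, pos0 + 1, base_chars[int(ref)], base_chars[int(alt)],
                frozenset({study_id}),
            )
        )
        existing[key] = len(new_records) - 1
    return VariantCatalog(new_records)
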