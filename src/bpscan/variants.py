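"""Variant catalogue ingestion, Ti/Tv and density metrics, submission filters.

Only biallelic SNVs are analysed; multi-allelic records, indels, MNVs and
records on unknown chromosomes are excluded at load time with per-reason
counts. Submitter provenance is read from a configurable INFO key (default
``SID``, comma-separated), since archive dialects for submission metadata
differ.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np
import pysam

from .genome import GenomeAssembly

log = logging.getLogger(__name__)

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_BASES = set("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    study_ids: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if self.ref not in _BASES or self.alt not in _BASES or self.ref == self.alt:
            raise ValueError(f"not a SNV: {self.ref}>{self.alt}")

    @property
    def is_transition(self) -> bool:
        return (self.ref, self.alt) in TRANSITIONS


class VariantCatalog:
    """A sorted collection of biallelic SNV sites."""

    def __init__(self, records: Iterable[VariantRecord]):
        self.records: List[VariantRecord] = sorted(
            records, key=lambda r: (r.chrom, r.pos)
        )
        self._pos_arrays: Dict[str, np.ndarray] = {}
        self._site_sets: Dict[str, Set[int]] = {}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self, chrom: str) -> np.ndarray:
        """Sorted 0-based positions of variant sites on a chromosome."""
        if chrom not in self._pos_arrays:
            self._pos_arrays[chrom] = np.array(
                sorted(r.pos - 1 for r in self.records if r.chrom == chrom),
                dtype=np.int64,
            )
        return self._pos_arrays[chrom]

    def site_set(self, chrom: str) -> Set[int]:
        """0-based variant positions on a chromosome as a set."""
        if chrom not in self._site_sets:
            self._site_sets[chrom] = {r.pos - 1 for r in self.records if r.chrom == chrom}
        return self._site_sets[chrom]

    def subset(self, predicate) -> "VariantCatalog":
        return VariantCatalog(r for r in self.records if predicate(r))


def load_variants(
    vcf_path: str,
    genome: Optional[GenomeAssembly] = None,
    study_info_key: str = "SID",
    rename_map: Optional[Dict[str, str]] = None,
) -> Tuple[VariantCatalog, Counter]:
    """Load biallelic SNVs from a VCF, returning (catalog, exclusion counts)."""
    rename_map = rename_map or {}
    counts: Counter = Counter()
    records: List[VariantRecord] = []
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except Exception as exc:
        raise ValueError(f"malformed VCF {vcf_path}: {exc}") from exc
    with vf:
        for rec in vf:
            chrom = rename_map.get(rec.chrom, rec.chrom)
            if genome is not None and chrom not in genome:
                counts["unknown_chrom"] += 1
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                counts["multiallelic" if len(alts) > 1 else "no_alt"] += 1
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
                counts["non_snv"] += 1
                continue
            if genome is not None:
                if rec.pos > genome.length(chrom):
                    counts["out_of_bounds"] += 1
                    continue
                if genome.sequence(chrom)[rec.pos - 1] != ref:
                    counts["ref_mismatch"] += 1
                    continue
            sids: FrozenSet[str] = frozenset()
            if study_info_key in rec.info:
                raw = rec.info[study_info_key]
                if isinstance(raw, (tuple, list)):
                    raw = ",".join(str(x) for x in raw)
                sids = frozenset(s for s in str(raw).split(",") if s)
            records.append(VariantRecord(chrom, rec.pos, ref, alt, sids))
            counts["retained"] += 1
    for reason, n in counts.items():
        if reason != "retained":
            log.info("excluded %d records: %s", n, reason)
    return VariantCatalog(records), counts


def write_vcf(
    catalog: VariantCatalog,
    path: str,
    genome: GenomeAssembly,
    study_info_key: str = "SID",
) -> None:
    """Write a sites-only VCF 4.2 with submission ids in an INFO key."""
    header = pysam.VariantHeader()
    header.add_line(
        f'##INFO=<ID={study_info_key},Number=.,Type=String,'
        f'Description="Submission study identifiers">'
    )
    for chrom in genome.chromosomes:
        header.contigs.add(chrom, length=genome.length(chrom))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in catalog.records:
            rec = out.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos,
                alleles=(r.ref, r.alt), filter="PASS",
            )
            if r.study_ids:
                rec.info[study_info_key] = tuple(sorted(r.study_ids))
            out.write(rec)


def titv_ratio(records: Iterable[VariantRecord]) -> Optional[float]:
    """Transition/transversion ratio; None when undefined (no transversions)."""
    ti = tv = 0
    for r in records:
        if r.is_transition:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


def genome_wide_density(catalog: VariantCatalog, genome: GenomeAssembly) -> float:
    """Variants per 100 bases of effective (non-N) genome."""
    eff = genome.effective_length()
    if eff == 0:
        raise ValueError("genome has zero effective length")
    return 100.0 * len(catalog) / eff


def filter_by_submission(
    catalog: VariantCatalog,
    min_submissions: Optional[int] = None,
    exclude_private_to: Optional[str] = None,
) -> Tuple[VariantCatalog, Counter]:
    """Submission-count or private-batch filtering.

    min-count mode keeps records carrying at least ``min_submissions`` study
    ids (records without study metadata are dropped when the threshold
    exceeds one, and counted); exclude mode drops records whose study ids are
    exactly the excluded batch, keeping sites that batch shares with others.
    """
    if min_submissions is not None and exclude_private_to is not None:
        raise ValueError("apply min-count and exclude modes sequentially, not together")
    counts: Counter = Counter()
    kept: List[VariantRecord] = []
    if min_submissions is not None:
        if min_submissions < 1:
            raise ValueError("min_submissions must be >= 1")
        for r in catalog:
            if not r.study_ids and min_submissions > 1:
                counts["dropped_no_metadata"] += 1
            elif len(r.study_ids) >= min_submissions or min_submissions == 1:
                kept.append(r)
                counts["kept"] += 1
            else:
                counts["dropped_below_min"] += 1
    elif exclude_private_to is not None:
        private = frozenset({exclude_private_to})
        for r in catalog:
            if r.study_ids == private:
                counts["dropped_private"] += 1
            else:
                kept.append(r)
                counts["kept"] += 1
    else:
        kept = list(catalog)
        counts["kept"] = len(kept)
    if counts.get("dropped_no_metadata"):
        log.info("dropped %d records without study metadata", counts["dropped_no_metadata"])
    return VariantCatalog(kept), counts


@dataclass
class CatalogSummary:
    n_snvs: int
    titv: Optional[float]
    pct_coding: float
    titv_coding: Optional[float]
    density_per_100bp: float

    def as_dict(self) -> dict:
        return {
            "n_snvs": self.n_snvs,
            "titv": self.titv,
            "pct_coding": self.pct_coding,
            "titv_coding": self.titv_coding,
            "density_per_100bp": self.density_per_100bp,
        }


def summarize(catalog: VariantCatalog, features, genome: GenomeAssembly) -> CatalogSummary:
    """Headline metrics: count, Ti/Tv (overall and coding), % coding, density."""
    from .constraint import variants_in_class  # local import avoids a cycle

    coding = variants_in_class(catalog, features, "coding")
    n = len(catalog)
    return CatalogSummary(
        n_snvs=n,
        titv=titv_ratio(catalog),
        pct_coding=100.0 * len(coding) / n if n else 0.0,
        titv_coding=titv_ratio(coding),
        density_per_100bp=genome_wide_density(catalog, genome) if n else 0.0,
    )
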