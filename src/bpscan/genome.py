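"""Genome container and interval primitives.

Internal coordinates are 0-based half-open throughout the package; the
standard file dialects (GTF 1-based inclusive, VCF 1-based points) are
converted at the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from pyfaidx import Fasta

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric base codes used for vectorised sequence work: A=0 C=1 G=2 T=3, N/other=4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of (start, end) pairs as a sorted list of disjoint intervals."""
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> Dict[str, List[Tuple[int, int]]]:
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}


class GenomeAssembly:
    """Named chromosome sequences (uppercase A/C/G/T/N) with N-aware accounting.

    The assembly is the coordinate universe for every other module: feature
    catalogues, variant positions and branch point predictions are all
    validated against it. Undetermined bases (N) are excluded from every
    effective-length denominator.
    """

    def __init__(self, sequences: Dict[str, str]):
        if not sequences:
            raise ValueError("assembly needs at least one chromosome")
        self._seqs: Dict[str, str] = {}
        self._codes: Dict[str, np.ndarray] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome name {name!r}")
            up = seq.upper()
            bad = set(up) - set("ACGTN")
            if bad:
                raise ValueError(f"chromosome {name!r} has invalid characters {bad}")
            self._seqs[name] = up
            self._codes[name] = encode(up)

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeAssembly":
        fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chromosomes(self) -> List[str]:
        return list(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def codes(self, chrom: str) -> np.ndarray:
        """Per-base numeric codes for a chromosome (A=0..T=3, N=4)."""
        return self._codes[chrom]

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def n_count(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int((self._codes[chrom] == 4).sum())
        return sum(self.n_count(c) for c in self._seqs)

    def effective_length(self) -> int:
        """Total assembly length excluding undetermined (N) bases."""
        return self.total_length() - self.n_count()

    def fetch(self, interval: GenomicInterval, oriented: bool = False) -> str:
        """Sequence of an interval; reverse-complemented if oriented and strand '-'."""
        if interval.chrom not in self._seqs:
            raise KeyError(interval.chrom)
        if interval.end > self.length(interval.chrom):
            raise ValueError(
                f"interval {interval} exceeds chromosome length "
                f"{self.length(interval.chrom)}"
            )
        seq = self._seqs[interval.chrom][interval.start : interval.end]
        if oriented and interval.strand == "-":
            seq = reverse_complement(seq)
        return seq

    def base_frequencies(self) -> np.ndarray:
        """Genome-wide A/C/G/T frequencies over non-N bases."""
        counts = np.zeros(4, dtype=np.int64)
        for codes in self._codes.values():
            counts += np.bincount(codes, minlength=5)[:4]
        total = counts.sum()
        if total == 0:
            raise ValueError("assembly contains no determined bases")
        return counts / total

    def effective_interval_length(
        self, by_chrom: Dict[str, Sequence[Tuple[int, int]]]
    ) -> int:
        """Non-N base count in a union of per-chromosome disjoint intervals."""
        total = 0
        for chrom, ivs in by_chrom.items():
            codes = self._codes[chrom]
            for s, e in ivs:
                total += (e - s) - int((codes[s:e] == 4).sum())
        return total

    def write_fasta(self, path: str, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
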