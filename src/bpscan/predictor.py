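"""Branch point sequence prediction.

The predictor scores every candidate heptamer in a configurable window
upstream of the 3' splice site and keeps the single best per intron. The
score is an explicit two-component log-odds (in bits):

    score(d) = sum_k log2( PWM[k][b_k] / q[b_k] )
             + lambda * sum_o log2( f_bin(d_o)(o) / g(o) )

where the first sum runs over the 7 heptamer positions against genome base
frequencies q, and the second over the sliding octanucleotides of the
polypyrimidine-tract context between the branch point and the 3' splice
site, compared between a distance-binned intronic frequency table f and a
genome-wide intronic octamer background g. The branch point is fixed at
heptamer position 6; distance d counts the branch point's rank from the
intron's 3' end (the last intron base has d = 1).
"""

from __future__ import annotations

import importlib.resources
import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .annotation import IntronRecord
from .genome import GenomeAssembly, encode

BASES = "ACGT"
_N_OCT = 4 ** 8

IUPAC_PAIRS = {"y": (1, 3), "r": (0, 2)}  # C/T and A/G column indices


class PWM:
    """7-position x 4-base probability matrix with pseudocount provenance."""

    def __init__(self, probs: np.ndarray, pseudocount: float = 0.0, label: str = ""):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (7, 4):
            raise ValueError(f"PWM must be 7x4, got {probs.shape}")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if np.any(probs <= 0):
            raise ValueError("PWM entries must be positive (apply a pseudocount)")
        self.probs = probs
        self.pseudocount = pseudocount
        self.label = label

    @classmethod
    def train(
        cls, heptamers: Sequence[str], pseudocount: float = 1.0, label: str = "trained"
    ) -> "PWM":
        """Column-wise base frequencies with a per-base pseudocount."""
        if not heptamers:
            raise ValueError("training needs at least one heptamer")
        counts = np.zeros((7, 4))
        for h in heptamers:
            if len(h) != 7 or any(b not in BASES for b in h):
                raise ValueError(f"invalid training heptamer {h!r}")
            for k, b in enumerate(h):
                counts[k, BASES.index(b)] += 1
        probs = (counts + pseudocount) / (len(heptamers) + 4 * pseudocount)
        return cls(probs, pseudocount, label)

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "PWM":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("pos"):
                    continue
                parts = line.split("\t")
                rows.append([float(x) for x in parts[1:5]])
        return cls(np.array(rows), label=label or str(path))

    @classmethod
    def default(cls) -> "PWM":
        """Package default branch point PWM (consensus 'nnyTrAy')."""
        ref = importlib.resources.files("bpscan.data").joinpath("default_bps_pwm.tsv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path, label="bpscan default (nnyTrAy)")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pos\tA\tC\tG\tT\n")
            for k, row in enumerate(self.probs, 1):
                fh.write(f"{k}\t" + "\t".join(f"{p:.6g}" for p in row) + "\n")

    def log_odds(self, q: np.ndarray) -> np.ndarray:
        """Per-position log2 odds against background base frequencies q."""
        q = np.asarray(q, dtype=float)
        if q.shape != (4,) or np.any(q <= 0):
            raise ValueError("q must be 4 positive frequencies")
        return np.log2(self.probs / q)

    def consensus(self, threshold: float = 0.75) -> str:
        return matrix_consensus(self.probs, threshold)

    def information_content(self) -> float:
        """Total relative entropy vs the uniform background, in bits."""
        return float((self.probs * np.log2(self.probs / 0.25)).sum())


def matrix_consensus(probs: np.ndarray, threshold: float = 0.75) -> str:
    """IUPAC-style consensus: uppercase base >= threshold, else a purine or
    pyrimidine pair jointly >= threshold ('r'/'y'), else 'n'."""
    out = []
    for row in probs:
        top = int(np.argmax(row))
        if row[top] >= threshold:
            out.append(BASES[top])
            continue
        for code, (i, j) in IUPAC_PAIRS.items():
            if row[i] + row[j] >= threshold:
                out.append(code)
                break
        else:
            out.append("n")
    return "".join(out)


class OctamerBackground:
    """Distance-binned intronic octamer frequencies with a genome-wide reference.

    Octamers from the last ``window`` transcript-orientation bases of each
    intron are tallied into bins of their 3'-end distance to the 3' splice
    site; a pseudocount of one per octamer per bin keeps every frequency
    positive. The reference table g is estimated from all intronic sequence.
    """

    def __init__(
        self,
        bin_freq: np.ndarray,
        genome_freq: np.ndarray,
        window: int,
        bin_width: int,
    ):
        self.bin_freq = bin_freq  # (n_bins, 4**8)
        self.genome_freq = genome_freq  # (4**8,)
        self.window = window
        self.bin_width = bin_width
        self.n_bins = bin_freq.shape[0]
        if not np.allclose(bin_freq.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("bin frequencies must each sum to 1")

    @classmethod
    def estimate(
        cls,
        introns: Sequence[IntronRecord],
        genome: GenomeAssembly,
        window: int = 150,
        bin_width: int = 10,
        pseudocount: float = 1.0,
    ) -> "OctamerBackground":
        if window < bin_width or bin_width < 8:
            raise ValueError("need window >= bin_width >= 8")
        n_bins = -(-window // bin_width)  # ceil: bins tile [0, window)
        bin_counts = np.zeros((n_bins, _N_OCT), dtype=np.int64)
        g_counts = np.zeros(_N_OCT, dtype=np.int64)
        usable = 0
        for intron in introns:
            codes = encode(intron.sequence(genome))
            n = len(codes)
            if n < 8:
                continue
            octs, valid = _octamer_codes(codes)
            if not valid.any():
                continue
            usable += 1
            g_counts += np.bincount(octs[valid], minlength=_N_OCT)
            w = min(window, n)
            starts = np.arange(n - 7)
            d3 = n - starts - 8  # distance of octamer 3' end to the 3' splice site
            in_window = valid & (starts >= n - w) & (d3 < window)
            for b in range(n_bins):
                sel = in_window & (d3 // bin_width == b)
                if sel.any():
                    bin_counts[b] += np.bincount(octs[sel], minlength=_N_OCT)
        if usable == 0:
            raise ValueError("no usable introns (length >= 8, non-N) for the background")
        bin_freq = (bin_counts + pseudocount) / (
            bin_counts.sum(axis=1, keepdims=True) + pseudocount * _N_OCT
        )
        genome_freq = (g_counts + pseudocount) / (g_counts.sum() + pseudocount * _N_OCT)
        return cls(bin_freq, genome_freq, window, bin_width)

    def octamer_log_odds(self, oct_code: int, d3: int) -> float:
        """log2 f_bin(o)/g(o) for an octamer whose 3' end is d3 bases from the 3'SS."""
        if not 0 <= d3 < self.window:
            raise ValueError(f"distance {d3} outside [0, {self.window})")
        b = d3 // self.bin_width
        return math.log2(self.bin_freq[b, oct_code] / self.genome_freq[oct_code])


def _octamer_codes(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding octamer base-4 codes and a validity mask (no N) per start."""
    n = len(codes)
    if n < 8:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, 8)
    valid = (win < 4).all(axis=1)
    safe = np.where(win < 4, win, 0).astype(np.int64)
    powers = 4 ** np.arange(7, -1, -1, dtype=np.int64)
    return safe @ powers, valid


@dataclass(frozen=True)
class BranchPointPrediction:
    """Best-scoring heptamer of one intron, branch point at heptamer position 6."""

    intron_id: str
    chrom: str
    strand: str
    bp_pos: int  # 1-based genomic position of the branch point (forward strand)
    distance: int  # branch point rank from the intron 3' end (last base = 1)
    heptamer: str  # transcript orientation
    score: float
    heptamer_positions: Tuple[int, ...]  # 1-based genomic positions of positions 1..7


def score_candidate(
    heptamer: str,
    context: str,
    pwm: PWM,
    bg: Optional[OctamerBackground],
    q: np.ndarray,
    lam: float = 1.0,
) -> float:
    """Score one candidate from its heptamer and downstream context.

    ``context`` is the transcript-orientation sequence from the base after
    the branch point through the intron's 3' end. Heptamers containing N are
    not scorable. Context octamers containing N or ending beyond the
    background window are skipped.
    """
    if len(heptamer) != 7:
        raise ValueError("heptamer must have length 7")
    hcodes = encode(heptamer)
    if (hcodes > 3).any():
        raise ValueError("heptamer contains undetermined bases")
    score = float(pwm.log_odds(q)[np.arange(7), hcodes].sum())
    if lam != 0.0 and bg is not None and len(context) >= 8:
        ccodes = encode(context)
        octs, valid = _octamer_codes(ccodes)
        m = len(context)
        for j in range(m - 7):
            d3 = m - j - 8  # context ends at the 3' splice site
            if valid[j] and 0 <= d3 < bg.window:
                score += lam * bg.octamer_log_odds(int(octs[j]), d3)
    return score


class PredictionSet:
    """Predictions plus the introns that yielded no valid candidate."""

    def __init__(
        self,
        predictions: List[BranchPointPrediction],
        unpredicted: List[str],
    ):
        self.predictions = predictions
        self.unpredicted = unpredicted

    def __len__(self) -> int:
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    def heptamers(self) -> List[str]:
        return [p.heptamer for p in self.predictions]

    def distances(self) -> np.ndarray:
        return np.array([p.distance for p in self.predictions])


def predict_branch_points(
    introns: Sequence[IntronRecord],
    genome: GenomeAssembly,
    pwm: PWM,
    bg: Optional[OctamerBackground] = None,
    lam: float = 1.0,
    d_min: int = 9,
    d_max: int = 150,
    donor_guard: int = 2,
    q: Optional[np.ndarray] = None,
) -> PredictionSet:
    """Best heptamer per intron over branch point distances [d_min, d_max].

    Candidates whose heptamer would run into the first ``donor_guard`` intron
    bases or that contain N are skipped; ties are broken toward the smaller
    distance (nearer the 3' splice site). Introns without any valid candidate
    are reported as unpredicted.
    """
    if d_min < 2:
        raise ValueError("d_min must be >= 2 so the heptamer fits in the intron")
    if lam != 0.0 and bg is None:
        raise ValueError("octamer background required when lambda != 0")
    if q is None:
        q = genome.base_frequencies()
    logodds = pwm.log_odds(q)
    predictions: List[BranchPointPrediction] = []
    unpredicted: List[str] = []

    for idx, intron in enumerate(introns):
        intron_id = f"{intron.chrom}:{intron.start + 1}-{intron.end}:{intron.strand}"
        seq = intron.sequence(genome)
        codes = encode(seq)
        n = len(codes)
        hi = min(d_max, n - donor_guard - 5)
        if hi < d_min:
            unpredicted.append(intron_id)
            continue

        # octamer context scores, shared by all candidates via a suffix sum
        if lam != 0.0 and n >= 8:
            octs, valid = _octamer_codes(codes)
            starts = np.arange(n - 7)
            d3 = n - starts - 8
            ok = valid & (d3 < bg.window)
            oscore = np.zeros(n - 7)
            if ok.any():
                b = d3[ok] // bg.bin_width
                oscore[ok] = np.log2(
                    bg.bin_freq[b, octs[ok]] / bg.genome_freq[octs[ok]]
                )
            suffix = np.zeros(n + 1)
            suffix[: n - 7] = oscore[::-1].cumsum()[::-1]
        else:
            suffix = np.zeros(n + 1)

        best_score, best_d = -np.inf, None
        win = np.lib.stride_tricks.sliding_window_view(codes, 7)
        for d in range(d_min, hi + 1):
            bp_idx = n - d
            h_start = bp_idx - 5
            hept = win[h_start]
            if (hept > 3).any():
                continue
            s = float(logodds[np.arange(7), hept].sum())
            if lam != 0.0:
                s += lam * float(suffix[bp_idx + 1])
            if s > best_score:
                best_score, best_d = s, d
        if best_d is None:
            unpredicted.append(intron_id)
            continue

        bp_idx = n - best_d
        t_positions = range(bp_idx - 5, bp_idx + 2)
        g_positions = tuple(intron.genomic_position(t) + 1 for t in t_positions)
        predictions.append(
            BranchPointPrediction(
                intron_id=intron_id,
                chrom=intron.chrom,
                strand=intron.strand,
                bp_pos=intron.genomic_position(bp_idx) + 1,
                distance=best_d,
                heptamer=seq[bp_idx - 5 : bp_idx + 2],
                score=best_score,
                heptamer_positions=g_positions,
            )
        )
    return PredictionSet(predictions, unpredicted)


def consensus_sequence(
    predictions: Iterable[BranchPointPrediction] | Sequence[str],
    threshold: float = 0.75,
) -> str:
    """IUPAC-style consensus of the predicted heptamers."""
    heptamers = [
        p.heptamer if isinstance(p, BranchPointPrediction) else p for p in predictions
    ]
    if not heptamers:
        raise ValueError("no predictions to summarise")
    counts = np.zeros((7, 4))
    for h in heptamers:
        for k, bchar in enumerate(h):
            counts[k, BASES.index(bchar)] += 1
    return matrix_consensus(counts / len(heptamers), threshold)


def canonical_tna_fraction(
    predictions: Iterable[BranchPointPrediction] | Sequence[str],
) -> float:
    """Fraction of heptamers with the canonical TnA motif (T at 4, A at 6)."""
    heptamers = [
        p.heptamer if isinstance(p, BranchPointPrediction) else p for p in predictions
    ]
    if not heptamers:
        raise ValueError("no predictions to summarise")
    hits = sum(1 for h in heptamers if h[3] == "T" and h[5] == "A")
    return hits / len(heptamers)


def distance_summary(predictions: PredictionSet | Sequence[BranchPointPrediction]) -> dict:
    """Median, 2.5/97.5 percentiles and per-distance histogram of BP distances."""
    preds = list(predictions)
    if not preds:
        raise ValueError("no predictions to summarise")
    d = np.array([p.distance for p in preds])
    return {
        "median": float(np.median(d)),
        "p2.5": float(np.percentile(d, 2.5)),
        "p97.5": float(np.percentile(d, 97.5)),
        "histogram": dict(sorted(Counter(d.tolist()).items())),
    }


def write_predictions_tsv(predictions: PredictionSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("intron_id\tchrom\tstrand\tbp_pos_1based\tdistance\theptamer\tscore\n")
        for p in predictions:
            fh.write(
                f"{p.intron_id}\t{p.chrom}\t{p.strand}\t{p.bp_pos}\t"
                f"{p.distance}\t{p.heptamer}\t{p.score:.4f}\n"
            )
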