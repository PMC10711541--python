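"""Relative variability of genomic features and nucleotide-level profiles.

Variability of a feature class is its variant density (variants per 100
effective bases) divided by the genome-wide density; values below 1 indicate
depletion, the footprint of purifying selection. Position profiles count
variable versus invariant *sites* (a site either overlaps at least one SNV
or it does not), and positions 4 and 6 of the branch point heptamer are
compared with a two-sided Fisher's exact test under a Bonferroni-corrected
significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import FeatureCatalog, IntronRecord
from .genome import GenomeAssembly
from .predictor import BranchPointPrediction, PredictionSet
from .variants import VariantCatalog, genome_wide_density


def variants_in_class(
    catalog: VariantCatalog, features: FeatureCatalog, cls: str
) -> List:
    """Variant records overlapping the union of a class's intervals.

    Each variant counts once per class even when it hits several intervals
    of that class; a variant may belong to several classes.
    """
    out = []
    for chrom, merged in features.merged(cls).items():
        if not merged:
            continue
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        pos = catalog.positions(chrom)
        if len(pos) == 0:
            continue
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        hit = set(pos[inside].tolist())
        out.extend(r for r in catalog.records if r.chrom == chrom and r.pos - 1 in hit)
    return out


def feature_variability(
    catalog: VariantCatalog,
    features: FeatureCatalog,
    genome: GenomeAssembly,
    classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-class variant counts, effective lengths and relative variability.

    Includes a ``genome_wide`` pseudo-class whose relative variability is 1
    by construction. Classes with zero effective length are reported absent
    (dropped) rather than raising.
    """
    gw_density = genome_wide_density(catalog, genome)
    rows = {}
    names = list(classes) if classes is not None else features.classes
    for cls in names:
        eff = features.effective_length(cls, genome)
        if eff == 0:
            continue
        n = len(variants_in_class(catalog, features, cls))
        dens = 100.0 * n / eff
        rows[cls] = (n, eff, dens, dens / gw_density if gw_density > 0 else np.nan)
    rows["genome_wide"] = (
        len(catalog),
        genome.effective_length(),
        gw_density,
        gw_density / gw_density if gw_density > 0 else np.nan,
    )
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["n_variants", "effective_length", "density_per_100bp", "relative_variability"],
    )
    df.index.name = "feature"
    df.attrs["genome_wide_density"] = gw_density
    return df


@dataclass
class PositionProfile:
    """Variable/invariant site counts per position of a sequence context."""

    label: str
    offsets: List[int | str]
    n_variable: List[int]
    n_total: List[int]
    relative: List[float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "n_variable_sites": self.n_variable,
                "n_total_sites": self.n_total,
                "relative_variability": self.relative,
            }
        )

    def at(self, offset) -> Tuple[int, int, float]:
        i = self.offsets.index(offset)
        return self.n_variable[i], self.n_total[i], self.relative[i]


def _profile_from_sites(
    label: str,
    offsets: Sequence[int | str],
    site_lists: Dict,
    catalog: VariantCatalog,
    gw_density: float,
) -> PositionProfile:
    n_var, n_tot, rel = [], [], []
    for off in offsets:
        sites = site_lists[off]  # list of (chrom, 0-based pos)
        total = len(sites)
        var = sum(1 for chrom, p in sites if p in catalog.site_set(chrom))
        n_var.append(var)
        n_tot.append(total)
        if total == 0 or gw_density == 0:
            rel.append(float("nan"))
        else:
            rel.append((100.0 * var / total) / gw_density)
    return PositionProfile(label, list(offsets), n_var, n_tot, rel)


def splice_site_profile(
    catalog: VariantCatalog,
    introns: Sequence[IntronRecord],
    genome: GenomeAssembly,
    exonic_flank: int = 3,
    intronic_flank: int = 8,
) -> Tuple[PositionProfile, PositionProfile]:
    """Per-offset variability around donor and acceptor junctions.

    Offsets are transcript-orientation: negative = exonic side, positive
    intronic for the donor window; negative intronic, positive exonic for
    the acceptor window. Sites that fall on N or off-chromosome are excluded
    from that offset's denominator.
    """
    if not introns:
        raise ValueError("no introns to profile")
    if exonic_flank < 0 or intronic_flank < 2:
        raise ValueError("flanks too small: need intronic_flank >= 2")
    gw = genome_wide_density(catalog, genome)
    donor_offsets = list(range(-exonic_flank, 0)) + list(range(1, intronic_flank + 1))
    acceptor_offsets = list(range(-intronic_flank, 0)) + list(range(1, exonic_flank + 1))
    donor_sites = {o: [] for o in donor_offsets}
    acceptor_sites = {o: [] for o in acceptor_offsets}

    for intron in introns:
        n = len(intron)
        step = -1 if intron.strand == "-" else 1
        if intron.strand == "-":
            donor_junction = intron.end - 1  # first intron base, transcript orientation
            acceptor_junction = intron.start  # last intron base
        else:
            donor_junction = intron.start
            acceptor_junction = intron.end - 1
        for off in donor_offsets:
            t = off - 1 if off > 0 else off  # offset +1 is the first intron base
            g = donor_junction + step * t
            _add_site(donor_sites[off], intron.chrom, g, genome)
        for off in acceptor_offsets:
            t = off + 1 if off < 0 else off  # offset -1 is the last intron base
            g = acceptor_junction + step * t
            _add_site(acceptor_sites[off], intron.chrom, g, genome)

    donor = _profile_from_sites("donor", donor_offsets, donor_sites, catalog, gw)
    acceptor = _profile_from_sites("acceptor", acceptor_offsets, acceptor_sites, catalog, gw)
    return donor, acceptor


def _add_site(bucket, chrom, g, genome):
    if 0 <= g < genome.length(chrom) and genome.sequence(chrom)[g] != "N":
        bucket.append((chrom, g))


def bps_profile(
    catalog: VariantCatalog,
    predictions: PredictionSet | Sequence[BranchPointPrediction],
    genome: GenomeAssembly,
) -> PositionProfile:
    """Site-level variability at heptamer positions 1..7 of the predictions."""
    preds = list(predictions)
    if not preds:
        raise ValueError("no predictions to profile")
    gw = genome_wide_density(catalog, genome)
    sites = {k: [] for k in range(1, 8)}
    for p in preds:
        for k, gpos in enumerate(p.heptamer_positions, 1):
            _add_site(sites[k], p.chrom, gpos - 1, genome)
    return _profile_from_sites("bps_heptamer", list(range(1, 8)), sites, catalog, gw)


@dataclass
class PositionComparison:
    position_a: int | str
    position_b: int | str
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float
    p_value: float
    alpha: float
    m_tests: int
    threshold: float
    significant: bool


def compare_positions(
    profile: PositionProfile,
    pos_a=4,
    pos_b=6,
    alpha: float = 0.05,
    m_tests: int = 1,
) -> PositionComparison:
    """Two-sided Fisher's exact test on variable/invariant sites at two positions.

    Two-sided by the point-probability rule: the p-value sums the
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.
    """
    var_a, tot_a, _ = profile.at(pos_a)
    var_b, tot_b, _ = profile.at(pos_b)
    if tot_a == 0 or tot_b == 0:
        raise ValueError("both positions need a non-zero site denominator")
    table = [[var_a, tot_a - var_a], [var_b, tot_b - var_b]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    thr = bonferroni_threshold(alpha, m_tests)
    return PositionComparison(
        position_a=pos_a,
        position_b=pos_b,
        table=((table[0][0], table[0][1]), (table[1][0], table[1][1])),
        odds_ratio=float(odds),
        p_value=float(p),
        alpha=alpha,
        m_tests=m_tests,
        threshold=thr,
        significant=bool(p < thr),
    )


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Per-test significance threshold alpha/m for m tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return alpha / m_tests
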