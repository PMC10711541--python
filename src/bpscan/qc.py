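"""Plausibility audit of a variant catalogue against three criteria.

A catalogue qualifies for constraint analysis only if (i) its genome-wide
density reaches one variant per 1000 effective bases, (ii) intergenic
regions are more variable than the genome-wide average, and (iii) variation
is depleted at each of the four bases overlapping splice sites (the two
donor and two acceptor dinucleotide positions). Ti/Tv ratios and the coding
variant fraction are reported as context but do not gate the verdict: a
catalogue can carry a plausible Ti/Tv and still show implausible splice-site
variability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .annotation import FeatureCatalog, IntronRecord
from .constraint import feature_variability, splice_site_profile
from .genome import GenomeAssembly
from .variants import VariantCatalog, genome_wide_density, summarize


@dataclass
class QCThresholds:
    min_density_per_kb: float = 1.0
    intergenic_min_relative: float = 1.0
    splice_max_relative: float = 1.0

    def __post_init__(self):
        if min(self.min_density_per_kb, self.intergenic_min_relative,
               self.splice_max_relative) <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class CriterionResult:
    name: str
    measured: Optional[object]
    threshold: float
    passed: bool
    note: str = ""


@dataclass
class QCReport:
    criteria: List[CriterionResult]
    verdict: bool
    context: Dict[str, object] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "criteria": [
                {
                    "name": c.name,
                    "measured": c.measured,
                    "threshold": c.threshold,
                    "passed": c.passed,
                    "note": c.note,
                }
                for c in self.criteria
            ],
            "verdict": "pass" if self.verdict else "fail",
            "context": self.context,
        }

    def to_json(self, path: Optional[str] = None) -> str:
        text = json.dumps(self.as_dict(), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = []
        for c in self.criteria:
            status = "PASS" if c.passed else "FAIL"
            lines.append(f"[{status}] {c.name}: measured={c.measured} threshold={c.threshold}")
            if c.note:
                lines.append(f"       {c.note}")
        for k, v in self.context.items():
            lines.append(f"       {k} = {v}")
        lines.append(f"VERDICT: {'pass' if self.verdict else 'fail'}")
        return "\n".join(lines)


SPLICE_OFFSETS = {
    "donor": (1, 2),  # first two intron bases
    "acceptor": (-2, -1),  # last two intron bases
}


def evaluate_database(
    catalog: VariantCatalog,
    features: FeatureCatalog,
    genome: GenomeAssembly,
    introns: Sequence[IntronRecord],
    thresholds: Optional[QCThresholds] = None,
) -> QCReport:
    """Apply the three plausibility criteria and assemble the audit report."""
    thr = thresholds or QCThresholds()
    criteria: List[CriterionResult] = []

    density_kb = 10.0 * genome_wide_density(catalog, genome)  # per 1000 bases
    criteria.append(
        CriterionResult(
            name="i_genome_wide_density",
            measured=round(density_kb, 4),
            threshold=thr.min_density_per_kb,
            passed=density_kb >= thr.min_density_per_kb,
            note="variants per 1000 effective bases",
        )
    )

    var_table = feature_variability(catalog, features, genome, classes=["intergenic"])
    if "intergenic" in var_table.index:
        rel = float(var_table.loc["intergenic", "relative_variability"])
        criteria.append(
            CriterionResult(
                name="ii_intergenic_above_genome_wide",
                measured=round(rel, 4),
                threshold=thr.intergenic_min_relative,
                passed=rel > thr.intergenic_min_relative,
                note="intergenic density relative to genome-wide",
            )
        )
    else:
        criteria.append(
            CriterionResult(
                name="ii_intergenic_above_genome_wide",
                measured=None,
                threshold=thr.intergenic_min_relative,
                passed=False,
                note="no intergenic sequence available; criterion not assessable (fail-safe)",
            )
        )

    if introns:
        donor, acceptor = splice_site_profile(
            catalog, introns, genome, exonic_flank=0, intronic_flank=2
        )
        measured = {}
        ok = True
        for label, profile in (("donor", donor), ("acceptor", acceptor)):
            for off in SPLICE_OFFSETS[label]:
                _, _, rel = profile.at(off)
                measured[f"{label}{off:+d}"] = round(rel, 4)
                ok = ok and rel < thr.splice_max_relative
        criteria.append(
            CriterionResult(
                name="iii_splice_site_depletion",
                measured=measured,
                threshold=thr.splice_max_relative,
                passed=ok,
                note="relative variability at the 4 splice-site bases; each must be depleted",
            )
        )
    else:
        criteria.append(
            CriterionResult(
                name="iii_splice_site_depletion",
                measured=None,
                threshold=thr.splice_max_relative,
                passed=False,
                note="no introns available; criterion not assessable (fail-safe)",
            )
        )

    summary = summarize(catalog, features, genome)
    report = QCReport(
        criteria=criteria,
        verdict=all(c.passed for c in criteria),
        context={
            "n_snvs": summary.n_snvs,
            "titv": None if summary.titv is None else round(summary.titv, 4),
            "pct_coding": round(summary.pct_coding, 4),
            "titv_coding": None if summary.titv_coding is None else round(summary.titv_coding, 4),
            "density_per_100bp": round(summary.density_per_100bp, 4),
        },
    )
    return report
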