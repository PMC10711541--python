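import numpy as np
import pytest

from bpscan import (
    GenomeAssembly,
    PWM,
    build_feature_catalog,
    derive_introns,
    parse_annotation,
    predict_branch_points,
)
from bpscan.simulate import SimulationConfig, generate_genome, simulate_variants


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A ~300 kb single-chromosome simulation round-tripped through files."""
    out = tmp_path_factory.mktemp("small_sim")
    cfg = SimulationConfig(n_chromosomes=1, chrom_length=300_000, n_genes=45, seed=11)
    sim = generate_genome(cfg)
    catalog = simulate_variants(sim)
    fasta, gtf = out / "genome.fa", out / "annotation.gtf"
    sim.write_fasta(fasta)
    sim.write_gtf(gtf)
    genome = GenomeAssembly.from_fasta(str(fasta))
    genes = parse_annotation(str(gtf), genome)
    introns = derive_introns(genes)
    features = build_feature_catalog(genes, genome, introns=introns)
    return {
        "cfg": cfg,
        "sim": sim,
        "catalog": catalog,
        "genome": genome,
        "genes": genes,
        "introns": introns,
        "features": features,
        "fasta": fasta,
        "gtf": gtf,
    }


@pytest.fixture(scope="session")
def big_sim():
    """The default study-scale simulation (3 Mb, ~1200 introns) with predictions."""
    cfg = SimulationConfig(seed=1)
    sim = generate_genome(cfg)
    catalog = simulate_variants(sim)
    genes = sim.genes
    introns = derive_introns(genes)
    features = build_feature_catalog(genes, sim.genome, introns=introns)
    pwm = PWM(cfg.generative_pwm, label="generative")
    preds = predict_branch_points(introns, sim.genome, pwm, lam=0.0)
    truth_by_intron = {
        (t.chrom, t.intron_start, t.intron_end, t.strand): t for t in sim.truth
    }
    return {
        "cfg": cfg,
        "sim": sim,
        "catalog": catalog,
        "genes": genes,
        "introns": introns,
        "features": features,
        "pwm": pwm,
        "preds": preds,
        "truth_by_intron": truth_by_intron,
    }


def truth_for_prediction(pred, truth_by_intron):
    chrom, span, strand = pred.intron_id.split(":")
    s, e = span.split("-")
    return truth_by_intron[(chrom, int(s) - 1, int(e), strand)]
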