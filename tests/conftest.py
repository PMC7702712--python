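import numpy as np
import pytest

from editscan.core import GeneModel, GenomicInterval
from editscan.simulate import (
    SimConfig,
    simulate_editing_reads,
    simulate_panel,
    simulate_reference,
)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        seed=11,
        n_samples=12,
        n_editing_sites=80,
        n_sites_neutral=400,
        frac_snp_editing=0.5,
        ecs_fraction=0.5,
        editing_level_beta=(2.0, 2.0),
        level_min=0.1,
        seq_error_rate=0.001,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """One shared synthetic dataset: reference, panel, pileups, DNA tables."""
    reference = simulate_reference(small_config)
    panel = simulate_panel(small_config, reference)
    rna, dna_geno, dna_counts = simulate_editing_reads(small_config, reference, panel)
    dna = {}
    for r in dna_geno.itertuples(index=False):
        dna.setdefault((r.sample, r.chrom, r.pos), {})[r.resource] = r.genotype
    return {
        "config": small_config,
        "reference": reference,
        "panel": panel,
        "rna": rna,
        "dna_genotypes": dna,
        "dna_counts": dna_counts,
    }


def make_gene(
    gene_id="g1",
    chrom="chr1",
    start=1000,
    strand="+",
    biotype="protein_coding",
    exon_bounds=((0, 300), (500, 900), (1100, 1400)),
    cds_span=(150, 1250),
):
    """A three-exon transcript with CDS covering the middle of the mRNA."""
    exons = [
        GenomicInterval(chrom, start + a, start + b, strand) for a, b in exon_bounds
    ]
    cds = []
    if biotype == "protein_coding" and cds_span is not None:
        lo, hi = cds_span
        for a, b in exon_bounds:
            s, e = max(a, lo), min(b, hi)
            if s < e:
                cds.append(GenomicInterval(chrom, start + s, start + e, strand))
    return GeneModel(
        gene_id=gene_id,
        transcript_id=gene_id + "_t1",
        strand=strand,
        exons=exons,
        cds=cds,
        biotype=biotype,
    )


@pytest.fixture
def plus_gene():
    return make_gene("gplus", strand="+")


@pytest.fixture
def minus_gene():
    return make_gene("gminus", strand="-", start=5000)
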