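import logging

import pytest
from hypothesis import HealthCheck, settings

from sbcis import GenomeIndex, SimConfig, build_index, simulate_cohort
from sbcis.genome_index import GeneRecord

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# simulator warnings about degenerate flat curves are expected at toy scale
logging.getLogger("sbcis.saturation").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small simulated cohort shared by read-only tests."""
    cfg = SimConfig(
        seed=5, n_chroms=2, chrom_len_bp=1_500_000, n_genes=120,
        n_samples=8, cohort_driver_pool=6,
        reads_per_sample=(5_000, 20_000), drivers_per_sample=(4, 20),
    )
    outdir = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(cfg, outdir)


@pytest.fixture(scope="session")
def small_index(small_cohort) -> GenomeIndex:
    return build_index(small_cohort.fasta_path, small_cohort.gff3_path)


def make_gene(gene_id="g1", chrom="chr1", start=100, end=200, strand="+",
              ext_start=None, ext_end=None, ta_count=10, insert_prob=1e-4):
    """Hand-built GeneRecord for unit tests that need no genome."""
    return GeneRecord(
        gene_id=gene_id, gene_name=gene_id.upper(), chrom=chrom, start=start,
        end=end, strand=strand, biotype="protein_coding",
        extended_start=start if ext_start is None else ext_start,
        extended_end=end if ext_end is None else ext_end,
        ta_count=ta_count, insert_prob=insert_prob,
    )


def make_index(genes, total_ta=100_000, genome_id="toy") -> GenomeIndex:
    return GenomeIndex(genes={g.gene_id: g for g in genes},
                       total_ta=total_ta, genome_id=genome_id)
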