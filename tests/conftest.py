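import numpy as np
import pandas as pd
import pytest

from apa_regulon import SimulationConfig, simulate_cohort
from apa_regulon.io_formats import PasAnnotation, PasCountMatrix


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_exons=40,
        n_samples_per_condition=20,
        n_rbps=6,
        n_true_regulations=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """One small simulated cohort shared (read-only) across tests."""
    return simulate_cohort(small_config)


def make_two_pas_exon(counts_by_sample, strand="+", exon="exonA"):
    """A single two-PAS exon count matrix from {sample: (proximal, distal)}."""
    k = 2
    anns = []
    for rank in (1, 2):
        offset = rank if strand == "+" else (k + 1 - rank)
        start = 1000 * offset
        anns.append(
            PasAnnotation(
                pas_id=f"{exon}:pas{rank}", exon_id=exon, gene_id="g1",
                chrom="chr1", start=start, end=start + 1, strand=strand,
                rank_from_5p=rank, is_distal=(rank == k),
            )
        )
    samples = list(counts_by_sample)
    data = {
        f"{exon}:pas1": [counts_by_sample[s][0] for s in samples],
        f"{exon}:pas2": [counts_by_sample[s][1] for s in samples],
    }
    counts = pd.DataFrame(data, index=samples).T
    return PasCountMatrix(annotations=anns, counts=counts)


@pytest.fixture
def two_pas_exon_factory():
    return make_two_pas_exon
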