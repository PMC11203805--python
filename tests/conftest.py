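import numpy as np
import pytest

from seleffect import (
    GeneModel,
    SimulationConfig,
    generate_cohort,
    synthetic_signature_catalog,
)


@pytest.fixture(scope="session")
def catalog():
    return synthetic_signature_catalog()


def make_gene_reference(cds: str, strand: str = "+", pad: str = "AATCG"):
    """A single-contig reference holding one gene with flanking sequence."""
    segment = cds
    if strand == "-":
        from seleffect import revcomp

        segment = revcomp(cds)
    seq = pad + segment + pad
    gene = GeneModel(
        gene_id="TOY",
        chrom="ctg",
        intervals=((len(pad) + 1, len(pad) + len(segment)),),
        strand=strand,
    )
    return {"ctg": seq}, gene


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-tumor cohort with the default gene set and planted drivers."""
    return generate_cohort(SimulationConfig(n_samples=200, seed=11))
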