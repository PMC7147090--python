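import numpy as np
import pytest

from somaticmmr import (
    Consequence,
    MutationCatalog,
    SomaticVariant,
    synthetic_panel,
    synthetic_reference_signatures,
    table1_fixture,
)


@pytest.fixture(scope="session")
def panel():
    return synthetic_panel()


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference_signatures()


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


def make_snv(
    sample_id="S1",
    gene="TP53",
    pos=100,
    ref="C",
    alt="T",
    consequence=Consequence.missense,
    t_ref=60,
    t_alt=40,
    n_ref=100,
    n_alt=0,
    context3="ACA",
    somatic_p=None,
):
    return SomaticVariant(
        sample_id=sample_id,
        gene=gene,
        chrom="chr1",
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        consequence=consequence,
        tumor_ref_reads=t_ref,
        tumor_alt_reads=t_alt,
        normal_ref_reads=n_ref,
        normal_alt_reads=n_alt,
        context3=context3,
        somatic_p=somatic_p,
    )


def expected_catalog(reference, weights, total):
    """Deterministic catalog of expected (rounded) counts under a mixture."""
    probs = reference.mixture_profile(weights)
    return MutationCatalog(sample_id="expected", counts=np.round(probs * total).astype(int))
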