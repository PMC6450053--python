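import pytest

from hurthleseq.synthdata import CohortSpec, ProgramSpec, generate_cohort

#: A small cohort that keeps every training stage feasible (each class large
#: enough for stratified CV) while staying fast enough for unit tests.
TINY_SPEC = CohortSpec(
    n_hpos_npos=14,
    n_hpos_nneg=18,
    n_hneg_npos=8,
    n_hneg_nneg=12,
    n_ni_labelled_nneg=10,
    n_genes=300,
    h_program=ProgramSpec(n_genes=20, log2fc=2.0, activity_sd=0.25),
    n_program=ProgramSpec(n_genes=10, log2fc=1.0, activity_sd=1.0),
    bm_program=ProgramSpec(n_genes=12, log2fc=1.0, activity_sd=0.5),
    variants_per_chromosome=25,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    return generate_cohort(TINY_SPEC)
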