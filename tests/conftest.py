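import pytest

from transhit.pipeline import run_pipeline
from transhit.synthetic_data import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort_config():
    # large enough that a private variant (AC=2 of 6*n alleles) is rare
    return CohortConfig(
        n_trios=100,
        n_genes=12,
        planted_trans_pairs=10,
        planted_cis_decoys=8,
        planted_denovo_decoys=8,
        planted_common_decoys=8,
        planted_qcfail_decoys=8,
        planted_benign_decoys=5,
        planted_cds_overlap_decoys=5,
        planted_fastpath_pairs=2,
        seed=20240901,
    )


@pytest.fixture(scope="session")
def cohort(cohort_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(cohort_config, outdir), outdir


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    _, outdir = cohort
    return run_pipeline(outdir)
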