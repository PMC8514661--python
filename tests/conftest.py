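import numpy as np
import pandas as pd
import pytest

from rriscore.io_formats import GenotypeMatrix, default_snp_meta
from rriscore.synthetic import (
    HumanSimSpec,
    LDBlock,
    MouseSimSpec,
    simulate_human_cohort,
    simulate_mouse_cohort,
)


@pytest.fixture(scope="session")
def human_cohort():
    """Small cohort with two causal hippocampal SNPs and one LD block."""
    spec = HumanSimSpec(
        n_subjects=400,
        n_candidate_snps=40,
        n_random_snps=40,
        causal_snp_effects={"cand0010": -0.03, "cand0011": 0.03},
        snp_mafs={"cand0010": 0.3, "cand0011": 0.25},
        ld_blocks=(LDBlock(size=3, r2=0.8),),
        seed=20,
    )
    genotypes, covariates, phenotypes, truth = simulate_human_cohort(spec)
    return {
        "spec": spec,
        "genotypes": genotypes,
        "covariates": covariates,
        "phenotypes": phenotypes,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def mouse_cohort():
    spec = MouseSimSpec(seed=7)
    behavior, ct_table, truth = simulate_mouse_cohort(spec)
    return {"spec": spec, "behavior": behavior, "ct": ct_table, "truth": truth}


def make_genotypes(dosage, snp_ids=None, subject_ids=None):
    dosage = np.asarray(dosage, dtype=float)
    snp_ids = snp_ids or [f"snp{j}" for j in range(dosage.shape[1])]
    subject_ids = subject_ids or [f"S{i}" for i in range(dosage.shape[0])]
    return GenotypeMatrix(subject_ids, snp_ids, dosage, default_snp_meta(snp_ids))


@pytest.fixture
def toy_covariates():
    rng = np.random.default_rng(0)
    n = 12
    return pd.DataFrame(
        {
            "subject_id": [f"S{i}" for i in range(n)],
            "sex": rng.integers(0, 2, n),
            "pds": rng.normal(3, 0.5, n),
            "tiv": rng.normal(1450, 100, n),
            "scanner": ["siteA", "siteB"] * 6,
        }
    )
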