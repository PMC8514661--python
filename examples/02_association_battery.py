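"""Fit the score-to-symptom association battery.

Each score is regressed against six psychometric outcomes: a Poisson GLM
for the count-like instruments (depression band, SDQ composites) and
log-OLS for the CAPE dimensions, each with a main-effect model and a
childhood-maltreatment (CM) interaction model, BH-FDR adjusted within
instrument families.
"""

import numpy as np

from rriscore import (
    HumanSimSpec,
    OutcomeSpec,
    build_rri,
    derive_cm,
    derive_sdq,
    run_battery,
    simulate_human_cohort,
)

spec = HumanSimSpec(
    n_subjects=800,
    n_candidate_snps=40,
    n_random_snps=0,
    causal_snp_effects={"cand0010": -0.03},
    snp_mafs={"cand0010": 0.3},
    outcome_specs={
        "depband": OutcomeSpec("poisson", intercept=np.log(0.8), b_score=0.1, clip=5),
        "es": OutcomeSpec("poisson", intercept=np.log(4.0), clip=20),
        "is": OutcomeSpec("poisson", intercept=np.log(4.0), clip=20),
        "cape_pds": OutcomeSpec("lognormal", intercept=np.log(10.0)),
        "cape_nds": OutcomeSpec("lognormal", intercept=np.log(14.0)),
        "cape_dds": OutcomeSpec("lognormal", intercept=np.log(12.0)),
    },
    seed=7,
)
genotypes, covariates, phenotypes, truth = simulate_human_cohort(spec)

_, scores, _ = build_rri(
    genotypes, phenotypes["hippocampus_ml"], covariates, region="hippocampus"
)

cm = derive_cm(phenotypes[[f"ctq{i}" for i in range(1, 7)]])
es, is_ = derive_sdq(
    phenotypes["sdq_conduct"], phenotypes["sdq_hyperactivity"],
    phenotypes["sdq_emotional"], phenotypes["sdq_peer"],
)
outcomes = phenotypes[["depband", "cape_pds", "cape_nds", "cape_dds"]].copy()
outcomes["es"], outcomes["is"] = es, is_

battery = run_battery(
    {"HRRI": scores["score"]}, outcomes, covariates["sex"].to_numpy(), cm
)
cols = ["outcome", "predictor", "family", "B", "p_raw", "p_fdr"]
print(battery[battery["reported"]][cols].to_string(index=False, float_format="%.4f"))
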