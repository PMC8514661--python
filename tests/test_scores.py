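import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from oracles import ols_normal_equations
from rriscore.scores import (
    DegenerateSNPError,
    NoScoreError,
    NormalizationError,
    RankDeficientError,
    ScoreDefinition,
    SNPEffect,
    build_control_score,
    build_covariate_design,
    build_rri,
    build_score_definition,
    combine_scores,
    compute_scores,
    fit_snp_volume_regression,
    ld_r2,
    prune_by_ld,
    screen_candidates,
    screen_snp_effects,
)


def _effect(snp_id, beta=0.0, p=0.5):
    return SNPEffect(snp_id=snp_id, beta_major=beta, se=0.01, t_stat=beta / 0.01,
                     p_value=p, n_used=100)


# ---------------------------------------------------------------------------
# per-SNP regression
# ---------------------------------------------------------------------------


def test_regression_matches_normal_equations(toy_covariates):
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, 12).astype(float)
    volume = rng.normal(1.2, 0.1, 12)
    eff = fit_snp_volume_regression(dosage, volume, toy_covariates, "rsX")

    X = build_covariate_design(toy_covariates)
    X.insert(1, "major_count", 2.0 - dosage)
    beta, se, t, p = ols_normal_equations(X.to_numpy(), volume)
    j = list(X.columns).index("major_count")
    assert eff.beta_major == pytest.approx(beta[j], abs=1e-10)
    assert eff.se == pytest.approx(se[j], abs=1e-10)
    assert eff.t_stat == pytest.approx(t[j], abs=1e-8)
    assert eff.p_value == pytest.approx(p[j], abs=1e-10)
    assert eff.n_used == 12


def test_constant_dosage_is_degenerate(toy_covariates):
    volume = np.linspace(1.0, 1.4, 12)
    with pytest.raises(DegenerateSNPError):
        fit_snp_volume_regression(np.ones(12), volume, toy_covariates)


def test_collinear_covariates_raise_named_error(toy_covariates):
    cov = toy_covariates.copy()
    cov["tiv"] = 2.0 * cov["pds"]  # exact collinearity with pds
    rng = np.random.default_rng(2)
    with pytest.raises(RankDeficientError, match="pds|tiv"):
        fit_snp_volume_regression(
            rng.integers(0, 3, 12).astype(float), rng.normal(1.2, 0.1, 12), cov
        )


def test_null_cohort_betas_small(human_cohort):
    """SNPs without injected effects show small coefficients."""
    g, cov, phe = (human_cohort[k] for k in ("genotypes", "covariates", "phenotypes"))
    eff = fit_snp_volume_regression(g.column("cand0030"), phe["hippocampus_ml"], cov,
                                    "cand0030")
    assert abs(eff.beta_major) < 5 * eff.se


# ---------------------------------------------------------------------------
# screening and pruning
# ---------------------------------------------------------------------------


def test_screen_uses_strict_threshold():
    effects = [_effect("a", p=0.05), _effect("b", p=0.1), _effect("c", p=0.2)]
    assert screen_candidates(effects, alpha=0.1) == ["a"]
    assert screen_candidates(effects, alpha=1.0) == ["a", "b", "c"]
    assert screen_candidates([_effect("x", p=0.5)], alpha=0.1) == []


def test_ld_r2_identity_flip_and_orthogonal():
    a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
    b = np.array([0, 1, 2, 2, 1, 0], dtype=float)
    assert ld_r2(a, a) == pytest.approx(1.0)
    assert ld_r2(a, 2 - a) == pytest.approx(1.0)
    assert ld_r2(a, b) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(DegenerateSNPError):
        ld_r2(a, np.ones(6))


def _ld_chain_matrix():
    """Three SNPs with r2(A,B) > 0.5, r2(B,C) > 0.5 but r2(A,C) <= 0.5."""
    rng = np.random.default_rng(3)
    n = 60
    a = rng.binomial(2, 0.4, n).astype(float)
    b, c = a.copy(), None
    # perturb A -> B, then B -> C until the chain condition holds
    for _ in range(200):
        b = a.copy()
        idx = rng.choice(n, 8, replace=False)
        b[idx] = rng.binomial(2, 0.4, 8)
        c = b.copy()
        idx = rng.choice(n, 8, replace=False)
        c[idx] = rng.binomial(2, 0.4, 8)
        if ld_r2(a, b) > 0.5 and ld_r2(b, c) > 0.5 and ld_r2(a, c) <= 0.5:
            return np.column_stack([a, b, c])
    raise RuntimeError("could not construct chain fixture")


def test_prune_chain_keeps_single_representative():
    g = make_genotypes(_ld_chain_matrix(), snp_ids=["A", "B", "C"])
    effects = {"A": _effect("A", p=0.05), "B": _effect("B", p=0.01), "C": _effect("C", p=0.03)}
    # A-B and B-C edges form one component; B has the smallest p
    assert prune_by_ld(["A", "B", "C"], effects, g) == ["B"]


def test_prune_no_edges_is_identity():
    rng = np.random.default_rng(4)
    g = make_genotypes(rng.binomial(2, 0.3, (200, 3)).astype(float), ["x", "y", "z"])
    effects = {s: _effect(s, p=0.05) for s in ("x", "y", "z")}
    assert prune_by_ld(["x", "y", "z"], effects, g) == ["x", "y", "z"]


def test_representatives_pairwise_below_cutoff(human_cohort):
    """No two pruning survivors may share an edge of the LD graph."""
    g, cov, phe = (human_cohort[k] for k in ("genotypes", "covariates", "phenotypes"))
    cand = [s for s in g.snp_ids if s.startswith("cand")]
    effects = screen_snp_effects(g, phe["hippocampus_ml"], cov, cand)
    candidates = screen_candidates(effects, alpha=0.5)  # plenty of candidates
    reps = prune_by_ld(candidates, effects, g, r2_cutoff=0.5)
    for i, a in enumerate(reps):
        for b in reps[i + 1:]:
            assert ld_r2(g.column(a), g.column(b)) <= 0.5


# ---------------------------------------------------------------------------
# weighting and normalization
# ---------------------------------------------------------------------------


def test_weight_is_minor_allele_effect():
    g = make_genotypes(np.array([[2.0], [0.0], [1.0]]), ["s1"])
    effects = {"s1": _effect("s1", beta=0.01)}
    defn = build_score_definition(["s1"], effects, g, "hippocampus")
    assert defn.entries["s1"] == pytest.approx(-0.01)
    # subject with dosage 2 has raw -0.02, which is the cohort minimum
    assert defn.raw_min == pytest.approx(-0.02)
    assert defn.raw_max == pytest.approx(0.0)


def test_weighted_sum_and_bounds():
    dosage = np.array([[1.0, 2.0], [0.0, 0.0], [2.0, 1.0]])
    g = make_genotypes(dosage, ["s1", "s2"])
    effects = {"s1": _effect("s1", beta=0.01), "s2": _effect("s2", beta=-0.02)}
    defn = build_score_definition(["s1", "s2"], effects, g, "mpfc")
    # weights: s1 -> -0.01, s2 -> +0.02; raws: 0.03, 0.0, 0.0
    assert defn.raw_max == pytest.approx(0.03)
    assert defn.raw_min == pytest.approx(0.0)
    with pytest.raises(NoScoreError):
        build_score_definition([], effects, g, "mpfc")


def test_scores_span_zero_to_ten_exactly(human_cohort):
    g, cov, phe = (human_cohort[k] for k in ("genotypes", "covariates", "phenotypes"))
    cand = [s for s in g.snp_ids if s.startswith("cand")]
    defn, scores, _ = build_rri(g, phe["hippocampus_ml"], cov, "hippocampus", snp_ids=cand)
    assert scores["score"].min() == 0.0
    assert scores["score"].max() == 10.0
    assert not scores["out_of_range"].any()


def test_midpoint_and_out_of_range():
    g = make_genotypes(np.array([[1.0]]), ["s1"], ["new"])
    defn = ScoreDefinition("hippocampus", {"s1": 0.01}, raw_min=0.0, raw_max=0.02)
    out = compute_scores(defn, g)
    assert out["score"].iloc[0] == pytest.approx(5.0)
    g3 = make_genotypes(np.array([[2.0]]), ["s1"], ["far"])
    defn2 = ScoreDefinition("hippocampus", {"s1": 0.015}, raw_min=0.0, raw_max=0.02)
    out2 = compute_scores(defn2, g3)  # raw 0.03 on range [0, 0.02]
    assert out2["score"].iloc[0] == pytest.approx(15.0)
    assert bool(out2["out_of_range"].iloc[0])


def test_degenerate_normalization_rejected():
    with pytest.raises(NormalizationError):
        ScoreDefinition("hippocampus", {"s1": 0.01}, raw_min=0.5, raw_max=0.5)


def test_orientation_invariance(human_cohort):
    """Flipping a stored allele orientation must not change normalized scores."""
    g, cov, phe = (human_cohort[k] for k in ("genotypes", "covariates", "phenotypes"))
    cand = [s for s in g.snp_ids if s.startswith("cand")]
    defn, scores, _ = build_rri(g, phe["hippocampus_ml"], cov, "hippocampus", snp_ids=cand)
    flipped_id = next(iter(defn.entries))
    dosage = g.dosage.copy()
    j = g.snp_ids.index(flipped_id)
    dosage[:, j] = 2.0 - dosage[:, j]
    g_flipped = make_genotypes(dosage, list(g.snp_ids), list(g.subject_ids))
    defn2, scores2, _ = build_rri(g_flipped, phe["hippocampus_ml"], cov, "hippocampus",
                                  snp_ids=cand)
    assert set(defn2.entries) == set(defn.entries)
    assert defn2.entries[flipped_id] == pytest.approx(-defn.entries[flipped_id])
    np.testing.assert_allclose(scores2["score"], scores["score"], atol=1e-8)


def test_combine_scores():
    h = pd.DataFrame({"subject_id": ["a", "b"], "score": [3.0, 10.0],
                      "out_of_range": [False, False]})
    m = pd.DataFrame({"subject_id": ["a", "b"], "score": [4.0, 10.0],
                      "out_of_range": [False, False]})
    hm = combine_scores(h, m)
    assert list(hm["score"]) == [7.0, 20.0]
    with pytest.raises(ValueError):
        combine_scores(h, m.assign(subject_id=["a", "c"]))


def test_causal_snps_screened_and_score_tracks_volume(human_cohort):
    """Injected causal SNPs survive screening; the score correlates with volume."""
    g, cov, phe = (human_cohort[k] for k in ("genotypes", "covariates", "phenotypes"))
    cand = [s for s in g.snp_ids if s.startswith("cand")]
    defn, scores, effects = build_rri(g, phe["hippocampus_ml"], cov, "hippocampus",
                                      snp_ids=cand)
    assert effects["cand0010"].p_value < 0.1
    assert effects["cand0011"].p_value < 0.1
    # higher score = more volume-increasing minor alleles
    resid = phe["hippocampus_ml"] - phe["hippocampus_ml"].mean()
    assert np.corrcoef(scores["score"], resid)[0, 1] > 0


# ---------------------------------------------------------------------------
# control scores
# ---------------------------------------------------------------------------


def test_control_score_seed_determinism(human_cohort):
    g, cov, phe = (human_cohort[k] for k in ("genotypes", "covariates", "phenotypes"))
    pool = [s for s in g.snp_ids if s.startswith("rand")]
    d1, s1, _, panel1 = build_control_score(g, phe["hippocampus_ml"], cov, "hippocampus",
                                            pool=pool, n_snps=30, seed=5)
    d2, s2, _, panel2 = build_control_score(g, phe["hippocampus_ml"], cov, "hippocampus",
                                            pool=pool, n_snps=30, seed=5)
    assert panel1 == panel2
    assert d1.entries == d2.entries
    _, _, _, panel3 = build_control_score(g, phe["hippocampus_ml"], cov, "hippocampus",
                                          pool=pool, n_snps=30, seed=6)
    assert panel3 != panel1
    with pytest.raises(ValueError, match="pool"):
        build_control_score(g, phe["hippocampus_ml"], cov, "hippocampus",
                            pool=pool, n_snps=10_000, seed=0)
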