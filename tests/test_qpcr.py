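import numpy as np
import pandas as pd
import pytest
import scipy.stats

from oracles import (
    anova_type2_f,
    exhaustive_gene_permutation_p,
    exhaustive_group_permutation_p,
)
from rriscore.mouse import derive_behavior
from rriscore.qpcr import (
    Correlogram,
    LowQualityError,
    build_correlogram,
    delta_delta_ct,
    pairwise_permutation_tests,
    permutation_factorial_anova,
    quantify_expression,
    regression_with_ci,
    two_way_f_stats,
)
from rriscore.synthetic import MouseSimSpec, simulate_mouse_cohort


# ---------------------------------------------------------------------------
# 2^-ddCt quantification
# ---------------------------------------------------------------------------


def test_ddct_hand_examples():
    # target mean 25, ref mean 22 -> dCt 3; calibrator 3 -> ddCt 0, rel 1
    rec = delta_delta_ct([25.0, 25.0, 25.0], [22.0, 22.0, 22.0], calibrator_delta_ct=3.0)
    assert rec["delta_ct"] == pytest.approx(3.0)
    assert rec["rel_level"] == pytest.approx(1.0)
    # one cycle earlier than the calibrator -> twofold expression
    rec = delta_delta_ct([24.0, 24.0], [22.0, 22.0], calibrator_delta_ct=3.0)
    assert rec["rel_level"] == pytest.approx(2.0)


def test_ddct_low_quality_raises():
    with pytest.raises(LowQualityError):
        delta_delta_ct([25.0, np.nan, np.nan], [22.0, 22.1, 21.9], calibrator_delta_ct=0.0)
    with pytest.raises(LowQualityError):
        delta_delta_ct([25.0, 25.1], [np.nan, np.nan, 22.0], calibrator_delta_ct=0.0)


def test_control_geometric_mean_is_one(mouse_cohort):
    expr = quantify_expression(
        mouse_cohort["ct"], mouse_cohort["behavior"][["animal_id", "group"]]
    )
    ns = expr[expr["group"] == "NS"]
    for gene, sub in ns.groupby("gene"):
        gm = np.exp(np.log(sub["rel_level"]).mean())
        assert gm == pytest.approx(1.0, abs=1e-9), gene


def test_quantify_excludes_low_quality_triplicates(caplog):
    ct = pd.DataFrame(
        {
            "animal_id": ["A"] * 4 + ["B"] * 6,
            "gene": ["Il18", "Rab5a", "Rab5a", "Rab5a"] + ["Il18"] * 3 + ["Rab5a"] * 3,
            "well": [1, 1, 2, 3, 1, 2, 3, 1, 2, 3],
            "ct": [25.0, 22.0, 22.1, 21.9, 25.0, 25.1, 24.9, 22.0, 22.1, 21.9],
        }
    )
    groups = pd.DataFrame({"animal_id": ["A", "B"], "group": ["MS", "NS"]})
    with caplog.at_level("WARNING"):
        expr = quantify_expression(ct, groups)
    # animal A has a single Il18 well -> excluded; only B's row survives
    assert len(expr) == 1 and expr.iloc[0]["animal_id"] == "B"
    assert "low-quality" in caplog.text


# ---------------------------------------------------------------------------
# permutation factorial ANOVA
# ---------------------------------------------------------------------------


def _tiny_expression(values, groups=("MS", "MS", "NS", "NS"), genes=("g1", "g2")):
    """Long-format expression table: values[animal][gene]."""
    rows = []
    for i, (grp, per_animal) in enumerate(zip(groups, values)):
        for g, v in zip(genes, per_animal):
            rows.append({"animal_id": f"A{i}", "gene": g, "group": grp, "rel_level": v})
    return pd.DataFrame(rows)


def test_f_stats_match_statsmodels_type2():
    rng = np.random.default_rng(0)
    df = _tiny_expression(rng.normal(1, 0.3, (6, 3)),
                          groups=("MS",) * 3 + ("NS",) * 3, genes=("g1", "g2", "g3"))
    gene_codes = df["gene"].astype("category").cat.codes.to_numpy()
    group_codes = df["group"].astype("category").cat.codes.to_numpy()
    f_gene, f_group, f_inter = two_way_f_stats(
        df["rel_level"].to_numpy(), gene_codes, group_codes
    )
    ref = anova_type2_f(df)
    assert f_gene == pytest.approx(ref["gene"], rel=1e-9)
    assert f_group == pytest.approx(ref["group"], rel=1e-9)
    assert f_inter == pytest.approx(ref["interaction"], rel=1e-9)


def test_constant_data_gives_p_one():
    df = _tiny_expression(np.ones((4, 2)))
    res = permutation_factorial_anova(df, n_perm=99, seed=1)
    assert res["gene"]["p"] == pytest.approx(1.0)
    assert res["group"]["p"] == pytest.approx(1.0)
    assert res["interaction"]["p"] == pytest.approx(1.0)


def test_exhaustive_matches_enumeration_oracle():
    rng = np.random.default_rng(2)
    df = _tiny_expression(rng.normal(1, 0.4, (4, 2)))
    res = permutation_factorial_anova(df, exhaustive=True)
    p_group_ref, p_inter_ref = exhaustive_group_permutation_p(df)
    p_gene_ref = exhaustive_gene_permutation_p(df)
    assert res["group"]["p"] == pytest.approx(p_group_ref, abs=1e-12)
    assert res["interaction"]["p"] == pytest.approx(p_inter_ref, abs=1e-12)
    assert res["gene"]["p"] == pytest.approx(p_gene_ref, abs=1e-12)


def test_injected_group_shift_detected():
    spec = MouseSimSpec(
        genes=("Il18", "Il10rb", "Ptgs1"),
        log2_shift={"Il18": -1.0, "Il10rb": -1.0, "Ptgs1": -1.0},
        ct_noise_sd=0.1,
        animal_ct_sd=0.05,
        seed=3,
    )
    behavior, ct, _ = simulate_mouse_cohort(spec)
    expr = quantify_expression(ct, behavior[["animal_id", "group"]])
    res = permutation_factorial_anova(expr, n_perm=499, seed=4)
    assert res["group"]["p"] < 0.05


def test_anova_rejects_thin_designs():
    df = _tiny_expression(np.random.default_rng(5).normal(size=(3, 2)),
                          groups=("MS", "NS", "NS"))
    with pytest.raises(ValueError, match="2 animals per group"):
        permutation_factorial_anova(df)


# ---------------------------------------------------------------------------
# pairwise permutation t-tests
# ---------------------------------------------------------------------------


def test_pairwise_identical_groups_p_one():
    df = _tiny_expression([[1.0, 2.0], [1.5, 2.5], [1.0, 2.0], [1.5, 2.5]])
    res = pairwise_permutation_tests(df, seed=6)
    assert (res["p_raw"] == 1.0).all()
    assert (res["t"] == 0.0).all()


def test_pairwise_shifted_gene_has_smallest_fdr(mouse_cohort):
    expr = quantify_expression(
        mouse_cohort["ct"], mouse_cohort["behavior"][["animal_id", "group"]]
    )
    res = pairwise_permutation_tests(expr, seed=7)
    assert (res["p_fdr"] >= res["p_raw"] - 1e-12).all()
    # the default design enumerates C(23,13) > limit -> Monte-Carlo branch
    assert (res["n_perm"] == 9999).all()
    # Il10rb carries the largest injected shift; it should be near the top
    top3 = set(res.nsmallest(3, "p_fdr")["gene"])
    assert "Il10rb" in top3


def test_pairwise_exhaustive_branch_exact():
    rng = np.random.default_rng(8)
    df = _tiny_expression(rng.normal(1, 0.3, (6, 1)),
                          groups=("MS",) * 3 + ("NS",) * 3, genes=("g1",))
    res = pairwise_permutation_tests(df, seed=9)
    assert res.iloc[0]["n_perm"] == 20  # C(6,3) distinct assignments
    # exact p must be a multiple of 1/20
    assert (res.iloc[0]["p_raw"] * 20) == pytest.approx(round(res.iloc[0]["p_raw"] * 20))


# ---------------------------------------------------------------------------
# correlograms
# ---------------------------------------------------------------------------


def test_correlogram_perfect_pairs():
    rng = np.random.default_rng(10)
    base = rng.normal(size=20)
    df = pd.DataFrame({"a": base, "b": 2 * base + 1, "c": -base, "d": rng.normal(size=20)})
    cg = build_correlogram(df)
    assert cg.r.loc["a", "b"] == pytest.approx(1.0)
    assert cg.r.loc["a", "c"] == pytest.approx(-1.0)
    assert cg.mask.loc["a", "b"]
    assert not cg.mask.loc["a", "d"]
    # signed PC1 ordering: a,b adjacent at one end, anticorrelated c at the
    # other, uncorrelated d in between
    ia, ib, ic, idx = (cg.order.index(k) for k in ("a", "b", "c", "d"))
    assert abs(ia - ib) == 1
    assert {ia, ib} in ({0, 1}, {2, 3})
    assert ic == (3 if 0 in (ia, ib) else 0)
    assert idx not in (0, 3)


def test_correlogram_deterministic_and_symmetric(mouse_cohort):
    behavior = derive_behavior(mouse_cohort["behavior"])
    expr = quantify_expression(
        mouse_cohort["ct"], mouse_cohort["behavior"][["animal_id", "group"]]
    )
    wide = expr.pivot(index="animal_id", columns="gene", values="rel_level")
    vars_df = behavior.set_index("animal_id")[["depression_index"]].join(wide)
    cg1 = build_correlogram(vars_df)
    cg2 = build_correlogram(vars_df)
    assert cg1.order == cg2.order
    pd.testing.assert_frame_equal(cg1.r, cg2.r)
    np.testing.assert_allclose(cg1.r.to_numpy(), cg1.r.to_numpy().T)


def test_correlogram_handles_degenerate_columns():
    rng = np.random.default_rng(11)
    df = pd.DataFrame({"a": rng.normal(size=10), "flat": np.ones(10)})
    cg = build_correlogram(df)
    assert cg.undefined == ["flat"]
    assert np.isnan(cg.r.loc["a", "flat"])
    # short pairwise overlap -> undefined correlation
    df2 = pd.DataFrame({"x": [1.0, 2.0, 3.0, np.nan, np.nan],
                        "y": [np.nan, 1.0, 2.0, 3.0, 4.0]})
    cg2 = build_correlogram(df2)
    assert np.isnan(cg2.r.loc["x", "y"])


def test_correlogram_null_false_positive_rate():
    rng = np.random.default_rng(12)
    hits = trials = 0
    for _ in range(40):
        df = pd.DataFrame(rng.normal(size=(25, 6)), columns=list("abcdef"))
        cg = build_correlogram(df)
        off = ~np.eye(6, dtype=bool)
        hits += cg.mask.to_numpy()[off].sum() / 2
        trials += 15
    rate = hits / trials
    assert 0.01 <= rate <= 0.10  # nominal 5%


# ---------------------------------------------------------------------------
# regression with confidence band
# ---------------------------------------------------------------------------


def test_regression_exact_line():
    x = np.arange(10, dtype=float)
    res = regression_with_ci(x, 2 * x + 1)
    assert res["slope"] == pytest.approx(2.0, abs=1e-10)
    assert res["intercept"] == pytest.approx(1.0, abs=1e-10)
    assert res["pearson_r"] == pytest.approx(1.0)
    band = res["band"]
    np.testing.assert_allclose(band["fit"], 2 * band["x"] + 1, atol=1e-8)


def test_regression_band_matches_toy_oracle():
    rng = np.random.default_rng(13)
    x = rng.normal(size=15)
    y = 0.5 * x + rng.normal(0, 0.3, 15)
    res = regression_with_ci(x, y, ci_points=5)
    # hand-computed CI of the conditional mean at each grid point
    n = len(x)
    xbar, sxx = x.mean(), ((x - x.mean()) ** 2).sum()
    b = ((x - xbar) * (y - y.mean())).sum() / sxx
    a = y.mean() - b * xbar
    s2 = ((y - a - b * x) ** 2).sum() / (n - 2)
    tcrit = scipy.stats.t.ppf(0.975, n - 2)
    for _, row in res["band"].iterrows():
        fit = a + b * row["x"]
        half = tcrit * np.sqrt(s2 * (1 / n + (row["x"] - xbar) ** 2 / sxx))
        assert row["fit"] == pytest.approx(fit, abs=1e-8)
        assert row["ci_lower"] == pytest.approx(fit - half, abs=1e-8)
        assert row["ci_upper"] == pytest.approx(fit + half, abs=1e-8)


def test_regression_degenerate_inputs():
    with pytest.raises(ValueError):
        regression_with_ci([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        regression_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
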