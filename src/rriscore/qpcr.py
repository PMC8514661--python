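"""Relative transcript quantification (2^-ddCt) and expression statistics.

Quantification: each candidate gene's triplicate cycle thresholds are
averaged, referenced against the housekeeping gene (delta-Ct), compared
to a calibrator (the mean delta-Ct of the non-separated control animals,
which makes the control geometric-mean fold change exactly 1), and
expressed as a fold change assuming doubling per cycle.

Statistics: a permutation-based two-way factorial ANOVA (gene x group) on
the relative levels, per-gene pairwise permutation t-tests with
Benjamini-Hochberg adjustment, behavior-expression correlograms ordered
by the first principal component of the correlation matrix, and simple
linear regressions with 95% confidence bands.
"""

from __future__ import annotations

import itertools
import logging
from math import comb
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from rriscore.association import bh_adjust

log = logging.getLogger(__name__)


class LowQualityError(ValueError):
    """Fewer than the required usable wells in a triplicate."""


# ---------------------------------------------------------------------------
# 2^-ddCt quantification
# ---------------------------------------------------------------------------


def delta_delta_ct(ct_target, ct_ref, calibrator_delta_ct: float, min_wells: int = 2) -> dict:
    """Quantify one animal x gene measurement.

    delta-Ct = mean(target wells) - mean(reference wells);
    delta-delta-Ct = delta-Ct - calibrator; rel_level = 2^(-ddCt).
    Raises :class:`LowQualityError` when either triplicate has fewer than
    ``min_wells`` usable (non-NaN) wells.
    """
    t = np.asarray(ct_target, dtype=float)
    r = np.asarray(ct_ref, dtype=float)
    t, r = t[~np.isnan(t)], r[~np.isnan(r)]
    if len(t) < min_wells or len(r) < min_wells:
        raise LowQualityError(
            f"triplicate has {len(t)} target / {len(r)} reference usable wells "
            f"(minimum {min_wells})"
        )
    dct = float(t.mean() - r.mean())
    ddct = dct - float(calibrator_delta_ct)
    return {
        "delta_ct": dct,
        "delta_delta_ct": ddct,
        "rel_level": float(2.0 ** (-ddct)),
        "n_target_wells": len(t),
        "n_ref_wells": len(r),
    }


def quantify_expression(
    ct_table: pd.DataFrame,
    groups: pd.DataFrame,
    reference_gene: str = "Rab5a",
    calibrator_group: str = "NS",
    min_wells: int = 2,
) -> pd.DataFrame:
    """Run the 2^-ddCt pipeline over a long-format Ct table.

    Parameters
    ----------
    ct_table
        Columns ``animal_id``, ``gene``, ``well``, ``ct`` (qpcr_ct schema).
    groups
        Columns ``animal_id``, ``group``; the ``calibrator_group`` mean
        delta-Ct per gene is the calibrator.

    Animal x gene measurements with fewer than ``min_wells`` usable wells
    are excluded with a log entry, mirroring wet-lab low-quality
    exclusions.  Returns one row per retained animal x gene with delta-Ct,
    delta-delta-Ct and the relative level.
    """
    grp = dict(zip(groups["animal_id"], groups["group"]))
    means = (
        ct_table.dropna(subset=["ct"])
        .groupby(["animal_id", "gene"])["ct"]
        .agg(["mean", "size"])
    )
    ref = means.xs(reference_gene, level="gene")
    rows = []
    for (animal, gene), rec in means.iterrows():
        if gene == reference_gene:
            continue
        if animal not in ref.index:
            log.warning("animal %s lacks reference-gene wells; excluded", animal)
            continue
        if rec["size"] < min_wells or ref.loc[animal, "size"] < min_wells:
            log.warning("low-quality triplicate excluded: %s x %s", animal, gene)
            continue
        rows.append(
            {
                "animal_id": animal,
                "gene": gene,
                "group": grp.get(animal),
                "delta_ct": rec["mean"] - ref.loc[animal, "mean"],
                "n_wells": int(rec["size"]),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no usable animal x gene measurements")
    calib = (
        out[out["group"] == calibrator_group].groupby("gene")["delta_ct"].mean().rename("calib")
    )
    out = out.merge(calib, on="gene", how="left")
    out["delta_delta_ct"] = out["delta_ct"] - out["calib"]
    out["rel_level"] = 2.0 ** (-out["delta_delta_ct"])
    return out.drop(columns="calib")


# ---------------------------------------------------------------------------
# Two-way factorial permutation ANOVA
# ---------------------------------------------------------------------------


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    d = np.zeros((len(codes), n_levels - 1))
    for k in range(1, n_levels):
        d[codes == k, k - 1] = 1.0
    return d


def two_way_f_stats(y: np.ndarray, gene_codes: np.ndarray, group_codes: np.ndarray):
    """Type-II F statistics for the gene x group factorial decomposition.

    Returns (F_gene, F_group, F_interaction); an effect whose sum of
    squares and the residual mean square are both zero gets F = 0 (so
    constant data yields permutation p = 1 for every effect).
    """
    g = int(gene_codes.max()) + 1
    h = int(group_codes.max()) + 1
    n = len(y)
    ones = np.ones((n, 1))
    Dg = _dummies(gene_codes, g)
    Dh = _dummies(group_codes, h)
    inter = np.einsum("ij,ik->ijk", Dg, Dh).reshape(n, -1)
    rss_full = _rss(y, np.hstack([ones, Dg, Dh, inter]))
    rss_add = _rss(y, np.hstack([ones, Dg, Dh]))
    rss_gene_only = _rss(y, np.hstack([ones, Dg]))
    rss_group_only = _rss(y, np.hstack([ones, Dh]))
    df_resid = n - g * h
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom (need >= 2 animals per cell)")
    mse = rss_full / df_resid
    ss = {
        "gene": (rss_group_only - rss_add, g - 1),
        "group": (rss_gene_only - rss_add, h - 1),
        "interaction": (rss_add - rss_full, (g - 1) * (h - 1)),
    }
    out = {}
    for name, (s, df) in ss.items():
        s = max(s, 0.0)
        out[name] = 0.0 if mse == 0 else s / df / mse
    return out["gene"], out["group"], out["interaction"]


def permutation_factorial_anova(
    data: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
    value_col: str = "rel_level",
):
    """Permutation p-values for the two-way gene x group factorial ANOVA.

    The randomized unit is the animal: for the group and interaction
    effects, group labels are permuted across animals (each animal's gene
    profile travels intact); for the gene effect, gene labels are permuted
    within each animal.  p = (1 + #{permuted F >= observed F}) /
    (1 + n_perm), which guarantees p >= 1/(n_perm + 1).

    ``exhaustive=True`` enumerates every distinct group-label assignment
    (group/interaction) and every product of within-animal gene
    permutations (gene effect; only feasible for tiny designs), replacing
    the Monte-Carlo estimate by the exact permutation p (no add-one).
    """
    df = data.dropna(subset=[value_col])
    wide = df.pivot(index="animal_id", columns="gene", values=value_col)
    if wide.isna().any().any():
        dropped = wide.index[wide.isna().any(axis=1)].tolist()
        log.warning("dropping animals with incomplete gene profiles: %s", dropped)
        wide = wide.dropna()
    animals = list(wide.index)
    genes = list(wide.columns)
    grp_per_animal = df.drop_duplicates("animal_id").set_index("animal_id")["group"]
    groups = grp_per_animal.loc[animals]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    per_cell = groups.value_counts()
    if per_cell.min() < 2:
        raise ValueError("need at least 2 animals per group (empty/thin cell)")

    Y = wide.to_numpy()  # animals x genes
    n_a, n_g = Y.shape
    gene_codes = np.tile(np.arange(n_g), n_a)
    group_codes_animal = np.array([levels.index(g) for g in groups])

    def stats_for(y_mat: np.ndarray, grp_codes_a: np.ndarray):
        y = y_mat.ravel()
        grp_codes = np.repeat(grp_codes_a, n_g)
        return two_way_f_stats(y, gene_codes, grp_codes)

    f_gene_obs, f_group_obs, f_inter_obs = stats_for(Y, group_codes_animal)

    rng = np.random.default_rng(seed)
    if exhaustive:
        # group & interaction: all distinct multiset permutations of labels
        ge_group = ge_inter = 0
        assignments = sorted(set(itertools.permutations(group_codes_animal)))
        for perm in assignments:
            _, f_g, f_i = stats_for(Y, np.array(perm))
            ge_group += f_g >= f_group_obs - 1e-12
            ge_inter += f_i >= f_inter_obs - 1e-12
        p_group = ge_group / len(assignments)
        p_inter = ge_inter / len(assignments)
        # gene effect: product of within-animal permutations
        perms_per_animal = list(itertools.permutations(range(n_g)))
        if len(perms_per_animal) ** n_a > 200_000:
            raise ValueError("exhaustive gene-effect enumeration infeasible for this design")
        ge_gene = 0
        count = 0
        for combo in itertools.product(perms_per_animal, repeat=n_a):
            Yp = np.vstack([Y[i, list(combo[i])] for i in range(n_a)])
            f_g, _, _ = stats_for(Yp, group_codes_animal)
            ge_gene += f_g >= f_gene_obs - 1e-12
            count += 1
        p_gene = ge_gene / count
        n_used = {"group": len(assignments), "gene": count}
    else:
        ge_gene = ge_group = ge_inter = 0
        for _ in range(n_perm):
            perm_groups = rng.permutation(group_codes_animal)
            _, f_g, f_i = stats_for(Y, perm_groups)
            ge_group += f_g >= f_group_obs - 1e-12
            ge_inter += f_i >= f_inter_obs - 1e-12
            Yp = np.vstack([Y[i, rng.permutation(n_g)] for i in range(n_a)])
            f_gene, _, _ = stats_for(Yp, group_codes_animal)
            ge_gene += f_gene >= f_gene_obs - 1e-12
        p_gene = (1 + ge_gene) / (1 + n_perm)
        p_group = (1 + ge_group) / (1 + n_perm)
        p_inter = (1 + ge_inter) / (1 + n_perm)
        n_used = {"group": n_perm, "gene": n_perm}

    return {
        "gene": {"F": f_gene_obs, "p": p_gene},
        "group": {"F": f_group_obs, "p": p_group},
        "interaction": {"F": f_inter_obs, "p": p_inter},
        "n_perm": n_used,
        "animals": animals,
        "genes": genes,
    }


# ---------------------------------------------------------------------------
# Pairwise permutation t-tests
# ---------------------------------------------------------------------------


def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b))))


def pairwise_permutation_tests(
    expr: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    exhaustive_limit: int = 20000,
    value_col: str = "rel_level",
) -> pd.DataFrame:
    """Per-gene MS-vs-NS permutation t-tests, BH-adjusted across genes.

    The test statistic is the pooled Student t; the reference distribution
    comes from permuting group labels.  When the number of distinct label
    assignments is at most ``exhaustive_limit`` the permutation
    distribution is enumerated exactly; otherwise Monte-Carlo sampling
    with the add-one estimator is used.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, sub in expr.groupby("gene", sort=True):
        sub = sub.dropna(subset=[value_col])
        vals = sub[value_col].to_numpy(dtype=float)
        labels = sub["group"].to_numpy()
        groups = sorted(pd.unique(labels))
        if len(groups) != 2:
            raise ValueError(f"{gene}: expected exactly two groups, got {groups}")
        mask_a = labels == groups[0]
        n_a, n = int(mask_a.sum()), len(vals)
        if n_a < 2 or n - n_a < 2:
            raise ValueError(f"{gene}: need >= 2 animals per group")
        t_obs = _pooled_t(vals[mask_a], vals[~mask_a])
        n_exact = comb(n, n_a)
        if n_exact <= exhaustive_limit:
            ge = 0
            for idx in itertools.combinations(range(n), n_a):
                m = np.zeros(n, dtype=bool)
                m[list(idx)] = True
                ge += abs(_pooled_t(vals[m], vals[~m])) >= abs(t_obs) - 1e-12
            p = ge / n_exact
            used = n_exact
        else:
            ge = 0
            for _ in range(n_perm):
                m = np.zeros(n, dtype=bool)
                m[rng.choice(n, size=n_a, replace=False)] = True
                ge += abs(_pooled_t(vals[m], vals[~m])) >= abs(t_obs) - 1e-12
            p = (1 + ge) / (1 + n_perm)
            used = n_perm
        rows.append({"gene": gene, "t": t_obs, "p_raw": p, "n_perm": used})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Correlograms and regressions
# ---------------------------------------------------------------------------


@dataclass
class Correlogram:
    """Pairwise Pearson correlations with significance mask and PC ordering."""

    order: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame
    alpha: float
    undefined: list[str] = field(default_factory=list)


def build_correlogram(variables: pd.DataFrame, alpha: float = 0.05, fdr: bool = False) -> Correlogram:
    """Correlation matrix of behavior and expression variables.

    Pairwise-complete Pearson correlations with two-sided t-approximation
    p-values; variables ordered by their loadings on the first principal
    component of the correlation matrix (eigenvector sign fixed so the
    largest-magnitude loading is positive, making the ordering
    deterministic).  The significance mask is unadjusted p < alpha by
    default; ``fdr=True`` masks on BH-adjusted p instead.
    """
    cols = list(variables.columns)
    n = len(cols)
    r = np.eye(n)
    p = np.zeros((n, n))
    undefined = [c for c in cols if variables[c].dropna().nunique() <= 1]
    for i in range(n):
        for j in range(i + 1, n):
            pair = variables[[cols[i], cols[j]]].dropna()
            if len(pair) < 4 or cols[i] in undefined or cols[j] in undefined:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = scipy.stats.pearsonr(pair[cols[i]], pair[cols[j]])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    ok = [c for c in cols if c not in undefined]
    idx = [cols.index(c) for c in ok]
    corr_ok = np.nan_to_num(r[np.ix_(idx, idx)], nan=0.0)
    eigvals, eigvecs = np.linalg.eigh(corr_ok)
    pc1 = eigvecs[:, -1]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    order = [ok[k] for k in np.argsort(-pc1, kind="stable")] + undefined

    r_df = pd.DataFrame(r, index=cols, columns=cols).loc[order, order]
    p_df = pd.DataFrame(p, index=cols, columns=cols).loc[order, order]
    if fdr:
        tri = np.triu_indices(n, k=1)
        pv = p_df.to_numpy()[tri]
        adj = np.full_like(pv, np.nan)
        good = ~np.isnan(pv)
        adj[good] = bh_adjust(pv[good])
        padj = np.full((n, n), np.nan)
        padj[tri] = adj
        padj = np.where(np.isnan(padj), padj.T, padj)
        np.fill_diagonal(padj, 0.0)
        mask = pd.DataFrame(padj < alpha, index=order, columns=order)
    else:
        mask = p_df < alpha
    np.fill_diagonal(mask.values, True)
    return Correlogram(order=order, r=r_df, p=p_df, mask=mask, alpha=alpha, undefined=undefined)


def plot_correlogram(cg: Correlogram, path=None):
    """Heatmap of significant correlations (colored only where masked True)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shown = cg.r.where(cg.mask)
    fig, ax = plt.subplots(figsize=(0.5 * len(cg.order) + 2,) * 2)
    im = ax.imshow(shown, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(cg.order)), cg.order, rotation=90)
    ax.set_yticks(range(len(cg.order)), cg.order)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def regression_with_ci(x, y, ci_points: int = 50):
    """OLS line of y on x with a pointwise 95% confidence band.

    Returns a dict with slope, intercept, Pearson r and two-sided p, and a
    DataFrame (``band``) of fitted means with lower/upper 95% CI evaluated
    on a grid spanning the observed x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]):
        raise ValueError("x is constant; regression undefined")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), ci_points)
    pred = res.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    r, p = scipy.stats.pearsonr(x, y)
    return {
        "slope": float(res.params[1]),
        "intercept": float(res.params[0]),
        "pearson_r": float(r),
        "p_value": float(p),
        "band": pd.DataFrame(
            {
                "x": grid,
                "fit": pred["mean"].to_numpy(),
                "ci_lower": pred["mean_ci_lower"].to_numpy(),
                "ci_upper": pred["mean_ci_upper"].to_numpy(),
            }
        ),
        "n": len(x),
    }
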