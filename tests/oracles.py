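"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package's
implementation: closed-form normal equations for OLS, Newton-Raphson for
the Poisson MLE, the literal step-up definition for Benjamini-Hochberg,
hypergeometric enumeration for Fisher's exact test, and
statsmodels-formula ANOVA plus explicit label enumeration for the
permutation factorial ANOVA.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """beta, se, t, two-sided p from (X'X)^-1 X'y and the t distribution."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (n - k)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2 * scipy.stats.t.sf(np.abs(t), n - k)
    return beta, se, t, p


def poisson_newton(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, maxiter: int = 200):
    """Poisson log-link MLE by explicit Newton-Raphson.

    Returns (beta, cov, deviance).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    # start from the intercept at log(mean) if a constant column exists
    const = np.where(np.all(X == 1.0, axis=0))[0]
    if const.size and y.mean() > 0:
        beta[const[0]] = np.log(y.mean())
    for _ in range(maxiter):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        H = X.T @ (mu[:, None] * X)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < tol and np.max(np.abs(step)) < tol:
            break
    mu = np.exp(X @ beta)
    cov = np.linalg.inv(X.T @ (mu[:, None] * X))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    deviance = 2.0 * np.sum(term - (y - mu))
    return beta, cov, deviance


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: adj_(i) = min_{j >= i} p_(j) * m / j, cap 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_i, m)]
        adj[order[rank_i]] = min(1.0, min(candidates))
    return adj


def fisher_two_sided_enumeration(table) -> float:
    """Sum of hypergeometric probabilities of tables at most as likely.

    Margins fixed; probabilities compared with a small relative slack to
    absorb floating-point ties.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = scipy.stats.hypergeom.pmf(ks, n, c1, r1)
    p_obs = pmf[ks == a][0]
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def anova_type2_f(df: pd.DataFrame, value_col: str = "rel_level"):
    """Type-II F statistics via statsmodels formula API (independent route)."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols(f"{value_col} ~ C(gene) * C(group)", data=df).fit()
    tab = anova_lm(model, typ=2)
    return {
        "gene": float(tab.loc["C(gene)", "F"]),
        "group": float(tab.loc["C(group)", "F"]),
        "interaction": float(tab.loc["C(gene):C(group)", "F"]),
    }


def exhaustive_group_permutation_p(df: pd.DataFrame, value_col: str = "rel_level"):
    """Exact permutation p for group and interaction by explicit enumeration.

    Reassigns group labels over animals in every distinct way, recomputing
    the type-II F with the statsmodels oracle each time.
    """
    animals = sorted(df["animal_id"].unique())
    labels = [df.loc[df["animal_id"] == a, "group"].iloc[0] for a in animals]
    obs = anova_type2_f(df, value_col)
    ge_group = ge_inter = 0
    perms = sorted(set(itertools.permutations(labels)))
    for perm in perms:
        relab = dict(zip(animals, perm))
        work = df.copy()
        work["group"] = work["animal_id"].map(relab)
        f = anova_type2_f(work, value_col)
        ge_group += f["group"] >= obs["group"] - 1e-12
        ge_inter += f["interaction"] >= obs["interaction"] - 1e-12
    return ge_group / len(perms), ge_inter / len(perms)


def exhaustive_gene_permutation_p(df: pd.DataFrame, value_col: str = "rel_level"):
    """Exact permutation p for the gene effect: within-animal relabelings."""
    animals = sorted(df["animal_id"].unique())
    genes = sorted(df["gene"].unique())
    wide = df.pivot(index="animal_id", columns="gene", values=value_col).loc[animals, genes]
    obs = anova_type2_f(df, value_col)["gene"]
    perms = list(itertools.permutations(range(len(genes))))
    ge = count = 0
    for combo in itertools.product(perms, repeat=len(animals)):
        rows = []
        for i, a in enumerate(animals):
            vals = wide.loc[a].to_numpy()[list(combo[i])]
            grp = df.loc[df["animal_id"] == a, "group"].iloc[0]
            for g, v in zip(genes, vals):
                rows.append({"animal_id": a, "gene": g, "group": grp, value_col: v})
        f = anova_type2_f(pd.DataFrame(rows), value_col)["gene"]
        ge += f >= obs - 1e-12
        count += 1
    return ge / count
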