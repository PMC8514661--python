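"""Questionnaire derivations and the score-to-symptom association battery.

Count outcomes (depression probability band, SDQ externalizing and
internalizing composites) are modeled with Poisson log-linear GLMs;
positively skewed dimensional outcomes (CAPE-42) with OLS on the natural
log.  Every model controls for sex and childhood maltreatment (CM, coded
numerically 0/1/2); the gene-by-environment term is the CM-by-score
interaction fitted in an extended model.  Raw p-values are adjusted by
the Benjamini-Hochberg step-up procedure within configurable families
(default: rows sharing a questionnaire instrument).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """The IRLS fit did not converge within the iteration budget."""


class DomainError(ValueError):
    """An outcome value is outside the model family's domain."""


@dataclass
class AssociationRow:
    """One fitted outcome ~ score (+ CM interaction) model row.

    Mirrors one line of the battery output: unstandardized coefficient B,
    its test statistic (z for Poisson, t for log-OLS), raw and
    FDR-adjusted p, and a fit diagnostic (residual deviance + df for
    Poisson, R^2 for OLS).
    """

    outcome: str
    predictor: str
    family: str  # "poisson" | "log_ols"
    B: float
    statistic: float
    p_raw: float
    p_fdr: float | None
    deviance: float | None
    df_resid: int
    r_squared: float | None
    n_used: int
    reported: bool = True  # CAPE interaction rows are computed but flaggable


# ---------------------------------------------------------------------------
# Questionnaire derivations
# ---------------------------------------------------------------------------


def derive_cm(ctq: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Childhood-maltreatment category 0-2 from six 0-4 subscale severities.

    Subjects are grouped by the maximum subscale severity (five groups,
    0-4); the three highest groups are merged: cm = min(max(subscales), 2).
    """
    arr = np.asarray(ctq, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 6:
        raise ValueError("expected six CTQ subscale columns")
    if np.nanmin(arr) < 0 or np.nanmax(arr) > 4 or not np.all(arr[~np.isnan(arr)] % 1 == 0):
        raise ValueError("CTQ subscale values must be integers in 0..4")
    g = arr.max(axis=1)
    return np.minimum(g, 2).astype(int)


def derive_sdq(conduct, hyperactivity, emotional, peer):
    """Externalizing = conduct + hyperactivity; internalizing = emotional + peer."""
    es = np.asarray(conduct) + np.asarray(hyperactivity)
    is_ = np.asarray(emotional) + np.asarray(peer)
    return es, is_


# ---------------------------------------------------------------------------
# Model fitters
# ---------------------------------------------------------------------------


def _check_full_rank(X: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design (columns {list(names)})")


def fit_poisson_glm(y: np.ndarray, design: pd.DataFrame, maxiter: int = 100):
    """Poisson log-linear GLM via IRLS maximum likelihood.

    Returns a statsmodels results object; z statistics and two-sided
    normal p-values are on ``.tvalues`` / ``.pvalues``, residual deviance
    on ``.deviance`` and residual df on ``.df_resid``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y % 1 != 0):
        raise DomainError("Poisson outcome must be a non-negative integer count")
    X = design.to_numpy(dtype=float)
    _check_full_rank(X, design.columns)
    model = sm.GLM(y, design.astype(float), family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=1e-12)
    if not res.converged:
        raise ConvergenceError(
            f"Poisson IRLS did not converge in {maxiter} iterations; "
            f"final deviance {res.deviance:.6g}"
        )
    return res


def fit_log_ols(y: np.ndarray, design: pd.DataFrame):
    """OLS of ln(y) on the design; y must be strictly positive.

    No silent offset is applied: a zero or negative outcome raises
    :class:`DomainError`.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise DomainError("log-OLS outcome must be strictly positive (no offset applied)")
    X = design.to_numpy(dtype=float)
    _check_full_rank(X, design.columns)
    return sm.OLS(np.log(y), design.astype(float)).fit()


def _design(score, sex, cm, interaction: bool) -> pd.DataFrame:
    X = pd.DataFrame(
        {
            "const": 1.0,
            "score": np.asarray(score, dtype=float),
            "sex": np.asarray(sex, dtype=float),
            "cm": np.asarray(cm, dtype=float),
        }
    )
    if interaction:
        X["cm:score"] = X["cm"] * X["score"]
    return X


def fit_score_outcome_model(
    outcome: np.ndarray,
    score: np.ndarray,
    sex: np.ndarray,
    cm: np.ndarray,
    interaction: bool = False,
    family: str = "poisson",
    outcome_label: str = "outcome",
    predictor_label: str = "score",
) -> AssociationRow:
    """Fit one battery model and extract the reported row.

    Main model: outcome ~ score + sex + cm (the ``score`` row).
    Interaction model: outcome ~ score + sex + cm + cm:score (the
    ``cm:score`` row).  CM enters numerically as 0/1/2.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(outcome, dtype=float),
            "score": np.asarray(score, dtype=float),
            "sex": np.asarray(sex, dtype=float),
            "cm": np.asarray(cm, dtype=float),
        }
    ).dropna()
    X = _design(df["score"], df["sex"], df["cm"], interaction)
    term = "cm:score" if interaction else "score"
    if family == "poisson":
        res = fit_poisson_glm(df["y"].to_numpy(), X)
        deviance, r2 = float(res.deviance), None
    elif family == "log_ols":
        res = fit_log_ols(df["y"].to_numpy(), X)
        deviance, r2 = None, float(res.rsquared)
    else:
        raise ValueError(f"unknown family {family!r}")
    return AssociationRow(
        outcome=outcome_label,
        predictor=predictor_label if not interaction else f"CM:{predictor_label}",
        family=family,
        B=float(res.params[term]),
        statistic=float(res.tvalues[term]),
        p_raw=float(res.pvalues[term]),
        p_fdr=None,
        deviance=deviance,
        df_resid=int(res.df_resid),
        r_squared=r2,
        n_used=len(df),
    )


def bh_adjust(p: np.ndarray, families: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, within families.

    Within each family the adjusted value is
    ``min_{j >= rank(i)} p_(j) * m / j`` capped at 1, returned in the
    original order.  ``families=None`` treats all p-values as one family.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if families is None:
        families = np.zeros(len(p))
    families = np.asarray(families)
    out = np.empty_like(p)
    for fam in pd.unique(families):
        idx = np.where(families == fam)[0]
        out[idx] = multipletests(p[idx], method="fdr_bh")[1]
    return out


def gof_deviance_test(deviance: float, df: int) -> float:
    """Upper-tail chi-squared goodness-of-fit p for a Poisson residual deviance."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(scipy.stats.chi2.sf(deviance, df))


# ---------------------------------------------------------------------------
# Battery
# ---------------------------------------------------------------------------

OUTCOME_FAMILIES = {
    "depband": ("poisson", "dawba"),
    "es": ("poisson", "sdq"),
    "is": ("poisson", "sdq"),
    "cape_pds": ("log_ols", "cape"),
    "cape_nds": ("log_ols", "cape"),
    "cape_dds": ("log_ols", "cape"),
}


def run_battery(
    scores: dict[str, pd.Series | np.ndarray],
    outcomes: pd.DataFrame,
    sex: np.ndarray,
    cm: np.ndarray,
    family_map: dict[str, str] | None = None,
    cape_interactions_reported: bool = False,
) -> pd.DataFrame:
    """Fit every score x outcome main and interaction model; adjust p by BH.

    Parameters
    ----------
    scores
        Mapping score label (e.g. HRRI/MRRI/HMRRI) -> per-subject values
        aligned with ``outcomes`` rows.
    outcomes
        Columns from ``depband``, ``es``, ``is``, ``cape_pds``,
        ``cape_nds``, ``cape_dds`` (missing columns are skipped with a
        log entry).
    family_map
        outcome label -> FDR family name; defaults to the instrument the
        outcome belongs to (DAWBA / SDQ / CAPE).
    cape_interactions_reported
        CAPE interaction rows are always computed; by default they are
        flagged ``reported=False`` (kept out of headline reporting).

    Returns a DataFrame with one row per fitted model, raw and
    FDR-adjusted p-values, and fit diagnostics.
    """
    rows: list[AssociationRow] = []
    for out_name in OUTCOME_FAMILIES:
        if out_name not in outcomes.columns:
            log.info("outcome %s absent; skipped", out_name)
            continue
        y = outcomes[out_name].to_numpy()
        if np.all(pd.isna(y)):
            log.info("outcome %s empty; skipped", out_name)
            continue
        fam, instrument = OUTCOME_FAMILIES[out_name]
        for score_name, score in scores.items():
            for interaction in (False, True):
                row = fit_score_outcome_model(
                    y,
                    np.asarray(score, dtype=float),
                    sex,
                    cm,
                    interaction=interaction,
                    family=fam,
                    outcome_label=out_name,
                    predictor_label=score_name,
                )
                if fam == "log_ols" and interaction and not cape_interactions_reported:
                    row.reported = False
                rows.append(row)

    table = pd.DataFrame(
        {
            "outcome": [r.outcome for r in rows],
            "predictor": [r.predictor for r in rows],
            "family": [r.family for r in rows],
            "B": [r.B for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "deviance": [r.deviance for r in rows],
            "df_resid": [r.df_resid for r in rows],
            "r_squared": [r.r_squared for r in rows],
            "n_used": [r.n_used for r in rows],
            "reported": [r.reported for r in rows],
        }
    )
    fam_default = {name: OUTCOME_FAMILIES[name][1] for name in OUTCOME_FAMILIES}
    fam_map = {**fam_default, **(family_map or {})}
    table["fdr_family"] = table["outcome"].map(fam_map)
    table["p_fdr"] = bh_adjust(table["p_raw"].to_numpy(), table["fdr_family"].to_numpy())
    table["gof_p"] = [
        gof_deviance_test(d, df) if pd.notna(d) else np.nan
        for d, df in zip(table["deviance"], table["df_resid"])
    ]
    return table
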