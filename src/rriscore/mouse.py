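"""Behavioral indices and group statistics for the maternal-separation arm.

Anhedonia is read out as a sucrose-preference percentage, anxiety as time
in the lit compartment of a dark-light box.  Each readout is
z-normalized against the non-separated (NS) control group, sign-flipped
so larger values mean more depressive-like behavior, and the two z-scores
are averaged into a per-animal depression index.  Group contrasts use the
pooled-variance Student t-test; the sex-ratio balance check uses Fisher's
exact test (two-sided, minimum-likelihood definition).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats


def sucrose_preference(sucrose_ml, water_ml) -> float:
    """Sucrose preference percentage: sucrose / (sucrose + water) * 100."""
    sucrose_ml = np.asarray(sucrose_ml, dtype=float)
    water_ml = np.asarray(water_ml, dtype=float)
    total = sucrose_ml + water_ml
    if np.any(total <= 0):
        raise ValueError("sucrose preference undefined when total consumption is 0")
    out = sucrose_ml / total * 100.0
    return float(out) if out.ndim == 0 else out


def z_normalize(values, control_mask, flip_sign: bool = False) -> np.ndarray:
    """z = (x - mean of controls) / SD of controls, optionally times -1.

    The control SD uses the sample (n-1) denominator.  ``flip_sign`` is
    used for readouts where LOWER raw values are more depressive-like
    (sucrose preference, lit-box time), so positive z always means more
    depressive.  The control group's mean z is exactly 0 by construction.
    """
    x = np.asarray(values, dtype=float)
    mask = np.asarray(control_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 control animals")
    mu = x[mask].mean()
    sd = x[mask].std(ddof=1)
    if sd == 0:
        raise ValueError("control SD is zero; z-scores undefined")
    z = (x - mu) / sd
    return -z if flip_sign else z


def depression_index(z_anhedonia, z_anxiety) -> np.ndarray:
    """Global depression index: the mean of the two behavioral z-scores."""
    return (np.asarray(z_anhedonia, dtype=float) + np.asarray(z_anxiety, dtype=float)) / 2.0


def two_sample_ttest(a, b):
    """Pooled-variance Student t-test, two-tailed.

    Returns (t, df, p) with df = n_a + n_b - 2.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Two-sided by the minimum-likelihood definition: the sum of
    hypergeometric probabilities (margins fixed) of all tables at most as
    probable as the observed one.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer entries")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


def derive_behavior(behavior: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns to a mouse_behavior table.

    Adds ``sucrose_pref_pct``, ``z_anhedonia``, ``z_anxiety`` and
    ``depression_index`` (all z-normalized against the NS group with the
    depressive sign convention).
    """
    out = behavior.copy()
    out["sucrose_pref_pct"] = sucrose_preference(out["sucrose_ml"], out["water_ml"])
    ns = (out["group"] == "NS").to_numpy()
    out["z_anhedonia"] = z_normalize(out["sucrose_pref_pct"], ns, flip_sign=True)
    out["z_anxiety"] = z_normalize(out["lit_time_s"], ns, flip_sign=True)
    out["depression_index"] = depression_index(out["z_anhedonia"], out["z_anxiety"])
    return out


def group_stats(derived: pd.DataFrame) -> pd.DataFrame:
    """MS vs NS pooled t-tests for each z-scored readout and the index."""
    rows = []
    ms = derived[derived["group"] == "MS"]
    ns = derived[derived["group"] == "NS"]
    for col in ("z_anhedonia", "z_anxiety", "depression_index"):
        t, df, p = two_sample_ttest(ms[col], ns[col])
        rows.append(
            {
                "measure": col,
                "t": t,
                "df": df,
                "p": p,
                "ms_mean": ms[col].mean(),
                "ms_sem": ms[col].sem(),
                "ns_mean": ns[col].mean(),
                "ns_sem": ns[col].sem(),
            }
        )
    return pd.DataFrame(rows)


def sex_ratio_fisher(behavior: pd.DataFrame) -> float:
    """Fisher exact p for the MS-vs-NS sex-ratio 2x2 table."""
    tab = pd.crosstab(behavior["group"], behavior["sex"])
    return fisher_exact_2x2(tab.loc[["MS", "NS"]].to_numpy())
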