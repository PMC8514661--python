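"""Construction of ROI-related immune-gene scores (RRIs) and controls.

The pipeline is: per-SNP linear regression of a regional gray-matter
volume on the SNP's major-allele count plus covariates (sex, puberty
score, total intracranial volume, scanner dummies); nominal screening at
p < 0.1; LD pruning that keeps, within each connected component of the
r-squared > 0.5 graph, the most significant SNP; then a per-subject
weighted sum of minor-allele counts, min-max normalized to 0-10 on the
construction cohort.  The same machinery applied to a random SNP panel
yields the negative-control score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from rriscore.io_formats import GenotypeMatrix

log = logging.getLogger(__name__)


class DegenerateSNPError(ValueError):
    """The SNP's dosage column is constant on the complete cases."""


class RankDeficientError(ValueError):
    """The regression design matrix is rank deficient."""


class NoScoreError(ValueError):
    """The screen/prune pipeline retained no SNPs."""


class NormalizationError(ValueError):
    """Raw score range is degenerate (max equals min)."""


@dataclass
class SNPEffect:
    """Per-SNP volume regression result (major-allele coding)."""

    snp_id: str
    beta_major: float  # ml per major allele
    se: float
    t_stat: float
    p_value: float
    n_used: int


@dataclass
class ScoreDefinition:
    """A fitted score: SNPs, per-minor-allele weights, normalization bounds.

    ``entries`` maps snp_id -> weight (ml per minor allele).  ``raw_min``
    and ``raw_max`` are the raw-score extremes observed on the construction
    cohort; they are persisted so the score can be applied to new cohorts
    (where values may fall outside 0-10 and are not clipped).
    """

    region: str
    entries: dict[str, float]
    raw_min: float
    raw_max: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise NoScoreError("a ScoreDefinition needs at least one SNP")
        if not self.raw_max > self.raw_min:
            raise NormalizationError(
                f"raw_max ({self.raw_max}) must exceed raw_min ({self.raw_min})"
            )

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "entries": {k: float(v) for k, v in self.entries.items()},
            "raw_min": float(self.raw_min),
            "raw_max": float(self.raw_max),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreDefinition":
        return cls(
            region=d["region"],
            entries=dict(d["entries"]),
            raw_min=float(d["raw_min"]),
            raw_max=float(d["raw_max"]),
            provenance=d.get("provenance", {}),
        )


def build_covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + sex + pds + tiv + scanner dummies (first site dropped)."""
    X = pd.DataFrame(
        {
            "const": 1.0,
            "sex": covariates["sex"].astype(float).to_numpy(),
            "pds": covariates["pds"].to_numpy(),
            "tiv": covariates["tiv"].to_numpy(),
        },
        index=covariates.index,
    )
    dummies = pd.get_dummies(covariates["scanner"], prefix="scanner", drop_first=True)
    return pd.concat([X, dummies.astype(float)], axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(arr):
                bad.append(col)
        raise RankDeficientError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_snp_volume_regression(
    dosage: np.ndarray,
    volume: np.ndarray,
    covariates: pd.DataFrame,
    snp_id: str = "snp",
) -> SNPEffect:
    """OLS of volume on major-allele count (2 - minor dosage) + covariates.

    Complete cases only; the two-sided p-value comes from the t
    distribution with residual degrees of freedom.
    """
    dosage = np.asarray(dosage, dtype=float)
    volume = np.asarray(volume, dtype=float)
    Xcov = build_covariate_design(covariates)
    keep = ~(np.isnan(dosage) | np.isnan(volume)) & ~Xcov.isna().any(axis=1).to_numpy()
    if keep.sum() < 10:
        raise ValueError(f"{snp_id}: fewer than 10 complete cases")
    d = dosage[keep]
    if np.all(d == d[0]):
        raise DegenerateSNPError(f"{snp_id}: dosage is constant on complete cases")
    major = 2.0 - d
    X = Xcov.loc[keep].copy()
    X.insert(1, "major_count", major)
    _check_rank(X)
    res = sm.OLS(volume[keep], X).fit()
    return SNPEffect(
        snp_id=snp_id,
        beta_major=float(res.params["major_count"]),
        se=float(res.bse["major_count"]),
        t_stat=float(res.tvalues["major_count"]),
        p_value=float(res.pvalues["major_count"]),
        n_used=int(keep.sum()),
    )


def screen_snp_effects(
    genotypes: GenotypeMatrix,
    volume: pd.Series,
    covariates: pd.DataFrame,
    snp_ids: list[str] | None = None,
) -> dict[str, SNPEffect]:
    """Fit the per-SNP volume regression for each SNP; skip degenerate ones.

    ``volume`` and ``covariates`` must be aligned to ``genotypes.subject_ids``
    (``covariates`` indexed however, but row order matching subjects).
    """
    snp_ids = list(snp_ids) if snp_ids is not None else list(genotypes.snp_ids)
    vol = np.asarray(volume, dtype=float)
    effects: dict[str, SNPEffect] = {}
    for sid in snp_ids:
        try:
            effects[sid] = fit_snp_volume_regression(
                genotypes.column(sid), vol, covariates, snp_id=sid
            )
        except DegenerateSNPError:
            log.info("excluding degenerate SNP %s from candidacy", sid)
    return effects


def screen_candidates(effects: list[SNPEffect] | dict[str, SNPEffect], alpha: float = 0.1) -> list[str]:
    """SNP ids with screening p strictly below ``alpha``, order preserved."""
    if isinstance(effects, dict):
        effects = list(effects.values())
    if not effects:
        raise ValueError("effects must be non-empty")
    return [e.snp_id for e in effects if e.p_value < alpha]


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage columns.

    Computed on shared complete cases; symmetric and invariant under
    allele flips (g -> 2 - g).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2 or np.all(a == a[0]) or np.all(b == b[0]):
        raise DegenerateSNPError("r2 undefined for a constant dosage column")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def prune_by_ld(
    candidates: list[str],
    effects: dict[str, SNPEffect],
    genotypes: GenotypeMatrix,
    r2_cutoff: float = 0.5,
) -> list[str]:
    """One representative per connected component of the r2 > cutoff graph.

    Within a component the SNP with the smallest screening p wins; ties
    break to the lexicographically smallest id.  Representatives are
    returned in the candidates' original order.
    """
    g = nx.Graph()
    g.add_nodes_from(candidates)
    cols = {sid: genotypes.column(sid) for sid in candidates}
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            if ld_r2(cols[a], cols[b]) > r2_cutoff:
                g.add_edge(a, b)
    reps = set()
    for comp in nx.connected_components(g):
        reps.add(min(comp, key=lambda sid: (effects[sid].p_value, sid)))
    return [sid for sid in candidates if sid in reps]


def build_score_definition(
    representatives: list[str],
    effects: dict[str, SNPEffect],
    genotypes: GenotypeMatrix,
    region: str,
    weight_convention: str = "minor_effect",
    provenance: dict | None = None,
) -> ScoreDefinition:
    """Weight each SNP and record the construction cohort's raw-score range.

    The default weight is the per-MINOR-allele volume effect, i.e.
    ``-beta_major``; ``weight_convention='beta_major'`` uses the signed
    major-allele coefficient instead (sensitivity analysis).
    """
    if not representatives:
        raise NoScoreError("no representative SNPs to build a score from")
    sign = -1.0 if weight_convention == "minor_effect" else 1.0
    if weight_convention not in ("minor_effect", "beta_major"):
        raise ValueError(f"unknown weight_convention {weight_convention!r}")
    entries = {sid: sign * effects[sid].beta_major for sid in representatives}
    raw = _raw_scores(entries, genotypes)
    return ScoreDefinition(
        region=region,
        entries=entries,
        raw_min=float(raw.min()),
        raw_max=float(raw.max()),
        provenance={"weight_convention": weight_convention, **(provenance or {})},
    )


def _raw_scores(entries: dict[str, float], genotypes: GenotypeMatrix) -> pd.Series:
    sub = genotypes.subset_snps(list(entries))
    dosage = sub.imputed_dosage("impute")
    w = np.array([entries[s] for s in sub.snp_ids])
    return pd.Series(dosage @ w, index=genotypes.subject_ids)


def compute_scores(defn: ScoreDefinition, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Apply a ScoreDefinition; returns subject_id, score, out_of_range.

    score = 10 * (raw - raw_min) / (raw_max - raw_min).  On the
    construction cohort scores span exactly [0, 10]; on a new cohort they
    may fall outside and are flagged rather than clipped.
    """
    missing = [s for s in defn.entries if s not in genotypes.snp_ids]
    if missing:
        raise KeyError(f"genotypes lack score SNPs: {missing}")
    raw = _raw_scores(defn.entries, genotypes)
    denom = defn.raw_max - defn.raw_min
    if denom <= 0:
        raise NormalizationError("degenerate normalization range")
    score = 10.0 * (raw - defn.raw_min) / denom
    return pd.DataFrame(
        {
            "subject_id": raw.index,
            "score": score.to_numpy(),
            "out_of_range": (score < 0) | (score > 10),
        }
    )


def combine_scores(h: pd.DataFrame, m: pd.DataFrame) -> pd.DataFrame:
    """Elementwise sum of two score vectors (0-20 on the construction cohort)."""
    if set(h["subject_id"]) != set(m["subject_id"]):
        raise ValueError("subject mismatch between the two score vectors")
    merged = h.merge(m, on="subject_id", suffixes=("_h", "_m"))
    return pd.DataFrame(
        {
            "subject_id": merged["subject_id"],
            "score": merged["score_h"] + merged["score_m"],
            "out_of_range": merged["out_of_range_h"] | merged["out_of_range_m"],
        }
    )


def build_rri(
    genotypes: GenotypeMatrix,
    volume: pd.Series,
    covariates: pd.DataFrame,
    region: str,
    snp_ids: list[str] | None = None,
    alpha: float = 0.1,
    r2_cutoff: float = 0.5,
    weight_convention: str = "minor_effect",
):
    """Full screen -> prune -> weight -> normalize pipeline for one region.

    Returns (ScoreDefinition, score DataFrame, effects dict).  Raises
    :class:`NoScoreError` if screening retains nothing.
    """
    effects = screen_snp_effects(genotypes, volume, covariates, snp_ids)
    candidates = screen_candidates(effects, alpha)
    if not candidates:
        raise NoScoreError(f"{region}: no SNP passed screening at p < {alpha}")
    reps = prune_by_ld(candidates, effects, genotypes, r2_cutoff)
    defn = build_score_definition(
        reps,
        effects,
        genotypes,
        region,
        weight_convention,
        provenance={"alpha": alpha, "r2_cutoff": r2_cutoff, "n_candidates": len(candidates)},
    )
    return defn, compute_scores(defn, genotypes), effects


def build_control_score(
    genotypes: GenotypeMatrix,
    volume: pd.Series,
    covariates: pd.DataFrame,
    region: str,
    pool: list[str] | None = None,
    n_snps: int = 674,
    seed: int = 0,
    alpha: float = 0.1,
    r2_cutoff: float = 0.5,
):
    """Random-SNP negative control: sample a panel, run the identical pipeline.

    ``pool`` defaults to every SNP in ``genotypes``; the panel is drawn
    uniformly without replacement with a dedicated seed recorded in the
    score's provenance.
    """
    pool = list(pool) if pool is not None else list(genotypes.snp_ids)
    if len(pool) < n_snps:
        raise ValueError(f"pool ({len(pool)}) smaller than requested panel ({n_snps})")
    rng = np.random.default_rng(seed)
    panel = [pool[i] for i in rng.choice(len(pool), size=n_snps, replace=False)]
    defn, scores, effects = build_rri(
        genotypes, volume, covariates, f"control_{region}", snp_ids=panel,
        alpha=alpha, r2_cutoff=r2_cutoff,
    )
    defn.provenance.update({"control": True, "seed": seed, "panel_size": n_snps})
    return defn, scores, effects, panel
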