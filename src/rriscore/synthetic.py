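"""Synthetic cohorts with the statistical structure the analyses assume.

The human generator emulates a multi-site adolescent imaging-genetics
cohort: MAF-distributed biallelic genotypes with optional LD blocks,
regional gray-matter volumes driven by sex, puberty score, total
intracranial volume and scanner site plus small injectable per-SNP
effects, Poisson-like count questionnaires and positively skewed
(log-normal) dimensional scores with score, maltreatment and
score-by-maltreatment effects, and a childhood-maltreatment category
distribution matching the 588/283/108 split of the reference cohort.

The mouse generator emulates a maternal-separation experiment: control
(NS) behavioral distributions, separation (MS) group shifts expressed in
control-SD units, and triplicate qPCR cycle thresholds whose MS shifts
are injected on the log2 scale so that 2^-ddCt quantification recovers
the injected fold change in expectation.

All randomness flows from a single seeded ``numpy.random.Generator``;
with a fixed seed the outputs are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from rriscore.io_formats import (
    CTQ_COLUMNS,
    GenotypeMatrix,
    default_snp_meta,
)

# Reference-cohort anchors: regional volume means/SDs and the childhood
# maltreatment category counts observed in the cohort the generator emulates.
HIPPOCAMPUS_MEAN_ML = 1.20
HIPPOCAMPUS_SD_ML = 0.109
MPFC_MEAN_ML = 30.1
MPFC_SD_ML = 3.42
CM_COUNTS = (588, 283, 108)

#: Immune genes profiled in the mouse arm (blood RT-qPCR panel); Rab5a is
#: the reference gene.  The six leading genes carry the default MS shifts.
DEFAULT_GENE_PANEL = (
    "Ikbkb",
    "Il10ra",
    "Il10rb",
    "Il18",
    "Pla2g6",
    "Ptgs1",
    "Il1a",
    "Il6ra",
    "Tnf",
    "Ccl2",
    "Cxcl1",
    "Nfkb1",
    "Ptgs2",
    "Alox5",
)

#: Default MS/NS log2 expression shifts: anti-inflammatory regulators down,
#: Ptgs1 up, mirroring the dysregulation directions the mouse arm tests for.
DEFAULT_LOG2_SHIFTS = {
    "Ikbkb": -0.6,
    "Il10ra": -0.6,
    "Il10rb": -0.8,
    "Il18": -0.5,
    "Pla2g6": -0.6,
    "Ptgs1": 0.6,
}


class SpecError(ValueError):
    """A simulation spec violates its invariants."""


@dataclass
class LDBlock:
    """A block of adjacent candidate SNPs in mutual linkage disequilibrium.

    ``size`` SNPs share one template; within-block pairwise genotypic
    r-squared approximates ``r2`` (must lie in (0, 1]).
    """

    size: int
    r2: float

    def __post_init__(self) -> None:
        if not 0 < self.r2 <= 1:
            raise SpecError(f"infeasible LD target r2={self.r2} (must be in (0, 1])")
        if self.size < 2:
            raise SpecError("LD block needs size >= 2")


@dataclass
class OutcomeSpec:
    """Generating model for one psychometric outcome.

    ``kind='poisson'``: counts drawn Poisson with log link on
    ``intercept + b_score*score + b_cm*cm + b_int*cm*score + b_sex*sex``.
    ``kind='lognormal'``: the same linear predictor on the log scale plus
    Gaussian noise of SD ``sigma``, exponentiated (positive, right-skewed).
    ``clip`` optionally bounds the realized value (instrument range).
    """

    kind: str = "poisson"
    intercept: float = 0.0
    b_score: float = 0.0
    b_cm: float = 0.0
    b_int: float = 0.0
    b_sex: float = 0.0
    sigma: float = 0.4
    clip: int | None = None


def default_outcome_specs() -> dict[str, OutcomeSpec]:
    return {
        "depband": OutcomeSpec("poisson", intercept=np.log(0.8), clip=5),
        "es": OutcomeSpec("poisson", intercept=np.log(4.0), clip=20),
        "is": OutcomeSpec("poisson", intercept=np.log(4.0), clip=20),
        "cape_pds": OutcomeSpec("lognormal", intercept=np.log(10.0), sigma=0.35),
        "cape_nds": OutcomeSpec("lognormal", intercept=np.log(14.0), sigma=0.35),
        "cape_dds": OutcomeSpec("lognormal", intercept=np.log(12.0), sigma=0.35),
    }


@dataclass
class HumanSimSpec:
    """Generating parameters for the human cohort."""

    n_subjects: int = 1563
    n_candidate_snps: int = 674
    n_random_snps: int = 674
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: tuple[LDBlock, ...] = ()
    #: snp_id -> volume change (ml) per minor allele, applied to causal_region
    causal_snp_effects: dict[str, float] = field(default_factory=dict)
    #: optional snp_id -> fixed MAF (otherwise drawn uniform on maf_range)
    snp_mafs: dict[str, float] = field(default_factory=dict)
    causal_region: str = "hippocampus"
    volume_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"hippocampus": 0.08, "mpfc": 2.4}
    )
    n_scanners: int = 8
    outcome_specs: dict[str, OutcomeSpec] = field(default_factory=default_outcome_specs)
    cm_probs: tuple[float, float, float] = tuple(np.asarray(CM_COUNTS) / sum(CM_COUNTS))
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 50:
            raise SpecError("n_subjects must be >= 50")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SpecError("maf_range must lie within (0, 0.5]")
        if abs(sum(self.cm_probs) - 1.0) > 1e-9:
            raise SpecError("cm_probs must sum to 1")
        for b in self.ld_blocks:
            if not isinstance(b, LDBlock):
                raise SpecError("ld_blocks entries must be LDBlock")


def _draw_snp_panel(
    rng: np.random.Generator,
    n_subjects: int,
    snp_ids: list[str],
    spec: HumanSimSpec,
    blocks: tuple[LDBlock, ...],
) -> tuple[np.ndarray, np.ndarray]:
    """Binomial(2, MAF) genotypes; LD blocks by copy-with-resampling.

    Within a block the first SNP is a template; each further SNP copies it
    and independently resamples each subject's genotype with probability
    ``1 - sqrt(r2)``, which makes the expected pairwise correlation
    ``sqrt(r2)`` and hence r-squared approximately the target while
    preserving the marginal MAF.
    """
    n_snps = len(snp_ids)
    mafs = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=n_snps)
    for j, sid in enumerate(snp_ids):
        if sid in spec.snp_mafs:
            mafs[j] = spec.snp_mafs[sid]
    dosage = rng.binomial(2, mafs[None, :], size=(n_subjects, n_snps)).astype(float)
    pos = 0
    for block in blocks:
        if pos + block.size > n_snps:
            raise SpecError("LD blocks exceed the candidate panel size")
        template = dosage[:, pos]
        keep_prob = np.sqrt(block.r2)
        for j in range(pos + 1, pos + block.size):
            mafs[j] = mafs[pos]
            fresh = rng.binomial(2, mafs[pos], size=n_subjects).astype(float)
            keep = rng.random(n_subjects) < keep_prob
            dosage[:, j] = np.where(keep, template, fresh)
        pos += block.size
    return dosage, mafs


def _draw_ctq(rng: np.random.Generator, cm: np.ndarray) -> pd.DataFrame:
    """Six subscale severities (0-4) whose maximum reproduces the CM category.

    cm=0 -> all subscales 0; cm=1 -> max exactly 1; cm=2 -> max in {2,3,4}
    (the three merged top severity groups).
    """
    n = len(cm)
    out = np.zeros((n, 6), dtype=int)
    for i, c in enumerate(cm):
        if c == 0:
            continue
        g = 1 if c == 1 else int(rng.integers(2, 5))
        vals = rng.integers(0, g + 1, size=6)
        vals[rng.integers(0, 6)] = g
        out[i] = vals
    return pd.DataFrame(out, columns=CTQ_COLUMNS)


def simulate_human_cohort(spec: HumanSimSpec):
    """Generate (genotypes, covariates, phenotypes, truth) for one cohort.

    Returns
    -------
    genotypes : GenotypeMatrix
        Candidate panel followed by the random-SNP pool; ``snp_meta``
        distinguishes them via ``category`` ('candidate' / 'random').
    covariates : DataFrame (covariates schema)
    phenotypes : DataFrame (phenotypes schema)
    truth : dict
        Every generating parameter plus per-subject latent variables
        (``true_score``, ``cm``) needed to recompute generating
        expectations.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    subject_ids = [f"S{i:05d}" for i in range(n)]

    cand_ids = [f"cand{i:04d}" for i in range(spec.n_candidate_snps)]
    rand_ids = [f"rand{i:04d}" for i in range(spec.n_random_snps)]
    cand_dosage, cand_mafs = _draw_snp_panel(rng, n, cand_ids, spec, spec.ld_blocks)
    rand_dosage, rand_mafs = _draw_snp_panel(rng, n, rand_ids, spec, ())

    dosage = np.hstack([cand_dosage, rand_dosage])
    snp_ids = cand_ids + rand_ids
    meta = default_snp_meta(snp_ids)
    meta.loc[cand_ids, "category"] = "candidate"
    meta.loc[rand_ids, "category"] = "random"
    meta.loc[cand_ids, "gene"] = [f"GENE{i % 90:02d}" for i in range(len(cand_ids))]

    if spec.missing_rate > 0:
        mask = rng.random(dosage.shape) < spec.missing_rate
        dosage = np.where(mask, np.nan, dosage)
    genotypes = GenotypeMatrix(subject_ids, snp_ids, dosage, meta)

    # covariates
    sex = rng.integers(0, 2, size=n)
    pds = np.clip(rng.normal(3.0, 0.6, size=n), 1.0, 4.0)
    tiv = rng.normal(1450.0, 110.0, size=n)
    scanner = rng.integers(0, spec.n_scanners, size=n)
    scanner_labels = np.array([f"site{k}" for k in range(spec.n_scanners)])
    covariates = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "sex": sex,
            "pds": pds,
            "tiv": tiv,
            "scanner": scanner_labels[scanner],
        }
    )

    # regional volumes: covariate signal + causal SNP effects + noise
    scanner_offsets = {
        "hippocampus": rng.normal(0.0, 0.02, size=spec.n_scanners),
        "mpfc": rng.normal(0.0, 0.5, size=spec.n_scanners),
    }
    base = {
        "hippocampus": HIPPOCAMPUS_MEAN_ML,
        "mpfc": MPFC_MEAN_ML,
    }
    cov_eff = {
        "hippocampus": {"sex": 0.03, "pds": 0.01, "tiv": 0.0004},
        "mpfc": {"sex": 0.8, "pds": 0.3, "tiv": 0.012},
    }
    volumes = {}
    for region in ("hippocampus", "mpfc"):
        eff = cov_eff[region]
        lp = (
            base[region]
            + eff["sex"] * sex
            + eff["pds"] * (pds - 3.0)
            + eff["tiv"] * (tiv - 1450.0)
            + scanner_offsets[region][scanner]
        )
        if region == spec.causal_region:
            for sid, beta in spec.causal_snp_effects.items():
                lp = lp + beta * np.nan_to_num(genotypes.column(sid))
        volumes[region] = lp + rng.normal(0.0, spec.volume_noise_sd[region], size=n)

    # latent score used in outcome generation: weighted minor-allele sum over
    # causal SNPs, min-max normalized to 0-10 (0 if there are no causal SNPs)
    raw = np.zeros(n)
    for sid, beta in spec.causal_snp_effects.items():
        raw = raw + beta * np.nan_to_num(genotypes.column(sid))
    if spec.causal_snp_effects and raw.max() > raw.min():
        true_score = 10.0 * (raw - raw.min()) / (raw.max() - raw.min())
    else:
        true_score = np.zeros(n)

    cm = rng.choice(3, size=n, p=np.asarray(spec.cm_probs))
    ctq = _draw_ctq(rng, cm)

    outcomes: dict[str, np.ndarray] = {}
    for name, ospec in spec.outcome_specs.items():
        lp = (
            ospec.intercept
            + ospec.b_score * true_score
            + ospec.b_cm * cm
            + ospec.b_int * cm * true_score
            + ospec.b_sex * sex
        )
        if ospec.kind == "poisson":
            y = rng.poisson(np.exp(lp)).astype(float)
        elif ospec.kind == "lognormal":
            y = np.exp(lp + rng.normal(0.0, ospec.sigma, size=n))
        else:
            raise SpecError(f"unknown outcome kind {ospec.kind!r}")
        if ospec.clip is not None:
            y = np.minimum(y, ospec.clip)
        outcomes[name] = y

    # SDQ composites are stored at subscale level; split each composite
    # binomially so subscale sums reproduce the generated composite
    es = outcomes["es"].astype(int)
    is_ = outcomes["is"].astype(int)
    conduct = rng.binomial(es, 0.5)
    emotional = rng.binomial(is_, 0.5)
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "hippocampus_ml": volumes["hippocampus"],
            "mpfc_ml": volumes["mpfc"],
            "depband": outcomes["depband"].astype(int),
            "cape_pds": outcomes["cape_pds"],
            "cape_nds": outcomes["cape_nds"],
            "cape_dds": outcomes["cape_dds"],
            "sdq_conduct": conduct,
            "sdq_hyperactivity": es - conduct,
            "sdq_emotional": emotional,
            "sdq_peer": is_ - emotional,
        }
    )
    phenotypes = pd.concat([phenotypes, ctq], axis=1)

    truth = {
        "spec": spec,
        "mafs": dict(zip(snp_ids, np.concatenate([cand_mafs, rand_mafs]))),
        "scanner_offsets": scanner_offsets,
        "covariate_effects": cov_eff,
        "true_score": true_score,
        "true_raw_score": raw,
        "cm": cm,
        "volume_base": base,
    }
    return genotypes, covariates, phenotypes, truth


# ---------------------------------------------------------------------------
# Mouse arm
# ---------------------------------------------------------------------------


@dataclass
class MouseSimSpec:
    """Generating parameters for the maternal-separation experiment.

    Group shifts are in control-SD units and were back-computed from the
    group contrasts the experiment is powered for (standardized mean
    differences ~1.75 for sucrose preference and ~0.93 for lit-box time
    with 13 vs 10 animals).
    """

    n_ms: int = 13
    n_ns: int = 10
    sucrose_shift_sd: float = 1.75
    lit_shift_sd: float = 0.93
    ns_sucrose_pref_mean: float = 78.0
    ns_sucrose_pref_sd: float = 6.0
    ns_lit_time_mean: float = 210.0
    ns_lit_time_sd: float = 45.0
    genes: tuple[str, ...] = DEFAULT_GENE_PANEL
    log2_shift: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG2_SHIFTS))
    ct_noise_sd: float = 0.15
    animal_ct_sd: float = 0.3
    reference_gene: str = "Rab5a"
    reference_gene_ct: float = 22.0
    #: (males, females) per group; defaults are the 4/9 vs 3/7 design
    ms_sex: tuple[int, int] = (4, 9)
    ns_sex: tuple[int, int] = (3, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ms < 3 or self.n_ns < 3:
            raise SpecError("need at least 3 animals per group")
        if self.ct_noise_sd < 0:
            raise SpecError("ct_noise_sd must be >= 0")
        unknown = set(self.log2_shift) - set(self.genes)
        if unknown:
            raise SpecError(f"log2_shift names genes outside the panel: {sorted(unknown)}")


def _sexes(rng, n, design):
    m, f = design
    if m + f == n:
        sexes = ["M"] * m + ["F"] * f
    else:
        sexes = ["M" if rng.random() < 0.35 else "F" for _ in range(n)]
    return sexes


def simulate_mouse_cohort(spec: MouseSimSpec):
    """Generate (behavior table, qPCR Ct table, truth) for one experiment.

    MS gene shifts are applied on the log2 expression scale: a shift of
    ``s`` moves the gene's true delta-Ct by ``-s`` cycles in MS animals,
    so downstream 2^-ddCt quantification recovers the injected fold change
    ``2**s`` in expectation.
    """
    rng = np.random.default_rng(spec.seed)
    groups = ["MS"] * spec.n_ms + ["NS"] * spec.n_ns
    ids = [f"MS{i:02d}" for i in range(spec.n_ms)] + [f"NS{i:02d}" for i in range(spec.n_ns)]
    sexes = _sexes(rng, spec.n_ms, spec.ms_sex) + _sexes(rng, spec.n_ns, spec.ns_sex)

    is_ms = np.array([g == "MS" for g in groups])
    pref = rng.normal(spec.ns_sucrose_pref_mean, spec.ns_sucrose_pref_sd, size=len(ids))
    pref = pref - is_ms * spec.sucrose_shift_sd * spec.ns_sucrose_pref_sd
    pref = np.clip(pref, 1.0, 99.0)
    total = np.clip(rng.normal(2.2, 0.35, size=len(ids)), 0.5, None)
    lit = rng.normal(spec.ns_lit_time_mean, spec.ns_lit_time_sd, size=len(ids))
    lit = np.clip(lit - is_ms * spec.lit_shift_sd * spec.ns_lit_time_sd, 0.0, 600.0)

    behavior = pd.DataFrame(
        {
            "animal_id": ids,
            "group": groups,
            "sex": sexes,
            "sucrose_ml": np.round(total * pref / 100.0, 3),
            "water_ml": np.round(total * (1 - pref / 100.0), 3),
            "lit_time_s": np.round(lit, 1),
        }
    )

    # qPCR: per-gene baseline delta-Ct, per-animal biological offsets, and
    # within-triplicate measurement noise around the true well value
    gene_delta_ct = {g: float(rng.uniform(2.0, 9.0)) for g in spec.genes}
    rows = []
    for i, animal in enumerate(ids):
        ref_true = spec.reference_gene_ct + rng.normal(0.0, 0.2)
        for well in (1, 2, 3):
            rows.append(
                (animal, spec.reference_gene, well, ref_true + rng.normal(0.0, spec.ct_noise_sd))
            )
        for g in spec.genes:
            dct = gene_delta_ct[g] + rng.normal(0.0, spec.animal_ct_sd)
            if is_ms[i]:
                dct -= spec.log2_shift.get(g, 0.0)
            target_true = ref_true + dct
            for well in (1, 2, 3):
                rows.append((animal, g, well, target_true + rng.normal(0.0, spec.ct_noise_sd)))
    ct_table = pd.DataFrame(rows, columns=["animal_id", "gene", "well", "ct"])
    ct_table["ct"] = ct_table["ct"].round(4)

    truth = {
        "spec": spec,
        "gene_delta_ct": gene_delta_ct,
        "true_pref": pref,
        "true_lit": lit,
    }
    return behavior, ct_table, truth


def truth_to_yaml_dict(truth: dict) -> dict:
    """JSON/YAML-safe view of a truth record (arrays become lists,
    numpy scalars become Python scalars, specs become plain dicts)."""
    return _plain(truth)


def _plain(v):
    if isinstance(v, (HumanSimSpec, MouseSimSpec, LDBlock, OutcomeSpec)):
        return _plain(asdict(v))
    if isinstance(v, dict):
        return {str(k): _plain(vv) for k, vv in v.items()}
    if isinstance(v, (list, tuple)):
        return [_plain(x) for x in v]
    if isinstance(v, np.ndarray):
        return _plain(v.tolist())
    if isinstance(v, np.generic):
        return v.item()
    return v
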