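"""Validated containers and readers/writers for the pipeline's tabular formats.

All tables are UTF-8 TSV with a header row; ``.`` marks a missing value.
Genotypes are stored internally as MINOR-allele dosage (0, 1 or 2 copies of
the cohort's less frequent allele); the major-allele coding used at
model-fit time is recovered as ``2 - dosage``.  Two genotype dialects are
supported: a simplified PLINK-``.raw``-style additive TSV (``subject_id``
plus one column per SNP) and VCF v4.x restricted to biallelic SNVs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = "."


class ParseError(ValueError):
    """A file could not be parsed under the named dialect."""


class SchemaError(ValueError):
    """A table's header does not match the requested schema."""


class ValidationError(ValueError):
    """Parsed values violate a container invariant."""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

SNP_META_COLUMNS = ["gene", "category", "minor_allele", "major_allele"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs minor-allele dosage matrix with per-SNP metadata.

    Parameters
    ----------
    subject_ids, snp_ids
        Unique row / column identifiers.
    dosage
        Float array of shape ``(n_subjects, n_snps)``; entries are 0, 1, 2
        or NaN (missing).
    snp_meta
        DataFrame indexed by ``snp_ids`` with columns ``gene``,
        ``category``, ``minor_allele``, ``major_allele``.
    n_skipped_records
        Count of input records skipped on load (e.g. non-biallelic VCF
        sites).
    """

    subject_ids: list[str]
    snp_ids: list[str]
    dosage: np.ndarray
    snp_meta: pd.DataFrame
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_ids), len(self.snp_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("subject_ids are not unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("snp_ids are not unique")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0, 2.0))]))
            raise ValidationError(f"dosage values outside {{0,1,2}}: {bad}")
        if list(self.snp_meta.index) != list(self.snp_ids):
            raise ValidationError("snp_meta index must equal snp_ids")
        missing_cols = [c for c in SNP_META_COLUMNS if c not in self.snp_meta.columns]
        if missing_cols:
            raise ValidationError(f"snp_meta missing columns: {missing_cols}")

    # -- convenience ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.subject_ids, columns=self.snp_ids)

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self.snp_ids.index(snp_id)]

    def maf(self) -> pd.Series:
        """Realized minor-allele frequency per SNP (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return pd.Series(freq, index=self.snp_ids)

    def imputed_dosage(self, policy: str = "impute") -> np.ndarray:
        """Resolve missing entries.

        ``impute`` replaces NaN with the per-SNP mean dosage; ``drop-subject``
        drops subjects with any missing dosage (returned array may have
        fewer rows; pair with :meth:`complete_subjects`).
        """
        if policy == "impute":
            out = self.dosage.copy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_means = np.nanmean(out, axis=0)
            col_means = np.where(np.isnan(col_means), 0.0, col_means)
            idx = np.where(np.isnan(out))
            out[idx] = col_means[idx[1]]
            return out
        if policy == "drop-subject":
            keep = ~np.isnan(self.dosage).any(axis=1)
            return self.dosage[keep]
        raise ValueError(f"unknown missingness policy: {policy!r}")

    def complete_subjects(self) -> list[str]:
        keep = ~np.isnan(self.dosage).any(axis=1)
        return [s for s, k in zip(self.subject_ids, keep) if k]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            snp_ids=list(snp_ids),
            dosage=self.dosage[:, idx],
            snp_meta=self.snp_meta.loc[snp_ids],
        )


def default_snp_meta(snp_ids: list[str], category: str = "unknown") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": ["unknown"] * len(snp_ids),
            "category": [category] * len(snp_ids),
            "minor_allele": ["A1"] * len(snp_ids),
            "major_allele": ["A2"] * len(snp_ids),
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "subject_id":
        raise SchemaError(f"{path}: first column must be 'subject_id', got {df.columns[0]!r}")
    snp_ids = list(df.columns[1:])
    subject_ids = list(df["subject_id"])
    n = len(subject_ids)
    dosage = np.full((n, len(snp_ids)), np.nan)
    for j, snp in enumerate(snp_ids):
        for i, raw in enumerate(df[snp]):
            if raw == MISSING or raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            if raw not in ("0", "1", "2"):
                # +2: header line and 1-based numbering
                raise ParseError(
                    f"{path}, line {i + 2}: invalid dosage {raw!r} for SNP {snp} "
                    "(expected 0, 1, 2 or '.')"
                )
            dosage[i, j] = float(raw)
    return GenotypeMatrix(subject_ids, snp_ids, dosage, default_snp_meta(snp_ids))


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    snp_ids: list[str] = []
    cols: list[np.ndarray] = []
    minor: list[str] = []
    major: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            log.warning("skipping non-biallelic-SNV record %s:%s", var.CHROM, var.POS)
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        alt_dosage = np.full(gt.shape, np.nan)
        alt_dosage[gt == 0] = 0.0
        alt_dosage[gt == 1] = 1.0
        alt_dosage[gt == 3] = 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            alt_freq = np.nanmean(alt_dosage) / 2.0
        if np.isnan(alt_freq):
            alt_freq = 0.0
        if alt_freq > 0.5:
            # ALT is the major allele in this cohort; store REF counts
            cols.append(2.0 - alt_dosage)
            minor.append(var.REF)
            major.append(var.ALT[0])
        else:
            cols.append(alt_dosage)
            minor.append(var.ALT[0])
            major.append(var.REF)
        snp_ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    dosage = (
        np.column_stack(cols) if cols else np.empty((len(subject_ids), 0))
    )
    meta = default_snp_meta(snp_ids)
    meta["minor_allele"] = minor
    meta["major_allele"] = major
    return GenotypeMatrix(subject_ids, snp_ids, dosage, meta, n_skipped_records=n_skipped)


def read_genotypes(path, format: str = "plink_raw_tsv") -> GenotypeMatrix:
    """Load genotypes as minor-allele dosages.

    ``plink_raw_tsv`` is a simplified additive TSV (``subject_id`` + one
    column per SNP, values 0/1/2/``.``) assumed already coded as minor-allele
    counts.  ``vcf`` converts genotypes to cohort minor-allele dosage: the
    cohort ALT frequency is recomputed and the stored counts are flipped to
    the REF allele wherever ALT turns out to be the major allele.
    Non-biallelic VCF records are skipped with a logged warning; the skip
    count is available as ``n_skipped_records`` on the result.
    """
    if format == "plink_raw_tsv":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as the plink_raw_tsv dialect."""
    df = gm.dosage_frame()
    out = df.map(lambda v: MISSING if np.isnan(v) else str(int(v)))
    out.insert(0, "subject_id", gm.subject_ids)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Typed tables
# ---------------------------------------------------------------------------

CTQ_COLUMNS = [f"ctq{i}" for i in range(1, 7)]

PHENOTYPE_COLUMNS = [
    "subject_id",
    "hippocampus_ml",
    "mpfc_ml",
    "depband",
    "cape_pds",
    "cape_nds",
    "cape_dds",
    "sdq_conduct",
    "sdq_hyperactivity",
    "sdq_emotional",
    "sdq_peer",
    *CTQ_COLUMNS,
]

_SCHEMAS: dict[str, dict] = {
    "covariates": {
        "required": ["subject_id", "sex", "pds", "tiv", "scanner"],
        "optional": [],
        "string": ["subject_id", "scanner"],
    },
    "phenotypes": {
        "required": PHENOTYPE_COLUMNS,
        "optional": ["audit"],
        "string": ["subject_id"],
    },
    "mouse_behavior": {
        "required": ["animal_id", "group", "sex", "sucrose_ml", "water_ml", "lit_time_s"],
        "optional": [],
        "string": ["animal_id", "group", "sex"],
    },
    "qpcr_ct": {
        "required": ["animal_id", "gene", "well", "ct"],
        "optional": [],
        "string": ["animal_id", "gene"],
    },
}


def _fail_rows(df: pd.DataFrame, bad: pd.Series, message: str) -> None:
    if bad.any():
        rows = list(df.index[bad][:20])
        raise ValidationError(f"{message}; offending rows (0-based): {rows}")


def _validate(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    if schema == "covariates":
        _fail_rows(df, ~df["tiv"].gt(0), "tiv must be > 0")
        _fail_rows(df, ~df["sex"].isin([0, 1]), "sex must be coded 0/1")
        if df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id in covariates")
    elif schema == "phenotypes":
        for col in ("hippocampus_ml", "mpfc_ml"):
            _fail_rows(df, df[col].le(0), f"{col} must be > 0")
        _fail_rows(
            df,
            df["depband"].notna() & ~df["depband"].isin(range(6)),
            "depband must be an integer in 0..5",
        )
        for col in CTQ_COLUMNS:
            _fail_rows(
                df,
                df[col].notna() & ~df[col].isin(range(5)),
                f"{col} must be an integer in 0..4",
            )
        for col in ("sdq_conduct", "sdq_hyperactivity", "sdq_emotional", "sdq_peer"):
            _fail_rows(df, df[col].notna() & df[col].lt(0), f"{col} must be >= 0")
        for col in ("cape_pds", "cape_nds", "cape_dds"):
            _fail_rows(df, df[col].notna() & df[col].le(0), f"{col} must be > 0")
    elif schema == "mouse_behavior":
        _fail_rows(df, ~df["group"].isin(["MS", "NS"]), "group must be MS or NS")
        _fail_rows(df, df["sucrose_ml"].lt(0), "sucrose_ml must be >= 0")
        _fail_rows(df, df["water_ml"].lt(0), "water_ml must be >= 0")
        _fail_rows(
            df,
            df["sucrose_ml"].eq(0) & df["water_ml"].eq(0),
            "sucrose_ml and water_ml cannot both be 0",
        )
        _fail_rows(
            df,
            ~df["lit_time_s"].between(0, 600),
            "lit_time_s must lie in [0, 600] (10 min test)",
        )
    elif schema == "qpcr_ct":
        _fail_rows(df, df["ct"].notna() & df["ct"].le(0), "ct must be > 0")
        _fail_rows(df, ~df["well"].isin([1, 2, 3]), "well must be 1, 2 or 3")
        # triplicates with < 3 usable wells are accepted but flagged
        counts = df[df["ct"].notna()].groupby(["animal_id", "gene"]).size()
        short = counts[counts < 3]
        if len(short):
            log.warning(
                "%d animal x gene triplicates have fewer than 3 usable wells", len(short)
            )
    return df


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's typed TSV tables.

    ``schema`` is one of ``covariates``, ``phenotypes``, ``mouse_behavior``
    or ``qpcr_ct``.  Raises :class:`SchemaError` on a header mismatch and
    :class:`ValidationError` (listing offending rows) on invariant
    violations.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = _SCHEMAS[schema]
    dtypes = {c: str for c in spec["string"]}
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], keep_default_na=False, dtype=dtypes)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: schema {schema!r} missing required columns {missing}")
    extra = [c for c in df.columns if c not in spec["required"] + spec["optional"]]
    if extra:
        raise SchemaError(f"{path}: schema {schema!r} has unexpected columns {extra}")
    return _validate(df, schema)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)
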