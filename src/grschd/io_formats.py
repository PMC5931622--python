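"""Readers/writers for genotypes, weights and phenotypes, plus cohort assembly.

Genotypes are effect-allele dosage counts per individual per variant,
either from a VCF (GT hard calls or DS imputed dosages, best-guess rounded)
or from a plain TSV dosage matrix (rows = samples, columns = rsids).
Variant weights arrive as a TSV with per-allele log-hazard effect sizes and
score-membership flags; variants imputed with r² < 0.85 are dropped at read
time. Cohort assembly applies the sequential eligibility filters (age
window, prior cardiovascular disease, missing risk-function components) and
logs each exclusion count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("grschd")

ANCESTRIES = ("AFR", "LAT", "EA", "EUR")

#: minimum imputation quality for a variant to be scored
IMPUTATION_R2_MIN = 0.85

#: Framingham risk-function component columns that must be non-missing
FRS_COMPONENTS = (
    "age", "sex", "total_chol", "hdl", "sbp", "dbp", "smoker", "diabetes",
)

WEIGHT_COLUMNS = (
    "rsid", "effect_allele", "other_allele", "beta",
    "in_grs12", "in_grs51", "haplotype_member", "imputation_r2",
)


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class VariantWeight:
    """A variant's effect allele and per-allele log-hazard weight."""

    rsid: str
    effect_allele: str
    other_allele: str
    weight: float
    in_grs12: bool = False
    in_grs51: bool = False
    haplotype_member: bool = False
    imputation_r2: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise FormatError(f"{self.rsid}: non-finite weight")
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.rsid}: effect allele equals other allele")


@dataclass
class WeightSet:
    """Scored variants plus the variants excluded for low imputation quality.

    ``variants`` holds every retained row (individually weighted variants and
    the haplotype-member variants); ``excluded`` the rows dropped for
    imputation r² below :data:`IMPUTATION_R2_MIN`.
    """

    variants: list[VariantWeight]
    excluded: list[VariantWeight] = field(default_factory=list)

    def __post_init__(self) -> None:
        rsids = [v.rsid for v in self.variants]
        if len(set(rsids)) != len(rsids):
            dupes = {r for r in rsids if rsids.count(r) > 1}
            raise FormatError(f"duplicate rsid(s) in weight set: {sorted(dupes)}")

    def __getitem__(self, rsid: str) -> VariantWeight:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise KeyError(rsid)

    def __len__(self) -> int:
        return len(self.variants)

    def members(self, which: str) -> list[VariantWeight]:
        """Individually weighted (non-haplotype) variants of one score."""
        flag = {"GRS12": "in_grs12", "GRS51": "in_grs51"}[which]
        return [
            v for v in self.variants
            if getattr(v, flag) and not v.haplotype_member
        ]

    @property
    def haplotype_members(self) -> list[VariantWeight]:
        return [v for v in self.variants if v.haplotype_member]


@dataclass
class GenotypeMatrix:
    """Best-guess dosages (0/1/2) of the counted allele, NaN = missing.

    ``dosages`` is a samples × rsids frame; ``counted_allele`` maps each
    rsid to the allele whose copies the dosage counts (the VCF ALT for the
    GT/DS paths, or the allele declared by the dosage-table header
    convention). Orientation to the weight table's effect allele happens in
    the scoring engine, not here.
    """

    dosages: pd.DataFrame
    counted_allele: pd.Series
    other_allele: pd.Series | None = None

    @property
    def samples(self) -> pd.Index:
        return self.dosages.index

    @property
    def rsids(self) -> pd.Index:
        return self.dosages.columns

    def missing_mask(self) -> pd.DataFrame:
        return self.dosages.isna()


def _best_guess(ds: float) -> float:
    """Nearest-integer dosage; ties (x.5) round half away from zero."""
    if np.isnan(ds):
        return np.nan
    return float(min(2, max(0, int(np.floor(ds + 0.5)))))


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from a VCF or a TSV dosage table.

    VCF records use DS when present (rounded to the nearest integer, ties
    away from zero — "best guess"), else the GT hard call; the counted
    allele is the ALT. Missing genotypes stay NaN, never silently zero.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return read_dosage_table(path)
    raise FormatError(f"unknown genotype format: {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # 0/1/2 = alt count, 3 = missing
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise FormatError("duplicate sample IDs in VCF header")
    cols: dict[str, np.ndarray] = {}
    counted: dict[str, str] = {}
    other: dict[str, str] = {}
    for rec in vcf:
        rsid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise FormatError(
                f"{rsid}: multi-allelic site; effect allele unresolvable"
            )
        if rsid in cols:
            raise FormatError(f"duplicate variant ID {rsid} in VCF")
        ds = rec.format("DS")
        if ds is not None:
            vals = np.array(
                [_best_guess(float(x)) for x in np.asarray(ds).ravel()]
            )
        else:
            # gt_types: 0=hom ref, 1=het, 2=hom alt (gts012), 3=unknown
            gt = np.asarray(rec.gt_types, dtype=float)
            vals = np.where(gt == 3, np.nan, np.where(gt == 2, 2.0, gt))
        cols[rsid] = vals
        counted[rsid] = rec.ALT[0]
        other[rsid] = rec.REF
    dosages = pd.DataFrame(cols, index=pd.Index(samples, name="sample"))
    return GenotypeMatrix(
        dosages=dosages,
        counted_allele=pd.Series(counted, name="counted_allele"),
        other_allele=pd.Series(other, name="other_allele"),
    )


def read_dosage_table(path, counted_alleles: pd.Series | None = None) -> GenotypeMatrix:
    """Read a samples × rsids TSV of dosages; blank cells stay missing.

    Without an explicit ``counted_alleles`` map the counted allele is
    assumed to be each variant's effect allele (the convention the
    simulator and writer use).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError("duplicate sample IDs in dosage table")
    df = df.astype(float)
    vals = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((vals < 0) | (vals > 2)):
            raise FormatError("dosages outside [0, 2] in dosage table")
    if counted_alleles is None:
        counted_alleles = pd.Series("EFFECT", index=df.columns)
    return GenotypeMatrix(
        dosages=df, counted_allele=counted_alleles.reindex(df.columns)
    )


def write_dosage_table(gm: GenotypeMatrix, path) -> None:
    gm.dosages.to_csv(path, sep="\t", index_label="sample")


def read_weights(path) -> WeightSet:
    """Read a variant-weight TSV, dropping variants with imputation r² < 0.85.

    The exclusions mirror the source scores' quality rule and are logged;
    haplotype-member rows define the 4-variant haplotype scored as one unit.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise FormatError(f"empty weight table: {path}")
    missing_cols = set(WEIGHT_COLUMNS[:7]) - set(df.columns)
    if missing_cols:
        raise FormatError(f"weight table missing columns {sorted(missing_cols)}")
    if df["rsid"].duplicated().any():
        raise FormatError(
            f"duplicate rsids: {sorted(df.loc[df['rsid'].duplicated(), 'rsid'])}"
        )
    if not pd.api.types.is_numeric_dtype(df["beta"]):
        raise FormatError("non-numeric beta column")
    kept, excluded = [], []
    for row in df.itertuples(index=False):
        r2 = getattr(row, "imputation_r2", None)
        r2 = None if r2 is None or pd.isna(r2) else float(r2)
        vw = VariantWeight(
            rsid=str(row.rsid),
            effect_allele=str(row.effect_allele),
            other_allele=str(row.other_allele),
            weight=float(row.beta),
            in_grs12=bool(row.in_grs12),
            in_grs51=bool(row.in_grs51),
            haplotype_member=bool(row.haplotype_member),
            imputation_r2=r2,
        )
        if r2 is not None and r2 < IMPUTATION_R2_MIN:
            excluded.append(vw)
        else:
            kept.append(vw)
    if excluded:
        logger.info(
            "excluded %d variant(s) with imputation r2 < %.2f: %s",
            len(excluded), IMPUTATION_R2_MIN, [v.rsid for v in excluded],
        )
    ws = WeightSet(variants=kept, excluded=excluded)
    n_hap = len(ws.haplotype_members)
    if n_hap not in (0, 4):
        raise FormatError(
            f"haplotype_member set for {n_hap} variants; expected exactly 4"
        )
    return ws


def write_weights(ws: WeightSet, path) -> None:
    rows = [
        {
            "rsid": v.rsid, "effect_allele": v.effect_allele,
            "other_allele": v.other_allele, "beta": v.weight,
            "in_grs12": v.in_grs12, "in_grs51": v.in_grs51,
            "haplotype_member": v.haplotype_member,
            "imputation_r2": v.imputation_r2,
        }
        for v in ws.variants + ws.excluded
    ]
    pd.DataFrame(rows, columns=WEIGHT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a phenotype/covariate CSV into a cohort table."""
    df = pd.read_csv(path)
    if "id" in df.columns:
        df = df.set_index("id")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise FormatError("duplicate individual IDs in cohort table")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index_label="id")


def pc_columns(cohort: pd.DataFrame, n_pcs: int = 6) -> list[str]:
    cols = [f"pc{i}" for i in range(1, n_pcs + 1)]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise FormatError(f"cohort lacks principal-component columns {missing}")
    return cols


def apply_cohort_filters(
    rows: pd.DataFrame, min_age: float = 30, max_age: float = 79
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the sequential eligibility exclusions, logging each count.

    Order is fixed: age outside [min_age, max_age] first, then prior
    cardiovascular disease, then missingness in any risk-function component.
    Counts therefore always sum to input minus output rows, and are
    independent of input row order.
    """
    log: dict[str, int] = {}
    keep = rows
    in_age = keep["age"].between(min_age, max_age)
    log["age"] = int((~in_age).sum())
    keep = keep[in_age]

    prior = keep["prior_cvd"].fillna(False).astype(bool) if "prior_cvd" in keep else (
        pd.Series(False, index=keep.index)
    )
    log["cvd"] = int(prior.sum())
    keep = keep[~prior]

    present = [c for c in FRS_COMPONENTS if c in keep.columns]
    absent = [c for c in FRS_COMPONENTS if c not in keep.columns]
    missing = keep[present].isna().any(axis=1) if present else pd.Series(
        False, index=keep.index
    )
    if absent:
        # a wholly absent component column means every row is missing it
        missing |= True
    log["missing"] = int(missing.sum())
    keep = keep[~missing]

    logger.info("cohort filters: %s (kept %d of %d)", log, len(keep), len(rows))
    return keep, log
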