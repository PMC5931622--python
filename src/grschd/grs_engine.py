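"""Weighted multi-locus genetic risk scores with a 4-variant haplotype term.

A score is the weighted sum of effect-allele dosages,

    GRS = sum_i beta_i * d_i  (+ w_hap * h),

where beta_i is the published per-allele log-hazard effect size, d_i in
{0,1,2} the effect-allele dosage, and h the haplotype term: one scored unit
for a 4-variant risk haplotype (the ALOX5AP haplotype B, weight 0.131).
Two score compositions are supported: a 12-unit score (8 individually
weighted variants + the haplotype) and a 51-unit score (47 + haplotype).
Scores are standardized and binned into tertiles within ancestry group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeMatrix, VariantWeight, WeightSet

#: published weight applied to presence of the ALOX5AP haplotype B
HAPLOTYPE_WEIGHT = 0.131

#: maximum fraction of scored variants a sample may be missing and still
#: receive a score (missing dosages are imputed at 2x the effect-allele
#: frequency of non-missing samples)
MAX_MISSING_FRACTION = 0.10

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScoringError(ValueError):
    """Raised when a score cannot be computed from the provided inputs."""


@dataclass(frozen=True)
class HaplotypeDefinition:
    """Four (rsid, effect allele) pairs scored as one weighted unit."""

    members: tuple[tuple[str, str], ...]
    weight: float = HAPLOTYPE_WEIGHT
    mode: str = "presence"  # or "min_dosage"

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise ScoringError(
                f"haplotype needs exactly 4 members, got {len(self.members)}"
            )
        if self.weight < 0:
            raise ScoringError("haplotype weight must be >= 0")

    @classmethod
    def from_weight_set(cls, ws: WeightSet, mode: str = "presence"):
        members = tuple(
            (v.rsid, v.effect_allele) for v in ws.haplotype_members
        )
        if not members:
            return None
        return cls(members=members, mode=mode)


@dataclass
class ScoreVector:
    """Per-individual score values with bookkeeping of variants used."""

    scores: pd.Series
    score_name: str
    n_variants_used: pd.Series


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G variants cannot be strand-resolved without frequencies."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def orient_dosage(
    observed_dosage, observed_counted_allele: str, variant: VariantWeight,
    strict: bool = True,
):
    """Re-express a dosage as copies of the variant's effect allele.

    Returns d if the counted allele is the effect allele and 2 - d if it is
    the other allele, trying the strand complement before giving up. In
    strict mode a palindromic (A/T or C/G) variant is an error since its
    strand cannot be confirmed.
    """
    if strict and is_palindromic(variant.effect_allele, variant.other_allele):
        raise ScoringError(
            f"{variant.rsid}: palindromic variant "
            f"({variant.effect_allele}/{variant.other_allele}) is "
            "strand-ambiguous; supply pre-oriented dosages or disable strict"
        )
    a = observed_counted_allele.upper()
    eff, oth = variant.effect_allele.upper(), variant.other_allele.upper()
    # exact-strand matches take precedence over complement (flip) matches
    if a in ("EFFECT", eff):
        return observed_dosage
    if a == oth:
        return 2 - observed_dosage
    if a == _COMPLEMENT.get(eff):
        return observed_dosage
    if a == _COMPLEMENT.get(oth):
        return 2 - observed_dosage
    raise ScoringError(
        f"{variant.rsid}: counted allele {a!r} matches neither "
        f"{eff!r} nor {oth!r}"
    )


def haplotype_copies(four_dosages, mode: str = "presence"):
    """Haplotype term from the four constituent effect-allele dosages.

    presence: 1 if every constituent dosage is >= 1 (the risk haplotype may
    be present on at least one chromosome), else 0. min_dosage: the minimum
    constituent dosage, an upper bound on haplotype copies under unknown
    phase. Any missing constituent makes the term 0 (absent, logged by the
    caller).
    """
    d = np.asarray(four_dosages, dtype=float)
    if d.shape[-1] != 4:
        raise ScoringError("haplotype term needs exactly 4 dosages")
    if mode == "presence":
        with np.errstate(invalid="ignore"):
            return np.where(np.min(d, axis=-1) >= 1, 1.0, 0.0)
    if mode == "min_dosage":
        return np.min(d, axis=-1)
    raise ScoringError(f"unknown haplotype mode {mode!r}")


def _oriented_dosages(
    genotypes: GenotypeMatrix, variant: VariantWeight, strict: bool
) -> pd.Series:
    if variant.rsid not in genotypes.dosages.columns:
        raise ScoringError(f"{variant.rsid}: variant absent from genotypes")
    counted = str(genotypes.counted_allele.get(variant.rsid, "EFFECT"))
    return orient_dosage(
        genotypes.dosages[variant.rsid], counted, variant, strict=strict
    )


def compute_grs(
    genotypes: GenotypeMatrix,
    weight_set: WeightSet,
    which: str = "GRS12",
    haplotype_mode: str = "presence",
    strict_strand: bool = False,
) -> ScoreVector:
    """Compute the weighted score for every individual.

    Missing dosages are imputed at twice the effect-allele frequency of the
    non-missing samples unless an individual is missing more than 10% of the
    scored variants, in which case their score is NaN.
    """
    members = weight_set.members(which)
    if which == "GRS12" and len(members) < 8:
        raise ScoringError(
            f"GRS12 requires >= 8 individually weighted variants, "
            f"got {len(members)}"
        )
    if not members:
        raise ScoringError(f"no variants flagged for {which}")

    oriented = pd.DataFrame(
        {v.rsid: _oriented_dosages(genotypes, v, strict_strand) for v in members}
    )
    betas = pd.Series({v.rsid: v.weight for v in members})

    hap = HaplotypeDefinition.from_weight_set(weight_set, mode=haplotype_mode)
    n_scored = len(members) + (1 if hap is not None else 0)

    missing = oriented.isna()
    n_missing = missing.sum(axis=1)

    # impute missing dosages at 2 x effect-allele frequency of the observed
    freqs = oriented.mean(axis=0, skipna=True) / 2.0
    filled = oriented.fillna(2.0 * freqs)

    scores = filled.to_numpy() @ betas.reindex(filled.columns).to_numpy()
    scores = pd.Series(scores, index=oriented.index, name=which.lower())

    n_used = pd.Series(len(members), index=oriented.index) - n_missing
    if hap is not None:
        hap_dos = pd.DataFrame(
            {r: _oriented_dosages(genotypes, weight_set[r], strict_strand)
             for r, _ in hap.members}
        )
        hap_missing = hap_dos.isna().any(axis=1)
        h = haplotype_copies(hap_dos.to_numpy(), mode=hap.mode)
        h = np.where(hap_missing, 0.0, h)
        scores = scores + hap.weight * h
        n_used = n_used + (~hap_missing).astype(int)

    too_missing = (n_missing / len(members)) > MAX_MISSING_FRACTION
    scores[too_missing] = np.nan

    return ScoreVector(
        scores=scores, score_name=which,
        n_variants_used=n_used.rename("n_variants_used"),
    )


def standardize(scores: pd.Series, group_labels: pd.Series) -> pd.Series:
    """Z-score within each (ancestry) group, sample SD with n-1 denominator."""
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    for g, idx in scores.groupby(group_labels).groups.items():
        vals = scores.loc[idx]
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ScoringError(f"group {g!r}: zero within-group score variance")
        out.loc[idx] = (vals - vals.mean()) / sd
    return out.rename(f"{scores.name}_z" if scores.name else "z")


def assign_tertiles(scores: pd.Series, group_labels: pd.Series) -> pd.Series:
    """Tertile label (1/2/3) within group; ties at a cut go to the lower bin.

    Cuts are the within-group 33.33% and 66.67% empirical quantiles
    (linear/type-7 interpolation).
    """
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    for g, idx in scores.groupby(group_labels).groups.items():
        vals = scores.loc[idx]
        if len(vals) < 3:
            raise ScoringError(f"group {g!r}: fewer than 3 individuals")
        if vals.nunique() < 2:
            raise ScoringError(f"group {g!r}: all scores equal")
        q1, q2 = np.quantile(vals.to_numpy(), [1 / 3, 2 / 3], method="linear")
        out.loc[idx] = 1.0 + (vals > q1).astype(int) + (vals > q2).astype(int)
    return out.astype(int).rename(
        f"{scores.name}_tertile" if scores.name else "tertile"
    )
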