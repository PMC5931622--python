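"""Synthetic multi-ancestry cohorts with the structure the analysis assumes.

The generator emulates what the downstream pipeline needs from a real
cohort: Hardy-Weinberg genotypes at configured effect-allele frequencies,
a 4-variant risk haplotype drawn at a configured haplotype frequency,
covariates matching published per-ancestry marginal distributions (African
American / Latino / East Asian), ancestry principal components, and
right-censored event times from a Weibull proportional-hazards model with
a configurable score effect. Mean follow-up is tuned to about 8.7 years
and the cumulative event fraction to about 4% by year nine, matching the
cohort the analysis design targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import GenotypeMatrix, VariantWeight, WeightSet

#: per-ancestry covariate profiles (means/SDs/proportions of the published
#: baseline table): age, sex, lipids, blood pressure, smoking, diabetes,
#: treatment flags, family history, education, BMI, alcohol
COVARIATE_PROFILES: dict[str, dict] = {
    "AFR": dict(
        age=(57.1, 9.7), female=0.697, total_chol=(190.4, 38.0),
        hdl=(55.5, 15.1), sbp=(128.9, 15.6), dbp=(76.8, 10.0),
        smoker=(0.593, 0.327, 0.080), diabetes=0.243, bp_treated=0.568,
        lipid_treated=0.372, family_history=0.243, college=0.784,
        bmi=(29.7, 6.4), alcohol=(2.5, 5.1),
    ),
    "LAT": dict(
        age=(55.3, 10.2), female=0.726, total_chol=(195.3, 37.2),
        hdl=(53.6, 14.3), sbp=(124.9, 15.3), dbp=(74.1, 9.9),
        smoker=(0.650, 0.295, 0.055), diabetes=0.195, bp_treated=0.385,
        lipid_treated=0.324, family_history=0.250, college=0.651,
        bmi=(28.4, 6.0), alcohol=(2.9, 5.2),
    ),
    "EA": dict(
        age=(55.6, 10.0), female=0.686, total_chol=(196.3, 36.1),
        hdl=(57.5, 15.0), sbp=(123.0, 15.7), dbp=(73.6, 10.2),
        smoker=(0.775, 0.195, 0.030), diabetes=0.175, bp_treated=0.386,
        lipid_treated=0.323, family_history=0.210, college=0.830,
        bmi=(24.7, 4.3), alcohol=(1.7, 3.8),
    ),
}

#: ancestry mix of the target study population (2,089 / 4,349 / 4,804)
DEFAULT_ANCESTRY_MIX = {
    "AFR": 2089 / 11242, "LAT": 4349 / 11242, "EA": 4804 / 11242,
}

#: default per-SD log hazard ratios of the outcome model; covariates are
#: standardized before entering the linear predictor
DEFAULT_COVARIATE_LOGHRS = {
    "age": float(np.log(2.0)),
    "male": float(np.log(1.8)),
    "sbp": float(np.log(1.3)),
    "total_chol": float(np.log(1.2)),
    "hdl": float(np.log(0.8)),
    "current_smoker": float(np.log(1.5)),
    "diabetes": float(np.log(1.5)),
}

#: plausible physiological ranges continuous draws are clipped to
_CLIPS = {
    "age": (30.0, 79.0), "total_chol": (90.0, 400.0), "hdl": (15.0, 120.0),
    "sbp": (80.0, 220.0), "dbp": (40.0, 130.0), "bmi": (14.0, 60.0),
}

HAPLOTYPE_RSIDS = ("rs10507391", "rs93155050", "rs17222842", "rs17216473")
HAPLOTYPE_EFFECT_ALLELES = ("A", "A", "G", "A")


@dataclass
class SimConfig:
    """Everything the generator needs; defaults are the study conditions."""

    n: int = 11242
    ancestry_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANCESTRY_MIX)
    )
    variant_freqs: dict[str, float] | None = None  # filled from weight set
    haplotype_b_freq: float = 0.15
    covariate_profile: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in COVARIATE_PROFILES.items()}
    )
    grs_loghr_per_sd: float = float(np.log(1.17))
    covariate_loghrs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LOGHRS)
    )
    baseline_shape: float = 1.2
    baseline_scale: float | None = None  # None -> calibrate to event rate
    target_event_rate: float = 0.04  # cumulative by calibration_horizon
    calibration_horizon: float = 9.0
    admin_censor_years: float = 9.1
    admin_censor_spread: float = 1.15  # uniform half-width of entry stagger
    dropout_rate: float = 0.005  # per-year hazard of loss to follow-up
    n_pcs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if abs(sum(self.ancestry_mix.values()) - 1.0) > 1e-9:
            raise ValueError("ancestry mix must sum to 1")
        if not 0 < self.haplotype_b_freq < 1:
            raise ValueError("haplotype frequency must be in (0, 1)")
        if self.baseline_shape <= 0 or (
            self.baseline_scale is not None and self.baseline_scale <= 0
        ):
            raise ValueError("Weibull parameters must be positive")


def default_weight_set(seed: int = 7) -> WeightSet:
    """A plausible variant-weight table for simulation.

    51 candidate variants with published-scale effect sizes (four of them at
    imputation r² = 0.80, hence excluded from scoring, leaving 47), of which
    8 carry the 12-unit score flag, plus the 4 haplotype-member variants.
    Alleles are drawn non-palindromic so strand checks stay decidable.
    """
    rng = np.random.default_rng(seed)
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
             ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
    variants: list[VariantWeight] = []
    low_r2 = {10, 20, 30, 40}  # four variants below the quality bar
    grs12_flagged = set(range(8))
    for i in range(51):
        eff, oth = pairs[int(rng.integers(len(pairs)))]
        r2 = 0.80 if i in low_r2 else float(rng.uniform(0.90, 1.0))
        variants.append(
            VariantWeight(
                rsid=f"rs{1000000 + i}",
                effect_allele=eff,
                other_allele=oth,
                weight=float(rng.uniform(0.04, 0.22)),
                in_grs12=i in grs12_flagged,
                in_grs51=True,
                haplotype_member=False,
                imputation_r2=r2,
            )
        )
    hap_other = ("G", "C", "A", "C")
    for rsid, eff, oth in zip(
        HAPLOTYPE_RSIDS, HAPLOTYPE_EFFECT_ALLELES, hap_other
    ):
        variants.append(
            VariantWeight(
                rsid=rsid, effect_allele=eff, other_allele=oth, weight=0.0,
                in_grs12=True, in_grs51=True, haplotype_member=True,
                imputation_r2=0.97,
            )
        )
    kept = [v for v in variants
            if v.imputation_r2 is None or v.imputation_r2 >= 0.85]
    excluded = [v for v in variants
                if v.imputation_r2 is not None and v.imputation_r2 < 0.85]
    return WeightSet(variants=kept, excluded=excluded)


def default_variant_freqs(ws: WeightSet, seed: int = 11) -> dict[str, float]:
    """Effect-allele frequencies in (0.05, 0.95), one per scored variant."""
    rng = np.random.default_rng(seed)
    return {
        v.rsid: float(rng.uniform(0.10, 0.90))
        for v in ws.variants
    }


def simulate_genotypes(
    config: SimConfig, weight_set: WeightSet, rng: np.random.Generator | None = None
) -> GenotypeMatrix:
    """Hardy-Weinberg dosages; the 4 haplotype variants share one haplotype
    draw.

    Non-haplotype variants are independent Binomial(2, freq) effect-allele
    counts. For the haplotype members, each person draws two haplotypes:
    with probability ``haplotype_b_freq`` a copy of the risk haplotype
    (effect allele at all four sites), otherwise a background haplotype
    carrying each effect allele independently at a frequency adjusted so
    the marginal allele frequency matches the configured one.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    freqs = config.variant_freqs or default_variant_freqs(weight_set)
    n = config.n
    samples = pd.Index([f"S{i:06d}" for i in range(n)], name="sample")
    hap_set = set(HAPLOTYPE_RSIDS) & {v.rsid for v in weight_set.variants}
    cols: dict[str, np.ndarray] = {}
    counted: dict[str, str] = {}
    for v in weight_set.variants:
        if v.rsid in hap_set:
            continue
        f = freqs.get(v.rsid)
        if f is None:
            raise KeyError(f"no allele frequency configured for {v.rsid}")
        cols[v.rsid] = rng.binomial(2, f, size=n).astype(float)
        counted[v.rsid] = v.effect_allele
    if hap_set:
        q = config.haplotype_b_freq
        hap_members = [v for v in weight_set.variants if v.rsid in hap_set]
        is_b = rng.random((n, 2)) < q  # two haplotypes per person
        for v in hap_members:
            f = freqs.get(v.rsid, 0.5)
            f_bg = min(max((f - q) / (1.0 - q), 0.01), 0.99)
            bg = rng.random((n, 2)) < f_bg
            alleles = np.where(is_b, True, bg)
            cols[v.rsid] = alleles.sum(axis=1).astype(float)
            counted[v.rsid] = v.effect_allele
    dosages = pd.DataFrame(cols, index=samples)
    return GenotypeMatrix(
        dosages=dosages, counted_allele=pd.Series(counted, name="counted_allele")
    )


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd < 0:
        raise ValueError("negative SD")
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def simulate_covariates(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Covariate table with per-ancestry marginal distributions.

    Continuous covariates are truncated normal, binary covariates
    Bernoulli, smoking a three-level categorical, principal components
    standard normal. Covariates are mutually independent within ancestry
    (the published profile gives only marginals).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    groups = list(config.ancestry_mix)
    probs = np.array([config.ancestry_mix[g] for g in groups])
    ancestry = rng.choice(groups, size=config.n, p=probs)
    samples = pd.Index([f"S{i:06d}" for i in range(config.n)], name="id")
    frames = []
    for g in groups:
        mask = ancestry == g
        m = int(mask.sum())
        if m == 0:
            continue
        prof = config.covariate_profile[g]
        d: dict[str, np.ndarray] = {"ancestry": np.repeat(g, m)}
        for c in ("age", "total_chol", "hdl", "sbp", "dbp", "bmi"):
            mean, sd = prof[c]
            d[c] = _truncated_normal(rng, mean, sd, *_CLIPS[c], size=m)
        mean, sd = prof["alcohol"]
        d["alcohol"] = np.maximum(rng.normal(mean, sd, m), 0.0)
        d["sex"] = np.where(rng.random(m) < prof["female"], "female", "male")
        d["smoker"] = rng.choice(
            ["never", "former", "current"], size=m, p=list(prof["smoker"])
        )
        for c in ("diabetes", "bp_treated", "lipid_treated",
                  "family_history", "college"):
            d[c] = rng.random(m) < prof[c]
        for k in range(1, config.n_pcs + 1):
            d[f"pc{k}"] = rng.normal(0.0, 1.0, m)
        d["prior_cvd"] = np.repeat(False, m)
        frames.append(pd.DataFrame(d, index=samples[mask]))
    out = pd.concat(frames).loc[samples]
    return out


def _linear_predictor(cohort: pd.DataFrame, config: SimConfig) -> np.ndarray:
    lp = np.zeros(len(cohort))
    for name, beta in config.covariate_loghrs.items():
        if beta == 0:
            continue
        if name == "male":
            x = (cohort["sex"] == "male").astype(float).to_numpy()
        elif name == "current_smoker":
            x = (cohort["smoker"] == "current").astype(float).to_numpy()
        else:
            x = cohort[name].astype(float).to_numpy()
        sd = x.std(ddof=1)
        if sd == 0:
            continue
        lp += beta * (x - x.mean()) / sd
    return lp


def simulate_outcomes(
    cohort: pd.DataFrame,
    grs_values: pd.Series | None,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Attach follow-up time and event indicator from a Weibull PH model.

    Event times come by inverse-transform sampling from
    S(t | x) = exp(-(t/scale)^shape * exp(lp)); observed time is the
    minimum of event time, exponential dropout and staggered administrative
    censoring. When ``baseline_scale`` is unset it is calibrated so the
    expected cumulative event fraction by ``calibration_horizon`` equals
    ``target_event_rate``.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    lp = _linear_predictor(cohort, config)
    if grs_values is not None:
        g = np.asarray(grs_values.reindex(cohort.index), dtype=float)
        sd = g.std(ddof=1)
        if sd > 0:
            g = (g - g.mean()) / sd
        lp = lp + config.grs_loghr_per_sd * g
    k = config.baseline_shape
    scale = config.baseline_scale
    if scale is None:
        scale = _calibrate_scale(
            lp, k, config.target_event_rate, config.calibration_horizon
        )
    u = rng.uniform(size=len(cohort))
    t_event = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / k)
    t_admin = rng.uniform(
        config.admin_censor_years - config.admin_censor_spread,
        config.admin_censor_years + config.admin_censor_spread,
        size=len(cohort),
    )
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, size=len(cohort))
    else:
        t_drop = np.full(len(cohort), np.inf)
    t_cens = np.minimum(t_admin, t_drop)
    time = np.minimum(t_event, t_cens)
    event = t_event <= t_cens
    out = cohort.copy()
    out["followup_time"] = np.maximum(time, 1e-6)
    out["event"] = event
    return out


def _calibrate_scale(lp, shape, target_rate, horizon) -> float:
    """Weibull scale so the mean event probability by ``horizon`` hits the
    target."""
    elp = np.exp(lp)

    def mean_rate(log_scale):
        lam = np.exp(log_scale)
        return np.mean(1.0 - np.exp(-((horizon / lam) ** shape) * elp)) - target_rate

    return float(np.exp(brentq(mean_rate, -5.0, 15.0)))


def simulate_study(
    config: SimConfig, weight_set: WeightSet | None = None,
    driver_score: str = "GRS12",
):
    """Full synthetic study: weights, genotypes, covariates, scores, outcomes.

    Returns (cohort, genotypes, weight_set, scores) where ``scores`` is a
    frame with raw/standardized scores and tertile labels for both score
    compositions. The hazard is driven by the standardized ``driver_score``.
    """
    from .grs_engine import assign_tertiles, compute_grs, standardize

    rng = np.random.default_rng(config.seed)
    ws = weight_set if weight_set is not None else default_weight_set()
    if config.variant_freqs is None:
        config.variant_freqs = default_variant_freqs(ws)
    genotypes = simulate_genotypes(config, ws, rng)
    cohort = simulate_covariates(config, rng)
    genotypes.dosages.index = cohort.index  # one row per simulated person

    scores = pd.DataFrame(index=cohort.index)
    for which in ("GRS12", "GRS51"):
        sv = compute_grs(genotypes, ws, which=which)
        col = which.lower()
        scores[col] = sv.scores
        scores[f"{col}_z"] = standardize(sv.scores, cohort["ancestry"])
        scores[f"{col}_tertile"] = assign_tertiles(
            sv.scores, cohort["ancestry"]
        )
    cohort = simulate_outcomes(
        cohort, scores[f"{driver_score.lower()}_z"], config, rng
    )
    return cohort, genotypes, ws, scores
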