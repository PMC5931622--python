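"""Survival-model fitting and evaluation for the score pipeline.

Cox proportional-hazards model suites with sequential covariate adjustment
(model "a": score + ancestry principal components; "b": + the classical
risk-function covariates; "c": + family history; "d": + education, body
mass index, treatment flags and alcohol), a proportional-hazards diagnostic
for the score, Harrell's concordance index, Kaplan-Meier event
probabilities with constant-hazard extrapolation beyond observed follow-up,
Hosmer-Lemeshow calibration over risk deciles, and age-adjusted incidence
rates per score tertile from Poisson regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import pc_columns

logger = logging.getLogger("grschd")

#: sequential covariate tiers; sex/smoker are encoded by design_matrix
TIER_B = ["age", "sex", "total_chol", "hdl", "sbp", "dbp", "smoker", "diabetes"]
TIER_C = ["family_history"]
TIER_D = ["college", "bmi", "bp_treated", "lipid_treated", "alcohol"]

MODEL_NAMES = ("1a", "1b", "1c", "1d", "2a", "2b", "2c", "2d")


class FitError(RuntimeError):
    """Raised when a survival model cannot be fit on the given data."""


@dataclass(frozen=True)
class ModelSpec:
    """One entry of the Cox model suite.

    Model family 1 enters the score per standard-deviation unit; family 2
    as tertile indicators against the lowest tertile. Letters a-d add
    covariate tiers cumulatively.
    """

    name: str
    n_pcs: int = 6

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")

    @property
    def grs_form(self) -> str:
        return "per_sd" if self.name.startswith("1") else "tertiles"

    @property
    def tier(self) -> str:
        return self.name[1]

    def covariates(self) -> list[str]:
        cols: list[str] = []
        if self.tier >= "b":
            cols += TIER_B
        if self.tier >= "c":
            cols += TIER_C
        if self.tier >= "d":
            cols += TIER_D
        return cols


@dataclass
class CoxFit:
    """A fitted Cox model with the pieces downstream evaluation needs."""

    params: pd.Series
    ses: pd.Series
    hr_table: pd.DataFrame  # hr, lcl, ucl per coefficient
    log_likelihood: float
    n: int
    events: int
    fitter: object = field(repr=False)
    design: pd.DataFrame = field(repr=False)
    durations: pd.Series = field(repr=False)
    event_observed: pd.Series = field(repr=False)

    def hazard_ratio(self, term: str) -> tuple[float, float, float]:
        row = self.hr_table.loc[term]
        return float(row["hr"]), float(row["lcl"]), float(row["ucl"])


def fit_cox_design(
    X: pd.DataFrame, durations: pd.Series, events: pd.Series
) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron tie handling) on a
    numeric design matrix."""
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if int(events.sum()) < 1:
        raise FitError("no events in cohort")
    X = X.astype(float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise FitError(f"constant design column(s): {const}")
    df = X.copy()
    df["_time"] = durations.astype(float).to_numpy()
    df["_event"] = events.astype(int).to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as e:  # separation / monotone likelihood
        raise FitError(f"Cox model did not converge: {e}") from e
    ci = np.exp(cph.confidence_intervals_)
    hr_table = pd.DataFrame(
        {
            "hr": np.exp(cph.params_),
            "lcl": ci.iloc[:, 0].to_numpy(),
            "ucl": ci.iloc[:, 1].to_numpy(),
        },
        index=cph.params_.index,
    )
    return CoxFit(
        params=cph.params_.copy(),
        ses=cph.standard_errors_.copy(),
        hr_table=hr_table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        events=int(df["_event"].sum()),
        fitter=cph,
        design=X,
        durations=durations.astype(float),
        event_observed=events.astype(int),
    )


def fit_cox(cohort: pd.DataFrame, spec: ModelSpec, score: pd.Series) -> CoxFit:
    """Fit one model of the suite for a given score column.

    ``score`` is the standardized score for family-1 models or the tertile
    labels (1/2/3) for family-2 models.
    """
    from .framingham import design_matrix

    X = pd.DataFrame(index=cohort.index)
    if spec.grs_form == "per_sd":
        if score.nunique() <= 1:
            raise FitError("score column is constant")
        X["grs"] = score.astype(float)
    else:
        X["grs_t2"] = (score == 2).astype(float)
        X["grs_t3"] = (score == 3).astype(float)
    for c in pc_columns(cohort, spec.n_pcs):
        X[c] = cohort[c].astype(float)
    cov = spec.covariates()
    if cov:
        X = pd.concat([X, design_matrix(cohort, cov)], axis=1)
    return fit_cox_design(X, cohort["followup_time"], cohort["event"])


def ph_check(fit: CoxFit, score_term: str = "grs") -> float:
    """Proportional-hazards diagnostic for the score term.

    Score test of association between the score's Schoenfeld residuals and
    follow-up time (identity transform) — the score-test analogue of adding
    a score × time interaction. Returns the p-value; values below 0.10 flag
    possible non-proportionality.
    """
    from lifelines.statistics import proportional_hazard_test

    if score_term not in fit.params.index:
        raise FitError(f"no term {score_term!r} in fitted model")
    df = fit.design.copy()
    df["_time"] = fit.durations.to_numpy()
    df["_event"] = fit.event_observed.to_numpy()
    res = proportional_hazard_test(fit.fitter, df, time_transform="identity")
    p = float(res.summary.loc[score_term, "p"].iloc[0]
              if isinstance(res.summary.loc[score_term, "p"], pd.Series)
              else res.summary.loc[score_term, "p"])
    if p < 0.10:
        logger.warning("PH diagnostic for %s: p = %.3f < 0.10", score_term, p)
    return p


def harrells_c(risk, time, event) -> float:
    """Harrell's concordance index for a risk score under right censoring.

    Fraction of comparable pairs ordered concordantly (higher risk, earlier
    event), ties in risk counted 1/2.
    """
    from lifelines.utils import concordance_index

    risk = np.asarray(risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) < 2:
        raise FitError("need at least 2 subjects")
    try:
        return float(concordance_index(time, -risk, event))
    except ZeroDivisionError as e:
        raise FitError("no comparable pairs") from e


def compare_concordance(
    risk_base, risk_updated, time, event, B: int = 500, seed: int = 0
) -> tuple[float, float, float]:
    """(C_base, C_updated, two-sided p) via a paired bootstrap over subjects."""
    rng = np.random.default_rng(seed)
    rb = np.asarray(risk_base, float)
    ru = np.asarray(risk_updated, float)
    t = np.asarray(time, float)
    e = np.asarray(event, int)
    c0, c1 = harrells_c(rb, t, e), harrells_c(ru, t, e)
    n = len(t)
    deltas = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, n)
        try:
            deltas[b] = harrells_c(ru[idx], t[idx], e[idx]) - harrells_c(
                rb[idx], t[idx], e[idx]
            )
        except FitError:
            deltas[b] = np.nan
    deltas = deltas[np.isfinite(deltas)]
    se = deltas.std(ddof=1)
    if se == 0:
        return c0, c1, 1.0
    z = (c1 - c0) / se
    return c0, c1, float(2 * stats.norm.sf(abs(z)))


def km_survival(
    time, event, t_star: float, extrapolate: bool = True
) -> float:
    """Kaplan-Meier event probability by ``t_star``.

    Beyond the last observed time the curve is extended with a constant
    hazard equal to the average hazard over the final observed year —
    needed because 10-year risk must be read off cohorts with shorter mean
    follow-up.
    """
    from lifelines import KaplanMeierFitter

    if t_star <= 0:
        raise ValueError("t_star must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise FitError("empty group")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    t_last = float(time.max())
    if t_star <= t_last:
        return float(1.0 - kmf.predict(t_star))
    if not extrapolate:
        if event.sum() == 0:
            raise FitError(
                "t_star beyond all-censored data and extrapolation disabled"
            )
        return float(1.0 - kmf.predict(t_last))
    s_last = float(kmf.predict(t_last))
    if s_last <= 0.0:
        return 1.0
    window = min(1.0, t_last)
    s_prev = float(kmf.predict(t_last - window)) if window > 0 else 1.0
    lam = (np.log(s_prev) - np.log(s_last)) / window if window > 0 else 0.0
    s_star = s_last * np.exp(-lam * (t_star - t_last))
    return float(1.0 - s_star)


def hosmer_lemeshow(
    pred_risk, time, event, bins: int = 10, t_star: float = 10.0
) -> tuple[float, int, float]:
    """Calibration chi-square over deciles of predicted risk.

    Observed events per bin come from the Kaplan-Meier event probability at
    ``t_star`` (extrapolated when follow-up is shorter); expected events are
    the sum of predicted risks. chi2 = sum (O-E)^2 / (E (1 - E/n_bin)),
    reported against bins-1 degrees of freedom.
    """
    pred_risk = pd.Series(np.asarray(pred_risk, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n = len(pred_risk)
    if n < bins:
        raise FitError("fewer subjects than bins")
    try:
        labels = pd.qcut(pred_risk, bins, labels=False, duplicates="drop")
    except ValueError:
        labels = pd.Series(0.0, index=pred_risk.index)
    if labels.isna().any():  # ties collapsed every edge -> one bin
        labels = pd.Series(0.0, index=pred_risk.index)
    n_labels = int(labels.max()) + 1
    if n_labels < bins:
        logger.info(
            "Hosmer-Lemeshow: tied risks collapsed %d bins to %d",
            bins, n_labels,
        )
    chi2 = 0.0
    used = 0
    for b in range(n_labels):
        mask = (labels == b).to_numpy()
        n_b = int(mask.sum())
        if n_b == 0:
            logger.info("Hosmer-Lemeshow: empty bin %d merged", b)
            continue
        p_obs = km_survival(time[mask], event[mask], t_star)
        obs = n_b * p_obs
        exp = float(pred_risk[mask].sum())
        if exp <= 0 or exp >= n_b:
            exp = min(max(exp, 1e-8), n_b - 1e-8)
        chi2 += (obs - exp) ** 2 / (exp * (1.0 - exp / n_b))
        used += 1
    df = used - 1
    p = float(stats.chi2.sf(chi2, df)) if df >= 1 else float("nan")
    return float(chi2), df, p


def cox_predicted_risk(
    fit: CoxFit, X: pd.DataFrame, t_star: float = 10.0
) -> pd.Series:
    """Per-individual event probability by ``t_star`` from a fitted Cox model.

    Uses the model's baseline cumulative hazard; beyond the last observed
    time each individual's cumulative hazard is extended at the constant
    rate observed over the final year of follow-up.
    """
    H = fit.fitter.predict_cumulative_hazard(X.astype(float))
    times = H.index.to_numpy(dtype=float)
    t_last = float(times.max())
    if t_star <= t_last:
        pos = np.searchsorted(times, t_star, side="right") - 1
        h_star = H.iloc[max(pos, 0)].to_numpy()
    else:
        h_last = H.iloc[-1].to_numpy()
        window = min(1.0, t_last)
        pos = np.searchsorted(times, t_last - window, side="right") - 1
        h_prev = H.iloc[max(pos, 0)].to_numpy()
        lam = (h_last - h_prev) / window if window > 0 else 0.0
        h_star = h_last + lam * (t_star - t_last)
    risks = 1.0 - np.exp(-h_star)
    return pd.Series(risks, index=X.index, name="cox_risk")


def age_adjusted_rates(
    cohort: pd.DataFrame, tertile_labels: pd.Series
) -> pd.DataFrame:
    """Age-adjusted incidence rate (events per person-year) per score tertile.

    Poisson regression of event counts on tertile indicators and age with a
    log person-time offset; rates are predicted at the cohort mean age.
    Returns a frame indexed by tertile with columns rate, se.
    """
    import statsmodels.api as sm

    pt = cohort["followup_time"].astype(float)
    if (pt <= 0).any():
        raise FitError("non-positive person-time")
    for t in (1, 2, 3):
        if pt[tertile_labels == t].sum() <= 0:
            raise FitError(f"tertile {t} has zero person-time")
    X = pd.DataFrame(
        {
            "t2": (tertile_labels == 2).astype(float),
            "t3": (tertile_labels == 3).astype(float),
            "age": cohort["age"].astype(float),
        },
        index=cohort.index,
    )
    X = sm.add_constant(X)
    model = sm.GLM(
        cohort["event"].astype(int),
        X,
        family=sm.families.Poisson(),
        offset=np.log(pt),
    )
    res = model.fit()
    mean_age = float(cohort["age"].mean())
    newX = pd.DataFrame(
        {
            "const": 1.0,
            "t2": [0.0, 1.0, 0.0],
            "t3": [0.0, 0.0, 1.0],
            "age": mean_age,
        },
        index=pd.Index([1, 2, 3], name="tertile"),
    )
    pred = res.get_prediction(newX, offset=np.zeros(3))
    frame = pred.summary_frame()
    return pd.DataFrame(
        {"rate": frame["mean"].to_numpy(), "se": frame["mean_se"].to_numpy()},
        index=newX.index,
    )
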