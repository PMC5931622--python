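"""10-year coronary heart disease risk from the Framingham risk function.

Implements the sex-specific categorical (risk-factor category) equation of
Wilson et al. (1998): a Cox-model linear predictor over age and categories
of total cholesterol, HDL cholesterol, blood pressure (JNC-V categories,
the higher of the systolic and diastolic category governing), diabetes and
current smoking, transformed to a 10-year probability through the published
baseline survival,

    p = 1 - S0(10) ** exp(L - G),

with L the individual's linear predictor and G its population mean. The
coefficients ship as an auditable CSV constants file whose checksum is
verified at load time. Predicted probabilities map onto four clinical
categories: low (<10%), intermediate-low (10-14.9%), intermediate-high
(15-19.9%) and high (>= 20%).
"""

from __future__ import annotations

import hashlib
from importlib import resources

import numpy as np
import pandas as pd

from .io_formats import FRS_COMPONENTS

#: sha256 of the shipped Wilson (1998) coefficient file
COEFFICIENTS_SHA256 = (
    "a5d0f9ec0eb2b27999a89236316ee7bc292799faa191ca7d14a5d909615644b3"
)

#: left-closed category boundaries: 10-14.9% is intermediate-low,
#: 15-19.9% intermediate-high, >= 20% high
RISK_CUTPOINTS = (0.10, 0.15, 0.20)
RISK_CATEGORIES = ("low", "intermediate_low", "intermediate_high", "high")


class RiskInputError(ValueError):
    """Raised for covariates outside the risk function's domain."""


def load_coefficients(path=None) -> dict:
    """Load the sex-specific coefficient tables (default: shipped file)."""
    if path is None:
        ref = resources.files("grschd.data").joinpath("wilson1998.csv")
        raw = ref.read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != COEFFICIENTS_SHA256:
            raise RiskInputError(
                "shipped coefficient file failed its checksum; "
                f"got {digest}"
            )
        df = pd.read_csv(ref.open("r"))
    else:
        df = pd.read_csv(path)
    out: dict = {}
    for sex, sub in df.groupby("sex"):
        out[sex] = {
            (t, l): float(c)
            for t, l, c in zip(sub["term"], sub["level"], sub["coefficient"])
        }
    if not {"male", "female"} <= set(out):
        raise RiskInputError("coefficient file must cover both sexes")
    return out


def _tc_level(tc: float) -> str:
    if tc < 160:
        return "lt160"
    if tc < 200:
        return "160_199"
    if tc < 240:
        return "200_239"
    if tc < 280:
        return "240_279"
    return "ge280"


def _hdl_level(hdl: float) -> str:
    if hdl < 35:
        return "lt35"
    if hdl < 45:
        return "35_44"
    if hdl < 50:
        return "45_49"
    if hdl < 60:
        return "50_59"
    return "ge60"


def _bp_level(sbp: float, dbp: float) -> str:
    """JNC-V category; when SBP and DBP disagree the higher category rules."""
    def cat(s, d):
        if s >= 160 or d >= 100:
            return 4
        if s >= 140 or d >= 90:
            return 3
        if s >= 130 or d >= 85:
            return 2
        if s >= 120 or d >= 80:
            return 1
        return 0

    return ["optimal", "normal", "high_normal", "stage1", "stage2_4"][cat(sbp, dbp)]


def _is_male(sex) -> bool:
    if isinstance(sex, str):
        s = sex.strip().lower()
        if s in ("m", "male", "1"):
            return True
        if s in ("f", "female", "0"):
            return False
        raise RiskInputError(f"unrecognized sex {sex!r}")
    return bool(int(sex) == 1)


def _is_current_smoker(smoker) -> bool:
    if isinstance(smoker, str):
        return smoker.strip().lower() == "current"
    return bool(smoker)


def frs_10yr_row(row, coefficients: dict | None = None) -> float:
    """10-year CHD probability for a single individual (mapping-like row)."""
    coef = coefficients if coefficients is not None else _COEF
    for c in FRS_COMPONENTS:
        if c not in row or pd.isna(row[c]):
            raise RiskInputError(f"missing risk-function component {c!r}")
    if not (row["total_chol"] > 0 and row["hdl"] > 0 and row["sbp"] > 0
            and row["dbp"] > 0):
        raise RiskInputError("lipid and blood-pressure values must be positive")
    tab = coef["male"] if _is_male(row["sex"]) else coef["female"]
    age = float(row["age"])
    lp = tab[("age", "per_year")] * age
    lp += tab.get(("age_squared", "per_year2"), 0.0) * age * age
    lp += tab[("total_chol", _tc_level(float(row["total_chol"])))]
    lp += tab[("hdl", _hdl_level(float(row["hdl"])))]
    lp += tab[("bp", _bp_level(float(row["sbp"]), float(row["dbp"])))]
    if bool(row["diabetes"]):
        lp += tab[("diabetes", "yes")]
    if _is_current_smoker(row["smoker"]):
        lp += tab[("smoker", "yes")]
    s0 = tab[("baseline_survival_10yr", "const")]
    g = tab[("mean_lp", "const")]
    p = 1.0 - s0 ** np.exp(lp - g)
    return float(min(max(p, 0.0), 1.0))


def frs_10yr(cohort: pd.DataFrame, coefficients: dict | None = None) -> pd.Series:
    """Vectorized 10-year risk over a cohort table (deterministic, row-order
    invariant)."""
    risks = cohort.apply(lambda r: frs_10yr_row(r, coefficients), axis=1)
    return risks.rename("frs_risk")


def risk_category(p) -> np.ndarray | str:
    """Map probabilities to the four clinical categories (left-closed cuts)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise RiskInputError("risk probabilities must lie in [0, 1]")
    idx = np.searchsorted(RISK_CUTPOINTS, arr, side="right")
    out = np.asarray(RISK_CATEGORIES, dtype=object)[idx]
    return out if arr.shape else str(out)


def category_index(categories) -> np.ndarray:
    """Ordinal position (0..3) of each category label."""
    order = {c: i for i, c in enumerate(RISK_CATEGORIES)}
    return np.asarray([order[c] for c in np.atleast_1d(categories)])


def updated_risk(
    cohort: pd.DataFrame,
    base_components: list[str],
    grs_z: pd.Series | None = None,
    t_star: float = 10.0,
):
    """10-year risk from a proportional-hazards fit on the cohort itself.

    Fits a Cox model on the risk-function components (plus the standardized
    score when given) and converts each individual's cumulative hazard at
    ``t_star`` years to an event probability, extrapolating with a constant
    hazard beyond the observed follow-up. Returns (risks, fit).
    """
    from .survival_eval import cox_predicted_risk, fit_cox_design

    cols = list(base_components)
    X = design_matrix(cohort, cols)
    if grs_z is not None:
        X = X.assign(grs_z=grs_z.reindex(X.index))
    fit = fit_cox_design(
        X, cohort.loc[X.index, "followup_time"], cohort.loc[X.index, "event"]
    )
    risks = cox_predicted_risk(fit, X, t_star=t_star)
    name = "frs_grs_risk" if grs_z is not None else "frs_components_risk"
    return risks.rename(name), fit


def design_matrix(cohort: pd.DataFrame, components: list[str]) -> pd.DataFrame:
    """Numeric design columns for model fitting (sex/smoking encoded)."""
    out = {}
    for c in components:
        col = cohort[c]
        if c == "sex":
            out["male"] = col.map(_is_male).astype(float)
        elif c == "smoker":
            out["current_smoker"] = col.map(_is_current_smoker).astype(float)
        else:
            out[c] = col.astype(float)
    return pd.DataFrame(out, index=cohort.index)


_COEF = load_coefficients()
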