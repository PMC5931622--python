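"""End-to-end orchestration: simulate -> score -> evaluate -> report.

Per-ancestry analyses run independently and are then pooled by
fixed-effects meta-analysis, mirroring a strata-then-meta design. Outputs
are three report tables (model-suite hazard ratios; calibration,
discrimination and reclassification metrics; screening utility) plus a JSON
manifest carrying the seed and input checksums for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_sim import SimConfig, simulate_study
from .framingham import frs_10yr, updated_risk
from .grs_engine import ScoringError
from .meta_fixed import StudyEstimate, pool_fixed
from .reclass_metrics import build_reclass_table, category_nri, idi
from .survival_eval import (
    FitError,
    ModelSpec,
    compare_concordance,
    fit_cox,
    harrells_c,
    hosmer_lemeshow,
    ph_check,
)
from .clinical_utility import screening_table
from .io_formats import FRS_COMPONENTS

logger = logging.getLogger("grschd")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation mode)."""

    sim: SimConfig = field(default_factory=SimConfig)
    scores: tuple[str, ...] = ("GRS12", "GRS51")
    models: tuple[str, ...] = ("1a", "1b", "1c", "1d", "2a", "2b", "2c", "2d")
    n_pcs: int = 6
    t_star: float = 10.0
    bootstrap_B: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **{
            k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
        })

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _model_rows(cohort, scores, run: RunConfig, ancestry: str) -> list[dict]:
    rows = []
    sub = cohort[cohort["ancestry"] == ancestry]
    for score_name in run.scores:
        col = score_name.lower()
        for model in run.models:
            spec = ModelSpec(model, n_pcs=run.n_pcs)
            s = (
                scores.loc[sub.index, f"{col}_z"]
                if spec.grs_form == "per_sd"
                else scores.loc[sub.index, f"{col}_tertile"]
            )
            try:
                fit = fit_cox(sub, spec, s)
            except FitError as e:
                logger.warning("%s %s %s: %s", ancestry, score_name, model, e)
                continue
            terms = (
                [("per_sd", "grs")] if spec.grs_form == "per_sd"
                else [("t2", "grs_t2"), ("t3", "grs_t3")]
            )
            for term, coef in terms:
                hr, lcl, ucl = fit.hazard_ratio(coef)
                rows.append(
                    {
                        "ancestry": ancestry, "score": score_name,
                        "model": model, "term": term,
                        "hr": hr, "lcl": lcl, "ucl": ucl,
                        "n": fit.n, "events": fit.events,
                    }
                )
            if spec.grs_form == "per_sd" and model == "1a":
                rows[-1]["ph_p"] = ph_check(fit, "grs")
    return rows


def _pool_rows(hr_rows: pd.DataFrame) -> list[dict]:
    pooled = []
    for (score, model, term), grp in hr_rows.groupby(["score", "model", "term"]):
        ests = [
            StudyEstimate(r.ancestry, r.hr, r.lcl, r.ucl)
            for r in grp.itertuples()
            if 0 < r.lcl < r.hr < r.ucl
        ]
        if not ests:
            continue
        res = pool_fixed(ests)
        pooled.append(
            {
                "ancestry": "combined", "score": score, "model": model,
                "term": term, "hr": res.hr, "lcl": res.lcl, "ucl": res.ucl,
                "q": res.q, "p_heterogeneity": res.p_heterogeneity,
                "i2": res.i2,
            }
        )
    return pooled


def _evaluate_stratum(cohort, scores, run: RunConfig, label: str) -> list[dict]:
    """Calibration / discrimination / reclassification rows for one stratum."""
    out = []
    base_risk = frs_10yr(cohort)
    time = cohort["followup_time"].to_numpy(float)
    event = cohort["event"].to_numpy(int)
    comp = list(FRS_COMPONENTS)
    for score_name in run.scores:
        col = f"{score_name.lower()}_z"
        grs_z = scores.loc[cohort.index, col]
        try:
            upd, _ = updated_risk(cohort, comp, grs_z, t_star=run.t_star)
            rows = _score_metric_rows(
                cohort, base_risk, upd, time, event, run, label, score_name
            )
        except (FitError, ScoringError) as e:
            logger.warning("stratum %s, %s: %s", label, score_name, e)
            continue
        out.extend(rows)
    return out


def _score_metric_rows(
    cohort, base_risk, upd, time, event, run: RunConfig, label, score_name
) -> list[dict]:
    out: list[dict] = []
    c0, c1, p_c = compare_concordance(
        base_risk, upd, time, event, B=min(run.bootstrap_B, 200),
        seed=run.seed + 13,
    )
    hl0 = hosmer_lemeshow(base_risk, time, event, t_star=run.t_star)
    hl1 = hosmer_lemeshow(upd, time, event, t_star=run.t_star)
    table = build_reclass_table(base_risk, upd, time, event, run.t_star)
    nri = category_nri(table)
    idi_val = idi(base_risk, upd, time, event, run.t_star)
    out.append(
        {
            "stratum": label, "score": score_name,
            "c_base": c0, "c_updated": c1, "c_diff_p": p_c,
            "hl_chi2_base": hl0[0], "hl_df_base": hl0[1],
            "hl_p_base": hl0[2],
            "hl_chi2_updated": hl1[0], "hl_df_updated": hl1[1],
            "hl_p_updated": hl1[2],
            "nri_events": nri.nri_events,
            "nri_nonevents": nri.nri_nonevents,
            "nri_total": nri.nri_total,
            "idi_percent": idi_val,
        }
    )
    for row in screening_table(table, score_name.lower()):
        row["stratum"] = label
        row["score"] = score_name
        out.append(row)
    return out


def run_pipeline(run: RunConfig, outdir) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns a dict with the in-memory result frames; writes hazard-ratio,
    evaluation and screening CSVs plus a manifest JSON into ``outdir``.
    Idempotent given the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run.sim.seed = int(run.seed)
    stage = "simulate"
    try:
        cohort, genotypes, ws, scores = simulate_study(run.sim)
        stage = "evaluate_models"
        ancestries = sorted(cohort["ancestry"].unique())
        hr_rows = []
        for g in ancestries:
            hr_rows += _model_rows(cohort, scores, run, g)
        hr_df = pd.DataFrame(hr_rows)
        pooled = pd.DataFrame(_pool_rows(hr_df))
        table2 = pd.concat([hr_df, pooled], ignore_index=True)

        stage = "evaluate_metrics"
        eval_rows = []
        for g in ancestries:
            eval_rows += _evaluate_stratum(
                cohort[cohort["ancestry"] == g], scores, run, g
            )
        eval_rows += _evaluate_stratum(cohort, scores, run, "combined")
        eval_df = pd.DataFrame(eval_rows)
        metrics = eval_df[eval_df["c_base"].notna()] if "c_base" in eval_df else eval_df
        screening = (
            eval_df[eval_df["arm"].notna()] if "arm" in eval_df else pd.DataFrame()
        )

        stage = "report"
        results = {
            "cohort": cohort, "scores": scores,
            "hazard_ratios": table2, "metrics": metrics,
            "screening": screening,
        }
        report_tables(results, outdir, run)
        return results
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        (outdir / "FAILED_STAGE.txt").write_text(stage + "\n")
        raise


def _round_cols(df: pd.DataFrame, cols: list[str], nd: int) -> pd.DataFrame:
    df = df.copy()
    for c in cols:
        if c in df.columns:
            df[c] = df[c].astype(float).round(nd)
    return df


def report_tables(results: dict, outdir, run: RunConfig) -> None:
    """Write the three report CSVs and the manifest (fixed column orders,
    hazard ratios and reclassification metrics to two decimals)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hr = _round_cols(results["hazard_ratios"], ["hr", "lcl", "ucl"], 2)
    hr.to_csv(outdir / "hazard_ratios.csv", index=False)
    metrics = _round_cols(
        results["metrics"],
        ["nri_events", "nri_nonevents", "nri_total", "idi_percent"], 2,
    )
    metrics.to_csv(outdir / "evaluation_metrics.csv", index=False)
    results["screening"].to_csv(outdir / "screening_utility.csv", index=False)
    manifest = {
        "package": "grschd",
        "version": __version__,
        "seed": int(run.seed),
        "n": int(run.sim.n),
        "scores": list(run.scores),
        "models": list(run.models),
        "checksums": {
            name: hashlib.sha256(
                (outdir / name).read_bytes()
            ).hexdigest()
            for name in (
                "hazard_ratios.csv", "evaluation_metrics.csv",
                "screening_utility.csv",
            )
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
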