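"""Published summary estimates used as worked-example inputs.

Per-ancestry hazard ratios (with 95% CIs, as printed to two decimals) for
the two genetic risk scores from a published multi-ethnic cohort
evaluation, plus the screening-table inputs (treated counts A and expected
10-year events B per stratum). The package recomputes the pooled
meta-analysis rows and the screening arithmetic from these inputs at run
time; the printed pooled/derived values are kept alongside for comparison.
"""

from __future__ import annotations

# (ancestry, score, model, term) -> (hr, lcl, ucl); term is "per_sd" for
# family-1 models and "t2"/"t3" for the tertile contrasts of Model 2a
PER_ANCESTRY_HR: dict[tuple[str, str, str, str], tuple[float, float, float]] = {
    ("AFR", "GRS12", "1a", "per_sd"): (1.17, 0.98, 1.40),
    ("AFR", "GRS12", "1b", "per_sd"): (1.16, 0.97, 1.39),
    ("AFR", "GRS12", "1c", "per_sd"): (1.17, 0.97, 1.40),
    ("AFR", "GRS12", "1d", "per_sd"): (1.20, 1.00, 1.44),
    ("AFR", "GRS12", "2a", "t2"): (1.33, 0.82, 2.17),
    ("AFR", "GRS12", "2a", "t3"): (1.81, 1.14, 2.88),
    ("AFR", "GRS51", "1a", "per_sd"): (1.11, 0.92, 1.34),
    ("AFR", "GRS51", "1b", "per_sd"): (1.09, 0.90, 1.32),
    ("AFR", "GRS51", "1c", "per_sd"): (1.09, 0.90, 1.32),
    ("AFR", "GRS51", "1d", "per_sd"): (1.14, 0.94, 1.39),
    ("AFR", "GRS51", "2a", "t2"): (1.14, 0.71, 1.82),
    ("AFR", "GRS51", "2a", "t3"): (1.42, 0.90, 2.23),
    ("LAT", "GRS12", "1a", "per_sd"): (1.18, 1.01, 1.37),
    ("LAT", "GRS12", "1b", "per_sd"): (1.23, 1.05, 1.43),
    ("LAT", "GRS12", "1c", "per_sd"): (1.23, 1.05, 1.44),
    ("LAT", "GRS12", "1d", "per_sd"): (1.19, 1.01, 1.40),
    ("LAT", "GRS12", "2a", "t2"): (0.94, 0.62, 1.41),
    ("LAT", "GRS12", "2a", "t3"): (1.59, 1.09, 2.31),
    ("LAT", "GRS51", "1a", "per_sd"): (1.19, 1.02, 1.39),
    ("LAT", "GRS51", "1b", "per_sd"): (1.19, 1.02, 1.39),
    ("LAT", "GRS51", "1c", "per_sd"): (1.19, 1.02, 1.38),
    ("LAT", "GRS51", "1d", "per_sd"): (1.16, 0.99, 1.36),
    ("LAT", "GRS51", "2a", "t2"): (0.99, 0.65, 1.48),
    ("LAT", "GRS51", "2a", "t3"): (1.61, 1.12, 2.34),
    ("EA", "GRS12", "1a", "per_sd"): (1.09, 0.93, 1.29),
    ("EA", "GRS12", "1b", "per_sd"): (1.10, 0.93, 1.30),
    ("EA", "GRS12", "1c", "per_sd"): (1.10, 0.94, 1.30),
    ("EA", "GRS12", "1d", "per_sd"): (1.07, 0.91, 1.28),
    ("EA", "GRS12", "2a", "t2"): (0.87, 0.57, 1.33),
    ("EA", "GRS12", "2a", "t3"): (1.19, 0.79, 1.79),
    ("EA", "GRS51", "1a", "per_sd"): (1.20, 1.02, 1.41),
    ("EA", "GRS51", "1b", "per_sd"): (1.24, 1.05, 1.46),
    ("EA", "GRS51", "1c", "per_sd"): (1.23, 1.04, 1.46),
    ("EA", "GRS51", "1d", "per_sd"): (1.18, 0.99, 1.40),
    ("EA", "GRS51", "2a", "t2"): (1.33, 0.87, 2.03),
    ("EA", "GRS51", "2a", "t3"): (1.48, 0.98, 2.25),
}

#: published pooled (fixed-effects) rows, for comparison with recomputation
PUBLISHED_POOLED: dict[tuple[str, str, str], tuple[float, float, float]] = {
    ("GRS12", "1a", "per_sd"): (1.15, 1.04, 1.26),
    ("GRS51", "1a", "per_sd"): (1.17, 1.06, 1.29),
    ("GRS12", "2a", "t3"): (1.49, 1.18, 1.89),
    ("GRS51", "2a", "t3"): (1.52, 1.20, 1.92),
}

# screening-table inputs: stratum -> arm -> (treated A, expected events B)
SCREENING_INPUTS: dict[str, dict[str, tuple[int, float]]] = {
    "AFR": {
        "one_stage": (473, 41.0),
        "two_stage_grs12": (33, 4.0),
        "two_stage_grs51": (12, 3.0),
    },
    "LAT": {
        "one_stage": (876, 48.0),
        "two_stage_grs12": (31, 6.0),
        "two_stage_grs51": (39, 9.0),
    },
    "EA": {
        "one_stage": (830, 46.0),
        "two_stage_grs12": (19, 2.0),
        "two_stage_grs51": (24, 2.0),
    },
    "combined": {
        "one_stage": (2179, 135.0),
        "two_stage_grs12": (59, 11.0),
        "two_stage_grs51": (30, 7.0),
    },
}

#: published one-stage NNTs per stratum (two of which are not reproducible
#: from the printed A and C under any standard rounding; see docs)
PUBLISHED_ONE_STAGE_NNT = {"AFR": 47, "LAT": 73, "EA": 75, "combined": 68}
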