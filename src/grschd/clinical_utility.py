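"""One-stage vs two-stage screening: events prevented, NNT and efficiency.

One-stage screening treats everyone at intermediate 10-year risk with a
statin; two-stage screening treats only the subjects a genetic score
up-reclassifies out of the intermediate band. Under an assumed 24% relative
reduction in coronary events on treatment, each strategy yields an expected
number of events prevented (C = B x 0.24, with B the expected 10-year
events among the treated) and a number needed to treat (D = A / C, with A
the treated count). The efficiency of two-stage screening is the ratio of
the one-stage to the two-stage NNT.

Rounding mirrors the reporting convention: C is rounded half-up to one
decimal before D, D to the nearest integer, the efficiency ratio to one
decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .framingham import RISK_CATEGORIES
from .reclass_metrics import ReclassTable

#: assumed relative reduction in major coronary events on statin treatment
STATIN_RRR = 0.24

_INTERMEDIATE_ROWS = (1, 2)  # intermediate_low, intermediate_high


class UtilityError(ValueError):
    """Raised for arithmetic that has no defined answer (e.g. NNT at C=0)."""


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10.0**decimals
    return math.floor(x * scale + 0.5) / scale


def events_prevented(expected_events: float, rrr: float = STATIN_RRR) -> float:
    """Expected events prevented by treating a group with B expected events,
    rounded half-up to one decimal."""
    if expected_events < 0:
        raise UtilityError("expected events must be non-negative")
    return _round_half_up(expected_events * rrr, 1)


def nnt(treated: float, prevented: float) -> int:
    """Individuals needed to treat to prevent one event, nearest integer."""
    if prevented <= 0:
        raise UtilityError("no events prevented; NNT is undefined")
    return int(_round_half_up(treated / prevented, 0))


@dataclass(frozen=True)
class ScreeningArm:
    """One screening strategy's accounting row (A, B, C, D)."""

    label: str
    treated: int
    expected_events_10yr: float

    @property
    def events_prevented(self) -> float:
        return events_prevented(self.expected_events_10yr)

    @property
    def nnt(self) -> int:
        return nnt(self.treated, self.events_prevented)


def efficiency_ratio(nnt_one_stage: float, nnt_two_stage: float) -> float:
    """NNT ratio of one-stage to two-stage screening, one decimal."""
    if nnt_two_stage == 0:
        raise UtilityError("two-stage NNT of zero")
    return _round_half_up(nnt_one_stage / nnt_two_stage, 1)


def screening_comparison(one_stage: ScreeningArm, two_stage: ScreeningArm) -> float:
    """Efficiency of two-stage vs one-stage screening: the NNT ratio, one
    decimal."""
    return efficiency_ratio(one_stage.nnt, two_stage.nnt)


def upreclassified_subset(table: ReclassTable) -> tuple[int, float]:
    """Treated count and expected events for the two-stage arm.

    A = baseline-intermediate subjects whose updated category is higher than
    their baseline category; B = their Kaplan-Meier expected 10-year events.
    """
    k = len(RISK_CATEGORIES)
    a = 0
    b = 0.0
    for i in _INTERMEDIATE_ROWS:
        for j in range(i + 1, k):
            a += int(table.counts[i, j])
            b += float(table.expected_events[i, j])
    return a, b


def intermediate_subset(table: ReclassTable) -> tuple[int, float]:
    """Treated count and expected events for the one-stage arm (everyone at
    baseline-intermediate risk)."""
    a = int(table.counts[list(_INTERMEDIATE_ROWS), :].sum())
    b = float(table.expected_events[list(_INTERMEDIATE_ROWS), :].sum())
    return a, b


def screening_table(
    table: ReclassTable, score_label: str
) -> list[dict]:
    """Table rows (A, B, C, D, efficiency) for one score's reclassification."""
    a1, b1 = intermediate_subset(table)
    a2, b2 = upreclassified_subset(table)
    one = ScreeningArm("one_stage", a1, b1)
    two = ScreeningArm(f"two_stage_{score_label}", a2, b2)
    rows = []
    for arm, eff_of in ((one, lambda: 1.0),
                        (two, lambda: screening_comparison(one, two))):
        row = {
            "arm": arm.label, "treated": arm.treated,
            "expected_events": _round_half_up(arm.expected_events_10yr, 0),
            "events_prevented": arm.events_prevented,
        }
        try:
            row["nnt"] = arm.nnt
            row["efficiency"] = eff_of()
        except UtilityError:  # no expected events in an arm of a small cohort
            row["nnt"] = np.nan
            row["efficiency"] = np.nan
        rows.append(row)
    return rows
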