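"""Outcome measures and guideline comparison tables.

Patient outcome: probability of a first CHD or stroke event by age 80.
Clinical policy: lifetime number-needed-to-treat (NNT) and events avoided
per 1,000 patients, both measured against the no-treatment reference run.
Health policy: discounted medication cost per event avoided, and the
efficient frontier of strategies in the (expected cost, event probability)
plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_engine import CohortTrajectory
from .metabolic_states import ValidationError

__all__ = [
    "published_guideline_impact",
    "OutcomeSummary",
    "Dominance",
    "UndefinedNNTError",
    "nnt",
    "events_avoided_per_1000",
    "cost_per_event_avoided",
    "incremental_cost_per_event",
    "efficient_frontier",
    "summarize_trajectory",
    "comparison_table",
]


def published_guideline_impact() -> pd.DataFrame:
    """Published per-guideline impact measures shipped as reference data.

    One row per (guideline, sex) with NNT, events avoided per 1,000,
    medication cost per event avoided, and — where reported — expected
    discounted cost and event probability.  Used for internal-consistency
    checks of the outcome arithmetic; not a model output.
    """
    from importlib import resources

    with resources.files("guidemark.data").joinpath(
        "published_guideline_impact.csv"
    ).open() as fh:
        return pd.read_csv(fh)


class UndefinedNNTError(ValueError):
    """Raised when a strategy avoids no events relative to the reference."""


@dataclass(frozen=True)
class OutcomeSummary:
    """Headline outcome measures for one guideline versus the reference."""

    guideline: str
    p_event: float
    expected_cost: float
    nnt: Optional[float] = None
    events_avoided_per_1000: Optional[float] = None
    cost_per_event_avoided: Optional[float] = None
    ever_treated_fraction: Optional[float] = None


def nnt(p_reference: float, p_guideline: float) -> float:
    """Lifetime number-needed-to-treat: 1 / absolute risk reduction."""
    arr = p_reference - p_guideline
    if arr <= 0:
        raise UndefinedNNTError(
            f"NNT undefined: reference risk {p_reference} <= guideline risk {p_guideline}"
        )
    return 1.0 / arr


def events_avoided_per_1000(
    p_reference: float,
    p_guideline: float,
    ever_treated_fraction: Optional[float] = None,
) -> float:
    """Events avoided per 1,000 patients.

    Default denominator is the whole cohort: ``1000 * ARR``, the reciprocal
    of the NNT scaled by 1,000.  Passing ``ever_treated_fraction`` switches
    to a per-ever-treated denominator.
    """
    arr = p_reference - p_guideline
    if arr < 0:
        raise UndefinedNNTError("guideline risk exceeds reference risk")
    if ever_treated_fraction is not None:
        if ever_treated_fraction <= 0:
            raise ValidationError("ever_treated_fraction must be > 0 for that mode")
        return 1000.0 * arr / ever_treated_fraction
    return 1000.0 * arr


def cost_per_event_avoided(
    expected_cost_guideline: float, p_reference: float, p_guideline: float
) -> float:
    """Discounted medication cost per event avoided versus no treatment.

    The no-treatment reference has zero medication cost, so the numerator
    is the guideline's own expected cost.
    """
    arr = p_reference - p_guideline
    if arr <= 0:
        raise UndefinedNNTError("cost per event avoided undefined: no risk reduction")
    return expected_cost_guideline / arr


@dataclass(frozen=True)
class Dominance:
    """Signal that one strategy dominates another (or the comparison is
    undefined) in an incremental cost-effectiveness quotient."""

    dominant: Optional[str] = None
    undefined: bool = False


def incremental_cost_per_event(a: OutcomeSummary, b: OutcomeSummary):
    """Incremental cost per additional event avoided going from a to b.

    Returns a float when b avoids strictly more events than a; otherwise a
    :class:`Dominance` signal (b dominated, or the quotient undefined when
    both strategies have identical event probability).
    """
    d_events = a.p_event - b.p_event  # events avoided by moving a -> b
    d_cost = b.expected_cost - a.expected_cost
    if d_events == 0 and d_cost == 0:
        return Dominance(undefined=True)
    if d_events <= 0 and d_cost >= 0:
        return Dominance(dominant=a.guideline)
    if d_events >= 0 and d_cost <= 0:
        return Dominance(dominant=b.guideline)
    return d_cost / d_events


def efficient_frontier(summaries: Sequence[OutcomeSummary]) -> list:
    """Strategies not dominated in the (expected cost, p_event) plane.

    A strategy is dominated if another has cost <= and event probability <=
    with at least one strict inequality.  The frontier is returned sorted
    by expected cost.
    """
    if not summaries:
        raise ValidationError("efficient_frontier needs at least one summary")
    keep = []
    for s in summaries:
        dominated = any(
            (o.expected_cost <= s.expected_cost and o.p_event <= s.p_event)
            and (o.expected_cost < s.expected_cost or o.p_event < s.p_event)
            for o in summaries
        )
        if not dominated:
            keep.append(s)
    return sorted(keep, key=lambda s: (s.expected_cost, s.p_event))


def summarize_trajectory(
    trajectory: CohortTrajectory,
    reference: Optional[CohortTrajectory] = None,
    treated_denominator: bool = False,
) -> OutcomeSummary:
    """Condense a cohort trajectory into the headline outcome measures.

    With a reference (no-treatment) trajectory the comparative measures
    (NNT, events avoided, cost per event avoided) are filled in; without
    one only the absolute measures are reported.
    """
    p = trajectory.p_event
    cost = trajectory.expected_cost
    etf = trajectory.ever_treated_fraction
    if reference is None:
        return OutcomeSummary(
            guideline=trajectory.guideline,
            p_event=p,
            expected_cost=cost,
            ever_treated_fraction=etf,
        )
    p_ref = reference.p_event
    denom = etf if treated_denominator else None
    return OutcomeSummary(
        guideline=trajectory.guideline,
        p_event=p,
        expected_cost=cost,
        nnt=nnt(p_ref, p),
        events_avoided_per_1000=events_avoided_per_1000(p_ref, p, denom),
        cost_per_event_avoided=cost_per_event_avoided(cost, p_ref, p),
        ever_treated_fraction=etf,
    )


def comparison_table(
    summaries: Iterable[OutcomeSummary], rounded: bool = True
) -> pd.DataFrame:
    """Guideline-impact table: one row per guideline.

    Rounding (NNT and events avoided to 1 decimal place, currency to whole
    dollars) is applied only at render time; inputs carry full precision.
    """
    rows = []
    for s in summaries:
        row = {
            "guideline": s.guideline,
            "p_event": s.p_event,
            "expected_cost": s.expected_cost,
            "nnt": s.nnt,
            "events_avoided_per_1000": s.events_avoided_per_1000,
            "cost_per_event_avoided": s.cost_per_event_avoided,
            "ever_treated_fraction": s.ever_treated_fraction,
        }
        if rounded:
            row["p_event"] = round(row["p_event"], 3)
            row["expected_cost"] = None if row["expected_cost"] is None else round(row["expected_cost"])
            row["nnt"] = None if row["nnt"] is None else round(row["nnt"], 1)
            row["events_avoided_per_1000"] = (
                None
                if row["events_avoided_per_1000"] is None
                else round(row["events_avoided_per_1000"], 1)
            )
            row["cost_per_event_avoided"] = (
                None
                if row["cost_per_event_avoided"] is None
                else round(row["cost_per_event_avoided"])
            )
        rows.append(row)
    return pd.DataFrame(rows)
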