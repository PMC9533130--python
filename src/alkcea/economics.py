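"""Incremental cost-effectiveness analysis: ICERs, dominance, NMB, frontier.

Decision rules at willingness-to-pay threshold w (USD/QALY), for an
intervention versus a comparator with cost and QALY differences
(dC, dQ) = intervention - comparator:

* dQ > 0, dC < 0: the intervention *dominates* (more health, less money).
* dQ < 0, dC > 0: the intervention is *dominated*.
* dQ > 0, dC > 0: ICER = dC/dQ; cost-effective iff ICER < w.
* dQ < 0, dC < 0: the ratio dC/dQ is the ICER of the *comparator* over the
  intervention (cost per QALY bought back by the dearer strategy); the
  intervention is cost-effective iff that ratio exceeds w, i.e. the QALYs
  forgone are cheaper to give up than the threshold values them.
* dQ = 0: no ICER; verdict follows the cost sign alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .markov import CEResult

__all__ = [
    "IncrementalResult",
    "incremental",
    "net_monetary_benefit",
    "pivot_comparisons",
    "frontier",
    "summary_table",
    "incremental_table",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
COST_EFFECTIVE = "cost-effective"
NOT_COST_EFFECTIVE = "not cost-effective"


@dataclass(frozen=True)
class IncrementalResult:
    intervention: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    verdict: str
    wtp: float


def incremental(
    intervention: CEResult, comparator: CEResult, wtp: float
) -> IncrementalResult:
    """Pairwise incremental analysis of intervention vs comparator."""
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qalys - comparator.total_qalys
    icer = dc / dq if dq != 0 else None
    if dq > 0:
        if dc <= 0:
            verdict = DOMINANT if dc < 0 else COST_EFFECTIVE
        else:
            verdict = COST_EFFECTIVE if icer < wtp else NOT_COST_EFFECTIVE
    elif dq < 0:
        if dc >= 0:
            # mirror of the dq > 0 branch: strictly costlier is dominated,
            # equal cost for fewer QALYs is merely not cost-effective
            verdict = DOMINATED if dc > 0 else NOT_COST_EFFECTIVE
        else:
            # forgoing QALYs saves dC; worthwhile iff savings per QALY > wtp
            verdict = COST_EFFECTIVE if icer > wtp else NOT_COST_EFFECTIVE
    else:
        verdict = DOMINANT if dc < 0 else (DOMINATED if dc > 0 else COST_EFFECTIVE)
    return IncrementalResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qalys=dq,
        icer=icer,
        verdict=verdict,
        wtp=wtp,
    )


def net_monetary_benefit(result: CEResult, wtp: float) -> float:
    """NMB = wtp x QALYs - cost; linearisation of the ICER rule."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * result.total_qalys - result.total_cost


def pivot_comparisons(
    results: dict, pivot: str, wtp: float, orientation: str = "higher_qaly"
) -> list:
    """Pairwise comparisons of every strategy against a pivot strategy.

    With the default orientation each pair is reported with the
    higher-QALY arm as the intervention, matching the usual presentation
    (the pivot vs less effective arms; more effective arms vs the pivot).
    """
    out = []
    pivot_res = results[pivot]
    for name, res in results.items():
        if name == pivot:
            continue
        if orientation == "higher_qaly" and res.total_qalys > pivot_res.total_qalys:
            out.append(incremental(res, pivot_res, wtp))
        else:
            out.append(incremental(pivot_res, res, wtp))
    return out


def frontier(results: dict, wtp: float = None) -> pd.DataFrame:
    """Fully incremental efficiency-frontier analysis (extension).

    Strategies are ordered by cost; strictly dominated and extendedly
    dominated options are flagged, and frontier ICERs are computed between
    adjacent non-dominated strategies.
    """
    rows = sorted(results.values(), key=lambda r: (r.total_cost, -r.total_qalys))
    status = {r.strategy: "" for r in rows}
    # strict dominance
    live = []
    for r in rows:
        if any(o.total_qalys >= r.total_qalys for o in live):
            status[r.strategy] = DOMINATED
        else:
            live.append(r)
    # extended dominance: prune until frontier ICERs increase monotonically
    changed = True
    while changed and len(live) > 2:
        changed = False
        icers = [
            (live[i + 1].total_cost - live[i].total_cost)
            / (live[i + 1].total_qalys - live[i].total_qalys)
            for i in range(len(live) - 1)
        ]
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                status[live[i + 1].strategy] = "extendedly dominated"
                del live[i + 1]
                changed = True
                break
    records = []
    prev = None
    for r in rows:
        icer = None
        if not status[r.strategy] and prev is not None:
            icer = (r.total_cost - prev.total_cost) / (r.total_qalys - prev.total_qalys)
        if not status[r.strategy]:
            prev = r
        records.append(
            {
                "strategy": r.strategy,
                "cost": r.total_cost,
                "qalys": r.total_qalys,
                "status": status[r.strategy] or "on frontier",
                "frontier_icer": icer,
            }
        )
    return pd.DataFrame(records)


def summary_table(results: dict) -> pd.DataFrame:
    """Per-strategy discounted totals, one row per arm."""
    return pd.DataFrame(
        [
            {
                "strategy": r.strategy,
                "cost_usd": r.total_cost,
                "qalys": r.total_qalys,
                "cost_undiscounted_usd": r.cost_undiscounted,
                "qalys_undiscounted": r.qalys_undiscounted,
                "life_years": r.life_years,
            }
            for r in results.values()
        ]
    )


def incremental_table(comparisons: Sequence[IncrementalResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "intervention": c.intervention,
                "comparator": c.comparator,
                "delta_cost_usd": c.delta_cost,
                "delta_qalys": c.delta_qalys,
                "icer_usd_per_qaly": c.icer,
                "verdict": c.verdict,
            }
            for c in comparisons
        ]
    )
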