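"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-evaluates the full model at each parameter's published low
and high bound (all else at baseline) and ranks parameters by the swing
they induce in the pairwise ICER (tornado).  A bisection threshold search
finds the parameter value at which the cost-effectiveness verdict flips.

PSA matches each uncertain parameter with a distribution (Normal for
hazard ratios, Gamma for costs, Beta for utilities and disutilities) by
moment matching — the published range is treated as a 95% interval, so
SD = (high - low) / (2 x 1.96) — and pushes joint Monte Carlo draws through
the full model.  Cost-effectiveness acceptability curves report, at each
willingness-to-pay value, the fraction of draws in which a strategy has the
highest net monetary benefit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, ParamRef, iter_parameters
from .economics import incremental, net_monetary_benefit
from .markov import evaluate_all, evaluate_strategy

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "CEACCurve",
    "one_way_dsa",
    "threshold_search",
    "moment_match",
    "run_psa",
    "ceac",
    "pairwise_ceac",
    "tornado_table",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # standard-normal 97.5th percentile


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float
    swing: float
    verdict_at_low: str
    verdict_at_high: str
    verdict_changes: bool


@dataclass(frozen=True)
class CEACCurve:
    """Probability of being the preferred option across a WTP grid."""

    wtp: np.ndarray
    probabilities: pd.DataFrame  # one column per strategy, rows align with wtp


@dataclass(frozen=True)
class PSAResult:
    """Joint Monte Carlo draws and their model outputs."""

    params: pd.DataFrame  # draw x parameter values
    costs: pd.DataFrame  # draw x strategy
    qalys: pd.DataFrame  # draw x strategy
    seed: int
    n_redraws: int

    @property
    def n(self) -> int:
        return len(self.params)


def _pair_icer(config: ModelConfig, intervention: str, comparator: str):
    res_i = evaluate_strategy(config.strategy(intervention), config)
    res_c = evaluate_strategy(config.strategy(comparator), config)
    inc = incremental(res_i, res_c, config.wtp_per_qaly)
    return inc.icer, inc.verdict


def one_way_dsa(
    config: ModelConfig, intervention: str, comparator: str
) -> list:
    """Tornado analysis of the intervention-vs-comparator ICER.

    Parameters without a sensitivity range (the base Weibull curves) are
    excluded; entries come back sorted by descending swing.
    """
    entries = []
    for ref in iter_parameters(config):
        if not ref.varied_in_dsa:
            logger.info("one_way_dsa: %s fixed in DSA, excluded", ref.label)
            continue
        icer_lo, verdict_lo = _pair_icer(
            ref.set(config, ref.low), intervention, comparator
        )
        icer_hi, verdict_hi = _pair_icer(
            ref.set(config, ref.high), intervention, comparator
        )
        lo = icer_lo if icer_lo is not None else math.nan
        hi = icer_hi if icer_hi is not None else math.nan
        entries.append(
            TornadoEntry(
                parameter=ref.label,
                low=ref.low,
                high=ref.high,
                icer_at_low=lo,
                icer_at_high=hi,
                swing=abs(hi - lo),
                verdict_at_low=verdict_lo,
                verdict_at_high=verdict_hi,
                verdict_changes=verdict_lo != verdict_hi,
            )
        )
    entries.sort(key=lambda e: (-(e.swing if math.isfinite(e.swing) else math.inf),
                                e.parameter))
    return entries


def tornado_table(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in entries])


def threshold_search(
    config: ModelConfig,
    parameter: str,
    intervention: str,
    comparator: str,
    wtp: float = None,
    lo: float = None,
    hi: float = None,
    rel_tol: float = 1e-6,
    bracket_points: int = 9,
) -> Optional[float]:
    """Parameter value at which the pairwise verdict flips at ``wtp``.

    The verdict flip is located as the sign change of the incremental net
    monetary benefit (NMB of intervention minus comparator), which is
    equivalent to the ICER-vs-WTP rule and well defined through dominance
    regions.  Bisection to relative tolerance ``rel_tol``; returns None if
    the NMB difference does not change sign over [lo, hi].
    """
    wtp = config.wtp_per_qaly if wtp is None else wtp
    ref = next((r for r in iter_parameters(config) if r.label == parameter), None)
    if ref is None:
        raise KeyError(f"no such parameter {parameter!r}")
    lo = ref.low if lo is None else lo
    hi = ref.high if hi is None else hi
    if lo is None or hi is None:
        raise ValueError(f"{parameter}: no search interval available")

    def f(x: float) -> float:
        cfg = ref.set(config, x)
        res_i = evaluate_strategy(cfg.strategy(intervention), cfg)
        res_c = evaluate_strategy(cfg.strategy(comparator), cfg)
        return net_monetary_benefit(res_i, wtp) - net_monetary_benefit(res_c, wtp)

    grid = np.linspace(lo, hi, bracket_points)
    vals = np.array([f(x) for x in grid])
    signs = np.sign(vals)
    changes = np.flatnonzero(np.diff(signs) != 0)
    if changes.size == 0:
        logger.info(
            "threshold_search: no verdict flip for %s in [%g, %g]; "
            "incremental NMB spans [%g, %g]",
            parameter, lo, hi, vals.min(), vals.max(),
        )
        return None
    if changes.size > 1:
        raise ValueError(
            f"{parameter}: incremental NMB is not monotone over [{lo}, {hi}] "
            f"({changes.size} sign changes); use a grid scan instead"
        )
    a, b = grid[changes[0]], grid[changes[0] + 1]
    fa = vals[changes[0]]
    scale = max(abs(lo), abs(hi), 1.0)
    while (b - a) > rel_tol * scale:
        m = 0.5 * (a + b)
        fm = f(m)
        if fm == 0.0:
            return m
        if np.sign(fm) == np.sign(fa):
            a, fa = m, fm
        else:
            b = m
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# Distributions for PSA
# ---------------------------------------------------------------------------

def moment_match(family: str, mean: float, low: float, high: float):
    """Frozen scipy distribution matching (mean, SD) with SD = range/3.92.

    Normal is parameterised directly; Gamma and Beta are solved by the
    method of moments.  Beta requires the variance to be feasible for the
    mean (var < mean(1-mean)).
    """
    if not low < high:
        raise ValueError(f"need low < high, got [{low}, {high}]")
    if not (low <= mean <= high):
        raise ValueError(f"mean {mean} outside [{low}, {high}]")
    sd = (high - low) / (2 * Z95)
    var = sd * sd
    if family == "normal":
        return stats.norm(loc=mean, scale=sd)
    if family == "gamma":
        if mean <= 0:
            raise ValueError("gamma requires mean > 0")
        shape = mean * mean / var
        scale = var / mean
        return stats.gamma(a=shape, scale=scale)
    if family == "beta":
        if not (0 <= low and high <= 1):
            raise ValueError("beta requires support within [0, 1]")
        if var >= mean * (1 - mean):
            raise ValueError(
                f"beta moments infeasible: var {var:.5g} >= mean(1-mean) "
                f"{mean * (1 - mean):.5g}"
            )
        nu = mean * (1 - mean) / var - 1.0
        return stats.beta(a=mean * nu, b=(1 - mean) * nu)
    raise ValueError(f"unknown family {family!r}")


def _psa_distribution(ref: ParamRef):
    if ref.dist == "normal":
        return moment_match("normal", ref.value, ref.low, ref.high)
    if ref.dist == "gamma":
        return moment_match("gamma", ref.value, ref.low, ref.high)
    if ref.dist == "beta":
        return moment_match("beta", ref.value, ref.low, ref.high)
    raise ValueError(f"{ref.label}: no PSA distribution for {ref.dist!r}")


def _row_valid(config: ModelConfig) -> bool:
    # only reject what the accumulators cannot evaluate; the utilities are
    # drawn independently, so u_pd > u_pfs is allowed to occur by chance
    u_pfs = config.utilities.u_pfs.value
    for s in config.strategies:
        if u_pfs - s.ae_disutility.value < 0:
            return False
    return True


def run_psa(
    config: ModelConfig,
    n: int = None,
    seed: int = None,
    hr_lognormal: bool = False,
) -> PSAResult:
    """Joint Monte Carlo over all distribution-tagged parameters.

    Hazard ratios are drawn Normal (truncated at zero by redraw), or
    log-Normal with matched 95% CI when ``hr_lognormal`` is set; costs are
    Gamma; utilities and disutilities Beta.  The base survival curves and
    the discount rate stay at baseline.  Draws that violate joint support
    constraints (utility ordering, non-negative on-treatment utility) are
    redrawn and counted.
    """
    n = config.psa.n_iterations if n is None else n
    seed = config.psa.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    refs = [r for r in iter_parameters(config) if r.varied_in_psa]

    def draw_one(ref: ParamRef) -> float:
        if ref.dist == "normal" and hr_lognormal:
            mu = math.log(ref.value)
            sigma = (math.log(ref.high) - math.log(ref.low)) / (2 * Z95)
            return float(math.exp(rng.normal(mu, sigma)))
        dist = _psa_distribution(ref)
        for _ in range(1000):
            x = float(dist.rvs(random_state=rng))
            if ref.dist != "normal" or x > 0:
                return x
        raise RuntimeError(f"{ref.label}: could not draw a positive value")

    strategy_names = [s.name for s in config.strategies]
    params_rows, cost_rows, qaly_rows = [], [], []
    n_redraws = 0
    for _ in range(n):
        for _attempt in range(1000):
            values = {ref.label: draw_one(ref) for ref in refs}
            cfg = config
            for ref in refs:
                cfg = ref.set(cfg, values[ref.label])
            if _row_valid(cfg):
                break
            n_redraws += 1
        else:
            raise RuntimeError("PSA: could not draw a valid joint parameter set")
        results = evaluate_all(cfg)
        params_rows.append(values)
        cost_rows.append({s: results[s].total_cost for s in strategy_names})
        qaly_rows.append({s: results[s].total_qalys for s in strategy_names})
    if n_redraws:
        logger.info("run_psa: %d joint draws redrawn for support violations", n_redraws)
    return PSAResult(
        params=pd.DataFrame(params_rows),
        costs=pd.DataFrame(cost_rows),
        qalys=pd.DataFrame(qaly_rows),
        seed=seed,
        n_redraws=n_redraws,
    )


def ceac(psa: PSAResult, wtp_grid) -> CEACCurve:
    """Probability each strategy has the highest NMB, per WTP value."""
    if psa.n < 1:
        raise ValueError("need at least one PSA sample")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    costs = psa.costs.to_numpy()
    qalys = psa.qalys.to_numpy()
    names = list(psa.costs.columns)
    probs = np.empty((len(wtp_grid), len(names)))
    for j, w in enumerate(wtp_grid):
        nmb = w * qalys - costs
        best = np.argmax(nmb, axis=1)
        probs[j] = np.bincount(best, minlength=len(names)) / psa.n
    return CEACCurve(wtp=wtp_grid, probabilities=pd.DataFrame(probs, columns=names))


def pairwise_ceac(
    psa: PSAResult, intervention: str, comparator: str, wtp_grid
) -> pd.DataFrame:
    """Fraction of draws in which the intervention's NMB beats the
    comparator's, per WTP value."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dq = psa.qalys[intervention].to_numpy() - psa.qalys[comparator].to_numpy()
    dc = psa.costs[intervention].to_numpy() - psa.costs[comparator].to_numpy()
    prob = [(w * dq - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, f"p_{intervention}_preferred": prob})


def ce_plane(psa: PSAResult, intervention: str, comparator: str) -> pd.DataFrame:
    """Per-draw incremental (cost, QALY) scatter for the CE plane."""
    return pd.DataFrame(
        {
            "delta_cost_usd": psa.costs[intervention] - psa.costs[comparator],
            "delta_qalys": psa.qalys[intervention] - psa.qalys[comparator],
        }
    )
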