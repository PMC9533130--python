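"""Cohort engine: state occupancy over the horizon, discounted accumulation.

Three health states: progression-free (PFS, on first-line treatment),
progressed disease (PD, on subsequent therapy) and death.  Two trace modes
are supported:

* ``partitioned`` (default): occupancy is read directly off the survival
  curves — PFS(t) = S_PFS(t), alive(t) = S_OS(t), PD(t) = S_OS - S_PFS
  (clamped at zero), death(t) = 1 - S_OS(t).  This is the standard reading
  of curve-driven three-state oncology models.
* ``state_transition``: a Markov chain driven by per-cycle hazards, with
  the death hazard from the OS curve applied to both alive states and
  progression taking up the remaining PFS exit hazard.  By construction the
  alive fraction equals S_OS exactly in both modes.

Costs per cycle: drug acquisition (daily cost x cycle length) plus routine
follow-up and best supportive care while progression-free; subsequent
anticancer therapy plus follow-up and BSC after progression; a one-time
adverse-event management cost at model entry; a terminal palliative-care
cost attached to incident deaths.  QALYs weight occupancy by health-state
utility, with the strategy's grade III/IV adverse-event disutility applied
during on-treatment (PFS) cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, SharedCosts, StrategyDefinition, UtilitySet
from .survival import WeibullParams, apply_hazard_ratio, weibull_survival

__all__ = [
    "CohortTrace",
    "CEResult",
    "resolve_curves",
    "build_trace",
    "discount_factor",
    "accumulate_qalys",
    "accumulate_costs",
    "evaluate_strategy",
    "evaluate_all",
]

logger = logging.getLogger(__name__)

PFS, PD, DEAD = 0, 1, 2


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy for one strategy.

    ``occupancy`` holds the cohort fractions at the cycle *boundaries*
    t = 0..N (rows sum to one); ``membership`` converts boundaries to
    per-cycle exposure, averaging adjacent boundaries when the half-cycle
    correction is on.
    """

    strategy: str
    occupancy: np.ndarray  # (n_cycles + 1, 3): [PFS, PD, DEAD]
    mode: str
    half_cycle: bool
    clamped_cycles: tuple = ()

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def membership(self) -> np.ndarray:
        """State exposure attributed to each cycle t = 0..N-1, shape (N, 3)."""
        occ = self.occupancy
        if self.half_cycle:
            return 0.5 * (occ[:-1] + occ[1:])
        return occ[:-1]

    @property
    def new_deaths(self) -> np.ndarray:
        """Incident deaths during each cycle, shape (N,)."""
        return np.diff(self.occupancy[:, DEAD])

    def validate(self, atol: float = 1e-9) -> None:
        occ = self.occupancy
        if not np.allclose(occ.sum(axis=1), 1.0, atol=atol):
            raise ValueError("trace rows must sum to 1")
        if np.any(occ < -atol):
            raise ValueError("trace occupancy must be non-negative")
        if np.any(np.diff(occ[:, DEAD]) < -atol):
            raise ValueError("death occupancy must be non-decreasing")
        if not np.allclose(occ[0], [1.0, 0.0, 0.0], atol=atol):
            raise ValueError("cycle-0 occupancy must be (1, 0, 0)")

    def to_frame(self, config: ModelConfig = None) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=["pfs", "pd", "death"])
        df.insert(0, "cycle", np.arange(self.n_cycles + 1))
        if config is not None:
            df["discount_factor"] = discount_factor(df["cycle"].to_numpy(), config)
        return df


@dataclass(frozen=True)
class CEResult:
    """Discounted totals for one strategy, with undiscounted twins."""

    strategy: str
    total_cost: float
    total_qalys: float
    cost_undiscounted: float
    qalys_undiscounted: float
    life_years: float  # undiscounted

    def validate(self) -> None:
        if self.total_cost > self.cost_undiscounted + 1e-9:
            raise ValueError("discounted cost exceeds undiscounted")
        if self.total_qalys > self.qalys_undiscounted + 1e-9:
            raise ValueError("discounted QALYs exceed undiscounted")
        if self.qalys_undiscounted > self.life_years + 1e-9:
            raise ValueError("QALYs exceed life-years")


def resolve_curves(strategy: StrategyDefinition, config: ModelConfig):
    """(OS, PFS) Weibull parameters for an arm: base or HR-adjusted."""
    os_base = config.base_survival["os"]
    pfs_base = config.base_survival["pfs"]
    if strategy.reference:
        return os_base, pfs_base
    return (
        apply_hazard_ratio(os_base, strategy.hr_os.point),
        apply_hazard_ratio(pfs_base, strategy.hr_pfs.point),
    )


def build_trace(
    strategy: StrategyDefinition,
    config: ModelConfig,
    mode: str = None,
    half_cycle: bool = None,
) -> CohortTrace:
    """Cohort occupancy at every cycle boundary over the horizon."""
    mode = config.conventions.trace_mode if mode is None else mode
    half_cycle = config.conventions.half_cycle if half_cycle is None else half_cycle
    params_os, params_pfs = resolve_curves(strategy, config)
    n = config.horizon_cycles
    t = np.arange(n + 1, dtype=float)
    s_os = weibull_survival(params_os, t)
    s_pfs = weibull_survival(params_pfs, t)

    clamped = np.flatnonzero(s_pfs > s_os + 1e-12)
    if clamped.size:
        logger.warning(
            "strategy %s: S_PFS > S_OS at %d cycles (%d..%d); PD clamped to 0",
            strategy.name,
            clamped.size,
            clamped[0],
            clamped[-1],
        )

    if mode == "partitioned":
        pfs = np.minimum(s_pfs, s_os)
        dead = 1.0 - s_os
        pd_ = np.maximum(s_os - s_pfs, 0.0)
    elif mode == "state_transition":
        # per-cycle hazards; death hazard from OS applied to both alive states
        h_os = 1.0 - s_os[1:] / s_os[:-1]
        h_exit_pfs = 1.0 - s_pfs[1:] / s_pfs[:-1]
        h_prog = np.maximum(h_exit_pfs - h_os, 0.0)
        pfs = np.empty(n + 1)
        pd_ = np.empty(n + 1)
        dead = np.empty(n + 1)
        pfs[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
        for k in range(n):
            die_pfs = pfs[k] * h_os[k]
            die_pd = pd_[k] * h_os[k]
            prog = pfs[k] * h_prog[k]
            pfs[k + 1] = pfs[k] - die_pfs - prog
            pd_[k + 1] = pd_[k] - die_pd + prog
            dead[k + 1] = dead[k] + die_pfs + die_pd
    else:
        raise ValueError(f"unknown trace mode {mode!r}")

    occ = np.column_stack([pfs, pd_, dead])
    trace = CohortTrace(
        strategy=strategy.name,
        occupancy=occ,
        mode=mode,
        half_cycle=half_cycle,
        clamped_cycles=tuple(int(c) for c in clamped),
    )
    trace.validate()
    return trace


def discount_factor(cycle, config: ModelConfig):
    """(1 + r)^(-cycle * cycle_length / 365.25); 1 at cycle 0 or r = 0."""
    cycle = np.asarray(cycle, dtype=float)
    if np.any(cycle < 0):
        raise ValueError("cycle must be >= 0")
    r = config.discount_rate_annual.value
    out = (1.0 + r) ** (-cycle * config.cycle_years)
    return float(out) if out.ndim == 0 else out


def _per_cycle_discount(trace: CohortTrace, config: ModelConfig) -> np.ndarray:
    return discount_factor(np.arange(trace.n_cycles), config)


def accumulate_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    strategy: StrategyDefinition,
    config: ModelConfig,
    discounted: bool = True,
) -> float:
    """Discounted QALY total: per-cycle utility-weighted occupancy.

    The strategy's AE disutility is subtracted from the PFS utility
    (treatment continues until progression); PD carries the progressed-state
    utility; death contributes nothing.
    """
    u_pfs = utilities.u_pfs.value - strategy.ae_disutility.value
    u_pd = utilities.u_pd.value
    if u_pfs < 0 or u_pd < 0:
        raise ValueError(
            f"negative per-state utility (u_pfs-disutility={u_pfs}, u_pd={u_pd})"
        )
    m = trace.membership
    d = _per_cycle_discount(trace, config) if discounted else 1.0
    return float(np.sum(d * (m[:, PFS] * u_pfs + m[:, PD] * u_pd)) * config.cycle_years)


def accumulate_costs(
    trace: CohortTrace,
    strategy: StrategyDefinition,
    shared: SharedCosts,
    config: ModelConfig,
    discounted: bool = True,
) -> float:
    """Discounted cost total across all included components."""
    drug_cycle = strategy.drug_cost_per_day.value * config.cycle_length_days
    fu = shared.followup_per_cycle.value
    bsc = shared.bsc_per_cycle.value
    sub = shared.subsequent_therapy_per_cycle.value
    pall = shared.palliative_terminal.value
    for label, v in (("drug", drug_cycle), ("followup", fu), ("bsc", bsc),
                     ("subsequent", sub), ("palliative", pall),
                     ("ae", strategy.ae_cost_once.value)):
        if v < 0:
            raise ValueError(f"negative cost component {label}: {v}")

    m = trace.membership
    n = trace.n_cycles
    d = _per_cycle_discount(trace, config) if discounted else np.ones(n)

    pfs_rate = drug_cycle + fu + bsc
    pd_rate = sub + fu + bsc
    total = float(np.sum(d * (m[:, PFS] * pfs_rate + m[:, PD] * pd_rate)))

    if config.conventions.palliative_timing == "once_at_death":
        total += float(np.sum(d * trace.new_deaths * pall))
    else:  # per_final_cycle: charge to the fraction dying during each cycle,
        # attributed at the end of the cycle
        d_end = discount_factor(np.arange(1, n + 1), config) if discounted else np.ones(n)
        total += float(np.sum(d_end * trace.new_deaths * pall))

    ae = strategy.ae_cost_once.value
    if config.conventions.ae_cost_timing == "once_at_entry" or n == 0:
        total += ae  # d(0) = 1
    else:  # amortized uniformly over expected on-treatment cycles
        exposure = m[:, PFS]
        weights = exposure / exposure.sum() if exposure.sum() > 0 else np.zeros(n)
        total += float(np.sum(d * weights * ae))
    return total


def evaluate_strategy(strategy: StrategyDefinition, config: ModelConfig) -> CEResult:
    """Full deterministic evaluation of one arm: trace + both accumulators."""
    trace = build_trace(strategy, config)
    qalys = accumulate_qalys(trace, config.utilities, strategy, config)
    cost = accumulate_costs(trace, strategy, config.shared_costs, config)
    qalys_u = accumulate_qalys(trace, config.utilities, strategy, config, discounted=False)
    cost_u = accumulate_costs(trace, strategy, config.shared_costs, config, discounted=False)
    m = trace.membership
    ly = float(np.sum(m[:, PFS] + m[:, PD]) * config.cycle_years)
    result = CEResult(
        strategy=strategy.name,
        total_cost=cost,
        total_qalys=qalys,
        cost_undiscounted=cost_u,
        qalys_undiscounted=qalys_u,
        life_years=ly,
    )
    result.validate()
    return result


def evaluate_all(config: ModelConfig) -> dict:
    """Evaluate every configured strategy; returns {name: CEResult}."""
    return {s.name: evaluate_strategy(s, config) for s in config.strategies}
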