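"""Synthetic trial data: Weibull IPD, Kaplan-Meier artifacts, config jitter.

These generators stand in for the published trial evidence the survival
stage consumes: individual patient data drawn from a known Weibull truth
under random (exponential) plus administrative censoring, and the
digitised-KM-curve + number-at-risk artifacts derived from such data.
Because the generating parameters are known, the reconstruction and
fitting stages are testable by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import HazardRatio, ModelConfig, Param
from .survival import KMArtifact, PseudoIPD, WeibullParams

__all__ = ["SimulationSpec", "simulate_ipd", "km_from_ipd", "perturb_config"]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and censoring mechanism for one simulated arm."""

    true_params: WeibullParams
    n_subjects: int
    censor_rate: float = 0.0  # target overall censored fraction
    admin_censor_time: float = np.inf  # end of follow-up, cycles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")


def simulate_ipd(spec: SimulationSpec) -> PseudoIPD:
    """Draw right-censored Weibull survival data.

    Event times come from the inverse CDF; random censoring is exponential
    with its rate calibrated by bisection (on the realised sample) so the
    overall censored fraction — administrative censoring included — hits
    ``censor_rate``.  Real trial censoring is administrative-heavy; the
    exponential emulation is a deliberate simplification.
    """
    rng = np.random.default_rng(spec.seed)
    lam, gam = spec.true_params.scale_lambda, spec.true_params.shape_gamma
    u = rng.uniform(size=spec.n_subjects)
    t_event = (-np.log(u) / lam) ** (1.0 / gam)
    e_cens = rng.exponential(size=spec.n_subjects)  # unit-rate draws, scaled below

    admin = spec.admin_censor_time

    def censored_fraction(rate: float) -> float:
        c = np.minimum(e_cens / rate, admin) if rate > 0 else np.full_like(t_event, admin)
        return float(np.mean(t_event > c))

    target = spec.censor_rate
    if target <= censored_fraction(0.0) or target == 0.0:
        rate = 0.0  # administrative censoring alone meets or exceeds the target
    else:
        lo, hi = 1e-9, 1e-9
        while censored_fraction(hi) < target and hi < 1e6:
            hi *= 10
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if censored_fraction(mid) < target:
                lo = mid
            else:
                hi = mid
        rate = 0.5 * (lo + hi)

    c = np.minimum(e_cens / rate, admin) if rate > 0 else np.full_like(t_event, admin)
    time = np.minimum(t_event, c)
    event = (t_event <= c).astype(int)
    if not np.isfinite(admin):
        # no administrative cut: uncensored subjects keep their event times
        time = np.where(event == 1, t_event, np.minimum(c, t_event))
    return PseudoIPD(time, event)


def km_from_ipd(ipd: PseudoIPD, risk_times=None) -> KMArtifact:
    """Product-limit estimate plus a number-at-risk table.

    Step coordinates come from lifelines' Kaplan-Meier fitter; the risk
    table counts subjects still under observation at the requested grid
    (default: 6 evenly spaced times from 0 to the last observation).
    """
    if len(ipd) < 1:
        raise ValueError("need at least one record")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if risk_times is None:
        risk_times = np.linspace(0.0, float(ipd.time.max()), 6)[:-1]
    risk_times = np.asarray(risk_times, dtype=float)
    n_at_risk = np.array([(ipd.time >= t).sum() for t in risk_times], dtype=int)
    return KMArtifact(
        times=times,
        survival=surv,
        risk_times=risk_times,
        n_at_risk=n_at_risk,
        n_total=len(ipd),
    )


def _jitter_param(p: Param, rng: np.random.Generator, magnitude: float) -> Param:
    if magnitude == 0:
        return p
    if p.low is not None and p.low < p.high:
        span = (p.high - p.low) * magnitude
        v = float(np.clip(p.value + rng.uniform(-span, span), p.low, p.high))
    else:
        v = p.value * float(1 + magnitude * rng.uniform(-1, 1))
    return replace(p, value=v)


def _jitter_hr(hr: HazardRatio, rng: np.random.Generator, magnitude: float) -> HazardRatio:
    if magnitude == 0:
        return hr
    span = (hr.ci_high - hr.ci_low) * magnitude
    v = float(np.clip(hr.point + rng.uniform(-span, span), hr.ci_low, hr.ci_high))
    return replace(hr, point=v)


def perturb_config(config: ModelConfig, seed: int, magnitude: float = 0.1) -> ModelConfig:
    """Randomly jittered but invariant-respecting copy of a configuration.

    Each uncertain input moves within its sensitivity bounds by up to
    ``magnitude`` of the bound width; the utility ordering u_pd <= u_pfs is
    preserved by construction.  Zero magnitude returns an identical config.
    """
    rng = np.random.default_rng(seed)
    strategies = []
    for s in config.strategies:
        strategies.append(
            replace(
                s,
                drug_cost_per_day=_jitter_param(s.drug_cost_per_day, rng, magnitude),
                ae_cost_once=_jitter_param(s.ae_cost_once, rng, magnitude),
                ae_disutility=_jitter_param(s.ae_disutility, rng, magnitude),
                hr_os=_jitter_hr(s.hr_os, rng, magnitude) if s.hr_os else None,
                hr_pfs=_jitter_hr(s.hr_pfs, rng, magnitude) if s.hr_pfs else None,
            )
        )
    u_pfs = _jitter_param(config.utilities.u_pfs, rng, magnitude)
    u_pd = _jitter_param(config.utilities.u_pd, rng, magnitude)
    if u_pd.value > u_pfs.value:
        u_pd = replace(u_pd, value=u_pfs.value)
    shared = config.shared_costs
    new = replace(
        config,
        strategies=tuple(strategies),
        utilities=replace(config.utilities, u_pfs=u_pfs, u_pd=u_pd),
        shared_costs=replace(
            shared,
            followup_per_cycle=_jitter_param(shared.followup_per_cycle, rng, magnitude),
            subsequent_therapy_per_cycle=_jitter_param(
                shared.subsequent_therapy_per_cycle, rng, magnitude
            ),
            bsc_per_cycle=_jitter_param(shared.bsc_per_cycle, rng, magnitude),
            palliative_terminal=_jitter_param(shared.palliative_terminal, rng, magnitude),
        ),
        discount_rate_annual=_jitter_param(config.discount_rate_annual, rng, magnitude),
    )
    new.validate()
    return new
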