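import dataclasses

import pytest

from alkcea.config import (
    Conventions,
    ModelConfig,
    Param,
    PSASpec,
    SharedCosts,
    StrategyDefinition,
    UtilitySet,
    load_baseline_config,
)
from alkcea.markov import evaluate_all
from alkcea.survival import WeibullParams


@pytest.fixture(scope="session")
def baseline_config() -> ModelConfig:
    """The bundled base-case inputs (six strategies)."""
    return load_baseline_config()


@pytest.fixture(scope="session")
def baseline_results(baseline_config):
    return evaluate_all(baseline_config)


def make_minimal_config(
    drug_cost=100.0,
    ae_cost=0.0,
    disutility=0.0,
    followup=0.0,
    subsequent=0.0,
    bsc=0.0,
    palliative=0.0,
    u_pfs=1.0,
    u_pd=1.0,
    discount=0.0,
    horizon_years=10.0,
    cycle_length_days=56.0,
    half_cycle=False,
    os_params=WeibullParams(0.02092, 1.25579),
    pfs_params=WeibullParams(0.08242, 1.21862),
    extra_strategies=(),
) -> ModelConfig:
    """Hand-built single-arm configuration for closed-form checks."""
    ref = StrategyDefinition(
        name="reference",
        drug_cost_per_day=Param(drug_cost),
        ae_cost_once=Param(ae_cost),
        ae_disutility=Param(disutility),
        reference=True,
    )
    cfg = ModelConfig(
        cycle_length_days=cycle_length_days,
        horizon_years=horizon_years,
        discount_rate_annual=Param(discount),
        wtp_per_qaly=37654.0,
        cny_per_usd=6.4515,
        base_survival={"os": os_params, "pfs": pfs_params},
        strategies=(ref,) + tuple(extra_strategies),
        shared_costs=SharedCosts(
            followup_per_cycle=Param(followup),
            subsequent_therapy_per_cycle=Param(subsequent),
            bsc_per_cycle=Param(bsc),
            palliative_terminal=Param(palliative),
        ),
        utilities=UtilitySet(u_pfs=Param(u_pfs), u_pd=Param(u_pd)),
        psa=PSASpec(n_iterations=10, seed=0),
        conventions=Conventions(half_cycle=half_cycle),
    )
    cfg.validate()
    return cfg


def comparator(name, hr_os, hr_pfs, drug_cost=100.0, ae_cost=0.0, disutility=0.0):
    from alkcea.config import HazardRatio

    return StrategyDefinition(
        name=name,
        drug_cost_per_day=Param(drug_cost),
        ae_cost_once=Param(ae_cost),
        ae_disutility=Param(disutility),
        hr_os=HazardRatio(hr_os, hr_os / 2, hr_os * 2),
        hr_pfs=HazardRatio(hr_pfs, hr_pfs / 2, hr_pfs * 2),
    )


def with_conventions(config: ModelConfig, **switches) -> ModelConfig:
    return dataclasses.replace(
        config, conventions=dataclasses.replace(config.conventions, **switches)
    )
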