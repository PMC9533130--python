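"""Model configuration: types, validation, (de)serialisation, results output.

The whole model specification — six treatment strategies, the reference
arm's Weibull curves, hazard ratios, costs, utilities, discounting and the
sensitivity-analysis metadata — lives in one human-editable YAML file.  A
fixture carrying the published base-case inputs ships with the package
(``alkcea.config.load_baseline_config``).

Every uncertain scalar input is a :class:`Param` carrying its baseline
value, its deterministic-sensitivity range and the distribution family used
in probabilistic sensitivity analysis, so the DSA/PSA specifications are
derived views over the configuration rather than parallel structures.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterator, Optional

import pandas as pd
import yaml

from .survival import WeibullParams

__all__ = [
    "Param",
    "HazardRatio",
    "StrategyDefinition",
    "SharedCosts",
    "UtilitySet",
    "Conventions",
    "PSASpec",
    "ModelConfig",
    "ParamRef",
    "ConfigError",
    "load_config",
    "save_config",
    "load_baseline_config",
    "iter_parameters",
    "config_hash",
    "write_results",
]

logger = logging.getLogger(__name__)

DISTRIBUTIONS = ("fixed", "normal", "gamma", "beta")
DAYS_PER_YEAR = 365.25


class ConfigError(ValueError):
    """Configuration failed validation; message names the offending field."""


@dataclass(frozen=True)
class Param:
    """Scalar model input with uncertainty metadata.

    ``low``/``high`` are the one-way sensitivity bounds (None = fixed in
    DSA); ``dist`` is the PSA distribution family ('fixed' = not drawn).
    """

    value: float
    low: Optional[float] = None
    high: Optional[float] = None
    dist: str = "fixed"

    def validate(self, name: str, lo: float = -float("inf"), hi: float = float("inf")) -> None:
        if self.dist not in DISTRIBUTIONS:
            raise ConfigError(f"{name}: unknown distribution {self.dist!r}")
        if not (lo <= self.value <= hi):
            raise ConfigError(f"{name}: value {self.value} outside [{lo}, {hi}]")
        if (self.low is None) != (self.high is None):
            raise ConfigError(f"{name}: range must give both bounds or neither")
        if self.low is not None and not (self.low <= self.value <= self.high):
            raise ConfigError(
                f"{name}: baseline {self.value} outside range [{self.low}, {self.high}]"
            )

    @property
    def varied_in_dsa(self) -> bool:
        return self.low is not None

    @property
    def varied_in_psa(self) -> bool:
        return self.dist != "fixed"


@dataclass(frozen=True)
class HazardRatio:
    """Point estimate and 95% CI of a hazard ratio versus the reference arm."""

    point: float
    ci_low: float
    ci_high: float
    dist: str = "normal"

    def validate(self, name: str) -> None:
        if not (0 < self.ci_low <= self.point <= self.ci_high):
            raise ConfigError(
                f"{name}: need 0 < ci_low <= point <= ci_high, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )


@dataclass(frozen=True)
class StrategyDefinition:
    """One treatment arm: curve source, acquisition cost, AE burden."""

    name: str
    drug_cost_per_day: Param
    ae_cost_once: Param
    ae_disutility: Param
    hr_os: Optional[HazardRatio] = None
    hr_pfs: Optional[HazardRatio] = None
    reference: bool = False

    def validate(self) -> None:
        n = self.name
        self.drug_cost_per_day.validate(f"strategies[{n}].drug_cost_per_day", lo=0)
        self.ae_cost_once.validate(f"strategies[{n}].ae_cost_once", lo=0)
        self.ae_disutility.validate(f"strategies[{n}].ae_disutility", lo=0, hi=1 - 1e-12)
        if self.reference:
            if self.hr_os is not None or self.hr_pfs is not None:
                raise ConfigError(f"strategies[{n}]: reference arm must not carry hazard ratios")
        else:
            if self.hr_os is None or self.hr_pfs is None:
                raise ConfigError(f"strategies[{n}]: non-reference arm needs hr_os and hr_pfs")
            self.hr_os.validate(f"strategies[{n}].hr_os")
            self.hr_pfs.validate(f"strategies[{n}].hr_pfs")


@dataclass(frozen=True)
class SharedCosts:
    """Care costs common to all arms, USD per cycle (palliative: terminal)."""

    followup_per_cycle: Param
    subsequent_therapy_per_cycle: Param
    bsc_per_cycle: Param
    palliative_terminal: Param

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            getattr(self, f.name).validate(f"shared_costs.{f.name}", lo=0)


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities (0 = death, 1 = full health)."""

    u_pfs: Param
    u_pd: Param

    def validate(self) -> None:
        self.u_pfs.validate("utilities.u_pfs", lo=0, hi=1)
        self.u_pd.validate("utilities.u_pd", lo=0, hi=1)
        if self.u_pd.value > self.u_pfs.value:
            raise ConfigError(
                f"utilities: u_pd {self.u_pd.value} exceeds u_pfs {self.u_pfs.value}"
            )


@dataclass(frozen=True)
class Conventions:
    """Structural switches not pinned down by the published methods."""

    trace_mode: str = "partitioned"  # or "state_transition"
    half_cycle: bool = True
    palliative_timing: str = "once_at_death"  # or "per_final_cycle"
    ae_cost_timing: str = "once_at_entry"  # or "amortized"

    def validate(self) -> None:
        if self.trace_mode not in ("partitioned", "state_transition"):
            raise ConfigError(f"conventions.trace_mode: unknown mode {self.trace_mode!r}")
        if self.palliative_timing not in ("once_at_death", "per_final_cycle"):
            raise ConfigError(
                f"conventions.palliative_timing: unknown value {self.palliative_timing!r}"
            )
        if self.ae_cost_timing not in ("once_at_entry", "amortized"):
            raise ConfigError(f"conventions.ae_cost_timing: unknown value {self.ae_cost_timing!r}")


@dataclass(frozen=True)
class PSASpec:
    """Monte Carlo settings for probabilistic sensitivity analysis."""

    n_iterations: int = 10_000
    seed: int = 20220921

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError(f"psa.n_iterations must be >= 1, got {self.n_iterations}")


@dataclass(frozen=True)
class ModelConfig:
    """Complete model specification; single source of truth for conventions."""

    cycle_length_days: float
    horizon_years: float
    discount_rate_annual: Param
    wtp_per_qaly: float
    cny_per_usd: float  # metadata only; the model operates in USD
    base_survival: dict  # {"os": WeibullParams, "pfs": WeibullParams}
    strategies: tuple
    shared_costs: SharedCosts
    utilities: UtilitySet
    psa: PSASpec = field(default_factory=PSASpec)
    conventions: Conventions = field(default_factory=Conventions)
    time_unit: str = "cycle"

    @property
    def horizon_cycles(self) -> int:
        # floor, tolerant of float representation of day counts
        return int(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days + 1e-9)

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    def strategy(self, name: str) -> StrategyDefinition:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    @property
    def reference_strategy(self) -> StrategyDefinition:
        return next(s for s in self.strategies if s.reference)

    def validate(self) -> None:
        if not self.cycle_length_days > 0:
            raise ConfigError(f"cycle_length_days must be > 0, got {self.cycle_length_days}")
        if not self.horizon_years >= 0:
            raise ConfigError(f"horizon_years must be >= 0, got {self.horizon_years}")
        self.discount_rate_annual.validate("discount_rate_annual", lo=0.0, hi=0.08)
        if not self.wtp_per_qaly >= 0:
            raise ConfigError(f"wtp_per_qaly must be >= 0, got {self.wtp_per_qaly}")
        for key in ("os", "pfs"):
            if key not in self.base_survival or not isinstance(
                self.base_survival[key], WeibullParams
            ):
                raise ConfigError(f"base_survival.{key}: missing or not WeibullParams")
        refs = [s for s in self.strategies if s.reference]
        if len(refs) != 1:
            raise ConfigError(
                f"strategies: exactly one reference arm required, found {len(refs)}"
            )
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ConfigError("strategies: duplicate names")
        for s in self.strategies:
            s.validate()
        self.shared_costs.validate()
        self.utilities.validate()
        self.psa.validate()
        self.conventions.validate()
        logger.info(
            "config validated: %d strategies, horizon %d cycles of %.0f days, "
            "discount %.3f, WTP %s",
            len(self.strategies),
            self.horizon_cycles,
            self.cycle_length_days,
            self.discount_rate_annual.value,
            self.wtp_per_qaly,
        )


# ---------------------------------------------------------------------------
# YAML (de)serialisation
# ---------------------------------------------------------------------------

def _param_from(node, name: str) -> Param:
    if isinstance(node, dict):
        try:
            value = float(node["value"])
        except KeyError:
            raise ConfigError(f"{name}: missing required field 'value'") from None
        rng = node.get("range")
        low, high = (float(rng[0]), float(rng[1])) if rng is not None else (None, None)
        return Param(value, low, high, node.get("dist", "fixed"))
    return Param(float(node))


def _param_to(p: Param) -> dict:
    out = {"value": p.value}
    if p.low is not None:
        out["range"] = [p.low, p.high]
    if p.dist != "fixed":
        out["dist"] = p.dist
    return out


def _hr_from(node, name: str) -> HazardRatio:
    try:
        point = float(node["point"])
        ci = node["ci"]
    except KeyError as err:
        raise ConfigError(f"{name}: missing required field {err.args[0]!r}") from None
    return HazardRatio(point, float(ci[0]), float(ci[1]), node.get("dist", "normal"))


def _hr_to(hr: HazardRatio) -> dict:
    out = {"point": hr.point, "ci": [hr.ci_low, hr.ci_high]}
    if hr.dist != "normal":
        out["dist"] = hr.dist
    return out


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return mapping[key]


def config_from_dict(doc: dict) -> ModelConfig:
    model = _require(doc, "model", "config")
    surv = _require(doc, "base_survival", "config")
    strategies = []
    for node in _require(doc, "strategies", "config"):
        name = _require(node, "name", "strategies[]")
        where = f"strategies[{name}]"
        strategies.append(
            StrategyDefinition(
                name=name,
                drug_cost_per_day=_param_from(
                    _require(node, "drug_cost_per_day", where), f"{where}.drug_cost_per_day"
                ),
                ae_cost_once=_param_from(
                    _require(node, "ae_cost_once", where), f"{where}.ae_cost_once"
                ),
                ae_disutility=_param_from(
                    _require(node, "ae_disutility", where), f"{where}.ae_disutility"
                ),
                hr_os=_hr_from(node["hr_os"], f"{where}.hr_os") if "hr_os" in node else None,
                hr_pfs=_hr_from(node["hr_pfs"], f"{where}.hr_pfs") if "hr_pfs" in node else None,
                reference=bool(node.get("reference", False)),
            )
        )
    shared = _require(doc, "shared_costs", "config")
    util = _require(doc, "utilities", "config")
    conv = doc.get("conventions", {})
    psa = doc.get("psa", {})
    cfg = ModelConfig(
        cycle_length_days=float(_require(model, "cycle_length_days", "model")),
        horizon_years=float(_require(model, "horizon_years", "model")),
        discount_rate_annual=_param_from(
            _require(model, "discount_rate_annual", "model"), "model.discount_rate_annual"
        ),
        wtp_per_qaly=float(_require(model, "wtp_per_qaly", "model")),
        cny_per_usd=float(model.get("cny_per_usd", float("nan"))),
        base_survival={
            k: WeibullParams(float(surv[k]["scale"]), float(surv[k]["shape"]))
            for k in ("os", "pfs")
            if k in surv or _require(surv, k, "base_survival")
        },
        strategies=tuple(strategies),
        shared_costs=SharedCosts(
            **{
                f.name: _param_from(_require(shared, f.name, "shared_costs"), f"shared_costs.{f.name}")
                for f in dataclasses.fields(SharedCosts)
            }
        ),
        utilities=UtilitySet(
            u_pfs=_param_from(_require(util, "u_pfs", "utilities"), "utilities.u_pfs"),
            u_pd=_param_from(_require(util, "u_pd", "utilities"), "utilities.u_pd"),
        ),
        psa=PSASpec(
            n_iterations=int(psa.get("n_iterations", 10_000)),
            seed=int(psa.get("seed", 20220921)),
        ),
        conventions=Conventions(
            trace_mode=conv.get("trace_mode", "partitioned"),
            half_cycle=bool(conv.get("half_cycle", True)),
            palliative_timing=conv.get("palliative_timing", "once_at_death"),
            ae_cost_timing=conv.get("ae_cost_timing", "once_at_entry"),
        ),
        time_unit=doc.get("base_survival", {}).get("time_unit", "cycle"),
    )
    cfg.validate()
    return cfg


def config_to_dict(cfg: ModelConfig) -> dict:
    strategies = []
    for s in cfg.strategies:
        node = {
            "name": s.name,
            "drug_cost_per_day": _param_to(s.drug_cost_per_day),
            "ae_cost_once": _param_to(s.ae_cost_once),
            "ae_disutility": _param_to(s.ae_disutility),
        }
        if s.reference:
            node["reference"] = True
        if s.hr_os is not None:
            node["hr_os"] = _hr_to(s.hr_os)
        if s.hr_pfs is not None:
            node["hr_pfs"] = _hr_to(s.hr_pfs)
        strategies.append(node)
    return {
        "model": {
            "cycle_length_days": cfg.cycle_length_days,
            "horizon_years": cfg.horizon_years,
            "discount_rate_annual": _param_to(cfg.discount_rate_annual),
            "wtp_per_qaly": cfg.wtp_per_qaly,
            "cny_per_usd": cfg.cny_per_usd,
        },
        "base_survival": {
            "time_unit": cfg.time_unit,
            "os": {
                "scale": cfg.base_survival["os"].scale_lambda,
                "shape": cfg.base_survival["os"].shape_gamma,
            },
            "pfs": {
                "scale": cfg.base_survival["pfs"].scale_lambda,
                "shape": cfg.base_survival["pfs"].shape_gamma,
            },
        },
        "strategies": strategies,
        "shared_costs": {
            f.name: _param_to(getattr(cfg.shared_costs, f.name))
            for f in dataclasses.fields(SharedCosts)
        },
        "utilities": {
            "u_pfs": _param_to(cfg.utilities.u_pfs),
            "u_pd": _param_to(cfg.utilities.u_pd),
        },
        "psa": {"n_iterations": cfg.psa.n_iterations, "seed": cfg.psa.seed},
        "conventions": dataclasses.asdict(cfg.conventions),
    }


def load_config(path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: not a mapping")
    return config_from_dict(doc)


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_baseline_config() -> ModelConfig:
    """The bundled base-case fixture (all published inputs)."""
    ref = resources.files("alkcea.data") / "table1.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)


def config_hash(cfg: ModelConfig) -> str:
    """Stable short hash of the canonical YAML form, for run logs."""
    blob = yaml.safe_dump(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Parameter enumeration for DSA/PSA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamRef:
    """Addressable scalar input: label, baseline, bounds, distribution, and a
    functional setter producing a new config with the value replaced."""

    label: str
    value: float
    low: Optional[float]
    high: Optional[float]
    dist: str
    setter: Callable[[ModelConfig, float], ModelConfig]

    @property
    def varied_in_dsa(self) -> bool:
        return self.low is not None

    @property
    def varied_in_psa(self) -> bool:
        return self.dist != "fixed"

    def set(self, cfg: ModelConfig, value: float) -> ModelConfig:
        return self.setter(cfg, value)


def _replace_strategy(cfg: ModelConfig, name: str, **changes) -> ModelConfig:
    new = tuple(replace(s, **changes) if s.name == name else s for s in cfg.strategies)
    return replace(cfg, strategies=new)


def iter_parameters(config: ModelConfig) -> Iterator[ParamRef]:
    """Every uncertain scalar input, in a stable order.

    Base-curve Weibull parameters are deliberately absent: they are fixed in
    both sensitivity analyses.
    """
    for s in config.strategies:
        name = s.name
        if s.hr_os is not None:
            yield ParamRef(
                f"hr_os[{name}]", s.hr_os.point, s.hr_os.ci_low, s.hr_os.ci_high, s.hr_os.dist,
                lambda c, v, n=name: _replace_strategy(
                    c, n, hr_os=replace(c.strategy(n).hr_os, point=v)
                ),
            )
        if s.hr_pfs is not None:
            yield ParamRef(
                f"hr_pfs[{name}]", s.hr_pfs.point, s.hr_pfs.ci_low, s.hr_pfs.ci_high,
                s.hr_pfs.dist,
                lambda c, v, n=name: _replace_strategy(
                    c, n, hr_pfs=replace(c.strategy(n).hr_pfs, point=v)
                ),
            )
        for attr in ("drug_cost_per_day", "ae_cost_once", "ae_disutility"):
            p: Param = getattr(s, attr)
            yield ParamRef(
                f"{attr}[{name}]", p.value, p.low, p.high, p.dist,
                lambda c, v, n=name, a=attr: _replace_strategy(
                    c, n, **{a: replace(getattr(c.strategy(n), a), value=v)}
                ),
            )
    for f in dataclasses.fields(SharedCosts):
        p = getattr(config.shared_costs, f.name)
        yield ParamRef(
            f.name, p.value, p.low, p.high, p.dist,
            lambda c, v, a=f.name: replace(
                c, shared_costs=replace(
                    c.shared_costs, **{a: replace(getattr(c.shared_costs, a), value=v)}
                )
            ),
        )
    for attr in ("u_pfs", "u_pd"):
        p = getattr(config.utilities, attr)
        yield ParamRef(
            attr, p.value, p.low, p.high, p.dist,
            lambda c, v, a=attr: replace(
                c, utilities=replace(
                    c.utilities, **{a: replace(getattr(c.utilities, a), value=v)}
                )
            ),
        )
    dr = config.discount_rate_annual
    yield ParamRef(
        "discount_rate_annual", dr.value, dr.low, dr.high, dr.dist,
        lambda c, v: replace(c, discount_rate_annual=replace(c.discount_rate_annual, value=v)),
    )


# ---------------------------------------------------------------------------
# Results output
# ---------------------------------------------------------------------------

def write_results(results: dict, path, config: ModelConfig = None, seed=None) -> list:
    """Write result tables as commented CSV files under ``path``.

    ``results`` maps table names (summary, incremental, tornado, psa_params,
    psa_outcomes, ceac, ...) to DataFrames; empty or missing tables are
    skipped with a log line.  Each file starts with '#'-prefixed header
    lines recording units and the conventions in force, so outputs are
    auditable and reruns with the same config and seed are byte-identical.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    header = ["# alkcea results", "# currency: USD; effects: QALY (discounted unless noted)"]
    if config is not None:
        c = config.conventions
        header += [
            f"# config_hash: {config_hash(config)}",
            f"# horizon_cycles: {config.horizon_cycles} x {config.cycle_length_days:g} days",
            f"# discount_rate_annual: {config.discount_rate_annual.value:g}",
            f"# wtp_per_qaly: {config.wtp_per_qaly:g}",
            f"# conventions: trace_mode={c.trace_mode} half_cycle={c.half_cycle} "
            f"palliative={c.palliative_timing} ae_cost={c.ae_cost_timing}",
        ]
    if seed is not None:
        header.append(f"# seed: {seed}")
    written = []
    for name, df in results.items():
        if df is None or (hasattr(df, "empty") and df.empty):
            logger.info("write_results: table %r empty, skipped", name)
            continue
        target = outdir / f"{name}.csv"
        with open(target, "w") as fh:
            fh.write("\n".join(header) + "\n")
            df.to_csv(fh, index=False)
        written.append(target)
    return written
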