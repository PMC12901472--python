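"""Model configuration: parameter containers, file I/O, validation.

A single :class:`ParameterSet` holds every input of the cost-effectiveness
model: annual transition probabilities of the reference (standard-of-care)
arm, age-banded all-cause mortality with stage-specific mortality hazard
ratios, state utilities, unit costs, the per-strategy treatment effects and
drug price schedules, the discount rate, and the sensitivity-analysis
metadata (one-way ranges and probabilistic distribution specifications).

Parameters are addressed throughout the package by flat dotted names
(``utility.MILD``, ``tp.MCI->MILD``, ``hr.lecanemab``, ``cost.inpatient``,
``mortality_hr.SEVERE``, ``discount.soc`` ...); :func:`get_param` and
:func:`with_param` resolve these names, and the one-way and probabilistic
sensitivity analyses are defined over them.

The on-disk format is a YAML file whose sections mirror the blocks of the
model's input table; see ``data/default_parameters.yaml`` for the shipped
default configuration and docs/methods.md for the schema.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .states import ALIVE_STATES, EARLY_AD_STATES, N_STATES, HealthState

TREATMENT_RULES = ("while_early_AD", "lifetime", "none")
DISTRIBUTION_FAMILIES = ("lognormal", "beta", "gamma", "fixed")
HR_METHODS = ("rate_based", "multiplicative")


class ParameterError(ValueError):
    """A parameter file is missing a required key or malformed."""


def _state(name: str) -> HealthState:
    try:
        return HealthState[name]
    except KeyError:
        raise ParameterError(f"unknown health state {name!r}") from None


def _parse_pair(key: str) -> tuple[HealthState, HealthState]:
    try:
        a, b = key.split("->")
    except ValueError:
        raise ParameterError(f"malformed transition key {key!r} (expected 'FROM->TO')") from None
    return _state(a), _state(b)


def _pair_key(pair: tuple[HealthState, HealthState]) -> str:
    return f"{pair[0].name}->{pair[1].name}"


def _number(raw, key: str) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise ParameterError(f"malformed number for {key!r}: {raw!r}") from None


# ---------------------------------------------------------------------------
# containers


@dataclass
class DistributionSpec:
    """One uncertain parameter's sampling distribution for the PSA.

    ``mean`` is the deterministic base-case value; ``se`` the standard
    error in the same units, or None when the source reported none (the
    conventional fallback SE = mean/10 is applied by :func:`resolve_psa_se`).
    ``family='fixed'`` marks a parameter held at base value in every draw.
    """

    family: str
    mean: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.family not in DISTRIBUTION_FAMILIES:
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ParameterError(f"beta distribution requires mean in (0,1), got {self.mean}")
        if self.family in ("gamma", "lognormal") and self.mean <= 0.0:
            raise ParameterError(f"{self.family} distribution requires mean > 0, got {self.mean}")
        if self.family == "fixed":
            self.se = None


def resolve_psa_se(spec: DistributionSpec) -> float:
    """Standard error used in the PSA: the reported SE when available,
    one-tenth of the mean otherwise, and 0 for fixed parameters."""
    if spec.family == "fixed":
        return 0.0
    if spec.se is not None:
        return float(spec.se)
    return abs(spec.mean) / 10.0


@dataclass
class MortalitySpec:
    """Age-banded annual all-cause mortality and stage mortality HRs.

    ``bands`` is an ordered tuple of (min_age, max_age or None for open,
    annual probability); bands are contiguous and cover ages from the first
    band minimum upwards.  ``stage_hr`` multiplies the band probability to
    give the per-state death probability (capped at 1).
    """

    bands: tuple[tuple[float, float | None, float], ...]
    stage_hr: dict[HealthState, float]
    stage_hr_se: dict[HealthState, float] = field(default_factory=dict)

    def band_labels(self) -> list[str]:
        out = []
        for lo, hi, _ in self.bands:
            out.append(f"{lo:g}-{hi:g}" if hi is not None else f"{lo:g}+")
        return out


@dataclass
class CostSpec:
    """Annual non-drug unit costs (US$/year), uniform across alive states."""

    administration: float
    outpatient: float
    inpatient: float
    outpatient_se: float | None = None
    inpatient_se: float | None = None


@dataclass
class StrategySpec:
    """One treatment arm.

    ``hr_progression`` maps (from, to) transitions to hazard ratios versus
    the reference arm (absent transitions default to HR 1).  The drug price
    schedule is a tuple of (first_cycle, annual price) steps; an empty
    schedule marks an untreated arm.  ``population`` names another strategy
    whose cohort description (starting age and state mix, discount rate)
    this arm shares; shared fields track that strategy under parameter
    overrides.
    """

    name: str
    start_age: float
    start_mci_fraction: float
    aria_rate: float
    aria_annual_cost: float
    drug_price_schedule: tuple[tuple[int, float], ...] = ()
    hr_progression: dict[tuple[HealthState, HealthState], float] = field(default_factory=dict)
    treatment_rule: str = "while_early_AD"
    discount_rate: float | None = None
    start_age_se: float | None = None
    population: str | None = None
    #: share of the annual administration cost this arm incurs, reflecting
    #: its infusion frequency (1.0 = the biweekly schedule the printed
    #: annual administration cost assumes; 0.5 = monthly infusions)
    admin_frequency_factor: float = 1.0

    @property
    def has_drug(self) -> bool:
        return len(self.drug_price_schedule) > 0

    @property
    def start_distribution(self):
        import numpy as np

        v = np.zeros(N_STATES)
        v[HealthState.MCI] = self.start_mci_fraction
        v[HealthState.MILD] = 1.0 - self.start_mci_fraction
        return v

    def drug_price(self, cycle: int) -> float:
        if not self.drug_price_schedule:
            return 0.0
        if cycle < self.drug_price_schedule[0][0]:
            raise ValueError(
                f"cycle {cycle} not covered by the drug price schedule of {self.name!r}"
            )
        price = 0.0
        for start, p in self.drug_price_schedule:
            if cycle >= start:
                price = p
        return price


@dataclass
class ModelConventions:
    """Resolved modelling conventions, logged with every run.

    hr_method: how a hazard ratio acts on an annual probability
        (``rate_based``: 1-(1-p)**hr, the actuarial transform;
        ``multiplicative``: min(1, p*hr)).
    half_cycle: average start- and end-of-cycle occupancy when accruing
        rewards (off by default: rewards attach to start-of-cycle state).
    age_cap: simulation stops once the cohort reaches this age.
    stop_tolerance: simulation stops early once the alive fraction falls
        below this.
    """

    hr_method: str = "rate_based"
    half_cycle: bool = False
    age_cap: float = 100.0
    stop_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.hr_method not in HR_METHODS:
            raise ParameterError(f"unknown hr_method {self.hr_method!r}")


@dataclass
class ParameterSet:
    """Single source of truth for one model configuration."""

    transitions: dict[tuple[HealthState, HealthState], float]
    mortality: MortalitySpec
    utilities: dict[HealthState, float]
    costs: CostSpec
    strategies: tuple[StrategySpec, ...]
    discount_rate: float
    wtp: float = 150_000.0
    conventions: ModelConventions = field(default_factory=ModelConventions)
    utilities_se: dict[HealthState, float] = field(default_factory=dict)
    osa_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    psa_distributions: dict[str, DistributionSpec] = field(default_factory=dict)

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise KeyError(f"no strategy named {name!r}")

    def transition(self, a: HealthState, b: HealthState) -> float:
        return self.transitions.get((a, b), 0.0)

    def strategy_discount(self, strategy: StrategySpec) -> float:
        return strategy.discount_rate if strategy.discount_rate is not None else self.discount_rate

    def row_offdiagonal_sum(self, state: HealthState) -> float:
        return sum(p for (a, _), p in self.transitions.items() if a == state)


# ---------------------------------------------------------------------------
# loading / writing


_REQUIRED_TOP = ("discount_rate", "transitions", "mortality", "utilities", "costs", "strategies")


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a model configuration from a YAML parameter file.

    Raises :class:`ParameterError` naming the missing key or the malformed
    value; raises on any validation violation (see :func:`validate`).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParameterError(f"{path} does not contain a parameter mapping")
    params = parameters_from_dict(raw)
    violations = validate(params)
    if violations:
        raise ParameterError(f"invalid parameter file {path}: " + "; ".join(violations))
    return params


def parameters_from_dict(raw: dict) -> ParameterSet:
    for key in _REQUIRED_TOP:
        if key not in raw:
            raise ParameterError(f"missing required parameter {key!r}")

    transitions: dict[tuple[HealthState, HealthState], float] = {}
    for frm, row in raw["transitions"].items():
        for to, p in (row or {}).items():
            transitions[(_state(frm), _state(to))] = _number(p, f"transitions.{frm}->{to}")

    mraw = raw["mortality"]
    for key in ("bands", "stage_hr"):
        if key not in mraw:
            raise ParameterError(f"missing required parameter 'mortality.{key}'")
    bands = tuple(
        (
            _number(b["min_age"], "mortality.band.min_age"),
            None if b.get("max_age") is None else _number(b["max_age"], "mortality.band.max_age"),
            _number(b["p"], "mortality.band.p"),
        )
        for b in mraw["bands"]
    )
    mortality = MortalitySpec(
        bands=bands,
        stage_hr={_state(k): _number(v, f"mortality.stage_hr.{k}") for k, v in mraw["stage_hr"].items()},
        stage_hr_se={
            _state(k): _number(v, f"mortality.stage_hr_se.{k}")
            for k, v in (mraw.get("stage_hr_se") or {}).items()
        },
    )

    utilities = {_state(k): _number(v, f"utilities.{k}") for k, v in raw["utilities"].items()}
    utilities_se = {
        _state(k): _number(v, f"utilities_se.{k}") for k, v in (raw.get("utilities_se") or {}).items()
    }

    craw = raw["costs"]
    for key in ("administration", "outpatient", "inpatient"):
        if key not in craw:
            raise ParameterError(f"missing required parameter 'costs.{key}'")
    costs = CostSpec(
        administration=_number(craw["administration"], "costs.administration"),
        outpatient=_number(craw["outpatient"], "costs.outpatient"),
        inpatient=_number(craw["inpatient"], "costs.inpatient"),
        outpatient_se=None if craw.get("outpatient_se") is None else _number(craw["outpatient_se"], "costs.outpatient_se"),
        inpatient_se=None if craw.get("inpatient_se") is None else _number(craw["inpatient_se"], "costs.inpatient_se"),
    )

    sraw = raw["strategies"]
    strategies = []
    for name, s in sraw.items():
        s = s or {}
        population = s.get("population")
        inherited: dict = {}
        if population is not None:
            if population not in sraw:
                raise ParameterError(f"strategy {name!r} references unknown population {population!r}")
            inherited = sraw[population] or {}

        def _field(key, default=None):
            if key in s:
                return s[key]
            if key in inherited:
                return inherited[key]
            return default

        for key in ("start_age", "start_mci_fraction", "aria_rate", "aria_annual_cost"):
            if _field(key) is None:
                raise ParameterError(f"missing required parameter 'strategies.{name}.{key}'")
        schedule = tuple(
            (int(e["from_cycle"]), _number(e["annual_price"], f"strategies.{name}.drug_price_schedule"))
            for e in (s.get("drug_price_schedule") or [])
        )
        hr_map = {
            _parse_pair(k): _number(v, f"strategies.{name}.hr_progression.{k}")
            for k, v in (s.get("hr_progression") or {}).items()
        }
        strategies.append(
            StrategySpec(
                name=name,
                start_age=_number(_field("start_age"), f"strategies.{name}.start_age"),
                start_mci_fraction=_number(_field("start_mci_fraction"), f"strategies.{name}.start_mci_fraction"),
                aria_rate=_number(_field("aria_rate"), f"strategies.{name}.aria_rate"),
                aria_annual_cost=_number(_field("aria_annual_cost"), f"strategies.{name}.aria_annual_cost"),
                drug_price_schedule=schedule,
                hr_progression=hr_map,
                treatment_rule=s.get("treatment_rule", "while_early_AD"),
                discount_rate=None if _field("discount_rate") is None else _number(_field("discount_rate"), f"strategies.{name}.discount_rate"),
                start_age_se=None if _field("start_age_se") is None else _number(_field("start_age_se"), f"strategies.{name}.start_age_se"),
                population=population,
                admin_frequency_factor=_number(
                    s.get("admin_frequency_factor", 1.0), f"strategies.{name}.admin_frequency_factor"
                ),
            )
        )

    conv_raw = raw.get("conventions") or {}
    conventions = ModelConventions(
        hr_method=conv_raw.get("hr_method", "rate_based"),
        half_cycle=bool(conv_raw.get("half_cycle", False)),
        age_cap=_number(conv_raw.get("age_cap", 100.0), "conventions.age_cap"),
        stop_tolerance=_number(conv_raw.get("stop_tolerance", 1e-6), "conventions.stop_tolerance"),
    )

    osa_ranges = {
        str(k): (_number(v[0], f"osa_ranges.{k}"), _number(v[1], f"osa_ranges.{k}"))
        for k, v in (raw.get("osa_ranges") or {}).items()
    }

    params = ParameterSet(
        transitions=transitions,
        mortality=mortality,
        utilities=utilities,
        utilities_se=utilities_se,
        costs=costs,
        strategies=tuple(strategies),
        discount_rate=_number(raw["discount_rate"], "discount_rate"),
        wtp=_number(raw.get("wtp", 150_000.0), "wtp"),
        conventions=conventions,
        osa_ranges=osa_ranges,
    )
    params.psa_distributions = build_psa_distributions(params)
    return params


def parameters_to_dict(params: ParameterSet) -> dict:
    trans: dict[str, dict[str, float]] = {}
    for (a, b), p in params.transitions.items():
        trans.setdefault(a.name, {})[b.name] = p
    out: dict = {
        "conventions": {
            "hr_method": params.conventions.hr_method,
            "half_cycle": params.conventions.half_cycle,
            "age_cap": params.conventions.age_cap,
            "stop_tolerance": params.conventions.stop_tolerance,
        },
        "discount_rate": params.discount_rate,
        "wtp": params.wtp,
        "transitions": trans,
        "mortality": {
            "bands": [
                {"min_age": lo, "max_age": hi, "p": p} for lo, hi, p in params.mortality.bands
            ],
            "stage_hr": {s.name: v for s, v in params.mortality.stage_hr.items()},
            "stage_hr_se": {s.name: v for s, v in params.mortality.stage_hr_se.items()},
        },
        "utilities": {s.name: v for s, v in params.utilities.items()},
        "utilities_se": {s.name: v for s, v in params.utilities_se.items()},
        "costs": {
            "administration": params.costs.administration,
            "outpatient": params.costs.outpatient,
            "inpatient": params.costs.inpatient,
            "outpatient_se": params.costs.outpatient_se,
            "inpatient_se": params.costs.inpatient_se,
        },
        "strategies": {},
        "osa_ranges": {k: list(v) for k, v in params.osa_ranges.items()},
    }
    for s in params.strategies:
        entry: dict = {
            "treatment_rule": s.treatment_rule,
            "start_age": s.start_age,
            "start_mci_fraction": s.start_mci_fraction,
            "aria_rate": s.aria_rate,
            "aria_annual_cost": s.aria_annual_cost,
            "drug_price_schedule": [
                {"from_cycle": c, "annual_price": p} for c, p in s.drug_price_schedule
            ],
        }
        if s.hr_progression:
            entry["hr_progression"] = {_pair_key(k): v for k, v in s.hr_progression.items()}
        if s.admin_frequency_factor != 1.0:
            entry["admin_frequency_factor"] = s.admin_frequency_factor
        if s.discount_rate is not None:
            entry["discount_rate"] = s.discount_rate
        if s.start_age_se is not None:
            entry["start_age_se"] = s.start_age_se
        if s.population is not None:
            entry["population"] = s.population
        out["strategies"][s.name] = entry
    return out


def write_parameters(params: ParameterSet, path: str | Path) -> None:
    """Serialize a ParameterSet to the package's YAML schema (round-trips
    through :func:`load_parameters`)."""
    Path(path).write_text(yaml.safe_dump(parameters_to_dict(params), sort_keys=False))


def default_parameters() -> ParameterSet:
    """The shipped default model configuration (the published input table)."""
    ref = resources.files("adcea").joinpath("data/default_parameters.yaml")
    with resources.as_file(ref) as p:
        return load_parameters(p)


# ---------------------------------------------------------------------------
# validation


def validate(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty when the set is valid).

    Each entry names the offending field and the violated rule.  Violations
    are returned, never raised.
    """
    v: list[str] = []

    for (a, b), p in params.transitions.items():
        if a == b:
            v.append(f"transitions.{_pair_key((a, b))}: self-transition must not be stored (it is the residual)")
        if a == HealthState.DEATH or b == HealthState.DEATH:
            v.append(f"transitions.{_pair_key((a, b))}: death transitions come from the mortality model")
        if not 0.0 <= p <= 1.0:
            v.append(f"transitions.{_pair_key((a, b))}: probability {p} outside [0,1]")
    for s in ALIVE_STATES:
        total = params.row_offdiagonal_sum(s)
        if total > 1.0 + 1e-12:
            v.append(f"transitions from {s.name}: outgoing probabilities sum to {total:.6g} > 1")

    bands = params.mortality.bands
    if not bands:
        v.append("mortality.bands: at least one band required")
    else:
        if bands[-1][1] is not None:
            v.append("mortality.bands: last band must be open-ended (max_age null)")
        prev_hi = None
        for i, (lo, hi, p) in enumerate(bands):
            if not 0.0 < p < 1.0:
                v.append(f"mortality.bands[{i}]: probability {p} outside (0,1)")
            if hi is not None and hi < lo:
                v.append(f"mortality.bands[{i}]: max_age {hi} below min_age {lo}")
            if prev_hi is not None and lo != prev_hi + 1:
                v.append(f"mortality.bands[{i}]: bands must be contiguous ({lo} does not follow {prev_hi})")
            prev_hi = hi
    for s in ALIVE_STATES:
        hr = params.mortality.stage_hr.get(s)
        if hr is None:
            v.append(f"mortality.stage_hr.{s.name}: missing")
        elif hr <= 0:
            v.append(f"mortality.stage_hr.{s.name}: hazard ratio {hr} must be > 0")

    for s in ALIVE_STATES:
        u = params.utilities.get(s)
        if u is None:
            v.append(f"utilities.{s.name}: missing")
        elif not 0.0 <= u <= 1.0:
            v.append(f"utilities.{s.name}: utility {u} outside [0,1]")
    if HealthState.DEATH in params.utilities and params.utilities[HealthState.DEATH] != 0.0:
        v.append("utilities.DEATH: must be 0")

    for name in ("administration", "outpatient", "inpatient"):
        if getattr(params.costs, name) < 0:
            v.append(f"costs.{name}: monetary value must be >= 0")

    n_reference = 0
    for s in params.strategies:
        if not 0.0 <= s.start_mci_fraction <= 1.0:
            v.append(f"strategies.{s.name}.start_mci_fraction: {s.start_mci_fraction} outside [0,1]")
        if s.treatment_rule not in TREATMENT_RULES:
            v.append(f"strategies.{s.name}.treatment_rule: unknown rule {s.treatment_rule!r}")
        if s.aria_rate < 0 or s.aria_rate > 1:
            v.append(f"strategies.{s.name}.aria_rate: {s.aria_rate} outside [0,1]")
        if s.aria_annual_cost < 0:
            v.append(f"strategies.{s.name}.aria_annual_cost: monetary value must be >= 0")
        if s.admin_frequency_factor < 0:
            v.append(f"strategies.{s.name}.admin_frequency_factor: must be >= 0")
        for pair, hr in s.hr_progression.items():
            if hr <= 0:
                v.append(f"strategies.{s.name}.hr_progression.{_pair_key(pair)}: hazard ratio {hr} must be > 0")
        if s.drug_price_schedule:
            if s.drug_price_schedule[0][0] != 0:
                v.append(f"strategies.{s.name}.drug_price_schedule: must cover cycle 0 onward")
            cycles = [c for c, _ in s.drug_price_schedule]
            if cycles != sorted(set(cycles)):
                v.append(f"strategies.{s.name}.drug_price_schedule: cycle starts must be strictly increasing")
            for _, price in s.drug_price_schedule:
                if price < 0:
                    v.append(f"strategies.{s.name}.drug_price_schedule: monetary value must be >= 0")
        if s.discount_rate is not None and not 0.0 <= s.discount_rate <= 0.5:
            v.append(f"strategies.{s.name}.discount_rate: {s.discount_rate} outside [0, 0.5]")
        is_reference = all(hr == 1.0 for hr in s.hr_progression.values()) and not s.has_drug
        n_reference += is_reference
    # a degenerate null intervention duplicating the reference is tolerated
    if len(params.strategies) >= 2 and n_reference == 0:
        v.append("strategies: a reference arm (all HRs 1, no drug cost) is required, found none")

    if not 0.0 <= params.discount_rate <= 0.5:
        v.append(f"discount_rate: {params.discount_rate} outside [0, 0.5]")

    for coll, coll_name in ((params.osa_ranges, "osa_ranges"), (params.psa_distributions, "psa_distributions")):
        for name in coll:
            try:
                get_param(params, name)
            except (KeyError, ParameterError) as exc:
                v.append(f"{coll_name}.{name}: does not resolve to a model field ({exc})")
    for name, (lo, hi) in params.osa_ranges.items():
        if lo > hi:
            v.append(f"osa_ranges.{name}: lower limit {lo} exceeds upper limit {hi}")

    return v


# ---------------------------------------------------------------------------
# flat parameter addressing


def _linked_strategies(params: ParameterSet, name: str) -> list[StrategySpec]:
    """The named strategy plus any arm sharing its cohort description."""
    out = [params.strategy(name)]
    out.extend(s for s in params.strategies if s.population == name)
    return out


def _band_index(params: ParameterSet, label: str) -> int:
    labels = params.mortality.band_labels()
    try:
        return labels.index(label)
    except ValueError:
        raise KeyError(f"no mortality band labelled {label!r} (have {labels})") from None


def get_param(params: ParameterSet, name: str) -> float:
    """Resolve a flat dotted parameter name to its current value."""
    head, _, rest = name.partition(".")
    if name == "discount_rate":
        return params.discount_rate
    if name == "wtp":
        return params.wtp
    if head == "tp":
        return params.transitions[_parse_pair(rest)]
    if head == "utility":
        return params.utilities[_state(rest)]
    if head == "mortality":
        lo, hi, p = params.mortality.bands[_band_index(params, rest)]
        return p
    if head == "mortality_hr":
        return params.mortality.stage_hr[_state(rest)]
    if head == "cost":
        sub, _, strat = rest.partition(".")
        if sub in ("administration", "outpatient", "inpatient"):
            return getattr(params.costs, sub)
        if sub == "aria":
            return params.strategy(strat).aria_annual_cost
        if sub == "drug":
            s = params.strategy(strat)
            if not s.has_drug:
                raise KeyError(f"strategy {strat!r} has no drug price schedule")
            return s.drug_price_schedule[0][1]
        raise KeyError(f"unknown cost parameter {name!r}")
    if head == "aria_rate":
        return params.strategy(rest).aria_rate
    if head == "start_age":
        return params.strategy(rest).start_age
    if head == "start_mci_fraction":
        return params.strategy(rest).start_mci_fraction
    if head == "discount":
        return params.strategy_discount(params.strategy(rest))
    if head == "hr":
        strat, _, pair = rest.partition(".")
        s = params.strategy(strat)
        if pair:
            return s.hr_progression.get(_parse_pair(pair), 1.0)
        if not s.hr_progression:
            raise KeyError(f"strategy {strat!r} has no progression HR entries")
        # the strategy-level HR: the common value, or the first transition's
        # value when the entries have been individually overridden
        return s.hr_progression[min(s.hr_progression)]
    raise KeyError(f"unknown parameter name {name!r}")


def set_param(params: ParameterSet, name: str, value: float) -> None:
    """Set a flat dotted parameter name in place (see :func:`with_param`)."""
    value = float(value)
    head, _, rest = name.partition(".")
    if name == "discount_rate":
        params.discount_rate = value
        return
    if name == "wtp":
        params.wtp = value
        return
    if head == "tp":
        pair = _parse_pair(rest)
        if pair not in params.transitions:
            raise KeyError(f"transition {rest!r} not present in the model")
        params.transitions[pair] = value
        return
    if head == "utility":
        params.utilities[_state(rest)] = value
        return
    if head == "mortality":
        i = _band_index(params, rest)
        bands = list(params.mortality.bands)
        lo, hi, _ = bands[i]
        bands[i] = (lo, hi, value)
        params.mortality.bands = tuple(bands)
        return
    if head == "mortality_hr":
        params.mortality.stage_hr[_state(rest)] = value
        return
    if head == "cost":
        sub, _, strat = rest.partition(".")
        if sub in ("administration", "outpatient", "inpatient"):
            setattr(params.costs, sub, value)
            return
        if sub == "aria":
            params.strategy(strat).aria_annual_cost = value
            return
        if sub == "drug":
            s = params.strategy(strat)
            if not s.has_drug:
                raise KeyError(f"strategy {strat!r} has no drug price schedule")
            base = s.drug_price_schedule[0][1]
            if base == 0:
                raise KeyError(f"strategy {strat!r} has a zero launch price; cannot rescale")
            scale = value / base
            s.drug_price_schedule = tuple((c, p * scale) for c, p in s.drug_price_schedule)
            return
        raise KeyError(f"unknown cost parameter {name!r}")
    if head == "aria_rate":
        params.strategy(rest).aria_rate = value
        return
    if head == "start_age":
        for s in _linked_strategies(params, rest):
            s.start_age = value
        return
    if head == "start_mci_fraction":
        for s in _linked_strategies(params, rest):
            s.start_mci_fraction = value
        return
    if head == "discount":
        for s in _linked_strategies(params, rest):
            s.discount_rate = value
        return
    if head == "hr":
        strat, _, pair = rest.partition(".")
        s = params.strategy(strat)
        if pair:
            s.hr_progression[_parse_pair(pair)] = value
        else:
            if not s.hr_progression:
                raise KeyError(f"strategy {strat!r} has no progression HR entries")
            for key in s.hr_progression:
                s.hr_progression[key] = value
        return
    raise KeyError(f"unknown parameter name {name!r}")


def with_param(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """A deep copy of ``params`` with one flat-named parameter replaced."""
    out = copy.deepcopy(params)
    set_param(out, name, value)
    return out


# ---------------------------------------------------------------------------
# PSA distribution metadata


def build_psa_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Distribution specification for every model parameter.

    Families follow the conventional choices for each parameter class:
    hazard ratios (treatment and stage mortality) are lognormal, utilities
    and transition probabilities are beta, costs are gamma.  Drug prices,
    mortality band rates, starting ages, ARIA occurrence rates and the
    discount rate are fixed.  Reported
    standard errors are attached where they exist; elsewhere the SE is left
    absent and resolved as mean/10 at draw time.
    """
    dists: dict[str, DistributionSpec] = {}

    for s in params.strategies:
        if s.hr_progression:
            values = set(s.hr_progression.values())
            if len(values) == 1:
                dists[f"hr.{s.name}"] = DistributionSpec("lognormal", values.pop())
            else:
                for pair, hr in s.hr_progression.items():
                    dists[f"hr.{s.name}.{_pair_key(pair)}"] = DistributionSpec("lognormal", hr)

    for pair, p in sorted(params.transitions.items()):
        name = f"tp.{_pair_key(pair)}"
        dists[name] = DistributionSpec("beta", p) if 0.0 < p < 1.0 else DistributionSpec("fixed", p)

    for s in ALIVE_STATES:
        dists[f"utility.{s.name}"] = DistributionSpec(
            "beta", params.utilities[s], params.utilities_se.get(s)
        )
        dists[f"mortality_hr.{s.name}"] = DistributionSpec(
            "lognormal", params.mortality.stage_hr[s], params.mortality.stage_hr_se.get(s)
        )

    dists["cost.administration"] = DistributionSpec("gamma", params.costs.administration)
    dists["cost.outpatient"] = DistributionSpec("gamma", params.costs.outpatient, params.costs.outpatient_se)
    dists["cost.inpatient"] = DistributionSpec("gamma", params.costs.inpatient, params.costs.inpatient_se)

    for s in params.strategies:
        if s.aria_annual_cost > 0:
            dists[f"cost.aria.{s.name}"] = DistributionSpec("gamma", s.aria_annual_cost)
        if s.has_drug:
            dists[f"cost.drug.{s.name}"] = DistributionSpec("fixed", s.drug_price_schedule[0][1])
        if s.population is None:
            # starting ages have no stated sampling family and interact with
            # the discrete mortality-band lookup, so they stay fixed in the PSA
            dists[f"start_age.{s.name}"] = DistributionSpec("fixed", s.start_age)
        dists[f"aria_rate.{s.name}"] = DistributionSpec("fixed", s.aria_rate)

    for label, (lo, hi, p) in zip(params.mortality.band_labels(), params.mortality.bands):
        dists[f"mortality.{label}"] = DistributionSpec("fixed", p)

    dists["discount_rate"] = DistributionSpec("fixed", params.discount_rate)
    return dists


def params_audit(params: ParameterSet) -> pd.DataFrame:
    """Normalized one-row-per-parameter dump for audit.

    Columns: parameter name, base value, PSA standard error (resolved,
    0 for fixed parameters), distribution family, one-way range limits.
    """
    names = sorted(set(params.psa_distributions) | set(params.osa_ranges))
    rows = []
    for name in names:
        spec = params.psa_distributions.get(name)
        lo, hi = params.osa_ranges.get(name, (None, None))
        rows.append(
            {
                "parameter": name,
                "value": get_param(params, name),
                "se": resolve_psa_se(spec) if spec else None,
                "family": spec.family if spec else None,
                "osa_low": lo,
                "osa_high": hi,
            }
        )
    return pd.DataFrame(rows)
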