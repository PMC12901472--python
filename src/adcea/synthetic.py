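"""Synthetic model instances and analytic fixtures.

Random but structurally valid model configurations (valid transition rows,
strictly decreasing utilities, three-band mortality, non-negative costs,
a known ground-truth treatment hazard ratio) exercise every stage of the
pipeline without the shipped default file, and a degenerate single-state
instance provides a closed-form oracle for the cohort engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import CohortTrace, state_mortality
from .parameters import (
    CostSpec,
    ModelConventions,
    MortalitySpec,
    ParameterSet,
    StrategySpec,
    build_psa_distributions,
)
from .states import ALIVE_STATES, HealthState


@dataclass
class SyntheticSpec:
    """Knobs of the random instance generator.

    ``progression_intensity`` scales the forward transition probabilities
    (must leave every off-diagonal row sum below 0.9); ``effect_hr`` is the
    ground-truth hazard ratio of the synthetic intervention on every
    forward transition.
    """

    seed: int
    n_alive_states: int = 4
    progression_intensity: float = 0.3
    effect_hr: float = 0.7
    cost_range: tuple[float, float] = (1_000.0, 30_000.0)
    utility_range: tuple[float, float] = (0.3, 0.9)
    drug_price: float = 20_000.0
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if not 1 <= self.n_alive_states <= 4:
            raise ValueError("n_alive_states must be in 1..4")
        if not 0.0 < self.progression_intensity <= 0.8:
            raise ValueError("progression_intensity must be in (0, 0.8] to keep rows valid")
        if self.effect_hr <= 0:
            raise ValueError("effect_hr must be > 0")


def generate_instance(spec: SyntheticSpec) -> ParameterSet:
    """A full two-arm model instance, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    active = ALIVE_STATES[: spec.n_alive_states]

    transitions: dict[tuple[HealthState, HealthState], float] = {}
    forward_pairs: list[tuple[HealthState, HealthState]] = []
    for i, frm in enumerate(active):
        if i + 1 < len(active):
            to = active[i + 1]
            transitions[(frm, to)] = spec.progression_intensity * rng.uniform(0.5, 1.0)
            forward_pairs.append((frm, to))
        if i > 0:
            transitions[(active[i], active[i - 1])] = rng.uniform(0.0, 0.05)

    p1 = rng.uniform(0.01, 0.05)
    p2 = rng.uniform(p1, 0.10)
    p3 = rng.uniform(p2, 0.30)
    stage_hr = {}
    hr = 1.0
    for s in ALIVE_STATES:
        hr *= rng.uniform(1.0, 2.0) if s in active else 1.0
        stage_hr[s] = hr
    mortality = MortalitySpec(
        bands=((65.0, 74.0, p1), (75.0, 84.0, p2), (85.0, None, p3)), stage_hr=stage_hr
    )

    lo, hi = spec.utility_range
    draws = np.sort(rng.uniform(lo, hi, size=4))[::-1]
    # strictly decreasing with severity so monotonicity checks bite
    utilities = {s: float(draws[i] - i * 1e-6) for i, s in enumerate(ALIVE_STATES)}

    clo, chi = spec.cost_range
    costs = CostSpec(
        administration=float(rng.uniform(0.0, clo)),
        outpatient=float(rng.uniform(clo, chi)),
        inpatient=float(rng.uniform(clo, chi)),
    )

    start_mci = 1.0 if spec.n_alive_states == 1 else float(rng.uniform(0.4, 0.8))
    start_age = float(rng.uniform(66.0, 80.0))
    soc = StrategySpec(
        name="soc",
        start_age=start_age,
        start_mci_fraction=start_mci,
        aria_rate=float(rng.uniform(0.0, 0.1)),
        aria_annual_cost=float(rng.uniform(0.0, 200.0)),
        treatment_rule="none",
    )
    if spec.drug_price > 0:
        intervention = StrategySpec(
            name="intervention",
            start_age=start_age,
            start_mci_fraction=start_mci,
            aria_rate=float(rng.uniform(0.0, 0.2)),
            aria_annual_cost=float(rng.uniform(0.0, 300.0)),
            drug_price_schedule=((0, spec.drug_price),),
            hr_progression={pair: spec.effect_hr for pair in forward_pairs},
            treatment_rule="while_early_AD",
        )
    else:
        # null intervention: no drug, same monitoring as the reference arm,
        # so an effect HR of 1 makes the two arms exactly identical
        intervention = StrategySpec(
            name="intervention",
            start_age=start_age,
            start_mci_fraction=start_mci,
            aria_rate=soc.aria_rate,
            aria_annual_cost=soc.aria_annual_cost,
            hr_progression={pair: spec.effect_hr for pair in forward_pairs},
            treatment_rule="none",
        )

    params = ParameterSet(
        transitions=transitions,
        mortality=mortality,
        utilities=utilities,
        costs=costs,
        strategies=(soc, intervention),
        discount_rate=spec.discount_rate,
        osa_ranges={
            "cost.inpatient": (costs.inpatient * 0.8, costs.inpatient * 1.2),
            "utility.MCI": (utilities[HealthState.MCI] * 0.8, min(1.0, utilities[HealthState.MCI] * 1.2)),
        },
    )
    if forward_pairs:
        first = forward_pairs[0]
        key = f"hr.intervention.{first[0].name}->{first[1].name}"
        params.osa_ranges[key] = (spec.effect_hr * 0.8, spec.effect_hr * 1.2)
    params.psa_distributions = build_psa_distributions(params)
    return params


def analytic_two_state_fixture(
    p_death: float, discount: float, cycles: int
) -> tuple[ParameterSet, float]:
    """A one-alive-state instance with constant death probability and its
    closed-form discounted life expectancy over ``cycles`` reward years:
    sum_t ((1-p)/(1+d))**t for t = 0..cycles-1."""
    if not 0.0 < p_death < 1.0:
        raise ValueError("p_death must be in (0,1)")
    params = ParameterSet(
        transitions={},
        mortality=MortalitySpec(
            bands=((65.0, None, p_death),), stage_hr={s: 1.0 for s in ALIVE_STATES}
        ),
        utilities={s: 1.0 for s in ALIVE_STATES},
        costs=CostSpec(administration=0.0, outpatient=0.0, inpatient=0.0),
        strategies=(
            StrategySpec(
                name="soc",
                start_age=70.0,
                start_mci_fraction=1.0,
                aria_rate=0.0,
                aria_annual_cost=0.0,
                treatment_rule="none",
            ),
        ),
        discount_rate=discount,
        conventions=ModelConventions(age_cap=math.inf, stop_tolerance=0.0),
    )
    ratio = (1.0 - p_death) / (1.0 + discount)
    expected_ly = sum(ratio**t for t in range(cycles))
    return params, expected_ly


def recover_hr(
    params: ParameterSet,
    trace: CohortTrace,
    from_state: HealthState,
    to_state: HealthState,
    method: str | None = None,
) -> float | None:
    """Invert the engine's hazard-ratio transform from a one-step trace.

    The trace must start with the whole cohort in ``from_state``; the
    observed first-cycle fraction in ``to_state`` is unscaled by the
    competing death risk and inverted through the configured (or given)
    HR-to-probability method against the reference-arm probability.
    Returns None when the source state starts empty.
    """
    occ0 = trace.occupancy[0]
    if occ0[from_state] == 0.0:
        return None
    if not math.isclose(occ0[from_state], 1.0):
        raise ValueError("recover_hr needs a probe cohort concentrated in the source state")
    method = method or params.conventions.hr_method
    p_death = state_mortality(trace.ages[0], from_state, params.mortality)
    observed = trace.occupancy[1][to_state] / (1.0 - p_death)
    p0 = params.transition(from_state, to_state)
    if method == "rate_based":
        return math.log1p(-observed) / math.log1p(-p0)
    return observed / p0
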