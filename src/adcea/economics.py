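"""Discounted accumulation of costs and effects, and incremental analysis.

Rewards attach to the start-of-cycle occupancy (cycle 0 undiscounted)
unless the half-cycle convention is on, in which case the mean of the
start- and end-of-cycle occupancies is used.  Per cycle:

* life-years: the alive fraction;
* QALYs: occupancy weighted by state utilities (death has utility 0);
* costs: outpatient + inpatient on the alive fraction, plus, for treated
  arms, (drug price for the cycle + administration + ARIA monitoring) on
  the treated fraction; untreated arms accrue their ARIA monitoring cost
  on the alive fraction.

The incremental analysis divides unrounded cost deltas by unrounded
effect deltas (ICER per QALY and per LY) and labels dominance.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace, simulate_cohort
from .parameters import CostSpec, ParameterSet, StrategySpec
from .states import ALIVE_STATES, HealthState

#: Pairwise comparisons of the shipped three-arm model, in display order.
STANDARD_PAIRS = (
    ("aducanumab", "soc"),
    ("lecanemab", "soc"),
    ("lecanemab", "aducanumab"),
)


def discount_factor(rate: float, cycle: int) -> float:
    """1/(1+rate)**cycle; cycle 0 is undiscounted."""
    if rate < 0:
        raise ValueError(f"discount rate {rate} must be >= 0")
    return (1.0 + rate) ** (-cycle)


def aria_annual_cost(mri_unit_cost: float, aria_rate: float) -> float:
    """Annual ARIA monitoring cost: three extra MRI scans per event times
    the annual event rate."""
    if mri_unit_cost < 0 or aria_rate < 0:
        raise ValueError("MRI unit cost and ARIA rate must be >= 0")
    return 3.0 * mri_unit_cost * aria_rate


def cycle_cost(
    strategy: StrategySpec,
    occupancy_row: np.ndarray,
    on_treatment: float,
    cycle: int,
    costs: CostSpec,
) -> float:
    """Undiscounted US$ accrued in one cycle by one cohort row."""
    alive = float(occupancy_row[: HealthState.DEATH].sum())
    total = (costs.outpatient + costs.inpatient) * alive
    if strategy.has_drug:
        total += (
            strategy.drug_price(cycle)
            + costs.administration * strategy.admin_frequency_factor
            + strategy.aria_annual_cost
        ) * on_treatment
    else:
        total += strategy.aria_annual_cost * alive
    return total


@dataclass
class EconResult:
    """Discounted and undiscounted lifetime totals for one strategy."""

    strategy_name: str
    ly: float
    qaly: float
    cost: float
    ly_undiscounted: float
    qaly_undiscounted: float
    cost_undiscounted: float


def _reward_rows(trace: CohortTrace, half_cycle: bool):
    """Yield (cycle, occupancy row, treated fraction) per lived cycle."""
    for t in range(trace.n_cycles):
        if half_cycle:
            yield (
                t,
                0.5 * (trace.occupancy[t] + trace.occupancy[t + 1]),
                0.5 * (trace.on_treatment[t] + trace.on_treatment[t + 1]),
            )
        else:
            yield t, trace.occupancy[t], trace.on_treatment[t]


def accumulate(trace: CohortTrace, params: ParameterSet, strategy: StrategySpec) -> EconResult:
    """Discounted and undiscounted LY, QALY and cost totals for a trace."""
    rate = params.strategy_discount(strategy)
    u = np.zeros(len(HealthState))
    for s in ALIVE_STATES:
        u[s] = params.utilities[s]
    ly = qaly = cost = ly_u = qaly_u = cost_u = 0.0
    for t, row, treated in _reward_rows(trace, params.conventions.half_cycle):
        df = discount_factor(rate, t)
        alive = float(row[: HealthState.DEATH].sum())
        q = float(row @ u)
        c = cycle_cost(strategy, row, treated, t, params.costs)
        ly += alive * df
        qaly += q * df
        cost += c * df
        ly_u += alive
        qaly_u += q
        cost_u += c
    return EconResult(trace.strategy_name, ly, qaly, cost, ly_u, qaly_u, cost_u)


def evaluate_strategies(
    params: ParameterSet, names: tuple[str, ...] | None = None, horizon: int | None = None
) -> dict[str, EconResult]:
    """Simulate and accumulate every requested strategy of the model."""
    out: dict[str, EconResult] = {}
    for s in params.strategies:
        if names is not None and s.name not in names:
            continue
        out[s.name] = accumulate(simulate_cohort(params, s, horizon=horizon), params, s)
    return out


@dataclass
class IncrementalResult:
    """Pairwise deltas and ICERs; ``label`` is '' for an ordinary trade-off,
    'dominant' (cheaper and more effective), 'dominated' (costlier and less
    effective) or 'undefined' (zero effect delta with nonzero cost delta)."""

    intervention: str
    reference: str
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    label: str
    cost_effective: bool | None = None


def _pairwise(a: EconResult, b: EconResult, wtp: float | None) -> IncrementalResult:
    dc = a.cost - b.cost
    dly = a.ly - b.ly
    dq = a.qaly - b.qaly
    icer_q = dc / dq if dq != 0.0 else None
    icer_l = dc / dly if dly != 0.0 else None
    if dc > 0 and dq < 0:
        label = "dominated"
    elif dc < 0 and dq > 0:
        label = "dominant"
    elif dq == 0.0 and dc != 0.0:
        label = "undefined"
    else:
        label = ""
    if wtp is None:
        ce = None
    elif label == "dominant":
        ce = True
    elif label in ("dominated", "undefined"):
        ce = False
    else:
        ce = bool(dq > 0 and icer_q < wtp) if icer_q is not None else True
    return IncrementalResult(a.strategy_name, b.strategy_name, dc, dly, dq, icer_q, icer_l, label, ce)


def incremental_analysis(
    results: dict[str, EconResult],
    pairs: tuple[tuple[str, str], ...] = STANDARD_PAIRS,
    wtp: float | None = None,
) -> list[IncrementalResult]:
    """Pairwise incremental comparison on unrounded accumulations."""
    out = []
    for intervention, reference in pairs:
        out.append(_pairwise(results[intervention], results[reference], wtp))
    return out


def base_case(
    params: ParameterSet, pairs: tuple[tuple[str, str], ...] = STANDARD_PAIRS
) -> tuple[dict[str, EconResult], list[IncrementalResult]]:
    """Full deterministic evaluation: every strategy plus pairwise analysis."""
    results = evaluate_strategies(params)
    return results, incremental_analysis(results, pairs, wtp=params.wtp)


_DISPLAY = {"soc": "SoC", "lecanemab": "Lecanemab", "aducanumab": "Aducanumab"}


def display_name(name: str, leading: bool = True) -> str:
    label = _DISPLAY.get(name, name.capitalize() if leading else name)
    if not leading and label not in ("SoC",):
        label = label[0].lower() + label[1:]
    return label


def comparison_label(pair: tuple[str, str]) -> str:
    return f"{display_name(pair[0])} vs. {display_name(pair[1], leading=False)}"


def base_case_frames(
    params: ParameterSet, pairs: tuple[tuple[str, str], ...] = STANDARD_PAIRS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-strategy and per-comparison tables (2-decimal display rounding;
    all arithmetic at full precision)."""
    results, increments = base_case(params, pairs)
    strat_rows = [
        {
            "strategy": display_name(r.strategy_name),
            "cost": round(r.cost, 2),
            "ly": round(r.ly, 2),
            "qaly": round(r.qaly, 2),
            "cost_undiscounted": round(r.cost_undiscounted, 2),
            "ly_undiscounted": round(r.ly_undiscounted, 2),
            "qaly_undiscounted": round(r.qaly_undiscounted, 2),
        }
        for r in results.values()
    ]
    comp_rows = [
        {
            "comparison": comparison_label((inc.intervention, inc.reference)),
            "incremental_cost": round(inc.delta_cost, 2),
            "incremental_ly": round(inc.delta_ly, 2),
            "incremental_qaly": round(inc.delta_qaly, 2),
            "icer_per_ly": None if inc.icer_per_ly is None else round(inc.icer_per_ly, 2),
            "icer_per_qaly": None if inc.icer_per_qaly is None else round(inc.icer_per_qaly, 2),
            "label": inc.label,
            "cost_effective_at_wtp": inc.cost_effective,
        }
        for inc in increments
    ]
    return pd.DataFrame(strat_rows), pd.DataFrame(comp_rows)


def value_based_price(
    params: ParameterSet, strategy_name: str, reference_name: str, wtp: float
) -> float | None:
    """Annual drug price at which the strategy's ICER versus the reference
    equals the willingness-to-pay threshold.

    The drug price enters the discounted cost linearly (effects are price
    independent), so the threshold price is solved in closed form from one
    zero-price evaluation.  Returns None when the strategy gains no QALYs
    over the reference (no finite price can reach the threshold).
    """
    strategy = params.strategy(strategy_name)
    if not strategy.has_drug:
        raise ValueError(f"strategy {strategy_name!r} has no drug price schedule")
    reference = params.strategy(reference_name)

    zero_priced = copy.deepcopy(strategy)
    zero_priced.drug_price_schedule = ((0, 0.0),)
    trace = simulate_cohort(params, zero_priced)
    econ_zero = accumulate(trace, params, zero_priced)
    econ_ref = accumulate(simulate_cohort(params, reference), params, reference)

    dq = econ_zero.qaly - econ_ref.qaly
    if dq <= 0:
        return None
    rate = params.strategy_discount(strategy)
    weight = sum(
        treated * discount_factor(rate, t)
        for t, _, treated in _reward_rows(trace, params.conventions.half_cycle)
    )
    if weight <= 0:
        return None
    return (wtp * dq - (econ_zero.cost - econ_ref.cost)) / weight
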