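"""Cohort engine: per-cycle transition matrices and lifetime simulation.

The cohort is deterministic (no microsimulation): a single age track starts
at the strategy's starting age and advances one year per cycle; the state
occupancy vector is propagated through an age-dependent row-stochastic
matrix rebuilt each cycle.

Matrix construction, per alive from-state:

1. the death entry is the age-band mortality times the stage mortality HR,
   capped at 1;
2. each alive-to-alive probability is the reference-arm annual probability
   with the strategy's hazard ratio applied, then scaled by (1 - p_death)
   so that death takes precedence as a competing risk;
3. the diagonal is the residual, which the scaling guarantees nonnegative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import MortalitySpec, ParameterSet, StrategySpec
from .states import ALIVE_STATES, N_STATES, HealthState

HR_METHODS = ("rate_based", "multiplicative")


def base_mortality(age: float, mortality: MortalitySpec) -> float:
    """Annual all-cause death probability for the band containing floor(age)."""
    a = math.floor(age)
    for lo, hi, p in mortality.bands:
        if a >= lo and (hi is None or a <= hi):
            return p
    lo0 = mortality.bands[0][0]
    raise ValueError(f"age {age} below the supported mortality range (ages >= {lo0:g})")


def state_mortality(age: float, state: HealthState, mortality: MortalitySpec) -> float:
    """Annual death probability in a given alive state: band mortality scaled
    by the stage hazard ratio, capped at 1."""
    if state == HealthState.DEATH:
        raise ValueError("state_mortality is defined for alive states only")
    return min(1.0, base_mortality(age, mortality) * mortality.stage_hr[state])


def apply_hazard_ratio(p: float, hr: float, method: str = "rate_based") -> float:
    """Apply a hazard ratio to an annual transition probability.

    ``rate_based`` converts through the constant-rate identity,
    p' = 1 - (1-p)**hr; ``multiplicative`` uses min(1, p*hr).
    """
    if method not in HR_METHODS:
        raise ValueError(f"unknown hr method {method!r}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0,1]")
    if hr <= 0.0:
        raise ValueError(f"hazard ratio {hr} must be > 0")
    if method == "rate_based":
        if p == 1.0 and hr != 1.0:
            raise ValueError("p = 1 has no finite annual rate; hazard ratio undefined")
        return 1.0 - (1.0 - p) ** hr
    return min(1.0, p * hr)


def build_transition_matrix(params: ParameterSet, strategy: StrategySpec, age: float) -> np.ndarray:
    """The 5x5 row-stochastic one-cycle matrix at a given cohort age."""
    method = params.conventions.hr_method
    m = np.zeros((N_STATES, N_STATES))
    m[HealthState.DEATH, HealthState.DEATH] = 1.0
    for i in ALIVE_STATES:
        p_death = state_mortality(age, i, params.mortality)
        off = 0.0
        for j in ALIVE_STATES:
            if i == j:
                continue
            p0 = params.transition(i, j)
            if p0 == 0.0:
                continue
            q = apply_hazard_ratio(p0, strategy.hr_progression.get((i, j), 1.0), method)
            off += q
            m[i, j] = q * (1.0 - p_death)
        if off > 1.0 + 1e-9:
            raise ValueError(
                f"outgoing probabilities from {i.name} sum to {off:.6g} > 1 after HR adjustment"
            )
        m[i, HealthState.DEATH] = p_death
        residual = 1.0 - p_death - m[i, : HealthState.DEATH].sum()
        if residual < -1e-12:
            raise ValueError(f"negative residual self-transition for {i.name}: {residual:.3g}")
        m[i, i] = max(residual, 0.0)
    return m


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one simulated strategy.

    ``occupancy`` has one row per cycle boundary (row 0 is the pre-transition
    start state), ``ages`` the cohort age at each boundary, and
    ``on_treatment`` the fraction of the cohort accruing drug-related costs
    under the strategy's treatment rule.
    """

    strategy_name: str
    occupancy: np.ndarray
    ages: np.ndarray
    on_treatment: np.ndarray

    @property
    def n_cycles(self) -> int:
        """Number of transition steps taken (rows minus one)."""
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, : HealthState.DEATH].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df["on_treatment"] = self.on_treatment
        return df


def _treated_fraction(occupancy: np.ndarray, rule: str) -> np.ndarray:
    if rule == "none":
        return np.zeros(occupancy.shape[0])
    if rule == "lifetime":
        return occupancy[:, : HealthState.DEATH].sum(axis=1)
    if rule == "while_early_AD":
        return occupancy[:, HealthState.MCI] + occupancy[:, HealthState.MILD]
    raise ValueError(f"unknown treatment rule {rule!r}")


def simulate_cohort(
    params: ParameterSet, strategy: StrategySpec, horizon: int | None = None
) -> CohortTrace:
    """Propagate the cohort from the starting distribution to the lifetime
    horizon (age cap, alive-fraction tolerance, or an explicit cycle count,
    whichever stops first)."""
    if horizon is not None and horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    conv = params.conventions
    occ = strategy.start_distribution.astype(float)
    rows = [occ]
    t = 0
    while True:
        age = strategy.start_age + t
        if age >= conv.age_cap:
            break
        if occ[: HealthState.DEATH].sum() < conv.stop_tolerance:
            break
        if horizon is not None and t >= horizon:
            break
        occ = occ @ build_transition_matrix(params, strategy, age)
        t += 1
        rows.append(occ)
    occupancy = np.vstack(rows)
    ages = strategy.start_age + np.arange(occupancy.shape[0], dtype=float)
    return CohortTrace(
        strategy_name=strategy.name,
        occupancy=occupancy,
        ages=ages,
        on_treatment=_treated_fraction(occupancy, strategy.treatment_rule),
    )
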