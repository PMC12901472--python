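"""Health states of the disease-progression model.

The cohort moves through mild cognitive impairment (MCI) due to AD, three
dementia stages (mild, moderate, severe), and death.  Death is the unique
absorbing state; MCI and mild dementia together form the "early AD"
population eligible for anti-amyloid treatment.
"""

from enum import IntEnum


class HealthState(IntEnum):
    MCI = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    DEATH = 4


ALIVE_STATES: tuple[HealthState, ...] = (
    HealthState.MCI,
    HealthState.MILD,
    HealthState.MODERATE,
    HealthState.SEVERE,
)

EARLY_AD_STATES: tuple[HealthState, ...] = (HealthState.MCI, HealthState.MILD)

N_STATES = 5
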