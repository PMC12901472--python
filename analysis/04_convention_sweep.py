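"""Sweep of the unstated modelling conventions against the published table.

The published analysis leaves four structural choices open: how a hazard
ratio acts on an annual probability (rate-based vs multiplicative), when
treatment costs stop accruing (while in early AD vs lifetime), whether a
half-cycle correction applies, and whether the reference arm shares the
antibody-trial starting state mix (the published increments are exactly
additive across the three comparisons, which requires a common starting
cohort).  This script enumerates the grid, scores each configuration by its
maximum relative error against the published incremental table, and shows
that the shipped frozen configuration (multiplicative, while_early_AD, no
half-cycle, shared start mix) is the minimizer.

Writes results/convention_sweep.csv.
"""

import copy
import itertools
from pathlib import Path

import pandas as pd

import adcea

OUT = Path(__file__).resolve().parent.parent / "results"

# published incremental table: (dCost, dLY, dQALY, ICER/LY, ICER/QALY);
# effect deltas back-solved to full precision from the printed ICERs
PUBLISHED = {
    ("aducanumab", "soc"): (101_770.83, 0.08226, 0.07513, 1_237_130.61, 1_354_544.47),
    ("lecanemab", "soc"): (131_789.80, 0.33302, 0.32184, 395_747.84, 409_488.34),
    ("lecanemab", "aducanumab"): (30_018.97, 0.25073, 0.24671, 119_716.27, 121_678.49),
}


def max_relative_error(params) -> float:
    _, increments = adcea.base_case(params)
    worst = 0.0
    for inc in increments:
        ref = PUBLISHED[(inc.intervention, inc.reference)]
        ours = (inc.delta_cost, inc.delta_ly, inc.delta_qaly, inc.icer_per_ly, inc.icer_per_qaly)
        worst = max(worst, max(abs(a - b) / abs(b) for a, b in zip(ours, ref)))
    return worst


def main() -> None:
    OUT.mkdir(exist_ok=True)
    base = adcea.default_parameters()
    rows = []
    grid = itertools.product(
        ("rate_based", "multiplicative"),
        ("while_early_AD", "lifetime"),
        (False, True),
        (True, False),  # shared start mix across arms?
    )
    for hr_method, rule, half_cycle, shared_start in grid:
        params = copy.deepcopy(base)
        params.conventions.hr_method = hr_method
        params.conventions.half_cycle = half_cycle
        for s in params.strategies:
            if s.treatment_rule != "none":
                s.treatment_rule = rule
        if not shared_start:
            params.strategy("soc").start_mci_fraction = 0.662  # trial placebo mix
        rows.append(
            {
                "hr_method": hr_method,
                "treatment_rule": rule,
                "half_cycle": half_cycle,
                "shared_start_mix": shared_start,
                "max_relative_error": max_relative_error(params),
            }
        )
    df = pd.DataFrame(rows).sort_values("max_relative_error").reset_index(drop=True)
    df.to_csv(OUT / "convention_sweep.csv", index=False)
    print(df.to_string(index=False))
    best = df.iloc[0]
    print(
        f"\nBest configuration: {best.hr_method}, {best.treatment_rule}, "
        f"half_cycle={best.half_cycle}, shared_start_mix={best.shared_start_mix} "
        f"(max relative error {best.max_relative_error:.3f}) — this is the "
        "configuration frozen in the shipped parameter file."
    )


if __name__ == "__main__":
    main()
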