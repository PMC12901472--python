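"""One-way (tornado) and probabilistic (Monte Carlo / CEAC) sensitivity.

The one-way analysis re-runs the full base case twice per parameter, at the
lower and upper limit of its range, holding everything else fixed — no
incremental shortcuts — and ranks parameters by ICER spread.

The probabilistic analysis draws every uncertain parameter independently
from its family (lognormal hazard ratios, beta utilities and transition
probabilities, gamma costs), moment-matched so that the distribution MEAN
equals the deterministic value and the SD equals the standard error.  Drug
prices, mortality band rates, starting ages and the discount rate stay
fixed in every draw.  All three arms are evaluated on the same draw,
so incremental deltas are additive across comparisons within a sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .economics import STANDARD_PAIRS, EconResult, evaluate_strategies, incremental_analysis
from .parameters import (
    DistributionSpec,
    ParameterError,
    ParameterSet,
    resolve_psa_se,
    set_param,
    validate,
    with_param,
)
from .states import ALIVE_STATES

# ---------------------------------------------------------------------------
# moment matching


def beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Shape parameters (alpha, beta) with the given mean and SD."""
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"beta moment matching infeasible: se^2 = {var:.3g} >= mean(1-mean) = {mean * (1 - mean):.3g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """(shape, scale) with the given mean and SD."""
    return (mean / se) ** 2, se * se / mean


def lognormal_moments(mean: float, se: float) -> tuple[float, float]:
    """(mu, sigma) of log-space such that the distribution mean (not the
    median) equals ``mean`` and the SD equals ``se``."""
    sigma2 = math.log1p((se / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _sample(spec: DistributionSpec, se: float, rng: np.random.Generator, name: str) -> float:
    try:
        if spec.family == "beta":
            a, b = beta_moments(spec.mean, se)
            return float(rng.beta(a, b))
        if spec.family == "gamma":
            shape, scale = gamma_moments(spec.mean, se)
            return float(rng.gamma(shape, scale))
        if spec.family == "lognormal":
            mu, sigma = lognormal_moments(spec.mean, se)
            return float(rng.lognormal(mu, sigma))
    except ParameterError as exc:
        raise ParameterError(f"parameter {name!r}: {exc}") from exc
    raise ParameterError(f"parameter {name!r}: cannot sample family {spec.family!r}")


# ---------------------------------------------------------------------------
# one-way sensitivity


@dataclass
class TornadoEntry:
    """One tornado bar: the comparison ICER at the parameter's two limits.

    ``spread`` is |icer_high - icer_low|, infinite when a limit makes the
    QALY delta change sign (dominance at one end).
    """

    parameter: str
    low_input: float
    high_input: float
    icer_low: float | None
    icer_high: float | None
    label_low: str
    label_high: str
    spread: float


def _comparison_icer(
    params: ParameterSet, comparison: tuple[str, str]
) -> tuple[float | None, str]:
    results = evaluate_strategies(params, names=tuple(set(comparison)))
    inc = incremental_analysis(results, (comparison,))[0]
    return inc.icer_per_qaly, inc.label


def one_way_sensitivity(
    params: ParameterSet, comparison: tuple[str, str] = ("lecanemab", "aducanumab")
) -> list[TornadoEntry]:
    """Tornado entries for every configured one-way range, sorted by spread
    (descending; ties broken by parameter name).  A limit that violates a
    model invariant skips the parameter with a warning."""
    entries: list[TornadoEntry] = []
    for name, (lo, hi) in params.osa_ranges.items():
        outputs = []
        skipped = False
        for bound in (lo, hi):
            candidate = with_param(params, name, bound)
            violations = validate(candidate)
            if violations:
                warnings.warn(
                    f"one-way limit {bound} for {name!r} violates model invariants; skipped: "
                    + "; ".join(violations)
                )
                skipped = True
                break
            outputs.append(_comparison_icer(candidate, comparison))
        if skipped:
            continue
        (icer_lo, label_lo), (icer_hi, label_hi) = outputs
        if icer_lo is not None and icer_hi is not None and label_lo == label_hi == "":
            spread = abs(icer_hi - icer_lo)
        elif icer_lo is not None and icer_hi is not None:
            spread = abs(icer_hi - icer_lo) if (icer_lo > 0) == (icer_hi > 0) else math.inf
        else:
            spread = math.inf
        entries.append(TornadoEntry(name, lo, hi, icer_lo, icer_hi, label_lo, label_hi, spread))
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return entries


# ---------------------------------------------------------------------------
# probabilistic sensitivity


def draw_parameters(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One Monte Carlo draw of the uncertain parameters.

    Parameters are drawn independently in sorted-name order (reproducible
    for a given generator state).  A transition row whose drawn outgoing
    probabilities exceed 1 is redrawn wholesale.
    """
    import copy

    out = copy.deepcopy(params)
    names = sorted(out.psa_distributions)

    def _draw_one(name: str) -> None:
        spec = out.psa_distributions[name]
        se = resolve_psa_se(spec)
        if spec.family == "fixed" or se == 0.0:
            return
        set_param(out, name, _sample(spec, se, rng, name))

    for name in names:
        _draw_one(name)

    for state in ALIVE_STATES:
        row_names = [
            n for n in names if n.startswith("tp.") and n.split(".", 1)[1].split("->")[0] == state.name
        ]
        tries = 0
        while out.row_offdiagonal_sum(state) > 1.0:
            for n in row_names:
                _draw_one(n)
            tries += 1
            if tries > 1000:
                raise ParameterError(f"transition row {state.name} infeasible after 1000 redraws")
    return out


@dataclass
class PsaSample:
    """One Monte Carlo evaluation: per-comparison (delta cost, delta QALY,
    delta LY) on a single joint parameter draw."""

    index: int
    deltas: dict[tuple[str, str], tuple[float, float, float]]
    params: ParameterSet | None = None


def run_psa(
    params: ParameterSet,
    n_draws: int,
    seed: int,
    comparisons: tuple[tuple[str, str], ...] = STANDARD_PAIRS,
    keep_params: bool = False,
) -> list[PsaSample]:
    """``n_draws`` full model evaluations on seeded joint parameter draws."""
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    arm_names = tuple({name for pair in comparisons for name in pair})
    rng = np.random.default_rng(seed)
    samples: list[PsaSample] = []
    for i in range(n_draws):
        drawn = draw_parameters(params, rng)
        results: dict[str, EconResult] = evaluate_strategies(drawn, names=arm_names)
        deltas = {}
        for a, b in comparisons:
            deltas[(a, b)] = (
                results[a].cost - results[b].cost,
                results[a].qaly - results[b].qaly,
                results[a].ly - results[b].ly,
            )
        samples.append(PsaSample(i, deltas, drawn if keep_params else None))
    return samples


@dataclass
class CeacCurve:
    """Probability cost-effective over a willingness-to-pay grid."""

    comparison: tuple[str, str]
    wtp: np.ndarray
    probability: np.ndarray


def default_wtp_grid(stop: float = 2_000_000.0, step: float = 10_000.0) -> np.ndarray:
    return np.arange(0.0, stop + step / 2, step)


def ceac(
    samples: list[PsaSample],
    wtp_grid: np.ndarray,
    comparisons: tuple[tuple[str, str], ...] | None = None,
) -> dict[tuple[str, str], CeacCurve]:
    """Acceptability curves: at each threshold, the fraction of draws with
    positive net monetary benefit (wtp * dQALY - dCost > 0)."""
    if not samples:
        raise ValueError("samples must be non-empty")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if np.any(np.diff(wtp_grid) <= 0):
        raise ValueError("wtp grid must be strictly ascending")
    if comparisons is None:
        comparisons = tuple(samples[0].deltas)
    curves = {}
    for pair in comparisons:
        dc = np.array([s.deltas[pair][0] for s in samples])
        dq = np.array([s.deltas[pair][1] for s in samples])
        nmb = wtp_grid[:, None] * dq[None, :] - dc[None, :]
        curves[pair] = CeacCurve(pair, wtp_grid, (nmb > 0).mean(axis=1))
    return curves


def ceac_multiway(
    samples: list[PsaSample], wtp_grid: np.ndarray, reference: str = "soc"
) -> dict[str, CeacCurve]:
    """Multi-strategy acceptability curves: at each threshold, the fraction
    of draws in which each strategy has the highest net monetary benefit.

    Uses the per-comparison deltas versus the common reference arm (whose
    own NMB is 0 by construction), so the curves of all strategies sum to 1
    at every threshold.  Ties go to the reference.
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    arms = [a for (a, b) in samples[0].deltas if b == reference]
    if not arms:
        raise ValueError(f"no comparisons against reference {reference!r} in the samples")
    nmb = {reference: np.zeros((wtp_grid.size, len(samples)))}
    for a in arms:
        dc = np.array([s.deltas[(a, reference)][0] for s in samples])
        dq = np.array([s.deltas[(a, reference)][1] for s in samples])
        nmb[a] = wtp_grid[:, None] * dq[None, :] - dc[None, :]
    stacked = np.stack([nmb[name] for name in (reference, *arms)])
    winner = stacked.argmax(axis=0)
    return {
        name: CeacCurve((name, reference), wtp_grid, (winner == i).mean(axis=1))
        for i, name in enumerate((reference, *arms))
    }


@dataclass
class CeacCrossing:
    """Where an acceptability curve first reaches a probability level;
    ``wtp`` is None when the level is never attained on the grid."""

    wtp: float | None
    max_probability: float


def ceac_crossing(curve: CeacCurve, level: float = 0.5) -> CeacCrossing:
    """Smallest grid threshold with probability >= level, linearly
    interpolated between the bracketing grid points."""
    prob = curve.probability
    max_p = float(prob.max())
    idx = np.nonzero(prob >= level)[0]
    if idx.size == 0:
        return CeacCrossing(None, max_p)
    i = int(idx[0])
    if i == 0:
        return CeacCrossing(float(curve.wtp[0]), max_p)
    p0, p1 = prob[i - 1], prob[i]
    w0, w1 = curve.wtp[i - 1], curve.wtp[i]
    if p1 == p0:
        return CeacCrossing(float(w1), max_p)
    return CeacCrossing(float(w0 + (level - p0) * (w1 - w0) / (p1 - p0)), max_p)
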