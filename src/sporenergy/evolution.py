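"""Selection on the loss of nonfunctional sporulation DNA.

When growth is continuously favored, sporulation genes sit unexpressed in
the genome yet still cost ATP to replicate.  A deletion of Δ bp relieves
a metabolic burden s(Δ) = (c_n / C_cell) · Δ, where c_n is the ATP cost
of one nucleotide and C_cell the per-generation cellular budget.  This
module computes the fixation probability of such beneficial deletions,
their fixation rate relative to neutral substitutions (a dN/dS-like
ratio adjusted for unequal mutation rates), its deletion-size dependence
under an empirical size distribution, and a forward Wright–Fisher
simulation that serves as an independent check on the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NE_PRESETS",
    "FixationModelParams",
    "DeletionSizeDistribution",
    "selection_coefficient",
    "fixation_probability",
    "fixation_ratio",
    "size_weighted_ratio",
    "threshold_deletion_size",
    "deletion_rate_from_indels",
    "wright_fisher_pfix",
]

#: Published effective population size estimates for *Bacillus*;
#: the smaller (mutation-accumulation-derived) value is the conservative default.
NE_PRESETS: dict[str, float] = {
    "ma2015": 6.119e7,
    "alt": 3.224e8,
}

_SERIES_CUTOFF = 1e-8   # |2Ns| below which the neutral series limit is used
_LARGE_X = 700.0        # beyond this, x / (1 - e^-x) -> x to double precision


@dataclass(frozen=True)
class FixationModelParams:
    """Mutation rates, population size, and per-nucleotide cost."""

    ne: float = NE_PRESETS["ma2015"]
    u_del: float = 6.0e-11      # deletions per site per generation
    u_sub: float = 3.35e-10     # substitutions per site per generation
    nucleotide_cost: float = 50.0   # ATP to build one nucleotide (c_n)
    cell_budget: float = 9.4e10     # ATP per generation (C_cell)

    def __post_init__(self) -> None:
        for name in ("ne", "u_del", "u_sub", "nucleotide_cost", "cell_budget"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.u_del > self.u_sub:
            # informational only: deletions are usually rarer than substitutions
            import logging
            logging.getLogger(__name__).info(
                "u_del (%.3g) exceeds u_sub (%.3g)", self.u_del, self.u_sub)


@dataclass(frozen=True)
class DeletionSizeDistribution:
    """Empirical deletion-size spectrum: sizes (bp) with probabilities."""

    sizes: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.probabilities):
            raise ValueError("sizes and probabilities must have equal length")
        if any(s <= 0 or s != int(s) for s in self.sizes):
            raise ValueError("deletion sizes must be positive integers")
        p = np.asarray(self.probabilities, dtype=float)
        if (p < 0).any():
            raise ValueError("probabilities must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {p.sum()!r}, expected 1")


def selection_coefficient(delta_bp: float,
                          params: FixationModelParams = FixationModelParams()) -> float:
    """Selective advantage of deleting ``delta_bp`` nonfunctional base pairs.

    Linear in deletion size: s(Δ) = (c_n / C_cell) · Δ.
    """
    if delta_bp < 0:
        raise ValueError(f"delta_bp must be >= 0, got {delta_bp!r}")
    return params.nucleotide_cost / params.cell_budget * delta_bp


def _x_over_one_minus_exp_neg(x: float) -> float:
    """x / (1 - e^(-x)), continuous through x = 0 and safe for large |x|."""
    if abs(x) < _SERIES_CUTOFF:
        # series: x / (1 - e^-x) = 1 + x/2 + O(x^2)
        return 1.0 + x / 2.0
    if x > _LARGE_X:
        return x
    if x < -_LARGE_X:
        # denominator -> -e^(-x), so the ratio -> -x e^x (a positive underflow);
        # evaluate in log space to avoid overflow of e^(-x)
        return math.exp(math.log(-x) + x) if x > -745 else 0.0
    return x / -math.expm1(-x)


def fixation_probability(s: float, f: float, n: float) -> float:
    """Diffusion-approximation fixation probability of a mutation.

    P_fix(s, f) = (1 - e^(-2Nsf)) / (1 - e^(-2Ns)); the s -> 0 limit is
    the initial frequency f, handled by a series branch; extreme |2Ns| is
    evaluated in log space.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"initial frequency must lie in [0, 1], got {f!r}")
    if n <= 0:
        raise ValueError(f"population size must be > 0, got {n!r}")
    if f == 0.0:
        return 0.0
    x = 2.0 * n * s
    if abs(x) < _SERIES_CUTOFF:
        # (1 - e^(-xf)) / (1 - e^(-x)) -> f (1 + x(1-f)/2 + ...)
        return f * (1.0 + x * (1.0 - f) / 2.0)
    if x > _LARGE_X:
        # denominator is 1; numerator may still need expm1
        return -math.expm1(-x * f)
    if x < -_LARGE_X:
        # both terms dominated by growing exponentials: ratio e^{x(1-f)} ... -> 0
        return math.exp(x * (1.0 - f)) if x * (1.0 - f) > -745 else 0.0
    return math.expm1(-x * f) / math.expm1(-x)


def fixation_ratio(delta_bp: float,
                   params: FixationModelParams = FixationModelParams()) -> float:
    """Fixation rate of beneficial deletions relative to neutral substitutions.

    ratio(Δ) = [2 N_e s / (1 - e^(-2 N_e s))] · (U_del / U_sub) with
    s = s(Δ).  At Δ = 0 this reduces exactly to U_del / U_sub, which is
    below 1 because deletions are rarer than substitutions; the bracketed
    factor grows without bound in Δ, so large deletions can overcome the
    mutation-rate deficit.
    """
    s = selection_coefficient(delta_bp, params)
    return _x_over_one_minus_exp_neg(2.0 * params.ne * s) * (params.u_del / params.u_sub)


def size_weighted_ratio(
    distribution: DeletionSizeDistribution,
    params: FixationModelParams = FixationModelParams(),
) -> pd.DataFrame:
    """Per-size fixation-rate ratios weighted by the deletion-size spectrum.

    Each row carries ratio(Δ) · p(Δ): the spectrum's sharp peaks at
    high-probability sizes appear directly in the weighted column.
    """
    rows = []
    for size, p in zip(distribution.sizes, distribution.probabilities):
        s = selection_coefficient(size, params)
        unweighted = fixation_ratio(size, params)
        rows.append({"delta_bp": size, "p": p, "s": s,
                     "ratio": unweighted, "weighted_ratio": unweighted * p})
    return pd.DataFrame(rows)


def threshold_deletion_size(
    params: FixationModelParams = FixationModelParams(),
    *,
    delta_max: int = 10_000_000,
) -> int | None:
    """Smallest deletion size whose fixation-rate ratio reaches 1.

    The ratio is strictly increasing in Δ for s > 0, so integer bisection
    finds the crossing; returns ``None`` if no crossing exists below
    ``delta_max``.
    """
    if fixation_ratio(delta_max, params) < 1.0:
        return None
    lo, hi = 0, delta_max   # ratio(lo) < 1 <= ratio(hi) unless already >= 1 at Δ=1
    if fixation_ratio(1, params) >= 1.0:
        return 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fixation_ratio(mid, params) >= 1.0:
            hi = mid
        else:
            lo = mid
    return hi


def deletion_rate_from_indels(indel_rate: float, fraction_deletions: float) -> float:
    """Deletion rate from a total indel rate and the observed deletion fraction."""
    if indel_rate < 0:
        raise ValueError(f"indel_rate must be >= 0, got {indel_rate!r}")
    if not 0.0 <= fraction_deletions <= 1.0:
        raise ValueError(f"fraction_deletions must lie in [0, 1], got {fraction_deletions!r}")
    return indel_rate * fraction_deletions


def wright_fisher_pfix(
    s: float,
    n: int,
    replicates: int = 100_000,
    seed: int | np.random.Generator = 0,
    *,
    max_generations: int | None = None,
    ci_level: float = 0.99,
) -> tuple[float, tuple[float, float]]:
    """Forward Wright–Fisher estimate of the fixation probability.

    Each replicate starts from a single mutant copy; every generation the
    mutant frequency is weighted by (1 + s) and the next generation is a
    binomial draw of size ``n``.  Returns the fixation-fraction estimate
    with a normal-approximation confidence interval.  Deterministic under
    a fixed seed.
    """
    if n <= 0 or replicates <= 0:
        raise ValueError("n and replicates must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if max_generations is None:
        max_generations = 100 * n

    counts = np.ones(replicates, dtype=np.int64)
    fixed = 0
    for _ in range(max_generations):
        active = (counts > 0) & (counts < n)
        if not active.any():
            break
        p = counts[active] / n
        p_sel = p * (1.0 + s) / (1.0 + p * s)
        counts[active] = rng.binomial(n, p_sel)
        newly_fixed = counts == n
        fixed += int(newly_fixed.sum())
        counts[newly_fixed] = 0  # retire fixed replicates (already tallied)
    estimate = fixed / replicates
    z = {0.95: 1.959964, 0.99: 2.575829}.get(ci_level)
    if z is None:
        from scipy.stats import norm
        z = float(norm.ppf(0.5 + ci_level / 2.0))
    half = z * math.sqrt(max(estimate * (1.0 - estimate), 1.0 / replicates) / replicates)
    return estimate, (max(0.0, estimate - half), min(1.0, estimate + half))
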