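"""Non-inferiority of two correlated accuracy rates: score test and power.

Two classifiers evaluated on the same n women yield paired correctness
indicators with cell probabilities p11 (both correct), p10 (reference A
only), p01 (comparator B only), p00.  Non-inferiority of B at margin
``d`` tests

    H0: p_B - p_A <= -d   versus   H1: p_B - p_A > -d,

one-sided.  The test statistic is a restricted-maximum-likelihood score
statistic (Tango-type): with x01, x10 the observed discordant counts and
delta0 = -d,

    Z = (x01 - x10 - n * delta0) / sqrt(n * (2 * p01~ - delta0 * (1 + delta0)))

where p01~ is the MLE of p01 under the constraint p01 - p10 = delta0,
the positive root of

    2 n p^2 - [x01 (1 + 3 delta0) + x10 (1 + delta0) + 2 m delta0] p
            + x01 delta0 (1 + delta0) = 0,        m = n - x01 - x10.

H0 is rejected when Z >= z_{1-alpha}.  Power at a design point is
estimated by Monte-Carlo simulation of the multinomial pairs; the joint
cell probabilities are built from the two marginal accuracies and a
correlation between the correctness indicators, with an explicit
feasibility check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PowerSpec:
    """Design of a paired non-inferiority power simulation.

    ``accuracy_reference`` is the reference method's accuracy p_A;
    the comparator's accuracy is p_A + ``true_difference``.  ``correlation``
    is the (phi) correlation between the two per-woman correctness
    indicators; 0 means independent errors.
    """

    n: int
    accuracy_reference: float
    true_difference: float
    margin: float = 0.05
    correlation: float = 0.0
    alpha: float = 0.05
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.margin > 0:
            raise ValueError("margin: must be strictly positive")
        pa = self.accuracy_reference
        pb = pa + self.true_difference
        if not (0 <= pa <= 1 and 0 <= pb <= 1):
            raise ValueError("accuracy_reference +/- true_difference must lie in [0, 1]")
        if self.n < 1 or self.n_sims < 1:
            raise ValueError("n and n_sims must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha: must be in (0, 1)")

    @property
    def accuracy_comparator(self) -> float:
        return self.accuracy_reference + self.true_difference


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    n_sims: int
    spec: PowerSpec


def joint_cell_probs(pa: float, pb: float, correlation: float) -> tuple[float, float, float, float]:
    """(p11, p10, p01, p00) from marginal accuracies and correlation.

    Raises with the feasible correlation interval named when the requested
    correlation is incompatible with the margins.
    """
    sd = math.sqrt(pa * (1 - pa) * pb * (1 - pb))
    p11 = pa * pb + correlation * sd
    p10 = pa - p11
    p01 = pb - p11
    p00 = 1 - p11 - p10 - p01
    cells = (p11, p10, p01, p00)
    if any(p < -1e-12 for p in cells):
        if sd == 0:
            raise ValueError("correlation infeasible: a degenerate margin admits only rho = 0")
        lo = (max(0.0, pa + pb - 1) - pa * pb) / sd
        hi = (min(pa, pb) - pa * pb) / sd
        raise ValueError(
            f"correlation {correlation} infeasible for accuracies ({pa}, {pb}); "
            f"feasible interval is [{lo:.4f}, {hi:.4f}]"
        )
    return tuple(max(0.0, p) for p in cells)  # type: ignore[return-value]


def paired_noninferiority_z(
    x01: np.ndarray | int, x10: np.ndarray | int, n: int, margin: float
) -> np.ndarray | float:
    """Score statistic for H0: p01 - p10 = -margin (vectorised over counts)."""
    x01 = np.asarray(x01, dtype=float)
    x10 = np.asarray(x10, dtype=float)
    d0 = -margin
    m = n - x01 - x10
    # positive root of 2n p^2 - B p + C = 0 (C <= 0 so the roots straddle 0)
    B = x01 * (1 + 3 * d0) + x10 * (1 + d0) + 2 * m * d0
    C = x01 * d0 * (1 + d0)
    disc = np.sqrt(np.maximum(B * B - 8 * n * C, 0.0))
    p01_t = (B + disc) / (4 * n)
    var = n * (2 * p01_t - d0 * (1 + d0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x01 - x10 - n * d0) / np.sqrt(var)
    z = np.where(var <= 0, np.inf * np.sign(x01 - x10 - n * d0 + 1e-300), z)
    if z.ndim == 0:
        return float(z)
    return z


def noninferiority_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo rejection rate of the paired non-inferiority score test.

    Deterministic under a fixed ``spec.seed``.  The returned interval is a
    95% Wilson interval for the simulated rejection probability.
    """
    cells = joint_cell_probs(spec.accuracy_reference, spec.accuracy_comparator, spec.correlation)
    rng = np.random.default_rng(spec.seed)
    draws = rng.multinomial(spec.n, cells, size=spec.n_sims)  # columns: 11, 10, 01, 00
    z = paired_noninferiority_z(draws[:, 2], draws[:, 1], spec.n, spec.margin)
    z_crit = stats.norm.ppf(1 - spec.alpha)
    rejections = int(np.sum(z >= z_crit))
    power = rejections / spec.n_sims
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(rejections, spec.n_sims, alpha=0.05, method="wilson")
    return PowerResult(power=power, ci_low=float(lo), ci_high=float(hi), n_sims=spec.n_sims, spec=spec)
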