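"""Sample size for testing Cohen's kappa between two binary raters.

Implements the asymptotic normal method of Flack, Afifi, Lachenbruch and
Schouten (1988): the minimum number of paired ratings N such that a test
of H0: kappa = kappa0 against H1: kappa = kappa1 at level alpha attains
the requested power, using the Fleiss-Cohen-Everitt large-sample standard
deviations of the sample kappa evaluated at the 2x2 joint distributions
implied by the rater positive rates under each hypothesis.  For two
binary raters the margins plus kappa pin down the joint distribution
uniquely, so no variance maximization over tables is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .agreement import kappa_from_counts
from .simulate import implied_cell_probs, simulate_raters_many

__all__ = [
    "KappaPowerSpec",
    "kappa_sample_size",
    "kappa_unit_sd",
    "kappa_test_z",
    "monte_carlo_power",
]


@dataclass(frozen=True)
class KappaPowerSpec:
    """Design of a two-rater kappa hypothesis test.

    pi1, pi2 : positive-rating probabilities of the two raters
    kappa0   : kappa under the null hypothesis
    kappa1   : true (alternative) kappa
    alpha    : significance level; power : target power
    two_sided: whether the test is two-sided
    """

    pi1: float
    pi2: float
    kappa0: float
    kappa1: float
    alpha: float = 0.05
    power: float = 0.8
    two_sided: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.pi1 < 1.0 and 0.0 < self.pi2 < 1.0):
            raise ValueError("pi1 and pi2 must lie strictly in (0, 1)")
        if not -1.0 <= self.kappa0 < self.kappa1 <= 1.0:
            raise ValueError("need -1 <= kappa0 < kappa1 <= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ValueError("power must lie in (0, 1)")
        # both implied tables must be feasible
        implied_cell_probs(self.pi1, self.pi2, self.kappa0)
        implied_cell_probs(self.pi1, self.pi2, self.kappa1)


def kappa_unit_sd(pi1: float, pi2: float, kappa: float) -> float:
    """Per-observation asymptotic SD of the sample kappa at the implied table."""
    p11, p10, p01, p00 = implied_cell_probs(pi1, pi2, kappa)
    scale = 1e9  # kappa_from_counts is scale-invariant in the counts
    _, var1 = kappa_from_counts(p11 * scale, p10 * scale, p01 * scale, p00 * scale)
    return math.sqrt(float(var1))


def kappa_sample_size(spec: KappaPowerSpec) -> int:
    """Minimum N for the kappa test described by ``spec``.

    N = ceil( ((z_{1-alpha[/2]} sigma0 + z_{power} sigma1) / (kappa1 - kappa0))^2 )

    with sigma0, sigma1 the per-observation SDs of the sample kappa under
    the null and alternative tables.
    """
    alpha = spec.alpha / 2.0 if spec.two_sided else spec.alpha
    z_a = float(norm.ppf(1.0 - alpha))
    z_b = float(norm.ppf(spec.power))
    sigma0 = kappa_unit_sd(spec.pi1, spec.pi2, spec.kappa0)
    sigma1 = kappa_unit_sd(spec.pi1, spec.pi2, spec.kappa1)
    delta = spec.kappa1 - spec.kappa0
    if delta <= 0:
        raise ValueError("kappa1 must exceed kappa0")
    n = ((z_a * sigma0 + z_b * sigma1) / delta) ** 2
    return int(math.ceil(n - 1e-9))


def kappa_test_z(counts: np.ndarray, kappa0: float) -> np.ndarray:
    """Z statistic of the Wald kappa test H0: kappa = kappa0.

    Standardizes the sample kappa by its Fleiss-Cohen-Everitt SE evaluated
    at the observed table (the same SE the kappa confidence interval uses,
    so rejecting at level alpha is equivalent to kappa0 falling outside
    the 1-alpha CI).  Vectorized over rows ``(a, b, c, d)``.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = counts.sum(axis=1)
    a, b, c, d = counts.T
    kappa_hat, var1 = kappa_from_counts(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (kappa_hat - kappa0) * np.sqrt(n) / np.sqrt(var1)
    z = np.where(np.isfinite(z), z, np.inf * np.sign(kappa_hat - kappa0))
    return z


def monte_carlo_power(spec: KappaPowerSpec, n: int, n_rep: int,
                      seed: int) -> float:
    """Empirical power of the kappa test at sample size ``n``.

    Draws ``n_rep`` tables from the alternative joint distribution and
    applies the Wald z test of H0: kappa = kappa0 at ``spec.alpha``.
    """
    counts = simulate_raters_many(spec.pi1, spec.pi2, spec.kappa1, n, n_rep, seed)
    z = kappa_test_z(counts, spec.kappa0)
    alpha = spec.alpha / 2.0 if spec.two_sided else spec.alpha
    z_crit = float(norm.ppf(1.0 - alpha))
    reject = np.abs(z) > z_crit if spec.two_sided else z > z_crit
    return float(np.mean(reject))
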