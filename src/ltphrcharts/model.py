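"""LTPHR lifetimes under progressive Type-II censoring.

Sampling, likelihood, closed-form MLEs, the pivotal shortcut used by the
Monte-Carlo calibration, and the shift-size parameterization.

In a progressive Type-II censored life test, n units start together; at the
j-th observed failure, r_j of the still-operating units are withdrawn, and
the test stops at the m-th failure. The censoring scheme r = (r_1, ..., r_m)
satisfies n = m + sum(r). Under the LTPHR(Fbar, mu, lam) model the batch MLEs
have pivotal in-control laws

    Fbar(muhat) / Fbar(mu0) ~ Beta(n*lam0, 1),
    2*m*lam0 / lamhat       ~ chi-square(2m - 2),

independent of each other and of the censoring scheme — which is why every
chart in this package needs only (n, m), never r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .baselines import SURVIVAL_FLOOR, BaselineSurvival


class DegenerateSampleError(ValueError):
    """All observed failure times coincide; the scale MLE is undefined."""


@dataclass(frozen=True)
class CensoringScheme:
    """A progressive Type-II life-test design (n, m, r)."""

    n: int
    m: int
    r: Tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "r", tuple(int(v) for v in self.r))
        if not (1 <= self.m <= self.n):
            raise ValueError(f"need 1 <= m <= n, got n={self.n}, m={self.m}")
        if len(self.r) != self.m:
            raise ValueError("removal vector r must have length m")
        if any(v < 0 for v in self.r):
            raise ValueError("removal counts must be nonnegative")
        if self.n != self.m + sum(self.r):
            raise ValueError(
                f"scheme inconsistent: n={self.n} != m + sum(r) = {self.m + sum(self.r)}"
            )

    @classmethod
    def complete(cls, n: int) -> "CensoringScheme":
        return cls(n, n, (0,) * n)

    @classmethod
    def type2(cls, n: int, m: int) -> "CensoringScheme":
        """Conventional Type-II right censoring: all removals at the end."""
        return cls(n, m, (0,) * (m - 1) + (n - m,))


@dataclass(frozen=True)
class LTPHRParams:
    """Model parameters: lower endpoint mu and hazard exponent lam > 0."""

    mu: float
    lam: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("lam must be positive")


@dataclass(frozen=True)
class ICSpec:
    """In-control parameters on the survival scale.

    The charts consume only Fbar(mu0), never mu0 itself, so the in-control
    state is the pair (Fbar(mu0), lam0).
    """

    sbar_mu0: float
    lambda0: float

    def __post_init__(self):
        if not 0.0 < self.sbar_mu0 < 1.0:
            raise ValueError("sbar_mu0 must lie in (0, 1)")
        if not self.lambda0 > 0:
            raise ValueError("lambda0 must be positive")


@dataclass(frozen=True)
class ShiftSpec:
    """Shift sizes (delta1, delta2); (0, 1) is the in-control point.

    delta1 = lam0 * ln(Fbar(mu0)/Fbar(mu1)) shifts the lower endpoint
    (positive delta1 means mu1 > mu0, i.e. lifetimes start later);
    delta2 = lam0 / lam1 rescales the hazard exponent.
    """

    delta1: float = 0.0
    delta2: float = 1.0

    def __post_init__(self):
        if not self.delta2 > 0:
            raise ValueError("delta2 must be positive")


IN_CONTROL = ShiftSpec(0.0, 1.0)


@dataclass(frozen=True)
class BatchEstimate:
    """Per-batch MLE pair (Fbar(muhat), lamhat) — the chart input."""

    sbar_mu_hat: float
    lambda_hat: float

    def __post_init__(self):
        if not 0.0 < self.sbar_mu_hat <= 1.0:
            raise ValueError("sbar_mu_hat must lie in (0, 1]")
        if not self.lambda_hat > 0:
            raise ValueError("lambda_hat must be positive")


@dataclass(frozen=True)
class ProgressiveSample:
    """Ordered failure times of one progressively censored batch."""

    times: Tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        arr = np.asarray(self.times)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("times must be a nonempty 1-d sequence")
        if np.any(np.diff(arr) < 0):
            raise ValueError("times must be nondecreasing")


def eta_weights(scheme: CensoringScheme) -> np.ndarray:
    """Number of units still at risk just before each observed failure.

    eta_j = sum_{k=j}^{m} (1 + r_k); eta_1 = n and eta is nonincreasing.
    """
    r = np.asarray(scheme.r, dtype=np.int64)
    return np.cumsum((1 + r)[::-1])[::-1]


def draw_progressive_sample(
    baseline: BaselineSurvival,
    params: LTPHRParams,
    scheme: CensoringScheme,
    rng: np.random.Generator,
) -> ProgressiveSample:
    """Draw one progressively Type-II censored LTPHR batch.

    Uses the exponential-spacings construction: with eta_j units at risk and
    E_1..E_m iid standard exponentials, Y_j = sum_{k<=j} E_k / (lam * eta_k)
    are the cumulative hazards of the order statistics, and
    X_j = inverse_survival(Fbar(mu) * exp(-Y_j)). Exact and O(m).
    """
    eta = eta_weights(scheme)
    e = rng.exponential(size=scheme.m)
    y = np.cumsum(e / (params.lam * eta))
    sbar_mu = float(baseline.survival(params.mu))
    surv = np.clip(sbar_mu * np.exp(-y), SURVIVAL_FLOOR, 1.0)
    times = np.asarray(baseline.inverse_survival(surv), dtype=float)
    return ProgressiveSample(tuple(np.maximum.accumulate(times)))


def loglik(
    sample: ProgressiveSample,
    scheme: CensoringScheme,
    baseline: BaselineSurvival,
    params: LTPHRParams,
) -> float:
    """Log-likelihood of one batch, up to an additive data-only constant.

    The dropped constant (log density terms and the at-risk factors) is free
    of (mu, lam) and cancels in every likelihood ratio the package computes.
    Returns -inf when the first failure precedes mu (outside the support);
    the boundary x_(1) = mu is evaluated on the finite branch, matching the
    MLE muhat = x_(1).
    """
    x = np.asarray(sample.times, dtype=float)
    if x.size != scheme.m:
        raise ValueError("sample length does not match scheme m")
    if x[0] < params.mu:
        return float("-inf")
    r = np.asarray(scheme.r, dtype=float)
    ls_mu = float(baseline.log_survival(params.mu))
    ls_x = np.asarray(baseline.log_survival(x), dtype=float)
    m = scheme.m
    return float(
        m * np.log(params.lam)
        - m * ls_mu
        + np.sum((params.lam * (1.0 + r) - 1.0) * (ls_x - ls_mu))
    )


def mle(
    sample: ProgressiveSample,
    scheme: CensoringScheme,
    baseline: BaselineSurvival,
) -> BatchEstimate:
    """Closed-form batch MLEs: muhat = x_(1), lamhat from the weighted sum.

    lamhat = m / [-sum_j (1 + r_j) * ln(Fbar(x_j)/Fbar(muhat))]. Requires
    m >= 2; raises :class:`DegenerateSampleError` when every observed time
    equals the first (zero denominator).
    """
    if scheme.m < 2:
        raise ValueError("m >= 2 required for the scale MLE")
    x = np.asarray(sample.times, dtype=float)
    if x.size != scheme.m:
        raise ValueError("sample length does not match scheme m")
    r = np.asarray(scheme.r, dtype=float)
    ls_x = np.asarray(baseline.log_survival(x), dtype=float)
    denom = -np.sum((1.0 + r) * (ls_x - ls_x[0]))
    if denom <= 0.0:
        raise DegenerateSampleError(
            "all observed failure times coincide; lambda MLE undefined"
        )
    sbar = float(np.clip(baseline.survival(x[0]), SURVIVAL_FLOOR, 1.0))
    return BatchEstimate(sbar_mu_hat=sbar, lambda_hat=float(scheme.m / denom))


def pivotal_draws(
    sbar_mu: float,
    lam: float,
    n: int,
    m: int,
    rng: np.random.Generator,
    size: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized pivotal draws of (Fbar(muhat), lamhat) — arrays of length size.

    B1 ~ Beta(n*lam, 1) (drawn as U^(1/(n*lam)) via the power distribution)
    and B2 ~ chi-square(2m - 2); then Fbar(muhat) = Fbar(mu) * B1 and
    lamhat = 2*m*lam / B2. Called with shifted parameters this draws from
    the out-of-control sampling distribution.
    """
    if not (n >= m >= 2):
        raise ValueError("need n >= m >= 2")
    b1 = rng.power(n * lam, size=size)
    b2 = rng.chisquare(2 * m - 2, size=size)
    return sbar_mu * b1, 2.0 * m * lam / b2


def pivotal_draw(
    sbar_mu: float, lam: float, n: int, m: int, rng: np.random.Generator
) -> BatchEstimate:
    """One pivotal draw of the batch-estimate pair (see :func:`pivotal_draws`)."""
    sb, lh = pivotal_draws(sbar_mu, lam, n, m, rng, size=1)
    return BatchEstimate(float(np.clip(sb[0], SURVIVAL_FLOOR, 1.0)), float(lh[0]))


def apply_shift(ic: ICSpec, shift: ShiftSpec) -> Tuple[float, float]:
    """Map shift sizes to out-of-control parameters (Fbar(mu1), lam1).

    Fbar(mu1) = Fbar(mu0) * exp(-delta1/lam0); lam1 = lam0 / delta2.
    Raises when the implied Fbar(mu1) leaves (0, 1).
    """
    sbar1 = ic.sbar_mu0 * np.exp(-shift.delta1 / ic.lambda0)
    if not 0.0 < sbar1 < 1.0:
        raise ValueError(
            f"shift delta1={shift.delta1} pushes Fbar(mu1)={sbar1} outside (0, 1)"
        )
    return float(sbar1), float(ic.lambda0 / shift.delta2)


def shift_of(ic: ICSpec, shifted: Tuple[float, float]) -> ShiftSpec:
    """Inverse of :func:`apply_shift`: shift sizes implied by (Fbar(mu1), lam1)."""
    sbar1, lam1 = shifted
    if not 0.0 < sbar1 < 1.0:
        raise ValueError("Fbar(mu1) must lie in (0, 1)")
    if not lam1 > 0:
        raise ValueError("lam1 must be positive")
    return ShiftSpec(
        delta1=float(ic.lambda0 * np.log(ic.sbar_mu0 / sbar1)),
        delta2=float(ic.lambda0 / lam1),
    )
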