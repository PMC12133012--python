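"""The four monitoring statistics and their sequential state machines.

Each chart consumes a stream of per-batch estimates (Fbar(muhat_i), lamhat_i)
and raises a signal the first time its statistic strictly exceeds the control
limit h:

* EWMA-LR      — EWMA of the likelihood-ratio statistic LR_i;
* EWMA-Max-MLE — EWMA of S_i = max(|T1_i|, |T2_i|), the larger of the two
  normal-score-transformed pivotal quantities;
* EWMA-MD      — EWMA of the Manhattan distance between the estimated and
  in-control parameter points;
* WL           — a cumulative weighted log-likelihood-ratio statistic built
  on exponentially weighted MLEs (no EWMA start value).

An infinite statistic (the estimated lower endpoint falls below the
in-control one, muhat < mu0) signals immediately regardless of h, since the
EWMA recursion would otherwise carry +inf forever.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import special, stats

from .model import BatchEstimate, ICSpec

CHART_KINDS = ("LR", "MaxMLE", "MD", "WL")

#: E[max(|T1|, |T2|)] for independent standard normals: 2/sqrt(pi).
MAXMLE_START = 2.0 / math.sqrt(math.pi)

# Probability clip applied before normal quantile transforms.
_EPS = 1e-12


@dataclass(frozen=True)
class ChartSpec:
    """Chart configuration: kind, smoothing gamma, limit h, EWMA start."""

    kind: str
    gamma: float
    h: float
    start: float = 0.0

    def __post_init__(self):
        if self.kind not in CHART_KINDS:
            raise ValueError(f"unknown chart kind {self.kind!r}; one of {CHART_KINDS}")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if not self.h > 0:
            raise ValueError("control limit h must be positive")


@dataclass
class ChartState:
    """Current EWMA value and batch index of a running EWMA chart."""

    value: float
    step: int = 0


@dataclass
class WLState:
    """Sequential state of the WL chart.

    The weighted MLEs are maintained through exponentially damped running
    sums, so each update is O(1):

    * ``wsum_invlam``  = sum_i w_i * m / lamhat_i
    * ``wsum_logsbar`` = sum_i w_i * ln Fbar(muhat_i)
    * ``sbar_max``     = Fbar(mutilde_t) = max_i Fbar(muhat_i)
      (the running-minimum endpoint estimate on the survival scale)

    with weights w_i = gamma * (1-gamma)^(t-i), total W_t = 1 - (1-gamma)^t.
    ``history`` records the consumed estimates for inspection.
    """

    t: int = 0
    wsum_invlam: float = 0.0
    wsum_logsbar: float = 0.0
    sbar_max: float = 0.0
    history: List[BatchEstimate] = field(default_factory=list)


@dataclass(frozen=True)
class ChartRun:
    """Per-step chart statistics and the first index exceeding h (1-based)."""

    kind: str
    statistics: Tuple[float, ...]
    h: float
    first_signal: Optional[int]

    @property
    def signals(self) -> Tuple[int, ...]:
        return tuple(
            i for i, v in enumerate(self.statistics, start=1) if v > self.h
        )


# ---------------------------------------------------------------------------
# Per-batch statistics (scalar API over vectorized kernels)
# ---------------------------------------------------------------------------

def _lr_kernel(sbar_hat, lam_hat, ic: ICSpec, n: int, m: int) -> np.ndarray:
    """Vectorized LR_i; +inf where Fbar(muhat) > Fbar(mu0) (muhat < mu0)."""
    sbar_hat = np.asarray(sbar_hat, dtype=float)
    lam_hat = np.asarray(lam_hat, dtype=float)
    d2 = ic.lambda0 / lam_hat
    d1 = n * ic.lambda0 * (np.log(ic.sbar_mu0) - np.log(sbar_hat))
    out = m * (d2 - np.log(d2) - 1.0) + d1
    return np.where(sbar_hat > ic.sbar_mu0, np.inf, out)


def _maxmle_kernel(sbar_hat, lam_hat, ic: ICSpec, n: int, m: int) -> np.ndarray:
    """Vectorized S_i = max(|T1|, |T2|) of the normal-scored pivots."""
    z1 = np.clip(np.asarray(sbar_hat, dtype=float) / ic.sbar_mu0, _EPS, 1.0 - _EPS)
    z2 = 2.0 * m * ic.lambda0 / np.asarray(lam_hat, dtype=float)
    # Beta(n*lam0, 1) cdf is z1 ** (n*lam0)
    u1 = np.clip(z1 ** (n * ic.lambda0), _EPS, 1.0 - _EPS)
    u2 = np.clip(special.gammainc(m - 1.0, z2 / 2.0), _EPS, 1.0 - _EPS)
    t1 = special.ndtri(u1)
    t2 = special.ndtri(u2)
    return np.maximum(np.abs(t1), np.abs(t2))


def _md_kernel(sbar_hat, lam_hat, ic: ICSpec) -> np.ndarray:
    """Vectorized Manhattan distance MD_i."""
    sbar_hat = np.asarray(sbar_hat, dtype=float)
    lam_hat = np.asarray(lam_hat, dtype=float)
    return ic.lambda0 * np.abs(
        np.log(ic.sbar_mu0) - np.log(sbar_hat)
    ) + np.abs(ic.lambda0 / lam_hat - 1.0)


def lr_statistic(est: BatchEstimate, ic: ICSpec, n: int, m: int) -> float:
    """Likelihood-ratio statistic of one batch.

    LR_i = m (d2 - ln d2 - 1) + d1 with d2 = lam0/lamhat and
    d1 = n lam0 ln(Fbar(mu0)/Fbar(muhat)); +inf when muhat < mu0
    (i.e. Fbar(muhat) > Fbar(mu0)). Always >= 0, zero exactly at the
    in-control point.
    """
    return float(_lr_kernel(est.sbar_mu_hat, est.lambda_hat, ic, n, m))


def maxmle_statistic(est: BatchEstimate, ic: ICSpec, n: int, m: int) -> float:
    """Max-MLE statistic S_i = max(|T1_i|, |T2_i|).

    T1 and T2 are the probability-integral/normal-quantile transforms of the
    pivots Z1 = Fbar(muhat)/Fbar(mu0) ~ Beta(n lam0, 1) and
    Z2 = 2 m lam0 / lamhat ~ chi-square(2m-2); both are standard normal in
    control. Z1 and the transform probabilities are clipped to keep S finite.
    """
    return float(_maxmle_kernel(est.sbar_mu_hat, est.lambda_hat, ic, n, m))


def md_statistic(est: BatchEstimate, ic: ICSpec) -> float:
    """Manhattan distance between estimated and in-control parameter points:
    lam0 |ln(Fbar(mu0)/Fbar(muhat))| + |lam0/lamhat - 1|."""
    return float(_md_kernel(est.sbar_mu_hat, est.lambda_hat, ic))


def ewma_step(prev: float, stat: float, gamma: float) -> float:
    """One EWMA update: (1 - gamma) * prev + gamma * stat; +inf propagates."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    return (1.0 - gamma) * prev + gamma * stat


# ---------------------------------------------------------------------------
# WL chart
# ---------------------------------------------------------------------------

def wl_update(
    state: WLState,
    est: BatchEstimate,
    ic: ICSpec,
    gamma: float,
    n: int,
    m: int,
) -> Tuple[WLState, float]:
    """Consume one batch estimate and return (new state, WL_t).

    The weighted MLEs are mutilde_t = min_i muhat_i (equivalently
    Fbar(mutilde_t) = max_i Fbar(muhat_i)) and

        lamtilde_t = m W_t / sum_i w_i (m/lamhat_i - n ln(Fbar(muhat_i)/Fbar(mutilde_t)))

    and WL_t = W_t [m (d2 - ln d2 - 1) + d1] with W_t = 1 - (1-gamma)^t,
    d2 = lam0/lamtilde_t, d1 = n lam0 ln(Fbar(mu0)/Fbar(mutilde_t)); +inf
    when mutilde_t < mu0. At t = 1 this collapses to gamma * LR_1.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    t = state.t + 1
    om = 1.0 - gamma
    new = WLState(
        t=t,
        wsum_invlam=om * state.wsum_invlam + gamma * m / est.lambda_hat,
        wsum_logsbar=om * state.wsum_logsbar + gamma * math.log(est.sbar_mu_hat),
        sbar_max=max(state.sbar_max, est.sbar_mu_hat),
        history=state.history + [est],
    )
    w_total = 1.0 - om**t
    if new.sbar_max > ic.sbar_mu0:
        return new, float("inf")
    denom = new.wsum_invlam - n * (new.wsum_logsbar - w_total * math.log(new.sbar_max))
    lam_tilde = m * w_total / denom
    d2 = ic.lambda0 / lam_tilde
    d1 = n * ic.lambda0 * (math.log(ic.sbar_mu0) - math.log(new.sbar_max))
    return new, w_total * (m * (d2 - math.log(d2) - 1.0) + d1)


def wl_estimates(state: WLState, gamma: float, n: int, m: int) -> Tuple[float, float]:
    """Current weighted MLEs (Fbar(mutilde_t), lamtilde_t) of a WL state."""
    if state.t == 0:
        raise ValueError("no batches consumed yet")
    w_total = 1.0 - (1.0 - gamma) ** state.t
    denom = state.wsum_invlam - n * (
        state.wsum_logsbar - w_total * math.log(state.sbar_max)
    )
    return state.sbar_max, m * w_total / denom


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def run_chart(
    stream: Sequence[BatchEstimate],
    spec: ChartSpec,
    ic: ICSpec,
    n: int,
    m: int,
) -> ChartRun:
    """Run one chart over a finite stream of batch estimates.

    Records every per-step chart value and the first (1-based) index whose
    statistic strictly exceeds h. Infinite statistics signal immediately.
    """
    if len(stream) == 0:
        raise ValueError("stream must be nonempty")
    values: List[float] = []
    first: Optional[int] = None
    if spec.kind == "WL":
        state = WLState()
        for i, est in enumerate(stream, start=1):
            state, v = wl_update(state, est, ic, spec.gamma, n, m)
            values.append(v)
            if first is None and v > spec.h:
                first = i
    else:
        ewma = spec.start
        for i, est in enumerate(stream, start=1):
            if spec.kind == "LR":
                s = lr_statistic(est, ic, n, m)
            elif spec.kind == "MaxMLE":
                s = maxmle_statistic(est, ic, n, m)
            else:
                s = md_statistic(est, ic)
            ewma = ewma_step(ewma, s, spec.gamma)
            values.append(ewma)
            if first is None and (ewma > spec.h or math.isinf(s)):
                first = i
    return ChartRun(spec.kind, tuple(values), spec.h, first)
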