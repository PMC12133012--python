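"""Monte-Carlo calibration and run-length evaluation of the charts.

The calibration machinery never simulates raw censored batches: under the
LTPHR model the batch estimates have parameter-free pivotal in-control laws
(Beta(n lam0, 1) and chi-square(2m-2)), so run lengths are simulated directly
from pivotal draws — the same shortcut drives both the in-control limit
search and the out-of-control ARL evaluation (with the shifted parameters
substituted into the draws).

Run lengths are simulated in synchronous cohorts: all live replications
advance one batch per iteration, which vectorizes the per-step statistic over
the cohort while remaining distributionally identical to one-at-a-time
simulation (each replication consumes its own independent draws).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .charts import (
    MAXMLE_START,
    ChartSpec,
    _lr_kernel,
    _maxmle_kernel,
    _md_kernel,
)
from .model import ICSpec, ShiftSpec, apply_shift, pivotal_draws

#: Reference in-control parameters used when only the (parameter-free)
#: in-control law of a statistic is needed.
_REFERENCE_IC = ICSpec(sbar_mu0=0.8, lambda0=1.0)


class CalibrationError(RuntimeError):
    """The control-limit search failed to bracket or converge."""


@dataclass(frozen=True)
class CalibrationConfig:
    """Inputs of the control-limit search (Monte-Carlo design + target)."""

    kind: str
    gamma: float
    n: int
    m: int
    ic: ICSpec = _REFERENCE_IC
    arl0_target: float = 370.0
    reps: int = 20_000
    rl_cap: int = 1_000_000
    tolerance: float = 0.01
    seed: int = 0
    start: Optional[float] = None  # EWMA start value; estimated if None
    h_init: float = 1.0
    max_bisect: int = 40

    def __post_init__(self):
        if self.reps < 1 or self.rl_cap < 1:
            raise ValueError("reps and rl_cap must be >= 1")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be positive")
        if not self.arl0_target >= 1:
            raise ValueError("arl0_target must be >= 1")


@dataclass(frozen=True)
class RunLengthSummary:
    """ARL/SDRL of replicated run lengths with replication metadata."""

    arl: float
    sdrl: float
    reps: int
    capped: int
    rl_cap: int
    seed: Optional[int] = None

    def __post_init__(self):
        if self.arl < 1 or self.sdrl < 0 or self.capped > self.reps:
            raise ValueError("inconsistent run-length summary")


def start_value(
    kind: str,
    n: int,
    m: int,
    reps: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """In-control mean of a chart statistic, used as the EWMA start value.

    MaxMLE has the closed form 2/sqrt(pi) = 1.1283791671 (mean of the larger
    of two independent half-normals) and is returned without simulation.
    LR and MD means are estimated from pivotal draws; both are free of the
    in-control parameters, so any reference (Fbar(mu0), lam0) gives the same
    law. WL has no start value.
    """
    if kind == "MaxMLE":
        return MAXMLE_START
    if kind not in ("LR", "MD"):
        raise ValueError(f"no start value defined for chart kind {kind!r}")
    if rng is None:
        rng = np.random.default_rng()
    ic = _REFERENCE_IC
    sb, lh = pivotal_draws(ic.sbar_mu0, ic.lambda0, n, m, rng, size=reps)
    if kind == "LR":
        vals = _lr_kernel(sb, lh, ic, n, m)
    else:
        vals = _md_kernel(sb, lh, ic)
    return float(np.mean(vals))


def md_start_analytic(n: int, m: int) -> float:
    """Closed-form in-control mean of the MD statistic.

    E[MD] = 1/n + E|chi2_{2m-2} - 2m| / (2m), from the pivotal laws
    (lam0 |ln B1| ~ Exp(n) and lam0/lamhat = chi2/(2m)). Used as an
    analytic cross-check of the Monte-Carlo start value.
    """
    from scipy import integrate, stats

    k = 2 * m - 2
    e_abs, _ = integrate.quad(
        lambda x: abs(x - 2 * m) * stats.chi2.pdf(x, k), 0.0, max(40.0, 20.0 * m)
    )
    return 1.0 / n + e_abs / (2 * m)


def lr_start_analytic(m: int) -> float:
    """Closed-form in-control mean of the LR statistic: m (ln m - psi(m-1)).

    Free of n; follows from d1 ~ Exp(1) and d2 = chi2_{2m-2}/(2m).
    """
    from scipy import special

    return float(m * (math.log(m) - special.digamma(m - 1)))


# ---------------------------------------------------------------------------
# Run-length simulation
# ---------------------------------------------------------------------------

def _chart_start(spec: ChartSpec) -> float:
    if spec.kind == "WL":
        return 0.0
    return spec.start


def simulate_run_lengths(
    spec: ChartSpec,
    ic: ICSpec,
    shift: ShiftSpec,
    n: int,
    m: int,
    reps: int,
    rl_cap: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``reps`` independent zero-state run lengths of one chart.

    Batch estimates are drawn from the pivotal shortcut under the shifted
    parameters apply_shift(ic, shift); the chart runs from its start value
    (zero-state) and each replication stops at the first batch whose
    statistic strictly exceeds spec.h, capped at rl_cap batches.
    """
    sbar1, lam1 = apply_shift(ic, shift)
    om = 1.0 - spec.gamma
    rl = np.zeros(reps, dtype=np.int64)
    alive = np.arange(reps)

    if spec.kind == "WL":
        p = np.zeros(reps)  # sum w * m/lamhat
        q = np.zeros(reps)  # sum w * ln Fbar(muhat)
        smax = np.zeros(reps)
        log_s0 = math.log(ic.sbar_mu0)
        t = 0
        while alive.size and t < rl_cap:
            t += 1
            sb, lh = pivotal_draws(sbar1, lam1, n, m, rng, size=alive.size)
            p[alive] = om * p[alive] + spec.gamma * m / lh
            q[alive] = om * q[alive] + spec.gamma * np.log(sb)
            smax[alive] = np.maximum(smax[alive], sb)
            w_total = 1.0 - om**t
            sm = smax[alive]
            denom = p[alive] - n * (q[alive] - w_total * np.log(sm))
            lam_t = m * w_total / denom
            d2 = ic.lambda0 / lam_t
            d1 = n * ic.lambda0 * (log_s0 - np.log(sm))
            wl = w_total * (m * (d2 - np.log(d2) - 1.0) + d1)
            sig = (wl > spec.h) | (sm > ic.sbar_mu0)
            rl[alive[sig]] = t
            alive = alive[~sig]
    else:
        ewma = np.full(reps, _chart_start(spec))
        t = 0
        while alive.size and t < rl_cap:
            t += 1
            sb, lh = pivotal_draws(sbar1, lam1, n, m, rng, size=alive.size)
            if spec.kind == "LR":
                stat = _lr_kernel(sb, lh, ic, n, m)
            elif spec.kind == "MaxMLE":
                stat = _maxmle_kernel(sb, lh, ic, n, m)
            else:
                stat = _md_kernel(sb, lh, ic)
            e = om * ewma[alive] + spec.gamma * stat
            ewma[alive] = e
            sig = (e > spec.h) | np.isinf(stat)
            rl[alive[sig]] = t
            alive = alive[~sig]

    rl[alive] = rl_cap  # replications that never signalled
    return rl


def simulate_run_length(
    spec: ChartSpec,
    ic: ICSpec,
    shift: ShiftSpec,
    n: int,
    m: int,
    rl_cap: int,
    rng: np.random.Generator,
) -> int:
    """One zero-state run length (single-replication convenience wrapper)."""
    return int(simulate_run_lengths(spec, ic, shift, n, m, 1, rl_cap, rng)[0])


def arl_sdrl(
    spec: ChartSpec,
    ic: ICSpec,
    shift: ShiftSpec,
    n: int,
    m: int,
    reps: int,
    rl_cap: int,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> RunLengthSummary:
    """ARL and SDRL (divisor reps - 1) of replicated run lengths.

    Warns when any replication hit rl_cap — the reported ARL is then a
    lower bound.
    """
    rl = simulate_run_lengths(spec, ic, shift, n, m, reps, rl_cap, rng)
    capped = int(np.sum(rl >= rl_cap))
    if capped:
        warnings.warn(
            f"{capped}/{reps} replications hit the run-length cap {rl_cap}; "
            "ARL is a lower bound",
            stacklevel=2,
        )
    sdrl = float(np.std(rl, ddof=1)) if reps > 1 else 0.0
    return RunLengthSummary(
        arl=float(np.mean(rl)),
        sdrl=sdrl,
        reps=reps,
        capped=capped,
        rl_cap=rl_cap,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Control-limit search
# ---------------------------------------------------------------------------

def calibrate_h(cfg: CalibrationConfig) -> Tuple[float, RunLengthSummary]:
    """Find the control limit h achieving the target in-control ARL.

    ARL is nondecreasing in h, so the search brackets the target by doubling
    or halving h and then bisects. The search runs in two phases: a pilot
    bisection at a reduced replication count localizes the bracket cheaply
    (far-off trial limits are expensive to evaluate exactly, so precision
    there is wasted), then the bisection continues at the full cfg.reps
    until the achieved ARL is within cfg.tolerance (relative) of the
    target. Every evaluation within a phase reuses the same random draws
    (common random numbers: a generator re-seeded from cfg.seed), so ARL(h)
    is a monotone deterministic function of h and the whole search is
    deterministic given the seed.
    """
    start = cfg.start
    if start is None and cfg.kind != "WL":
        start = start_value(
            cfg.kind, cfg.n, cfg.m, reps=200_000,
            rng=np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11])),
        )

    target = cfg.arl0_target
    # Run lengths during the search are capped at 30x the target: a run
    # whose ARL is on target hits the cap with probability ~exp(-30), so the
    # accepted ARL is unbiased to far below the tolerance, while a
    # far-overshot trial h costs bounded work (capped replications make the
    # mean a lower bound, which still orders the trial correctly against
    # the target).
    search_cap = min(cfg.rl_cap, max(1, int(30 * target)))

    def arl_at(h: float, reps: int, phase: int) -> RunLengthSummary:
        spec = ChartSpec(cfg.kind, cfg.gamma, h, start if start is not None else 0.0)
        # identical draws for every h within a phase
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xCA1, phase]))
        rl = simulate_run_lengths(
            spec, cfg.ic, ShiftSpec(0.0, 1.0), cfg.n, cfg.m,
            reps, search_cap, rng,
        )
        return RunLengthSummary(
            arl=float(np.mean(rl)),
            sdrl=float(np.std(rl, ddof=1)) if reps > 1 else 0.0,
            reps=reps,
            capped=int(np.sum(rl >= search_cap)),
            rl_cap=search_cap,
            seed=cfg.seed,
        )

    # --- phase 1: bracket and coarse bisection at pilot replication -------
    pilot_reps = min(cfg.reps, 2_000)
    pilot_tol = max(cfg.tolerance, 4.0 / math.sqrt(pilot_reps))

    h = cfg.h_init
    summary = arl_at(h, pilot_reps, 1)
    lo = hi = None
    if summary.arl < target:
        lo = h
        for _ in range(60):
            h *= 2.0
            summary = arl_at(h, pilot_reps, 1)
            if summary.arl >= target:
                hi = h
                break
            lo = h
        else:
            raise CalibrationError("failed to bracket the target ARL in 60 doublings")
    else:
        hi = h
        for _ in range(60):
            h *= 0.5
            summary = arl_at(h, pilot_reps, 1)
            if summary.arl < target:
                lo = h
                break
            hi = h
        else:
            raise CalibrationError("failed to bracket the target ARL in 60 halvings")

    for _ in range(cfg.max_bisect):
        if abs(summary.arl - target) / target <= pilot_tol:
            break
        h = 0.5 * (lo + hi)
        summary = arl_at(h, pilot_reps, 1)
        if summary.arl < target:
            lo = h
        else:
            hi = h

    # --- phase 2: refine at full replication ------------------------------
    if cfg.reps <= pilot_reps:
        if abs(summary.arl - target) / target <= cfg.tolerance:
            return h, summary
        lo2, hi2 = lo, hi
    else:
        # widen the pilot bracket by the pilot's Monte-Carlo uncertainty
        lo2, hi2 = lo * 0.9, hi * 1.1
        s_lo = arl_at(lo2, cfg.reps, 2)
        if s_lo.arl >= target:  # pilot bracket missed low; fall back
            lo2 = lo * 0.5
            s_lo = arl_at(lo2, cfg.reps, 2)
            if s_lo.arl >= target:
                raise CalibrationError("pilot bracket inconsistent at full reps")

    for _ in range(cfg.max_bisect):
        h = 0.5 * (lo2 + hi2)
        summary = arl_at(h, cfg.reps, 2)
        if abs(summary.arl - target) / target <= cfg.tolerance:
            return h, summary
        if summary.arl < target:
            lo2 = h
        else:
            hi2 = h
    raise CalibrationError(
        f"bisection did not reach {cfg.tolerance:.1%} of ARL0={target} "
        f"in {cfg.max_bisect} iterations (last ARL {summary.arl:.1f})"
    )


# ---------------------------------------------------------------------------
# Table regeneration
# ---------------------------------------------------------------------------

def reproduce_tables(
    selection: Sequence[dict],
    reps: int = 20_000,
    rng: Optional[np.random.Generator] = None,
    rl_cap: int = 1_000_000,
) -> pd.DataFrame:
    """Regenerate start-value / ARL table cells at configurable replication.

    ``selection`` is a sequence of row requests. Two kinds are understood:

    * ``{"table": "start", "n": ..., "m": ...}`` — Monte-Carlo start values
      EL0 and EMD0 (plus the constant EM0) for one (n, m);
    * ``{"table": "arl", "chart": ..., "n": ..., "m": ..., "gamma": ...,
      "h": ..., "start": ..., "delta1": ..., "delta2": ...}`` — ARL/SDRL of
      one chart at one shift.

    Returns a tidy DataFrame with Monte-Carlo standard errors; an empty
    selection yields an empty frame.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for req in selection:
        kind = req["table"]
        if kind == "start":
            n_, m_ = req["n"], req["m"]
            rows.append(
                {
                    "table": "start",
                    "n": n_,
                    "m": m_,
                    "EL0": start_value("LR", n_, m_, reps=reps, rng=rng),
                    "EM0": MAXMLE_START,
                    "EMD0": start_value("MD", n_, m_, reps=reps, rng=rng),
                    "mc_se_EL0": _statistic_se("LR", n_, m_, reps, rng),
                    "mc_se_EMD0": _statistic_se("MD", n_, m_, reps, rng),
                }
            )
        elif kind == "arl":
            spec = ChartSpec(
                req["chart"], req["gamma"], req["h"], req.get("start", 0.0)
            )
            shift = ShiftSpec(req.get("delta1", 0.0), req.get("delta2", 1.0))
            ic = req.get("ic", _REFERENCE_IC)
            s = arl_sdrl(
                spec, ic, shift, req["n"], req["m"], reps, rl_cap, rng
            )
            rows.append(
                {
                    "table": "arl",
                    "chart": spec.kind,
                    "n": req["n"],
                    "m": req["m"],
                    "gamma": spec.gamma,
                    "delta1": shift.delta1,
                    "delta2": shift.delta2,
                    "h": spec.h,
                    "arl": s.arl,
                    "sdrl": s.sdrl,
                    "mc_se": s.sdrl / math.sqrt(s.reps),
                    "reps": s.reps,
                    "capped": s.capped,
                }
            )
        else:
            raise ValueError(f"unknown table request {kind!r}")
    return pd.DataFrame(rows)


def _statistic_se(kind: str, n: int, m: int, reps: int, rng) -> float:
    ic = _REFERENCE_IC
    sb, lh = pivotal_draws(ic.sbar_mu0, ic.lambda0, n, m, rng, size=min(reps, 50_000))
    vals = _lr_kernel(sb, lh, ic, n, m) if kind == "LR" else _md_kernel(sb, lh, ic)
    return float(np.std(vals, ddof=1) / math.sqrt(reps))
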