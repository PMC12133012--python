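"""Baseline survival functions for the LTPHR family.

A lifetime X follows the lower-truncated proportional-hazard-rate (LTPHR)
model when its survival function is ``[Fbar(x) / Fbar(mu)] ** lam`` for
x >= mu, where ``Fbar`` is an absolutely continuous baseline survival
function. Everything the monitoring machinery needs from the baseline is the
survival function, its inverse, and (for full log-likelihood values) the
density. Three baselines are provided: the standard exponential, the
gamma-uniform distribution on (0, 1) used for the mouse-lifetime example,
and a monotone interpolant of a user-supplied tabulated survival curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import special

# Survival probabilities are floored before taking logs so that extreme tail
# draws do not overflow to -inf in double precision.
SURVIVAL_FLOOR = 1e-300


@dataclass(frozen=True)
class BaselineSurvival:
    """A baseline survival function with its inverse and optional density.

    Parameters
    ----------
    survival
        Vectorized map x -> Fbar(x), nonincreasing with values in (0, 1].
    inverse_survival
        Vectorized map p -> x with survival(x) = p, for p in (0, 1].
    density
        Optional vectorized density f(x); only needed for absolute
        log-likelihood values (it cancels in every ratio the charts use).
    name
        Short identifier ("exponential", "gamma_uniform", "tabulated").
    """

    survival: Callable[[np.ndarray], np.ndarray]
    inverse_survival: Callable[[np.ndarray], np.ndarray]
    density: Optional[Callable[[np.ndarray], np.ndarray]] = None
    name: str = field(default="custom")

    def log_survival(self, x) -> np.ndarray:
        """log Fbar(x), floored to avoid -inf overflow."""
        s = np.clip(np.asarray(self.survival(x), dtype=float), SURVIVAL_FLOOR, 1.0)
        return np.log(s)


def exponential() -> BaselineSurvival:
    """Standard exponential baseline, Fbar(x) = exp(-x) on [0, inf)."""
    return BaselineSurvival(
        survival=lambda x: np.exp(-np.asarray(x, dtype=float)),
        inverse_survival=lambda p: -np.log(np.asarray(p, dtype=float)),
        density=lambda x: np.exp(-np.asarray(x, dtype=float)),
        name="exponential",
    )


def gamma_uniform_survival(x, a: float = 1.2809, b: float = 0.3902):
    """Survival function of the gamma-uniform distribution on (0, 1).

    ``Fbar(x) = Q(a, x / (b (1 - x)))`` where Q is the upper regularized
    incomplete gamma function. With the fitted shape a = 1.2809 and scale
    b = 0.3902 this is the baseline of the mouse-lifetime example;
    Fbar(0.0364) ≈ 0.9587.
    """
    x = np.asarray(x, dtype=float)
    if np.any((x <= 0.0) | (x >= 1.0)):
        raise ValueError("gamma-uniform support is the open interval (0, 1)")
    return special.gammaincc(a, x / (b * (1.0 - x)))


def gamma_uniform(a: float = 1.2809, b: float = 0.3902) -> BaselineSurvival:
    """Gamma-uniform baseline on (0, 1) with shape ``a`` and scale ``b``."""
    if a <= 0 or b <= 0:
        raise ValueError("shape and scale must be positive")

    def _surv(x):
        return gamma_uniform_survival(x, a, b)

    def _inv(p):
        z = special.gammainccinv(a, np.asarray(p, dtype=float))
        return z * b / (1.0 + z * b)

    def _dens(x):
        x = np.asarray(x, dtype=float)
        z = x / (b * (1.0 - x))
        # d/dx Q(a, z(x)) = -z^{a-1} e^{-z} / Gamma(a) * z'(x)
        dz = 1.0 / (b * (1.0 - x) ** 2)
        return np.exp((a - 1.0) * np.log(z) - z - special.gammaln(a)) * dz

    return BaselineSurvival(_surv, _inv, _dens, name="gamma_uniform")


def tabulated(x: np.ndarray, s: np.ndarray) -> BaselineSurvival:
    """Baseline from a tabulated survival curve with monotone interpolation.

    ``x`` must be strictly increasing and ``s`` strictly decreasing with
    values in (0, 1]. Interpolation is linear in log-survival, which keeps
    the interpolant a valid (strictly decreasing) survival function.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.ndim != 1 or x.shape != s.shape or x.size < 2:
        raise ValueError("need two equal-length 1-d arrays with >= 2 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("support points must be strictly increasing")
    if np.any(np.diff(s) >= 0) or np.any(s <= 0) or np.any(s > 1):
        raise ValueError("survival values must be strictly decreasing in (0, 1]")
    ls = np.log(s)

    def _surv(q):
        return np.exp(np.interp(np.asarray(q, dtype=float), x, ls))

    def _inv(p):
        lp = np.log(np.clip(np.asarray(p, dtype=float), SURVIVAL_FLOOR, 1.0))
        # np.interp needs increasing ordinates; ls is decreasing
        return np.interp(-lp, -ls, x)

    return BaselineSurvival(_surv, _inv, density=None, name="tabulated")


_NAMED = {"exponential": exponential, "gamma_uniform": gamma_uniform}


def get_baseline(name: str, **kwargs) -> BaselineSurvival:
    """Look up a named built-in baseline ("exponential", "gamma_uniform")."""
    try:
        factory = _NAMED[name]
    except KeyError:
        raise ValueError(
            f"unknown baseline {name!r}; choose from {sorted(_NAMED)}"
        ) from None
    return factory(**kwargs)
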