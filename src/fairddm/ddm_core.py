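"""Wiener diffusion first-passage-time kernel.

The two-boundary drift-diffusion model (DDM) describes a binary decision as a
noisy accumulation of evidence x(t) starting at ``z * a`` (relative start
``z`` in (0, 1)) that drifts with rate ``v`` (diffusion coefficient fixed at
1, the scale convention) until it is absorbed at the upper boundary ``a``
(here: the fairness-congruent option) or the lower boundary 0 (the
fairness-incongruent option).  An observed response time adds the
non-decision time ``t0`` (encoding and motor latency) to the first-passage
time.

This module provides

* :func:`absorption_probability` — the closed-form probability of upper-
  boundary absorption, the analytic oracle for choice fractions;
* :func:`wfpt_density` — the first-passage-time density at either boundary,
  computed with the classic small-time / large-time series expansions and an
  automatic switching rule based on the number of terms each expansion needs;
* :func:`dataset_loglik` — the summed log-likelihood of a set of
  (choice, RT) observations, the quantity all hierarchical fitting relies on;
* :func:`simulate_fpt` — an independent Euler path simulator with a Brownian-
  bridge boundary-crossing correction, kept separate from the series density
  so that the two routes can be checked against each other.

No inter-trial variability parameters (sv, sz, st) are modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "DDMParameters",
    "absorption_probability",
    "wfpt_density",
    "dataset_loglik",
    "simulate_fpt",
]

#: absolute truncation tolerance of the density series
SERIES_EPS = 1e-7


@dataclass(frozen=True)
class DDMParameters:
    """Diffusion parameters for one subject/condition.

    v : drift rate (evidence units/s), positive toward the upper
        (fairness-congruent) boundary
    a : boundary separation (> 0)
    z : relative starting point in (0, 1); 0.5 is unbiased; the absolute
        start is ``z * a``
    t0 : non-decision time in seconds (>= 0)
    """

    v: float
    a: float
    z: float
    t0: float = 0.0

    def validate(self) -> "DDMParameters":
        if not np.isfinite([self.v, self.a, self.z, self.t0]).all():
            raise ValueError("DDM parameters must be finite")
        if self.a <= 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not 0.0 < self.z < 1.0:
            raise ValueError(f"relative start z must lie in (0, 1), got {self.z}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")
        return self


def absorption_probability(params: DDMParameters) -> float:
    """Probability that the process is absorbed at the upper boundary.

    For drift v, boundary a and relative start z (diffusion coefficient 1)

        P(upper) = (1 - exp(-2 v z a)) / (1 - exp(-2 v a)),     v != 0
        P(upper) = z,                                           v == 0
    """
    params.validate()
    v, a, z = params.v, params.a, params.z
    if abs(2.0 * v * a) < 1e-9:
        return float(z)
    # expm1 keeps the ratio stable for small |v a|
    return float(np.expm1(-2.0 * v * z * a) / np.expm1(-2.0 * v * a))


# ---------------------------------------------------------------------------
# series expansions for the drift-free density on the unit interval
# ---------------------------------------------------------------------------
# f0(u, w) is the density of first passage through 0 at normalised time
# u = (t - t0) / a**2 for a zero-drift process on (0, 1) started at w.
# The full lower-boundary density is then
#   f_lower(t) = f0(u, w) / a**2 * exp(-v a w - v**2 (t - t0) / 2).


@njit(cache=True)
def _f0_small(u: float, w: float, K: int) -> float:
    """Small-time expansion with K terms (sum over image charges)."""
    lo = -((K - 1) // 2)
    hi = (K - 1) // 2 + (K - 1) % 2
    s = 0.0
    for k in range(lo, hi + 1):
        arg = w + 2.0 * k
        s += arg * np.exp(-arg * arg / (2.0 * u))
    return s / np.sqrt(2.0 * np.pi * u ** 3)


@njit(cache=True)
def _f0_large(u: float, w: float, K: int) -> float:
    """Large-time (spectral) expansion with K terms."""
    s = 0.0
    for k in range(1, K + 1):
        s += k * np.exp(-(k * k) * (np.pi * np.pi) * u / 2.0) * np.sin(k * np.pi * w)
    return np.pi * s


@njit(cache=True)
def _nterms(u: float, eps: float):
    """Terms needed by each expansion at absolute tolerance eps.

    Standard error-bound criterion: each returned count makes the truncated
    tail of the respective series smaller than eps.
    """
    # small-time
    if 2.0 * np.sqrt(2.0 * np.pi * u) * eps < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * u * np.log(2.0 * eps * np.sqrt(2.0 * np.pi * u)))
        ks = max(ks, np.sqrt(u) + 1.0)
    else:
        ks = 2.0
    # large-time
    if np.pi * u * eps < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * u * eps) / (np.pi * np.pi * u))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(u)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(u))
    return ks, kl


@njit(cache=True)
def _wfpt_lower(t: float, v: float, a: float, w: float, t0: float, eps: float) -> float:
    """Density of first passage through the LOWER boundary at clock time t."""
    tt = t - t0
    if tt <= 0.0:
        return 0.0
    u = tt / (a * a)
    ks, kl = _nterms(u, eps)
    if ks < kl:  # switch where term counts are equal
        f0 = _f0_small(u, w, int(np.ceil(ks)))
    else:
        f0 = _f0_large(u, w, int(np.ceil(kl)))
    if f0 < 0.0:  # series truncation can leave tiny negative values
        f0 = 0.0
    return f0 / (a * a) * np.exp(-v * a * w - v * v * tt / 2.0)


@njit(cache=True)
def _loglik_arrays(rt, upper, v, a, z, t0, eps: float) -> float:
    """Summed WFPT log-density; per-trial parameter arrays; -inf on zero density."""
    total = 0.0
    for i in range(rt.shape[0]):
        if upper[i]:
            d = _wfpt_lower(rt[i], -v[i], a[i], 1.0 - z[i], t0[i], eps)
        else:
            d = _wfpt_lower(rt[i], v[i], a[i], z[i], t0[i], eps)
        if d <= 0.0:
            return -np.inf
        total += np.log(d)
    return total


def wfpt_density(
    t: float,
    boundary: str,
    params: DDMParameters,
    *,
    eps: float = SERIES_EPS,
    force: str | None = None,
) -> float:
    """First-passage-time density at the named boundary at clock time ``t``.

    Parameters
    ----------
    t : response time in seconds (density is 0 for t <= t0).
    boundary : "upper" (congruent) or "lower" (incongruent).
    params : diffusion parameters.
    eps : absolute truncation tolerance of the series.
    force : force the "small" or "large" time expansion (testing hook for the
        switching rule); None selects automatically.
    """
    params.validate()
    if boundary == "upper":
        v, w = -params.v, 1.0 - params.z
    elif boundary == "lower":
        v, w = params.v, params.z
    else:
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    if force is None:
        return float(_wfpt_lower(float(t), v, params.a, w, params.t0, eps))
    tt = t - params.t0
    if tt <= 0:
        return 0.0
    u = tt / params.a ** 2
    ks, kl = _nterms(u, eps)
    if force == "small":
        f0 = _f0_small(u, w, int(np.ceil(ks)))
    elif force == "large":
        f0 = _f0_large(u, w, int(np.ceil(kl)))
    else:
        raise ValueError("force must be None, 'small' or 'large'")
    return float(max(f0, 0.0) / params.a ** 2 * np.exp(-v * params.a * w - v * v * tt / 2.0))


def dataset_loglik(
    rt: np.ndarray,
    response: np.ndarray,
    params: DDMParameters | None = None,
    *,
    v=None,
    a=None,
    z=None,
    t0=None,
) -> float:
    """Summed log WFPT density of observed (choice, RT) pairs.

    ``response`` is the binary congruence code: 1 means absorption at the
    upper (congruent) boundary.  Parameters are taken either from a single
    :class:`DDMParameters` or from per-trial arrays/scalars ``v, a, z, t0``
    (the latter is what condition-dependent models use).

    Any trial with rt <= t0 has zero density; its index is flagged with a
    warning and the function returns ``-inf``.  An empty dataset has
    log-likelihood 0.
    """
    rt = np.asarray(rt, dtype=np.float64)
    response = np.asarray(response)
    if rt.shape != response.shape:
        raise ValueError("rt and response must have the same shape")
    n = rt.shape[0]
    if n == 0:
        return 0.0
    if params is not None:
        params.validate()
        v, a, z, t0 = params.v, params.a, params.z, params.t0
    if v is None or a is None or z is None or t0 is None:
        raise ValueError("provide either params or all of v, a, z, t0")
    v = np.broadcast_to(np.asarray(v, dtype=np.float64), (n,)).copy()
    a = np.broadcast_to(np.asarray(a, dtype=np.float64), (n,)).copy()
    z = np.broadcast_to(np.asarray(z, dtype=np.float64), (n,)).copy()
    t0 = np.broadcast_to(np.asarray(t0, dtype=np.float64), (n,)).copy()
    bad = np.nonzero(rt <= t0)[0]
    if bad.size:
        warnings.warn(
            f"{bad.size} trial(s) with rt <= t0 contribute zero density "
            f"(trial indices {bad[:10].tolist()}...); log-likelihood is -inf",
            stacklevel=2,
        )
        return -np.inf
    upper = response.astype(np.bool_)
    return float(_loglik_arrays(rt, upper, v, a, z, t0, SERIES_EPS))


# ---------------------------------------------------------------------------
# independent path simulator
# ---------------------------------------------------------------------------


@njit(cache=True)
def _simulate_paths(n: int, v: float, a: float, z: float, dt: float, seed: int):
    """Euler–Maruyama paths with Brownian-bridge crossing correction.

    Between grid points the probability that a Brownian bridge from x1 to x2
    crossed a boundary is exp(-2 (b - x1)(b - x2) / dt); sampling these
    crossings removes the leading O(sqrt(dt)) discretisation bias of plain
    Euler first-passage sampling.
    """
    np.random.seed(seed)
    fpt = np.empty(n)
    hit_upper = np.empty(n, dtype=np.bool_)
    sdt = np.sqrt(dt)
    for i in range(n):
        x = z * a
        t = 0.0
        while True:
            xn = x + v * dt + sdt * np.random.randn()
            t += dt
            if xn >= a:
                fpt[i] = t
                hit_upper[i] = True
                break
            if xn <= 0.0:
                fpt[i] = t
                hit_upper[i] = False
                break
            # bridge crossing of the upper boundary
            if np.random.rand() < np.exp(-2.0 * (a - x) * (a - xn) / dt):
                fpt[i] = t
                hit_upper[i] = True
                break
            # bridge crossing of the lower boundary
            if np.random.rand() < np.exp(-2.0 * x * xn / dt):
                fpt[i] = t
                hit_upper[i] = False
                break
            x = xn
    return fpt, hit_upper


def simulate_fpt(
    params: DDMParameters,
    n: int,
    rng: np.random.Generator,
    *,
    dt: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` first-passage times and boundaries by corrected Euler.

    Returns ``(rt, upper)`` where ``rt`` includes the non-decision time t0
    and ``upper`` marks upper-boundary (congruent) absorption.  This sampler
    is independent of the series density and serves as its cross-check.
    """
    params.validate()
    seed = int(rng.integers(0, 2**31 - 1))
    fpt, hit_upper = _simulate_paths(int(n), params.v, params.a, params.z, dt, seed)
    return fpt + params.t0, hit_upper
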