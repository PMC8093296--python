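"""Wiener diffusion first-passage-time kernel.

A two-boundary drift--diffusion process with drift ``v``, boundary
separation ``a``, start point ``z`` (default ``a/2``, i.e. unbiased) and
non-decision time ``t``, with the diffusion coefficient fixed at 1 (one of
the two standard scale conventions; all drift/boundary values are in
unit-diffusion scale).  The module provides the defective first-passage
density at either boundary, the closed-form absorption probability, an
Euler--Maruyama trial simulator, and the trial-set log-likelihood.  The
same compiled kernel backs both data synthesis and hierarchical inference.

The density is evaluated with the classic dual series expansion: a
small-time and a large-time representation of the density of the scaled
process, with the representation chosen per evaluation to minimise the
number of terms needed for the requested truncation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "DDMParameters",
    "fpt_density",
    "choice_probability",
    "simulate_trials",
    "log_likelihood",
]


@dataclass(frozen=True)
class DDMParameters:
    """Diffusion parameters in unit-diffusion scale.

    v : drift rate (evidence units / s)
    a : boundary separation (> 0)
    z : start point (0 < z < a); defaults to a/2 (no bias)
    t : non-decision time (s, >= 0)
    """

    v: float
    a: float
    t: float
    z: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.z is None:
            object.__setattr__(self, "z", self.a / 2.0)
        if not np.isfinite(self.v):
            raise ValueError("drift rate must be finite")
        if self.a <= 0:
            raise ValueError("boundary separation must be positive")
        if not 0 < self.z < self.a:
            raise ValueError("start point must satisfy 0 < z < a")
        if self.t < 0:
            raise ValueError("non-decision time must be non-negative")

    @property
    def w(self) -> float:
        """Relative start point z / a."""
        return self.z / self.a


@njit(cache=True)
def _fpt01(tt: float, w: float, err: float) -> float:
    """Density of the scaled process (a=1, v=0, start w) at the lower bound.

    Chooses between the small-time and large-time series by comparing the
    number of terms each needs for truncation error <= err.
    """
    if tt <= 0.0:
        return 0.0
    # terms needed by the large-time series
    if np.pi * tt * err < 1.0:
        kl = np.sqrt(-2.0 * np.log(np.pi * tt * err) / (np.pi * np.pi * tt))
        kl = max(kl, 1.0 / (np.pi * np.sqrt(tt)))
    else:
        kl = 1.0 / (np.pi * np.sqrt(tt))
    # terms needed by the small-time series
    if 2.0 * np.sqrt(2.0 * np.pi * tt) * err < 1.0:
        ks = 2.0 + np.sqrt(-2.0 * tt * np.log(2.0 * np.sqrt(2.0 * np.pi * tt) * err))
        ks = max(ks, np.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:  # small-time representation
        K = int(np.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            p += x * np.exp(-x * x / (2.0 * tt))
        p /= np.sqrt(2.0 * np.pi * tt * tt * tt)
    else:  # large-time representation
        K = int(np.ceil(kl))
        for k in range(1, K + 1):
            p += k * np.exp(-k * k * np.pi * np.pi * tt / 2.0) * np.sin(k * np.pi * w)
        p *= np.pi
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def _fpt_lower(td: float, v: float, a: float, w: float, err: float) -> float:
    """Defective FPT density at the lower boundary for decision time td."""
    if td <= 0.0 or a <= 0.0:
        return 0.0
    tt = td / (a * a)
    mult = np.exp(-v * a * w - v * v * td / 2.0) / (a * a)
    if mult <= 0.0 or not np.isfinite(mult):
        return 0.0
    # request truncation error err on the final density
    return _fpt01(tt, w, err / max(mult * a * a, 1e-6)) * mult


@njit(cache=True)
def _log_density_trial(rt: float, upper: bool, v: float, a: float, t: float, w: float) -> float:
    """Log FPT density of one trial; -inf outside the support."""
    td = rt - t
    if td <= 0.0 or a <= 0.0 or w <= 0.0 or w >= 1.0:
        return -np.inf
    if upper:
        d = _fpt_lower(td, -v, a, 1.0 - w, 1e-10)
    else:
        d = _fpt_lower(td, v, a, w, 1e-10)
    if d <= 0.0:
        return -np.inf
    return np.log(d)


@njit(cache=True)
def _loglik_array(
    rt: np.ndarray,
    upper: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    t: np.ndarray,
    w: float = 0.5,
) -> np.ndarray:
    out = np.empty(rt.shape[0])
    for i in range(rt.shape[0]):
        out[i] = _log_density_trial(rt[i], upper[i], v[i], a[i], t[i], w)
    return out


@njit(cache=True)
def _simulate_kernel(
    v: float, a: float, z: float, t_nd: float, n: int, max_rt: float, dt: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    np.random.seed(seed)
    rts = np.empty(n)
    upper = np.zeros(n, dtype=np.int8)
    timeout = np.zeros(n, dtype=np.bool_)
    sqdt = np.sqrt(dt)
    max_td = max_rt - t_nd
    for i in range(n):
        x = z
        td = 0.0
        while True:
            x += v * dt + sqdt * np.random.randn()
            td += dt
            if x >= a:
                upper[i] = 1
                break
            if x <= 0.0:
                break
            if td >= max_td:
                timeout[i] = True
                break
        rts[i] = t_nd + td
    return rts, upper, timeout


def fpt_density(
    td: float | np.ndarray, params: DDMParameters, boundary: str = "upper"
) -> float | np.ndarray:
    """Defective first-passage-time density at one boundary.

    Parameters
    ----------
    td
        Decision time(s) in seconds (non-decision time already removed).
        Non-positive times return 0.
    params
        Diffusion parameters.
    boundary
        ``"upper"`` or ``"lower"``.

    Returns
    -------
    Density in 1/s; integrates over td to the absorption probability of the
    chosen boundary.  Absolute truncation error <= 1e-7.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    w = params.w
    if boundary == "upper":
        v, wl = -params.v, 1.0 - w
    else:
        v, wl = params.v, w
    tds = np.atleast_1d(np.asarray(td, dtype=float))
    out = np.array([_fpt_lower(x, v, params.a, wl, 1e-10) for x in tds])
    return float(out[0]) if np.isscalar(td) or np.ndim(td) == 0 else out


def choice_probability(params: DDMParameters) -> float:
    """Probability of absorption at the upper boundary.

    Closed form ``(1 - exp(-2 v z)) / (1 - exp(-2 v a))`` for unit
    diffusion, with the drift-free limit ``z / a``.
    """
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-10:
        return z / a
    with np.errstate(over="ignore"):
        num = -np.expm1(-2.0 * v * z)
        den = -np.expm1(-2.0 * v * a)
    if not np.isfinite(den) or den == 0.0:
        return 1.0 if v > 0 else 0.0
    return float(num / den)


def simulate_trials(
    params: DDMParameters,
    n: int,
    seed: int,
    max_rt: float = 6.0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate first-passage trials by Euler--Maruyama integration.

    Returns a DataFrame with columns ``rt`` (seconds, = non-decision time +
    decision time), ``upper`` (1 if the upper boundary was hit) and
    ``timeout`` (True if no boundary was reached before ``max_rt``, the
    display deadline).  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params.t >= max_rt:
        raise ValueError("non-decision time exceeds the response deadline")
    rts, upper, timeout = _simulate_kernel(
        params.v, params.a, params.z, params.t, int(n), float(max_rt), float(dt), int(seed)
    )
    return pd.DataFrame({"rt": rts, "upper": upper.astype(int), "timeout": timeout})


def log_likelihood(trials: pd.DataFrame, params: DDMParameters) -> float:
    """Total log FPT density of a trial set (correct and error responses).

    ``trials`` needs columns ``rt`` (s) and ``upper``; rows with
    ``timeout`` True are excluded.  A trial with rt <= t contributes a log
    density of -inf, which propagates to the total.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    if "timeout" in trials:
        trials = trials.loc[~trials["timeout"].astype(bool)]
        if len(trials) == 0:
            raise ValueError("all trials are timeouts")
    rt = trials["rt"].to_numpy(dtype=float)
    upper = trials["upper"].to_numpy(dtype=bool)
    k = len(rt)
    ll = _loglik_array(
        rt,
        upper,
        np.full(k, params.v),
        np.full(k, params.a),
        np.full(k, params.t),
        params.w,
    )
    return float(ll.sum())
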