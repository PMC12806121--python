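"""Time integrators: classical RK4 and a Caputo predictor-corrector.

The fractional solver is the Adams-Bashforth-Moulton scheme for Caputo
initial-value problems on a uniform grid: a fractional Adams-Bashforth
predictor followed by one Adams-Moulton corrector pass, with the full
convolution history retained (no kernel truncation), so the cost is O(M^2)
in the number of steps M.  At ``alpha = 1`` the scheme's weights collapse to
the classical Euler/trapezoid pair; we dispatch to RK4 instead, which is the
exact memoryless limit of the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "Trajectory",
    "SolverBlowUpError",
    "solve_rk4",
    "solve_caputo_pc",
    "mittag_leffler",
]


class SolverBlowUpError(RuntimeError):
    """Raised when the state becomes non-finite; carries the last finite time."""

    def __init__(self, t_last: float):
        super().__init__(f"solution became non-finite; last finite time t = {t_last:g}")
        self.t_last = t_last


@dataclass
class Trajectory:
    """Uniform-grid solution history with solver provenance.

    ``times`` has constant spacing ``dt * store_every``; ``states`` is
    ``(len(times), dim)``.  ``dt`` records the internal solver step.
    """

    times: np.ndarray
    states: np.ndarray
    alpha: float
    dt: float
    solver: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim == 1:
            self.states = self.states[:, None]
        if self.states.shape[0] != self.times.shape[0]:
            raise ValueError("times and states row counts differ")
        steps = np.diff(self.times)
        if len(steps) and (np.any(steps <= 0) or np.ptp(steps) > 1e-9 * steps[0]):
            raise ValueError("time grid must be strictly increasing with constant step")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def first_crossing(self, column: int, level: float) -> float:
        """First grid time at which ``states[:, column]`` reaches ``level``.

        Linear interpolation between the bracketing grid points; ``nan`` if
        the level is never reached.
        """
        y = self.states[:, column]
        above = np.nonzero(y >= level)[0]
        if len(above) == 0:
            return math.nan
        i = above[0]
        if i == 0:
            return float(self.times[0])
        t0, t1 = self.times[i - 1], self.times[i]
        y0, y1 = y[i - 1], y[i]
        return float(t0 + (level - y0) / (y1 - y0) * (t1 - t0))


def _grid(t_end: float, dt: float, store_every: int) -> int:
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    m = int(round(t_end / dt))
    if abs(m * dt - t_end) > 1e-9 * max(1.0, t_end):
        raise ValueError(f"t_end = {t_end} is not an integer multiple of dt = {dt}")
    if store_every < 1 or m % store_every:
        raise ValueError("store_every must divide the number of steps")
    return m


def solve_rk4(rhs, y0, t_end: float, dt: float = 0.01, *, store_every: int = 1) -> Trajectory:
    """Classical fourth-order Runge-Kutta for ``y' = rhs(t, y)``.

    ``store_every`` thins the stored history (the integration step is always
    ``dt``); memory for long network runs stays bounded.
    """
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    m = _grid(t_end, dt, store_every)
    n_keep = m // store_every + 1
    out = np.empty((n_keep, y0.size))
    out[0] = y0
    y = y0.copy()
    t = 0.0
    for n in range(m):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = (n + 1) * dt
        if not np.all(np.isfinite(y)):
            raise SolverBlowUpError(n * dt)
        if (n + 1) % store_every == 0:
            out[(n + 1) // store_every] = y
    times = np.arange(n_keep) * dt * store_every
    return Trajectory(times, out, alpha=1.0, dt=dt, solver="rk4")


def rk4_endpoint(rhs, y0, t_end: float, dt: float = 0.01, *, check_finite: bool = True) -> np.ndarray:
    """Endpoint-only RK4 (no history stored); used for large batched runs.

    With ``check_finite=False`` non-finite components are tolerated (useful
    when integrating independent samples in one batch, where a diverging
    sample must not abort the rest).
    """
    y = np.asarray(y0, dtype=float).copy()
    m = _grid(t_end, dt, 1)
    t = 0.0
    with np.errstate(over="ignore", invalid="ignore"):
        for n in range(m):
            k1 = rhs(t, y)
            k2 = rhs(t + dt / 2, y + dt / 2 * k1)
            k3 = rhs(t + dt / 2, y + dt / 2 * k2)
            k4 = rhs(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = (n + 1) * dt
    if check_finite and not np.all(np.isfinite(y)):
        raise SolverBlowUpError(t)
    return y


def solve_caputo_pc(
    rhs,
    y0,
    alpha: float,
    t_end: float,
    dt: float = 0.01,
    *,
    store_every: int = 1,
) -> Trajectory:
    """Adams-Bashforth-Moulton predictor-corrector for ``D^alpha y = rhs(t, y)``.

    Predictor weights are ``(dt^alpha/alpha) [(n+1-j)^alpha - (n-j)^alpha]``
    divided by ``Gamma(alpha)``; the corrector applies the fractional
    trapezoid weights ``(n-j+2)^{alpha+1} + (n-j)^{alpha+1}
    - 2 (n-j+1)^{alpha+1}`` scaled by ``dt^alpha / Gamma(alpha+2)``, with one
    correction per step.  ``alpha = 1`` dispatches to :func:`solve_rk4`.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha = {alpha} must lie in (0, 1]")
    if alpha == 1.0:
        return solve_rk4(rhs, y0, t_end, dt, store_every=store_every)

    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    m = _grid(t_end, dt, store_every)
    dim = y0.size

    k = np.arange(m + 1, dtype=float)
    # predictor convolution kernel c[k] applied to f_{n-k}
    c = (k + 1) ** alpha - k**alpha
    # corrector kernel d[k] for j >= 1 terms; j = 0 gets its own weight a0w(n)
    d = (k + 2) ** (alpha + 1) + k ** (alpha + 1) - 2 * (k + 1) ** (alpha + 1)
    pred_coef = dt**alpha / (alpha * _gamma(alpha))
    corr_coef = dt**alpha / _gamma(alpha + 2)

    f_hist = np.empty((m + 1, dim))
    n_keep = m // store_every + 1
    out = np.empty((n_keep, dim))
    out[0] = y0
    y = y0.copy()
    f_hist[0] = rhs(0.0, y)
    for n in range(m):
        t_next = (n + 1) * dt
        wp = np.ascontiguousarray(c[n::-1])
        y_pred = y0 + pred_coef * (wp @ f_hist[: n + 1])
        a0w = n ** (alpha + 1) - (n - alpha) * (n + 1) ** alpha
        tail = a0w * f_hist[0]
        if n >= 1:
            wc = np.ascontiguousarray(d[n - 1 :: -1])
            tail = tail + wc @ f_hist[1 : n + 1]
        y = y0 + corr_coef * (rhs(t_next, y_pred) + tail)
        if not np.all(np.isfinite(y)):
            raise SolverBlowUpError(n * dt)
        f_hist[n + 1] = rhs(t_next, y)
        if (n + 1) % store_every == 0:
            out[(n + 1) // store_every] = y
    times = np.arange(n_keep) * dt * store_every
    return Trajectory(times, out, alpha=alpha, dt=dt, solver="caputo_pc")


def mittag_leffler(alpha: float, z: float, tol: float = 1e-16, max_terms: int = 500) -> float:
    """One-parameter Mittag-Leffler function ``E_alpha(z)`` by direct series.

    ``E_alpha(z) = sum_k z^k / Gamma(alpha k + 1)``; valid as a numerical
    oracle for moderate arguments (|z| <= 10), where the series converges
    before cancellation dominates.  ``E_1(z) = exp(z)``.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha = {alpha} must lie in (0, 1]")
    if abs(z) > 10:
        raise ValueError("series evaluation restricted to |z| <= 10")
    if alpha == 1.0:
        return math.exp(z)
    total = 0.0
    for n in range(max_terms):
        if z == 0:
            term = 1.0 if n == 0 else 0.0
        else:
            term = math.copysign(1.0, z) ** n * math.exp(
                n * math.log(abs(z)) - math.lgamma(alpha * n + 1)
            )
        total += term
        if n > abs(z) ** (1 / alpha) and abs(term) < tol * max(1.0, abs(total)):
            return total
    raise ValueError("Mittag-Leffler series did not converge (argument too large)")
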