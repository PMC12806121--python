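"""Equilibria, Jacobian, and stability of the five-variable temporal model.

The stationarity conditions factorize, so the equilibria are enumerated by a
branch cascade rather than by multistart root finding:

* astrocytes: ``w = 0`` or ``w = c0 c1``;
* amyloid: ``u = 0`` or ``a0 - a1 u - a2 u~ = 0`` crossed with ``u~ = 0`` or
  ``a2 u - mu (w - u~) = a1_tilde`` (a linear 2x2 on the interior branch);
* tau (given ``u~``): ``(v, v~) = (0, 0)``, ``(b0/b1, 0)``, or the interior
  pair ``v = b1_tilde / (b2 + b3 u~)``, ``v~ = (b0 - b1 v)/(b2 + b3 u~)``.

Each nonnegative candidate is polished by a Newton-type root finder and kept
only if the residual drops below 1e-10.  Fractional stability uses the
argument condition ``|arg(lambda_i)| > alpha pi / 2`` on the Jacobian
spectrum (the Matignon-type criterion); at ``alpha = 1`` this coincides with
the usual negative-real-part test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .model import _rhs_local, disease_free_state
from .params import ModelParameters, require_valid

RESIDUAL_TOL = 1e-10
DEDUP_TOL = 1e-8
MARGINAL_TOL = 1e-9


@dataclass
class EquilibriumPoint:
    """A nonnegative stationary state with its branch label and residual."""

    state: np.ndarray
    branch: str
    residual: float

    def __post_init__(self) -> None:
        self.state = np.asarray(self.state, dtype=float)


@dataclass
class StabilityVerdict:
    """Spectrum-based classification of an equilibrium.

    ``margin`` is ``min_i (|arg lambda_i| - alpha pi/2)`` for the fractional
    criterion and ``-max_i Re lambda_i`` for the integer-order one; the point
    is stable iff the margin is positive, and reported as marginal when the
    margin sits within 1e-9 of zero.
    """

    eigenvalues: np.ndarray
    stable: bool
    marginal: bool
    criterion: str
    margin: float


def jacobian(point, params: ModelParameters) -> np.ndarray:
    """Analytic 5x5 Jacobian of the reaction field at ``point``.

    The sparsity pattern reflects the model couplings: amyloid does not feel
    tau (rows 1-2, columns 3-4 vanish), astrocytes are autonomous (row 5 has
    only the diagonal entry), and only toxic amyloid feels astrocytes.
    """
    u, ut, v, vt, w = np.asarray(point, dtype=float)
    p = params
    J = np.zeros((5, 5))
    J[0, 0] = p.a0 - 2 * p.a1 * u - p.a2 * ut
    J[0, 1] = -p.a2 * u
    J[1, 0] = p.a2 * ut
    J[1, 1] = -p.a1_tilde + p.a2 * u - p.mu * (w - 2 * ut)
    J[1, 4] = -p.mu * ut
    J[2, 1] = -p.b3 * v * vt
    J[2, 2] = p.b0 - 2 * p.b1 * v - p.b2 * vt - p.b3 * ut * vt
    J[2, 3] = -p.b2 * v - p.b3 * ut * v
    J[3, 1] = p.b3 * v * vt
    J[3, 2] = p.b2 * vt + p.b3 * ut * vt
    J[3, 3] = -p.b1_tilde + p.b2 * v + p.b3 * ut * v
    J[4, 4] = p.c0 - 2 * w / p.c1
    return J


def _candidates(p: ModelParameters):
    """Yield (state, branch-label) for every branch of the cascade."""
    for w, wb in ((0.0, "w0"), (p.c0 * p.c1, "w+")):
        # amyloid branches: (u, u~)
        ab = [((0.0, 0.0), "u0.ut0")]
        ab.append(((p.a0 / p.a1, 0.0), "u+.ut0"))
        if p.mu > 0:
            ab.append(((0.0, (p.a1_tilde + p.mu * w) / p.mu), "u0.ut+"))
        # interior: a1 u + a2 u~ = a0 ; a2 u + mu u~ = a1_tilde + mu w
        det = p.a1 * p.mu - p.a2**2
        if abs(det) > 1e-14:
            u_i = (p.a0 * p.mu - p.a2 * (p.a1_tilde + p.mu * w)) / det
            ut_i = (p.a1 * (p.a1_tilde + p.mu * w) - p.a2 * p.a0) / det
            ab.append(((u_i, ut_i), "u+.ut+"))
        for (u, ut), aub in ab:
            tb = [((0.0, 0.0), "v0.vt0"), ((p.b0 / p.b1, 0.0), "v+.vt0")]
            denom = p.b2 + p.b3 * ut
            if denom > 1e-14:
                v_i = p.b1_tilde / denom
                vt_i = (p.b0 - p.b1 * v_i) / denom
                tb.append(((v_i, vt_i), "v+.vt+"))
            for (v, vt), tvb in tb:
                yield np.array([u, ut, v, vt, w]), f"{aub}.{tvb}.{wb}"


def find_equilibria(
    params: ModelParameters, *, return_excluded: bool = False
) -> list[EquilibriumPoint] | tuple[list[EquilibriumPoint], list[EquilibriumPoint]]:
    """All nonnegative equilibria via the branch cascade with Newton polish.

    Negative-component branch roots are discarded (returned separately when
    ``return_excluded`` is set); accepted points are deduplicated within
    1e-8 and have max-norm residual below 1e-10.
    """
    require_valid(params)
    kept: list[EquilibriumPoint] = []
    excluded: list[EquilibriumPoint] = []
    for cand, branch in _candidates(params):
        if not np.all(np.isfinite(cand)):
            continue
        sol = root(lambda y: _rhs_local(y, params), cand, method="hybr", tol=1e-13)
        y = sol.x
        res = float(np.max(np.abs(_rhs_local(y, params))))
        # snap polish drift on components the branch pins to zero
        y = np.where(np.abs(y) < 1e-12, 0.0, y)
        point = EquilibriumPoint(y, branch, res)
        if res > RESIDUAL_TOL or np.linalg.norm(y - cand) > 0.5 * (1 + np.linalg.norm(cand)):
            continue
        if np.any(y < -1e-12):
            excluded.append(point)
            continue
        if any(np.max(np.abs(k.state - y)) < DEDUP_TOL for k in kept):
            continue
        kept.append(point)
    kept.sort(key=lambda e: tuple(-e.state))
    if return_excluded:
        return kept, excluded
    return kept


def positive_equilibrium(params: ModelParameters) -> EquilibriumPoint:
    """The coexistence equilibrium with every component strictly positive.

    Raises ``ValueError`` if no such point exists for the given parameters.
    """
    for eq in find_equilibria(params):
        if np.all(eq.state > 1e-12):
            return eq
    raise ValueError("no strictly positive equilibrium for these parameters")


def classify_stability(
    point, params: ModelParameters, alpha: float | None = None
) -> StabilityVerdict:
    """Stability of ``point`` at fractional order ``alpha`` (default: params.alpha)."""
    if alpha is None:
        alpha = params.alpha
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha = {alpha} must lie in (0, 1]")
    state = point.state if isinstance(point, EquilibriumPoint) else np.asarray(point, float)
    lam = np.linalg.eigvals(jacobian(state, params))
    if alpha == 1.0:
        criterion = "real-part"
        margin = float(-np.max(lam.real))
    else:
        criterion = "argument"
        margin = float(np.min(np.abs(np.angle(lam))) - alpha * np.pi / 2)
    marginal = abs(margin) <= MARGINAL_TOL
    return StabilityVerdict(
        eigenvalues=lam,
        stable=bool(margin > 0 and not marginal),
        marginal=marginal,
        criterion=criterion,
        margin=margin,
    )


def classify_tauopathy(params: ModelParameters) -> str:
    """``"primary"`` if toxic tau can invade without amyloid, else ``"secondary"``.

    In the tau-only subsystem at the healthy baseline ``v = b0/b1``, the
    growth rate of a toxic perturbation is ``b2 b0/b1 - b1_tilde``; strictly
    positive growth means tau sustains itself (primary tauopathy), otherwise
    the amyloid coupling ``b3`` is required (secondary).
    """
    require_valid(params)
    if params.b1 <= 0:
        raise ValueError("b1 must be > 0 to define the healthy tau baseline")
    return "primary" if params.b2 * params.b0 / params.b1 > params.b1_tilde else "secondary"


def equilibrium_report(params: ModelParameters, alphas=(1.0,)) -> list[dict]:
    """JSON-ready records: state, branch, eigenvalues, verdict per alpha."""
    records = []
    for eq in find_equilibria(params):
        rec = {
            "state": [float(x) for x in eq.state],
            "branch": eq.branch,
            "residual": eq.residual,
            "verdicts": [],
        }
        for a in alphas:
            v = classify_stability(eq, params, a)
            rec["verdicts"].append(
                {
                    "alpha": a,
                    "criterion": v.criterion,
                    "stable": v.stable,
                    "marginal": v.marginal,
                    "margin": v.margin,
                    "eigenvalues": [[float(z.real), float(z.imag)] for z in v.eigenvalues],
                }
            )
        records.append(rec)
    return records
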