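"""Right-hand sides of the five-variable temporal model and the damage equation.

State ordering throughout the package: ``(u, u~, v, v~, w)`` — healthy
amyloid-beta, toxic amyloid-beta, healthy tau, toxic tau, astrocytes — plus a
separate damage fraction ``q`` in [0, 1].

The kinetics are a heterodimer scheme with logistic growth for the healthy
species, first-order clearance of the toxic species, an amyloid-to-tau
coupling term ``b3 u~ v v~``, and a logistic astrocyte population whose
interaction ``mu u~ (w - u~)`` clears toxic amyloid when astrocytes are
abundant and amplifies it otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, require_valid

#: Canonical variable names, concentration block then damage.
STATE_NAMES: tuple[str, ...] = ("u", "u_tilde", "v", "v_tilde", "w")
FULL_STATE_NAMES: tuple[str, ...] = STATE_NAMES + ("q",)


@dataclass
class LocalState:
    """One node's concentrations plus its damage fraction."""

    u: float
    u_tilde: float
    v: float
    v_tilde: float
    w: float
    q: float = 0.0

    def concentrations(self) -> np.ndarray:
        return np.array([self.u, self.u_tilde, self.v, self.v_tilde, self.w], dtype=float)

    def full(self) -> np.ndarray:
        return np.array(
            [self.u, self.u_tilde, self.v, self.v_tilde, self.w, self.q], dtype=float
        )


def rhs_local(state, params: ModelParameters) -> np.ndarray:
    """Time derivatives of ``(u, u~, v, v~, w)``.

    ``state`` may be a 5-vector or an array with the variables along the last
    axis (batched evaluation).  Input is validated; use :func:`_rhs_local` in
    inner solver loops.
    """
    y = np.asarray(state, dtype=float)
    if y.shape[-1] != 5:
        raise ValueError(f"expected 5 state components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state component")
    require_valid(params)
    return _rhs_local(y, params)


def _rhs_local(y: np.ndarray, p) -> np.ndarray:
    """Unchecked kernel; ``p`` may hold scalars or per-sample arrays."""
    u, ut, v, vt, w = (y[..., i] for i in range(5))
    conv_tau = p.b2 * v * vt + p.b3 * ut * v * vt
    out = np.empty_like(y)
    out[..., 0] = u * (p.a0 - p.a1 * u) - p.a2 * u * ut
    out[..., 1] = -p.a1_tilde * ut + p.a2 * u * ut - p.mu * ut * (w - ut)
    out[..., 2] = v * (p.b0 - p.b1 * v) - conv_tau
    out[..., 3] = -p.b1_tilde * vt + conv_tau
    out[..., 4] = w * (p.c0 - w / p.c1)
    return out


def rhs_damage(q, u_tilde, v_tilde, params: ModelParameters) -> np.ndarray:
    """Damage rate ``(1 - q)(k1 u~ + k2 v~ + k3 u~ v~ + k4 q)``.

    Nonnegative whenever ``q`` is in [0, 1] and the toxic loads are
    nonnegative, so damage never heals; ``q = 1`` is absorbing.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("damage fraction q must lie in [0, 1]")
    require_valid(params)
    return _rhs_damage(q, np.asarray(u_tilde, float), np.asarray(v_tilde, float), params)


def _rhs_damage(q, ut, vt, p) -> np.ndarray:
    return (1.0 - q) * (p.k1 * ut + p.k2 * vt + p.k3 * ut * vt + p.k4 * q)


def rhs_local_damage(state6, params: ModelParameters) -> np.ndarray:
    """Derivatives of the 6-vector ``(u, u~, v, v~, w, q)`` (single node)."""
    y = np.asarray(state6, dtype=float)
    if y.shape[-1] != 6:
        raise ValueError(f"expected 6 state components, got shape {y.shape}")
    out = np.empty_like(y)
    out[..., :5] = _rhs_local(y[..., :5], params)
    out[..., 5] = _rhs_damage(y[..., 5], y[..., 1], y[..., 3], params)
    return out


def disease_free_state(params: ModelParameters) -> np.ndarray:
    """Toxin-free equilibrium ``(a0/a1, 0, b0/b1, 0, c0 c1)`` (closed form)."""
    p = params
    return np.array([p.a0 / p.a1, 0.0, p.b0 / p.b1, 0.0, p.c0 * p.c1])


def toxic_abeta_equilibrium(params: ModelParameters) -> float:
    """Interior toxic-amyloid level u~* on the coexistence branch.

    Eliminating u between the u and u~ stationarity conditions (with
    w* = c0 c1) gives the closed form

        u~* = (a2 a0 / a1 - a1_tilde - mu c0 c1) / (a2^2 / a1 - mu),

    used as the analytic oracle for the astrocyte dual-role study.
    """
    p = params
    return (p.a2 * p.a0 / p.a1 - p.a1_tilde - p.mu * p.c0 * p.c1) / (
        p.a2**2 / p.a1 - p.mu
    )
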