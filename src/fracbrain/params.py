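"""Model parameters for the amyloid-beta / tau / astrocyte network model.

All quantities are nondimensional.  The default constructor reproduces the
synthetic parameter set of the secondary-tauopathy study exactly; individual
fields may be overridden per node for mixed-tauopathy runs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping

import yaml

#: Names of the 16 local (reaction) parameters, in canonical order.  The four
#: diffusion coefficients and the fractional order are excluded: they act only
#: in the network coupling and the time-derivative operator, respectively.
LOCAL_PARAM_NAMES: tuple[str, ...] = (
    "a0", "a1", "a2", "a1_tilde",
    "b0", "b1", "b2", "b1_tilde", "b3",
    "c0", "c1", "mu",
    "k1", "k2", "k3", "k4",
)

DIFFUSION_PARAM_NAMES: tuple[str, ...] = ("rho_u", "rho_u_tilde", "rho_v", "rho_v_tilde")

ALL_PARAM_NAMES: tuple[str, ...] = LOCAL_PARAM_NAMES + DIFFUSION_PARAM_NAMES + ("alpha",)


@dataclass(frozen=True)
class ModelParameters:
    """Reaction, clearance, coupling, astrocyte, damage and diffusion constants.

    Parameters
    ----------
    a0, a1
        Production and clearance rates of healthy amyloid-beta (u).
    a2
        Healthy-to-toxic conversion rate of amyloid-beta (heterodimer term).
    a1_tilde
        Clearance rate of toxic amyloid-beta (u~).
    b0, b1, b2, b1_tilde
        Analogous rates for healthy/toxic tau (v, v~).
    b3
        Amyloid-tau coupling: toxic amyloid catalyses tau conversion.
    c0, c1
        Astrocyte production rate and carrying-capacity scale; the astrocyte
        population saturates at ``c0 * c1``.
    mu
        Astrocyte-toxic-amyloid interaction rate.  When astrocytes outnumber
        toxic amyloid (w > u~) this term clears u~; otherwise it feeds it —
        the "dual role".
    k1, k2, k3, k4
        Neuronal-damage weights for toxic amyloid, toxic tau, their product,
        and damage self-amplification.
    rho_u, rho_u_tilde, rho_v, rho_v_tilde
        Per-species network diffusion coefficients scaling the graph
        Laplacian for u, u~, v, v~.  Astrocytes and damage do not diffuse.
    alpha
        Fractional (Caputo) order in (0, 1]; ``alpha = 1`` is the classical
        memoryless model.
    """

    a0: float = 1.035
    a1: float = 1.38
    a2: float = 1.38
    a1_tilde: float = 0.828
    b0: float = 0.69
    b1: float = 1.38
    b2: float = 1.035
    b1_tilde: float = 0.552
    b3: float = 4.14
    c0: float = 1.0
    c1: float = 0.1
    mu: float = 0.1
    k1: float = 0.0001
    k2: float = 0.01
    k3: float = 0.1
    k4: float = 0.001
    rho_u: float = 1.38
    rho_u_tilde: float = 0.138
    rho_v: float = 1.38
    rho_v_tilde: float = 0.014
    alpha: float = 1.0

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ModelParameters":
        unknown = set(d) - set(ALL_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Load from a flat YAML or JSON key-value file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ValueError(f"{path}: expected a flat mapping of parameter names to values")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(d, sort_keys=False))


def validate_params(params: ModelParameters) -> list[str]:
    """Return the list of violated invariants (empty for a valid set)."""
    report: list[str] = []
    for name in LOCAL_PARAM_NAMES + DIFFUSION_PARAM_NAMES:
        value = getattr(params, name)
        if not _finite(value):
            report.append(f"{name} = {value!r} is not finite")
        elif value < 0:
            report.append(f"{name} = {value} must be >= 0")
    if params.c1 <= 0:
        report.append(f"c1 = {params.c1} must be > 0 (astrocyte carrying capacity)")
    if not _finite(params.alpha) or not (0.0 < params.alpha <= 1.0):
        report.append(f"alpha = {params.alpha!r} must lie in (0, 1]")
    return report


def require_valid(params: ModelParameters) -> ModelParameters:
    """Raise ``ValueError`` listing every violated invariant, else pass through."""
    report = validate_params(params)
    if report:
        raise ValueError("invalid parameters: " + "; ".join(report))
    return params


def _finite(x: float) -> bool:
    try:
        return x == x and abs(x) != float("inf")
    except TypeError:
        return False
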