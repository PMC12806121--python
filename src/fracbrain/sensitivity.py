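"""Global sensitivity of the temporal model by uniform parameter sampling.

Each of the 16 local reaction parameters is perturbed independently and
uniformly within +/- 10% of its nominal value; the memoryless model (with
damage) is integrated to t = 200 from a fixed near-healthy initial state and
the Pearson correlation of every parameter against every output
(u, u~, v, v~, w, q at the evaluation time) is reported.  Diffusion
coefficients are excluded: the procedure runs on the single-compartment
temporal model, which has no network coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .fde import rk4_endpoint
from .model import FULL_STATE_NAMES, _rhs_damage, _rhs_local
from .params import LOCAL_PARAM_NAMES, ModelParameters, require_valid

#: Initial condition of the sensitivity runs: healthy baselines with a 1%
#: toxic perturbation, astrocytes at their carrying capacity, no damage.
SENSITIVITY_IC = np.array([0.75, 0.0075, 0.5, 0.005, 0.1, 0.0])


@dataclass
class SensitivityConfig:
    n_samples: int = 1000
    deviation: float = 0.10
    t_eval: float = 200.0
    dt: float = 0.01
    seed: int = 0
    parameters: tuple[str, ...] = LOCAL_PARAM_NAMES
    initial: np.ndarray = field(default_factory=lambda: SENSITIVITY_IC.copy())


@dataclass
class SensitivityResult:
    """Samples, endpoint outputs, and the parameter-output correlation matrix."""

    parameter_names: tuple[str, ...]
    nominal: np.ndarray
    samples: np.ndarray  # (n, n_params)
    outputs: np.ndarray  # (n, 6)
    correlations: np.ndarray  # (n_params, 6)
    n_excluded: int
    config: SensitivityConfig

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.correlations, index=list(self.parameter_names), columns=list(FULL_STATE_NAMES)
        )

    def correlation(self, parameter: str, output: str) -> float:
        return float(
            self.correlations[
                self.parameter_names.index(parameter), FULL_STATE_NAMES.index(output)
            ]
        )


def sample_parameters(
    nominal: ModelParameters,
    n: int = 1000,
    deviation: float = 0.10,
    seed: int | None = None,
    parameters: tuple[str, ...] = LOCAL_PARAM_NAMES,
) -> np.ndarray:
    """(n, n_params) matrix of i.i.d. uniform draws on [p(1-d), p(1+d)]."""
    require_valid(nominal)
    if not (0 <= deviation < 1):
        raise ValueError("deviation must lie in [0, 1)")
    if n < 3:
        raise ValueError("need at least 3 samples for correlations")
    rng = np.random.default_rng(seed)
    nom = np.array([getattr(nominal, name) for name in parameters])
    return nom * (1.0 + deviation * rng.uniform(-1.0, 1.0, size=(n, len(parameters))))


def pearson(x, y) -> float:
    """Product-moment correlation; ``nan`` when either input has no variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _batched_endpoint(samples: np.ndarray, cfg: SensitivityConfig) -> np.ndarray:
    """Integrate all samples at once: state (n, 6), per-sample parameters."""
    n = samples.shape[0]
    p = SimpleNamespace(
        **{name: samples[:, i] for i, name in enumerate(cfg.parameters)}
    )
    for name in LOCAL_PARAM_NAMES:  # parameters held at nominal if unsampled
        if not hasattr(p, name):
            setattr(p, name, np.full(n, getattr(ModelParameters(), name)))

    def rhs(t, flat):
        y = flat.reshape(n, 6)
        out = np.empty_like(y)
        out[:, :5] = _rhs_local(y[:, :5], p)
        out[:, 5] = _rhs_damage(y[:, 5], y[:, 1], y[:, 3], p)
        return out.reshape(-1)

    y0 = np.ascontiguousarray(np.broadcast_to(cfg.initial, (n, 6))).reshape(-1)
    # blow-ups stay confined to their own sample's rows (no cross-sample
    # coupling), so non-finite rows are filtered afterwards instead of
    # aborting the whole batch
    return rk4_endpoint(rhs, y0, cfg.t_eval, cfg.dt, check_finite=False).reshape(n, 6)


def run_sensitivity(
    nominal: ModelParameters | None = None, config: SensitivityConfig | None = None
) -> SensitivityResult:
    """Full sampling -> integration -> correlation pipeline."""
    nominal = nominal or ModelParameters()
    cfg = config or SensitivityConfig()
    samples = sample_parameters(
        nominal, cfg.n_samples, cfg.deviation, cfg.seed, cfg.parameters
    )
    outputs = _batched_endpoint(samples, cfg)
    good = np.all(np.isfinite(outputs), axis=1)
    n_excluded = int((~good).sum())
    samples_g, outputs_g = samples[good], outputs[good]
    corr = np.empty((len(cfg.parameters), 6))
    for i in range(corr.shape[0]):
        for j in range(6):
            corr[i, j] = pearson(samples_g[:, i], outputs_g[:, j])
    nom = np.array([getattr(nominal, name) for name in cfg.parameters])
    return SensitivityResult(
        parameter_names=tuple(cfg.parameters),
        nominal=nom,
        samples=samples,
        outputs=outputs,
        correlations=corr,
        n_excluded=n_excluded,
        config=cfg,
    )
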