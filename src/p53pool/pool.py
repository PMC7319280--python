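"""The model pool: shared kinetics plus subpopulation-specific fold changes.

A pool couples one set of 22 shared rate constants with a ``K x 6`` matrix
of log10 fold-change modifiers on the noise-susceptible production
parameters — one row per subpopulation — and subpopulation weights given by
assigned cell counts.  Population-level readouts are weight-averaged over
the member simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ode import DamageInput, Perturbation, SimulationResult, OBSERVABLE_NAMES, simulate
from .parameters import NOISE_SUSCEPTIBLE, ModelParameters

__all__ = ["ModelPool"]


@dataclass
class ModelPool:
    """Shared parameters, per-subpopulation modifiers and cluster weights."""

    shared: ModelParameters
    modifiers: np.ndarray          # (K, 6) log10 fold changes, columns = NOISE_SUSCEPTIBLE
    weights: np.ndarray            # (K,) non-negative, sum to 1
    scale: float = 1.0             # reporter intensity per model concentration
    offset: float = 0.0            # reporter background

    def __post_init__(self) -> None:
        self.modifiers = np.atleast_2d(np.asarray(self.modifiers, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.modifiers.shape[1] != len(NOISE_SUSCEPTIBLE):
            raise ValueError(
                f"modifier matrix must have {len(NOISE_SUSCEPTIBLE)} columns"
            )
        if self.weights.shape != (self.modifiers.shape[0],):
            raise ValueError("weights must have one entry per subpopulation")
        if np.any(self.weights < 0) or not np.isfinite(self.weights.sum()) or self.weights.sum() <= 0:
            raise ValueError("weights must be non-negative and normalizable")
        self.weights = self.weights / self.weights.sum()

    @property
    def n_subpopulations(self) -> int:
        return self.modifiers.shape[0]

    @property
    def n_candidate_modifiers(self) -> int:
        """Candidate subpopulation-specific parameters before regularization."""
        return self.modifiers.size

    def count_specific(self, zero_tolerance: float = 1e-3) -> int:
        """Number of modifiers with magnitude at or above ``zero_tolerance``."""
        return int(np.count_nonzero(np.abs(self.modifiers) >= zero_tolerance))

    def member_params(self, k: int) -> ModelParameters:
        return self.shared.apply_modifiers(self.modifiers[k])

    def simulate_member(
        self,
        k: int,
        damage: DamageInput | None = None,
        perturbations: Sequence[Perturbation] = (),
        t_span: tuple[float, float] = (0.0, 24.0),
        **kwargs,
    ) -> SimulationResult:
        return simulate(self.member_params(k), damage=damage,
                        perturbations=perturbations, t_span=t_span, **kwargs)

    def population_readouts(
        self,
        perturbations: Sequence[Perturbation] = (),
        t_span: tuple[float, float] = (0.0, 24.0),
        dt: float = 0.05,
        **kwargs,
    ) -> pd.DataFrame:
        """Weighted-mean observables over the pool, one column per readout."""
        acc: dict[str, np.ndarray] = {}
        t = None
        for k in range(self.n_subpopulations):
            res = self.simulate_member(k, perturbations=perturbations,
                                       t_span=t_span, dt=dt, **kwargs)
            if t is None:
                t = res.t
            for name in OBSERVABLE_NAMES:
                acc[name] = acc.get(name, 0.0) + self.weights[k] * res.observable(name)
        out = pd.DataFrame({"time_h": t})
        for name in OBSERVABLE_NAMES:
            out[name] = acc[name]
        return out

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "shared": self.shared.as_dict(),
            "modifier_columns": list(NOISE_SUSCEPTIBLE),
            "modifiers": self.modifiers.tolist(),
            "weights": self.weights.tolist(),
            "scale": self.scale,
            "offset": self.offset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelPool":
        return cls(
            shared=ModelParameters.from_dict(d["shared"]),
            modifiers=np.asarray(d["modifiers"], dtype=float),
            weights=np.asarray(d["weights"], dtype=float),
            scale=float(d.get("scale", 1.0)),
            offset=float(d.get("offset", 0.0)),
        )
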