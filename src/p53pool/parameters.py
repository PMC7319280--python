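"""Kinetic parameters of the ATM--p53--Mdm2--Wip1 network model.

The model carries 22 fitted rate constants plus one fixed Hill exponent for
p53-dependent transcription.  Six production-rate parameters (transcription,
translation and synthesis/activation rates) are flagged *noise susceptible*:
they are the only parameters allowed to differ between subpopulations of
cells, on the rationale that mRNA/protein production is the dominant entry
point of intrinsic noise while biochemical conversion rates (phosphorylation,
binding, degradation chemistry) are shared by all cells.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping

import numpy as np

#: Canonical ordering of the 22 fitted parameters.
PARAM_NAMES: tuple[str, ...] = (
    "beta_s",      # ATM activation by damage signal, 1/h
    "alpha_s",     # basal ATM-P inactivation, 1/h
    "alpha_ws",    # Wip1-mediated ATM-P inactivation, 1/(conc h)
    "beta_p",      # p53 synthesis, conc/h
    "alpha_pi",    # basal degradation of inactive p53, 1/h
    "alpha_mpi",   # Mdm2-mediated degradation of inactive p53, 1/(conc h)
    "beta_sp",     # maximal ATM-mediated p53 activation rate, 1/h
    "T_s",         # ATM-P half saturation for p53 activation, conc
    "alpha_wpa",   # Wip1-mediated deactivation of active p53, 1/(conc h)
    "alpha_mpa",   # Mdm2-mediated degradation of active p53, 1/(conc h)
    "beta_mt",     # basal Mdm2 transcription, conc/h
    "beta_pamt",   # p53-dependent Mdm2 transcription max rate, conc/h
    "T_pa",        # active-p53 half saturation for target transcription, conc
    "alpha_mt",    # Mdm2 mRNA degradation, 1/h
    "beta_mtm",    # Mdm2 translation, 1/h
    "alpha_m",     # basal Mdm2 degradation, 1/h
    "alpha_sm",    # ATM-dependent Mdm2 degradation, 1/(conc h)
    "beta_wt",     # basal Wip1 transcription, conc/h
    "beta_pawt",   # p53-dependent Wip1 transcription max rate, conc/h
    "alpha_wt",    # Wip1 mRNA degradation, 1/h
    "beta_wtw",    # Wip1 translation, 1/h
    "alpha_w",     # Wip1 degradation, 1/h
)

#: Production-rate parameters susceptible to intrinsic noise; only these may
#: carry subpopulation-specific fold changes.
NOISE_SUSCEPTIBLE: tuple[str, ...] = (
    "beta_mt", "beta_mtm", "beta_p", "beta_s", "beta_wt", "beta_wtw",
)

#: State variable names (order used throughout the package).
STATE_NAMES: tuple[str, ...] = ("S", "Pi", "Pa", "Zm", "M", "Zw", "W")


@dataclass(frozen=True)
class ModelParameters:
    """The 22 kinetic rate constants plus the fixed Hill exponent ``hill_n``.

    All rate constants must be strictly positive.  ``hill_n`` parameterises
    the cooperativity of p53-dependent transcription of Mdm2 and Wip1; it is
    fixed (not fitted) so that the fitted parameter count stays at 22.
    """

    beta_s: float
    alpha_s: float
    alpha_ws: float
    beta_p: float
    alpha_pi: float
    alpha_mpi: float
    beta_sp: float
    T_s: float
    alpha_wpa: float
    alpha_mpa: float
    beta_mt: float
    beta_pamt: float
    T_pa: float
    alpha_mt: float
    beta_mtm: float
    alpha_m: float
    alpha_sm: float
    beta_wt: float
    beta_pawt: float
    alpha_wt: float
    beta_wtw: float
    alpha_w: float
    hill_n: float = 4.0

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be positive")

    # -- conversions ----------------------------------------------------
    def to_array(self) -> np.ndarray:
        """22 fitted values in canonical order, followed by ``hill_n``."""
        return np.array([getattr(self, n) for n in PARAM_NAMES] + [self.hill_n])

    @classmethod
    def from_array(cls, values: np.ndarray, hill_n: float | None = None) -> "ModelParameters":
        values = np.asarray(values, dtype=float)
        if values.size == 23 and hill_n is None:
            hill_n = float(values[22])
            values = values[:22]
        if values.size != 22:
            raise ValueError(f"expected 22 parameter values, got {values.size}")
        kwargs = dict(zip(PARAM_NAMES, values.tolist()))
        return cls(hill_n=4.0 if hill_n is None else float(hill_n), **kwargs)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        return cls(**{k: float(v) for k, v in mapping.items()})

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    # -- subpopulation modifiers ----------------------------------------
    def apply_modifiers(self, modifiers: Mapping[str, float] | Iterable[float]) -> "ModelParameters":
        """Scale noise-susceptible parameters by ``10**delta``.

        ``modifiers`` is either a mapping from (a subset of) the six
        noise-susceptible names to log10 fold changes, or a sequence of six
        values ordered like :data:`NOISE_SUSCEPTIBLE`.  A modifier on any
        other parameter is rejected.
        """
        if isinstance(modifiers, Mapping):
            bad = set(modifiers) - set(NOISE_SUSCEPTIBLE)
            if bad:
                raise ValueError(
                    f"modifiers only allowed on noise-susceptible parameters, got {sorted(bad)}"
                )
            items = modifiers.items()
        else:
            values = list(modifiers)
            if len(values) != len(NOISE_SUSCEPTIBLE):
                raise ValueError(
                    f"expected {len(NOISE_SUSCEPTIBLE)} modifier values, got {len(values)}"
                )
            items = zip(NOISE_SUSCEPTIBLE, values)
        changes = {name: getattr(self, name) * 10.0 ** float(delta) for name, delta in items}
        return self.replace(**changes)


#: Bundled reference parameter set (a package fixture, tuned so that a step
#: damage input yields relaxation-type p53 pulses with a 4-7 h period and
#: near-uniform amplitude over 24 h).  Values are in the units listed above
#: with concentrations in arbitrary units.
REFERENCE_PARAMETERS = ModelParameters(
    beta_s=2.9929,
    alpha_s=0.3967,
    alpha_ws=10.1663,
    beta_p=0.7633,
    alpha_pi=0.0698,
    alpha_mpi=38.2897,
    beta_sp=7.1664,
    T_s=0.26,
    alpha_wpa=2.4853,
    alpha_mpa=1.7785,
    beta_mt=0.0399,
    beta_pamt=2.0659,
    T_pa=0.6898,
    alpha_mt=0.4899,
    beta_mtm=1.6621,
    alpha_m=0.5334,
    alpha_sm=0.5743,
    beta_wt=0.0209,
    beta_pawt=5.1753,
    alpha_wt=1.0193,
    beta_wtw=0.5813,
    alpha_w=1.477,
    hill_n=4.0,
)
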