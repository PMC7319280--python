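"""Screening for the processes targeted by a pathway perturbation.

Two complementary strategies identify which rate constants a pharmacological
perturbation acts on:

1. *Feature-based sensitivity analysis* — each shared parameter (or signed
   pair) is nudged by a small relative amount and the effect on four pulse
   features (timing of maxima, timing of minima, inter-peak interval,
   dampening factor) is condensed per subpopulation; combinations whose
   condensed pattern matches the experimentally observed all-features-
   increased signature in enough subpopulations are candidate interaction
   points.
2. *Perturbation-combination inference* — log10 fold changes on a pair or
   triplet of shared parameters are fitted to the perturbation-condition
   peak-based means with everything else frozen at calibrated values;
   candidates are ranked by weighted chi-square, validated on time-variant
   onset datasets and filtered by qualitative population-level readouts.

Surviving combinations are merged into mechanism groups under the process
identity of the p53-activation parameters (the maximal activation rate and
its half-saturation constant act on the same process with opposite sign).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .calibration import (CalibrationConfig, pool_residuals, simulated_extrema,
                          weighted_chi2)
from .clustering import PeakBasedMean
from .ode import Perturbation, SimulationError
from .parameters import PARAM_NAMES
from .pool import ModelPool
from .trajectories import extract_features

__all__ = [
    "SignedCombination",
    "enumerate_combinations",
    "feature_sensitivity",
    "condense",
    "condensed_report",
    "match_expected_pattern",
    "CombinationFit",
    "fit_combination",
    "rank_combinations",
    "validate_time_variant",
    "qualitative_filters",
    "MechanismGroup",
    "group_mechanisms",
    "SENSITIVITY_FEATURES",
    "CONSIDERED_PEAKS",
]

#: The four features consistently shifted by the pathway perturbation.
SENSITIVITY_FEATURES: tuple[str, ...] = ("t_max", "t_min", "ipi", "df")

#: Peak indices considered per feature (first four pulses).
CONSIDERED_PEAKS: dict[str, tuple[int, ...]] = {
    "t_max": (1, 2, 3, 4),
    "t_min": (1, 2, 3, 4),
    "ipi": (1, 2, 3),
    "df": (2, 3, 4),
}


@dataclass(frozen=True)
class SignedCombination:
    """An unordered set of shared parameters with perturbation signs."""

    params: tuple[str, ...]
    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.params) != len(self.signs):
            raise ValueError("one sign per parameter required")
        for p in self.params:
            if p not in PARAM_NAMES:
                raise ValueError(f"unknown parameter {p!r}")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")

    @property
    def label(self) -> str:
        return " & ".join(f"{p}{'+' if s > 0 else '-'}"
                          for p, s in zip(self.params, self.signs))

    def flipped(self) -> "SignedCombination":
        return SignedCombination(self.params, tuple(-s for s in self.signs))


def enumerate_combinations(
    names: Sequence[str] = PARAM_NAMES,
    size: int = 2,
) -> list[SignedCombination]:
    """Deterministic enumeration of signed single/pair perturbations.

    Singles: both directions per parameter (``2m``).  Pairs: per unordered
    pair the two first-order distinct sign patterns, both-increased and
    first-increased/second-decreased (mirror patterns are redundant),
    giving ``C(m, 2) * 2`` combinations.
    """
    names = list(names)
    if size > len(names):
        raise ValueError("combination size exceeds the parameter count")
    if size == 1:
        return [SignedCombination((n,), (s,)) for n in names for s in (1, -1)]
    if size == 2:
        out = []
        for a, b in itertools.combinations(names, 2):
            out.append(SignedCombination((a, b), (1, 1)))
            out.append(SignedCombination((a, b), (1, -1)))
        return out
    raise ValueError("sensitivity screening supports sizes 1 and 2")


def _member_features(params, config: CalibrationConfig,
                     scale: float = 1.0, offset: float = 0.0) -> dict[tuple[str, int], float]:
    traj, seq = simulated_extrema(params, config, scale=scale, offset=offset)
    feats = extract_features(seq, max_peaks=4,
                             initial_value=float(traj.values[0]),
                             initial_time=float(traj.times[0]))
    out = {}
    for feature in SENSITIVITY_FEATURES:
        for idx in CONSIDERED_PEAKS[feature]:
            if idx in feats[feature]:
                out[(feature, idx)] = feats[feature][idx]
    return out


def _perturbed_params(params, combination: SignedCombination, delta: float):
    changes = {}
    for p, s in zip(combination.params, combination.signs):
        changes[p] = getattr(params, p) * (1.0 + delta * s)
    return params.replace(**changes)


def feature_sensitivity(
    pool: ModelPool,
    combination: SignedCombination,
    delta: float = 0.01,
    config: CalibrationConfig = CalibrationConfig(),
) -> pd.DataFrame:
    """Relative feature changes ``s = (F' - F) / F`` per subpopulation.

    ``delta`` is the relative parameter perturbation (e.g. +0.01, +0.30 or
    -0.30) applied with each member's sign.  Entries whose feature is
    undefined in either the reference or the perturbed simulation (lost
    pulsatility) carry ``NaN``.
    """
    rows = []
    for k in range(pool.n_subpopulations):
        base = pool.member_params(k)
        try:
            ref = _member_features(base, config, pool.scale, pool.offset)
        except (SimulationError, ValueError):
            ref = {}
        try:
            pert = _member_features(_perturbed_params(base, combination, delta),
                                    config, pool.scale, pool.offset)
        except (SimulationError, ValueError):
            pert = {}
        for feature in SENSITIVITY_FEATURES:
            for idx in CONSIDERED_PEAKS[feature]:
                key = (feature, idx)
                if key in ref and key in pert and ref[key] != 0:
                    s = (pert[key] - ref[key]) / ref[key]
                else:
                    s = np.nan
                rows.append({"combination": combination.label,
                             "subpopulation": k + 1, "feature": feature,
                             "peak_index": idx, "s": s})
    return pd.DataFrame(rows)


def condense(coefficients: Sequence[float], theta_lo: float = 1e-4,
             theta_hi: float = 1e-3) -> str:
    """Condense peak-wise sensitivity coefficients to a single call.

    ``no-effect`` when every defined coefficient is below ``theta_lo`` in
    magnitude; ``increase``/``decrease`` when all defined coefficients
    share the sign; ``inconsistent`` for mixed signs; ``undefined`` when no
    coefficient is defined.  ``theta_hi`` marks calls as *strong* upstream
    (display shading); the call logic uses ``theta_lo``.
    """
    if theta_lo >= theta_hi:
        raise ValueError("theta_lo must be below theta_hi")
    vals = np.asarray([c for c in coefficients if np.isfinite(c)], dtype=float)
    if vals.size == 0:
        return "undefined"
    if np.all(np.abs(vals) < theta_lo):
        return "no-effect"
    if np.all(vals > 0):
        return "increase"
    if np.all(vals < 0):
        return "decrease"
    return "inconsistent"


def condensed_report(
    pool: ModelPool,
    combinations: Sequence[SignedCombination],
    delta: float = 0.01,
    config: CalibrationConfig = CalibrationConfig(),
    theta_lo: float = 1e-4,
    theta_hi: float = 1e-3,
) -> pd.DataFrame:
    """Condensed sensitivity calls per (combination, feature, subpopulation)."""
    frames = []
    for comb in combinations:
        table = feature_sensitivity(pool, comb, delta=delta, config=config)
        condensed = (
            table.groupby(["combination", "subpopulation", "feature"])["s"]
            .apply(lambda v: condense(v.to_numpy(), theta_lo, theta_hi))
            .reset_index(name="call")
        )
        frames.append(condensed)
    return pd.concat(frames, ignore_index=True)


def match_expected_pattern(
    report: pd.DataFrame,
    combinations: Sequence[SignedCombination],
    min_subpopulations: int = 7,
) -> list[SignedCombination]:
    """Select combinations reproducing the expected perturbation pattern.

    A combination matches when all four features are condensed ``increase``
    in at least ``min_subpopulations`` subpopulations; an all-``decrease``
    pattern counts as a match for the sign-flipped combination.
    """
    by_label = {c.label: c for c in combinations}
    selected: list[SignedCombination] = []
    for label, sub in report.groupby("combination"):
        pivot = sub.pivot_table(index="subpopulation", columns="feature",
                                values="call", aggfunc="first")
        if pivot.shape[1] < len(SENSITIVITY_FEATURES):
            continue
        n_inc = int((pivot == "increase").all(axis=1).sum())
        n_dec = int((pivot == "decrease").all(axis=1).sum())
        if n_inc >= min_subpopulations:
            selected.append(by_label[label])
        if n_dec >= min_subpopulations:
            selected.append(by_label[label].flipped())
    return selected


# ----------------------------------------------------------------------
# perturbation-combination inference
# ----------------------------------------------------------------------
@dataclass
class CombinationFit:
    """A fitted parameter combination with its fold changes and fit quality."""

    params: tuple[str, ...]
    pi: np.ndarray                 # fitted log10 fold changes
    t_inh: float
    chi2: float
    log10_chi2: float
    success: bool = True
    validation: dict[float, float] = field(default_factory=dict)
    summarized_log10_chi2: float | None = None
    filter_verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return " & ".join(self.params)

    def perturbations(self, t_inh: float | None = None) -> tuple[Perturbation, ...]:
        onset = self.t_inh if t_inh is None else t_inh
        return tuple(Perturbation(p, float(v), onset)
                     for p, v in zip(self.params, self.pi))


def fit_combination(
    pool: ModelPool,
    param_set: Sequence[str],
    targets: Sequence[PeakBasedMean],
    t_inh: float = -1.0,
    config: CalibrationConfig = CalibrationConfig(),
    bound: float = 1.5,
    x0: np.ndarray | None = None,
    max_nfev: int | None = 60,
) -> CombinationFit:
    """Fit the log10 fold changes of one parameter set to perturbation data.

    The calibrated pool stays frozen; the fold changes apply identically to
    every subpopulation from ``t_inh`` onward.  Deterministic (single start
    from zero fold changes by default).
    """
    param_set = tuple(param_set)
    if not 1 <= len(param_set) <= 3:
        raise ValueError("combination size must be 1-3")
    for p in param_set:
        if p not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {p!r}")

    def fun(pi: np.ndarray) -> np.ndarray:
        perts = tuple(Perturbation(p, float(v), t_inh)
                      for p, v in zip(param_set, pi))
        return pool_residuals(pool, targets, config, perturbations=perts)

    start = np.zeros(len(param_set)) if x0 is None else np.asarray(x0, float)
    try:
        sol = least_squares(fun, start, bounds=(-bound, bound), method="trf",
                            diff_step=config.diff_step, max_nfev=max_nfev)
        chi2 = float(2.0 * sol.cost)
        return CombinationFit(
            params=param_set, pi=sol.x.copy(), t_inh=t_inh, chi2=chi2,
            log10_chi2=float(np.log10(max(chi2, config.log_chi2_floor))),
            success=bool(sol.status > 0),
        )
    except Exception:  # noqa: BLE001 - flagged fit, screening continues
        return CombinationFit(params=param_set, pi=np.full(len(param_set), np.nan),
                              t_inh=t_inh, chi2=np.inf, log10_chi2=np.inf,
                              success=False)


def rank_combinations(fits: Sequence[CombinationFit], top_n: int = 30) -> list[CombinationFit]:
    """Ascending by fit chi-square; ties break lexicographically by label."""
    return sorted(fits, key=lambda f: (f.chi2, f.label))[:top_n]


def validate_time_variant(
    pool: ModelPool,
    fit: CombinationFit,
    datasets: Mapping[float, Sequence[PeakBasedMean]],
    groups: Sequence[Sequence[float]] = ((1.5,), (2.5, 3.0), (5.0,)),
    config: CalibrationConfig = CalibrationConfig(),
) -> CombinationFit:
    """Score a fitted combination on time-variant onset datasets.

    The fitted fold changes are frozen; only the onset changes per dataset.
    Each dataset yields a weighted chi-square; onsets within one group are
    pooled and the summarized score is the sum of log10 group chi-squares.
    """
    validation: dict[float, float] = {}
    for onset, targets in sorted(datasets.items()):
        chi2, _ = weighted_chi2(pool, targets, config,
                                perturbations=fit.perturbations(t_inh=onset))
        validation[float(onset)] = chi2
    summarized = 0.0
    for group in groups:
        members = [validation[t] for t in group if t in validation]
        if members:
            summarized += float(np.log10(max(sum(members), config.log_chi2_floor)))
    return replace(fit, validation=validation, summarized_log10_chi2=summarized)


def qualitative_filters(
    pool: ModelPool,
    perturbations: Sequence[Perturbation],
    config: CalibrationConfig = CalibrationConfig(),
    mdm2_protein_floor: float = 0.2,
    mdm2_mrna_ceiling: float = 5.0,
) -> dict[str, bool]:
    """Population-readout plausibility checks for a fitted combination.

    (i) damage-kinase activity (pATM proxy) must not decrease (AUC);
    (ii) peak Mdm2 protein must stay above ``mdm2_protein_floor`` times the
    unperturbed peak; (iii) peak Mdm2 mRNA must stay below
    ``mdm2_mrna_ceiling`` times the unperturbed peak; plus the expected
    delayed accumulation of the Mdm2/Wip1 feedback (time to half-max not
    earlier).  ``pass_all`` aggregates (i)-(iii).
    """
    kw = dict(t_span=config.t_span, dt=config.sim_dt,
              rtol=config.solver_rtol, atol=config.solver_atol)
    ref = pool.population_readouts((), **kw)
    try:
        pert = pool.population_readouts(tuple(perturbations), **kw)
    except SimulationError:
        # a combination whose readouts cannot even be simulated is implausible
        keys = ("kinase_activity_not_decreased", "mdm2_protein_not_depleted",
                "mdm2_mrna_not_overshooting", "mdm2_accumulation_delayed",
                "wip1_accumulation_delayed", "pass_all")
        return {k: False for k in keys}

    def auc(tab, name):
        return float(np.trapezoid(tab[name], tab["time_h"]))

    def t_half(tab, name):
        y = tab[name].to_numpy()
        target = y[0] + 0.5 * (y.max() - y[0])
        idx = np.argmax(y >= target)
        return float(tab["time_h"].iloc[idx])

    verdicts = {
        "kinase_activity_not_decreased": auc(pert, "patm") >= auc(ref, "patm") * (1 - 1e-9),
        "mdm2_protein_not_depleted":
            pert["mdm2"].max() >= mdm2_protein_floor * ref["mdm2"].max(),
        "mdm2_mrna_not_overshooting":
            pert["mdm2_mrna"].max() <= mdm2_mrna_ceiling * ref["mdm2_mrna"].max(),
        "mdm2_accumulation_delayed": t_half(pert, "mdm2") >= t_half(ref, "mdm2"),
        "wip1_accumulation_delayed": t_half(pert, "wip1") >= t_half(ref, "wip1"),
    }
    verdicts["pass_all"] = (verdicts["kinase_activity_not_decreased"]
                            and verdicts["mdm2_protein_not_depleted"]
                            and verdicts["mdm2_mrna_not_overshooting"])
    return verdicts


# ----------------------------------------------------------------------
# mechanism grouping
# ----------------------------------------------------------------------
#: Biochemical process affected by each parameter.  The maximal
#: ATM-mediated activation rate and its half-saturation constant act on the
#: same process; raising the half-saturation *lowers* activation, hence the
#: direction flip.
_PROCESS: dict[str, tuple[str, int]] = {p: (p, +1) for p in PARAM_NAMES}
_PROCESS["beta_sp"] = ("p53 activation by ATM", +1)
_PROCESS["T_s"] = ("p53 activation by ATM", -1)


@dataclass
class MechanismGroup:
    """Combinations equivalent up to the p53-activation process identity."""

    processes: frozenset[tuple[str, int]]  # (process label, direction)
    members: list[CombinationFit]

    @property
    def label(self) -> str:
        parts = sorted(f"{name} {'up' if d > 0 else 'down'}"
                       for name, d in self.processes)
        return "; ".join(parts)


def signed_processes(fit: CombinationFit) -> frozenset[tuple[str, int]]:
    out = set()
    for p, v in zip(fit.params, fit.pi):
        name, flip = _PROCESS[p]
        direction = int(np.sign(v)) * flip
        out.add((name, direction))
    return frozenset(out)


def group_mechanisms(fits: Sequence[CombinationFit]) -> list[MechanismGroup]:
    """Merge combinations whose signed processes coincide."""
    groups: dict[frozenset, list[CombinationFit]] = {}
    for fit in fits:
        if not np.all(np.isfinite(fit.pi)):
            continue
        groups.setdefault(signed_processes(fit), []).append(fit)
    return [MechanismGroup(processes=k, members=v)
            for k, v in sorted(groups.items(), key=lambda kv: sorted(kv[0]))]
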