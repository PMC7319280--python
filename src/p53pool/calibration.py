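"""Calibration of the model pool against peak-based means.

The central estimation problem: one set of 22 shared kinetic parameters and
a ``K x 6`` matrix of subpopulation-specific log10 fold changes are fitted
*simultaneously* to the peak-based means of all K subpopulations.  The
objective is a cell-count-weighted sum of squared extrema residuals
(timings and values, each scaled by its uncertainty) plus an L1 penalty on
the fold changes; sweeping the penalty weight and keeping the largest
penalty that does not degrade the fit identifies which fold changes are
dispensable ("unspecific").

Follows the Model/Results convention: :class:`ModelPoolCalibration` holds
the data and configuration, ``fit()`` returns
:class:`PoolCalibrationResults` carrying estimates, diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .clustering import PeakBasedMean
from .ode import DamageInput, Perturbation, SimulationError, observe_p53, simulate
from .parameters import NOISE_SUSCEPTIBLE, PARAM_NAMES, REFERENCE_PARAMETERS, ModelParameters
from .pool import ModelPool
from .trajectories import Trajectory, detect_extrema

__all__ = [
    "CalibrationConfig",
    "ModelPoolCalibration",
    "PoolCalibrationResults",
    "L1PathResults",
    "pool_residuals",
    "weighted_chi2",
    "simulated_extrema",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Numerical settings of the pool objective and optimizer."""

    sigma_t: float = 0.25            # timing uncertainty, h (one frame)
    sigma_y_frac: float = 0.05       # value uncertainty, fraction of first-peak value
    missing_peak_penalty: float = 5.0  # residual per unmatched target extremum
    huber_eps: float = 1e-6          # smoothing of |delta| in the L1 term
    zero_tolerance: float = 1e-3     # |delta| below this is reported as zero
    shared_bound: float = 3.0        # log10 box around the initial shared values
    modifier_bound: float = 1.0      # log10 box for fold changes
    n_starts: int = 50
    start_scale: float = 1.0         # LHS start dispersion as a fraction of the bounds
    t_span: tuple[float, float] = (0.0, 24.0)
    sim_dt: float = 0.05
    solver_rtol: float = 1e-6
    solver_atol: float = 1e-8
    diff_step: float = 1e-3
    max_nfev: int | None = None
    min_separation: float = 2.0
    prominence_fraction: float = 0.05
    log_chi2_floor: float = 1e-12


def simulated_extrema(
    params: ModelParameters,
    config: CalibrationConfig,
    perturbations: Sequence[Perturbation] = (),
    scale: float = 1.0,
    offset: float = 0.0,
):
    """Simulate one pool member and detect its (sub-grid refined) extrema."""
    t0 = min(config.t_span[0], min((p.onset for p in perturbations), default=0.0))
    res = simulate(params, damage=DamageInput(), perturbations=perturbations,
                   t_span=(t0, config.t_span[1]), dt=config.sim_dt,
                   rtol=config.solver_rtol, atol=config.solver_atol)
    mask = res.t >= config.t_span[0]
    t, y = observe_p53(res, scale=scale, offset=offset)
    traj = Trajectory("sim", t[mask], y[mask])
    seq = detect_extrema(traj, min_separation=config.min_separation,
                         prominence_fraction=config.prominence_fraction,
                         refine=True)
    return traj, seq


def _member_residuals(
    traj: Trajectory,
    seq,
    target: PeakBasedMean,
    config: CalibrationConfig,
) -> np.ndarray:
    """Extrema residuals of one member against one peak-based mean."""
    sigma_y = config.sigma_y_frac * abs(target.peak_values[0])
    if sigma_y <= 0:
        raise ValueError("target first-peak value must be nonzero")
    out: list[float] = []
    # initial-value residual at the first observed time
    y0 = float(np.interp(target.initial_time, traj.times, traj.values))
    out.append((y0 - target.initial_value) / sigma_y)
    maxima, minima = seq.maxima, seq.minima
    min_by_peak = {}
    for i, m in enumerate(maxima):
        nxt = maxima[i + 1].time if i + 1 < len(maxima) else np.inf
        for e in minima:
            if m.time < e.time < nxt:
                min_by_peak[i] = e
                break
    # lenient trailing pairing: when the target demands a minimum after the
    # last simulated maximum, use the simulated tail's global minimum even
    # if it is not an interior local minimum (observation-window edge)
    last = len(maxima) - 1
    if (last >= 0 and last < target.n_peaks and last not in min_by_peak
            and not np.isnan(target.min_times[last])):
        tail = traj.times > maxima[last].time
        if np.sum(tail) >= 2:
            i_min = np.argmin(traj.values[tail])
            from .trajectories import Extremum

            min_by_peak[last] = Extremum("min",
                                         float(traj.times[tail][i_min]),
                                         float(traj.values[tail][i_min]))
    for n in range(target.n_peaks):
        if n < len(maxima):
            out.append((maxima[n].time - target.peak_times[n]) / config.sigma_t)
            out.append((maxima[n].value - target.peak_values[n]) / sigma_y)
        else:
            # fixed-length penalty block keeps the residual vector shape
            # independent of the simulated peak count
            out.extend([config.missing_peak_penalty] * 2)
        if not np.isnan(target.min_times[n]):
            if n in min_by_peak:
                e = min_by_peak[n]
                out.append((e.time - target.min_times[n]) / config.sigma_t)
                out.append((e.value - target.min_values[n]) / sigma_y)
            else:
                out.extend([config.missing_peak_penalty] * 2)
    return np.asarray(out)


def pool_residuals(
    pool: ModelPool,
    targets: Sequence[PeakBasedMean],
    config: CalibrationConfig = CalibrationConfig(),
    perturbations: Sequence[Perturbation] = (),
    weighted: bool = True,
) -> np.ndarray:
    """Stacked residual vector over all subpopulations.

    With ``weighted=True`` each member's residual block is multiplied by
    the square root of its cluster weight, so the squared norm equals the
    weighted sum of squared residuals.  A failed simulation yields an
    all-penalty block (flagged infinite objective upstream is avoided to
    keep optimizers moving).
    """
    if len(targets) != pool.n_subpopulations:
        raise ValueError("one target per subpopulation required")
    blocks = []
    for k, target in enumerate(targets):
        w = np.sqrt(pool.weights[k]) if weighted else 1.0
        try:
            traj, seq = simulated_extrema(pool.member_params(k), config,
                                          perturbations=perturbations,
                                          scale=pool.scale, offset=pool.offset)
            r = _member_residuals(traj, seq, target, config)
        except (SimulationError, ValueError):
            n = 1 + 2 * target.n_peaks + 2 * int(np.sum(~np.isnan(target.min_times)))
            r = np.full(n, 10.0 * config.missing_peak_penalty)
        blocks.append(w * r)
    return np.concatenate(blocks)


def weighted_chi2(
    pool: ModelPool,
    targets: Sequence[PeakBasedMean],
    config: CalibrationConfig = CalibrationConfig(),
    perturbations: Sequence[Perturbation] = (),
) -> tuple[float, float]:
    """Cell-count-weighted chi-square and its guarded log10.

    ``chi2 = sum_k w_k sum_i (x_ki - x_hat_ki)^2 / sigma_ki^2`` over the
    extrema residuals; the log10 is floored for perfect fits.
    """
    r = pool_residuals(pool, targets, config, perturbations=perturbations)
    chi2 = float(np.sum(r * r))
    return chi2, float(np.log10(max(chi2, config.log_chi2_floor)))


def pool_targets(
    pool: ModelPool,
    config: CalibrationConfig = CalibrationConfig(),
    perturbations: Sequence[Perturbation] = (),
    max_peaks: int = 4,
    obs_start: float = 0.5,
) -> list[PeakBasedMean]:
    """Noiseless peak-based means of a pool's members (ground-truth targets).

    Each member's simulated extrema (restricted to the first ``max_peaks``
    pulses) stand in for a cluster average; member counts mirror the pool
    weights so downstream weighting is preserved.
    """
    targets = []
    counts = np.maximum(1, np.round(100 * pool.weights)).astype(int)
    for k in range(pool.n_subpopulations):
        traj, seq = simulated_extrema(pool.member_params(k), config,
                                      perturbations=perturbations,
                                      scale=pool.scale, offset=pool.offset)
        maxima = seq.maxima[:max_peaks]
        if not maxima:
            raise SimulationError(f"pool member {k} shows no pulse")
        minima = seq.minima
        mt, mv = [], []
        for i, m in enumerate(maxima):
            nxt = maxima[i + 1].time if i + 1 < len(maxima) else np.inf
            found = next((e for e in minima if m.time < e.time < nxt), None)
            mt.append(found.time if found else np.nan)
            mv.append(found.value if found else np.nan)
        y0 = float(np.interp(obs_start, traj.times, traj.values))
        targets.append(PeakBasedMean(
            cluster=k + 1, n_members=int(counts[k]),
            initial_value=y0, initial_time=obs_start,
            peak_times=[m.time for m in maxima],
            peak_values=[m.value for m in maxima],
            min_times=mt, min_values=mv,
        ))
    return targets


@dataclass
class L1PathResults:
    """Outcome of the penalty sweep: selected weight and per-step table."""

    lam_star: float
    results: "PoolCalibrationResults"
    path: pd.DataFrame


class ModelPoolCalibration:
    """Joint fit of shared kinetics and subpopulation fold changes.

    Parameters
    ----------
    targets : sequence of PeakBasedMean
        One peak-based mean per subpopulation (the fitting data).
    weights : array-like, optional
        Cluster weights; defaults to the targets' member counts.
    shared_init : ModelParameters
        Nominal shared parameter values; fitting is done in log10 space
        around these.
    scale, offset : float
        Fixed observation mapping from model concentration to reporter
        intensity.
    fit_shared : bool
        When False only the fold-change matrix is optimised.
    """

    def __init__(
        self,
        targets: Sequence[PeakBasedMean],
        weights: np.ndarray | None = None,
        shared_init: ModelParameters = REFERENCE_PARAMETERS,
        config: CalibrationConfig = CalibrationConfig(),
        scale: float = 1.0,
        offset: float = 0.0,
        fit_shared: bool = True,
    ) -> None:
        if not targets:
            raise ValueError("no calibration targets")
        self.targets = list(targets)
        if weights is None:
            counts = np.array([t.n_members for t in self.targets], dtype=float)
            weights = counts / counts.sum()
        self.weights = np.asarray(weights, dtype=float)
        self.shared_init = shared_init
        self.config = config
        self.scale = scale
        self.offset = offset
        self.fit_shared = fit_shared
        self.k = len(self.targets)
        self.n_modifiers = self.k * len(NOISE_SUSCEPTIBLE)

    # -- parameter vector mapping ---------------------------------------
    def _unpack(self, x: np.ndarray) -> ModelPool:
        if self.fit_shared:
            shared_log = x[: len(PARAM_NAMES)]
            delta = x[len(PARAM_NAMES):]
        else:
            shared_log = np.zeros(len(PARAM_NAMES))
            delta = x
        shared = ModelParameters.from_array(
            self.shared_init.to_array()[:22] * 10.0 ** shared_log,
            hill_n=self.shared_init.hill_n,
        )
        return ModelPool(shared=shared,
                         modifiers=delta.reshape(self.k, len(NOISE_SUSCEPTIBLE)),
                         weights=self.weights.copy(),
                         scale=self.scale, offset=self.offset)

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        lo, hi = [], []
        if self.fit_shared:
            lo += [-cfg.shared_bound] * len(PARAM_NAMES)
            hi += [cfg.shared_bound] * len(PARAM_NAMES)
        lo += [-cfg.modifier_bound] * self.n_modifiers
        hi += [cfg.modifier_bound] * self.n_modifiers
        return np.asarray(lo), np.asarray(hi)

    def _penalty(self, delta: np.ndarray, lam: float) -> np.ndarray:
        if lam == 0.0:
            return np.empty(0)
        eps = self.config.huber_eps
        return np.sqrt(lam * (np.sqrt(delta ** 2 + eps ** 2) - eps) + 1e-300)

    def residuals(self, x: np.ndarray, lam: float = 0.0) -> np.ndarray:
        pool = self._unpack(x)
        r = pool_residuals(pool, self.targets, self.config)
        delta = pool.modifiers.ravel()
        return np.concatenate([r, self._penalty(delta, lam)])

    def objective(self, pool: ModelPool, lam: float = 0.0) -> float:
        """``J = sum_k w_k SSR_k + lam * sum |delta|``."""
        r = pool_residuals(pool, self.targets, self.config)
        return float(np.sum(r * r) + lam * np.sum(np.abs(pool.modifiers)))

    # -- fitting ---------------------------------------------------------
    def _starts(self, n_starts: int, seed: int) -> np.ndarray:
        lo, hi = self._bounds()
        dim = lo.size
        starts = [np.zeros(dim)]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=dim, seed=seed)
            unit = sampler.random(n_starts - 1)
            span = self.config.start_scale * (hi - lo)
            centre = 0.5 * (hi + lo)
            pts = centre + (unit - 0.5) * span
            starts.extend(np.clip(pts, lo, hi))
        return np.asarray(starts)

    def _stage1(self, s: np.ndarray, lam: float) -> np.ndarray:
        """Warm start: optimise the fold changes at fixed shared values."""
        cfg = self.config
        n_shared = len(PARAM_NAMES)
        shared_part = s[:n_shared]

        def fun(delta: np.ndarray) -> np.ndarray:
            return self.residuals(np.concatenate([shared_part, delta]), lam)

        sol = least_squares(
            fun, s[n_shared:],
            bounds=(-cfg.modifier_bound * np.ones(self.n_modifiers),
                    cfg.modifier_bound * np.ones(self.n_modifiers)),
            method="trf", diff_step=cfg.diff_step, max_nfev=cfg.max_nfev,
        )
        return np.concatenate([shared_part, sol.x])

    def fit(
        self,
        lam: float = 0.0,
        n_starts: int | None = None,
        seed: int = 0,
        x0: np.ndarray | None = None,
        staged: bool = True,
    ) -> "PoolCalibrationResults":
        """Multi-start bounded trust-region least squares (deterministic
        given ``seed``).

        With ``staged=True`` (and shared parameters free) each start first
        optimises the fold-change matrix at fixed shared values — a cheap,
        well-conditioned subproblem — before the joint fit, which markedly
        reduces the rate of poor local optima.
        """
        cfg = self.config
        lo, hi = self._bounds()
        if x0 is not None:
            starts = np.asarray([x0])
            staged = False
        else:
            starts = self._starts(n_starts or cfg.n_starts, seed)
        trace = []
        best = None
        for i, s in enumerate(starts):
            try:
                if staged and self.fit_shared:
                    s = self._stage1(s, lam)
                sol = least_squares(
                    self.residuals, s, args=(lam,), bounds=(lo, hi),
                    method="trf", diff_step=cfg.diff_step, max_nfev=cfg.max_nfev,
                )
                cost = 2.0 * sol.cost
                trace.append({"start": i, "cost": cost, "nfev": sol.nfev,
                              "status": sol.status})
                if best is None or cost < best[0]:
                    best = (cost, sol)
            except Exception as exc:  # noqa: BLE001 - optimizer diagnostics
                trace.append({"start": i, "cost": np.inf, "nfev": 0,
                              "status": f"failed: {exc}"})
        if best is None:
            raise RuntimeError(f"all optimization starts failed: {trace}")
        sol = best[1]
        pool = self._unpack(sol.x)
        return PoolCalibrationResults(model=self, pool=pool, x=sol.x, lam=lam,
                                      trace=pd.DataFrame(trace), seed=seed)

    def fit_l1_path(
        self,
        lam_grid: Sequence[float] | None = None,
        n_starts: int | None = None,
        seed: int = 0,
        ssr_tolerance: float = 0.05,
        ssr_slack: float = 2.0,
    ) -> L1PathResults:
        """Warm-started sweep over ascending penalty weights.

        The selected weight is the largest one whose weighted SSR stays
        within ``ssr_tolerance`` (relative) of the unpenalized SSR; fold
        changes below the zero tolerance are then set to exactly zero.
        ``ssr_slack`` is an absolute allowance (in squared sigma units)
        that keeps the rule meaningful when the unpenalized fit is
        essentially exact, as on noiseless synthetic targets.
        """
        if lam_grid is None:
            lam_grid = [0.0] + list(np.logspace(-2, 2, 20))
        lam_grid = sorted(set(float(x) for x in lam_grid))
        if not lam_grid:
            raise ValueError("empty penalty grid")
        if lam_grid[0] != 0.0:
            raise ValueError("penalty grid must include 0")
        base = self.fit(lam=0.0, n_starts=n_starts, seed=seed)
        records = [{"lam": 0.0, "ssr": base.ssr_weighted,
                    "n_specific": base.n_specific}]
        fits = {0.0: base}
        x_prev = base.x
        for lam in lam_grid[1:]:
            res = self.fit(lam=lam, x0=x_prev)
            x_prev = res.x
            fits[lam] = res
            records.append({"lam": lam, "ssr": res.ssr_weighted,
                            "n_specific": res.n_specific})
        path = pd.DataFrame(records)
        admissible = path[path["ssr"] <=
                          (1.0 + ssr_tolerance) * base.ssr_weighted + ssr_slack]
        lam_star = float(admissible["lam"].max())
        chosen = fits[lam_star].sparsified()
        return L1PathResults(lam_star=lam_star, results=chosen, path=path)


@dataclass
class PoolCalibrationResults:
    """Estimates, diagnostics and reporting for a fitted model pool."""

    model: ModelPoolCalibration
    pool: ModelPool
    x: np.ndarray
    lam: float
    trace: pd.DataFrame
    seed: int

    @property
    def ssr_weighted(self) -> float:
        r = pool_residuals(self.pool, self.model.targets, self.model.config)
        return float(np.sum(r * r))

    @property
    def objective(self) -> float:
        return self.model.objective(self.pool, self.lam)

    @property
    def n_specific(self) -> int:
        return self.pool.count_specific(self.model.config.zero_tolerance)

    def member_residuals(self) -> dict[int, float]:
        """Unweighted SSR per subpopulation."""
        out = {}
        for k, target in enumerate(self.model.targets):
            single = ModelPool(shared=self.pool.shared,
                               modifiers=self.pool.modifiers[[k]],
                               weights=np.array([1.0]),
                               scale=self.pool.scale, offset=self.pool.offset)
            r = pool_residuals(single, [target], self.model.config)
            out[k] = float(np.sum(r * r))
        return out

    def sparsified(self) -> "PoolCalibrationResults":
        """Copy with below-tolerance fold changes set to exactly zero."""
        mods = self.pool.modifiers.copy()
        mods[np.abs(mods) < self.model.config.zero_tolerance] = 0.0
        pool = ModelPool(shared=self.pool.shared, modifiers=mods,
                         weights=self.pool.weights.copy(),
                         scale=self.pool.scale, offset=self.pool.offset)
        return replace(self, pool=pool)

    def shared_log10_deviation(self) -> pd.Series:
        """log10 of fitted shared values relative to the initial values."""
        fitted = self.pool.shared.to_array()[:22]
        init = self.model.shared_init.to_array()[:22]
        return pd.Series(np.log10(fitted / init), index=list(PARAM_NAMES))

    def summary(self) -> str:
        buf = io.StringIO()
        cfg = self.model.config
        print("Model pool calibration results", file=buf)
        print("=" * 64, file=buf)
        print(f"subpopulations: {self.model.k}    "
              f"candidate modifiers: {self.model.n_modifiers}", file=buf)
        print(f"penalty weight lambda: {self.lam:g}    "
              f"specific modifiers (|d|>={cfg.zero_tolerance:g}): {self.n_specific}",
              file=buf)
        print(f"weighted SSR: {self.ssr_weighted:.4g}    "
              f"objective: {self.objective:.4g}", file=buf)
        print("-" * 64, file=buf)
        print("shared parameters (fitted value, log10 vs initial):", file=buf)
        dev = self.shared_log10_deviation()
        for name in PARAM_NAMES:
            print(f"  {name:<10} {getattr(self.pool.shared, name):>12.5g} "
                  f"{dev[name]:>+8.3f}", file=buf)
        print("-" * 64, file=buf)
        print("fold-change matrix (log10, rows = subpopulations):", file=buf)
        header = "  ".join(f"{n:>9}" for n in NOISE_SUSCEPTIBLE)
        print("        " + header, file=buf)
        for k in range(self.model.k):
            row = "  ".join(f"{v:>+9.3f}" for v in self.pool.modifiers[k])
            print(f"  sp{k + 1:02d}  {row}   w={self.pool.weights[k]:.3f}", file=buf)
        return buf.getvalue()
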