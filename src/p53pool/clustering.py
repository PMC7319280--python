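"""Subpopulation clustering of pulsatile trajectories.

Cells with similar dynamics are grouped by hierarchical (Ward) clustering of
pairwise Euclidean dissimilarities between smoothed, per-cell
range-normalised trajectories; the cluster number is selected by the
Calinski-Harabasz index.  Per cluster, a *peak-based mean* (mean peak
timings and values) preserves pulse shape that a pointwise average would
blur.  Trajectories recorded under a pathway perturbation are assigned to
the calibration clusters by direction criteria on their dynamic features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .trajectories import (
    ExtremaSequence,
    Trajectory,
    detect_extrema,
    extract_features,
    features_dataframe,
    smooth,
)

__all__ = [
    "trajectory_matrix",
    "pairwise_dissimilarity",
    "hierarchical_cluster",
    "calinski_harabasz",
    "select_cluster_count",
    "PeakBasedMean",
    "peak_based_mean",
    "AssignmentRule",
    "DEFAULT_ASSIGNMENT_RULES",
    "ClusterFeatureSummary",
    "assign_to_clusters",
    "assignment_percentages",
    "cluster_weights",
    "UNASSIGNABLE",
]

UNASSIGNABLE = 0  # label for trajectories without detectable pulses


def trajectory_matrix(
    trajectories: Sequence[Trajectory],
    sigma: float = 0.5,
    normalize: str = "range",
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Stack smoothed, per-cell normalised trajectories on a common grid.

    ``normalize``: ``"range"`` maps each cell to [0, 1] (the default
    representation for dissimilarities), ``"none"`` keeps raw intensities.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    if grid is None:
        start = max(t.times[0] for t in trajectories)
        stop = min(t.times[-1] for t in trajectories)
        if stop <= start:
            raise ValueError("trajectories have non-overlapping time spans")
        dt = trajectories[0].dt
        grid = start + dt * np.arange(int((stop - start) / dt) + 1)
    rows = []
    for traj in trajectories:
        s = smooth(traj, sigma=sigma) if sigma else traj
        y = np.interp(grid, s.times, s.values)
        if normalize == "range":
            rng = y.max() - y.min()
            y = (y - y.min()) / rng if rng > 0 else np.zeros_like(y)
        elif normalize != "none":
            raise ValueError(f"unknown normalisation {normalize!r}")
        rows.append(y)
    return np.asarray(rows)


def pairwise_dissimilarity(
    trajectories: Sequence[Trajectory],
    method: str = "trajectory",
    sigma: float = 0.5,
) -> np.ndarray:
    """Symmetric dissimilarity matrix between cells.

    ``method="trajectory"`` (default): Euclidean distance between smoothed,
    range-normalised trajectories resampled to the common grid.
    ``method="features"``: Euclidean distance between z-scored feature
    vectors (missing features imputed with the column mean).
    """
    if method == "trajectory":
        X = trajectory_matrix(trajectories, sigma=sigma)
    elif method == "features":
        X = _feature_embedding(trajectories, sigma=sigma)
    else:
        raise ValueError(f"unknown dissimilarity method {method!r}")
    return squareform(pdist(X, metric="euclidean"))


def _feature_embedding(trajectories: Sequence[Trajectory], sigma: float = 0.5) -> np.ndarray:
    table = features_dataframe(trajectories, sigma=sigma)
    wide = table.pivot_table(index="cell_id", columns=["feature", "peak_index"], values="value")
    wide = wide.reindex([t.cell_id for t in trajectories])
    X = wide.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def hierarchical_cluster(
    dissimilarity: np.ndarray,
    k: int,
    method: str = "ward",
) -> np.ndarray:
    """Cut an agglomerative tree at ``k`` clusters; labels are 1..k.

    Labels are renumbered contiguously in order of first appearance so the
    result is deterministic given the dissimilarity matrix.
    """
    n = dissimilarity.shape[0]
    if not 2 <= k < n:
        raise ValueError(f"cluster count must satisfy 2 <= k < n, got k={k}, n={n}")
    condensed = squareform(dissimilarity, checks=False)
    Z = linkage(condensed, method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = np.zeros_like(raw)
    mapping: dict[int, int] = {}
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[i] = mapping[r]
    return labels


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion ``[B/(K-1)] / [W/(N-K)]``.

    ``B``/``W`` are the between- and within-cluster sums of squared
    deviations in the representation space ``X``.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ValueError("need at least 2 clusters")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        mask = labels == u
        centroid = X[mask].mean(axis=0)
        B += mask.sum() * float(np.sum((centroid - grand) ** 2))
        W += float(np.sum((X[mask] - centroid) ** 2))
    if W == 0.0:
        raise ValueError("degenerate clustering: zero within-cluster scatter")
    return (B / (k - 1)) / (W / (n - k))


def select_cluster_count(
    trajectories: Sequence[Trajectory],
    k_range: Iterable[int] = range(2, 16),
    sigma: float = 0.5,
    method: str = "ward",
) -> tuple[int, np.ndarray, pd.DataFrame]:
    """Choose the cluster number maximising the Calinski-Harabasz index.

    Ties break toward smaller ``k``.  Returns ``(k_star, labels, score
    table)``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty cluster-count range")
    X = trajectory_matrix(trajectories, sigma=sigma)
    D = squareform(pdist(X, metric="euclidean"))
    best: tuple[float, int, np.ndarray] | None = None
    records = []
    for k in ks:
        labels = hierarchical_cluster(D, k, method=method)
        score = calinski_harabasz(X, labels)
        records.append({"k": k, "calinski_harabasz": score})
        if best is None or score > best[0]:
            best = (score, k, labels)
    assert best is not None
    return best[1], best[2], pd.DataFrame(records)


# ----------------------------------------------------------------------
# peak-based means
# ----------------------------------------------------------------------
@dataclass
class PeakBasedMean:
    """Per-cluster mean pulse shape: mean extrema timings and values.

    ``min_times``/``min_values`` are aligned with the peak indices; the
    entry for the last pulse may be NaN when no trailing minimum exists.
    """

    cluster: int
    n_members: int
    initial_value: float
    peak_times: np.ndarray
    peak_values: np.ndarray
    min_times: np.ndarray
    min_values: np.ndarray
    initial_time: float = 0.0

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_values = np.asarray(self.peak_values, dtype=float)
        self.min_times = np.asarray(self.min_times, dtype=float)
        self.min_values = np.asarray(self.min_values, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("mean peak times must be strictly increasing")
        # alternation: each minimum lies after its peak (and before the next)
        for i, tm in enumerate(self.min_times):
            if np.isnan(tm):
                continue
            if tm <= self.peak_times[i]:
                raise ValueError("mean extrema do not alternate")
            if i + 1 < self.peak_times.size and tm >= self.peak_times[i + 1]:
                raise ValueError("mean extrema do not alternate")

    @property
    def n_peaks(self) -> int:
        return self.peak_times.size

    def to_dict(self) -> dict:
        return {
            "cluster": int(self.cluster),
            "n_members": int(self.n_members),
            "initial_time": float(self.initial_time),
            "initial_value": float(self.initial_value),
            "peak_times": self.peak_times.tolist(),
            "peak_values": self.peak_values.tolist(),
            "min_times": self.min_times.tolist(),
            "min_values": self.min_values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PeakBasedMean":
        return cls(
            cluster=d["cluster"], n_members=d["n_members"],
            initial_value=d["initial_value"], initial_time=d.get("initial_time", 0.0),
            peak_times=d["peak_times"], peak_values=d["peak_values"],
            min_times=d["min_times"], min_values=d["min_values"],
        )


def peak_based_mean(
    trajectories: Sequence[Trajectory],
    sequences: Sequence[ExtremaSequence] | None = None,
    cluster: int = 1,
    coverage: float = 0.5,
    sigma: float = 0.5,
) -> PeakBasedMean:
    """Average extrema of a cluster in a peak-wise manner.

    Pulse index ``n`` is retained while at least ``coverage`` of the
    members possess an ``n``-th maximum; mean timings and values are taken
    over the possessing members.  The initial value is the mean first
    observed (smoothed) sample.
    """
    if not trajectories:
        raise ValueError("empty cluster")
    if sequences is None:
        smoothed = [smooth(t, sigma=sigma) if sigma else t for t in trajectories]
        sequences = [detect_extrema(s) for s in smoothed]
        inits = [float(s.values[0]) for s in smoothed]
        init_ts = [float(s.times[0]) for s in smoothed]
    else:
        inits = [float(t.values[0]) for t in trajectories]
        init_ts = [float(t.times[0]) for t in trajectories]
    counts = [seq.n_peaks for seq in sequences]
    if max(counts, default=0) == 0:
        raise ValueError("no member of the cluster has a detected peak")
    n_members = len(sequences)
    p_max = max(p for p in range(1, max(counts) + 1)
                if sum(c >= p for c in counts) / n_members >= coverage)
    pt, pv, mt, mv = [], [], [], []
    for idx in range(p_max):
        have = [seq for seq in sequences if seq.n_peaks > idx]
        pt.append(np.mean([s.maxima[idx].time for s in have]))
        pv.append(np.mean([s.maxima[idx].value for s in have]))
        have_min = [s.minima[idx] for s in have if len(s.minima) > idx
                    and s.minima[idx].time > s.maxima[idx].time]
        if len(have_min) / n_members >= coverage:
            mt.append(np.mean([e.time for e in have_min]))
            mv.append(np.mean([e.value for e in have_min]))
        else:
            mt.append(np.nan)
            mv.append(np.nan)
    return PeakBasedMean(
        cluster=cluster, n_members=n_members,
        initial_value=float(np.mean(inits)), initial_time=float(np.mean(init_ts)),
        peak_times=pt, peak_values=pv, min_times=mt, min_values=mv,
    )


def cluster_weights(labels: np.ndarray, include_unassignable: bool = False) -> dict[int, float]:
    """Cluster weights proportional to assigned cell counts (sum to 1)."""
    labels = np.asarray(labels)
    if not include_unassignable:
        labels = labels[labels != UNASSIGNABLE]
    uniq, counts = np.unique(labels, return_counts=True)
    total = counts.sum()
    if total == 0:
        raise ValueError("no assignable cells; weights are not normalizable")
    return {int(u): float(c) / total for u, c in zip(uniq, counts)}


# ----------------------------------------------------------------------
# assignment of perturbation trajectories to calibration clusters
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class AssignmentRule:
    """A signed inequality between a trajectory feature and the cluster's
    calibration value: direction ``+`` (larger), ``-`` (smaller) or ``~``
    (comparable within relative ``tolerance``)."""

    feature: str
    peak_index: int
    direction: str
    tolerance: float = 0.3


#: Nine default criteria encoding the experimentally observed response to
#: the pathway perturbation: delayed maxima/minima, longer inter-peak
#: intervals, stronger dampening, comparable first-pulse amplitude.
DEFAULT_ASSIGNMENT_RULES: tuple[AssignmentRule, ...] = (
    AssignmentRule("t_max", 1, "+"),
    AssignmentRule("t_max", 2, "+"),
    AssignmentRule("t_min", 1, "+"),
    AssignmentRule("t_min", 2, "+"),
    AssignmentRule("ipi", 1, "+"),
    AssignmentRule("ipi", 2, "+"),
    AssignmentRule("df", 2, "+"),
    AssignmentRule("df", 3, "+"),
    AssignmentRule("f_max", 1, "~", 0.3),
)


@dataclass
class ClusterFeatureSummary:
    """Per-cluster mean feature values and population stds for assignment."""

    cluster_means: dict[int, dict[tuple[str, int], float]]
    population_std: dict[tuple[str, int], float]

    @classmethod
    def from_features(cls, features: pd.DataFrame, labels: Sequence[int],
                      cell_ids: Sequence[str]) -> "ClusterFeatureSummary":
        lab = pd.DataFrame({"cell_id": list(cell_ids), "cluster": list(labels)})
        merged = features.merge(lab, on="cell_id")
        merged = merged[merged["cluster"] != UNASSIGNABLE]
        means: dict[int, dict[tuple[str, int], float]] = {}
        for (k, feat, idx), grp in merged.groupby(["cluster", "feature", "peak_index"]):
            means.setdefault(int(k), {})[(feat, int(idx))] = float(grp["value"].mean())
        stds = {
            (feat, int(idx)): float(grp["value"].std(ddof=0)) or 1.0
            for (feat, idx), grp in merged.groupby(["feature", "peak_index"])
        }
        return cls(cluster_means=means, population_std=stds)


def assign_to_clusters(
    trajectories: Sequence[Trajectory],
    summary: ClusterFeatureSummary,
    rules: Sequence[AssignmentRule] | None = DEFAULT_ASSIGNMENT_RULES,
    sigma: float = 0.5,
) -> pd.DataFrame:
    """Assign trajectories to calibration clusters by direction criteria.

    Each trajectory goes to the cluster satisfying the most rules; among
    ties, the cluster with minimal z-scored feature distance wins.  With
    ``rules=None`` (or an empty list) assignment is purely by distance.
    Trajectories without any detected pulse receive the ``UNASSIGNABLE``
    label 0.  Returns a frame ``cell_id, cluster, score, distance``.
    """
    rules = tuple(rules) if rules else ()
    features = features_dataframe(trajectories, sigma=sigma)
    rows = []
    for traj in trajectories:
        cell = features[features["cell_id"] == traj.cell_id]
        values = {(r.feature, int(r.peak_index)): float(r.value)
                  for r in cell.itertuples()}
        if not values or ("t_max", 1) not in values:
            rows.append({"cell_id": traj.cell_id, "cluster": UNASSIGNABLE,
                         "score": 0, "distance": np.nan})
            continue
        best: tuple[float, float, int] | None = None  # (-score, distance, cluster)
        for k, means in sorted(summary.cluster_means.items()):
            score = 0
            for rule in rules:
                key = (rule.feature, rule.peak_index)
                if key not in values or key not in means:
                    continue
                x, m = values[key], means[key]
                if rule.direction == "+" and x > m:
                    score += 1
                elif rule.direction == "-" and x < m:
                    score += 1
                elif rule.direction == "~" and m != 0 and abs(x - m) <= rule.tolerance * abs(m):
                    score += 1
            sq, cnt = 0.0, 0
            for key, m in means.items():
                if key in values:
                    sd = summary.population_std.get(key, 1.0)
                    sq += ((values[key] - m) / sd) ** 2
                    cnt += 1
            distance = np.sqrt(sq / cnt) if cnt else np.inf
            cand = (-score, distance, k)
            if best is None or cand < best:
                best = cand
        assert best is not None
        rows.append({"cell_id": traj.cell_id, "cluster": best[2],
                     "score": -best[0], "distance": best[1]})
    return pd.DataFrame(rows)


def assignment_percentages(assignment: pd.DataFrame) -> pd.Series:
    """Per-cluster percentage of assignable cells (for comparing the
    perturbation-condition composition against calibration)."""
    assigned = assignment[assignment["cluster"] != UNASSIGNABLE]
    if assigned.empty:
        raise ValueError("no assignable cells")
    return assigned["cluster"].value_counts(normalize=True).sort_index() * 100.0
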