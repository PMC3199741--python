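"""Temporal dyadic association trajectories and their typing.

Each core dyad's association index tracked across the ordered seasons forms a
*trajectory*.  Dyads that never associate are excluded.  Dyads whose bond
stays at or above a floor (default 0.3) in every season are *stable* (type
A).  The remainder are clustered by the *shape* of their trajectory using
K-means under correlation distance, implemented as Euclidean K-means on
per-trajectory z-scored vectors (squared Euclidean distance between z-scored
vectors is an increasing function of correlation distance).  The number of
clusters is selected by maximizing the expected Bayesian Information
Criterion over repeated randomized-initialization (k-means++) fits, under a spherical-Gaussian
per-cluster model.  Cluster centroids are labeled *single-peak* (type B, a
temporary association peaking in one season) or *cyclic* (type C, peaks in
multiple seasons) by counting local maxima, with endpoints counting as peaks
when they exceed their single neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .association import AssociationMatrix

__all__ = [
    "TrajectorySet",
    "KSelection",
    "ClusteringResult",
    "build_trajectories",
    "split_stable",
    "correlation_distance",
    "select_k_by_bic",
    "cluster_trajectories",
    "label_trajectory_types",
]


@dataclass
class TrajectorySet:
    """Per-dyad SRI vectors across the ordered seasons."""

    dyads: list[tuple[str, str]]
    values: np.ndarray  # (n_dyads, n_seasons)
    season_labels: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape != (
            len(self.dyads),
            len(self.season_labels),
        ):
            raise ValueError("values must be (n_dyads, n_seasons)")
        if len(self.dyads) and not (self.values != 0).any(axis=1).all():
            raise ValueError("all-zero trajectories must be excluded")

    def __len__(self) -> int:
        return len(self.dyads)


def build_trajectories(
    matrices: Sequence[AssociationMatrix] | Mapping[str, AssociationMatrix],
    cohort: Sequence[str],
    season_labels: Sequence[str] | None = None,
) -> TrajectorySet:
    """One SRI vector per unordered cohort dyad with >= 1 non-zero entry.

    ``matrices`` must be in season order (or a mapping traversed in
    ``season_labels`` order).  A cohort member absent from a season's matrix
    contributes SRI 0 for that season.
    """
    if isinstance(matrices, Mapping):
        if season_labels is None:
            season_labels = list(matrices.keys())
        mats = [matrices[lab] for lab in season_labels]
    else:
        mats = list(matrices)
        if season_labels is None:
            season_labels = [f"season_{i}" for i in range(len(mats))]
    cohort = sorted(cohort)
    dyads: list[tuple[str, str]] = []
    rows: list[np.ndarray] = []
    for i in range(len(cohort)):
        for j in range(i + 1, len(cohort)):
            a, b = cohort[i], cohort[j]
            vec = np.array(
                [
                    m.value(a, b) if (a in m._index and b in m._index) else 0.0
                    for m in mats
                ]
            )
            if (vec != 0).any():
                dyads.append((a, b))
                rows.append(vec)
    values = np.array(rows) if rows else np.zeros((0, len(mats)))
    return TrajectorySet(dyads, values, list(season_labels))


def split_stable(
    ts: TrajectorySet, floor: float = 0.3
) -> tuple[list[tuple[str, str]], TrajectorySet]:
    """Split off stable (type A) dyads: min SRI over seasons >= floor."""
    if not 0 <= floor <= 1:
        raise ValueError("floor must lie in [0, 1]")
    if len(ts) == 0:
        return [], ts
    stable_mask = ts.values.min(axis=1) >= floor
    type_a = [d for d, m in zip(ts.dyads, stable_mask) if m]
    rest = TrajectorySet(
        [d for d, m in zip(ts.dyads, stable_mask) if not m],
        ts.values[~stable_mask],
        ts.season_labels,
    )
    return type_a, rest


def correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """d = 1 - Pearson(u, v), in [0, 2].  Undefined for flat vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc, vc = u - u.mean(), v - v.mean()
    su, sv = np.sqrt((uc**2).sum()), np.sqrt((vc**2).sum())
    if su == 0 or sv == 0:
        raise ValueError("correlation distance undefined for a zero-variance vector")
    return float(1.0 - (uc * vc).sum() / (su * sv))


def standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score each row; returns (z, flat_mask) where flat rows are excluded
    from z (they have no shape and cannot enter correlation-distance
    clustering — callers report them as a separate flat bin)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    z = np.zeros_like(values, dtype=float)
    ok = ~flat
    z[ok] = (values[ok] - mu[ok]) / sd[ok]
    return z[ok], flat


@dataclass
class KSelection:
    """BIC-based selection of the number of trajectory clusters."""

    k_range: list[int]
    bic_per_run: dict[int, np.ndarray]  # K -> BIC of each random-start run
    k_opt: int

    @property
    def mean_bic(self) -> dict[int, float]:
        return {k: float(np.mean(v)) for k, v in self.bic_per_run.items()}


def _bic_of_fit(z: np.ndarray, labels: np.ndarray, centers: np.ndarray, k: int) -> float:
    """Spherical-Gaussian BIC of a K-means partition.

    Pooled per-dimension variance MLE sigma^2 = SSE / (d (n - K)); log
    likelihood of the K-component spherical mixture with hard assignments;
    penalty (K (d+1) + 1)/2 * ln n.  Pooled variance keeps the criterion
    finite when a run leaves a cluster nearly empty.
    """
    n, d = z.shape
    if n <= k:
        return -np.inf
    sse = float(((z - centers[labels]) ** 2).sum())
    sigma2 = sse / (d * (n - k))
    if sigma2 <= 0:
        return -np.inf
    counts = np.bincount(labels, minlength=k)
    nz = counts[counts > 0]
    ll = (
        float((nz * np.log(nz / n)).sum())
        - n * d / 2 * np.log(2 * np.pi * sigma2)
        - d * (n - k) / 2
    )
    n_params = k * (d + 1) + 1
    return ll - n_params / 2 * np.log(n)


def select_k_by_bic(
    ts: TrajectorySet,
    k_range: Sequence[int] = range(2, 16),
    runs_per_k: int = 100,
    seed: int = 0,
) -> KSelection:
    """Fit K-means ``runs_per_k`` times per K and pick the K maximizing the
    mean BIC over runs.  Raises on degenerate input (no shape variance)."""
    from sklearn.cluster import KMeans

    z, flat = standardize_rows(ts.values)
    if len(z) == 0:
        raise ValueError("no trajectories with shape variance: nothing to cluster")
    if np.allclose(z, z[0]):
        raise ValueError("all trajectories share one shape: K selection is degenerate")
    k_range = [k for k in k_range if k < len(z)]
    if not k_range:
        raise ValueError("fewer trajectories than the smallest K")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    bic_per_run: dict[int, np.ndarray] = {}
    for k in k_range:
        bics = np.empty(runs_per_k)
        for r in range(runs_per_k):
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(z)
            bics[r] = _bic_of_fit(z, km.labels_, km.cluster_centers_, k)
        bic_per_run[k] = bics
    mean_bic = {k: float(np.mean(v)) for k, v in bic_per_run.items()}
    k_opt = max(mean_bic, key=mean_bic.get)
    return KSelection(list(k_range), bic_per_run, k_opt)


@dataclass
class ClusteringResult:
    """Best-of-runs K-means partition of the (non-flat) trajectories."""

    assignment: dict[tuple[str, str], int]
    centroids_std: np.ndarray  # per-cluster mean of z-scored trajectories
    centroids_raw: np.ndarray  # per-cluster mean of raw trajectories (plotting)
    inertia: float
    flat_unstable: list[tuple[str, str]]  # flat, non-zero, below the type-A floor
    season_labels: list[str]


def cluster_trajectories(
    ts: TrajectorySet, k: int, runs: int = 1000, seed: int = 0
) -> ClusteringResult:
    """Best-of-``runs`` K-means partition (minimum within-cluster sum of
    squared distances on z-scored trajectories)."""
    from sklearn.cluster import KMeans

    if k < 2:
        raise ValueError("k must be >= 2")
    z, flat = standardize_rows(ts.values)
    keep_dyads = [d for d, f in zip(ts.dyads, flat) if not f]
    flat_dyads = [d for d, f in zip(ts.dyads, flat) if f]
    if len(z) < k:
        raise ValueError("fewer clusterable trajectories than clusters")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    best = None
    for _ in range(runs):
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(z)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    raw = ts.values[~flat]
    centroids_raw = np.vstack(
        [
            raw[best.labels_ == c].mean(axis=0) if (best.labels_ == c).any() else np.zeros(raw.shape[1])
            for c in range(k)
        ]
    )
    return ClusteringResult(
        assignment={d: int(c) for d, c in zip(keep_dyads, best.labels_)},
        centroids_std=best.cluster_centers_,
        centroids_raw=centroids_raw,
        inertia=float(best.inertia_),
        flat_unstable=flat_dyads,
        season_labels=ts.season_labels,
    )


def _peak_indices(vec: np.ndarray, min_prominence: float) -> list[int]:
    """Local maxima; an endpoint is a peak when it exceeds its single
    neighbour.  A maximum only counts when it rises above the vector's floor
    by at least ``min_prominence`` of the full range, so small sampling
    wiggles on an otherwise flat stretch are not read as peaks."""
    n = len(vec)
    floor = vec.min() + min_prominence * np.ptp(vec)
    peaks = []
    for i in range(n):
        left = vec[i - 1] if i > 0 else -np.inf
        right = vec[i + 1] if i < n - 1 else -np.inf
        if vec[i] > left and vec[i] > right and vec[i] > floor:
            peaks.append(i)
    return peaks


def label_trajectory_types(
    centroids: np.ndarray,
    season_labels: Sequence[str],
    min_prominence: float = 0.25,
) -> dict[int, tuple[str, list[str]]]:
    """Label each centroid B (single peak) or C (>= 2 peaks, cyclic).

    Returns cluster -> (type, peak season labels).  A perfectly flat centroid
    has no peaks and is labeled "flat".  ``min_prominence`` (fraction of the
    centroid's range a maximum must stand above its minimum) is the
    configurable peak rule.
    """
    if len(centroids) == 0:
        raise ValueError("no centroids to label")
    out: dict[int, tuple[str, list[str]]] = {}
    for c, vec in enumerate(np.asarray(centroids, dtype=float)):
        peaks = _peak_indices(vec, min_prominence)
        labels = [season_labels[i] for i in peaks]
        if len(peaks) == 0:
            out[c] = ("flat", [])
        elif len(peaks) == 1:
            out[c] = ("B", labels)
        else:
            out[c] = ("C", labels)
    return out
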