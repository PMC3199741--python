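"""Season-level weighted networks and ego-network statistics.

A season's social network has individuals as nodes and an edge (weighted by
the SRI) between every pair that associated at least once; isolates are kept
as nodes.  An *ego-network* is the subgraph on an individual (ego) and her
direct associates (alters).  The five classical measures:

- Size: number of alters.
- Pairs: ordered pairs of alters, size*(size-1).
- Ties: ordered ties among alters (each undirected alter-alter edge counts
  twice; edges to ego are excluded).
- Density: Ties/Pairs — the fraction of possible alter-alter links realized.
- 2-Step Reach: number of distinct individuals (excluding ego) within two
  steps of ego.

Because measures across individuals are not independent, seasons are compared
through a bootstrap over sampling days: each replicate resamples the season's
days with replacement, recomputes the SRI, network, and the cohort mean of
each measure.  Percentile intervals of between-season differences give the
comparison; the bootstrap mean is reported next to the observed value because
day resampling systematically drops rare co-occurrences and shifts the
statistics (a known bias of this procedure).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .association import AssociationMatrix, DailyAssociationSet, compute_sri

__all__ = [
    "EgoMeasures",
    "BootstrapComparison",
    "build_season_network",
    "ego_measures",
    "bootstrap_ego_statistics",
    "EGO_STATISTICS",
]

EGO_STATISTICS = ("size", "ties", "pairs", "density", "two_step_reach")


def build_season_network(matrix: AssociationMatrix) -> nx.Graph:
    """Weighted graph with an edge for every dyad with SRI > 0; isolates kept."""
    g = nx.Graph()
    g.add_nodes_from(matrix.ids)
    n = len(matrix.ids)
    iu, ju = np.triu_indices(n, k=1)
    pos = matrix.sri[iu, ju] > 0
    for i, j in zip(iu[pos], ju[pos]):
        g.add_edge(matrix.ids[i], matrix.ids[j], weight=float(matrix.sri[i, j]))
    return g


@dataclass(frozen=True)
class EgoMeasures:
    size: int
    ties: int
    pairs: int
    density: float  # NaN when pairs == 0 (undefined)
    two_step_reach: int

    def as_dict(self) -> dict[str, float]:
        return {
            "size": self.size,
            "ties": self.ties,
            "pairs": self.pairs,
            "density": self.density,
            "two_step_reach": self.two_step_reach,
        }


def ego_measures(net: nx.Graph, ego: str) -> EgoMeasures:
    """The five ego-network measures for one individual."""
    if ego not in net:
        raise KeyError(f"ego {ego!r} not in network")
    alters = set(net.neighbors(ego))
    size = len(alters)
    pairs = size * (size - 1)
    undirected_ties = sum(1 for a in alters for b in net.neighbors(a) if b in alters) // 2
    ties = 2 * undirected_ties
    density = ties / pairs if pairs > 0 else float("nan")
    two_step = set(alters)
    for a in alters:
        two_step.update(net.neighbors(a))
    two_step.discard(ego)
    return EgoMeasures(size, ties, pairs, density, len(two_step))


def _cohort_means(
    daily: Sequence[DailyAssociationSet], cohort: Sequence[str]
) -> dict[str, float]:
    """Mean of each ego measure over the cohort, for one set of days.

    Individuals never seen in the resampled days remain isolates (all-zero
    measures, NaN density); densities are averaged over defined values.
    """
    ids = sorted(set().union(*(das.ids for das in daily)) | set(cohort))
    matrix = compute_sri(daily, ids)
    net = build_season_network(matrix)
    acc: dict[str, list[float]] = {k: [] for k in EGO_STATISTICS}
    for ego in cohort:
        m = ego_measures(net, ego).as_dict()
        for k in EGO_STATISTICS:
            acc[k].append(m[k])
    out = {}
    for k, vals in acc.items():
        arr = np.asarray(vals, dtype=float)
        out[k] = float(np.nanmean(arr)) if not np.isnan(arr).all() else float("nan")
    return out


@dataclass
class BootstrapComparison:
    """Bootstrap distributions of one ego-network statistic by season, plus
    pairwise season contrasts."""

    statistic: str
    observed: dict[str, float]  # season -> observed cohort mean
    bootstrap: dict[str, np.ndarray]  # season -> B replicate values
    seed: int

    @property
    def B(self) -> int:
        return len(next(iter(self.bootstrap.values())))

    def bootstrap_mean(self, season: str) -> float:
        return float(np.nanmean(self.bootstrap[season]))

    def compare(self, season_a: str, season_b: str, ci: float = 0.95) -> dict:
        """Percentile CI and two-sided bootstrap p for the difference
        (season_a - season_b) of the statistic."""
        diff = self.bootstrap[season_a] - self.bootstrap[season_b]
        alpha = 1 - ci
        lo, hi = np.nanpercentile(diff, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        b = len(diff)
        p_low = (1 + int((diff <= 0).sum())) / (1 + b)
        p_high = (1 + int((diff >= 0).sum())) / (1 + b)
        return {
            "difference": float(np.nanmean(diff)),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "p": min(1.0, 2 * min(p_low, p_high)),
            "covers_zero": bool(lo <= 0 <= hi),
        }


def bootstrap_ego_statistics(
    daily_by_season: dict[str, Sequence[DailyAssociationSet]],
    residents: Sequence[str],
    B: int = 1000,
    seed: int = 0,
) -> dict[str, BootstrapComparison]:
    """Day-resampling bootstrap of the cohort-mean ego measures per season.

    For each season and replicate, the season's sampling days are resampled
    with replacement, the SRI matrix and network rebuilt, and the cohort mean
    of each ego measure recorded.  Returns one comparison object per
    statistic.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    residents = sorted(residents)
    if not residents:
        raise ValueError("residents must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    observed: dict[str, dict[str, float]] = {}
    boots: dict[str, dict[str, np.ndarray]] = {k: {} for k in EGO_STATISTICS}
    for season, daily in daily_by_season.items():
        daily = list(daily)
        observed[season] = _cohort_means(daily, residents)
        per_stat = {k: np.empty(B) for k in EGO_STATISTICS}
        n_days = len(daily)
        for b in range(B):
            pick = rng.integers(n_days, size=n_days)
            rep = [daily[i] for i in pick]
            # resampled duplicate days keep distinct identities as sampling
            # intervals; compute_sri only counts day entries, so pass as-is
            means = _cohort_means(rep, residents)
            for k in EGO_STATISTICS:
                per_stat[k][b] = means[k]
        for k in EGO_STATISTICS:
            boots[k][season] = per_stat[k]
    return {
        k: BootstrapComparison(
            statistic=k,
            observed={s: observed[s][k] for s in daily_by_season},
            bootstrap=boots[k],
            seed=seed,
        )
        for k in EGO_STATISTICS
    }
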