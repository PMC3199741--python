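"""Companion fidelity: top-n associates, companion slots, turnover, trade-off.

Each core individual allocates n "companion slots" per season to her top-n
associates by association index.  An associate present in her top-n for m of
the S seasons is an *m-term associate* occupying m slots, so with k_i(m)
m-term associates the fraction of slots individual i allocates to them is

    f_i(m) = k_i(m) * m / (S * n),

which sums to one over m.  The population mean F(m) measures whether
individuals keep the same companions (mass at m = S) or reshuffle them (mass
at m = 1).  Under the null that each individual draws a uniformly random
top-n from the other N-1 every season, k(m) is binomial and

    E[F(m)] = (N-1) * C(S, m) * q^m * (1-q)^(S-m) * m / (S * n),  q = n/(N-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .association import AssociationMatrix

__all__ = [
    "SlotAllocation",
    "TurnoverProfile",
    "top_n_associates",
    "slot_allocation",
    "null_slot_allocation",
    "companion_turnover",
    "gregariousness_tradeoff",
]


def top_n_associates(
    matrix: AssociationMatrix,
    ego: str,
    n: int,
    sighting_counts: Mapping[str, int] | None = None,
    candidates: Sequence[str] | None = None,
) -> list[str]:
    """The n individuals with the highest SRI to ``ego``, SRI descending.

    Only partners with SRI > 0 qualify; if fewer than n exist the list is
    short.  Ties are broken deterministically: higher total sighting count
    first (when provided), then lexicographic id.  ``candidates`` restricts
    the eligible partners (e.g. to the core cohort).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ego not in matrix._index:
        raise KeyError(f"ego {ego!r} not in matrix")
    pool = [i for i in (candidates if candidates is not None else matrix.ids) if i != ego]
    row = matrix.sri[matrix.index_of(ego)]
    scored = [
        (
            -row[matrix.index_of(other)],
            -(sighting_counts.get(other, 0) if sighting_counts else 0),
            other,
        )
        for other in pool
        if row[matrix.index_of(other)] > 0
    ]
    scored.sort()
    return [other for _, _, other in scored[:n]]


@dataclass
class SlotAllocation:
    """Companion-slot bookkeeping for one cohort over S seasons."""

    n_individuals: int  # N
    n_slots: int  # n, slots per season
    n_seasons: int  # S
    k: dict[str, dict[int, int]]  # ego -> m -> count of m-term associates
    f: dict[str, dict[int, float]]  # ego -> m -> fraction of companion slots
    shortfall: dict[str, int]  # ego -> unfilled slots over the study

    def population_mean_f(self) -> dict[int, float]:
        """F(m): mean over individuals of f_i(m), for m = 1..S."""
        out = {}
        for m in range(1, self.n_seasons + 1):
            out[m] = float(np.mean([fi.get(m, 0.0) for fi in self.f.values()]))
        return out


def slot_allocation(per_season_topn: Mapping[str, Sequence[Sequence[str]]]) -> SlotAllocation:
    """Tally m-term associates and slot fractions from per-season top-n lists.

    ``per_season_topn`` maps each ego to its S ranked lists (one per season).
    f_i(m) = k_i(m) * m / (S * n) with n the nominal slots per season (the
    longest list observed); if an ego has fewer than n qualifying partners in
    a season the shortfall is reported and her fractions still use S * n, so
    sum_m f_i(m) = 1 only when every slot was filled.
    """
    egos = list(per_season_topn)
    if not egos:
        raise ValueError("empty top-n table")
    S = len(per_season_topn[egos[0]])
    if any(len(v) != S for v in per_season_topn.values()):
        raise ValueError("every ego needs the same number of seasons")
    n = max(len(lst) for v in per_season_topn.values() for lst in v)
    k: dict[str, dict[int, int]] = {}
    f: dict[str, dict[int, float]] = {}
    shortfall: dict[str, int] = {}
    for ego, lists in per_season_topn.items():
        tally: dict[str, int] = {}
        filled = 0
        for lst in lists:
            if len(set(lst)) != len(lst):
                raise ValueError(f"duplicate partner in a top-n list of {ego!r}")
            filled += len(lst)
            for other in lst:
                tally[other] = tally.get(other, 0) + 1
        km = {m: 0 for m in range(1, S + 1)}
        for m in tally.values():
            km[m] += 1
        k[ego] = km
        f[ego] = {m: km[m] * m / (S * n) for m in km}
        shortfall[ego] = S * n - filled
    return SlotAllocation(len(egos), n, S, k, f, shortfall)


def per_season_top_n(
    matrices: Sequence[AssociationMatrix],
    cohort: Sequence[str],
    n: int = 5,
    sighting_counts: Mapping[str, int] | None = None,
) -> dict[str, list[list[str]]]:
    """Convenience: top-n lists (within the cohort) for every cohort member
    in every season."""
    return {
        ego: [
            top_n_associates(m, ego, n, sighting_counts=sighting_counts, candidates=cohort)
            for m in matrices
        ]
        for ego in cohort
    }


def null_slot_allocation(
    N: int,
    n: int,
    S: int,
    mode: str = "analytic",
    reps: int = 10_000,
    seed: int = 0,
    with_se: bool = False,
) -> dict[int, float] | tuple[dict[int, float], dict[int, float]]:
    """Expected F(m) when every individual redraws a uniform top-n each season.

    Analytic mode evaluates the binomial expectation exactly; simulate mode
    Monte-Carlo-estimates the same quantity with ``reps`` replicate egos
    (partners are exchangeable and egos independent, so one ego per replicate
    estimates the population mean).  With ``with_se`` the simulate mode also
    returns the Monte-Carlo standard error of each F(m).
    """
    if not 1 <= n < N:
        raise ValueError("need 1 <= n < N")
    q = n / (N - 1)
    if mode == "analytic":
        return {
            m: (N - 1) * comb(S, m) * q**m * (1 - q) ** (S - m) * m / (S * n)
            for m in range(1, S + 1)
        }
    if mode != "simulate":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = np.zeros((reps, S + 1))
    for r in range(reps):
        counts = np.zeros(N - 1, dtype=np.int64)
        for _s in range(S):
            counts[rng.choice(N - 1, size=n, replace=False)] += 1
        for m in range(1, S + 1):
            draws[r, m] = int((counts == m).sum()) * m / (S * n)
    means = {m: float(draws[:, m].mean()) for m in range(1, S + 1)}
    if not with_se:
        return means
    ses = {
        m: float(draws[:, m].std(ddof=1) / np.sqrt(reps)) for m in range(1, S + 1)
    }
    return means, ses


@dataclass
class TurnoverProfile:
    """How many top-n companions each individual keeps across all seasons."""

    retained: dict[str, int]  # ego -> size of the intersection of top-n sets
    n_slots: int

    def histogram(self) -> dict[int, float]:
        """Fraction of individuals retaining exactly r companions, r = 0..n."""
        vals = list(self.retained.values())
        return {r: sum(v == r for v in vals) / len(vals) for r in range(self.n_slots + 1)}


def companion_turnover(per_season_topn: Mapping[str, Sequence[Sequence[str]]]) -> TurnoverProfile:
    """Count, per ego, the associates present in her top-n in *every* season."""
    egos = list(per_season_topn)
    if not egos:
        raise ValueError("empty top-n table")
    S = len(per_season_topn[egos[0]])
    if S < 2:
        raise ValueError("turnover needs at least two seasons")
    n = max(len(lst) for v in per_season_topn.values() for lst in v)
    retained = {}
    for ego, lists in per_season_topn.items():
        sets = [set(lst) for lst in lists]
        retained[ego] = len(set.intersection(*sets))
    return TurnoverProfile(retained, n)


def gregariousness_tradeoff(
    matrices: Sequence[AssociationMatrix], cohort: Sequence[str]
) -> dict:
    """Degree-versus-strength trade-off across the cohort.

    For each individual: x = number of non-zero-SRI partners averaged over
    seasons, y = mean non-zero SRI averaged over seasons (seasons with no
    partner contribute to x as zero and are skipped for y).  Returns the
    per-individual points with the least-squares slope, R^2 and p-value of
    y on x.
    """
    from scipy import stats

    points: dict[str, tuple[float, float]] = {}
    for ego in cohort:
        degs, strengths = [], []
        for m in matrices:
            if ego not in m._index:
                degs.append(0.0)
                continue
            row = m.sri[m.index_of(ego)].copy()
            row[m.index_of(ego)] = 0.0
            nz = row[row > 0]
            degs.append(float(len(nz)))
            if len(nz):
                strengths.append(float(nz.mean()))
        if strengths:
            points[ego] = (float(np.mean(degs)), float(np.mean(strengths)))
    if len(points) < 3:
        raise ValueError("need at least 3 individuals with associates")
    x = np.array([v[0] for v in points.values()])
    y = np.array([v[1] for v in points.values()])
    fit = stats.linregress(x, y)
    return {
        "points": points,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
    }
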