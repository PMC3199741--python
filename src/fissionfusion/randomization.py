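"""Permutation inference for association data.

Two nulls are implemented.  Within a season, the *fill* randomization keeps
the observed day x group-size skeleton and each individual's number of
sighting-days, and refills the groups at random; comparing the observed mean
association index against this ensemble tests whether group composition is
random given gregariousness and observation effort.  Across seasons, a Mantel
permutation test measures whether the dyadic association structure of two
seasons is correlated beyond chance, over the individuals seen in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import AssociationMatrix, DailyAssociationSet

__all__ = [
    "PermutationEnsemble",
    "MantelResult",
    "generate_fill_permutations",
    "test_nonrandom_association",
    "mantel_correlation",
]

_REPAIR_CAP = 100_000


@dataclass
class PermutationEnsemble:
    """Fill-permutation replicates over a fixed day x part-size skeleton.

    Replicates are stored compactly as slot->individual index arrays; use
    :meth:`replicate_daily_sets` to materialize one as association sets.
    Every replicate preserves each individual's number of sighting-days and
    the multiset of part sizes on every day, exactly.
    """

    ids: list[str]
    days: list  # calendar dates, one per sampling day
    part_sizes: list[list[int]]  # per day, observed part sizes
    assignments: list[np.ndarray]  # per replicate, token -> id index
    seed: int
    preserved: str = "per-individual sighting-day counts; per-day part-size multisets"
    # slot bookkeeping (derived, shared by all replicates)
    slot_day: np.ndarray = field(init=False, repr=False)
    part_slices: list[tuple[int, int, int]] = field(init=False, repr=False)  # (day, lo, hi)

    def __post_init__(self) -> None:
        slot_day = []
        slices = []
        pos = 0
        for d, sizes in enumerate(self.part_sizes):
            for s in sizes:
                slices.append((d, pos, pos + s))
                slot_day.extend([d] * s)
                pos += s
        self.slot_day = np.asarray(slot_day, dtype=np.int32)
        self.part_slices = slices

    @property
    def n_perm(self) -> int:
        return len(self.assignments)

    def replicate_daily_sets(self, r: int) -> list[DailyAssociationSet]:
        tokens = self.assignments[r]
        by_day: dict[int, list[frozenset[str]]] = {}
        for d, lo, hi in self.part_slices:
            by_day.setdefault(d, []).append(
                frozenset(self.ids[t] for t in tokens[lo:hi])
            )
        return [DailyAssociationSet(self.days[d], parts) for d, parts in sorted(by_day.items())]

    def check_margins(self, observed_day_counts: dict[str, int]) -> bool:
        """Assert the defining invariant on every replicate."""
        n = len(self.ids)
        expected = np.zeros(n, dtype=np.int64)
        for k, ind in enumerate(self.ids):
            expected[k] = observed_day_counts[ind]
        for tokens in self.assignments:
            if not np.array_equal(np.bincount(tokens, minlength=n), expected):
                return False
            # no within-day repeats
            for d in range(len(self.part_sizes)):
                day_tokens = tokens[self.slot_day == d]
                if len(np.unique(day_tokens)) != len(day_tokens):
                    return False
        return True


def _skeleton(daily: Sequence[DailyAssociationSet]):
    ids = sorted(set().union(*(das.ids for das in daily)))
    index = {i: k for k, i in enumerate(ids)}
    part_sizes = [[len(p) for p in das.parts] for das in daily]
    day_counts = np.zeros(len(ids), dtype=np.int64)
    observed_tokens = []
    for das in daily:
        for p in das.parts:
            for ind in p:
                day_counts[index[ind]] += 1
                observed_tokens.append(index[ind])
    return ids, part_sizes, day_counts, np.asarray(observed_tokens, dtype=np.int64)


def _fill_one(
    day_counts: np.ndarray,
    slot_day: np.ndarray,
    n_days: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One fill replicate: shuffle the individual-day token multiset into the
    slots, then repair within-day duplicates by random pairwise swaps."""
    n_ids = len(day_counts)
    tokens = np.repeat(np.arange(n_ids), day_counts)
    rng.shuffle(tokens)
    # per-day occupancy counts and slot ranges
    occ = np.zeros((n_days, n_ids), dtype=np.int16)
    np.add.at(occ, (slot_day, tokens), 1)
    day_slots: list[np.ndarray] = [np.flatnonzero(slot_day == d) for d in range(n_days)]
    dup_slots = [s for s in range(len(tokens)) if occ[slot_day[s], tokens[s]] > 1]
    attempts = 0
    stalled = 0
    while dup_slots:
        attempts += 1
        if attempts > _REPAIR_CAP:
            raise RuntimeError(
                "fill permutation: margins could not be repaired within the attempt cap"
            )
        s = dup_slots[-1]
        x, d = tokens[s], slot_day[s]
        if occ[d, x] <= 1:  # already repaired by an earlier swap
            dup_slots.pop()
            continue
        # move x to a day where it is absent, pulling back a token that is
        # not yet on day d — this keeps both margins intact
        free_days = np.flatnonzero(occ[:, x] == 0)
        if free_days.size == 0:
            raise RuntimeError("infeasible margins: individual present on every day")
        e = int(free_days[rng.integers(free_days.size)])
        j = int(day_slots[e][rng.integers(len(day_slots[e]))])
        y = tokens[j]
        if occ[d, y] != 0:
            # a duplicate-resolving swap may not exist (the ids missing from
            # day d can all be absent from every x-free day); after repeated
            # failures accept a margin-preserving *neutral* swap, which hands
            # the duplicate to y and lets the repair walk out of the deadlock
            stalled += 1
            if stalled < 200:
                continue
            tokens[s], tokens[j] = y, x
            occ[d, x] -= 1
            occ[e, x] += 1
            occ[e, y] -= 1
            occ[d, y] += 1
            dup_slots.pop()
            if occ[d, y] > 1:
                dup_slots.append(s)
            stalled = 0
            continue
        tokens[s], tokens[j] = y, x
        occ[d, x] -= 1
        occ[e, x] += 1
        occ[e, y] -= 1
        occ[d, y] += 1
        if occ[d, x] <= 1:
            dup_slots.pop()
        stalled = 0
    return tokens


def generate_fill_permutations(
    daily: Sequence[DailyAssociationSet], n_perm: int, seed: int
) -> PermutationEnsemble:
    """Generate ``n_perm`` fill replicates of the observed daily sets."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids, part_sizes, day_counts, _ = _skeleton(daily)
    n_days = len(daily)
    # feasibility: an individual cannot be sighted on more days than exist
    if day_counts.max(initial=0) > n_days:
        raise ValueError("infeasible margins: an individual exceeds the day count")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ens = PermutationEnsemble(ids, [das.day for das in daily], part_sizes, [], seed)
    for _ in range(n_perm):
        ens.assignments.append(_fill_one(day_counts, ens.slot_day, n_days, rng))
    return ens


def _mean_sri_from_tokens(
    tokens: np.ndarray,
    ens: PermutationEnsemble,
    day_counts: np.ndarray,
) -> float:
    """Mean off-diagonal SRI implied by one replicate's slot assignment."""
    n = len(ens.ids)
    n_days = len(ens.part_sizes)
    x_ab = np.zeros((n, n), dtype=np.int64)
    for _, lo, hi in ens.part_slices:
        if hi - lo >= 2:
            members = tokens[lo:hi]
            x_ab[np.ix_(members, members)] += 1
    np.fill_diagonal(x_ab, 0)
    present = np.zeros((n_days, n), dtype=np.int64)
    present[ens.slot_day, tokens] = 1
    both = present.T @ present
    either = day_counts[:, None] + day_counts[None, :] - both  # = X_t - X_n
    iu = np.triu_indices(n, k=1)
    denom = either[iu]
    vals = np.where(denom > 0, x_ab[iu] / np.maximum(denom, 1), 0.0)
    mask = denom > 0
    return float(vals[mask].mean()) if mask.any() else 0.0


def test_nonrandom_association(
    observed: AssociationMatrix,
    ensemble: PermutationEnsemble,
    alternative: str = "two_sided",
) -> dict:
    """Permutation test of random within-season association.

    The test statistic is the mean SRI over all off-diagonal dyads.  The
    empirical p-value uses the add-one convention,
    p = (1 + #{replicates at least as extreme}) / (1 + n_perm); for the
    two-sided alternative, extremeness is distance from the null mean.
    Secondary descriptives (SD of SRI, proportion of non-zero dyads) are
    reported for the observed matrix.
    """
    if alternative not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if set(observed.ids) != set(ensemble.ids):
        raise ValueError("observed matrix and ensemble cover different id universes")

    n = len(observed.ids)
    iu = np.triu_indices(n, k=1)
    obs_vals = observed.sri[iu]
    obs_stat = float(obs_vals.mean())

    day_counts = np.zeros(len(ensemble.ids), dtype=np.int64)
    for tokens in ensemble.assignments[:1]:
        day_counts = np.bincount(tokens, minlength=len(ensemble.ids))
    null_stats = np.array(
        [
            _mean_sri_from_tokens(tokens, ensemble, day_counts)
            for tokens in ensemble.assignments
        ]
    )
    if alternative == "greater":
        extreme = null_stats >= obs_stat - 1e-15
    elif alternative == "less":
        extreme = null_stats <= obs_stat + 1e-15
    else:
        center = null_stats.mean()
        extreme = np.abs(null_stats - center) >= abs(obs_stat - center) - 1e-15
    p = (1 + int(extreme.sum())) / (1 + len(null_stats))
    return {
        "statistic": obs_stat,
        "p": p,
        "alternative": alternative,
        "n_perm": len(null_stats),
        "null_mean": float(null_stats.mean()),
        "null_sd": float(null_stats.std(ddof=1)) if len(null_stats) > 1 else 0.0,
        "sd_sri": float(obs_vals.std(ddof=1)) if len(obs_vals) > 1 else 0.0,
        "prop_nonzero": float((obs_vals > 0).mean()),
        "null_stats": null_stats,
    }


@dataclass(frozen=True)
class MantelResult:
    """Mantel matrix-correlation test result over matched individuals."""

    r: float
    p: float
    n_matched: int
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.r <= 1 + 1e-9:
            raise ValueError("r out of range")
        if not 0 < self.p <= 1:
            raise ValueError("p out of range")


def mantel_correlation(
    a: AssociationMatrix, b: AssociationMatrix, n_perm: int = 10_000, seed: int = 0
) -> MantelResult:
    """Mantel test between two seasons' SRI matrices.

    Both matrices are restricted to the individuals present in both; r is the
    Pearson correlation over corresponding off-diagonal entries, and the null
    is built by simultaneously permuting the rows and columns of the second
    matrix.  Two-tailed empirical p with the add-one convention.
    """
    shared = [i for i in a.ids if i in set(b.ids)]
    if len(shared) < 3:
        raise ValueError("Mantel test needs at least 3 shared individuals")
    A = a.restrict(shared).sri
    B = b.restrict(shared).sri
    n = len(shared)
    iu = np.triu_indices(n, k=1)

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        xc, yc = x - x.mean(), y - y.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        if denom == 0:
            return 0.0
        return float((xc * yc).sum() / denom)

    r_obs = corr(A[iu], B[iu])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        if abs(corr(A[iu], Bp[iu])) >= abs(r_obs) - 1e-15:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p=p, n_matched=n, n_perm=n_perm, seed=seed)
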