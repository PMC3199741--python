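"""Daily association sets and Simple Ratio Index (SRI) matrices.

Association is defined by the gambit of the group: all individuals recorded
in the same (merged) group within one day-long sampling interval are
associated.  Groups sharing at least one identified member within a day are
merged transitively, so non-independent re-sightings of the same party do not
inflate association counts.  The dyadic association index is the Simple Ratio
Index

    SRI(A, B) = X_AB / (X_t - X_n)

where X_AB is the number of sampling days on which A and B were together,
X_t the total number of sampling days, and X_n the number of days on which
neither A nor B was seen.  It estimates the proportion of time the two
individuals spend together, given that at least one of them is observed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import SightingTable

__all__ = [
    "DailyAssociationSet",
    "AssociationMatrix",
    "UncertaintyMatrix",
    "aggregate_daily",
    "compute_sri",
    "estimate_sri_uncertainty",
]


@dataclass
class DailyAssociationSet:
    """The merged association sets ("parts") observed on one sampling day."""

    day: _dt.date
    parts: list[frozenset[str]]

    def __post_init__(self) -> None:
        all_ids: set[str] = set()
        for p in self.parts:
            if all_ids & p:
                raise ValueError(f"parts on {self.day} are not disjoint")
            all_ids |= p

    @property
    def ids(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.parts:
            out |= p
        return frozenset(out)


@dataclass
class AssociationMatrix:
    """Symmetric SRI matrix with the underlying per-dyad counts.

    ``sri``, ``x_ab`` and ``x_n`` are (n, n) arrays indexed by ``ids``;
    ``x_t`` is the scalar number of sampling days.  The diagonal is zeroed
    and carries no meaning.
    """

    ids: list[str]
    sri: np.ndarray
    x_ab: np.ndarray
    x_t: int
    x_n: np.ndarray
    se: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("sri", "x_ab", "x_n"):
            arr = getattr(self, name)
            if arr.shape != (n, n):
                raise ValueError(f"{name} must be ({n}, {n})")
        if not np.allclose(self.sri, self.sri.T):
            raise ValueError("sri must be symmetric")
        if self.sri.min() < 0 or self.sri.max() > 1 + 1e-12:
            raise ValueError("sri values must lie in [0, 1]")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def index_of(self, individual: str) -> int:
        return self._index[individual]

    def value(self, a: str, b: str) -> float:
        return float(self.sri[self._index[a], self._index[b]])

    def restrict(self, ids: Iterable[str]) -> "AssociationMatrix":
        """Submatrix over ``ids`` (kept in this matrix's order)."""
        keep = [i for i in self.ids if i in set(ids)]
        idx = np.array([self._index[i] for i in keep], dtype=int)
        se = self.se[np.ix_(idx, idx)] if self.se is not None else None
        return AssociationMatrix(
            keep,
            self.sri[np.ix_(idx, idx)],
            self.x_ab[np.ix_(idx, idx)],
            self.x_t,
            self.x_n[np.ix_(idx, idx)],
            se=se,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form dyad table: id_a, id_b, sri, x_ab, x_t, x_n[, se]."""
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                row = {
                    "id_a": self.ids[i],
                    "id_b": self.ids[j],
                    "sri": self.sri[i, j],
                    "x_ab": int(self.x_ab[i, j]),
                    "x_t": self.x_t,
                    "x_n": int(self.x_n[i, j]),
                }
                if self.se is not None:
                    row["se"] = self.se[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_square_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sri, index=self.ids, columns=self.ids)


@dataclass
class UncertaintyMatrix:
    """Jackknife standard errors of the SRI values, plus relative errors."""

    ids: list[str]
    se: np.ndarray
    relative: np.ndarray  # se / sri where sri > 0, NaN elsewhere

    def __post_init__(self) -> None:
        if (self.se < -1e-12).any():
            raise ValueError("se must be nonnegative")


def aggregate_daily(
    table: SightingTable, exclude_lonely_singletons: bool = True
) -> list[DailyAssociationSet]:
    """Merge each day's groups into association sets.

    Groups sharing an identified individual are merged transitively
    (connected components of the day's group-overlap graph).  When
    ``exclude_lonely_singletons`` is on — which presumes the table covers a
    single season — individuals whose entire seasonal record is one sighting,
    alone, are dropped, since a single solitary record carries no association
    information.
    """
    by_day: dict[_dt.date, dict[str, set[str]]] = {}
    for r in table.records:
        by_day.setdefault(r.day, {}).setdefault(r.group_label, set()).add(r.individual_id)

    daily: list[DailyAssociationSet] = []
    for day in sorted(by_day):
        groups = list(by_day[day].values())
        # union-find over group indices via shared members
        owner: dict[str, int] = {}
        parent = list(range(len(groups)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for gi, members in enumerate(groups):
            for ind in members:
                if ind in owner:
                    ra, rb = find(owner[ind]), find(gi)
                    if ra != rb:
                        parent[rb] = ra
                else:
                    owner[ind] = gi
        merged: dict[int, set[str]] = {}
        for gi, members in enumerate(groups):
            merged.setdefault(find(gi), set()).update(members)
        daily.append(DailyAssociationSet(day, [frozenset(p) for p in merged.values()]))

    if exclude_lonely_singletons:
        appearances: dict[str, int] = {}
        alone: dict[str, int] = {}
        for das in daily:
            for part in das.parts:
                for ind in part:
                    appearances[ind] = appearances.get(ind, 0) + 1
                    if len(part) == 1:
                        alone[ind] = alone.get(ind, 0) + 1
        drop = {i for i, c in appearances.items() if c == 1 and alone.get(i, 0) == 1}
        if drop:
            cleaned: list[DailyAssociationSet] = []
            for das in daily:
                parts = [frozenset(p - drop) for p in das.parts]
                parts = [p for p in parts if p]
                if parts:
                    cleaned.append(DailyAssociationSet(das.day, parts))
            daily = cleaned
    return daily


def _membership_arrays(
    daily: Sequence[DailyAssociationSet], ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day part labels (-1 = unseen) and presence mask, (n_days, n_ids)."""
    index = {i: k for k, i in enumerate(ids)}
    n_days, n_ids = len(daily), len(ids)
    labels = np.full((n_days, n_ids), -1, dtype=np.int32)
    for d, das in enumerate(daily):
        for p, part in enumerate(das.parts):
            for ind in part:
                if ind in index:
                    labels[d, index[ind]] = p
    return labels, labels >= 0


def sri_counts(
    daily: Sequence[DailyAssociationSet], ids: Sequence[str]
) -> tuple[np.ndarray, int, np.ndarray]:
    """Vectorized (X_AB, X_t, X_n) over an explicit id ordering."""
    labels, present = _membership_arrays(daily, ids)
    n_days, n_ids = labels.shape
    x_ab = np.zeros((n_ids, n_ids), dtype=np.int64)
    for d in range(n_days):
        lab = labels[d]
        for p in np.unique(lab[lab >= 0]):
            members = np.flatnonzero(lab == p)
            if members.size >= 2:
                x_ab[np.ix_(members, members)] += 1
    np.fill_diagonal(x_ab, 0)
    seen = present.astype(np.int64)
    both_seen = seen.T @ seen  # days where both seen (any part)
    days_each = seen.sum(axis=0)
    # X_n = days where neither seen
    x_n = n_days - (days_each[:, None] + days_each[None, :] - both_seen)
    np.fill_diagonal(x_n, n_days - days_each)
    return x_ab, n_days, x_n


def compute_sri(daily: Sequence[DailyAssociationSet], ids: Sequence[str] | None = None) -> AssociationMatrix:
    """Compute the per-dyad Simple Ratio Index over a list of sampling days.

    X_t is the number of sampling days in ``daily`` (observation effort);
    the denominator X_t - X_n is then the number of days on which at least
    one member of the dyad was seen, which is positive for every dyad drawn
    from the parts.
    """
    if len(daily) == 0:
        raise ValueError("compute_sri requires at least one sampling day")
    if ids is None:
        ids = sorted(set().union(*(das.ids for das in daily)))
    else:
        ids = list(ids)
    x_ab, x_t, x_n = sri_counts(daily, ids)
    denom = x_t - x_n
    with np.errstate(divide="ignore", invalid="ignore"):
        sri = np.where(denom > 0, x_ab / np.maximum(denom, 1), 0.0)
    np.fill_diagonal(sri, 0.0)
    return AssociationMatrix(ids, sri, x_ab, x_t, x_n)


def estimate_sri_uncertainty(
    daily: Sequence[DailyAssociationSet], ids: Sequence[str] | None = None
) -> UncertaintyMatrix:
    """Delete-one-day jackknife standard error of each dyad's SRI.

    The sampling day is the exchangeable unit, so the jackknife drops one day
    at a time, recomputes the SRI, and reports

        se = sqrt((n-1)/n * sum_i (sri_(-i) - mean(sri_(-.)))^2)

    over the replicates for which the dyad's SRI remains defined.  Relative
    uncertainty se/SRI is reported for dyads with SRI > 0.
    """
    n_days = len(daily)
    if n_days < 2:
        raise ValueError("jackknife needs at least two sampling days")
    if ids is None:
        ids = sorted(set().union(*(das.ids for das in daily)))
    else:
        ids = list(ids)
    x_ab, x_t, x_n = sri_counts(daily, ids)
    full = compute_sri(daily, ids)

    n = len(ids)
    # per-day contributions, so leave-one-out counts are cheap
    labels, present = _membership_arrays(daily, ids)
    reps = np.empty((n_days, n, n))
    counts = np.zeros((n, n), dtype=np.int64)
    for d in range(n_days):
        lab = labels[d]
        ab_d = np.zeros((n, n), dtype=np.int64)
        for p in np.unique(lab[lab >= 0]):
            members = np.flatnonzero(lab == p)
            if members.size >= 2:
                ab_d[np.ix_(members, members)] = 1
        np.fill_diagonal(ab_d, 0)
        seen_d = present[d].astype(np.int64)
        either_d = (seen_d[:, None] | seen_d[None, :]).astype(np.int64)
        denom_d = (x_t - x_n) - either_d  # days with either seen, minus day d
        ab_loo = x_ab - ab_d
        with np.errstate(divide="ignore", invalid="ignore"):
            rep = np.where(denom_d > 0, ab_loo / np.maximum(denom_d, 1), np.nan)
        reps[d] = rep
        counts += (denom_d > 0).astype(np.int64)

    with np.errstate(invalid="ignore"):
        mean_rep = np.nanmean(reps, axis=0)
        var = np.nansum((reps - mean_rep) ** 2, axis=0)
    m = np.maximum(counts, 1)
    se = np.sqrt((m - 1) / m * var)
    se[counts < 2] = np.nan
    np.fill_diagonal(se, 0.0)
    se = np.nan_to_num(se, nan=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(full.sri > 0, se / np.where(full.sri > 0, full.sri, 1), np.nan)
    return UncertaintyMatrix(ids, se, rel)
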