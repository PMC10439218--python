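"""Presence splitting and background (pseudo-absence) sampling.

Presence-only records state where an access point was found but never where
one is absent, so classifiers are trained against sampled *background*
cells drawn from the cells where no presence of any access type is
recorded. Two schemes are provided: uniform sampling, and sampling weighted
by the inverse of a population-proportional prior expectation of access
points per cell (so sparsely populated cells, least likely to hold an
undetected point, are over-represented among the pseudo-absences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .grid import CellTable

UNIFORM = "uniform"
WEIGHTED = "weighted"


@dataclass
class PresenceSet:
    """Presence-only records for one access type.

    ``cells`` may contain duplicates when several points share a cell;
    ``n`` is the number of records, not the number of distinct cells.
    """

    access_type: str
    cells: np.ndarray

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int)

    @property
    def n(self) -> int:
        return int(self.cells.size)

    def unique_cells(self) -> np.ndarray:
        return np.unique(self.cells)


@dataclass
class BackgroundSet:
    access_type: str
    cells: np.ndarray
    scheme: str = UNIFORM

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int)

    @property
    def s(self) -> int:
        return int(self.cells.size)


@dataclass
class PriorExpectation:
    """Per-cell expected access-point counts used as sampling prior.

    ``np_per_cell`` is indexed by cell id; within each stratum it sums to
    that stratum's expected total.
    """

    access_type: str
    np_per_cell: pd.Series
    p_total_by_stratum: dict[str, float] = field(default_factory=dict)


def all_presence_cells(all_presences: Mapping[str, PresenceSet] | Iterable[PresenceSet]) -> np.ndarray:
    """Distinct cells carrying a recorded presence of any access type."""
    sets = all_presences.values() if isinstance(all_presences, Mapping) else all_presences
    arrays = [p.cells for p in sets if p.n > 0]
    if not arrays:
        return np.empty(0, dtype=int)
    return np.unique(np.concatenate(arrays))


def split_presences(
    p: PresenceSet, train_fraction: float, seed: int
) -> tuple[PresenceSet, PresenceSet]:
    """Record-level train/test split, both partitions guaranteed non-empty."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if p.n < 2:
        raise ValueError("cannot split fewer than two presence records")
    k = int(round(train_fraction * p.n))
    k = min(max(k, 1), p.n - 1)
    perm = np.random.default_rng(seed).permutation(p.n)
    return (
        PresenceSet(p.access_type, p.cells[perm[:k]]),
        PresenceSet(p.access_type, p.cells[perm[k:]]),
    )


def _eligible_pool(table: CellTable, all_presences) -> np.ndarray:
    pool = np.setdiff1d(table.cell_ids, all_presence_cells(all_presences))
    if pool.size == 0:
        raise ValueError("no cells without recorded presences to sample from")
    return pool


def _draw(pool, s, seed, probabilities=None, replace=None):
    if replace is None:
        replace = s > pool.size
        if replace:
            warnings.warn(
                f"background pool of {pool.size} cells smaller than requested "
                f"sample of {s}; sampling with replacement", stacklevel=3
            )
    rng = np.random.default_rng(seed)
    return rng.choice(pool, size=s, replace=replace, p=probabilities)


def sample_uniform_background(
    table: CellTable,
    all_presences,
    n_presence: int,
    ratio: float,
    seed: int,
    access_type: str = "",
    replace: bool | None = None,
) -> BackgroundSet:
    """Draw ``round(ratio * n_presence)`` cells uniformly from the no-presence pool."""
    pool = _eligible_pool(table, all_presences)
    s = max(int(round(ratio * n_presence)), 1)
    return BackgroundSet(access_type, _draw(pool, s, seed, replace=replace), UNIFORM)


def compute_prior_expectation(
    table: CellTable,
    totals,
    access_type: str,
    stratified: bool = True,
) -> PriorExpectation:
    """Distribute the expected total of access points over cells by population.

    Within each stratum the expected count of cell *i* is
    ``P_total * Pop_i / sum_j Pop_j``, with the urban cells sharing the
    urban total and the rural cells the rural total. ``stratified=False``
    pools both strata and normalizes by the total population.
    """
    df = table.df
    npc = pd.Series(0.0, index=df["cell_id"].to_numpy())
    totals_by_stratum = dict(totals.y) if hasattr(totals, "y") else dict(totals)
    if not stratified:
        p_total = float(sum(totals_by_stratum.values()))
        pop = df["population"].to_numpy()
        if pop.sum() <= 0 and p_total > 0:
            raise ValueError("positive expected total but zero total population")
        npc[:] = p_total * pop / pop.sum() if pop.sum() > 0 else 0.0
        return PriorExpectation(access_type, npc, {"pooled": p_total})

    for stratum, p_total in totals_by_stratum.items():
        sel = df["stratum"] == stratum
        pop = df.loc[sel, "population"].to_numpy()
        if p_total > 0 and (pop.size == 0 or pop.sum() <= 0):
            raise ValueError(
                f"stratum {stratum!r} has positive expected total but no population"
            )
        if pop.size and pop.sum() > 0:
            npc[df.loc[sel, "cell_id"].to_numpy()] = p_total * pop / pop.sum()
    return PriorExpectation(access_type, npc, totals_by_stratum)


def selection_probabilities(np_per_cell: pd.Series) -> pd.Series:
    """Inverse-expectation weights, normalized to selection probabilities.

    Cells with zero expected count get the *largest* weight found among the
    cells with positive expectation (not infinity), so unpopulated cells
    are the most likely pseudo-absences rather than a degenerate mass.
    """
    npc = np_per_cell.to_numpy(dtype=float)
    positive = npc > 0
    if not positive.any():
        raise ValueError("all expected counts are zero: no populated cells")
    omega = np.empty_like(npc)
    omega[positive] = 1.0 / npc[positive]
    omega[~positive] = omega[positive].max()
    return pd.Series(omega / omega.sum(), index=np_per_cell.index)


def sample_weighted_background(
    prior: PriorExpectation,
    table: CellTable,
    all_presences,
    n_presence: int,
    ratio: float,
    seed: int,
    replace: bool | None = None,
) -> BackgroundSet:
    """Draw background cells with probability inversely proportional to the prior."""
    pool = _eligible_pool(table, all_presences)
    probs = selection_probabilities(prior.np_per_cell.loc[pool])
    s = max(int(round(ratio * n_presence)), 1)
    cells = _draw(pool, s, seed, probabilities=probs.to_numpy(), replace=replace)
    return BackgroundSet(prior.access_type, cells, WEIGHTED)


def save_points(sets: Iterable[PresenceSet | BackgroundSet], path) -> None:
    """Points CSV: access_type,cell_id plus a scheme column for background sets."""
    rows = []
    for st in sets:
        scheme = getattr(st, "scheme", "presence")
        for c in st.cells:
            rows.append((st.access_type, int(c), scheme))
    pd.DataFrame(rows, columns=["access_type", "cell_id", "scheme"]).to_csv(
        path, index=False
    )
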