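"""From relative probabilities to absolute per-cell access-point counts.

A presence-only classifier yields only a relative probability surface p*.
To turn it into expected *numbers* of access points per cell, the package
estimates (a) how many persons one access point of each type serves, from
cell population over co-located point counts, (b) the expected total number
of points per type and stratum, from household-survey usage shares, and
(c) distributes that total over cells proportionally to p*, separately for
urban and rural cells, so stratum sums are conserved exactly.

The persons-per-point step assumes the point register is complete for the
cells it covers; that assumption is surfaced in the summary report rather
than corrected for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .grid import CellTable

STRATA = ("urban", "rural")

#: assumption under which persons-per-point is estimated; echoed in reports
COMPLETENESS_ASSUMPTION = (
    "persons-per-point estimates assume the point register is complete for "
    "every cell where it records at least one access point"
)


@dataclass
class AccessShares:
    """Share of population whose primary source is each access type, per stratum."""

    shares: dict[tuple[str, str], float]  # (access_type, stratum) -> share

    def __post_init__(self):
        for (t, j), v in self.shares.items():
            if v < 0:
                raise ValueError(f"negative share for ({t}, {j})")
        for j in self.strata:
            tot = sum(v for (t, s), v in self.shares.items() if s == j)
            if tot > 1 + 1e-9:
                raise ValueError(f"shares in stratum {j!r} sum to {tot} > 1")

    @property
    def types(self) -> list[str]:
        return sorted({t for t, _ in self.shares})

    @property
    def strata(self) -> list[str]:
        return sorted({j for _, j in self.shares})

    def share(self, access_type: str, stratum: str) -> float:
        return self.shares.get((access_type, stratum), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"access_type": t, "stratum": j, "share": v}
            for (t, j), v in sorted(self.shares.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AccessShares":
        return cls({
            (r.access_type, r.stratum): float(r.share) for r in df.itertuples()
        })


@dataclass
class PersonsPerSource:
    """Estimated persons served per access point, per stratum; NaN = undefined."""

    access_type: str
    s: dict[str, float]
    n_cells_used: dict[str, int] = field(default_factory=dict)

    def defined(self, stratum: str) -> bool:
        return stratum in self.s and np.isfinite(self.s[stratum]) and self.s[stratum] > 0


@dataclass
class TotalPresences:
    """Expected total number of access points per stratum for one type."""

    access_type: str
    y: dict[str, float]

    def __post_init__(self):
        for j, v in self.y.items():
            if v < 0:
                raise ValueError(f"negative expected total for stratum {j!r}")

    @property
    def total(self) -> float:
        return float(sum(self.y.values()))


@dataclass
class CountMap:
    """Expected number of access points per cell (non-negative, conserving strata)."""

    access_type: str
    y: pd.Series  # indexed by cell_id

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "cell_id": self.y.index,
            "access_type": self.access_type,
            "expected_count": self.y.to_numpy(),
        })
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def persons_per_point(table: CellTable, all_presences: Mapping) -> pd.Series:
    """Persons per recorded access point, s_i = Pop_i / n_i, on cells with points.

    ``n_i`` counts the recorded points of *all* access types in cell i, so
    co-located types share the cell's population. Cells without any
    recorded point are absent from the result.
    """
    counts: dict[int, int] = {}
    for p in all_presences.values():
        for c in p.cells:
            counts[int(c)] = counts.get(int(c), 0) + 1
    if not counts:
        return pd.Series(dtype=float)
    cells = np.array(sorted(counts))
    n_i = np.array([counts[c] for c in cells], dtype=float)
    pop = table.df.set_index("cell_id")["population"].loc[cells].to_numpy()
    return pd.Series(pop / n_i, index=cells)


def average_persons_per_type(
    s_cells: pd.Series,
    all_presences: Mapping,
    access_type: str,
    table: CellTable,
) -> PersonsPerSource:
    """Unweighted mean of s_i over the cells where the target type is recorded,
    separately for urban and rural cells."""
    target = all_presences[access_type].unique_cells()
    strata = table.df.set_index("cell_id")["stratum"]
    s, n_used = {}, {}
    for stratum in STRATA:
        qualifying = [c for c in target if c in s_cells.index and strata.get(c) == stratum]
        n_used[stratum] = len(qualifying)
        s[stratum] = float(s_cells.loc[qualifying].mean()) if qualifying else float("nan")
    return PersonsPerSource(access_type, s, n_used)


def total_expected_presences(
    shares: AccessShares,
    table: CellTable,
    pps: PersonsPerSource,
) -> TotalPresences:
    """Expected total points per stratum: y = share * stratum population / s."""
    t = pps.access_type
    pop_by_stratum = table.df.groupby("stratum")["population"].sum()
    y = {}
    for stratum in STRATA:
        share = shares.share(t, stratum)
        if share == 0.0:
            y[stratum] = 0.0
            continue
        if not pps.defined(stratum):
            raise ValueError(
                f"share of ({t}, {stratum}) is positive but persons-per-point "
                "is undefined for that stratum"
            )
        y[stratum] = share * float(pop_by_stratum.get(stratum, 0.0)) / pps.s[stratum]
    return TotalPresences(t, y)


def scale_to_counts(p_star, totals: TotalPresences, table: CellTable) -> CountMap:
    """Distribute each stratum's expected total over its cells in proportion to p*.

    y_i = y_stratum * p*_i / sum of p* over the stratum. Doubling all p*
    within a stratum leaves the counts unchanged, and stratum sums equal
    the totals up to floating-point error. The presence threshold used in
    evaluation plays no role here.
    """
    ps = p_star.p_star if hasattr(p_star, "p_star") else p_star
    ps = pd.Series(np.asarray(ps.to_numpy() if hasattr(ps, "to_numpy") else ps,
                              dtype=float),
                   index=ps.index if hasattr(ps, "index") else table.cell_ids)
    y = pd.Series(0.0, index=table.cell_ids)
    strata = table.df.set_index("cell_id")["stratum"]
    for stratum, total in totals.y.items():
        cells = strata.index[strata == stratum]
        if total == 0.0 or len(cells) == 0:
            continue
        denom = float(ps.loc[cells].sum())
        if denom <= 0:
            raise ValueError(
                f"stratum {stratum!r} carries a positive total but its "
                "relative probabilities sum to zero"
            )
        y.loc[cells] = total * ps.loc[cells] / denom
    return CountMap(totals.access_type, y)


def summary_json(pps_by_type, totals_by_type, path=None) -> dict:
    """Per type x stratum summary of persons-per-point and expected totals."""
    out = {"assumption": COMPLETENESS_ASSUMPTION, "types": {}}
    for t in sorted(pps_by_type):
        pps, tot = pps_by_type[t], totals_by_type[t]
        out["types"][t] = {
            j: {
                "persons_per_point": None if not pps.defined(j) else pps.s[j],
                "n_cells_used": pps.n_cells_used.get(j, 0),
                "expected_total": tot.y.get(j, 0.0),
            }
            for j in STRATA
        }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)
    return out
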