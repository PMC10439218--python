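"""Cell lattice, typed feature layers, resampling and collinearity screening.

The study area is a regular grid of square cells (row-major, 0-based, cell
(0, 0) at the north-west corner). Every per-cell quantity in the package --
feature values, population, suitability, counts -- is stored as a flat array
of length ``n_rows * n_cols``; a boolean mask marks the cells inside the
study area. Feature layers are either numerical (real-valued, resampled by
bilinear interpolation) or categorical (integer codes, resampled by nearest
neighbour).

Before modelling, pairwise associations between layers are screened so that
no strongly collinear pair survives: Pearson's r for numerical-numerical
pairs, Cramer's V for categorical-categorical pairs and the correlation
ratio (eta squared) for mixed pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

NUMERICAL = "numerical"
CATEGORICAL = "categorical"

#: stratum codes used throughout the package
RURAL, URBAN = 0, 1
STRATUM_NAMES = {RURAL: "rural", URBAN: "urban"}
STRATUM_CODES = {"rural": RURAL, "urban": URBAN}


@dataclass(frozen=True)
class GridSpec:
    """A regular lattice of square cells.

    Cells are indexed row-major with cell (0, 0) at the north-west corner;
    cell extents are half-open and the centre of cell (r, c) lies at
    ``((r + 0.5) * cell_size, (c + 0.5) * cell_size)``.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1.0
    mask: np.ndarray | None = None  # bool, flat, length n_rows * n_cols

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.mask is None:
            object.__setattr__(
                self, "mask", np.ones(self.n_rows * self.n_cols, dtype=bool)
            )
        else:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (self.n_rows * self.n_cols,):
                raise ValueError("mask length must equal n_rows * n_cols")
            object.__setattr__(self, "mask", m)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def masked_cells(self) -> np.ndarray:
        """Cell ids inside the study area."""
        return np.flatnonzero(self.mask)

    def rowcol(self, cell_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cell_ids = np.asarray(cell_ids)
        return cell_ids // self.n_cols, cell_ids % self.n_cols

    def cell_centres(self, cell_ids: np.ndarray) -> np.ndarray:
        """(n, 2) array of (y, x) centre coordinates."""
        r, c = self.rowcol(cell_ids)
        return np.stack([(r + 0.5) * self.cell_size, (c + 0.5) * self.cell_size], axis=1)

    def extent(self) -> tuple[float, float]:
        return self.n_rows * self.cell_size, self.n_cols * self.cell_size


@dataclass
class FeatureLayer:
    """One per-cell variable; ``kind`` is 'numerical' or 'categorical'."""

    name: str
    kind: str
    values: np.ndarray
    nodata: float = np.nan

    def __post_init__(self):
        if self.kind not in (NUMERICAL, CATEGORICAL):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        self.values = np.asarray(
            self.values, dtype=float if self.kind == NUMERICAL else int
        ).ravel()


@dataclass
class FeatureStack:
    """An ordered set of feature layers sharing one grid."""

    grid: GridSpec
    layers: list[FeatureLayer] = field(default_factory=list)

    def __post_init__(self):
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        for l in self.layers:
            if l.values.shape != (self.grid.n_cells,):
                raise ValueError(f"layer {l.name!r} does not match the grid")

    def __getitem__(self, name: str) -> FeatureLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def drop(self, names) -> "FeatureStack":
        names = set([names] if isinstance(names, str) else names)
        return FeatureStack(self.grid, [l for l in self.layers if l.name not in names])


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_layer(layer: FeatureLayer, src: GridSpec, dst: GridSpec) -> FeatureLayer:
    """Resample a layer from one grid to another covering the same extent.

    Numerical layers are bilinearly interpolated at destination cell
    centres; categorical layers take the value of the nearest source cell
    centre. Destination centres outside the convex hull of source centres
    (a strip of half a source cell at the border) are clamped to the edge.
    """
    if layer.kind not in (NUMERICAL, CATEGORICAL):
        raise ValueError(f"unknown layer kind {layer.kind!r}")
    if src.n_cells == 0 or dst.n_cells == 0:
        raise ValueError("degenerate grid")
    ext_s, ext_d = src.extent(), dst.extent()
    if not (np.isclose(ext_s[0], ext_d[0]) and np.isclose(ext_s[1], ext_d[1])):
        raise ValueError("source and destination grids must cover the same extent")
    if layer.values.shape != (src.n_cells,):
        raise ValueError("layer does not belong to the source grid")

    ys = (np.arange(src.n_rows) + 0.5) * src.cell_size
    xs = (np.arange(src.n_cols) + 0.5) * src.cell_size
    grid_vals = layer.values.reshape(src.n_rows, src.n_cols).astype(float)
    method = "linear" if layer.kind == NUMERICAL else "nearest"
    interp = RegularGridInterpolator((ys, xs), grid_vals, method=method)

    pts = dst.cell_centres(np.arange(dst.n_cells))
    # clamp to the source-centre hull: constant extrapolation at the border
    pts[:, 0] = np.clip(pts[:, 0], ys[0], ys[-1])
    pts[:, 1] = np.clip(pts[:, 1], xs[0], xs[-1])
    out = interp(pts)
    if layer.kind == CATEGORICAL:
        out = np.rint(out).astype(int)
    return FeatureLayer(layer.name, layer.kind, out, layer.nodata)


# ---------------------------------------------------------------------------
# collinearity screening
# ---------------------------------------------------------------------------

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(x, y).statistic)


def cramers_v(a: np.ndarray, b: np.ndarray) -> float:
    """Cramer's V from the chi-square of the joint contingency table."""
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    if min(table.shape) < 2:
        raise ValueError("Cramer's V needs at least two categories per layer")
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    n = table.sum()
    return float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))


def eta_squared(numeric: np.ndarray, categories: np.ndarray) -> float:
    """Correlation ratio: between-group over total sum of squares."""
    numeric = np.asarray(numeric, dtype=float)
    grand = numeric.mean()
    ss_total = float(np.sum((numeric - grand) ** 2))
    if ss_total == 0.0:
        raise ValueError("numeric layer is constant")
    ss_between = 0.0
    for code in np.unique(categories):
        grp = numeric[categories == code]
        ss_between += grp.size * (grp.mean() - grand) ** 2
    return float(ss_between / ss_total)


@dataclass
class ScreenReport:
    """Pairwise association statistics and the layers dropped."""

    pairs: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs)


def _pair_statistic(la: FeatureLayer, lb: FeatureLayer, mask: np.ndarray):
    a, b = la.values[mask], lb.values[mask]
    if la.kind == NUMERICAL and lb.kind == NUMERICAL:
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("constant layer")
        return "pearson_r", pearson_r(a, b)
    if la.kind == CATEGORICAL and lb.kind == CATEGORICAL:
        return "cramers_v", cramers_v(a, b)
    if la.kind == NUMERICAL:
        return "eta_squared", eta_squared(a, b.astype(int))
    return "eta_squared", eta_squared(b, a.astype(int))


def correlation_screen(
    stack: FeatureStack,
    r_max: float = 0.7,
    v_max: float = 0.65,
    eta_max: float = 0.7,
) -> tuple[FeatureStack, ScreenReport]:
    """Drop one layer of every pair whose association exceeds its threshold.

    Statistics are computed over masked cells only. When a pair exceeds its
    threshold the layer with the larger mean absolute association to all
    other layers is dropped (tie: the later layer in stack order), so the
    surviving stack keeps the most independent information. Screening the
    surviving stack again drops nothing.
    """
    if len(stack.layers) < 2:
        raise ValueError("screening needs at least two layers")
    mask = stack.grid.mask
    names = stack.names
    thresholds = {"pearson_r": r_max, "cramers_v": v_max, "eta_squared": eta_max}

    assoc = pd.DataFrame(np.nan, index=names, columns=names)
    records = {}
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            try:
                stat_name, value = _pair_statistic(stack[na], stack[nb], mask)
            except ValueError as err:
                warnings.warn(
                    f"skipping pair ({na}, {nb}): {err}", stacklevel=2
                )
                continue
            records[(na, nb)] = {
                "layer_a": na, "layer_b": nb,
                "statistic_name": stat_name, "value": value,
                "dropped_layer": None,
            }
            assoc.loc[na, nb] = assoc.loc[nb, na] = abs(value)

    surviving = list(names)
    dropped: set[str] = set()
    while True:
        offender = None
        for (na, nb), rec in records.items():
            if na in dropped or nb in dropped:
                continue
            if abs(rec["value"]) > thresholds[rec["statistic_name"]]:
                offender = (na, nb)
                break
        if offender is None:
            break
        na, nb = offender
        cols = [n for n in surviving if n not in (na, nb)]
        mean_a = assoc.loc[na, cols].mean() if cols else 0.0
        mean_b = assoc.loc[nb, cols].mean() if cols else 0.0
        mean_a = 0.0 if np.isnan(mean_a) else mean_a
        mean_b = 0.0 if np.isnan(mean_b) else mean_b
        # tie -> later layer in stack order (nb comes after na)
        victim = na if mean_a > mean_b else nb
        records[offender]["dropped_layer"] = victim
        dropped.add(victim)
        surviving = [n for n in surviving if n != victim]

    report = ScreenReport(list(records.values()))
    return stack.drop(dropped), report


# ---------------------------------------------------------------------------
# model-ready cell table
# ---------------------------------------------------------------------------

@dataclass
class CellTable:
    """One row per masked cell with stratum, population and encoded features.

    ``feature_cols`` lists the encoded feature columns (numericals passed
    through, categoricals one-hot expanded, reference category kept);
    ``groups`` maps each original layer to its encoded columns and
    ``numeric_cols`` names the purely numerical ones -- both are needed when
    basis expansion or permutation shuffling must treat a categorical
    layer's indicator columns as one unit.
    """

    df: pd.DataFrame
    feature_cols: list[str]
    numeric_cols: list[str]
    groups: dict[str, list[str]]
    grid: GridSpec

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy()

    def features(self, cells=None, drop: set[str] | None = None) -> np.ndarray:
        """Encoded feature matrix, optionally restricted to given cells."""
        cols = [c for c in self.feature_cols if not drop or c not in drop]
        df = self.df.set_index("cell_id") if cells is not None else self.df
        if cells is not None:
            return df.loc[np.asarray(cells), cols].to_numpy(dtype=float)
        return df[cols].to_numpy(dtype=float)

    def drop_feature(self, layer_name: str) -> "CellTable":
        """A view of the table without one original feature layer."""
        cols = set(self.groups.get(layer_name, [layer_name]))
        return CellTable(
            df=self.df.drop(columns=[c for c in cols if c in self.df.columns]),
            feature_cols=[c for c in self.feature_cols if c not in cols],
            numeric_cols=[c for c in self.numeric_cols if c not in cols],
            groups={k: v for k, v in self.groups.items() if k != layer_name},
            grid=self.grid,
        )

    def stratum_cells(self, stratum: str) -> np.ndarray:
        return self.df.loc[self.df["stratum"] == stratum, "cell_id"].to_numpy()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def build_cell_table(
    stack: FeatureStack,
    population: FeatureLayer,
    strata: FeatureLayer,
    stratum_names: dict[int, str] = STRATUM_NAMES,
) -> CellTable:
    """Assemble the model-ready table over masked cells.

    Numerical layers pass through unchanged (scaling is a model-side
    concern); each categorical layer expands to one-hot indicator columns
    over the codes observed inside the mask.
    """
    grid = stack.grid
    cells = grid.masked_cells()
    if cells.size == 0:
        raise ValueError("empty mask: no cells inside the study area")
    pop = population.values[cells]
    if np.any(pop < 0):
        raise ValueError("population must be non-negative")
    codes = strata.values[cells].astype(int)
    unknown = set(np.unique(codes)) - set(stratum_names)
    if unknown:
        raise ValueError(f"unknown stratum codes {sorted(unknown)}")

    r, c = grid.rowcol(cells)
    data = {
        "cell_id": cells, "row": r, "col": c,
        "stratum": [stratum_names[k] for k in codes],
        "population": pop.astype(float),
    }
    feature_cols: list[str] = []
    numeric_cols: list[str] = []
    groups: dict[str, list[str]] = {}
    for layer in stack.layers:
        vals = layer.values[cells]
        if layer.kind == NUMERICAL:
            data[layer.name] = vals.astype(float)
            feature_cols.append(layer.name)
            numeric_cols.append(layer.name)
            groups[layer.name] = [layer.name]
        else:
            cols = []
            for code in np.unique(vals):
                col = f"{layer.name}={int(code)}"
                data[col] = (vals == code).astype(float)
                cols.append(col)
            feature_cols.extend(cols)
            groups[layer.name] = cols
    return CellTable(pd.DataFrame(data), feature_cols, numeric_cols, groups, grid)


# ---------------------------------------------------------------------------
# stack I/O: per-layer CSV plus a JSON manifest
# ---------------------------------------------------------------------------

def _write_layer_csv(path: Path, values: np.ndarray) -> None:
    # %.17g round-trips float64 exactly
    pd.DataFrame({"cell_id": np.arange(values.size), "value": values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def _read_layer_csv(path: Path, n_cells: int) -> np.ndarray:
    df = pd.read_csv(path, float_precision="round_trip")
    if len(df) != n_cells:
        raise ValueError(f"{path.name}: expected {n_cells} rows, found {len(df)}")
    out = np.empty(n_cells)
    out[df["cell_id"].to_numpy()] = df["value"].to_numpy()
    return out


def save_stack(stack: FeatureStack, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid": {
            "n_rows": stack.grid.n_rows,
            "n_cols": stack.grid.n_cols,
            "cell_size": stack.grid.cell_size,
        },
        "layers": [
            {"name": l.name, "kind": l.kind,
             "nodata": None if np.isnan(l.nodata) else l.nodata}
            for l in stack.layers
        ],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    _write_layer_csv(path / "mask.csv", stack.grid.mask.astype(int))
    for l in stack.layers:
        _write_layer_csv(path / f"{l.name}.csv", l.values)


def load_stack(path) -> FeatureStack:
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"missing manifest {manifest_file}")
    manifest = json.loads(manifest_file.read_text())
    g = manifest["grid"]
    n_cells = g["n_rows"] * g["n_cols"]
    mask = _read_layer_csv(path / "mask.csv", n_cells).astype(bool)
    grid = GridSpec(g["n_rows"], g["n_cols"], g["cell_size"], mask)
    layers = []
    for entry in manifest["layers"]:
        vals = _read_layer_csv(path / f"{entry['name']}.csv", n_cells)
        nodata = entry.get("nodata")
        layers.append(
            FeatureLayer(entry["name"], entry["kind"], vals,
                         np.nan if nodata is None else nodata)
        )
    return FeatureStack(grid, layers)
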