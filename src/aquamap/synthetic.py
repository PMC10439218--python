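"""Synthetic gridded worlds with known ground truth.

Real studies of water-point mapping combine a point register (presence-only
access-point records), gridded feature rasters, population and urban/rural
strata, household-survey usage shares and a local validation survey. None
of these are distributable here, so this module generates format-compatible
worlds with *known* ground truth: smooth Gaussian random fields as feature
layers, a clustered settlement field, per-type latent suitability surfaces
with stated coefficients, Poisson access-point counts, a population layer
implied by the counts and persons-per-point, and spatially biased
presence-only observations of the counts.

Everything downstream (screening, sampling, model fitting, count scaling,
evaluation) can therefore be tested against quantities the generator knows
exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .background import PresenceSet
from .grid import (
    CATEGORICAL, NUMERICAL, RURAL, STRATUM_NAMES, URBAN,
    CellTable, FeatureLayer, FeatureStack, GridSpec, build_cell_table,
    load_stack, save_stack,
)
from .scaling import AccessShares

DEFAULT_ACCESS_TYPES = ("borehole", "piped", "spring")

# Persons served per access point, (urban, rural); magnitudes follow typical
# national estimates: communal boreholes serve hundreds, piped connections
# serve tens, springs sit in between.
DEFAULT_PERSONS_PER_POINT = {
    "borehole": {"urban": 75.0, "rural": 300.0},
    "piped": {"urban": 40.0, "rural": 50.0},
    "spring": {"urban": 150.0, "rural": 130.0},
}


@dataclass(frozen=True)
class SuitabilitySpec:
    """Linear + pairwise-product combination of named layers."""

    linear: tuple[tuple[str, float], ...] = ()
    products: tuple[tuple[str, str, float], ...] = ()
    intercept: float = 0.0

    def referenced_layers(self) -> set[str]:
        out = {n for n, _ in self.linear}
        for a, b, _ in self.products:
            out |= {a, b}
        return out

    def evaluate(self, layer_values: dict[str, np.ndarray]) -> np.ndarray:
        some = next(iter(layer_values.values()))
        eta = np.full(some.shape, self.intercept, dtype=float)
        for name, coef in self.linear:
            eta += coef * layer_values[name]
        for a, b, coef in self.products:
            eta += coef * layer_values[a] * layer_values[b]
        return eta


def _default_suitability() -> dict[str, SuitabilitySpec]:
    return {
        "borehole": SuitabilitySpec(linear=(("num_0", 1.0), ("num_1", 0.8))),
        "piped": SuitabilitySpec(linear=(("num_1", 1.2), ("num_2", -0.6))),
        "spring": SuitabilitySpec(linear=(("num_2", 1.0), ("num_3", 0.7))),
    }


@dataclass
class WorldConfig:
    """Study conditions for one synthetic world.

    ``base_intensity`` is the mean expected number of true access points
    per cell and type (about 0.12/km^2, the per-type density of a national
    point register); ``unserved_fraction`` is the share of the population
    not served by any modeled type, spread over the settlement field so
    cells without points still carry people.
    """

    n_rows: int = 60
    n_cols: int = 60
    cell_size: float = 1.0
    n_numeric_layers: int = 5
    n_categorical_layers: int = 2
    n_categories: int = 3
    access_types: tuple[str, ...] = DEFAULT_ACCESS_TYPES
    suitability_spec: dict[str, SuitabilitySpec] = field(default_factory=_default_suitability)
    persons_per_point_true: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PERSONS_PER_POINT.items()}
    )
    base_intensity: float = 0.12
    population_exponent: float = 0.5
    intensity_noise_sd: float = 1.0  # lognormal overdispersion of the point process
    detection_rate: float = 0.8
    bias_strength: float = 0.0
    smooth_sigma: float = 6.0
    urban_quantile: float = 0.8
    unserved_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.access_types:
            raise ValueError("at least one access type required")
        if not 0.0 < self.detection_rate <= 1.0:
            raise ValueError("detection_rate must be in (0, 1]")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        layer_names = {f"num_{k}" for k in range(self.n_numeric_layers)} | {
            f"cat_{k}" for k in range(self.n_categorical_layers)
        }
        for t in self.access_types:
            spec = self.suitability_spec.get(t)
            if spec is None:
                raise ValueError(f"no suitability spec for access type {t!r}")
            missing = spec.referenced_layers() - layer_names
            if missing:
                raise ValueError(
                    f"suitability spec of {t!r} references unknown layers {sorted(missing)}"
                )


@dataclass
class World:
    stack: FeatureStack
    population: FeatureLayer
    strata: FeatureLayer
    true_suitability: dict[str, np.ndarray]
    true_intensity: dict[str, np.ndarray]
    true_counts: dict[str, np.ndarray]
    presences: dict[str, PresenceSet]
    shares: AccessShares
    config: WorldConfig
    settlement: np.ndarray | None = None  # latent field behind population

    @property
    def grid(self) -> GridSpec:
        return self.stack.grid

    def cell_table(self, include_population_feature: bool = True) -> CellTable:
        """Model-ready table; optionally appends population density as a feature."""
        stack = self.stack
        if include_population_feature:
            stack = FeatureStack(
                stack.grid,
                stack.layers + [FeatureLayer("population_density", NUMERICAL,
                                             self.population.values)],
            )
        return build_cell_table(stack, self.population, self.strata)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    f = f - f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_world(config: WorldConfig) -> World:
    """Generate a world; bit-reproducible for a given config and seed."""
    rng = np.random.default_rng(config.seed)
    shape = (config.n_rows, config.n_cols)
    grid = GridSpec(config.n_rows, config.n_cols, config.cell_size)

    layers: list[FeatureLayer] = []
    values: dict[str, np.ndarray] = {}
    for k in range(config.n_numeric_layers):
        f = _smooth_field(rng, shape, config.smooth_sigma).ravel()
        layers.append(FeatureLayer(f"num_{k}", NUMERICAL, f))
        values[f"num_{k}"] = f
    for k in range(config.n_categorical_layers):
        f = _smooth_field(rng, shape, config.smooth_sigma).ravel()
        qs = np.quantile(f, np.linspace(0, 1, config.n_categories + 1)[1:-1])
        codes = np.digitize(f, qs)
        layers.append(FeatureLayer(f"cat_{k}", CATEGORICAL, codes))
        values[f"cat_{k}"] = codes.astype(float)
    stack = FeatureStack(grid, layers)

    # clustered settlement field (log-normal) and urban/rural strata
    settlement = np.exp(1.5 * _smooth_field(rng, shape, config.smooth_sigma)).ravel()
    settlement /= settlement.mean()
    urban_cut = np.quantile(settlement, config.urban_quantile)
    strata_codes = np.where(settlement > urban_cut, URBAN, RURAL)
    strata = FeatureLayer("stratum", CATEGORICAL, strata_codes)
    stratum_name = np.array([STRATUM_NAMES[c] for c in strata_codes])

    # latent suitability, true intensity and Poisson counts per type;
    # sub-linear population modulation: communal sources serve many people,
    # so source density grows slower than settlement density
    pop_factor = np.clip(settlement, None, 5.0) ** config.population_exponent
    true_suitability: dict[str, np.ndarray] = {}
    true_intensity: dict[str, np.ndarray] = {}
    true_counts: dict[str, np.ndarray] = {}
    for t in config.access_types:
        eta = config.suitability_spec[t].evaluate(values)
        suit = expit(eta)
        true_suitability[t] = suit
        weight = suit * pop_factor
        # unit-mean lognormal overdispersion: siting of real infrastructure
        # is far from fully explained by mapped features
        if config.intensity_noise_sd > 0:
            sd = config.intensity_noise_sd
            weight = weight * np.exp(rng.normal(0.0, sd, weight.size) - sd**2 / 2)
        intensity = config.base_intensity * weight / weight.mean()
        true_intensity[t] = intensity
        true_counts[t] = rng.poisson(intensity)

    # population implied by counts and persons-per-point, plus unserved people
    served = np.zeros(grid.n_cells)
    for t in config.access_types:
        s_true = config.persons_per_point_true[t]
        per_point = np.where(strata_codes == URBAN, s_true["urban"], s_true["rural"])
        served += true_counts[t] * per_point
    total_served = served.sum()
    if total_served > 0 and config.unserved_fraction > 0:
        unserved_total = config.unserved_fraction / (1 - config.unserved_fraction) * total_served
    else:
        unserved_total = 10.0 * grid.n_cells if total_served == 0 else 0.0
    # unserved people follow the settlement field with its density capped,
    # like the intensity modulation, so they do not pile up in a few cells
    alloc = np.clip(settlement, None, 5.0)
    population = FeatureLayer(
        "population", NUMERICAL, served + unserved_total * alloc / alloc.sum(),
    )

    # usage shares: persons served per type, normalized within each stratum
    share_dict: dict[tuple[str, str], float] = {}
    for code, jname in STRATUM_NAMES.items():
        sel = strata_codes == code
        served_by_type = {
            t: float((true_counts[t][sel]
                      * config.persons_per_point_true[t][jname]).sum())
            for t in config.access_types
        }
        denom = sum(served_by_type.values())
        if denom <= 0:
            warnings.warn(f"stratum {jname!r} has no served population; "
                          "assigning equal shares", stacklevel=2)
            for t in config.access_types:
                share_dict[(t, jname)] = 1.0 / len(config.access_types)
        else:
            for t in config.access_types:
                share_dict[(t, jname)] = served_by_type[t] / denom
    shares = AccessShares(share_dict)

    world = World(stack, population, strata, true_suitability, true_intensity,
                  true_counts, {}, shares, config, settlement)
    for t in config.access_types:
        world.presences[t] = observe_presences(
            world, t, config.detection_rate, config.bias_strength,
            seed=int(rng.integers(2**31 - 1)),
        )
    return world


def observe_presences(
    world: World,
    access_type: str,
    detection_rate: float,
    bias_strength: float,
    seed: int,
    centre: int | None = None,
) -> PresenceSet:
    """Presence-only, possibly spatially biased observation of the true counts.

    Each cell holding at least one true point is detected independently
    with probability ``detection_rate * b_i`` where the bias factor decays
    with distance from a randomly placed survey centre
    (b_i = exp(-bias_strength * d_i / d_max); identically 1 when
    bias_strength is 0). A detected cell contributes one record per true
    point it holds, as a register surveying the cell lists all of them.
    No absences are recorded.
    """
    if access_type not in world.true_counts:
        raise KeyError(f"unknown access type {access_type!r}")
    if not 0.0 < detection_rate <= 1.0:
        raise ValueError("detection_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)
    grid = world.grid
    occupied = np.flatnonzero((world.true_counts[access_type] > 0) & grid.mask)
    if bias_strength > 0:
        if centre is None:
            centre = rng.choice(grid.masked_cells())
        d = np.linalg.norm(
            grid.cell_centres(occupied) - grid.cell_centres(np.array([centre])), axis=1
        )
        d_max = max(float(d.max()), 1e-12) if d.size else 1.0
        b = np.exp(-bias_strength * d / d_max)
    else:
        b = np.ones(occupied.size)
    detected = occupied[rng.random(occupied.size) < detection_rate * b]
    counts = world.true_counts[access_type][detected]
    return PresenceSet(access_type, np.repeat(detected, counts))


# ---------------------------------------------------------------------------
# lossless CSV/JSON round trip
# ---------------------------------------------------------------------------

def export_world(world: World, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    save_stack(world.stack, path / "layers")
    cfg = world.config
    meta = {
        "format_version": 1,
        "access_types": list(cfg.access_types),
        "persons_per_point_true": cfg.persons_per_point_true,
        "detection_rate": cfg.detection_rate,
        "bias_strength": cfg.bias_strength,
        "base_intensity": cfg.base_intensity,
        "unserved_fraction": cfg.unserved_fraction,
        "seed": cfg.seed,
    }
    (path / "world.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    n = np.arange(world.grid.n_cells)
    pd.DataFrame({"cell_id": n, "value": world.population.values}).to_csv(
        path / "population.csv", index=False, float_format="%.17g")
    pd.DataFrame({"cell_id": n, "value": world.strata.values}).to_csv(
        path / "strata.csv", index=False)
    if world.settlement is not None:
        pd.DataFrame({"cell_id": n, "value": world.settlement}).to_csv(
            path / "settlement.csv", index=False, float_format="%.17g")
    for t in cfg.access_types:
        pd.DataFrame({"cell_id": n, "value": world.true_suitability[t]}).to_csv(
            path / f"suitability_{t}.csv", index=False, float_format="%.17g")
        pd.DataFrame({"cell_id": n, "value": world.true_intensity[t]}).to_csv(
            path / f"intensity_{t}.csv", index=False, float_format="%.17g")
        pd.DataFrame({"cell_id": n, "value": world.true_counts[t]}).to_csv(
            path / f"counts_{t}.csv", index=False)
    rows = [(t, int(c)) for t in cfg.access_types for c in world.presences[t].cells]
    pd.DataFrame(rows, columns=["access_type", "cell_id"]).to_csv(
        path / "presences.csv", index=False)
    world.shares.to_frame().to_csv(path / "shares.csv", index=False,
                                   float_format="%.17g")


def import_world(path) -> World:
    path = Path(path)
    meta_file = path / "world.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"missing manifest {meta_file}")
    meta = json.loads(meta_file.read_text())
    stack = load_stack(path / "layers")
    n_cells = stack.grid.n_cells

    def col(name, dtype=float):
        df = pd.read_csv(path / name, float_precision="round_trip")
        if len(df) != n_cells:
            raise ValueError(f"{name}: schema mismatch ({len(df)} rows, "
                             f"expected {n_cells})")
        out = np.empty(n_cells, dtype=dtype)
        out[df["cell_id"].to_numpy()] = df["value"].to_numpy()
        return out

    population = FeatureLayer("population", NUMERICAL, col("population.csv"))
    strata = FeatureLayer("stratum", CATEGORICAL, col("strata.csv", int))
    settlement = (col("settlement.csv")
                  if (path / "settlement.csv").exists() else None)
    types = meta["access_types"]
    suit = {t: col(f"suitability_{t}.csv") for t in types}
    intensity = {t: col(f"intensity_{t}.csv") for t in types}
    counts = {t: col(f"counts_{t}.csv", int) for t in types}

    pres_df = pd.read_csv(path / "presences.csv")
    presences = {
        t: PresenceSet(t, pres_df.loc[pres_df["access_type"] == t,
                                      "cell_id"].to_numpy(dtype=int))
        for t in types
    }
    shares_df = pd.read_csv(path / "shares.csv", float_precision="round_trip")
    for stratum, grp in shares_df.groupby("stratum"):
        tot = grp["share"].sum()
        if abs(tot - 1.0) > 1e-6:
            raise ValueError(
                f"shares in stratum {stratum!r} sum to {tot}, expected 1")
    shares = AccessShares.from_frame(shares_df)

    for t in types:
        bad = np.setdiff1d(presences[t].unique_cells(),
                           np.flatnonzero(counts[t] > 0))
        if bad.size:
            raise ValueError(
                f"presences of {t!r} recorded in cells without true counts: {bad[:5]}")

    config = WorldConfig(
        n_rows=stack.grid.n_rows, n_cols=stack.grid.n_cols,
        cell_size=stack.grid.cell_size,
        n_numeric_layers=sum(l.kind == NUMERICAL for l in stack.layers),
        n_categorical_layers=sum(l.kind == CATEGORICAL for l in stack.layers),
        access_types=tuple(types),
        persons_per_point_true=meta["persons_per_point_true"],
        detection_rate=meta["detection_rate"],
        bias_strength=meta["bias_strength"],
        base_intensity=meta["base_intensity"],
        unserved_fraction=meta["unserved_fraction"],
        seed=meta["seed"],
    )
    return World(stack, population, strata, suit, intensity, counts, presences,
                 shares, config, settlement)
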