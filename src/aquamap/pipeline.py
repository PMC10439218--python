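"""End-to-end orchestration: world -> screen -> sample -> train -> scale -> evaluate.

A single :class:`RunConfig` and master seed drive every stage. Each
stochastic stage draws its own seed from a counter-based derivation that is
recorded in the run manifest, so any single stage can be reproduced from
the manifest alone and an identical config + seed reproduces every output
byte for byte.

The population-density feature participates as an ordinary feature layer
for the standard models; the weighted-background model drops it from its
feature set (its backgrounds are already selected by population, and
keeping the layer would let the model learn settlement presence instead of
water-point suitability).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .background import (
    compute_prior_expectation, sample_uniform_background,
    sample_weighted_background, split_presences,
)
from .evaluation import DEFAULT_THETA, evaluate_scores, sensitivity_sweep
from .grid import FeatureLayer, FeatureStack, NUMERICAL, build_cell_table, correlation_screen
from .models import (
    FeatureBasis, HyperSearchSpace, fit_maxent, fit_mlp, hyperparameter_search,
    predict_maxent, SuitabilityMap,
)
from .scaling import (
    average_persons_per_type, persons_per_point, scale_to_counts,
    summary_json, total_expected_presences,
)
from .synthetic import World, WorldConfig, generate_world, import_world

log = logging.getLogger("aquamap")

POPULATION_FEATURE = "population_density"
MODEL_IDS = ("maxent", "mlp", "mlp-weighted")


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Defaults encode the reference study setup: background ratio 4, 70/30
    presence split, presence threshold 0.3, 200 hyper-search trials with
    5-fold cross-validation.
    """

    world: WorldConfig | str = field(default_factory=WorldConfig)
    out_dir: str = "run"
    access_types: tuple[str, ...] | None = None  # None = all in the world
    models: tuple[str, ...] = MODEL_IDS
    ratio: float = 4.0
    theta: float = DEFAULT_THETA
    train_fraction: float = 0.7
    # hyperparameter search; 0 trials = fixed MLP configuration below
    hyper_trials: int = 200
    k_folds: int = 5
    search_space: HyperSearchSpace | None = None
    mlp_layer_sizes: tuple[int, ...] = (50,)
    mlp_activation: str = "relu"
    mlp_max_iter: int = 500
    maxent_basis: FeatureBasis = field(default_factory=FeatureBasis)
    lambda_scale: float = 1.0
    screen: bool = True
    r_max: float = 0.7
    v_max: float = 0.65
    eta_max: float = 0.7
    sweep_ratios: tuple[float, ...] | None = None
    sweep_access_type: str | None = None
    households: str | None = None
    survey_model: str = "mlp-weighted"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.models) - set(MODEL_IDS)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}")


class SeedLedger:
    """Counter-based derivation of per-stage seeds from one master seed."""

    def __init__(self, master: int):
        self.master = int(master)
        self.counter = 0
        self.record: dict[str, int] = {}

    def next(self, stage: str) -> int:
        h = zlib.crc32(f"{stage}:{self.counter}".encode())
        seed = (self.master * 2654435761 + h + self.counter) % (2**31 - 1)
        self.record[f"{stage}#{self.counter}"] = seed
        self.counter += 1
        return seed


def _augmented_stack(world: World) -> FeatureStack:
    return FeatureStack(
        world.grid,
        world.stack.layers
        + [FeatureLayer(POPULATION_FEATURE, NUMERICAL, world.population.values)],
    )


def _maxent_matrices(table, cells=None):
    df = table.df.set_index("cell_id")
    sub = df.loc[np.asarray(cells)] if cells is not None else df
    Zn = sub[table.numeric_cols].to_numpy(dtype=float)
    cat_cols = [c for c in table.feature_cols if c not in table.numeric_cols]
    Zc = sub[cat_cols].to_numpy(dtype=float) if cat_cols else None
    return Zn, Zc, cat_cols


def _train_model(model_id, table, train_cells, bg_cells, cfg: RunConfig,
                 seeds: SeedLedger, eval_presence=None, eval_background=None):
    if model_id == "maxent":
        Zn_p, Zc_p, cat_cols = _maxent_matrices(table, train_cells)
        Zn_b, Zc_b, _ = _maxent_matrices(table, bg_cells)
        return fit_maxent(
            Zn_p, Zn_b, cfg.maxent_basis, cfg.lambda_scale,
            presence_categorical=Zc_p, background_categorical=Zc_b,
            categorical_names=cat_cols, numeric_names=table.numeric_cols,
        )
    Xp = table.features(train_cells)
    Xb = table.features(bg_cells)
    if cfg.hyper_trials > 0:
        space = cfg.search_space or HyperSearchSpace(
            n_trials=cfg.hyper_trials, k_folds=cfg.k_folds)
        model, cv = hyperparameter_search(
            space, Xp, Xb, table.features(eval_presence),
            table.features(eval_background), seed=seeds.next(f"search[{model_id}]"),
        )
        model.training_meta["cv_trials"] = int(cv["trial"].max()) + 1
        return model
    return fit_mlp(Xp, Xb, cfg.mlp_layer_sizes, cfg.mlp_activation,
                   max_iter=cfg.mlp_max_iter,
                   seed=seeds.next(f"mlp[{model_id}]"))


def _predict_all(model_id, model, table) -> pd.Series:
    if model_id == "maxent":
        return predict_maxent(model, table).p_star
    return pd.Series(model.predict_pstar(table.features()), index=table.cell_ids)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and return the run directory."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = SeedLedger(config.seed)
    manifest = {"package_version": _pkg_version, "master_seed": config.seed,
                "counts": {}, "stages": []}
    stage = "setup"
    try:
        stage = "world"
        if isinstance(config.world, (str, Path)):
            world = import_world(config.world)
        else:
            world = generate_world(config.world)
        types = tuple(config.access_types or world.config.access_types)
        manifest["counts"]["presences"] = {t: world.presences[t].n for t in types}
        log.info("world: %d cells, %d types", world.grid.n_cells, len(types))

        stage = "screen"
        stack = _augmented_stack(world)
        if config.screen:
            stack, report = correlation_screen(
                stack, config.r_max, config.v_max, config.eta_max)
            report.to_frame().to_csv(out / "screen_report.csv", index=False)
            log.info("screen: %d layers survive", len(stack.layers))
        table = build_cell_table(stack, world.population, world.strata)
        table_nopop = (table.drop_feature(POPULATION_FEATURE)
                       if POPULATION_FEATURE in table.groups else table)
        manifest["counts"]["masked_cells"] = int(len(table.df))
        manifest["counts"]["feature_columns"] = {
            "standard": list(table.feature_cols),
            "weighted": list(table_nopop.feature_cols),
        }

        stage = "scaling-priors"
        s_cells = persons_per_point(table, world.presences)
        pps, totals = {}, {}
        for t in types:
            pps[t] = average_persons_per_type(s_cells, world.presences, t, table)
            totals[t] = total_expected_presences(world.shares, table, pps[t])
        summary_json(pps, totals, out / "scaling_summary.json")

        table1_rows = []
        for t in types:
            stage = f"split[{t}]"
            train, test = split_presences(
                world.presences[t], config.train_fraction, seeds.next(stage))
            manifest["counts"][f"split[{t}]"] = {"train": train.n, "test": test.n}
            log.info("%s: %d train / %d test presences", t, train.n, test.n)

            for model_id in config.models:
                weighted = model_id == "mlp-weighted"
                tbl = table_nopop if weighted else table
                stage = f"background[{t}][{model_id}]"
                if weighted:
                    prior = compute_prior_expectation(table, totals[t], t)
                    bg = sample_weighted_background(
                        prior, tbl, world.presences, train.n, config.ratio,
                        seeds.next(stage))
                    bg_eval = sample_weighted_background(
                        prior, tbl, world.presences, test.n, config.ratio,
                        seeds.next(stage + ".eval"))
                else:
                    bg = sample_uniform_background(
                        tbl, world.presences, train.n, config.ratio,
                        seeds.next(stage), access_type=t)
                    bg_eval = sample_uniform_background(
                        tbl, world.presences, test.n, config.ratio,
                        seeds.next(stage + ".eval"), access_type=t)
                manifest["counts"][stage] = {"train_bg": bg.s, "eval_bg": bg_eval.s}

                stage = f"train[{t}][{model_id}]"
                model = _train_model(model_id, tbl, train.cells, bg.cells,
                                     config, seeds,
                                     eval_presence=test.cells,
                                     eval_background=bg_eval.cells)
                stage = f"predict[{t}][{model_id}]"
                pstar = _predict_all(model_id, model, tbl)

                stage = f"scale[{t}][{model_id}]"
                cmap = scale_to_counts(
                    SuitabilityMap(t, pstar, model_id), totals[t], table)
                cmap.to_csv(out / f"countmap_{t}_{model_id}.csv")

                stage = f"evaluate[{t}][{model_id}]"
                rep = evaluate_scores(
                    pstar.loc[test.cells].to_numpy(),
                    pstar.loc[np.asarray(bg_eval.cells)].to_numpy(),
                    config.theta, t, model_id,
                    background_scheme=bg.scheme,
                )
                rep.to_json(out / f"eval_{t}_{model_id}.json")
                table1_rows.append({
                    "access_type": t, "model": model_id, "n": rep.n,
                    "tpr": rep.tpr, "fpr": rep.fpr, "auc": rep.auc,
                })
                log.info("%s/%s: TPR %.3f FPR %.3f AUC %.3f",
                         t, model_id, rep.tpr, rep.fpr, rep.auc)
        pd.DataFrame(table1_rows).to_csv(out / "table1.csv", index=False)

        if config.sweep_ratios:
            stage = "sweep"
            t = config.sweep_access_type or types[0]

            def trainer(Xp, Xb, s):
                return fit_mlp(Xp, Xb, config.mlp_layer_sizes,
                               config.mlp_activation,
                               max_iter=config.mlp_max_iter, seed=s)

            sweep = sensitivity_sweep(
                trainer, table, world.presences, t, config.sweep_ratios,
                config.theta, config.train_fraction, seeds.next(stage))
            sweep.to_csv(out / f"sensitivity_{t}.csv", index=False)

        if config.households:
            stage = "survey"
            from .survey import compare_usage_groups, comparison_table, load_households
            hh = load_households(config.households)
            model_id = (config.survey_model if config.survey_model in config.models
                        else config.models[0])
            comps = []
            for t in types:
                if f"uses_{t}" not in hh.columns:
                    continue
                cmap_df = pd.read_csv(out / f"countmap_{t}_{model_id}.csv")
                y = pd.Series(cmap_df["expected_count"].to_numpy(),
                              index=cmap_df["cell_id"].to_numpy())
                comps.append(compare_usage_groups(y, hh, t))
            comparison_table(comps, out / "survey_comparison.csv")
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        manifest["seeds"] = seeds.record
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest["seeds"] = seeds.record
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    return out
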