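"""Reproduction experiments: self-contained runs that measure the package's
headline behaviours on synthetic worlds.

Each function generates its own inputs from a seed, runs the relevant part
of the pipeline and returns the measured quantities, so the same code backs
both the acceptance checks and the reproduction script. Problem sizes are
desk-scale: a 60x60 world for the background-ratio sweep (the default study
grid), an 80x80 world for persons-per-point recovery (to guarantee well
over 200 qualifying cells per stratum), and ten replicates for the
model-class comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import log_loss

from .background import (
    PriorExpectation, sample_uniform_background, sample_weighted_background,
    selection_probabilities, split_presences,
)
from .evaluation import sensitivity_sweep
from .grid import CATEGORICAL, NUMERICAL, FeatureLayer, FeatureStack, GridSpec, build_cell_table
from .models import (
    FeatureBasis, HyperSearchSpace, expand_features, fit_maxent, fit_mlp,
    hyperparameter_search, maxent_objective,
)
from .scaling import (
    average_persons_per_type, persons_per_point, scale_to_counts,
    total_expected_presences,
)
from .synthetic import SuitabilitySpec, WorldConfig, generate_world


def _sub_seed(seed: int, offset: int) -> int:
    return int((seed * 7919 + offset) % (2**31 - 1))


# ---------------------------------------------------------------------------
# background-ratio sensitivity (TPR/FPR trade-off vs AUC insensitivity)
# ---------------------------------------------------------------------------

def ratio_sweep_experiment(seed: int, ratios=(0.5, 4.0, 20.0)) -> pd.DataFrame:
    """Sweep the background ratio on the default world with a fixed split."""
    world = generate_world(WorldConfig(seed=_sub_seed(seed, 1)))
    table = world.cell_table()

    def trainer(Xp, Xb, s):
        return fit_mlp(Xp, Xb, (20,), "relu", max_iter=300, seed=s)

    return sensitivity_sweep(trainer, table, world.presences, "borehole",
                             ratios, seed=_sub_seed(seed, 2))


# ---------------------------------------------------------------------------
# weighted background sampling law (chi-square goodness of fit)
# ---------------------------------------------------------------------------

def weighted_sampling_gof_experiment(seed: int, n_cells: int = 50,
                                     n_zero: int = 10,
                                     n_draws: int = 100_000) -> dict:
    """Empirical selection frequencies vs inverse-expectation probabilities.

    A pool of ``n_cells`` cells (``n_zero`` of them with zero expected
    count, exercising the max-weight rule) is sampled ``n_draws`` times
    with replacement; the frequencies are tested against the
    omega-proportional law with a chi-square goodness-of-fit test.
    """
    rng = np.random.default_rng(_sub_seed(seed, 3))
    grid = GridSpec(5, n_cells // 5)
    stack = FeatureStack(grid, [FeatureLayer("f", NUMERICAL,
                                             rng.normal(size=n_cells))])
    pop = FeatureLayer("population", NUMERICAL, np.ones(n_cells))
    strata = FeatureLayer("stratum", CATEGORICAL, np.ones(n_cells, dtype=int))
    table = build_cell_table(stack, pop, strata)

    np_vals = np.concatenate([rng.uniform(5.0, 100.0, n_cells - n_zero),
                              np.zeros(n_zero)])
    rng.shuffle(np_vals)
    prior = PriorExpectation("bh", pd.Series(np_vals, index=np.arange(n_cells)))
    bg = sample_weighted_background(prior, table, {}, n_draws, 1.0,
                                    seed=_sub_seed(seed, 4), replace=True)
    probs = selection_probabilities(prior.np_per_cell)
    observed = np.bincount(bg.cells, minlength=n_cells).astype(float)
    res = stats.chisquare(observed, probs.to_numpy() * n_draws)
    return {"chi2": float(res.statistic), "p_value": float(res.pvalue),
            "n_draws": n_draws, "n_cells": n_cells}


# ---------------------------------------------------------------------------
# persons-per-point and expected-total recovery
# ---------------------------------------------------------------------------

def recovery_experiment(seed: int, persons_per_point_true: float = 40.0) -> dict:
    """Recover known persons-per-point and per-stratum totals at full detection."""
    types = ("borehole", "piped", "spring")
    pps_true = {t: {"urban": persons_per_point_true,
                    "rural": persons_per_point_true} for t in types}
    world = generate_world(WorldConfig(
        n_rows=80, n_cols=80, seed=_sub_seed(seed, 5), detection_rate=1.0,
        persons_per_point_true=pps_true))
    table = world.cell_table()
    strata = table.df.set_index("cell_id")["stratum"]
    s_cells = persons_per_point(table, world.presences)

    worst_s = worst_y = 0.0
    min_cells = np.inf
    for t in types:
        pps = average_persons_per_type(s_cells, world.presences, t, table)
        totals = total_expected_presences(world.shares, table, pps)
        for j in ("urban", "rural"):
            true_y = float(world.true_counts[t][strata.index[strata == j]].sum())
            worst_s = max(worst_s, abs(pps.s[j] / persons_per_point_true - 1.0))
            worst_y = max(worst_y, abs(totals.y[j] / true_y - 1.0))
            min_cells = min(min_cells, pps.n_cells_used[j])
    return {"worst_s_rel_err": worst_s, "worst_y_rel_err": worst_y,
            "min_qualifying_cells": int(min_cells),
            "persons_per_point_true": persons_per_point_true}


# ---------------------------------------------------------------------------
# count-map conservation
# ---------------------------------------------------------------------------

def conservation_experiment(seed: int) -> dict:
    """Stratum sums of scaled count maps vs estimated totals."""
    world = generate_world(WorldConfig(n_rows=40, n_cols=40,
                                       seed=_sub_seed(seed, 6)))
    table = world.cell_table()
    strata = table.df.set_index("cell_id")["stratum"]
    s_cells = persons_per_point(table, world.presences)
    worst = 0.0
    for t in world.config.access_types:
        pps = average_persons_per_type(s_cells, world.presences, t, table)
        totals = total_expected_presences(world.shares, table, pps)
        train, _ = split_presences(world.presences[t], 0.7,
                                   seed=_sub_seed(seed, 7))
        bg = sample_uniform_background(table, world.presences, train.n, 4.0,
                                       seed=_sub_seed(seed, 8))
        model = fit_mlp(table.features(train.cells), table.features(bg.cells),
                        (10,), "relu", max_iter=200, seed=_sub_seed(seed, 9))
        ps = pd.Series(model.predict_pstar(table.features()),
                       index=table.cell_ids)
        cmap = scale_to_counts(ps, totals, table)
        for j, y_j in totals.y.items():
            got = float(cmap.y[strata == j].sum())
            if y_j > 0:
                worst = max(worst, abs(got - y_j) / y_j)
    return {"max_rel_conservation_err": worst}


# ---------------------------------------------------------------------------
# model-class ordering: tuned MLP vs interaction-blind MaxEnt
# ---------------------------------------------------------------------------

def _maxent_split(table, cells):
    df = table.df.set_index("cell_id")
    num = table.numeric_cols
    cat = [c for c in table.feature_cols if c not in num]
    return (df.loc[np.asarray(cells), num].to_numpy(dtype=float),
            df.loc[np.asarray(cells), cat].to_numpy(dtype=float), num, cat)


def model_ordering_replicate(seed: int) -> tuple[float, float]:
    """One replicate: held-out log loss of the tuned MLP and of MaxEnt.

    The world's true suitability is driven by a product of two layers; the
    MaxEnt basis deliberately excludes the product class, so only the MLP
    can represent the interaction.
    """
    spec = {"well": SuitabilitySpec(products=(("num_0", "num_1", 3.0),))}
    world = generate_world(WorldConfig(
        seed=seed, access_types=("well",), suitability_spec=spec,
        persons_per_point_true={"well": {"urban": 75.0, "rural": 300.0}}))
    table = world.cell_table()
    rng = np.random.default_rng(seed)
    train, test = split_presences(world.presences["well"], 0.7,
                                  int(rng.integers(2**31 - 1)))
    bg = sample_uniform_background(table, world.presences, train.n, 4.0,
                                   int(rng.integers(2**31 - 1)))
    bg_eval = sample_uniform_background(table, world.presences, test.n, 4.0,
                                        int(rng.integers(2**31 - 1)))
    y_eval = np.concatenate([np.ones(test.n), np.zeros(bg_eval.s)])

    Zn_p, Zc_p, num, cat = _maxent_split(table, train.cells)
    Zn_b, Zc_b, _, _ = _maxent_split(table, bg.cells)
    maxent = fit_maxent(Zn_p, Zn_b,
                        FeatureBasis(("linear", "quadratic", "hinge",
                                      "categorical")),
                        presence_categorical=Zc_p, background_categorical=Zc_b,
                        categorical_names=cat, numeric_names=num)
    Zn_e, Zc_e, _, _ = _maxent_split(table, np.concatenate([test.cells,
                                                            bg_eval.cells]))
    loss_maxent = log_loss(y_eval, maxent.predict_pstar(Zn_e, Zc_e),
                           labels=[0, 1])

    space = HyperSearchSpace(
        hidden_layer_sizes=((10,), (20,)), activations=("relu", "tanh"),
        learning_rate_schedules=("constant",), l1_ratios=(0.0,),
        max_iters=(300,), n_trials=4, k_folds=3)
    mlp, _ = hyperparameter_search(
        space, table.features(train.cells), table.features(bg.cells),
        table.features(test.cells), table.features(bg_eval.cells), seed=seed)
    X_eval = np.vstack([table.features(test.cells),
                        table.features(bg_eval.cells)])
    loss_mlp = log_loss(y_eval, mlp.predict_pstar(X_eval), labels=[0, 1])
    return loss_mlp, loss_maxent


def model_ordering_experiment(seed: int, n_replicates: int = 10) -> dict:
    losses = [model_ordering_replicate(_sub_seed(seed, 10 + r))
              for r in range(n_replicates)]
    wins = sum(m <= x for m, x in losses)
    return {"n_replicates": n_replicates, "mlp_wins": wins,
            "mlp_losses": [m for m, _ in losses],
            "maxent_losses": [x for _, x in losses]}


# ---------------------------------------------------------------------------
# MaxEnt 1-D brute-force oracle agreement
# ---------------------------------------------------------------------------

def maxent_oracle_experiment(seed: int) -> dict:
    """Fitted beta vs dense 1-D grid optimum of the same penalized objective."""
    rng = np.random.default_rng(_sub_seed(seed, 20))
    worst = 0.0
    cases = [
        # (presence sample, background sample, lambda scale)
        (np.array([[1.0]] * 80 + [[0.0]] * 20),
         np.array([[1.0]] * 100 + [[0.0]] * 100), 0.0),
        (np.array([[1.0]] * 70 + [[0.0]] * 30),
         np.array([[1.0]] * 100 + [[0.0]] * 100), 0.5),
        (rng.normal(0.8, 1.0, (300, 1)), rng.normal(0.0, 1.0, (400, 1)), 0.2),
    ]
    for pres, bg, lam_scale in cases:
        model = fit_maxent(pres, bg, FeatureBasis(("linear",)),
                           lambda_scale=lam_scale)
        H_p, _ = expand_features(pres, model.basis, model.scaling)
        H_b, _ = expand_features(bg, model.basis, model.scaling)
        grid = np.linspace(-6.0, 6.0, 24001)
        values = [maxent_objective(np.array([b]), H_p, H_b, model.lam)
                  for b in grid]
        worst = max(worst, abs(float(model.beta[0]) - grid[int(np.argmax(values))]))
    return {"max_abs_beta_diff": worst, "n_cases": len(cases)}
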