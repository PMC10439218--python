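"""Presence/background classifiers: MaxEnt and a multi-layer perceptron.

MaxEnt models the feature density at presence cells as the background
density tilted by an exponential family, f1(z) = f(z) exp(alpha + beta'h(z)),
where h(z) stacks basis expansions of the features (linear, quadratic,
product, hinge, threshold and categorical indicator classes). The
coefficients maximize the mean log Gibbs density over presence cells minus
an L1 penalty, with alpha normalizing the Gibbs weights over the background
sample. The raw density is mapped to a relative probability p* in [0, 1] by
a logistic transform calibrated so the background mean equals the assumed
prevalence of 0.5 (the prevalence itself is unidentifiable from
presence-only data).

The MLP route treats presence vs background as binary classification,
minimizing log loss with Adam; its logistic output is read as p* directly.
Hyperparameters are tuned by uniform random search over a fixed grid with
stratified k-fold cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import expit, logsumexp
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

ALL_CLASSES = ("linear", "quadratic", "product", "hinge", "threshold", "categorical")

#: prevalence assumed when mapping relative densities to probabilities
DEFAULT_PREVALENCE = 0.5

#: box bound on each MaxEnt coefficient; binding it signals separability
BETA_CAP = 30.0


@dataclass(frozen=True)
class FeatureBasis:
    """Which basis-function classes MaxEnt may use, and how many knots."""

    classes: tuple[str, ...] = ALL_CLASSES
    hinge_knots: int = 5
    threshold_knots: int = 5

    def __post_init__(self):
        if not self.classes:
            raise ValueError("at least one basis class required")
        unknown = set(self.classes) - set(ALL_CLASSES)
        if unknown:
            raise ValueError(f"unknown basis classes {sorted(unknown)}")
        if "hinge" in self.classes and self.hinge_knots < 1:
            raise ValueError("hinge_knots must be >= 1")
        if "threshold" in self.classes and self.threshold_knots < 1:
            raise ValueError("threshold_knots must be >= 1")


def fit_feature_scaling(background: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature min/max over background cells, used to map features to [0, 1]."""
    background = np.atleast_2d(np.asarray(background, dtype=float))
    return background.min(axis=0), background.max(axis=0)


def _knots(k: int) -> np.ndarray:
    return np.arange(1, k + 1) / (k + 1)


def expand_features(
    z: np.ndarray,
    basis: FeatureBasis,
    scaling: tuple[np.ndarray, np.ndarray],
    names: list[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Apply the enabled basis classes to min-max-scaled numeric features.

    Returns the expanded design matrix and its column names. Scaled values
    far outside the background range (beyond [-0.5, 1.5]) trigger a warning;
    all scaled values are clipped into [0, 1], where the hinge and threshold
    bases are defined.
    """
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    lo, hi = scaling
    span = np.where(hi > lo, hi - lo, 1.0)
    S = (Z - lo) / span
    if np.any((S < -0.5) | (S > 1.5)):
        warnings.warn(
            "features far outside the background range; clipping to [0, 1]",
            stacklevel=2,
        )
    S = np.clip(S, 0.0, 1.0)
    d = S.shape[1]
    if names is None:
        names = [f"z{k}" for k in range(d)]

    cols, col_names = [], []
    if "linear" in basis.classes:
        cols.append(S)
        col_names += [f"lin({n})" for n in names]
    if "quadratic" in basis.classes:
        cols.append(S ** 2)
        col_names += [f"quad({n})" for n in names]
    if "product" in basis.classes:
        for k, l in combinations(range(d), 2):
            cols.append((S[:, k] * S[:, l])[:, None])
            col_names.append(f"prod({names[k]},{names[l]})")
    if "hinge" in basis.classes:
        for t in _knots(basis.hinge_knots):
            cols.append(np.maximum(0.0, S - t) / (1.0 - t))
            col_names += [f"hinge({n},{t:.3g})" for n in names]
    if "threshold" in basis.classes:
        for t in _knots(basis.threshold_knots):
            cols.append((S > t).astype(float))
            col_names += [f"thr({n},{t:.3g})" for n in names]
    if not cols:
        return np.empty((S.shape[0], 0)), []
    return np.hstack(cols), col_names


def _class_of(col_name: str) -> str:
    return {"lin": "linear", "qua": "quadratic", "pro": "product",
            "hin": "hinge", "thr": "threshold", "cat": "categorical"}[col_name[:3]]


#: relative L1 weight per basis class; hinge/threshold penalized more
LAMBDA_MULTIPLIERS = {
    "linear": 1.0, "quadratic": 1.0, "product": 1.0,
    "hinge": 2.0, "threshold": 2.0, "categorical": 1.0,
}


@dataclass
class MaxEntModel:
    basis: FeatureBasis
    scaling: tuple[np.ndarray, np.ndarray]
    beta: np.ndarray
    alpha: float
    lam: np.ndarray
    column_names: list[str]
    kept_columns: np.ndarray  # indices into the full expansion
    numeric_names: list[str]
    calibration_c: float = 1.0
    converged: bool = True

    def design(self, Z_numeric: np.ndarray, Z_cat: np.ndarray | None = None) -> np.ndarray:
        H, _ = expand_features(Z_numeric, self.basis, self.scaling, self.numeric_names)
        if Z_cat is not None and Z_cat.size and "categorical" in self.basis.classes:
            H = np.hstack([H, np.atleast_2d(Z_cat)])
        return H[:, self.kept_columns]

    def raw_density(self, Z_numeric, Z_cat=None) -> np.ndarray:
        """Gibbs density exp(alpha + beta'h(z)), normalized over the training background."""
        return np.exp(self.alpha + self.design(Z_numeric, Z_cat) @ self.beta)

    def predict_pstar(self, Z_numeric, Z_cat=None) -> np.ndarray:
        q = self.raw_density(Z_numeric, Z_cat) * self.calibration_c
        return q / (1.0 + q)

    def to_json(self, path) -> None:
        payload = {
            "format_version": 1, "model": "maxent",
            "basis": {"classes": list(self.basis.classes),
                      "hinge_knots": self.basis.hinge_knots,
                      "threshold_knots": self.basis.threshold_knots},
            "scaling": [self.scaling[0].tolist(), self.scaling[1].tolist()],
            "beta": self.beta.tolist(), "alpha": self.alpha,
            "lambda": self.lam.tolist(),
            "column_names": self.column_names,
            "kept_columns": self.kept_columns.tolist(),
            "numeric_names": self.numeric_names,
            "calibration_c": self.calibration_c, "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MaxEntModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            FeatureBasis(tuple(p["basis"]["classes"]), p["basis"]["hinge_knots"],
                         p["basis"]["threshold_knots"]),
            (np.array(p["scaling"][0]), np.array(p["scaling"][1])),
            np.array(p["beta"]), p["alpha"], np.array(p["lambda"]),
            p["column_names"], np.array(p["kept_columns"], dtype=int),
            p["numeric_names"], p["calibration_c"], p["converged"],
        )


def maxent_objective(beta, H_presence, H_background, lam):
    """Penalized MaxEnt objective (to be maximized).

    mean over presences of beta'h(z) minus log of the background mean of
    exp(beta'h), minus the L1 penalty. The background log-mean term is the
    normalizer alpha with opposite sign, so this equals the mean log Gibbs
    density over presences minus the penalty.
    """
    beta = np.asarray(beta, dtype=float)
    gain = float(H_presence.mean(axis=0) @ beta)
    log_norm = float(logsumexp(H_background @ beta) - np.log(H_background.shape[0]))
    return gain - log_norm - float(np.sum(lam * np.abs(beta)))


def fit_maxent(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    basis: FeatureBasis = FeatureBasis(),
    lambda_scale: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-8,
    presence_categorical: np.ndarray | None = None,
    background_categorical: np.ndarray | None = None,
    categorical_names: list[str] | None = None,
    numeric_names: list[str] | None = None,
) -> MaxEntModel:
    """Fit the L1-penalized exponential tilt of background toward presences.

    The non-smooth L1 term is handled exactly by splitting beta into
    positive and negative parts with box constraints, leaving a smooth
    concave problem solved by L-BFGS-B. A perfectly separating feature with
    no penalty pushes its coefficient to infinity along a flat ridge of the
    objective; coefficients are therefore boxed at +-BETA_CAP and a binding
    cap (or running out of iterations) is reported with a warning instead
    of diverging.
    """
    P = np.atleast_2d(np.asarray(presence_features, dtype=float))
    B = np.atleast_2d(np.asarray(background_features, dtype=float))
    if P.shape[0] < 1 or B.shape[0] < 2:
        raise ValueError("need at least 1 presence and 2 background rows")
    scaling = fit_feature_scaling(B)
    numeric_names = numeric_names or [f"z{k}" for k in range(P.shape[1])]
    H_p, names = expand_features(P, basis, scaling, numeric_names)
    H_b, _ = expand_features(B, basis, scaling, numeric_names)
    if "categorical" in basis.classes and presence_categorical is not None \
            and np.size(presence_categorical):
        Cp = np.atleast_2d(presence_categorical).astype(float)
        Cb = np.atleast_2d(background_categorical).astype(float)
        cat_names = categorical_names or [f"c{k}" for k in range(Cp.shape[1])]
        H_p = np.hstack([H_p, Cp])
        H_b = np.hstack([H_b, Cb])
        names = names + [f"cat({n})" for n in cat_names]

    if not np.all(np.isfinite(H_p)) or not np.all(np.isfinite(H_b)):
        bad = [names[j] for j in range(len(names))
               if not (np.all(np.isfinite(H_p[:, j])) and np.all(np.isfinite(H_b[:, j])))]
        raise ValueError(f"non-finite basis columns: {bad}")

    allH = np.vstack([H_p, H_b])
    keep = np.flatnonzero(allH.std(axis=0) > 0)
    if keep.size < len(names):
        dropped = [names[j] for j in range(len(names)) if j not in set(keep)]
        warnings.warn(f"dropping zero-variance basis columns {dropped}", stacklevel=2)
    H_p, H_b = H_p[:, keep], H_b[:, keep]
    kept_names = [names[j] for j in keep]
    lam = lambda_scale * np.array([LAMBDA_MULTIPLIERS[_class_of(n)] for n in kept_names])
    # classic MaxEnt shrinks the penalty as presence information grows
    lam = lam / np.sqrt(max(P.shape[0], 1))

    h_bar = H_p.mean(axis=0)
    nb = H_b.shape[0]

    def negative(theta):
        u, v = theta[: keep.size], theta[keep.size:]
        beta = u - v
        eta = H_b @ beta
        log_norm = logsumexp(eta) - np.log(nb)
        value = -(h_bar @ beta - log_norm) + lam @ (u + v)
        w = np.exp(eta - logsumexp(eta))
        grad_beta = h_bar - w @ H_b
        return value, np.concatenate([-grad_beta + lam, grad_beta + lam])

    theta0 = np.zeros(2 * keep.size)
    res = minimize(
        negative, theta0, jac=True, method="L-BFGS-B",
        bounds=[(0, BETA_CAP)] * theta0.size,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    # on a flat ridge (separating feature, no penalty) the optimizer can
    # report success at an arbitrarily large coefficient; treat any
    # coefficient beyond half the cap as a separability stop
    capped = bool(np.any(res.x > BETA_CAP / 2))
    converged = bool(res.success) and not capped
    if not converged:
        warnings.warn(
            "MaxEnt optimisation stopped before convergence (possibly a "
            "perfectly separating feature with no regularisation)", stacklevel=2
        )
    beta = res.x[: keep.size] - res.x[keep.size:]
    alpha = float(np.log(nb) - logsumexp(H_b @ beta))

    model = MaxEntModel(basis, scaling, beta, alpha, lam, kept_names, keep,
                        numeric_names, converged=converged)
    # calibrate the logistic transform so the background mean of p* is the
    # assumed prevalence
    q_b = np.exp(alpha + H_b @ beta)
    model.calibration_c = _calibrate(q_b, DEFAULT_PREVALENCE)
    return model


def _calibrate(q: np.ndarray, target: float) -> float:
    def gap(log_c):
        qc = q * np.exp(log_c)
        return float(np.mean(qc / (1.0 + qc)) - target)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:  # degenerate densities; fall back to c=1
        return 1.0
    return float(np.exp(brentq(gap, lo, hi, xtol=1e-12)))


def predict_maxent(model: MaxEntModel, table, access_type: str = "",
                   model_id: str = "maxent"):
    """Relative-probability map over all masked cells of a cell table."""
    Zn = table.df[model.numeric_names].to_numpy(dtype=float)
    cat_cols = [n[4:-1] for n in model.column_names if n.startswith("cat(")]
    Zc = table.df[cat_cols].to_numpy(dtype=float) if cat_cols else None
    ps = model.predict_pstar(Zn, Zc)
    return SuitabilityMap(access_type, pd.Series(ps, index=table.cell_ids), model_id)


@dataclass
class SuitabilityMap:
    """Per-cell relative probability of presence, in [0, 1]."""

    access_type: str
    p_star: pd.Series
    model_id: str = ""

    def __post_init__(self):
        vals = self.p_star.to_numpy(dtype=float)
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise ValueError("relative probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# multi-layer perceptron
# ---------------------------------------------------------------------------

_ACTIVATIONS = {
    "identity": lambda x: x,
    "logistic": expit,
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
}


@dataclass
class MLPModel:
    """A fitted perceptron: standardization constants plus layer weights.

    Prediction runs the forward pass directly on the stored weights, so a
    model round-trips losslessly through JSON. The output unit is logistic
    and its value is read as the relative probability p*.
    """

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    layer_sizes: tuple[int, ...]
    activation: str
    training_meta: dict = field(default_factory=dict)

    def predict_pstar(self, X: np.ndarray) -> np.ndarray:
        act = _ACTIVATIONS[self.activation]
        h = (np.atleast_2d(np.asarray(X, dtype=float)) - self.scaler_mean) / self.scaler_scale
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = act(h @ W + b)
        return expit(h @ self.coefs[-1] + self.intercepts[-1]).ravel()

    def to_json(self, path) -> None:
        payload = {
            "format_version": 1, "model": "mlp",
            "layer_sizes": list(self.layer_sizes), "activation": self.activation,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "coefs": [w.tolist() for w in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "training_meta": self.training_meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            np.array(p["scaler_mean"]), np.array(p["scaler_scale"]),
            [np.array(w) for w in p["coefs"]],
            [np.array(b) for b in p["intercepts"]],
            tuple(p["layer_sizes"]), p["activation"], p["training_meta"],
        )


def fit_mlp(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    layer_sizes: tuple[int, ...] = (50,),
    activation: str = "relu",
    learning_rate_schedule: str = "constant",
    l1_ratio: float = 0.0,
    max_iter: int = 500,
    seed: int = 0,
    alpha: float = 1e-4,
) -> MLPModel:
    """Train the binary presence/background classifier by log loss with Adam.

    Inputs are standardized on the training rows. sklearn's MLP exposes an
    L2 weight-decay term only; the ``l1_ratio`` hyperparameter scales it
    down (1.0 disables decay). Non-convergence returns the model with a
    warning and the final loss recorded in ``training_meta``.
    """
    P = np.atleast_2d(np.asarray(presence_features, dtype=float))
    B = np.atleast_2d(np.asarray(background_features, dtype=float))
    if P.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 rows per class")
    X = np.vstack([P, B])
    y = np.concatenate([np.ones(P.shape[0]), np.zeros(B.shape[0])])
    scaler = StandardScaler().fit(X)
    net = MLPClassifier(
        hidden_layer_sizes=tuple(layer_sizes), activation=activation,
        solver="adam", learning_rate=learning_rate_schedule,
        alpha=alpha * (1.0 - l1_ratio), max_iter=max_iter, random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        net.fit(scaler.transform(X), y)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if not converged:
        warnings.warn(
            f"MLP did not converge in {max_iter} iterations "
            f"(final loss {net.loss_:.4g})", stacklevel=2
        )
    meta = {"seed": seed, "iterations": int(net.n_iter_),
            "final_loss": float(net.loss_), "converged": converged}
    return MLPModel(
        scaler.mean_.copy(), scaler.scale_.copy(),
        [w.copy() for w in net.coefs_], [b.copy() for b in net.intercepts_],
        tuple(layer_sizes), activation, meta,
    )


# Table-8-style hyperparameter grid
DEFAULT_HIDDEN_SIZES = tuple(
    [(k,) for k in (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)]
    + [(k, k) for k in (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)]
)


@dataclass
class HyperSearchSpace:
    hidden_layer_sizes: tuple = DEFAULT_HIDDEN_SIZES
    activations: tuple = ("identity", "logistic", "tanh", "relu")
    learning_rate_schedules: tuple = ("constant", "invscaling", "adaptive")
    l1_ratios: tuple = (0.0, 1.0)
    max_iters: tuple = (500, 1000, 2500)
    n_trials: int = 200
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("hidden_layer_sizes", "activations",
                     "learning_rate_schedules", "l1_ratios", "max_iters"):
            if not getattr(self, name):
                raise ValueError(f"empty candidate set {name}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "layer_sizes": self.hidden_layer_sizes[rng.integers(len(self.hidden_layer_sizes))],
            "activation": self.activations[rng.integers(len(self.activations))],
            "learning_rate_schedule":
                self.learning_rate_schedules[rng.integers(len(self.learning_rate_schedules))],
            "l1_ratio": self.l1_ratios[rng.integers(len(self.l1_ratios))],
            "max_iter": self.max_iters[rng.integers(len(self.max_iters))],
        }


def hyperparameter_search(
    space: HyperSearchSpace,
    presence_features: np.ndarray,
    background_features: np.ndarray,
    eval_presence: np.ndarray,
    eval_background: np.ndarray,
    seed: int,
) -> tuple[MLPModel, pd.DataFrame]:
    """Uniform random search with stratified k-fold cross-validation.

    Configurations are sampled uniformly from the grid and scored by mean
    validation log loss across folds; the first trial attaining the minimal
    mean wins. Among the winner's fold models, the one with the lowest log
    loss on the held-aside evaluation partition is returned. The report
    records every (trial, fold) loss.
    """
    P = np.atleast_2d(presence_features)
    B = np.atleast_2d(background_features)
    X = np.vstack([P, B])
    y = np.concatenate([np.ones(P.shape[0]), np.zeros(B.shape[0])])
    if min(P.shape[0], B.shape[0]) < space.k_folds:
        raise ValueError("not enough rows per class for stratified k-fold splitting")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(space.k_folds, shuffle=True,
                          random_state=int(rng.integers(2**31 - 1)))
    folds = list(skf.split(X, y))

    rows, best = [], None
    for trial in range(space.n_trials):
        params = space.sample(rng)
        fit_seed = int(rng.integers(2**31 - 1))
        fold_models, fold_losses = [], []
        for fold_id, (tr, va) in enumerate(folds):
            m = fit_mlp(X[tr][y[tr] == 1], X[tr][y[tr] == 0], seed=fit_seed,
                        **params)
            loss = log_loss(y[va], m.predict_pstar(X[va]), labels=[0, 1])
            fold_models.append(m)
            fold_losses.append(loss)
            rows.append({"trial": trial, "fold": fold_id, "val_log_loss": loss,
                         **{k: str(v) for k, v in params.items()}})
        mean_loss = float(np.mean(fold_losses))
        if best is None or mean_loss < best[0]:
            best = (mean_loss, trial, params, fold_models)

    X_eval = np.vstack([np.atleast_2d(eval_presence), np.atleast_2d(eval_background)])
    y_eval = np.concatenate([
        np.ones(np.atleast_2d(eval_presence).shape[0]),
        np.zeros(np.atleast_2d(eval_background).shape[0]),
    ])
    eval_losses = [log_loss(y_eval, m.predict_pstar(X_eval), labels=[0, 1])
                   for m in best[3]]
    winner = best[3][int(np.argmin(eval_losses))]
    winner.training_meta.update({
        "cv_mean_loss": best[0], "trial": best[1],
        "eval_loss": float(min(eval_losses)),
        "params": {k: str(v) for k, v in best[2].items()},
    })
    return winner, pd.DataFrame(rows)


def permutation_importance(
    score_fn,
    X: np.ndarray,
    y: np.ndarray,
    groups: dict[str, list[int]] | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Relative contribution of each feature to the log loss.

    For each feature (all one-hot columns of a categorical shuffled
    jointly) the rows of its columns are permuted and the mean increase in
    log loss over ``n_repeats`` shuffles is divided by the unpermuted loss.
    ``score_fn`` maps a feature matrix to predicted probabilities; a fitted
    model with ``predict_pstar`` is also accepted.
    """
    if hasattr(score_fn, "predict_pstar"):
        score_fn = score_fn.predict_pstar
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if groups is None:
        groups = {f"z{j}": [j] for j in range(X.shape[1])}
    base = log_loss(y, score_fn(X), labels=[0, 1])
    rng = np.random.default_rng(seed)
    increases = {}
    for name in sorted(groups):
        cols = groups[name]
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            perm = rng.permutation(X.shape[0])
            Xp[:, cols] = X[perm][:, cols]
            deltas.append(log_loss(y, score_fn(Xp), labels=[0, 1]) - base)
        increases[name] = float(np.mean(deltas))
    out = pd.Series(increases)
    if base <= 1e-12:
        warnings.warn("zero total loss; returning unnormalized contributions",
                      stacklevel=2)
        return out
    return out / base
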