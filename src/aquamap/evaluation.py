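"""Threshold-based evaluation and the background-ratio sensitivity sweep.

Models are scored by the true positive rate (share of held-out presence
cells whose relative probability strictly exceeds a threshold theta,
default 0.3) and the false positive rate (same share among background
cells). Because background cells may contain undetected presences, the
best attainable FPR is typically above zero. AUC is reported for
comparison only: it is invariant to monotone rescaling of the scores and
to the presence/background ratio, which is exactly why it can hide the
trade-off that TPR/FPR expose when the number of background points is
varied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .background import (
    sample_uniform_background, split_presences,
)

DEFAULT_THETA = 0.3
DEFAULT_RATIOS = (0.5, 2.0, 4.0, 8.0, 20.0)


def tpr(scores_on_test_presences, theta: float = DEFAULT_THETA) -> float:
    """Fraction of presence scores strictly greater than theta."""
    scores = np.asarray(scores_on_test_presences, dtype=float)
    if scores.size == 0:
        raise ValueError("empty presence score list")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    return float(np.mean(scores > theta))


def fpr(scores_on_background, theta: float = DEFAULT_THETA) -> float:
    """Fraction of background scores strictly greater than theta."""
    scores = np.asarray(scores_on_background, dtype=float)
    if scores.size == 0:
        raise ValueError("empty background score list")
    return float(np.mean(scores > theta))


def auc(presence_scores, background_scores) -> float:
    """Probability a random presence outscores a random background cell, ties 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


@dataclass
class EvalReport:
    access_type: str
    model_id: str
    theta: float
    tpr: float
    fpr: float
    auc: float
    n: int  # test presence count
    s: int  # evaluation background count
    background_scheme: str = "uniform"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def evaluate_scores(
    presence_scores, background_scores,
    theta: float = DEFAULT_THETA,
    access_type: str = "", model_id: str = "",
    background_scheme: str = "uniform",
) -> EvalReport:
    return EvalReport(
        access_type, model_id, theta,
        tpr(presence_scores, theta), fpr(background_scores, theta),
        auc(presence_scores, background_scores),
        n=len(presence_scores), s=len(background_scores),
        background_scheme=background_scheme,
    )


def sensitivity_sweep(
    trainer,
    table,
    presences: dict,
    access_type: str,
    ratios=DEFAULT_RATIOS,
    theta: float = DEFAULT_THETA,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-train and re-evaluate the model across background ratios.

    The presence train/test split is fixed across ratios; for each ratio a
    fresh training background is drawn, the model re-trained via
    ``trainer(presence_features, background_features, seed)`` and scored on
    the fixed test presences against a freshly drawn evaluation background
    of the same ratio. Returns one row (ratio, tpr, fpr, auc, n, s) per
    ratio.
    """
    p = presences[access_type]
    if p.n < 2:
        raise ValueError(f"access type {access_type!r} has too few presences")
    rng = np.random.default_rng(seed)
    split_seed = int(rng.integers(2**31 - 1))
    train, test = split_presences(p, train_fraction, split_seed)
    X_test = table.features(test.cells)

    rows = []
    for ratio in ratios:
        bg_train = sample_uniform_background(
            table, presences, train.n, ratio, seed=int(rng.integers(2**31 - 1)),
            access_type=access_type,
        )
        model = trainer(
            table.features(train.cells), table.features(bg_train.cells),
            int(rng.integers(2**31 - 1)),
        )
        bg_eval = sample_uniform_background(
            table, presences, test.n, ratio, seed=int(rng.integers(2**31 - 1)),
            access_type=access_type,
        )
        sp = model.predict_pstar(X_test)
        sb = model.predict_pstar(table.features(bg_eval.cells))
        rows.append({
            "ratio": ratio, "tpr": tpr(sp, theta), "fpr": fpr(sb, theta),
            "auc": auc(sp, sb), "n": test.n, "s": bg_eval.s,
        })
    return pd.DataFrame(rows)
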