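"""The supervised core: scaling, shadow-feature selection, tuning,
gradient-boosted training, and Shapley attribution.

All statistics that touch the data — scaler ranges, feature selection,
hyper-parameter choices — are computed on training rows only; nothing
from a test split enters any fit.  Models are trained per outer fold and
never merged or refit on combined folds; Shapley attributions of the
outer test folds are combined by concatenation.

Attributions use the exact tree-path Shapley implementation built into
XGBoost (``pred_contribs``), which satisfies local accuracy: per row,
attributions plus the base value equal the model's margin prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import binom

from .config import HyperParamBounds
from .evaluate import average_precision

_BASE_PARAMS = {
    "objective": "binary:logistic",
    "tree_method": "hist",
    "verbosity": 0,
}


@dataclass
class UnitScaler:
    """Per-feature min/max scaling to the unit interval.

    ``x' = (x - min) / (max - min)`` with statistics from the fit rows
    only.  Constant columns map to 0; transformed values of unseen rows
    may fall outside [0, 1] — no clipping.
    """

    mins: pd.Series
    ranges: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "UnitScaler":
        if len(X) == 0:
            raise ValueError("cannot fit a scaler on zero rows")
        mins = X.min(axis=0)
        ranges = X.max(axis=0) - mins
        return cls(mins=mins, ranges=ranges)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = self.mins.index
        out = X[cols].sub(self.mins, axis=1)
        nonconst = self.ranges != 0
        out.loc[:, nonconst] = out.loc[:, nonconst].div(self.ranges[nonconst], axis=1)
        out.loc[:, ~nonconst] = 0.0
        return out


def scale_unit_interval(
    X: pd.DataFrame, fit_rows: pd.Index
) -> tuple[UnitScaler, pd.DataFrame]:
    """Fit on ``fit_rows`` only, transform the whole matrix."""
    scaler = UnitScaler.fit(X.loc[fit_rows])
    return scaler, scaler.transform(X)


@dataclass
class ModelBundle:
    """One outer fold's fitted pipeline state."""

    booster: xgb.Booster
    scaler: UnitScaler | None
    selected_features: list[str]
    params: dict
    outer_fold: int = -1
    seed: int = 0
    best_iteration: int = 0
    early_stop_rounds: int = 0


@dataclass
class ShapMatrix:
    """Per-row, per-feature Shapley attributions for one model."""

    values: pd.DataFrame  # rows x features
    base_values: np.ndarray  # one per row (identical for one model)
    fold: int = -1


@dataclass
class BorutaResult:
    confirmed: list[str]
    tentative: list[str]
    rejected: list[str]
    hits: pd.Series
    n_rounds: int

    def selected(self, keep_tentative: bool = True) -> list[str]:
        sel = list(self.confirmed)
        if keep_tentative:
            sel += self.tentative
        return sel


def _dmatrix(X: pd.DataFrame, y: np.ndarray | None = None) -> xgb.DMatrix:
    return xgb.DMatrix(X.to_numpy(dtype=np.float32), label=y, feature_names=list(X.columns))


def _ap_metric(preds: np.ndarray, dtrain: xgb.DMatrix) -> tuple[str, float]:
    y = dtrain.get_label()
    if y.sum() == 0:
        return "ap", 0.0
    return "ap", average_precision(preds, y)


def train_model(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    params: dict,
    X_val: pd.DataFrame | None = None,
    y_val: np.ndarray | None = None,
    early_stop_rounds: int = 50,
    num_boost_round: int | None = None,
    seed: int = 0,
    outer_fold: int = -1,
    scaler: UnitScaler | None = None,
) -> ModelBundle:
    """Train one boosted ensemble with early stopping on validation AP.

    Boosting stops when the validation average precision fails to
    improve for ``early_stop_rounds`` rounds; the bundle records the
    stopping round.  Single-class training labels are an error.
    """
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")
    full = dict(_BASE_PARAMS)
    full.update({k: v for k, v in params.items() if k != "n_rounds"})
    full["seed"] = seed
    rounds = num_boost_round or int(params.get("n_rounds", 500))
    dtrain = _dmatrix(X_train, y_train)
    evals = [(dtrain, "train")]
    callbacks = []
    if X_val is not None and y_val is not None and np.asarray(y_val).sum() > 0:
        dval = _dmatrix(X_val, np.asarray(y_val))
        evals.append((dval, "val"))
        callbacks.append(
            xgb.callback.EarlyStopping(
                rounds=early_stop_rounds,
                metric_name="ap",
                data_name="val",
                maximize=True,
                save_best=True,
            )
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        booster = xgb.train(
            full,
            dtrain,
            num_boost_round=rounds,
            evals=evals,
            custom_metric=_ap_metric,
            callbacks=callbacks,
            verbose_eval=False,
        )
    best_it = getattr(booster, "best_iteration", None)
    if best_it is None:
        best_it = rounds - 1
    return ModelBundle(
        booster=booster,
        scaler=scaler,
        selected_features=list(X_train.columns),
        params=dict(params),
        outer_fold=outer_fold,
        seed=seed,
        best_iteration=int(best_it),
        early_stop_rounds=early_stop_rounds,
    )


def predict_scores(bundle: ModelBundle, X: pd.DataFrame) -> np.ndarray:
    """Probability scores in (0, 1); row order preserved.

    ``X`` may carry extra columns; only the bundle's selected features
    are used.  A missing selected feature is an error naming it.
    """
    missing = [c for c in bundle.selected_features if c not in X.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    if len(X) == 0:
        return np.empty(0)
    return bundle.booster.predict(_dmatrix(X[bundle.selected_features]))


def shap_attributions(bundle: ModelBundle, X: pd.DataFrame) -> ShapMatrix:
    """Exact tree Shapley attributions per row and feature."""
    missing = [c for c in bundle.selected_features if c not in X.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    contribs = bundle.booster.predict(
        _dmatrix(X[bundle.selected_features]), pred_contribs=True
    )
    values = pd.DataFrame(
        contribs[:, :-1], index=X.index, columns=bundle.selected_features
    )
    return ShapMatrix(values=values, base_values=contribs[:, -1], fold=bundle.outer_fold)


def concat_shap(matrices: list[ShapMatrix]) -> ShapMatrix:
    """Combine per-fold attributions by concatenation (rows stacked)."""
    cols = set(matrices[0].values.columns)
    for m in matrices[1:]:
        if set(m.values.columns) != cols:
            raise ValueError("attribution matrices have differing feature sets")
    return ShapMatrix(
        values=pd.concat([m.values for m in matrices], axis=0),
        base_values=np.concatenate([m.base_values for m in matrices]),
        fold=-1,
    )


def rank_features_by_mean_abs_shap(
    matrices: list[ShapMatrix] | ShapMatrix,
) -> pd.Series:
    """Features ranked by mean |attribution| over all concatenated rows.

    Descending; ties broken by feature name for a stable ordering.
    """
    if isinstance(matrices, list):
        matrices = concat_shap(matrices)
    means = matrices.values.abs().mean(axis=0)
    order = sorted(means.index, key=lambda c: (-means[c], c))
    return means.loc[order]


def boruta_select(
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    n_rounds: int = 20,
    alpha_sel: float = 0.05,
    params: dict | None = None,
    num_boost_round: int = 80,
) -> BorutaResult:
    """Shadow-feature selection with Shapley importances.

    Each round appends a permuted shadow copy of every feature, trains a
    preliminary ensemble, and scores a *hit* for every real feature
    whose mean |attribution| beats the best shadow's.  After
    ``n_rounds``, hit counts above the upper binomial(0.5) bound at
    ``alpha_sel`` are confirmed, below the lower bound rejected, the
    remainder tentative.
    """
    if n_rounds < 5:
        raise ValueError("n_rounds must be >= 5 for the binomial test to mean anything")
    y = np.asarray(y)
    prelim = dict(params or {"max_depth": 4, "learning_rate": 0.1})
    prelim.setdefault("scale_pos_weight", float((y == 0).sum() / max((y == 1).sum(), 1)))
    rng = np.random.default_rng(seed)
    hits = pd.Series(0, index=X.columns, dtype=int)
    for r in range(n_rounds):
        shadow = X.apply(lambda col: rng.permutation(col.to_numpy()))
        shadow.columns = [f"shadow__{c}" for c in X.columns]
        Xr = pd.concat([X.reset_index(drop=True), shadow.reset_index(drop=True)], axis=1)
        full = dict(_BASE_PARAMS)
        full.update(prelim)
        full["seed"] = seed * 613 + r
        dtrain = _dmatrix(Xr, y)
        booster = xgb.train(full, dtrain, num_boost_round=num_boost_round)
        contribs = booster.predict(dtrain, pred_contribs=True)[:, :-1]
        importance = pd.Series(np.abs(contribs).mean(axis=0), index=Xr.columns)
        shadow_max = importance[[c for c in Xr.columns if c.startswith("shadow__")]].max()
        hits += (importance[X.columns] > shadow_max).astype(int)
    upper = binom.ppf(1 - alpha_sel, n_rounds, 0.5)
    lower = binom.ppf(alpha_sel, n_rounds, 0.5)
    confirmed = [c for c in X.columns if hits[c] > upper]
    rejected = [c for c in X.columns if hits[c] < lower]
    tentative = [c for c in X.columns if c not in confirmed and c not in rejected]
    return BorutaResult(
        confirmed=confirmed,
        tentative=tentative,
        rejected=rejected,
        hits=hits,
        n_rounds=n_rounds,
    )


def sample_hyperparams(
    rng: np.random.Generator, bounds: HyperParamBounds, n_pos: int, n_neg: int
) -> dict:
    """Draw one candidate from the declared search space."""

    def log_u(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    w_lo, w_hi = bounds.resolved_pos_weight(n_pos, n_neg)
    return {
        "max_depth": int(rng.integers(bounds.max_depth[0], bounds.max_depth[1] + 1)),
        "learning_rate": log_u(*bounds.learning_rate),
        "min_child_weight": log_u(*bounds.min_child_weight),
        "subsample": float(rng.uniform(*bounds.subsample)),
        "colsample_bytree": float(rng.uniform(*bounds.colsample_bytree)),
        "reg_alpha": log_u(*bounds.reg_alpha),
        "reg_lambda": log_u(*bounds.reg_lambda),
        "scale_pos_weight": log_u(max(w_lo, 1e-6), max(w_hi, w_lo + 1e-6)),
        "n_rounds": int(rng.integers(100, bounds.n_rounds_max + 1)),
    }


def tune_hyperparams(
    X: pd.DataFrame,
    y: np.ndarray,
    inner_assign: pd.Series,
    budget: int = 25,
    seed: int = 0,
    bounds: HyperParamBounds | None = None,
    early_stop_rounds: int = 30,
    max_rounds_cap: int = 400,
) -> tuple[dict, pd.DataFrame]:
    """Random search maximizing mean average precision over inner folds.

    Each candidate is trained on every inner training split with early
    stopping on the inner validation split and scored by validation AP;
    the argmax of the across-fold mean wins.  Deterministic under
    ``seed``.  Returns the winning parameters and the search trace.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    bounds = bounds or HyperParamBounds()
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    folds = sorted(inner_assign.unique())
    trace_rows = []
    best_params, best_map = None, -np.inf
    for c in range(budget):
        cand = sample_hyperparams(rng, bounds, n_pos, n_neg)
        cand["n_rounds"] = min(cand["n_rounds"], max_rounds_cap)
        aps = []
        for f in folds:
            val_rows = inner_assign.index[inner_assign == f]
            tr_rows = inner_assign.index[inner_assign != f]
            y_tr = y[X.index.get_indexer(tr_rows)]
            y_va = y[X.index.get_indexer(val_rows)]
            if y_va.sum() == 0 or len(np.unique(y_tr)) < 2:
                continue
            bundle = train_model(
                X.loc[tr_rows],
                y_tr,
                cand,
                X_val=X.loc[val_rows],
                y_val=y_va,
                early_stop_rounds=early_stop_rounds,
                seed=seed,
            )
            aps.append(average_precision(predict_scores(bundle, X.loc[val_rows]), y_va))
        mean_ap = float(np.mean(aps)) if aps else -np.inf
        trace_rows.append({**cand, "mean_inner_ap": mean_ap, "candidate": c})
        if mean_ap > best_map:
            best_map, best_params = mean_ap, cand
    assert best_params is not None
    return best_params, pd.DataFrame(trace_rows)
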