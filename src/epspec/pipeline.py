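"""End-to-end orchestration of the EP-specificity analysis.

Two training profiles are provided:

* ``run_nested_cv`` — the full protocol: per outer fold, unit-interval
  scaling, optional shadow-feature (Boruta) selection, random-search
  hyper-parameter tuning on the inner folds maximizing mean average
  precision, training with early stopping, out-of-fold prediction, and
  Shapley attribution concatenated across folds.
* ``run_fast_holdout`` — a reduced profile used for repeated
  parameter-recovery experiments: chromosome holdout, fixed mid-range
  hyper-parameters, a group-aware validation split for early stopping,
  no selection or tuning.  Orders of magnitude cheaper while exercising
  the same leakage-safe structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import blocking, features, learner, synth, tfclusters
from .config import HyperParamBounds, PipelineConfig
from .dataio import ContactMap, ElementTable
from .evaluate import average_precision
from .learner import ModelBundle, ShapMatrix
from .synth import SimConfig, SimTruth

FAST_PARAMS = {
    "max_depth": 6,
    "learning_rate": 0.08,
    "min_child_weight": 2.0,
    "subsample": 0.9,
    "colsample_bytree": 0.8,
    "n_rounds": 400,
}


@dataclass
class SimData:
    """One simulated study: genome, assays, candidates, outcomes."""

    elements: ElementTable
    contacts: ContactMap
    tf_presence: pd.DataFrame
    ep: pd.DataFrame  # candidates + hic_contact + adj_p/effect_direction/label
    truth: SimTruth
    config: SimConfig


def simulate_dataset(
    sim_config: SimConfig | None = None, window_bp: int | None = None
) -> SimData:
    """Generate a full synthetic study under one seed."""
    cfg = sim_config or SimConfig()
    if window_bp is not None:
        cfg.window_bp = window_bp
    elements, elem_truth = synth.simulate_elements(cfg)
    contacts = synth.simulate_contacts(elements, cfg)
    ep = features.ep_candidates(elements, window_bp=cfg.window_bp)
    ep = features.attach_contact(ep, contacts)
    presence, tf_truth = synth.simulate_tf_presence(elements, cfg)
    ep, truth = synth.simulate_labels(ep, elements, presence, tf_truth, elem_truth, cfg)
    return SimData(
        elements=elements,
        contacts=contacts,
        tf_presence=presence,
        ep=ep,
        truth=truth,
        config=cfg,
    )


def build_feature_matrix(
    ep: pd.DataFrame,
    elements: ElementTable,
    contacts: ContactMap,
    tf_presence: pd.DataFrame | None = None,
    peak_tables: dict[str, pd.DataFrame] | None = None,
    config: PipelineConfig | None = None,
    with_nmf: bool = True,
    nmf_seed: int = 0,
) -> features.FeatureMatrix:
    """Assemble every enabled feature family for a candidate table."""
    cfg = config or PipelineConfig()
    if "hic_contact" not in ep.columns:
        ep = features.attach_contact(ep, contacts)
    fams: dict[str, pd.DataFrame] = {}
    fams["distance"] = ep[["distance"]].astype(float)
    fams["contact"] = ep[["hic_contact"]]
    fams["abc"] = features.abc_score(ep, elements).to_frame()
    fams["relative"] = pd.concat(
        [features.contact_relative_features(ep), features.remaining_contact_sums(ep)],
        axis=1,
    )
    fams["density"] = features.density_counts(ep, elements, window_bp=cfg.window_bp)
    sig = features.signal_features(ep, elements)
    hist_cols = [c for c in sig.columns if "H3K" in c]
    dhs_cols = [c for c in sig.columns if c.startswith("DHS")]
    expr_cols = [c for c in sig.columns if c == "TargetGeneExpression"]
    if hist_cols:
        fams["histone"] = sig[hist_cols]
    if dhs_cols:
        fams["accessibility"] = sig[dhs_cols]
    if expr_cols:
        fams["expression"] = sig[expr_cols]
    if tf_presence is not None:
        fams["tf"] = features.tf_presence_from_matrix(ep, tf_presence)
    elif peak_tables is not None:
        fams["tf"] = features.tf_presence(
            ep, peak_tables, elements, tss_flank_bp=cfg.tss_flank_bp
        )
    if with_nmf and tf_presence is not None:
        nmf_cols = []
        for side in ("enhancer", "tss"):
            ids = elements.of_kind(side)["element_id"]
            side_matrix = tf_presence.loc[tf_presence.index.isin(ids)]
            k = min(cfg.nmf_k, min(side_matrix.shape))
            fit = tfclusters.nmf_fit(side_matrix, k=k, side=side, seed=nmf_seed)
            nmf_cols.append(tfclusters.nmf_features(fit, ep))
        fams["nmf"] = pd.concat(nmf_cols, axis=1)
    return features.assemble_features(ep, fams)


@dataclass
class CVResult:
    """Outputs of the full nested-CV protocol."""

    bundles: list[ModelBundle]
    fold_ap: dict[int, float]
    oof_scores: pd.Series
    shap: ShapMatrix
    plan: blocking.FoldPlan
    selection: dict[int, list[str]] = field(default_factory=dict)


def _validation_split(
    rows: pd.Index, groups: pd.Series, labels: pd.Series, k: int, seed: int
) -> tuple[pd.Index, pd.Index]:
    """Group-aware (train, val) split of a training set: one packed fold.

    When the training set holds fewer blocking groups than folds (tiny
    genomes), falls back to a seeded stratified row split — the split
    only steers early stopping, never evaluation.
    """
    g = groups.loc[rows]
    y_all = labels.loc[rows]
    k_eff = min(k, int(g.nunique()))
    if k_eff >= 2:
        rng = np.random.default_rng(seed)
        uniq = np.array(sorted(g.unique()))
        pos = y_all.groupby(g).sum().astype(int).to_dict()
        size = g.value_counts().to_dict()
        assign = blocking._pack_groups(uniq, pos, size, k_eff, rng)
        fold = g.map(assign)
        val = fold.index[fold == 0]
        train = fold.index[fold != 0]
        return train, val
    rng = np.random.default_rng(seed)
    y = labels.loc[rows]
    val_parts = []
    for cls in (0, 1):
        cls_rows = rows[(y == cls).to_numpy()]
        n_val = max(1, len(cls_rows) // k) if len(cls_rows) else 0
        if n_val:
            val_parts.append(
                pd.Index(rng.choice(cls_rows, size=n_val, replace=False))
            )
    val = val_parts[0].append(val_parts[1:]) if val_parts else rows[:0]
    train = rows.difference(val)
    return train, val


def run_fast_holdout(
    fm: features.FeatureMatrix,
    labels: pd.Series,
    ep: pd.DataFrame,
    elements: ElementTable,
    config: PipelineConfig | None = None,
    seed: int = 0,
    params: dict | None = None,
) -> dict:
    """Reduced profile: chromosome holdout, fixed params, one model.

    Scaling and the early-stopping validation split use non-holdout rows
    only; returns held-out scores, AP, and the mean-|SHAP| ranking on
    the held-out rows.
    """
    cfg = config or PipelineConfig()
    train_idx, test_idx = blocking.chromosome_holdout(ep, cfg.holdout_chroms)
    if len(test_idx) == 0 or labels.loc[test_idx].sum() == 0:
        raise ValueError("holdout set is empty or has no positives")
    elem_groups = blocking.assign_element_groups(elements, cfg.gap_bp)
    groups = blocking.assign_ep_groups(ep, elem_groups)
    X = fm.matrix()
    scaler, Xs = learner.scale_unit_interval(X, train_idx)
    tr, val = _validation_split(train_idx, groups, labels, 4, seed)
    p = dict(params or FAST_PARAMS)
    n_pos = int(labels.loc[train_idx].sum())
    n_neg = len(train_idx) - n_pos
    p.setdefault("scale_pos_weight", float(np.sqrt(n_neg / max(n_pos, 1))))
    bundle = learner.train_model(
        Xs.loc[tr],
        labels.loc[tr].to_numpy(),
        p,
        X_val=Xs.loc[val],
        y_val=labels.loc[val].to_numpy(),
        early_stop_rounds=40,
        seed=seed,
        scaler=scaler,
    )
    scores = learner.predict_scores(bundle, Xs.loc[test_idx])
    ap = average_precision(scores, labels.loc[test_idx].to_numpy())
    shap = learner.shap_attributions(bundle, Xs.loc[test_idx])
    ranking = learner.rank_features_by_mean_abs_shap(shap)
    return {
        "bundle": bundle,
        "test_idx": test_idx,
        "train_idx": train_idx,
        "scores": pd.Series(scores, index=test_idx),
        "ap": ap,
        "shap": shap,
        "ranking": ranking,
    }


def run_nested_cv(
    fm: features.FeatureMatrix,
    labels: pd.Series,
    ep: pd.DataFrame,
    elements: ElementTable,
    config: PipelineConfig | None = None,
    seed: int = 0,
    do_boruta: bool = True,
    boruta_rounds: int = 12,
    tune_budget: int = 10,
    bounds: HyperParamBounds | None = None,
) -> CVResult:
    """Full nested blocked CV on the non-holdout data.

    Every data-dependent step (scaler, selection, tuning) sees only the
    outer training split; the four per-fold models are evaluated
    separately and never refit on combined folds.
    """
    cfg = config or PipelineConfig()
    elem_groups = blocking.assign_element_groups(elements, cfg.gap_bp)
    groups = blocking.assign_ep_groups(ep, elem_groups)
    plan = blocking.nested_group_kfold(
        ep, groups, labels, outer_k=cfg.outer_folds, inner_k=cfg.inner_folds, seed=seed
    )
    X = fm.matrix()
    bundles, shaps = [], []
    fold_ap: dict[int, float] = {}
    selection: dict[int, list[str]] = {}
    oof = pd.Series(np.nan, index=ep.index)
    for f in range(cfg.outer_folds):
        test_rows = plan.outer.index[plan.outer == f]
        train_rows = plan.outer.index[plan.outer != f]
        scaler, Xs = learner.scale_unit_interval(X, train_rows)
        y_tr = labels.loc[train_rows].to_numpy()
        cols = list(X.columns)
        if do_boruta:
            sel = learner.boruta_select(
                Xs.loc[train_rows], y_tr, seed=seed * 97 + f, n_rounds=boruta_rounds
            )
            cols = sel.selected(keep_tentative=True)
            if not cols:
                cols = list(X.columns)
        selection[f] = cols
        inner = plan.inner[f]
        params, _trace = learner.tune_hyperparams(
            Xs.loc[train_rows, cols],
            y_tr,
            inner,
            budget=tune_budget,
            seed=seed * 31 + f,
            bounds=bounds,
        )
        val_rows = inner.index[inner == 0]
        fit_rows = inner.index[inner != 0]
        bundle = learner.train_model(
            Xs.loc[fit_rows, cols],
            labels.loc[fit_rows].to_numpy(),
            params,
            X_val=Xs.loc[val_rows, cols],
            y_val=labels.loc[val_rows].to_numpy(),
            early_stop_rounds=40,
            seed=seed,
            outer_fold=f,
            scaler=scaler,
        )
        bundles.append(bundle)
        scores = learner.predict_scores(bundle, Xs.loc[test_rows, cols])
        oof.loc[test_rows] = scores
        if labels.loc[test_rows].sum() > 0:
            fold_ap[f] = average_precision(scores, labels.loc[test_rows].to_numpy())
        shaps.append(learner.shap_attributions(bundle, Xs.loc[test_rows, cols]))
    common = set.intersection(*(set(s.values.columns) for s in shaps))
    aligned = [
        ShapMatrix(s.values[sorted(common)], s.base_values, s.fold) for s in shaps
    ]
    return CVResult(
        bundles=bundles,
        fold_ap=fold_ap,
        oof_scores=oof,
        shap=learner.concat_shap(aligned),
        plan=plan,
        selection=selection,
    )


def labeled_view(
    fm: features.FeatureMatrix, ep: pd.DataFrame, alpha_label: float = 0.1
) -> tuple[pd.DataFrame, pd.Series, features.FeatureMatrix]:
    """Label outcomes and restrict the feature matrix to labeled rows.

    Rows with missing adjusted p-values drop out of the labeled set.
    """
    ep_l = features.label_positives(ep, alpha_label)
    fm_l = features.FeatureMatrix(
        df=fm.df.loc[ep_l.index], provenance=dict(fm.provenance)
    )
    return ep_l, ep_l["label"], fm_l


def recovered_causal_groups(
    ranking: pd.Series, groups: dict[str, list[str]], top_n: int = 8
) -> dict[str, bool]:
    """Which planted causal terms have a proxy column in the top ranks."""
    top = set(ranking.index[:top_n])
    return {name: bool(top & set(cols)) for name, cols in groups.items()}
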