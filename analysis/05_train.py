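#!/usr/bin/env python
"""Train the gradient-boosted EP classifier.

Default profile: chromosome-holdout training with fixed mid-range
hyper-parameters (fast; used for repeated experiments).  With --full,
runs the complete nested blocked CV — per-fold scaling, Boruta shadow
selection, random-search tuning on the inner folds maximizing mean
average precision — and reports per-fold test AP separately, never
refitting on combined folds.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from epspec import dataio, pipeline
from epspec.config import PipelineConfig


def load_inputs(outdir: Path):
    elements = dataio.read_elements(outdir / "elements.tsv")
    ep = dataio.read_ep_table(outdir / "ep.tsv")
    fm_df = dataio.read_table(outdir / "feature_matrix.tsv")
    prov = dataio.read_table(outdir / "provenance.tsv")
    from epspec.features import FeatureMatrix

    fm = FeatureMatrix(
        df=fm_df, provenance=dict(zip(prov["column"], prov["family"]))
    )
    return elements, ep, fm


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--full", action="store_true", help="nested CV with selection + tuning")
    ap.add_argument("--tune-budget", type=int, default=5)
    args = ap.parse_args()

    elements, ep_all, fm = load_inputs(args.outdir)
    cfg = PipelineConfig(
        holdout_chroms=("chr5",), outer_folds=4, inner_folds=2, seed=args.seed
    )
    ep, labels, fm = pipeline.labeled_view(fm, ep_all)

    metrics = {}
    if args.full:
        from epspec import blocking

        train_idx, _ = blocking.chromosome_holdout(ep, cfg.holdout_chroms)
        res = pipeline.run_nested_cv(
            fm.__class__(fm.df.loc[train_idx], dict(fm.provenance)),
            labels.loc[train_idx],
            ep.loc[train_idx],
            elements,
            cfg,
            seed=args.seed,
            do_boruta=True,
            boruta_rounds=10,
            tune_budget=args.tune_budget,
        )
        dataio.write_table(
            res.oof_scores.rename("score").reset_index(), args.outdir / "oof_scores.tsv"
        )
        dataio.write_table(
            res.shap.values.reset_index(drop=True), args.outdir / "shap_cv.tsv"
        )
        metrics["outer_fold_test_ap"] = {str(k): round(v, 4) for k, v in res.fold_ap.items()}
        metrics["selected_features_per_fold"] = {
            str(k): len(v) for k, v in res.selection.items()
        }
        print("outer-fold test AP:", metrics["outer_fold_test_ap"])
    else:
        res = pipeline.run_fast_holdout(fm, labels, ep, elements, cfg, seed=args.seed)
        dataio.write_table(
            res["scores"].rename("score").reset_index(), args.outdir / "holdout_scores.tsv"
        )
        dataio.write_table(
            res["ranking"].rename("mean_abs_shap").rename_axis("feature").reset_index(),
            args.outdir / "shap_ranking.tsv",
        )
        metrics["holdout_ap"] = round(res["ap"], 4)
        metrics["best_iteration"] = res["bundle"].best_iteration
        print(f"held-out AP {metrics['holdout_ap']} (chr5, {len(res['test_idx'])} pairs)")
    (args.outdir / "train_manifest.json").write_text(json.dumps(metrics, indent=2))


if __name__ == "__main__":
    main()
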