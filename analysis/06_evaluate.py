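#!/usr/bin/env python
"""Imbalance-aware evaluation of the trained model against baselines.

Compares the classifier with the ABC score and inverse genomic distance
at matched recall (0.70), writes the PR curves, the confusion matrix at
the matched-recall threshold, density-stratified error proportions, and
the weak/strong contact partition of the positives.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from epspec import dataio, evaluate, pipeline
from epspec.config import PipelineConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    ep_all = dataio.read_ep_table(args.outdir / "ep.tsv")
    fm_df = dataio.read_table(args.outdir / "feature_matrix.tsv")
    scores_tab = dataio.read_table(args.outdir / "holdout_scores.tsv")
    cfg = PipelineConfig(holdout_chroms=("chr5",))

    from epspec import features

    ep = features.label_positives(ep_all)
    test_idx = scores_tab["index"].to_numpy()
    ep_test = ep.loc[test_idx]
    y = ep_test["label"].to_numpy()
    fm_test = fm_df.loc[test_idx]
    ep_test = ep_test.assign(abc_score=fm_test["abc_score"].to_numpy())

    models = {
        "xgb": scores_tab["score"].to_numpy(),
        "abc": evaluate.baseline_scores(ep_test, "abc"),
        "inverse_distance": evaluate.baseline_scores(ep_test, "inverse_distance"),
    }
    report_rows, pr_frames, confusion_rows = [], [], []
    for name, s in models.items():
        ap_val = evaluate.average_precision(s, y)
        t = evaluate.threshold_at_recall(s, y, cfg.recall_target)
        counts, rates = evaluate.confusion_and_rates(y, scores=s, threshold=t)
        report_rows.append(
            {
                "model": name,
                "average_precision": ap_val,
                "threshold_at_recall_070": t,
                **{k: (np.nan if v is None else v) for k, v in rates.items()},
            }
        )
        confusion_rows.append(
            {"model": name, "tn": counts.tn, "fp": counts.fp, "fn": counts.fn, "tp": counts.tp}
        )
        pr_frames.append(evaluate.pr_curve(s, y).assign(model=name))

    dataio.write_table(pd.DataFrame(report_rows), args.outdir / "eval_report.tsv")
    dataio.write_table(pd.DataFrame(confusion_rows), args.outdir / "confusion.tsv")
    dataio.write_table(pd.concat(pr_frames), args.outdir / "pr_points.tsv")

    # density-stratified errors for the classifier at matched recall
    density = (
        fm_test["Enhancer.count.near.TSS"] + fm_test["TSS.count.near.enhancer"]
    ).to_numpy()
    t = report_rows[0]["threshold_at_recall_070"]
    preds = (models["xgb"] >= t).astype(int)
    edges = np.quantile(density, [0, 0.25, 0.5, 0.75, 1.0])
    dens = evaluate.density_stratified_errors(density, preds, y, np.unique(edges))
    dataio.write_table(dens, args.outdir / "density_bins.tsv")

    part = evaluate.contact_partition_metrics(
        ep_test["hic_contact"].to_numpy(), y, cfg.weak_contact_threshold, models["xgb"]
    )
    dataio.write_table(part, args.outdir / "contact_partition.tsv")

    for r in report_rows:
        print(
            f"{r['model']}: AP {r['average_precision']:.3f}, "
            f"FPR at recall 0.70 = {r['false_positive_rate']:.3f}"
        )


if __name__ == "__main__":
    main()
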