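#!/usr/bin/env python
"""Blocked data splitting: chromosome holdout, groups, nested folds.

Groups are single-linkage clusters of elements separated by >= 5 Mb,
merged across pair endpoints; the synthetic genome's five chromosomes
support four outer folds but only two inner folds per outer training
split (real genomes, with ~23 chromosomes, support the full 4x4).
"""

import argparse
from pathlib import Path

import pandas as pd

from epspec import blocking, dataio, features
from epspec.config import PipelineConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    elements = dataio.read_elements(args.outdir / "elements.tsv")
    ep = features.label_positives(dataio.read_ep_table(args.outdir / "ep.tsv"))
    cfg = PipelineConfig(
        holdout_chroms=("chr5",), outer_folds=4, inner_folds=2, seed=args.seed
    )

    train_idx, test_idx = blocking.chromosome_holdout(ep, cfg.holdout_chroms)
    elem_groups = blocking.assign_element_groups(elements, cfg.gap_bp)
    groups = blocking.assign_ep_groups(ep.loc[train_idx], elem_groups)
    plan = blocking.nested_group_kfold(
        ep.loc[train_idx],
        groups,
        ep.loc[train_idx, "label"],
        outer_k=cfg.outer_folds,
        inner_k=cfg.inner_folds,
        seed=args.seed,
    )
    assert blocking.check_no_leakage(ep.loc[train_idx], elements, plan.outer, cfg.gap_bp)

    out = ep[["enhancer_id", "tss_id", "chrom", "label"]].copy()
    out["split"] = "holdout"
    out.loc[train_idx, "split"] = "cv"
    out["group"] = groups.reindex(out.index)
    out["outer_fold"] = plan.outer.reindex(out.index)
    for f, inner in plan.inner.items():
        out[f"inner_of_outer{f}"] = inner.reindex(out.index)
    dataio.write_table(out, args.outdir / "foldplan.tsv")
    pos = blocking.fold_positive_counts(plan.outer, ep["label"], cfg.outer_folds)
    print(
        f"holdout {len(test_idx)} pairs; cv {len(train_idx)} pairs in "
        f"{groups.nunique()} groups; positives per outer fold: {list(pos)} "
        f"(leakage check passed)"
    )


if __name__ == "__main__":
    main()
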