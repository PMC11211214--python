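#!/usr/bin/env python
"""Report the model's most important features and TF co-binding clusters.

Prints the top features by mean |SHAP| from the held-out attribution
ranking and the top TF members of the leading NMF co-binding clusters
per side, mirroring how the learned model is interrogated for biology.
"""

import argparse
from pathlib import Path

import pandas as pd

from epspec import dataio, tfclusters


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--top", type=int, default=32)
    args = ap.parse_args()

    ranking = dataio.read_table(args.outdir / "shap_ranking.tsv")
    top = ranking.head(args.top)
    dataio.write_table(top, args.outdir / "top_features.tsv")
    print(f"top {min(args.top, len(ranking))} features by mean |SHAP|:")
    for _, row in top.head(12).iterrows():
        print(f"  {row['feature']}: {row['mean_abs_shap']:.4f}")

    elements = dataio.read_elements(args.outdir / "elements.tsv")
    presence = pd.read_csv(
        args.outdir / "tf_presence.tsv", sep="\t", index_col="element_id"
    )
    member_rows = []
    for side in ("enhancer", "tss"):
        ids = elements.of_kind(side)["element_id"]
        fit = tfclusters.nmf_fit(
            presence.loc[presence.index.isin(ids)], k=12, side=side, seed=args.seed
        )
        for ci in (1, 2, 3):
            members = tfclusters.cluster_members(fit, ci, top_n=5)
            for tf, w in members.items():
                member_rows.append(
                    {"side": side, "cluster": f"NMF{ci}", "tf": tf, "membership": w}
                )
    dataio.write_table(pd.DataFrame(member_rows), args.outdir / "nmf_members.tsv")
    print("wrote NMF cluster memberships (top 3 clusters per side)")


if __name__ == "__main__":
    main()
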