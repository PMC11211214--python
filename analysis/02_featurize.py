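#!/usr/bin/env python
"""Assemble the EP feature matrix from the simulated study's files.

Reads the outputs of 01_simulate.py back through the dataio readers
(exercising the on-disk round trip) and writes the assembled feature
matrix plus a column -> family provenance table.
"""

import argparse
from pathlib import Path

import pandas as pd

from epspec import dataio, pipeline
from epspec.config import PipelineConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    elements = dataio.read_elements(args.outdir / "elements.tsv")
    contacts = dataio.read_contacts(args.outdir / "contacts.bedpe")
    ep = dataio.read_ep_table(args.outdir / "ep.tsv")
    presence = pd.read_csv(
        args.outdir / "tf_presence.tsv", sep="\t", index_col="element_id"
    )

    cfg = PipelineConfig(holdout_chroms=("chr5",), seed=args.seed)
    fm = pipeline.build_feature_matrix(
        ep, elements, contacts, tf_presence=presence, config=cfg, nmf_seed=args.seed
    )
    dataio.write_table(fm.df, args.outdir / "feature_matrix.tsv")
    prov = pd.DataFrame(
        {"column": list(fm.provenance), "family": list(fm.provenance.values())}
    )
    dataio.write_table(prov, args.outdir / "provenance.tsv")
    fams = fm.families()
    print(f"{len(fm.feature_columns)} feature columns across {len(fams)} families:")
    for fam, cols in fams.items():
        print(f"  {fam}: {len(cols)}")


if __name__ == "__main__":
    main()
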