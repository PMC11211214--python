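"""Independent brute-force oracles used to check the production code.

Everything here is deliberately naive — explicit loops, no grouping or
vectorization — and stays independent of the implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def naive_feature_table(elements, cmap, window_bp: int) -> pd.DataFrame:
    """All-pairs loop reimplementation of candidate pairing and the
    contact/relative/remaining/density/ABC feature families."""
    half = window_bp // 2
    df = elements.df
    enh = df[df["kind"] == "enhancer"]
    tss = df[df["kind"] == "tss"]
    rows = []
    for _, t in tss.iterrows():
        for _, e in enh.iterrows():
            if e["chrom"] != t["chrom"]:
                continue
            mid_e = (e["start"] + e["end"]) // 2
            d = abs(mid_e - t["start"])
            if d <= half:
                rows.append(
                    {
                        "enhancer_id": e["element_id"],
                        "tss_id": t["element_id"],
                        "chrom": t["chrom"],
                        "enh_mid": mid_e,
                        "tss_pos": t["start"],
                        "distance": d,
                    }
                )
    tab = pd.DataFrame(rows)
    if tab.empty:
        return tab
    tab = tab.sort_values(["chrom", "tss_id", "enhancer_id"], kind="stable").reset_index(
        drop=True
    )
    contacts = []
    for _, r in tab.iterrows():
        contacts.append(
            cmap.lookup(
                r["chrom"], r["enh_mid"] // cmap.bin_size, r["tss_pos"] // cmap.bin_size
            )
        )
    tab["hic_contact"] = contacts

    # ABC: activity = sqrt(H3K27ac * DHS) if DHS present
    acts = {}
    for _, e in df.iterrows():
        a = e["H3K27ac"]
        if "DHS" in df.columns:
            a = np.sqrt(a * e["DHS"])
        acts[e["element_id"]] = a
    abc = []
    for i, r in tab.iterrows():
        denom = 0.0
        for j, r2 in tab.iterrows():
            if r2["tss_id"] == r["tss_id"]:
                denom += acts[r2["enhancer_id"]] * r2["hic_contact"]
        num = acts[r["enhancer_id"]] * r["hic_contact"]
        abc.append(num / denom if denom > 0 else 0.0)
    tab["abc_score"] = abc

    for i, r in tab.iterrows():
        to_tss = [
            r2["hic_contact"] for _, r2 in tab.iterrows() if r2["tss_id"] == r["tss_id"]
        ]
        from_enh = [
            r2["hic_contact"]
            for _, r2 in tab.iterrows()
            if r2["enhancer_id"] == r["enhancer_id"]
        ]
        c = r["hic_contact"]
        tab.loc[i, "max.contact.to.TSS"] = max(to_tss)
        tab.loc[i, "diff.from.max.contact.to.TSS"] = max(to_tss) - c
        tab.loc[i, "contact.rank.to.TSS"] = 1 + len(
            {v for v in to_tss if v > c}
        )  # dense rank, ties share the better rank
        tab.loc[i, "max.contact.from.enhancer"] = max(from_enh)
        tab.loc[i, "diff.from.max.contact.from.enhancer"] = max(from_enh) - c
        tab.loc[i, "contact.rank.from.enhancer"] = 1 + len({v for v in from_enh if v > c})
        tab.loc[i, "remaining.enhancers.contact.to.TSS"] = sum(to_tss) - c
        tab.loc[i, "remaining.TSS.contact.from.enhancer"] = sum(from_enh) - c
        n_enh_near = 0
        for _, e in enh.iterrows():
            if e["chrom"] == r["chrom"]:
                mid = (e["start"] + e["end"]) // 2
                if abs(mid - r["tss_pos"]) <= half:
                    n_enh_near += 1
        n_tss_near = 0
        for _, t in tss.iterrows():
            if t["chrom"] == r["chrom"] and abs(t["start"] - r["enh_mid"]) <= half:
                n_tss_near += 1
        tab.loc[i, "Enhancer.count.near.TSS"] = n_enh_near
        tab.loc[i, "TSS.count.near.enhancer"] = n_tss_near
    return tab


def enumerate_path_label(
    graph, kinds: dict, promoter: str, enhancer: str, bin_e: int, bin_p: int
) -> str:
    """EP class by exhaustive simple-path enumeration.

    Considers every simple path from the promoter to the enhancer whose
    intermediate nodes are all enhancer-kind, takes the minimum length,
    and maps 1/2/3 to e1/e2/e3, anything longer or no path to einf; a
    shared bin is e0 regardless.
    """
    if bin_e == bin_p:
        return "e0"
    nodes = list(graph.nodes)
    # only lengths 1..3 map to named classes; anything longer is einf,
    # so enumerating 0..2 intermediates is exhaustive for the label
    for n_inter in range(0, 3):
        for inter in itertools.permutations(
            [n for n in nodes if n not in (promoter, enhancer)], n_inter
        ):
            if any(kinds[n] != "enhancer" for n in inter):
                continue
            path = [promoter, *inter, enhancer]
            if all(graph.has_edge(a, b) for a, b in zip(path, path[1:])):
                return f"e{len(path) - 1}"
    return "einf"


def brute_average_precision(scores, labels) -> float:
    """AP straight from the definition, quadratic time."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    precisions = []
    tp = 0
    for rank, i in enumerate(order, start=1):
        if labels[i] == 1:
            tp += 1
            precisions.append(tp / rank)
    return float(np.mean(precisions))
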