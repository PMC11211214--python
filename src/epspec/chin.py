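"""Promoter-centric Chromatin Interaction Networks (ChINs).

A ChIN is built per promoter: nodes are the promoter and the enhancers
tested in the perturbation screen, and an edge connects two nodes when
their contact-map bin pair carries a *significant* chromatin loop.  Edge
weights are the KR-normalized contact values.

Each EP pair is then labeled by enhancer-mediated graph distance:

* ``e0``  — enhancer and promoter share a contact bin (takes precedence
  over any graph distance);
* ``e1``  — directly connected by a significant loop;
* ``e2``/``e3`` — connected through one/two *enhancer* intermediates
  (other promoters never serve as intermediates);
* ``einf`` — more than three edges apart or not in the promoter's ChIN.

Loop significance normally comes from an external caller's q-value
table; a built-in distance-stratified top-quantile rule is provided only
so the pipeline can run self-contained, and is flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import ContactMap, ElementTable

EP_CLASSES = ("e0", "e1", "e2", "e3", "einf")
E1MINUS = frozenset({"e0", "e1"})
E2PLUS = frozenset({"e2", "e3", "einf"})


@dataclass
class ChIN:
    """One promoter's chromatin interaction network."""

    promoter_id: str
    graph: nx.Graph  # node attr "kind"; edge attr "weight" (> 0)

    def __post_init__(self) -> None:
        for u, v, w in self.graph.edges(data="weight"):
            if w is None or w <= 0:
                raise ValueError(f"non-positive edge weight on ({u}, {v})")


def call_significant_edges(
    contacts: ContactMap,
    significance_table: pd.DataFrame | None = None,
    q_threshold: float = 0.05,
    n_distance_bins: int = 8,
) -> set[tuple[str, int, int]]:
    """Select significant loop bin pairs.

    External mode (``significance_table`` with columns chrom, bin_i,
    bin_j, q): keep pairs with q < ``q_threshold``.  Built-in fallback:
    bin pairs are stratified into log-spaced genomic-distance bins and
    the top ``q_threshold`` fraction by contact within each stratum is
    kept (a stand-in for a proper loop caller, for self-contained runs).
    """
    if not 0 < q_threshold <= 1:
        raise ValueError(f"q_threshold must lie in (0, 1], got {q_threshold}")
    if significance_table is not None:
        keep = significance_table[significance_table["q"] < q_threshold]
        return {
            (str(c), min(int(i), int(j)), max(int(i), int(j)))
            for c, i, j in zip(keep["chrom"], keep["bin_i"], keep["bin_j"])
        }
    if len(contacts) == 0:
        return set()
    keys = list(contacts.entries.keys())
    values = np.array([contacts.entries[k] for k in keys])
    dist = np.array([k[2] - k[1] for k in keys], dtype=float)
    # log-spaced distance strata (in bins); distance 0 gets its own stratum
    with np.errstate(divide="ignore"):
        logd = np.where(dist > 0, np.log10(dist), -1.0)
    finite = logd[logd >= 0]
    if len(finite) and finite.max() > finite.min():
        edges = np.linspace(finite.min(), finite.max() + 1e-9, n_distance_bins + 1)
        strata = np.where(logd < 0, -1, np.digitize(logd, edges) - 1)
    else:
        strata = np.where(logd < 0, -1, 0)
    significant: set[tuple[str, int, int]] = set()
    order = np.arange(len(keys))
    for s in np.unique(strata):
        sel = order[strata == s]
        k_keep = int(np.floor(q_threshold * len(sel) + 1e-9))
        if k_keep == 0:
            continue
        # strongest contacts win; ties broken by canonical key order
        ranked = sorted(sel, key=lambda i: (-values[i], keys[i]))
        for i in ranked[:k_keep]:
            significant.add(keys[i])
    return significant


def build_chin(
    edges: set[tuple[str, int, int]],
    elements: ElementTable,
    promoter_id: str,
    tested_enhancer_ids: list[str] | pd.Index,
    bin_size: int = 5_000,
) -> ChIN:
    """Restrict the loop graph to one promoter and its tested enhancers.

    Nodes: the promoter plus every tested enhancer (isolated ones
    remain).  An edge connects two nodes when their midpoint-bin pair is
    in the significant set; its weight is irrelevant for labeling but
    kept as 1-weight placeholder when no contact value is attached.
    """
    elem = elements.df.set_index("element_id")
    if promoter_id not in elem.index:
        raise KeyError(f"unknown promoter_id {promoter_id!r}")
    node_ids = [promoter_id] + [e for e in tested_enhancer_ids if e != promoter_id]
    missing = [e for e in node_ids if e not in elem.index]
    if missing:
        raise KeyError(f"elements absent from element table: {missing}")
    g = nx.Graph()
    bins: dict[str, tuple[str, int]] = {}
    for nid in node_ids:
        row = elem.loc[nid]
        mid = int((row["start"] + row["end"]) // 2)
        bins[nid] = (row["chrom"], mid // bin_size)
        g.add_node(nid, kind=row["kind"], bin=mid // bin_size, chrom=row["chrom"])
    for i, a in enumerate(node_ids):
        ca, ba = bins[a]
        for b in node_ids[i + 1 :]:
            cb, bb = bins[b]
            if ca != cb:
                continue
            key = (ca, min(ba, bb), max(ba, bb))
            if key in edges:
                g.add_edge(a, b, weight=1.0)
    return ChIN(promoter_id=promoter_id, graph=g)


def attach_edge_weights(chin: ChIN, contacts: ContactMap) -> None:
    """Set edge weights to the KR-normalized contact of the bin pair."""
    g = chin.graph
    for u, v in g.edges:
        cu, bu = g.nodes[u]["chrom"], g.nodes[u]["bin"]
        bv = g.nodes[v]["bin"]
        w = contacts.lookup(cu, bu, bv)
        if w > 0:
            g[u][v]["weight"] = w


def label_ep_distance(
    chin: ChIN, enhancer_id: str, bin_of_enhancer: int, bin_of_promoter: int
) -> str:
    """Class of one EP pair by enhancer-mediated graph distance.

    The bin test (``e0``) precedes the graph test.  The search from the
    promoter may only pass *through* enhancer nodes; reaching the target
    enhancer at depth 1, 2, 3 gives ``e1``, ``e2``, ``e3``; anything
    farther, or an enhancer outside the ChIN's connectivity, is ``einf``.
    """
    g = chin.graph
    if enhancer_id not in g:
        raise KeyError(f"enhancer {enhancer_id!r} is not a node of this ChIN")
    if bin_of_enhancer == bin_of_promoter:
        return "e0"
    dist = {chin.promoter_id: 0}
    frontier = [chin.promoter_id]
    for depth in (1, 2, 3):
        nxt = []
        for node in frontier:
            # only the source promoter and enhancer nodes may be expanded
            if node != chin.promoter_id and g.nodes[node]["kind"] != "enhancer":
                continue
            for nb in g.neighbors(node):
                if nb not in dist:
                    dist[nb] = depth
                    nxt.append(nb)
        if enhancer_id in dist:
            return f"e{dist[enhancer_id]}"
        frontier = nxt
        if not frontier:
            break
    return "einf"


def label_ep_table(
    ep: pd.DataFrame,
    elements: ElementTable,
    edges: set[tuple[str, int, int]],
    bin_size: int = 5_000,
) -> pd.Series:
    """Label every EP row of a table; tested enhancers per promoter are
    the candidate enhancers appearing with that promoter in ``ep``."""
    labels = pd.Series(index=ep.index, dtype=object, name="ep_class")
    for tss_id, sub in ep.groupby("tss_id", sort=True):
        tested = sorted(sub["enhancer_id"].unique())
        chin = build_chin(edges, elements, str(tss_id), tested, bin_size=bin_size)
        bin_p = chin.graph.nodes[tss_id]["bin"]
        for idx, enh in zip(sub.index, sub["enhancer_id"]):
            bin_e = chin.graph.nodes[enh]["bin"]
            labels.loc[idx] = label_ep_distance(chin, enh, bin_e, bin_p)
    return labels


def partition_by_class(labels: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split EPs into direct-contact (e1minus: e0, e1) and indirect
    (e2plus: e2, e3, einf) classes — disjoint and exhaustive."""
    unknown = set(labels.unique()) - set(EP_CLASSES)
    if unknown:
        raise ValueError(f"unknown EP class labels: {sorted(unknown)}")
    e1minus = labels.index[labels.isin(E1MINUS)]
    e2plus = labels.index[labels.isin(E2PLUS)]
    return e1minus, e2plus
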