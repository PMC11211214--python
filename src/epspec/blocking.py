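"""Genomically blocked data splitting.

Proximal examples leak label information across standard CV folds (they
share enhancers, promoters, and local chromatin context).  This module
prevents that by (1) setting whole chromosomes aside as an untouched
test set, and (2) clustering the remaining elements into *groups*
separated by at least ``gap_bp`` (5 Mb by default) of genomic gap and
assigning groups whole to folds of a nested (outer x inner) scheme.

Fold assignment is a deterministic greedy bin-packing that balances
positive counts first and total counts second (seeded shuffle for
ties) — a dependency-free stand-in for a stratified group splitter with
the same guarantees: groups never span folds, stratification is
approximate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ElementTable


@dataclass
class FoldPlan:
    """Nested fold memberships.

    ``outer`` maps every (non-holdout) EP row to an outer fold id in
    ``0..outer_k-1``.  ``inner[f]`` maps every EP row *outside* outer
    fold ``f`` to an inner fold id, defined on that outer training
    split.  All EPs of one blocking group share every assignment.
    """

    outer: pd.Series
    inner: dict[int, pd.Series] = field(default_factory=dict)
    outer_k: int = 4
    inner_k: int = 4


def assign_element_groups(elements: ElementTable, gap_bp: int = 5_000_000) -> pd.Series:
    """Single-linkage clustering of elements along each chromosome.

    Walking elements in midpoint order, a new group starts whenever the
    gap to the previous element is at least ``gap_bp``; different
    chromosomes never share a group.
    """
    if gap_bp <= 0:
        raise ValueError(f"gap_bp must be positive, got {gap_bp}")
    df = elements.sorted().df
    mids = ((df["start"] + df["end"]) // 2).to_numpy()
    chroms = df["chrom"].to_numpy()
    group = np.zeros(len(df), dtype=int)
    gid = -1
    prev_chrom, prev_mid = None, None
    for i in range(len(df)):
        if chroms[i] != prev_chrom or mids[i] - prev_mid >= gap_bp:
            gid += 1
        group[i] = gid
        prev_chrom, prev_mid = chroms[i], mids[i]
    return pd.Series(group, index=df["element_id"].to_numpy(), name="group")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def assign_ep_groups(ep: pd.DataFrame, element_groups: pd.Series) -> pd.Series:
    """Group id per EP: the (transitively merged) group of its endpoints.

    When a pair bridges two element groups the groups are merged, so the
    >= gap separation guarantee between *distinct* final groups is
    preserved — merged groups are connected by a real pair.
    """
    n_groups = int(element_groups.max()) + 1 if len(element_groups) else 0
    uf = _UnionFind(n_groups)
    ge = element_groups.reindex(ep["enhancer_id"]).to_numpy()
    gt = element_groups.reindex(ep["tss_id"]).to_numpy()
    if np.isnan(ge).any() or np.isnan(gt).any():
        raise KeyError("EP endpoint missing from element group assignment")
    for a, b in zip(ge.astype(int), gt.astype(int)):
        if a != b:
            uf.union(a, b)
    merged = np.array([uf.find(int(a)) for a in ge])
    # relabel to consecutive ids for stability
    uniq = {g: i for i, g in enumerate(sorted(set(merged)))}
    return pd.Series([uniq[g] for g in merged], index=ep.index, name="group")


def chromosome_holdout(
    ep: pd.DataFrame, holdout_chroms: tuple[str, ...]
) -> tuple[pd.Index, pd.Index]:
    """Exhaustive train/test split by the TSS chromosome of each pair.

    Pairs are intra-chromosomal, so the TSS chromosome decides; stated
    explicitly for determinism.
    """
    holdout = set(holdout_chroms)
    is_test = ep["chrom"].isin(holdout)
    return ep.index[~is_test], ep.index[is_test]


def _pack_groups(
    group_ids: np.ndarray,
    pos_per_group: dict[int, int],
    size_per_group: dict[int, int],
    k: int,
    rng: np.random.Generator,
) -> dict[int, int]:
    """Greedy balanced bin-packing: positives first, then totals."""
    tie = {g: rng.random() for g in group_ids}
    order = sorted(
        group_ids, key=lambda g: (-pos_per_group[g], -size_per_group[g], tie[g])
    )
    fold_pos = [0] * k
    fold_tot = [0] * k
    assignment = {}
    for g in order:
        f = min(range(k), key=lambda i: (fold_pos[i], fold_tot[i], i))
        assignment[g] = f
        fold_pos[f] += pos_per_group[g]
        fold_tot[f] += size_per_group[g]
    if min(fold_pos) == 0 and sum(fold_pos) > 0:
        warnings.warn(
            "degenerate stratification: at least one fold received no positives",
            stacklevel=3,
        )
    return assignment


def nested_group_kfold(
    ep: pd.DataFrame,
    groups: pd.Series,
    labels: pd.Series,
    outer_k: int = 4,
    inner_k: int = 4,
    seed: int = 0,
) -> FoldPlan:
    """Nested blocked K-folds: groups assigned whole, label-stratified.

    Outer folds partition all rows; within each outer *training* split
    (all rows not in that fold) the same packing yields inner folds.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    uniq = np.array(sorted(groups.unique()))
    if len(uniq) < max(outer_k, inner_k):
        raise ValueError(
            f"{len(uniq)} groups are fewer than the requested folds "
            f"({outer_k} outer / {inner_k} inner)"
        )
    pos = labels.groupby(groups).sum().astype(int).to_dict()
    size = groups.value_counts().to_dict()
    outer_assign = _pack_groups(uniq, pos, size, outer_k, rng)
    outer = groups.map(outer_assign).rename("outer")
    inner: dict[int, pd.Series] = {}
    for f in range(outer_k):
        train_rows = outer.index[outer != f]
        g_train = groups.loc[train_rows]
        uniq_in = np.array(sorted(g_train.unique()))
        if len(uniq_in) < inner_k:
            raise ValueError(
                f"outer training split {f} has {len(uniq_in)} groups < inner_k={inner_k}"
            )
        pos_in = labels.loc[train_rows].groupby(g_train).sum().astype(int).to_dict()
        size_in = g_train.value_counts().to_dict()
        inner_rng = np.random.default_rng(seed * 1009 + f + 1)
        inner_assign = _pack_groups(uniq_in, pos_in, size_in, inner_k, inner_rng)
        inner[f] = g_train.map(inner_assign).rename(f"inner_of_outer{f}")
    return FoldPlan(outer=outer, inner=inner, outer_k=outer_k, inner_k=inner_k)


def check_no_leakage(
    ep: pd.DataFrame,
    elements: ElementTable,
    outer: pd.Series,
    gap_bp: int = 5_000_000,
) -> bool:
    """Assert the blocking guarantee on an outer fold assignment.

    For any two EPs in different outer folds, every pair of their
    elements on the same chromosome must be separated by >= ``gap_bp``.
    Equivalently: no genomic window narrower than ``gap_bp`` contains
    elements used by EPs of two different folds.
    """
    elem = elements.df.set_index("element_id")
    incidences: list[tuple[str, int, int]] = []  # (chrom, midpoint, fold)
    for side in ("enhancer_id", "tss_id"):
        ids = ep.loc[outer.index, side]
        rows = elem.loc[ids]
        mids = ((rows["start"] + rows["end"]) // 2).to_numpy()
        for c, m, f in zip(rows["chrom"].to_numpy(), mids, outer.to_numpy()):
            incidences.append((c, int(m), int(f)))
    frame = pd.DataFrame(incidences, columns=["chrom", "mid", "fold"]).drop_duplicates()
    for _, sub in frame.groupby("chrom"):
        sub = sub.sort_values("mid", kind="stable")
        mids = sub["mid"].to_numpy()
        folds = sub["fold"].to_numpy()
        left = 0
        counts: dict[int, int] = {}
        distinct = 0
        for right in range(len(mids)):
            f = folds[right]
            counts[f] = counts.get(f, 0) + 1
            if counts[f] == 1:
                distinct += 1
            while mids[right] - mids[left] >= gap_bp:
                lf = folds[left]
                counts[lf] -= 1
                if counts[lf] == 0:
                    distinct -= 1
                left += 1
            if distinct > 1:
                return False
    return True


def fold_positive_counts(outer: pd.Series, labels: pd.Series, k: int) -> np.ndarray:
    """Positive count per outer fold (stratification diagnostics)."""
    return np.array([int(labels.loc[outer.index[outer == f]].sum()) for f in range(k)])
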