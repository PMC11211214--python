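"""Imbalance-aware evaluation of EP classifiers.

With ~2% positive prevalence, accuracy and ROC curves are uninformative;
the metrics here are precision-recall based: average precision (the mean
over positives of the precision at each positive's rank), confusion
matrices at a matched recall floor (0.70 by default, chosen on the
evaluation set itself), the false-positive rate, simple ABC and
inverse-distance baselines, gene-conditioned filtering, density-
stratified error analysis, and weak/strong contact partitions.

Degenerate ratios (0/0) are reported as ``None``/NaN — *undefined*,
never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConfusionCounts:
    """Standard confusion-matrix counts; totals are conserved."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    def false_positive_rate(self) -> float | None:
        d = self.fp + self.tn
        return self.fp / d if d else None

    def rates(self) -> dict[str, float | None]:
        return {
            "precision": self.precision(),
            "recall": self.recall(),
            "false_positive_rate": self.false_positive_rate(),
        }


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP: mean over positives of the precision at each positive's rank.

    Rows are ranked by descending score; ties keep stable input order
    (documented tie policy).  At least one positive is required.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("average precision is undefined without positives")
    order = np.argsort(-scores, kind="stable")
    y = (labels[order] == 1).astype(int)
    cum_tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    precision_at = cum_tp / ranks
    return float(precision_at[y == 1].mean())


def pr_curve(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Precision-recall points at every distinct score threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("PR curve undefined without positives")
    order = np.argsort(-scores, kind="stable")
    y = (labels[order] == 1).astype(int)
    s = scores[order]
    cum_tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    # last index of each distinct threshold value
    last = np.r_[s[1:] != s[:-1], True]
    return pd.DataFrame(
        {
            "threshold": s[last],
            "precision": (cum_tp / ranks)[last],
            "recall": (cum_tp / n_pos)[last],
        }
    )


def threshold_at_recall(
    scores: np.ndarray, labels: np.ndarray, recall_target: float = 0.70
) -> float:
    """Largest threshold whose recall (score >= t) meets the floor.

    Maximizes precision subject to recall >= ``recall_target``; recall
    is non-increasing in t, so the answer is the largest score value at
    which the running recall first reaches the target.
    """
    if not 0 < recall_target <= 1:
        raise ValueError(f"recall_target must lie in (0, 1], got {recall_target}")
    curve = pr_curve(scores, labels)
    feasible = curve[curve["recall"] >= recall_target]
    return float(feasible["threshold"].iloc[0])


def confusion_and_rates(
    labels: np.ndarray,
    scores: np.ndarray | None = None,
    threshold: float | None = None,
    predictions: np.ndarray | None = None,
) -> tuple[ConfusionCounts, dict[str, float | None]]:
    """Tally the confusion matrix from scores-at-threshold or predictions."""
    labels = np.asarray(labels)
    if predictions is None:
        if scores is None or threshold is None:
            raise ValueError("provide either predictions or scores + threshold")
        scores = np.asarray(scores, dtype=float)
        if len(scores) != len(labels):
            raise ValueError("scores and labels differ in length")
        predictions = (scores >= threshold).astype(int)
    predictions = np.asarray(predictions)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    pos = labels == 1
    pred_pos = predictions == 1
    counts = ConfusionCounts(
        tn=int((~pos & ~pred_pos).sum()),
        fp=int((~pos & pred_pos).sum()),
        fn=int((pos & ~pred_pos).sum()),
        tp=int((pos & pred_pos).sum()),
    )
    return counts, counts.rates()


def baseline_scores(ep: pd.DataFrame, kind: str) -> np.ndarray:
    """Unsupervised baselines: ``abc`` or ``inverse_distance``.

    Inverse distance maps a zero distance to the maximum finite score
    plus a small increment, keeping it ranked first.
    """
    if kind == "abc":
        if "abc_score" not in ep.columns:
            raise KeyError("ep table lacks an abc_score column")
        return ep["abc_score"].to_numpy(dtype=float)
    if kind == "inverse_distance":
        d = ep["distance"].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            s = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), np.inf)
        if np.isinf(s).any():
            finite_max = s[~np.isinf(s)].max() if (~np.isinf(s)).any() else 1.0
            s[np.isinf(s)] = finite_max * (1 + 1e-9)
        return s
    raise ValueError(f"unknown baseline kind {kind!r}")


def filter_genes_with_positive(ep: pd.DataFrame, labels: pd.Series) -> pd.Index:
    """Rows of genes that have at least one positive EP anywhere."""
    genes_pos = set(ep.loc[labels.index[labels == 1], "gene_id"])
    return ep.index[ep["gene_id"].isin(genes_pos)]


def density_stratified_errors(
    density: np.ndarray | pd.Series,
    predictions: np.ndarray,
    labels: np.ndarray,
    bin_edges: np.ndarray,
) -> pd.DataFrame:
    """Confusion counts and proportions per regulatory-density bin.

    Each row is one density bin (edges half-open, last closed) with
    TP/FP/TN/FN counts and the proportion of each outcome within the
    bin; empty bins report zero counts and undefined (NaN) proportions.
    """
    density = np.asarray(density, dtype=float)
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if not (len(density) == len(predictions) == len(labels)):
        raise ValueError("inputs differ in length")
    which = np.digitize(density, bin_edges) - 1
    which[density == bin_edges[-1]] = len(bin_edges) - 2  # closed last edge
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = which == b
        n = int(sel.sum())
        pos = labels[sel] == 1
        pp = predictions[sel] == 1
        tp = int((pos & pp).sum())
        fp = int((~pos & pp).sum())
        fn = int((pos & ~pp).sum())
        tn = int((~pos & ~pp).sum())
        rows.append(
            {
                "bin_lo": bin_edges[b],
                "bin_hi": bin_edges[b + 1],
                "n": n,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
                "prop_tp": tp / n if n else np.nan,
                "prop_fp": fp / n if n else np.nan,
                "prop_fn": fn / n if n else np.nan,
                "prop_tn": tn / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def contact_partition_metrics(
    contact: np.ndarray | pd.Series,
    labels: np.ndarray,
    contact_threshold: float = 0.002,
    scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Weak/strong contact partition (>= threshold is strong).

    Reports size, positive count, and prevalence per partition, plus
    average precision when scores are given and the partition has a
    positive.
    """
    contact = np.asarray(contact, dtype=float)
    labels = np.asarray(labels)
    strong = contact >= contact_threshold
    rows = []
    for name, sel in (("weak", ~strong), ("strong", strong)):
        n = int(sel.sum())
        n_pos = int((labels[sel] == 1).sum())
        row = {
            "partition": name,
            "n": n,
            "n_pos": n_pos,
            "prevalence": n_pos / n if n else np.nan,
        }
        if scores is not None and n_pos > 0:
            row["average_precision"] = average_precision(
                np.asarray(scores)[sel], labels[sel]
            )
        else:
            row["average_precision"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
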