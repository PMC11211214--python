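"""Candidate EP pairs and the feature families of the specificity model.

A candidate pair is any (enhancer, TSS) on the same chromosome whose
center-to-center distance is at most half the candidate window (5 Mb
total span by default, i.e. +/- 2.5 Mb, closed boundary).  On the
candidates this module computes:

* activity-by-contact (ABC) scores, normalized per promoter;
* relative contact strength against the neighborhood (max, difference
  from max, dense rank), separately TSS-centric ("contacts reaching the
  TSS") and enhancer-centric ("contacts originating from the enhancer");
* remaining (non-focal) contact sums on both sides;
* regulatory element density counts (region totals, the focal element
  included);
* histone/accessibility/expression signals per side;
* binary TF presence at the enhancer (``<TF>_e``) and at the TSS within
  a +/- 500 bp flank (``<TF>_TSS``);
* binary labels from perturbation outcomes (adjusted p < alpha and
  down-regulation; up-regulation is never positive; missing adjusted
  p-values drop the row from the labeled set).

"Near" means the same half-window used for candidate pairing — there is
one neighborhood knob, not two.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ContactMap, ElementTable

ENHANCER_SIGNAL_NAMES = {
    "H3K27ac": "normalized_H3K27ac_e",
    "H3K4me3": "H3K4me3_e",
    "H3K27me3": "H3K27me3_e",
    "DHS": "DHS_e",
}
TSS_SIGNAL_NAMES = {
    "H3K27ac": "H3K27ac.RPKM.quantile_TSS",
    "H3K4me3": "H3K4me3_TSS",
    "H3K27me3": "H3K27me3_TSS",
    "DHS": "DHS_TSS",
    "TargetGeneExpression": "TargetGeneExpression",
}


@dataclass
class FeatureMatrix:
    """Assembled per-EP feature matrix with column provenance.

    ``df`` carries the EP key columns (enhancer_id, tss_id) plus every
    feature column; ``provenance`` maps feature column -> family name.
    Row keys are unique and no feature value is missing.
    """

    df: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def feature_columns(self) -> list[str]:
        return list(self.provenance.keys())

    def matrix(self) -> pd.DataFrame:
        return self.df[self.feature_columns]

    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for col, fam in self.provenance.items():
            fams.setdefault(fam, []).append(col)
        return fams


def ep_candidates(elements: ElementTable, window_bp: int = 5_000_000) -> pd.DataFrame:
    """Enumerate same-chromosome (enhancer, TSS) pairs within the window.

    Distance is |enhancer midpoint - TSS position|; pairs at exactly
    window_bp/2 are included (closed boundary).  One gene per TSS: the
    gene id equals the TSS id.
    """
    half = window_bp // 2
    enh = elements.of_kind("enhancer")
    tss = elements.of_kind("tss")
    out_frames = []
    for chrom in sorted(tss["chrom"].unique()):
        t = tss[tss["chrom"] == chrom]
        e = enh[enh["chrom"] == chrom]
        if len(e) == 0 or len(t) == 0:
            continue
        e = e.assign(mid=(e["start"] + e["end"]) // 2).sort_values(
            ["mid", "element_id"], kind="stable"
        )
        mids = e["mid"].to_numpy()
        tpos = t["start"].to_numpy()
        lo = np.searchsorted(mids, tpos - half, side="left")
        hi = np.searchsorted(mids, tpos + half, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        t_idx = np.repeat(np.arange(len(t)), counts)
        e_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi)])
        frame = pd.DataFrame(
            {
                "enhancer_id": e["element_id"].to_numpy()[e_idx],
                "tss_id": t["element_id"].to_numpy()[t_idx],
                "chrom": chrom,
                "enh_mid": mids[e_idx],
                "tss_pos": tpos[t_idx],
            }
        )
        out_frames.append(frame)
    if not out_frames:
        return pd.DataFrame(
            columns=["enhancer_id", "tss_id", "gene_id", "chrom", "enh_mid", "tss_pos", "distance"]
        )
    out = pd.concat(out_frames, ignore_index=True)
    out["distance"] = (out["enh_mid"] - out["tss_pos"]).abs()
    out["gene_id"] = out["tss_id"]
    out = out.sort_values(["chrom", "tss_id", "enhancer_id"], kind="stable").reset_index(
        drop=True
    )
    return out[["enhancer_id", "tss_id", "gene_id", "chrom", "enh_mid", "tss_pos", "distance"]]


def attach_contact(ep: pd.DataFrame, contacts: ContactMap) -> pd.DataFrame:
    """Add the ``hic_contact`` column by bin lookup at element midpoints."""
    out = ep.copy()
    bins_e = ep["enh_mid"].to_numpy() // contacts.bin_size
    bins_t = ep["tss_pos"].to_numpy() // contacts.bin_size
    out["hic_contact"] = contacts.lookup_many(
        ep["chrom"].to_numpy(), bins_e, bins_t
    )
    return out


def enhancer_activity(elements: ElementTable) -> pd.Series:
    """ABC enhancer activity: geometric mean of H3K27ac and DHS.

    Falls back to H3K27ac alone when no DHS signal column exists.
    Negative activity signals are an error.
    """
    df = elements.df
    k27 = df["H3K27ac"]
    if (k27 < 0).any():
        raise ValueError("negative H3K27ac activity signal")
    if "DHS" in df.columns:
        dhs = df["DHS"]
        if (dhs < 0).any():
            raise ValueError("negative DHS activity signal")
        act = np.sqrt(k27 * dhs)
    else:
        act = k27.astype(float)
    return pd.Series(act.to_numpy(), index=df["element_id"].to_numpy(), name="activity")


def abc_score(
    ep: pd.DataFrame, elements: ElementTable, contacts: ContactMap | None = None
) -> pd.Series:
    """Activity-by-contact score, normalized over each promoter's candidates.

    score(e, p) = A_e * C_ep / sum over candidate enhancers e' of A_e' * C_e'p.
    A zero denominator yields 0 for every pair of that promoter.
    """
    if "hic_contact" not in ep.columns:
        if contacts is None:
            raise ValueError("ep table lacks hic_contact and no ContactMap given")
        ep = attach_contact(ep, contacts)
    act = enhancer_activity(elements)
    a = act.reindex(ep["enhancer_id"]).to_numpy()
    num = a * ep["hic_contact"].to_numpy()
    denom = pd.Series(num).groupby(ep["tss_id"].to_numpy()).transform("sum").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.Series(score, index=ep.index, name="abc_score")


def contact_relative_features(ep: pd.DataFrame) -> pd.DataFrame:
    """Relative contact strength of the focal pair within its neighborhood.

    TSS-centric columns compare the focal contact against all contacts
    reaching the focal TSS from its candidate enhancers; enhancer-centric
    columns against all contacts originating from the focal enhancer to
    its candidate TSSs.  Dense ranks: 1 = strongest, ties share the
    better rank.
    """
    c = ep["hic_contact"]
    out = pd.DataFrame(index=ep.index)
    by_tss = c.groupby(ep["tss_id"].to_numpy())
    out["max.contact.to.TSS"] = by_tss.transform("max")
    out["diff.from.max.contact.to.TSS"] = out["max.contact.to.TSS"] - c
    out["contact.rank.to.TSS"] = by_tss.rank(method="dense", ascending=False)
    by_enh = c.groupby(ep["enhancer_id"].to_numpy())
    out["max.contact.from.enhancer"] = by_enh.transform("max")
    out["diff.from.max.contact.from.enhancer"] = out["max.contact.from.enhancer"] - c
    out["contact.rank.from.enhancer"] = by_enh.rank(method="dense", ascending=False)
    return out


def remaining_contact_sums(ep: pd.DataFrame) -> pd.DataFrame:
    """Sums of non-focal contacts on both sides of each pair.

    ``remaining.enhancers.contact.to.TSS``: contacts between all the
    other candidate enhancers and the focal TSS.
    ``remaining.TSS.contact.from.enhancer``: contacts between all the
    other candidate TSSs and the focal enhancer.
    """
    c = ep["hic_contact"]
    out = pd.DataFrame(index=ep.index)
    out["remaining.enhancers.contact.to.TSS"] = (
        c.groupby(ep["tss_id"].to_numpy()).transform("sum") - c
    )
    out["remaining.TSS.contact.from.enhancer"] = (
        c.groupby(ep["enhancer_id"].to_numpy()).transform("sum") - c
    )
    return out


def density_counts(
    ep: pd.DataFrame, elements: ElementTable, window_bp: int = 5_000_000
) -> pd.DataFrame:
    """Regulatory element density in each pair's neighborhood.

    ``Enhancer.count.near.TSS``: enhancers with midpoint within the
    half-window of the focal TSS (the focal enhancer is counted, so the
    minimum on a candidate row is 1).  ``TSS.count.near.enhancer``
    analogous.  Counts are region totals, not "other element" counts.
    """
    half = window_bp // 2
    enh = elements.of_kind("enhancer")
    tss = elements.of_kind("tss")
    out = pd.DataFrame(index=ep.index)

    def _counts(points: pd.DataFrame, centers: np.ndarray, chroms: np.ndarray) -> np.ndarray:
        res = np.zeros(len(centers), dtype=int)
        for chrom in np.unique(chroms):
            sub = points[points["chrom"] == chrom]
            mids = np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
            sel = chroms == chrom
            pos = centers[sel]
            res[sel] = np.searchsorted(mids, pos + half, side="right") - np.searchsorted(
                mids, pos - half, side="left"
            )
        return res

    chroms = ep["chrom"].to_numpy()
    out["Enhancer.count.near.TSS"] = _counts(enh, ep["tss_pos"].to_numpy(), chroms)
    out["TSS.count.near.enhancer"] = _counts(tss, ep["enh_mid"].to_numpy(), chroms)
    return out


def _overlap_any(
    peaks: pd.DataFrame, chrom: np.ndarray, start: np.ndarray, end: np.ndarray
) -> np.ndarray:
    """Half-open overlap of query intervals against a peak set."""
    hit = np.zeros(len(chrom), dtype=bool)
    for ch, sub in peaks.groupby("chrom", sort=False):
        sel = chrom == ch
        if not sel.any():
            continue
        sub = sub.sort_values("start", kind="stable")
        starts = sub["start"].to_numpy()
        ends_cummax = np.maximum.accumulate(sub["end"].to_numpy())
        idx = np.searchsorted(starts, end[sel], side="left")
        ok = idx > 0
        qs = start[sel]
        ok[ok] = ends_cummax[idx[ok] - 1] > qs[ok]
        hit[sel] = ok
    return hit


def tf_presence(
    ep: pd.DataFrame,
    peak_tables: dict[str, pd.DataFrame],
    elements: ElementTable,
    tss_flank_bp: int = 500,
) -> pd.DataFrame:
    """Binary TF presence columns ``<TF>_e`` and ``<TF>_TSS`` per pair.

    ``<TF>_e`` is 1 iff any peak overlaps the enhancer interval
    (half-open); ``<TF>_TSS`` iff any peak overlaps TSS +/- the flank.
    """
    names = list(peak_tables.keys())
    if len(set(names)) != len(names):
        raise ValueError("duplicate TF names in peak tables")
    elem = elements.df.set_index("element_id")
    e_rows = elem.loc[ep["enhancer_id"]]
    t_rows = elem.loc[ep["tss_id"]]
    e_chrom = e_rows["chrom"].to_numpy()
    e_start = e_rows["start"].to_numpy()
    e_end = e_rows["end"].to_numpy()
    t_chrom = t_rows["chrom"].to_numpy()
    t_start = np.maximum(t_rows["start"].to_numpy() - tss_flank_bp, 0)
    t_end = t_rows["end"].to_numpy() + tss_flank_bp
    out = pd.DataFrame(index=ep.index)
    for tf in names:
        peaks = peak_tables[tf]
        out[f"{tf}_e"] = _overlap_any(peaks, e_chrom, e_start, e_end).astype(np.int8)
        out[f"{tf}_TSS"] = _overlap_any(peaks, t_chrom, t_start, t_end).astype(np.int8)
    return out


def tf_presence_from_matrix(ep: pd.DataFrame, presence: pd.DataFrame) -> pd.DataFrame:
    """Side-specific TF columns from a precomputed element x TF matrix."""
    if presence.columns.duplicated().any():
        raise ValueError("duplicate TF names in presence matrix")
    e = presence.reindex(ep["enhancer_id"]).to_numpy()
    t = presence.reindex(ep["tss_id"]).to_numpy()
    cols_e = {f"{tf}_e": e[:, i] for i, tf in enumerate(presence.columns)}
    cols_t = {f"{tf}_TSS": t[:, i] for i, tf in enumerate(presence.columns)}
    out = pd.DataFrame({**cols_e, **cols_t}, index=ep.index)
    return out[[c for tf in presence.columns for c in (f"{tf}_e", f"{tf}_TSS")]]


def signal_features(ep: pd.DataFrame, elements: ElementTable) -> pd.DataFrame:
    """Histone/accessibility signals per side plus target gene expression."""
    elem = elements.df.set_index("element_id")
    out = pd.DataFrame(index=ep.index)
    for raw, name in ENHANCER_SIGNAL_NAMES.items():
        if raw in elem.columns:
            out[name] = elem.loc[ep["enhancer_id"], raw].to_numpy()
    for raw, name in TSS_SIGNAL_NAMES.items():
        if raw in elem.columns:
            out[name] = elem.loc[ep["tss_id"], raw].to_numpy()
    return out


def label_positives(ep: pd.DataFrame, alpha_label: float = 0.1) -> pd.DataFrame:
    """Assign binary labels from perturbation outcomes.

    Positive iff adjusted p < alpha AND the effect direction is ``down``;
    significant up-regulation is not positive.  Rows with missing
    adjusted p are dropped from the labeled set.
    """
    if not 0 < alpha_label < 1:
        raise ValueError(f"alpha_label must lie in (0, 1), got {alpha_label}")
    out = ep[ep["adj_p"].notna()].copy()
    out["label"] = (
        (out["adj_p"] < alpha_label) & (out["effect_direction"] == "down")
    ).astype(int)
    return out


FAMILY_ORDER = [
    "distance",
    "contact",
    "abc",
    "relative",
    "density",
    "histone",
    "accessibility",
    "expression",
    "tf",
    "nmf",
]


def assemble_features(
    ep: pd.DataFrame, family_frames: dict[str, pd.DataFrame]
) -> FeatureMatrix:
    """Join feature families into one matrix with recorded provenance.

    Column order is deterministic: families in :data:`FAMILY_ORDER`, then
    column name within each family.  Conflicting column names across
    families are an error, as are missing values.
    """
    key = ep[["enhancer_id", "tss_id"]].reset_index(drop=True)
    if key.duplicated().any():
        raise ValueError("duplicate (enhancer_id, tss_id) row keys")
    provenance: dict[str, str] = {}
    pieces = [key]
    order = [f for f in FAMILY_ORDER if f in family_frames] + [
        f for f in family_frames if f not in FAMILY_ORDER
    ]
    for fam in order:
        frame = family_frames[fam].reset_index(drop=True)
        frame = frame[sorted(frame.columns)] if fam != "tf" else frame
        for col in frame.columns:
            if col in provenance:
                raise ValueError(f"conflicting feature column name: {col!r}")
            provenance[col] = fam
        pieces.append(frame)
    df = pd.concat(pieces, axis=1)
    feat = df[list(provenance.keys())]
    if feat.isna().any().any():
        bad = feat.columns[feat.isna().any()].tolist()
        raise ValueError(f"missing values in feature columns {bad}")
    return FeatureMatrix(df=df, provenance=provenance)
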