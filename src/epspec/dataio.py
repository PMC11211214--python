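"""Readers, writers, and in-memory containers for the on-disk formats.

Coordinate convention is BED throughout: 0-based, half-open intervals.
A TSS is represented as a 1-bp interval at the transcription start.
Strand is ignored everywhere; no operation in this analysis is strand-aware.

Formats
-------
elements
    Tab-separated, header line ``chrom  start  end  element_id  kind  <signals...>``.
    ``kind`` is ``enhancer`` or ``tss``; any further columns are numeric
    signal columns (e.g. ``normalized_H3K27ac_e``, ``TargetGeneExpression``)
    and are preserved verbatim.
contacts
    BEDPE-like: ``chrom1 start1 end1 chrom2 start2 end2 value`` with no
    header.  Values are KR-normalized Hi-C contact strengths (unitless,
    nonnegative); anchors are mapped to fixed-size bins.
peaks
    BED or narrowPeak; only chrom/start/end are used, the TF name comes
    from the file name stem (or an explicit name argument).
EP tables
    TSV with header; mandatory columns ``enhancer_id``, ``tss_id``,
    ``adj_p``, ``effect_direction``; missing adjusted p-values are the
    literal string ``NA``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ELEMENT_CORE_COLUMNS = ["chrom", "start", "end", "element_id", "kind"]
ELEMENT_KINDS = frozenset({"enhancer", "tss"})
EP_MANDATORY_COLUMNS = ["enhancer_id", "tss_id", "adj_p", "effect_direction"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass
class ElementTable:
    """Ordered table of genomic regulatory elements (enhancers and TSSs).

    Wraps a DataFrame with the core columns plus arbitrary numeric signal
    columns.  Element ids are unique; ``0 <= start < end`` holds for every
    row.  Sorting by (chrom, start, element_id) is stable and deterministic.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ELEMENT_CORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"element table missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
            bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])][0]
            raise ParseError(
                f"element row {bad} ({df.loc[bad, 'element_id']!r}): "
                f"invalid interval [{df.loc[bad, 'start']}, {df.loc[bad, 'end']})"
            )
        unknown_kinds = set(df["kind"].unique()) - ELEMENT_KINDS
        if unknown_kinds:
            raise ParseError(f"unknown element kind(s): {sorted(unknown_kinds)}")
        if df["element_id"].duplicated().any():
            dup = df.loc[df["element_id"].duplicated(), "element_id"].iloc[0]
            raise ParseError(f"duplicate element_id: {dup!r}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def signal_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in ELEMENT_CORE_COLUMNS]

    def sorted(self) -> "ElementTable":
        out = self.df.sort_values(
            ["chrom", "start", "element_id"], kind="stable"
        ).reset_index(drop=True)
        return ElementTable(out)

    def midpoints(self) -> pd.Series:
        return (self.df["start"] + self.df["end"]) // 2

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind].reset_index(drop=True)

    def signals_for(self, element_ids: pd.Series | np.ndarray) -> pd.DataFrame:
        indexed = self.df.set_index("element_id")
        return indexed.loc[np.asarray(element_ids)].reset_index()


@dataclass
class ContactMap:
    """Sparse symmetric pairwise contact values between fixed-size bins.

    Entries are stored once under the canonical key ``bin_i <= bin_j`` and
    queried both ways; absent pairs read as 0.  Duplicate rows for the same
    bin pair are summed (deterministic, order-independent) with a warning.
    """

    bin_size: int = 5_000
    entries: dict[tuple[str, int, int], float] = field(default_factory=dict)

    def bin_of(self, pos: int) -> int:
        return int(pos) // self.bin_size

    def add(self, chrom: str, bin_i: int, bin_j: int, value: float, *, warn_dup: bool = True) -> None:
        if value < 0:
            raise ValueError(f"negative contact value {value} for {chrom}:{bin_i}-{bin_j}")
        key = (chrom, min(bin_i, bin_j), max(bin_i, bin_j))
        if key in self.entries:
            if warn_dup:
                warnings.warn(
                    f"duplicate contact entry for {key}; values summed", stacklevel=2
                )
            self.entries[key] += float(value)
        else:
            self.entries[key] = float(value)

    def lookup(self, chrom: str, bin_i: int, bin_j: int) -> float:
        key = (chrom, min(bin_i, bin_j), max(bin_i, bin_j))
        return self.entries.get(key, 0.0)

    def lookup_many(
        self, chroms: np.ndarray, bins_i: np.ndarray, bins_j: np.ndarray
    ) -> np.ndarray:
        get = self.entries.get
        lo = np.minimum(bins_i, bins_j)
        hi = np.maximum(bins_i, bins_j)
        return np.fromiter(
            (get((c, int(i), int(j)), 0.0) for c, i, j in zip(chroms, lo, hi)),
            dtype=float,
            count=len(lo),
        )

    def contact_between(self, chrom: str, pos_a: int, pos_b: int) -> float:
        return self.lookup(chrom, self.bin_of(pos_a), self.bin_of(pos_b))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"chrom": c, "bin_i": i, "bin_j": j, "contact": v}
            for (c, i, j), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["chrom", "bin_i", "bin_j", "contact"])

    def __len__(self) -> int:
        return len(self.entries)


def read_elements(path: str | Path) -> ElementTable:
    """Read a tab-separated element table (header required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ELEMENT_CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing columns {missing}")
    try:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path.name}: non-integer coordinates ({exc})") from exc
    try:
        return ElementTable(df)
    except ParseError as exc:
        raise ParseError(f"{path.name}: {exc}") from exc


def write_elements(table: ElementTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_contacts(path: str | Path, bin_size: int = 5_000) -> ContactMap:
    """Read BEDPE-like contact rows into a binned symmetric map.

    Anchors map to bins by integer division of the anchor start by
    ``bin_size``.  Inter-chromosomal rows are skipped with a warning
    (the analysis is intra-chromosomal); negative values are an error.
    """
    cmap = ContactMap(bin_size=bin_size)
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path.name}:{lineno}: expected 7 BEDPE columns")
            c1, s1, _e1, c2, s2, _e2, val = parts[:7]
            value = float(val)
            if value < 0:
                raise ParseError(f"{path.name}:{lineno}: negative contact value {value}")
            if c1 != c2:
                warnings.warn(
                    f"{path.name}:{lineno}: inter-chromosomal contact skipped",
                    stacklevel=2,
                )
                continue
            cmap.add(c1, int(s1) // bin_size, int(s2) // bin_size, value)
    return cmap


def write_contacts(cmap: ContactMap, path: str | Path) -> None:
    """Write one BEDPE row per stored bin pair (canonical order)."""
    bs = cmap.bin_size
    with open(path, "w") as fh:
        for (chrom, bi, bj), v in sorted(cmap.entries.items()):
            fh.write(
                f"{chrom}\t{bi * bs}\t{(bi + 1) * bs}"
                f"\t{chrom}\t{bj * bs}\t{(bj + 1) * bs}\t{v:.10g}\n"
            )


def read_peaks(path: str | Path, name: str | None = None) -> pd.DataFrame:
    """Read a BED/narrowPeak interval file for one TF.

    Only chrom/start/end are used; extra narrowPeak columns are ignored;
    overlapping peaks are kept as-is (no merging).  An empty file yields an
    empty interval table, not an error.
    """
    path = Path(path)
    tf = name if name is not None else path.stem
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path.name}:{lineno}: expected >= 3 BED columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ParseError(
                    f"{path.name}:{lineno}: invalid interval [{start}, {end})"
                )
            rows.append((parts[0], start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["tf"] = tf
    return df


def read_ep_table(path: str | Path) -> pd.DataFrame:
    """Read an EP-pair TSV; ``NA`` in ``adj_p`` becomes a missing value."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in EP_MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path.name}: missing mandatory columns {missing}")
    df["adj_p"] = pd.to_numeric(df["adj_p"], errors="raise")
    return df


def write_ep_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EP_MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"EP table missing mandatory columns {missing}")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic TSV-with-header reader (feature matrices, fold plans)."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_table(df: pd.DataFrame, path: str | Path, *, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")
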