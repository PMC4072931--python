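"""Interval arithmetic on 0-based half-open genomic intervals.

Interval sets are pandas DataFrames with columns ``chrom``, ``start``, ``end``
(plus optional extra columns such as ``name``).  All operations assume and
preserve the BED convention: 0-based, half-open, ``start < end``.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from twindisc.errors import InputError

BED_COLUMNS = ["chrom", "start", "end"]


def validate_intervals(df: pd.DataFrame, name: str = "intervals") -> pd.DataFrame:
    """Check required columns and start < end; return a sorted copy."""
    for col in BED_COLUMNS:
        if col not in df.columns:
            raise InputError(f"{name}: missing column {col!r}")
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise InputError(
            f"{name}: malformed interval {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    if len(df) and (df["start"] < 0).any():
        raise InputError(f"{name}: negative coordinate")
    out = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    return out.reset_index(drop=True)


def merge_intervals(sets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Union of one or more interval sets; book-ended intervals are merged.

    Every input interval is contained in exactly one output interval.
    """
    frames = [validate_intervals(df[BED_COLUMNS]) for df in sets]
    allint = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=BED_COLUMNS)
    if allint.empty:
        return allint
    allint = allint.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, grp in allint.groupby("chrom", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:  # overlap or book-ended
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def overlap_pairs(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All (index_a, index_b) pairs whose intervals overlap by >= 1 bp."""
    hits = []
    b_by_chrom = {c: g for c, g in b.groupby("chrom")}
    for ia, row in a.iterrows():
        g = b_by_chrom.get(row["chrom"])
        if g is None:
            continue
        mask = (g["start"] < row["end"]) & (g["end"] > row["start"])
        for ib in g.index[mask]:
            hits.append((ia, ib))
    return pd.DataFrame(hits, columns=["index_a", "index_b"])


def point_to_interval_distance(pos: int, start: int, end: int) -> int:
    """Minimum gap between a point and a half-open interval; 0 if inside."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - end + 1
    return 0


def nearest_interval(pos: int, chrom: str, ivals: pd.DataFrame) -> tuple[int | None, int]:
    """Index and distance of the nearest interval on ``chrom``.

    Ties are broken toward the lower-coordinate interval (the frame is
    assumed chrom/start sorted).  Returns (None, -1) when the contig is empty.
    """
    g = ivals[ivals["chrom"] == chrom]
    if g.empty:
        return None, -1
    dists = np.array(
        [point_to_interval_distance(pos, s, e) for s, e in zip(g["start"], g["end"])]
    )
    best = int(np.argmin(dists))  # argmin is first-on-ties; frame sorted by start
    return int(g.index[best]), int(dists[best])


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Set difference a \\ b on merged interval sets."""
    a = merge_intervals([a])
    b = merge_intervals([b]) if len(b) else b
    rows = []
    b_by_chrom = {c: g for c, g in b.groupby("chrom")} if len(b) else {}
    for _, row in a.iterrows():
        cur = int(row["start"])
        end = int(row["end"])
        g = b_by_chrom.get(row["chrom"])
        if g is not None:
            sub = g[(g["start"] < end) & (g["end"] > cur)].sort_values("start")
            for _, s in sub.iterrows():
                if s["start"] > cur:
                    rows.append((row["chrom"], cur, int(s["start"])))
                cur = max(cur, int(s["end"]))
        if cur < end:
            rows.append((row["chrom"], cur, end))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def positions_in_intervals(
    chroms: pd.Series, positions: pd.Series, intervals: pd.DataFrame
) -> np.ndarray:
    """Boolean mask: does each (chrom, pos) point fall inside any interval?"""
    mask = np.zeros(len(chroms), dtype=bool)
    by_chrom = {c: g for c, g in intervals.groupby("chrom")}
    for i, (c, p) in enumerate(zip(chroms, positions)):
        g = by_chrom.get(c)
        if g is None:
            continue
        mask[i] = bool(((g["start"] <= p) & (g["end"] > p)).any())
    return mask


def peak_ids(peaks: pd.DataFrame) -> pd.Index:
    """Canonical peak identifiers chrom:start-end."""
    return pd.Index(
        [f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])],
        name="peak_id",
    )
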