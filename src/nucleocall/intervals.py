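"""Small interval-set helpers shared across modules.

All intervals are 0-based half-open, carried in DataFrames with at least
``chrom``, ``start``, ``end`` columns.  These routines cover only what the
pipeline needs: merging, membership against a merged set, and point lookup
against non-overlapping intervals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED3 = ["chrom", "start", "end"]


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Union of intervals, joining pieces separated by < ``gap`` bp (end-to-start)."""
    if len(df) == 0:
        return pd.DataFrame(columns=BED3)
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e < gap or s <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED3)


class IntervalIndex:
    """Query structure over a set of intervals (merged internally).

    Supports vectorized "does [start, end) overlap anything" and point lookup
    of the covering interval's ordinal (for non-overlapping inputs).
    """

    def __init__(self, df: pd.DataFrame, merge: bool = True):
        self.raw = df.reset_index(drop=True)
        merged = merge_intervals(df) if merge else self.raw
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._rows: dict[str, np.ndarray] = {}
        for chrom, sub in merged.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            self._starts[chrom] = sub["start"].to_numpy(dtype=np.int64)
            self._ends[chrom] = sub["end"].to_numpy(dtype=np.int64)
            self._rows[chrom] = sub.index.to_numpy()

    def overlaps(self, chrom: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Boolean array: query i overlaps >=1 stored interval by >=1 bp."""
        chrom = np.asarray(chrom, dtype=object)
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        out = np.zeros(len(start), dtype=bool)
        for c in np.unique(chrom):
            if c not in self._starts:
                continue
            m = chrom == c
            s, e = start[m], end[m]
            # candidate: last stored interval starting before query end
            j = np.searchsorted(self._starts[c], e, side="left") - 1
            ok = j >= 0
            hit = np.zeros(len(s), dtype=bool)
            hit[ok] = self._ends[c][j[ok]] > s[ok]
            out[m] = hit
        return out

    def locate_points(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Row index (into the merged set) of the interval covering each point, -1 if none."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.full(len(pos), -1, dtype=np.int64)
        for c in np.unique(chrom):
            if c not in self._starts:
                continue
            m = chrom == c
            p = pos[m]
            j = np.searchsorted(self._starts[c], p, side="right") - 1
            ok = (j >= 0) & (self._ends[c][np.clip(j, 0, None)] > p)
            res = np.full(len(p), -1, dtype=np.int64)
            res[ok] = self._rows[c][j[ok]]
            out[m] = res
        return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per-row boolean: does each query interval overlap any subject interval."""
    if len(subject) == 0:
        return np.zeros(len(query), dtype=bool)
    idx = IntervalIndex(subject)
    return idx.overlaps(query["chrom"].to_numpy(), query["start"].to_numpy(),
                        query["end"].to_numpy())
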