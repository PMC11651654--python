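"""Capture viewpoints: consensus peak construction and mononucleosomal occupancy.

A viewpoint is a consensus region of replicate mononucleosomal (H3K4me3)
peaks acting as the anchored end of every measured interaction.  Consensus =
genomic bases covered by peaks in >= ``min_reps`` distinct replicates;
consensus pieces closer than ``merge_gap`` bp are merged.  Viewpoints with a
raw total distal-pair coverage (all replicates combined) above
``min_coverage`` are retained for interaction calling.

Occupancy is the mean per-base mononucleosomal depth of a region, a
length-free quantity used to normalize contact counts for local
immunoprecipitation propensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import BED3, merge_intervals

logger = logging.getLogger("nucleocall")

DEFAULT_MIN_REPS = 3
DEFAULT_MERGE_GAP = 1000
DEFAULT_MIN_COVERAGE = 1000


@dataclass
class Viewpoint:
    id: int
    chrom: str
    start: int
    end: int
    mono_occupancy: float = float("nan")
    raw_total_coverage: int = 0
    retained: bool = True

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


def viewpoints_frame(viewpoints: list[Viewpoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in viewpoints],
            "start": [v.start for v in viewpoints],
            "end": [v.end for v in viewpoints],
            "id": [v.id for v in viewpoints],
            "mono_occupancy": [v.mono_occupancy for v in viewpoints],
            "raw_total_coverage": [v.raw_total_coverage for v in viewpoints],
            "retained": [v.retained for v in viewpoints],
        }
    )


# ---------------------------------------------------------------------------
# consensus peaks
# ---------------------------------------------------------------------------

def consensus_peaks(
    peaksets: list[pd.DataFrame],
    min_reps: int = DEFAULT_MIN_REPS,
    merge_gap: int = DEFAULT_MERGE_GAP,
) -> pd.DataFrame:
    """Maximal regions covered by peaks from >= ``min_reps`` distinct replicates.

    Each replicate's peaks are flattened first, so one replicate contributes at
    most depth 1 per base.  Resulting consensus pieces separated by
    < ``merge_gap`` bp (strict, end-to-start) are merged.  Replicate order does
    not matter.
    """
    if len(peaksets) < min_reps:
        raise ValueError(f"need >= {min_reps} peak sets, got {len(peaksets)}")
    events: dict[str, list] = {}
    for ps in peaksets:
        flat = merge_intervals(ps[BED3]) if len(ps) else ps
        for chrom, s, e in flat[BED3].itertuples(index=False) if len(flat) else []:
            events.setdefault(chrom, []).append((s, 1))
            events.setdefault(chrom, []).append((e, -1))
    pieces = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        depth = 0
        open_start = None
        for pos, delta in ev:
            new_depth = depth + delta
            if depth < min_reps <= new_depth:
                open_start = pos
            elif new_depth < min_reps <= depth:
                if pos > open_start:
                    pieces.append((chrom, open_start, pos))
                open_start = None
            depth = new_depth
    cons = pd.DataFrame(pieces, columns=BED3)
    return merge_intervals(cons, gap=merge_gap)


# ---------------------------------------------------------------------------
# depth / occupancy
# ---------------------------------------------------------------------------

class DepthTrack:
    """Piecewise-constant per-base depth with O(log n) range base-count queries.

    Built from mononucleosomal fragments (BED3) or from a bedGraph.  Internally
    per chromosome: breakpoints ``bp``, depth in each piece, and a running
    total of covered bases for interpolation.
    """

    def __init__(self, pieces: dict[str, tuple[np.ndarray, np.ndarray]],
                 chrom_sizes: dict[str, int] | None = None):
        # pieces: chrom -> (breakpoints[n+1], depth[n])
        self._bp = {}
        self._depth = {}
        self._cumbases = {}
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else None
        total = 0.0
        length = 0
        for chrom, (bp, depth) in pieces.items():
            bp = np.asarray(bp, dtype=np.int64)
            depth = np.asarray(depth, dtype=float)
            widths = np.diff(bp)
            self._bp[chrom] = bp
            self._depth[chrom] = depth
            self._cumbases[chrom] = np.concatenate([[0.0], np.cumsum(depth * widths)])
            total += float(np.sum(depth * widths))
            size = (self.chrom_sizes or {}).get(chrom, int(bp[-1]))
            length += size
        self.total_bases = total
        self.genome_length = length

    @property
    def genome_mean(self) -> float:
        return self.total_bases / self.genome_length if self.genome_length else 0.0

    @classmethod
    def from_fragments(cls, frags: pd.DataFrame,
                       chrom_sizes: dict[str, int] | None = None) -> "DepthTrack":
        pieces = {}
        chroms = set(frags["chrom"]) | set(chrom_sizes or {})
        for chrom in sorted(chroms):
            sub = frags[frags["chrom"] == chrom]
            if len(sub) == 0:
                size = (chrom_sizes or {}).get(chrom, 1)
                pieces[chrom] = (np.array([0, size]), np.array([0.0]))
                continue
            edges = np.unique(np.concatenate([sub["start"].to_numpy(), sub["end"].to_numpy()]))
            depth = np.zeros(len(edges) - 1)
            starts = np.searchsorted(edges, sub["start"].to_numpy())
            ends = np.searchsorted(edges, sub["end"].to_numpy())
            delta = np.zeros(len(edges))
            np.add.at(delta, starts, 1.0)
            np.add.at(delta, ends, -1.0)
            depth = np.cumsum(delta)[:-1]
            bp = edges
            if bp[0] > 0:
                bp = np.concatenate([[0], bp])
                depth = np.concatenate([[0.0], depth])
            size = (chrom_sizes or {}).get(chrom)
            if size is not None and bp[-1] < size:
                bp = np.concatenate([bp, [size]])
                depth = np.concatenate([depth, [0.0]])
            pieces[chrom] = (bp, depth)
        return cls(pieces, chrom_sizes)

    @classmethod
    def from_bedgraph(cls, bg: pd.DataFrame,
                      chrom_sizes: dict[str, int] | None = None) -> "DepthTrack":
        """Build from a bedGraph DataFrame (chrom, start, end, value); gaps are depth 0."""
        pieces = {}
        chroms = set(bg["chrom"]) | set(chrom_sizes or {})
        for chrom in sorted(chroms):
            sub = bg[bg["chrom"] == chrom].sort_values("start")
            bp_list, d_list = [0], []
            cur = 0
            for s, e, v in sub[["start", "end", "value"]].itertuples(index=False):
                if s > cur:
                    bp_list.append(s)
                    d_list.append(0.0)
                bp_list.append(e)
                d_list.append(float(v))
                cur = e
            size = (chrom_sizes or {}).get(chrom, cur if cur else 1)
            if size > cur:
                bp_list.append(size)
                d_list.append(0.0)
            pieces[chrom] = (np.array(bp_list), np.array(d_list))
        return cls(pieces, chrom_sizes)

    def bases(self, chrom: str, start: int, end: int) -> float:
        """Total aligned bases (depth integrated over position) in [start, end)."""
        if chrom not in self._bp:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end <= start:
            raise ValueError("empty region")
        bp, cum, depth = self._bp[chrom], self._cumbases[chrom], self._depth[chrom]
        start = max(int(start), int(bp[0]))
        end = min(int(end), int(bp[-1]))
        if end <= start:
            return 0.0

        def prefix(x):
            j = np.searchsorted(bp, x, side="right") - 1
            j = min(max(j, 0), len(depth) - 1)
            return cum[j] + depth[j] * (x - bp[j])

        return float(prefix(end) - prefix(start))

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        return self.bases(chrom, start, end) / (end - start)


def region_occupancy(track: DepthTrack, chrom: str, start: int, end: int) -> float:
    """Mean per-base mononucleosomal depth of ``[start, end)`` on ``chrom``."""
    return track.mean_depth(chrom, start, end)


# ---------------------------------------------------------------------------
# viewpoint assembly & filtering
# ---------------------------------------------------------------------------

def build_viewpoints(consensus: pd.DataFrame, track: DepthTrack | None = None) -> list[Viewpoint]:
    """Turn consensus intervals into Viewpoint objects with occupancy filled in."""
    vps = []
    for i, (chrom, s, e) in enumerate(consensus[BED3].itertuples(index=False)):
        occ = track.mean_depth(chrom, s, e) if track is not None else float("nan")
        vps.append(Viewpoint(id=i, chrom=chrom, start=int(s), end=int(e), mono_occupancy=occ))
    return vps


def filter_viewpoints(viewpoints: list[Viewpoint],
                      min_coverage: int = DEFAULT_MIN_COVERAGE) -> list[Viewpoint]:
    """Set ``retained`` = (raw_total_coverage > min_coverage); order preserved."""
    for v in viewpoints:
        v.retained = v.raw_total_coverage > min_coverage
    return [v for v in viewpoints if v.retained]


def call_fixed_peaks(track: DepthTrack, threshold_factor: float = 4.0,
                     min_width: int = 147) -> pd.DataFrame:
    """Threshold peak caller over a depth track (synthetic test path only).

    Emits maximal runs with depth >= threshold_factor * genome-mean depth and
    width >= min_width.  Real pipelines consume externally called narrowPeak
    files; this exists so the synthetic bundle can exercise the consensus step.
    """
    thr = threshold_factor * track.genome_mean
    rows = []
    for chrom, bp in track._bp.items():
        depth = track._depth[chrom]
        above = depth >= thr
        i = 0
        n = len(depth)
        while i < n:
            if above[i]:
                j = i
                while j < n and above[j]:
                    j += 1
                s, e = int(bp[i]), int(bp[j])
                if e - s >= min_width:
                    rows.append((chrom, s, e))
                i = j
            else:
                i += 1
    return pd.DataFrame(rows, columns=BED3)
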