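"""Binned viewpoint contact records, normalization, profiles and distance decay.

Distal pairs are aggregated into contact records, one per unique
(viewpoint, 250-bp other-end bin) with >= 1 read.  A pair whose mate overlaps
a viewpoint contributes one event to that viewpoint; a pair with both mates
in two different viewpoints contributes to both.  Signal is then normalized
twice:

1. occupancy normalization — raw count divided by the mean mononucleosomal
   occupancy of the viewpoint and the other-end bin, correcting for local
   immunoprecipitation propensity;
2. viewpoint normalization — after discarding records farther than 2.5 Mb,
   division by the viewpoint's total occupancy-normalized signal, making
   profiles of differently covered viewpoints comparable (per-viewpoint
   normalized signal sums to 1).

The distance rank of a record counts 250-bp bin units between the viewpoint
edge and the bin edge: rank 1 = directly adjacent bin, rank 10,000 = 2.5 Mb
away, rank 0 = bin overlapping the viewpoint itself (never called).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import BED3, IntervalIndex
from .pairs import DEFAULT_BIN_WIDTH
from .viewpoints import DepthTrack, Viewpoint, viewpoints_frame

logger = logging.getLogger("nucleocall")

MAX_DISTANCE = 2_500_000

CONTACT_COLUMNS = [
    "viewpoint_id", "chrom", "bin_start", "bin_end",
    "raw_count", "distance", "rank", "occ_norm", "vp_norm",
]


def gap_and_rank(vp_start: np.ndarray, vp_end: np.ndarray,
                 bin_start: np.ndarray, bin_end: np.ndarray,
                 bin_width: int = DEFAULT_BIN_WIDTH) -> tuple[np.ndarray, np.ndarray]:
    """Edge-to-edge gap (bp) and distance rank for viewpoint/bin interval pairs.

    Overlapping pairs get gap 0 and rank 0; otherwise rank = 1 + gap // width,
    so an abutting bin (gap 0) has rank 1.
    """
    right_gap = bin_start - vp_end      # bin right of viewpoint
    left_gap = vp_start - bin_end       # bin left of viewpoint
    gap = np.maximum(np.maximum(right_gap, left_gap), 0)
    overlap = (bin_start < vp_end) & (vp_start < bin_end)
    rank = np.where(overlap, 0, 1 + gap // bin_width)
    gap = np.where(overlap, 0, gap)
    return gap.astype(np.int64), rank.astype(np.int64)


def distance_rank(gap: int, bin_width: int = DEFAULT_BIN_WIDTH) -> int:
    """Rank of a non-overlapping record with edge gap ``gap`` bp."""
    if gap < 0:
        raise ValueError("gap must be >= 0")
    return 1 + gap // bin_width


def aggregate_contacts(pairs: pd.DataFrame, viewpoints: list[Viewpoint],
                       bin_width: int = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
    """Aggregate deduplicated distal pairs into per-(viewpoint, bin) counts.

    Mate membership in viewpoints is resolved by point lookup (viewpoints are
    non-overlapping).  Pairs touching no viewpoint are dropped.
    """
    vp_df = viewpoints_frame(viewpoints)
    idx = IntervalIndex(vp_df[BED3], merge=False)
    row_to_id = vp_df["id"].to_numpy()
    vp_start = vp_df["start"].to_numpy()
    vp_end = vp_df["end"].to_numpy()
    vp_chrom = vp_df["chrom"].to_numpy()

    hit1 = idx.locate_points(pairs["chrom1"].to_numpy(), pairs["pos1"].to_numpy())
    hit2 = idx.locate_points(pairs["chrom2"].to_numpy(), pairs["pos2"].to_numpy())

    events = []
    for vp_hit, other_chrom, other_pos in (
        (hit1, "chrom2", "pos2"),
        (hit2, "chrom1", "pos1"),
    ):
        m = vp_hit >= 0
        if not m.any():
            continue
        rows = vp_hit[m]
        events.append(pd.DataFrame({
            "vp_row": rows,
            "chrom": pairs.loc[m, other_chrom].to_numpy(),
            "pos": pairs.loc[m, other_pos].to_numpy(),
        }))
    if not events:
        return pd.DataFrame(columns=CONTACT_COLUMNS)
    ev = pd.concat(events, ignore_index=True)
    ev["bin_start"] = (ev["pos"] // bin_width) * bin_width
    grouped = (ev.groupby(["vp_row", "chrom", "bin_start"], sort=True)
                 .size().rename("raw_count").reset_index())
    grouped["bin_end"] = grouped["bin_start"] + bin_width
    rows = grouped["vp_row"].to_numpy()
    grouped["viewpoint_id"] = row_to_id[rows]
    gap, rank = gap_and_rank(vp_start[rows], vp_end[rows],
                             grouped["bin_start"].to_numpy(),
                             grouped["bin_end"].to_numpy(), bin_width)
    # cross-chromosome other ends should not occur for distal (cis) pairs;
    # guard anyway by marking them rank -1 for upstream filtering
    same = grouped["chrom"].to_numpy() == vp_chrom[rows]
    grouped["distance"] = np.where(same, gap, -1)
    grouped["rank"] = np.where(same, rank, -1)
    grouped["occ_norm"] = np.nan
    grouped["vp_norm"] = np.nan
    return grouped[CONTACT_COLUMNS].reset_index(drop=True)


def normalize(contacts: pd.DataFrame, track: DepthTrack, viewpoints: list[Viewpoint],
              max_distance: int = MAX_DISTANCE) -> pd.DataFrame:
    """Two-stage normalization of contact records.

    Drops records farther than ``max_distance`` from the viewpoint and records
    whose mean occupancy is zero (counted in the log), then fills ``occ_norm``
    and ``vp_norm``.  Per viewpoint the ``vp_norm`` column sums to 1.
    """
    occ_by_vp = {v.id: v.mono_occupancy for v in viewpoints}
    df = contacts[(contacts["distance"] >= 0) & (contacts["distance"] <= max_distance)].copy()
    n_far = len(contacts) - len(df)
    if n_far:
        logger.info("normalize: dropped %d records beyond %d bp", n_far, max_distance)

    bin_occ = np.array([
        track.mean_depth(c, s, e)
        for c, s, e in df[["chrom", "bin_start", "bin_end"]].itertuples(index=False)
    ]) if len(df) else np.array([])
    vp_occ = df["viewpoint_id"].map(occ_by_vp).to_numpy(dtype=float)
    mean_occ = 0.5 * (vp_occ + bin_occ) if len(df) else np.array([])
    bad = mean_occ <= 0
    if bad.any():
        logger.warning("normalize: dropped %d records with zero mean occupancy", int(bad.sum()))
        df = df.loc[~bad].copy()
        mean_occ = mean_occ[~bad]
    df["occ_norm"] = df["raw_count"].to_numpy() / mean_occ
    totals = df.groupby("viewpoint_id")["occ_norm"].transform("sum")
    df["vp_norm"] = df["occ_norm"] / totals
    return df.reset_index(drop=True)


def viewpoint_totals(contacts: pd.DataFrame) -> pd.Series:
    """Raw distal-pair total per viewpoint (used for the coverage filter)."""
    return contacts.groupby("viewpoint_id")["raw_count"].sum()


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def build_profile(contacts: pd.DataFrame, chrom: str, start: int, end: int,
                  bin_width: int = DEFAULT_BIN_WIDTH,
                  viewpoint_id: int | None = None,
                  value: str = "raw_count") -> pd.DataFrame:
    """Per-bin sums of other-end events over ``[start, end)``.

    Merged profile by default; restricted to one viewpoint if requested.
    Bins are aligned to the bin-width grid and tile the region.
    """
    lo = (start // bin_width) * bin_width
    edges = np.arange(lo, end + bin_width, bin_width)
    starts = edges[:-1]
    values = np.zeros(len(starts))
    sub = contacts[contacts["chrom"] == chrom]
    if viewpoint_id is not None:
        sub = sub[sub["viewpoint_id"] == viewpoint_id]
    sub = sub[(sub["bin_start"] >= lo) & (sub["bin_start"] < end)]
    if len(sub):
        pos = ((sub["bin_start"].to_numpy() - lo) // bin_width).astype(int)
        np.add.at(values, pos, sub[value].to_numpy())
    return pd.DataFrame({"chrom": chrom, "start": starts,
                         "end": starts + bin_width, "value": values})


def distance_decay(contacts: pd.DataFrame, n_bins: int = 30,
                   log10_min: float = 3.5, log10_max: float = 6.5,
                   value: str = "raw_count") -> pd.DataFrame:
    """Aggregate signal in ``n_bins`` log10-equal-width distance bins.

    Defaults cover 10^3.5 (3,162 bp) to 10^6.5 (~3.16 Mb); distances outside
    the range are ignored.
    """
    edges = np.logspace(log10_min, log10_max, n_bins + 1)
    d = contacts["distance"].to_numpy(dtype=float)
    v = contacts[value].to_numpy(dtype=float)
    ok = (d >= edges[0]) & (d < edges[-1])
    which = np.searchsorted(edges, d[ok], side="right") - 1
    sums = np.zeros(n_bins)
    np.add.at(sums, which, v[ok])
    return pd.DataFrame({"dist_lo": edges[:-1], "dist_hi": edges[1:], "signal": sums})


def profile_correlation(a: pd.DataFrame, b: pd.DataFrame,
                        exclude: pd.DataFrame | None = None,
                        require_both_nonzero: bool = True) -> float:
    """Pearson correlation of two identically binned profiles after filtering.

    Bins overlapping ``exclude`` intervals (e.g. viewpoints) are removed; when
    ``require_both_nonzero``, bins with zero signal in either profile are also
    removed.  Raises if fewer than two usable bins remain.
    """
    if len(a) != len(b) or not np.array_equal(a["start"].to_numpy(), b["start"].to_numpy()):
        raise ValueError("profiles must share binning")
    keep = np.ones(len(a), dtype=bool)
    if exclude is not None and len(exclude):
        idx = IntervalIndex(exclude)
        keep &= ~idx.overlaps(a["chrom"].to_numpy(), a["start"].to_numpy(), a["end"].to_numpy())
    va, vb = a["value"].to_numpy(dtype=float), b["value"].to_numpy(dtype=float)
    if require_both_nonzero:
        keep &= (va > 0) & (vb > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable bins for correlation")
    r, _ = sps.pearsonr(va[keep], vb[keep])
    return float(r)
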