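"""Distance-preserving randomization of interaction other-ends and enrichment stats.

The null model for "what overlaps a promoter-interacting region (PIR) by
chance" must respect the distance structure of the interaction set: PIRs sit
at characteristic distances from their viewpoints.  Randomized PIR sets are
therefore built by reshuffling the signed viewpoint-to-PIR distances among
interactions (per chromosome) and re-placing each PIR at its viewpoint plus
a permuted distance.  Placements falling off the chromosome re-draw a
distance from the multiset (logged); up to re-draws the |distance| multiset
is preserved exactly.

On top of the permutations:

* feature enrichment — log2(observed / expected) PIR-feature overlap counts,
  expectation averaged over permutations;
* TAD-boundary crossing — observed vs expected interactions whose
  viewpoint-to-other-end span strictly contains a boundary;
* CTCF motif orientation — towards/away counts of motifs in PIRs relative to
  the interacting promoter, optionally stratified by the promoter's
  transcription direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import BED3, IntervalIndex

logger = logging.getLogger("nucleocall")

DEFAULT_N_PERM = 100

# narrowPeak-style filters applied before any TRF / CTCF / DHS analysis
TRF_MIN_SIGNAL = 25
CTCF_MIN_SCORE = 250
DHS_MIN_SIGNAL = 200


def filter_features(features: pd.DataFrame, min_signal: float | None = None,
                    min_score: float | None = None) -> pd.DataFrame:
    """Drop feature intervals below the configured signalValue / score cutoffs."""
    keep = np.ones(len(features), dtype=bool)
    if min_signal is not None and "signalValue" in features:
        keep &= features["signalValue"].to_numpy() >= min_signal
    if min_score is not None and "score" in features:
        keep &= features["score"].to_numpy() >= min_score
    return features.loc[keep].reset_index(drop=True)


@dataclass
class EnrichmentResult:
    feature: str
    observed: int
    expected_mean: float
    expected_sd: float
    log2_enrichment: float


def _interaction_geometry(interactions: pd.DataFrame) -> pd.DataFrame:
    """Viewpoint and other-end centers plus signed distance for each interaction."""
    df = interactions.copy()
    df["vp_center"] = 0.5 * (df["vp_start"] + df["vp_end"])
    df["pir_center"] = 0.5 * (df["bin_start"] + df["bin_end"])
    df["pir_width"] = df["bin_end"] - df["bin_start"]
    df["signed_distance"] = df["pir_center"] - df["vp_center"]
    return df


def permute_pirs(interactions: pd.DataFrame, n_perm: int, seed: int,
                 chrom_sizes: dict[str, int]) -> list[pd.DataFrame]:
    """``n_perm`` randomized PIR sets preserving the per-chromosome distance multiset.

    ``interactions`` needs chrom, vp_start, vp_end, bin_start, bin_end columns
    (one row per interaction).  Each returned frame has BED3 PIR intervals
    plus the anchoring viewpoint geometry, in the original row order.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    geo = _interaction_geometry(interactions)
    rng = np.random.default_rng(seed)
    out = []
    total_redraws = 0
    for _ in range(n_perm):
        perm = geo.copy()
        new_center = np.empty(len(perm))
        for chrom, sub in geo.groupby("chrom", sort=True):
            size = chrom_sizes[chrom]
            dists = sub["signed_distance"].to_numpy()
            vp_c = sub["vp_center"].to_numpy()
            half_w = 0.5 * sub["pir_width"].to_numpy()
            assigned = dists[rng.permutation(len(dists))]
            centers = vp_c + assigned
            bad = (centers - half_w < 0) | (centers + half_w > size)
            tries = 0
            while bad.any() and tries < 1000:
                redraw = rng.choice(dists, size=int(bad.sum()))
                centers[bad] = vp_c[bad] + redraw
                total_redraws += int(bad.sum())
                bad = (centers - half_w < 0) | (centers + half_w > size)
                tries += 1
            if bad.any():  # pathological geometry: clip as last resort
                centers[bad] = np.clip(centers[bad], half_w[bad], size - half_w[bad])
            new_center[sub.index.to_numpy()] = centers
        perm["start"] = np.round(new_center - 0.5 * perm["pir_width"]).astype(np.int64)
        perm["end"] = perm["start"] + perm["pir_width"].astype(np.int64)
        out.append(perm[["chrom", "start", "end", "vp_start", "vp_end", "vp_center"]])
    if total_redraws:
        logger.info("permute_pirs: %d off-chromosome placements re-drawn", total_redraws)
    return out


def count_overlapping(pirs: pd.DataFrame, features: pd.DataFrame) -> int:
    """Number of PIR intervals overlapping >= 1 feature interval (>= 1 bp)."""
    if len(pirs) == 0 or len(features) == 0:
        return 0
    idx = IntervalIndex(features[BED3])
    hits = idx.overlaps(pirs["chrom"].to_numpy(), pirs["start"].to_numpy(),
                        pirs["end"].to_numpy())
    return int(hits.sum())


def feature_enrichment(pirs: pd.DataFrame, features: pd.DataFrame,
                       permuted_sets: list[pd.DataFrame],
                       name: str = "feature") -> EnrichmentResult:
    """Observed vs permutation-expected PIR-feature overlap counts, log2 ratio."""
    observed = count_overlapping(pirs, features)
    counts = np.array([count_overlapping(p, features) for p in permuted_sets], dtype=float)
    mean, sd = float(counts.mean()), float(counts.std(ddof=0))
    if mean > 0 and observed > 0:
        log2 = float(np.log2(observed / mean))
    else:
        log2 = float("nan")
    return EnrichmentResult(name, observed, mean, sd, log2)


def enrichment_table(pirs: pd.DataFrame, trf_sets: dict[str, pd.DataFrame],
                     permuted_sets: list[pd.DataFrame],
                     min_signal: float | None = TRF_MIN_SIGNAL) -> pd.DataFrame:
    """Enrichment of every TRF peak set in the PIRs, one row per factor."""
    rows = []
    for name, feats in trf_sets.items():
        feats = filter_features(feats, min_signal=min_signal)
        r = feature_enrichment(pirs, feats, permuted_sets, name=name)
        rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TAD-boundary crossing
# ---------------------------------------------------------------------------

def _crossings(vp_lo, vp_hi, pir_lo, pir_hi, boundary_points: dict[str, np.ndarray],
               chroms) -> int:
    n = 0
    inner_lo = np.minimum(vp_hi, pir_hi).astype(float)
    inner_hi = np.maximum(vp_lo, pir_lo).astype(float)
    for c in np.unique(np.asarray(chroms, dtype=object)):
        pts = boundary_points.get(c)
        if pts is None or len(pts) == 0:
            continue
        m = np.asarray(chroms, dtype=object) == c
        lo, hi = inner_lo[m], inner_hi[m]
        # boundaries strictly inside the open gap (lo, hi)
        cnt = np.searchsorted(pts, hi, side="left") - np.searchsorted(pts, lo, side="right")
        n += int(np.sum(cnt > 0))
    return n


def tad_crossing(interactions: pd.DataFrame, boundaries: pd.DataFrame,
                 permuted_sets: list[pd.DataFrame]) -> tuple[int, float]:
    """Observed vs permutation-expected counts of boundary-crossing interactions.

    An interaction crosses when >= 1 boundary midpoint lies strictly between
    the facing edges of the viewpoint and the other-end bin.
    """
    pts = {}
    for chrom, sub in boundaries.groupby("chrom"):
        mids = np.sort(0.5 * (sub["start"].to_numpy() + sub["end"].to_numpy()))
        pts[chrom] = mids
    geo = _interaction_geometry(interactions)
    observed = _crossings(geo["vp_start"].to_numpy(), geo["vp_end"].to_numpy(),
                          geo["bin_start"].to_numpy(), geo["bin_end"].to_numpy(),
                          pts, geo["chrom"].to_numpy())
    expected = [
        _crossings(p["vp_start"].to_numpy(), p["vp_end"].to_numpy(),
                   p["start"].to_numpy(), p["end"].to_numpy(),
                   pts, p["chrom"].to_numpy())
        for p in permuted_sets
    ]
    return observed, float(np.mean(expected)) if expected else float("nan")


# ---------------------------------------------------------------------------
# CTCF motif orientation
# ---------------------------------------------------------------------------

def motif_towards(motif_strand: str, motif_pos: float, promoter_pos: float) -> bool:
    """True when the motif points at the promoter along the genome axis.

    A + motif points rightward, so it is "towards" when it lies 5' (left) of
    the promoter; a - motif points leftward, "towards" when right of it.
    """
    if motif_strand == "+":
        return motif_pos < promoter_pos
    if motif_strand == "-":
        return motif_pos > promoter_pos
    raise ValueError(f"bad strand {motif_strand!r}")


def ctcf_orientation(pir_interactions: pd.DataFrame, motifs: pd.DataFrame,
                     promoter_strands: dict[int, str] | None = None) -> pd.DataFrame:
    """Towards/away motif counts for PIR-borne CTCF motifs, per promoter side.

    ``pir_interactions`` rows carry chrom, start, end (the PIR), vp_center and
    viewpoint_id; every motif overlapping a PIR contributes one count
    (motif-level counting).  When promoter strands are supplied, counts are
    additionally stratified by whether the PIR lies upstream or downstream of
    the transcription direction.
    """
    rows = []
    midx = {c: sub.sort_values("start") for c, sub in motifs.groupby("chrom")}
    for rec in pir_interactions.itertuples(index=False):
        sub = midx.get(rec.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] < rec.end) & (sub["end"] > rec.start)]
        strand = (promoter_strands or {}).get(getattr(rec, "viewpoint_id", None))
        for m in hit.itertuples(index=False):
            mpos = 0.5 * (m.start + m.end)
            towards = motif_towards(m.strand, mpos, rec.vp_center)
            if strand in ("+", "-"):
                pir_right = 0.5 * (rec.start + rec.end) > rec.vp_center
                downstream = pir_right if strand == "+" else not pir_right
                side = "downstream" if downstream else "upstream"
            else:
                side = "unstranded"
            rows.append({"side": side, "towards": towards})
    if not rows:
        return pd.DataFrame(columns=["side", "towards", "away", "fraction_towards"])
    df = pd.DataFrame(rows)
    groups = []
    for side, sub in df.groupby("side"):
        t = int(sub["towards"].sum())
        a = int((~sub["towards"]).sum())
        groups.append({"side": side, "towards": t, "away": a,
                       "fraction_towards": t / (t + a)})
    allt = int(df["towards"].sum())
    alla = int((~df["towards"]).sum())
    groups.append({"side": "all", "towards": allt, "away": alla,
                   "fraction_towards": allt / (allt + alla)})
    return pd.DataFrame(groups)
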