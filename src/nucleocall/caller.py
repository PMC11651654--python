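"""Distance-rank Weibull background model and interaction calling.

For each distance rank r (250-bp units from the viewpoint edge), the
normalized signals of all observed (viewpoint, bin) records at that rank form
an empirical background.  A two-parameter Weibull (location 0) is fitted by
maximum likelihood per rank; a record is significant when its upper-tail
probability S(x) = exp(-(x/scale)^shape) falls below alpha AND its raw read
count clears the count threshold.  Ranks below ``near_rank`` carry almost no
signal (distal pairs are > 5 kb apart) and are never called; beyond
``far_rank`` backgrounds are too sparse to fit and calls are count-only.

Defaults mirror the method: ranks 20-4000 modeled, alpha = 0.01, replicate
calls need more than 3 reads, aggregate (summed-replicate) calls need at
least 6.

The Weibull MLE is solved on the profile likelihood: the shape k is the root
of  g(k) = sum(x^k ln x)/sum(x^k) - 1/k - mean(ln x),  which is monotone in
k; the scale is then (mean(x^k))^(1/k).  Data are rescaled by their median
before solving to keep x^k in floating range.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .intervals import BED3, IntervalIndex
from .viewpoints import Viewpoint, viewpoints_frame

logger = logging.getLogger("nucleocall")

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_READS = 3        # strict: raw_count must exceed this (replicate mode)
DEFAULT_AGGREGATE_MIN_READS = 6   # inclusive: raw_count >= this (aggregate mode)
DEFAULT_NEAR_RANK = 20
DEFAULT_FAR_RANK = 4000
DEFAULT_MIN_OBS = 50
DEFAULT_REPRO_TOLERANCE = 1000

CALL_COLUMNS = [
    "viewpoint_id", "chrom", "bin_start", "bin_end",
    "raw_count", "vp_norm", "rank", "p_value", "klass",
]


@dataclass
class RankBackground:
    rank: int
    shape: float
    scale: float
    n_obs: int
    fit_ok: bool


def weibull_mle(values: np.ndarray, tol: float = 1e-10) -> tuple[float, float]:
    """Maximum-likelihood (shape, scale) of a 2-parameter Weibull, location 0."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Weibull MLE requires strictly positive values")
    med = float(np.median(x))
    y = x / med
    logy = np.log(y)
    mlog = logy.mean()

    def g(k):
        yk = np.exp(k * logy)  # y**k, stable after median rescale
        return float(np.sum(yk * logy) / np.sum(yk) - 1.0 / k - mlog)

    lo, hi = 1e-3, 1.0
    while g(hi) < 0 and hi < 1e4:
        hi *= 2.0
    if g(hi) < 0 or g(lo) > 0:
        raise RuntimeError("Weibull shape root not bracketed")
    k = optimize.brentq(g, lo, hi, xtol=tol, rtol=8 * np.finfo(float).eps)
    scale_y = float(np.mean(np.exp(k * logy)) ** (1.0 / k))
    return float(k), float(scale_y * med)


def fit_rank_background(values, rank: int, min_obs: int = DEFAULT_MIN_OBS) -> RankBackground:
    """Fit the Weibull background for one rank; fit_ok reflects data sufficiency."""
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("background values must be positive (zero-count records "
                         "are never materialized)")
    n = len(x)
    if n < min_obs or n == 0 or np.allclose(x, x[0] if n else 0):
        return RankBackground(rank, math.nan, math.nan, n, False)
    try:
        shape, scale = weibull_mle(x)
    except (RuntimeError, FloatingPointError):
        logger.warning("Weibull fit failed at rank %d (n=%d)", rank, n)
        return RankBackground(rank, math.nan, math.nan, n, False)
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        return RankBackground(rank, math.nan, math.nan, n, False)
    return RankBackground(rank, shape, scale, n, True)


def fit_backgrounds(contacts: pd.DataFrame,
                    near_rank: int = DEFAULT_NEAR_RANK,
                    far_rank: int = DEFAULT_FAR_RANK,
                    min_obs: int = DEFAULT_MIN_OBS,
                    value: str = "vp_norm") -> dict[int, RankBackground]:
    """Fit per-rank backgrounds for every rank in [near_rank, far_rank]."""
    sub = contacts[(contacts["rank"] >= near_rank) & (contacts["rank"] <= far_rank)]
    by_rank = dict(tuple(sub.groupby("rank")[value]))
    out = {}
    for rank in range(near_rank, far_rank + 1):
        vals = by_rank.get(rank)
        if vals is None or len(vals) == 0:
            out[rank] = RankBackground(rank, math.nan, math.nan, 0, False)
        else:
            out[rank] = fit_rank_background(vals.to_numpy(), rank, min_obs=min_obs)
    n_ok = sum(b.fit_ok for b in out.values())
    logger.info("fit_backgrounds: %d/%d ranks fitted", n_ok, len(out))
    return out


def weibull_pvalue(x: float, bg: RankBackground) -> float:
    """Upper-tail probability S(x) = exp(-(x/scale)^shape) under a rank background."""
    if x < 0:
        raise ValueError("signal must be >= 0")
    if not bg.fit_ok:
        raise ValueError(f"background at rank {bg.rank} is not fitted")
    return float(math.exp(-((x / bg.scale) ** bg.shape)))


def _nearest_ok(backgrounds: dict[int, RankBackground], rank: int) -> RankBackground | None:
    """Nearest fit_ok background to ``rank`` (ties go to the nearer-viewpoint side)."""
    ok_ranks = [r for r, b in backgrounds.items() if b.fit_ok]
    if not ok_ranks:
        return None
    best = min(ok_ranks, key=lambda r: (abs(r - rank), r))
    return backgrounds[best]


def call_interactions(contacts: pd.DataFrame,
                      backgrounds: dict[int, RankBackground],
                      alpha: float = DEFAULT_ALPHA,
                      min_reads: int = DEFAULT_MIN_READS,
                      near_rank: int = DEFAULT_NEAR_RANK,
                      far_rank: int = DEFAULT_FAR_RANK,
                      count_inclusive: bool = False,
                      value: str = "vp_norm") -> pd.DataFrame:
    """Call significant viewpoint-bin interactions.

    Ranks in [near_rank, far_rank]: significant iff p < alpha and the count
    criterion holds (strict ``raw_count > min_reads`` by default, or
    ``raw_count >= min_reads`` when ``count_inclusive``).  Ranks beyond
    far_rank: count criterion only, p_value reported as NaN.  Ranks below
    near_rank (including rank 0, bins inside the viewpoint) are never called.
    Records at a rank whose fit failed borrow the nearest fitted background.
    """
    rank = contacts["rank"].to_numpy()
    count = contacts["raw_count"].to_numpy()
    sig = contacts[value].to_numpy(dtype=float)
    count_ok = (count >= min_reads) if count_inclusive else (count > min_reads)

    pvals = np.full(len(contacts), np.nan)
    called = np.zeros(len(contacts), dtype=bool)

    mid = (rank >= near_rank) & (rank <= far_rank) & count_ok
    n_borrowed = 0
    for i in np.nonzero(mid)[0]:
        bg = backgrounds.get(int(rank[i]))
        if bg is None or not bg.fit_ok:
            bg = _nearest_ok(backgrounds, int(rank[i]))
            n_borrowed += 1
            if bg is None:
                continue
        pvals[i] = weibull_pvalue(sig[i], bg)
        called[i] = pvals[i] < alpha
    if n_borrowed:
        logger.info("call_interactions: %d records used a borrowed background", n_borrowed)

    far = (rank > far_rank) & count_ok
    called |= far

    out = contacts.loc[called, ["viewpoint_id", "chrom", "bin_start", "bin_end",
                                "raw_count", value, "rank"]].copy()
    out = out.rename(columns={value: "vp_norm"})
    out["p_value"] = pvals[called]
    out["klass"] = ""
    return out.reset_index(drop=True)


def call_aggregate(contacts: pd.DataFrame,
                   backgrounds: dict[int, RankBackground],
                   alpha: float = DEFAULT_ALPHA,
                   aggregate_min_reads: int = DEFAULT_AGGREGATE_MIN_READS,
                   near_rank: int = DEFAULT_NEAR_RANK,
                   far_rank: int = DEFAULT_FAR_RANK) -> pd.DataFrame:
    """Interaction calling on summed-replicate signal (count criterion >= 6)."""
    return call_interactions(contacts, backgrounds, alpha=alpha,
                             min_reads=aggregate_min_reads,
                             near_rank=near_rank, far_rank=far_rank,
                             count_inclusive=True)


# ---------------------------------------------------------------------------
# reproducibility & classification
# ---------------------------------------------------------------------------

def replicate_reproducibility(call_sets: list[pd.DataFrame],
                              tolerance: int = DEFAULT_REPRO_TOLERANCE) -> pd.DataFrame:
    """Per-replicate fraction of calls with a correspondent in >= 1 other replicate.

    Two calls correspond when their viewpoints are identical and their
    other-end bin centers lie within ``tolerance`` bp.
    """
    if len(call_sets) < 2:
        raise ValueError("need >= 2 replicates")
    prepared = []
    for df in call_sets:
        centers = 0.5 * (df["bin_start"].to_numpy() + df["bin_end"].to_numpy())
        prepared.append((df["viewpoint_id"].to_numpy(), centers))
    rows = []
    for i, (vp_i, c_i) in enumerate(prepared):
        matched = np.zeros(len(vp_i), dtype=bool)
        for j, (vp_j, c_j) in enumerate(prepared):
            if i == j:
                continue
            order = np.lexsort((c_j, vp_j))
            vp_js, c_js = vp_j[order], c_j[order]
            for k in range(len(vp_i)):
                if matched[k]:
                    continue
                lo = np.searchsorted(vp_js, vp_i[k], side="left")
                hi = np.searchsorted(vp_js, vp_i[k], side="right")
                if lo < hi and np.any(np.abs(c_js[lo:hi] - c_i[k]) <= tolerance):
                    matched[k] = True
        frac = float(matched.mean()) if len(matched) else float("nan")
        rows.append({"replicate": i, "n_calls": len(vp_i), "fraction_reproduced": frac})
    return pd.DataFrame(rows)


def classify_calls(calls: pd.DataFrame, viewpoints: list[Viewpoint]) -> pd.DataFrame:
    """Split calls into promoter-promoter (P-P) vs promoter-PIR (P-PIR).

    P-P iff the other-end bin overlaps any viewpoint interval.
    """
    calls = calls.copy()
    if len(calls) == 0:
        calls["klass"] = pd.Series(dtype=object)
        return calls
    vp_df = viewpoints_frame(viewpoints)
    idx = IntervalIndex(vp_df[BED3])
    pp = idx.overlaps(calls["chrom"].to_numpy(), calls["bin_start"].to_numpy(),
                      calls["bin_end"].to_numpy())
    calls["klass"] = np.where(pp, "P-P", "P-PIR")
    return calls


def pir_bins(classified_calls: pd.DataFrame) -> pd.DataFrame:
    """Deduplicated promoter-interacting regions (unique P-PIR other-end bins)."""
    pirs = classified_calls.loc[classified_calls["klass"] == "P-PIR",
                                ["chrom", "bin_start", "bin_end"]]
    pirs = pirs.drop_duplicates().rename(columns={"bin_start": "start", "bin_end": "end"})
    return pirs.sort_values(["chrom", "start"]).reset_index(drop=True)
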