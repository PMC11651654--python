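"""Benchmarking interaction calls against CRISPRi-verified element-promoter pairs.

Functional ground truth: element-gene pairs from CRISPRi screens, each
labeled verified-regulatory or non-regulatory, restricted to promoters that
overlap a viewpoint and elements 5 kb - 1 Mb away.  A pair counts as
"interacting" when some call anchored at the pair's viewpoint has a padded
other-end interval (default 500 bp each side) overlapping the element by
>= 1 bp.  Confusion statistics (recall, precision, false positive rate) are
reported as percentages to one decimal with Wald normal-approximation
confidence intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger("nucleocall")

DEFAULT_PIR_PAD = 500
DEFAULT_ANCHOR_PAD = 2500
DEFAULT_Z = 1.96

LABEL_VERIFIED = "verified-regulatory"
LABEL_NONREG = "non-regulatory"


def round_pct(fraction: float, digits: int = 1) -> float:
    """Half-up percentage rounding (0.60655 -> 60.7)."""
    if not math.isfinite(fraction):
        return float("nan")
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def wald_ci(k: int, n: int, z: float = DEFAULT_Z) -> tuple[float, float]:
    """Wald binomial CI for k/n: p +/- z*sqrt(p(1-p)/n), clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    p = k / n
    half = z * math.sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


@dataclass
class ConfusionStats:
    tp: int
    fp: int
    fn: int
    tn: int
    z: float = DEFAULT_Z

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    def _ci(self, k, n):
        if n == 0:
            return (float("nan"), float("nan"))
        lo, hi = wald_ci(k, n, self.z)
        return (round_pct(lo), round_pct(hi))

    def report(self) -> dict:
        """Percent-scale summary rounded to 1 decimal, with Wald CIs."""
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "recall_pct": round_pct(self.recall),
            "recall_ci_pct": self._ci(self.tp, self.tp + self.fn),
            "precision_pct": round_pct(self.precision),
            "precision_ci_pct": self._ci(self.tp, self.tp + self.fp),
            "fpr_pct": round_pct(self.fpr),
            "fpr_ci_pct": self._ci(self.fp, self.fp + self.tn),
        }


def confusion(labeled: pd.DataFrame, z: float = DEFAULT_Z) -> ConfusionStats:
    """Confusion counts from a labeled pair table (columns label, interacting)."""
    verified = labeled["label"].to_numpy() == LABEL_VERIFIED
    inter = labeled["interacting"].to_numpy(dtype=bool)
    return ConfusionStats(
        tp=int((verified & inter).sum()),
        fn=int((verified & ~inter).sum()),
        fp=int((~verified & inter).sum()),
        tn=int((~verified & ~inter).sum()),
        z=z,
    )


def overlap_calls(pairs: pd.DataFrame, calls: pd.DataFrame,
                  pir_pad: int = DEFAULT_PIR_PAD) -> pd.DataFrame:
    """Mark each element-gene pair as interacting / not against a call set.

    ``pairs`` columns: chrom, start, end (the element), viewpoint_id, label.
    A pair interacts iff some call shares its viewpoint and the call's
    other-end bin, padded by ``pir_pad`` bp on both sides, overlaps the
    element.  Pairs whose viewpoint is absent from the call universe's
    viewpoint set stay scored (not interacting); pairs with viewpoint_id < 0
    (no matching viewpoint) are excluded and counted.
    """
    valid = pairs["viewpoint_id"].to_numpy() >= 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("overlap_calls: excluded %d pairs without a matching viewpoint",
                    n_excluded)
    out = pairs.loc[valid].copy()
    inter = np.zeros(len(out), dtype=bool)
    by_vp = {vp: sub for vp, sub in calls.groupby("viewpoint_id")}
    for i, rec in enumerate(out.itertuples(index=False)):
        sub = by_vp.get(rec.viewpoint_id)
        if sub is None:
            continue
        same = sub["chrom"].to_numpy() == rec.chrom
        lo = sub["bin_start"].to_numpy() - pir_pad
        hi = sub["bin_end"].to_numpy() + pir_pad
        inter[i] = bool(np.any(same & (lo < rec.end) & (hi > rec.start)))
    out["interacting"] = inter
    out.attrs["n_excluded"] = n_excluded
    return out.reset_index(drop=True)


def site_enrichment_profile(profile: pd.DataFrame, sites: pd.DataFrame,
                            stat: str = "median"):
    """Center vs background signal ratios of a 250-bp profile at a site set.

    Per site: center = the two bins around the site midpoint; background =
    the bins at +/-1 kb and +/-5 kb from the midpoint.  Returns
    (center/5kb ratio, 1kb/5kb ratio, per-site matrix of the six values).
    ``stat`` picks the across-sites statistic ('median' or 'mean').
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    width = int(profile["end"].iloc[0] - profile["start"].iloc[0])
    lookup = {(c, s): v for c, s, v in
              profile[["chrom", "start", "value"]].itertuples(index=False)}

    def value_at(chrom, pos):
        return lookup.get((chrom, (int(pos) // width) * width), 0.0)

    rows = []
    for rec in sites[["chrom", "start", "end"]].itertuples(index=False):
        mid = 0.5 * (rec.start + rec.end)
        rows.append({
            "center_l": value_at(rec.chrom, mid - width / 2),
            "center_r": value_at(rec.chrom, mid + width / 2),
            "bg1k_l": value_at(rec.chrom, mid - 1000 - width / 2),
            "bg1k_r": value_at(rec.chrom, mid + 1000 + width / 2),
            "bg5k_l": value_at(rec.chrom, mid - 5000 - width / 2),
            "bg5k_r": value_at(rec.chrom, mid + 5000 + width / 2),
        })
    mat = pd.DataFrame(rows)
    agg = mat.median if stat == "median" else mat.mean
    s = agg(axis=0)
    center = 0.5 * (s["center_l"] + s["center_r"])
    bg1k = 0.5 * (s["bg1k_l"] + s["bg1k_r"])
    bg5k = 0.5 * (s["bg5k_l"] + s["bg5k_r"])
    center_ratio = center / bg5k if bg5k > 0 else float("nan")
    res_ratio = bg1k / bg5k if bg5k > 0 else float("nan")
    return center_ratio, res_ratio, mat


def distance_baseline(pairs: pd.DataFrame, thresholds) -> pd.DataFrame:
    """Distance-threshold predictor: regulatory iff distance <= threshold.

    Emits (threshold, recall, precision, fpr) per threshold for ROC/PR curves.
    """
    verified = pairs["label"].to_numpy() == LABEL_VERIFIED
    dist = pairs["distance"].to_numpy(dtype=float)
    rows = []
    for t in thresholds:
        pred = dist <= t
        cs = ConfusionStats(
            tp=int((verified & pred).sum()), fn=int((verified & ~pred).sum()),
            fp=int((~verified & pred).sum()), tn=int((~verified & ~pred).sum()))
        rows.append({"threshold": float(t), "recall": cs.recall,
                     "precision": cs.precision, "fpr": cs.fpr})
    return pd.DataFrame(rows)
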