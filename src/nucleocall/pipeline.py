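"""End-to-end convenience driver: synthetic bundle (or pair frames) -> calls.

Chains the module operations in their canonical order — classify,
deduplicate, aggregate, filter viewpoints, normalize, fit backgrounds,
call, classify calls — so tests, the CLI examples and the acceptance script
share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import caller as cl
from . import pairs as pr
from . import signal as sg
from . import viewpoints as vp
from .synth import SimBundle


@dataclass
class PipelineResult:
    viewpoints: list
    track: vp.DepthTrack
    contacts: pd.DataFrame          # raw aggregated records (all replicates summed)
    normalized: pd.DataFrame        # after the two-stage normalization
    backgrounds: dict
    calls: pd.DataFrame             # aggregate-mode calls, classified P-P / P-PIR
    replicate_normalized: list      # per-replicate normalized contact tables


def viewpoints_from_bundle(bundle: SimBundle) -> tuple[list, vp.DepthTrack]:
    track = vp.DepthTrack.from_bedgraph(bundle.occupancy_bedgraph,
                                        bundle.config.chrom_sizes)
    vps = [
        vp.Viewpoint(id=int(r.id), chrom=r.chrom, start=int(r.start), end=int(r.end),
                     mono_occupancy=track.mean_depth(r.chrom, r.start, r.end))
        for r in bundle.viewpoints.itertuples(index=False)
    ]
    return vps, track


def run_pipeline(bundle: SimBundle, min_coverage: int = vp.DEFAULT_MIN_COVERAGE,
                 alpha: float = cl.DEFAULT_ALPHA,
                 per_replicate: bool = False) -> PipelineResult:
    """Run the full calling chain on a synthetic bundle (aggregate mode)."""
    vps, track = viewpoints_from_bundle(bundle)
    rep_distal = []
    for df in bundle.replicate_pairs:
        distal = df[pr.classify_frame(df) == "distal"]
        rep_distal.append(pr.deduplicate_frame(distal))
    all_pairs = pd.concat(rep_distal, ignore_index=True)

    contacts = sg.aggregate_contacts(all_pairs, vps)
    totals = sg.viewpoint_totals(contacts)
    for v in vps:
        v.raw_total_coverage = int(totals.get(v.id, 0))
    retained = vp.filter_viewpoints(vps, min_coverage=min_coverage)
    retained_ids = {v.id for v in retained}
    contacts = contacts[contacts["viewpoint_id"].isin(retained_ids)].reset_index(drop=True)

    normalized = sg.normalize(contacts, track, vps)
    backgrounds = cl.fit_backgrounds(normalized)
    calls = cl.call_aggregate(normalized, backgrounds, alpha=alpha)
    calls = cl.classify_calls(calls, vps)

    rep_norm = []
    if per_replicate:
        for distal in rep_distal:
            c = sg.aggregate_contacts(distal, vps)
            c = c[c["viewpoint_id"].isin(retained_ids)].reset_index(drop=True)
            rep_norm.append(sg.normalize(c, track, vps))

    return PipelineResult(vps, track, contacts, normalized, backgrounds, calls, rep_norm)


def calibration_fraction(result: PipelineResult,
                         near_rank: int = cl.DEFAULT_NEAR_RANK,
                         far_rank: int = cl.DEFAULT_FAR_RANK) -> dict:
    """False-call rate of the caller over the tested rank window.

    Returns the fraction of records at ranks [near_rank, far_rank] that end
    up called (p < alpha AND count criterion) — the pipeline's per-record
    false-positive rate on null data — plus the count-conditional fraction
    (called / records with count above the replicate threshold) for
    reference.
    """
    norm = result.normalized
    tested = norm[(norm["rank"] >= near_rank) & (norm["rank"] <= far_rank)]
    calls = result.calls
    mid_calls = calls[(calls["rank"] >= near_rank) & (calls["rank"] <= far_rank)]
    eligible = tested[tested["raw_count"] > cl.DEFAULT_MIN_READS]
    return {
        "n_tested": int(len(tested)),
        "n_called": int(len(mid_calls)),
        "false_call_rate": float(len(mid_calls) / len(tested)) if len(tested) else 0.0,
        "n_count_eligible": int(len(eligible)),
        "count_conditional_rate": float(len(mid_calls) / len(eligible)) if len(eligible) else 0.0,
    }


def planted_recall(bundle: SimBundle, calls: pd.DataFrame) -> float:
    """Fraction of planted loops present in the call set (exact bin match)."""
    loops = bundle.truth["planted_loops"]
    if not loops:
        return float("nan")
    called = set(map(tuple, calls[["viewpoint_id", "chrom", "bin_start"]].to_numpy()))
    hits = sum((t["vp_id"], t["chrom"], t["bin_start"]) in called for t in loops)
    return hits / len(loops)
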