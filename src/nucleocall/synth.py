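"""Synthetic MNase proximity-ligation experiments for end-to-end testing.

The generator emits a complete desk-scale experiment bundle: a genome with
capture viewpoints, a mononucleosomal occupancy field, per-replicate pair
files with a power-law distance-decay background and optional planted loops,
replicate peak files, DHS/TRF/CTCF-motif annotations and a CRISPRi-style
truth table.  Everything is drawn from one seeded generator, so a given
seed reproduces the bundle byte for byte.

Statistical design
------------------
* Occupancy: log-normal piecewise-constant field (5 kb blocks), elevated at
  viewpoints — emulating the promoter-biased histone-mark occupancy that the
  two-stage normalization must remove.
* Distal other-ends: distance decays as d^-alpha over 5 kb - 2.5 Mb on both
  sides of the viewpoint, modulated multiplicatively by the local occupancy
  (capture bias) and by the fold-enrichment of planted loops.  Other-end
  bins never fall inside viewpoints, so each pair touches exactly one
  viewpoint and per-viewpoint pair totals are exact.
* The positive, right-skewed per-rank signal this produces is
  Weibull-compatible by construction but is not literally Weibull-sampled;
  calibration tests bound, rather than pin, the caller's false-positive
  rate.

Default scale (one chromosome of 20 Mb, 60 viewpoints, 4 replicates, ~800
distal pairs per viewpoint per replicate, i.e. ~2x10^5 distal pairs total)
runs the full pipeline in well under five minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pairs import DEFAULT_BIN_WIDTH, PAIR_FIELDS, write_pairs
from .intervals import BED3

OCC_BLOCK = 5000


@dataclass(frozen=True)
class PlantedLoop:
    """A true interaction: viewpoint index, signed other-end offset (bp), fold."""
    vp_index: int
    offset: int
    fold: float


@dataclass
class SimConfig:
    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 20_000_000})
    n_viewpoints: int = 60
    viewpoint_width: int = 1000
    occupancy_mu: float = 0.7      # log-normal log-mean of block depth
    occupancy_sigma: float = 0.4   # log-normal log-sd
    viewpoint_occ_factor: float = 6.0  # occupancy boost at viewpoints
    decay_alpha: float = 1.0       # p(d) ~ d^-alpha
    reads_per_viewpoint: float = 800.0  # expected distal pairs / viewpoint / replicate
    viewpoint_strength_sigma: float = 0.35  # log-normal spread of viewpoint coverage
    n_replicates: int = 4
    mono_pairs_per_replicate: int = 5000
    planted_loops: list = field(default_factory=list)
    n_background_dhs: int = 150
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for loop in self.planted_loops:
            if abs(loop.offset) > 2_500_000:
                raise ValueError(f"planted target at {loop.offset} bp exceeds 2.5 Mb")
            if loop.fold < 1:
                raise ValueError("fold-enrichment must be >= 1")


def default_benchmark_config(seed: int = 0, fold: float = 8.0,
                             n_loops: int = 40) -> SimConfig:
    """Default planted-loop benchmark: ``n_loops`` loops at 10-60 kb, given fold.

    Offsets are capped where the background expectation times the enrichment
    still comfortably exceeds the aggregate count threshold, i.e. planted
    loops have adequate coverage to be detectable in principle; beyond that
    distance recovery is limited by Poisson thinning of the read counts, not
    by the caller.
    """
    rng = np.random.default_rng(seed + 7)
    cfg = SimConfig(seed=seed)
    vps = rng.permutation(cfg.n_viewpoints)[:n_loops]
    loops = []
    for vp in vps:
        off = int(rng.integers(10_000, 60_000))
        side = 1 if rng.random() < 0.5 else -1
        loops.append(PlantedLoop(int(vp), side * off, fold))
    cfg.planted_loops = loops
    return cfg


class SimBundle:
    """In-memory result of a simulation (file emission is optional)."""

    def __init__(self):
        self.config: SimConfig = None
        self.viewpoints: pd.DataFrame = None      # chrom,start,end,id
        self.replicate_pairs: list[pd.DataFrame] = []
        self.replicate_peaks: list[pd.DataFrame] = []
        self.occupancy_bedgraph: pd.DataFrame = None
        self.dhs: pd.DataFrame = None
        self.trf_sets: dict = {}
        self.ctcf_motifs: pd.DataFrame = None
        self.crispri: pd.DataFrame = None
        self.truth: dict = {}


def _occupancy_field(cfg: SimConfig, vp_df: pd.DataFrame, rng) -> pd.DataFrame:
    rows = []
    for chrom, size in cfg.chrom_sizes.items():
        edges = np.arange(0, size + OCC_BLOCK, OCC_BLOCK)
        edges[-1] = size
        vals = np.exp(rng.normal(cfg.occupancy_mu, cfg.occupancy_sigma,
                                 len(edges) - 1))
        for s, e, v in zip(edges[:-1], edges[1:], vals):
            if e > s:
                rows.append((chrom, int(s), int(e), float(v)))
    bg = pd.DataFrame(rows, columns=BED3 + ["value"])
    # carve out elevated viewpoint blocks
    pieces = []
    for chrom, sub in bg.groupby("chrom"):
        vps = vp_df[vp_df["chrom"] == chrom]
        cut = np.unique(np.concatenate([
            sub["start"].to_numpy(), sub["end"].to_numpy(),
            vps["start"].to_numpy(), vps["end"].to_numpy()]))
        base = np.repeat(sub["value"].to_numpy(),
                         np.searchsorted(cut, sub["end"]) - np.searchsorted(cut, sub["start"]))
        starts, ends = cut[:-1], cut[1:]
        vals = base.copy()
        for s, e in vps[["start", "end"]].itertuples(index=False):
            m = (starts >= s) & (ends <= e)
            vals[m] *= cfg.viewpoint_occ_factor
        pieces.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                    "end": ends, "value": vals}))
    return pd.concat(pieces, ignore_index=True)


def _place_viewpoints(cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    sizes = cfg.chrom_sizes
    total = sum(sizes.values())
    vp_id = 0
    for chrom, size in sizes.items():
        n = max(1, round(cfg.n_viewpoints * size / total))
        margin = 120_000
        lo, hi = margin, size - margin - cfg.viewpoint_width
        pos = np.sort(rng.choice(
            np.arange(lo, hi, 2 * cfg.viewpoint_width + 5000), size=n, replace=False))
        for p in pos:
            rows.append((chrom, int(p), int(p) + cfg.viewpoint_width, vp_id))
            vp_id += 1
    return pd.DataFrame(rows, columns=BED3 + ["id"])


def _other_end_grid(cfg: SimConfig, vp, chrom_size: int, vp_index_all: pd.DataFrame):
    """Candidate other-end bins for one viewpoint: positions, weights base."""
    w = DEFAULT_BIN_WIDTH
    cand = []
    # right side: first grid bin fully beyond vp_end + 5 kb
    b0 = int(np.ceil((vp.end + 5000) / w))
    b_max = int(min(chrom_size // w - 1, (vp.end + 2_500_000) // w))
    if b_max >= b0:
        starts = np.arange(b0, b_max + 1) * w
        cand.append(pd.DataFrame({"bin_start": starts, "side": 1}))
    # left side
    b1 = int((vp.start - 5000) // w) - 1
    b_min = int(max(0, (vp.start - 2_500_000) // w))
    if b1 >= b_min:
        starts = np.arange(b_min, b1 + 1) * w
        cand.append(pd.DataFrame({"bin_start": starts, "side": -1}))
    grid = pd.concat(cand, ignore_index=True)
    grid["bin_end"] = grid["bin_start"] + w
    # exclude bins inside (or touching) any viewpoint, so every pair touches
    # exactly one viewpoint
    from .intervals import IntervalIndex
    idx = IntervalIndex(vp_index_all[BED3])
    keep = ~idx.overlaps(np.full(len(grid), vp.chrom, dtype=object),
                         grid["bin_start"].to_numpy(), grid["bin_end"].to_numpy())
    grid = grid.loc[keep].reset_index(drop=True)
    gap = np.where(grid["side"] > 0, grid["bin_start"] - vp.end,
                   vp.start - grid["bin_end"])
    grid["gap"] = gap
    return grid


def simulate_experiment(cfg: SimConfig) -> SimBundle:
    """Generate the full synthetic bundle in memory (deterministic given seed)."""
    rng = np.random.default_rng(cfg.seed)
    bundle = SimBundle()
    bundle.config = cfg

    vp_df = _place_viewpoints(cfg, rng)
    bundle.viewpoints = vp_df
    occ = _occupancy_field(cfg, vp_df, rng)
    bundle.occupancy_bedgraph = occ

    # occupancy lookup per 250-bp bin via block field
    occ_by_chrom = {c: (sub["start"].to_numpy(), sub["value"].to_numpy())
                    for c, sub in occ.groupby("chrom")}

    def occ_at(chrom, pos):
        starts, vals = occ_by_chrom[chrom]
        j = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(vals) - 1)
        return vals[j]

    planted_by_vp: dict[int, list[PlantedLoop]] = {}
    for loop in cfg.planted_loops:
        planted_by_vp.setdefault(loop.vp_index, []).append(loop)

    vp_strength = np.exp(rng.normal(0, cfg.viewpoint_strength_sigma, len(vp_df)))
    vp_strength /= vp_strength.mean()

    truth_loops = []
    per_vp_totals = np.zeros((cfg.n_replicates, len(vp_df)), dtype=int)
    rep_pairs: list[list] = [[] for _ in range(cfg.n_replicates)]

    for vi, vp in enumerate(vp_df.itertuples(index=False)):
        chrom_size = cfg.chrom_sizes[vp.chrom]
        grid = _other_end_grid(cfg, vp, chrom_size, vp_df)
        d_eff = grid["gap"].to_numpy() + DEFAULT_BIN_WIDTH  # avoid zero distances
        weights = d_eff.astype(float) ** (-cfg.decay_alpha)
        weights *= occ_at(vp.chrom, grid["bin_start"].to_numpy())
        for loop in planted_by_vp.get(vi, []):
            target_center = 0.5 * (vp.start + vp.end) + loop.offset
            tbin = int(target_center // DEFAULT_BIN_WIDTH) * DEFAULT_BIN_WIDTH
            j = np.nonzero(grid["bin_start"].to_numpy() == tbin)[0]
            if len(j) == 0:  # target fell in an excluded bin: snap to nearest candidate
                j = [int(np.argmin(np.abs(grid["bin_start"].to_numpy() - tbin)))]
                tbin = int(grid["bin_start"].iloc[j[0]])
            weights[j[0]] *= loop.fold
            truth_loops.append({"vp_index": vi, "vp_id": int(vp.id),
                                "chrom": vp.chrom, "bin_start": tbin,
                                "bin_end": tbin + DEFAULT_BIN_WIDTH,
                                "fold": loop.fold, "offset": loop.offset})
        p = weights / weights.sum()
        for rep in range(cfg.n_replicates):
            n = rng.poisson(cfg.reads_per_viewpoint * vp_strength[vi])
            per_vp_totals[rep, vi] = n
            if n == 0:
                continue
            counts = rng.multinomial(n, p)
            nz = np.nonzero(counts)[0]
            for j in nz:
                c = counts[j]
                vp_pos = rng.integers(vp.start, vp.end, size=c)
                other_pos = rng.integers(grid["bin_start"].iloc[j],
                                         grid["bin_end"].iloc[j], size=c)
                strands_vp = np.where(rng.random(c) < 0.5, "+", "-")
                strands_ot = np.where(rng.random(c) < 0.5, "+", "-")
                for a, b, sa, sb in zip(vp_pos, other_pos, strands_vp, strands_ot):
                    if a <= b:
                        rep_pairs[rep].append((vp.chrom, int(a), sa, vp.chrom, int(b), sb))
                    else:
                        rep_pairs[rep].append((vp.chrom, int(b), sb, vp.chrom, int(a), sa))

    # mononucleosomal pairs: block sampled by occupancy mass, convergent, 101-200 bp
    block_mass = occ["value"].to_numpy() * (occ["end"] - occ["start"]).to_numpy()
    block_p = block_mass / block_mass.sum()
    occ_rows = occ.reset_index(drop=True)
    for rep in range(cfg.n_replicates):
        blocks = rng.choice(len(occ_rows), size=cfg.mono_pairs_per_replicate, p=block_p)
        for bi in blocks:
            row = occ_rows.iloc[bi]
            sep = int(rng.integers(101, 201))
            hi = max(int(row["start"]) + 1, int(row["end"]) - sep)
            p1 = int(rng.integers(row["start"], hi))
            rep_pairs[rep].append((row["chrom"], p1, "+", row["chrom"], p1 + sep, "-"))

    for rep in range(cfg.n_replicates):
        df = pd.DataFrame(rep_pairs[rep], columns=list(PAIR_FIELDS))
        df = df.sort_values(["chrom1", "pos1", "chrom2", "pos2"], kind="mergesort")
        bundle.replicate_pairs.append(df.reset_index(drop=True))

    # replicate peak files: viewpoint intervals with small per-replicate jitter
    for rep in range(cfg.n_replicates):
        jitter = rng.integers(-100, 101, size=(len(vp_df), 2))
        peaks = pd.DataFrame({
            "chrom": vp_df["chrom"],
            "start": np.maximum(0, vp_df["start"].to_numpy() + jitter[:, 0]),
            "end": vp_df["end"].to_numpy() + jitter[:, 1],
        })
        bundle.replicate_peaks.append(peaks)

    # annotations: DHSs at planted targets + background DHSs; CRISPRi truth table
    dhs_rows, crispri_rows = [], []
    dhs_width = 300
    for t in truth_loops:
        center = t["bin_start"] + DEFAULT_BIN_WIDTH // 2
        dhs_rows.append((t["chrom"], center - dhs_width // 2, center + dhs_width // 2,
                         400.0, True, t["vp_id"]))
    vp_centers = 0.5 * (vp_df["start"] + vp_df["end"])
    for _ in range(cfg.n_background_dhs):
        vi = int(rng.integers(0, len(vp_df)))
        chrom = vp_df["chrom"].iloc[vi]
        size = cfg.chrom_sizes[chrom]
        for _try in range(100):
            off = int(rng.integers(5000, 1_000_000)) * (1 if rng.random() < 0.5 else -1)
            center = int(vp_centers.iloc[vi]) + off
            if dhs_width // 2 < center < size - dhs_width // 2:
                break
        dhs_rows.append((chrom, center - dhs_width // 2, center + dhs_width // 2,
                         250.0, False, int(vp_df["id"].iloc[vi])))
    dhs = pd.DataFrame(dhs_rows, columns=BED3 + ["signalValue", "is_enhancer", "vp_id"])
    planted_keys = {(t["vp_id"], t["chrom"], t["bin_start"]) for t in truth_loops}
    for rec in dhs.itertuples(index=False):
        center = 0.5 * (rec.start + rec.end)
        vp_row = vp_df[vp_df["id"] == rec.vp_id].iloc[0]
        dist = abs(center - 0.5 * (vp_row["start"] + vp_row["end"]))
        crispri_rows.append({
            "chrom": rec.chrom, "start": rec.start, "end": rec.end,
            "gene": f"gene{rec.vp_id}", "viewpoint_id": rec.vp_id,
            "distance": int(dist),
            "label": "verified-regulatory" if rec.is_enhancer else "non-regulatory",
        })
    bundle.dhs = dhs
    bundle.crispri = pd.DataFrame(crispri_rows)

    # CTCF-like motifs at a random half of DHSs, strands uniform
    motif_rows = []
    for rec in dhs.itertuples(index=False):
        if rng.random() < 0.5:
            mid = (rec.start + rec.end) // 2
            strand = "+" if rng.random() < 0.5 else "-"
            motif_rows.append((rec.chrom, mid - 10, mid + 9, "CTCF", 0, strand))
    bundle.ctcf_motifs = pd.DataFrame(
        motif_rows, columns=BED3 + ["name", "score", "strand"])

    # simple TRF peak sets: one factor enriched at enhancer DHSs, one uniform decoy
    trf_rows_a = [(r.chrom, r.start, r.end, 100.0) for r in dhs.itertuples(index=False)
                  if r.is_enhancer or rng.random() < 0.2]
    trf_rows_b = [(r.chrom, r.start, r.end, 100.0) for r in dhs.itertuples(index=False)
                  if rng.random() < 0.5]
    bundle.trf_sets = {
        "TRF_enh": pd.DataFrame(trf_rows_a, columns=BED3 + ["signalValue"]),
        "TRF_rand": pd.DataFrame(trf_rows_b, columns=BED3 + ["signalValue"]),
    }

    bundle.truth = {
        "seed": cfg.seed,
        "chrom_sizes": cfg.chrom_sizes,
        "planted_loops": truth_loops,
        "per_viewpoint_totals": per_vp_totals.tolist(),
        "n_replicates": cfg.n_replicates,
        "dhs_labels": dhs["is_enhancer"].astype(int).tolist(),
    }
    return bundle


def write_bundle(bundle: SimBundle, out_dir) -> dict:
    """Write the bundle's standard-format files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, df in enumerate(bundle.replicate_pairs):
        p = out / f"rep{i + 1}.pairs"
        write_pairs(p, df)
        paths[f"pairs_rep{i + 1}"] = str(p)
    for i, peaks in enumerate(bundle.replicate_peaks):
        p = out / f"rep{i + 1}.narrowPeak"
        np10 = peaks.copy()
        np10["name"] = [f"peak{j}" for j in range(len(peaks))]
        np10["score"] = 1000
        np10["strand"] = "."
        np10["signalValue"] = 50.0
        np10["pValue"] = -1
        np10["qValue"] = -1
        np10["peak"] = -1
        np10.to_csv(p, sep="\t", header=False, index=False)
        paths[f"peaks_rep{i + 1}"] = str(p)
    p = out / "occupancy.bedGraph"
    bundle.occupancy_bedgraph.to_csv(p, sep="\t", header=False, index=False)
    paths["occupancy"] = str(p)
    for name, df in (("dhs.bed", bundle.dhs), ("ctcf_motifs.bed", bundle.ctcf_motifs),
                     ("crispri.tsv", bundle.crispri)):
        p = out / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    for trf, df in bundle.trf_sets.items():
        p = out / f"{trf}.bed"
        df.to_csv(p, sep="\t", header=False, index=False)
        paths[trf] = str(p)
    p = out / "truth.json"
    with open(p, "w") as fh:
        json.dump(bundle.truth, fh, indent=0, sort_keys=True)
    paths["truth"] = str(p)
    return paths


def simulate_feature_table(n_pairs: int, causal_features: list[str],
                           effect_sizes: list[float], noise_sd: float,
                           seed: int, n_decoys: int = 20) -> tuple[pd.DataFrame, dict]:
    """Feature table for selection tests: target = g(distance) + effects + noise.

    Base columns: distance (log-uniform 5 kb - 250 kb), CTCF signal at
    viewpoint and site, two CTCF-orientation indicators per side.  Candidate
    columns: the causal features plus independent standard-normal decoys.
    """
    rng = np.random.default_rng(seed)
    dist = np.exp(rng.uniform(np.log(5000), np.log(250_000), n_pairs))
    tbl = pd.DataFrame({
        "distance": dist,
        "ctcf_vp": rng.exponential(1.0, n_pairs),
        "ctcf_dhs": rng.exponential(1.0, n_pairs),
        "ctcf_orient_vp_fwd": rng.integers(0, 2, n_pairs),
        "ctcf_orient_dhs_fwd": rng.integers(0, 2, n_pairs),
    })
    target = 3.0 * (dist / 5000.0) ** (-0.7)  # power-law distance decay
    for name, eff in zip(causal_features, effect_sizes):
        tbl[name] = rng.normal(0, 1, n_pairs)
        target = target + eff * tbl[name].to_numpy()
    for i in range(n_decoys):
        tbl[f"decoy{i}"] = rng.normal(0, 1, n_pairs)
    tbl["signal"] = target + rng.normal(0, noise_sd, n_pairs)
    truth = {"causal": list(causal_features), "effects": list(effect_sizes),
             "decoys": [f"decoy{i}" for i in range(n_decoys)]}
    return tbl, truth
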