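# nucleocall

Interaction calling and downstream analysis for **viewpoint-centered MNase
proximity-ligation experiments** (MChIP-C-style): assays that capture, at
single-nucleosome resolution, which genomic regions physically contact a set
of promoters marked by a chromatin feature such as H3K4me3.

The package is aimed at regulatory-genomics analysts who have ligation pair
files and replicate peak calls and want to go from raw pair records to a set
of statistically supported promoter–region interactions, and then to the
standard follow-up analyses: enrichment of transcription-related factor
(TRF) binding in promoter-interacting regions, TAD-boundary-crossing
statistics, CTCF motif orientation bias, clustering of promoter-interacting
DHSs, random-forest modeling of contact strength, and benchmarking of calls
against CRISPRi-verified enhancer–promoter pairs.

## The model

Every analysis anchors on **viewpoints**: consensus intervals covered by
mononucleosomal peaks in ≥ 3 replicates (pieces < 1 kb apart merged).
Deduplicated distal pairs (cis, > 5 kb) are aggregated into records
(*viewpoint v*, *250-bp other-end bin b*) with raw count
*N<sub>vb</sub>* ≥ 1, then normalized twice:

1. **occupancy normalization** — *N<sub>vb</sub>* / mean(occ(*v*), occ(*b*)),
   where occ is mean per-base mononucleosomal depth, correcting for local
   immunoprecipitation propensity;
2. **viewpoint normalization** — division by the viewpoint's total
   occupancy-normalized signal within 2.5 Mb, so per-viewpoint normalized
   profiles sum to 1.

Each record gets a **distance rank** *r* = 250-bp units between the
viewpoint edge and the bin edge (rank 1 = adjacent, rank 10,000 = 2.5 Mb).
For each rank 20 ≤ *r* ≤ 4000, the normalized signals *x* of all records at
that rank form the background, fitted with a two-parameter Weibull by
maximum likelihood; a record is significant when

&nbsp;&nbsp;&nbsp;&nbsp;S(*x*) = exp(−(*x*/λ<sub>r</sub>)<sup>k<sub>r</sub></sup>) < 0.01
&nbsp;&nbsp;and&nbsp;&nbsp;*N<sub>vb</sub>* > 3
&nbsp;&nbsp;(≥ 6 for summed-replicate calling),

with count-only calls beyond rank 4000. Calls are split into
promoter–promoter (other end inside another viewpoint) and promoter–PIR.
Null models for enrichment questions use distance-preserving permutations:
signed viewpoint→PIR distances are reshuffled among interactions per
chromosome, preserving the distance distribution exactly.

A synthetic-experiment generator (`nucleocall.synth`) emits complete
desk-scale bundles — pair files with a d<sup>−α</sup> distance-decay
background, occupancy fields, planted loops, annotations and truth tables —
so the whole chain is testable without external data.

## Worked example

```python
import nucleocall as nc
from nucleocall import pipeline as pl

bundle = nc.simulate_experiment(nc.default_benchmark_config(seed=1))
result = pl.run_pipeline(bundle)

print(f"viewpoints retained : {len([v for v in result.viewpoints if v.retained])}")
print(f"contact records     : {len(result.normalized)}")
print(f"interactions called : {len(result.calls)}")
print(f"planted-loop recall : {pl.planted_recall(bundle, result.calls):.3f}")

labeled = nc.overlap_calls(bundle.crispri, result.calls)
rep = nc.confusion(labeled).report()
print(f"screen benchmark    : recall {rep['recall_pct']}%, "
      f"precision {rep['precision_pct']}%, FPR {rep['fpr_pct']}%")
```

prints

```
viewpoints retained : 60
contact records     : 118631
interactions called : 317
planted-loop recall : 0.900
screen benchmark    : recall 90.0%, precision 94.7%, FPR 1.3%
```

All 60 simulated viewpoints clear the >1000-pair coverage filter; the
118,631 surviving (viewpoint, bin) records yield 317 aggregate-mode calls,
recovering 36/40 planted 8-fold loops. Scored against the bundle's
CRISPRi-style truth table (calls padded ±500 bp), 90% of the true
element–promoter pairs have an underlying called interaction while 1.3% of
non-regulatory pairs do.

The same steps are available from the shell:

```
nucleocall simulate --seed 1 --out sim/
nucleocall viewpoints --peaks sim/rep1.narrowPeak ... --out vps.bed
nucleocall signal aggregate --pairs sim/rep1.pairs ... --viewpoints vps.bed \
    --occupancy sim/occupancy.bedGraph --out contacts.tsv
nucleocall call --contacts contacts.tsv --viewpoints vps.bed --aggregate --out calls.tsv
nucleocall benchmark --pairs sim/crispri.tsv --calls calls.tsv --out report.json
```

## Layout

| Module | Role |
| --- | --- |
| `nucleocall.pairs` | pair I/O, classification, deduplication, subsampling, bins |
| `nucleocall.viewpoints` | consensus peaks, depth tracks, occupancy, coverage filter |
| `nucleocall.signal` | contact aggregation, double normalization, profiles, decay |
| `nucleocall.caller` | Weibull backgrounds, interaction calling, reproducibility |
| `nucleocall.permutation` | distance-preserving permutations, TRF/TAD/CTCF enrichment |
| `nucleocall.downstream` | DHS clustering, binomial enrichment, RF feature selection |
| `nucleocall.benchmark` | CRISPRi confusion statistics, Wald CIs, distance baseline |
| `nucleocall.synth` | synthetic experiment and feature-table generators |
| `nucleocall.pipeline` | end-to-end driver chaining the above |

See `docs/methods.md` for the statistical details and design choices.
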