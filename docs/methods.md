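# Methods

This note documents the statistical model, the tunable parameters, the
synthetic-data design, and the numerical and design choices behind
`nucleocall`.

## Input model and coordinate conventions

The atomic observation is a ligation read pair: chromosome, 5′ position and
strand per mate, mates stored upper-triangular (smaller (chrom, pos)
first). All coordinates are 0-based half-open internally; 1-based forms
appear only at I/O boundaries that demand them. Pair separation is measured
on the stored 5′ positions; fragment midpoints are not used (the pairs
format carries 5′ positions, and the classification windows below are
defined on them).

Pairs are partitioned exhaustively into three classes with strict
inequalities:

* **mononucleosomal** — cis, convergent (+/− under upper-triangular
  ordering), 100 < separation < 201 bp. These span a single nucleosome and
  proxy the captured histone mark's occupancy.
* **distal** — cis, separation > 5000 bp: the proximity-ligation signal.
* **other** — everything else, including all trans pairs; retained in files
  but never analyzed.

"Convergent" is interpreted as (+, −) under the mate ordering — the
standard inward-facing convention for nucleosome-spanning pairs.
Deduplication keeps the first record of any group sharing strands with both
mates within a tolerance (default 0 bp, i.e. exact duplicates), matching
standard pair-tool behavior.

## Viewpoints and occupancy

Viewpoints are maximal regions covered by mononucleosomal peaks from ≥ 3
(`min_reps`) distinct replicates, with consensus pieces < 1000 bp apart
(`merge_gap`, strict, end-to-start) merged. Peak scores are ignored:
consensus is a pure presence/absence criterion. Only viewpoints with raw
total distal coverage (all replicates combined) strictly above 1000 pairs
(`min_coverage`) enter calling.

Occupancy of a region is its **mean per-base mononucleosomal depth**. A raw
base count would scale with region length and make the mean of a ~1 kb
viewpoint occupancy and a 250 bp bin occupancy meaningless; the per-base
mean is length-free, and any global scale factor cancels in the viewpoint
normalization anyway. Depth tracks are piecewise-constant structures built
from fragment BED files or bedGraphs, with O(log n) range queries.

A minimal fixed-threshold peak caller (depth ≥ 4× genome mean over ≥ 147 bp)
exists solely so synthetic bundles can exercise the consensus step; real
pipelines consume externally called narrowPeak files.

## Contact records and normalization

Each deduplicated distal pair whose mate overlaps a viewpoint contributes
one event to (that viewpoint, the 250-bp bin of the other mate); a pair
joining two viewpoints contributes to both. Zero-count pairs are never
materialized. Records farther than 2.5 Mb (edge-to-edge) are discarded;
records with zero mean occupancy are dropped and counted rather than given
infinite signal. The two normalization stages are described in the README;
after them, each viewpoint's normalized signal sums to 1 (enforced to
1e-9 in tests).

Distance rank is computed edge-to-edge: rank = 1 + gap // 250, with bins
overlapping the viewpoint at rank 0 (never called). Edge measurement makes
"rank 1 = directly adjacent bin" literal; a center-based rank would make
rank depend on viewpoint length.

## Weibull background and calling

Per rank in [20, 4000], the positive normalized signals are fitted with a
two-parameter Weibull (location 0). The MLE is solved on the profile
likelihood: the shape k is the unique root of

  g(k) = Σ x^k ln x / Σ x^k − 1/k − mean(ln x),

which is monotone increasing in k; `brentq` solves it to 1e-10 after
rescaling the data by their median (so x^k stays in floating range), and
the scale follows in closed form as (mean x^k)^(1/k). Tests verify the
solver against an independent grid-search likelihood maximizer and against
`scipy.stats.weibull_min.fit(floc=0)`.

Ranks with fewer than 50 positive records (`min_obs`), or where the
optimizer fails, are flagged unusable; records there borrow the nearest
fitted rank's background (logged). This preserves calling continuity at
desk scale, where far ranks are sparse.

Calling: p = S(x) < 0.01 AND raw count > 3 within ranks 20–4000; count-only
beyond rank 4000. Summed-replicate ("aggregate") calling raises the count
criterion to ≥ 6 — "increase the threshold to 6" is read as the new minimum
allowed count, i.e. inclusive, switchable by argument. The far-rank
count-only rule applies in aggregate mode with the same threshold, for
consistency. No multiple-testing correction is applied: the procedure is a
fixed per-record p < 0.01 rule by design, and is documented as such.

Two calls in different replicates correspond when their viewpoints are
identical and other-end bin centers are ≤ 1 kb apart; per replicate we
report the fraction of calls with a correspondent in at least one other
replicate.

### Calibration: what the null simulation shows

On null simulations (no planted loops) the suite bounds the **per-record
false-call rate**: the fraction of all records tested at ranks 20–4000 that
end up called (p < α and count criterion) stays ≤ 0.02 (≈ 0.003 in
practice). The count-*conditional* rate — calls divided by only those
records with count > 3 — is also reported but not bounded: for any
continuous background model applied to sparse discrete counts, a record
with ≥ 4 reads at a rank whose typical positive record has 1–2 reads is
necessarily in the extreme tail, so the conditional rate approaches 1 at
sparse ranks regardless of fit quality and is a property of sequencing
depth, not of the caller.

## Permutation null models

Randomized PIR sets preserve the interaction-distance structure: signed
viewpoint-center→PIR-center distances are permuted among interactions
within each chromosome; a placement falling off the chromosome re-draws a
distance from the multiset (counted and logged) rather than being clipped.
Signed (side-preserving) permutation is the default because it preserves
left/right asymmetry near chromosome ends. Distances here are
center-to-center, which is symmetric and avoids artifacts from variable
viewpoint lengths. Overlap is ≥ 1 bp intersection throughout.

Feature enrichment is log2(observed / expected) PIR-overlap counts with the
expectation averaged over 100 permutations; TAD-boundary crossing counts an
interaction when ≥ 1 boundary midpoint lies strictly between the facing
edges of viewpoint and other-end bin. CTCF motif orientation is counted at
the motif level (a PIR with several motifs contributes each once): a motif
points "towards" the promoter when its strand direction faces the
viewpoint center on the genome axis, with optional stratification by the
promoter's transcription direction.

narrowPeak-style inputs are pre-filtered with the standard cutoffs used
throughout: TRF peaks need signalValue ≥ 25, CTCF peaks score ≥ 250, DHS
peaks signalValue ≥ 200.

## Clustering and contact-strength modeling

The DHS × TRF binding matrix is binary (≥ 1 bp peak overlap); columns are
kept when bound to > 1000 DHSs and PIR-enriched > 2 (log2). Rows are
clustered by Ward's minimum-variance linkage on Euclidean distances of the
raw binary vectors (no scaling), tree cut at k = 4; per cluster the top 20
factors by bound-DHS count are reported together with their union.

Cluster enhancer enrichment uses a one-sided binomial test with null
proportion p0 = cluster size / total clustered DHSs — the natural
cluster-membership null; the p-value is P(X ≥ x) for the x
enhancer-overlapping DHSs landing in the cluster out of n overall.

Contact strength between viewpoint–DHS pairs (< 250 kb, ≥ 1 read; IQR
outlier rule on the target available with configurable multiplier) is
modeled with random forests: 100 trees, 3 features tried per split,
3-fold cross-validation scoring mean per-fold R² (regression) or AUC
(classification above/below the median signal, folds stratified by that
split). The greedy forward selection loop retrains the forest for every
remaining candidate at every step and appends the best scorer; the loop, CV
protocol and scoring are implemented here, with scikit-learn supplying only
the forest itself. CV R² is averaged per fold rather than pooled
out-of-fold; a test fold with zero target variance scores 0 (no variance to
explain).

## Benchmarking against CRISPRi screens

Element–gene pairs (promoter overlapping a viewpoint, element 5 kb–1 Mb
away) are scored pair-level — an element regulating two genes forms two
independently scored pairs. A pair "interacts" when a call at the pair's
viewpoint, with its other-end bin padded ±500 bp, overlaps the element by
≥ 1 bp. Confusion statistics are reported as percentages rounded half-up to
one decimal with Wald normal-approximation intervals p̂ ± 1.96·√(p̂(1−p̂)/n),
clipped to [0, 1]; the Wald form (not Wilson) exactly reproduces the
intervals this experimental design publishes alongside its counts. A
distance-threshold baseline (regulatory iff distance ≤ t) provides ROC/PR
reference curves.

## Synthetic experiment design

The generator emulates the statistical structure the caller assumes, at a
scale that runs the full pipeline in well under five minutes on one CPU:

| Parameter | Default | Why |
| --- | --- | --- |
| genome | 1 chromosome, 20 Mb | smallest span holding 60 viewpoints with full ±2.5 Mb windows |
| viewpoints | 60 × 1 kb, ≥ 7 kb apart | desk-scale stand-in for a genome-wide promoter set |
| occupancy | log-normal (μ=0.7, σ=0.4) per 5 kb block, ×6 at viewpoints | right-skewed occupancy field with promoter-biased capture, the bias the double normalization must remove |
| distance decay | p(d) ∝ d^−1 over 5 kb–2.5 Mb, both sides | the classic contact-frequency P(s) ~ s^−1 regime |
| coverage | Poisson, mean 800 distal pairs/viewpoint/replicate, log-normal (σ=0.35) viewpoint strength, 4 replicates | ≈ 2×10⁵ distal pairs total; per-viewpoint depth of the same order as a deeply sequenced real experiment |
| planted loops (benchmark config) | 40 loops, fold 8, offsets 10–60 kb | "adequate coverage": within 60 kb the background expectation × 8 comfortably exceeds the aggregate count threshold of 6 even for below-average-coverage viewpoints, so recovery measures the caller, not Poisson thinning |

Other-end bins are drawn from the 250-bp grid with weights
(gap + 250)^−α × occupancy × planted fold (renormalized), then read
positions are jittered uniformly within bins; the grid excludes bins
overlapping any viewpoint, so each pair touches exactly one viewpoint and
per-viewpoint totals are an exact conservation invariant (promoter–promoter
call classification is exercised by hand-built fixtures instead).
Everything derives from one seeded generator; a seed reproduces the bundle
byte for byte.

What the generator does **not** emulate: sequence content, mappability and
duplication artifacts, trans contacts, TAD/compartment structure in the
background, cell-to-cell heterogeneity, and the genuinely Weibull-shaped
tails of real normalized signal — the synthetic background is
Weibull-compatible (positive, right-skewed, continuous after occupancy
division) but not literally Weibull-sampled. Calibration results on
synthetic nulls therefore bound the false-call rate under a plausible
background; they do not certify calibration on real data, where background
shape, coverage and viewpoint counts differ by orders of magnitude.

## Numerical details and degenerate inputs

* Weibull MLE: brentq to 1e-10 on the shape after median rescaling;
  all-equal samples or n < `min_obs` are flagged unfitted.
* Quartiles in the IQR outlier rule use linear interpolation; zero IQR
  drops nothing (warned).
* Pearson correlations raise on < 2 usable bins or zero variance rather
  than returning NaN.
* Permutation re-draws are capped (1000 rounds) with clipping as a last
  resort for pathological geometries; re-draw counts are logged.
* Ties in nearest-rank background borrowing resolve toward the viewpoint.

## Known limitations

* Per-rank fitting needs deep data; at desk scale most ranks beyond ~800
  borrow a neighbor's background. Real-scale inputs fit the full 20–4000
  range.
* The caller applies no FDR control, faithfully to the fixed p < 0.01
  design it implements; interpret call counts accordingly.
* Loop-anchored (two-sided) call sets are supported in benchmarking only
  through the padded-overlap interface; all-vs-all matrix loop calling is
  out of scope.
* The CLI covers the processing chain (simulate, classify, viewpoints,
  aggregate, call, enrich, benchmark, cluster-dhs, rf-select); profile
  plotting and figure generation are left to the caller's environment.
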