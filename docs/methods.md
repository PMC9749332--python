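# Methods

This note documents the models, defaults and design choices behind
`hrdscan`, and what the synthetic experiments do and do not demonstrate.

## Coordinate frame

All coordinates are 0-based, half-open `[start, end)` base pairs; interval
length is always `end − start`.  Only autosomes are modelled.  A bundled
hg19-like table supplies 22 autosome lengths and centromere intervals;
tests mostly use toy builds (equal-length chromosomes, 3–4 Mb centromere)
so that brute-force oracles stay exact.  Arm boundaries are the centromere
interval's edges; the centromere interior belongs to no arm.  Marker maps
attach a GC fraction to each marker at construction (conceptually the GC
content of a fixed window around the marker), so no reference sequence is
ever required; synthetic maps draw GC from a smooth two-sinusoid landscape
(~37 Mb and ~7 Mb periods) around a genome-typical 0.42.

## Scar metrics

Given integer allele-specific segments (major ≥ minor ≥ 0) tiling each
chromosome:

* **LOH**: segments with minor = 0 and major ≥ 1 are merged across adjacent
  runs (so a deletion-LOH run abutting copy-neutral LOH counts once); a
  merged region counts if strictly longer than 15 Mb and strictly shorter
  than its chromosome.  Homozygous deletions (major = 0) break runs.
* **TAI**: allelic imbalance (major ≠ minor) merged the same way; a region
  counts if it touches a chromosome terminus, does not overlap the
  centromere, and does not span the whole chromosome.  No minimum length by
  default; `tai_min_mb` accommodates variants that use a floor (e.g. 11 Mb).
* **LST**: computed per chromosome arm (segments clipped at the centromere;
  a state change across the centromere is never a breakpoint).  Smoothing
  first removes segments shorter than 3 Mb — shortest first, leftmost on
  ties; flanks that then share a state merge across the gap, unequal flanks
  extend to the integer midpoint, an edge segment's single neighbour
  absorbs the gap — iterating until nothing is below the floor.  A
  breakpoint then counts when both flanking segments are ≥ 10 Mb and differ
  in state.

Thresholds follow the definitions' wording literally (strict >15 Mb,
inclusive ≥10 Mb, strict <3 Mb) and are configurable.  The HRD sum is the
unweighted sum of the three counts, classified positive at ≥ 42 (inclusive).
The arm-based LST computation and the even gap split are deliberate choices
where the one-sentence definitions are silent; both follow the original
algorithms' published descriptions and are isolated behind parameters.

## Synthetic cohorts

The generator's defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_samples` | 40 | cohort size |
| `class_mix` | 0.5 | fraction of HRD-like samples |
| `purity_range` | (0.4, 0.9) | per-sample tumor purity, uniform |
| `base_ploidy` | 2 | balanced background state (1,1); 4 allowed |
| `event_rates` | LOH 1.0, telomeric AI 1.0, gain 1.0, whole-chrom LOH 0.3 | expected events/genome, scar-poor class |
| `hrd_multiplier` | 10 | rate multiplier for HRD-like samples |
| `noise_sd_lrr` | 0.15 | Gaussian LRR noise (array-realistic) |
| `noise_sd_baf` | 0.03 | Gaussian BAF noise, clipped to [0, 1] |
| `gc_wave_amplitude` | 0.1 | LRR units per SD of marker GC |
| `hom_fraction` | 0.6 | homozygous markers (BAF near 0/1) |
| `gamma` | 0.55 | platform compression factor |

Event classes dose the metrics independently: interstitial deletion-LOH
(17–45 Mb, log-uniform), telomeric single-copy gains anchored at a
terminus (12–40 Mb), short interstitial gains (12–25 Mb), and
whole-chromosome copy-neutral LOH (qualifies for nothing — a deliberate
negative class).  Placement keeps 12 Mb of clearance between events,
centromere edges and chromosome ends (except a telomeric event's anchored
end).  Two consequences: (1) each event's qualification under every scar
rule is decidable in isolation at injection time, so the event ledger's
totals equal the truth profile's scores exactly; (2) event-length bounds
sit ≥ 2 Mb away from every scar threshold, so segment-boundary placement
error (at most half a marker gap) cannot flip a qualification on
noise-free data.  HRD-like samples land well above the 42 cut-off (HRD
sums typically 50–80), scar-poor samples well below (0–20).

The simulator does **not** model subclonality, replication-timing waves,
probe-specific bias, FFPE degradation, or germline CNVs.  Passing tests
demonstrate correctness of the scoring/estimation machinery under the
stated signal model — not performance on real arrays, whose noise is
neither independent nor Gaussian.

Signal rendering uses the standard allele-specific array model (README) with
LRR normalized at the sample's length-weighted mean ploidy ψ, the
convention allele-specific callers assume and the one that makes ploidy an
estimable parameter; `baseline="diploid"` switches to an absolute diploid
reference.  Homozygous markers keep BAF at 0/1 regardless of copy number
(the normal-cell allele matches), and the measured "B" allele is
randomized per marker.

## Estimation stage

**GC correction** residualizes LRR on GC with statsmodels' lowess
(local-linear, span 0.3, one pass, `delta` = 1% of the GC range), then
restores the genome-wide median so absolute calibration survives.  The
copy-number signal is (nearly) independent of GC, so it passes through to
the residual; an injected linear or smooth wave is removed essentially
completely (post-correction |corr(LRR, GC)| ≲ 0.002 at wave amplitude 0.3).
A constant GC column makes the step a logged no-op.

**Segmentation** minimizes, per chromosome, the within-segment sum of
squares of the LRR series plus the folded (≥ 0.5) BAF of heterozygous
markers, plus `penalty` per changepoint — solved exactly by
optimal-partitioning dynamic programming (O(n²), numba-accelerated with an
equivalent numpy fallback).  Heterozygous markers are identified
germline-free as raw BAF in [0.15, 0.85].  The default penalty is
BIC-like, `2·σ̂²·log n` summed over channels with σ̂ from median absolute
first differences, floored at 0.05: with near-zero noise the MAD estimate
collapses and smoother-residual wiggle (≪ 0.01 LRR) would otherwise
over-segment, while a true copy-number jump reduces the cost by orders of
magnitude more than the floor.  Segment bp bounds are inter-marker
midpoints (chromosome ends at the extremes), so segments always tile.

**Purity/ploidy fitting** inverts the signal model per segment on a grid
(purity 0.10–1.00 step 0.01 × ploidy 1.0–5.0 step 0.05) and scores the
marker-weighted squared distance of continuous allele copies from the
nearest non-negative integers.  Segments with fewer than 5 heterozygous
markers are excluded from the distance: their fallback BAF mean (folded
mean over all markers) is contaminated by genuine homozygotes — e.g. a
high-purity copy-neutral-LOH chromosome — and would bias the fit; they are
still called afterwards, where only the rounding matters.  A sample with
no segment of ≥ 10 heterozygous markers raises an "uninformative sample"
error (the analogue of real samples failing copy-number evaluability; this
is what degrades evaluability at extreme downsampling).

Branch selection: allele-specific distance surfaces are degenerate across
integer rescalings (purity ρ/k — or certain ρ·k — with all states shifted
by integers fits equally well; a flat diploid genome fits *every* purity at
ploidy 2, which is why purity is only estimable for aberrant samples).  On
near-noise-free input all branches reach the grid-quantization floor, so
the fit restricts the choice to local minima within a small band above the
minimum and prefers the ploidy closest to diploid, then the largest purity.
An earlier "smallest ploidy first" rule mis-selects on deletion-heavy
genomes (mean ploidy < 2), where the spurious branches sit at *lower*
ploidy than the truth.  With realistic noise the spurious branches sit
roughly k² above the floor and the plain argmin applies; the diploid
preference assumes near-diploid backgrounds (true for the simulator's
default; genuinely tetraploid genomes would need the `base_ploidy=4`
conditions and care).

**Integer calling** rounds the inverted copies at the fitted (ρ, ψ),
enforces major ≥ minor, and merges adjacent identical segments.  Noise-free
purity-1 cohorts round-trip exactly: pipeline scar scores equal truth
scores sample for sample.

## Concordance statistics

AUROC is the Mann–Whitney estimator (midranks; ties count ½) with a 95%
DeLong structural-components CI; the exact complement identity
`auroc(s) + auroc(−s) = 1` holds to the last bit.  AUPRC follows the
average-precision convention and is reported with its baseline, the
positive prevalence.  Spearman (average-rank ties) and Pearson carry
Fisher-z CIs with SE 1/√(n−3).  The panel joins samples pairwise-complete
(dropped counts logged, no imputation) and evaluates every scar component
and the sum against each binary comparator plus the continuous reference.

## Downsampling experiment

Markers are subsampled uniformly without replacement to the fixed grid
{0.25%, 0.5%, 1%, 2.5%, 5%, 10%, 20%, …, 90%} — fourteen proportions, ten
seeded replicates each (replicate seeds derived as
`base_seed·1000003 + crc32(proportion:rep) mod 2³¹`).  Every replicate
re-runs the full pipeline per sample and records the Spearman correlation
of HRD sums against a fixed reference (truth scores in simulation mode, or
any user-supplied column — the clinically validated reference score is
proprietary and unavailable) over evaluable samples; the summary statistic
is the median over replicates.  The optimal proportion is the smallest one
attaining the maximum median correlation among proportions whose median
evaluability clears a floor (default 0.95); replicates with < 3 evaluable
samples record an undefined correlation.  At the test problem size
(10,000 markers) the curve shows low-end collapse (complete
unevaluability at 0.25%) and a high plateau; the interior optimum reported
on real clinical arrays with 20–80× more markers is not expected to
reproduce at this scale, only the qualitative shape.

## Problem sizes

Defaults chosen for the bundled experiments: 10,000–20,000 synthetic
markers per sample (the estimation behavior of interest — detectability of
≥ 12 Mb events, evaluability collapse under downsampling — is already
expressed at this density), cohorts of 10–50 samples, 14 × 10 downsampling
grid on 20 samples.  All stages are deterministic given their seeds; CLI
runs are byte-identical on rerun.

## Known limitations

* The segmentation penalty floor and the heterozygous band are tuned to
  the simulator's signal scale; grossly different LRR scalings need a
  manual penalty.
* Purity is unidentifiable for aberration-free genomes (reported by
  convention as the largest purity at diploid ploidy) and biased for
  genomes whose every aberration is consistent with a rescaled branch.
* The scar definitions here follow the published one-sentence definitions
  plus the cited originals' arm conventions; proprietary implementations
  may differ in unstated details (centromere handling, length floors), so
  absolute score values are comparable only within a convention.
* GC correction assumes the wave is a smooth function of GC alone;
  position-dependent waves uncorrelated with GC are untouched.
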