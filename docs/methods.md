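# Methods

This note documents the models implemented in `edmakit`, their assumptions,
the defaults that matter, and what the synthetic-data generator does and
does not emulate.

## Assay model

The platform interrogates methylation indirectly. MseI (recognition TTAA,
cut T/TAA) fragments the genome into short AT-flanked pieces while sparing
GC-rich regions; adaptors are ligated; a cocktail of methyl-sensitive
restriction endonucleases (MSREs: HpaII C/CGG, HinP1I GC/GC, AciI C/CGC)
then cleaves every *unmethylated* copy of its site. Only intact — i.e.
methylated, "protected" — fragments amplify in the subsequent
ligation-mediated PCR and produce array signal. Consequences built into the
code:

* the analysis unit is the MseI–MseI fragment; probes map onto fragments;
* a fragment with no internal MSRE site is never cleaved and therefore
  carries no methylation information (`has_msre` gates informativeness);
* an MSRE motif straddling an MseI cut is destroyed by fragmentation and is
  not counted ("strictly inside" rule);
* MSRE sites are counted on both strands for the non-palindromic AciI
  (CCGC/GCGG), configurable, since cleavability does not depend on strand.
  Cut coordinates are modelled for MseI only; for MSREs only site
  presence/counts matter.

Coordinates are 0-based half-open everywhere internally, BED on disk.

## Cleavage quality control

With perfect per-cycle doubling, the uncleaved residue of the unprotected
spike-in template is `2^(−ΔCt)` where `ΔCt = Ct(unprotected) −
Ct(protected)` within each enzyme's template pair; cleavage efficiency is
`1 − 2^(−ΔCt)` (ΔCt = 5 ⇒ 96.875 %, reported as 97 %). The reference is the
protected member of the same pair, not the undigested positive control; the
amplification efficiency (default 2.0/cycle) is a parameter for sensitivity
analysis. A negative ΔCt is treated as an assay failure, not clamped. The
sample gate is strict: every one of HpaII, HinP1I, AciI must exceed 0.97.
The array-side limit of detection is the negative-control mean plus four
sample standard deviations (n−1 estimator; the estimator choice is ours —
the quantity is only ever compared against itself). The genomic-digestion
check reports the fraction of MseI-centred control probes above the LOD;
near zero means fragmentation was complete.

## Normalization and inference

* **M/A**: M = log₂(Cy5/Cy3), negated on dye-swap arrays; A = mean log₂
  intensity. Probes with a nonpositive intensity in either channel on any
  array are excluded (no background subtraction is modelled) and reported.
* **Loess**: per array, M := M − f̂(A) with robust locally weighted
  regression; span 0.3 of the data, 3 robustness iterations (conventional
  two-color defaults, configurable). The implementation delegates to
  statsmodels `lowess` with an interpolation `delta` of 1 % of the A-range,
  far below the bandwidth.
* **Inter-array**: full quantile normalization of the M matrix (every
  array's sorted vector becomes the rank-wise mean; ties averaged;
  idempotent). The phrase "quantile scale normalization" is ambiguous
  between quantile and scale normalization, so a median-absolute-deviation
  scale variant is available behind a config switch (`inter_array_method =
  scale`); quantile is the default.
* **Moderated t**: one-sample fit on oriented M. Residual variances s² with
  d = n−1 df are shrunk toward a prior s₀² with weight d₀:
  s̃² = (d₀s₀² + ds²)/(d₀+d); t = M̄/(s̃/√n) on d₀+d df. The prior is
  estimated by matching the moments of log s² to its log-F distribution
  under the hierarchical model; the trigamma inversion is solved by
  bracketed root finding. When the observed spread of log s² does not
  exceed pure χ² noise, d₀ = ∞ and every probe uses s₀² (this is the
  typical outcome on the simulator's homoscedastic noise). Forcing d₀ = 0
  reproduces the ordinary t-test exactly; the estimated path matches
  Bioconductor limma's `eBayes` to ~1e-15 (cross-checked in the test suite
  via Rscript).
* **DMR rule**: p < 0.05 (raw, per the platform's criterion — no multiple
  testing correction in the headline rule) and |M̄| ≥ 1.5; direction from
  the sign of M̄ (positive = hypermethylated in group A).
  Benjamini–Hochberg q-values are reported as an additional column. The
  probe is the analysis unit; fragment-level aggregation, when wanted, is a
  mean of probe M per fragment before fitting.

## Annotation and enrichment

Promoter windows are the 1 kb / 5 kb / 50 kb intervals 5′ of the TSS
(strand-mirrored, clipped at the chromosome start); exon/intron flags come
from BED12 models, and a fragment spanning a boundary carries both. Island
relation: overlap ⇒ island; otherwise the gap d to the nearest island maps
to shore (d ≤ 2000, including abutting intervals), shelf (2000 < d ≤ 4000),
open sea (d > 4000). Islands arrive as a BED track (island calling is out
of scope); their length and density classes use the 20th/80th
linear-interpolation percentiles of the surveyed cohort, with values
exactly at a cut assigned to the intermediate class, and density defined as
CpG count / length (the density metric is our choice; an observed/expected
variant would slot into the same field). A fragment overlapping several
islands takes the nearest/overlapping one's classes, ties to the longer
island. Repeat classes are the text before "/" in the BED name field
(RepeatMasker convention).

Enrichment counts, per category, DMRs hypermethylated in each group — a DMR
contributes to *every* category it belongs to — and reports
log₂((n_A + c)/(n_B + c)) with Haldane–Anscombe pseudocount c = 0.5 so
empty cells stay finite. Hot spots average p-values over ±100 kb around
each probe (probe position = fragment midpoint); the output is explicitly
an indicator, not a statistic. Circos windows tile chromosomes from 0 in
fixed 5 Mb half-open bins (empty bins emitted as missing) and the top-100
DMR table ranks by ascending p with ties broken by descending |M̄|.

## Synthetic-data generator

The simulator emulates the *structure* of the assay's data, with truth
recorded for every quantity a test needs:

* genome: i.i.d. background with A=T=0.30 (AT-rich, mean MseI fragment
  ≈ 120–130 nt — the short-fragment regime the assay is designed for),
  island blocks re-drawn with C/G share boosted by √5 per base (factor 1 =
  no enrichment), gene models with 2–8 exons, repeats from {LINE, SINE,
  LTR, Low_complexity, Simple_repeat};
* fragmentation is *not* re-modelled: the simulator calls the production
  digest module on its own genome;
* methylation: per-fragment Beta draws (concentration 20) around
  category-conditional means — islands 0.15, repeats 0.85, other 0.50;
* planted DMRs: drawn among probe-bearing (MSRE-containing) fragments;
  exactly round(0.85·n) hyper in group A by construction. The planted log₂
  difference is split symmetrically between the groups
  (signal_A = base·2^(+ΔM/2), signal_B = base·2^(−ΔM/2)). The symmetric
  split keeps a probe's average intensity A at the pair mean, so
  differential status is not confounded with intensity: with a one-sided
  shift, the extreme-A range of the array is populated exclusively by DMRs
  and the robust loess partially fits — and removes — the planted effect.
  Noiseless recovery is exact (M = ΔM) either way;
* intensities: expected channel signal = 2000·methylation + 20 background,
  multiplicative log-normal noise of 0.4/√2 log₂ units per channel (M-noise
  sd 0.4), and a smooth dye bias of 0.2 + 0.05·A log₂ units added to Cy5 so
  the loess step has a real trend to remove; dye-swap pairs share the
  biological signal and differ only in channel assignment and noise;
* controls: negative probes at background; MseI genomic controls at
  background (complete digestion), tiled every 25 kb — a desk-scale
  stand-in for the production array's 1-per-Mb tiling on a gigabase
  genome; protected spike-ins at full scale, unprotected at
  (1−f)·scale + background;
* spike-in Ct: ΔCt = −log₂(1−f) plus Gaussian noise (sd 0.05 cycles);
  f = 1 is rejected at config time.

Default study conditions: 2 × 3 Mb chromosomes, 20,000 probes, 200 planted
DMRs of |ΔM| = 2 (85 % hyper in A), 4 dye-swap pairs (8 arrays), seed 42.
All randomness flows from one seeded `numpy` generator, so config + seed
fixes every output byte-for-byte.

**What passing tests do and do not show.** The generator's noise is
homoscedastic and log-normal, probes are independent, biological replicate
variance is folded into the measurement noise, and there is no spatial
artefact, background gradient, probe-sequence effect, or partial-digestion
kinetics. Recovery results (sensitivity ≥ 0.9, FDP ≤ 0.1 at the defaults)
therefore validate the *pipeline logic* — orientation, normalization,
shrinkage, thresholding — not performance on real hybridizations, where
effect sizes are smaller and noise is structured. Real-data headline
counts from gigabase genomes are out of scope at desk scale.

## Numerical choices and edge cases

* Percentiles use numpy's linear interpolation; island cohorts under 5 are
  refused rather than classified.
* A genome without CpGs reports the CpG coverage fraction as NaN rather
  than raising.
* Probes with zero residual variance are excluded from the log-moment
  prior estimation (they cannot enter log s²); p-values are clipped away
  from exact 0 to honour the (0, 1] contract.
* Quantile normalization requires a complete matrix; incomplete probes are
  excluded (and reported) when the M matrix is built.
* Hot-spot smoothing uses prefix sums per chromosome (O(n log n)); the
  quadratic scan survives only as a test oracle.
* Bedgraph export refuses overlapping intervals by default; a "merge"
  policy clips starts to the previous end (used for the per-probe midpoint
  tracks, where adjacent 1-nt intervals can coincide).
* Test problem sizes: the standard simulation (20,000 probes, 8 arrays)
  runs the full chain in a few seconds; property suites use 5 kb sequences,
  1 Mb genomes and 1,000-probe tracks, sizes at which the independent
  oracles remain exact and fast.

## Known limitations

* Between-group ordination (eigen-analysis style sample overviews) and
  transcriptome integration are not implemented; a join on gene id is the
  intended route for the latter.
* Vendor feature-extraction file formats are not parsed; intensities enter
  as plain long-form TSV.
* The annotation module treats CTCF or other TF-site tracks as out of
  scope; the island relation assumes islands are non-overlapping, as UCSC
  tracks are.
* The CLI is a thin wrapper; anything beyond stage-by-stage runs (custom
  designs, contrasts with covariates) is library territory.
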