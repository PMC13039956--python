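# Methods

## The screen

`svfold` quantifies the effect of a somatic structural variant (SV) on
local 3D genome folding by in-silico mutagenesis: build a reference (REF)
and an alternate (ALT) DNA sequence differing only by the variant, predict
a chromatin contact map for each, and measure how much the maps differ.
The screen then aggregates these per-variant scores across a tumor cohort
to calibrate a "highly disruptive" cutoff, find recurrently disrupted 1 Mb
regions, weight disruption by enhancer activity, and relate disruption to
tumor stage and expression.

## Window geometry

All predictions use a fixed geometry: an input window of L_in = 2^20 =
1,048,576 bp whose central 448 × 2,048 = 917,504 bp are visible in the
contact map; 65,536 bp (32 bins) on each side are cropped margin. The
window is centered on the SV midpoint ((start+end)//2); windows that
would leave the contig are shifted (never truncated), and a contig
shorter than L_in is an error. The 2,048 bp bin size is implied by the
span of published example windows (917,504 / 448).

## Sequence construction

ALT sequences are length-matched to L_in so REF and ALT maps are
cell-by-cell comparable:

- **DEL** removes [start, end) and extends the window flanks by
  ceil(l/2) left / floor(l/2) right (left-heavy for odd lengths).
- **DUP** inserts a tandem copy after the span and trims the two window
  ends by the same ceil/floor split.
- **INS** places the inserted sequence at `start` with symmetric trimming.
- **INV** reverse-complements the span in place (no length change).
- **BND** builds a fusion of two L_in/2 arms — the arm ending at the
  recorded breakpoint joined to the partner arm, reverse-complemented
  when the bracket orientation joins like strands. Each breakend is
  scored twice (once per breakpoint window) against the reference window
  centered on that breakpoint, with the half of the map contributed by
  the partner locus masked; the two half-window scores are averaged.
  This extends the averaging the ABC score defines for multi-breakpoint
  variants to the plain scores, for consistency.

Each variant is scored under four augmentations — none, −1 bp window
shift, +1 bp window shift, reverse complement — and the per-augmentation
scores are aggregated by the median (mean also stored). For the reverse
complement the difference map is mirrored back before track accumulation
so per-bin tracks stay in genomic orientation.

Masking: scores are computed over upper-triangle cells at least 2 bins
off the diagonal whose row and column both avoid the variant's bins (the
SV span plus the ALT junction bin for DEL/INS). Scores therefore reflect
changes to contacts *outside* the variant.

## Scores

- `MSE`: mean squared REF−ALT difference over the evaluation cells.
- `CORR`: 1 − Pearson r over the same cells (0 = identical, 2 = perfectly
  anticorrelated). If either map is constant over the evaluation cells,
  CORR is undefined and reported as 0 with a `zero_variance` flag.
- 1D disruption track: `track[i]` = mean of (REF−ALT)² over row i's
  unmasked cells; masked bins are 0. The mean of the track over rows
  approximates the overall MSE (small deviations come from near-diagonal
  row-count differences).

Both scores are invariant to adding a constant to both maps; MSE scales
quadratically and CORR is invariant under joint scaling — the predictor's
absolute scale therefore never matters, only REF−ALT contrasts.

## The toy predictor

Trained model weights are out of scope; the predictor is a contract
(`predict(seq) -> 448×448 symmetric map`, deterministic) plus a
mechanistic toy implementation whose folding grammar is explicit:

- scan the visible window on both strands for a **boundary motif**
  (default `GCCACCAGGTGG`, CTCF-core-like); bins touched by a match are
  boundary bins, and maximal runs between them are blocks (TADs);
- `map[i,j] = −γ·log10(|i−j|+1) + c_in·[same block] + c_out·[otherwise]
  + loop_bonus·[convergent anchor pair within loop_max_dist]`,
  with γ=1, c_in=0.6, c_out=0, loop_bonus=0.8, loop_max_dist=200 bins;
  anchor motif default `TTACGCGTAACC`, loops require a forward hit
  upstream of a reverse-strand hit;
- cells with |i−j| < 2 are zeroed and excluded from all scoring;
- a window containing **no** boundary motif is pure distance decay (no
  block elevation): a window without delimiters has no TAD structure,
  rather than being one giant block. This makes the motif-free map the
  model's explicit null.

A motif match is credited to *every* bin its 12 bp span overlaps, which
makes bin assignment exactly mirror-symmetric under reverse complement;
consequently `predict(revcomp(s))` equals the 180°-rotated map of
`predict(s)` bit for bit, and the revcomp augmentation reproduces the
unaugmented score exactly. N bases never match a motif. Motifs are
validated non-palindromic and strand-disjoint so forward/reverse hits are
unambiguous.

The motif scan is a vectorized numpy candidate-prefilter (three probe
bases compared across the window, candidates then verified in full) —
exhaustively equivalent to naive search at ~75 ms per scored variant on
one CPU.

## Callset filters

Variants are read from Manta-style VCFs (symbolic ALTs; breakends as
bracket-notation mate pairs joined by MATEID, emitted once per pair).
Filters, applied in order and tallied in a conserved report: non-PASS
calls; breakends whose mate record is absent; non-BND variants longer
than 500 kb (the remaining map area is too small to interpret); and
variants sharing identical breakpoints (chrom, start, end, svtype) with
another variant — *all* members of such a group are removed (a
`keep_one` mode exists). Duplicate matching is per sample by default
(`duplicate_scope="cohort"` widens it); the within-sample default is a
deliberate choice where the matching scope was ambiguous.

## ABC weighting

Candidate regulatory elements (~500 bp) with ATAC and H3K27ac read
counts get Activity = geometric mean of the two counts. Any visible bin
overlapping an element is assigned its activity (max over elements by
default; `sum` selectable); other bins are 0. The ABC disruption score is
the activity-weighted mean of the 1D disruption track, Σ A·D / Σ A — the
reading of "weighted average of the two tracks" consistent with
"activity multiplied by the disruption score for that region"; windows
with no enhancer score 0 and are flagged. For breakends the final score
is the arithmetic mean of the per-breakpoint weighted averages. Rank
shifts compare descending rankings under plain MSE and ABC scores:
`normalized = (rank_mse − rank_abc) · 1000/N`, up-/down-weighted at
|normalized| ≥ 40. The 1000/N scale makes the published ≥|40| threshold
select well under 1% of variants on cohort-sized inputs; the constant
and threshold are both config knobs, as the exact normalization was left
open by its description.

## Recurrently disrupted regions

The genome is divided into 1 Mb bins; entry (s, b) of the sample-by-bin
matrix is the maximum aggregated score among sample s's SVs intersecting
bin b (breakends count at both breakpoint loci). Sample rows are embedded
with UMAP (seeded) and clustered with DBSCAN (eps 1.0, min_samples 4) —
the operationalization of what was originally a visual step; the review
artifacts (embedding, labels, per-bin table) are exported so a human can
still inspect them. For each cluster, the candidate bin is the one every
member disrupts past the score cutoff (smallest coordinate on ties);
recurrence is tested per bin with a one-sided binomial test of the
disrupted-sample count against the genome-wide mean per-bin rate,
BH-corrected across bins, calling RDRs at q < 0.05. Bins whose predicted
reference map fails a Pearson r ≥ 0.5 concordance check against a
supplied experimental map are dropped (`reference_quality_filter`);
without a map the bin is kept flagged `unchecked`. The RDR score cutoff
defaults to the cohort's 98.8th percentile but is an independent config
value from the "highly disruptive" label.

## Cohort statistics

- **Cutoff calibration** evaluates percentile grids 90–99 (step 1) and
  98.5–99.9 (step 0.1) on both metrics, recording thresholds and, per
  grid point, the 5 lowest-scoring variants above threshold per metric
  (10 total) as the visual-review list. "Highly disruptive" = strictly
  above the chosen percentile (default 98.8) on either metric.
- **Initial vs progressive**: per participant with both stages, one
  sample per stage is drawn uniformly (seeded, persisted); progressive
  SVs exactly matching an initial SV on (chrom, start, end, svtype) are
  subtracted; Welch's t compares the remaining progressive scores to the
  initial scores (positive = progressive more disruptive). Count
  log-fold-change uses the full callsets.
- **Disrupted genes**: protein-coding genes intersecting the ±300 kb
  flanks of a highly disruptive SV but not the SV itself; a config switch
  applies the exon-overlap criterion instead (intron-only overlaps then
  qualify). Genes hit in ≥ 2 tumor types are marked recurrent.
- **Peak-overlap enrichment**: per-variant fraction covered by a peak
  set; two-sided Mann–Whitney U between disruptive and other variants
  within each length bin (log10 decades by default).
- **Expression extremity**: focal sample's TPM ranked against same-type
  samples with no SV within 300 kb of the gene (the same flank as the
  disrupted-gene rule, adopted where "near" was unquantified); strict
  inequalities, ties reported separately.
- **Breakpoint CIs and repeats**: total CI width = CIPOS width + CIEND
  width; a variant is repeat-matched when both breakpoints ±50 bp overlap
  repeats of the same family.
- **Associations**: Spearman score~length and score~purity; SVs classed
  coding / intronic / intergenic by exon/gene-span overlap.

## Synthetic study generator

The generator emulates the statistical structure every stage consumes,
as a pure deterministic function of a seeded config (sub-generators are
spawned per stage from one SeedSequence):

- **Genome**: 3 contigs × 6 Mb of uniform random sequence; boundary
  motifs planted every ~400 kb (jitter 60 kb); convergent anchor pairs
  inside blocks at rate 0.5. Chance occurrences of any motif are scrubbed
  so planted copies are the only ones the predictor sees. Genes
  (5 exons × 200 bp, ~2 kb introns, 90% protein-coding), repeats
  (SINE/LINE/LTR/Simple_repeat) round out the annotation.
- **Epigenome**: 400 enhancers of 500 bp, 70% placed within 20 kb of a
  gene start; ATAC and H3K27ac counts are negative-binomial (mean 50,
  dispersion 0.5) via a shared per-element gamma factor, which also
  induces their correlation — overdispersion and coupling typical of
  real count tracks.
- **Cohort**: 6 tumor types in 3 categories, 10 samples per type;
  Poisson-35 SVs per sample; SV-type mixture matching the target cohort's
  overall fractions (BND 0.48, DEL 0.33, DUP 0.10, INS 0.05, INV 0.04),
  tilted slightly per category; passenger intervals uniform, motif-free,
  50 bp–5 kb log-uniform. 25% of samples are progressive: paired with an
  initial sample from the same participant and sharing half of its SVs.
  Drivers are DELs removing exactly one boundary motif: 8 carriers
  (spread over ≥ 2 tumor types) in each of 2 designated 1 Mb bins, plus
  4 enhancer-proximal drivers near high-activity enhancers for the ABC
  analyses. Driver CIs are wider (20–60 bp) than passengers' (≤ 10 bp).
- **Expression**: log-normal baseline per gene (meanlog 3, sdlog 0.6,
  per-sample noise 0.3); carriers of a driver within 300 kb of a gene are
  shifted by ±1.5 log2-fold (sign recorded in the truth table).

What the generator does **not** emulate: realistic chromosome-scale
sequence composition, mutational signatures, subclonality/purity effects
on calling, co-occurring or complex SVs, and cell-type-specific folding.
Passing tests therefore demonstrate that the pipeline's logic recovers
planted signals under its stated assumptions — not that the toy
predictor approximates a trained model's biology.

## Numerical and design choices

- Evaluation on the upper triangle: for MSE symmetric cells are
  redundant; Pearson differs from the full-matrix value only through
  duplicated cells, so the triangle is used for both.
- CORR uses Pearson (the "1 − correlation" reading), computed on the
  identical cell set as MSE.
- Percentile thresholds use numpy's default linear interpolation.
- Rank ties break by stable input order (sv_id order), making ranks
  permutations of 1..N by construction.
- Per-variant scoring failures at cohort scale are logged and excluded,
  never fatal.
- Problem sizes in tests and the acceptance script (60-sample cohorts,
  ~2,100 variants per seed, 5 seeds for the recovery property, 10–100
  random maps for oracle checks) were chosen so the full suite exercises
  every stage end to end at desk scale.

## Known limitations

- The toy predictor's map is piecewise-constant over blocks; real contact
  maps have richer within-TAD structure, so absolute score magnitudes are
  not comparable to a trained model's.
- Windows are compared cell-by-cell without coordinate re-alignment
  beyond masking; for large length-changing variants the ALT map is a
  shifted view of the genome, which inflates scores with variant length —
  consistent with the length association the screen itself reports.
- Effects beyond the 1 Mb window (compartment-scale changes, multi-SV
  haplotypes, chromothripsis) are out of scope by design.
- The UMAP/DBSCAN operationalization of cluster detection has free
  parameters (eps, min_samples); defaults were set for cohorts of tens
  of samples and are config-exposed rather than universal.
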