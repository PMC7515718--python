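# Methods

## Coordinate and overlap conventions

All coordinates are 0-based half-open (BED native), on disk and in memory.
Overlap means ≥ 1 shared base on the same chromosome; bookended intervals
(gap 0) do **not** overlap but **are** merged by `merge_intervals`, matching
bedtools-intersect and bedtools-merge defaults. Summit-centred resizing to
width *w* takes `[summit − ⌊w/2⌋, summit + ⌈w/2⌉)` (odd widths put the extra
base on the right) and clips to `[0, chromosome length)` rather than
discarding, preserving peaks near chromosome ends. A narrowPeak summit of −1
falls back to the interval midpoint so plain BED-derived peaks stay usable.

## Conserved-site construction

ChIA-PET peaks are resized to 500 bp around their summits. A reference-set
peak (first set in the given order, for reproducibility) is *conserved* when
it overlaps ≥ 1 peak in at least `min_cell_types − 1` of the other sets;
the default requires support in every set. "Super conserved" sites
additionally require overlap with `min_datasets` compendium ChIP-seq sets
(default: all), reflecting the near-universal support that the notion of a
super-conserved site implies; both thresholds are explicit parameters
because intermediate stringencies are scientifically reasonable. Each
retained site carries its compendium support count (the conservation
histogram is the distribution of these counts) and the mean signal of its
best-overlapping supporting peaks.

## Overlap-ratio screen

Factor peaks are sorted by signal (narrowPeak column 7) descending — ties
broken by genomic position for determinism — truncated to the top 100,000,
and resized to 200 bp, as are the reference sites. The ratio is the
fraction of reference sites hit. The cap sort key follows the use of
binding strength for the genome-wide top-K trimming; the screen is monotone
in the cap. Factors are ranked by their maximum ratio over datasets (max,
not mean, because a factor's best dataset is its best evidence of
co-localisation), ties lexicographic. The top-K comparison pairs ratios by
(factor, dataset) and reports least-squares slope/intercept and Pearson r
per K; a zero-variance axis is flagged and reported as r = 0 rather than
NaN.

## Candidate regulatory modules

All factor peaks are resized (default 100 bp — merging wider peaks chains
nearby modules together, and 100 bp regions already produce long merged
regions) and merged; every input peak lands in exactly one CRM. CTCF CRMs
contain exactly one CTCF peak (anchors must map one-to-one to binding
sites), optionally requiring a cohesin subunit member and ChIA-PET peak
overlap. Widths are summarised by the symmetric percentile interval
covering a central mass (default 90% → 5th/95th percentiles,
linear-interpolation definition).

Grouping uses Ward-linkage hierarchical clustering on the binary CRM ×
factor membership matrix, cut at k = 4. Binary membership was chosen over
signal values because only the four-level co-binding ordering is consumed
downstream; a signal-weighted matrix is available behind `use_signal`.
Clusters are relabelled dense > medium > light > CTCF-solo by descending
mean co-binding count, so the label ordering is guaranteed by construction;
CTCF-solo is the lowest-mean cluster rather than a hard zero-count rule.
Unreachable k (e.g. all-identical rows) is an error, not a silent merge.
Group comparisons use two-sided Wilcoxon rank-sum (Mann–Whitney) tests.

## Loop-anchor statistics

Anchor loop strength is the sum of PET counts over all loop ends
overlapping the anchor; a self-looping anchor contributes its PET count
once per end, which makes the conservation law
`Σ_anchors strength = Σ_loops pet × (retained ends hit)` exact and testable.

The co-binding test partitions anchors by whether their (200 bp-resized)
CTCF peak overlaps a (200 bp-resized) factor peak — the same convention as
the screen — and applies a **one-sided** Wilcoxon rank-sum test (co-bound
greater), since the screened hypothesis is directional; a flag switches to
two-sided. The exact null distribution is used when both strata are small
(≤ 60), which resolves complete separations far beyond the asymptotic
tail; large strata use the normal approximation. The Bonferroni-adjusted
p-value is reported under the name "FDR" for continuity with common usage
in this literature, but it is a family-wise adjustment; the screen gate is
−log10(FDR) ≥ 20 and untestable factors (an empty stratum) are excluded
rather than given a score.

Binding is normalised as `log2(count·10⁹ / (length·10⁶))`; the precedence
reading of the normalisation only shifts values by a constant, leaving the
consumed Pearson correlations unchanged. Zero counts (and zero loop
strengths before their log2 transform) take a +1 pseudocount, consistent
with the +1 used in loop fold changes. Stratified correlations report
−log10(Bonferroni-adjusted p), forced to exactly 0.0 (never −0.0 or NaN)
when the stratum has n < 1000 or raw p > 0.01 — the reliability gate.

Chromatin-state annotation collapses the 18 states to five categories
(promoter, enhancer, transcription, reprPCWk, quies; unknown labels fall to
quies), assigning each site the category with maximal base overlap, ties by
the fixed priority promoter > enhancer > transcription > reprPCWk > quies.

Differential loops: filter `max(control, knockdown) < 2`; fold change
`(control+1)/(knockdown+1)`; differential iff strictly > 2-fold in either
direction, with direction recorded. Swapping the condition columns swaps
directions but preserves the differential set. The binding-change binning
(default edges ±1 and ±log2(1.2), i.e. ±2-fold and ±1.2-fold) is
configurable since no canonical edges exist.

## Factor-pair networks

Each loop contributes its strength to every (a ∈ anchor-A factors,
b ∈ anchor-B factors) ordered occurrence, folded onto unordered edges.
Cross-product counting (rather than per-loop deduplication) was chosen
because it makes the conservation law `Σ edges = Σ_l s_l·|A_l|·|B_l|`
exact and the result independent of anchor labelling; self-pairs are kept
because they carry the homotypic CTCF–CTCF signal. Export is a
Cytoscape-loadable TSV, deterministic (score descending, then names).

## EP loops and classification

Candidate promoters are TSS ± 500 bp, one per transcript (not merged);
active elements must intersect ≥ 1 transcribed interval. A loop qualifies
as an EP loop only when the enhancer and promoter sit on *opposite*
anchors; both orientations are expanded as cross products without
deduplication, so the expansion count is exactly
`Σ_loops Σ_orientations (enhancers on one side × promoters on the other)`.

Classification of a CTCF loop against an EP loop orients both loops by
genomic order and evaluates, in fixed precedence: (4) reciprocal anchor
overlap (first↔first and second↔second, ≥ 1 bp each); (1) EP span strictly
inside CTCF span; (2) the converse; (3) spans overlap; (5) disjoint or
different chromosomes. Containment is strict on both ends, which makes
role exchange map categories 1↔2 exactly and leaves 3/4/5 fixed; boundary
cases (shared span endpoints without reciprocal anchors) therefore fall to
category 3. Every pair receives exactly one category. Gene-expression
integration is a join of per-gene fold changes onto promoter category
membership compared with a Kruskal–Wallis test; expression estimation
itself is out of scope.

## Synthetic data: what it emulates and what it does not

The generator stands in for a multi-cell-type CTCF compendium, co-factor
ChIP-seq sets, ChIA-PET/HiChIP loops, two-condition loop counts, an
18-state segmentation and TSS/enhancer/transcription tracks. Default
conditions: two 10 Mb chromosomes; 2,000 CTCF sites on a jittered 2 kb grid
(≥ 1 kb apart so 500 bp site windows never collide); 4 cell types at
conservation probability 0.9, presence optionally coupled to the signal
quantile to plant "conserved sites bind more strongly"; lognormal(3, 1)
peak signals (heavy-tailed, like MACS2 enrichments); factor peaks placed
within ±50 bp of distinct CTCF summits for a planted fraction *f*, plus
background peaks whose summits stay > 500 bp from every CTCF summit — the
avoidance makes *f* the exact expected overlap ratio; 2,000 loops between
same-chromosome sites with PET = 1 + Poisson(5), multiplied by the boost
once per promoting factor bound at either anchor; planted differential
loops split their fold symmetrically (control mean = pet·√fold, knockdown
mean = pet/√fold) so the planted ratio is exact; segment lengths uniform
1–20 kb with quiescent-dominated state frequencies; TSS/enhancer centres
on a 3 kb grid so candidate regions never collide and the active truth
table is exact.

One integer seed drives a root `SeedSequence`; each output family uses a
fixed spawn key, so outputs are byte-identical under a fixed seed and
adding an output never perturbs the others.

Not emulated: sequence content and motifs, read-level noise, peak-caller
artefacts, chromosome-scale covariates (GC, mappability, A/B compartments),
distance decay of contact frequency, and inter-factor correlation beyond
CTCF co-binding. Passing tests therefore demonstrate the correctness and
operating characteristics of the statistics under planted structure, not
performance on real data with those confounders.

## Problem sizes and numerical choices

Test and acceptance runs use 2,000 CTCF sites, 2,000 loops, ~1,500–1,800
retained anchors, 10,000-loop Monte-Carlo nulls and 500 label permutations —
sizes at which binomial/permutation tolerances (3 SE bands, α + 2 SE
bounds) are tight enough to be meaningful while the whole suite stays
fast. Planted screening conditions use co-binding fraction 0.3 for the
loop-promoting factor: at higher fractions most loops carry the factor at
one end or the other, which contaminates the non-co-bound stratum and
dilutes the contrast — a real phenomenon worth noting when interpreting
screens of near-ubiquitous factors like cohesin.

## Known limitations

- `conserved_chiapet_peaks` reports reference-set intervals only; sites
  absent from the reference cell type are not recovered.
- The exact Wilcoxon null is only used for small strata; very extreme
  asymptotic p-values (< 1e-300) saturate to the float limit before the
  −log10 transform.
- The EP expansion does not deduplicate (enhancer, promoter) pairs that
  qualify in both orientations of the same loop; such pairs are rare and
  counted per orientation by design.
- Blacklist filtering is exposed as a generic exclude-regions operation;
  no blacklist is bundled.
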