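# Methods

## Coordinate and data model

All regions are 0-based half-open (BED convention); GTF input (1-based
inclusive) is converted on read, with the TSS at the record start for
plus-strand genes and at the end for minus-strand genes. One TSS per gene:
isoform-aware TSS selection is out of scope. Enhancer–gene association uses
the gene whose TSS is closest to the region midpoint (ties: smaller TSS
coordinate, then gene id); the 100 kb proximity rule is a closed bound on
|TSS − midpoint|. Promoter exclusion removes regions whose **midpoint**
falls within ±2 kb of any TSS — the center rule used by common
peak-annotation tools; the alternative (any-overlap) would exclude slightly
more regions.

## Differential enhancer calling

Counts are modeled per region as negative binomial with a single common
dispersion φ (variance µ + φµ²). φ is estimated by method of moments from
within-group replicate variability: each (region, condition) cell with ≥ 2
replicates contributes its normalized-count mean m and variance v, and φ
solves Σ(v − m) = φ·Σm². The weighted form keeps the estimator stable when
per-region variance estimates have one degree of freedom; planted
between-condition changes do not bias it because only within-group
variability enters. With no replication anywhere the test falls back to
Poisson with a warning.

Significance comes from a conditional exact test on the two group sums
(the sum of n i.i.d. NB(µ, size r) variables is NB(nµ, nr)): conditional
on the total, the group-1 sum has a one-dimensional discrete distribution
whose outcomes no more probable than the observed one are summed,
two-sided. A **mid-p** correction (half weight on equally probable
outcomes) is applied so that null p-values are approximately uniform;
without it the discrete test is conservative by construction and the null
rejection rate would sit measurably below the nominal level. Above a total
of 20,000 the enumeration switches to a delta-method z-test on the log
ratio of group sums (variance 1/s₁ + φ/n₁ + 1/s₂ + φ/n₂). Multiple testing
is Benjamini–Hochberg.

Fold change is computed on library-size-normalized means with a
pseudocount of 0.5 (in normalized-count units), making calls invariant to
a global rescale of the stated library sizes. The activity floor defining
"active in both conditions" for non-IREs is 1 count per million per
condition (config). Calls partition regions into IRE (fold change ≥ 1.5
and FDR < 0.05, or p < 0.01 under the p-value criterion), non-IRE (active
in both, no significant increase), and excluded.

This stage deliberately replaces the DiffBind/edgeR/DESeq2 machinery with
a fully stated test; on real count tables it will approximate, not
bit-match, results from those tools.

## Motif scanning and statistics

IUPAC codes are compiled to regular-expression character classes with a
lookahead so overlapping windows are all reported. A sequence `N` satisfies
only a pattern `N`; a pattern `N` matches any base (the registry uses `N`
as "any", following the usual IUPAC reading). Soft-masked lowercase is
uppercased before scanning. Three strand modes: `forward`,
`both_dedup` (default; unique forward-coordinate windows matched on either
strand) and `both_sum`. The AP-1 consensus TKASTMA is its own IUPAC
reverse complement, so its counts are strand-mode-invariant; ETS
(VVGGAWVY) counts differ roughly two-fold between `both_sum` and
`forward`, which is why the mode is a flag rather than a constant.

Motif frequency is f = 1000·c/s with s the region's full native length.
Presence enrichment is a two-sided Fisher exact test on a 2×2 presence
table against a background sampled to match the foreground's GC histogram
(bin width = 2 × tolerance, largest-remainder apportionment, sampling
without replacement, seeded); it is a simplified, fully specified
substitute for a known-motif enrichment tool, not a reproduction of its
log-odds model. The relative overlapping ratio bins (typically 1 kb)
sequences by motif frequency — bin 0 is exactly motif-free — and reports
r_i = n_i/n₀, where n_i counts bin-i sequences overlapping ≥ 1 TF peak; a
length- and chromosome-preserving uniform repositioning of the peaks
(seeded) provides the flat control curve.

## Cross-species orthologous enhancers

Ortholog resolution keeps, per query gene, the candidate with the highest
percent identity (ties: lexicographically smaller target id). The mapping
aligns the IRE sequence into the ±100 kb window around the resolved
ortholog's TSS (truncated at chromosome ends with a warning) under the
affine gap contract cost(L) = 10 + 0.5·L with match +5 / mismatch −4; `N`
scores as a mismatch against everything, including itself.

Two numerical choices matter here:

* **End gaps.** `global_align` penalizes end gaps (pinned by the
  score("A","") = −10.5 contract). The window mapping instead leaves
  terminal gaps free — the referenced aligner's default — because with
  penalized end gaps the optimum provably scatters terminal query bases
  into the window flank whenever a chance match refunds the 0.5
  open-cost difference, inflating the mapped span and depressing identity
  even for a verbatim copy.
* **Window size.** A full DP on a 1 kb × 200 kb problem is wasteful, so
  above 20 kb the query is first localized by an edit-distance infix
  search (edlib HW mode) and the exact affine DP runs on the located
  subwindow plus a margin of max(100, len/4) bp; at or below 20 kb the
  window is aligned directly, keeping small-instance oracle tests exact.

The orthologous segment is the minimal target span covering all columns
where both rows hold residues; identity is computed over the columns
between the first and last query residue (window flanks trimmed). A
mapping below 50% identity is declared unmapped: the null identity of a
kilobase query forced into an unrelated window measures ~40–45% under
these scores, while genuine orthologs stay above 80% out to 20% per-base
divergence, so the floor is insensitive across a wide band. A mapped IRE
is *shared* if its segment overlaps (≥ 1 bp, config) an IRE of the target
species, otherwise *species-specific*. Gene-level classification
partitions IRE-associated genes into common / query-specific /
target-specific via the ortholog map, reporting ortholog-less genes
separately.

## Expression

TPM_i = 10⁶·(q_i/l_i)/Σ_j(q_j/l_j); columns sum to 10⁶ by construction.
Differential expression uses median-of-ratios size factors (falling back
to total-count ratios when no gene is detected in every sample) and the
same conditional exact NB test; the significance rule feeding the
single-cell step is fold change > 1.5 and FDR < 0.1. Note a power ceiling
inherent to the design, not the test: with 2+2 replicates at φ = 0.1 the
log-fold-change standard error cannot fall below √(2φ/n) ≈ 0.32, so a
3-fold induction sits near z ≈ 3.5 and the BH threshold at ~4% discoveries
caps sensitivity near 0.75 regardless of sequencing depth. The planted
benchmarks assert recovery within that attainable regime.

Single-cell values are log1p(10⁴·count/cell-total) per cell, which cancels
uniform per-cell depth differences. Per gene and cell type, the fold
change of mean normalized expression (injured vs uninjured) is guarded by
a pseudocount of 0.01 (config; the procedure does not define one for a
zero uninjured mean), and the gene is assigned to the argmax type —
largest *positive* change by default, with a flag for magnitude-in-either-
direction. Ties break by a fixed order (the canonical ten cardiac types,
then alphabetically). Types observed in only one condition are excluded
with a warning.

## Enhancer states and signal summaries

Signal matrices bin mean coverage around anchors (region midpoints, or
TSSs with minus-strand rows flipped); off-chromosome bases contribute
zeros with a warning. Enhancer states come from k-means (k = 3, k-means++,
10 restarts, fixed seed) on concatenated H3K27ac/H3K27me3 row vectors;
clusters are named by their mean signals — highest H3K27me3 → poised, then
higher H3K27ac → active, the remaining one primed. Conservation summaries
are means over a 1 kb window centred on the region midpoint; missing bases
are excluded rather than imputed, and a fully missing window is undefined
(NaN), never zero.

## Synthetic data

The generator's defaults define the study conditions: two species × two
2 Mb chromosomes of i.i.d. background at GC 0.42, 200 genes (minimum-
spacing grid with jitter), 300 enhancers of 500–1500 bp placed 4–50 kb
from a TSS while avoiding ±2 kb promoter zones and each other; 30% of
enhancers are IREs with injury fold changes uniform in [3, 6]; planted
motif content is 1 AP-1 + 3 ETS realizations per IRE and 0 + 1 per
non-IRE (each a uniform concrete realization of the IUPAC code, written at
non-overlapping offsets and re-counted on the emitted sequence so truth
and scanner agree). 60% of genes have a one-to-one ortholog (with
occasional weaker decoy candidates so best-ortholog selection is
exercised); each source-species IRE whose nearest gene has an ortholog
receives a copy near that ortholog's TSS, substituted per base at rate d
(default 0.1, always to a different base so identity ≈ 100·(1−d)) and,
with probability 0.5, *ablated*: each planted motif window is shuffled
until its family consensus no longer matches nearby (poly-A fallback,
mirroring the experimental motif mutation). Non-ablated copies are IREs of
the second species (→ planted class *shared*); ablated ones are not
(→ *species-specific*). ChIP counts are NB (dispersion 0.1, 2+2
replicates, base mean 50, library size 10⁶); RNA baselines are lognormal
(meanlog 4, sdlog 1) with IRE-linked genes induced 3-fold; single-cell
matrices use Poisson sampling at baseline mean 2 with 4-fold induction
confined to each gene's true type, 5 types × 40 cells per condition, and
0.7–1.3× per-cell depth variation.

What the generator does **not** emulate: repeat structure and
mappability/GC bias (read-level artifacts are out of scope), indel
divergence between orthologs (substitutions only), correlated
gene–enhancer placement beyond nearest-TSS linking, and single-cell
dropout beyond Poisson sparsity. Passing tests therefore demonstrate the
statistical machinery recovers planted structure under the stated noise
models, not robustness to alignment-level artifacts of real data.

Benchmark problem sizes used by the test suite and the acceptance script —
1,000 null + 200 responsive regions for differential calling, 2,000 genes
with 100 induced for expression, an 80-enhancer pair of 600 kb genomes for
orthology mapping, 50 genes × 5 types × 160 cells for single-cell
assignment — were chosen so the whole suite completes in well under a
minute while keeping binomial noise on the measured rates small.

## Known limitations

* The NB test is a stated simplification; real-data IRE counts will
  approximate published DiffBind/DESeq2-derived numbers, not match them.
* Orthology mapping assumes the ortholog table is given and correct;
  ortholog inference, liftover chains and synteny are out of scope.
* The motif model is presence/frequency of degenerate consensus codes; no
  position-weight-matrix scoring.
* Genomes are held in memory; the package targets region-scale and
  simulated inputs, not streaming over full mammalian assemblies.
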