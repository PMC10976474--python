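# Methods

This note documents the models and procedures implemented in `phostress`,
the parameter defaults and the reasoning behind them, what the synthetic
generators do and do not emulate, and the numerical conventions that affect
results.

## Coordinates and formats

Genomic coordinates are 1-based inclusive throughout (GenBank convention);
`start ≤ stop` always, with strand carrying orientation. BED output
converts to 0-based half-open at the writer boundary. TSV files are
tab-separated with `#` comments; Newick branch lengths default to 0.0 when
absent (this choice feeds directly into weighted Robinson–Foulds values and
is therefore stated here rather than hidden).

## Pho box model and scanning

The PhoB-binding motif is modelled as a degenerate half-site — the
cyanobacterial consensus `PyTTAAPyPyT/A`, compiled to eight allowed-base
sets `[{C,T},{T},{T},{A},{A},{C,T},{C,T},{T,A}]` — arranged in tandem:
two or more half-sites separated by short spacers. Scanning is a
Hamming-to-set sliding window on the promoter's coding strand; `N` counts
as a mismatch at every position.

Parameter defaults and why:

* **Promoter window 200 nt.** The deepest curated box position is −162, so
  200 covers every recorded case with margin. Configurable.
* **max_mismatch 1 per half-site.** Several curated boxes (e.g. the
  half-site `TTTAACTG`) miss the consensus at exactly one position; a
  budget of 1 admits them while 0 does not. Configurable 0–3.
* **Spacer lengths {3}.** Every curated multi-half-site box shows 3-nt
  spacers. Configurable set.
* **Position convention.** The first base of the start codon is +1,
  upstream positions are negative, there is no 0; a box's position is the
  offset of its *first* base. The curated tables do not state their anchor
  convention; this one is a documented choice.
* **Coding strand only** by default; `both_strands=True` also scans the
  reverse complement of each promoter.

Tandem assembly reports *maximal* runs of ≥ 2 half-site hits joined by
allowed spacers as one box anchored at the run's first base. Overlapping
hits are all reported (no greedy masking). One consequence worth knowing:
if a chance background half-site happens to sit one spacer upstream of a
planted box, the reported box extends upstream and its anchor moves — on
random 200 kb genomes this affects on the order of 0–1 planted boxes in 20,
which is visible as a recovery rate slightly below 1.0 for some seeds.

At 0 mismatches the per-position background hit probability on uniform
i.i.d. sequence is the product of allowed-set fractions,
(½)(¼)(¼)(¼)(¼)(½)(½)(½) = 16/4⁸ ≈ 2.44×10⁻⁴; the test suite checks the
empirical rate on >10⁶ positions against the binomial interval around this
value.

## Tree congruence

Trees are treated as unrooted for both splits and path sums; the two edges
of a bifurcating root are merged. The unweighted Robinson–Foulds distance
is the symmetric difference of non-trivial bipartitions; the weighted form
is the branch-score style L1 difference of split lengths over *all* splits,
an absent split contributing its full length. `normalized` divides the
unweighted distance by the total non-trivial split count of the two trees
(2(n−3) for binary trees).

The congruence statistic is the Pearson correlation between the
upper-triangle patristic vectors of the two trees over their shared leaves
(≥ 4 required), with the plain regression p-value that treats pairs as
independent — this mirrors the common practice of regressing gene-tree
against core-tree leaf distances. Because pairwise distances are
autocorrelated, that p-value is optimistic; a Mantel permutation test
(joint row/column permutations, p ≥ 1/(permutations+1)) is available and
recommended when the p-value itself matters. Patristic (branch-length)
distances are the default; nodal (edge-count) distances sit behind
`metric="nodal"`.

## Differential expression

The test is deliberately simple and fully specified, so that every number
is reproducible from the definitions; it does not attempt to replicate any
particular published tool's shrinkage machinery.

1. **Size factors**: median-of-ratios (each sample's median, over genes
   with no zero count, of count / gene geometric mean).
2. **Fold change**: `log2((m₂+c)/(m₁+c))` on normalized group means with
   pseudocount c = 0.5 (keeps zero-count genes finite).
3. **Dispersion**: gene-wise method of moments under `Var = μ + φμ²`,
   averaged over the two conditions, floored at 10⁻⁸.
4. **Inference**: delta-method SE from `Var(m_c) = (m_c + φm_c²)/n_c`; the
   Wald statistic is referred to Student-t with n₁+n₂−2 df. The t
   reference is a small-sample calibration: with gene-wise dispersion at
   n = 3 per group, a normal reference rejects ~12% of null genes at the
   5% level, whereas the t reference is close to nominal (~5%, checked by
   simulation in the test suite).
5. **Multiplicity**: Benjamini–Hochberg step-up; significance at FDR < α
   (default 0.05).

**Known limitation.** Without cross-gene information sharing, per-gene
p-values at n = 3 are bounded by the heavy t₄ tail (a |t| of 5 gives
p ≈ 0.007), so genome-wide BH calls at α = 0.05 cannot single out a
~1.3-log2FC gene among thousands — power is therefore assessed at the
per-gene test level (p < 0.05), where sensitivity for a 1.33 log2FC gene at
mean 500 exceeds 0.9. Detecting such effects at genome-wide FDR requires
more replicates or an empirical-Bayes dispersion/shrinkage apparatus that
is intentionally out of scope here.

**Clustering**: significant genes are clustered single-linkage along the
genomic line; consecutive (start-sorted) genes join when
`next.start − prev.stop − 1 ≤ max_gap`, overlaps giving non-positive gaps.
Default `max_gap` 50 nt: the curated six-gene replication block has
internal gaps ≤ 11 nt while the nearest other significant neighbours are
hundreds of nt away, so 50 separates the cases cleanly. Strand is ignored
(operonic structure on either strand is a genomic-proximity statement).

The curated DE table is filtered by excluding the three rows flagged as
probable misannotations rather than re-applying the FDR threshold: one
retained row has a printed FDR of 5.03×10⁻², marginally above 0.05, and the
curated gene set of record is the 14 non-flagged rows.

## Infection kinetics

Lysis is called as the earliest grid time at which the infected OD₇₅₀ drops
to ≤ (1−f) of the uninfected control on the same grid, `f = 0.25` by
default — there is no standard operational OD definition of lysis, and 0.25
cleanly separates exponential lysis decline from growth noise in the
generator's regime; it is the key free parameter and is configurable. The
delayed-lysis phenotype requires the phosphate-deplete lysis time to exceed
the replete one by *strictly more than* 2 h. A deplete culture that never
lyses within the horizon is reported delayed with a censoring flag rather
than dropped. Replication rate is the OLS slope of intracellular phage DNA
(percent of initial) within the closed window [2, 6] h. The two-sample
comparison is the pooled-variance t test (df = n₁+n₂−2), two-sided; Welch
is deliberately not the default since the pooled form is the textbook
two-sample t.

## AMG presence and association

Smith–Waterman local alignment with a linear gap penalty; DNA scoring
+2/−1/−2, protein scoring BLOSUM62 with gap −11. Traceback is deterministic
(tie order diagonal > up > left, anchored at the first maximal cell in
row-major order). Presence of a homologue is called when some protein
aligns at ≥ 35% identity over ≥ 50% of the query length, or scores ≥ half
the query's self-score — a conservative rule on synthetic data; it replaces
E-value-based search, and E-value statistics are out of scope. The
genotype–phenotype association is Fisher's exact test: one-sided p in the
direction of the observed cross-product, two-sided by the point-probability
rule (conventions differ, so the choice is stated).

## Phosphate budget

`total = burst × genome_length × strand_factor × phosphates_per_nt`, order
of magnitude `floor(log10 total)` (not nearest power). Defaults: 12 progeny
per cell under phosphate depletion, 200 000 nt per genome, 2 phosphates per
incorporated nucleotide, strand factor 1. Whether "genome length" should be
doubled for duplex synthesis is genuinely ambiguous, so it is exposed as a
flag; both readings (4.8×10⁶ and 9.6×10⁶) floor to 10⁶, which is why the
result is reported as an order of magnitude.

## Synthetic generators

All generators draw from a single `numpy.random.default_rng(seed)` stream
per call in a fixed documented order, so identical configs give identical
outputs across runs and platforms.

* **Genome**: i.i.d. background at GC 0.377 (the phage genome's
  composition; the host is far more GC-rich), 200 kb, 20 genes of 900 nt on
  alternating strands, each preceded by a 200 nt promoter window; tandem
  boxes (two consensus-drawn half-sites, 3 nt spacer) planted at −63 on the
  coding strand of every other gene. Not emulated: codon structure, real
  intergenic architecture, motif position preferences.
* **Trees**: random binary topology by sequential random joins with
  exponential branch lengths (mean 0.1); the gene tree multiplies each
  length by lognormal noise and then applies leaf regrafts (detach a random
  leaf, reattach to a random edge) — the simplest event that erodes
  distance correlation, standing in for horizontal transfer. Not emulated:
  sequence evolution, alignment/inference error, within-clade rate shifts.
* **Counts**: NB(mean, dispersion) with `Var = μ + φμ²`, baseline means
  log-uniform on [50, 2000], φ = 0.05, n = 3 per condition, uniform
  [0.7, 1.3] library-size multipliers; the deplete mean of a regulon gene
  is scaled by 2^1.33 (the strongest curated up-regulation). Totals equal
  the column sums of the simulated matrix. Not emulated: read-level
  sampling, gene-length bias, dispersion–mean trends, host-transcriptome
  degradation.
* **Growth curves**: logistic control (OD₀ 0.25, capacity 1.0, rate
  0.08 h⁻¹ — a slow marine cyanobacterial culture); infected replicates
  track the control until the condition's lysis time (9 h replete latent
  period, +3 h under depletion — illustrative values, the delay chosen to
  exceed the 2 h phenotype threshold), then decline exponentially at
  1 h⁻¹ so the lysis caller is exercised non-trivially; samples every 2 h.
* **qPCR**: 100% at t = 0, linear rise at 25 %·h⁻¹ in both conditions (no
  true between-condition difference, matching the study system's null
  finding) through the 2–6 h window, plateau after, Gaussian noise sd 5,
  clipped at 0.

Because the generators plant clean, known signals, passing tests
demonstrate *correctness of the estimators and callers*, not performance on
real sequencing or plate-reader data; noise levels and effect sizes are
plausible but not fitted to any dataset.

## Problem sizes used in checks

The automated checks run the null-calibration simulation at 3 × 2000 genes,
the planted-effect recovery at 200 simulations of 50 genes, scanner
exactness on 1000 random sequences plus >10⁶ background positions, RF
exactness on 500 random tree pairs (n ≤ 8), congruence decay on 2 × 50
simulated 20-leaf pairs, and alignment exactness on 200 short pairs —
sizes chosen so the whole battery completes in seconds while keeping
Monte-Carlo standard errors well inside the asserted bands.
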