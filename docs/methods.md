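# Methods

This note documents the models, rules and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Coordinates and shared types

All internal coordinates are 0-based half-open intervals; GTF/GFF3 readers
and writers convert at the boundary. This makes overlap logic exact at
edges: `[a, b)` and `[b, c)` do not overlap, and a gene ending where a
window begins is "adjacent at distance 0", never off by one. Biotypes form
a closed vocabulary (`protein_coding`, `rRNA`, `tRNA`, `snRNA`, `snoRNA`,
`lncRNA`, `other`); anything unrecognized maps to `other` and is treated as
neither coding nor housekeeping. The coding-alignment hit table is BLAST
tabular order extended with an explicit coverage column (interpreted as
query coverage), because the cascade's coverage rule is not a standard
outfmt-6 field.

## Volatile quantification

Emission rate per compound and sample is computed from the internal-standard
ratio:

    rate [µg·g⁻¹·h⁻¹] = (peak_area / IS_peak_area × IS_conc [µg·µL⁻¹]
                         × IS_volume [µL]) / sample_mass [g] / time [h]

The formula is exactly linear in the compound's peak area and invariant to
detector gain (rescaling both peak areas together). Rates are computed per
replicate and then averaged; class shares are percentages of the per-stage
scent total with non-scent compounds excluded beforehand. Compound→class
membership is supplied as a table, not hard-coded chemistry: deciding which
detected molecules count as floral scent is curation, not computation.
Stage contrasts use the Welch (unequal-variance) two-sample *t*-test on
replicate values; with the large (≥ several-fold) stage effects this test is
meant for, its conservatism at n = 3 costs little (a planted 10× effect is
detected at p < 0.05 in ≥ 95 % of simulations).

## lncRNA identification cascade

Filters run in a fixed order; each stage records input, removed and
surviving counts, and the report enforces the accounting identity at every
stage. The housekeeping and exon-count filters commute (same final set in
either order); the annotated split does not, since it routes transcripts out
of the novel-candidate path.

1. **Housekeeping**: remove any transcript with ≥ 1 bp exonic overlap
   (either strand) with an rRNA/tRNA/snRNA/snoRNA exon.
2. **Exon count**: keep transcripts with ≥ 2 exons (single-exon assemblies
   are unreliable).
3. **Coding alignment**: remove transcripts with at least one protein hit
   passing *all three* strict inequalities p < 1e−10, identity > 90,
   coverage > 80. A hit at identity exactly 90.0 does not exclude.
4. **Annotated split**: transcripts with same-strand exonic overlap against
   an annotated lncRNA locus are accepted directly and skip the remaining
   evidence gates. Exon-level overlap rather than full chain identity is
   used deliberately: assembled transcript boundaries jitter relative to
   reference models.
5. **Length/ORF**: keep candidates with length ≥ 200 nt (inclusive — "longer
   than 200" and "shorter than 200 removed" are both satisfied by the
   inclusive keep, which is the convention here) and longest ORF < 100 aa.
6. **Coding potential**: a Pfam domain hit at E ≤ 1e−5 removes the
   transcript regardless of score; otherwise a coding-potential score < 0
   keeps it. External score tables take precedence; without one, a built-in
   heuristic supplies scores.

**ORF definition.** An ORF is an ATG followed by an in-frame stop
(TAA/TAG/TGA); its length in aa counts codons from the ATG through the codon
before the stop (`ATGAAATAA` → 2). Open-ended runs without a stop are not
ORFs — the stricter, testable reading of "longest consecutive codon chain".
Only the three forward frames are scanned because strand-specific assembly
yields sense-strand sequences; a `six_frame` flag exists for non-stranded
inputs. Codons containing N match neither ATG nor a stop. Ties break to the
smallest start offset, then the smallest frame. The finder is validated
against an exhaustive enumeration oracle.

**Built-in coding-potential heuristic.**
`score = 2·(ORF_coverage − 0.5) + (fickett_testcode − 0.95)`, where
ORF_coverage = 3·aa/length and the Fickett TESTCODE statistic uses the
classic position-asymmetry/composition lookup tables. Negative means
non-coding. This is a deliberately simple scorer standing behind the same
interface as an external classifier table; it separates long-ORF,
codon-biased sequences from ORF-poor ones but is *not* an SVM-grade
classifier, which is why external score tables, when available, win.

## Positional classification

Categories are assigned with exon-level evidence ranked above containment:
antisense (lncRNA exon overlaps coding exon, opposite strand) >
sense-overlapping (same strand) > sense-intronic (lncRNA wholly inside a
coding gene span with no exonic overlap on either strand) > lincRNA. The
definitions come without an explicit precedence; this order is the package's
choice and is applied uniformly. Containment, not strand, drives the
intronic class — intronic lncRNAs occur on both strands. The partner gene is
the one providing the triggering overlap, ties broken by span-midpoint
distance. Unstranded (`.`) lncRNAs can never satisfy the strand-dependent
rules and fall through to containment/lincRNA. Length histograms use
left-closed bins (`[300,400)` …), exon bins 1–10 and >10, ORF bins in 100-aa
steps to ≥ 1000.

## Target prediction

Cis: a lncRNA pairs with every gene whose interval lies within 100 kb on the
same chromosome; distance is the gap between closest interval edges
(0 when overlapping), inclusive at the window boundary, strand ignored — the
anchor point is a convention the package fixes since "within 100 kb" does
not define one. Trans: Pearson correlation across shared samples, computed
only when more than five samples are shared; the threshold (default 0.95)
applies to *signed* r, so perfect anti-correlation does not pair — negative
regulation is biologically plausible, so an `absolute` option exists but is
off by default. Constant profiles have undefined correlation and never pair.
Curated gene lists (synthases, transcription-factor homologs) are inputs;
their curation is out of scope.

## Differential expression

log₂FC = log₂((mean_b + ε)/(mean_a + ε)) with ε = 0.01 on the FPKM scale;
the p-value comes from a two-sample *t* on log₂(value + ε) across
replicates, adjusted per contrast by Benjamini–Hochberg over all transcripts
in the matrix. A transcript is up (down) iff log₂FC ≥ 1 (≤ −1) *and*
adjusted p < 0.05; the |log₂FC| = 1 boundary passes. This t-on-log test is a
deliberate surrogate for count-model DE callers: it is validated by
planted-truth recovery, not by matching any specific caller's output.

The default is the **pooled-variance** (Student) t rather than Welch: at
three replicates the Welch–Satterthwaite degrees of freedom collapse toward
two whenever sample variances differ by chance, and measured sensitivity on
planted 4-fold changes (log₂ noise sd 0.25, 50 simulations) drops to ~0.86
versus ~0.99 for the pooled test at the same observed FDR of 0. On the log
scale with a common noise model the equal-variance assumption is reasonable;
`equal_var=False` restores Welch for heteroscedastic data.

Zero-variance degenerate rows get p = 1 when group means are equal and p = 0
otherwise (a zero-spread difference is maximally significant by this test's
logic; it cannot occur under the generator's continuous noise).

The expression floor excludes a transcript only when its stage-mean
expression is below 0.5 in *every* stage (AND semantics). Core transcripts
are those DE in both successive contrasts; patterns are up_down, down_up, or
other. ΔΔCt follows RQ = 2^−ΔΔCt with
ΔΔCt = (Ct_target,t − Ct_ref,t) − (Ct_target,c − Ct_ref,c), and concordance
is an OLS regression of qPCR on sequencing fold changes reporting R².

## Co-expression network

Unsigned soft-threshold adjacency a_ij = |cor|^β with β = 6 and zero
diagonal; topological overlap

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_u a_iu·a_uj,  k_i = Σ_u a_iu,  TOM_ii = 1,

validated to 1e−12 against a double-loop oracle; clustering uses
average-linkage on 1 − TOM. **Branch cutting is a documented simplified
variant of dynamic tree cut**: a static cut at height 0.99 followed by
re-cutting each branch at `0.99 − 0.05·deepSplit` (deepSplit = 4 →
effective sub-branch height 0.79), with clusters below minModuleSize = 6
sent to grey. It is accepted via planted-module recovery (ARI ≥ 0.9 on 13
planted modules), not bit-equivalence with the reference tree-cut
implementation. Module colours follow the conventional palette in
decreasing size order; grey is reserved for unassigned transcripts.

Eigengenes are the first principal component of the member-standardized
matrix, scaled to unit variance and sign-oriented so the mean correlation
with members is positive (ties orient toward the first member). Merging
iteratively joins the closest pair of modules while their eigengene
dissimilarity 1 − cor(ME_i, ME_j) is below 0.15, recomputing eigengenes
after each join; re-running merge on merged output is a fixed point. Two
merge-like thresholds exist in common parameterizations (mergeCutHeight 0.1,
MEDissThres 0.15); here MEDissThres drives merging and mergeCutHeight is
retained only as an inert alias. Module–trait correlation is Pearson r
between each eigengene and each compound's per-sample emission vector;
modules are ranked per compound by |r| (the sign is reported) because
published per-compound module lists carry no signs; the top three distinct
modules are reported. At least 15 samples are required for network analysis.

## Synthetic data generator

The generator emulates the data shapes of a three-stage flowering
experiment with four cultivars (3 stages × 3 replicates × 4 cultivars = 36
samples, above the 15-sample network minimum):

* **Geometry** — one chromosome partitioned into per-feature windows
  (window < 7.5 kb is a configuration error); coding genes have three exons
  with a large (≥ 2 kb) second intron to host sense-intronic lncRNAs;
  antisense lncRNAs overlap ≥ 50 bp of a coding exon on the opposite strand;
  sense-overlapping lncRNAs share an exon on the same strand;
  lincRNAs, noise and decoys occupy their own windows. Half the lncRNA loci
  (configurable) are annotated in the reference with biotype lncRNA.
* **Sequences** — lncRNA/noise sequences are built ORF-free
  (`plant_orf_free_sequence`: rejection sampling, then stop-block
  interleaving — an 11-mer carrying a stop codon in each forward frame —
  then ATG removal as a last resort; every return value is verified with the
  ORF finder). Coding transcripts carry a planted ORF ≥ 100 aa covering
  65–90 % of the transcript whose codons are drawn with position-specific
  base composition (G-rich first position, G-poor second, C/G-leaning
  wobble) so the planted frame is statistically coding-like, not merely
  long. Decoys come in three families, each failing exactly one gate:
  a qualifying alignment hit, a positive external coding-potential score, or
  a ≥ 100 aa ORF.
* **Expression** — log-normal (multiplicative) noise around log₂-scale
  means, matching FPKM heteroscedasticity; default log₂ noise sd 0.2.
  Planted DE patterns (9 up-down, 9 down-up, 8 single-transition by
  default, matching the study design this emulates, plus 3 low-expression
  transcripts that are DE by ratio but below the 0.5 floor everywhere)
  shift stage means by 2–3.5 log₂ units identically across cultivars.
  Module members are loading × trajectory + noise with loadings in
  [0.8, 1.2] and i.i.d. standard-normal per-sample trajectories. Planted
  co-expression partners copy a DE lncRNA's profile with small (sd 0.05)
  log-noise, giving raw-scale r ≈ 0.99.
* **Volatiles/GC-MS** — each scent compound is an affine function of a
  standardized module trajectory mixed with noise at a planted correlation
  (default r = 0.9), floored just above zero; peak areas are back-computed
  through the inverse of the emission formula with a per-sample internal
  standard area, so recomputing rates from the emitted table reproduces the
  manifest targets to ~1e−15 relative error.
* **Determinism** — one seed; fixed per-artifact sub-streams
  (`default_rng([stream_id, seed])`) keep each file reproducible
  byte-for-byte and insulated from unrelated configuration edits.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (no FASTQ, no assembly
uncertainty), splice-isoform complexity (single-isoform genes), sequence
homology between loci, count-based mean–variance relationships (noise is
log-normal, not negative-binomial), stage structure in the co-expression
trajectories (module trajectories are stageless by design, so volatile stage
effects are not planted in the default bundle), and the curation judgment in
compound-class and gene lists. Planted-truth recovery shows the machinery is
correct, not that thresholds are optimal for any particular organism.

## Problem sizes

Default validation sizes, chosen to exercise every code path at desk scale:
~513 transcripts (300 coding, 133 lncRNAs over the four classes, 20
housekeeping, 40 single-exon noise, 20 decoys), 36 samples, 13 modules of
6–10 members, 12 volatile compounds (10 scent + 2 non-scent controls).
Oracle suites use 1000 random sequences (30–3000 nt), 500 random gene/lncRNA
geometries, 20 random 8-node networks, and 50-seed simulations for DE and
module–trait recovery. The full test suite runs in well under a minute of
CPU; `scripts/acceptance.py` in ~10 s.

## Known limitations

* The coding-potential heuristic is a two-feature linear score; it is a
  provenance-tracked stand-in interface, not a replacement for a trained
  classifier, and external score tables always take precedence.
* The tree-cut variant has no adaptive cut-height or PAM stage; very uneven
  module sizes or strongly correlated modules may fragment or merge where
  the reference dynamic tree cut would not.
* DE calling on three replicates with a t-on-log surrogate has no variance
  shrinkage; borderline effects near the |log₂FC| = 1 gate are called
  conservatively.
* Cis target prediction ignores strand and regulatory directionality; it is
  a candidate generator, not an assertion of mechanism.
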