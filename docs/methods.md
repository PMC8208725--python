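# Methods

`strainwise` re-implements, as a tested pipeline over synthetic data, the
inference chain used to dissect how natural genetic variation between two
inbred mouse strains reshapes cytokine-induced enhancer activation in
macrophages: stimulus-responsive element calling, low/equal/high-basal
categorization of strain-differential enhancers, cis/trans decomposition of
expression differences in F1 hybrids, motif-mutation association testing,
convolutional sequence modelling with per-nucleotide importance scores, and
attribution of variant-free differential enhancers to connected elements.

## Element calling

Elements are classified from replicate-averaged, normalized tag counts
(tags per 10⁷) of two activity markers, H3K27ac and RNA Pol II, under basal
and stimulated conditions. An element whose maximum-over-conditions signal
falls below 16 H3K27ac tags or 8 Pol II tags is `below_minimum`. Otherwise
fold changes are computed as (stimulated + 1)/(basal + 1) — the pseudocount
of 1 stabilizes near-zero counts, whose treatment the underlying protocol
leaves open — and the element is `induced` when both markers change ≥ 2.5-
fold upward, `repressed` when both change ≥ 2.5-fold downward, `neutral`
when both stay strictly inside the 1.4-fold band, and `ambiguous` otherwise.
Treating the mixed band as an explicit state (rather than silently dropping
such elements) keeps the partition exhaustive and testable.

Super enhancers are called ROSE-style: enhancers within 12.5 kb are
stitched (the stitching distance is a convention of that method, not a
measured constant, and is exposed in the config), signal within ±2.5 kb of a
TSS is excluded, stitched regions are ranked by total H3K27ac, both axes of
the rank–signal curve are scaled to [0, 1], and the cutoff is the signal at
which the tangent slope reaches 1 (computed as the argmin of scaled-signal
minus scaled-rank, exact for the convex hockey-stick curves this produces).
A perfectly flat curve has no geometric cutoff; the implementation then
calls zero super enhancers. Response-dispersion differences between super
and conventional enhancers use Levene's test with median centering on log2
fold changes.

## Strain comparison

Strain-differential induced genes/enhancers (induced in exactly one strain
of a pair) fall into three categories by the basal ratio between the
noninduced and induced strain (pseudocount 1): `high_basal` when the
noninduced strain is at least 1.5-fold (genes) or 2-fold (enhancers) higher,
`low_basal` for the mirror image, `equal_basal` in between. The inclusive
(≥) comparison at the category threshold, and the strict (<, >) comparisons
for the similar/tier bands, are fixed and asserted by tests; the textual
sources mix "at least" and "more than" phrasings. Enhancer categorization
additionally requires the two strains' H3K27ac induction fold changes to
differ more than 2-fold.

Difference tiers use the larger-over-smaller stimulated H3K27ac ratio:
`similar` below 1.5, and nested tiers >1.5, >2, >3, >4. Variant search uses
a ±150 bp window around the element center, inclusive at both ends.

cis/trans: a gene is `cis` when |log2(parental fold change) − log2(F1 fold
change)| < 1 — the allelic ratio survives in the shared trans environment
of the hybrid — and `trans` when the parental ratio is at least 2-fold in
either direction while the F1 ratio is attenuated toward 1 (|log2 F1| <
|log2 parental|; the attenuation rule is applied symmetrically for both
directions of change). F1 totals are split between alleles in proportion to
allele-informative (variant-overlapping) reads; transcripts with zero
informative reads for either allele are filtered. A published description
of this assignment includes a "times 10" factor that cancels in the ratio;
it is treated as cosmetic scaling.

## Motif-mutation association

For each homologous element pair, the responsive strain's sequence is the
positive and the other strain's the negative; for each PWM the statistic is
the difference of best log2-odds scores (both strands, all offsets,
pseudocount 0.25 per count cell, uniform background; ambiguous bases score
as a 10⁻³ pseudo-probability). Pairs with zero difference carry no
information about that motif and are dropped; the remaining differences are
tested against a zero median with the Wilcoxon signed-rank test (exact null
below 26 nonzero differences without ties, normal approximation with
continuity correction otherwise), summarized as sign(median) × −log10 p.
Motifs are grouped single-linkage at Pearson correlation of score-difference
vectors > 0.6; clusters are reported when any member's TF gene exceeds 2 TPM.
No multiple-testing correction is applied to the signed statistic (matching
how such screens are reported); a Benjamini–Hochberg column can be derived
from the emitted p-values by the user.

## Sequence model

A compact 1-D convolutional network (three conv layers — 16 filters of
widths 12/4/4, max pooling 2/1/global — and two fully connected layers,
16 hidden units) classifies 300-bp sequences as active enhancer vs
GC-matched genomic background. The implementation is pure numpy with
analytic backpropagation: training is bit-reproducible under a fixed seed
and the same backward pass yields exact input gradients. Backgrounds are
drawn deterministically by enumerating, via prefix sums, every window of
equal length within 100 kb whose GC content matches within 2 percentage
points and which overlaps no foreground, then sampling one with the seeded
generator; the search range widens once (×10) before failing.

Training uses binary cross-entropy, Adam, and the stated schedule: the
learning rate drops by ×0.9 when learning stagnates (5 epochs without a new
best training loss) and training stops after 20 epochs without improvement,
up to a hard cap of 80 epochs. Two deliberate departures from the protocol
this mirrors: initialization is random rather than fine-tuned from
pretrained weights (no external weights may be required), and the initial
learning rate is 3 × 10⁻⁴ rather than the 10⁻⁴ appropriate to fine-tuning —
from a random start the smaller rate cannot escape the initial plateau
before the stopping rule fires. The stagnation/stopping monitor is the
training loss; validation loss selects the weights that are kept.
Splits are by genomic coordinate — thirds of the single synthetic
chromosome standing in for leaving whole chromosomes out (train / validation
/ test) — so homologous windows never straddle partitions.

Importance scores are integrated-gradients attributions of the positive
logit against a uniform-base reference (16 path steps; attributions satisfy
completeness), computed for the sequence and its reverse complement, the
latter re-aligned, with the final per-position score the absolute maximum
of the two — making tracks exactly reverse-complement symmetric. The top
20% of positions per window (60 of 300; ties broken leftmost) are predicted
functional, and variants overlapping any such position of a covering window
are flagged. 5-mer interpretation scores each occurrence by its mean
importance, cross-tabulates the global top 10% against the rest per 5-mer
identity, and reports Haldane-corrected odds ratios with two-sided Fisher
p-values.

**Ensembled importance.** With GC-random backgrounds, both planted motif
classes are individually sufficient for classification, and an individual
training run may exploit one and largely ignore the other (the same
redundancy effect that motivates retraining such models with noninduced
enhancers as the background). Variant prioritization therefore averages
importance tracks over an ensemble of five independently initialized
trainings, each track normalized by its model-wide mean and weighted by the
member's validation auROC above chance. Which motif class an individual
member favours remains initialization-dependent; the ensemble reduces, but
does not remove, this variance — a known limitation discussed below.

## Connectivity

Interaction anchors match the closest annotated element within 2.5 kb
(closest edges; an anchor overlapping a promoter and an enhancer at the
same gap counts as the promoter, keeping enhancer–promoter counts
conservative), classifying pairs as E–E, E–P, P–P or unassigned. E–P pairs
feed a 3×3 (promoter state × enhancer state) contingency table with
two-sided Fisher tests of three collapsed comparisons (induced vs
non-induced, repressed vs non-repressed, induced vs repressed). Connected-
enhancer analysis preselects enhancers with ≥ 4-fold between-strain H3K27ac
differences, computes per-pair Pearson correlations across strains
(requires ≥ 3 strains), and compares connected pairs against two nulls —
random same-chromosome pairs and distance-matched unconnected pairs (100-kb
distance bins) — by Mann–Whitney U with Cohen's d. Strain-differential
enhancers are attributed `local_only` / `both_ends` / `connected_only` /
`neither` from flagged variants within ±150 bp of their own and their
E–E-connected partners' centers.

## Synthetic data generator

The generator emulates a responsive strain (A) and a variant-carrying
strain (B) on one synthetic chromosome (~2.2 kb per feature), with 300-bp
elements each carrying one lineage-determining (LDTF) and one
signal-dependent (SDTF) motif instance, and interleaved genes with promoter
elements at their TSSs. Activity follows an occupancy model

    mean = base + b·occ_L + a·g·occ_L·occ_S·s(condition)

with per-assay baselines and coefficient multipliers (H3K27ac base 4,
b = 36, a = 160; Pol II, ATAC and TF tracks scaled versions), a per-element
induced-term gain g log-uniform in [1, 2] (spreading fold differences
across the tier range), s(stimulated) = 1 and s(basal) = relief(occ_L):
basal SDTF engagement is granted only when LDTF occupancy exceeds the
planted-allele level, so consensus-improved LDTF motifs render elements
constitutively active. Occupancies are logistic in the planted instance's
log-odds score (slope 1.5 per log2 unit, midpoint 3.5 below the responsive
allele's score), giving occupancy ≈ 0.995 for planted alleles, ≈ 0.03 after
a core knockout, ≈ 1 after consensus improvement.

Packaged motifs are 12-bp consensus-like PWMs (PU.1-like and C/EBP-like
standing in for the LDTF class; STAT6-like and EGR-like for the SDTF
class): four core positions at probability 0.95 and flanks at 0.9. Planted
instances sample flanking bases from the PWM (natural sites vary in
affinity) and keep consensus cores; a "weak" allele knocks one core
position (chosen uniformly among the equally informative cores) down to one
of the equally low-probability bases — this tie-sampled randomization of the
edit prevents any decoy motif from cross-reacting consistently with a
stereotyped causal variant. Mechanisms map to strain edits: `low_basal`
(LDTF knocked out in B), `equal_basal` (SDTF knocked out in B),
`high_basal` (weak LDTF in A, consensus-restored in B), `conserved` (no
edit), `background` (no motifs, quiescent just above the minimum-tag
filter), plus a separate `linked` class — sequence-identical elements whose
induced term in B is externally suppressed (log-uniform 1.8–6×) and which
are wired by an interaction to a causal equal-basal partner. Default
mechanism mix: 10/20/15/40/15% plus 5% linked.

Tag counts are negative-binomial (variance μ + 0.05 μ²) averaged over 3
replicates; dispersion 0 yields the exact means, the deterministic limit in
which category recovery must be — and is — exact. Silent variants are
planted at half of all variants (matching the observation that even
similar-enhancer sets carry variants at double-digit percentages), at
uniform non-motif element positions; a few short indels are planted between
elements, so homologous element windows stay length-aligned while the
variant-application invariant (A genome + variant table = B genome) is
exercised with indels. Gene expression uses the same noise model (TPM ×10
counts, 3 replicates) with induction ×4 for responsive genes; q-values come
from a Welch t-test on log2 counts with Benjamini–Hochberg adjustment —
a documented simple stand-in for a full count-model test, sufficient to
exercise the significance gate. cis/trans genes carry strain ratios of
1.75–3 log2 units; F1 allelic counts are binomial with ~150 informative
reads of ~500 total (depths typical of allele-specific expression designs;
log-ratio precision at lower informative depth would not support reliable
cis calls). The study-condition sizes used by the checks are 1,500 elements
(category recovery, prioritization, attribution), 500 + 500 pure cis/trans
genes, 2,000 + 2,000 training sequences, and 50 replicates of 400
equal-basal pairs (motif statistic).

What the generator does not emulate: read-level data and mapping bias,
linkage structure among variants, chromatin-state autocorrelation along the
genome, multi-strain panels (except a dedicated five-strain helper for the
connected-correlation comparison, where connected pairs share a per-strain
lognormal latent activity factor), and real motif redundancy/degeneracy
beyond the packaged matrices. Passing recovery tests therefore demonstrates
the correctness and calibration of the inference chain under the stated
generative model, not performance on real sequencing data.

## Numerical choices and degenerate inputs

Fold changes and ratios use pseudocount 1 throughout; PWM probabilities use
pseudocount 0.25 per count cell; odds ratios use Haldane 0.5. Sequences
shorter than a motif score at the motif's floor rather than raising.
Constant score-difference vectors form singleton motif clusters (their
correlation is undefined). Levene's test on two constant groups returns
p = 1 with a warning. All-equal importance scores select the leftmost 60
positions. Zero informative F1 reads for either allele flag the transcript
as filtered. The config object validates its invariants (neutral < induce
threshold, fractions in (0, 1), positive windows) at construction and
rejects unknown keys on load.

## Known limitations

* From-scratch training of the small CNN is initialization-sensitive:
  individual runs may favour one of the redundant motif classes, and on
  unfavourable seeds a run can fail to leave the initial plateau. The
  weighted ensemble mitigates this for variant prioritization; single-run
  auROCs should be read with that variance in mind.
* The auROC values reported on synthetic data characterize the synthetic
  task only; they are not comparable to values obtainable on real
  epigenomic compendia with pretrained initialization.
* The connectivity analysis treats the interaction set as condition-static,
  consistent with differential-interaction analyses that find no
  significant condition-specific loops.
* The 2-strain generator cannot exercise the ≥3-strain correlation
  comparison; that operation is validated on the dedicated multi-strain
  panel helper instead.
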