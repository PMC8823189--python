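# Methods

## Study design and data model

The package targets a paired two-arm design: subjects are biopsied at
baseline and after a five-week bed-rest period; within each age/sex-matched
pair exactly one subject receives an exercise countermeasure (`exercise`)
while the other rests only (`control`). The data model accepts a
three-subject female trio under a single pair id, but only two-subject male
pairs enter the blinded analysis, matching the original protocol. Expression
arrives as gene × sample TPM matrices; the per-sample library size used for
junction normalization is the count of unambiguously mapped genic reads
recorded in the sample sheet.

All stages consume TPM. Count-level modeling (negative-binomial dispersion
machinery as in DESeq2-style tools) is deliberately out of scope: the
package's contribution is the design — pairing, nesting, blinding, the
bookkeeping — not a count likelihood, and every contract downstream is
expressible on the TPM scale.

## Coding-gene renormalization and fold changes

Because the non-coding fraction varies between libraries, samples are
rescaled so that protein-coding genes alone sum to 10⁶ TPM. The operation is
scale-invariant and idempotent at the value level; a sample with zero total
coding expression is an error, not a silent NaN. Within-subject fold changes
are log₂((post + ε)/(baseline + ε)) with ε = 0.01 TPM by default. The
pseudocount policy is ours (the upstream protocol does not state one): ε
keeps ratios finite at zeros while perturbing any TPM ≥ 1 by < 1.5%. Genes
with both timepoints below ε in a subject are flagged *unobserved* and
excluded from that subject's blinded lists, avoiding 0/0 artifacts.

## Blinded grouping inference

* **Divergence criterion.** With θ = 0.585 (log₂ of a 1.5-fold change), a
  gene is classified per subject as up (log₂FC ≥ θ, boundary inclusive),
  down (≤ −θ), or no change. The published linear band (0.66, 1.5) is
  asymmetric in log space by rounding only (log₂ 0.66 = −0.599; 0.66 is
  evidently 1/1.5), so the band is implemented symmetrically as (−θ, θ). A
  gene is *divergent* within a pair when one subject changed and the other
  shows no change or the opposite sign; "opposing" requires only an opposite
  sign, since sub-threshold opposite values are already captured by the
  no-change class. Divergence lists are intersected across all pairs.
* **Relative variance.** σ²/μ of TPM (unbiased variance, n−1; the source
  protocol does not specify the estimator) within an analysis unit. The
  default unit is the four samples of a pair (both subjects × both
  timepoints); a two-sample per-subject unit is available via
  `variance_unit="subject"` because the protocol wording admits either
  reading. Genes with zero mean are flagged and never ranked. The top
  k = 500 per unit are intersected across units, and the final blinded set
  is the intersection of the divergence- and variance-consistent lists.
  Ties are broken lexicographically by gene id everywhere, for exact
  reproducibility.
* **Clustering and the two-group cut.** Samples are clustered
  agglomeratively (UPGMA by default, matching an ultrametric display) on
  1 − Pearson-r distances. The grouping step clusters post-intervention
  samples restricted to the divergence-consistent gene list — the list that
  carries the arm signal — and computes Pearson on log₂(TPM + ε): on the
  linear scale a single very abundant gene can dominate the correlation of
  every sample pair and mask the grouping; the log transform is a pure
  numerical-stability choice (`log_distance=False` restores linear TPM,
  which the all-genes dendrograms use). The tree is cut into two clusters;
  any pair whose members land in one cluster is repaired by moving whichever
  member has the lower mean distance to the other cluster. This makes the
  original protocol's manual reassignment of an outlier pair deterministic
  and always yields a one-per-pair partition.
* **Intervention call.** Per group, vote = Σ over marker genes of
  sign(mean group log₂FC) × expected sign in the control arm; the group with
  the higher vote is labeled control, an exact tie is reported as uncalled.
  Default markers are XIRP1, TNFRSF12A and HSPB1 with "up in control"
  expectation; both the set and the signs are configurable because marker
  directions are genuinely uncertain (the original blinded call used prior
  bed-rest literature and still mislabeled the arms). With three markers the
  exercise group's signs are noise, so ties occur in roughly 1/8 of runs —
  an honest property of a sign vote, reported rather than hidden.

## Paired differential expression

Per arm, genes passing a TPM > 0.1 floor (mean over the arm's samples; the
aggregation is our choice, the floor is the protocol's) are tested with a
one-sample location test of within-subject log₂FC against zero, two-sided.
By default the per-gene variance is moderated: sample variances s²_g on
d = n−1 degrees of freedom are assumed scaled-χ² around gene variances with
a scaled inverse-χ² prior (d₀, s₀²) estimated by method of moments on
log s² (the limma squeezeVar model; our implementation reproduces
limma::squeezeVar to ≥ 6 significant digits on a frozen cross-check).
Posterior variances (d₀s₀² + d s²)/(d₀ + d) give a t statistic on d + d₀
degrees of freedom. With n = 5 subjects per arm a raw df = 4 t-test is far
too unstable for genome-wide thresholds; shrinkage borrows strength across
genes just as dispersion shrinkage does in count-based tools, which is what
the moderated test stands in for. `moderated=False` gives the plain t-test,
with zero-variance genes assigned p = 1 and a `degenerate` flag.

Benjamini–Hochberg adjustment (α = 0.05 on adjusted p) is delegated to
statsmodels and verified in tests against a brute-force evaluation of the
step-up definition. Overlap bookkeeping partitions the genes significant in
both arms by log₂FC sign agreement; the identity
shared = same-direction-up + same-direction-down + opposing holds on all
inputs (a zero fold change on either side counts as opposing, since no
direction agreement can be claimed). Top-gene tables rank significant genes
by |log₂FC| per direction.

## Interactome

Upregulated significant DEGs (matching by gene symbol, with an optional
alias map) are intersected with a (ligand, receptor) pair table; a ligand is
kept when at least one receptor has target-tissue abundance ≥ τ. τ defaults
to 1.0 TPM — the upstream DRG resource's notion of "expressed" is not
restated in the protocol, so τ is an explicit free parameter recorded in
output metadata. Receptors are listed in descending abundance with
lexicographic tie-break; output is monotone in τ by construction. A
downregulated mode exists but is off by default, as in the original
analysis.

## Splice quantification

Inputs are junction bridge-read count tables plus junction metadata (target
exon, exon length, inclusion/skipping role) — not BAMs; counting is assumed
done upstream, keeping the stage deterministic. RPM = count/(library/10⁶)
with the genic-read library size; RPKM divides further by exon length in kb.
Group pooling sums counts and divides by summed library sizes (never a mean
of per-sample RPMs), so pooled RPM always lies between the per-sample
extremes. Detection calls are strict (RPM > threshold, default 0.5).

## Synthetic-study generator

The generator is the package's study-condition definition, not a test dial.
A shared gene profile x_g ~ logNormal(μ = 1, σ = 1.5 in ln-TPM) is modulated
per subject by 2^a, a ~ N(0, 0.2²) (log₂ biological noise chosen to give
baseline inter-subject Pearson ≈ 0.97, emulating the high cross-sample
homology of real muscle); post samples multiply the baseline by
2^(β_g + b), b ~ N(0, 0.3²), where β_g is the planted signed effect of the
subject's arm. Defaults: 5 male pairs + 1 female trio (deeper libraries,
75–92 M vs 15–35 M genic reads, as in deep female libraries of the original
cohort), 12,000 genes with 90% coding, 300 control-specific and 30
exercise-specific DEGs (the ~10:1 arm asymmetry at reduced scale) sharing 8
same-direction and 4 opposing genes, |β| ~ N(1.2, 0.3²) with random signs,
markers planted up-in-control. Within-pair arm assignment is randomized per
seed so the blinded stage has a non-trivial target. Ligand–receptor assets
plant 5 upregulated-control ligands with ≥ 1 receptor at or above τ and 3
decoy ligands mapping only below τ. Junction counts are Poisson with mean
planted-RPM × library/10⁶; planted inclusion RPMs (control 1.2, exercise
0.55 against the 0.5 detection threshold) emulate the reported pattern of
robust detection in most samples with partial detection in the exercised
arm (≈ 22 of 26 samples above threshold).

What the generator does *not* emulate: count-level sampling noise
(log-normal TPM noise only), gene–gene correlation structure, batch or sex
effects on expression, and isoform-level complexity beyond the single
targeted junction pair. Passing tests therefore demonstrate correctness of
the procedures and their bookkeeping under the planted model, not
performance on real libraries — in particular, real DEG recovery rates
depend on dispersion structure the simulator does not model.

## Numerical choices and limitations

* Renormalization tolerance 10⁻⁶ relative on the 10⁶ column sum; expression
  TSVs round-trip doubles exactly (repr formatting, round-trip parsing).
* Deterministic tie-breaks: lexicographic by gene id in rankings and
  receptor lists; the pair-repair step resolves cost ties by subject id.
* All simulation randomness flows from a single integer seed through
  per-stage child streams; identical configs produce byte-identical outputs.
* The trigamma inversion in the variance moderation is solved by bisection
  to 10⁻¹² and the prior df is capped at 10⁷ (an effectively infinite prior
  yields a pooled-variance z-like test).
* Because each sample is rescaled to a fixed coding total, strong planted
  effects shift every other gene's fold change slightly (compositional
  coupling); under the default conditions this inflates the realized false
  discovery count mildly above the nominal α on alternative-laden runs,
  a property shared by all closed-composition normalizations.
* The package never attempts to reproduce the original cohort's published
  gene lists or counts; those require the deposited raw data and exact
  count-model parity, both outside this package's scope.
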