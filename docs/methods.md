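# Methods

This note records the models implemented in dmskit, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was open.

## BarSeq fitness model

Clone fitness is estimated from the cumulative growth-rate chain described
in the README. Decisions within it:

* **Pseudocount.** The chain is undefined at zero barcode counts, which
  occur routinely for depleted clones at late selective timepoints. A
  pseudocount of 0.5 is added to every count before forming relative
  shares (configurable; set it to 0 for noise-free instances).
* **Pool growth rate ρ\*.** Computed from pool totals,
  ρ\* = (P\*(t_k)/P\*(t_{k−1}))^(1/Δt), which equals the count-weighted
  average clone rate.
* **Temperature normalization.** φ′ divides clone *i*'s selective φ by the
  *same clone's* permissive φ, correcting clone-specific growth artifacts
  (plasmid burden, barcode effects) that appear at both temperatures.
* **Control calibration.** s′ is anchored on the *median* cumulative score
  of null-control and wild-type-control clones — robust to a few outlier
  control wells. Scores are normalized per replicate (so each replicate's
  control set absorbs its own batch scale), averaged, and the mean is then
  re-anchored against the control medians so that the reported score
  satisfies the exact invariant null-median ≡ 0, wt-median ≡ 1.
* **Temperature labels.** Samples are labelled `permissive`/`selective`
  rather than by degrees, since the selective temperature is a property of
  the host strain, not of the model.

### Standard-deviation regularization

With only ~3 replicates, empirical standard deviations are unstable. A
prior σ₀ is predicted for every clone by ordinary least squares of the
empirical sd on log₁₀(mean permissive count) and the fitness score
(clamped at a 10⁻³ floor), then combined with the empirical value s by

σ² = (v₀σ₀² + (n−1)s²) / (v₀ + n − 2),

with prior weight v₀ = 3 by default — equal to the replicate count, so
prior and data carry similar weight. Standard errors are σ/√n and the
degrees of freedom reported per clone equal the replicate count (they are
later summed when measurements are joined). Instances with a single
replicate or too few clones for the regression (< 10) skip shrinkage and
carry the raw sd.

Clones with exactly one amino-acid change (extra synonymous codon changes
ignored) are biological replicates of that variant; their scores are
combined by inverse-variance (1/se²) weighting.

## TileSeq scoring

A codon change is counted only when both mates of a read pair report the
identical mutant codon; per-base errors ε then produce false calls at
order ε² instead of ε. Reads are compared to their amplicon tile at fixed
coordinates (tiles are designed, not discovered), and pairs with an
indel-length mismatch or more than 10% mismatched bases are discarded —
this replaces a general-purpose aligner without changing the counting
contract. Each codon change in a multi-variant pair is counted
independently.

Scoring per codon variant: frequency = count/depth; the wild-type control
mean frequency is subtracted from the nonselect and select frequencies;
the enrichment ratio E = adj_select/adj_nonselect is formed per replicate
pair and averaged. Numerical guards:

* **Poorly-measured filter.** Variants whose *input* (nonselect)
  frequency is within three standard deviations of the wild-type-control
  frequency are removed. The input-condition reading is deliberate: the
  filter's purpose is confident detection of post-selection reduction, and
  filtering on the post-selection frequency would discard genuinely null
  variants. `filter_on="select"` restores the literal reading.
* **Control sd floor.** With two control replicates the empirical sd is
  unstable; it is floored at the Poisson expectation √(count)/depth.
* **Adjusted-frequency floor.** ε = 1/(10·max depth) keeps E finite for
  fully depleted variants (E ≈ 0 rather than negative or infinite).
* **Anchoring.** score = (E − median_nonsense)/(median_syn −
  median_nonsense), requiring ≥ 5 scored variants in each anchor class and
  erroring when the medians coincide (no dynamic range). E is used on the
  linear ratio scale throughout; the anchor transform is affine, so sd and
  se scale by the same factor.

Codon variants reaching the same amino-acid change are combined by
inverse-variance weighting into the amino-acid-level map.

## Cross-platform rescaling and joining

The transform f(x) = a·eˣ + b·x + c is fitted by constrained least squares
(a ≥ 0, b > 0, tolerance 10⁻¹⁰) with two starts — a linear fit and
(0.1, 1, 0) — keeping the better optimum; the constraint makes f strictly
increasing, so score order is preserved. Pairs are unweighted. Standard
deviations propagate by the first-order factor f′(x) = a·eˣ + b.

Joining uses w₀ = 1/(1+se₀/se₁), μ_joint = w₀μ₀ + w₁μ₁, and the mixture
variance σ²_joint = w₀(σ₀²+μ₀²) + w₁(σ₁²+μ₁²) − μ²_joint. Floating-point
cancellation can push σ²_joint a hair below its algebraic floor
w₀σ₀² + w₁σ₁² when μ₀ ≈ μ₁; it is clamped there with a logged warning.
df_joint = df₀ + df₁, exactly as the standard-error denominator implies.

## Imputation and refinement

Features per variant: the confidence-weighted (1/se²) mean score of
*other* observed substitutions at the position (leave-one-out, so
cross-validation never leaks a variant's own measurement into its
feature); optionally the weighted mean over multi-mutant clones containing
the variant and the multiplicative estimate f_A = f_AB/f_B from
double/single clone pairs; signed differences in residue mass, volume,
polarity, charge and hydropathy (a fixed table documented in
`aa_properties`; stops have no properties and carry NaN); BLOSUM62; and
supplied per-position annotations (conservation, SIFT/PROVEAN-style
scores, secondary structure one-hot as helix/strand/coil, solvent
accessibility, interface burial, hydrogen-bond/salt-bridge flags). Missing
values are filled with training-column medians plus a missingness
indicator column — never silently zero.

The regressor is a 500-tree random forest with mtry = n_feat/3, bootstrap
sampling of n_obs rows, terminal node size 5 and unlimited depth (the R
randomForest regression defaults, mapped onto scikit-learn). Accuracy is
the RMSD of out-of-fold predictions under 10-fold cross-validation with
seeded, unstratified fold assignment. Feature relevance is the percent
increase in training MSE when one feature column is permuted once.

Above-wild-type ("hypercomplementing") scores are folded back below 1 by
s → 1/s (sd × 1/s²) before training by default — above-wild-type growth in
the yeast assay is best treated as deleterious in the native context — and
the transform is idempotent, so re-running it is safe; a flag preserves
the untransformed map.

Refinement joins each measured variant with its prediction using the
joining formula above, taking the cross-validation RMSD as both σ and se
of the prediction and giving it df_virtual = 1 (a prediction counts as one
pseudo-observation; configurable). Unmeasured variants are reported as
pure predictions with provenance `imputed`. Because the joint mean is a
convex combination, refinement can never move a score past its prediction.

## Synthetic-data generator

Defaults describe a realistic single-gene screen: a 50-residue target,
20,000 clones, a mean of 2.1 amino-acid changes per clone (Poisson;
truncated to ≥ 1 in BarSeq mode where only substitution-carrying clones
are arrayed) plus Poisson(0.15) synonymous NNK draws, 40% of missense
variants deleterious with effect sizes ~ Beta(0.5, 5) and the rest ~
N(1, 0.05) truncated at 0 (reproducing the bimodal synonymous/nonsense
separation of real maps), wild-type growth 0.42 doublings/h vs 0.04 for
null at the selective temperature, BarSeq sampling at 0/6/12/24/48 h in
triplicate at 10⁶ reads/sample with 5% lognormal OD noise, TileSeq at
2×10⁶ reads per tile and condition with per-base sequencing error 10⁻³
and template (PCR/plasmid) error 10⁻⁵ shared by both strands.

**Fitness-to-growth map.** A clone's cumulative population gain over the
scoring horizon interpolates *linearly* between the null and wild-type
gains: 2^{g(f)·H} = (1−f)·2^{g_null·H} + f·2^{g_wt·H} (H = selection hours
for TileSeq; the number of scored intervals for BarSeq, whose score
multiplies one hourly-rate ratio per interval). Growth itself remains
exponential per clone. This choice makes the noise-free scoring chain an
identity on true scores — the natural calibration for a generator whose
purpose is parameter-recovery testing: recovery error then measures the
pipeline's noise behaviour, not an arbitrary link function. A
rate-linear map (g(f) = g_null + f·(g_wt−g_null)) would make the
recovered score an exponential distortion of the truth and no pipeline
could invert it without knowing the generator's internals.

The generator does **not** emulate: growth saturation or lag phases,
quality-score structure, adapter read-through, indels, PCR duplicates,
position-dependent coverage, or clone cross-contamination. Passing
recovery tests therefore demonstrates correctness of the scoring
arithmetic and its behaviour under multinomial/binomial sampling noise,
multi-mutant averaging and sequencing error — not robustness to every
artifact of real libraries.

Scale of the standard recovery runs: TileSeq uses the default
configuration above; BarSeq uses 1,500 clones plus 25 null and 25 wild-type
controls at 10⁶ reads/sample — a deliberately compact pool that keeps the
demonstration fast while leaving ≥ 500 reads per clone, the regime the
scoring model targets. Both recover the hidden truth at Pearson r ≥ 0.94.

## POPCode design

Arms grow outward from the target codon one nucleotide at a time (minimum
10 nt, maximum 40 nt) until the predicted melting temperature reaches the
target (default 60 °C), using nearest-neighbor thermodynamics (SantaLucia
2004 parameters, 50 mM monovalent salt, 50 nM oligo). Any model monotone
in length would satisfy the design contract; the parameter set is
configuration, not contract. Codons whose flank inside the ORF is shorter
than the minimum arm raise an error by default (amplicons normally extend
into vector sequence; `on_insufficient_flank="skip"` omits them). The
initiator methionine and the stop codon are not targeted.

## Clinical evaluation

The Mann–Whitney U here counts pairs where the *first* group scores lower
(ties = ½): with damage-oriented scores, a large U for
(case group, control group) means cases score lower. The p-value uses the
normal approximation with tie and continuity corrections, two-sided by
default with a one-sided (`"less"`) option; U is the primary statistic.
Precision-recall treats *low* score as disease-predictive, sweeps
thresholds over the unique scores, and integrates by rectangle summation
over recall increments (no interpolation). Diploid genotypes under
recessive inheritance score as the maximum over the two alleles.
Reference bracketing calls a variant damaging only below both the highest
known-pathogenic score and the lowest population-reference score, benign
only above both, otherwise uncertain — by construction a partition of the
score line into at most three contiguous regions.

## Known limitations

* BarSeq assumes the barcode library, sample tags and pool sizes are
  given; no plate demultiplexing or OD calibration is performed.
* TileSeq counting is amplicon-coordinate based: it cannot score indels
  and does not handle reads that only partially cover a tile.
* The rescale transform is fitted unweighted; confidence-weighted
  regression is a possible refinement.
* Joining handles two platforms per call; more are joined pairwise.
* Imputation is trained per map; no cross-gene transfer.
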