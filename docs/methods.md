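# Methods

## The hierarchical model

The package models repression of the lambda P_R promoter by the CI
repressor as two coupled equilibria.

**Folding.** CI folds two-state: f_N(ΔG_F) = e^(−ΔG_F/RT)/(1+e^(−ΔG_F/RT)),
with R = 1.98×10⁻³ kcal/(mol·K) and T = 310.15 K. The wild-type folding
equilibrium constant K_fold = 114 fixes ΔG_F,wt = −RT·ln 114 = −2.908
kcal/mol and f_N,wt = 114/115 = 0.9913. Mutational effects are additive in
ΔG_F: ΔG_F,AB = ΔG_F,A + ΔG_F,B − ΔG_F,wt. Mutations are assumed to act
only through folding — binding-affinity changes, expression changes and
aggregation are out of scope.

**Regulation.** The three operators OR1–3 bound by CI dimers define eight
configuration states. State probabilities are Boltzmann weights
f_CSi ∝ e^(−ΔG_CSi/RT)·[CI₂]^Ni with the empty state as reference; P_R is
repressed in every state except the empty operator and the single dimer on
OR3. GFP interpolates linearly between the auto-fluorescence floor and the
unrepressed ceiling with 1−P_s. Total CI relates to free dimer through
[CI_T] = √([CI₂]/K_a) + 2[CI₂] + 2[OR_total]·Σ N_i f_CSi, using the
normalized state probabilities throughout (the occupancy expression keeps
the empty-state term in its normalization).

The shipped configuration free energies are the classic lysogen parameter
set for this system (intrinsic −11.7/−10.1/−10.1 kcal/mol, −2.0 pairwise
cooperativity; dimerization K_a = 7×10⁷ M⁻¹; OR_total = 2×10⁻⁹ M). They
live in `src/cidms/data/ackers_default.yaml`, are loaded as configuration
and never hard-coded in logic. With these values the self-consistent
calibration below lands within ~10% of the experiment-derived expressed
concentration (5.5×10⁻⁸ M), which we consider adequate for a synthetic
stand-in.

**Inversion.** All forward maps (ci2→GFP, ci2→CI_T, ΔG_F→f_N) are strictly
monotone. Inverses use vectorized bisection in log-concentration space on
the bracket [10⁻⁴⁰, 10⁻³] M (120 halvings, far below any tolerance we
assert). We deliberately avoid smoothing-based inversion: bisection is
deterministic, tolerance-controlled and exactly invertible.

**Calibration of experiment-specific constants.** GFP_max is the
inverse-variance weighted mean of nonsense variants at low expression
(default log₂ 11.76). GFP_auto is found by requiring the inferred wild-type
total-CI ratio between conditions to equal the measured 15:1 expression
ratio (default log₂ 4.54). CI_E,low follows from the wild-type phenotype:
CI_E = f′_Ackers(GFP_wt)/f_N,wt; CI_E,high = 15·CI_E,low. When the pipeline
has produced phenotypes, all of these are re-derived from that dataset
(`workflow.calibrate_params_from_phenotypes`) so that the model curve and
the measurements share a single scale — projecting measured phenotypes onto
a curve anchored to external constants is exquisitely sensitive to small
scale offsets at the curve's flat foot.

## Sort-seq scoring pipeline

Per condition (low/high expression), counts from Input, Output1
(near-neutral gate) and Output2 (intermediate gate) × 3 replicates are
processed as:

1. keep variants with ≥100 input reads in all replicates and ≤2 nucleotide
   changes;
2. per-replicate enrichment scores
   S = log₂((C_out+½)/(C_wt,out+½)) − log₂((C_in+½)/(C_wt,in+½)), with the
   four-term Poisson error;
3. Output2 reflection: variants depleted from the near-neutral gate beyond
   the wild-type-synonymous score cloud *and* depleted from Output2 get
   S_o2trans = q95(S_o2) + |S_o2|, making the transformed score increase
   with severity. The detriment threshold is the 5% (depletion-edge)
   quantile of the wild-type + synonymous Output1 scores; thresholds are
   type-7 quantiles computed per replicate. (Thresholding at the opposite
   edge of the neutral cloud would reflect roughly half the neutral
   variants on o2-score noise alone, splitting the neutral phenotype
   cluster bimodally and discarding most of it at the error filter.)
4. replicate combination with an iterative random-effects model: the
   between-replicate variance starts at the unweighted sample variance and
   is updated multiplicatively for exactly 50 iterations with weights
   1/(between + within); convergence is not tested, by design;
5. variants with combined Output1+Output2 error > 1 are removed;
6. a weighted linear calibration O = α + β·S_o1 + γ·S_o2trans is fit to a
   small individually measured confirmation set (weights = inverse
   variances). The γ term can be kept, dropped when insignificant, or
   forced to zero per condition; the default forces γ = 0 for the
   high-expression condition. Errors propagate coefficient uncertainty and
   the empirical within-replicate covariance of the two scores;
7. replicates are affinely mapped onto the reference replicate (replicate
   2) using wild-type and nonsense-mean anchors; the affine slope also
   scales the standard errors;
8. after cross-replicate combination, the dataset is affinely anchored onto
   the confirmation scale (pooled wild-type+synonymous and nonsense-mean
   anchors). This removes the global scale compromise a single linear
   calibration leaves behind (the score→GFP relation is only piecewise
   linear), and makes the data consistent with the data-derived model
   constants;
9. amino-acid aggregation: within replicate, synonymous encodings are
   averaged with weights 1/SE (read literally; 1/SE² is available by
   configuration), then combined across replicates with the random-effects
   model;
10. detection-limit rescaling: means are replaced by the Gaussian-weighted
    mean of 1000 bin centers spanning [4.5, 12.8] log₂ AU; standard errors
    are kept. A sub-bin-width Gaussian therefore snaps to the nearest bin
    center (bin width 0.0083).

## Sub-model comparison and epistasis

Each sub-model defines a curve in the (log₂GFP_low, log₂GFP_high) plane:
the full model and the folding-only model sample 100 ΔG_F values in
[−3, 3] kcal/mol; the regulation-only model samples [CI_T] from 0 to its
wild-type value; the log-additive "curve" is the wild-type offset line.
Observed variants are projected to the nearest point of a densely
re-evaluated curve (10⁴ points, exact model evaluations, cKDTree nearest
neighbour); the projected point carries a unique latent parameter (ΔG_F or
CI_T) and the summed squared distances (SSDC) measure curve fit. The
bounded ΔG grid doubles as a regularizer for noisy near-ceiling points.

The folding-only model's inter-condition offset C is grid-searched over
[−3.3, −1.3] in steps of 0.03 by minimizing SSDC to the sampled line
high = low + C; β = C/log₂15 and α = log₂GFP_wt,low − β·log₂(f_N,wt·CI_E,low)
follow. (The printed α of the source analysis is not reproducible from its
printed inputs, so α is always computed, never asserted.)

Doubles compose per model (ΔG_F additive; CI_T additive with negative
compositions clamped to zero and flagged; log-additive in log₂GFP), and
epistasis is expected − predicted log₂GFP, so positive = suppressive.
Summaries include percent variance explained (1 − SS_res/SS_tot)×100,
5×5 equal-population binned medians (stable tie-break by effect then
variant id), epistasis-change classes between conditions
(stable / magnitude shift / sign switches, dead band 0.1 log₂ AU by
default), and optional one-sample Wilcoxon tests against zero with
Bonferroni correction.

## Synthetic data generator

The generator emulates the study conditions so the pipeline can be
validated against ground truth:

* **Library:** each position of the 177-nt doped region mutates to each
  non-reference nucleotide with probability 0.004, independently per
  molecule (10⁵ molecules by default). The printed 250-nt oligo (36-nt and
  37-nt constant flanks, case-sensitive) ships as a FASTA fixture.
* **Effects:** per-(position, amino-acid) ΔΔG values are drawn from a
  three-component Gaussian mixture — 0.46·N(1.0, 1.0), 0.30·N(3.3, 0.8),
  0.24·N(6.5, 1.0) kcal/mol — whose weights were chosen, through the
  model's class boundaries, to reproduce the reported proportions of the
  four single-mutant phenotype classes (~42% near-neutral at both
  expression levels, ~26% detrimental at low only, ~5% partial at high /
  null at low, ~20% null at both) and hence bimodal phenotype
  distributions. Synonymous variants are wild-type-like; nonsense variants
  sit at GFP_max.
* **Sorting:** measured log₂-GFP = per-replicate affine batch shift of the
  true value + cell noise. The near-neutral gate is the central 90% of the
  (shifted) wild-type population, the completely detrimental gate the
  central 90% of the no-repressor population, Output2 everything between.
  Gate occupancies are computed as exact noise-distribution integrals (the
  infinite-cell limit) and reads are multinomial over within-gate expected
  frequencies, so each sample's counts sum exactly to the requested depth
  (10⁶ by default, 3 replicates).
* **Cell noise:** Laplace by default (sd 0.8 log₂ units), Gaussian
  available. Exponential tails in log fluorescence are the typical
  cytometry shape, and they make gate-depletion log-ratios exactly linear
  in the true phenotype — the generative regime the linear score→GFP
  calibration assumes. Under Gaussian noise those log-ratios are quadratic
  and no linear calibration is well-specified.
* **Confirmation set:** 31 genotypes — always including wild type,
  synonymous and nonsense variants, the rest spanning the phenotype range
  evenly in value — re-measured with small noise (sd 0.1), mirroring the
  individually assayed verification experiment.

What the generator does **not** emulate: PCR/sequencing errors and indels
(upstream read processing is external by design), cell-to-cell variation in
copy number, phenotype-dependent noise width, sort impurity, or
concentration-dependent folding. Passing tests on synthetic data therefore
validate the statistical machinery and the model's internal consistency,
not robustness to those real-data artifacts.

## Toy expression-fitness landscapes

Three stylized transfer functions replace the repression curve downstream
of folding: ω_I = p/(0.1+p), ω_O = 1.2p/(0.1+p)·1/(1+0.1p) (optimum at
p = 1), ω_D = 1/(1+0.1p), with p = f_N·concentration. Mutation grids use 50
ΔΔG values in [−1, +5] kcal/mol at wild-type ΔG_F ∈ {−3, −1.6, −1, 0}. For
monotone shapes the two concentrations default to 0.25 (sensitive) and 5.0
(buffered); for the peaked shape they are solved at run time so wild-type
fitness is equal on both sides of the optimum (default target 85% of peak).
The expectation composes single fitness effects log-additively
(ω_A·ω_B/ω_wt) and epistasis is the plain fitness difference
observed − expected. Root finding for ambiguous inversion scans
[−15, 15] kcal/mol for sign changes and polishes each bracket with Brent's
method; outcomes within 10⁻⁹ are deduplicated.

Note that on monotone landscapes a small set of grid cells shows genuinely
opposite-signed epistasis of negligible magnitude (|ε| ≲ 0.02); the
magnitude-only statement holds above a 0.03 dead band. The peaked
landscape's two-root ambiguity (and the up-to-four double-mutant outcomes)
appears on the above-optimum concentration arm.

## Numerical and design choices

* Pseudocount 0.5 everywhere in scores and errors; 100-read input filter;
  SE ≤ 1 combined-error filter; 50 random-effects iterations; detection
  range [4.5, 12.8] with 1000 bins; C grid [−3.3, −1.3] step 0.03;
  100-point ΔG curves in [−3, 3]; expression ratio 15. All are
  configuration with these defaults.
* Quantiles are linear-interpolation (type 7).
* Degenerate inputs fail loudly: missing wild-type rows, single replicates,
  rank-deficient calibration designs, gates that overlap, non-positive
  errors, out-of-range GFP, and missing ΔΔG table entries all raise with a
  diagnostic.
* Reproducibility: every stochastic component takes an explicit seed;
  identical spec + seed gives byte-identical tables, and the `run-all`
  manifest records config, seeds and per-stage summaries.

## Known limitations

* The linear score→GFP calibration is structurally a compromise: gate
  depletion log-ratios are piecewise linear across gate regimes, so even an
  oracle linear fit leaves a coherent ~0.2–0.3 log₂-AU sag between the
  wild-type plateau and the mid-transition. At the transition foot, where
  the phenotype responds shallowly to ΔG_F, this caps the accuracy of
  recovered single-mutant ΔΔG at roughly 0.2–0.3 kcal/mol even at 10⁶
  reads/sample; deeper sequencing does not remove it.
* ΔΔG is identifiable only where a variant's phenotype sits in the dynamic
  band of at least one condition; variants pinned at the repressed plateau
  of both conditions (|ΔΔG| ≲ 2 kcal/mol here, given the wild-type folding
  reserve) or at the ceiling carry no free-energy information, and at high
  expression the floor degeneracy makes rank correlations uninformative.
* The Ackers configuration energies are a published-parameter stand-in, not
  a fit to data; absolute concentrations inherit their uncertainty.
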