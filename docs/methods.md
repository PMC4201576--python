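# Methods

`refstab` screens candidate loading controls (reference proteins) for
quantitative western blot in a multi-condition animal study, and compares
their behaviour with paired qPCR measurements of the same genes.  This note
records the statistical models, the estimators actually implemented, the
synthetic-data generator's assumptions, and the numerical conventions.

## Study structure assumed by the analysis

The data model is a long table of background-normalized band intensities
(mean band fluorescence minus local background, arbitrary units) for each
(animal, candidate) pair, with animal metadata: experiment 1–10, strain,
sex, *Ahr* genotype, TCDD dose (µg/kg), harvest time (h) and blot id.  The
encoded design fixture reproduces the source study's layout: 192 animals in
47 experimental groups (an experimental group is one combination of
experiment × strain × sex × genotype × dose × time), one western blot per
experiment, with timecourse arms (500 µg/kg vs vehicle at 6–144 h; the 19 h
experiment also used 5 µg/kg) and dose-response arms (0–1000 µg/kg at
96 h).  Treated groups are compared against the vehicle (dose 0) group of
the same experiment/strain/sex/genotype/time; 32 such comparisons exist in
the full design, of which 31 are testable (one group has a single animal).

Wells with unsatisfactory loading are carried as an explicit `excluded`
flag rather than deleted; excluded records never enter any statistic, and
tests assert that flagging equals physical deletion.  Experiments are split
into a training cohort (experiments 1, 4, 6, 8, 9) and a validation cohort
(2, 3, 5, 7, 10) so every multivariate result can be checked in two
independent halves of comparable composition.

## Fold-difference screen

For each testable comparison, the fold-difference is M = mean(treated) /
mean(control) on the linear intensity scale, reported as log2 M with the SD
of the per-animal log2(treated_j / mean(control)) values.  Differential
abundance is tested with an unpaired two-tailed Welch t-test
(Welch–Satterthwaite degrees of freedom) on linear intensities at
uncorrected α = 0.05; a candidate's profile is the count of significant
conditions over testable conditions.  The test scale is a convention
choice: densitometry t-tests are customarily run on linear intensities, and
the Welch statistic is invariant to the per-blot multiplicative shifts the
generator plants (both groups share a blot).  Groups with fewer than two
animals are untestable and drop out of the denominator.  Cross-candidate
similarity of response is summarised by the Pearson correlation of log2 M
profiles over shared evaluable conditions (minimum 3).

## Variance-decomposition stability values

Stability follows the NormFinder model.  On log2 intensities, with
candidate i, group g ∈ {TCDD-treated, control}, animal j (n candidates, G
groups, n_g animals in group g):

    y_igj = α_ig + b_gj + ε_igj,   ε_igj ~ N(0, σ²_ig)

where b_gj is a per-animal sample effect shared by all candidates (this is
what a loading control is supposed to absorb) and σ²_ig is
candidate-specific intra-group variance.  The implemented estimators:

* MS_ig = Σ_j (y_igj − ȳ_ig· − ȳ·gj + ȳ·g·)² / (n_g − 1), the mean square
  of double-centered residuals;
* σ̂²_ig = max(0, n/(n−2) · (MS_ig − Σ_i′ MS_i′g / (n(n−1)))).  The
  correction makes the estimator exactly unbiased before truncation:
  E[MS_ig] = (1−1/n)² σ²_ig + Σ_{i′≠i} σ²_{i′g}/n², and the stated linear
  combination has expectation σ²_ig (n−2)/n.  Monte-Carlo tests confirm
  <5% bias, and the candidate mean of the untruncated estimates equals the
  classical two-way ANOVA residual mean square per group exactly (asserted
  against statsmodels to 1e-9);
* d_ig = (ȳ_ig· − ȳ·g·) − (ȳ_i·· − ȳ···), the inter-group expression
  difference, which sums to zero over candidates within each group;
* γ̂² = max(0, Σ_ig d²_ig / (n(G−1)) − mean_ig(σ̂²_ig/n_g)), a
  moment-matching estimate of the variance of true inter-group differences,
  shared by all candidates;
* the empirical-Bayes shrunk difference d̃_ig = d_ig · γ̂²/(γ̂² + σ̂²_ig/n_g),
  and the stability value

      ρ_i = (1/G) Σ_g [ |d̃_ig| + sqrt( (σ̂²_ig/n_g) · γ̂²/(γ̂² + σ̂²_ig/n_g) ) ].

Lower ρ means a more reliable loading control.  Negative variance estimates
are truncated at zero (variance components are non-negative); when γ̂² = 0
every shrink factor, and hence every score, is exactly 0 — the algorithm's
floor, reached e.g. in the noise-free limit.

**Identifiability.** Because d_ig is centered across the candidate panel,
only *differential* treatment response is visible: a log-scale shift common
to every candidate is absorbed by the sample effects and cannot influence
any score.  Likewise multiplying one blot (or the whole dataset) by a
positive constant changes nothing; both invariances are asserted exactly in
the tests.  Rank-recovery experiments must therefore plant orderings in the
identifiable component (heterogeneous, near-zero-sum effect patterns).

**Combinations.** Every non-empty subset of the 7 candidates (127 subsets)
is scored as a pseudo-candidate: the per-animal arithmetic mean of member
log2 values, i.e. the log2 geometric-mean normalization factor.  The
pseudo-candidate is scored against the sample effects ȳ·gj − ȳ·g·, the
MS-sum correction and γ̂² estimated once from the full 7-candidate matrix,
because the sample effect is a property of the animal/blot, not of the
chosen subset.  This convention makes singleton scores identical to the
per-candidate scores (asserted to 1e-10).  Animals missing any panel member
are dropped listwise with a logged count.  Scores scale linearly with the
log base; base 2 is the default and is recorded in the run log.

## Pairwise comparative normalization

The intensity-scale adaptation of the comparative ΔCq idea: with reference
k and target i, each animal's normalized value is
v_j = (y_ij / y_kj) · median_j(y_kj) — the per-animal ratio rescaled back
to intensity units by the reference's median.  The SD of v is taken within
each experimental group (≥2 animals), averaged over groups, then averaged
over the six targets to give the reference's score; lower is better.
Grouping by experimental group keeps genuine treatment responses of the
targets from being charged to the reference.  The rescaling makes scores
*equivariant* under global intensity rescaling (×c multiplies every score
by c), so candidates with intrinsically bright bands carry larger absolute
scores; this screen is therefore read ordinally, together with the
scale-free ones.

## Attribution of combination stability

The 127 combination scores of one cohort are regressed on seven Boolean
inclusion indicators with no intercept, Y = Σ_p α_p x_p + ε, by OLS
(statsmodels).  A negative α_p means including candidate p lowers
(improves) the stability of combinations that contain it.  Per-coefficient
two-sided t-tests are adjusted across the seven-candidate family with
Benjamini–Hochberg FDR.  With zero residual the design gives exact
recovery of planted coefficients (asserted at 1e-10), and 95% CIs attain
nominal coverage in simulation.

## Protein–mRNA concordance

Per gene, Spearman's ρ between log2 protein intensity and the paired mean
quantification cycle across animals.  Cq is an inverse abundance scale
(one cycle ≈ one doubling), so a *negative* ρ against Cq indicates
concordant abundances; the sign flips exactly under Cq → −Cq.
Significance uses the AS 89 algorithm: exact enumeration of the
permutation distribution of S = Σ(rank differences)² for n ≤ 9 without
ties, and the Edgeworth-series tail approximation otherwise (also used,
approximately, under ties, where exactness is impossible).  Two-sided
p-values double the smaller tail, using the even-valued support of S for
the continuity point.  The implementation reproduces R's `cor.test`
(which uses AS 89) to machine precision and stays within 0.005 of exact
enumeration at n = 8.

mRNA combination stability reuses the protein code path verbatim by
mapping Cq onto pseudo-intensities 2^(−Cq), so log2 "intensity" equals
−Cq; cross-platform agreement of the 127-combination score vectors is
summarised by Spearman's ρ (the ordering, not the magnitude, of stability
scores is meaningful).

## Synthetic-data generator

The generator emulates the study conditions on the encoded 192-animal
design with a log-additive (multiplicative on intensity) model:

    log2 intensity_ij = baseline_i + δ_i(dose_j, time_j) + blot_b(j) + ε_ij

with blot_b ~ N(0, blot_sd²) shared per experiment (one blot per
experiment, the "systemic variation between runs" component), and
ε_ij ~ N(0, σ²_i).  Defaults: baselines span 2^10–2^13 with ACTB brightest
(its bands are far brighter in practice, which is what penalises it in the
comparative screen); σ_intra = 0.25 log2 units (≈19% CV, typical
densitometry noise); blot SD 0.3.  Even usable reference candidates drift
slightly under a strong transcriptional modulator, so each carries a small
dose-saturating shift δ_i = a_i·min(1, dose/500) with mixed-sign
amplitudes |a_i| ≤ 0.35; the CYP1A1-like positive control is induced +6
log2 units (64-fold) at ≥125 µg/kg and +3 below, an order of magnitude
above the candidates.  The induction magnitude is a free parameter chosen
for unambiguous detection at the design's group sizes, not calibrated to
any measured value.

Cq values are coupled to the realized log2 intensities through a Gaussian
copula: normal scores of the intensity ranks are mixed with fresh noise at
the Pearson equivalent 2·sin(π·ρ_s/6) of the target Spearman coupling and
mapped to Cq = baseline − sd·z (sign inverted for the inverse Cq scale).
The achieved Spearman correlation is within ±0.05 of the target at n=192.
The default coupling (0.2) mirrors the weak protein–mRNA agreement
reported for such panels; at weak coupling the mRNA panel inherits almost
no treatment structure and its γ̂² can truncate to zero (all combination
scores at the floor), so cross-platform concordance demonstrations use a
strong-coupling configuration.

All draws come from counter-based substreams keyed on (seed, stream,
animal id, candidate id), so removing animals or candidates never shifts
the remaining draws; identical seeds give bit-identical datasets.

Not emulated: scanner saturation/censoring, within-animal technical
replicates (the study measured each animal once per protein), per-candidate
exclusion patterns, and any correlation of δ with time.  Passing synthetic
tests therefore shows estimator correctness under the planted model, not
robustness to those real-data features.

## Numerical conventions and problem sizes

* Deterministic sort orders everywhere; floats serialized at 12
  significant digits; re-reading written tables reproduces integers
  bit-identically.
* Zero-variance Welch comparisons degenerate to t=0, p=1 (equal means) or
  |t|=∞, p=0; groups under two animals return an untestable marker.
* Constant inputs to Spearman yield an undefined-ρ marker (NaN), never an
  exception.
* Monte-Carlo problem sizes: type-I calibration uses 10,000 simulated
  treated-vs-control conditions; variance-component bias uses 1,000
  replicates of a balanced 2×20 design (20 animals/group keeps MC noise in
  the mean near 1–2%, well inside the 5% bound the check enforces);
  rank recovery uses 100 seeds of the full 192-animal design with a
  1.8× variance ladder (σ = 0.05–0.29) and near-zero-sum effect signs.

## Reproducing the source study's numbers

The published band intensities and Cq values exist only as journal
supplementary spreadsheets without a public accession, so they are not
redistributed here.  The reproduction tests in
`tests/test_acceptance.py::TestStudyReproduction` run automatically once
those tables are exported (long TSV schema, see README) to
`data/study/abundances.tsv` and `data/study/cq.tsv`; without the files
they fail with an explanatory message rather than silently skipping.

## Known limitations

* With G = 2 pooled treated/control groups, heterogeneous treatment
  effects across the 47 design cells are flattened into one inter-group
  difference per candidate; this matches the published grouping but
  discards dose/time structure in the stability values.
* The comparative-normalization statistic is scale-dependent by design and
  is only interpreted ordinally.
* The empirical-Bayes shrinkage uses a single γ̂² shared across candidates;
  with very few candidates (n = 3) the MS-sum correction is noisy and
  truncation at zero becomes frequent.
* AS 89 p-values under heavy ties are approximate; exact tie-aware
  enumeration is not implemented (matching the behaviour of standard
  implementations).
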