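# Methods

This note documents the statistical model behind `rvcluster`, the simulator
used to exercise it, the numerical conventions, and the design decisions that
were genuinely open.

## The region statistic

A region holds *K* variant sites after the common-variant filter (pooled
case+control MAF ≤ 5%, monomorphic sites removed; the boundary MAF = 0.05 is
retained). Per site the test uses:

- **P-value** *p_i*: two-sided Fisher mid-P on the 2×2 table of minor/major
  **allele** counts (two alleles per subject) by case/control status.
  The mid-P rule is probability-based: sum the hypergeometric probabilities
  strictly smaller than the observed outcome's, plus half the tied
  probabilities. Discrete exact tests are conservative; the mid-P correction
  recenters the null distribution toward uniform, which matters when P-values
  are compared to fixed truncation thresholds. Optionally a logistic
  regression Wald P for the dosage term supports covariate adjustment.
- **Direction** δ_i: deleterious-inclined iff the case minor-allele frequency
  strictly exceeds the control frequency, protective-inclined iff strictly
  smaller. Ties belong to neither class and contribute nothing.
- **Weight** w_i = 1/√(n·q_i(1−q_i)), q_i = (m_i^U+1)/(2n^U+2) the
  +1-smoothed control minor-allele frequency (Madsen–Browning). The
  smoothing keeps q in (0,1) even when the permuted "controls" carry no
  minor alleles.

For each truncation threshold τ_j in an ascending grid (default 0.10–0.20 in
steps of 0.01), signal vectors u_del and u_pro have elements
δ_i·w_i·g(p_i)·1[p_i < τ_j] (strict inequality), and

    S_j = u_del' C u_del + u_pro' C u_pro.

The kernel C has c_ij = (1 − (d_ij/d_max)²)³ for inter-site base-pair
distance d_ij < d_max and 0 beyond (tri-weight; default d_max = 20 kb,
continuous at the boundary). The two direction classes are deliberately never
cross-multiplied: deleterious and protective variants may each form their own
clusters, and mixing them would inject the distance between oppositely acting
sites into the statistic. A pooled variant (`statistic_variant="pooled"`)
that sums the vectors before the quadratic form is available for comparison;
it gains power when roughly half the causal variants act in each direction
and loses power when effects share one direction.

The per-site magnitude g(p) defaults to 1 (pure truncation indicator);
g(p) = −log10(p) is available (`transform="neglog10"`). Both reduce to an
adaptive-combination-of-P-values statistic under the identity kernel, and the
permutation machinery is calibrated for either; results record which variant
was used.

C is not forced to be positive semi-definite. The statistic enters inference
only through permutation ranks, so indefiniteness cannot invalidate the
P-value; S_j may in principle be negative for exotic kernels, never for the
identity.

## Permutation min-P inference

With B label shuffles (case/control totals preserved), the per-site total
minor count m_i is invariant, so under the Fisher engine the mid-P of a
shuffled dataset depends only on the case minor count a_i. The engine builds
one hypergeometric mid-P lookup table per site (cached on the margin triple)
and evaluates all B+1 datasets by table lookup and matrix products; tie
classification inside a table uses exact integer binomial-coefficient
arithmetic, so near-equal floating-point probabilities cannot be misgrouped.
Weights, directions, and P-values are all recomputed inside every
permutation — the permuted statistic reproduces the observed statistic's
construction exactly, which permutation validity requires.

Per-threshold P-values are plain rank proportions over the B permuted
statistics: p̂_j = #{b: S_j^(b) ≥ S_j}/B for the observed sample and the
self-inclusive analogue for each permuted sample (the same convention on both
sides keeps the comparison symmetric). The observed minimum over thresholds
is compared against the permuted minima, and the reported adjusted P-value is
(1 + #{b: minP^(b) ≤ minP_obs})/(B+1). The add-one form cannot report zero
and is exact under exchangeability: at B = 500 the achievable adjusted
P-values are k/501, so nominal levels are attainable to within 1/501.

The logistic engine refits every site under every permutation; it exists for
covariate-adjusted analyses and is orders of magnitude slower than the
Fisher path. Sites whose fit fails (separation, non-convergence) get p = 1
with a warning, never a spuriously small value.

Degenerate cases: a region where no site ever passes any threshold (all tied
or all p ≥ max τ) yields adjusted P = 1 with a warning; B = 0 is an error.

## The weighted-sum baseline

WS assigns each subject the score Σ_i g_i/w'_i with w'_i = √(n·q_i(1−q_i))
(control-based q as above), ranks subjects with midranks, and sums the case
ranks — one-sided for excess burden in cases, as in the original
weighted-sum proposal. The P-value uses the same permutation engine
(weights recomputed from each shuffle's controls) and the same add-one
estimator. Its one-sidedness is why it has essentially no power against
protective variants, a contrast the power experiments surface.

## The simulator

The generator emulates a resequenced region, not a coalescent: site
positions are uniform without replacement over the region; rare-site pool
frequencies follow f(x) ∝ 1/x truncated to [1/H, 0.05] (inverse-CDF
sampling), a rare-skewed spectrum; 15% of sites (configurable) are common
with frequency uniform on (0.05, 0.5) so the MAF filter has work to do;
haplotype alleles are independent across sites. Rare variants carry little
linkage disequilibrium in real data, and the test's operating characteristics
are driven by frequencies, positions and the effect model, all of which are
preserved. An optional block-copy mixing step (`ld_mix_rounds`) induces
local allele sharing for sensitivity checks. What the generator does *not*
reproduce: realistic LD with common variants, demographic structure,
recombination maps. Calibration and ordering results on these data therefore
speak to the test's permutation validity and relative behaviour, not to
power magnitudes on any particular real gene.

Causal placement: *clustered* mode draws a random window of `cluster_span` bp
(6 kb for 20 causal variants, 3 kb for 10 at full density) containing enough
rare sites and samples the causal set inside it; *non-clustered* mode assigns
each of n_causal ideal equally spaced grid points its nearest unused rare
site. Direction labels distribute n_protective/n_deleterious uniformly.

Disease model: a causal variant with population attributable risk `par` and
pool frequency `maf` gets genotype relative risk GRR = par/(maf·(1−par)) + 1;
protective variants use the reciprocal. Pool (not sample) frequency is used
because PAR is a population quantity. A subject formed from two haplotypes
drawn with replacement is diseased with probability
min(f0·Π_j GRR_j^{g_j}, 1), baseline penetrance f0 = 1%; drawing continues
until both the case and control quotas are filled, surplus subjects of a
filled class being discarded. Note the asymmetry: on the odds-ratio scale a
deleterious variant's effect magnitude exceeds a protective variant's at the
same PAR and MAF, so all-protective scenarios are intrinsically harder —
visible in the power experiments.

Emitted panels re-code any site whose sample frequency drifted past 0.5 to
the sample minor allele, keeping the minor-allele-count contract consistent
between the matrix and VCF writers and the VCF reader's minor-allele rule
(such sites are common and removed by the filter anyway).

## Experiment scales

Type-I error and power drivers spawn per-replicate RNG streams from one seed
(`numpy.random.SeedSequence`), making every rejection decision reproducible.
The package's desk-scale study conditions (`reduced_scale_config`) are 2,000
null replicates of 200 cases + 200 controls over 20 kb with 70 sites (~60
rare), B = 500 — sized so a full calibration runs in minutes on one CPU while
keeping the binomial envelope around nominal levels tight (±0.013 at
α = 0.05). Power orderings use the full simulation design (500+500 subjects,
330 sites, 20 causal variants clustered within 6 kb) with B = 200 and 300
replicates — enough to resolve the qualitative contrasts of interest
(CLUSTER vs WS under all-protective effects; power growth in PAR). The same
API and CLI flags reach the full-fidelity design (100,000 replicates,
B = 10,000) when compute allows; permutation counts are naturally set higher
for type-I studies than power studies because tail calibration needs finer
P-value resolution.

Fewer than 100 replicates is refused by default (`allow_small=True`
overrides) — rates estimated from a handful of replicates invite
over-interpretation.

## Known limitations

- Single region, single chromosome; no multi-gene orchestration.
- No covariate support outside the (slow) logistic engine; no imputation —
  subjects with missing genotypes are dropped at VCF load.
- Only tri-weight and identity kernels ship; the kernel seam accepts any
  precomputed symmetric matrix with unit diagonal and entries in [0, 1].
- The permutation cost grows linearly in B; no adaptive early stopping or
  analytic approximation is provided.
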