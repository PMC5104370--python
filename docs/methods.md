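# Methods

## Model and procedure

The package analyses *group-level structural covariance* in regional glucose
metabolism. For each group g with n_g subjects, the network is the matrix of
Pearson correlations R_ij between region i and region j computed across the
group's subjects. The correlation matrix is reduced to a binary, undirected
graph by sparsity thresholding: at sparsity S ∈ (0, 1), the
E = round(S·N(N−1)/2) node pairs with the largest correlations receive an
edge. Rounding is half-away-from-zero; ties in R are broken by ascending
(i, j) index order, making the binarization fully deterministic. Ranking is
on *signed* correlation by default — an edge exists where R_ij exceeds the
data-derived threshold — with an `absolute` mode available for users who want
magnitude-based thresholding; neither mode is asserted to be universally
correct, the choice is exposed in the configuration.

Topology follows the classical small-world toolkit on the binary graph:

* clustering C_i = 2E_i / (D_i(D_i−1)) with E_i the edge count among node
  i's neighbours; C_i ≔ 0 where D_i < 2 (the ratio is 0/0 there — the
  standard convention that keeps the mean defined);
* per-node path length L_i = mean breadth-first distance to all other nodes;
  the characteristic path length L_p is the mean of L_i, which for an
  undirected graph equals the all-pairs mean. Path metrics refuse
  disconnected input and report component sizes rather than folding infinite
  distances into an average;
* betweenness B_i = Σ over unordered pairs (j, k), endpoints excluded, of
  σ_jk(i)/σ_jk, computed with Brandes' accumulation and left unnormalized.
  A normalized variant (÷ (N−1)(N−2)/2) is exposed but never used for hub
  calls, since the hub rule B_i > 2·mean(B) is invariant to normalization;
* small-world ratios γ = C_p/C_random and λ = L_p/L_random against an
  ensemble of degree-preserving random graphs, σ = γ/λ.

The null ensemble uses Maslov–Sneppen double edge swaps: 10·E attempted
swaps per draw (a common mixing heuristic; configurable), rejecting swaps
that would create self-loops or duplicate edges. Because L_random must be
defined, draws that disconnect are re-randomized from scratch with a bounded
retry budget; the swap mechanism itself is an assumption — the ensemble is
specified only as "degree-matched" in the literature this design follows,
and edge-swap rewiring is the conventional realization.

## Statistics

*Region-level.* Subjects' profiles are first divided by their own global
mean (`global-mean` mode; `none` disables it), then per-region OLS on
[1, age, gender(0/1)] over the pooled sample removes covariate effects; the
output is residual + intercept, so values keep an interpretable level while
being exactly orthogonal to age and gender. Group differences use Welch
t tests (the groups' printed SDs differ; at n ≈ 80 the distinction from the
pooled test is negligible), and depression association uses Pearson
correlation of each region with the BDI-II score within the patient group.
Both families are corrected with Benjamini–Hochberg step-up FDR at α = 0.01
across the N regions; degenerate regions (zero variance in both groups) are
excluded from the FDR family with a warning rather than silently assigned a
p value. Demographics use the 2×2 Pearson chi-square (1 df, no continuity
correction) for gender and a Welch t test for age.

*Network-level.* Global metric differences (patients − controls) are tested
by permutation: subjects are pooled and reassigned to two groups of the
original sizes, both networks rebuilt at every sparsity in the sweep, and
the observed difference referred to the permutation distribution. The
two-sided p uses the add-one estimator p = (#{|Δ*| ≥ |Δ|} + 1)/(B_valid + 1)
— never exactly zero, never above one — and the 95% empirical percentile
band is reported alongside, so significance can equivalently be read as the
observed Δ falling outside the band (the two agree for symmetric
distributions). Permutation draws where a permuted group's network
disconnects (relevant to L_p only) are recorded as invalid and excluded with
their count reported, never silently dropped. Covariate adjustment is fitted
once on the pooled sample before permuting; the fit uses only age and
gender, never group labels, so refitting inside each draw would reproduce
identical residuals and is therefore not performed.

Edge-wise comparison transforms each correlation with Fisher's z = atanh(r)
and tests Z = (z_1 − z_2)/√(1/(n_1−3) + 1/(n_2−3)) against the standard
normal, two-sided and uncorrected by default (a BH option exists). Pairs
with |r| = 1 have infinite z and are excluded with a warning. Significant
pairs are classed as increases/decreases by sign and as long-range where the
straight-line Euclidean distance between region centroids exceeds 75 mm;
the distance anchors are the region-table centroids, and the packaged table's
coordinates are approximate synthetic stand-ins, so range classification with
the packaged table demonstrates the rule rather than exact anatomy.

## Synthetic cohorts

The generator emulates a two-group regional FDG-PET study at the region
level only — no images, voxels, partial-volume effects, or scanner noise.
Each subject's 90-vector is

    mean_level + MVN(0, Σ_group) + age·β_age + 1[female]·β_gender + ε,

with ε iid N(0, noise_sd²). Defaults reproduce the emulated study's printed
demographics: n = 80/78; gender 45/35 and 43/35; ages normal(49, 7) and
normal(51, 11) truncated at 18. Patient BDI-II scores come from a
three-component severity mixture (weights 44:16:18; means 6, 15, 26; SDs
3, 1, 6) truncated to [0, 63] by clipping, which shifts the lowest stratum
mean by < 0.1 point. A planted coupling list shifts chosen patient regions
by sign·strength·(BDI − mean BDI); the default strength 0.15 uptake units
per BDI point yields a population region–BDI correlation near 0.7 at unit
regional variance, i.e. a strong, comfortably detectable effect.
`mean_level = 100` keeps uptake values strictly positive in practice. One
`numpy` Generator seeded from the spec drives all draws in a fixed stream
order, so an identical spec reproduces the cohort bit for bit; matching
between groups is distributional only (no pairwise subject matching is
simulated, since the design being emulated does not state any).

Covariance builders: `two_block_cov` (two equal blocks — a clean
parameter-recovery contrast) and `modular_cov` (many small equal
communities). A caveat discovered while validating the pipeline and worth
stating: *global-mean normalization removes the shared metabolic component*,
so a covariance built as two large blocks becomes, after normalization, a
strongly bipartite anti-correlated structure whose thresholded graph
segregates (long paths, λ well above 1). A modular structure with many small
communities (e.g. 9 blocks of 10, within-r 0.5, between-r 0.2, noise 0.5)
survives normalization and produces the small-world signature — γ ≈ 1.7,
λ ≈ 1.0 — which is why those are the generator conditions used for the
signature-recovery checks and the acceptance script.

What passing tests on these cohorts do *not* show: multivariate-normal,
linearly-confounded data cannot exhibit the heavy tails, site effects,
registration error, or spatially autocorrelated noise of real PET tables, so
recovery rates here are upper bounds on real-data behaviour.

## Numerical choices and degenerate inputs

* Correlation matrices are symmetrized ((R + Rᵀ)/2), clipped to [−1, 1], and
  given an exact unit diagonal before use; constant region columns are
  rejected with the offending region named (detected by zero peak-to-peak
  range, which is robust to floating-point mean round-off).
* Group sizes below 4 are rejected everywhere (Fisher's SE needs n − 3 > 0).
* Connectivity at the fixed sparsity is checked and *reported*, not silently
  enforced; a disconnected group network aborts the pipeline with the
  minimum connected sparsity (found by union-find over the ranked edge
  order) in the error.
* Sparsity grids are generated as s_min + k·step with an epsilon guard, so
  0.24–0.50 by 0.01 yields exactly 27 points.
* `normalize_and_adjust` is idempotent in its regression step (residuals are
  already orthogonal to the covariates); re-applying the `global-mean`
  scaling to already-adjusted output perturbs values at the order of the
  residual row means and is not a supported round trip.
* All stage randomness derives from one master seed via named substreams
  (cohort, nulls, permutations, nodal), so stages re-run in isolation
  reproduce the full pipeline's numbers.

## Problem sizes

The test suite and `scripts/acceptance.py` use reduced but fully stated
replicate counts chosen to keep a complete run in the minutes range on one
CPU: 100–1000 null rewirings per ensemble, 200–500 permutations per test,
100–200 outer replicates for calibration and recovery rates. The reference
analysis defaults (1000 nulls, 1000 permutations) remain the package
defaults and are what `metabnet run-all` uses.

## Known limitations

* Binary, undirected networks only; no weighted, directed, efficiency,
  modularity, or rich-club analysis.
* Region-level throughout: voxel-wise statistics, cluster-extent
  thresholding, and peak coordinate reporting require images and are out of
  scope, as are PET acquisition, reconstruction, and spatial normalization.
* The packaged centroid table is synthetic-approximate; exact long/short
  range classification needs a user-supplied atlas table.
* The permutation test assumes exchangeability of subjects under the null
  after covariate adjustment; strong group-specific covariate effects would
  violate it.
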