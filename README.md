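# metabnet

Group-level **metabolic brain covariance networks** from regional FDG-PET
data: network construction, small-world topology against degree-matched random
nulls, betweenness hubs, and permutation / Fisher-z / FDR group statistics —
plus a synthetic cohort generator so every stage is testable without imaging
data.

## The scientific problem

Resting-state FDG-PET measures regional cerebral glucose uptake, a proxy for
neuronal activity. Across a group of subjects, regions whose metabolism rises
and falls together are treated as *connected*: the group's network is the
N × N matrix **R** of Pearson correlations R_ij between regional metabolism
values, computed over subjects (one network per group, not per subject). The
package targets the classic two-group design — healthy controls versus a
clinical group (here modelled on pre-chemotherapy cancer patients with
depressive symptoms, BDI-II scored) — on the 90-region cerebral AAL
parcellation (45 regions per hemisphere).

The analysis chain is:

1. **Normalization** — each subject's regional values are divided by that
   subject's whole-brain mean, then per-region ordinary least squares removes
   linear age and gender effects; the retained value is residual + intercept.
2. **Network construction** — R is thresholded into a binary, undirected
   adjacency A at sparsity S (the fraction of realized edges among
   N(N−1)/2 pairs): the E = round(S·N(N−1)/2) largest correlations become
   edges. The fixed analysis sparsity defaults to S = 0.24 (961 edges at
   N = 90), with a comparison sweep over 24–50% in 1% steps.
3. **Topology** — per node: degree D_i, clustering
   C_i = 2E_i/(D_i(D_i−1)), path length L_i (mean BFS distance), and
   unnormalized betweenness B_i = Σ_{j<k} σ_jk(i)/σ_jk. Globally: C_p and
   L_p, normalized by the means of 1000 degree-preserving Maslov–Sneppen
   rewirings to give γ = C_p/C_rand, λ = L_p/L_rand, σ = γ/λ (small-world:
   γ > 1, λ ≈ 1). Hubs are nodes with B_i > 2 × mean(B).
4. **Inference** — group differences in C_p, L_p and nodal B_i via
   label-shuffling permutation tests (add-one two-sided p, 95% permutation
   interval, 1000 repetitions at each sparsity); edge-wise comparison via
   Fisher's z, Z = (z_1 − z_2)/√(1/(n_1−3) + 1/(n_2−3)), with long-range
   edges defined by centroid distance > 75 mm; region-level group t tests and
   BDI–metabolism Pearson correlations corrected with Benjamini–Hochberg FDR
   at 0.01.

The packaged region table carries the standard AAL-90 labels with
**synthetic approximate centroids** (see `metabnet/data/`); supply your own
CSV for exact atlas coordinates.

## Worked example

```python
import metabnet as m

regions = m.load_regions()                      # packaged 90-region AAL table
spec = m.SimulationSpec(
    base_cov=m.two_block_cov(90, 0.3, 0.3),     # controls: uniform covariance
    cov_cancer=m.modular_cov(90, 10, 0.5, 0.2), # patients: 9 tight modules
    noise_sd=0.5,
    seed=4,
)
cohort = m.generate_cohort(spec, regions)
norm = m.normalize_and_adjust(cohort)           # global-mean + age/gender OLS

demo = m.demographics_table(cohort)
print(f"gender chi-square p = {demo.gender_p:.3f}")

net = m.correlation_network(norm, "cancer")
bnet = m.binarize_at_sparsity(net, 0.24)
nulls = m.random_null_ensemble(bnet, n_rand=100, seed=5)
gm = m.small_world(bnet, nulls)
print(f"C_p={gm.C_p:.3f} L_p={gm.L_p:.3f} "
      f"gamma={gm.gamma:.2f} lambda={gm.lambda_:.2f} sigma={gm.sigma:.2f}")

res = m.permute_metric(norm, "C_p", [0.24], n_permutations=500, seed=6)[0]
print(f"delta C_p (patients - controls) = {res.observed:+.3f}, "
      f"permutation p = {res.p:.4f}")
```

prints

```
gender chi-square p = 0.887
C_p=0.408 L_p=1.794 gamma=1.78 lambda=1.02 sigma=1.75
delta C_p (patients - controls) = +0.115, permutation p = 0.0020
```

Reading the numbers: the default cohort reproduces the 45/35 vs 43/35 gender
split (chi-square p = 0.887, i.e. groups are gender-matched). The patient
network, built from modular covariance, is small-world — clustering 1.78×
its degree-matched random ensemble (γ > 1) at essentially random path length
(λ = 1.02) — and its clustering coefficient exceeds the control group's by
0.115, a difference never reached by 500 label permutations except at the
add-one floor (p = 2/501 ≈ 0.002).

The same analysis is available from the shell:

```sh
metabnet simulate --out cohort.csv --seed 1
metabnet validate cohort.csv
metabnet run-all --cohort cohort.csv --out results/ --seed 1
```

`run-all` writes every intermediate artifact (correlation CSVs, edge lists,
GraphML, nodal metric tables, permutation and Fisher-z tables) plus
`summary.json` / `summary.md` stamped with the config hash and seeds;
`metabnet init-config` emits the full default configuration
(S = 0.24, sweep 0.24–0.50 step 0.01, 1000 nulls, 1000 permutations,
FDR α = 0.01, edge α = 0.01, 75 mm long-range cutoff) as editable YAML.

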