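# adnetworks

Stage-wise graph analysis of resting-state functional brain networks across
the Alzheimer's disease spectrum: healthy subjects (HS), amnestic mild
cognitive impairment (aMCI), and three Clinical Dementia Rating stages
(CDR 0.5, 1, 2).

## The problem

Functional connectivity studies of AD disagree about how network topology
changes with disease stage, partly because cohorts mix stages and partly
because thresholding choices change graph size. This package implements a
pipeline designed to make stages comparable:

1. **Connectivity.** For each subject, the dependence between every pair of
   the 90 cerebral regions of the AAL parcellation is quantified by plug-in
   mutual information (in bits), estimated from a joint histogram after
   marginal equiprobable binning:

   `MI(X,Y) = Σ_x Σ_y p(x,y) log2[ p(x,y) / (p(x)p(y)) ]`

   MI, unlike Pearson correlation, is sensitive to non-linear dependence;
   quantile binning makes it invariant under monotone signal transforms.
2. **Fixed-density networks.** Every subject's binary graph keeps exactly
   the `round(d·N(N−1)/2)` strongest connections (default density
   d = 7%, i.e. 280 of the 4005 possible edges), so group comparisons are
   never confounded by differing edge counts: `d = 2E / (N(N−1))`.
   An absolute-threshold variant supports a subject-exclusion screen that
   flags network degrees outside Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR).
3. **Graph measures.** Seven whole-network measures (characteristic path
   length, clustering coefficient, global efficiency, local efficiency,
   betweenness centrality, assortativity, modularity), their nodal forms,
   and lobar averages over frontal / parietal / occipital / temporal /
   subcortical divisions per hemisphere.
4. **Rich-club organization.** `Φ(k) = 2E_k / (N_k(N_k−1))` over the nodes
   of degree ≥ k, normalized by the mean of a Maslov–Sneppen
   degree-preserving rewiring ensemble, with an add-one permutation
   p-value: `Φ_norm(k) = Φ(k) / Φ_random(k)`.
5. **Group statistics.** One-way ANOVA with Tukey–Kramer post-hoc
   comparisons across the five stages, and Pearson correlations between
   network measures and clinical scores (per group and pooled,
   uncorrected p by default).

Because no public dataset accompanies this design, the package ships a
synthetic cohort generator (`adnetworks.synthetic`) that emulates the study
conditions — five groups of 31/50/25/36/10 subjects, 90 regions, 120 time
points — with a modular, stage-dependent Gaussian signal model and clinical
scores genuinely coupled to each subject's realized connectivity. See
`docs/methods.md` for the model and its limitations.

## Worked example

```python
from adnetworks import CohortSpec, PipelineConfig, generate_cohort, run_group_pipeline

spec = CohortSpec(seed=1, group_sizes={"HS": 8, "aMCI": 8, "CDR0.5": 8,
                                       "CDR1": 8, "CDR2": 8})
cohort = generate_cohort(spec)
bundle = run_group_pipeline(cohort, PipelineConfig(seed=1, n_random=100))

print(bundle["metrics"].groupby("group")["global_efficiency"].mean().round(3))
```

```
group
CDR0.5    0.243
CDR1      0.375
CDR2      0.242
HS        0.286
aMCI      0.378
```

The generator's stage couplings are non-monotonic (integration high in
aMCI and CDR1), and the recovered group-mean global efficiency follows the
same order: HS < aMCI > CDR0.5 < CDR1 > CDR2. The post-hoc contrast for
the adjacent aMCI vs CDR0.5 pair is decisive:

```
 mean_diff  adjusted_p
    0.1349      0.0001
```

Group-level rich-club organization at degree threshold k = 9 (from the
mean connectivity matrix per group, 100 rewired nulls):

```
 group   phi  phi_norm  perm_p  n_nodes  n_edges
    HS 0.327     1.271    0.01       25       98
  aMCI 0.281     1.178    0.01       22       65
CDR0.5 0.490     1.502    0.01       23      124
  CDR1 0.326     1.337    0.01       24       90
  CDR2 0.494     1.460    0.01       23      125
```

`phi` is the edge density among surviving hubs, `phi_norm > 1` with
`perm_p ≤ 0.05` indicates rich-club organization beyond what the degree
sequence enforces, and `n_nodes`/`n_edges` are the club's size.

The same analyses are available from the shell:

```sh
adnetworks generate --out cohort/ --seed 1
adnetworks run --cohort cohort/ --out results/ --density 0.07 --seed 1
adnetworks richclub --timeseries cohort/sub-0000.tsv --k-max 15 --n-random 1000 --seed 7
```

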