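# Methods

This note documents the models, estimators, conventions and numerical
choices behind `adnetworks`, and what the synthetic cohort does and does
not establish about real data.

## Mutual-information connectivity

The dependence between two regional time series is the plug-in mutual
information of their joint histogram, in bits. Choices a user should know
about:

- **Binning.** Marginal equiprobable (quantile) bins, count
  `b = ceil(sqrt(T/5))` clipped to [4, 16] (b = 5 at the default
  T = 120). Quantile binning is invariant under monotone transforms of
  either series; since only the *rank order* of MI values feeds the
  density threshold, this makes the network construction robust to
  signal scaling and monotone drift. Bin boundaries are
  linear-interpolation quantiles; a value equal to a boundary goes to the
  lower bin.
- **No bias correction.** The plug-in estimator has a positive bias of
  roughly `(b−1)²/(2T ln 2)` bits under independence. It is common to all
  pairs and cannot reorder them, so it is left in place rather than
  corrected.
- **Degenerate input.** A constant series occupies one bin and returns
  MI = 0, logged rather than raised: an all-zero region should not abort
  a cohort run.
- **Scale.** Log base 2. Any base rescales every pair identically and
  leaves the thresholded edge set unchanged.

## Network construction

- **Fixed density.** `E = round(d·N(N−1)/2)` strongest off-diagonal
  entries become edges (rounding half away from zero; d = 0.07 and N = 90
  give E = 280). Ties at the cutoff are broken lexicographically by
  (row, column) index — deterministic, logged when it happens.
- **Degree screen.** The exclusion screen thresholds connectivity at an
  absolute value (default 0.8, configurable — MI scales differ across
  estimators, so the value is a parameter, not a constant), sums each
  subject's degrees, and excludes subjects outside
  [Q1 − 1.5·IQR, Q3 + 1.5·IQR] (linear-interpolation quartiles). The
  screen is off by default in the pipeline: the synthetic cohort has no
  planted artifacts, and screening is a data-cleaning step for real
  cohorts.
- **Group-level networks.** Group rich-club analyses threshold the
  element-wise *mean* connectivity matrix of the group's subjects. How a
  representative group network should be built is genuinely open
  (mean matrix, representative subject, edge-frequency consensus…); the
  mean matrix is this package's choice, stated here because results at
  the group level depend on it.

## Graph measures

Shortest-path machinery, clustering, betweenness and Louvain come from
networkx; conventions fixed here:

- Characteristic path length averages over *reachable* ordered pairs only
  (count of skipped pairs logged). Efficiency-based measures handle
  disconnection natively (1/∞ = 0), which is why they are preferred for
  sparse networks.
- Local efficiency of a node is the global efficiency of the subgraph
  induced on its neighbours (0 below degree 2).
- Betweenness uses fractional counting over equal-length shortest paths,
  normalized by (N−1)(N−2)/2.
- Assortativity is the Pearson correlation of endpoint degrees over the
  edge list with both orientations; on a regular graph it is undefined
  and raises `DegenerateGraphError` (the pipeline records NaN) instead of
  returning a misleading number.
- Modularity Q is maximized by seeded multilevel (Louvain) search with 20
  restarts, keeping the best partition; deterministic given the seed. For
  graphs of ≤ 8 nodes the optimum is found by exhaustive partition
  enumeration instead — cheap at that size, and exact.
- Lobar values are unweighted means of nodal values within each of the 10
  lobe × hemisphere cells of the shipped region table. The assignment of
  the 45 region pairs to five lobar divisions is a stated convention
  (anterior + middle cingulate → frontal, posterior cingulate → parietal,
  medial temporal structures and fusiform → temporal, insula →
  subcortical); users can pass their own table.

## Rich-club analysis

- **Filter convention.** "Nodes of degree ≥ k survive", with degrees
  measured once in the full graph — a single-pass filter, not k-core
  peeling.
- **Null model.** Degree-preserving double-edge swaps; each null network
  uses 10 × E successful swaps (a standard mixing allowance). Graphs with
  no swappable edge pair return unchanged after an attempt budget, so the
  routine terminates on degenerate inputs like a two-edge path.
- **Normalization.** Φ_random(k) is the ensemble *mean* over nulls where
  Φ is defined. Undefined entries (fewer than two survivors) are carried
  as NaN and listed in `undefined_k`, never silently dropped.
- **Significance.** `perm_p = (1 + #{null Φ ≥ observed}) / (1 + n_random)`
  (add-one form), so p is never exactly zero and is bounded below by
  1/(n_random + 1).
- **Ensemble size.** Production default 1000 nulls. The test suite uses
  100–200 nulls; at 200 nulls the smallest attainable p is ~0.005 and the
  Φ_random mean has a relative SE well under 2% for the graphs tested,
  which is ample for the pass/fail bands the tests assert.

## Group statistics

One-way ANOVA (`scipy.stats.f_oneway`) with Tukey–Kramer post-hoc
comparisons (`scipy.stats.tukey_hsd`, studentized-range based, valid for
unequal group sizes and conservative under the global null — verified by
simulation at the cohort's sizes 31/50/25/36/10). Correlations are
Pearson r with R² = r² and two-sided p, computed per group and pooled;
missing values are pairwise-deleted and logged. Correlation p-values are
uncorrected by default — lobar and correlation tests are treated as
independent hypotheses — with optional Benjamini–Hochberg adjustment for
users who prefer control of the false-discovery rate.

## Synthetic cohort generator

The generator defines the package's study conditions: five groups of
31/50/25/36/10 subjects, 90 regions mapped to five lobar modules, 120
time points (emulating ~6 min of resting fMRI at a 3 s sampling
interval), and nine clinical scores anchored at healthy-cohort baselines.

**Signal model.** Stationary multivariate Gaussian,

    x_i = sqrt(w)·[sqrt(1−c)·u_m(i) + sqrt(c)·g] + sqrt(1−w)·e_i  (+ noise)

with module factors `u_m`, a global factor `g`, private signal `e_i`, and
optional AR(1) temporal filtering (default off). Implied correlation: `w`
within a module (default 0.45), `c·w` between modules, all shrunk by
1/(1+noise_sd²) by the measurement noise (default SD 0.2). The matrix is
positive definite for every w < 1, c ∈ [0, 1) by construction.

**Why the stage parameter is between-module integration.** The coupling
`c` (per group: HS 0.35, aMCI 0.75, CDR0.5 0.20, CDR1 0.65, CDR2 0.30 —
the non-monotonic stage profile, with subject-level jitter SD 0.02)
scales how coherent the lobar modules are with each other, not how strong
they are internally. The reason is a property of fixed-density
thresholding that we verified numerically while designing the generator:
with the edge budget fixed, making *within-module* dependence stronger
only concentrates edges inside modules, so global efficiency *falls* as
that kind of coupling rises (a noise-only matrix yields an Erdős–Rényi-
like graph, which is already near the efficiency ceiling for its
density). Scaling *between-module* coherence instead lets inter-lobe
edges compete into the budget: group-mean global efficiency rises
monotonically from ≈ 0.22 to ≈ 0.38 as c goes from 0.15 to 0.8 at
w = 0.45. Under hub-factor variants and within-module-coupling variants
the response was flat or inverted, so those designs were rejected.
Substantively this models stage-dependent *functional integration
between lobes*, the mechanism consistent with reports of transient
hyperconnectivity and hyperactivation in prodromal AD.

**Clinical scores.** Each score is
`baseline + clinical_effect · SD · (realized mean off-diagonal correlation) + 0.5·SD·ε`
with clinical_effect = −8 score-SDs per unit coupling: subjects whose
realized connectivity is higher score lower, so metric–score correlations
in the pipeline are recoverable by construction, with within-group
magnitudes around |r| ≈ 0.3–0.45 at the default noise.

**What passing tests do not show.** The generator is stationary Gaussian
with block-plus-global covariance; real fMRI has autocorrelated,
non-Gaussian, artifact-laden signals, spatially heterogeneous coupling,
and no ground-truth stage parameter. Tests on this cohort establish that
the pipeline recovers known structure under controlled conditions — not
that real AD cohorts exhibit that structure, and not that the generator's
group means match any published cohort's values.

## Problem sizes used in tests

The shipped suite runs full cohorts of 152 subjects for stage-ordering
recovery (50 seeds), 200 random graphs of ≤ 8 nodes for brute-force
metric equivalence, 1000 rewiring calls for degree conservation, 200-null
ensembles for rich-club calibration, and 2000 replicates for the
Tukey–Kramer family-wise error simulation (via the exact max-q shortcut:
a pair is rejected iff its studentized-range statistic exceeds the single
critical value, so simulating the maximum avoids thousands of numerical
SF integrations; the shortcut is spot-checked against the full routine).

## Known limitations

- Exact numeric parity with any particular published connectivity matrix
  is not attainable: histogram scheme, bin count and log base of the MI
  estimator are rarely reported, and they change MI's scale (though not,
  under quantile binning, the qualitative ranking behaviour).
- The absolute screening threshold (0.8) is meaningful only relative to
  the estimator's scale; treat it as a tunable.
- Binary undirected graphs only; no weighted or directed variants, no
  multi-density sweep beyond re-running at chosen densities.
- Louvain above 8 nodes is a heuristic; restarts mitigate but do not
  guarantee the global optimum.
- The rich-club filter uses single-pass degrees; an iterative (k-core)
  reading would give different clubs on some graphs.
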