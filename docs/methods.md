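# Methods

## The model

`conwas` tests whether the *pattern* of a brain region's white-matter
connections differs between diagnostic groups, region by region across a
90-node (AAL, non-cerebellar) structural connectome, and then asks which
individual connections drive a detected difference, whether connection
*amplitude* also changes, and how well the implicated connections
predict diagnosis.

For region *i*, each subject contributes a connectivity vector: the 89
weights from *i* to every other region, taken from the
density-thresholded connectivity matrix.  Subjects *u*, *v* are compared
by the correlation distance

    d_uv = sqrt(2 (1 - r_uv)),   r_uv = Pearson correlation of the
                                        two connectivity vectors,

which is bounded in [0, 2] and Euclidean-embeddable.  Distance matrix
regression decomposes the squared distances:

    SST = (1/n) Σ_{u<v} d_uv²
    SSW = Σ_g (1/n_g) Σ_{u<v in g} d_uv²     (within-group, per group g)
    SSA = SST − SSW
    pseudo-F = (n − 1) · SSA / SSW.

Significance comes from permutation: subject labels are shuffled, the
statistic recomputed, and p = (1 + #{F_perm ≥ F_obs}) / (B + 1)
(add-one convention, ties counted as extreme; p can never be 0).  The
scan over 90 regions is corrected by Benjamini–Hochberg FDR.

### Covariates

Age, sex and APOE-4 carrier status are adjusted through the Gower
machinery: with G = C(−D²/2)C the centered inner-product matrix,
H_cov the hat matrix of intercept + covariates and H_full additionally
spanning the group indicators,

    F = (n − 1) · tr((H_full − H_cov) G) / tr((I − H_full) G).

With no covariates this reduces *exactly* to the statistic above (an
asserted identity: tr(H_d G) = SSA, tr((I − H_full) G) = SSW).  The
permutation scheme is Freedman–Lane by default — the reduced-model
residual structure R_cov G R_cov is permuted while the design is held
fixed — with raw subject-index permutation available via
`permutation_scheme="raw"`.  Because SST is permutation-invariant, the
(n−1)-scaled statistic and the classical dof-scaled F are strictly
monotone in one another and give identical permutation p-values (checked
by exhaustive enumeration at small n).

### δ effect size (post-hoc attribution)

For a significant seed region, the contribution of each single
connection j is measured as the mean drop in pseudo-R² = SSA/SST when
column j of the seed's connectivity vectors is independently permuted
across subjects (default 100 randomizations; the covariate-adjusted
analogue uses the semi-partial trace ratio).  Implementation note: a
single-column permutation changes the inter-subject correlation matrix
through rank-one updates of the Gram matrix, row sums and row sums of
squares, so each randomization costs O(n²) instead of a full O(n²·m)
distance-matrix rebuild; the fast path is verified against a brute-force
recomputation oracle.  The top five partners per seed (ties broken by
node order, flagged) define the "key" connections.

### Nodal strength (amplitude comparison)

Overall connectivity strength of a node is the sum of absolute incident
edge weights.  Group differences are tested by an OLS partial-F test
(group indicators vs. covariates-only), and pairwise group contrasts by
a two-sided permutation test on covariate-residualized strengths
(add-one convention).

### Classification

For a binary contrast the cohort is split stratified 80/20 (161
subjects → 129 train / 32 test), five times.  Features are either the
deduplicated union of key connections — re-derived *within the training
subjects only* (scan → seed selection → δ top-5) — or all n(n−1)/2 edge
weights.  The classifier is PLS regression on a 0/1 class indicator
thresholded at 0.5, its component count tuned by 5-fold cross-validated
AUC inside the training set.  Test-set sensitivity (patient class
positive), specificity, and rank-formula (Mann–Whitney) AUC are
reported per repeat; key-vs-full differences are assessed by a paired
t-test across repeats.  An instrumented test poisons the held-out
subjects and asserts the selected features are unchanged (no leakage).

## Network construction

Edge weights follow the connection-density convention: for regions i, j
with surface areas S_i, S_j and streamlines f of length len_f,

    w_ij = (2 / (S_i + S_j)) · Σ_f 1 / len_f .

A 5% density threshold keeps the ⌊0.05 · n(n−1)/2⌋ largest
upper-triangle weights (the 95th percentile over all possible edges,
zeros included); ties at the cut are all retained and logged, so the
achieved density can marginally exceed the target.  Thresholding is
idempotent and contractive.  The count rounding (floor) and the
percentile basis (all pairs, not only nonzero ones — "density"
conventionally counts all possible edges) are package choices; the
nonzero-only basis is not offered because the two coincide whenever the
input is denser than the target, the only case that arises in this
pipeline.

## The synthetic cohort generator

The generator emulates the data situation of a four-group
(CN/sMCI/cMCI/AD) diffusion-tractography study *after* network
construction; no images, tensors or streamline geometry are simulated.

* **Population template.** Edges exist with probability `base_density`
  (default 0.10, so that the 5% threshold is active); present edges get
  log-normal weights (`edge_weight_mu=0`, `edge_weight_sigma=1` —
  heavy-tailed, as streamline-count-derived weights are).  Planted seed
  regions are treated as hubs: their rows are twice as dense as the
  background, mirroring the hub-like subcortical/limbic regions this
  kind of analysis implicates.
* **Subjects.** Each subject multiplies every template edge by an
  independent log-normal factor (`subject_sigma=0.4`).
* **Planted disease effect.** Per seed region, a fixed plan — drawn once
  and shared by all affected subjects, so it is a *group-level pattern*
  — shifts `amplified_fraction` (0.30) of the seed's edges up and an
  equal fraction down by the factor exp(±0.15·eff) and reroutes
  `rerouted_fraction` (0.15), moving the fraction 1 − exp(−0.15·eff) of
  each rerouted edge's weight, split over three previously absent
  partners.  Patterned edges are chosen among the seed's edges above
  the template's own 5% density cut (so the shift survives per-subject
  thresholding) whose partners are hubs for which that edge is a small
  share of total strength; per-seed pools and reroute targets are
  disjoint.  This design concentrates the *multivariate* signal at the
  seed region: every individual partner sees one modest, noise-scale
  change, while the seed's profile shifts coherently across many
  coordinates.  Effect magnitude is `effect_size ×` a stage multiplier
  (CN 0, sMCI 0, cMCI 1, AD 2): stable MCI shows essentially no
  alteration and magnitude grows with disease stage.
* **Covariates.** Age, sex and APOE-4 are drawn per group with the
  matched-cohort defaults (ages ≈ 74–77 ± 6–8 y; APOE-4 carrier rates
  0/16.7/22.2/15%).  A `confounded` switch shifts age means with stage,
  and `effect_driver="age"` makes the connectivity shift a function of
  age rather than group — together they exercise covariate adjustment
  (unadjusted significant, age-adjusted not).
* **Determinism.** One master seed; template, perturbation plans,
  subject noise and covariates use separate derived streams, so
  regeneration is bit-identical and a cohort with zero effect is
  distributionally independent of group labels.

What the generator does **not** emulate: spatial/geometric structure of
real parcellations, distance-dependent connection probability,
site/scanner effects, missing data, or realistic inter-edge correlation
beyond the shared template.  Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under a controlled
generative model, not performance on real diffusion MRI cohorts.

## Study conditions used by the test suite and acceptance script

Simulation sizes were chosen so the whole suite runs on a single CPU in
minutes while keeping each check informative:

* **Type-I calibration:** 20-node networks, 20+20 subjects, zero effect,
  B = 199, 500 replicates, covariate-free two-group scan; pooled
  rejection rate at α = 0.05 expected in [0.03, 0.07].  (At this scale a
  lone minimum p of 1/200 cannot reach q < 0.05 over 20 regions, so the
  companion "no FDR discoveries under the null" check is conservative by
  construction.)
* **Planted-seed recovery:** full 90-node atlas, three hub seeds,
  40+40 subjects, `effect_size=2.0`, `edge_weight_sigma=0.6`, 5%
  threshold, B = 199, age/sex/APOE-adjusted scan, 100 replicates.  The
  moderated weight tail is part of the stated condition: under extreme
  heavy tails (σ = 1) the correlation distance is dominated by a few
  edges and exact top-3 ranking of all three seeds needs a larger cohort
  than is sensible here.  Success requires all three seeds to be the
  three smallest p-values (pseudo-F breaking ties at the permutation
  floor) and all to reach q < 0.05; the δ check requires each seed's
  top-5 to intersect its truly perturbed partners.  Exact top-3 ranking
  is the most stringent of the three: because planted edges are
  symmetric, every patterned partner region carries a genuine (if
  small) pattern change of its own, and in a small fraction of sampled
  templates the strongest partner outranks the weakest seed.  The
  q-recovery and δ-recovery checks are robust to this;
  `scripts/acceptance.py` reports all three rates.
* **Classification:** same condition at `effect_size=1.0`, 30+30
  subjects, 3 repeated splits, B = 199 selection scans with seed
  threshold p < 0.011 (the selection threshold is matched to the
  attainable p-value resolution at B = 199; at the full-scale default
  B = 5000 the conventional p < 0.001 applies), components tuned over
  1–3.  Under this sparse signal the key-connection model is expected to
  match or beat the 190-times-larger full-edge model on mean test AUC;
  under zero effect both sit at chance.

## Numerical choices

* Zero-variance connectivity vectors (isolated nodes): r := 0,
  d := sqrt(2), flagged — subjects are never dropped, keeping the
  subject space consistent across regions.
* Permutation tie tolerance: F_perm ≥ F_obs − 1e-9·|F_obs| counts as
  extreme (conservative).
* SSW = 0 (all within-group distances zero): F := +inf, flagged; p
  still valid by the counting convention.
* Constant covariate columns are dropped with a warning; rank-deficient
  designs raise an error naming the collinear columns.
* APOE-4 enters as a carrier indicator (0/1); allele counts pass
  through unchanged if supplied.
* PLS component grids are truncated to the rank of the centered
  training block (NIPALS deflation is degenerate beyond it).
* BH q-values come from `statsmodels.stats.multitest`; OLS fits from
  `statsmodels`; PLS and stratified CV from `scikit-learn`.

## Known limitations

* The δ statistic is an interpretation (mean pseudo-R² drop under
  single-column randomization); other operationalizations of a
  randomization-based univariate effect size exist.
* Freedman–Lane permutation is asymptotically exact, not exact, in the
  presence of covariates.
* The pairwise strength permutation residualizes once on the pooled
  two-group sample; with strongly group-dependent covariate effects
  this is an approximation.
* Reported classification metrics aggregate over repeated random
  splits by the arithmetic mean; per-repeat values are retained in the
  report table.
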