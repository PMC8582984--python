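# Methods

This note documents the models, algorithms and numerical choices behind
`perceptrisk`, what the synthetic data generator does and does not emulate,
and where the design was genuinely open.

## Risk coding and scoring

Each survey item is single-choice. The codebook assigns every category a
sign in {−1, 0, +1} reflecting agreement with expected protective knowledge
and behaviour; the three recognised item dimensions are *knowledge*,
*perception/severity* and *preventive practice*. Encoding produces one
column per (item, category) pair: the chosen category's column carries its
sign, all other columns in the item's block are 0.

Consequences worth knowing:

- a **missing answer** leaves the item's block at zero, contributing 0 to
  the score — no imputation is attempted, which the additive score
  tolerates;
- a chosen category whose sign is 0 is indistinguishable from a missing
  answer in the encoded matrix (it carries no risk information), so
  decoding recovers chosen categories only for ±1 choices;
- zero-signed categories therefore produce identically-zero dummy columns.
  The pipeline drops constant columns before the categorical PCA (which
  rejects constant variables); under the reference synthetic codebook this
  keeps 80 informative columns of 166.

The score is the row sum, an integer in [−m, m]. Quartile labels 1–4 are
assigned against the empirical 25/50/75 percentiles with boundary scores
going to the lower group, so a score value never straddles two groups and
heavily tied integer scores give similar-but-unequal group sizes. All
scores identical yields a single group with a warning.

**Bimodality** is operationalised, not eyeballed: one- and two-component
univariate Gaussian mixtures are fitted (five restarts for the
two-component fit, fixed seed) and the distribution is called bimodal when
the two-component model wins on BIC *and* the component means are farther
apart than the weight-averaged component standard deviation. Both
conditions matter: BIC alone flags skewed unimodal distributions.

**Descriptive tables.** Contingency tables carry row/column/grand totals
and percent-of-grand-total; the chi-square test is the plain Pearson
statistic, no continuity correction, df = (r−1)(c−1). Age bands are fixed
at 15–24, 25–34, …, 75–84, 85+ for comparability across tables.

## Optimal-scaling categorical PCA

The alternating-least-squares routine minimises the Gifi loss

σ(X, z, a) = (1/m) Σⱼ ‖X − Gⱼ zⱼ aⱼ′‖²,  with X centred and X′X = n·I,

where Gⱼ is variable j's indicator matrix, zⱼ its category quantifications
(normalised to zⱼ′Dⱼzⱼ = n, weighted mean 0) and aⱼ its p-vector of
loadings — a rank-one ("single") treatment of every variable. Scaling
levels restrict zⱼ: **nominal** free, **ordinal** monotone in the sorted
category order (weighted pool-adjacent-violators, with the better of the
increasing/decreasing fit chosen and the sign absorbed into aⱼ), **numeric**
fixed at the standardised category values.

Numerical choices:

- **Object-score update by orthogonal Procrustes.** The minimiser of the
  loss over centred column-orthonormal X is √n·UV′ from the SVD of the
  centred average Σⱼ Gⱼzⱼaⱼ′/m; using it makes the loss provably
  non-increasing, which the tests assert over many seeds. (A Gram–Schmidt
  update is the textbook alternative but does not guarantee monotonicity.)
- **Principal-axis rotation at the end.** The loss is invariant to a joint
  rotation of X and the loadings, so after convergence the solution is
  rotated to diagonalise A′A with decreasing eigenvalues. Component s then
  has VAF share λₛ/m ∈ [0, 1], the shares come out sorted, and with
  all-numeric scaling they equal classical PCA eigenvalue shares — the
  test-suite oracle (agreement to ~1e-15 on random continuous data).
- Convergence: loss decrease < tol (default 1e-6), max 500 iterations
  (150 in the pipeline), random orthonormalised start from the seed.
  Non-convergence returns a flagged result rather than raising.
- A restriction step that collapses a quantification to a constant keeps
  the previous zⱼ; loadings are re-optimised for the final zⱼ either way.

Component selection keeps the smallest k whose cumulative VAF reaches the
threshold (inclusive, default 0.80) and errors if the fitted
dimensionality cannot reach it. The pipeline fits up to 150 dimensions by
default (bounded by the variable count and n−1).

## Similarity network

Cosine similarity on the selected object-score columns; an edge joins
every pair strictly above the cutoff (default 0.5 — a tie at exactly the
cutoff is *not* an edge). Pairs are evaluated in row blocks (default 1024)
so transient memory is O(block·n) and the full ~12.6k-respondent case is
feasible on a desktop. Zero-norm score vectors are an error naming the
respondents; isolated nodes are kept — they are the "dispersed"
respondents that later become DBSCAN noise. Object scores are whitened
(X′X = nI), so cosine similarity weighs every retained component equally;
with many near-noise components retained this dilutes similarity — see the
generator notes below.

## Force-directed layout

ForceAtlas2 conventions: linear attraction d along edges, repulsion
k_r·(deg_i+1)(deg_j+1)/d between all pairs, classic gravity g·(deg+1)
toward the origin, and the adaptive speed scheme driven by per-node
swinging and traction (jitter tolerance 1, local speed factor 0.1,
displacement cap 10/|F|, global speed growth capped at 1.5×). Defaults
k_r = 2, g = 1, a fixed iteration count (1000 standalone, 500 in the
pipeline) rather than an early-stop — deterministic runtimes and exact
reproducibility from the seed, with per-iteration swinging/traction
recorded for inspection. Initial positions are uniform in a disc of radius
10; coincident nodes are pushed apart along a small antisymmetric random
jitter so Newton's third law holds exactly in the exact mode.

Above 2000 nodes repulsion switches to a Barnes–Hut quadtree
(θ default 0.9; the supernode criterion is size/d < θ). The physics checks
in the tests: two connected degree-1 nodes with gravity off equilibrate at
separation 2√k_r (linear attraction balancing k_r·4/d), a symmetric
triangle stays equilateral, and a two-clique benchmark keeps within-clique
distances below between-clique distances. LinLog and overlap-prevention
variants are rejected explicitly rather than half-supported.

## Density clustering and profiles

DBSCAN with classic core/border/noise semantics (a core point counts
itself among its ≥ min_pts neighbours). Determinism is pinned down by a
documented tie rule: a border point reachable from several clusters joins
the cluster of its **smallest-index core neighbour**; clusters are then
renumbered 1..C by decreasing size (ties by smallest member index), noise
is 0. The implementation uses a KD-tree for neighbourhoods; the tests hold
it equal to a naive quadratic reference over many (eps, min_pts) settings.

Neither eps nor min_pts is given by the modelled study, so defaults are
min_pts = 10 and eps from the k-distance elbow: the sorted k-NN distance
curve is normalised to the unit square and the elbow is the point farthest
below the end-to-end chord (the Kneedle criterion — a robust
operationalisation of "maximum curvature"). The chord is computed on the
bulk of the curve, excluding the top 2% of k-distances: isolated layout
points otherwise stretch the chord and drag the elbow into the sparse
tail, merging genuinely separate clusters. Every pipeline run logs the
values used.

Cluster profiles report, for the top-k largest clusters plus a population
row and a noise row: size, share of population, and the prevalence of
gender, age bands, quartiles, emotions and media flags. Deltas are given
against **two baselines** — the full population and the clustered
(non-noise) subset — because the natural baseline is genuinely ambiguous
when part of the population stays unclustered. Coverage is the fraction of
the population inside the top-k clusters (noise excluded). The
heterogeneity summary gives, per quartile, the number of clusters holding
≥ 5% of the quartile's members, the largest-cluster share, and the
normalised entropy of the cluster membership distribution (0 = all in one
cluster; 1 = spread evenly over the clusters occupied; noise excluded from
the distribution).

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, at
a desk-friendly default of n = 2000:

- **Latent trait.** θ ~ ½N(−1.6, 0.6²) + ½N(+1.6, 0.6²), plus +0.25 for
  women and +0.10 per age band above the first — a clearly bimodal trait
  with the gender/age gradients the descriptive tables show (62% women;
  age-band weights shaped like a university community, 43% in 15–24).
- **Items.** 40 single-choice items (6 with five categories, 34 with four;
  166 dummy columns), each with one +1 and one −1 category. The
  risk-consistent answer is chosen with probability
  σ(aⱼ·(θ − bⱼ)) — the standard two-parameter logistic IRT form, with
  discriminations aⱼ ~ U[2.5, 4] and difficulties bⱼ ~ U[−2, 2];
  otherwise the −1 category is chosen with probability 0.85, else a
  neutral category at random.
- **Archetypes.** Low-component respondents are split evenly over 3
  archetypes; each archetype owns a disjoint set of 13 items on which its
  members give a fixed archetype-specific non-protective answer with
  probability 0.95. This is what makes the low-risk population
  heterogeneous: three internally homogeneous, mutually dissimilar
  response patterns.
- **Flags.** Nine emotions and six media sources are Bernoulli with
  logit = logit(base prevalence) + slope·θ + gender and age-band terms;
  slopes are positive for the alert/worry-type flags and negative for
  boredom-type flags, matching the reported monotone gradients.

Why the steep discriminations and concentrated answers: cosine similarity
is computed on *whitened* object scores, so the components retained at the
80% cutoff contribute equally regardless of eigenvalue. With weak items
(a ≈ 1–2) the retained space is noise-dominated, within-group similarity
sits near 0.15 and no structure crosses the 0.5 edge cutoff at desk scale
— the generator would then describe a population whose network stage is
vacuous. The chosen defaults put within-group similarity well above the
cutoff and between-archetype similarity near or below 0, so the generated
population actually carries the homogeneous-high/heterogeneous-low
structure the pipeline is meant to expose. The difficulty parameter acts
on the θ scale (2PL form) rather than additively; with an additive offset
the strong discriminations would drive >25% of high-trait respondents to a
perfect score, the 75th percentile would equal the maximum and the top
quartile would be empty.

What the generator does **not** emulate: real item wording and dependence
between items beyond the single latent trait plus archetypes; item-level
nonresponse; acquiescence or social-desirability response styles;
correlations among emotion/media flags beyond their common dependence on
θ, gender and age. Passing the end-to-end tests therefore shows the
pipeline recovers structure *of this planted kind* — it does not validate
the substantive findings of any particular survey, and replication of
full-scale figures (e.g. 166 variables → 80 components, 13 clusters
covering 54.6%) additionally depends on the real data and on layout and
clustering parameters that published analyses typically leave unreported.

## Reference conditions and problem sizes

The reference ("paper-like") configuration used by the examples, the
end-to-end tests and the acceptance script is n = 2000 with the defaults
above, princals at up to 150 dimensions (tolerance 1e-6, 150 iterations),
cosine cutoff 0.5, 500 layout iterations and elbow-chosen eps with
min_pts = 10 — sizes chosen so a full run takes a couple of minutes on one
CPU while preserving the structure of interest. One global seed fans out
to every stochastic stage by fixed offsets, so runs are exactly
reproducible and artifact checksums in the manifest are stable.

## Known limitations

- The ordinal level assumes the sorted category order is the substantive
  order; codebooks whose categories are listed non-monotonically should
  use nominal scaling.
- Cosine similarity on whitened scores treats all retained components
  equally; an eigenvalue-weighted variant may be preferable when many
  near-noise components are retained, but would change the documented
  contract.
- ForceAtlas2 is a heuristic embedding: cluster *shapes* in the layout are
  not meaningful, only the density structure that DBSCAN consumes.
- The Barnes–Hut approximation changes individual trajectories; it
  reproduces exact-mode geometry (median pairwise-distance error well
  under 5% at θ = 0.3) but is not bit-identical to exact mode.
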