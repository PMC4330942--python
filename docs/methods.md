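# Methods

This note records the statistical model behind `seasonet`, the choices
made where the procedure was genuinely open, and what the synthetic data
do and do not establish about real measurements.

## Data model

The unit of analysis is one seed state (dry, germinated, or dehydrated
after germination) observed monthly for a year. Metabolite values are
relative peak responses already normalized upstream (internal standard,
dry weight); the package treats them as nonnegative reals with explicit
NaNs for missing measurements, never silent zeros. Traits are binomial
outcomes: per month, four replicate batches of 50 seeds scored for
germination and for survival of a three-week dehydration.

Correlations are computed on **monthly means** (n = 12): traits exist
only at monthly resolution, and averaging the four replicate profiles
puts metabolites on the same footing. A consequence worth stating: every
downstream p-value rests on 12 exchangeable time points, not on 48
samples. Metabolites missing in more than half of the months are dropped
(logged); remaining missingness is handled pairwise-complete.

## Preprocessing

Order of operations: per-metabolite mean normalization over the monthly
time-point means → arcsine-square-root transform of trait percentages
(the standard variance stabilizer; the transform is strictly monotone, so
it is irrelevant to rank correlations but kept for faithfulness and for
any Pearson use) → pareto scaling of every variable, (x − x̄)/√s with the
n−1 sample sd. Pareto scaling leaves each column with variance equal to
its original sd — the defining property distinguishing it from
unit-variance scaling — and the tests assert exactly that. Zero-mean or
zero-variance columns are errors naming the offending variable. A 0–1
min-max scaler is provided for heatmap-style displays; constant entries
map to 0.5 with a warning.

## Correlation and edge selection

Spearman's ρ is computed as Pearson's correlation of mid-ranked data
(average ranks under ties), pairwise-complete. The normality screen
(Shapiro–Wilk per variable across time points) recommends Spearman when
more than half the variables reject at α = 0.05; the pipeline follows the
published choice of Spearman regardless and reports the screen.

**P-values.** For tie-free pairs with n ≤ 13 observations the two-sided
p-value comes from the exact permutation null of ρ: with integer ranks, ρ
is linear in T = Σᵢ r_x(i)·r_y(i), and the null distribution of T over
uniform permutations is built once per n by a subset-convolution dynamic
program (2ⁿ states, exact integer counts; validated against full
enumeration for n ≤ 7). With ties, or n > 13, the t-approximation with
n − 2 df is used. The exact null is the default because FDR correction
over thousands of pairs probes the extreme tail, where the
t-approximation is several-fold anti-conservative at n = 12 — enough to
triple the realized family-wise false-edge rate. A brute-force
permutation-enumeration p (valid under ties) is available for n ≤ 9 via
`exact_max_n`.

**FDR.** The q-value machinery is Benjamini–Hochberg over the upper
triangle only (m = k(k−1)/2 tests, each pair counted once); BH was chosen
over Storey-type estimators because it is deterministic and conservative
at this m. `p_threshold_for_q` returns the largest p(k) with
p(k) ≤ q·k/m, so "p ≤ threshold" and "q ≤ target" select identical edge
sets. Whether to correct per state-network or jointly across the three
states was open; the package corrects per network, since the three
networks are built and interpreted separately.

**Edges.** (i, j) is an edge iff |ρ| strictly exceeds the coefficient
threshold and p is at or below the FDR-derived cutoff. Using |ρ| keeps
strong negative trait–metabolite edges; the sign is stored per edge.
Isolated nodes are retained.

## Threshold robustness scan

The coefficient threshold is selected by requiring the network to be
insensitive to the significance cutoff: for each r on a grid (default
0.30–0.95, step 0.05) the four properties (average degree = 2|E|/|V|,
global transitivity, density, diameter of the largest component in hops)
are computed at every p in a grid of BH cutoffs for q = 0.01…0.10. The
stability score of r is the worst normalized range
(max − min)/max(|median|, ε) across the p grid; the smallest r with score
≤ 0.1 wins, with argmin-plus-warning as fallback. The criterion, grids,
tolerance and tie-break are this package's formalization of "robust
behavior" and are all configurable and logged. Transitivity (3·triangles
/ connected triples) was preferred to mean local clustering to avoid
per-node 0/0 conventions on sparse graphs; the diameter is taken on the
largest component because disconnected thresholded graphs are the norm.

## Walktrap communities

Implementation of the Pons–Latapy random-walk scheme, weighted by |ρ|:
P = D⁻¹A with a unit self-loop added to isolated nodes so the walk is
defined everywhere; community walk profiles are averaged member rows of
P^t (t = 4, the conventional walk length; configurable); the pair of
*adjacent* communities minimizing the Ward increase
Δσ = |C₁||C₂| r²(C₁,C₂) / (n(|C₁|+|C₂|)) merges at each step, with ties
broken on the smallest community-id pair for determinism. Disconnected
components never merge, so the dendrogram holds exactly
n − #components merges. The partition is read at the cut maximizing
weighted Newman modularity (computed on the original graph, without the
walk's self-loops). Negative edge weights are rejected with a pointer to
use |ρ|.

## Community significance

For every community with **more than nine nodes** (smaller ones are
returned untested), each member's degree in the isolated community
subgraph is paired with its residual degree — its degree in the full
network after all intra-community edges are deleted; the two always sum
to the full-network degree, an invariant the tests enforce. The paired
differences enter a two-sided Wilcoxon signed-rank test with classic
zero-dropping (the dropped count is logged). The null distribution is
exact for up to 25 nonzero pairs, computed by sign-flip dynamic
programming over doubled mid-ranks — exact even under tied |differences|,
which the degree data produce routinely — and a normal approximation with
tie and continuity corrections beyond. Sidedness was open; two-sided is
the default, with the directional "internal > residual" alternative
available since cohesion is one-sided by nature. All-zero differences
yield p = 1 with a degenerate flag.

## Synthetic data generator

`simulate_dataset` emulates the study design: months ordered June→May;
summer = {Jun–Sep}, winter = {Nov–Feb}, shoulder months carry no seasonal
shift. Metabolite j of block b in month m, replicate k, state s:

    x = baseline_j + scale_s · A_b · s(m) + L_b · (η_b(m) + ζ_b(m,k)) + ε

with s(m) ∈ {+1, −1, 0} the seasonal square wave, η the replicate-shared
monthly block factor (sd 0.9), ζ replicate-level (sd 0.3), ε iid noise
(sd 0.2), loadings L_b = 0.9. Defaults: 69 metabolites in four blocks
(sugar 18, amino acid 17, organic acid 17, flavonoid 17; 71 network nodes
with the traits), amplitudes A = (0.8, 0, 0.6, −0.6) — strongest summer
accumulation in the sugar block, a season-free block, and a
winter-accumulating flavonoid block — and state scales 0.15 / 1.0 / 1.2
for dry / germinated / dehydrated, so dry-seed metabolism barely moves
with season. The germinated and dehydrated states share η (one monthly
physiology); dry seeds get independent factors, which is why trait edges
appear only in the germinated/dehydrated networks.

**Traits.** Survival: latent cos(2π(m − phase)/12) (phase January)
plus 0.4 · Σ_b c_b η_b, squashed through Φ(λ/0.2) into a probability and
sampled Binomial(50, p) per replicate. The squash saturates near the
solstices — July ≈ 0%, January ≈ 100% survive the coupling noise — and is
monotone, so it does not disturb rank correlations. Germination: high
baseline 0.90 with dips (Nov 76.5%, May 66%) plus 0.2 · Σ_b c_b η_b,
clipped to [0.02, 0.99]. Default couplings: survival −0.9 to the sugar
block and +0.4 to the flavonoid block; germination +0.9 to the amino-acid
block. Ground truth records block membership, coupling signs and the
planted seasonal means.

**In-sample factor decorrelation.** With 12 monthly values, iid factor
draws exhibit chance cross-correlations of ±0.3 and more, which blur the
planted structure badly (different runs would plant effectively different
block separations). The monthly factors are therefore Gram-Schmidt
orthogonalized in-sample against the intercept, the seasonal square wave,
the survival cosine and one another, then rescaled to sd 0.9. This makes
the planted design identifiable at n = 12 and is the main deliberate
departure from realism: real metabolite data guarantee no such
orthogonality, so recovery rates measured here are upper bounds on what
identical settings would deliver on real profiles. Two further realism
gaps: abundances are Gaussian on the linear scale (real peak responses
are right-skewed — hence the normality screen often recommends Pearson on
synthetic data while the pipeline keeps the published Spearman choice),
and replicate noise is homoscedastic. The null generator
(`simulate_null_dataset`) zeroes all loadings, amplitudes and couplings,
leaving iid Gaussian metabolites for FDR calibration.

Amplitudes, coupling scales and the survival squash sharpness were fixed
in a design study so that the generator's defaults simultaneously realize
the planted annual survival cycle and keep both the blocks and the
strongly coupled (|c| ≥ 0.8) trait–block signs recoverable by the
downstream pipeline in ≥ 90% of seeded runs; they are study conditions,
not per-analysis tuning knobs.

## Problem sizes and numerics

The verification studies use: 1,000 random tied pairs (n ≤ 8) for the
Spearman oracle; 200 null datasets of 70 metabolites × 12 months for FDR
calibration; 50 seeded end-to-end simulations for block- and
trait-recovery rates; 100 random graphs (≤ 30 nodes) for brute-force
property comparison — sizes at which every check completes in seconds
while estimator noise stays well below the decision margins. Determinism
is bit-level: one `numpy` Generator seeded from the run seed drives all
sampling in a fixed order, and artifact writers are order-stable.
Floating-point tie-breaks in the walktrap merge use a 1e-15 tolerance and
lexicographic community ids. Degenerate inputs (constant variables,
empty networks, single nodes, all-zero difference vectors) return defined
values with warnings or raise errors naming the offender, as documented
per function.

## Known limitations

- Trait–metabolite correlations rest on 12 monthly means; p-values are
  exact under exchangeability but power is inherently low, and lag
  structure (traits responding to earlier months) is out of scope, as are
  partial correlations.
- The walktrap implementation is O(n³)-ish and intended for the
  ~70-node networks of this design, not for thousands of nodes.
- The community-significance test inherits the arbitrariness of the
  community boundary; its p-values are conditional on the detected
  partition and are not corrected for having selected the communities on
  the same data.
- Reported community p-values depend on sidedness and zero-handling
  conventions; this package fixes them (two-sided, zero-dropping) and
  makes no claim of numerically matching any previously published
  community p-values.
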