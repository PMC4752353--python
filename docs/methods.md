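# Methods

This note documents the statistical procedures implemented in `pelletdiet`,
the assumptions behind them, the defaults and why, and what the synthetic
data generator does and does not emulate.

## Data model and units

The sampling unit is the faecal pellet: covariates (year, month 1–12, area
label), a mapping taxon → non-negative integer count, a plant fraction in
[0, 1], and optionally per-item (taxon, length, width) measurements for the
subset of items that were measurable. A pellet with zero prey items and
zero plant fraction carries no dietary information and breaks proportion
denominators, so loaders reject it. Availability samples are biocenometer
censuses (per-taxon counts per area and date); they represent only epigeal
and flying prey, which is why electivity outputs carry per-taxon degeneracy
flags instead of silent NaNs. Units are fixed globally: lengths/widths in
mm, volumes in cm³ (mm³/1000), dry masses in mg. The canonical file format
is a wide CSV (one row per pellet, one column per taxon); a long dialect
and an XLSX reader with a user-supplied column mapping are provided for
deposited supplementary workbooks whose internal schema is not fixed.

## Composition

Per group (any subset of year/month/area, or pooled):

* %nᵢ = 100·Σcountsᵢ / Σall counts; %pᵢ = 100·#{pellets with countᵢ>0}/n.
* %volᵢ applies the *taxon-mean* volume V̄ᵢ to the count table:
  %volᵢ = 100·countᵢ·V̄ᵢ / Σⱼ countⱼ·V̄ⱼ. Per-item volumes are deliberately
  not supported in this pathway: the volumetric representation is defined
  as average volumes applied to frequency tables. Volume models: prolate
  spheroid V = (4/3)π(L/2)(W/2)² (the standard ellipsoid-of-revolution
  volume of the diet literature; used for most arthropods), cylinder
  V = π(W/2)²L (millipedes), and a fixed displacement volume measured in
  alcohol (isopods, crabs, snails). Displacement volumes of shelled or
  partially eaten prey overestimate the ingested soft tissue; this bias is
  annotated (`volume_overestimate`) and reported, never corrected.
* %b uses per-item masses where lengths were recorded and a strict
  three-tier hierarchy otherwise: (1) taxon allometry m = a·Lᵇ when a
  regression and a length exist; (2) the taxon's mean recorded dry mass;
  (3) the overall mean across groups for unidentifiable remains. Exactly
  one tier fires for any input; if none can, the computation fails loudly.
  The shipped default trait table carries placeholder coefficients on
  realistic scales and is meant to be replaced by measured values.

Each defined percentage vector sums to 100 within 1e-9, enforced by tests.

## Electivity

D = (r−p)/(r+p−2rp) maps preference to [−1, +1] with 0 at r = p. For E*,
Wᵢ = (rᵢ/pᵢ)/Σⱼ(rⱼ/pⱼ) is normalised over the taxa with p > 0, and
n in E*ᵢ = (Wᵢ−1/n)/(Wᵢ+1/n) is the number of *available* prey types
(p > 0) in the chosen universe — the defensible reading of "number of
available prey types" when diet taxa are missing from the availability
census. The default universe is the union of diet and availability taxa;
an availability-only universe is available. A taxon eaten but absent from
availability gets the +1 limit for both indices and the
`absent_in_availability` flag; absent from the diet only, −1 and
`absent_in_diet`; absent from both, NaN and `absent_in_both`. Availability
replicates are pooled by default (per-replicate averaging by option);
with equal replicate sizes the two coincide.

## Hill-number diversity and bootstrap contrasts

For pooled group counts with relative abundances pᵢ (zero-count categories
always excluded — mandatory for q < 0, where they would carry infinite
weight), ᵠD = (Σpᵢᵠ)^(1/(1−q)) and ¹D = exp(−Σpᵢ ln pᵢ). The default grid
is the integral orders {−1, 0, 1, 2, 3}; tests default to {0, 1, 2}
(richness, exp-Shannon, inverse Simpson). Identities ⁰D = S, ²D = 1/λ and
continuity at q = 1 are regression-tested. Near q = 1 the general formula
is evaluated as exp(log Σpᵢᵠ/(1−q)), stable to ~1e-10 at |q−1| = 1e-6.

Simpson diversity is reported as 1−λ (Gini–Simpson) alongside λ = Σp̂ᵢ²;
its variance is the classical large-sample estimator
var = (4/N)(Σp̂ᵢ³ − (Σp̂ᵢ²)²).

Group comparisons are all-pairs contrasts with a pellet-level bootstrap:
pellets — the independent sampling units of a scat survey — are resampled
with replacement within their group (B = 5000 by default; a seed is
mandatory and recorded in every output). For each replicate the pooled
counts and the Hill-number difference are recomputed. The two-tailed raw
p-value compares |observed difference| against the centred bootstrap
distribution |diff* − diff_obs|, with the (count+1)/(B+1) estimator. The
single-step max-modulus adjustment studentises each pair's centred
difference by its bootstrap standard deviation and compares each observed
studentised statistic with the bootstrap distribution of the maximum over
pairs; this controls the family-wise error within each order and
guarantees p_adj ≥ p_raw. Holm is available by option.

Calibration: with two groups of 20 pellets drawn from one multinomial, the
measured type-I error at α = 0.05 over 500-run batches is ≈0.06–0.09 at
q = 1 and q = 2 — the mild liberality typical of bootstrap difference
tests at small cluster counts, hovering at the upper edge of the binomial
99% band of the nominal level and occasionally beyond it depending on the
batch — and ≈0.01–0.02 at q = 0: the richness difference is
lattice-valued, so its resampling test is conservative. Larger groups
tighten both effects. Conservative, never anticonservative, is the
accepted failure direction for discrete statistics; the acceptance suite
encodes exactly that asymmetry.

## PERMANOVA and dispersion homogeneity

PERMANOVA partitions the total sum of squared interpoint distances via the
Gower-centred inner-product matrix G = J(−½D²)J. Terms are sequential
(Type-I) in the order the formula expands them (`a*b` → a, b, a:b); the
order is user-visible in the output. Factors are treated as categorical;
per-term projectors are built from rank-revealing orthonormal bases of the
cumulative dummy design, so term SS = tr(ΔH G), residual SS = tr((I−H)G),
and pseudo-F = (SSₜ/dfₜ)/(SS_res/df_res). Significance is by free
permutation of observation labels with p = (#{F* ≥ F_obs}+1)/(n_perm+1),
never zero; an exact mode enumerates all n! permutations for n ≤ 9. An
aliased term (zero rank increment) is an error naming the term. The
default distance is Bray–Curtis on per-pellet counts (Euclidean and
Jaccard as options); empty pellets must be excluded first, and the CLI
does so with a logged count. With a univariate response and Euclidean
distance the pseudo-F equals the classical one-way ANOVA F, a closed-form
oracle used in the tests, alongside frozen cross-checks against vegan's
adonis2 and scikit-bio's one-way PERMANOVA.

The dispersion test embeds the distance matrix by principal coordinates,
retaining negative-eigenvalue axes; squared distances to the own-group
spatial centroid subtract the imaginary-axis contribution and are floored
at zero. The one-way F on those distances is assessed by permuting the
distance values among groups. Centroid distances and F agree with vegan's
betadisper (type="centroid") to 1e-9 on a frozen fixture.

## Classical tests

G = 2ΣO·ln(O/E) over cells with O > 0, referred to χ² with df = k−1
(one-way; uniform or supplied expectations rescaled to the observed total)
or (r−1)(c−1) (two-way; independence expectations). No Williams or Yates
correction by default — corrections are opt-in flags — matching common
reporting practice in diet studies. Pairwise batteries test each pair of
rows on its 2×k subtable (categories empty in both rows dropped), raw p by
default, Holm by option. Fisher's exact test is two-sided by the
"probabilities ≤ observed" convention (documented because conventions
differ); r×c tables use seeded Monte-Carlo sampling of fixed-margins
tables via label permutation, p = (hits+1)/(reps+1). Kruskal–Wallis uses
the tie-corrected H with a χ² reference; an all-identical input returns
H = 0, p = 1 rather than an error.

## Synthetic data generator

The generator emulates the *structure* of a multi-year scat survey — a
year × month × area grid, availability vectors per area, diet composition
= selection × availability renormalised (or a direct per-area override),
overdispersed pellets via Dirichlet-multinomial with one concentration
scalar, Poisson item counts, zero-inflated-Beta plant fractions drawn
independently of prey counts, and five availability replicates per cell.
Defaults are anchored to the magnitudes of the motivating survey: 3.4 prey
items per pellet, plant matter present in ~44% of pellets, a few tens of
invertebrates per biocenometer sample, an ant-dominated rank-abundance
profile. The between-pellet dispersion (default concentration 50) is an
assumption, not an estimate — real overdispersion is unknown.

It does **not** emulate: individual identity or repeated measures, spatial
autocorrelation within areas, seasonality beyond cell-level composition
differences, taxon misidentification, or the size-selection of prey within
taxa. Passing calibration and power suites therefore demonstrates the
correctness of the machinery under the stated sampling model, not
robustness to those unmodelled features.

Presets: `null_homogeneous` (identical composition everywhere; type-I
suites), `area_shift` (one area's composition permuted; multivariate
power), `strong_selection` (selection coefficients geometric from 0.1 to
10; electivity recovery), `diversity_gap` (uniform-over-10 vs
90%-dominated; diversity power). Ground truth (cell compositions, implied
D/E*, cell Hill numbers) is computed from the configuration before any
sampling, so recovery is measured against known targets.

## Numerical choices and degenerate inputs

* Permutation and bootstrap p-values always use the +1 estimators and can
  never be zero.
* Seeds are mandatory for every stochastic routine and recorded in
  outputs; identical seed ⇒ identical output bytes.
* jacobs_D clips float round-off at the ±1 boundaries; (r,p) = (0,0) is
  NaN with a flag, (1,1) returns the limit 0.
* Rank decisions in the PERMANOVA design use an SVD tolerance of
  max(m,n)·eps·σ₁; degenerate designs and zero total SS raise.
* Groups with a single pellet cannot be resampled or give a centroid
  spread; both raise informative errors.
* Problem sizes in the calibration suites (500 null runs at B = 1000 for
  the Hill contrasts; 200 runs at 499 permutations for PERMANOVA; 100–200
  runs for the power suites) were chosen to give binomial 99% bands tight
  enough to be informative while keeping the whole suite in the minutes
  range on one CPU.

## Known limitations

* %vol uses taxon-mean volumes by design; studies wanting per-item volume
  integration need a different pathway.
* The electivity indices are only as good as the availability census;
  hypogeal prey are structurally under-sampled by a biocenometer and will
  show spuriously positive electivity.
* The bootstrap Hill contrasts are mildly liberal at small group sizes
  (see calibration above) and conservative at q = 0.
* Exact PERMANOVA enumeration is limited to n ≤ 9; beyond that p-values
  are Monte-Carlo with the usual (count+1)/(n_perm+1) granularity.
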