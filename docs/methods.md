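# Methods

## Model

The pipeline estimates maximum lifespan (MLS, years) from two mitochondrial
quantities: a metabolic-rate proxy and the amino-acid composition of the
mtDNA-encoded membrane proteins.

**Allometry and the per-species exponent.** Across species, BMR ≈ a·M^b with
a and b from OLS of ln(BMR) on ln(M) (mass in grams, BMR in watts). Each
species then receives B = ln(BMR/a)/ln(M), the exponent that reproduces its
observed BMR exactly: a·M^B = BMR holds to machine precision by
construction, and the package asserts it. B is undefined at M = 1 g
(ln M = 0); the code raises an explicit singular-mass error rather than
perturbing the value, and the caller is told to re-unit the masses.

**The mitochondrial metabolic rate.** mtMR(α) = a·M^((B−1)/α), α ≥ 1. This
functional form is pinned down by three requirements it must satisfy
simultaneously: it reduces to msBMR = a·M^(B−1) at α = 1 (so that
mtLEO = MLS × mtMR reduces to the classical LEE), it tends to the constant a
as α → ∞ (mtMR becomes mass-independent at large α), and on b = 0.75
allometric data at α = 2 the regression slope of ln(mtMR) on ln(M) is
(b−1)/α = −0.125, matching the mammal-wide value. Note that replacing the
fitted a by any other positive constant only translates ln(mtMR) — the α
scan and all correlations are invariant to it; only intercepts move.

**Choosing α.** For each α on a grid (default 1.00–20.00, step 0.05,
covering all optima of practical interest; ties break to the smaller α), the
scan records (i) the s.d. of ln(mtLEO) about its mean, (ii) the residual
s.d. about the OLS regression of ln(mtLEO) on the four weighted AAVs,
refitted at every α, and (iii) that regression's multiple correlation. The
regression-criterion argmin is the default α for downstream fits, matching
the stratified procedure; an optional golden-section refinement sharpens a
grid optimum. A boundary optimum triggers a warning, since a flat profile
(e.g. in clades where mtMR ≈ constant) makes the argmin fragile. The
headline dispersion-reduction statistic is 100·(1 − sd(α*)/sd(1)), i.e. how
much narrower mtLEO is than LEE.

**The lifespan regression.** ln(mtLEO(α)) = A0 + W·(A1·SC + A2·TC + A3·CC +
A4·HYD) + ε by OLS, where the per-species weight W multiplies the AAV
combination only — never the intercept or the response — so a common weight
rescaling is absorbed into A1..A4 and leaves predictions unchanged (asserted
numerically). Rearranged, MLS = exp(AAV)/mtMR decomposes predicted lifespan
into a stability factor and a metabolic factor. Reported statistics: R is
the Pearson correlation of observed vs fitted ln(MLS) (identical to the
multiple R of the free-slope 5-regressor model, and reported alongside the
mtLEO-scale multiple correlation); F and its tail p come from statsmodels;
AIC uses the comparative Gaussian form n·ln(RSS/n) + 2(k+1) with the
additive constant dropped, so only AIC *differences* are meaningful; σ is
the residual s.d. with n−k−1 degrees of freedom.

**Robustness refits.** Freeing the constrained −1 slope — ln(MLS) on
ln(mtMR) plus the AAVs — must return A5 = −1 when the constrained model
generated the data; refitting on ln(msBMR) instead returns A5 = −1/α, since
ln mtMR = ln msBMR/α up to a constant. Both are computed and reported with
standard errors.

**Outliers.** Species are flagged when the observation falls outside the
95% interval. The default band is the prediction interval for a new
observation rather than the narrower mean-confidence band — with ~4% of
species flagged in a well-specified fit, this convention matches flagging a
few extreme species out of ~70 — and the convention is switchable and
recorded in the result. A numerically perfect fit (residual σ at rounding
level) flags nothing, since any band there is pure floating-point noise.

**Stratified analysis.** Groups partition the species; each group of at
least `min_group_size` (default 7, the smallest size leaving a df of 1 past
the 4-regressor fit with a margin) gets its own α scan and fit; smaller
groups are recorded as skipped, never silently dropped. The pooled R is the
correlation of observed vs predicted ln(MLS) across all fitted species.
Pooling beats the one-step fit exactly when groups truly differ in α, which
the synthetic two-clade study demonstrates; a single group degenerates to
the one-step analysis exactly.

## Amino-acid variables

Per-residue hydropathy S uses the Kyte–Doolittle scale (the conventional
"standard model" for transmembrane detection); the scale is a named,
swappable table. S_av is the centered moving average over a window of 11
residues — an odd width inside the conventional 9–19 range for
membrane-helix detection; the width is a configuration knob and no
conclusion in this package depends on its exact value. Edge rule: positions
whose full window does not fit carry no S_av (no truncated windows), which
keeps the statistic unbiased at termini and gives a crisp testable contract.
Non-standard symbols (X, B, Z, gaps) carry no score and poison every
covering window, so they can never be selected — preferable to inventing
hydropathy values. Site selection is strict: S_av > 1.5, with equality
excluded.

SC/TC/CC are percentages of Ser/Thr/Cys among the selected sites pooled
over the analysis subunit set (default: the six large proton-pump subunits
ND2, ND4, ND5, CO1, CO3, CYTB) — pooled counts, not per-subunit averages,
so subunit order is irrelevant. HYD is by default the mean S_av over
selected sites (hence HYD > 1.5 whenever defined); a documented alternative
averages over all positions with defined S_av, selectable via `hyd_over`,
because the mean-"about all sequences" convention is ambiguous in the
field's usage. Empty selections raise an error that points at the
threshold/window.

## Branching weights

W is an analysis *input*: the primary path reads it from a CSV column, and
the unweighted W ≡ 1 path is bit-identical to plain OLS. Because no
computational definition of the weight accompanies the published analyses,
the derivation schemes shipped here are clearly labelled approximations for
synthetic studies: normalized inverse root-to-tip path lengths on a
midpoint-rooted tree (ultrametric trees give W ≡ 1) and per-clade
multipliers. All derived weight vectors are normalized to mean 1 so the
weighting cannot rescale the response. The convenience tree builder is
neighbor joining on Poisson-corrected p-distances (d = −ln(1−p) over shared
standard-residue sites) via scikit-bio; it is deterministic given input
order, clamps NJ's occasional small negative branch lengths to zero, and is
not a substitute for model-based phylogenetic inference.

## Synthetic generator

`generate_traits` emulates the statistical structure of the study: masses
log-uniform on [3 g, 1e8 g] (a shrew-to-bowhead-whale span); BMR = a·M^b
with a = 0.019 W, b = 0.75 (Kleiber's law in gram/watt units) and ln-scale
noise 0.3; AAVs uniform on SC ∈ [4,9]%, TC ∈ [7,12]%, CC ∈ [0.3,1.2]%,
HYD ∈ [2.1,2.7] (realistic hydrophobic-domain compositions); lifespans from
the log-linear model at α* = 2.1 with coefficients A1 = 0.5, A2 = 0.3,
A3 = −2.0, A4 = −1.5 and A0 = −3.1 (centres MLS near ~20 yr with a
house-mouse-to-bowhead spread). The lifespan noise default, σ = 0.7, was set
from the closed form R = √(V_signal/(V_signal+σ²)) under these ranges so the
default cohort reproduces a combined-model fit quality of R ≈ 0.86 — the
regime the method is meant to operate in. Per-group α truths are supported
for stratified studies; all randomness flows through one seeded NumPy
generator, and identical seeds give byte-identical tables.

What the generator does **not** emulate: correlated AAVs (real compositions
co-evolve), phylogenetic autocorrelation of traits, measurement error
structure in AnAge-style databases, or body-mass clustering by clade.
Passing recovery tests on this generator therefore demonstrates
identifiability and correctness of the estimators under the model, not
robustness to real comparative-data pathologies.

`generate_sequences` is constructive, not evolutionary: a hydrophobic core
mixing Ile/Ala tuned to the HYD target, with Ser/Thr/Cys interleaved at even
spacing so every core window stays above the selection threshold, split
across the six subunits with edge pads. SC/TC/CC targets are met exactly at
count resolution (verified in-process; infeasible targets — contents over
100%, unreachable HYD, polar loads too dense for the window — raise typed
errors), while HYD lands within a small tolerance (±0.2) because edge
windows average over pad residues.

## Numerical choices and degenerate inputs

* α grid built from integer steps to avoid floating-point drift; argmin/
  argmax take the first (smallest-α) optimum on exact ties.
* Residual s.d. in the scan divides by n−k−1 (regression df) while the
  about-the-mean s.d. divides by n−1, both configurable. With mismatched
  denominators the inequality sd_reg ≤ sd_mean can invert on pure-noise data
  (R² < 4/(n−1)); on any data with signal it holds, and reductions are
  ratio-based so the choice largely cancels.
* Collinear AAV designs (condition number > 1e10) are rejected with the
  offending columns named; tiny samples (n ≤ k+1) are rejected.
* p-values are exact F tails printed at full precision; published-style
  bounds ("p < 10⁻²⁴") should be compared as bounds.
* All CSV/JSON outputs are deterministic for a fixed config and seed; plots
  are exempt.

## Scope and limitations

Problem sizes follow the study conditions: cohorts of 72 species, 200
replicates for the coverage simulation, and ~1000-site sequence cores —
sizes at which every analysis completes in seconds. Reproducing the
published 72-mammal numbers requires the article's supplementary variable
tables, which are not redistributable with this package; the acceptance
tests that need them look for a documented local drop-in and otherwise fail
with instructions. The five-group mammal classification ships as an
order→group mapping rather than a species list for the same reason. No
phylogenetic GLS is attempted: W is a scalar per-species weight by design,
not an error-covariance structure.
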