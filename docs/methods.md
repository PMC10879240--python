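# Methods

## Derived lipid indexes

Fatty-acid profiles are mol% of total fatty acids plus dimethylacetals
(DMAs); lipid-class profiles are % of total lipid. Species names follow
the `C:Dn-S` shorthand with an optional ` DMA` suffix; a DMA carries the
double-bond count of its parent chain and proxies plasmalogen ether
lipids, so DMAs are totalled as their own family and excluded from the
saturate/unsaturate sums and from both unsaturation-type indexes.

- UIx = Σ mol% × double bonds (standard unsaturation index).
- PIx = 0.025·monoenes + 1·dienes + 2·trienes + 4·tetraenes +
  6·pentaenes + 8·hexaenes, the conventional peroxidability weighting.
- Sat/Unsat = Σ saturates / Σ unsaturates, both DMA-free.
- LCPUFA = species with ≥ 20 carbons and ≥ 2 double bonds.
- CHO/SE and the anionic/zwitterionic ratio (PG+PI+PS)/(PC+PE) come from
  the class table; SM is counted with the sphingolipids (SM + sulfatides
  + other sphingolipids), not as a zwitterionic phospholipid.

Zero denominators produce flagged NaNs, never exceptions. Closure is
enforced on read: table sums within 100 ± 1 pass silently beyond a
warning threshold of ±1, and ±5 is a hard error — chromatography and
densitometry tables rarely close exactly.

## Synthetic cohorts

Per-subject raft lipid tables of this kind are essentially never
deposited, so the package ships a generator whose *structure* is the
published summary statistics and which is itself first-class, tested
code. Each group is a logistic-normal draw: latent Gaussian over all
tokens of both tables jointly, exponentiated and renormalized to 100
per table. Lognormal moment matching (σ² = log(1+cv²), latent mean
log μ − σ²/2) makes the expected abundances equal the configured means.
Default dispersion is cv = 0.15 per token.

Group means: the control profile is an editorial, plausible myelin-rich
spinal-cord raft composition (saturate- and oleate-rich, substantial
DMAs, arachidonate and DHA as dominant LCPUFA; cholesterol ≈ 40% of the
class table). Disease means are the control means times the reported
ratios (SE ×3.23, sulfatides ×0.821, PE ×0.871, PG ×1.692, PI ×1.225,
PS ×1.1746, arachidonate ×1.165, 20:3n-6 ×1.688, 16:1n-9 ×1.856,
DHA ×0.935) plus modest monoene increases (18:1n-9 ×1.10, 16:1n-7
×1.35, 18:1n-7 ×1.15) encoding the reported monoene rise that has no
printed magnitude; stearic acid and cholesterol are solved last to
restore closure, which reproduces their reported declines. Group sizes
default to 6 controls / 4 cases, the study's sampling description;
recovery analyses run at 200–500 per group where estimates are
statistically meaningful.

Correlation plan: the strong group-specific, sign-flipping
phospholipid/fatty-acid correlations are planted (PE–AA +0.72 in
controls; PE–AA −0.94, PE–DHA −0.75, PS–AA −0.81, PS–DHA −0.97 in
disease). Weak published associations (|r| < 0.5) are deliberately left
unplanted: at these dispersions their sampling error alone exceeds any
sensible recovery band. A Dirichlet model cannot plant arbitrary
pairwise correlation signs, hence logistic-normal.

Closure distorts correlations: if every token fluctuates independently,
the renormalization denominator adds noise that attenuates observed
correlations by tens of percent, making targets like −0.97 unreachable
from any latent correlation. The generator therefore constructs the
latent covariance so each table's mean-weighted fluctuation is zero to
first order: tokens named in the correlation plan keep their full
covariance (planted entries exact; remaining entries completed to the
nearest valid correlation matrix by alternating projections holding the
planted entries fixed), while the other "filler" tokens linearly
compensate the planted tokens' contribution to the table sum and draw
their own noise inside the filler block's closure tangent space. The
compensation manifests as a realistic saturates-vs-PUFA /
cholesterol-vs-phospholipid trade-off; filler dispersions shrink
somewhat below nominal cv. A short deterministic fixed-point loop
(three iterations against a 20 000-draw internal Monte-Carlo estimate,
fixed internal stream) then nudges the latent planted values so the
*observed-scale* correlations match the targets; residual distortion is
second order. Infeasible plans raise an error naming the offending
pairs.

What the generator does *not* emulate: instrument noise models,
censoring/detection limits, subject covariate structure (age, sex,
post-mortem delay are carried but not generative), and any real
biological covariance beyond the planted pairs plus the closure-induced
trade-offs. Passing recovery tests therefore demonstrates that the
pipeline measures what was planted — not that real spinal-cord rafts
behave this way.

## Statistical battery

- Mann–Whitney U: exact permutation null when the pooled sample is ≤ 12
  and tie-free, otherwise normal approximation with tie and continuity
  corrections; the method used is recorded. Two identical samples give
  p = 1 with a warning. All p-values are two-sided; no multiplicity
  correction by default (a Benjamini–Hochberg column is optional) —
  per-variable raw p-values are the convention in this literature.
- Cohen's d = (mean_ref − mean_dis)/s_pooled, so decreases with disease
  plot positive. The 95% CI uses the large-sample SE
  √((n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))) rather than noncentral-t: the CI
  method behind published forest plots of this kind is rarely stated,
  and the normal approximation is transparent and testable. |d| > 0.8
  flags a large effect.
- PCA runs on the correlation matrix (z-scored variables — lipid
  variables span 0.1–40%), retains a configurable number of components
  (default 2), and varimax-rotates the retained loadings; "rotated
  space" conventions in this literature default to varimax. Scores use
  the regression method (Z R⁻¹ Λ) and are tested per component by
  one-way ANOVA. Constant variables are dropped with a warning.
- Correlation heatmaps report per-group Pearson r and R² = r² per
  (class, fatty-acid-variable) pair. The between-group difference is
  Cohen's q = |arctanh r₁ − arctanh r₂|; published "Cohen's f" labels on
  correlation-difference maps have no standard definition for two
  correlations, so q is computed and documented as the interpretation.
- Slope heterogeneity fits the pooled two-slope model y ~ x·group and
  tests the interaction with F on (1, n−4) df; per-group OLS slopes are
  reported alongside, as in the CHO→SE esterification analysis.

## Microviscosity

The steady-state Perrin convention for DPH-family probes:
η_app = C·r/(r₀ − r), with limiting anisotropy r₀ = 0.362 (TMA-DPH) and
calibration constant C = 2.4 poise, both config-exposed. The inverse
r = r₀·η/(C + η) is exact; both maps are strictly monotone and mutually
inverse to machine precision. Fluidity is 1/η, so a viscosity decrease
reads as a percent fluidity increase:
Δ% = 100·(mean(1/η_dis)/mean(1/η_ref) − 1). Relative quantities
(fluidity change, Cohen's d) are invariant to C.

The composition model is OLS of η on {Sat/Unsat, total n-6 LCPUFA,
%18:1n-9} — the variables whose disease shifts the fluidity change
tracks. The true upstream regression coefficients are not published;
the defaults (4.0, −0.3, −0.2 poise per unit) carry the conventional
signs and give the three predictors comparable contributions to
cohort-scale viscosity variation, so each is identifiable from
realistic data. `calibrate_intercept` solves the intercept in closed
form so the group contrast at the predictor means equals a target
fluidity change (default +14.8%); the generator uses this to
forward-synthesize anisotropies (Gaussian noise truncated into
[0, r₀)). No claim is made to reproduce absolute published η values.

## Membrane lattice model

An L×L periodic square lattice (default L = 64; boundary effects are
eliminated rather than merely small) with one agent per site from seven
groups: CHO, SE, DHA, n-6 LCPUFA, MUFA, SFA, SL. Composition is the
model input and must be conserved, so dynamics are Kawasaki
(conservative) Metropolis exchanges: per sweep, L² attempts; each picks
a random site and random 4-neighbour and swaps with probability
min(1, e^(−ΔE/T)), ΔE from nearest-neighbour pair energies J. The
default J encodes textbook raft physics — J(CHO,SL) = J(SL,SL) =
J(CHO,SFA) = −1 (raft affinity), J(CHO,PUFA) = +0.8 (PUFA aversion),
J(SE,·) = +0.4 (packing disruptor), T = 1 — and is fully
config-exposed; no published parameterization is reproduced.
Same-species exchanges still move the tagged agents (tracer
convention). The sweep kernel is numba-compiled; randomness comes from
one numpy generator per state, so runs are bit-reproducible given the
seed, and replicate seeds spawn from a master `SeedSequence`.

Bulk composition maps onto the seven groups as: CHO, SE and the
sphingolipid pool straight from the class table; acyl-chain groups
(DHA, n-6 LCPUFA, MUFA, SFA) from the fatty-acid table scaled into the
glycerophospholipid mass share, then all seven renormalized to 1.
Initialization allocates counts by largest-remainder rounding and
shuffles them onto the lattice.

Raft detection is geometric: a site is raft-like when the fraction of
{CHO, SL, SFA} in its 9-site Moore neighbourhood (centre included)
reaches θ = 0.5; rafts are 4-connected components of at least 5 sites,
merged across the periodic seam. θ, the minimum size, and the
raft-forming set are unpublished upstream and are config defaults here.
With brain-raft-like compositions the raft-forming fraction is high and
the detected raft phase percolates into one spanning domain; group
contrasts then live in the area fraction and the spanning domain's
size, which is the regime the default parameters probe. Mobility is
the mean squared displacement per sweep of tagged agents over a
measurement window (≥ 10 sweeps), classified by raft membership at the
window start and accumulated with periodic unwrapping. Whether the
upstream model is lattice- or continuum-based is not published; MSD per
sweep on a lattice is the documented stand-in.

## Problem sizes and numerical choices

Recovery analyses use 200 subjects per group for mean ratios and effect
signatures and 500 per group for correlation recovery — the sizes at
which two-standard-error and ±0.05 bands are informative. Membrane
contrasts use L = 64, 2000 burn-in sweeps and 200 measurement sweeps,
which equilibrate the default compositions well past the point where
the group ordering of raft area, size and mobility stabilizes.
Alternating-projection correlation repair runs to 1e-8 with a final
PSD check at −1e-6; covariance sampling uses the eigendecomposition, so
exactly singular (tangent-projected) covariances are handled without
jitter. OLS, ANOVA, varimax rotation and rank tests are delegated to
scipy/statsmodels; effect-size constructions, the Perrin algebra, the
generator and the lattice model are implemented here.

## Known limitations

- The generator's filler-compensation covariance is a modelling device:
  it yields realistic-looking trade-offs but is not fitted to any real
  covariance structure.
- Cohen's d CIs use the normal approximation; at the study's native
  n = 4–6 they are anti-conservative, which is why recovery claims are
  made at n = 200+.
- The lattice model has no leaflet asymmetry, curvature, proteins or
  off-lattice physics; its predictions are qualitative orderings, not
  absolute raft dimensions.
- Absolute microviscosities depend on unpublished calibration
  coefficients; only relative group contrasts are meaningful.
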