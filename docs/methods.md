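# Methods

## Model

A single-cross hybrid receives one gamete from each of two heterotic groups
of fully inbred lines. At one biallelic locus with alleles B/b, origin-
specific frequencies (p₁, p₂) and functional effects (a₁, a₂, d), the
genotypic values are G(B₁B₂)=a₁+a₂, G(B₁b₂)=a₁+d, G(b₁B₂)=a₂+d, G(b₁b₂)=0.
Averaging over the ideal hybrid population (random union of gametes, class
frequencies p₁p₂, p₁q₂, q₁p₂, q₁q₂) yields origin-specific substitution
effects

    α₁ = a₁ + (q₂ − p₂) d        α₂ = a₂ + (q₁ − p₁) d

gamete additive values gA = z·α with z ∈ {q, −p}, and dominance deviations
gD = w·d with w = −2z₁z₂. The three codes have zero weighted mean and zero
pairwise weighted cross-products for *any* (p₁, p₂): the partition into
additive (per origin), dominance and — via Kronecker products of the same
codes — epistatic deviations is orthogonal by construction, with component
variances

    σ²_A(1) = p₁q₁α₁²,  σ²_A(2) = p₂q₂α₂²,  σ²_D = 4p₁q₁p₂q₂d²,

and, e.g., within-group-1 additive×additive variance p₁ₖq₁ₖ·p₁ₘq₁ₘ·αα².
`locus.py` implements this decomposition twice — closed forms and exhaustive
enumeration (including the subtraction route G − E(G) − gA1 − gA2 for the
dominance deviations) — and the test suite requires the routes to agree to
machine precision. The enumeration is the oracle for everything downstream.

Summing over markers in linkage equilibrium gives the relationship
matrices of `kinship.py`:

| matrix | construction | denominator |
|---|---|---|
| G_A(1), G_A(2) | ZZ′ | Σ p q (within group) |
| D | WW′ | Σ 4p₁q₁p₂q₂ |
| G_AA(1,1), G_AA(2,2) | G_A ⊙ G_A | tr(·)/n |
| G_AA(1,2) | (T₁G_A1T₁′) ⊙ (T₂G_A2T₂′) | tr(·)/n |
| G_A(1)D, G_A(2)D, G_DD | Hadamard products with D | tr(·)/n |
| G_AH, D_H, G_AAH | NOIA codings Ha/Hd (G-model) | tr(·)/n |

With observed within-group frequencies, G_A has mean diagonal exactly 1 and
mean entry exactly 0 (centered columns), and D shares both properties under
a complete factorial; the tr/n matrices have unit mean diagonal by
construction. Variance components multiplying them therefore read directly
as genetic variances. σ²_A here refers to the fully inbred reference
population; VanRaden's method-1 matrix from 0/2 coding equals 2·G_A because
its reference population is outbred at the same frequencies.

The evaluation models are the GCA-model

    y = 1μ + T₁gA1 + T₂gA2 + gD + T₁gAA(1,1) + T₂gAA(2,2) + gAA(1,2)
        + T₁r(1) + T₂r(2) + e

(stock codes GCA:A, GCA:AD, GCA:AAA12, GCA:ADAA12, GCA:ADAA11AA22AA12, each
with or without the r terms) and the hybrid-level G-model
y = 1μ + gAH + gDH + gAAH + e (codes G:A, G:ADH, G:AAAH, G:ADHAAH). The
"residual genetic" r effects are i.i.d. line effects, estimable because
lines repeat across hybrids; they absorb within-group epistasis of any
order not explicitly modeled and belong to the GCA aggregates:
σ²GCA(1) = σ²_A(1) + σ²_AA(1,1) + σ²_r(1), σ²SCA = σ²_D + σ²_AA(1,2)
(+ dominance-involving terms when fit). The A×D and D×D matrices are
constructible but excluded from the stock menu — their variance estimates
are too inaccurate to be useful — and can be added explicitly.

## Inference

Each random term contributes covariance σ²ₜ·TKT′ at the hybrid level. We
eigendecompose C = TKT′ (symmetrized, plus a 1e-8 diagonal ridge used only
inside this step; eigenvalues at or below the ridge scale, or below
1e-10·λmax, are dropped) and use the design B = VΛ^½, so coefficients
v ~ N(0, σ²ₜI) give Bv the exact required covariance and σ²ₜ is reported on
the kinship scale. The Gibbs sampler uses conjugate updates: flat prior on
μ, scaled-inverse-χ² priors on all variances with df = 5 and scale set so
the prior mode equals an equal split of the phenotypic variance across
terms (residual gets the complementary half).

Two blocking choices matter for mixing:

* **Hybrid-level terms** (D, G_AA(1,2), all G-model terms): the
  observed-row design is rotated once so its cross-product is diagonal;
  the variance is then slice-sampled from its *collapsed* conditional (the
  coefficient block integrated out, an O(m) evaluation), followed by an
  exact joint draw of the block.
* **Line-mapped terms sharing an incidence** (A1/AA11/r1 via T₁, similarly
  for group 2): all of the group's coefficient blocks are integrated out
  when updating each variance, via the Woodbury identity in line space
  (O(n_lines³) per evaluation), and the blocks are redrawn jointly. This is
  what lets the chain traverse the σ²_A/σ²_r ridge (below) instead of
  creeping along it: lag-1 autocorrelation of thinned σ²_A(1) samples drops
  from ≈0.9 to ≈0.15.

Defaults follow the standard practice for this model class: 60,000
iterations, 30,000 burn-in, thinning 10. Reported per model fit: posterior
means/SDs of all variances, broad-sense heritability H² (per sample, the
summed genetic-term variances — r included — over that sum plus σ²ₑ; the
set of terms entering the numerator is a convention and is stated in the
output notes), DIC = mean deviance + pD with pD = mean deviance minus the
deviance at posterior means (conditional Gaussian deviance given sampled
effects — DIC variants differ, so the convention is recorded), and the
GCA/SCA aggregates. Prediction is μ̂ plus each term's design row times
posterior-mean coefficients; designs are built over the union of all
pedigree hybrids, so untested crosses (including T0) always have rows.
Clamping all variances turns the posterior mean into the
mixed-model-equations BLUP, which the tests verify against a direct GLS
solve (r > 0.999).

Missing phenotypes are handled by fitting on observed design rows, not by
data augmentation — equivalent for point prediction and simpler.

## Cross-validation

A replicate samples n_D group-1 and n_F group-2 lines, pools the crosses
among them, draws the training hybrids uniformly from the pool (resampling
lines up to 50 times if the pool is short), and labels each remaining
hybrid T2/T1/T0 by how many of its parents occur among training parents.
Predictive ability per class is the correlation of predicted and observed
values divided by H² (from a full-data fit of the most complete GCA model
unless supplied). Division by H² is the printed convention of the study
this package is modeled on; correlation/√H² is the more common definition
of predictive ability, so both are implemented and the mode is recorded in
the result. Split streams are derived as seed + replicate, so different
model codes evaluated with one seed see identical splits (paired
comparison).

## Synthetic data

The generator mirrors the structure of the public Dent × Flint grain-yield
study: defaults n₁ = 123, n₂ = 86 lines, 35,478 SNPs, 1,254 hybrids in an
incomplete factorial with every line guaranteed ≥ 1 hybrid, variance
targets set to the full GCA-model estimates from that data set
(σ²_A(1)=19.06, σ²_A(2)=10.61, σ²_D=2.3, σ²_AA(1,1)=5.41, σ²_AA(2,2)=5.57,
σ²_AA(1,2)=3.24, σ²_r(1)=3.8, σ²_r(2)=4.56, σ²_e=13.67, in (q/ha)²), and a
trait mean of 100 q/ha (a typical grain-yield level; the source data are
adjusted entry means without a stated mean). Founder frequencies are drawn
per group from Beta(2,2) truncated to [0.05, 0.95] — a neutral bell-shaped
spectrum; the two groups diverge by independent draws — and line calls are
independent Bernoulli(p): linkage equilibrium and unrelated lines by
construction, matching the standing assumption of the variance theory.

Marker-based effect classes (α₁, α₂, d, epistatic pair effects on a sparse
random set of 500 pairs) are drawn i.i.d. normal and rescaled once so each
realized analytic variance (e.g. Σp₁q₁α₁²) equals its target *exactly*;
line-level r effects and residuals are drawn at their target variances
without rescaling. A functional mode draws (a₁, a₂, d) per locus and derives
the statistical effects through the locus theory before the same rescaling.

What the generator does **not** emulate: within-group LD and pedigree
relatedness (real heterotic groups have both), multi-year trial structure,
selection. Consequences for what passing tests mean:

* Recovery tests exercise exactly the generative model the kinship-based
  likelihood assumes, so they test the inference machinery, not robustness
  to LD or population structure.
* Under LE with unrelated lines the realized G_A is close to the identity
  (‖G_A(1) − I‖_F ≈ 2.5 at 100 lines × 2,000 markers), so σ²_A and σ²_r of
  the same group are nearly unidentified: the measured marginal
  log-likelihood changes by < 0.4 units across the entire ridge
  σ²_A + σ²_r = const. The data sharply identify the sum (the GCA
  variance); the split follows the prior. Real panels identify the split
  through LD/relatedness structure. The recovery test therefore judges
  per-component recovery on posterior samples pooled over replicate
  studies and additionally asserts the identified sums.

## Numerical choices and edge cases

* Monomorphic markers (in one or both groups) are kept; their pq = 0 terms
  contribute nothing to the affected scalings. All markers fixed in a group
  is an error (zero denominator).
* NOIA dominance columns whose class-frequency denominator
  pBB + pbb − (pBB − pbb)² vanishes (e.g. all hybrids heterozygous) are
  zeroed rather than dropped: a zero coding adds no covariance and panel
  alignment is preserved.
* Boundary allele frequencies in the locus oracle give zero-variance
  components, not errors.
* Stored kinship matrices are never ridged; the 1e-8 ridge exists only
  inside the eigendecomposition step, and each matrix records its scaling
  denominator (`scale_constant`).
* Kinship text formats write 17 significant digits and are read back with
  round-trip float parsing, so write/read cycles are bit-exact.
* Observed frequencies are the default for centering (zero column sums
  exactly); user-supplied reference frequencies are accepted, waiving that
  invariant.
* Missing genotype calls fail loudly unless per-marker mean imputation is
  explicitly requested; marker-panel reconciliation between groups is an
  explicit flag (`intersect_panels`), default off.

## Test problem sizes

The suite runs everything at reduced scale chosen to keep each check sharp:
matrix identities on 20–50-line panels with 200–2,000 markers; BLUP
equivalence at 300 hybrids; parameter recovery at 100 × 80 lines, 1,000
hybrids, 2,000 markers with 6,000-iteration chains over three replicate
studies; cross-validation ordering with 6 replicates on a complete 15 × 12
factorial. These sizes are the package's own test design; the identities
they check are exact at any scale.

## Known limitations

Two heterotic groups only; biallelic markers; no multi-trait or
genotype-by-environment modeling; no REML engine (Bayesian only); fixed
covariates beyond the intercept are carried through the data containers but
not fit; third- and higher-order epistatic matrices are not emitted (the
Hadamard pattern extends directly if needed). DIC and H² follow stated
conventions and are comparable within, not across, software.
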