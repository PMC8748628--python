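# Methods

## Model

The population is haploid with non-overlapping generations, two biallelic
loci (P: male preference; T: female trait) and no mutation or drift in the
deterministic core. Sexes share one zygote genotype-frequency vector
x = (x₁, x₂, x₃, x₄) over (P₁T₁, P₁T₂, P₂T₁, P₂T₂); because transmission is
sex-independent, viability selection produces transient female and male
pools rather than a persistent sex split. All matrices are oriented rows =
female genotype i, columns = male genotype j.

A generation applies, in order:

1. **Viability selection**, females then males (both before any sexual
   selection; with both costs active the order is immaterial because the
   sexes are independent, but it is fixed for determinism). Carrier
   genotypes are weighted by 1 − s and the pool renormalized by its mean
   viability (1 − s_f·t₂ for females, 1 − s_m·p₂ for males).
2. **Courtship** M_ij = x_f[i]·x_m[j]·(1 + d·a)/y_j, d = 1 iff female i
   carries T₂ and male j carries P₂, y_j = Σᵢ x_f[i](1 + d·a). The
   normalization encodes that genotypes differ in how they *allocate*
   courtship, not in total output: column sums equal the male frequencies.
3. **Pairing** F_ij = M_ij/z_i with z_i = Σ_j M_ij / x_f[i]: polygyny with
   equal female mating success, so row sums equal the female frequencies.
   When x_f[i] = 0 the quotient is 0/0; the row is defined as zero (absent
   genotypes contribute no matings, and normalization is preserved).
4. **Post-pairing tables.** Guarding trade-off: Θ_ij = θ − Δθ when a P₂
   male is paired with a T₁ female, else θ; φ ≡ 1. Care trade-off:
   Θ ≡ θ; φ_ij = 1 + b(1 − δ) for P₂ × T₁ pairs, else 1 + b. In both,
   E_ij = e + Δe for P₂ × T₁ pairs, else e.
5. **Extra-pair siring** ρ_j = Σᵢ F_ij E_ij / Σ_ij F_ij E_ij — extra-pair
   paternity is proportional to aggregate EPC effort; females gain no
   direct benefit from EPCs.
6. **Offspring accounting.** O^wp_ij = F_ij Θ_ij φ_ij / N̄ and
   O^ep_ij = ρ_j·Σ_j′ F_ij′ φ_ij′ (1 − Θ_ij′) / N̄, N̄ = Σ F φ. The inner
   sum runs over the mother's possible *social* mates j′ independently of
   the sire index: an extra-pair offspring inherits the survival context
   (φ, Θ) of its mother's social pair and the genotype of its sire. The
   alternative reading — extra-pair survival depending on the sire's own
   pairing — is rejected because the within-/extra-pair fitness
   decomposition underlying the care-model analysis, (1+b)(1−θ) vs
   [1+b(1−δ)](1−θ), requires the social pair's φ. By construction
   Σ(O^wp + O^ep) = 1 identically.
7. **Transmission.** For mother i and father j, the transient diploid emits
   each parental haplotype with probability (1 − r)/2 and each recombinant
   with r/2. General r ∈ [0, 0.5] is implemented (it enables the
   LD-decay property test D′ = (1 − r)D under neutrality); the model's
   standard regime is free recombination r = 0.5. The resulting vector is
   renormalized (tolerance 1e−12) to absorb floating-point drift.

The female viability formula is implemented as weight-then-renormalize,
i.e. denominator 1 − s_f·t₂. (A printed form with denominator "1 − b_f t₂"
does not normalize and is not the identity at s_f = 0; it is treated as a
typographical slip for the mean viability.)

## Parameters

| name | meaning | range | default |
|---|---|---|---|
| a | preference strength (courtship weight 1 + a) | ≥ 0 | 1.0 |
| theta (θ) | within-pair paternity share under full guarding | (0, 1] | 0.8 |
| delta_theta (Δθ) | paternity loss of P₂ × T₁ pairs (guarding) | [0, θ) | 0 |
| e | baseline EPC effort | > 0 | 0.8 |
| delta_e (Δe) | extra EPC effort of P₂ × T₁ males | ≥ 0 | 0 |
| b | male-care effect on brood size (care) | ≥ 0 | 0 |
| delta (δ) | care reduction of P₂ × T₁ males | [0, 1] | 0 |
| s_f, s_m | viability costs of T₂ / P₂ | [0, 1) | 0 |
| r | recombination rate P–T | [0, 0.5] | 0.5 |

Defaults e = θ = 0.8 are the baseline used throughout the benchmark
experiments; all selective asymmetries default to off. θ subsumes the
underlying EPC probability and extra-pair brood fraction (θ = 1 − αβ);
the two never enter separately.

## Analytic conditions and edge equilibria

Evaluated as strict inequalities (behaviour exactly at equality is not
specified by the theory and is resolved as "not satisfied"):

* guarding polymorphism: Δe/e > Δθ/(1 − θ);
* care-model preference persistence: Δe/e > bδθ/((1 + b)(1 − θ));
* costly-trait evolvability: δ > s_f(1 + 1/b);
* costly-trait interior stability: s_f < 1 − θ and
  Δe/e > bδθ/((1 + b)(1 − s_f − θ));
* joint-cost bound: (1 − s_f)(1 − s_m) > θ.

On the trait-lost edge t₂ = 0 the care model has the closed-form
equilibrium p₂* = (Δe(1+b)(1−θ) − beδθ)/(Δe·bδ), generalized under a
preference cost s_m to
(Δe(1+b)(1−s_m)(1−θ) − e(bδθ + s_m(1+b−bδθ))) /
((Δe(1−s_m) − e·s_m)(s_m(1+b(1−δ)) + bδ)). Both forms are verified in the
test suite to be exact fixed points of the edge dynamics (one-step residual
at machine precision) and to agree with an independent bisection root of
the edge fixed-point equation; values outside (0, 1) are reported as
absent.

## Numerical choices

* **Convergence**: iteration stops when the L∞ per-generation change drops
  below 1e−10 (primary) or 1e−13 (hard stall floor near neutral lines),
  with a cap of 2×10⁵ generations; non-convergence is flagged, not raised.
  An allele counts as fixed/lost within 1e−6 of 1/0.
* **Stability**: the one-step Jacobian is built in (p₂, t₂, D) coordinates
  — a polynomial bijection of the simplex, so its spectrum equals that of
  the map on the simplex — by central finite differences with step 1e−6.
  The coordinate inverse is polynomial and evaluable slightly outside the
  feasible region, which keeps central differences well-defined at
  boundary equilibria. Classes: STABLE if all |λ| < 1 − 1e−4;
  NEUTRAL_LINE if exactly one |λ| is within 1e−4 of 1 and the rest are
  below (neutral directions contract at exactly rate 1; discretization
  noise is orders of magnitude below 1e−4); UNSTABLE otherwise.
  Degenerate monomorphic corners under fully neutral parameters sit on
  multi-dimensional neutral sets and are reported UNSTABLE by this
  three-way scheme; they are not biologically meaningful attractors.
* **Sweeps** start from D = 0 (the standard protocol specifies only p₂ and
  t₂); region maps default to analytic classification with an optional
  numeric mode (boundary-equilibrium eigenvalues plus outcome probing from
  five standard starts).

## Figure-data protocols

The `figures` command regenerates the numerical content behind the four
benchmark figures. Panel values not printed in the source are the
package's own choices: the guarding-model equilibrium lines are traced for
Δe ∈ {0.5, 0.6, 0.7} (all inside the polymorphism region at e = 0.8,
θ = 0.8, Δθ = 0.1) and preference strengths a ∈ {0.5, 1, 2}; region maps
span δ ∈ [0, 0.6] × Δe ∈ [0, 1.2] at 41×41 resolution by default
(configurable). Plotting is deliberately out of scope: the CSV data are
the contract, and any rendering layer can sit on top without entering the
tested surface.

## Individual-based oracle

The stochastic simulation holds N females and N males per replicate and
runs the identical life cycle: multinomial survival sampling from the
post-viability distribution, per-female social-mate choice weighted by
realized courtship effort, then multinomial offspring production over the
(mother, genetic father) outcome distribution implied by the *realized*
mating tables. That last design choice makes the ABM's conditional
expectation exactly the deterministic recursion evaluated at the realized
frequencies — which is the point: replicate means must match `step()`
within Monte-Carlo error if and only if both implementations encode the
same model. Replicate k uses an independent stream seeded `seed + k`;
identical configurations are bit-identical.

The oracle emulates demographic stochasticity (binomial/multinomial noise
in survival, pairing and reproduction) and nothing else: no spatial
structure, age structure, explicit pair-bond duration, mutation or
environmental variance. Agreement between oracle and recursion therefore
validates the transition map, not the realism of either with respect to
field data.

## Problem sizes

The test suite iterates full trajectories at the published parameter sets
(10³–10⁴ generations per run), checks simplex conservation over 10³ random
parameter/state draws, and runs the oracle comparison at N = 10⁴ with 500
replicates per parameter set (10 sets), which resolves one-generation
allele-frequency changes to standard errors of ~2×10⁻⁴. The acceptance
script iterates three deterministic trajectories to the 1e−10 tolerance
(≈ 1.5–8.5×10³ generations each).

## Known limitations

* Near the boundary between coexisting basins of attraction (e.g. the
  costly-trait regime where both the t₂ = 1 line and a stable interior
  point attract), the final outcome of a single start is sensitive to the
  start itself; basin boundaries are reported empirically by sweeps, not
  asserted analytically.
* The full closed-form stability conditions of the costly models are not
  re-derived; region maps combine the main-text conditions with numerical
  Jacobian classification.
* Convergence along neutral equilibrium lines is asymptotic; the stall
  floor stops iteration when per-generation motion is numerically zero,
  so points reported on a neutral line carry ~1e−6-level positional
  uncertainty along the line (transverse to it they are converged).
* The deterministic core has no drift; finite-population effects live
  exclusively in the oracle, which is a validation instrument rather than
  a research-grade individual-based model.
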