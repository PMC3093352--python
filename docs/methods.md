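# Methods

## Model

The phototransduction cascade is a chemical reaction network of eleven
discrete species plus continuous intracellular calcium.  One activated
metarhodopsin (M\*) catalyses G-protein activation (G → G\*); G\* converts
PLC to its active form PLC\* (the G-protein entering a refractory pool that
recycles back); PLC\* produces the channel activator D (diacylglycerol or a
downstream messenger) while active; D opens transduction channels
cooperatively; open channels admit calcium.  Calcium closes two loops,
each a Hill function:

* positive feedback `f_p = Ca^m_p / (Ca^m_p + K_p^m_p)` promotes channel
  opening;
* negative feedback `f_n = B*^m_n / (B*^m_n + K_n^m_n)` — mediated by a
  Ca-activated species B\* (B → B\* at a rate proportional to Ca) —
  accelerates channel closing, M\* deactivation and PLC\* deactivation.

A reaction tagged with a feedback has its mass-action propensity multiplied
by `1 + gain · f`.  The multiplicative `1 + gain·f` form (rather than a bare
`f` factor) keeps baseline kinetics alive at zero feedback: with a bare
`f_n` factor nothing could deactivate before any B\* exists and the bump
could never terminate.  Channel opening is
`k_open · C_closed · hill(D; K_D, m_D) · (1 + amp_p · f_p(Ca))`.

Calcium obeys `dCa/dt = k_ca_in · C_open · Ca_ext − γ_Ca (Ca − Ca_eq)`:
influx proportional to the open-channel count and the external
concentration, extrusion relaxing to the intracellular equilibrium.

The exact algebraic rate forms were chosen as the standard mass-action
reading of the cascade topology (catalytic activations, first-order decays,
bimolecular G\*+PLC); every constant is a named entry of the shipped
parameter table (`data/reference_params.tsv`), so the modulation map and all
rates are auditable and configurable.

### Reference parameters

Rates are per ms, calcium in µM, species in copy numbers.  The reference
set was calibrated so the wild-type response reproduces the qualitative
single-photon phenotype: a transient average bump of ~8 open channels (of a
pool of 15) peaking near 10 ms with ~12 ms FWHM, mean latency ~6 ms with
large trial-to-trial spread, and a clearly sub-unit reliability (~0.9 at
detection threshold θ = 2 channels) so that both successes and failures
occur.  Sixteen parameters are flagged locus-eligible (all first-order
rates, bimolecular rates, Hill constants and feedback gains); Hill
exponents, pool sizes and the calcium constants stay fixed in every
genotype.

## Stochastic simulation

Discrete species follow the exact Gillespie algorithm.  Calcium is a fast,
high-copy variable and is integrated as a continuous concentration: at
fixed open-channel count its ODE is linear, so it is advanced by the exact
exponential solution between events.  While calcium is moving (open
channels, or Ca away from equilibrium), event sampling proceeds in
micro-steps capped at 0.01 ms; propensities are constant within a
micro-step and the next-event time is drawn from the exact exponential law
conditional on that step, so a calcium-decoupled network reduces to the
textbook exact SSA (verified distributionally: single-molecule decay times
against Exponential(γ) by Kolmogorov–Smirnov at n = 10⁴).  In the quiescent
state (no open channels, Ca at equilibrium) propensities are exactly
constant and the simulator jumps directly between events.

Defaults: horizon 500 ms (captures the latency tail), recording grid
0.5 ms.  Per-trial and per-vertex seeds derive from a base seed by a fixed
multiplicative-hash XOR, so every ensemble and landscape is bit-reproducible
and evaluation-order independent.

## Traits

* **reliability** — fraction of trials whose open-channel count reaches
  θ = 2 channels (θ separates single-channel flicker from genuine bumps and
  is configurable); binomial standard error.
* **amplitude / duration** — peak and FWHM (linear interpolation at the
  half-maximum crossings) of the trial-averaged trace, failures included,
  as in a flash average over many microvilli.  A per-trial variant
  (mean of per-trial peaks/widths) is available behind a flag.
* **latency** — mean first θ-crossing time over successful trials.
* **composite** — `logistic(A; A₀, ΔA) · (1 − logistic(T; T₀, ΔT))`,
  rewarding large, brief responses.  Anchors default to the reference
  genotype's A and T with widths 0.2×anchor, making the trait
  dimensionless, equal to 0.25 at reference, and comparable across allele
  sets.

## Genotypes and the Walsh decomposition

Alleles use the log-Gaussian generator `p± = p_ref·exp(ε ξ±)` with two
independent draws per locus; it matches the stated Gaussian perturbation
properties, keeps parameters positive at any ε, and makes
`log(p⁺/p⁻)` exactly `ε·√2`-distributed (an additive variant
`p_ref(1+εξ)` exists behind a flag).  Shared-ξ mode rescales one fixed draw
across an ε grid, which removes generator variance from ε-scaling fits;
independent draws per (ε, replicate) reproduce the ensemble averaging
design.

Bit conventions are fixed package-wide: bit i of a vertex/subset integer is
locus i; a set bit means s_i = +1 (vertex) or i ∈ S (subset).  The
transform carries the 2^−L averaging factor, so F₀ is the grand mean, f_S
is the uniform-background averaged effect of subset S, `D_k` is the mean
squared order-k coefficient, and Parseval gives
`Σ_{S≠∅} f_S² = Var(F)` under the uniform genotype distribution.  The fast
butterfly is checked against a literal subset-averaging oracle.

Per-locus variance split: `v_add(i) = f_i²`,
`v_epi(i) = Σ_{S∋i, |S|≥2} f_S²` — the unique order-≥2 quantity measuring
how much of a locus's effect depends on genetic background.

**Noise floor.**  Finite trial counts add i.i.d. noise of variance σ² per
vertex, which inflates every `E[f_S²]` by σ²/2^L uniformly across orders.
The floor is estimated non-parametrically by evaluating each landscape as
two disjoint trial halves: the spectrum of half their difference has
exactly the noise power of the averaged landscape.  Floors are reported and
used to decide which orders are resolved; they are never subtracted from
published coefficients.

## Experiment design and problem sizes

The full study design is 16 loci × five ε values
(0.01, 0.03, 0.1, 0.3, 1.0) × 20 allele sets, with per-ε trial counts of
5000/2000/1000 (small/middle/large ε) because small-ε allele effects
approach sampling noise.  The package's shipped experiment and acceptance
runs use a reduced instance chosen to keep a complete run on one CPU within
minutes while preserving every qualitative phenomenon: L = 8 loci
(2⁸ = 256 genotypes), ε = 0.3, three allele sets, 1000 trials per genotype
split into two 500-trial halves for the noise floor.  At these sizes orders
k = 1–3 are resolved above the floor and order 4 is marginal; the monotone
decay of noise-corrected `C(L,k)·D_k` is assessed over the resolved orders.
The composite trait is used for the reduced experiment: its dynamic range
resolves higher-order terms better than reliability, which sits near its
ceiling at the reference.

ε-scaling exponents are fitted on analytic log-polynomial traits
(`F(p) = c₀ + Σ cᵢ log pᵢ + Σ c_ij log pᵢ log pⱼ + …`) in shared-ξ mode:
with exp-form alleles these are polynomials in ε, so `D_k ∝ ε^{2k}` holds
with essentially zero model error and the fitted log–log slopes are exact
to three decimals — a calibration of the fitting machinery, not a
simulation result.

## What the synthetic traits do and do not emulate

The analytic generators reproduce the *structure* of simulator landscapes —
declared Walsh spectra, ε-scaling, vertex-keyed sampling noise with the
σ²/2^L floor — and exercise the full allele/genotype plumbing.  They do not
emulate bump waveforms, trait nonlinearities of the cascade (saturation of
reliability, feedback-induced compensation), or heteroscedastic noise
(binomial variance depends on the vertex's reliability).  Tests passing on
synthetic traits therefore validate the decomposition and orchestration
machinery; claims about the cascade itself rest on the simulator runs.

## Numerical choices and degenerate inputs

* Transform tolerances: oracle agreement ≤1e−12 (scaled), round-trip
  ≤1e−10; both far above double-precision round-off at L ≤ 16.
* FWHM of a flat-zero average is 0 (not an error); a landscape with any
  non-finite vertex is rejected before decomposition.
* Additive ranking ties break by locus index; recovery curves count a
  subset once all its members are in the ranking prefix.
* The additive-only recovery curve tops out at the additive fraction of
  variance; only the total-variance curve reaches 1 at m = L.
* Exceedance fractions of the pair scatter are reported at 0.5× and 1×
  thresholds; the additive comparator is √(fᵢ²+fⱼ²) (sum and max variants
  behind a flag).

## Known limitations

* The kinetic constants are calibrated to qualitative single-photon
  phenomenology, not fitted to electrophysiological recordings; absolute
  trait values (ms, channel counts) are model-scale, though the epistasis
  statistics are dimensionless or normalised.
* Haploid, biallelic, one-parameter-per-locus genotypes only; no
  dominance, linkage or allele-frequency weighting.
* Exhaustive enumeration caps L at 24 in principle and ~16 in practice;
  no sparse-recovery estimation from subsampled genotypes.
* Calcium micro-stepping is O(h) accurate in the feedback coupling;
  h = 0.01 ms is far below every reaction timescale (≥1 ms⁻¹ rates appear
  only in Ca relaxation, which is integrated exactly).
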