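# Methods

## Model

Ising(k) assigns each node s of a simple undirected graph a spin
x_s ∈ Ω_k = {(−k+j)/k : j = 0,…,2k}, i.e. 2k+1 equally spaced values in
[−1, 1]; k is a positive integer, and k = 1/2 is the two-state special case
Ω = {−1, +1}.  With external field τ ∈ ℝ and ferromagnetic coupling σ ≥ 0,

    H(x) = −τ Σ_s x_s − σ Σ_{(s,t)∈E} x_s x_t,

each unordered edge counted once, and configurations follow the Boltzmann
distribution at inverse temperature β.  Graphs are arbitrary simple graphs;
the generator provided is Erdős–Rényi G(n, p_e), whose nominal mean degree
is d = p_e(n−1).  All analytical results are mean-field statements in d.

## Mean-field family

The mean-field approximation replaces each node's neighbourhood by the
average field dμ, giving the variational Gibbs free energy

    G(μ) = σμ²nd/2 − (n/β) log Σ_{x∈Ω_k⁺} 2cosh(βγx),   γ = τ + σμd,

with Ω_k⁺ = {0, 1/k, …, 1} (for k = 1/2: Ω⁺ = {1}, so the sums collapse to
sinh/cosh).  Stationarity of G is the self-consistency equation

    μ = f(μ) = Σ x sinh(xβγ) / Σ cosh(xβγ),

and ∂μ/∂τ gives χ = β(Σx²cosh/Σcosh − μ²).  These three formulas are a
single consistent variational family and are implemented exactly in this
form.

**Half-set weighting caveat.**  The half-set sums give the x = 0 term of
integer-k models weight 2cosh(0) = 2, whereas a one-site Boltzmann average
over the full Ω_k counts the zero state once.  Consequently f differs from
the exact single-site thermal average, and the linearisation factor
r = (2k+1)/6k differs from the full-set second moment (k+1)/3k.  The family
is kept verbatim because it is internally consistent (f is exactly ∇G = 0,
and r is exactly f′(0)/βσd); the exact average is available as the clearly
named comparison helper `single_site_thermal_average` and is used nowhere in
the solvers.  One visible consequence, confirmed by the Monte Carlo
experiments: on large dense graphs the sampler converges to the *exact*
self-consistent magnetisation, which sits slightly above the half-set value
in the ordered phase (e.g. 0.698 vs 0.591 at 1.2β_c, k = 3).

**Regular-model convention.**  The r formula is an integer-k object; at
k = 1/2 the map is tanh(βγ) with unit slope factor, so `critical_beta` and
the near-critical laws use slope 1 there (β_c = 1/σd), labelled "regular".

## Fixed points and equilibrium selection

f(μ) − μ is bracketed on a uniform 2001-point grid over [−1, 1] (f is smooth
and bounded; at this density no bracket straddles two roots in the regimes
used, up to k = 2000 and β ≈ 5σd) and refined by Brent's method to
|f(μ*) − μ*| ≤ 1e−12.  Stability is |f′| vs 1 with a central difference,
step 1e−6; attracting roots are local minima of G, repelling roots local
maxima (asserted in tests).  The thermodynamic equilibrium is the attracting
root with least G; the symmetric τ = 0 pair ties and is broken toward the
non-negative root.  Evaluation of all half-set sums factors out the largest
exponential, so k up to a few thousand and βγ of order 10² stay finite.

## Landau quantities and exponents

r = (2k+1)/6k decreases from 1/2 (k = 1) to 1/3 (k → ∞); β_c = 1/(rσd).
Near β_c the solved magnetisation follows μ = A·(β/β_c − 1)^1/2 — note the
amplitude A = 1/√(−c) (c the cubic coefficient of f at β_c) is *not* 1:
A = √3 for the regular model (the classical Curie–Weiss amplitude) and
A ≈ 1.53 for k = 3.  The package therefore asserts the exponents, not unit
amplitudes.  Exponent fits use log–log least squares over fixed default
windows chosen so higher-order terms contribute well under the asserted
tolerance: β/β_c − 1 ∈ [1e−4, 1e−2] for the exponent 1/2 and
|τ| ∈ [1e−6, 1e−3] at β = β_c for the exponent 1/3 (measured slopes 0.499
and 0.333).

The hysteresis-location estimate τ* = rσd = 1/β_c is leading-order only:
the true mean-field spinodal is 0 at β_c and grows toward σd as β → ∞.
Mapping it with the package (k = 3, σ = 0.1, d = 9.9) shows the estimate is
accurate in the moderately deep ordered phase, crossing within 5% around
β ≈ 3β_c; the property test pins the claim there.  At the loop-experiment
setting β = 5 ≈ 1.9β_c the actual jumps sit near ±0.22.

## Metropolis sampler

Single-site Metropolis: pick a node uniformly, propose uniformly from all
2k+1 values (symmetric, k-independent, well-mixing even at k = 2000),
accept with min(1, e^{−βΔH}), ΔH computed from the node's field term and
neighbour sum (CSR adjacency, O(degree) per update).  One sweep = n
proposals; defaults n_sweeps = 5000, burn_in = 500, thin = 1.  Chain
randomness is pre-generated per 256-sweep chunk from one seeded PCG64
stream; the inner loop is numba-compiled when numba imports, and the pure
Python fallback consumes the identical streams, so trajectories are
bit-identical either way.  Graph generation uses its own seed so one graph
can be reused across temperatures.  Magnetisation errors use batch means
(20 batches) to absorb autocorrelation.  Correctness anchors: exact
enumeration of all (2k+1)^n configurations on n ≤ 6 systems (capped at 10⁷
states), β = 0 uniformity, and the σ = 0 closed-form single-site average.

## Experiment protocols

* **Temperature sweeps** report the mean-field global equilibrium |μ| per β
  (dependent only on the nominal d, never on seeds) and optionally MC mean
  |m| on one shared graph — |m| because finite symmetric systems have m ≈ 0
  but |m| > 0.
* **Hysteresis** sweeps τ up then down (default −0.5…0.5, step 0.01), each
  point warm-started: mean-field mode keeps the attracting fixed point
  nearest the previous μ, following a metastable branch until its spinodal;
  MC mode restarts from the previous final configuration.  Jumps are
  |Δm| > 0.2 between consecutive steps (configurable), located at the
  midpoint of the straddling pair.  Width-vs-k runs use the supercritical
  regime β = 5, σ = 0.1, d = 9.9 (rβσd ∈ [1.65, 2.47] for all k) over
  τ ∈ [−0.8, 0.8]: widths 0.71, 0.33, 0.27, 0.27 for k = 1, 10, 200, 2000 —
  monotone, saturating, with k = 200 and k = 2000 equal to within the step.
* **Phase maps** use the global Gibbs minimiser per (β, τ) cell — single
  valued, no metastable branches; only the hysteresis driver follows those.
* **Finite-size/degree study**: curves over (n, p_e) pairs on a *common*
  absolute β axis ({0.5, 0.75, 1.0, 1.25}×β_c of the smallest/sparsest
  curve), 600 sweeps, 2 seeds per point, k = 3, σ = 0.1; the figure of merit
  is max_β |MC − mean-field|.  On a common axis this deviation conflates
  three effects — finite-size fluctuations, degree corrections, and the
  half-set offset above, all largest where the curve's true transition sits —
  which is exactly how accuracy-vs-size is read off a fixed-β-axis plot.
  Measured: 0.45 → 0.09 (n = 200 → 500 complete) and 0.49 → 0.02
  (p_e = 0.3 → 1 at n = 500).

## What the generated data do and do not show

All experiments are self-generating (ER graphs + simulated chains); there is
no external data.  Passing tests show the sampler targets the model's exact
distribution, that mean-field theory describes dense graphs well away from
criticality, and that the category-dependence (r, β_c shift, loop narrowing
and saturation) behaves as derived.  They do not validate the model against
empirical networks: real social/psychometric graphs are degree-heterogeneous,
clustered and small-world, none of which ER graphs emulate, and mean-field
accuracy on such topologies is untested here.

## Problem sizes and determinism

Default suite sizes: enumeration oracles at n ≤ 6, k ≤ 3 (≤ 729 states);
Metropolis validation at 10⁶ updates; width-vs-k at four k values up to
2000; finite-size study at n ≤ 500 with 600 sweeps × 2 seeds.  Every driver
is a pure function of (parameters, seeds): per-point seeds are spawned from
one SeedSequence, reruns are byte-identical, and `scripts/acceptance.py`
derives all of its randomness from the single `--seed` argument.

## Known limitations

* Only single-site Metropolis — no cluster updates, so critical slowing-down
  limits near-critical MC precision; tests deliberately sample away from the
  critical point.
* The half-set equations are kept verbatim (see caveat above); users wanting
  the exact dense-graph limit should compare against
  `single_site_thermal_average`.
* Near-critical fit windows and the jump-detection threshold are defaults
  tuned to the regimes documented here; both are configurable arguments.
* Mean-field quantities use the nominal d = p_e(n−1) for reproducibility;
  the realised mean degree of each sampled graph is recorded in metadata.
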