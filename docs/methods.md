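# Methods

## Model and assumptions

`randpam` models one time-bin of light capture by a photoreceptor with
N_u identical, independent sampling units (microvilli). The input is the
number of photons *absorbed* per bin — a fixed integer, not a Poisson
draw: the model isolates how the internal sampling geometry shapes gain,
so external shot noise is deliberately excluded (an input file or
generator can pre-noise counts if a user wants it). All photons are
absorbed; spectral sensitivity is folded into the effective photon rate;
microvillus geometry (depth in the stack, length taper) is ignored, so
units are exchangeable; and bins are independent, so a time series is
handled by repeating the single-bin process.

Under these assumptions the hit count x of one microvillus is
Binomial(N_ph, 1/N_u), and Poisson(λ_M = N_ph/N_u) when N_ph ≪ N_u². The
package's validity rule for switching to the Poisson form is
N_ph/N_u² ≤ 0.01 **and** N_u ≥ 100; the first threshold keeps two orders
of margin below the brightest realistic fly regime (≈5×10⁶ photons per
integration window against N_u² = 9×10⁸), the second enforces the
many-units premise of the limit. `poisson_approx_valid` always returns the
raw ratio so callers can apply a different cutoff. A grid check in the
test suite confirms total-variation distance < 10⁻³ between the two pmfs
throughout the admitted region.

## Stochastic realization

Independent Poisson draws per microvillus would make the bin total itself
Poisson(N_ph), i.e. sometimes exceed the fixed input. Both allocators
therefore conserve the total exactly:

- **multinomial** (default): each photon lands on a uniform microvillus.
  The joint hit vector is Multinomial(N_ph; 1/N_u, …), marginally the
  exact binomial; conservation holds by construction. This is also the
  cheaper scheme and the one used for large Monte-Carlo runs.
- **compound_binomial**: occupancy-class realization. For
  x = x_n down to 1 — x_n the largest x with N_u·P(x) > 1, the
  digitization limit below which a class would need less than one
  microvillus — the allocator draws round(N_u·P(x)) distinct microvilli
  (distinct across classes: one hit multiplicity per microvillus per bin)
  to absorb x photons each. Rounding is half-away-from-zero with a floor
  of one microvillus per retained class. Because rounded expectations
  need not sum to N_ph, a residual-correction step settles the difference
  with the smallest available perturbation: a surplus of photons is added
  as 1-hit events on uniformly chosen unoccupied microvilli; a deficit is
  removed by deleting uniformly chosen 1-hit events, decrementing ≥2-hit
  events only once the 1-hit pool is exhausted. If the correction cannot
  reach the target (e.g. a handful of microvilli asked to absorb many
  photons with an almost-degenerate class structure), an
  `AllocationInfeasibleError` names the bin rather than silently
  mis-conserving. The correction rule and the per-bin x_n are recorded in
  the allocation metadata.

Event tables are stored sparsely as (bin, microvillus, hits) because
occupancy per bin is ≈ λ_M ≪ 1 in the regimes of interest; a dense export
exists for small problems. One seeded `numpy.random.Generator` drives a
run; identical (stimulus, geometry, seed, method) reproduce identical
event lists.

For convergence studies at large photon loads,
`empirical_multi_photon_fraction` replays bins in chunks through an
offset bincount, accumulating hit/multi-hit tallies without materializing
events; 10⁴ bins × 10⁴ photons (10⁸ draws) runs in seconds within modest
memory.

## Gain analysis

Bump-charge models map hit multiplicity x to QB charge C_x (fC):
`linear` (C_x = x·C_1), `no_summation` (C_x = C_1), `parametric`
(C_x = C_1·(1 + s·(x−1)), 0 ≤ s < 1) and `tabulated` (exact lookup; C_x
held at the last tabulated value beyond the table, which is conservative
and preserves the sublinear band C_1 ≤ C_x < x·C_1). Tables violating the
band or monotonicity are rejected with the offending x listed. All
headline quantities are charge *ratios*, so the absolute value of C_1
never affects a result (asserted by test).

Analytic gains use the Poisson pmf with an adaptive truncation
x_max = ⌈λ + 12√(λ+1) + 20⌉, beyond which the omitted tail is below
double-precision resolution; widening the truncation further changes
results by < 10⁻¹². The quantum-gain factor is computed as
1 − normalized gain; the equivalent occupancy expansion
1 − P(0) − Σ_{x≥2}(C_x/C_1)P(x)/λ_M (via the identity P(1)/λ = P(0))
agrees to machine precision and is exercised in the tests.
`empirical_gain` evaluates the same ratio on realized allocations — for
the no-summation model it reduces exactly to hit-microvilli-per-photon,
N_A/N_ph.

Numerical edge cases: P_M and N_A/N_ph are 0/0 at λ = 0 and are defined
by their continuous limits (0 and 1); `expm1` keeps both stable at small
λ. Beyond λ ≈ 40 the deficit 1 − P_M underflows double precision, so P_M
saturates to exactly 1.0 (and table cells print 100.00).

## Stimulus generators

The generators emulate the three standard input regimes at 1 kHz
sampling (1 ms bins; a warning is emitted below 200 Hz, under which fly
response dynamics are under-resolved):

- **constant**: every bin carries round(rate/sampling_rate) photons
  (half-even); the rounding residual is reported as metadata.
- **white noise**: spectral synthesis with iid complex-Gaussian Fourier
  amplitudes up to the cutoff (default 20 Hz) and zero above, scaled to
  standard deviation = contrast × mean. Contrast has no published
  default; where this package's own examples and checks need one they
  use 0.3, a typical natural-scene RMS contrast.
- **naturalistic (1/f)**: a log-intensity trace with 1/f *power* spectrum
  and random phases is exponentiated, then scaled to the target mean.
  Synthesis in the log domain keeps intensities positive and positively
  skewed (rare bright events), as in natural scenes; with the default
  log-standard-deviation of 0.5 the exponential preserves the power-law
  shape, and the fitted log-log periodogram slope of generated traces
  sits near −1 over 0.5–100 Hz.

Integerization (both noise generators) clips at zero and rounds
half-even, with no re-normalization afterwards — the resulting integer
counts *are* the ground-truth input; the induced mean shift is recorded
in metadata. The generators are statistical stand-ins: they reproduce
mean level, contrast and spectral shape but not the higher-order
spatiotemporal structure of recorded natural light traces, so tests
passing on them demonstrate correctness of the sampling and gain
machinery, not fidelity to any particular recorded scene.

## Published-table note

Across the 5 × 6 grid of multi-photon percentages, six cells of the
published table differ from the closed form 1 − λ/(e^λ − 1) by 0.01–0.17
percentage points (at N_u = 300 and 1500 for 100–1000 photons/ms, and at
N_u = 6000 for 10⁴–10⁵ photons/ms); their provenance (binomial exact
evaluation, simulation, or different rounding) is not stated. This
package always reports the closed-form values; the comparison suite
checks only the formula-consistent cells.

## Problem sizes

Default verification runs use 10⁴ replicate bins for distributional and
convergence checks (≥10⁶ photons, giving sub-0.05-point standard errors
on P_M), 2-second stimuli for conservation identities, and a 40-point
log grid over λ_M ∈ [10⁻³, 10] for gain bounds. These sizes make every
check's sampling error far smaller than the effects being verified while
keeping the full suite under half a minute.

## Known limitations

Downstream transduction is out of scope by design: no microvillus
refractoriness or photon loss, no QB waveforms or light-induced current,
no membrane dynamics — the package ends where the photon-to-microvillus
mapping and its charge-gain bookkeeping end. Multi-photon bump charges
C_x are user inputs (tabulated or parametric), not derived from
biochemistry. The compound-binomial residual-correction rule is this
package's own construction to honor exact conservation; it perturbs the
drawn occupancy by at most the rounding residual but is not the only
possible reconciliation.
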