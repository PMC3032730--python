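# Methods

This note documents the models, estimators and numerical choices behind
`mpflim`, what the synthetic data generator does and does not emulate, and
the known limitations.

## Decay model and reference reconvolution

A pixel's histogram over time channels of width Δt is modelled as

    m_i = Σ_j α_j Φ_{j,i},   Σ_i Φ_{j,i} = 1,

with between 1 and 4 exponential components per channel. The unit-area
kernels Φ_j are built from the binned decay of a mono-exponential reference
dye (lifetime τ_ref) by δ-function reconvolution:

    Φ_j ∝ ref + (1/τ_ref − 1/τ_j) · (ref ⊛ exp(−t/τ_j)).

Because kernels have unit area, α_j is the expected number of photons of
component j and Σ_j α_j equals the pixel photon count. Two derived
normalizations are used: intensity fractions a_j = α_j / Σ|α| (giving the
intensity-averaged lifetime τ_av = Σ a_j τ_j / Σ a_j) and molecule fractions
p_j ∝ α_j/τ_j (giving the amplitude-averaged lifetime
τ_mean = Σ p_j τ_j / Σ p_j). Absolute-value normalization keeps both
meaningful when a component carries a negative (rising) amplitude, the
signature of acceptor emission fed by energy transfer; for all-positive
fractions τ_mean ≤ τ_av always.

**Discretization.** The convolution is evaluated channel-by-channel,
treating the reference histogram as a piecewise-constant photon density.
Under that premise the double integral over source and target channels has
a closed form (a geometric-kernel discrete convolution), so the only
approximation is the piecewise-constant assumption itself. An independent
oracle — exact exponential-integrator propagation of C′ = ρ − C/τ on a
16×-oversampled grid — agrees with the implementation to ≲10⁻⁵ relative per
channel. Against a *continuous* reference density the residual error is
the irreducible binning of the reference: about 0.3 % around the response
peak at the default 48.8 ps channels, 10⁻⁵ in the decay tail. Convolution
is truncated at the window edge (no periodic wrap); with a ~60 ns pulse
interleave and lifetimes ≤ 5 ns the wrapped tail is below 10⁻⁵ of the
signal.

**Negative amplitudes.** Components must be declared `sign="free"` to carry
negative amplitude; the model is validated post hoc (every m_i ≥ 0). Note
that fitted tables of *molecule* fractions such as (−33 %, 67 %) on
(0.44 ns, 2.49 ns) correspond to area amplitudes of roughly (−8 %, 92 %) —
interpreting the molecule fractions directly as area amplitudes produces a
negative, unphysical model.

## Three-stage estimation

**Stage 1 — segmentation.** Photon-count thresholding (default 30
photons/pixel, the low end of the customary 30–50 range) followed by
connected-component labelling (default 8-connectivity; 4 available). Labels
are assigned in raster order of each component's first pixel, so the
labelling is deterministic. Polygon regions of interest can replace the
threshold mask.

**Stage 2 — lifetimes from pooled traces.** Region-summed decays are fitted
jointly over channels by weighted least squares with lifetimes shared
through link keys and channel amplitudes eliminated analytically (variable
projection). Weights default to *iterated Pearson* (w = m from a Neyman
pre-fit): plain Neyman weights (w = max(n, 1)) systematically pull
lifetimes down by 1–3 % at the photon levels of interest because downward
fluctuations in low-count tail channels are over-weighted; Pearson
weighting removes this bias (0.5 ns / 3.7 ns recovered to ≈0.1 % from a
5·10⁶-photon pooled trace). Neyman remains selectable. Optimization uses
bounded trust-region least squares on log-lifetimes (bounds 10 ps – 20 ns,
tolerances 10⁻¹²), with optional multi-start (±1.5× perturbations) as a
local-minimum guard; 68 % confidence intervals come from profiling the
objective to a unit increase.

**Stage 3 — per-pixel amplitudes.** With lifetimes fixed, the multinomial
deviance is minimized per pixel under Σα = N and sign constraints. The
problem is convex; the solver eliminates one positive component to absorb
the sum constraint and runs a projected Newton iteration, vectorized over
all pixels of a region (chunked at 4096 pixels), with backtracking to keep
the model non-negative. Zero-count channels contribute nothing to gradient
or Hessian. Termination at a projected-gradient norm below 10⁻¹¹·N; two
different feasible starts agree to better than 10⁻⁸·N, and the result
matches a generic SLSQP minimization of the same objective.

At 1000 photons/pixel the empirical standard deviation of the fast-component
amplitude matches the numerically computed multinomial CRLB to well under
1 % over 10⁴ pixels; the estimate is unbiased for N ≳ 100 photons, with a
small positive bias appearing at N ≲ 50 (boundary truncation of the
non-negativity constraint) — the expected small-count behaviour of a
bound-constrained MLE.

## Estimation-theory diagnostics

The Fisher information is computed under the fixed-N multinomial model (to
match the deviance estimator) by central finite differences of the model
probabilities (relative step 10⁻⁶); lifetime derivatives rebuild the kernels
from the reference at perturbed lifetimes. A singular information matrix
raises an error naming the null direction (e.g. two equal lifetimes).

The photon economy F = σ_τ·√N/τ compares any lifetime estimator to the
shot-noise-limited ideal F = 1 (mono-exponential decay, negligible response,
window ≫ τ — verified numerically to 10⁻⁴). Two reference points:

* **Gated detection.** For two contiguous equal-width gates and the rapid
  lifetime determination estimator τ̂ = w/ln(N₁/N₂), Poisson error
  propagation gives F² = (2 + eˣ + e⁻ˣ)/x² at gate width x = w/τ, counting
  the photons detected in the gates; the minimum is F ≈ 1.509 at x ≈ 2.44.
  For more gates the bound follows from the Poisson Fisher information of
  the gate counts with amplitude and lifetime free (≈1.16 at 4 gates,
  ≈1.05 at 8); the two routes agree exactly at two gates, where the
  estimator is exactly identified.
* **Global analysis.** When lifetimes come from the pooled region trace,
  a pixel spends its photons only on amplitudes, and the derived τ_av
  reaches F ≈ 0.6 on the bi-exponential calibration scene — below the
  single-pixel ideal, which no per-pixel lifetime estimator can beat
  (per-pixel mono-exponential ML fitting on the same data gives F ≈ 1.07).

The calibration harness (`calibration_experiment`) sweeps photon levels
(default 20–1000, mirroring the low-count regime the method targets), drawing
fixed-N multinomial pixels so that empirical moments are directly comparable
to the fixed-N CRLB.

## Synthetic data generator

The simulator emulates four-channel PIE TCSPC acquisition: a 150 ps FWHM
Gaussian response centred 2.44 ns into a 1024 × 48.8 ps ≈ 50 ns window
(inside the ~60 ns interleave), an 86 ps reference dye, Poisson pixel
totals, and micro-times drawn *at channel resolution* from the discretized
model (exact multinomial), so simulated data lie exactly in the fitted model
family. Rising components are simulated by sampling the validated
non-negative mixture, never by signed sampling. Optional uniform background
and a row-stochastic emitter-to-channel crosstalk matrix are available;
photobleaching and detector dead time are not modelled (negligible in the
low-intensity operating regime this analysis targets). The reference decay
itself can be sampled continuously (`simulate_reference`).

Preset scenes (defaults, not dials):

* `rhodamine6g` — uniform bi-exponential dye, 0.5 ns / 3.7 ns at 10 % / 90 %
  intensity fractions. The 10 % is stored as an intensity (area) fraction.
* `donor_only` — triple-exponential donor-only cell, 0.18/1.72/2.71 ns at
  17/28/55 % molecule fractions (the 0.18 ns term plays the role of cellular
  auto-fluorescence).
* `fret_construct` — donor–acceptor fusion: donor 0.44/1.64/2.71 ns at
  42/41/17 %, transfer-excited acceptor 0.44/2.49 ns at −33/67 % (rising
  edge), directly excited acceptor 0.10/0.97/2.28 ns at 25/15/60 %, and an
  empty fourth channel.
* `moving_mito` — a Gaussian emitter (σ = 1.2 px) translating at constant
  velocity with a constant bi-exponential decay (0.97/2.28 ns at 15/85 %
  intensity fractions, the two dominant terms of the directly excited
  acceptor protein); the bi-exponential form keeps the per-bin average
  lifetime a non-trivial estimate in kymogram tests.

Because micro-times are discretized and the model family is exact, passing
tests demonstrate estimator properties (bias, efficiency, sign structure),
not robustness to model misspecification, incomplete reference
characterization, or detector artefacts in real instruments.

## Kymograms

Paths are resampled at 1-pixel arc-length steps; photons are assigned to the
nearest path sample (KD-tree) within a transverse corridor of `width/2` and
to frames of fixed duration. Each (position, frame) bin keeps its micro-time
histogram; bins with at least `min_photons` (default 30) get a stage-3
amplitude fit at the globally fitted lifetimes, yielding an average-lifetime
kymogram with NaN below the floor. On constant-truth simulations the per-bin
scatter of τ_av matches the per-bin CRLB prediction within ~5 %.

## Identifiability limits

Close lifetime pairs (ratio ≲ 1.6, e.g. 1.72 ns vs 2.71 ns) are only weakly
identifiable from pooled traces below ~10⁷ photons: statistically equivalent
fits trade amplitude between the two components while the fast fraction and
the derived mean/average lifetimes stay stable. Tests and applications
should therefore assert component-resolved fractions only with lifetimes
held at their global values, and treat free-lifetime triple-exponential
splits of nearby components as qualitative. The per-pixel maps themselves
are conditional on the stage-2 lifetimes; lifetime uncertainty is reported
through the profile confidence intervals, not propagated into the maps.

## Problem sizes

The shipped tests and the acceptance script run the full chain at reduced
problem sizes chosen to keep Monte-Carlo errors well inside the assertion
bands: 10⁴ pixels × 1000 photons for CRLB attainment (std ratio resolved to
0.7 %), 2000 pixels per level for the bias sweep, 5000 pixels for the
two-stage recovery, 4000 replicates for the high-count efficiency check,
and a 40-frame kymogram with ~175 fitted bins.
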