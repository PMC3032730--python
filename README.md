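# mpflim

Global multi-exponential analysis of multi-channel time-correlated
single-photon-counting (TCSPC) FLIM data.

## The problem

Time-domain fluorescence lifetime imaging records a full photon-arrival
histogram in every pixel. Under gentle, long-term illumination of living
cells only tens to hundreds of photons per pixel are available — far too few
to fit a multi-exponential decay pixel by pixel. `mpflim` implements the
analysis strategy that makes such data quantitative:

1. **Segmentation** — pixels are split into a dark background and bright
   connected regions by photon-count thresholding and connected-component
   labelling.
2. **Global lifetime estimation** — within a region the decays are summed
   into one high-count trace per acquisition channel, and the component
   lifetimes τ_j are fitted by weighted least squares, assuming lifetimes
   are spatially invariant inside the region. A lifetime can be *linked*
   across channels (e.g. an energy-transfer component that appears with
   positive amplitude in the donor channel and negative, rising amplitude in
   the acceptor channel must share one value).
3. **Per-pixel amplitude estimation** — with lifetimes frozen, the
   per-component amplitudes α_{j,k} of pixel *k* are found by minimizing the
   multinomial deviance

       D = 2 Σ_i n_i ln(n_i / m_i),     m_i = Σ_j α_j Φ_{j,i},

   subject to Σ_j α_j = N_k (the pixel photon count). D is the exact
   likelihood-ratio statistic for histogram counts, convex in α, and the
   resulting maps are unbiased and reach the Cramér–Rao lower bound down to
   very low photon counts.

The basis decays Φ_j are built by *reference reconvolution*: instead of a
scattered-light instrument response, the measured decay of a reference dye
with known mono-exponential lifetime τ_ref (e.g. Erythrosine B, 86 ps) is
convolved with `δ(t) + (1/τ_ref − 1/τ_j)·exp(−t/τ_j)`. Because the reference
is recorded through the same spectral band as the probe, the wavelength
dependence of the instrument response cancels.

On top of the fitting chain the package provides:

* amplitude conventions and derived lifetimes — intensity fractions a_j with
  the intensity-averaged lifetime τ_av = Σ a_j τ_j, and molecule
  (pre-exponential) fractions p_j ∝ α_j/τ_j with the amplitude-averaged
  lifetime τ_mean = Σ p_j τ_j;
* FRET quantification — apparent efficiency E_app = 1 − τ_DA/τ_D, real
  efficiency E = E_app/f for a FRET-active donor fraction f, donor–acceptor
  distance r = R0·((1−E)/E)^(1/6), and the four-channel evidence checklist
  for pulsed interleaved excitation (PIE) data;
* estimation-theory diagnostics — multinomial Fisher information, CRLB, the
  photon economy F = σ_τ·√N/τ, and the gated-detection (rapid lifetime
  determination) theory it is compared against;
* intensity and average-lifetime kymograms along a user-drawn path for
  organelle-transport studies;
* a synthetic four-channel PIE data generator (photon lists and decay cubes)
  with preset scenes, so every stage is testable without instrument data.

## Worked example

```python
import numpy as np
from mpflim import (
    ComponentSpec, ModelSpec, PipelineConfig, run_pipeline, fret_from_fractions,
)
from mpflim.simulator import preset_scene, simulate_decay_cube

# 1. simulate the bi-exponential calibration dye at 500 photons/pixel
scene = preset_scene("rhodamine6g", seed=42, shape=(40, 40), photons_per_pixel=500)
cube, truth = simulate_decay_cube(scene)

# 2. three-stage global analysis: segment, shared lifetimes, per-pixel MLE
model = ModelSpec({"532RFP": [ComponentSpec(tau=700.0), ComponentSpec(tau=3000.0)]})
result = run_pipeline(cube, PipelineConfig(model, scene.reference(), threshold=30))

fit = result.region_fits[1]
taus = sorted(fit.taus.values())
print(f"fitted lifetimes: {taus[0]/1000:.3f} ns, {taus[1]/1000:.3f} ns")

maps = result.maps["532RFP"]
fast = int(np.argmin(maps.taus))
print(f"mean fast amplitude fraction: {np.nanmean(maps.amplitude_fractions[fast])*100:.2f} %")
print(f"mean average lifetime: {np.nanmean(maps.tau_av)/1000:.3f} ns")

# 3. FRET arithmetic from fitted donor parameters (lifetimes in ns)
fp = fret_from_fractions(
    donor_taus=(0.44, 1.64, 2.71), donor_preexp=(0.42, 0.41, 0.17),
    donor_ref_taus=(0.18, 1.72, 2.71), donor_ref_preexp=(0.17, 0.28, 0.55),
    r0_nm=5.8,
)
print(f"corrected donor lifetime: {fp.tau_d_corrected:.2f} ns")
print(f"real FRET efficiency:     {fp.e_real:.2f}")
print(f"donor-acceptor distance:  {fp.distance_nm:.1f} nm")
```

Output:

```
fitted lifetimes: 0.509 ns, 3.720 ns
mean fast amplitude fraction: 10.27 %
mean average lifetime: 3.390 ns
corrected donor lifetime: 2.38 ns
real FRET efficiency:     0.81
donor-acceptor distance:  4.5 nm
```

The simulated dye decays with 0.5 ns (10 % intensity fraction) and 3.7 ns
(90 %) components; the two-stage fit recovers both lifetimes from the pooled
region trace and the fast amplitude fraction pixel by pixel at only 500
photons per pixel. The FRET block turns fitted donor parameters into a
transfer efficiency and a donor–acceptor distance: the quenched 0.44 ns
donor component against an auto-fluorescence-corrected donor-only lifetime
of 2.38 ns gives E = 0.81, i.e. r ≈ 4.5 nm at a 5.8 nm Förster radius.

A thin command-line interface wraps the same functions:

```sh
mpflim simulate --preset fret_construct --seed 1 --out cube.h5 --truth truth.json
mpflim segment  --cube cube.h5 --threshold 30 --out labels.csv
mpflim fit      --cube cube.h5 --model model.yaml --out results/
mpflim calibrate --preset rhodamine6g --seed 0 --out calib.json
```

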