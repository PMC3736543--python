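# ciliadyn

Quantitative analysis of single-molecule membrane-protein motion in primary
cilia. The package is written for cell biologists and biophysicists who
track individual receptors (e.g. SSTR3 or Smoothened) along cilia and want
to answer two questions:

1. **What fraction of the observed movement is motor-driven (IFT) transport,
   as opposed to free diffusion in the ciliary membrane?**
2. **How fast does the protein diffuse, and does diffusion alone suffice to
   explore the cilium?**

It provides four analysis stages plus a synthetic-data generator that
produces trajectories and FRAP curves with known ground truth, so every
stage can be validated end to end without any experimental data.

## Methods at a glance

**Instant velocities.** Each track's own cilium axis is fitted by PCA on
the localizations plus the basal-body position; essentially stationary
tracks (axial variance < 0.1 μm²) are excluded. Instant velocities are
consecutive axial differences divided by the frame interval Δt = 0.46 s,
signed so that anterograde (base → tip) is positive.

**Velocity-mixture deconvolution** ("effective histogram subtraction").
Live-cell velocities v are modeled, per direction class, as

    p(v) = f · N(v; μ, σ²) + (1 − f) · p_ref(v)

where p_ref is the velocity distribution measured in a motor-inactive
reference condition (ATP depletion or digitonin permeabilization) and the
Gaussian is the active-transport component. Histograms use the
Shimazaki–Shinomoto bin width minimizing C(Δ) = (2k̄ − v̂)/Δ²; (f, μ, σ)
are estimated by nonlinear least squares on bin densities; a two-sample
Kolmogorov–Smirnov test compares the raw samples without binning, and an
F-test with (3, m − 3) degrees of freedom checks that the three Gaussian
parameters are justified.

**FRAP in a bounded 1D geometry.** For a cilium of length L with the
region [0, a] photobleached, the cumulative density of bleached molecules
is the sine series

    H(x,t) = xa/L + Σ_{n≥1} (2L/π²n²) sin(nπa/L) sin(nπx/L) exp(−π²Dn²t/L²),

and the fractional intensity in a measurement segment [a1, a2] follows
from H together with the bleached fraction f_b and mobile fraction f_m.
`fit_diffusion` estimates f_b from the first post-bleach point, f_m from
the recovery plateau, then fits the apparent diffusion coefficient D by
least squares. A 10⁵-particle Brownian simulation serves as an
independent cross-check of the series solution.

**Transport metrics.** The Péclet number Pe = UR/D compares advection by
IFT-train traffic (speed U, ciliary radius R) with diffusion, and
L²/(2D) vs L/v compare diffusive and motor-driven transit times.

## Worked example

Run the end-to-end demo on synthetic data (200 live + 200 motor-inactive
tracks in a 4 μm cilium, D = 0.25 μm²/s, 25% directed occupancy, plus a
half-cilium FRAP trace):

```bash
ciliadyn run-demo --seed 5 --out-dir demo_out
```

prints

```
anterograde: f = 0.221 ± 0.038, mu = 0.306 μm/s, p_KS = 8.11e-25, p_F = 4.64e-12
retrograde: f = 0.193 ± 0.020, mu = 0.266 μm/s, p_KS = 2.39e-23, p_F = 4.18e-19
perpendicular control: p_KS = 0.208
FRAP: D = 0.2658 μm²/s
reports in demo_out
```

Reading the output: the mixture fit attributes ~20% of the live-cell
steps in each direction to a narrow, fast component (the simulation's
ground-truth per-direction active fractions, recorded in
`demo_out/manifest.json`, are 0.179 and 0.176); both the KS and F tests
reject the diffusion-only explanation, while the perpendicular components
— which motors cannot affect — show no difference (p = 0.21), and the
FRAP fit recovers the generative D = 0.25 μm²/s to ~6% on a single noisy
trace. JSON reports for every stage land in `demo_out/`.

The individual stages are available as subcommands (`simulate-tracks`,
`velocities`, `mixture-fit`, `simulate-frap`, `frap-fit`, `peclet`,
`transit`) and as library functions (`ciliadyn.fit_axis`,
`ciliadyn.fit_value_mixture`, `ciliadyn.fit_diffusion`, ...).

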