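# sasbme

Bayesian/Maximum-Entropy (BME) refinement of multi-domain protein
conformational ensembles against small-angle X-ray and neutron
scattering (SAXS/SANS) data.

## The problem

Proteins built from folded domains joined by flexible linkers populate
broad conformational ensembles in solution. Molecular simulations can
generate candidate ensembles, but imperfect energy functions typically
leave them too compact or too expanded; small-angle scattering measures
the true size and shape distribution at low resolution. `sasbme`
implements the analysis that reconciles the two:

1. **Forward model** — SAXS/SANS intensities of bead-model conformers
   via the Debye formula,

   *I(q) = Σᵢⱼ Δbᵢ Δbⱼ sin(q rᵢⱼ)/(q rᵢⱼ)*,

   with per-bead excess scattering lengths Δbᵢ set by the probe: for
   neutrons they depend on the solvent D₂O fraction and per-chain
   deuteration (contrast variation), for X-rays they do not. Gaussian
   resolution smearing with per-point widths σ_q handles SANS
   instrumental resolution.

2. **BME reweighting** — frame weights *w* minimize

   *L(w) = χ²(w)/2 − θ·S(w)*,  *S(w) = −Σⱼ wⱼ ln(wⱼ/w⁰ⱼ)*,

   the minimal perturbation of the simulation prior *w⁰* consistent
   with the data. The regularization strength θ is chosen by scanning
   the (φ_eff, χ²ᵣ) L-curve, where φ_eff = exp(S) is the effective
   fraction of prior frames retained. −ln(φ_eff) (in units of k_BT) is
   a free-energy-like estimate of the force-field error as seen by the
   data.

3. **Nuisance parameters** — a six-step protocol estimates one global
   scale and background per ensemble (per-frame free fits → reweighting
   → weighted-average parameters → fixed-parameter refit per θ),
   avoiding the drastic overfitting of per-conformer fits.

4. **Contrast design and cross-validation** — match-point solvers
   (e.g. hydrogenated protein matches out at 42% D₂O; 69%
   perdeuteration matches pure D₂O under the default scattering length
   densities), signed pair distance distributions p(r), and
   SAXS-training / SANS-validation χ²ᵣ tracking along the θ path.

Because experimental multi-domain datasets are not redistributable, the
package ships a first-class synthetic generator: a Metropolis
Monte-Carlo sampler of a three-domain bead protein (rigid domains A, B,
C joined by flexible linkers) whose single solvent-quality parameter κ
controls inter-domain stickiness, emulating the protein–water
interaction rescaling used to tune coarse-grained force fields. Every
stage of the analysis is therefore testable end-to-end with known
ground truth.

## Worked example

The `demo` subcommand runs the full recovery loop: sample a
good-solvent truth ensemble (κ = 2), simulate a 1%-noise SAXS dataset
from it, then reweight a too-compact prior (κ = 1) against that data:

```sh
sasbme demo --outdir demo_out --seed 1 --n-frames 300
```

prints the θ-scan table and summary (abridged):

```
       theta    chi2_r  phi_eff
10000.000000 63.720290 0.921623
 2335.721469 17.528386 0.697080
  545.559478  3.008373 0.500885
  206.913808  1.244978 0.435030
   78.475997  0.851051 0.400657
   18.329807  0.763423 0.379483
    1.000000  0.753360 0.356487
selected theta = 18.3298 (diminishing-returns)
chi2_r = 0.763, phi_eff = 0.379, force-field error = 0.97 kBT
truth mean Rg      = 15.47 A
prior mean Rg      = 12.22 A
reweighted mean Rg = 15.49 A
```

Reading the output: the prior fits the data poorly (χ²ᵣ ≈ 64 with the
original weights); lowering θ improves the fit until it flattens near
χ²ᵣ ≈ 0.8. The selected ensemble keeps 38% of the prior frames
(φ_eff = 0.38, i.e. a ~1 k_BT force-field error) and moves the mean
radius of gyration from the too-compact prior value (12.2 Å) onto the
truth (15.5 Å).

Other subcommands (`generate`, `simulate-data`, `calc`, `reweight`,
`scan-theta`, `protocol`, `scan-solvent`, `crossval`, `contrast`,
`analyze`) expose the individual pipeline stages; `sasbme --help`
lists them. The same functionality is available as a library
(`import sasbme`).

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator
and its calibration, numerical choices, and known limitations.
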