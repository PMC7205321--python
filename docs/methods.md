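# Methods

This note documents the models implemented in `sasbme`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Forward scattering model

Conformers are bead models: each bead has a volume *V* (default
100 Å³, uniform) and an excess scattering length Δb = V·(ρ_bead −
ρ_solvent). Intensities follow the Debye formula over bead pairs, with
the i = j self-terms contributing Δb². Two evaluation paths exist: an
exact O(n²·|q|) double sum and a histogram-accelerated path that
accumulates pair contrast products on a fine distance grid (default
0.005 Å) with linear cloud-in-cell splitting; the two agree to better
than 10⁻⁶ relative on the q-ranges used here, and the test suite
enforces this on random signed-contrast frames.

The model deliberately omits atomic form factors, the hydration shell
and excluded-volume solvent terms: its role is to supply a forward
operator with the same mathematical structure as full-featured
calculators, not atomic-level accuracy. Consequently the fitted
nuisance parameters are a global scale *S* and flat background *B*
(K = 2 degrees of freedom in χ²ᵣ by default; K is configurable for
comparisons against conventions that count additional hydration
parameters, e.g. K = 4).

### Contrast

Neutron scattering length densities interpolate linearly between
hydrogenated and deuterated protein (fraction *x*) and between H₂O and
D₂O (fraction *f*):

ρ_s(f) = (1−f)·ρ_H₂O + f·ρ_D₂O,  ρ_p(x) = ρ_H + x·(ρ_D − ρ_H).

Defaults (Å⁻²): ρ_H₂O = −0.562×10⁻⁶, ρ_D₂O = 6.404×10⁻⁶ (literature
values), ρ_H = 2.364×10⁻⁶ and ρ_D = 8.219×10⁻⁶. The protein constants
are calibrated so two standard contrast conditions hold exactly: a
fully hydrogenated component matches out at 42% D₂O, and perdeuteration
to 69% matches pure D₂O. Labile-hydrogen exchange is not modelled
separately; it is folded into the effective ρ_H. Match points are
closed-form linear solves; out-of-range solutions are returned
unclipped with a warning (e.g. a fully deuterated component cannot be
matched by any H₂O/D₂O mixture).

X-ray contrast uses electron-density-based constants and ignores
isotope composition entirely.

### Resolution smearing

SANS curves are smeared with per-point Gaussian kernels of width σ_q:
the reported point is a normalized quadrature of the model curve over a
dense internal grid. Normalizing the kernel on the truncated grid makes
constant curves exact regardless of truncation (the kernel convention
itself does not fix the quadrature, so this is a documented choice).
The grid must resolve each kernel with ≥ 4 points per σ_q; violations
raise an error naming the offending q. σ_q = 0 reproduces the model
point exactly. Model support is extended beyond the data range as the
kernels require.

### Pair distance distributions

p(r) is computed in direct space from coordinates as the
contrast-weighted histogram of inter-bead distances, cloud-in-cell
binned; bead self-terms are excluded and carried separately, so the
duality I(q) = self + Σ_bins p(r)·sinc(qr) holds to second order in the
bin width (≤ 1% at 0.5 Å bins in the tests). Signed contrasts make
p(r) negative at distances between opposite-contrast components — the
signature of alternating-contrast SANS conditions.

## BME reweighting

The objective L(w) = χ²(w)/2 − θ·S(w) is minimized in the dual: with
σ-whitened per-frame intensities A and data b, stationary weights have
the exponential-family form wⱼ ∝ w⁰ⱼ·exp(−Σᵢ λᵢ Aⱼᵢ) and λ minimizes
the smooth convex function ln Z(λ) + λ·b + (θ/2)|λ|². L-BFGS-B with
the analytic gradient, followed by Newton polishing, reaches a
stationarity tolerance of 10⁻⁸ (max-norm of the dual gradient);
non-convergence raises an error carrying the best iterate. The
contract is stationarity plus agreement with a brute-force simplex
grid search, which the tests enforce on random tiny instances; the
dual algorithm itself is an implementation detail.

Multiple datasets combine by summing χ² (each point weighted 1/σ²);
optional per-dataset multipliers are exposed but default to 1, the
neutral choice.

### θ selection

The scan runs down a log-spaced θ grid (default 10⁵ → 1, 30 points)
and reports the full (θ, χ²ᵣ, φ_eff) table; along the path χ²ᵣ and
φ_eff are both non-increasing as θ decreases, which the tests assert.
The automatic selection emulates the by-eye rule — lower θ while the
χ²ᵣ decrease is substantial, stop once the φ_eff loss dominates — as a
diminishing-returns criterion: select the θ at the first grid segment
where Δln χ²ᵣ < Δln φ_eff. Both quantities enter on a log scale, so
the criterion is invariant to the data's units and to how far the
prior starts from the data. A maximum-curvature construction on the
normalized linear axes was tried first and rejected: when the prior is
nearly consistent with the data, φ_eff barely moves and the chord
construction selects before χ²ᵣ has flattened. If the whole scan is
flat (χ²ᵣ range < 0.1, e.g. a prior that already fits), the largest θ
is returned by convention. The automatic choice is advisory: the full
table is always returned and logged.

### Force-field error

φ_eff = exp(S) estimates the fraction of prior frames effectively
retained, and −ln(φ_eff) (k_BT) converts it into a free-energy-like
upper view of the force-field error as seen by the data: 0 for an
ensemble the data leave untouched, ≈ 5.5 k_BT when only 0.4% of frames
survive. It measures only what the data can see — a force field can be
wrong in ways scattering cannot detect.

## Global nuisance-parameter protocol

Fitting scale and background freely per conformer would overfit, so a
single global set is estimated per ensemble: (1) per-frame free fits;
(2) BME reweighting over a θ grid (default log-spaced 500 → 1, 15
points); (3) weighted-average parameters ⟨p⟩_w = Σᵢ wθ,ᵢ·pᵢ; (4)
fixed-parameter recomputation of every frame's curve; (5) reduced
chi-square with M − 2 degrees of freedom; (6) refit of S and B per θ
and selection of the minimizing θ. Step (6) can only lower χ²ᵣ
relative to step (5), which the tests assert. The reweighting is a
single pass — parameters are not re-iterated after averaging (an
optional `refinement_passes` argument re-solves with the averaged
parameters, but defaults to 0, as the single-pass procedure is the
plain reading of the algorithm). Per-frame fit failures are skipped and
counted; more than 50% failures aborts.

The protocol is written over the (S, B) parameter vector; additional
parameters average and refit the same way without structural change.

## Synthetic ensembles

The generator stands in for long coarse-grained MD: a three-domain
bead protein (chains A, B, C; rigid compact domains of
`n_beads_per_domain` beads on a cubic lattice, joined by flexible
linker beads, linkers belonging to the chain of the following domain)
sampled by Metropolis Monte Carlo. The energy (k_BT units) is

* harmonic bonds along the chain (k = 1 k_BT/Å², rest length = bead
  contact distance),
* hard-core repulsion between non-bonded beads (0.8 × contact),
* a square-well attraction of depth ε₀/κ and width 6 Å between beads
  of different rigid domains.

κ is the solvent-quality dial: large κ weakens inter-domain attraction
(good solvent, expanded), small κ collapses the domains — the same
compact↔expanded phenomenology produced by rescaling protein–water
interactions in coarse-grained force fields, controlled by one
monotone parameter. κ = 0 (infinite attraction) is rejected with
guidance. Moves are rigid translations+rotations of whole domains and
displacement/crankshaft moves of linker beads; rigid bodies are
re-anchored to their reference geometry at every recorded frame, so
intra-domain distances are frame-independent to ≈ 10⁻¹⁴ Å (the tests
require 10⁻⁹). All randomness flows from one seed; identical seeds
give bit-identical trajectories.

**Calibration.** ε₀ = 0.2 k_BT was chosen once so that the κ ladder
{0.5, 1, 2, 4} spans the regimes the analysis is designed to probe: at
the study conditions (500 frames, 60-point SAXS-like data at 1% noise)
κ = 0.5 is a far prior needing heavy reweighting, κ = 1 is biased but
"good enough" (reweights to χ²ᵣ ≈ 1 while keeping ~half the frames),
κ = 2 is the truth condition, and κ = 4 over-expands. Mean R_g is
monotone in κ seed-by-seed across this ladder. Defaults: 1,000 frames
(tests and the demo use 300–500), 20 MC sweeps between frames, 200
burn-in sweeps; the frame stride has no physical analogue and is a
free choice.

**Simulated datasets.** The "experimental" curve is the truth-weighted
ensemble average (smeared if resolution widths are given) plus
independent Gaussian noise with σ(q) = noise_scale·(a·I₀ +
b·√(I(q)·I₀)), a baseline plus a shot-noise-like term that grows
relatively as the signal decays (a = 0.1, b = 0.9). SANS-like presets
use ~5× the SAXS noise scale, a coarser, shorter q grid and constant
σ_q = 0.005 Å⁻¹, reflecting the generally lower information content of
SANS data. noise_scale = 0 returns the exact forward model. The χ²
calibration of the noise model (mean χ²ᵣ of the generating model
against replicate datasets = 1) is enforced in the tests. Truth
weights for weight-recovery fixtures default to a compact/expanded
two-population mixture split at the median R_g.

**What the synthetic tests show — and don't.** They demonstrate that
the estimators are correct and well-calibrated under the generative
assumptions (independent Gaussian noise with known σ, a forward model
identical in form to the one used for fitting, rigid domains). Real
data add systematic effects the generator does not emulate —
hydration-shell contrast, inter-particle interference, aggregation
upturns, correlated errors, buffer-subtraction artefacts — so passing
these tests validates the machinery, not the physics of any particular
experimental system.

## Collective variables and diagnostics

R_g is computed over all beads (uniform masses — a uniform-bead toy
has no meaningful mass heterogeneity; per-bead masses are accepted),
and D₁₂/D₁₃/D₂₃ between unweighted all-bead domain centroids.
Prior-vs-posterior comparisons use normalized weighted histograms and
the overlap coefficient Σ min(m₁, m₂); block analysis (successive
pairwise averaging, plateau detection by the first level whose SEM
stops rising beyond its own uncertainty) estimates errors on
simulation time series. Block analysis operates on unweighted series;
error estimation for reweighted series is out of scope.

## Cross-validation

Reweighting trains on one dataset and tracks held-out χ²ᵣ per θ, with
scale and background refit on each validation curve at each θ (the
permissive choice; the training χ²ᵣ reported in the same table goes
through the identical refit so that validating against the training
set is an exact identity). The 42%-D₂O analogue (deuterated chain A,
hydrogenated B/C at their match point) probes essentially one rigid
domain and is flat in θ — its per-frame curves are nearly identical —
while bulk-contrast analogues (0% D₂O) improve alongside the SAXS
training fit when the prior is far from the truth.

## File formats and reproducibility

Curves are whitespace text with '#' headers: q (Å⁻¹), I, σ, and for
SANS a fourth column σ_q. Ensembles are multi-model PDB (one MODEL per
frame, beads as pseudo-atoms, chain IDs A/B/C) with a JSON sidecar for
what PDB cannot carry (volumes, roles, domain ranges, bonds, weights);
coordinates round-trip to PDB precision (10⁻³ Å). The YAML pipeline
config rejects unknown keys by name. Every CLI run logs its seed,
version and a config hash; all operations are deterministic functions
of (inputs, options, seed).

## Known limitations

* The forward model has no hydration shell or excluded-volume solvent
  term; absolute-scale intensities are arbitrary.
* The generator's square-well energy is a phenomenological stand-in:
  it reproduces compact↔expanded behaviour, not any specific force
  field's thermodynamics.
* θ selection is a heuristic; for publication-grade analyses inspect
  the full L-curve.
* Uncertainties on reweighted observables (beyond φ_eff) are not
  propagated.
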