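# Methods

## Observation model

A measurement is N diffraction intensity patterns I_n (nonnegative, probe-
window shape) plus N real scan positions r_n in object pixels, (y, x),
denoting the top-left corner of the probe window on the object canvas.
Each position splits into an integer part s_int = ⌊r + 0.5⌋ (fraction in
[−0.5, 0.5), ties up) and a subpixel part s_sub = r − s_int.  The integer
part selects the object patch O_n; the subpixel part shifts the probe by a
unit-modulus linear phase ramp in the frequency domain (band-limited
interpolation, energy-preserving and exactly invertible).  The exit wave is
ψ_n = P_n ⊙ O_n; propagation to the detector is the **unitary** 2-D DFT
(norm="ortho" both ways), chosen so Parseval holds: real-space and
reciprocal-space squared errors coincide, and the Lipschitz constants of
the engine subproblems take the clean forms |P_n|²_max and |O_n|²_max.

The magnitude projection (revised exit wave) is
ψ′ = F⁻¹[√I ⊙ sign(Fψ)] with sign(z) = z/|z| and sign(0) := 1 (the measured
modulus is kept with zero phase where the model field vanishes).  By
construction |Fψ′|² = I to rounding; the test suite checks 10⁻⁸ relative
over random pairs.

Noise is Poisson per pixel on the clean intensities, drawn once at
simulation time from a dedicated seeded stream and never re-drawn.  The
model's additive-noise placeholder is not separately simulated.

## Engines

All engines share the same sweep: each outer iteration draws a fresh
permutation of sample indices from a seeded generator (independent of the
noise stream), then per sample forms ψ, ψ′ and updates the object patch and
the shifted probe from the residual Δ = ψ′ − ψ, writing the patch back and
un-shifting the probe.  Both updates read the pre-update fields.  Per
iteration the trace records the pooled R_F (recomputed from the updated
fields), the mean pre-update sample cost, and (CRISP) ξ.

* **ePIE**: O_n += α_o conj(P_n)/|P_n|²_max ⊙ Δ, probe mirror-image; equal
  to a gradient step on g(O) = ‖ψ′ − P⊙O‖²_F with η = α/|P|²_max.  With
  α ∈ (0, 1], η is within the reciprocal Lipschitz bound, so a single step
  never increases the subproblem cost (property-tested on random
  instances).
* **rPIE**: element-wise denominator (1−γ)|P_n|² + γ|P_n|²_max; reduces to
  ePIE with α = 1 at γ = 1.
* **CRISP**: per-sample subgradient projection with cost e = ‖Δ‖²_F, step
  function G = (e−ξ)₊/‖conj(Q)⊙Δ‖²_F (Q the co-factor field), clipped at
  ν/|Q|²_max, direction D = clip(G)·conj(Q)⊙Δ, update x += λ D.  ν = 1
  caps the coefficient at ePIE's ("ePIE-like" clipping; with λ = α and the
  cap always active the trajectories coincide exactly);
  ν = "scale_adaptive" uses the cap 1/|Q|_max.  ξ is a single scalar shared
  by all samples, initialized as c·mean(e) from the starting fields and
  re-tuned to c·mean(e) after every sweep, with e recorded at
  direction-computation time (pre-update residuals).  λ is accepted in
  (0, 2) with a warning above 1, the range used in practice.

Degenerate visits (vanishing update denominator with cost above threshold)
are skipped and counted; ξ never goes negative because e ≥ 0 and c > 0.

Step sizes follow the two dose conditions of the simulation study:
high dose α_o = λ_o = 1.0, α_p = λ_p = 0.4, γ = (0.1, 1.0), c = 0.5,
K = 300; low dose α = λ = (0.4, 0.2), γ = (0.1, 5.0), c = 0.01, K = 400
(`PRESETS`).  For noise-free identifiability runs CRISP uses c = 0.01: the
attainable cost floor is zero, and a large c would freeze the half of the
samples whose cost falls below the running mean.

## Toy subgradient harness

`ToyProblem` isolates the step-size behavior on 2-D differentiable costs
g ≥ E with analytic gradients.  Three regimes: E = 0, ξ = 0 converges like
gradient descent; ξ > E stops inside {g ≤ ξ}; E > 0, ξ = 0 blows up.  For
the quadratic bowl the blow-up is subtle: with λ = 1 the radial iteration
is a cotangent doubling map whose excursions are unbounded in supremum but
which rarely crosses a fixed norm bound in a finite run.  The harness
therefore also flags divergence when the gradient vanishes while the cost
exceeds ξ — there the step coefficient is +∞, the genuine blow-up — and the
clean monotone-runaway exhibit uses a Gaussian-well cost
g = E + 1 − exp(−‖x‖²/2), whose exponentially flattening tails make every
overshoot land in flatter territory.  Clipping the coefficient (cap 1.0 in
the tests) tames that regime, mirroring the engine.

## Synthetic data

The generator emulates a hard-X-ray ptychographic measurement at desk
scale.  Defaults (one-time design choices):

* **Object phantom**: clear film (transmission 1) with 12 random disks,
  radius 1.5–3 px, transmission amplitude 0.75–0.95, phase 0.1–0.5 rad —
  weak contrast as appropriate for thin specimens at ~8 keV.  Particle
  centers are confined to the central 0.2·canvas band (the scanned field
  of view): structure outside the illuminated area is unconstrainable by
  the data and would only add an artificial convergence tail.  A
  Siemens-star phantom (binary amplitude, sector count = total spokes,
  clear hub) is available for resolution-chart studies.
* **Probe**: radially symmetric soft-edged disk (logistic edge, ~1.5 px
  10–90% width), diameter 10 px in a 16 px window, flat phase by default —
  an idealization of the in-focus demagnified image of a beam-defining
  aperture, not a wave-optical zone-plate model (the nominal optics — 20 µm
  aperture, 5× demagnification, 416 µm/86 nm zone plate at 8 keV, 4.5 m
  detector — are carried as metadata, `BEAMLINE_OPTICS`).  Optional
  quadratic defocus phase.  Unit energy before dose scaling.
* **Scan**: 5×5 raster, step 3 px (70 % linear overlap), uniform jitter
  ±0.2 px.  Jitter breaks the raster phase-ramp ambiguity of a perfectly
  periodic grid; larger jitter measurably slows the convergence tail under
  subpixel probe frames, so it is kept small.
* **Dose**: one global scale sets max_n I_n[0,0] (DC bin of the unshifted
  transform) to I0 — 10¹⁰ high dose, 10⁸ low dose; a single incident flux
  for the whole measurement.  The truth probe stored with a dataset absorbs
  √scale so the stored truth reproduces the scaled data exactly.
* **Initializers** (blind start): all-ones object; soft disk probe at
  0.6·window diameter, scaled so its energy equals the mean total counts
  per pattern (Parseval puts the start on the data's scale).

Phantom, scan-jitter, noise and permutation randomness come from separate
seeded streams; datasets and runs are bit-reproducible.

What the generator does **not** emulate: partial coherence, detector
point-spread/readout noise and gaps, position errors (positions are known
exactly to the reconstruction), wave-optical probe structure, thick
specimens.  Passing tests therefore show algorithmic correctness and
desk-scale behavior, not beamline-grade performance.

## Metrics

* **R_F** = Σ_n Σ_q |√I_n − |Fψ_n|| / Σ_n Σ_q √I_n, pooled over all
  patterns; scale-consistent and zero iff the model reproduces every
  modulus.
* **Alignment**: translation from the complex cross-correlation peak
  (upsampled-DFT subpixel refinement, factor 50), then the global phase
  from the inner product.  Applied before any image comparison; without it
  FRC and τ are meaningless under the inherent ambiguities.
* **FRC** per integer-radius ring (1 frequency-pixel annuli) up to
  Nyquist; computed on the illuminated sub-canvas only — the bounding box
  of pixels whose accumulated illumination Σ_n|P_n|² exceeds 10 % of its
  maximum — because pixels outside carry no constraint.  Half-Nyquist
  means ring frequency < 0.25 cycles/pixel.  No half-bit/2σ threshold
  criteria are applied.
* **τ** = ‖align(O_i→O_j) − O_j‖²_F / (‖O_i‖_F ‖O_j‖_F).  The underlying
  dispersion score is defined in cited prior work and its exact algebra is
  not reproduced here; this normalized aligned-difference form preserves
  the ordering semantics (lower = more similar), so only orderings and
  dispersions are meaningful, not absolute printed values.
* **Probe correlation**: modulus of the normalized inner product of the
  propagated probes on an aperture mask (default: support of the reference
  spectrum above 10⁻³ of peak).

## Study sizes and numerical choices

The standard desk-scale study is a 64×64 object, 16×16 probe window and
5×5 scan (25 patterns); engines run K = 300 noise-free and K = 150 for the
ten-order dispersion study.  These sizes make every end-to-end check run in
seconds to a couple of minutes on one CPU while preserving the phenomena
of interest.  Tolerances: magnitude projection 10⁻⁸ relative; propagation
round trip 10⁻¹⁰; paired-trajectory equivalence 10⁻⁸ after 50 iterations;
noise-free recovery R_F < 10⁻³ in ≤ 300 iterations with FRC > 0.95 below
half-Nyquist and probe correlation > 0.99.

Known limitation: at desk scale the update-order dispersion comparison is
weakly resolved.  Both engines converge to nearly the same solution on the
default dataset (pairwise τ ~ 10⁻⁶), and the variance ratio of the two τ
distributions fluctuates with the dataset seed around unity (medians
slightly favor the subgradient-projection engine).  The comparison is
therefore directional, not a reproduction of the large-scale dispersion
gap measured on real data.
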