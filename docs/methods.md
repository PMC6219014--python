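# Methods

## Problem

Atrial repolarization (the Ta wave) is normally invisible on the surface ECG:
it coincides with, and is two orders of magnitude weaker than, the ventricular
QRS complex. `taview` recovers it by solving the inverse problem at the source
level: reconstruct transmembrane potentials (TMPs) on a coarse myocardial
surface model from the 8 independent channels of the standard 12-lead ECG,
then re-project only the atrial source block back to the body surface. The
output is an atrial-only ECG containing the P and Ta waves with the
ventricular contribution removed by construction rather than cancelled by
waveform templates.

## Forward model

The quasi-static potential of myocardial sources in a homogeneous medium is a
Poisson problem; its discretization gives the linear lead field

    phi(t) = L u(t),

with `u` the per-node TMP and `phi` the electrode potentials. L is built from
the equivalent-double-layer kernel: each heart vertex carries a uniform dipole
layer over its barycentric patch (one third of incident triangle area, along
the outward vertex normal), contributing `A (n . r̂) / (4 pi sigma r^2)` at a
field point — the first-order solid-angle approximation of the layer
potential. Rows are sampled at the electrode nearest vertices and referenced
to the mean over the 8 electrode rows. The torso boundary is deliberately
ignored (unbounded-medium kernel): the resulting systematic error is absorbed
by the transfer-matrix uncertainty ΔL that the inversion estimates. Full
boundary-element correction is an extension point, not implemented.

Conductivity defaults to σ = 0.2 S/m (conventional lumped torso value; pure
scale factor). The 8 independent channels are {I, II, V1–V6}; III and the
augmented leads are derived algebraically (III = II − I, aVR = −(I+II)/2,
aVL = I − II/2, aVF = II − I/2), so Einthoven's identity holds to machine
precision on every derived record. Output amplitude carries a single global
gain (default 1) because the normalized source model has no absolute scale.

## Source dynamics

Excitation–recovery follows the two-variable Aliev–Panfilov-type system

    du/dt = div(D grad u) + k u (u − a)(1 − u) − u v
    dv/dt = −e (v + k u (u − a − 1)),

with u normalized TMP (rest 0, peak ≈ 1) and v the recovery variable.
Defaults k = 8, a = 0.15, e = 0.01 follow the phenomenological-model
literature; all are configuration, and θ = (k, a, e) is estimated by the
inversion. Diffusion is discretized with a cotangent-weighted surface
Laplacian (symmetric, negative semidefinite, zero row sums), harmonic-mean
diffusivity on region-crossing edges, normalized by the mean barycentric
vertex area so units are 1/ms. Time stepping is explicit Euler (Heun
available for convergence checks) with the stability bound
`dt <= 2 / (2 max|L_ii| + k)` (Gershgorin estimate of the diffusion spectrum
plus the reaction Lipschitz bound). Activation time is defined as the first
upward crossing of u = 0.5.

The linearized form augments the state with dummy co-states arranged in a
delay chain behind v (each block relaxes toward its predecessor at rate e),
ten blocks per node by default; the chain semantics is this package's
concrete choice for an otherwise open design, and the rest state remains an
exact fixed point of the augmented propagator.

## Coarse source model

Inversion from 8 channels is only meaningful on a drastically reduced source
space (~20 nodes). Fine heart vertices are clustered by k-means per region
(fixed seed 1905, deterministic), coarse lead-field columns are sums of member
columns (so spatially uniform TMPs project identically at both resolutions),
and the coarse diffusion operator is the Galerkin aggregation `P^T L P` of the
fine Laplacian rescaled by cluster sizes, with the zero-row-sum (no-flux)
property restored on the diagonal. On a ~20-node graph the effective
diffusivity needed for front propagation is much larger than tissue-scale
values; the default D = 50 mm²/ms was chosen once so that a single atrial
stimulus activates every atrial node within ~10 ms and the two-stimulus
protocol (atrial at t = 0, ventricular after a 120 ms AV delay standing in
for the His–Purkinje system) yields the physiological atrium-first sequence.

## Hierarchical Bayesian inversion

The state-space data model is

    x_{k+1} = F_theta(x_k) + w_k,      w ~ N(0, xi_w I)
    phi_k   = (L + DeltaL) u_k + z_k,  z ~ N(0, xi_z I)

with x = (u, v) and the observation touching only the u-block. The joint
posterior factorizes hierarchically as

    P(x, DeltaL, theta, xi_w, xi_z | phi) ∝
      P(phi | x, DeltaL, xi_z) P(x | theta, xi_w)
      P(DeltaL) P(xi_z) p(theta) P(xi_w),

sampled by blocked Gibbs:

- **Trajectory.** The default block linearizes the paced dynamics along a
  reference trajectory (tangent-linear maps accumulated through the
  integration substeps) and draws exactly from the resulting time-varying
  linear-Gaussian smoothing posterior by forward-filtering
  backward-sampling. The reference is the smoothed mean of the previous
  iteration (initially the deterministic paced rollout); using the mean, not
  the draw, prevents draw noise from re-entering the linearization. Two
  alternatives are exposed: a stochastic ensemble Kalman filter with
  perturbed observations plus a backward ensemble (RTS-form) smoother, and
  an exact FFBS on the rest-point linearized augmented propagator.
- **θ = (k, a, e).** Enters the dynamics nonlinearly, so each component is
  updated by Neal's slice sampler (stepping-out/shrinkage) on its full
  conditional.
- **ΔL.** Row-wise exact Gaussian conditional (ridge regression of the
  observation residual on the u trajectory).
- **Variances.** Conjugate inverse-gamma updates
  IG(shape + n/2, scale + SS/2). Gaussian priors are conjugate for θ-linear
  and ΔL blocks but not for variances, hence the inverse-gamma family here.

The pacing protocol enters the dynamics as a known exogenous input: the
inversion estimates the sources and parameters, not the beat onset. All
randomness flows from one seeded generator, so chains are bit-reproducible.

Numerical safeguards: ensemble members and trajectory draws are projected
onto the envelope [−0.5, 1.8] (the explicit cubic diverges far outside the
physiological range [0, 1]; the clamp almost never binds for well-posed
runs); filter covariances are symmetrized each step; Gaussian draws use an
eigenvalue square root robust to tiny negative eigenvalues; ensemble
collapse (spread < 1e−13) raises a degeneracy error suggesting inflation.

## Atrial extraction

Separation happens in TMP space: the atrial node block of the reconstructed
trajectory is projected through the atrial columns of L and the 12 leads are
derived. In posterior mode every stored trajectory draw is projected and the
pointwise median and central 90% band are reported (pointwise, not
simultaneous, quantiles — the simplest honest uncertainty display). The
additive decomposition atrial + ventricular = full ECG is exact by linearity.
Wave landmarks (P peak, Ta extremum after an 80 ms activation window) are
purely descriptive local-extremum reports.

## Synthetic data and what passing tests show

`make_experiment` builds everything from scratch: a two-lobe heart (two
closed ellipsoid components; vertices above the junction plane are atrial,
ties atrial) inside an ellipsoidal torso, electrodes at fixed fractional
(azimuth, height) coordinates, the fine and reduced lead fields, a
ground-truth TMP movie, and clean/noisy ECGs generated through a perturbed
transfer matrix L + ΔL* (ΔL* i.i.d. Gaussian, default sd = 5% of the RMS
lead-field entry). Measurement noise is set per channel from the stated SNR
(default 20 dB, RMS power ratio), with each channel's realization normalized
to the exact target power so the stated SNR is met sample-for-sample.

The ground truth is generated **on the coarse source model itself** with the
same dynamics the inversion uses, and by default without process noise — so
recovery experiments are exactly identified ("inverse crime" by design).
Passing them therefore demonstrates the correctness and internal consistency
of the machinery (forward physics, dynamics, samplers, end-to-end plumbing),
not robustness to the model misspecification, geometry error beyond ΔL, or
beat-to-beat variability of real recordings. Real ECGs also contain baseline
wander and powerline interference, which the preprocessing module (zero-phase
IIR notch Q = 30, zero-phase 4th-order Butterworth high-pass at 0.5 Hz in
second-order sections) addresses, and which the generator does not emulate.

## Recovery study conditions

The canonical experiment (`run_recovery_experiment`) uses the small bundle —
20 source nodes, 8 channels, one ~600 ms beat sampled at 500 Hz on the
observation grid (simulation dt 0.1 ms, 20 substeps per observation) — with
θ priors centred at the generating values (relative sd 15% for k and a, 25%
for e), the ΔL prior matched to the generating sd, and an informative
IG(10⁴, 10⁻³) prior on xi_w (mean 10⁻⁷). The xi_w prior is deliberately
tight and near zero because the synthetic truth realizes the deterministic
dynamics exactly: the process-noise term exists to absorb model error, and
its prior encodes that here there is essentially none. Looser xi_w priors
let linearization residuals at the stiff activation front inflate xi_w and
bias the stiffness parameter k upward. Chains run 2000 iterations with 500
burn-in; diagnostics report per-scalar ESS and split-R̂ (the slowly mixing k
component shows R̂ > 1.1 at this length; posterior means are nonetheless
stable across seeds, which the reproducibility tests check).

Problem sizes throughout (20 sources, ~300 observation samples, 2000
iterations, 20 000 sampler draws in the distributional checks) were chosen
once as the package's working resolution for single-CPU experiments.

## Known limitations

- Unbounded-medium lead field; no torso boundary correction (absorbed by ΔL).
- Scalar per-region diffusivity; no fiber anisotropy.
- Scalar (shared) xi_w and xi_z variances rather than per-node/per-channel.
- The trajectory block samples from a reference linearization, not the exact
  nonlinear smoothing posterior; near-front curvature can bias stiffness
  parameters when the process-noise prior is loose (see above).
- The pacing protocol is treated as known; beat detection from data is out
  of scope.
- WFDB input is not supported in this build; records enter via the CSV
  dialect.
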