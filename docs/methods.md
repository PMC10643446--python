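# Methods

This note records the models, algorithms, parameter choices and known
limitations of the `nonrad` package: a pipeline for simulating and
diagnosing non-radiative S1 → S0 decay in two-state model systems, and
for testing the "carbonyl-lock" trapping hypothesis — that stiffening
the gap-closing stretch (for peptide chromophores, the CO elongation,
e.g. by a strong hydrogen bond) blocks access to the S1/S0 conical
intersection and so traps an emissive excited state.

## Surface-hopping engine

The engine implements decoherence-corrected fewest-switches trajectory
surface hopping for two electronic states over analytic diabatic models.
Per nuclear step, the order of operations is: velocity-Verlet step of
the nuclei on the active adiabatic surface → re-diagonalization of the
2×2 diabatic matrix → electronic-amplitude propagation → decoherence
damping → stochastic hop attempt.

*Adiabatization.* The 2×2 diabatic matrix is diagonalized analytically.
Adiabatic gradients and the nonadiabatic coupling vector (NACV) use the
Hellmann–Feynman forms, exact for a 2×2 model:
g_i = u_iᵀ (∂V/∂R) u_i and d01 = u_0ᵀ (∂V/∂R) u_1 / (E1 − E0).
Eigenvector phases follow the previous frame (overlap kept
non-negative). The NACV denominator is floored at 1e-8 hartree; frames
where the floor engages are flagged in the trajectory metadata. Below
the 0.1 eV stop gap with the system still excited, hopping remains
governed by the fewest-switches probability — there is no forced hop.

*Electronic propagation.* The two amplitudes follow the time-dependent
Schrödinger equation in the adiabatic basis,
dc_j/dt = −i E_j c_j − Σ_i c_i (Ṙ·d_ij), integrated by RK4 over 20
substeps per nuclear step (configurable) with linear interpolation of
the energies and of the scalar coupling Ṙ·d01 between frame endpoints.
A mean-energy gauge shift (E_j → E_j − Ē) is applied during
integration; this is a pure global phase with no effect on populations,
coherences or hop probabilities, and it keeps the RK4 norm drift below
1e-10 per step on the benchmark systems (asserted ≤ 1e-8 in the tests).
The norm is restored once per nuclear step and the pre-renormalization
deviation is recorded.

*Hopping.* The hop probability out of the active state i is the
integral of −2 Re[c_i* c_j Ṙ·d_ij]/|c_i|², accumulated by the
rectangle rule over the electronic substeps and clamped to [0, 1]. The
printed form of this expression in the literature omits an explicit
real-part operator; only the Re(·) reading yields a real probability,
and the sign convention of d_ij must match the one used in the TDSE
coupling term (the engine uses the matched pair; mixing conventions
silently zeroes the hopping rate). One uniform draw per nuclear step
decides the hop. On an accepted hop the velocity is rescaled along the
NACV direction to conserve total energy; upward hops with insufficient
kinetic energy along the NACV are frustrated and leave the velocity
unchanged (reversal available behind a flag, off by default). After
decay, upward recrossing is forbidden (configurable), and the
trajectory terminates once the adiabatic gap drops below 0.1 eV on the
ground state, mirroring the usual production protocol (0.5 fs step,
250 fs horizon, vertical excitation to S1 from 300 K ground-state
sampling).

*Decoherence.* Inactive amplitudes are damped as exp(−Δt/τ) with
τ = (1/|ΔE|)(1 + C/E_kin), C = 0.1, and the active amplitude is rescaled
to restore the norm — the standard companion step, without which
population leaks. At zero kinetic energy the damping step is skipped
(τ → ∞ limit). Note that for scattering through a *single* crossing at
E_kin ≈ C the damping is not small during the passage itself and biases
final populations by ≈ 0.08; the exact-wavepacket validation therefore
runs with the correction disabled (its closed-form damping time is
tested separately), while bound-dynamics production runs keep it on.

*Validation.* On the 1-D single-avoided-crossing model (A = 0.01,
B = 1.6, C = 0.005, D = 1, mass 2000, all atomic units) at incoming
momentum k = 20 a.u., a 2000-trajectory swarm with initial conditions
drawn from the Wigner transform of the Gaussian wavepacket
(σ_x = 0.5 bohr, σ_p = 1/(2σ_x)) reproduces the exact split-operator
populations to ≈ 0.01–0.035 (acceptance band 0.05). The nuclear step
for this scattering benchmark is 2 a.u. (≈ 0.05 fs), converged against
0.5 a.u.

## Exact wavepacket oracle

The oracle propagates a two-component wavefunction on a uniform 1-D
grid in the *diabatic* representation: spectral kinetic half-steps and
an analytic 2×2 matrix-exponential potential step (Strang splitting).
Working diabatically avoids the NACV singularity at the crossing.
Adiabatic populations are projected only at analysis time, point by
point, and partitioned into transmitted/reflected by the sign of x.
Defaults: 2048 points on [−40, 40] bohr, dt = 0.5 a.u.; norm is
conserved to 1e-10, and doubling the grid changes the asymptotic
populations by < 1e-4. Guards reject wavepackets that reach the grid
edge or that are still inside the coupling region at analysis time.

## Model surfaces

All surfaces are analytic inventions validated by qualitative
properties, not fits.

*Single avoided crossing* (engine validation): the standard scattering
form above.

*Gap-closing ("carbonyl-lock") model*: 2–3 coordinates in hartree
atomic units.

| parameter | default | meaning |
|---|---|---|
| r0, k_r, m_r | 2.3 bohr, 0.08 Eh/a0², 6.86 amu | gap-closing stretch (≈ 560 cm⁻¹) |
| q0, k_q, m_q | 0, 0.34 Eh/a0², 1 amu | proton-transfer coordinate (≈ 3000 cm⁻¹) |
| s0, k_s, m_s | 0, 0.2 Eh/a0², 3 amu | uncoupled spectator (optional, on by default) |
| gap0 | 0.147 Eh (4.0 eV) | vertical gap at equilibrium |
| slope_r | 0.085 Eh/a0 | gap-closing rate along r |
| couple_q | 0.03 Eh/a0 | gap modulation by q |
| v12 | 0.004 Eh | diabatic coupling (constant; Gaussian-damped option) |
| k_lock | 0 | harmonic stiffening of r added to both diabats |

V11 is a sum of harmonic wells; V22 = V11 + gap0 − slope_r(r−r0)
− couple_q(q0−q); the lock ½k_lock(r−r0)² enters both states, so it
stiffens the stretch without shifting the vertical gap — the minimal
representation of a strong local interaction that blocks large
elongations. The diabatic seam sits at r−r0 = gap0/slope_r ≈ 1.73 bohr
(for q = q0), where the adiabatic gap equals 2·v12. An energy argument
gives the critical lock ≈ 2·slope_r²/gap0 − k_r ≈ 0.018 Eh/a0²: above
it a vertically excited trajectory started from the minimum cannot
classically reach the seam. The lock family used throughout is
{none: 0, weak: 0.02, strong: 0.04}, giving 250 fs decay fractions of
≈ 1.0, ≈ 0.75 and ≈ 0.03–0.06 — a free, an intermediate and a trapped
(fluorescent-regime) variant.

The stretch is deliberately *softer* than a literal CO stretch
(≈ 560 cm⁻¹ rather than ≈ 1700 cm⁻¹): the pipeline's constraint
experiments use harmonic biases of order 100 kcal/mol/Å²
(≈ 0.045 Eh/a0²), and all scales — 300 K sampling, the 250 fs horizon,
the bias stiffness — must act on one energy scale for the trapping
mechanism to be visible at desk scale. Consequences: crossing-point
elongations (≈ 0.9 Å) are larger than molecular CO displacements, and
decay-time distributions stretch over tens of femtoseconds rather than
single periods of a real CO mode.

*Thermal sampling.* Ground-state initial conditions come from BAOAB
Langevin dynamics on the lower adiabatic surface at 300 K, friction
20 ps⁻¹ (underdamped for every mode yet fast enough that single-chain
energies decorrelate within the 100 fs sampling stride), 1 ps burn-in,
0.5 fs step. Vertical excitation sets the active state to S1 with
amplitudes (0, 1).

*Harmonic restraint unit caveat.* Restraint constants are exposed in
kcal/mol/Å² (kcal/mol/rad² for angles). Printed values of such
constants sometimes appear as "kcal/mol·Å", which is dimensionally a
force, not a stiffness; this package always means the quadratic-form
constant.

## Mock amide-dimer generator

A 12-atom cyclic formamide-like dimer (two N–H···O bonds of 1.90 Å,
N···O 2.91 Å) serves as the Cartesian test bed for the
relaxation-coordinate estimator. Internal-coordinate time series are
mapped onto the fixed reference by displacing only the atoms of each
coordinate along the Moore–Penrose direction g/|g|² of its Cartesian
gradient, so a displacement value v changes the coordinate by v to
first order and the planted Cartesian decay direction g/|g| is known
exactly.

The decay mode (the CO stretch of molecule A by default) starts
0.15 Å below the diabatic seam and drifts linearly at a rate set by its
amplitude, plus white noise (σ = 0.05 Å); the signed diabatic gap is
linear in the decay displacement, 4 eV at the start and zero at the
seam, and the active state flips at the first frame the signed gap
drops below 0.1 eV. Spectators (the CO stretch and amide improper
dihedral of molecule B) fluctuate as i.i.d. noise. The generator
emulates the statistical structure of excited-state ensembles — a
gap-correlated collective drift buried in thermal fluctuation — but
not their dynamics: no inertia or mode coupling, white rather than
vibrationally colored noise, a planar geometry, and a decay coordinate
that stays displaced after the crossing (a transfer-type event, like a
proton transfer, rather than a stretch that recoils). Passing the
recovery tests therefore demonstrates that the estimator separates
gap-correlated drift from noise of realistic relative magnitude — not
that it resolves anharmonic or strongly coupled relaxation pathways in
real trajectories.

## Relaxation-coordinate estimator

For pooled frames x(t) with signed diabatic gap ΔE_D(t),

  c_i = ⟨ f_i · Sign[−ΔE_D] · w ⟩ / sqrt(⟨f_i²⟩ ⟨w²⟩),
  w = exp(−|ΔE_D| / (α k T)),

with f_i the centered fluctuation of Cartesian coordinate i, α = 100,
T = 300 K and k in eV/K (so α·kT ≈ 2.59 eV). The diabatic gap is the
adiabatic one with state identities swapped from the first-crossing
frame on (the exact-crossing frame belongs to the swapped side); the
sign term orients c from excited-state toward ground-state
configurations, and the Arrhenius-like weight concentrates the average
on near-degeneracy frames. Each component is a weighted correlation,
hence |c_i| ≤ 1 (Cauchy–Schwarz); coordinates with fluctuation variance
below 1e-12 Å² get c_i = 0 (the 0/0 convention for frozen coordinates).

Choices where usage is genuinely open:

- *Frames admitted*: every frame of each decaying trajectory, both
  sides of the crossing — the sign term needs both sides to define a
  direction. Non-decaying trajectories are excluded by default
  (include_nondecaying admits them with an unswapped gap). A windowed
  average around the crossing is available through pre-slicing the
  trajectories.
- *Alignment*: each pooled frame is Kabsch-superposed onto the pooled
  mean (one fixed-point iteration) before fluctuations are taken; off
  by flag. For drift-free inputs aligned and unaligned vectors agree in
  direction to ~1e-8 in cosine, but components of *exactly frozen*
  coordinates (the out-of-plane direction of the planar mock dimer) can
  pick up second-order rotation noise that the per-component
  normalization then amplifies; with alignment off they are exactly
  zero. Interpret near-zero-variance components with alignment on
  accordingly.
- *No mass weighting* by default (the estimator is defined on bare
  Cartesian fluctuations); a mass-weighted variant sits behind a flag.
- α-stability: doubling α changes the planted-mode cosine by < 0.05 on
  the standard fixture.

Projections onto named internal coordinates are signed normalized inner
products between the unit relaxation vector and each coordinate's unit
Cartesian gradient at a reference structure, with relative shares over
the requested set.

## Ensemble statistics

*Crossing frames.* The crossing (CoIn proxy) of a decayed trajectory is
the first frame near the S1→S0 passage with adiabatic gap < 0.1 eV; if
coarse stepping jumped over the criterion, the hop frame is used and
flagged. The threshold must be below the vertical gap at excitation.

*Ensembles.* S1 = excited-state frames strictly before the crossing;
S0 = post-decay frames or externally supplied ground-state sampling;
CoIn = crossing frames. Histograms share binning across ensembles.

*D statistic.* D = (mean_CoIn − mean_S1)/sd_S1 with the population
standard deviation (sample-sd switchable). D is invariant under affine
rescaling applied jointly to both samples. On the lock family D rises
from the weak (≈ 1.4) to the strong (≈ 1.5) variant: the stiffer the
lock, the rarer the elongation required to cross. The unlocked variant
is excluded from this comparison by design: it decays ballistically on
the first seam approach (~20 fs), so its "excited-state distribution"
is a truncated ramp rather than an established ensemble and the
statistic does not describe fluctuation rarity there. The weak/strong
contrast at model scale is real but modest; in molecular systems the
trapped species also *reshapes* its excited-state displacement, a
second effect the symmetric stiffening deliberately does not model.

*Variance hierarchy.* Var(Y_i^j) is the variance of measured DoF i over
pooled excited-state frames of a swarm constrained along DoF j. Two
conventions are reported side by side and never merged: the percent
reduction (V0 − Vj)/V0, and the printed normalized-variance form
1 − [Var(Y_i^j) − Var(Y_i^0)]/Var(Y_i^0), which equals 1 + reduction
and hence ranges up to 2. On the standard model the reduction matrix is
diagonal-dominant: each constraint suppresses its own coordinate most
(self-reduction ≈ 0.44 for the gap mode at 100 kcal/mol/Å²), and only
the gap-mode constraint suppresses decay (paired one-sided p ≪ 0.01;
spectator constraint indistinguishable from baseline).

*Paired decay test.* Constraint effects are tested on seed-paired
swarms with an exact one-sided McNemar-style binomial test on the
discordant pairs.

## Numerical conventions

Hartree atomic units internally (1 Eh = 27.211386 eV,
1 a0 = 0.529177 Å, 1 a.u. time = 0.02418884 fs); fs/Å/eV at all
interfaces. Seeds: swarm member k runs with base_seed + k; every output
file embeds the seed and a configuration hash. Problem sizes used by
the tests and the acceptance script — 2000 scattering trajectories,
200-trajectory swarms per lock value (600 for the strong-lock D
statistic), 50 mock-dimer trajectories of 500 frames (100 000 pooled
frames for the null-coordinate bound) — were chosen so each check has
clear statistical power at interactive runtimes.

## Known limitations

- Two electronic states only; no spin–orbit/intersystem crossing
  channels, no geometry-dependent coupling by default, no ab initio
  interfaces.
- The exact oracle is 1-D; the 2–3-D lock model is validated by
  properties (monotonicity, constraint specificity, seam identities),
  not by exact dynamics.
- Fixed-momentum observations about real peptides (specific bond
  lengths, hydrogen-bond networks) are outside what these toy surfaces
  can reproduce; the pipeline demonstrates the *mechanism* and the
  *method*, and reads externally supplied trajectories in the
  documented extended-XYZ + TSV schema for real-data analysis.
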