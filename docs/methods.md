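# Methods

## Model

The aggregate is a set of N two-level chromophores with a Frenkel-exciton
Hamiltonian: fluctuating site energies ε_n(t) on the diagonal, static
excitonic couplings J_nm off the diagonal, and fixed transition dipoles
μ_n (the Condon approximation).  A segmentation assigns every site to
exactly one segment; intra-segment blocks are treated fully coherently,
while inter-segment blocks enter only through an incoherent rate
description.  The segmentation is the user's modelling decision;
`segmentation_report` summarizes intra- versus inter-segment coupling
scales to support it (the intended regime is inter-segment couplings much
smaller than intra-segment ones, e.g. 10 vs several hundred cm⁻¹).

Units follow spectroscopic convention throughout: energies and couplings
in cm⁻¹, times in fs, kinetic rates in ps⁻¹, temperature in kelvin with
kB = 0.695035 cm⁻¹/K.  Quantum phases accumulate as 2πc·E·t with
c = 2.9979×10⁻⁵ cm/fs.

## Bath

Each site energy is an independent stationary Ornstein–Uhlenbeck process
with standard deviation σ (cm⁻¹) and correlation time Λ⁻¹ (fs):
⟨δε(t) δε(0)⟩ = σ² e^(−Λt).  The discrete update is the exact OU
transition kernel, ε(t+dt) = m + (ε(t)−m) e^(−Λdt) + σ√(1−e^(−2Λdt)) ξ,
so the sampled statistics are independent of the time step; each site
consumes its own random stream spawned from the master seed, making a
site's trace independent of how many other sites exist.  This classical
bath has no back-reaction: emission is not Stokes-shifted, and the
high-temperature (HT) limit is its natural regime.  Coupling fluctuations
are not modelled — in rigid multichromophoric structures they are an order
of magnitude smaller than energy fluctuations.

## Propagation

One- and two-exciton propagators are time-ordered products of per-frame
steps.  The default step is the exact exponential of the frozen frame
Hamiltonian via batched eigendecomposition; a symmetric split-step
alternative, exp(−i·diag·dt/2)·exp(−iJdt)·exp(−i·diag·dt/2) with the
static coupling exponential precomputed once, is second order in dt
(halving dt reduces the error ≈4×, verified) and cheaper for large
segments.  Propagators are unitary products of unitaries; unitarity and
the composition property hold to rounding error.

The two-exciton basis is, by default, the *strict* hard-core basis of site
pairs m<n with dimension N(N−1)/2 — electronic two-level molecules have no
doubly excited site, and a single two-level site has an empty two-exciton
manifold, making the excited-state absorption vanish identically.  A
bosonic-counting variant (m≤n, dimension N(N+1)/2) with a configurable
on-site anharmonic shift Δ and √2 factors on same-site elements is
provided for compatibility with conventions that count N(N+1)/2 doubly
excited states.  The two-exciton Hamiltonian construction is pinned
against a brute-force restriction of the full 2^N Fock-space Hamiltonian.

## Doorway and window functions

The third-order response factorizes over the three pulse delays.  The
doorway D_{αβ}(t1) = ⟨μ_β†U^ee(t1)μ_α⟩ is shared by all three diagram
classes; the rephasing doorway is its complex conjugate.  Windows are
pathway-independent: GB is the same contraction as the doorway; SE inserts
the segment equilibrium density ρ^eq; EA contracts one- and two-exciton
propagators with the e→f dipoles and carries the overall minus sign.  At
t=0 all tables reduce to analytic dipole contractions, asserted to 1e−10.

Ensemble averages run over starting points placed equidistantly along one
long trajectory (default spacing: one coherence window).  Doorway and
window averages use separate trajectory stretches (seeds spawned from the
master seed) — justified when t2 is long against the bath memory — except
in oracle comparisons, where both paths deliberately share one trajectory
to cancel Monte-Carlo variance.

ρ^eq is I/D exactly in the HT limit.  At finite temperature it is the
per-frame Boltzmann operator of the instantaneous segment Hamiltonian; the
default export averages the operator over the trajectory and normalizes by
the trajectory-averaged trace (unit trace by construction).  A per-frame
normalized variant is available (`normalization="frame"`); the averaging
order is a genuinely open choice and the ensemble-trace convention follows
the trajectory-average reading most literally.  The segment energy E_S is
the trajectory average of the per-frame thermal expectation of the
instantaneous exciton eigenvalues (equal weights in the HT limit).

The single-site lineshape check closes the loop on all bath and
propagation conventions at once: the ensemble-averaged |D(t)| of one OU
site must follow the cumulant e^(−g(t)) with
g(t) = (σ_ang/Λ)²(e^(−Λt) − 1 + Λt), σ_ang = 2πc·σ.

## Kinetics

The rate matrix K (ps⁻¹) acts on column population vectors with
column-sum-zero convention: K[j,i] ≥ 0 is the rate from segment i into j.
Rates are *inputs* — supplied by the user, loaded from a file, or taken
from the built-in fixtures — not derived from the Hamiltonian; deriving
multichromophoric transfer rates is a separate problem outside this
package.  T(t2) = exp(Kt2) is computed by eigendecomposition with a
scaling-and-squaring fallback for ill-conditioned eigenbases, and is
column-stochastic with the semigroup property.

Detailed balance is imposed pairwise while preserving every forward+
backward rate sum: k(i→j)/k(j→i) = (D_j/D_i)·e^(−βΔẼ) with Ẽ the
ΔE-adjusted segment energies and D the segment site counts.  The
degeneracy factor matters: high-temperature rate matrices already carry
the acceptor-size ratio (the 18-fold B850/B800 asymmetry), and the β = 0
correction must — and does — leave such a matrix unchanged.  For
equal-size segments the form reduces to the symmetric logistic split, and
for equal energies the rates pass through untouched.  The stationary state
of a corrected matrix is the degeneracy-weighted Boltzmann distribution
∝ D·e^(−βẼ).  The adjustment ΔE_S = kBT ln(N·P_S/D_S) shifts segment
energies toward target equilibrium populations P and vanishes when P is
the HT equilibrium D/N.

The ten-segment LH2 fixture encodes the elementary rates 0.775/0.0431
(HT) or 1.48/1.29×10⁻³ (RT) ps⁻¹ between each B800 site and the B850
segment plus 1.83 ps⁻¹ between neighbouring B800 sites; its inter-ring
relaxation eigenvalues are 1.163 and 1.492 ps⁻¹ and the HT stationary
B850-to-B800 ratio is 18.  The two-segment dimer rate fixture is
synthetic: a forward+backward sum of 0.1 ps⁻¹ (HT: symmetric; RT:
thermally corrected across the 500 cm⁻¹ gap at 300 K, giving an ~11-fold
downhill preference) chosen to put equilibration on the tens-of-ps scale
where cross-peak growth is cleanly resolvable.

## Spectra

The orientational weights are the closed-form isotropic four-point
averages for the all-parallel (ZZZZ) and crossed (ZZXX) lab sequences;
each has exactly 21 nonzero Cartesian components.  They are verified, not
trusted: an SO(3) quadrature oracle (Gauss–Legendre × trapezoid over Euler
angles, exact for the degree-4 integrand) reproduces them to machine
precision, and a Monte-Carlo random-rotation estimate converges to them at
the expected 1/√n rate.

Response assembly contracts doorways, the transfer map and windows over
segments and Cartesian indices.  The GB diagram applies T(t2) by default
(the literal summation); an identity kernel is selectable
(`gb_kernel="identity"`) since a ground-state hole does not physically
transfer — for the fixtures studied here the difference appears only in
multi-segment GB cross terms.

The double Fourier transform demodulates the response at a rotating-frame
carrier before the FFT (electronic transitions near 12000 cm⁻¹ exceed the
8339 cm⁻¹ Nyquist range of a 2 fs grid), transforms the rephasing pathway
with the opposite ω1 sign so both pathways share a positive excitation
axis, half-weights the first time points, applies a squared-cosine taper,
and zero-pads 4× by default.  The absorptive spectrum is the real part of
the pathway sum; raw arrays are always retained and normalization (to unit
peak) is recorded in metadata.

Cross-peak kinetics box-integrates the absorptive spectrum over a (ω1, ω3)
rectangle per waiting time and fits A(1−e^(−k·t2)) + C.  Because every
element of a 2×2 transfer map shares the single relaxation constant
k_f + k_b, the fitted rate matches the rate-matrix eigenvalue essentially
exactly for the dimer — the method's kinetics–spectroscopy consistency
check.  Anisotropy is r = (I∥ − I⊥)/(I∥ + 2I⊥) elementwise, 0.4 for a
fixed dipole, with vanishing denominators flagged as NaN.

## Validation oracle

`full_2des_small` evaluates all six double-sided diagrams of the full,
unsegmented system (≤ 4 sites) by explicit one- and two-exciton
propagation through t1, t2 and t3 — no factorization, no equilibration
assumption, HT dynamics.  Shared-noise comparison with the coarse-grained
path on the single-segment dimer (σ = 198 cm⁻¹, Λ⁻¹ = 220 fs, J = 100
cm⁻¹) at a waiting time long past the bath memory agrees to an RMS
difference below 0.5% of the normalized peak at 600 realizations — far
inside the 5% agreement band expected at these statistics.

The oracle also makes the method's limitations measurable rather than
anecdotal: at t2 = 0 the full response retains inter-site coherence and
cross-bleach pathways between segments that population-only
coarse-graining drops (for two identical uncoupled bright sites they
exactly double the t=0 amplitude), and the factorized doorway–window
product is only valid once t2 exceeds the bath memory.  Both statements
are asserted in the test suite.

## Problem sizes and defaults

Desk-scale defaults are deliberately far below production scale:
trajectories of ~10⁴–10⁵ frames and 10²–10³ realizations against ~10⁷
frames and 10⁵ realizations for publication-quality surfaces.  All
statistical tests are tolerance-based, with tolerances set from the
standard error at the default realization counts.  Defaults: dt = 2 fs,
128-point coherence grids (254 fs), squared-cosine apodization, 4×
zero-padding, strict two-exciton basis, Δ = 0.

Doorway/window tables depend on everything except the waiting-time list,
so the pipeline caches them under a configuration hash; adding waiting
times reuses the cache and costs only a transfer map and an FFT per t2.
All outputs embed the configuration hash, and all randomness flows from
one master seed.

## Known limitations

- No intra-segment relaxation during t2: each segment is assumed
  instantly equilibrated, so single-segment spectra are exactly
  t2-independent and short-waiting-time lineshape evolution is absent.
- Inter-segment coherence pathways are dropped (see the oracle section);
  spectra at t2 ≲ bath memory are qualitative.
- No Stokes shift in emission; the bath does not respond to excitation.
- The classical-trajectory propagation is a high-temperature formalism;
  finite-temperature effects enter only through ρ^eq, the segment
  energies and the rate-matrix correction.
- The two-ring fixture is a geometric surrogate (tangential dipoles,
  point dipole–dipole couplings rescaled to the stated nearest-neighbour
  values), not a structure-derived Hamiltonian; it reproduces topology
  and coupling scales, not detailed exciton wavefunctions.
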