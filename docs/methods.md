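# Methods

`gafdyn` turns per-residue solid-state NMR dynamics observables — dipolar
order parameters and 15N relaxation rates — into motional parameters for
membrane-protein helices, and provides the trajectory observables used to
relate those motions to function. This note records the models, the
numerical choices, and what the synthetic-data tests do and do not show.

## Observables and their forward models

**Dipolar order parameters.** S = D_expt / D_rigid, the ratio of the
motionally averaged dipolar coupling to its rigid limit
D_rigid = (mu0/4pi) |gamma1 gamma2| hbar / (2 pi r^3). Default bond lengths:
r(Ca-Ha) = 1.10 A (D_rigid ~ 22.70 kHz), r(N-Ca) = 1.46 A (~984 Hz),
r(N-H) = 1.02 A (~11.48 kHz). S = 1 means rigid; 0 means isotropically
averaged.

**TEDOR buildup.** The 15N-13Ca coupling is read from a z-filtered TEDOR
buildup of Ca nucleus *i* coupled to two 15N spins:

    S_i(t) = Lambda_i {1 - J0(sqrt(2) D_i1 t)^2} {1 + J0(sqrt(2) D_i2 t)^2},
    Lambda_i = 2^-N_i V_i(0) lambda_i exp(-Gamma_i t),   N_i = 2,

with D in Hz and t in seconds. The signal vanishes identically at t = 0 and
is bounded by 2 Lambda_i. V_i(0) and lambda_i enter only through their
product, so the fit estimates the product amplitude and splits it against a
caller-supplied reference V0; four effective parameters are fitted
(amplitude, Gamma, D1, D2) by weighted least squares with ten log-spaced D1
starts in [100 Hz, 2 x rigid limit], because the Bessel oscillations create
local minima. The default mixing schedule is the 12-point series
0.57-16.57 ms.

**Relaxation decays.** Spinlock: M(t) = M0 exp(-t R1rho) on the 16-point
0-220 ms schedule. Inversion recovery: M(t) = M0 (1 - 2 exp(-t R1)) on the
6-point 0-32 s schedule. 95% intervals come from a parametric residual
Monte-Carlo: the residual scale is estimated with the n-2 degrees-of-freedom
correction, each of 200 replicates draws its own scale from the scaled
inverse-chi-square law (this reproduces t-like widths, which matters at a
6-point schedule), synthetic curves are refitted with a vectorized
Levenberg-Marquardt, and the 2.5/97.5 percentiles are reported. Empirical
coverage at 2% noise is ~94-96%. Note that a calibrated 95% interval at 2%
noise on the spinlock schedule cannot be narrower than ~10.7% of the rate
(Cramer-Rao); interval widths near that bound are correct, not loose.

## Rate model and SMF inversion

The solid-sample spectral density is

    J(w) = (2/5) (1 - S^2) tau_c / (1 + (w tau_c)^2),

which vanishes in the rigid limit (no overall tumbling in a solid). With
delta_NH = 2 pi D_rigid(N-H) and delta_CSA the reduced axially symmetric
15N CSA (default -170 ppm, configurable; the value is a standard backbone
amide choice and must be recorded with any fit):

    R1      = (3/4)(delta_CSA w_N)^2 J(w_N)
              + (delta_NH^2/4)[J(w_H - w_N) + 3 J(w_N) + 6 J(w_H + w_N)]
    R1rho   = R1/2 + R1rho_CSA + R1rho_NH,

where the rotating-frame terms sample J at w1 +/- wr and w1 +/- 2 wr with
weights 2/3 and 1/3 (MAS sideband pattern) and the N-H term adds 3 J(w_H).
Default conditions: 800 MHz proton frequency (15N derived via the
gyromagnetic ratio), 40 kHz MAS, 10 kHz spinlock. A guard warns within
500 Hz of the rotary-resonance conditions w1 = wr, 2 wr, where this
perturbative rate expression loses meaning.

**SMF inversion** scans chi^2(S^2, tau_c) — weighted squared residuals of
the two rates — on a 200 x 200 grid, linear in S^2 over [0, 1] and
log-spaced in tau_c over [10 ps, 10 ms]. All local minima are reported
ranked by chi^2, using a watershed pass with persistence merging (basins
shallower than chi^2 = 1 are absorbed), because the surface is generically
bimodal: a tens-of-ns branch and a slow branch above ~100 us. On the slow
branch all sampled frequencies satisfy w tau >> 1, so both rates depend
only on (1 - S^2)/tau_c and the branch is a one-dimensional degeneracy
valley; its reported representative is one point on that valley, and the
identifiable quantity is the ratio. Zero measured rates return the S^2 = 1
solution flagged as timescale-unidentifiable; a best chi^2 above 10 flags
"no-SMF-solution".

## The 3D GAF model

A secondary-structure segment is treated as a rigid body whose orientation
fluctuates about three orthogonal axes attached to each peptide plane with
independent Gaussian amplitudes (sigma_alpha, sigma_beta, sigma_gamma) and
one timescale tau_c. The squared order parameter of interaction vectors
mu, nu with frame spherical coordinates e_mu, e_nu is the quintuple Wigner
sum over l, k, k', m, m' in -2..2:

    S2_mu_nu = (4pi/5) sum (-i)^(k-k')
               exp[-sig_a^2(k^2+k'^2)/2 - sig_b^2 l^2 - sig_g^2(m^2+m'^2)/2]
               d2_kl(pi/2) d2_k'l(pi/2) d2_mk(pi/2) d2_m'k'(pi/2)
               Y_2m(e_mu) Y*_2m'(e_nu).

This closed form is the exact orientational average of the composition
R = R_y(b) R_x(a) R_z(c) with (alpha, beta, gamma) = (x, y, z): the
gamma-rotation acts innermost, beta outermost. The identification was made
against Gauss-Hermite quadrature of candidate compositions (agreement at
machine precision for the stated one, ~1e-3 discrepancies for the
alternatives) and the Monte-Carlo cross-check (`gaf_s2_monte_carlo`)
samples exactly that composition. Implementation-wise the sum factorizes
through a 5x5 coefficient matrix per (sigma_alpha, sigma_gamma), making
grid screening over all sigma combinations a set of small einsums.
Axis-relabel symmetry holds only to the small-angle commutation error of
the composition (~1e-3 at 25 degrees), which is also the scale of the
closed-form-vs-sampling agreement.

**Frames.** For residue i: gamma along Ca(i) -> Ca(i+1); beta is the
peptide-plane normal (from C(i), O(i), N(i+1)) orthogonalised against
gamma; alpha completes the right-handed triad. Note that in an ideal
alpha-helix this gamma axis sits ~66 degrees from the global helix axis
(1.5 A rise vs ~3.8 A Ca-Ca step) — the frame is peptide-plane-attached,
not helix-axis-attached. The two adjustment angles rotate the triad about
its alpha axis by delta_theta and about its gamma axis by delta_phi; this
two-angle reorientation is one consistent reading of a frame adjustment
that is not known a priori, and it is isolated in the frame builder. The
15N CSA symmetry axis is placed in the amide plane tilted 17 degrees
(configurable) from N-H towards the preceding carbonyl.

**Predictions.** S_CaHa = sqrt of the Ca-Ha auto term; R1 and R1rho use
the N-H dipole auto term inside the dipolar spectral densities and the CSA
axis auto term inside the CSA ones. Amplitudes alone fix S_CaHa; tau_c
enters only the rates.

**Fit.** The reduced chi^2 sums three branches — squared Ca-Ha order
parameters, R1rho, R1 — over the residues carrying each observable,
divided by (N1 + N2 + N3 - p - 1) with p = 6. The S-branch compares
squared order parameters; its denominator uses the propagated uncertainty
of S^2, sigma(S^2) = 2 S sigma(S), so that all three branches are
unit-variance under the stated errors (weighting a residual in S^2 by the
error of S would make that branch ~4 S^2 times over-weighted). Search:
full grid over sigmas in [0, 25 deg] step 2.5, tau_c log-spaced over
[1 ns, 10 us] (25 points), delta angles in [-30, 30 deg] step 15; then
Nelder-Mead refinement from the five best nodes with sigmas clipped to
[0, 45 deg] and deltas to the grid range. Ties in chi^2 break towards the
smallest total sigma^2 (parsimony). Everything is deterministic given the
options. Parameter intervals (`gaf_uncertainty`) come from resampling the
observables by their stated errors and refitting from the converged point;
68% percentile intervals, bit-reproducible per seed.

## What the synthetic data shows — and a known identifiability limit

The generators produce exactly what the pipeline consumes: TEDOR curves
and exponential decays from the forward models with Gaussian noise
(defaults 5% of the curve maximum and of M0); an ideal alpha-helix
(phi = -57, psi = -47, standard internal coordinates, NeRF-built, L-configured)
with {S_CaHa, R1, R1rho} computed from a known GAF truth plus 2%/5%
relative noise; a rigid helix rocking by two independent stationary
Ornstein-Uhlenbeck angle processes about axes perpendicular to the helix,
pivoted one helix length below the base (a membrane-anchored lever, so
residue displacements are collective rather than anti-correlated about a
mid-helix node), plus optional per-atom jitter; and piecewise-smooth water
z-paths realising scheduled slab crossings and same-side excursions
exactly. Every generator is a pure function of its arguments including the
seed, and writes its truth JSON next to the data.

Round trips on this data verify: TEDOR D1 to 0.1% noiseless and ~2-5% at
5% noise; rates to 4+ digits noiseless with calibrated CIs; SMF branch
detection; DCC limits (rigid translation = 1, independent noise ~ 0,
rocking > 0.9 at windows far above the correlation time, with the 1-ns vs
80-ns window contrast reproduced when jitter is added); rocking-SD
recovery within a few percent once the frame-0 anchor bias is removed (the
reference axis is itself a draw from the rocking distribution, so
E[angle^2] = 2 sigma^2 + delta_anchor^2 — the estimator subtracts the
anchor term); and exact permeation counting.

**The GAF amplitude limit.** An ideal helix is screw-symmetric: every
residue presents *identical* interaction-vector geometry in its own
peptide-plane frame, so the per-residue observable set collapses to three
independent numbers while the model has six parameters. tau_c remains
well determined (the R1rho/R1 ratio pins it; recovered within ~2%), and
the fit quality behaves as expected (chi2_red ~ 1 at nominal noise), but
(delta_theta, delta_phi) act as a near-exact gauge freedom that
redistributes amplitude among the sigmas: the noiseless chi^2 global
minimum is exactly at the truth, yet the surrounding manifold is flat to
~1e-7 of the noise scale, so at realistic noise the fitted sigmas slide
along it (mean absolute deviation ~3-5 degrees from the generating
values). This is a property of the synthetic source, not of the fit: real
helices have varied local geometry that breaks the symmetry and restores
leverage on the amplitudes. Passing amplitude-recovery tests on an ideal
helix is therefore not attainable, and results on real structures should
be read with per-segment geometry variation in mind.

Features of real data the generators do not emulate: chemical-shift
overlap and peak-picking errors, coherent 1H-1H contributions (suppressed
experimentally by deuteration and fast MAS), non-Gaussian noise, lipid and
water dynamics, and periodic-boundary effects (a guard rejects wrapped
trajectories rather than unwrapping them).

## Trajectory observables

DCC uses one atom per residue (CA), non-overlapping windows with
per-window mean removal — the windowed variant is what distinguishes
short- from long-interval correlation — and averages the per-window maps;
zero-variance atoms are masked as undefined rather than propagating NaN.
Helix orientation is the principal CA direction per frame, sign-fixed by
continuity. Permeation scoring is a two-state machine per molecule: an
event requires entering the slab through one boundary and next leaving
through the other. H-bond criteria default to donor-acceptor < 3.5 A and
donor-H-acceptor > 150 degrees (geometric conventions; configurable);
partner frequency counts distinct identities ever bound, per unit time.

## Problem sizes and defaults

Defaults are chosen so the full test suite and the acceptance script run
in a few minutes: 20-residue helices, 10 recovery seeds, 2e5 Monte-Carlo
rotations per order-parameter check, 500 CI-calibration repeats,
2000-10000-frame trajectories. Noise defaults (2% on order parameters, 5%
on rates and intensities) mirror typical experimental error-bar
magnitudes for well-resolved solid-state spectra. All randomness flows
through explicit integer seeds; default 0.
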