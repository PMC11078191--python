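# gafdyn

Solid-state NMR analysis of collective protein dynamics: from raw
per-residue buildup/decay curves to dipolar order parameters and 15N
relaxation rates, through simple-model-free timescale estimation, to
three-dimensional Gaussian-axial-fluctuation (3D GAF) fitting of
concerted helix motions — plus the trajectory observables (dynamic
cross-correlation, helix rocking, water permeation, hydrogen-bond
occupancy) used to connect those motions to function in a water channel.

It is written for spectroscopists and simulators who have per-peak
intensity tables (no spectral processing happens here) and want motional
amplitudes and timescales with honest uncertainties, and it ships
synthetic-data generators with known ground truth so every stage is
testable without any experimental download.

## The models in brief

- **Order parameters**: S = D_expt / D_rigid with
  D_rigid = (mu0/4pi) |gamma1 gamma2| hbar / (2 pi r^3)
  (r(CaHa) = 1.10 A, r(NCa) = 1.46 A by default).
- **TEDOR buildup** for the N-Ca coupling of a three-spin N-Ca-N system:
  S_i(t) = Lambda_i {1 - J0(sqrt2 D_i1 t)^2}{1 + J0(sqrt2 D_i2 t)^2},
  Lambda_i = 2^-N V0 lambda exp(-Gamma t).
- **Relaxation**: M(t) = M0 e^(-t R1rho) (spinlock) and
  M(t) = M0 (1 - 2 e^(-t R1)) (inversion recovery); rates map to motion
  through the solid-sample spectral density
  J(w) = (2/5)(1 - S^2) tau_c / (1 + (w tau_c)^2) evaluated at the Larmor,
  spinlock and MAS sideband frequencies.
- **3D GAF**: rigid-body rocking of a helix segment about peptide-plane
  axes with Gaussian amplitudes (sigma_alpha, sigma_beta, sigma_gamma) and
  one timescale tau_c; the squared order parameter is a quintuple Wigner
  sum over second-rank indices, and six parameters (three sigmas, tau_c,
  two frame-adjustment angles) are screened against {S_CaHa, R1, R1rho}
  simultaneously with a reduced chi^2.

See `docs/methods.md` for the full account, including numerical choices
and a documented identifiability limit of ideal-helix synthetic data.

## Worked example

The `analysis/` scripts run the whole pipeline on synthetic ground truth
(each is a thin driver over the `gafdyn` library; outputs land in
`results/`):

```sh
python analysis/01_simulate_inputs.py
python analysis/02_fit_tedor.py
python analysis/03_fit_relaxation.py
python analysis/04_smf_timescales.py
python analysis/05_fit_gaf.py
python analysis/06_trajectory_observables.py
```

Representative output (seed 0):

```
fitted D1 = 976.1 Hz (truth 985, error 0.9%), S_NCa = 0.992
R1rho = 5.28 /s  (95% CI 5.005-5.534)
R1 = 0.03004 /s  (95% CI 0.02935-0.03082)
19 residues analysed; 19 show multiple branches
top-branch tau_c median = 63 ns (range 57-63 ns)
fitted sigma = [8.6, 13.4, 0.0] deg (truth [8.0, 12.0, 6.0]), tau_c = 60.8 ns (truth 60), chi2_red = 0.77
DCC (short 1-ns window): mean off-diagonal 0.28
DCC (long 80-ns window): mean off-diagonal 0.92
helix rocking SD estimate: 9.5 deg (generator truth 10 deg)
permeation: 10 events counted (10 scheduled), 25.1 per 100 ns
```

Reading this: the TEDOR fit recovers the one-bond N-Ca coupling within 1%
at 5% noise, giving a near-rigid S_NCa; the relaxation fits return the
generating rates with calibrated 95% intervals; the SMF scan puts the
motional timescale in the tens of nanoseconds and reports both chi^2
branches rather than silently picking one; the GAF fit recovers the
timescale (60.8 vs 60 ns) and fits the data at chi2_red ~ 1, while the
amplitude split across the three axes is only loosely determined on an
ideal helix (its screw symmetry makes the frame angles a gauge freedom —
see the methods note); and the trajectory stage reproduces the
short-vs-long window correlation contrast of collective rocking, the
generator's rocking amplitude, and the exact scheduled permeation count.

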