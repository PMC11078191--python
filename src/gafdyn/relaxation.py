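"""Exponential relaxation fitting, the solid-state spectral density, the 15N
rate model under MAS and spinlock, and per-residue simple-model-free (SMF)
inversion.

Rotating-frame decays follow M(t) = M0 exp(-t R1rho); inversion recovery
follows M(t) = M0 (1 - 2 exp(-t R1)).  Rates connect to motion through the
solid-sample spectral density

    J(w) = (2/5) (1 - S^2) tau_c / (1 + (w tau_c)^2)

which, unlike the solution-state form, vanishes in the rigid limit S^2 = 1:
overall tumbling is absent in a solid, so only the internal motion
contributes.  R1 is driven by J at the Larmor combinations; R1rho adds
spinlock/MAS sideband terms J(w1 +/- wr), J(w1 +/- 2 wr).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .datamodel import FitOptions, SpectrometerConfig
from .dipolar import DegenerateDataError, FitFailure, rigid_limit_coupling

#: sampling schedules of the measurement scheme this package targets
DEFAULT_SPINLOCK_TIMES_MS = np.array(
    [0, 10, 20, 30, 40, 50, 60, 70, 80, 100, 120, 140, 160, 180, 200, 220], float
)
DEFAULT_RECOVERY_TIMES_S = np.array([0, 3, 5, 8, 16, 32], float)


@dataclass
class DecayCurve:
    times_s: np.ndarray
    amplitudes: np.ndarray
    mode: str = "spinlock"  # spinlock | inversion_recovery

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, float)
        self.amplitudes = np.asarray(self.amplitudes, float)
        if len(self.times_s) != len(self.amplitudes):
            raise ValueError("time/amplitude length mismatch")
        if np.any(self.times_s < 0) or np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be nonnegative and strictly increasing")
        if self.mode not in ("spinlock", "inversion_recovery"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RateFitResult:
    M0: float
    rate: float  # s^-1
    ci95: tuple[float, float]
    residual_sum: float
    mode: str = "spinlock"
    zero_crossing_s: Optional[float] = None  # inversion recovery diagnostic


def _spinlock_model(t, m0, r):
    return m0 * np.exp(-r * t)


def _recovery_model(t, m0, r):
    return m0 * (1 - 2 * np.exp(-r * t))


def _batch_refit(t: np.ndarray, Y: np.ndarray, mode: str, p0: np.ndarray) -> np.ndarray:
    """Vectorized Levenberg-Marquardt for B two-parameter exponential fits.

    ``Y`` is (B, n); returns (B, 2) of (M0, rate).  All draws share the same
    design, so the 2x2 normal equations are solved in closed form per draw.
    """
    B = Y.shape[0]
    p = np.tile(np.asarray(p0, float), (B, 1))
    lam = np.full(B, 1e-3)
    def model_jac(p):
        m0, r = p[:, :1], p[:, 1:2]
        e = np.exp(-np.clip(r, 0, None) * t)
        if mode == "spinlock":
            f = m0 * e
            j0_, j1 = e, -m0 * t * e
        else:
            f = m0 * (1 - 2 * e)
            j0_, j1 = 1 - 2 * e, 2 * m0 * t * e
        return f, j0_, j1
    f, j0_, j1 = model_jac(p)
    res = f - Y
    cost = np.sum(res**2, axis=1)
    for _ in range(60):
        a = np.sum(j0_ * j0_, axis=1)
        b = np.sum(j0_ * j1, axis=1)
        c = np.sum(j1 * j1, axis=1)
        g0 = np.sum(j0_ * res, axis=1)
        g1 = np.sum(j1 * res, axis=1)
        a_d = a * (1 + lam)
        c_d = c * (1 + lam)
        det = a_d * c_d - b * b
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d0 = (c_d * g0 - b * g1) / det
        d1 = (a_d * g1 - b * g0) / det
        p_new = p - np.stack([d0, d1], axis=1)
        p_new[:, 1] = np.clip(p_new[:, 1], 0, None)
        f_new, _, _ = model_jac(p_new)
        res_new = f_new - Y
        cost_new = np.sum(res_new**2, axis=1)
        better = cost_new < cost
        p = np.where(better[:, None], p_new, p)
        lam = np.where(better, lam * 0.3, lam * 3.0)
        res = np.where(better[:, None], res_new, res)
        cost = np.minimum(cost, cost_new)
        f, j0_, j1 = model_jac(p)
        if np.all(lam > 1e6):
            break
    return p


def _fit_decay(curve: DecayCurve, mode: str, seed: int, n_draws: int) -> RateFitResult:
    if curve.mode != mode:
        raise ValueError(f"curve mode {curve.mode!r}, expected {mode!r}")
    if len(curve.times_s) < 3:
        raise ValueError("need >= 3 points")
    t, y = curve.times_s, curve.amplitudes
    model = _spinlock_model if mode == "spinlock" else _recovery_model
    if mode == "spinlock" and np.all(y <= 0):
        raise DegenerateDataError("non-positive amplitudes throughout")
    if np.ptp(y) == 0 and mode == "spinlock":
        # constant curve: rate exactly 0
        return RateFitResult(M0=float(y[0]), rate=0.0, ci95=(0.0, 0.0),
                             residual_sum=0.0, mode=mode)
    m0_guess = y[0] if mode == "spinlock" else abs(y[-1])
    span = max(t[-1] - t[0], 1e-12)
    try:
        popt, _ = curve_fit(
            model, t, y, p0=[m0_guess if m0_guess != 0 else 1.0, 1.0 / span],
            bounds=([-np.inf, 0], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitFailure(str(exc))
    yhat = model(t, *popt)
    ss = float(np.sum((y - yhat) ** 2))
    # 95% CI by Monte-Carlo residual resampling: parametric draws with the
    # dof-corrected residual scale, refit in batch, percentile interval
    dof = max(len(t) - 2, 1)
    sigma_hat = np.sqrt(ss / dof)
    if sigma_hat == 0:
        ci = (popt[1], popt[1])
    else:
        rng = np.random.default_rng(seed)
        # propagate the uncertainty of the residual scale itself: each
        # replicate draws its noise SD from the scaled inverse-chi^2 law,
        # which recovers t-like interval widths at few-point schedules
        sigma_b = sigma_hat * np.sqrt(dof / rng.chisquare(dof, size=n_draws))
        Y = yhat[None, :] + rng.normal(0, 1, size=(n_draws, len(t))) * sigma_b[:, None]
        draws = _batch_refit(t, Y, mode, popt)
        lo, hi = np.percentile(draws[:, 1], [2.5, 97.5])
        ci = (max(float(lo), 0.0), float(hi))
    zc = None
    if mode == "inversion_recovery" and popt[1] > 0:
        zc = float(np.log(2) / popt[1])
    return RateFitResult(M0=float(popt[0]), rate=float(popt[1]), ci95=ci,
                         residual_sum=ss, mode=mode, zero_crossing_s=zc)


def fit_spinlock_decay(curve: DecayCurve, seed: int = 0, n_draws: int = 200) -> RateFitResult:
    """Fit M(t) = M0 exp(-t R1rho) by nonlinear least squares with MC 95% CI."""
    return _fit_decay(curve, "spinlock", seed, n_draws)


def fit_inversion_recovery(curve: DecayCurve, seed: int = 0, n_draws: int = 200) -> RateFitResult:
    """Fit M(t) = M0 (1 - 2 exp(-t R1)); reports the ln2/R1 zero-crossing."""
    return _fit_decay(curve, "inversion_recovery", seed, n_draws)


# ---------------------------------------------------------------- rate model

@dataclass
class MotionModelParams:
    S2: float
    tau_c: float  # s
    chi2: float = 0.0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.S2 <= 1):
            raise ValueError("S2 must lie in [0, 1]")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be > 0")


def spectral_density_solid(omega, S2, tau_c):
    """J(w) = (2/5)(1 - S^2) tau_c / (1 + (w tau_c)^2); rigid limit gives 0."""
    omega = np.asarray(omega, float)
    out = 0.4 * (1.0 - np.asarray(S2, float)) * tau_c / (1.0 + (omega * tau_c) ** 2)
    return out


def _delta_nh(cfg: SpectrometerConfig) -> float:
    """N-H dipolar coupling strength in rad/s from the configured bond length."""
    return 2 * np.pi * rigid_limit_coupling(cfg.r_NH, "NH")


def _delta_csa_omega(cfg: SpectrometerConfig) -> float:
    """delta_CSA * omega_N in rad/s (ppm converted to a fraction)."""
    return cfg.delta_csa * 1e-6 * cfg.omega_N


def check_rotary_resonance(cfg: SpectrometerConfig) -> None:
    for k in (1, 2):
        if abs(cfg.omega_1 - k * cfg.omega_r) < 2 * np.pi * 500.0:
            warnings.warn(
                f"spinlock within 500 Hz of {k}x MAS rate: rotating-frame rate "
                "model near rotary resonance is of doubtful interpretation",
                stacklevel=2,
            )


def r1_model(tau_c, cfg: SpectrometerConfig, s2_nh, s2_csa=None):
    """Longitudinal 15N rate: CSA term plus N-H dipolar term.

    ``s2_nh`` weights the dipolar spectral density, ``s2_csa`` (defaults to
    ``s2_nh``) the CSA one; passing distinct values lets the GAF stage use
    each interaction's own order parameter.  Broadcasts over arrays.
    """
    if s2_csa is None:
        s2_csa = s2_nh
    wN, wH = cfg.omega_N, cfg.omega_H
    d_nh = _delta_nh(cfg)
    d_csa = _delta_csa_omega(cfg)
    J = spectral_density_solid
    r1_csa = 0.75 * d_csa**2 * J(wN, s2_csa, tau_c)
    r1_nh = (d_nh**2 / 4.0) * (
        J(wH - wN, s2_nh, tau_c) + 3 * J(wN, s2_nh, tau_c) + 6 * J(wH + wN, s2_nh, tau_c)
    )
    return r1_csa + r1_nh


def r1rho_model(tau_c, cfg: SpectrometerConfig, s2_nh, s2_csa=None):
    """Rotating-frame 15N rate: R1rho = R1/2 + R1rho_CSA + R1rho_NH.

    The spinlock terms sample J at w1 +/- wr and w1 +/- 2 wr with 2/3 and 1/3
    weights respectively (MAS sideband pattern of the recoupled interaction).
    """
    if s2_csa is None:
        s2_csa = s2_nh
    w1, wr, wH = cfg.omega_1, cfg.omega_r, cfg.omega_H
    d_nh = _delta_nh(cfg)
    d_csa = _delta_csa_omega(cfg)
    J = spectral_density_solid

    def sidebands(s2):
        return (
            (1 / 3) * J(w1 - 2 * wr, s2, tau_c)
            + (2 / 3) * J(w1 - wr, s2, tau_c)
            + (2 / 3) * J(w1 + wr, s2, tau_c)
            + (1 / 3) * J(w1 + 2 * wr, s2, tau_c)
        )

    r1rho_csa = (d_csa**2 / 4.0) * sidebands(s2_csa)
    r1rho_nh = (d_nh**2 / 4.0) * (3 * J(wH, s2_nh, tau_c) + sidebands(s2_nh))
    return 0.5 * r1_model(tau_c, cfg, s2_nh, s2_csa) + r1rho_csa + r1rho_nh


# ----------------------------------------------------------------- SMF fit

@dataclass
class SMFResult:
    solutions: list[MotionModelParams]
    flags: list[str] = field(default_factory=list)
    grid_chi2_min: float = np.inf


def smf_chi2(r1, r1_err, r1rho, r1rho_err, s2, tau_c, cfg: SpectrometerConfig):
    """Weighted squared residuals of the two rates against the SMF model."""
    m1 = r1_model(tau_c, cfg, s2)
    m1r = r1rho_model(tau_c, cfg, s2)
    return ((m1 - r1) / r1_err) ** 2 + ((m1r - r1rho) / r1rho_err) ** 2


def fit_smf(
    r1: float, r1_err: float, r1rho: float, r1rho_err: float,
    cfg: SpectrometerConfig, options: FitOptions | None = None,
) -> SMFResult:
    """Scan the (S^2, tau_c) chi^2 surface and report all local minima.

    The grid is log-spaced in tau_c over [10 ps, 10 ms] and linear in S^2
    over [0, 1]; the surface is typically bimodal (a tens-of-ns branch and a
    100 us - ms branch), and both minima are returned ranked by chi^2 rather
    than silently resolved.
    """
    opt = options or FitOptions()
    check_rotary_resonance(cfg)
    if r1 == 0 and r1rho == 0:
        sol = MotionModelParams(S2=1.0, tau_c=1e-9, chi2=0.0,
                                flags=["tau_c unidentifiable at S2=1"])
        return SMFResult(solutions=[sol], flags=["degenerate: zero rates"],
                         grid_chi2_min=0.0)
    tau = np.geomspace(opt.smf_tauc_lo, opt.smf_tauc_hi, opt.smf_n_tauc)
    s2 = np.linspace(0.0, 1.0, opt.smf_n_s2)
    chi2 = smf_chi2(r1, r1_err, r1rho, r1rho_err, s2[:, None], tau[None, :], cfg)
    minima = _grid_local_minima(chi2)
    sols = []
    for i, j in minima:
        sols.append(MotionModelParams(S2=float(s2[i]), tau_c=float(tau[j]),
                                      chi2=float(chi2[i, j])))
    sols.sort(key=lambda m: m.chi2)
    flags = []
    if not sols or sols[0].chi2 > opt.smf_chi2_threshold:
        flags.append("no-SMF-solution")
    return SMFResult(solutions=sols, flags=flags, grid_chi2_min=float(chi2.min()))


def _grid_local_minima(chi2: np.ndarray, persistence: float = 1.0) -> list[tuple[int, int]]:
    """One representative minimum per watershed basin of the chi^2 surface.

    Cells are visited in ascending chi^2; a cell with no already-assigned
    neighbour seeds a new basin (a local minimum), otherwise it joins its
    lowest neighbouring basin.  Flat valleys therefore collapse into a
    single reported minimum instead of one per grid cell.
    """
    ni, nj = chi2.shape
    order = np.argsort(chi2, axis=None, kind="stable")
    basin = -np.ones((ni, nj), int)
    minima: list[tuple[int, int]] = []
    min_val: list[float] = []
    parent: list[int] = []

    def find(b):
        while parent[b] != b:
            parent[b] = parent[parent[b]]
            b = parent[b]
        return b

    for f in order:
        i, j = divmod(int(f), nj)
        v = float(chi2[i, j])
        neigh = {find(basin[a, b])
                 for a in range(max(i - 1, 0), min(i + 2, ni))
                 for b in range(max(j - 1, 0), min(j + 2, nj))
                 if basin[a, b] >= 0}
        if not neigh:
            basin[i, j] = len(minima)
            minima.append((i, j))
            min_val.append(v)
            parent.append(len(parent))
            continue
        tgt = min(neigh, key=lambda b: min_val[b])
        basin[i, j] = tgt
        # saddle between basins: merge any basin whose depth below this
        # saddle is shallow (persistence < tolerance) into the deeper one
        for b in neigh:
            if b != tgt and v - min_val[b] < persistence:
                parent[b] = tgt
    roots = sorted({find(b) for b in range(len(minima))})
    return [minima[b] for b in roots]
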