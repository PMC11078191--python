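"""Ground-truth generators emulating every input the pipeline consumes.

Each generator is a pure function of its arguments including the seed, and
returns the data together with a ``truth`` dict of the generating
parameters; with ``out_dir`` set, data and truth are also written to disk
(truth as JSON next to the data).  Defaults mirror the measurement
conditions the pipeline targets: the 12-point TEDOR schedule, the 16-point
spinlock and 6-point recovery schedules, 2% relative noise on order
parameters and 5% on rates and curve intensities.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import MeasurementTable, SegmentDefinition, SpectrometerConfig
from .dipolar import DEFAULT_TEDOR_TIMES_MS, TEDORCurve, tedor_signal
from .gaf import GAFParams, build_gaf_frames, predict_observables
from .relaxation import (
    DEFAULT_RECOVERY_TIMES_S,
    DEFAULT_SPINLOCK_TIMES_MS,
    DecayCurve,
)
from .structure import BackboneStructure, build_ideal_helix, helix_axis, write_pdb
from .trajectory import TrajectorySeries

DEFAULT_NOISE_ORDER_PARAM = 0.02  # relative
DEFAULT_NOISE_RATE = 0.05
DEFAULT_NOISE_CURVE = 0.05


def _write_truth(out_dir, name, truth):
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        with open(Path(out_dir) / f"{name}_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, default=float)


def gen_tedor_curve(
    V0: float = 1.0,
    lam: float = 1.0,
    gamma: float = 15.0,
    D1_hz: float = 985.0,
    D2_hz: float = 150.0,
    n_coupled: int = 2,
    times_ms: Optional[np.ndarray] = None,
    noise: float = DEFAULT_NOISE_CURVE,
    seed: int = 0,
    out_dir=None,
) -> tuple[TEDORCurve, dict]:
    """TEDOR buildup at the standard 12 dephasing times plus Gaussian noise.

    Noise is relative per point (sigma_i = noise * |clean_i|, floored at
    1e-3 of the curve maximum so no point gets zero uncertainty); the error
    column carries the true noise scales.
    """
    t_ms = np.asarray(times_ms if times_ms is not None else DEFAULT_TEDOR_TIMES_MS, float)
    clean = tedor_signal(t_ms * 1e-3, V0, lam, gamma, D1_hz, D2_hz, n_coupled)
    rng = np.random.default_rng(seed)
    if noise > 0:
        sigma = noise * np.maximum(np.abs(clean), 1e-3 * np.max(np.abs(clean)))
        y = clean + rng.normal(0, 1, len(t_ms)) * sigma
        errors = sigma
    else:
        y = clean.copy()
        errors = None
    truth = {"V0": V0, "lam": lam, "gamma": gamma, "D1_hz": D1_hz, "D2_hz": D2_hz,
             "n_coupled": n_coupled, "noise": noise, "seed": seed}
    curve = TEDORCurve(mix_times_ms=t_ms, intensities=y, errors=errors)
    if out_dir is not None:
        df = pd.DataFrame({"t_mix_ms": t_ms, "intensity": y})
        if errors is not None:
            df["error"] = errors
        df.to_csv(Path(out_dir) / "tedor_curve.tsv", sep="\t", index=False,
                  float_format="%.9g")
        _write_truth(out_dir, "tedor_curve", truth)
    return curve, truth


def gen_decay_curve(
    M0: float = 10.0,
    rate: float = 5.0,
    mode: str = "spinlock",
    times_s: Optional[np.ndarray] = None,
    noise: float = DEFAULT_NOISE_CURVE,
    seed: int = 0,
    out_dir=None,
) -> tuple[DecayCurve, dict]:
    """Mono-exponential decay (spinlock) or inversion recovery with noise."""
    if times_s is None:
        times_s = (DEFAULT_SPINLOCK_TIMES_MS * 1e-3 if mode == "spinlock"
                   else DEFAULT_RECOVERY_TIMES_S)
    t = np.asarray(times_s, float)
    if mode == "spinlock":
        clean = M0 * np.exp(-rate * t)
    else:
        clean = M0 * (1 - 2 * np.exp(-rate * t))
    rng = np.random.default_rng(seed)
    sigma = noise * abs(M0)
    y = clean + rng.normal(0, sigma, len(t)) if noise > 0 else clean.copy()
    truth = {"M0": M0, "rate": rate, "mode": mode, "noise": noise, "seed": seed}
    curve = DecayCurve(times_s=t, amplitudes=y, mode=mode)
    if out_dir is not None:
        pd.DataFrame({"time_s": t, "amplitude": y}).to_csv(
            Path(out_dir) / f"decay_{mode}.tsv", sep="\t", index=False,
            float_format="%.9g")
        _write_truth(out_dir, f"decay_{mode}", truth)
    return curve, truth


def gen_gaf_helix(
    n_res: int = 20,
    params: Optional[GAFParams] = None,
    noise_s: float = DEFAULT_NOISE_ORDER_PARAM,
    noise_r: float = DEFAULT_NOISE_RATE,
    seed: int = 0,
    cfg: Optional[SpectrometerConfig] = None,
    out_dir=None,
) -> tuple[BackboneStructure, MeasurementTable, dict]:
    """Ideal alpha-helix with per-residue {S_CaHa, R1, R1rho} from GAF truth.

    Default truth: sigma = (8, 12, 6) degrees, tau_c = 60 ns, no frame
    adjustment; 2% relative noise on S, 5% on rates, with the noise scales
    recorded in the error columns.
    """
    if n_res < 6:
        raise ValueError("need >= 6 residues")
    if params is None:
        params = GAFParams(*np.deg2rad([8.0, 12.0, 6.0]), tau_c=60e-9)
    if cfg is None:
        cfg = SpectrometerConfig()
    helix = build_ideal_helix(n_res)
    segment = SegmentDefinition("H1", 1, n_res, "helix")
    _, vectors = build_gaf_frames(helix, segment, params.delta_theta,
                                  params.delta_phi, cfg.csa_tilt_deg)
    clean = predict_observables(params, vectors, cfg)
    rng = np.random.default_rng(seed)
    df = clean.copy()
    s_sig = noise_s * df["S_CaHa"].abs()
    r1_sig = noise_r * df["R1"].abs()
    rr_sig = noise_r * df["R1rho"].abs()
    if noise_s > 0:
        df["S_CaHa"] = (df["S_CaHa"] + rng.normal(0, 1, len(df)) * s_sig).clip(0, 1.1)
    if noise_r > 0:
        df["R1"] = (df["R1"] + rng.normal(0, 1, len(df)) * r1_sig).clip(lower=0)
        df["R1rho"] = (df["R1rho"] + rng.normal(0, 1, len(df)) * rr_sig).clip(lower=0)
    # error columns carry the assumed noise model; with zero perturbation the
    # nominal scales are kept so downstream chi^2 stays well-conditioned
    err_s = noise_s if noise_s > 0 else DEFAULT_NOISE_ORDER_PARAM
    err_r = noise_r if noise_r > 0 else DEFAULT_NOISE_RATE
    df["S_CaHa_err"] = np.maximum(err_s * clean["S_CaHa"].abs(), 1e-12)
    df["R1_err"] = np.maximum(err_r * clean["R1"].abs(), 1e-12)
    df["R1rho_err"] = np.maximum(err_r * clean["R1rho"].abs(), 1e-12)
    df["residue_name"] = "ALA"
    df["segment_id"] = segment.name
    table = MeasurementTable(df.copy(), validate=False)
    truth = {
        "sigma_deg": list(params.sigmas_deg), "tau_c_s": params.tau_c,
        "delta_theta": params.delta_theta, "delta_phi": params.delta_phi,
        "n_res": n_res, "noise_s": noise_s, "noise_r": noise_r, "seed": seed,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pdb(helix, out / "helix.pdb")
        table.frame.reset_index().to_csv(out / "measurements.tsv", sep="\t",
                                         index=False, float_format="%.9g")
        _write_truth(out_dir, "gaf_helix", truth)
    return helix, table, truth


def gen_rocking_trajectory(
    n_res: int = 20,
    rock_sd_deg: float = 10.0,
    corr_time_ns: float = 60.0,
    dt_ns: float = 1.0,
    n_frames: int = 2000,
    atom_noise: float = 0.0,
    seed: int = 0,
    out_dir=None,
) -> tuple[TrajectorySeries, dict]:
    """Rigid ideal helix rocking about two axes perpendicular to its axis.

    The two rocking angles follow independent stationary Ornstein-Uhlenbeck
    processes with the stated SD and correlation time; optional independent
    Gaussian jitter is added per atom and frame.  The pivot sits one helix
    length below the base along the axis, as for a helix anchored in the
    membrane: the whole helix swings to the same side and residue
    displacements are collective rather than anti-correlated about a
    mid-helix node.
    """
    if n_frames < 100:
        raise ValueError("need >= 100 frames")
    helix = build_ideal_helix(n_res, with_protons=False, with_cb=False)
    nums = helix.residue_numbers()
    ca = np.array([helix.residues[i]["CA"] for i in nums])
    axis = helix_axis(helix)
    length = float((ca[-1] - ca[0]) @ axis)
    center = ca[0] - length * axis  # pivot below the base
    # two perpendicular rocking axes
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ax1 = np.cross(axis, ref)
    ax1 /= np.linalg.norm(ax1)
    ax2 = np.cross(axis, ax1)
    rng = np.random.default_rng(seed)
    sd = np.deg2rad(rock_sd_deg)
    th1 = _ou_series(n_frames, sd, corr_time_ns, dt_ns, rng)
    th2 = _ou_series(n_frames, sd, corr_time_ns, dt_ns, rng)
    coords = np.empty((n_frames, len(nums), 3))
    rel = ca - center
    for f in range(n_frames):
        R = _rodrigues(ax1, th1[f]) @ _rodrigues(ax2, th2[f])
        coords[f] = rel @ R.T + center
    if atom_noise > 0:
        coords += rng.normal(0, atom_noise, coords.shape)
    series = TrajectorySeries(coords, dt_ns=dt_ns, atom_names=["CA"] * len(nums),
                              residue_numbers=np.array(nums))
    truth = {"rock_sd_deg": rock_sd_deg, "corr_time_ns": corr_time_ns,
             "dt_ns": dt_ns, "n_frames": n_frames, "atom_noise": atom_noise,
             "n_res": n_res, "seed": seed}
    if out_dir is not None:
        _write_xyz(series, Path(out_dir) / "rocking.xyz")
        _write_truth(out_dir, "rocking", truth)
    return series, truth


def _ou_series(n, sd, tau, dt, rng):
    """Stationary Ornstein-Uhlenbeck draw: SD ``sd``, correlation time ``tau``."""
    if tau <= 0:
        return rng.normal(0, sd, n)
    rho = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    innov = rng.normal(0, sd * np.sqrt(1 - rho**2), n - 1)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def _rodrigues(axis, angle):
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _write_xyz(series: TrajectorySeries, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    names = series.atom_names or ["C"] * series.n_atoms
    with open(path, "w") as fh:
        for f in range(series.n_frames):
            fh.write(f"{series.n_atoms}\nframe {f}\n")
            for a in range(series.n_atoms):
                x, y, z = series.coordinates[f, a]
                fh.write(f"{names[a][0]} {x:.6f} {y:.6f} {z:.6f}\n")


class ScheduleError(ValueError):
    """Water-path schedule segments overlap or are malformed."""


def gen_water_paths(
    schedules: Sequence[Sequence[dict]],
    n_frames: int,
    dt_ns: float = 0.1,
    z_lo: float = -15.0,
    z_hi: float = 15.0,
    margin: float = 5.0,
    out_dir=None,
) -> tuple[np.ndarray, dict]:
    """Piecewise-smooth z(t) per molecule realising a stated crossing schedule.

    Each molecule's schedule is a list of events
    ``{"kind": "cross"|"bounce", "start": frame, "end": frame,
       "direction": +1|-1}`` (direction of a cross; the side of a bounce).
    Crossings traverse the whole slab; bounces enter through one boundary
    and re-exit through the same one, scoring no permeation.
    """
    z = np.empty((len(schedules), n_frames))
    truth_events = []
    for m, sched in enumerate(schedules):
        events = sorted(sched, key=lambda e: e["start"])
        for a, b in zip(events, events[1:]):
            if b["start"] < a["end"]:
                raise ScheduleError(f"molecule {m}: overlapping events")
        for e in events:
            if not (0 <= e["start"] < e["end"] <= n_frames - 1):
                raise ScheduleError(f"molecule {m}: event outside trajectory")
        side = -1 if not events else (
            -events[0]["direction"] if events[0]["kind"] == "cross" else events[0]["direction"]
        )
        lo_rest, hi_rest = z_lo - margin, z_hi + margin
        level = lo_rest if side < 0 else hi_rest
        cur = np.full(n_frames, level)
        pos = 0
        for e in events:
            s, t = int(e["start"]), int(e["end"])
            cur[pos:s] = level
            ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, t - s + 1)))
            if e["kind"] == "cross":
                target = hi_rest if e["direction"] > 0 else lo_rest
                cur[s:t + 1] = level + (target - level) * ramp
                level = target
            elif e["kind"] == "bounce":
                # dip to mid-slab and return to the same side
                mid = 0.5 * (z_lo + z_hi)
                bump = np.sin(np.linspace(0, np.pi, t - s + 1))
                cur[s:t + 1] = level + (mid - level) * bump
            else:
                raise ScheduleError(f"unknown event kind {e['kind']!r}")
            pos = t + 1
        cur[pos:] = level
        z[m] = cur
        for e in events:
            if e["kind"] == "cross":
                truth_events.append({"molecule": m, "end_frame": e["end"],
                                     "direction": "+z" if e["direction"] > 0 else "-z"})
    truth = {"n_crossings": len(truth_events), "events": truth_events,
             "dt_ns": dt_ns, "z_lo": z_lo, "z_hi": z_hi, "n_frames": n_frames}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / "water_z.tsv", z.T, delimiter="\t", fmt="%.6g")
        _write_truth(out_dir, "water_paths", truth)
    return z, truth
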