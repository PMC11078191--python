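"""Trajectory-derived collective-motion observables.

Four observables connect trajectory dynamics to the ssNMR picture:
windowed dynamic cross-correlation (DCC) between residue fluctuations,
helix orientation fluctuation, water permeation counting across a membrane
slab, and hydrogen-bond occupancy/partner frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel import FormatError


@dataclass
class TrajectorySeries:
    """Frame-major coordinates (frames x atoms x 3, Angstrom) with labels."""

    coordinates: np.ndarray
    dt_ns: float = 0.1
    atom_names: list[str] = field(default_factory=list)
    residue_numbers: np.ndarray | None = None  # per atom

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (frames, atoms, 3)")
        if self.coordinates.shape[0] < 2:
            raise ValueError("need >= 2 frames")
        if self.residue_numbers is not None:
            self.residue_numbers = np.asarray(self.residue_numbers, int)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def select(self, names: Sequence[str] | None = None,
               residues: Sequence[int] | None = None) -> "TrajectorySeries":
        mask = np.ones(self.n_atoms, bool)
        if names is not None:
            mask &= np.isin(np.asarray(self.atom_names), list(names))
        if residues is not None and self.residue_numbers is not None:
            mask &= np.isin(self.residue_numbers, list(residues))
        if not mask.any():
            raise ValueError("selection matches 0 atoms")
        return TrajectorySeries(
            self.coordinates[:, mask], self.dt_ns,
            [n for n, m in zip(self.atom_names, mask) if m],
            self.residue_numbers[mask] if self.residue_numbers is not None else None,
        )


def read_trajectory(path, selection: Optional[str] = None, dt_ns: float = 0.1,
                    box: Optional[float] = None) -> TrajectorySeries:
    """Read a multi-frame PDB or XYZ trajectory.

    PDB models are read with Biopython so that per-model atom order is
    preserved and frames 2..N can be canonicalized to frame-1 order by atom
    identity.  ``selection`` filters by atom name (e.g. "CA").  ``box``, if
    given, enables a guard that rejects wrapped trajectories (frame-to-frame
    displacement above half the box).
    """
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        series = _read_pdb_trajectory(path, dt_ns)
    elif path.suffix.lower() == ".xyz":
        series = _read_xyz_trajectory(path, dt_ns)
    else:
        raise FormatError(f"unsupported trajectory format: {path.suffix}")
    if selection:
        series = series.select(names=[selection])
    if box is not None:
        step = np.abs(np.diff(series.coordinates, axis=0)).max()
        if step > box / 2:
            raise ValueError(
                f"frame-to-frame displacement {step:.1f} exceeds half the box "
                f"({box / 2:.1f}); trajectory appears periodic-wrapped"
            )
    return series


def _read_pdb_trajectory(path, dt_ns):
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("t", str(path))
    models = list(structure)
    if len(models) < 2:
        raise FormatError(f"{path}: need >= 2 models")
    frames, keys_ref, names, resnums = [], None, None, None
    for model in models:
        keys, coords = [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    keys.append((chain.id, res.id[1], atom.get_name()))
                    coords.append(atom.get_coord())
        if keys_ref is None:
            keys_ref = keys
            order = {k: j for j, k in enumerate(keys)}
            names = [k[2] for k in keys]
            resnums = np.array([k[1] for k in keys])
            frames.append(np.asarray(coords, float))
        else:
            if len(keys) != len(keys_ref):
                raise FormatError(f"{path}: inconsistent atom count across models")
            if keys != keys_ref:
                if sorted(keys) != sorted(keys_ref):
                    raise FormatError(f"{path}: atom identities differ across models")
                arr = np.empty((len(keys), 3))
                for k, c in zip(keys, coords):
                    arr[order[k]] = c
                frames.append(arr)
            else:
                frames.append(np.asarray(coords, float))
    return TrajectorySeries(np.stack(frames), dt_ns, names, resnums)


def _read_xyz_trajectory(path, dt_ns):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="XYZ")
        if len(u.trajectory) < 2:
            raise FormatError(f"{path}: need >= 2 frames")
        names = [a.name for a in u.atoms]
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
    return TrajectorySeries(coords.astype(float), dt_ns, names, None)


# ------------------------------------------------------------------ DCC

@dataclass
class DCCMatrix:
    matrix: np.ndarray  # residues x residues in [-1, 1]
    window_ns: float
    residues: np.ndarray | None = None
    undefined: np.ndarray | None = None  # bool mask of entries lacking variance


def dcc_matrix(traj: TrajectorySeries, window_ns: float,
               selection: str = "CA") -> DCCMatrix:
    """Windowed dynamic cross-correlation between one atom per residue.

    Within each non-overlapping window the mean position is removed and
    DCC_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>); the returned matrix
    averages the per-window maps.  Zero-variance atoms in a window are
    marked undefined rather than propagating NaN.
    """
    sel = traj.select(names=[selection]) if traj.atom_names else traj
    n_win_frames = max(int(round(window_ns / sel.dt_ns)), 1)
    if n_win_frames < 2:
        raise ValueError("window must cover >= 2 frames")
    n_windows = sel.n_frames // n_win_frames
    if n_windows < 1:
        raise ValueError("window longer than trajectory")
    n = sel.n_atoms
    acc = np.zeros((n, n))
    count = np.zeros((n, n))
    for w in range(n_windows):
        x = sel.coordinates[w * n_win_frames:(w + 1) * n_win_frames]
        dx = x - x.mean(axis=0, keepdims=True)
        cov = np.einsum("fik,fjk->ij", dx, dx) / dx.shape[0]
        var = np.diag(cov).copy()
        ok = var > 1e-18
        denom = np.sqrt(np.outer(var, var))
        valid = np.outer(ok, ok)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(valid, cov / np.where(denom > 0, denom, 1.0), 0.0)
        acc += np.where(valid, c, 0.0)
        count += valid
    undefined = count == 0
    with np.errstate(invalid="ignore"):
        mat = np.where(undefined, np.nan, acc / np.where(count > 0, count, 1))
    np.fill_diagonal(mat, np.where(np.diag(undefined), np.nan, 1.0))
    residues = sel.residue_numbers
    return DCCMatrix(matrix=mat, window_ns=window_ns, residues=residues,
                     undefined=undefined)


# ----------------------------------------------------------- helix angles

def _axis_series(traj: TrajectorySeries, residues: Sequence[int] | None) -> np.ndarray:
    sel = traj
    if residues is not None:
        sel = traj.select(residues=residues)
    coords = sel.coordinates
    if coords.shape[1] < 4:
        raise ValueError("need >= 4 atoms to define a helix axis")
    centered = coords - coords.mean(axis=1, keepdims=True)
    axes = np.empty((coords.shape[0], 3))
    prev = None
    for f in range(coords.shape[0]):
        _, s, vt = np.linalg.svd(centered[f], full_matrices=False)
        if s[0] < 1e-9 or s[1] < 1e-9 * s[0]:
            raise ValueError(f"degenerate (collinear/coincident) coordinates in frame {f}")
        ax = vt[0]
        if prev is not None and np.dot(ax, prev) < 0:
            ax = -ax
        axes[f] = ax
        prev = ax
    return axes


def helix_angle_series(traj: TrajectorySeries, residues: Sequence[int] | None = None
                       ) -> np.ndarray:
    """Per-frame angle (degrees) between the helix axis and its frame-0 axis.

    The axis is the principal direction of the CA coordinates, sign-fixed by
    continuity to the previous frame to avoid 180-degree flips.
    """
    axes = _axis_series(traj, residues)
    cosang = np.clip(axes @ axes[0], -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def rocking_sd_estimate(traj: TrajectorySeries,
                        residues: Sequence[int] | None = None) -> float:
    """Per-axis rocking SD (degrees) estimated from the helix-axis series.

    The frame-0 reference axis is itself a draw from the rocking
    distribution, so raw angle statistics are biased by the anchor tilt.
    With two independent Gaussian tilt axes of SD sigma and an anchor offset
    delta (angle between the frame-0 axis and the mean axis),
    E[angle^2] = 2 sigma^2 + delta^2; this method-of-moments estimator
    removes the anchor term.
    """
    axes = _axis_series(traj, residues)
    mean_ax = axes.mean(axis=0)
    mean_ax /= np.linalg.norm(mean_ax)
    ang = np.arccos(np.clip(axes @ axes[0], -1.0, 1.0))
    delta = np.arccos(np.clip(float(axes[0] @ mean_ax), -1.0, 1.0))
    s2 = max((np.mean(ang**2) - delta**2) / 2.0, 0.0)
    return float(np.degrees(np.sqrt(s2)))


# ------------------------------------------------------------ permeation

@dataclass
class PermeationRecord:
    events: int
    event_times_ns: list[float]
    directions: list[str]  # "+z" | "-z"
    rate_per_100ns: float


def count_permeations(z_series: np.ndarray, z_lo: float, z_hi: float,
                      dt_ns: float = 0.1) -> PermeationRecord:
    """Count complete crossings of the [z_lo, z_hi] slab.

    ``z_series`` is (molecules, frames) or (frames,) of z coordinates.  A
    crossing is scored when a molecule enters the slab through one boundary
    and next leaves through the other; re-exit through the entry side scores
    nothing.
    """
    if z_lo >= z_hi:
        raise ValueError("z_lo must be < z_hi")
    z = np.atleast_2d(np.asarray(z_series, float))
    times, dirs = [], []
    for mol in z:
        state = None  # None: outside/unknown; else side of entry (-1 below, +1 above)
        for f in range(len(mol)):
            zi = mol[f]
            if zi < z_lo:
                if state == 1:
                    times.append(f * dt_ns)
                    dirs.append("-z")
                state = -1
            elif zi > z_hi:
                if state == -1:
                    times.append(f * dt_ns)
                    dirs.append("+z")
                state = 1
    order = np.argsort(times, kind="stable")
    times = [times[i] for i in order]
    dirs = [dirs[i] for i in order]
    total_ns = (z.shape[1] - 1) * dt_ns
    rate = 100.0 * len(times) / total_ns if total_ns > 0 else 0.0
    return PermeationRecord(events=len(times), event_times_ns=times,
                            directions=dirs, rate_per_100ns=rate)


# ------------------------------------------------------------- H-bonds

@dataclass
class HBondCriteria:
    max_da_distance: float = 3.5  # Angstrom, donor-acceptor
    min_dha_angle_deg: float = 150.0  # donor-H-acceptor


@dataclass
class HBondReport:
    occupancy: float  # fraction of frames with >= 1 satisfied partner
    partner_occupancy: dict  # partner -> fraction of frames bound
    n_partners: int  # distinct partners ever bound
    partner_frequency_per_ns: float


def hb_occupancy(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptors: Mapping[str, np.ndarray],
    criteria: HBondCriteria | None = None,
    dt_ns: float = 0.1,
) -> HBondReport:
    """Geometric hydrogen-bond occupancy and distinct-partner frequency.

    ``donor``/``hydrogen`` are (frames, 3); ``acceptors`` maps a partner
    identity to its (frames, 3) series.  A frame counts as bound to a
    partner when the donor-acceptor distance and donor-H-acceptor angle
    satisfy the criteria.
    """
    crit = criteria or HBondCriteria()
    donor = np.asarray(donor, float)
    hydrogen = np.asarray(hydrogen, float)
    n_frames = donor.shape[0]
    any_bound = np.zeros(n_frames, bool)
    partner_occ = {}
    n_partners = 0
    for name, acc in acceptors.items():
        acc = np.asarray(acc, float)
        if acc.shape[0] != n_frames:
            raise ValueError(f"partner {name}: frame count mismatch")
        da = np.linalg.norm(acc - donor, axis=1)
        v1 = donor - hydrogen
        v2 = acc - hydrogen
        cosang = np.sum(v1 * v2, axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-30
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        bound = (da < crit.max_da_distance) & (ang > crit.min_dha_angle_deg)
        partner_occ[name] = float(bound.mean())
        if bound.any():
            n_partners += 1
        any_bound |= bound
    total_ns = (n_frames - 1) * dt_ns
    freq = n_partners / total_ns if total_ns > 0 else 0.0
    return HBondReport(occupancy=float(any_bound.mean()), partner_occupancy=partner_occ,
                       n_partners=n_partners, partner_frequency_per_ns=freq)
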