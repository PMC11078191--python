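"""Domain types shared by all pipeline stages.

The pipeline turns per-residue ssNMR observables (dipolar order parameters
S_CaHa / S_NCa and the 15N relaxation rates R1, R1rho) into motional
parameters.  The types here carry those observables with uncertainties,
describe the spectrometer conditions the rate equations need, and declare
the secondary-structure segmentation over which collective motions are
fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

# gyromagnetic ratios, rad s^-1 T^-1 (CODATA / standard NMR tables)
GAMMA_H1 = 2.6752218744e8
GAMMA_C13 = 6.728284e7
GAMMA_N15 = -2.7126180399e7

#: observable columns of a measurement table: (value column, error column)
OBSERVABLE_COLUMNS = {
    "S_CaHa": ("S_CaHa", "S_CaHa_err"),
    "S_NCa": ("S_NCa", "S_NCa_err"),
    "R1": ("R1", "R1_err"),
    "R1rho": ("R1rho", "R1rho_err"),
}

ORDER_PARAM_MAX = 1.1  # small >1 excursions tolerated as noise, flagged


class ValidationError(ValueError):
    """A table or config violates a declared invariant."""


class FormatError(ValueError):
    """An input file does not have the expected layout."""


@dataclass(frozen=True)
class ResidueKey:
    """Identity of a residue within the protein: number, 3-letter name, segment label."""

    residue_number: int
    residue_name: str = "UNK"
    segment_id: str = ""


@dataclass(frozen=True)
class SegmentDefinition:
    """A contiguous secondary-structure segment (helix or loop)."""

    name: str
    first_residue: int
    last_residue: int
    kind: str = "helix"  # helix | loop

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValidationError(
                f"segment {self.name}: first_residue {self.first_residue} > "
                f"last_residue {self.last_residue}"
            )
        if self.kind not in ("helix", "loop"):
            raise ValidationError(f"segment {self.name}: kind must be helix or loop")

    def residues(self) -> range:
        return range(self.first_residue, self.last_residue + 1)

    def __contains__(self, residue_number: int) -> bool:
        return self.first_residue <= residue_number <= self.last_residue


def check_segments_disjoint(segments: list[SegmentDefinition]) -> None:
    spans = sorted((s.first_residue, s.last_residue, s.name) for s in segments)
    for (a0, a1, an), (b0, b1, bn) in zip(spans, spans[1:]):
        if b0 <= a1:
            raise ValidationError(f"segments {an} and {bn} overlap")


class MeasurementTable:
    """Per-residue experimental dynamics observables with uncertainties.

    Thin wrapper around a :class:`pandas.DataFrame` indexed by residue number
    with columns from :data:`OBSERVABLE_COLUMNS` (missing observables simply
    absent), plus optional ``residue_name`` / ``segment_id`` columns.  Extra
    columns are preserved as annotations.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        if "residue_number" in frame.columns:
            frame = frame.set_index("residue_number")
        self.frame = frame.sort_index()
        self.flags: list[str] = []
        if validate:
            self.validate()

    def validate(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate residue numbers: {dup}")
        present = [k for k in OBSERVABLE_COLUMNS if k in df.columns]
        if not present:
            raise FormatError("table has no recognised observable column")
        for name, (vcol, ecol) in OBSERVABLE_COLUMNS.items():
            if vcol not in df.columns:
                continue
            vals = df[vcol]
            if ecol in df.columns:
                errs = df[ecol]
                bad = df.index[(errs <= 0) & vals.notna() & errs.notna()]
                if len(bad):
                    raise ValidationError(
                        f"non-positive uncertainty for {name} at residue(s) "
                        f"{bad.tolist()}"
                    )
            if name.startswith("R"):
                bad = df.index[(vals < 0) & vals.notna()]
                if len(bad):
                    raise ValidationError(
                        f"negative rate {name} at residue(s) {bad.tolist()}"
                    )
            else:
                bad = df.index[((vals < 0) | (vals > ORDER_PARAM_MAX)) & vals.notna()]
                if len(bad):
                    raise ValidationError(
                        f"order parameter {name} outside [0, {ORDER_PARAM_MAX}] "
                        f"at residue(s) {bad.tolist()}"
                    )
                above1 = df.index[(vals > 1.0) & vals.notna()]
                for r in above1:
                    self.flags.append(f"{name} > 1 at residue {r} (tolerated as noise)")

    @property
    def residues(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def observables_present(self) -> list[str]:
        return [k for k in OBSERVABLE_COLUMNS if k in self.frame.columns]

    def restrict(self, segment: SegmentDefinition) -> "MeasurementTable":
        mask = (self.frame.index >= segment.first_residue) & (
            self.frame.index <= segment.last_residue
        )
        return MeasurementTable(self.frame.loc[mask].copy(), validate=False)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(
                self.frame, other.frame, check_like=True, rtol=1e-9
            )
            return True
        except AssertionError:
            return False


@dataclass
class SpectrometerConfig:
    """Field, spinning and spinlock conditions plus geometry entering the rate model.

    Defaults reproduce the measurement conditions of the dataset this package
    was built around: an 800-MHz instrument at 40-kHz magic-angle spinning
    with a 10-kHz 15N spinlock.  ``delta_csa`` is the reduced axially
    symmetric 15N CSA in ppm; bond lengths are in Angstrom and set the
    rigid-limit dipolar couplings.
    """

    proton_larmor: float = 800.0e6  # Hz
    mas_rate: float = 40.0e3  # Hz
    spinlock: float = 10.0e3  # Hz
    delta_csa: float = -170.0  # ppm, reduced 15N CSA
    r_NH: float = 1.02  # Angstrom
    r_CaHa: float = 1.10
    r_NCa: float = 1.46
    csa_tilt_deg: float = 17.0  # CSA symmetry axis tilt from N-H, in peptide plane

    def __post_init__(self) -> None:
        for name in ("proton_larmor", "mas_rate", "spinlock"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("r_NH", "r_CaHa", "r_NCa"):
            r = getattr(self, name)
            if not (0.9 <= r <= 2.0):
                raise ValidationError(f"{name}={r} outside [0.9, 2.0] Angstrom")
        if self.spinlock >= self.mas_rate / 2:
            warnings.warn(
                "spinlock >= mas_rate/2: rotary-resonance conditions nearby; "
                "rotating-frame rate model is near-singular",
                stacklevel=2,
            )

    @property
    def nitrogen_larmor(self) -> float:
        """15N Larmor frequency in Hz, derived from the proton frequency."""
        return self.proton_larmor * abs(GAMMA_N15) / GAMMA_H1

    # angular frequencies, rad/s
    @property
    def omega_H(self) -> float:
        return 2 * np.pi * self.proton_larmor

    @property
    def omega_N(self) -> float:
        return 2 * np.pi * self.nitrogen_larmor

    @property
    def omega_r(self) -> float:
        return 2 * np.pi * self.mas_rate

    @property
    def omega_1(self) -> float:
        return 2 * np.pi * self.spinlock


@dataclass
class FitOptions:
    """Grids, tolerances and seeds for the fitting stages."""

    seed: int = 0
    # TEDOR
    tedor_n_coupled: int = 2
    tedor_d1_starts: int = 10
    # SMF grid
    smf_tauc_lo: float = 10e-12
    smf_tauc_hi: float = 10e-3
    smf_n_tauc: int = 200
    smf_n_s2: int = 200
    smf_chi2_threshold: float = 10.0
    # GAF grid
    gaf_sigma_max_deg: float = 25.0
    gaf_sigma_step_deg: float = 2.5
    gaf_tauc_lo: float = 1e-9
    gaf_tauc_hi: float = 10e-6
    gaf_n_tauc: int = 25
    gaf_delta_max_deg: float = 30.0
    gaf_delta_step_deg: float = 15.0
    gaf_n_refine: int = 5
    # Monte-Carlo CIs
    ci_draws: int = 200


@dataclass
class RunConfig:
    """Bundle of everything a pipeline run needs; every option has a default."""

    spectrometer: SpectrometerConfig = field(default_factory=SpectrometerConfig)
    segments: list[SegmentDefinition] = field(default_factory=list)
    fit: FitOptions = field(default_factory=FitOptions)
    dt_ns: float = 0.1  # trajectory time step
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        check_segments_disjoint(self.segments)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "spectrometer" in d and isinstance(d["spectrometer"], dict):
            d["spectrometer"] = SpectrometerConfig(**d["spectrometer"])
        if "segments" in d:
            d["segments"] = [
                s if isinstance(s, SegmentDefinition) else SegmentDefinition(**s)
                for s in d["segments"]
            ]
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitOptions(**d["fit"])
        return cls(**d)
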