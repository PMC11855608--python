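"""Core domain types shared by every analysis stage.

Canonical internal units follow GROMACS conventions: length in nm, time in
ps, energy in kJ/mol, force in kJ mol^-1 nm^-1, temperature in K.
Diffusivities are computed in nm^2/ps and converted to cm^2/s only at the
reporting boundary (factor 1e-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "R_KJ_PER_MOL_K",
    "NM2_PER_PS_TO_CM2_PER_S",
    "AtomRecord",
    "SimulationBox",
    "LabeledFrame",
    "Trajectory",
    "AnalysisWindow",
    "ScpermeateError",
    "ParseError",
    "SelectionError",
    "ConfigurationError",
    "AnalysisError",
]

#: Gas constant, kJ mol^-1 K^-1.
R_KJ_PER_MOL_K: float = 8.31446e-3

#: 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s.
NM2_PER_PS_TO_CM2_PER_S: float = 1e-2


class ScpermeateError(Exception):
    """Base class for all package errors."""


class ParseError(ScpermeateError):
    """A structure or time-series file could not be parsed."""


class SelectionError(ScpermeateError):
    """An atom-selection expression is invalid."""


class ConfigurationError(ScpermeateError):
    """A run configuration or parameter combination is invalid."""


class AnalysisError(ScpermeateError):
    """An analysis operation received unusable input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus position in nm."""

    residue_name: str
    atom_name: str
    residue_id: int
    position: np.ndarray  # shape (3,), nm
    element: str | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got shape {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("position components must be finite")
        if self.residue_id < 1:
            raise ValueError(f"residue_id must be >= 1, got {self.residue_id}")
        object.__setattr__(self, "position", pos)


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic periodic box, edge lengths in nm."""

    lx: float
    ly: float
    lz: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0 and self.lz > 0):
            raise ValueError(
                f"box edges must be positive, got ({self.lx}, {self.ly}, {self.lz})"
            )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def cross_section(self) -> float:
        """In-plane (xy) area, nm^2."""
        return self.lx * self.ly


@dataclass
class LabeledFrame:
    """One configuration: ordered atoms plus the periodic box."""

    atoms: list[AtomRecord]
    box: SimulationBox
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a frame must contain at least one atom")
        if self.time < 0:
            raise ValueError(f"frame time must be >= 0, got {self.time}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm."""
        return np.array([a.position for a in self.atoms])

    def translated(self, shift: Sequence[float]) -> "LabeledFrame":
        """Return a copy rigidly translated by ``shift`` (nm)."""
        dv = np.asarray(shift, dtype=float)
        atoms = [
            AtomRecord(a.residue_name, a.atom_name, a.residue_id, a.position + dv, a.element)
            for a in self.atoms
        ]
        return LabeledFrame(atoms=atoms, box=self.box, time=self.time)


@dataclass
class Trajectory:
    """Ordered frames with identical atom layout and strictly increasing time."""

    frames: list[LabeledFrame]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("a trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        times = [f.time for f in self.frames]
        for i, f in enumerate(self.frames):
            if f.n_atoms != n0:
                raise ValueError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n0} (all frames "
                    "must share atom layout)"
                )
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[LabeledFrame]:
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class AnalysisWindow:
    """Time window [t_start, t_end] in ps over which frames are analyzed.

    Defaults to the final 20 ns of a 100 ns production run, the
    equilibrated portion used for all structural averages.
    """

    t_start: float = 80_000.0
    t_end: float = 100_000.0

    def __post_init__(self) -> None:
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(
                f"require 0 <= t_start < t_end, got [{self.t_start}, {self.t_end}]"
            )

    def contains(self, time: float) -> bool:
        return self.t_start <= time <= self.t_end

    def select_frames(self, traj: Trajectory) -> list[LabeledFrame]:
        frames = [f for f in traj.frames if self.contains(f.time)]
        if not frames:
            raise AnalysisError(
                f"no trajectory frames fall inside window [{self.t_start}, "
                f"{self.t_end}] ps"
            )
        return frames
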