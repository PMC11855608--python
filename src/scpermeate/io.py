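"""Readers and writers for structure files (GRO, PDB, XYZ) and two-column
time series.

All readers normalize coordinates to nm on the way in (PDB and XYZ are
Angstrom dialects and are scaled by 0.1); all writers convert back to the
dialect's native unit. Time-series files are whitespace-delimited
``time value`` text with ``#``/``@`` comment lines, compatible with the
xvg dumps produced by common MD engines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .model import (
    AtomRecord,
    ConfigurationError,
    LabeledFrame,
    ParseError,
    SimulationBox,
    Trajectory,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_timeseries",
    "write_timeseries",
    "TimeSeries",
]

StructureFormat = Literal["gro", "pdb", "xyz"]

_ANGSTROM_TO_NM = 0.1


# ---------------------------------------------------------------------------
# structure files
# ---------------------------------------------------------------------------

def _infer_format(path: Path, format: str | None) -> StructureFormat:
    if format is not None:
        fmt = format.lower()
    else:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("gro", "pdb", "xyz"):
        raise ConfigurationError(f"unsupported structure format {fmt!r}")
    return fmt  # type: ignore[return-value]


def read_structure(
    path: str | Path,
    format: str | None = None,
    box: SimulationBox | None = None,
) -> LabeledFrame:
    """Read a single-configuration structure file into a :class:`LabeledFrame`.

    Parameters
    ----------
    path
        File to read. The dialect is taken from ``format`` or, when omitted,
        the file extension.
    format
        One of ``"gro"``, ``"pdb"``, ``"xyz"``.
    box
        Required for XYZ input (the dialect carries no box); ignored for
        GRO/PDB, which carry their own box line.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    frames = _read_frames(path, fmt, box)
    if len(frames) != 1:
        raise ParseError(
            f"{path}: expected a single configuration, found {len(frames)} frames"
            " (use read_trajectory for multi-frame files)"
        )
    return frames[0]


def read_trajectory(
    source: str | Path | Iterable[str | Path],
    format: str | None = None,
    box: SimulationBox | None = None,
    dt_guess: float = 1.0,
) -> Trajectory:
    """Read a trajectory from a multi-frame file or an ordered list of
    per-frame files.

    Frames lacking an explicit time stamp (PDB models, XYZ, per-frame files)
    are assigned times ``i * dt_guess`` ps in encounter order.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = _infer_format(path, format)
        frames = _read_frames(path, fmt, box)
    else:
        frames = []
        for p in source:
            p = Path(p)
            fmt = _infer_format(p, format)
            frames.extend(_read_frames(p, fmt, box))
    # assign synthetic times where the dialect carried none
    times = [f.time for f in frames]
    if len(set(times)) != len(times) or any(
        t2 <= t1 for t1, t2 in zip(times, times[1:])
    ):
        for i, f in enumerate(frames):
            f.time = i * dt_guess
    return Trajectory(frames=frames)


def _read_frames(
    path: Path, fmt: StructureFormat, box: SimulationBox | None
) -> list[LabeledFrame]:
    if not path.exists():
        raise ParseError(f"structure file not found: {path}")
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "pdb":
        return _read_pdb(path)
    if box is None:
        raise ConfigurationError(
            f"{path}: XYZ files carry no box; a SimulationBox must be supplied"
        )
    return _read_xyz(path, box)


def _read_gro(path: Path) -> list[LabeledFrame]:
    frames: list[LabeledFrame] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        try:
            n_atoms = int(lines[i + 1].strip())
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}:{i + 2}: expected atom count, got "
                             f"{lines[i + 1]!r}" if i + 1 < len(lines)
                             else f"{path}: truncated GRO header") from exc
        atom_lines = lines[i + 2 : i + 2 + n_atoms]
        if len(atom_lines) < n_atoms or i + 2 + n_atoms >= len(lines):
            raise ParseError(f"{path}: truncated GRO frame starting at line {i + 1}")
        atoms = []
        for j, ln in enumerate(atom_lines):
            lineno = i + 3 + j
            try:
                resid = int(ln[0:5])
                resname = ln[5:10].strip()
                atomname = ln[10:15].strip()
                x = float(ln[20:28])
                y = float(ln[28:36])
                z = float(ln[36:44])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed GRO atom record "
                                 f"{ln!r}") from exc
            atoms.append(AtomRecord(resname, atomname, resid, np.array([x, y, z])))
        box_line = lines[i + 2 + n_atoms]
        box_fields = box_line.split()
        if len(box_fields) < 3:
            raise ParseError(
                f"{path}:{i + 3 + n_atoms}: malformed GRO box line {box_line!r}"
            )
        try:
            lx, ly, lz = (float(v) for v in box_fields[:3])
        except ValueError as exc:
            raise ParseError(
                f"{path}:{i + 3 + n_atoms}: malformed GRO box line {box_line!r}"
            ) from exc
        if any(abs(float(v)) > 1e-9 for v in box_fields[3:]):
            raise ConfigurationError(
                f"{path}: triclinic box not supported (off-diagonal elements "
                "present in GRO box line)"
            )
        time = _gro_title_time(title)
        frames.append(
            LabeledFrame(
                atoms=atoms,
                box=SimulationBox(lx, ly, lz),
                time=time if time is not None else float(len(frames)),
            )
        )
        i += 3 + n_atoms
    if not frames:
        raise ParseError(f"{path}: no GRO frames found")
    return frames


def _gro_title_time(title: str) -> float | None:
    """GROMACS writes 'system t= 123.000' in multi-frame GRO titles."""
    if "t=" not in title:
        return None
    try:
        return float(title.split("t=")[1].split()[0])
    except (IndexError, ValueError):
        return None


def _read_pdb(path: Path) -> list[LabeledFrame]:
    frames: list[LabeledFrame] = []
    box: SimulationBox | None = None
    atoms: list[AtomRecord] = []
    model_index = 0
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        rec = ln[:6].strip()
        if rec == "CRYST1":
            try:
                a = float(ln[6:15]) * _ANGSTROM_TO_NM
                b = float(ln[15:24]) * _ANGSTROM_TO_NM
                c = float(ln[24:33]) * _ANGSTROM_TO_NM
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed CRYST1 record") from exc
            angles = ln[33:54].split()
            if angles and any(abs(float(v) - 90.0) > 1e-6 for v in angles):
                raise ConfigurationError(
                    f"{path}:{lineno}: non-orthorhombic box not supported"
                )
            box = SimulationBox(a, b, c)
        elif rec in ("ATOM", "HETATM"):
            try:
                atomname = ln[12:16].strip()
                resname = ln[17:21].strip()
                resid = int(ln[22:26])
                x = float(ln[30:38]) * _ANGSTROM_TO_NM
                y = float(ln[38:46]) * _ANGSTROM_TO_NM
                z = float(ln[46:54]) * _ANGSTROM_TO_NM
            except (ValueError, IndexError) as exc:
                raise ParseError(
                    f"{path}:{lineno}: malformed {rec} record {ln!r}"
                ) from exc
            element = ln[76:78].strip() or None
            atoms.append(
                AtomRecord(resname, atomname, resid, np.array([x, y, z]), element)
            )
        elif rec in ("ENDMDL", "END") and atoms:
            frames.append(_finish_pdb_frame(path, atoms, box, float(model_index)))
            atoms = []
            model_index += 1
    if atoms:
        frames.append(_finish_pdb_frame(path, atoms, box, float(model_index)))
    if not frames:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return frames


def _finish_pdb_frame(
    path: Path, atoms: list[AtomRecord], box: SimulationBox | None, time: float
) -> LabeledFrame:
    if box is None:
        raise ConfigurationError(
            f"{path}: PDB file lacks a CRYST1 record; a periodic box is required"
        )
    return LabeledFrame(atoms=atoms, box=box, time=time)


def _read_xyz(path: Path, box: SimulationBox) -> list[LabeledFrame]:
    lines = path.read_text().splitlines()
    frames: list[LabeledFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(
                f"{path}:{i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        atoms = []
        for j in range(n_atoms):
            lineno = i + 3 + j
            try:
                fields = lines[i + 2 + j].split()
                element = fields[0]
                pos = np.array([float(v) for v in fields[1:4]]) * _ANGSTROM_TO_NM
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed XYZ record") from exc
            atoms.append(AtomRecord(element, element, j + 1, pos, element))
        frames.append(LabeledFrame(atoms=atoms, box=box, time=float(len(frames))))
        i += 2 + n_atoms
    if not frames:
        raise ParseError(f"{path}: no XYZ frames found")
    return frames


def write_structure(
    frame: LabeledFrame, path: str | Path, format: str | None = None,
    title: str = "scpermeate frame",
) -> None:
    """Write a frame in the requested dialect (GRO fixed-width by default)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.write_text(_format_frame(frame, fmt, title))


def write_trajectory(
    traj: Trajectory, path: str | Path, format: str | None = None,
    title: str = "scpermeate frame",
) -> None:
    """Write a multi-frame GRO or PDB trajectory."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        text = "".join(_format_frame(f, "xyz", title) for f in traj.frames)
    elif fmt == "gro":
        text = "".join(_format_frame(f, "gro", title) for f in traj.frames)
    else:
        chunks = []
        for i, f in enumerate(traj.frames, start=1):
            chunks.append(f"MODEL     {i:4d}\n")
            chunks.append(_format_frame(f, "pdb", title, end_record=False))
            chunks.append("ENDMDL\n")
        chunks.append("END\n")
        text = "".join(chunks)
    path.write_text(text)


def _format_frame(
    frame: LabeledFrame, fmt: StructureFormat, title: str, end_record: bool = True
) -> str:
    if fmt == "gro":
        lines = [f"{title} t= {frame.time:.3f}", f"{frame.n_atoms:5d}"]
        for i, a in enumerate(frame.atoms, start=1):
            x, y, z = a.position
            lines.append(
                f"{a.residue_id % 100000:5d}{a.residue_name:<5.5s}"
                f"{a.atom_name:>5.5s}{i % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}"
            )
        b = frame.box
        lines.append(f"{b.lx:10.5f}{b.ly:10.5f}{b.lz:10.5f}")
        return "\n".join(lines) + "\n"
    if fmt == "pdb":
        b = frame.box
        lines = [
            f"CRYST1{b.lx / _ANGSTROM_TO_NM:9.3f}{b.ly / _ANGSTROM_TO_NM:9.3f}"
            f"{b.lz / _ANGSTROM_TO_NM:9.3f}  90.00  90.00  90.00 P 1           1"
        ]
        for i, a in enumerate(frame.atoms, start=1):
            x, y, z = a.position / _ANGSTROM_TO_NM
            el = (a.element or "")[:2]
            lines.append(
                f"ATOM  {i % 100000:5d} {a.atom_name:<4.4s}{a.residue_name:<4.4s} "
                f"{a.residue_id % 10000:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"  1.00  0.00          {el:>2s}"
            )
        if end_record:
            lines.append("END")
        return "\n".join(lines) + "\n"
    # xyz
    lines = [f"{frame.n_atoms}", title]
    for a in frame.atoms:
        x, y, z = a.position / _ANGSTROM_TO_NM
        lines.append(f"{a.element or a.atom_name} {x:.5f} {y:.5f} {z:.5f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """A uniformly sampled (time, value) series read from disk.

    ``dt`` is the detected sampling interval; ``uniform`` is False when the
    intervals vary beyond 1e-6 relative tolerance (a warning is emitted, the
    data are still returned in file order).
    """

    times: np.ndarray  # ps
    values: np.ndarray
    dt: float  # ps
    uniform: bool = True

    def __len__(self) -> int:
        return len(self.times)


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a two-column ``time value`` text file ('#'/'@' comments skipped)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"time-series file not found: {path}")
    times: list[float] = []
    values: list[float] = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        stripped = ln.strip()
        if not stripped or stripped[0] in "#@":
            continue
        fields = stripped.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {ln!r}")
        try:
            times.append(float(fields[0]))
            values.append(float(fields[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric field in {ln!r}") from exc
    if len(times) < 2:
        raise ParseError(f"{path}: need at least 2 data rows, found {len(times)}")
    t = np.array(times)
    v = np.array(values)
    dts = np.diff(t)
    if np.any(dts <= 0):
        bad = int(np.argmax(dts <= 0))
        raise ParseError(
            f"{path}: times must be strictly increasing (violated between rows "
            f"{bad} and {bad + 1}: {t[bad]} -> {t[bad + 1]})"
        )
    dt = float(np.median(dts))
    uniform = bool(np.all(np.abs(dts - dt) <= 1e-6 * max(dt, 1e-300)))
    if not uniform:
        warnings.warn(
            f"{path}: non-uniform sampling interval (median dt={dt} ps); "
            "series returned as read",
            stacklevel=2,
        )
    return TimeSeries(times=t, values=v, dt=dt, uniform=uniform)


def write_timeseries(
    path: str | Path,
    times: np.ndarray,
    values: np.ndarray,
    header: str | None = None,
) -> None:
    """Write a two-column series in the same dialect :func:`read_timeseries`
    consumes, at full float precision (round-trip exact)."""
    path = Path(path)
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for t, v in zip(times, values):
        lines.append(f"{float(t)!r} {float(v)!r}")
    path.write_text("\n".join(lines) + "\n")
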