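"""Hydrogen-bond counting and permeant-to-midplane distance tracking.

Hydrogen bonds use the geometric criterion standard in membrane trajectory
analysis: a donor-acceptor pair is bonded when its minimum-image distance
is at or below the cutoff (default 3.0 Angstrom = 0.30 nm). An optional
donor-hydrogen-acceptor angle criterion can be enabled when hydrogen
positions are available; it is off by default.

Permeant depth is tracked as the per-frame minimum distance between the
permeant group's atoms and the bilayer midplane (recomputed each frame from
the lipid reference atoms, since the bilayer drifts under pressure
coupling), either along z or as a full minimum-image 3D distance to the
lipid center of geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .model import AnalysisError, AnalysisWindow, ConfigurationError, LabeledFrame, Trajectory
from .selections import Predicate, select_atoms

__all__ = [
    "HBondCriterion",
    "DistanceSeries",
    "detect_hbonds",
    "hbond_count_summary",
    "min_distance_series",
    "average_series",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    ``da_cutoff`` is the donor-acceptor distance cutoff in nm (default
    0.30 nm). ``angle_cutoff`` in degrees enables the angle test: the
    donor-hydrogen-acceptor angle must be >= 180 - angle_cutoff.
    """

    da_cutoff: float = 0.30
    angle_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be positive")
        if self.angle_cutoff is not None and not (0 < self.angle_cutoff <= 90):
            raise ValueError("angle_cutoff must be in (0, 90] degrees")


@dataclass
class DistanceSeries:
    """Per-frame minimum distance of a permeant group to the bilayer
    midplane, for one replicate."""

    times: np.ndarray  # ps
    distances: np.ndarray  # nm
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")


def _minimum_image_deltas(
    pos_a: np.ndarray, pos_b: np.ndarray, box_lengths: np.ndarray
) -> np.ndarray:
    """(len(a), len(b), 3) displacement vectors under the minimum-image
    convention in an orthorhombic box."""
    delta = pos_a[:, None, :] - pos_b[None, :, :]
    delta -= box_lengths * np.round(delta / box_lengths)
    return delta


def detect_hbonds(
    frame: LabeledFrame,
    donors: Sequence[int],
    acceptors: Sequence[int],
    criterion: HBondCriterion = HBondCriterion(),
    hydrogens: Mapping[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Donor-acceptor pairs satisfying the geometric criterion.

    Self-pairs (same atom as donor and acceptor) are skipped. Pairs are
    returned sorted by (donor index, acceptor index). When the angle
    criterion is enabled, ``hydrogens`` must map each donor atom index to
    its hydrogen atom index.
    """
    donors = sorted(donors)
    acceptors = sorted(acceptors)
    if not donors or not acceptors:
        return []
    if criterion.angle_cutoff is not None and hydrogens is None:
        raise ConfigurationError(
            "angle criterion enabled but no donor->hydrogen mapping supplied"
        )
    pos = frame.positions
    box = frame.box.lengths
    delta = _minimum_image_deltas(pos[donors], pos[acceptors], box)
    dist = np.linalg.norm(delta, axis=-1)
    pairs: list[tuple[int, int]] = []
    for di, d in enumerate(donors):
        for ai, a in enumerate(acceptors):
            if d == a or dist[di, ai] > criterion.da_cutoff:
                continue
            if criterion.angle_cutoff is not None:
                h = hydrogens.get(d)  # type: ignore[union-attr]
                if h is None:
                    raise ConfigurationError(
                        f"angle criterion enabled but donor atom {d} has no "
                        "hydrogen mapping"
                    )
                if _dha_angle(pos[d], pos[h], pos[a], box) < 180.0 - criterion.angle_cutoff:
                    continue
            pairs.append((d, a))
    return pairs


def _dha_angle(
    donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray, box: np.ndarray
) -> float:
    """Donor-hydrogen-acceptor angle in degrees, minimum-image."""
    v1 = donor - hydrogen
    v1 -= box * np.round(v1 / box)
    v2 = acceptor - hydrogen
    v2 -= box * np.round(v2 / box)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbond_count_summary(
    traj: Trajectory,
    donors: Sequence[int],
    acceptors: Sequence[int],
    criterion: HBondCriterion = HBondCriterion(),
    window: AnalysisWindow | None = None,
    hydrogens: Mapping[int, int] | None = None,
) -> float:
    """Mean hydrogen-bond count over the analysis-window frames.

    Replicate standard errors are computed by the caller via
    :func:`scpermeate.bilayer.aggregate_replicates`.
    """
    frames = window.select_frames(traj) if window is not None else traj.frames
    counts = [
        len(detect_hbonds(f, donors, acceptors, criterion, hydrogens)) for f in frames
    ]
    return float(np.mean(counts))


def min_distance_series(
    traj: Trajectory,
    group_selector: str | Predicate,
    lipid_reference_selector: str | Predicate,
    mode: Literal["z_midplane", "com_point_3d"] = "z_midplane",
    replicate_id: int = 0,
) -> DistanceSeries:
    """Per-frame minimum distance from a permeant group to the bilayer
    center.

    ``z_midplane`` (default): min over group atoms of ``|z - midplane_z|``,
    the midplane being the mean z of the lipid reference atoms in that
    frame. ``com_point_3d``: min over group atoms of the minimum-image 3D
    distance to the lipid reference center of geometry.
    """
    times, dists = [], []
    for frame in traj.frames:
        group = select_atoms(frame, group_selector)
        if not group:
            raise AnalysisError(
                f"permeant group selector matched no atoms at t={frame.time} ps"
            )
        ref = select_atoms(frame, lipid_reference_selector)
        if not ref:
            raise AnalysisError(
                f"lipid reference selector matched no atoms at t={frame.time} ps"
            )
        pos = frame.positions
        if mode == "z_midplane":
            midplane = pos[list(ref), 2].mean()
            d = float(np.min(np.abs(pos[list(group), 2] - midplane)))
        elif mode == "com_point_3d":
            center = pos[list(ref)].mean(axis=0)
            delta = _minimum_image_deltas(
                pos[list(group)], center[None, :], frame.box.lengths
            )[:, 0, :]
            d = float(np.min(np.linalg.norm(delta, axis=-1)))
        else:
            raise ConfigurationError(f"unknown distance mode {mode!r}")
        times.append(frame.time)
        dists.append(d)
    return DistanceSeries(
        times=np.array(times), distances=np.array(dists), replicate_id=replicate_id
    )


@dataclass
class AveragedSeries:
    times: np.ndarray
    mean: np.ndarray
    std: np.ndarray  # pointwise population standard deviation


def average_series(series: Sequence[DistanceSeries]) -> AveragedSeries:
    """Pointwise mean and population standard deviation across replicates.

    Series on different time grids are linearly interpolated onto the first
    series' grid, restricted to the overlapping time range (interpolation
    only, never extrapolation). A single series yields a zero band with a
    warning.
    """
    if not series:
        raise AnalysisError("average_series needs at least one series")
    if len(series) == 1:
        warnings.warn(
            "single replicate: standard-deviation band is identically zero",
            stacklevel=2,
        )
        s = series[0]
        return AveragedSeries(
            times=s.times.copy(), mean=s.distances.copy(), std=np.zeros_like(s.distances)
        )
    t0 = series[0].times
    t_lo = max(s.times[0] for s in series)
    t_hi = min(s.times[-1] for s in series)
    if t_lo > t_hi:
        raise AnalysisError("replicate series have no overlapping time range")
    grid = t0[(t0 >= t_lo) & (t0 <= t_hi)]
    stack = np.vstack([np.interp(grid, s.times, s.distances) for s in series])
    return AveragedSeries(
        times=grid, mean=stack.mean(axis=0), std=stack.std(axis=0, ddof=0)
    )
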