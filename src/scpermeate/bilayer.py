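"""Structural observables of a lipid bilayer: leaflet assignment, thickness,
and area-per-lipid via periodic Voronoi tessellation.

Thickness is the difference between the mean z of headgroup atoms in the
upper and lower leaflets (the bilayer normal is taken along z throughout).
Area-per-lipid tessellates each leaflet's reference atoms in the xy-plane
with full periodic images (3x3 tiling) so every central cell is closed; the
cell areas of one leaflet always sum to the box cross-section.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from .model import AnalysisError, AnalysisWindow, LabeledFrame, Trajectory
from .selections import Predicate, compile_selector, select_atoms

__all__ = [
    "LeafletAssignment",
    "BilayerMetrics",
    "assign_leaflets",
    "bilayer_thickness",
    "area_per_lipid",
    "aggregate_replicates",
]


@dataclass
class LeafletAssignment:
    """Partition of lipid reference atoms into upper/lower leaflets."""

    upper: tuple[int, ...]
    lower: tuple[int, ...]
    midplane_z: float  # nm

    def __post_init__(self) -> None:
        if set(self.upper) & set(self.lower):
            raise ValueError("upper and lower leaflets must be disjoint")


@dataclass
class BilayerMetrics:
    """Table of structural observables, mean +/- standard error over
    replicate simulations (standard error over replicate means, never
    pooled frames)."""

    thickness: float  # nm
    thickness_se: float
    area_per_lipid: float  # nm^2
    area_per_lipid_se: float
    hbond_count: float
    hbond_count_se: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.area_per_lipid <= 0:
            raise ValueError("thickness and area_per_lipid must be positive")
        if min(self.thickness_se, self.area_per_lipid_se, self.hbond_count_se) < 0:
            raise ValueError("standard errors must be non-negative")


def assign_leaflets(
    frame: LabeledFrame, reference_selector: str | Predicate
) -> LeafletAssignment:
    """Split lipid reference atoms into leaflets about their mean z.

    The midplane is the mean z of all reference atoms; atoms above it go to
    the upper leaflet, below to the lower. An atom exactly at the midplane
    is assigned upper with a warning. An empty leaflet (all atoms on one
    side) raises: that is not a bilayer.
    """
    idx = select_atoms(frame, reference_selector)
    if len(idx) < 2:
        raise AnalysisError(
            f"leaflet assignment needs >= 2 reference atoms, selector matched {len(idx)}"
        )
    z = np.array([frame.atoms[i].position[2] for i in idx])
    midplane = float(z.mean())
    upper = tuple(i for i, zi in zip(idx, z) if zi >= midplane)
    lower = tuple(i for i, zi in zip(idx, z) if zi < midplane)
    if any(zi == midplane for zi in z):
        warnings.warn(
            "reference atom exactly at the midplane; assigned to upper leaflet",
            stacklevel=2,
        )
    if not upper or not lower:
        raise AnalysisError(
            "all reference atoms lie on one side of their mean z: not a bilayer"
        )
    return LeafletAssignment(upper=upper, lower=lower, midplane_z=midplane)


@dataclass
class ThicknessResult:
    times: np.ndarray  # ps
    values: np.ndarray  # nm, per frame
    mean: float  # nm, over window frames


def bilayer_thickness(
    traj: Trajectory,
    headgroup_selector: str | Predicate,
    window: AnalysisWindow | None = None,
) -> ThicknessResult:
    """Per-frame bilayer thickness and its window mean.

    Per frame: thickness = mean z of upper-leaflet headgroups minus mean z
    of lower-leaflet headgroups, leaflets assigned per frame from the same
    selection. Replicate standard errors are the caller's job via
    :func:`aggregate_replicates`.
    """
    pred = (
        compile_selector(headgroup_selector)
        if isinstance(headgroup_selector, str)
        else headgroup_selector
    )
    frames = window.select_frames(traj) if window is not None else traj.frames
    times, values = [], []
    for frame in frames:
        try:
            leaflets = assign_leaflets(frame, pred)
        except AnalysisError as exc:
            raise AnalysisError(
                f"thickness at t={frame.time} ps: {exc}"
            ) from exc
        zu = np.mean([frame.atoms[i].position[2] for i in leaflets.upper])
        zl = np.mean([frame.atoms[i].position[2] for i in leaflets.lower])
        times.append(frame.time)
        values.append(float(zu - zl))
    return ThicknessResult(
        times=np.array(times), values=np.array(values), mean=float(np.mean(values))
    )


@dataclass
class AreaPerLipidResult:
    upper_areas: np.ndarray  # nm^2, one per upper-leaflet lipid
    lower_areas: np.ndarray
    upper_mean: float
    lower_mean: float
    frame_mean: float  # unweighted mean of the two leaflet means


def _periodic_voronoi_areas(points_xy: np.ndarray, lx: float, ly: float) -> np.ndarray:
    """Voronoi cell areas of seeds in a periodic lx-by-ly cell.

    Seeds are wrapped into the central cell, tiled into the 8 neighboring
    images, and tessellated; only central-copy cells are kept, so every
    retained region is finite as long as cells are smaller than the box.
    """
    n = len(points_xy)
    if n < 3:
        raise AnalysisError(f"Voronoi tessellation needs >= 3 seeds, got {n}")
    pts = points_xy.copy()
    pts[:, 0] %= lx
    pts[:, 1] %= ly
    shifts = [
        (dx * lx, dy * ly) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
    ]
    tiled = np.vstack([pts] + [pts + np.array(s) for s in shifts])
    vor = Voronoi(tiled)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise AnalysisError(
                "open Voronoi cell after periodic tiling: a cell spans more "
                "than one box length"
            )
        verts = vor.vertices[region]
        # shoelace
        x, y = verts[:, 0], verts[:, 1]
        areas[i] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return areas


def area_per_lipid(
    frame: LabeledFrame,
    reference_selector: str | Predicate | None = None,
    leaflets: LeafletAssignment | None = None,
) -> AreaPerLipidResult:
    """Per-lipid Voronoi areas and leaflet means for one frame.

    Each leaflet's reference atoms are projected onto the xy-plane and
    tessellated with periodic images. The frame value is the unweighted
    mean of the two leaflet means (leaflets may hold unequal lipid counts
    after permeant insertion; symmetric treatment avoids weighting one
    leaflet by count). Pass either a precomputed ``leaflets`` assignment or
    a ``reference_selector`` to derive one.
    """
    if leaflets is None:
        if reference_selector is None:
            raise AnalysisError(
                "area_per_lipid needs a reference_selector or a LeafletAssignment"
            )
        leaflets = assign_leaflets(frame, reference_selector)
    box = frame.box
    pos = frame.positions
    out = {}
    for name, idx in (("upper", leaflets.upper), ("lower", leaflets.lower)):
        if len(idx) < 3:
            raise AnalysisError(
                f"{name} leaflet has {len(idx)} reference atoms; need >= 3"
            )
        areas = _periodic_voronoi_areas(pos[list(idx), :2], box.lx, box.ly)
        total = areas.sum()
        if abs(total - box.cross_section) > 1e-9 * box.cross_section:
            raise AnalysisError(
                f"Voronoi areas of the {name} leaflet sum to {total:.12g} nm^2, "
                f"expected box cross-section {box.cross_section:.12g} nm^2"
            )
        out[name] = areas
    upper_mean = float(out["upper"].mean())
    lower_mean = float(out["lower"].mean())
    return AreaPerLipidResult(
        upper_areas=out["upper"],
        lower_areas=out["lower"],
        upper_mean=upper_mean,
        lower_mean=lower_mean,
        frame_mean=0.5 * (upper_mean + lower_mean),
    )


def aggregate_replicates(values) -> tuple[float, float]:
    """Mean and standard error over replicate summaries.

    Standard error is sample-std/sqrt(n) over replicate means (ddof=1);
    zero for a single replicate.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise AnalysisError("aggregate_replicates needs at least one replicate")
    mean = float(values.mean())
    if values.size == 1:
        return mean, 0.0
    se = float(values.std(ddof=1) / np.sqrt(values.size))
    return mean, se
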