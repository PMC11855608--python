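"""Synthetic data with known ground truth for every analysis stage.

Three generator families:

* **Restrained-permeant force series** — an overdamped Langevin (Ornstein-
  Uhlenbeck) particle in a harmonic restraint, integrated by Euler-Maruyama
  at the storage interval. The restraint force -k(z - z0) is recorded every
  dt, exactly the input the diffusivity estimator consumes, with D known by
  construction. Spatially varying D(z) landscapes use the Ito convention
  with the dD/dz drift correction (without it the stationary density is
  wrong and recovery tests would be biased).

* **Pseudo-bilayer frames** — two leaflets of single-site pseudo-lipids on
  jittered lattices at z = +/- separation/2, with planted donor-acceptor
  pairs (0.28 nm apart, inside the hydrogen-bond cutoff) and decoy pairs
  (0.35 nm, outside it). Thickness, area-per-lipid and hydrogen-bond counts
  are exact by construction on the unjittered lattice.

* **Adsorption traces** — a deterministic approach-to-the-bilayer drift
  plus seeded Gaussian noise, clipped at zero, emulating replicate
  permeant-depth time series.

Default scales mirror a body-temperature stratum-corneum permeation study:
T = 310 K, storage every 0.1 ps, 10 ns analyzed per window, spring
constants 1000-3000 kJ/mol/nm^2, D around 1e-4 nm^2/ps (~1e-6 cm^2/s).
All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.signal import lfilter

from .diffusivity import ForceSeries
from .interactions import DistanceSeries
from .model import (
    AnalysisError,
    AtomRecord,
    ConfigurationError,
    LabeledFrame,
    R_KJ_PER_MOL_K,
    SimulationBox,
)

__all__ = [
    "LandscapeSpec",
    "BilayerSpec",
    "simulate_ou_window",
    "simulate_permeant_windows",
    "build_synthetic_bilayer",
    "simulate_adsorption_traces",
]


@dataclass
class LandscapeSpec:
    """Piecewise-linear ground-truth D(z) (nm^2/ps) and optional potential
    of mean force (kJ/mol) over z in [z_knots[0], z_knots[-1]]."""

    z_knots: np.ndarray  # nm, ascending
    d_knots: np.ndarray  # nm^2/ps
    pmf_knots: np.ndarray | None = None  # kJ/mol
    temperature: float = 310.0  # K

    def __post_init__(self) -> None:
        self.z_knots = np.asarray(self.z_knots, dtype=float)
        self.d_knots = np.asarray(self.d_knots, dtype=float)
        if self.z_knots.ndim != 1 or len(self.z_knots) < 2:
            raise ValueError("need at least two z knots")
        if np.any(np.diff(self.z_knots) <= 0):
            raise ValueError("z knots must be strictly ascending")
        if self.d_knots.shape != self.z_knots.shape:
            raise ValueError("d_knots must match z_knots in length")
        if np.any(self.d_knots <= 0):
            raise ValueError("D(z) must be positive everywhere")
        if self.pmf_knots is not None:
            self.pmf_knots = np.asarray(self.pmf_knots, dtype=float)
            if self.pmf_knots.shape != self.z_knots.shape:
                raise ValueError("pmf_knots must match z_knots in length")

    def d_of_z(self, z: float) -> float:
        return float(np.interp(z, self.z_knots, self.d_knots))

    def d_slope(self, z: float) -> float:
        """dD/dz of the piecewise-linear profile (one-sided at knots)."""
        i = int(np.clip(np.searchsorted(self.z_knots, z) - 1, 0, len(self.z_knots) - 2))
        return float(
            (self.d_knots[i + 1] - self.d_knots[i])
            / (self.z_knots[i + 1] - self.z_knots[i])
        )

    def pmf_force(self, z: float) -> float:
        """-dV/dz in kJ mol^-1 nm^-1 (0 when no potential is set)."""
        if self.pmf_knots is None:
            return 0.0
        i = int(np.clip(np.searchsorted(self.z_knots, z) - 1, 0, len(self.z_knots) - 2))
        return float(
            -(self.pmf_knots[i + 1] - self.pmf_knots[i])
            / (self.z_knots[i + 1] - self.z_knots[i])
        )

    def contains(self, z: float) -> bool:
        return self.z_knots[0] <= z <= self.z_knots[-1]

    @classmethod
    def flat(
        cls, d0: float, z_max: float = 3.5, temperature: float = 310.0
    ) -> "LandscapeSpec":
        return cls(
            z_knots=np.array([-z_max, z_max]),
            d_knots=np.array([d0, d0]),
            temperature=temperature,
        )


def simulate_ou_window(
    D_true: float,
    k: float = 1000.0,
    T: float = 310.0,
    z0: float = 0.0,
    dt: float = 0.1,
    duration: float = 10_000.0,
    seed: int = 0,
) -> ForceSeries:
    """Restraint-force series of a harmonically restrained Brownian particle.

    Euler-Maruyama for dz = -(D/RT) k (z - z0) dt + sqrt(2 D dt) xi, started
    from the stationary distribution N(z0, RT/k); forces F_i = -k (z_i - z0)
    recorded every dt. Parameters: D_true in nm^2/ps, k in kJ/mol/nm^2, T in
    K, dt and duration in ps.

    The ground-truth relations used throughout the tests: force variance
    k RT, force correlation time tau = RT/(k D), ACF integral (RT)^2 / D.
    """
    if D_true <= 0 or k <= 0 or T <= 0 or dt <= 0 or duration <= 0:
        raise ValueError("D_true, k, T, dt, duration must all be positive")
    rt = R_KJ_PER_MOL_K * T
    theta = k * D_true / rt  # relaxation rate, 1/ps
    tau = 1.0 / theta
    if dt >= 2 * tau:
        raise AnalysisError(
            f"unstable integration: dt={dt} ps >= 2*tau={2 * tau:.4g} ps"
        )
    if dt > tau / 10:
        warnings.warn(
            f"dt={dt} ps exceeds tau/10={tau / 10:.4g} ps; discretization bias "
            "may be noticeable",
            stacklevel=2,
        )
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    a = 1.0 - theta * dt
    sigma = np.sqrt(2.0 * D_true * dt)
    x_init = rng.normal(0.0, np.sqrt(rt / k))
    noise = rng.normal(0.0, sigma, size=n - 1)
    # AR(1) recursion x_i = a x_{i-1} + w_i, vectorized as an IIR filter
    tail = lfilter([1.0], [1.0, -a], noise)
    tail += x_init * a ** np.arange(1, n)
    x = np.concatenate(([x_init], tail))
    return ForceSeries(
        values=-k * x, dt=dt, window_center_z=z0, spring_k=k, temperature=T
    )


def simulate_permeant_windows(
    landscape: LandscapeSpec,
    centers: Sequence[float],
    k: float = 1000.0,
    dt: float = 0.1,
    duration: float = 10_000.0,
    seed: int = 0,
) -> list[ForceSeries]:
    """One restrained window per center on an inhomogeneous D(z) landscape.

    Each window integrates overdamped Langevin dynamics with the local
    diffusivity, the Ito drift correction dD/dz, and the total force
    -dV/dz - k (z - z0). Per-window seeds are ``seed + window index``.
    Where D is locally constant this reduces exactly to
    :func:`simulate_ou_window`'s dynamics.
    """
    for z0 in centers:
        if not landscape.contains(z0):
            raise AnalysisError(
                f"window center {z0} nm outside landscape domain "
                f"[{landscape.z_knots[0]}, {landscape.z_knots[-1]}] nm"
            )
    rt = R_KJ_PER_MOL_K * landscape.temperature
    n = int(round(duration / dt))
    centers_sorted = np.array(sorted(centers))
    m = len(centers_sorted)
    # independent per-window noise streams, seed + window index
    z = np.empty(m)
    noise = np.empty((n - 1, m))
    for i in range(m):
        rng = np.random.default_rng(seed + i)
        z[i] = centers_sorted[i] + rng.normal(0.0, np.sqrt(rt / k))
        noise[:, i] = rng.standard_normal(n - 1)
    zk = landscape.z_knots
    dk = landscape.d_knots
    d_slopes = np.diff(dk) / np.diff(zk)
    if landscape.pmf_knots is not None:
        pmf_slopes = np.diff(landscape.pmf_knots) / np.diff(zk)
    else:
        pmf_slopes = None
    zs = np.empty((n, m))
    zs[0] = z
    # one Euler-Maruyama loop stepping every window column at once
    for j in range(1, n):
        seg = np.clip(np.searchsorted(zk, z) - 1, 0, len(zk) - 2)
        d = np.interp(z, zk, dk)
        force = -k * (z - centers_sorted)
        if pmf_slopes is not None:
            force = force - pmf_slopes[seg]
        z = z + (d / rt * force + d_slopes[seg]) * dt + np.sqrt(2.0 * d * dt) * noise[j - 1]
        zs[j] = z
    return [
        ForceSeries(
            values=-k * (zs[:, i] - centers_sorted[i]),
            dt=dt,
            window_center_z=float(centers_sorted[i]),
            spring_k=k,
            temperature=landscape.temperature,
        )
        for i in range(m)
    ]


@dataclass
class BilayerSpec:
    """Parametric pseudo-bilayer: lattice lipids in two leaflets plus
    planted hydrogen-bond donors/acceptors and decoys.

    The box cross-section is ``n_lipids_per_leaflet * apl_target`` by
    construction, so an unjittered lattice has exactly the target
    area-per-lipid.
    """

    n_lipids_per_leaflet: int = 150
    apl_target: float = 1.00  # nm^2
    headgroup_plane_separation: float = 4.53  # nm
    jitter_amplitude: float = 0.0  # nm, uniform in x, y, z
    planted_hbond_pairs: int = 0
    decoy_pairs: int = 0
    seed: int = 0

    #: residue names cycled over lattice sites (ceramide NS, cholesterol,
    #: free fatty acid — the equimolar stratum-corneum lipid mix)
    species: tuple[str, ...] = ("CER", "CHL", "FFA")
    head_atom: str = "HG"

    PLANTED_DISTANCE = 0.28  # nm, inside the 0.30 nm cutoff
    DECOY_DISTANCE = 0.35  # nm, outside it

    def __post_init__(self) -> None:
        if self.n_lipids_per_leaflet < 3:
            raise ValueError("need at least 3 lipids per leaflet")
        if self.apl_target <= 0 or self.headgroup_plane_separation <= 0:
            raise ValueError("apl_target and plane separation must be positive")
        if self.jitter_amplitude < 0:
            raise ValueError("jitter_amplitude must be non-negative")


def _lattice_dims(n: int) -> tuple[int, int]:
    """Divisor pair (nx, ny) with nx*ny == n, as close to square as possible."""
    nx = int(np.floor(np.sqrt(n)))
    while n % nx:
        nx -= 1
    return nx, n // nx


def build_synthetic_bilayer(spec: BilayerSpec) -> LabeledFrame:
    """Construct a pseudo-bilayer frame with planted ground truth.

    Lipids are single-site headbeads on an nx-by-ny lattice per leaflet at
    z = +/- separation/2, jittered uniformly in [-j, j] per coordinate.
    Donor atoms (residue DON, atom OD) sit 1 nm above the upper plane with
    their acceptors (residue ACC, atom OA) displaced +0.28 nm in z; decoy
    pairs (residues DEC/DCA) are displaced +0.35 nm. Output is
    deterministic for a given spec.
    """
    n = spec.n_lipids_per_leaflet
    nx, ny = _lattice_dims(n)
    spacing = np.sqrt(spec.apl_target)
    lx, ly = nx * spacing, ny * spacing
    if spec.jitter_amplitude >= spacing / 2:
        raise ConfigurationError(
            f"jitter {spec.jitter_amplitude} nm >= half lattice spacing "
            f"{spacing / 2:.3g} nm: leaflet lattices would scramble"
        )
    half_sep = spec.headgroup_plane_separation / 2
    lz = spec.headgroup_plane_separation + 4.0  # room for a water slab
    z_offset = lz / 2  # midplane at box center
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    resid = 1
    for leaflet_sign in (+1, -1):
        z_plane = z_offset + leaflet_sign * half_sep
        for iy in range(ny):
            for ix in range(nx):
                site = ix + iy * nx
                pos = np.array(
                    [(ix + 0.5) * spacing, (iy + 0.5) * spacing, z_plane]
                )
                if spec.jitter_amplitude > 0:
                    pos = pos + rng.uniform(
                        -spec.jitter_amplitude, spec.jitter_amplitude, size=3
                    )
                atoms.append(
                    AtomRecord(
                        residue_name=spec.species[site % len(spec.species)],
                        atom_name=spec.head_atom,
                        residue_id=resid,
                        position=pos,
                    )
                )
                resid += 1
    # planted donor-acceptor pairs and decoys above the upper plane,
    # spaced >= 0.8 nm apart so no cross-pair contact is within any
    # plausible cutoff
    pair_grid = 0.8
    per_row = max(int(lx / pair_grid), 1)
    z_pairs = z_offset + half_sep + 1.0
    for kind, count, dz, names in (
        ("planted", spec.planted_hbond_pairs, BilayerSpec.PLANTED_DISTANCE, ("DON", "ACC", "OD", "OA")),
        ("decoy", spec.decoy_pairs, BilayerSpec.DECOY_DISTANCE, ("DEC", "DCA", "OD", "OA")),
    ):
        row_offset = 0.0 if kind == "planted" else 0.4
        for p in range(count):
            px = (p % per_row) * pair_grid + 0.4
            py = (p // per_row) * pair_grid + 0.4 + row_offset
            if py >= ly:
                raise ConfigurationError(
                    "too many planted/decoy pairs for the box cross-section"
                )
            dres, ares, datom, aatom = names
            dpos = np.array([px, py, z_pairs])
            atoms.append(AtomRecord(dres, datom, resid, dpos))
            atoms.append(AtomRecord(ares, aatom, resid + 1, dpos + np.array([0, 0, dz])))
            resid += 2
    return LabeledFrame(atoms=atoms, box=SimulationBox(lx, ly, lz), time=0.0)


def simulate_adsorption_traces(
    n_replicates: int,
    drift_profile: Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.2,
    dt: float = 100.0,
    duration: float = 100_000.0,
    seed: int = 0,
) -> list[DistanceSeries]:
    """Replicate permeant-depth traces: deterministic drift plus noise.

    ``drift_profile`` maps times (ps) to the noise-free minimum distance
    (nm); the default is an exponential approach from 3.5 nm to 0.5 nm with
    a 20 ns time constant, the shape of an adsorbing permeant. Each
    replicate adds N(0, noise_sd^2) (seeded ``seed + replicate``) and clips
    at zero.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if drift_profile is None:
        drift_profile = lambda t: 0.5 + 3.0 * np.exp(-t / 20_000.0)
    times = np.arange(0.0, duration + dt / 2, dt)
    drift = np.asarray(drift_profile(times), dtype=float)
    traces = []
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        noisy = drift + rng.normal(0.0, noise_sd, size=len(times)) if noise_sd > 0 else drift.copy()
        traces.append(
            DistanceSeries(
                times=times.copy(), distances=np.clip(noisy, 0.0, None), replicate_id=r
            )
        )
    return traces
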