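"""Hydrogen-bond detection, window counting, permeant-depth tracking."""

import numpy as np
import pytest

from scpermeate.interactions import (
    DistanceSeries,
    HBondCriterion,
    average_series,
    detect_hbonds,
    hbond_count_summary,
    min_distance_series,
)
from scpermeate.model import AnalysisWindow, ConfigurationError, Trajectory
from scpermeate.selections import select_atoms
from scpermeate.synthetic import BilayerSpec, build_synthetic_bilayer


def pair_frame(frame_factory, separation, box=(5.0, 5.0, 5.0)):
    return frame_factory(
        [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0 + separation]],
        residue_names=["DON", "ACC"],
        atom_names=["OD", "OA"],
        box=box,
    )


def test_pair_inside_cutoff_detected(frame_factory):
    frame = pair_frame(frame_factory, 0.29)
    assert detect_hbonds(frame, [0], [1]) == [(0, 1)]


def test_pair_outside_cutoff_rejected(frame_factory):
    frame = pair_frame(frame_factory, 0.31)
    assert detect_hbonds(frame, [0], [1]) == []


def test_planted_pairs_found_decoys_rejected():
    frame = build_synthetic_bilayer(
        BilayerSpec(n_lipids_per_leaflet=100, planted_hbond_pairs=10, decoy_pairs=5)
    )
    donors = select_atoms(frame, "residue_name in {DON, DEC}")
    acceptors = select_atoms(frame, "residue_name in {ACC, DCA}")
    pairs = detect_hbonds(frame, donors, acceptors)
    assert len(pairs) == 10


def test_count_monotone_in_cutoff():
    frame = build_synthetic_bilayer(
        BilayerSpec(n_lipids_per_leaflet=49, planted_hbond_pairs=8, decoy_pairs=6)
    )
    donors = select_atoms(frame, "residue_name in {DON, DEC}")
    acceptors = select_atoms(frame, "residue_name in {ACC, DCA}")
    counts = [
        len(detect_hbonds(frame, donors, acceptors, HBondCriterion(da_cutoff=c)))
        for c in (0.2, 0.29, 0.36, 0.5)
    ]
    assert counts == sorted(counts)
    assert counts[1] == 8 and counts[2] == 14


def test_detection_invariant_under_translation_and_wrap(frame_factory):
    frame = pair_frame(frame_factory, 0.28)
    # translate so the acceptor wraps across the periodic boundary
    shifted = frame.translated([0.0, 0.0, 3.85])
    assert detect_hbonds(shifted, [0], [1]) == [(0, 1)]


def test_angle_criterion_requires_hydrogens(frame_factory):
    frame = pair_frame(frame_factory, 0.28)
    crit = HBondCriterion(angle_cutoff=30.0)
    with pytest.raises(ConfigurationError, match="hydrogen"):
        detect_hbonds(frame, [0], [1], crit)


def test_angle_criterion_filters_bent_geometry(frame_factory):
    # donor, its hydrogen, and two acceptors: one collinear, one at 90 deg
    frame = frame_factory(
        [
            [1.0, 1.0, 1.0],  # donor
            [1.0, 1.0, 1.1],  # hydrogen, along +z
            [1.0, 1.0, 1.29],  # acceptor collinear (DHA = 180)
            [1.0, 1.25, 1.0],  # acceptor sideways (DHA ~ 68 deg)
        ],
        residue_names=["DON", "DON", "ACC", "ACC"],
        atom_names=["OD", "H", "OA", "OA"],
    )
    crit = HBondCriterion(da_cutoff=0.30, angle_cutoff=30.0)
    pairs = detect_hbonds(frame, [0], [2, 3], crit, hydrogens={0: 1})
    assert pairs == [(0, 2)]


def test_hbond_count_summary_window_mean(frame_factory):
    frames = []
    for i, sep in enumerate([0.28, 0.32, 0.28, 0.32]):
        f = pair_frame(frame_factory, sep)
        f.time = float(i)
        frames.append(f)
    traj = Trajectory(frames=frames)
    assert hbond_count_summary(traj, [0], [1]) == pytest.approx(0.5)
    assert hbond_count_summary(
        traj, [0], [1], window=AnalysisWindow(t_start=0, t_end=1)
    ) == pytest.approx(0.5)


def test_hbond_bernoulli_plant_matches_binomial(frame_factory):
    """200 frames with 40 sites each present with p=0.5: the window mean
    must fall within 3 binomial standard errors of 20."""
    rng = np.random.default_rng(11)
    n_sites, n_frames, p = 40, 200, 0.5
    frames = []
    for t in range(n_frames):
        present = rng.random(n_sites) < p
        positions, resnames, atnames = [], [], []
        for s in range(n_sites):
            sep = 0.28 if present[s] else 0.40
            x = 1.0 + s * 1.0
            positions += [[x, 1.0, 1.0], [x, 1.0, 1.0 + sep]]
            resnames += ["DON", "ACC"]
            atnames += ["OD", "OA"]
        f = frame_factory(positions, resnames, atnames, box=(50.0, 50.0, 5.0))
        f.time = float(t)
        frames.append(f)
    traj = Trajectory(frames=frames)
    donors = select_atoms(frames[0], "residue_name == DON")
    acceptors = select_atoms(frames[0], "residue_name == ACC")
    mean = hbond_count_summary(traj, donors, acceptors)
    tol = 3 * np.sqrt(n_sites * p * (1 - p) / n_frames)
    assert abs(mean - n_sites * p) < tol


def test_min_distance_single_atom(frame_factory):
    frames = []
    f = frame_factory(
        [[1.0, 1.0, 2.0], [1.0, 1.0, 2.0], [2.0, 2.0, 5.0]],
        residue_names=["CER", "CER", "NIA"],
        atom_names=["HG", "HG", "C1"],
        box=(10, 10, 10),
    )
    frames.append(f)
    traj = Trajectory(frames=frames)
    series = min_distance_series(traj, "residue_name == NIA", "residue_name == CER")
    assert series.distances[0] == pytest.approx(3.0)


def test_min_distance_takes_group_minimum(frame_factory):
    f = frame_factory(
        [[0, 0, 2.0], [0, 0, 2.0], [0, 0, 3.0], [0, 0, 2.4], [0, 0, 4.2]],
        residue_names=["CER", "CER", "NIA", "NIA", "NIA"],
        atom_names=["HG", "HG", "C1", "C2", "C3"],
        box=(10, 10, 10),
    )
    traj = Trajectory(frames=[f])
    series = min_distance_series(traj, "residue_name == NIA", "residue_name == CER")
    assert series.distances[0] == pytest.approx(0.4)


def test_com_mode_uses_minimum_image(frame_factory):
    """3D mode distance equals brute-force minimum over all 27 periodic
    image shifts."""
    box = (4.0, 5.0, 6.0)
    f = frame_factory(
        [[0.2, 0.3, 0.1], [3.9, 4.8, 5.9]],
        residue_names=["CER", "NIA"],
        atom_names=["HG", "C1"],
        box=box,
    )
    traj = Trajectory(frames=[f])
    series = min_distance_series(
        traj, "residue_name == NIA", "residue_name == CER", mode="com_point_3d"
    )
    center = np.array([0.2, 0.3, 0.1])
    atom = np.array([3.9, 4.8, 5.9])
    brute = min(
        np.linalg.norm(atom + np.array([i, j, k]) * np.array(box) - center)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
    )
    assert series.distances[0] == pytest.approx(brute, abs=1e-12)


def test_average_identical_series_zero_band():
    t = np.arange(5.0)
    d = np.array([3.0, 2.5, 2.0, 1.5, 1.0])
    avg = average_series([DistanceSeries(t, d, 0), DistanceSeries(t, d.copy(), 1)])
    np.testing.assert_allclose(avg.mean, d)
    np.testing.assert_allclose(avg.std, 0.0)


def test_average_offset_series_band_is_half_gap():
    t = np.arange(4.0)
    d = np.array([3.0, 2.0, 1.5, 1.0])
    avg = average_series([DistanceSeries(t, d, 0), DistanceSeries(t, d + 2, 1)])
    np.testing.assert_allclose(avg.mean, d + 1)
    np.testing.assert_allclose(avg.std, 1.0)


def test_average_single_series_warns():
    t = np.arange(3.0)
    with pytest.warns(UserWarning, match="single replicate"):
        avg = average_series([DistanceSeries(t, t + 1, 0)])
    np.testing.assert_allclose(avg.std, 0.0)


def test_average_noisy_series_band_matches_noise_scale(rng):
    """10 replicates of g(t) + N(0, 0.5^2): the pointwise std estimate
    (population, n=10) follows sigma*sqrt(chi2_9/10), so the band lies in
    [0.3, 0.7] for ~91.5% of points; assert a 5-sigma-safe 85% plus the
    overall scale."""
    t = np.arange(0.0, 500.0)
    g = 1.0 + 2.0 * np.exp(-t / 100.0)
    series = [
        DistanceSeries(t, np.clip(g + rng.normal(0, 0.5, len(t)), 0, None), r)
        for r in range(10)
    ]
    avg = average_series(series)
    frac = np.mean((avg.std >= 0.3) & (avg.std <= 0.7))
    assert frac >= 0.85
    assert np.mean(avg.std) == pytest.approx(0.5, abs=0.05)


def test_average_resamples_onto_first_grid():
    t1 = np.arange(0.0, 10.0)
    t2 = np.arange(0.5, 9.6)
    s1 = DistanceSeries(t1, np.ones_like(t1), 0)
    s2 = DistanceSeries(t2, np.full_like(t2, 3.0), 1)
    avg = average_series([s1, s2])
    assert avg.times[0] >= 0.5 and avg.times[-1] <= 9.5
    np.testing.assert_allclose(avg.mean, 2.0)
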