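"""Trajectory analytics: contacts, hotspots, interactions, energies, states."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from padock.structures import Atom, Structure, StructureError, Trajectory
from padock.trajectory import (AnalysisError, aggregate_replicas,
                               classify_sidechain, combine_profiles,
                               conditional_energy, contact_delta,
                               contact_frequencies, detect_interactions,
                               interaction_energy_series, select_hotspots)


def _pair_system(distance):
    atoms = [
        Atom(1, "CA", "C", "GLY", 10, "E", (0.0, 0.0, 0.0)),
        Atom(2, "S1", "C", "SUB", 1, "S", (0.0, 0.0, distance)),
    ]
    s = Structure(atoms)
    s.set_group("enzyme", [0])
    s.set_group("substrate", [1])
    return s


@pytest.mark.parametrize("distance,expected", [(2.4, 100.0), (2.5, 100.0),
                                               (2.6, 0.0)])
def test_contact_cutoff_is_inclusive(distance, expected):
    s = _pair_system(distance)
    traj = Trajectory(structure=s, frames=np.repeat(s.coords[None], 10, axis=0))
    prof = contact_frequencies(traj)
    assert prof.freqs[0, 0] == expected


def test_contact_frequencies_match_brute_force_oracle(rng):
    n_res, n_sub, n_frames = 6, 5, 20
    atoms, idx_e, idx_s = [], [], []
    serial = 1
    for r in range(n_res):
        atoms.append(Atom(serial, "CA", "C", "GLY", r + 1, "E", (0, 0, 0)))
        idx_e.append(serial - 1)
        serial += 1
        atoms.append(Atom(serial, "CB", "C", "GLY", r + 1, "E", (0, 0, 0)))
        idx_e.append(serial - 1)
        serial += 1
    for k in range(n_sub):
        atoms.append(Atom(serial, f"S{k}", "C", "SUB", 1, "S", (0, 0, 0)))
        idx_s.append(serial - 1)
        serial += 1
    s = Structure(atoms)
    s.set_group("enzyme", idx_e)
    s.set_group("substrate", idx_s)
    frames = rng.uniform(-4, 4, (n_frames, len(atoms), 3))
    traj = Trajectory(structure=s, frames=frames)
    prof = contact_frequencies(traj, cutoff=2.5)
    for ri in range(n_res):
        res_atoms = [2 * ri, 2 * ri + 1]
        hits = 0
        for f in range(n_frames):
            dmin = min(np.linalg.norm(frames[f, i] - frames[f, j])
                       for i in res_atoms for j in idx_s)
            hits += dmin <= 2.5
        assert prof.freqs[0, ri] == pytest.approx(100.0 * hits / n_frames)


def test_contact_frequency_monotone_in_cutoff(rng):
    s = _pair_system(2.0)
    frames = s.coords[None] + rng.uniform(-2, 2, (30, 2, 3))
    traj = Trajectory(structure=s, frames=frames)
    freqs = [contact_frequencies(traj, cutoff=c).freqs[0, 0]
             for c in (1.5, 2.5, 3.5, 5.0)]
    assert all(a <= b for a, b in zip(freqs, freqs[1:]))


def test_hotspot_threshold_inclusive_and_exclusion():
    s = _pair_system(2.0)
    prof = contact_frequencies(
        Trajectory(structure=s, frames=s.coords[None]))
    # synthetic profile objects with controlled means
    from padock.trajectory import ContactProfile
    residues = [("E", 91, "GLY"), ("E", 98, "GLY"), ("E", 267, "THR"),
                ("E", 134, "PHE")]
    p = ContactProfile(residues=residues,
                       freqs=np.array([[60.0, 49.9, 80.0, 70.0]]),
                       cutoff=2.5, replica_ids=[0])
    assert select_hotspots(p, threshold=50.0) == [267, 134, 91]
    assert select_hotspots(p, threshold=50.0, exclude={267}) == [134, 91]
    assert 98 not in select_hotspots(p, threshold=50.0)


def test_planted_hotspots_recovered(planted_trajectories):
    truth, trajs = planted_trajectories
    profiles = [contact_frequencies(t) for t in trajs]
    got = select_hotspots(profiles, threshold=50.0, exclude={267})
    assert set(got) == set(truth.expected_hotspots(exclude={267}))


def test_contact_delta_and_uncertainty():
    from padock.trajectory import ContactProfile
    residues = [("E", 330, "ARG")]
    a = ContactProfile(residues, np.array([[18.0], [20.0], [22.0]]), 2.5,
                       [0, 1, 2])
    b = ContactProfile(residues, np.array([[69.0], [71.0], [73.0]]), 2.5,
                       [0, 1, 2])
    df, unc = contact_delta(a, b, 330)
    assert df == pytest.approx(-51.0)
    assert unc == pytest.approx(np.sqrt(2) * 2.0 / np.sqrt(3), rel=1e-9)
    same, unc0 = contact_delta(a, a, 330)
    assert same == 0.0
    with pytest.raises(AnalysisError):
        c = ContactProfile(residues, np.array([[18.0]]), 3.5, [0])
        contact_delta(a, c, 330)


def _hbond_system(n_o_dist, angle_deg):
    """Donor N-H and acceptor O with a controlled N..O distance and angle."""
    h = np.array([0.0, 0.0, 1.0])
    # place O such that angle N-H-O equals angle_deg with |N-O| = n_o_dist
    theta = np.radians(180.0 - angle_deg)
    direction = np.array([np.sin(theta), 0.0, np.cos(theta)])
    lo, hi = 0.0, 20.0
    for _ in range(80):  # bisection on the H->O length
        mid = (lo + hi) / 2
        o = h + mid * direction
        if np.linalg.norm(o) < n_o_dist:
            lo = mid
        else:
            hi = mid
    o = h + ((lo + hi) / 2) * direction
    atoms = [
        Atom(1, "NH1", "N", "ARG", 330, "E", (0, 0, 0), charge=0.6),
        Atom(2, "HH1", "H", "ARG", 330, "E", h),
        Atom(3, "OXT", "O", "SUB", 1, "S", o, charge=-0.6),
    ]
    s = Structure(atoms)
    s.set_group("donor", [0, 1])
    s.set_group("acceptor", [2])
    return s


def test_hbond_geometry_gates():
    good = _hbond_system(2.9, 180.0)
    traj = Trajectory(structure=good, frames=good.coords[None])
    assert detect_interactions(traj, "donor", "acceptor", "hbond").counts[0] == 1
    bent = _hbond_system(2.9, 100.0)
    traj = Trajectory(structure=bent, frames=bent.coords[None])
    assert detect_interactions(traj, "donor", "acceptor", "hbond").counts[0] == 0
    far = _hbond_system(3.8, 180.0)
    traj = Trajectory(structure=far, frames=far.coords[None])
    assert detect_interactions(traj, "donor", "acceptor", "hbond").counts[0] == 0


def test_hbond_requires_hydrogens():
    atoms = [Atom(1, "NH1", "N", "ARG", 330, "E", (0, 0, 0)),
             Atom(2, "OXT", "O", "SUB", 1, "S", (0, 0, 2.9))]
    s = Structure(atoms)
    s.set_group("donor", [0])
    s.set_group("acceptor", [1])
    traj = Trajectory(structure=s, frames=s.coords[None])
    with pytest.raises(StructureError, match="hydrogen"):
        detect_interactions(traj, "donor", "acceptor", "hbond")


def test_salt_bridge_distance_and_charge_gates():
    s = _hbond_system(3.9, 180.0)
    traj = Trajectory(structure=s, frames=s.coords[None])
    assert detect_interactions(traj, "donor", "acceptor",
                               "salt_bridge").counts[0] == 1
    s = _hbond_system(4.2, 180.0)
    traj = Trajectory(structure=s, frames=s.coords[None])
    assert detect_interactions(traj, "donor", "acceptor",
                               "salt_bridge").counts[0] == 0


def test_planted_occupancy_recovered_exactly_from_pattern():
    # deterministic 67%-on pattern: occupancy is exact, not statistical
    s = _hbond_system(2.9, 180.0)
    on = s.coords
    off = on.copy()
    off[2, 2] = 12.0
    pattern = (np.arange(100) % 3) != 0  # 67 of 100 frames unbonded? no: 66
    frames = np.where(pattern[:, None, None], on, off)
    traj = Trajectory(structure=s, frames=frames)
    series = detect_interactions(traj, "donor", "acceptor", "hbond")
    assert series.occupancy == pytest.approx(100.0 * pattern.mean())


def test_energy_series_consistency_and_oracle(rng):
    from padock.docking import nonbonded_energy
    atoms = []
    for i in range(4):
        atoms.append(Atom(i + 1, "CA", "C", "GLY", i + 1, "E",
                          rng.uniform(0, 5, 3), charge=rng.uniform(-0.4, 0.4),
                          lj_sigma=3.3, lj_epsilon=0.3))
    for i in range(3):
        atoms.append(Atom(10 + i, f"S{i}", "C", "SUB", 1, "S",
                          rng.uniform(0, 5, 3), charge=rng.uniform(-0.4, 0.4),
                          lj_sigma=3.3, lj_epsilon=0.3))
    s = Structure(atoms)
    s.set_group("enzyme", range(4))
    s.set_group("substrate", range(4, 7))
    frames = rng.uniform(0, 6, (20, 7, 3))
    traj = Trajectory(structure=s, frames=frames)
    series = interaction_energy_series(traj, cutoff=10.0)
    q = s.charges()
    sig, eps = s.lj_params()
    for f in range(20):
        expected = nonbonded_energy(frames[f, :4], q[:4], sig[:4], eps[:4],
                                    frames[f, 4:], q[4:], sig[4:], eps[4:],
                                    cutoff=10.0)
        assert series.energies[f] == pytest.approx(expected, rel=1e-12)


def test_energy_zero_when_uncharged_and_no_lj():
    atoms = [Atom(1, "CA", "C", "GLY", 1, "E", (0, 0, 0)),
             Atom(2, "S1", "C", "SUB", 1, "S", (0, 0, 3.0))]
    s = Structure(atoms)
    s.set_group("enzyme", [0])
    s.set_group("substrate", [1])
    traj = Trajectory(structure=s, frames=np.repeat(s.coords[None], 5, axis=0))
    series = interaction_energy_series(traj)
    assert np.all(series.energies == 0.0)


def test_conditional_energy_group_means_and_conservation():
    from padock.trajectory import EnergySeries, InteractionSeries
    energies = np.array([-200.0, -102.0, -200.0, -101.0, -199.0,
                         -103.0, -201.0, -102.0, -200.0, -102.0])
    counts = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
    e = EnergySeries(energies=energies, cutoff=10.0)
    s = InteractionSeries(counts=counts, kind="hbond")
    out = conditional_energy(e, s)
    # spreadsheet oracle: group-by means
    assert out.e_bound == pytest.approx(np.mean([-200, -200, -199, -201, -200]))
    assert out.e_unbound == pytest.approx(np.mean([-102, -101, -103, -102, -102]))
    assert out.delta_e == pytest.approx(out.e_bound - out.e_unbound)
    n_b, n_u = counts.sum(), (counts == 0).sum()
    total = n_b * out.e_bound + n_u * out.e_unbound
    assert total == pytest.approx(energies.sum(), rel=1e-9)


def test_conditional_energy_flags_sparse_state():
    from padock.trajectory import EnergySeries, InteractionSeries
    e = EnergySeries(energies=np.full(10, -5.0), cutoff=10.0)
    s = InteractionSeries(counts=np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0]),
                          kind="hbond")
    out = conditional_energy(e, s)
    assert not out.delta_defined
    assert out.delta_e is None
    constant = conditional_energy(
        EnergySeries(energies=np.full(10, -5.0), cutoff=10.0),
        InteractionSeries(counts=np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0]),
                          kind="hbond"))
    assert constant.delta_e == pytest.approx(0.0)


def _aromatic_system(theta_deg):
    from padock.synthetic import _ring_coords
    cb = np.array([0.0, 0.0, 0.0])
    direction = np.array([np.sin(np.radians(theta_deg)), 0.0,
                          np.cos(np.radians(theta_deg))])
    ring = _ring_coords(cb + 2.0 * direction, direction)
    atoms = [Atom(1, "CB", "C", "PHE", 134, "E", cb)]
    for i, (nm, xyz) in enumerate(zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                                      ring)):
        atoms.append(Atom(2 + i, nm, "C", "PHE", 134, "E", xyz))
    atoms.append(Atom(10, "CA", "C", "THR", 267, "E", (0.0, 5.0, -10.0)))
    atoms.append(Atom(11, "MTH", "C", "MTH", 998, "M", (0.0, 5.0, 10.0)))
    s = Structure(atoms)
    s.set_group("catalytic_triad", [7])
    s.set_group("pocket_mouth", [8])
    return s


@pytest.mark.parametrize("theta,label", [(0.0, 1), (90.0, 2), (44.0, 1),
                                         (46.0, 2)])
def test_sidechain_axis_angle_classification(theta, label):
    s = _aromatic_system(theta)
    traj = Trajectory(structure=s, frames=s.coords[None])
    series = classify_sidechain(traj, 134)
    assert series.labels[0] == label
    assert series.angles[0] == pytest.approx(theta, abs=1e-6)


def test_sidechain_rejects_non_aromatic():
    atoms = [Atom(1, "CB", "C", "ALA", 12, "E", (0, 0, 0))]
    s = Structure(atoms)
    traj = Trajectory(structure=s, frames=s.coords[None])
    with pytest.raises(AnalysisError, match="not aromatic"):
        classify_sidechain(traj, 12)


def test_planted_sidechain_fractions(planted_trajectories):
    truth, trajs = planted_trajectories
    fr = [classify_sidechain(t, truth.aromatic_residue).fractions[0]
          for t in trajs]
    mean, sem = aggregate_replicas(fr)
    assert mean == pytest.approx(truth.sidechain_fraction_1, abs=0.05)


def test_aggregate_replicas_hand_values():
    mean, sem = aggregate_replicas([40.0, 50.0, 60.0])
    assert mean == 50.0
    assert sem == pytest.approx(10.0 / np.sqrt(3), rel=1e-9)
    assert aggregate_replicas([50.0, 50.0, 50.0]) == (50.0, 0.0)
    m_only, s_none = aggregate_replicas([42.0])
    assert m_only == 42.0 and s_none is None
    # ordering invariance
    assert aggregate_replicas([60.0, 40.0, 50.0])[0] == 50.0
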