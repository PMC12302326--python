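"""Docking: scoring function, seed placement, growth, clustering, full runs."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from padock.docking import (DockingConfig, DockingError, Pose,
                            cluster_and_rank, dock_oligomer, extend_increment,
                            nonbonded_energy, pose_rmsd, sample_torsion_values,
                            score_pose, seed_placement)
from padock.oligomer import (OligomerSpec, build_oligomer,
                             substrate_nonbonded_table)
from padock.structures import COULOMB_CONSTANT, Atom, ParameterError, Structure


# -- scoring ----------------------------------------------------------------

def test_lj_zero_crossing_and_minimum():
    one = np.array([[0.0, 0.0, 0.0]])
    sigma, eps = np.array([3.4]), np.array([0.4])
    q = np.array([0.0])
    at_sigma = np.array([[3.4, 0.0, 0.0]])
    assert nonbonded_energy(one, q, sigma, eps, at_sigma, q, sigma, eps) == \
        pytest.approx(0.0, abs=1e-12)
    at_min = np.array([[3.4 * 2 ** (1 / 6), 0.0, 0.0]])
    assert nonbonded_energy(one, q, sigma, eps, at_min, q, sigma, eps) == \
        pytest.approx(-0.4, abs=1e-9)


def test_energy_matches_brute_force_double_loop(rng):
    n = 10
    xyz_a = rng.uniform(-4, 4, (n, 3))
    xyz_b = rng.uniform(-4, 4, (n, 3)) + 5.0
    qa, qb = rng.uniform(-0.5, 0.5, n), rng.uniform(-0.5, 0.5, n)
    sa, sb = rng.uniform(3, 3.6, n), rng.uniform(3, 3.6, n)
    ea, eb = rng.uniform(0.1, 0.6, n), rng.uniform(0.1, 0.6, n)
    expected = 0.0
    for i in range(n):
        for j in range(n):
            r = np.linalg.norm(xyz_a[i] - xyz_b[j])
            sij = 0.5 * (sa[i] + sb[j])
            eij = np.sqrt(ea[i] * eb[j])
            expected += 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
            expected += COULOMB_CONSTANT * qa[i] * qb[j] / r
    got = nonbonded_energy(xyz_a, qa, sa, ea, xyz_b, qb, sb, eb, cutoff=1e6)
    assert got == pytest.approx(expected, rel=1e-10)
    # symmetric in partner order
    swapped = nonbonded_energy(xyz_b, qb, sb, eb, xyz_a, qa, sa, ea, cutoff=1e6)
    assert swapped == pytest.approx(got, rel=1e-12)


def test_score_requires_assigned_parameters(dimer_conformer):
    bare = Structure([Atom(1, "CA", "C", "POC", 1, "E", (0, 0, 0))])
    pose = Pose(conformer=dimer_conformer,
                coords=dimer_conformer.structure.coords)
    with pytest.raises(ParameterError):
        score_pose(bare, pose)


# -- seed placement ---------------------------------------------------------

def test_seed_placement_without_enzyme_retains_all(dimer_conformer):
    # a lone hydrogen marks the site; heavy-atom clash checks cannot trigger
    empty = Structure([Atom(1, "H", "H", "POC", 500, "E", (100.0, 100.0, 100.0),
                            lj_epsilon=0.1, lj_sigma=1.0)])
    empty.set_group("catalytic_triad", [0])
    poses = seed_placement(empty, dimer_conformer, n_samples=50, seed=3,
                           config=DockingConfig(radius=5.0))
    assert len(poses) == 50


def test_seed_placement_deterministic(channel_complex, dimer_conformer):
    enzyme, _ = channel_complex
    a = seed_placement(enzyme, dimer_conformer, n_samples=100, seed=11)
    b = seed_placement(enzyme, dimer_conformer, n_samples=100, seed=11)
    assert len(a) == len(b)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.coords, pb.coords)
        assert pa.score == pb.score


def test_wall_fixture_rejects_all_seeds(wall_complex, dimer_conformer):
    enzyme, _ = wall_complex
    with pytest.raises(DockingError, match="clash"):
        seed_placement(enzyme, dimer_conformer, n_samples=200, seed=5,
                       config=DockingConfig(radius=3.0))


# -- growth -----------------------------------------------------------------

def test_extension_scores_sorted_ascending(channel_complex, dimer_conformer,
                                           small_config):
    enzyme, _ = channel_complex
    seeds = seed_placement(enzyme, dimer_conformer, n_samples=200, seed=2,
                           config=small_config)
    seeds = sorted(seeds, key=lambda p: p.score)[:10]
    grown = extend_increment(enzyme, seeds, n_dihedral_samples=2, keep_k=15,
                             seed=3, config=small_config)
    scores = [p.score for p in grown]
    assert scores == sorted(scores)
    assert all(p.increment == 2 for p in grown)
    assert len(grown) <= 15


def test_two_unit_growth_equals_exhaustive_enumeration(channel_complex,
                                                       dimer_conformer):
    """Pipeline best score equals an independent brute-force enumeration of
    the same seed placements and torsion samples."""
    enzyme, _ = channel_complex
    cfg = DockingConfig(n_samples=60, keep_k=10)
    seeds = seed_placement(enzyme, dimer_conformer, n_samples=60, seed=9,
                           config=cfg)
    seeds = sorted(seeds, key=lambda p: p.score)[:10]
    keys = dimer_conformer.variable_keys(2)
    samples = sample_torsion_values(keys, 3, cfg.dihedral_jitter,
                                    np.random.default_rng(77))
    grown = extend_increment(enzyme, seeds, keep_k=5, config=cfg,
                             torsion_samples=samples)
    # oracle: enumerate every completion, score with an independent loop
    n_total = dimer_conformer.unit_slices[1][1]
    heavy = np.array([r.element != "H" for r in dimer_conformer.zrows])
    enz_heavy = np.array([a.coords for a in enzyme.atoms if not a.is_hydrogen])
    sub = dimer_conformer.structure
    q, (sig, eps) = sub.charges(), sub.lj_params()
    eq = enzyme.charges()
    esig, eeps = enzyme.lj_params()
    exyz = enzyme.coords
    best = np.inf
    for pose in seeds:
        for combo in itertools.product(*(samples[k] for k in keys)):
            torsions = dict(pose.torsions)
            torsions.update(zip(keys, combo))
            coords = dimer_conformer.extend_coords(pose.coords, n_total,
                                                   torsions)
            new = coords[pose.n_placed:]
            if (cdist(new[heavy[pose.n_placed:]], enz_heavy) < 2.0).any():
                continue
            # intra clash: new heavy vs earlier heavy beyond geminal pairs
            clash = False
            adj = {}
            for i, j, _ in dimer_conformer.bonds:
                adj.setdefault(i, set()).add(j)
                adj.setdefault(j, set()).add(i)
            for i in range(pose.n_placed, n_total):
                if not heavy[i]:
                    continue
                near = adj.get(i, set()) | {
                    k for j in adj.get(i, set()) for k in adj.get(j, set())
                }
                for j in range(i):
                    if heavy[j] and j not in near and \
                            np.linalg.norm(coords[i] - coords[j]) < 2.0:
                        clash = True
            if clash:
                continue
            e = nonbonded_energy(coords, q, sig, eps, exyz, eq, esig, eeps,
                                 cutoff=cfg.cutoff)
            best = min(best, e)
    assert min(p.score for p in grown) == pytest.approx(best, rel=1e-12)


def test_no_room_to_grow_raises(wall_complex, dimer_conformer):
    enzyme, _ = wall_complex
    # orient the pose so its single fully-extended completion lands inside the
    # solid block (chain along the block diagonal, second unit centred on it)
    n_frag = dimer_conformer.unit_slices[0][1]
    n_total = dimer_conformer.unit_slices[1][1]
    full = dimer_conformer.build_coords()
    c, s = np.cos(np.pi / 4), np.sin(np.pi / 4)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    full = full @ rot.T
    full -= full[n_frag:n_total].mean(axis=0)
    pose = Pose(conformer=dimer_conformer, coords=full[:n_frag],
                increment=1, score=0.0)
    keys = dimer_conformer.variable_keys(2)
    with pytest.raises(DockingError, match="increment"):
        extend_increment(enzyme, [pose], keep_k=5, seed=1,
                         torsion_samples={k: [180.0] for k in keys})


# -- clustering -------------------------------------------------------------

def _pose_at(conformer, offset, score):
    coords = conformer.build_coords(n_atoms=conformer.unit_slices[-1][1])
    return Pose(conformer=conformer, coords=coords + offset, score=score,
                increment=len(conformer.unit_slices))


def test_identical_poses_form_one_cluster(dimer_conformer):
    poses = [_pose_at(dimer_conformer, (0, 0, 0), -1.0) for _ in range(6)]
    res = cluster_and_rank(poses, rmsd_cutoff=2.0)
    assert len(res.clusters) == 1
    assert res.clusters[0]["population"] == 6


def test_population_ties_broken_by_mean_score(dimer_conformer):
    low = [_pose_at(dimer_conformer, (0, 0, 0), -10.0 - i) for i in range(5)]
    high = [_pose_at(dimer_conformer, (50, 0, 0), -1.0 - i) for i in range(5)]
    res = cluster_and_rank(high + low, rmsd_cutoff=2.0)
    assert len(res.clusters) == 2
    assert res.clusters[0]["mean_score"] < res.clusters[1]["mean_score"]
    assert res.best_pose.score == -14.0
    assert res.binding_energy_estimate == -14.0
    assert sum(c["population"] for c in res.clusters) == 10


def test_cluster_assignment_matches_all_pairs_single_link(dimer_conformer,
                                                          rng):
    # well-separated bundles (> 2x cutoff): leader and single-link agree
    centers = [(0, 0, 0), (40, 0, 0), (0, 40, 0)]
    poses = []
    for c in centers:
        for _ in range(5):
            jitter = rng.normal(0, 0.2, 3)
            poses.append(_pose_at(dimer_conformer, np.add(c, jitter),
                                  float(rng.normal(-5, 1))))
    res = cluster_and_rank(poses, rmsd_cutoff=2.0)
    # oracle: single-link components from the all-pairs RMSD graph
    n = len(poses)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            adj[i, j] = pose_rmsd(poses[i], poses[j]) <= 2.0
    seen, components = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(np.nonzero(adj[k])[0])
        seen |= comp
        components.append(comp)
    leader_clusters = {}
    for i, p in enumerate(poses):
        leader_clusters.setdefault(p.cluster_id, set()).add(i)
    assert sorted(map(frozenset, components)) == \
        sorted(map(frozenset, leader_clusters.values()))


def test_empty_pose_list_raises():
    with pytest.raises(DockingError):
        cluster_and_rank([], 2.0)


# -- full runs --------------------------------------------------------------

def test_channel_dock_threads_with_negative_energy(channel_complex,
                                                   small_config):
    enzyme, _ = channel_complex
    res = dock_oligomer(enzyme, OligomerSpec(2, "Ace", "COO_minus"),
                        config=small_config, seed=4)
    assert res.binding_energy_estimate < 0
    assert res.best_pose.score <= min(p.score for p in res.poses) + 1e-12 or \
        res.best_pose.score == min(p.score for p in res.poses)
    assert res.per_increment_counts[0] > 0


def test_both_orientations_independent(channel_complex, small_config):
    enzyme, _ = channel_complex
    spec = OligomerSpec(2, "Ace", "COO_minus")
    r1 = dock_oligomer(enzyme, spec, config=small_config, seed=4)
    from dataclasses import replace
    r2 = dock_oligomer(enzyme, replace(spec, orientation=2),
                       config=small_config, seed=4)
    assert r1.orientation_label != r2.orientation_label
    assert not np.array_equal(r1.best_pose.coords, r2.best_pose.coords)


def test_single_unit_dock_equals_seed_plus_cluster(channel_complex):
    enzyme, _ = channel_complex
    cfg = DockingConfig(n_samples=150)
    spec = OligomerSpec(1, "Ace", "COO_minus")
    res = dock_oligomer(enzyme, spec, config=cfg, seed=6)
    stream = np.random.default_rng([6, 1])
    seed_seq = int(stream.integers(2 ** 31))
    conf = build_oligomer(spec)
    from padock.structures import assign_nonbonded
    conf.structure = assign_nonbonded(conf.structure,
                                      substrate_nonbonded_table())
    seeds = seed_placement(enzyme, conf, n_samples=150, seed=seed_seq,
                           config=cfg)
    oracle = cluster_and_rank(seeds, cfg.rmsd_cutoff)
    assert res.binding_energy_estimate == pytest.approx(
        oracle.binding_energy_estimate, rel=1e-12)


def test_dock_is_bit_identical_under_fixed_seed(channel_complex, small_config):
    enzyme, _ = channel_complex
    spec = OligomerSpec(2, "Ace", "COO_minus")
    r1 = dock_oligomer(enzyme, spec, config=small_config, seed=8)
    r2 = dock_oligomer(enzyme, spec, config=small_config, seed=8)
    assert r1.binding_energy_estimate == r2.binding_energy_estimate
    assert np.array_equal(r1.best_pose.coords, r2.best_pose.coords)
    assert r1.clusters == r2.clusters
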