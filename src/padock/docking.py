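"""Incremental fragment-growth docking of flexible oligomers into a pocket.

The oligomer is grown unit by unit inside a rigid receptor: rigid-body seed
placements of the first repeat unit, then per-unit backbone-torsion sampling
with a global top-k survivor selection, and finally greedy leader clustering
of the complete poses.  Clusters are ranked by population and mean score
(the "high population and affinity" rule); the affinity proxy is the
short-range Lennard-Jones + Coulomb enzyme-substrate energy, so the reported
``binding_energy_estimate`` is a nonbonded score, not a free energy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import random_point_in_sphere, random_rotation
from .oligomer import (OligomerConformer, OligomerSpec, build_oligomer,
                       substrate_nonbonded_table)
from .structures import COULOMB_CONSTANT, ParameterError, Structure, assign_nonbonded


class DockingError(RuntimeError):
    """Raised when a docking stage cannot produce any valid pose."""


@dataclass
class DockingConfig:
    """Tunable docking parameters (Å, kJ mol⁻¹, degrees)."""

    cutoff: float = 10.0            # nonbonded interaction cutoff
    clash_threshold: float = 2.0    # heavy-atom overlap rejection
    radius: float = 8.0             # seed-placement sphere around the site
    n_samples: int = 5000           # rigid-body seed placements
    keep_k: int = 50                # survivors per growth increment
    n_dihedral_samples: int = 3     # torsion samples per rotatable bond
    dihedral_jitter: float = 15.0   # uniform jitter around rotamer values
    rmsd_cutoff: float = 2.0        # leader-clustering radius
    constrain_attack_site: bool = False
    attack_site_radius: float = 6.0  # max attack-amide-N distance to the site
    site_group: str = "catalytic_triad"


_ROTAMERS = (60.0, 180.0, -60.0)


@dataclass
class Pose:
    """A placed (possibly partial) conformer with its score."""

    conformer: OligomerConformer
    coords: np.ndarray              # world coordinates of placed atoms
    torsions: dict = field(default_factory=dict)
    score: float = np.inf
    increment: int = 0
    cluster_id: int | None = None

    @property
    def n_placed(self) -> int:
        return len(self.coords)


@dataclass
class DockingResult:
    poses: list
    clusters: list                  # [{"population", "mean_score"}] in rank order
    best_pose: Pose
    binding_energy_estimate: float
    per_increment_counts: list
    orientation_label: str = ""


def _require_params(structure: Structure):
    q = structure.charges()
    _, eps = structure.lj_params()
    if not (np.any(q != 0) or np.any(eps != 0)):
        raise ParameterError("nonbonded parameters not assigned (all zero)")


def nonbonded_energy(coords_a, charge_a, sigma_a, eps_a,
                     coords_b, charge_b, sigma_b, eps_b,
                     cutoff: float = 10.0) -> float:
    """Pairwise LJ + Coulomb energy between two atom sets within ``cutoff``.

    Lorentz-Berthelot combination: σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_i ε_j).
    """
    r = cdist(np.atleast_2d(coords_a), np.atleast_2d(coords_b))
    mask = (r <= cutoff) & (r > 1e-9)
    if not mask.any():
        return 0.0
    ia, ib = np.nonzero(mask)
    rij = r[ia, ib]
    sij = 0.5 * (np.asarray(sigma_a)[ia] + np.asarray(sigma_b)[ib])
    eij = np.sqrt(np.asarray(eps_a)[ia] * np.asarray(eps_b)[ib])
    sr6 = (sij / rij) ** 6
    lj = 4.0 * eij * (sr6 * sr6 - sr6)
    coul = COULOMB_CONSTANT * np.asarray(charge_a)[ia] * np.asarray(charge_b)[ib] / rij
    return float(np.sum(lj) + np.sum(coul))


def _group_arrays(structure: Structure, indices=None):
    idx = np.arange(structure.n_atoms) if indices is None else np.asarray(indices)
    q = structure.charges()[idx]
    sig, eps = structure.lj_params()
    return structure.coords[idx], q, sig[idx], eps[idx]


class _ScoreContext:
    """Cached parameter arrays for repeated pose scoring against one enzyme."""

    def __init__(self, enzyme: Structure, substrate: Structure, cutoff: float):
        _require_params(enzyme)
        _require_params(substrate)
        self.cutoff = cutoff
        self.e_xyz, self.e_q, self.e_sig, self.e_eps = _group_arrays(enzyme)
        self.s_q = substrate.charges()
        self.s_sig, self.s_eps = substrate.lj_params()

    def score(self, coords: np.ndarray) -> float:
        n = len(coords)
        return nonbonded_energy(coords, self.s_q[:n], self.s_sig[:n],
                                self.s_eps[:n], self.e_xyz, self.e_q,
                                self.e_sig, self.e_eps, cutoff=self.cutoff)


def score_pose(enzyme: Structure, pose: Pose, cutoff: float = 10.0) -> float:
    """Enzyme-substrate nonbonded energy of a pose (kJ mol⁻¹)."""
    ctx = _ScoreContext(enzyme, pose.conformer.structure, cutoff)
    return ctx.score(pose.coords)


def _heavy_mask(conformer: OligomerConformer, n=None):
    m = np.array([r.element != "H" for r in conformer.zrows])
    return m if n is None else m[:n]


def _enzyme_heavy_coords(enzyme: Structure):
    return np.array([a.coords for a in enzyme.atoms if not a.is_hydrogen])


def _clashes_enzyme(coords, heavy_mask, enzyme_heavy, threshold):
    if len(enzyme_heavy) == 0:
        return False
    sub = coords[heavy_mask]
    if len(sub) == 0:
        return False
    return bool((cdist(sub, enzyme_heavy) < threshold).any())


def seed_placement(enzyme: Structure, fragment: OligomerConformer,
                   site=None, n_samples: int = 5000, seed: int = 0,
                   config: DockingConfig | None = None) -> list[Pose]:
    """Rigid-body placements of the first growth increment.

    Samples positions uniformly in a sphere of radius ``config.radius`` around
    the site centroid with uniform random orientations; placements with any
    heavy-atom overlap below the clash threshold are discarded.
    """
    cfg = config or DockingConfig()
    if site is None:
        if cfg.site_group not in enzyme.groups:
            raise DockingError(f"enzyme has no '{cfg.site_group}' group")
        site = enzyme.groups[cfg.site_group]
    site = np.asarray(list(site), dtype=int)
    if site.size == 0:
        raise DockingError("site group is empty")
    center = enzyme.coords[site].mean(axis=0)

    n_frag = fragment.unit_slices[0][1]
    local = fragment.build_coords(n_atoms=n_frag)
    local = local - local.mean(axis=0)
    heavy = _heavy_mask(fragment, n_frag)
    enzyme_heavy = _enzyme_heavy_coords(enzyme)

    rng = np.random.default_rng(seed)
    ctx = _ScoreContext(enzyme, fragment.structure, cfg.cutoff)
    poses = []
    for _ in range(int(n_samples)):
        rot = random_rotation(rng)
        t = random_point_in_sphere(center, cfg.radius, rng)
        coords = local @ rot.T + t
        if _clashes_enzyme(coords, heavy, enzyme_heavy, cfg.clash_threshold):
            continue
        pose = Pose(conformer=fragment, coords=coords, torsions={}, increment=1)
        pose.score = ctx.score(coords)
        poses.append(pose)
    if not poses:
        raise DockingError(
            "all seed placements clash; increase the placement radius or use "
            "a smaller fragment"
        )
    return poses


def sample_torsion_values(keys, n: int, jitter: float,
                          rng: np.random.Generator) -> dict:
    """Per-bond torsion samples from the anti/gauche rotamer set ± jitter."""
    out = {}
    for key in keys:
        base = [_ROTAMERS[i % 3] for i in range(n)]
        out[key] = [b + rng.uniform(-jitter, jitter) for b in base]
    return out


def _intra_exclusions(conformer: OligomerConformer):
    """Atom pairs at graph distance ≤ 2 (bonded + geminal)."""
    adj = {}
    for i, j, _ in conformer.bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    excl = set()
    for i, nbrs in adj.items():
        for j in nbrs:
            excl.add(frozenset((i, j)))
            for k in adj.get(j, ()):
                if k != i:
                    excl.add(frozenset((i, k)))
    return excl


def _intra_allowed_matrix(conformer, n_old, n_new_total, excl):
    """Boolean matrix of (new heavy, earlier heavy) pairs that may not overlap."""
    heavy = _heavy_mask(conformer, n_new_total)
    new_idx = [i for i in range(n_old, n_new_total) if heavy[i]]
    old_idx = [j for j in range(n_new_total) if heavy[j]]
    allowed = np.ones((len(new_idx), len(old_idx)), dtype=bool)
    for a, i in enumerate(new_idx):
        for b, j in enumerate(old_idx):
            if j >= i or frozenset((i, j)) in excl:
                allowed[a, b] = False
    return np.asarray(new_idx), np.asarray(old_idx), allowed


def _clashes_intra(coords, new_idx, old_idx, allowed, threshold):
    if len(new_idx) == 0 or len(old_idx) == 0:
        return False
    r = cdist(coords[new_idx], coords[old_idx])
    return bool(((r < threshold) & allowed).any())


def extend_increment(enzyme: Structure, poses: list[Pose],
                     n_dihedral_samples: int = 3, keep_k: int = 50,
                     seed: int = 0, config: DockingConfig | None = None,
                     torsion_samples: dict | None = None) -> list[Pose]:
    """Grow every pose by one repeat unit and keep the global top ``keep_k``.

    Backbone torsions of the new unit are sampled per bond from the rotamer
    set with jitter; every combination is scored.  Returned poses are sorted
    by ascending score.  ``torsion_samples`` may supply the per-bond values
    explicitly (used by exhaustive-enumeration cross-checks).
    """
    cfg = config or DockingConfig()
    if not poses:
        raise DockingError("no poses to extend")
    conformer = poses[0].conformer
    unit = poses[0].increment + 1
    if unit > len(conformer.unit_slices):
        raise DockingError("all units already placed")
    n_new_total = conformer.unit_slices[unit - 1][1]
    keys = conformer.variable_keys(unit)
    if torsion_samples is None:
        rng = np.random.default_rng(seed)
        torsion_samples = sample_torsion_values(keys, n_dihedral_samples,
                                                cfg.dihedral_jitter, rng)
    enzyme_heavy = _enzyme_heavy_coords(enzyme)
    excl = _intra_exclusions(conformer)
    heavy = _heavy_mask(conformer, n_new_total)
    n_old0 = poses[0].n_placed
    new_idx, old_idx, allowed = _intra_allowed_matrix(conformer, n_old0,
                                                      n_new_total, excl)
    ctx = _ScoreContext(enzyme, conformer.structure, cfg.cutoff)

    survivors = []
    for pose in poses:
        if pose.increment != unit - 1:
            raise DockingError("poses have inconsistent increments")
        n_old = pose.n_placed
        for combo in itertools.product(*(torsion_samples[k] for k in keys)):
            torsions = dict(pose.torsions)
            torsions.update(zip(keys, combo))
            coords = conformer.extend_coords(pose.coords, n_new_total, torsions)
            new_heavy = coords[n_old:n_new_total][heavy[n_old:n_new_total]]
            if len(enzyme_heavy) and len(new_heavy) and (
                cdist(new_heavy, enzyme_heavy) < cfg.clash_threshold
            ).any():
                continue
            if _clashes_intra(coords, new_idx, old_idx, allowed,
                              cfg.clash_threshold):
                continue
            new = Pose(conformer=conformer, coords=coords, torsions=torsions,
                       increment=unit)
            new.score = ctx.score(coords)
            survivors.append(new)
    if not survivors:
        raise DockingError(f"no clash-free extension at increment {unit}")
    survivors.sort(key=lambda p: p.score)
    return survivors[:keep_k]


def pose_rmsd(a: Pose, b: Pose) -> float:
    """Heavy-atom RMSD without superposition (poses share the enzyme frame)."""
    heavy = _heavy_mask(a.conformer, a.n_placed)
    d = a.coords[heavy] - b.coords[heavy]
    return float(np.sqrt((d * d).sum() / heavy.sum()))


def cluster_and_rank(poses: list[Pose], rmsd_cutoff: float = 2.0,
                     orientation_label: str = "",
                     per_increment_counts=None) -> DockingResult:
    """Greedy leader clustering; rank by (population desc, mean score asc)."""
    if not poses:
        raise DockingError("no poses to cluster")
    order = sorted(range(len(poses)), key=lambda i: poses[i].score)
    leaders: list[int] = []
    members: dict[int, list[int]] = {}
    for i in order:
        for li, leader in enumerate(leaders):
            if pose_rmsd(poses[i], poses[leader]) <= rmsd_cutoff:
                members[li].append(i)
                poses[i].cluster_id = li
                break
        else:
            leaders.append(i)
            members[len(leaders) - 1] = [i]
            poses[i].cluster_id = len(leaders) - 1
    stats = []
    for li in members:
        scores = [poses[i].score for i in members[li]]
        stats.append({"cluster_id": li, "population": len(scores),
                      "mean_score": float(np.mean(scores))})
    stats.sort(key=lambda s: (-s["population"], s["mean_score"]))
    top = stats[0]["cluster_id"]
    best = min((poses[i] for i in members[top]), key=lambda p: p.score)
    return DockingResult(
        poses=poses,
        clusters=stats,
        best_pose=best,
        binding_energy_estimate=best.score,
        per_increment_counts=per_increment_counts or [],
        orientation_label=orientation_label,
    )


def dock_oligomer(enzyme: Structure, spec: OligomerSpec,
                  config: DockingConfig | None = None, seed: int = 0,
                  nonbonded_table=None) -> DockingResult:
    """Full incremental docking run: seed → grow → cluster and rank."""
    cfg = config or DockingConfig()
    conformer = build_oligomer(spec)
    table = nonbonded_table or substrate_nonbonded_table()
    conformer.structure = assign_nonbonded(conformer.structure, table)
    # independent, reproducible stream per orientation
    stream = np.random.default_rng([seed, spec.orientation])
    seed_seq = int(stream.integers(2**31))
    poses = seed_placement(enzyme, conformer, n_samples=cfg.n_samples,
                           seed=seed_seq, config=cfg)
    counts = [len(poses)]
    if spec.n_units > 1:
        # only the best-scoring seeds are grown further
        poses = sorted(poses, key=lambda p: p.score)[: cfg.keep_k]
        counts.append(len(poses))
    for unit in range(2, spec.n_units + 1):
        ext_seed = int(stream.integers(2**31))
        poses = extend_increment(enzyme, poses, cfg.n_dihedral_samples,
                                 cfg.keep_k, seed=ext_seed, config=cfg)
        counts.append(len(poses))
    if cfg.constrain_attack_site and conformer.attack_site is not None:
        site = enzyme.groups[cfg.site_group]
        center = enzyme.coords[site].mean(axis=0)
        n_attack = conformer.attack_site[1]
        kept = [p for p in poses
                if np.linalg.norm(p.coords[n_attack] - center) <= cfg.attack_site_radius]
        if not kept:
            raise DockingError("no pose keeps the attack-site amide near the site")
        poses = kept
        counts.append(len(poses))
    return cluster_and_rank(poses, cfg.rmsd_cutoff,
                            orientation_label=spec.label,
                            per_increment_counts=counts)
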