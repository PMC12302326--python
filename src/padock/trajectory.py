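"""Trajectory-derived interaction statistics.

Implements the analyses used to nominate and explain beneficial
substitutions: per-residue contact frequencies and hotspot selection,
hydrogen-bond / salt-bridge occupancies, enzyme-substrate interaction
energies conditioned on the bond state, contact-frequency differences
between variants, and aromatic side-chain conformation classification.

A residue is "in contact" in a frame when the minimum distance between any
of its atoms (hydrogens included) and any substrate atom is within the
cutoff (2.5 Å, inclusive).  Replicas are aggregated as mean ± SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .docking import nonbonded_energy
from .structures import Structure, StructureError, Trajectory


class AnalysisError(ValueError):
    """Raised for invalid analysis inputs."""


def _resolve_group(structure: Structure, group):
    if isinstance(group, str):
        if group not in structure.groups:
            raise AnalysisError(f"structure has no group '{group}'")
        return np.asarray(structure.groups[group], dtype=int)
    return np.asarray(list(group), dtype=int)


def aggregate_replicas(values):
    """Mean and standard error of the mean across replicas.

    With a single replica the SEM is undefined and returned as ``None``.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise AnalysisError("no replica values")
    mean = float(vals.mean())
    if vals.size < 2:
        return mean, None
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return mean, sem


@dataclass
class ContactProfile:
    """Per-residue contact frequencies (percent of frames), per replica."""

    residues: list                  # (chain_id, residue_id, residue_name)
    freqs: np.ndarray               # (n_replicas, n_residues), percent
    cutoff: float
    replica_ids: list = field(default_factory=list)

    @property
    def mean(self) -> np.ndarray:
        return self.freqs.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.freqs.shape[0]
        if n < 2:
            return np.full(self.freqs.shape[1], np.nan)
        return self.freqs.std(axis=0, ddof=1) / np.sqrt(n)

    def residue_ids(self):
        return [r[1] for r in self.residues]

    def frequency(self, residue_id: int) -> float:
        i = self.residue_ids().index(residue_id)
        return float(self.mean[i])


def contact_frequencies(traj: Trajectory, enzyme_group="enzyme",
                        substrate_group="substrate",
                        cutoff: float = 2.5) -> ContactProfile:
    """Percent of frames each enzyme residue touches the substrate."""
    if traj.n_frames < 1:
        raise AnalysisError("empty trajectory")
    e_idx = _resolve_group(traj.structure, enzyme_group)
    s_idx = _resolve_group(traj.structure, substrate_group)
    if e_idx.size == 0 or s_idx.size == 0:
        raise AnalysisError("enzyme and substrate groups must be non-empty")
    residues = traj.structure.residues(e_idx)
    res_atoms = [
        np.asarray([i for i in e_idx
                    if (traj.structure.atoms[i].chain_id,
                        traj.structure.atoms[i].residue_id) == (ch, rid)])
        for ch, rid, _ in residues
    ]
    hits = np.zeros(len(residues), dtype=int)
    for frame in traj.frames:
        sub = frame[s_idx]
        for ri, atoms in enumerate(res_atoms):
            if cdist(frame[atoms], sub).min() <= cutoff:
                hits[ri] += 1
    freqs = 100.0 * hits / traj.n_frames
    return ContactProfile(residues=residues, freqs=freqs[None, :],
                          cutoff=cutoff, replica_ids=[traj.replica_id])


def combine_profiles(profiles) -> ContactProfile:
    """Stack per-replica profiles computed with identical cutoff and residues."""
    profiles = list(profiles)
    if not profiles:
        raise AnalysisError("no profiles")
    first = profiles[0]
    for p in profiles[1:]:
        if p.cutoff != first.cutoff:
            raise AnalysisError("profiles have different cutoffs")
        if p.residues != first.residues:
            raise AnalysisError("profiles cover different residues")
    return ContactProfile(
        residues=first.residues,
        freqs=np.vstack([p.freqs for p in profiles]),
        cutoff=first.cutoff,
        replica_ids=sum((p.replica_ids for p in profiles), []),
    )


def select_hotspots(profiles, threshold: float = 50.0, exclude=()) -> list[int]:
    """Residues whose replica-mean contact frequency is ≥ threshold.

    ``exclude`` removes residues that must not be nominated (e.g. the
    catalytic nucleophile).  Sorted by descending mean frequency.
    """
    profile = profiles if isinstance(profiles, ContactProfile) \
        else combine_profiles(profiles)
    exclude = set(exclude)
    pairs = [
        (rid, m)
        for (_, rid, _), m in zip(profile.residues, profile.mean)
        if m >= threshold and rid not in exclude
    ]
    pairs.sort(key=lambda x: (-x[1], x[0]))
    return [rid for rid, _ in pairs]


def contact_delta(a: ContactProfile, b: ContactProfile, residue_id: int):
    """Δf = mean_a − mean_b for a residue, with SEMs combined in quadrature."""
    if a.cutoff != b.cutoff:
        raise AnalysisError("profiles computed with different cutoffs")
    fa, fb = a.frequency(residue_id), b.frequency(residue_id)
    ia = a.residue_ids().index(residue_id)
    ib = b.residue_ids().index(residue_id)
    sa, sb = a.sem[ia], b.sem[ib]
    unc = float(np.sqrt(np.nan_to_num(sa) ** 2 + np.nan_to_num(sb) ** 2))
    return fa - fb, unc


@dataclass
class InteractionSeries:
    """Per-frame count of qualifying interactions between two groups."""

    counts: np.ndarray
    kind: str

    @property
    def occupancy(self) -> float:
        """Percent of frames with at least one interaction."""
        return float(100.0 * np.count_nonzero(self.counts) / len(self.counts))

    @property
    def bound_mask(self) -> np.ndarray:
        return self.counts >= 1


def _donor_hydrogens(structure: Structure, coords0, donor_idx):
    """Map donor heavy atom → attached hydrogen indices (from frame-0 geometry)."""
    hydro = [i for i in range(structure.n_atoms) if structure.atoms[i].is_hydrogen]
    out = {}
    for d in donor_idx:
        if structure.atoms[d].element.upper() not in ("N", "O"):
            continue
        hs = [h for h in hydro if np.linalg.norm(coords0[h] - coords0[d]) <= 1.25]
        if hs:
            out[d] = hs
    return out


def detect_interactions(traj: Trajectory, donor_group, acceptor_group,
                        kind: str = "hbond", distance_cutoff: float | None = None,
                        angle_cutoff: float = 150.0,
                        charge_threshold: float = 0.2) -> InteractionSeries:
    """Count hydrogen bonds or salt bridges between two groups per frame.

    H-bond: donor-acceptor heavy-atom distance ≤ 3.5 Å and donor-H-acceptor
    angle ≥ 150°.  Salt bridge: any (positively charged N, negatively charged
    O) pair ≤ 4.0 Å; charge signs are read from the assigned partial charges.
    """
    s = traj.structure
    d_idx = _resolve_group(s, donor_group)
    a_idx = _resolve_group(s, acceptor_group)
    if kind == "hbond":
        cutoff = 3.5 if distance_cutoff is None else distance_cutoff
        donors = _donor_hydrogens(s, traj.frames[0], d_idx)
        if not donors:
            raise StructureError(
                "hydrogen-bond detection needs polar hydrogens on the donor "
                "group; none found"
            )
        acceptors = [i for i in a_idx if s.atoms[i].element.upper() in ("N", "O")]
        if not acceptors:
            raise AnalysisError("no N/O acceptors in acceptor group")
        counts = np.zeros(traj.n_frames, dtype=int)
        for f, frame in enumerate(traj.frames):
            n = 0
            for d, hs in donors.items():
                for a in acceptors:
                    if a == d:
                        continue
                    if np.linalg.norm(frame[d] - frame[a]) > cutoff:
                        continue
                    for h in hs:
                        v1 = frame[d] - frame[h]
                        v2 = frame[a] - frame[h]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                        if ang >= angle_cutoff:
                            n += 1
                            break
            counts[f] = n
        return InteractionSeries(counts=counts, kind="hbond")
    if kind == "salt_bridge":
        cutoff = 4.0 if distance_cutoff is None else distance_cutoff
        cations = [i for i in d_idx
                   if s.atoms[i].element.upper() == "N"
                   and s.atoms[i].charge > charge_threshold]
        anions = [i for i in a_idx
                  if s.atoms[i].element.upper() == "O"
                  and s.atoms[i].charge < -charge_threshold]
        if not cations or not anions:
            raise AnalysisError(
                "salt-bridge detection needs charged N (donor side) and O "
                "(acceptor side) atoms; assign partial charges first"
            )
        counts = np.zeros(traj.n_frames, dtype=int)
        for f, frame in enumerate(traj.frames):
            r = cdist(frame[cations], frame[anions])
            counts[f] = int((r <= cutoff).sum())
        return InteractionSeries(counts=counts, kind="salt_bridge")
    raise ValueError(f"unknown interaction kind '{kind}'")


@dataclass
class EnergySeries:
    """Per-frame short-range LJ+Coulomb energy between two groups (kJ mol⁻¹)."""

    energies: np.ndarray
    cutoff: float
    e_bound: float | None = None
    e_unbound: float | None = None
    sd_bound: float | None = None
    sd_unbound: float | None = None
    delta_e: float | None = None
    delta_e_sd: float | None = None
    delta_defined: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.energies)


def interaction_energy_series(traj: Trajectory, enzyme_group="enzyme",
                              substrate_group="substrate",
                              cutoff: float = 10.0) -> EnergySeries:
    """Per-frame enzyme-substrate nonbonded energy along a trajectory."""
    s = traj.structure
    e_idx = _resolve_group(s, enzyme_group)
    s_idx = _resolve_group(s, substrate_group)
    q = s.charges()
    sig, eps = s.lj_params()
    energies = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        energies[f] = nonbonded_energy(
            frame[e_idx], q[e_idx], sig[e_idx], eps[e_idx],
            frame[s_idx], q[s_idx], sig[s_idx], eps[s_idx], cutoff=cutoff,
        )
    return EnergySeries(energies=energies, cutoff=cutoff)


def conditional_energy(e: EnergySeries, s: InteractionSeries,
                       min_frames: int = 5) -> EnergySeries:
    """Split the energy series by bond state and report ΔE = E_bound − E_unbound.

    ΔE is flagged undefined when either state occurs in fewer than
    ``min_frames`` frames.
    """
    if len(s.counts) != e.n_frames:
        raise AnalysisError("energy and interaction series have different lengths")
    bound = e.energies[s.bound_mask]
    unbound = e.energies[~s.bound_mask]
    out = EnergySeries(energies=e.energies, cutoff=e.cutoff)
    if len(bound):
        out.e_bound = float(bound.mean())
        out.sd_bound = float(bound.std(ddof=1)) if len(bound) > 1 else 0.0
    if len(unbound):
        out.e_unbound = float(unbound.mean())
        out.sd_unbound = float(unbound.std(ddof=1)) if len(unbound) > 1 else 0.0
    if len(bound) >= min_frames and len(unbound) >= min_frames:
        out.delta_e = out.e_bound - out.e_unbound
        out.delta_e_sd = float(np.sqrt(
            out.sd_bound**2 / len(bound) + out.sd_unbound**2 / len(unbound)
        ))
        out.delta_defined = True
    return out


_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass
class SideChainStateSeries:
    """Per-frame vertical/horizontal classification of an aromatic side chain."""

    labels: np.ndarray              # 1 = toward the active site, 2 = away
    angles: np.ndarray              # degrees
    residue_id: int
    boundary: float

    @property
    def fractions(self) -> tuple[float, float]:
        f1 = float(np.mean(self.labels == 1))
        return f1, 1.0 - f1


def classify_sidechain(traj: Trajectory, residue_id: int,
                       pocket_axis=("catalytic_triad", "pocket_mouth"),
                       boundary: float = 45.0) -> SideChainStateSeries:
    """Classify an aromatic ring as pointing toward or away from the pocket.

    The per-frame angle θ is measured between the Cβ→ring-centroid vector and
    the pocket axis (origin-group centroid → mouth-group centroid); θ ≤
    ``boundary`` is conformation 1 (toward the active site).
    """
    s = traj.structure
    res_idx = s.atom_indices_of_residue(residue_id)
    if not res_idx:
        raise AnalysisError(f"no residue {residue_id}")
    resname = s.atoms[res_idx[0]].residue_name
    if resname not in _RING_ATOMS:
        raise AnalysisError(f"residue {residue_id} ({resname}) is not aromatic")
    names = {s.atoms[i].name: i for i in res_idx}
    try:
        cb = names["CB"]
        ring = [names[n] for n in _RING_ATOMS[resname]]
    except KeyError as exc:
        raise AnalysisError(f"residue {residue_id} misses ring atoms") from exc
    origin = _resolve_group(s, pocket_axis[0])
    mouth = _resolve_group(s, pocket_axis[1])
    labels = np.empty(traj.n_frames, dtype=int)
    angles = np.empty(traj.n_frames)
    for f, frame in enumerate(traj.frames):
        axis = frame[mouth].mean(axis=0) - frame[origin].mean(axis=0)
        vec = frame[ring].mean(axis=0) - frame[cb]
        cosang = np.dot(axis, vec) / (np.linalg.norm(axis) * np.linalg.norm(vec))
        theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        angles[f] = theta
        labels[f] = 1 if theta <= boundary else 2
    return SideChainStateSeries(labels=labels, angles=angles,
                                residue_id=residue_id, boundary=boundary)
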