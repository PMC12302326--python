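"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators plant statistics directly — frame-level Bernoulli/Gaussian
construction — instead of simulating physics: the quantity of interest is
whether the analysis code recovers known truth, not whether a force field is
realistic.  Every generator is deterministic under a fixed seed and its
:class:`PlantedTruth` can be serialized next to the data.

The trajectory generator builds a statistical enzyme-substrate complex:

* one "CA" pseudo-atom per enzyme residue, each paired with a dedicated
  substrate atom toggled between a contact (2.0 Å) and a non-contact (9 Å)
  position by independent Bernoulli draws at the planted frequency;
* an arginine-like donor (N-H) and a charged substrate oxygen that realize a
  compliant hydrogen-bond/salt-bridge geometry (2.9 Å, collinear) in bonded
  frames and sit far outside all cutoffs otherwise;
* a pure-Coulomb anchor pair at fixed short distance that realizes the
  planted unbound interaction energy, with the bonded-state energy drop
  realized by the donor-acceptor charges — so the energy analysis computes
  the planted ΔE from coordinates rather than reading it from the truth;
* an aromatic (Phe) side chain whose ring centroid points along or across
  the pocket axis at the planted state fractions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .structures import (COULOMB_CONSTANT, Atom, NonbondedTable, Structure,
                         Trajectory)

__all__ = [
    "PlantedTruth", "default_trajectory_truth", "make_toy_complex",
    "make_trajectory", "make_screen_plate", "make_melt_curve", "make_msa",
    "make_conserved_patch_profile", "make_timecourse",
]


class SyntheticError(ValueError):
    """Raised for conflicting or illegal planted targets."""


@dataclass
class PlantedTruth:
    """Ground truth serialized alongside every generated dataset."""

    # trajectory targets
    contact_freqs: dict | None = None        # residue id -> percent of frames
    hbond_occupancy: float | None = None     # percent of frames bonded
    e_bound: float | None = None             # kJ/mol
    e_unbound: float | None = None           # kJ/mol
    energy_noise_sd: float | None = None     # kJ/mol
    sidechain_fraction_1: float | None = None
    aromatic_residue: int | None = None
    donor_residue: int | None = None
    anchor_residue: int | None = None        # always-contact catalytic stand-in
    contact_threshold: float = 50.0
    # screening-plate targets
    true_folds: dict | None = None           # variant -> fold vs parent
    parent_activity: float | None = None     # μmol h⁻¹ mg⁻¹
    noise_cv: float | None = None
    # melt-curve targets
    tm: float | None = None                  # °C
    # conservation targets
    variable_positions: list | None = None
    conserved_patch: tuple | None = None
    # docking fixture
    pocket: str | None = None

    @property
    def delta_e(self) -> float | None:
        if self.e_bound is None or self.e_unbound is None:
            return None
        return self.e_bound - self.e_unbound

    def expected_hotspots(self, exclude=()) -> list[int]:
        """Residues whose planted contact frequency meets the threshold."""
        freqs = dict(self.contact_freqs or {})
        if self.donor_residue is not None and self.hbond_occupancy is not None:
            freqs.setdefault(self.donor_residue, self.hbond_occupancy)
        if self.anchor_residue is not None:
            freqs.setdefault(self.anchor_residue, 100.0)
        hits = [(r, f) for r, f in freqs.items()
                if f >= self.contact_threshold and r not in set(exclude)]
        hits.sort(key=lambda x: (-x[1], x[0]))
        return [r for r, _ in hits]

    def to_json(self, path):
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True, default=default)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("contact_freqs"):
            d["contact_freqs"] = {int(k): v for k, v in d["contact_freqs"].items()}
        if d.get("true_folds"):
            d["true_folds"] = dict(d["true_folds"])
        if d.get("conserved_patch"):
            d["conserved_patch"] = tuple(d["conserved_patch"])
        return cls(**d)


def default_trajectory_truth() -> PlantedTruth:
    """Planted trajectory statistics used as the standard study conditions.

    Eleven residues meet the 50% contact rule (the arginine-like donor
    through its bond occupancy and the always-contacting catalytic stand-in
    included); the catalytic residue is the one a nomination step excludes.
    """
    return PlantedTruth(
        contact_freqs={91: 85.0, 98: 62.0, 111: 56.0, 134: 88.0, 137: 70.0,
                       139: 58.0, 144: 57.0, 146: 60.0, 305: 75.0,
                       24: 30.0, 99: 40.0, 160: 10.0},
        hbond_occupancy=67.0,
        e_bound=-200.0,
        e_unbound=-102.0,
        energy_noise_sd=3.0,
        sidechain_fraction_1=0.70,
        aromatic_residue=134,
        donor_residue=330,
        anchor_residue=267,
    )


# ---------------------------------------------------------------------------
# docking fixture
# ---------------------------------------------------------------------------

def make_toy_complex(pocket: str = "channel", seed: int = 0):
    """Rigid pseudo-enzyme with a labelled catalytic triad and a shaped pocket.

    ``channel`` is an open tube a short oligomer can thread, ``cleft`` an
    open groove, ``wall`` a solid block in which every seed placement
    clashes.  Returns (Structure, NonbondedTable).
    """
    rng = np.random.default_rng([seed, 101])
    atoms = []
    serial = 1

    def add(name, element, resname, resid, xyz):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=element,
                          residue_name=resname, residue_id=resid, chain_id="E",
                          coords=np.asarray(xyz, float)))
        serial += 1

    triad_indices = []
    if pocket == "channel":
        radius, n_per_ring = 4.5, 12
        zs = np.arange(0.0, 13.6, 1.5)
        resid = 1
        for zi, z in enumerate(zs):
            offset = (zi % 2) * (np.pi / n_per_ring)
            for k in range(n_per_ring):
                ang = 2 * np.pi * k / n_per_ring + offset
                if zi == 1 and k in (0, 1, 2):
                    # catalytic triad on the channel wall near the entrance
                    rid = {0: 267, 1: 306, 2: 308}[k]
                    rn = {0: "THR", 1: "ASP", 2: "ASP"}[k]
                    triad_indices.append(len(atoms))
                    add("CA", "C", rn, rid,
                        (radius * np.cos(ang), radius * np.sin(ang), z))
                else:
                    add("CA", "C", "POC", resid,
                        (radius * np.cos(ang), radius * np.sin(ang), z))
                    resid += 1
    elif pocket == "cleft":
        resid = 1
        for x in np.arange(-7.5, 8.0, 1.5):
            for y in np.arange(-7.5, 8.0, 1.5):
                add("CA", "C", "POC", resid, (x, y, 0.0))
                resid += 1
        for i, rid in enumerate((267, 306, 308)):
            triad_indices.append(len(atoms))
            add("CA", "C", "THR" if i == 0 else "ASP", rid,
                (-1.5 + 1.5 * i, 0.0, 1.0))
    elif pocket == "wall":
        # solid lattice dense enough (1.5 Å spacing, ≥ 1.5 Å margin) that any
        # fragment seeded within a 3 Å radius of the centre must overlap it
        resid = 1
        grid_xy = np.arange(-4.5, 4.6, 1.5)
        for x in grid_xy:
            for y in grid_xy:
                for z in np.arange(-6.0, 6.1, 1.5):
                    add("CA", "C", "POC", resid, (x, y, z))
                    resid += 1
        for i, rid in enumerate((267, 306, 308)):
            triad_indices.append(len(atoms))
            add("CA", "C", "THR" if i == 0 else "ASP", rid,
                (-0.75 + 0.75 * i, 0.2, 0.2))
    else:
        raise SyntheticError(f"unknown pocket shape '{pocket}'")

    # small positional jitter so the lattice is not perfectly degenerate
    for a in atoms:
        a.coords = a.coords + rng.normal(0.0, 0.05, size=3)

    structure = Structure(atoms)
    structure.set_group("enzyme", range(len(atoms)))
    structure.set_group("catalytic_triad", triad_indices)
    entries = {}
    for rn in ("POC", "THR", "ASP"):
        entries[(rn, "CA")] = (0.0, 3.4, 0.40)
    table = NonbondedTable(entries=entries)
    table.residue_formal_charges = {"POC": 0, "THR": 0, "ASP": 0}
    return structure, table


# ---------------------------------------------------------------------------
# trajectories with planted statistics
# ---------------------------------------------------------------------------

_ANCHOR_R = 2.2          # Å, always-in-contact anchor distance
_ANCHOR_Q_ENZ = 0.5      # e
_DONOR_Q = 0.6           # e
_HBOND_R = 2.9           # Å donor-acceptor distance in bonded frames
_UNBOUND_R = 12.5        # Å, outside all interaction cutoffs


def _build_stat_complex(truth: PlantedTruth):
    """Topology of the statistical complex (see module docstring)."""
    freqs = dict(truth.contact_freqs or {})
    occ = truth.hbond_occupancy if truth.hbond_occupancy is not None else 0.0
    if truth.donor_residue in freqs and freqs[truth.donor_residue] != occ:
        raise SyntheticError(
            f"conflicting targets: residue {truth.donor_residue} contact "
            f"frequency {freqs[truth.donor_residue]}% vs bond occupancy {occ}%"
        )
    if truth.anchor_residue in freqs and freqs[truth.anchor_residue] != 100.0:
        raise SyntheticError(
            f"conflicting targets: anchor residue {truth.anchor_residue} is "
            "in permanent contact (100%)"
        )
    for rid, f in freqs.items():
        if not 0.0 <= f <= 100.0:
            raise SyntheticError(f"illegal contact frequency {f}% for {rid}")
    if not 0.0 <= occ <= 100.0:
        raise SyntheticError(f"illegal occupancy {occ}%")

    atoms, serial = [], 1

    def add(name, element, resname, resid, chain, xyz, q=0.0):
        nonlocal serial
        atoms.append(Atom(serial=serial, name=name, element=element,
                          residue_name=resname, residue_id=resid,
                          chain_id=chain, coords=np.asarray(xyz, float),
                          charge=q))
        serial += 1
        return len(atoms) - 1

    contact_resids = sorted(r for r in freqs if r != truth.aromatic_residue)
    enzyme_idx, substrate_idx = [], []
    pair_map = {}  # residue id -> substrate partner atom index
    for i, rid in enumerate(contact_resids):
        e = add("CA", "C", "GLY", rid, "E", (20.0 * i, 0.0, 0.0))
        s = add(f"S{i + 1}", "C", "SUB", 1, "S", (20.0 * i, 0.0, 9.0))
        enzyme_idx.append(e)
        substrate_idx.append(s)
        pair_map[rid] = s

    # aromatic side chain + its own substrate partner
    arom_cb = None
    if truth.aromatic_residue is not None:
        x0 = -60.0
        arom_cb = add("CB", "C", "PHE", truth.aromatic_residue, "E", (x0, 0, 0))
        enzyme_idx.append(arom_cb)
        ring0 = _ring_coords(np.array([x0, 0.0, 2.0]), np.array([0.0, 0.0, 1.0]))
        for nm, xyz in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), ring0):
            enzyme_idx.append(add(nm, "C", "PHE", truth.aromatic_residue, "E", xyz))
        if truth.aromatic_residue in freqs:
            s = add("SA", "C", "SUB", 1, "S", (x0, 9.0, 0.0))
            substrate_idx.append(s)
            pair_map[truth.aromatic_residue] = s

    # donor (arginine-like side chain) and charged acceptor terminus
    donor_n = donor_h = acceptor_o = None
    if truth.donor_residue is not None:
        q_o = 0.0
        if truth.delta_e is not None:
            q_o = truth.delta_e * _HBOND_R / (COULOMB_CONSTANT * _DONOR_Q)
        donor_n = add("NH1", "N", "ARG", truth.donor_residue, "E",
                      (-40.0, 0.0, 0.0), q=_DONOR_Q)
        donor_h = add("HH1", "H", "ARG", truth.donor_residue, "E",
                      (-40.0, 0.0, 1.0), q=0.0)
        acceptor_o = add("OXT", "O", "SUB", 2, "S", (-40.0, 0.0, _UNBOUND_R),
                         q=q_o)
        enzyme_idx += [donor_n, donor_h]
        substrate_idx.append(acceptor_o)

    # pure-Coulomb anchor pair that realizes the unbound baseline energy
    anchor_e = anchor_s = None
    if truth.anchor_residue is not None:
        q_s = 0.0
        if truth.e_unbound is not None:
            q_s = truth.e_unbound * _ANCHOR_R / (COULOMB_CONSTANT * _ANCHOR_Q_ENZ)
        anchor_e = add("CA", "C", "THR", truth.anchor_residue, "E",
                       (-80.0, 0.0, 0.0), q=_ANCHOR_Q_ENZ)
        anchor_s = add("OA", "O", "SUB", 3, "S", (-80.0, 0.0, _ANCHOR_R), q=q_s)
        enzyme_idx.append(anchor_e)
        substrate_idx.append(anchor_s)

    mouth = add("MTH", "C", "MTH", 998, "M", (-80.0, 0.0, 20.0))

    structure = Structure(atoms)
    structure.set_group("enzyme", enzyme_idx)
    structure.set_group("substrate", substrate_idx)
    if donor_n is not None:
        structure.set_group("donor_sidechain", [donor_n, donor_h])
        structure.set_group("substrate_terminus", [acceptor_o])
    if anchor_e is not None:
        structure.set_group("catalytic_triad", [anchor_e])
    structure.set_group("pocket_mouth", [mouth])
    layout = {
        "pair_map": pair_map, "arom_cb": arom_cb, "donor_n": donor_n,
        "donor_h": donor_h, "acceptor_o": acceptor_o, "anchor_e": anchor_e,
        "anchor_s": anchor_s,
    }
    return structure, layout


def _ring_coords(centroid, normal):
    """Regular hexagon (1.4 Å radius) centred at ``centroid`` ⊥ ``normal``."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, normal)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    return [centroid + 1.4 * (np.cos(a) * u + np.sin(a) * w)
            for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]


def make_trajectory(truth: PlantedTruth, n_frames: int = 200,
                    n_replicas: int = 3, seed: int = 0,
                    dt: float = 100.0) -> list[Trajectory]:
    """Replica trajectories realizing the planted statistics frame by frame."""
    if n_frames < 1 or n_replicas < 1:
        raise SyntheticError("need n_frames >= 1 and n_replicas >= 1")
    structure, layout = _build_stat_complex(truth)
    base = structure.coords
    freqs = dict(truth.contact_freqs or {})
    occ = (truth.hbond_occupancy or 0.0) / 100.0
    frac1 = truth.sidechain_fraction_1
    trajs = []
    for rep in range(n_replicas):
        rng = np.random.default_rng([seed, 11, rep])
        frames = np.repeat(base[None, :, :], n_frames, axis=0)
        # per-residue contact toggling
        for rid, partner in layout["pair_map"].items():
            p = freqs[rid] / 100.0
            contact = rng.random(n_frames) < p
            axis = 1 if rid == truth.aromatic_residue else 2
            near, far = (2.4, 9.0) if rid == truth.aromatic_residue else (2.0, 9.0)
            frames[:, partner, axis] = np.where(contact, near, far)
        # hydrogen-bond / salt-bridge toggling
        bond_states = None
        if layout["acceptor_o"] is not None:
            bond_states = rng.random(n_frames) < occ
            frames[:, layout["acceptor_o"], 2] = np.where(
                bond_states, _HBOND_R, _UNBOUND_R
            )
        # anchor distance jitter -> Gaussian-ish energy noise
        if layout["anchor_s"] is not None and truth.e_unbound:
            sd_r = 0.0
            if truth.energy_noise_sd:
                sd_r = truth.energy_noise_sd * _ANCHOR_R / abs(truth.e_unbound)
            jitter = np.clip(rng.normal(0.0, sd_r, n_frames), -0.25, 0.25)
            frames[:, layout["anchor_s"], 2] = _ANCHOR_R + jitter
        # aromatic ring state
        if layout["arom_cb"] is not None and frac1 is not None:
            cb = base[layout["arom_cb"]]
            ring_idx = [layout["arom_cb"] + 1 + k for k in range(6)]
            up = _ring_coords(cb + np.array([0, 0, 2.0]), np.array([0, 0, 1.0]))
            out = _ring_coords(cb + np.array([2.0, 0, 0]), np.array([1, 0, 0.0]))
            state1 = rng.random(n_frames) < frac1
            for k, idx in enumerate(ring_idx):
                frames[:, idx] = np.where(state1[:, None], up[k], out[k])
        trajs.append(Trajectory(structure=structure, frames=frames, dt=dt,
                                replica_id=rep))
    return trajs


# ---------------------------------------------------------------------------
# screening plates, melt curves, MSAs, time courses
# ---------------------------------------------------------------------------

def make_screen_plate(true_folds: dict, parent_activity: float = 77.0,
                      noise_cv: float = 0.05, n_replicates: int = 2,
                      seed: int = 0, enzyme_nM: float = 50.0,
                      enzyme_mg_per_L: float = 1.90, time_h: float = 2.0,
                      loading_g_per_L: float = 456.0, substrate: str = "PA6",
                      background_uM: float = 5.0,
                      n_background_wells: int = 8):
    """Screening-plate activity table with known per-variant fold-changes.

    Measurement noise is mean-preserving lognormal with coefficient of
    variation ``noise_cv``; the parent is included as variant ``"parent"``
    and background wells as variant ``"blank"``.  Returns (DataFrame, truth).
    """
    if any(f <= 0 for f in true_folds.values()):
        raise SyntheticError("fold-changes must be positive")
    if noise_cv < 0:
        raise SyntheticError("noise_cv must be non-negative")
    rng = np.random.default_rng([seed, 21])
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    variants = [("parent", 1.0)] + sorted(true_folds.items())
    for variant, fold in variants:
        activity = parent_activity * fold
        amine_true = activity * enzyme_mg_per_L * time_h  # μM
        for rep in range(1, n_replicates + 1):
            noise = np.exp(rng.normal(0.0, sigma) - sigma**2 / 2) if sigma else 1.0
            rows.append({
                "variant": variant, "substrate": substrate,
                "enzyme_nM": enzyme_nM, "enzyme_mg_per_L": enzyme_mg_per_L,
                "loading_g_per_L": loading_g_per_L, "time_h": time_h,
                "amine_uM": max(amine_true * noise, 0.0), "replicate": rep,
            })
    for w in range(1, n_background_wells + 1):
        noise = np.exp(rng.normal(0.0, sigma) - sigma**2 / 2) if sigma else 1.0
        rows.append({
            "variant": "blank", "substrate": substrate, "enzyme_nM": 0.0,
            "enzyme_mg_per_L": 0.0, "loading_g_per_L": loading_g_per_L,
            "time_h": time_h, "amine_uM": max(background_uM * noise, 0.0),
            "replicate": w,
        })
    truth = PlantedTruth(true_folds=dict(true_folds),
                         parent_activity=parent_activity, noise_cv=noise_cv)
    return pd.DataFrame(rows), truth


def make_melt_curve(tm: float = 85.7, slope: float = 1.2, noise: float = 0.01,
                    seed: int = 0, t_min: float = 40.0, t_max: float = 99.5,
                    grid: float = 0.5):
    """Two-state melt curve (temperature °C, unfolded fraction signal)."""
    if not t_min < tm < t_max:
        raise SyntheticError("planted Tm must lie inside the scanned range")
    rng = np.random.default_rng([seed, 31])
    t = np.arange(t_min, t_max + grid / 2, grid)
    y = 1.0 / (1.0 + np.exp((tm - t) / slope))
    y = y + rng.normal(0.0, noise, size=len(t))
    truth = PlantedTruth(tm=tm)
    return np.column_stack([t, y]), truth


def make_conserved_patch_profile(length: int = 310, patch=(300, 308),
                                 variable_positions=(304, 305),
                                 seed: int = 0) -> np.ndarray:
    """Per-column amino-acid frequency profile (length × 20).

    Background columns mix three residues (moderate conservation), patch
    columns are fully conserved except the listed variable positions, which
    are uniform over all 20 amino acids.
    """
    rng = np.random.default_rng([seed, 41])
    prof = np.zeros((length, 20))
    for j in range(length):
        picks = rng.choice(20, size=3, replace=False)
        prof[j, picks] = (0.5, 0.3, 0.2)
    lo, hi = patch
    for j in range(lo - 1, hi):
        prof[j] = 0.0
        prof[j, rng.integers(20)] = 1.0
    for pos in variable_positions:
        prof[pos - 1] = 1.0 / 20.0
    return prof


def make_msa(profile: np.ndarray, n_seqs: int = 60, seed: int = 0,
             variable_positions=(304, 305), patch=(300, 308)):
    """Sample an alignment column-wise from a frequency profile.

    Returns (list of sequences, truth).
    """
    from .conservation import AMINO_ACIDS

    rng = np.random.default_rng([seed, 51])
    profile = np.asarray(profile, dtype=float)
    length = profile.shape[0]
    cols = np.empty((n_seqs, length), dtype="U1")
    for j in range(length):
        p = profile[j] / profile[j].sum()
        cols[:, j] = rng.choice(list(AMINO_ACIDS), size=n_seqs, p=p)
    seqs = ["".join(cols[i]) for i in range(n_seqs)]
    truth = PlantedTruth(variable_positions=list(variable_positions),
                         conserved_patch=tuple(patch))
    return seqs, truth


def write_msa_fasta(seqs, path):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs, 1):
            fh.write(f">seq{i:04d}\n{s}\n")


def make_timecourse(initial_rate: float = 50.0, saturation_uM: float = 400.0,
                    background_rate: float = 2.0, times_h=None,
                    noise_cv: float = 0.02, seed: int = 0,
                    enzyme_mg_per_L: float = 1.90) -> pd.DataFrame:
    """Degradation time course: saturating enzymatic release + linear background.

    With ``enzyme_mg_per_L = 0`` the sample reproduces the pure background
    series.  Released amine in μM; returns a tidy DataFrame with matched
    sample and blank columns.
    """
    rng = np.random.default_rng([seed, 61])
    t = np.asarray(times_h if times_h is not None else
                   [0, 8, 24, 48, 72, 96, 120], dtype=float)
    k = initial_rate / saturation_uM if saturation_uM > 0 else 0.0
    enzymatic = saturation_uM * (1.0 - np.exp(-k * t))
    if enzyme_mg_per_L == 0:
        enzymatic = np.zeros_like(t)
    background = background_rate * t
    sigma = np.sqrt(np.log1p(noise_cv**2))
    def noisy(x):
        if sigma == 0:
            return x
        return x * np.exp(rng.normal(0, sigma, size=len(x)) - sigma**2 / 2)
    return pd.DataFrame({
        "time_h": t,
        "amine_uM": noisy(enzymatic + background),
        "blank_uM": noisy(background.copy()),
        "enzyme_mg_per_L": enzyme_mg_per_L,
    })
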