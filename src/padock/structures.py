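"""Typed model of structures, trajectories and nonbonded parameters.

Coordinates are in Å, charges in elementary charge units, Lennard-Jones
``sigma`` in Å and ``epsilon`` in kJ mol⁻¹.  Residue numbering is taken
verbatim from the input file (1-based), so positions such as T267 or F134
address the same residues as in the source structure.

Hydrogens are first-class atoms: hydrogen-bond geometry needs them, and
analyses that require them fail fast when a structure carries none.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

#: Coulomb constant in kJ mol^-1 Å e^-2
COULOMB_CONSTANT = 1389.35458


class StructureError(ValueError):
    """Raised for malformed structure/trajectory input."""


class ParameterError(KeyError):
    """Raised when nonbonded parameters are missing or inconsistent."""


@dataclass
class Atom:
    """A single atom with coordinates and nonbonded parameters."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    coords: np.ndarray
    charge: float = 0.0
    lj_sigma: float = 0.0
    lj_epsilon: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial}: coords must be a finite 3-vector")
        if self.residue_id < 1:
            raise StructureError(f"atom {self.serial}: residue_id must be >= 1")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise StructureError(f"atom {self.serial}: LJ parameters must be non-negative")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


class Structure:
    """An ordered collection of atoms with named atom-index groups.

    Groups are index sets into the atom list; conventional group names are
    ``"enzyme"``, ``"substrate"`` and ``"catalytic_triad"``.
    """

    def __init__(self, atoms, groups=None):
        self.atoms = list(atoms)
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureError("atom serials must be unique")
        self.groups: dict[str, np.ndarray] = {}
        for name, idx in (groups or {}).items():
            self.set_group(name, idx)
        self._check_disjoint()

    def _check_disjoint(self):
        if "enzyme" in self.groups and "substrate" in self.groups:
            if set(self.groups["enzyme"]) & set(self.groups["substrate"]):
                raise StructureError("'enzyme' and 'substrate' groups must be disjoint")

    def set_group(self, name: str, indices):
        idx = np.asarray(sorted(indices), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= len(self.atoms)):
            raise StructureError(f"group '{name}' has out-of-range indices")
        self.groups[name] = idx
        self._check_disjoint()

    def group_by_residues(self, name: str, residue_ids, chain_id=None):
        """Define a group from residue numbers (optionally chain-restricted)."""
        wanted = set(residue_ids)
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_id in wanted and (chain_id is None or a.chain_id == chain_id)
        ]
        self.set_group(name, idx)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, {k: v.copy() for k, v in self.groups.items()})

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    def lj_params(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([a.lj_sigma for a in self.atoms]),
            np.array([a.lj_epsilon for a in self.atoms]),
        )

    def residues(self, indices=None):
        """Ordered unique (chain_id, residue_id, residue_name) over ``indices``."""
        out, seen = [], set()
        idx = range(self.n_atoms) if indices is None else indices
        for i in idx:
            a = self.atoms[i]
            key = (a.chain_id, a.residue_id)
            if key not in seen:
                seen.add(key)
                out.append((a.chain_id, a.residue_id, a.residue_name))
        return out

    def atom_indices_of_residue(self, residue_id: int, chain_id=None):
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_id == residue_id and (chain_id is None or a.chain_id == chain_id)
        ]

    def has_hydrogens(self) -> bool:
        return any(a.is_hydrogen for a in self.atoms)


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Å; ``dt`` is the frame
    spacing in ps.
    """

    structure: Structure
    frames: np.ndarray
    dt: float = 1.0
    replica_id: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise StructureError("trajectory needs at least one frame of shape (n_atoms, 3)")
        if self.frames.shape[1:] != (self.structure.n_atoms, 3):
            raise StructureError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.structure.n_atoms})"
            )
        if self.dt <= 0:
            raise StructureError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class NonbondedTable:
    """(residue_name, atom_name) → (charge, sigma, epsilon) lookup.

    Pair parameters are combined with Lorentz–Berthelot rules.  Optional
    per-residue formal charges allow validating that a complete residue entry
    sums to its formal charge.
    """

    entries: dict = field(default_factory=dict)
    combination_rule: str = "lorentz-berthelot"
    residue_formal_charges: dict = field(default_factory=dict)

    def lookup(self, residue_name: str, atom_name: str):
        return self.entries[(residue_name, atom_name)]

    def validate_formal_charges(self, tol: float = 1e-6):
        sums: dict[str, float] = {}
        for (res, _), (q, _, _) in self.entries.items():
            sums[res] = sums.get(res, 0.0) + q
        for res, formal in self.residue_formal_charges.items():
            if res in sums and abs(sums[res] - formal) > tol:
                raise ParameterError(
                    f"residue {res}: charges sum to {sums[res]:.6f}, expected {formal}"
                )

    @classmethod
    def from_file(cls, path) -> "NonbondedTable":
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"residue", "atom", "charge", "sigma", "epsilon"}
        if not required.issubset(df.columns):
            raise ParameterError(
                f"parameter table must have columns {sorted(required)}, got {list(df.columns)}"
            )
        entries = {
            (str(r.residue), str(r.atom)): (float(r.charge), float(r.sigma), float(r.epsilon))
            for r in df.itertuples()
        }
        return cls(entries=entries)

    def to_file(self, path):
        rows = [
            {"residue": res, "atom": atom, "charge": q, "sigma": s, "epsilon": e}
            for (res, atom), (q, s, e) in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_ELEMENT_GUESSES = ("CL", "BR", "NA", "MG", "ZN", "FE", "CA")


def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if stripped[:2].upper() in _ELEMENT_GUESSES:
        return stripped[:2].capitalize()
    return stripped[:1].upper()


def _structure_from_atom_array(arr) -> Structure:
    atoms = []
    serials = arr.get_annotation("atom_id") if "atom_id" in arr.get_annotation_categories() else None
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip()
        name = str(arr.atom_name[i]).strip()
        if not element:
            element = _infer_element(name)
            warnings.warn(f"atom {name}: element missing, inferred '{element}'")
        atoms.append(
            Atom(
                serial=int(serials[i]) if serials is not None else i + 1,
                name=name,
                element=element,
                residue_name=str(arr.res_name[i]).strip(),
                residue_id=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]).strip() or "A",
                coords=np.asarray(arr.coord[i], dtype=float),
            )
        )
    return Structure(atoms)


def _scan_pdb_for_error(text: str):
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
                int(line[22:26])
            except (ValueError, IndexError):
                return lineno
    return None


def read_structure(path, format: str | None = None) -> Structure:
    """Read a single-model PDB or XYZ file into a :class:`Structure`.

    Atom order and residue numbering are preserved verbatim.
    """
    fmt = format or ("xyz" if str(path).lower().endswith(".xyz") else "pdb")
    if fmt == "pdb":
        with open(path) as fh:
            text = fh.read()
        try:
            pdb = PDBFile.read(io.StringIO(text))
            arr = pdb.get_structure(model=1)
        except Exception as exc:
            lineno = _scan_pdb_for_error(text)
            where = f" at line {lineno}" if lineno else ""
            raise StructureError(f"malformed PDB record{where}: {exc}") from exc
        return _structure_from_atom_array(arr)
    if fmt == "xyz":
        frames, elements = _read_xyz_blocks(path)
        atoms = [
            Atom(serial=i + 1, name=el, element=el, residue_name="UNK",
                 residue_id=1, chain_id="A", coords=c)
            for i, (el, c) in enumerate(zip(elements, frames[0]))
        ]
        return Structure(atoms)
    raise ValueError(f"unknown format '{fmt}'")


def _to_atom_array(structure: Structure, coords=None):
    n = structure.n_atoms
    arr = bts.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else structure.coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_id for a in structure.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in structure.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in structure.atoms], dtype="U6")
    arr.element = np.array([a.element for a in structure.atoms], dtype="U2")
    arr.set_annotation("atom_id", np.array([a.serial for a in structure.atoms], dtype=int))
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_structure(structure: Structure, path, format: str | None = None, coords=None):
    """Write a structure as PDB (3-decimal coordinates) or XYZ."""
    fmt = format or ("xyz" if str(path).lower().endswith(".xyz") else "pdb")
    if fmt == "pdb":
        pdb = PDBFile()
        pdb.set_structure(_to_atom_array(structure, coords))
        pdb.write(str(path))
    elif fmt == "xyz":
        xyz = coords if coords is not None else structure.coords
        with open(path, "w") as fh:
            _write_xyz_block(fh, structure, xyz)
    else:
        raise ValueError(f"unknown format '{fmt}'")


def _write_xyz_block(fh, structure: Structure, coords, comment=""):
    fh.write(f"{structure.n_atoms}\n{comment}\n")
    for atom, c in zip(structure.atoms, coords):
        fh.write(f"{atom.element:<2s} {c[0]:12.6f} {c[1]:12.6f} {c[2]:12.6f}\n")


def _read_xyz_blocks(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    frames, elements, i, frame_idx = [], None, 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise StructureError(f"frame {frame_idx}: bad atom-count line {i + 1}") from exc
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise StructureError(f"frame {frame_idx}: truncated (expected {n} atoms)")
        els, coords = [], []
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise StructureError(f"frame {frame_idx}: malformed line {i + 3 + j}")
            els.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if elements is None:
            elements = els
        frames.append(np.asarray(coords))
        i += 2 + n
        frame_idx += 1
    if not frames:
        raise StructureError("no frames found")
    return frames, elements


def _split_pdb_models(text: str):
    """Split multi-model PDB text into per-model lists of ATOM/HETATM lines."""
    models, current, in_model = [], [], False
    has_model_records = "MODEL" in text
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            in_model = True
            current = []
        elif rec == "ENDMDL":
            models.append(current)
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            current.append(line)
    if not has_model_records and current:
        models.append(current)
    return models


def read_trajectory(path, topology: Structure, dt: float = 1.0,
                    replica_id: int = 0, format: str | None = None) -> Trajectory:
    """Read a multi-model PDB or concatenated-XYZ stack as a trajectory.

    Every frame must carry exactly ``topology.n_atoms`` atoms; a mismatch
    reports the offending frame index.
    """
    fmt = format or ("xyz" if str(path).lower().endswith(".xyz") else "pdb")
    n = topology.n_atoms
    if fmt == "pdb":
        with open(path) as fh:
            text = fh.read()
        models = _split_pdb_models(text)
        if not models:
            raise StructureError("no coordinate records found")
        for k, lines in enumerate(models):
            if len(lines) != n:
                raise StructureError(f"frame {k}: has {len(lines)} atoms, expected {n}")
        frames = np.empty((len(models), n, 3))
        for k, lines in enumerate(models):
            for j, line in enumerate(lines):
                try:
                    frames[k, j] = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except ValueError as exc:
                    raise StructureError(f"frame {k}: malformed coordinates") from exc
    elif fmt == "xyz":
        blocks, _ = _read_xyz_blocks(path)
        for k, b in enumerate(blocks):
            if b.shape[0] != n:
                raise StructureError(f"frame {k}: has {b.shape[0]} atoms, expected {n}")
        frames = np.stack(blocks)
    else:
        raise ValueError(f"unknown format '{fmt}'")
    return Trajectory(structure=topology, frames=frames, dt=dt, replica_id=replica_id)


def write_trajectory(traj: Trajectory, path, format: str | None = None):
    """Write a trajectory as multi-model PDB or a concatenated XYZ stack."""
    fmt = format or ("xyz" if str(path).lower().endswith(".xyz") else "pdb")
    if fmt == "pdb":
        pdb = PDBFile()
        n = traj.structure.n_atoms
        stack = bts.AtomArrayStack(traj.n_frames, n)
        template = _to_atom_array(traj.structure)
        for cat in template.get_annotation_categories():
            stack.set_annotation(cat, template.get_annotation(cat))
        stack.coord = traj.frames.astype(np.float32)
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif fmt == "xyz":
        with open(path, "w") as fh:
            for k in range(traj.n_frames):
                _write_xyz_block(fh, traj.structure, traj.frames[k], comment=f"frame {k}")
    else:
        raise ValueError(f"unknown format '{fmt}'")


def assign_nonbonded(structure: Structure, table: NonbondedTable) -> Structure:
    """Return a copy of ``structure`` with charges and LJ parameters assigned.

    All missing (residue, atom) keys are aggregated into a single error.
    """
    missing = []
    atoms = []
    for a in structure.atoms:
        key = (a.residue_name, a.name)
        if key not in table.entries:
            missing.append(key)
            atoms.append(a)
        else:
            q, s, e = table.entries[key]
            atoms.append(replace(a, charge=q, lj_sigma=s, lj_epsilon=e))
    if missing:
        raise ParameterError(f"missing nonbonded parameters for: {sorted(set(missing))}")
    return Structure(atoms, {k: v.copy() for k, v in structure.groups.items()})
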