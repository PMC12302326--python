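"""Construction of polyamide-6 oligomer substrates for docking.

An oligomer is a chain of 6-aminohexanoic-acid (6-AHA) repeat units with one
capped terminus (Ace or NMe, mimicking chain continuation) and one charged
terminus (carboxylate or ammonium, mimicking a polymer chain end).  The
carboxy-terminus proxy is Ace-[6-AHA]n-COO⁻, the amine-terminus proxy
NMe-[6-AHA]n-NH₃⁺.

Geometry is built from standard amide/alkane internal coordinates.  Amide ω
dihedrals are frozen trans; only backbone single bonds are docking degrees of
freedom.  The oligomer carries polar hydrogens only (amide N-H, ammonium H);
aliphatic hydrogens are not modelled at this resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import place_atom
from .structures import Atom, NonbondedTable, Structure

# internal-coordinate constants (Å / degrees)
_D_CC = 1.53       # sp3 C-C
_D_CC_CO = 1.52    # sp3 C - carbonyl C
_D_CN_AMIDE = 1.335
_D_NC_SP3 = 1.455  # amide N - sp3 C
_D_CO = 1.23       # C=O
_D_CO_CARBOX = 1.25
_D_NH = 1.01
_A_SP3 = 111.5
_A_AMIDE = 121.0
_A_CNC = 121.5     # C'-N-C2
_A_CCN = 114.0     # C6-C7-N (acyl)
_A_CARBOX = 118.0

CAPS = ("Ace", "NMe")
TERMINI = ("COO_minus", "NH3_plus")


class OligomerError(ValueError):
    """Raised for invalid oligomer specifications."""


@dataclass(frozen=True)
class OligomerSpec:
    """Chemical description of a capped/charged [6-AHA]n chain."""

    n_units: int = 4
    terminus_a: str = "Ace"
    terminus_b: str = "COO_minus"
    orientation: int = 1

    def __post_init__(self):
        if self.n_units < 1:
            raise OligomerError("n_units must be >= 1")
        if self.terminus_a not in CAPS or self.terminus_b not in TERMINI:
            raise OligomerError(
                f"unknown cap/terminus: {self.terminus_a}/{self.terminus_b}"
            )
        if (self.terminus_a, self.terminus_b) not in (
            ("Ace", "COO_minus"),
            ("NMe", "NH3_plus"),
        ):
            raise OligomerError(
                "invalid pairing: Ace caps the carboxy-terminus proxy (COO_minus) "
                "and NMe the amine-terminus proxy (NH3_plus)"
            )
        if self.orientation not in (1, 2):
            raise OligomerError("orientation must be 1 or 2")

    @property
    def formal_charge(self) -> int:
        return -1 if self.terminus_b == "COO_minus" else +1

    @property
    def label(self) -> str:
        body = f"[6-AHA]{self.n_units}"
        if self.terminus_b == "COO_minus":
            fwd, rev = f"Ace-{body}-COO-", f"-OOC-{body}-Ace"
        else:
            fwd, rev = f"NMe-{body}-NH3+", f"+H3N-{body}-NMe"
        return fwd if self.orientation == 1 else rev


@dataclass
class _ZRow:
    """One internal-coordinate row: atom placed from three reference atoms."""

    name: str
    element: str
    residue_name: str
    residue_id: int
    refs: tuple  # (a, b, c) indices; c is the bonded parent
    bond: float
    angle: float
    torsion: float
    var_key: tuple | None = None       # (unit, label) if torsion is a docking DOF
    torsion_offset: float = 0.0        # offset applied on top of a variable torsion
    amide_to_parent: bool = False


@dataclass
class OligomerConformer:
    """A built conformer: structure, docking degrees of freedom, bookkeeping.

    ``rotatable_bonds`` lists dihedral atom quadruples (a, b, c, d); the
    torsion about b-c is a docking degree of freedom.  ``unit_slices`` maps
    growth increments (cap+unit1, unit2, ...) to atom index ranges.
    """

    structure: Structure
    rotatable_bonds: list
    formal_charge: int
    spec: OligomerSpec
    zrows: list = field(repr=False, default_factory=list)
    unit_slices: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    amide_pairs: list = field(default_factory=list)
    attack_site: tuple | None = None

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def variable_keys(self, unit: int | None = None):
        """Docking torsion keys, optionally restricted to one growth unit."""
        keys = [r.var_key for r in self.zrows if r.var_key is not None]
        seen, out = set(), []
        for k in keys:
            if k not in seen and (unit is None or k[0] == unit):
                seen.add(k)
                out.append(k)
        return out

    def build_coords(self, torsions: dict | None = None,
                     n_atoms: int | None = None) -> np.ndarray:
        """Cartesian coordinates for the first ``n_atoms`` atoms.

        ``torsions`` overrides variable backbone torsions by key; unset keys
        stay at the extended (all-anti, 180°) default.
        """
        torsions = torsions or {}
        n = n_atoms if n_atoms is not None else len(self.zrows)
        coords = np.zeros((n, 3))
        for i in range(n):
            row = self.zrows[i]
            if i == 0:
                coords[i] = (0.0, 0.0, 0.0)
            elif i == 1:
                coords[i] = (row.bond, 0.0, 0.0)
            elif i == 2:
                theta = np.radians(row.angle)
                a, b, c = row.refs
                coords[i] = coords[c] + row.bond * np.array(
                    [-np.cos(theta), np.sin(theta), 0.0]
                )
            else:
                a, b, c = row.refs
                tor = row.torsion
                if row.var_key is not None and row.var_key in torsions:
                    tor = torsions[row.var_key] + row.torsion_offset
                coords[i] = place_atom(coords[a], coords[b], coords[c],
                                       row.bond, row.angle, tor)
        return coords

    def extend_coords(self, coords_partial: np.ndarray, n_new_total: int,
                      torsions: dict) -> np.ndarray:
        """Grow a partially placed conformer in its current (world) frame.

        ``coords_partial`` holds the already-placed atoms; rows up to
        ``n_new_total`` are appended with the given torsion assignments.
        """
        n0 = len(coords_partial)
        coords = np.vstack([coords_partial, np.zeros((n_new_total - n0, 3))])
        for i in range(n0, n_new_total):
            row = self.zrows[i]
            a, b, c = row.refs
            tor = row.torsion
            if row.var_key is not None and row.var_key in torsions:
                tor = torsions[row.var_key] + row.torsion_offset
            coords[i] = place_atom(coords[a], coords[b], coords[c],
                                   row.bond, row.angle, tor)
        return coords


def _heavy_degree(bonds, n_atoms, elements):
    deg = np.zeros(n_atoms, dtype=int)
    for i, j, _ in bonds:
        if elements[i] != "H" and elements[j] != "H":
            deg[i] += 1
            deg[j] += 1
    return deg


def build_oligomer(spec: OligomerSpec) -> OligomerConformer:
    """Build an extended (all-anti) conformer for ``spec``.

    Atoms are ordered for incremental growth: cap + unit 1 first, then units
    2..n, then the terminal decoration.  The attack-site amide is the central
    backbone amide (between units ⌈n/2⌉ and ⌈n/2⌉+1 for n ≥ 2).
    """
    rows: list[_ZRow] = []
    bonds: list[tuple] = []  # (i, j, is_amide)
    amides: list[tuple] = []  # (C index, N index)
    unit_slices: list[tuple] = []
    rot_quads: dict[tuple, tuple] = {}  # var_key -> dihedral quadruple

    def add(row: _ZRow, parent: int | None):
        rows.append(row)
        i = len(rows) - 1
        if parent is not None:
            bonds.append((parent, i, row.amide_to_parent))
        return i

    def add_unit(unit, resname, resid, prev, prev_key, first_backbone=None,
                 n_torsion=180.0):
        """Append one repeat unit; ``prev_key`` is the preceding C6-C7 torsion key."""
        if first_backbone is None:
            a, b, c = prev
            # amide N, torsion shared with the previous unit's C6-C7 key
            n_idx = add(_ZRow("N", "N", resname, resid, (a, b, c), _D_CN_AMIDE,
                              _A_CCN, n_torsion, var_key=prev_key,
                              amide_to_parent=True), c)
            amides.append((c, n_idx))
            add(_ZRow("H", "H", resname, resid, (b, c, n_idx), _D_NH, 119.0,
                      0.0), n_idx)
            c2 = add(_ZRow("C2", "C", resname, resid, (b, c, n_idx), _D_NC_SP3,
                           _A_CNC, 180.0), n_idx)
            c3 = add(_ZRow("C3", "C", resname, resid, (c, n_idx, c2), _D_CC,
                           _A_SP3, 180.0, var_key=(unit, "N-C2")), c2)
            rot_quads[(unit, "N-C2")] = (c, n_idx, c2, c3)
            chain = (n_idx, c2, c3)
        else:
            chain = first_backbone  # (N/C2 ..) already placed
            n_idx, c2, c3 = chain
            c4 = None
        n_ref, c2, c3 = chain
        c4 = add(_ZRow("C4", "C", resname, resid, (n_ref, c2, c3), _D_CC,
                       _A_SP3, 180.0, var_key=(unit, "C2-C3")), c3)
        rot_quads[(unit, "C2-C3")] = (n_ref, c2, c3, c4)
        c5 = add(_ZRow("C5", "C", resname, resid, (c2, c3, c4), _D_CC, _A_SP3,
                       180.0, var_key=(unit, "C3-C4")), c4)
        rot_quads[(unit, "C3-C4")] = (c2, c3, c4, c5)
        c6 = add(_ZRow("C6", "C", resname, resid, (c3, c4, c5), _D_CC, _A_SP3,
                       180.0, var_key=(unit, "C4-C5")), c5)
        rot_quads[(unit, "C4-C5")] = (c3, c4, c5, c6)
        c7 = add(_ZRow("C7", "C", resname, resid, (c4, c5, c6), _D_CC_CO,
                       112.0, 180.0, var_key=(unit, "C5-C6")), c6)
        rot_quads[(unit, "C5-C6")] = (c4, c5, c6, c7)
        last_carbox = resname == "AHC"
        od = _D_CO_CARBOX if last_carbox else _D_CO
        oa = _A_CARBOX if last_carbox else _A_AMIDE
        # the (unit, "C6-C7") torsion is defined on the chain continuation
        # (next amide N, torsion 180 default); the carbonyl O sits anti to it
        o7 = add(_ZRow("O", "O", resname, resid, (c5, c6, c7), od, oa, 0.0,
                       var_key=(unit, "C6-C7"), torsion_offset=180.0), c7)
        rot_quads[(unit, "C6-C7")] = (c5, c6, c7, o7)
        if last_carbox:
            add(_ZRow("OXT", "O", resname, resid, (c5, c6, c7), od, oa, 180.0,
                      var_key=(unit, "C6-C7")), c7)
        return (c5, c6, c7), (unit, "C6-C7")

    if spec.terminus_a == "Ace":
        # Ace cap: CH3-C(=O)- ; then n units; the last ends in COO-
        start = len(rows)
        ch3 = add(_ZRow("CH3", "C", "ACE", 1, (), _D_CC_CO, 0, 0), None)
        cp = add(_ZRow("C", "C", "ACE", 1, (), _D_CC_CO, 0, 0), ch3)
        o = add(_ZRow("O", "O", "ACE", 1, (None, ch3, cp), _D_CO, _A_AMIDE, 0), cp)
        prev, prev_key = (o, ch3, cp), None
        for unit in range(1, spec.n_units + 1):
            last = unit == spec.n_units
            resname = "AHC" if last else "AHA"
            prev, prev_key = add_unit(unit, resname, unit + 1, prev, prev_key)
            unit_slices.append((start, len(rows)))
            start = len(rows)
    else:
        # NH3+ start: ammonium N leads; NMe cap closes the chain
        start = len(rows)
        n0 = add(_ZRow("N", "N", "AHN", 1, (), _D_NC_SP3, 0, 0), None)
        c2 = add(_ZRow("C2", "C", "AHN", 1, (), _D_NC_SP3, 0, 0), n0)
        c3 = add(_ZRow("C3", "C", "AHN", 1, (None, n0, c2), _D_CC, _A_SP3, 0), c2)
        for k, tor in enumerate((60.0, 180.0, 300.0)):
            add(_ZRow(f"H{k + 1}", "H", "AHN", 1, (c3, c2, n0), _D_NH, 109.5,
                      tor), n0)
        prev, prev_key = add_unit(1, "AHN", 1, None, None,
                                  first_backbone=(n0, c2, c3))
        unit_slices.append((start, len(rows)))
        start = len(rows)
        for unit in range(2, spec.n_units + 1):
            prev, prev_key = add_unit(unit, "AHA", unit, prev, prev_key)
            unit_slices.append((start, len(rows)))
            start = len(rows)
        a, b, c = prev
        ncap = add(_ZRow("N", "N", "NME", spec.n_units + 1, (a, b, c),
                         _D_CN_AMIDE, _A_CCN, 180.0, var_key=prev_key,
                         amide_to_parent=True), c)
        amides.append((c, ncap))
        add(_ZRow("H", "H", "NME", spec.n_units + 1, (b, c, ncap), _D_NH,
                  119.0, 0.0), ncap)
        add(_ZRow("CH3", "C", "NME", spec.n_units + 1, (b, c, ncap), _D_NC_SP3,
                  _A_CNC, 180.0), ncap)
        # cap belongs to the final growth increment
        s0, _ = unit_slices[-1]
        unit_slices[-1] = (s0, len(rows))

    conf = OligomerConformer(
        structure=None,  # filled below
        rotatable_bonds=[rot_quads[k] for k in sorted(rot_quads)],
        formal_charge=spec.formal_charge,
        spec=spec,
        zrows=rows,
        unit_slices=unit_slices,
        bonds=bonds,
        amide_pairs=amides,
    )
    coords = conf.build_coords()
    atoms = [
        Atom(serial=i + 1, name=r.name, element=r.element, residue_name=r.residue_name,
             residue_id=r.residue_id, chain_id="S", coords=coords[i])
        for i, r in enumerate(rows)
    ]
    structure = Structure(atoms)
    structure.set_group("substrate", range(len(atoms)))
    conf.structure = structure

    # attack-site amide: the central backbone amide
    if amides:
        conf.attack_site = amides[len(amides) // 2]
    return conf


def enumerate_orientations(spec: OligomerSpec) -> list[OligomerSpec]:
    """Both docking orientations (mirrored termini) of the same chemistry."""
    return [replace(spec, orientation=1), replace(spec, orientation=2)]


def check_clashes(conformer: OligomerConformer, coords=None,
                  threshold: float = 2.0) -> int:
    """Number of nonbonded heavy-atom pairs closer than ``threshold`` Å.

    Directly bonded pairs are excluded; 1-3 and further pairs count.
    """
    xyz = coords if coords is not None else conformer.structure.coords
    heavy = [i for i, r in enumerate(conformer.zrows) if r.element != "H"]
    bonded = {frozenset((i, j)) for i, j, _ in conformer.bonds}
    n_clash = 0
    for ii, i in enumerate(heavy):
        for j in heavy[ii + 1 :]:
            if frozenset((i, j)) in bonded:
                continue
            if np.linalg.norm(xyz[i] - xyz[j]) < threshold:
                n_clash += 1
    return n_clash


def substrate_nonbonded_table() -> NonbondedTable:
    """Toy nonbonded parameters covering all oligomer residue types.

    Charges sum to each residue's formal charge (0 for ACE/AHA/NME, -1 for
    the carboxylate unit AHC, +1 for the ammonium unit AHN).
    """
    entries = {}

    def put(res, atom, q, s, e):
        entries[(res, atom)] = (q, s, e)

    put("ACE", "CH3", 0.00, 3.4, 0.35)
    put("ACE", "C", 0.45, 3.4, 0.35)
    put("ACE", "O", -0.45, 3.0, 0.50)
    for res in ("AHA", "AHC"):
        put(res, "N", -0.40, 3.3, 0.50)
        put(res, "H", 0.30, 1.0, 0.05)
        put(res, "C2", 0.10, 3.4, 0.35)
        for c in ("C3", "C4", "C5", "C6"):
            put(res, c, 0.00, 3.4, 0.35)
    put("AHA", "C7", 0.45, 3.4, 0.35)
    put("AHA", "O", -0.45, 3.0, 0.50)
    put("AHC", "C7", 0.60, 3.4, 0.35)
    put("AHC", "O", -0.80, 3.0, 0.50)
    put("AHC", "OXT", -0.80, 3.0, 0.50)
    put("AHN", "N", 0.10, 3.3, 0.50)
    for h in ("H1", "H2", "H3"):
        put("AHN", h, 0.30, 1.0, 0.05)
    put("AHN", "C2", 0.00, 3.4, 0.35)
    for c in ("C3", "C4", "C5", "C6"):
        put("AHN", c, 0.00, 3.4, 0.35)
    put("AHN", "C7", 0.45, 3.4, 0.35)
    put("AHN", "O", -0.45, 3.0, 0.50)
    put("NME", "N", -0.30, 3.3, 0.50)
    put("NME", "H", 0.30, 1.0, 0.05)
    put("NME", "CH3", 0.00, 3.4, 0.35)
    table = NonbondedTable(entries=entries)
    table.residue_formal_charges = {"ACE": 0, "AHA": 0, "AHC": -1, "AHN": 1, "NME": 0}
    table.validate_formal_charges()
    return table
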