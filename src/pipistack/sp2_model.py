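"""Definition and extraction of planar sp2 groups (and sp3 control planes).

The planar pi systems scored by this package are the nine sp2-bearing
sidechains (Trp, Phe, Tyr, His, Arg, Gln, Asn, Glu, Asp), the backbone
peptide bond between consecutive bonded residues, and the C-terminal
carboxyl.  Each group carries a unit plane normal computed by the cross
product of three of its atoms.  Groups missing any expected heavy atom are
never instantiated; they are counted so the skip rate stays observable.

Atom tables live in ``data/sp2_groups.json`` so alternate definitions can be
swapped in for sensitivity tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from math import inf

import numpy as np

from .structure_io import AMINO3_TO_1, StructureModel

SIDECHAIN_IDENTITIES = ("W", "F", "Y", "H", "R", "Q", "N", "E", "D")
AROMATIC_IDENTITIES = frozenset(("W", "F", "Y", "H"))


class DegeneratePlaneError(ValueError):
    """Three collinear atoms cannot define a plane normal."""


def load_group_definitions() -> dict:
    """Load the shipped atom tables (callers may pass edited copies around)."""
    with resources.files("pipistack.data").joinpath("sp2_groups.json").open() as fh:
        return json.load(fh)


_DEFS = load_group_definitions()

RESIDUE_TO_IDENTITY = {v["residue"]: k for k, v in _DEFS["sidechain"].items()}


@dataclass(frozen=True)
class Sp2GroupInstance:
    """One planar group in a structure, with coordinates and plane normal.

    ``residue_index`` is the internal 0-based index of the anchoring residue
    (for the peptide unit, of the first flanking residue i).
    ``residue_indices`` lists every residue the group belongs to; sequence
    separations are minimum index distances between these sets.
    """

    identity: str                 # one-letter sidechain code, dipeptide, or CTERM
    category: str                 # sidechain | backbone | cterm | sp3
    chain_id: str
    residue_index: int
    residue_indices: tuple[int, ...]
    atom_names: tuple[str, ...]
    coords: np.ndarray            # (n_members, 3)
    normal: np.ndarray            # unit (3,)
    aromatic: bool
    carbon_count: int
    copy_label: str | None = None   # symmetry copy label, None for ASU
    atom_keys: frozenset = field(default_factory=frozenset)

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.coords - self.centroid, axis=1).max())

    def shares_atoms(self, other: "Sp2GroupInstance") -> bool:
        return bool(self.atom_keys & other.atom_keys)

    def translated(self, normal=None, coords=None, **kw) -> "Sp2GroupInstance":
        from dataclasses import replace
        return replace(self, normal=self.normal if normal is None else normal,
                       coords=self.coords if coords is None else coords, **kw)


@dataclass
class GroupExtraction:
    groups: list[Sp2GroupInstance]
    n_skipped: int = 0

    def __iter__(self):
        return iter(self.groups)

    def __len__(self):
        return len(self.groups)


def compute_plane_normal(p1, p2, p3) -> np.ndarray:
    """Unit normal of the plane through three points: (p2-p1) x (p3-p1)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    n = np.cross(p2 - p1, p3 - p1)
    norm = np.linalg.norm(n)
    if norm < 1e-6:
        raise DegeneratePlaneError("collinear plane triple")
    return n / norm


def _mk_instance(identity, category, chain, ridx, rindices, names, coords,
                 plane_idx, copy_label=None, aromatic=False, elements=None):
    coords = np.asarray(coords, dtype=float)
    try:
        normal = compute_plane_normal(*(coords[i] for i in plane_idx))
    except DegeneratePlaneError:
        return None
    if elements is None:
        elements = [n[0] for n in names]
    carbon = sum(1 for e in elements if e == "C")
    keys = frozenset((copy_label, chain, ri, nm)
                     for nm, ri in zip(names, _name_res(names, rindices)))
    return Sp2GroupInstance(identity=identity, category=category, chain_id=chain,
                            residue_index=ridx, residue_indices=tuple(rindices_set(rindices)),
                            atom_names=tuple(names), coords=coords, normal=normal,
                            aromatic=aromatic, carbon_count=carbon,
                            copy_label=copy_label, atom_keys=keys)


def _name_res(names, rindices):
    # rindices is either an int (all atoms same residue) or a list parallel to names
    if isinstance(rindices, int):
        return [rindices] * len(names)
    return rindices


def rindices_set(rindices):
    if isinstance(rindices, int):
        return (rindices,)
    return tuple(sorted(set(rindices)))


def extract_sp2_groups(model: StructureModel, definitions: dict | None = None,
                       copy_label: str | None = None,
                       atoms=None) -> GroupExtraction:
    """Extract all complete sp2 planar groups from a normalized structure.

    Returns one instance per complete sidechain group, per peptide unit
    between consecutive bonded residues (C(i)-N(i+1) <= 1.8 A), and per
    C-terminal carboxyl.  Incomplete groups are skipped and counted.
    """
    defs = definitions or _DEFS
    pep = defs["peptide"]
    max_bond = pep.get("max_peptide_bond", 1.8)
    groups: list[Sp2GroupInstance] = []
    n_skipped = 0

    # allow extraction over an explicit atom list (symmetry copies)
    if atoms is not None:
        tmp = StructureModel(atoms=list(atoms), chains=model.chains)
        res_iter_model = tmp
    else:
        res_iter_model = model

    for chain_id in {a.chain_id for a in res_iter_model.atoms}:
        residues = list(res_iter_model.residues(chain_id))
        # ---- sidechain groups
        for _, ridx, resname, amap in residues:
            ident = RESIDUE_TO_IDENTITY.get(resname)
            if ident is None:
                continue
            d = defs["sidechain"][ident]
            if not all(n in amap for n in d["members"]):
                n_skipped += 1
                continue
            coords = [amap[n].coords for n in d["members"]]
            plane_idx = [d["members"].index(n) for n in d["plane"]]
            inst = _mk_instance(ident, "sidechain", chain_id, ridx, ridx,
                                d["members"], coords, plane_idx,
                                copy_label=copy_label,
                                aromatic=d["aromatic"])
            if inst is None:
                n_skipped += 1
            else:
                groups.append(inst)
        # ---- peptide units
        for (_, i, rn_i, am_i), (_, j, rn_j, am_j) in zip(residues, residues[1:]):
            if j != i + 1:
                continue
            need_i, need_j = pep["members_i"], pep["members_next"]
            if not (all(n in am_i for n in need_i) and all(n in am_j for n in need_j)):
                n_skipped += 1
                continue
            if np.linalg.norm(am_i["C"].coords - am_j["N"].coords) > max_bond:
                continue  # chain break, not a skip
            names = need_i + need_j
            rlist = [i] * len(need_i) + [j] * len(need_j)
            coords = [am_i[n].coords for n in need_i] + [am_j[n].coords for n in need_j]
            plane_idx = []
            for nm, which in pep["plane"]:
                base = 0 if which == 0 else len(need_i)
                lst = need_i if which == 0 else need_j
                plane_idx.append(base + lst.index(nm))
            ident = AMINO3_TO_1.get(rn_i, "X") + AMINO3_TO_1.get(rn_j, "X")
            inst = _mk_instance(ident, "backbone", chain_id, i, rlist,
                                names, coords, plane_idx, copy_label=copy_label)
            if inst is None:
                n_skipped += 1
            else:
                groups.append(inst)
        # ---- C-terminal carboxyl (any residue carrying OXT)
        ct = defs["cterm"]
        for _, ridx, resname, amap in residues:
            if "OXT" not in amap:
                continue
            if not all(n in amap for n in ct["members"]):
                n_skipped += 1
                continue
            coords = [amap[n].coords for n in ct["members"]]
            plane_idx = [ct["members"].index(n) for n in ct["plane"]]
            inst = _mk_instance("CTERM", "cterm", chain_id, ridx, ridx,
                                ct["members"], coords, plane_idx,
                                copy_label=copy_label)
            if inst is None:
                n_skipped += 1
            else:
                groups.append(inst)

    groups.sort(key=lambda g: (g.copy_label or "", g.chain_id, g.residue_index,
                               g.category, g.identity))
    return GroupExtraction(groups=groups, n_skipped=n_skipped)


def extract_sp3_controls(model: StructureModel, definitions: dict | None = None,
                         copy_label: str | None = None) -> GroupExtraction:
    """Extract terminal three-atom planes of saturated sidechains (the null control)."""
    defs = definitions or _DEFS
    by_res = {v["residue"]: (k, v) for k, v in defs["sp3"].items()}
    groups: list[Sp2GroupInstance] = []
    n_skipped = 0
    for chain_id in {a.chain_id for a in model.atoms}:
        for _, ridx, resname, amap in model.residues(chain_id):
            entry = by_res.get(resname)
            if entry is None:
                continue
            ident, d = entry
            if not all(n in amap for n in d["plane"]):
                n_skipped += 1
                continue
            coords = [amap[n].coords for n in d["plane"]]
            inst = _mk_instance(ident, "sp3", chain_id, ridx, ridx,
                                d["plane"], coords, [0, 1, 2],
                                copy_label=copy_label)
            if inst is None:
                n_skipped += 1
            else:
                groups.append(inst)
    groups.sort(key=lambda g: (g.chain_id, g.residue_index, g.identity))
    return GroupExtraction(groups=groups, n_skipped=n_skipped)
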