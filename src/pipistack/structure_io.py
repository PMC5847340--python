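"""Read macromolecular structures and expand crystallographic symmetry.

Structures are normalized to the conventions used throughout the package:
first-altloc filtering, waters retained but flagged, hydrogens retained but
excluded from heavy-atom work, selenomethionine-style residues mapped to
their parent standard residue, and a contiguous 0-based internal residue
index per chain that all sequence-separation arithmetic uses.

Parsing is delegated to :mod:`gemmi`; this module owns the normalized
in-memory model and the symmetry-image expansion.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: non-standard residue -> parent standard residue
STANDARD_PARENT = {
    "MSE": "MET",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "CSO": "CYS",
    "CME": "CYS",
    "CSD": "CYS",
    "HYP": "PRO",
    "MLY": "LYS",
    "KCX": "LYS",
    "LLP": "LYS",
    "FME": "MET",
    "PCA": "GLU",
}

AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

WATER_NAMES = {"HOH", "WAT", "DOD"}


class StructureError(Exception):
    """Raised for unreadable or empty structure files."""


class SymmetryUnavailableError(StructureError):
    """Raised when crystal records required for symmetry expansion are absent."""


@dataclass
class AtomRecord:
    element: str
    name: str
    coords: np.ndarray          # (3,) Angstrom
    residue_index: int          # 0-based internal, contiguous per chain
    author_seq: str             # author residue number + insertion code
    residue_name: str           # 3-letter code after parent mapping
    chain_id: str
    is_water: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class StructureModel:
    atoms: list[AtomRecord]
    chains: list[str]
    resolution: float | None = None
    r_factor: float | None = None
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    symmetry_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    name: str = ""

    def heavy_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def residues(self, chain_id: str | None = None, include_waters: bool = False):
        """Yield (chain_id, residue_index, residue_name, {atom name: AtomRecord})."""
        out: dict[tuple[str, int], dict] = {}
        meta: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            if a.is_water and not include_waters:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            key = (a.chain_id, a.residue_index)
            out.setdefault(key, {})
            meta[key] = a.residue_name
            # first-altloc filtering already applied; keep first atom per name
            out[key].setdefault(a.name, a)
        for key in sorted(out):
            yield key[0], key[1], meta[key], out[key]

    def water_oxygens(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.is_water and a.element == "O"]
        return np.asarray(pts, dtype=float).reshape(-1, 3)

    def chain_sequence(self, chain_id: str) -> str:
        letters = []
        for _, _, resname, _ in self.residues(chain_id):
            letters.append(AMINO3_TO_1.get(resname, "X"))
        return "".join(letters)


def _normalize_gemmi(st: gemmi.Structure, path: str) -> StructureModel:
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path}: no models in structure")
    model = st[0]

    atoms: list[AtomRecord] = []
    chains: list[str] = []
    for chain in model:
        if chain.name not in chains:
            chains.append(chain.name)
        ridx = -1
        for res in chain:
            resname = res.name
            is_water = resname in WATER_NAMES
            if not is_water:
                if resname in STANDARD_PARENT:
                    resname = STANDARD_PARENT[res.name]
                elif resname not in AMINO3_TO_1:
                    logger.warning("skipping non-standard residue %s in %s", res.name, path)
                    continue
            ridx += 1
            seen: set[str] = set()
            first_alt: str | None = None
            for atom in res:
                alt = atom.altloc if atom.altloc not in ("\x00", " ", "") else ""
                if alt:
                    if first_alt is None:
                        first_alt = alt
                    if alt != first_alt:
                        continue  # keep only the first conformation in file order
                if atom.name in seen:
                    continue
                seen.add(atom.name)
                atoms.append(AtomRecord(
                    element=atom.element.name,
                    name=atom.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    residue_index=ridx,
                    author_seq=str(res.seqid.num) + (res.seqid.icode.strip() or ""),
                    residue_name=resname,
                    chain_id=chain.name,
                    is_water=is_water,
                    altloc=alt,
                    occupancy=atom.occ,
                ))
    if not atoms:
        raise StructureError(f"{path}: empty structure (no usable atoms)")

    cell = st.cell
    unit_cell = None
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = []
    if cell and cell.a > 1.0:
        unit_cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
        sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm or "P 1")
        if sg is None:
            sg = gemmi.find_spacegroup_by_name("P 1")
        for op in sg.operations():
            rot = np.array(op.rot, dtype=float) / op.DEN
            tran = np.array(op.tran, dtype=float) / op.DEN
            sym_ops.append((rot, tran))

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    r_factor = None
    raw = st.raw_remarks if hasattr(st, "raw_remarks") else []
    for line in raw:
        if "R VALUE" in line and "WORKING SET" in line and ":" in line:
            tail = line.split(":")[-1].strip()
            try:
                r_factor = float(tail)
                break
            except ValueError:
                continue

    return StructureModel(atoms=atoms, chains=chains, resolution=resolution,
                          r_factor=r_factor, unit_cell=unit_cell,
                          symmetry_ops=sym_ops, name=Path(path).stem)


def parse_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file into a normalized :class:`StructureModel`.

    First-altloc filtering is applied (the first conformation in file order is
    kept), waters are retained and flagged, and hydrogens are kept but ignored
    by all heavy-atom geometry downstream.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format: {format}")
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: parse error: {exc}") from exc
    return _normalize_gemmi(st, str(path))


def _gemmi_cell(model: StructureModel) -> gemmi.UnitCell:
    return gemmi.UnitCell(*model.unit_cell)


def expand_symmetry(model: StructureModel, radius: float,
                    max_shift: int = 1) -> list[tuple[str, list[AtomRecord]]]:
    """Return symmetry/lattice images with any atom within ``radius`` of the model.

    Lattice translations are enumerated over ``-max_shift..max_shift`` in each
    axis.  The identity image (identity operator, zero shift) is excluded.
    Copy labels encode the operator index and lattice shift.
    """
    if not model.symmetry_ops or model.unit_cell is None:
        raise SymmetryUnavailableError("structure has no crystal symmetry records")
    if radius <= 0:
        return []

    cell = _gemmi_cell(model)
    ortho = np.array(cell.orth.mat.tolist())
    frac_mat = np.array(cell.frac.mat.tolist())

    heavy = [a for a in model.atoms if not a.is_hydrogen]
    xyz = np.array([a.coords for a in heavy])
    frac = xyz @ frac_mat.T

    from scipy.spatial import cKDTree
    tree = cKDTree(xyz)

    images: list[tuple[str, list[AtomRecord]]] = []
    shifts = range(-max_shift, max_shift + 1)
    for i_op, (rot, tran) in enumerate(model.symmetry_ops):
        base = frac @ rot.T + tran
        for sx, sy, sz in itertools.product(shifts, shifts, shifts):
            if i_op == 0 and sx == sy == sz == 0 and np.allclose(rot, np.eye(3)) \
                    and np.allclose(tran, 0):
                continue
            moved = base + np.array([sx, sy, sz], dtype=float)
            cart = moved @ ortho.T
            d, _ = tree.query(cart, k=1, distance_upper_bound=radius)
            if not np.any(np.isfinite(d)):
                continue
            if np.min(d) > radius:
                continue
            label = f"sym{i_op}_{sx}{sy}{sz}"
            copy = []
            for rec, c in zip(heavy, cart):
                copy.append(AtomRecord(
                    element=rec.element, name=rec.name, coords=c.copy(),
                    residue_index=rec.residue_index, author_seq=rec.author_seq,
                    residue_name=rec.residue_name, chain_id=rec.chain_id,
                    is_water=rec.is_water, altloc=rec.altloc,
                    occupancy=rec.occupancy))
            images.append((label, copy))
    return images


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a minimal single-model PDB file (CRYST1 + ATOM/HETATM/TER)."""
    lines = []
    if model.unit_cell is not None:
        a, b, c, al, be, ga = model.unit_cell
        sg = model.spacegroup if hasattr(model, "spacegroup") else "P 1"
        lines.append(
            f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}"
        )
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS.")
    serial = 0
    prev_chain = None
    for atom in model.atoms:
        serial += 1
        if prev_chain is not None and atom.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = atom.chain_id
        record = "HETATM" if atom.is_water else "ATOM  "
        name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
        x, y, z = atom.coords
        try:
            resseq = int(atom.author_seq)
            icode = " "
        except ValueError:
            resseq = int(atom.author_seq[:-1])
            icode = atom.author_seq[-1]
        lines.append(
            f"{record}{serial:5d} {name:<4s}{atom.altloc or ' '}"
            f"{atom.residue_name:>3s} {atom.chain_id:1s}{resseq:4d}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def build_model(atoms: list[AtomRecord], unit_cell=None, spacegroup: str = "P 1",
                resolution: float | None = None, r_factor: float | None = None,
                name: str = "model") -> StructureModel:
    """Assemble a StructureModel from in-memory atoms (used by the fixture writers)."""
    chains: list[str] = []
    for a in atoms:
        if a.chain_id not in chains:
            chains.append(a.chain_id)
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = []
    if unit_cell is not None:
        sg = gemmi.find_spacegroup_by_name(spacegroup)
        if sg is None:
            raise ValueError(f"unknown spacegroup {spacegroup!r}")
        for op in sg.operations():
            sym_ops.append((np.array(op.rot, dtype=float) / op.DEN,
                            np.array(op.tran, dtype=float) / op.DEN))
    m = StructureModel(atoms=atoms, chains=chains, resolution=resolution,
                       r_factor=r_factor, unit_cell=unit_cell,
                       symmetry_ops=sym_ops, name=name)
    m.spacegroup = spacegroup
    return m
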