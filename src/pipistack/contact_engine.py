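"""Planar pi-pi contact decision and classification.

A face-to-face planar contact between two sp2 groups requires, with the
default criteria:

* at least 2 heavy-atom pairs within the 4.9 A van der Waals threshold,
* surfaces elevated 1.7 A above each plane to approach within 1.5 A
  (minimum over both normal signs of both groups), and
* |dot product| of the two unit plane normals >= 0.8 (within ~37 deg of
  parallel).

All thresholds are inclusive.  Contacts are classified by sequence
separation (short <= 4 residues; long otherwise or inter-chain) and by chain
relation (intra-chain, inter-chain within the asymmetric unit, or to a
crystal symmetry image).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .sp2_model import Sp2GroupInstance

#: sentinel returned by count_vdw_pairs for groups sharing an atom
SHARED_ATOMS = -1


@dataclass(frozen=True)
class ContactCriteria:
    vdw_cutoff: float = 4.9       # A, heavy-atom pair threshold
    min_atom_pairs: int = 2
    elevation: float = 1.7        # A above the sp2 plane
    surface_cutoff: float = 1.5   # A between elevated surfaces
    min_abs_dot: float = 0.8      # |n_a . n_b|

    def __post_init__(self):
        if not (0 < self.min_abs_dot <= 1):
            raise ValueError("min_abs_dot must be in (0, 1]")
        for f in ("vdw_cutoff", "min_atom_pairs", "elevation", "surface_cutoff"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


DEFAULT_CRITERIA = ContactCriteria()


@dataclass(frozen=True)
class PlanarContact:
    group_a: Sp2GroupInstance
    group_b: Sp2GroupInstance
    n_vdw_pairs: int
    min_atom_distance: float
    abs_dot: float
    min_surface_distance: float
    seq_separation: float         # residues, or inf for inter-chain
    range_class: str              # short | long
    chain_class: str              # intra | inter_asu | symmetry


@dataclass
class DetectionResult:
    contacts: list[PlanarContact]
    n_symmetry_clashes: int = 0

    def __iter__(self):
        return iter(self.contacts)

    def __len__(self):
        return len(self.contacts)


def count_vdw_pairs(a: Sp2GroupInstance, b: Sp2GroupInstance,
                    cutoff: float = 4.9) -> int:
    """Number of heavy-atom pairs across the two groups within ``cutoff``.

    Groups sharing any atom return :data:`SHARED_ATOMS` and are never
    contact candidates.
    """
    if a.shares_atoms(b):
        return SHARED_ATOMS
    d = cdist(a.coords, b.coords)
    return int(np.count_nonzero(d <= cutoff))


def surface_distance(a: Sp2GroupInstance, b: Sp2GroupInstance,
                     elevation: float = 1.7) -> float:
    """Minimum distance between surfaces elevated above each sp2 plane.

    Every atom of each group is displaced by ``elevation`` along the group
    normal; the minimum is taken over all atom pairs and over both normal
    signs of both groups, so the result is independent of the arbitrary sign
    of the cross-product normal.
    """
    best = inf
    for s in (1.0, -1.0):
        pa = a.coords + s * elevation * a.normal
        for t in (1.0, -1.0):
            pb = b.coords + t * elevation * b.normal
            best = min(best, float(cdist(pa, pb).min()))
    return best


def is_planar_pi_contact(a: Sp2GroupInstance, b: Sp2GroupInstance,
                         criteria: ContactCriteria = DEFAULT_CRITERIA):
    """Evaluate the full planar-pi criterion; return a PlanarContact or None."""
    n_pairs = count_vdw_pairs(a, b, criteria.vdw_cutoff)
    if n_pairs == SHARED_ATOMS or n_pairs < criteria.min_atom_pairs:
        return None
    abs_dot = abs(float(np.dot(a.normal, b.normal)))
    if abs_dot < criteria.min_abs_dot:
        return None
    surf = surface_distance(a, b, criteria.elevation)
    if surf > criteria.surface_cutoff:
        return None
    ga, gb = _ordered(a, b)
    sep, rng, cls = classify_pair(ga, gb)
    return PlanarContact(group_a=ga, group_b=gb, n_vdw_pairs=n_pairs,
                         min_atom_distance=float(cdist(a.coords, b.coords).min()),
                         abs_dot=abs_dot, min_surface_distance=surf,
                         seq_separation=sep, range_class=rng, chain_class=cls)


def _ordered(a, b):
    ka = (a.copy_label or "", a.chain_id, a.residue_index, a.category, a.identity)
    kb = (b.copy_label or "", b.chain_id, b.residue_index, b.category, b.identity)
    return (a, b) if ka <= kb else (b, a)


def classify_pair(a: Sp2GroupInstance, b: Sp2GroupInstance):
    """(sequence separation, range class, chain class) for a group pair."""
    if a.copy_label is not None or b.copy_label is not None:
        return inf, "long", "symmetry"
    if a.chain_id != b.chain_id:
        return inf, "long", "inter_asu"
    sep = min(abs(i - j) for i in a.residue_indices for j in b.residue_indices)
    return sep, ("short" if sep <= 4 else "long"), "intra"


def detect_contacts(groups, partner_groups=(),
                    criteria: ContactCriteria = DEFAULT_CRITERIA,
                    clash_cutoff: float = 1.0) -> DetectionResult:
    """All accepted planar contacts among ``groups`` (+ one-sided vs partners).

    ``groups`` are the groups of the chain(s) of interest; ``partner_groups``
    (e.g. symmetry-copy groups) are only tested against ``groups``, never
    against each other.  Candidate pairs come from a KD-tree on group
    centroids with a conservative radius (cutoff + both bounding radii), so
    the result is identical to exhaustive evaluation.

    Symmetry-partner atom pairs closer than ``clash_cutoff`` are tallied as
    clashes (a known artifact of deposited symmetry mates).
    """
    groups = list(groups)
    partner_groups = list(partner_groups)
    allg = groups + partner_groups
    n_primary = len(groups)
    if len(allg) < 2:
        return DetectionResult([], 0)

    centroids = np.array([g.centroid for g in allg])
    radii = np.array([g.radius for g in allg])
    rmax = radii.max() if len(radii) else 0.0
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(criteria.vdw_cutoff + 2 * rmax, output_type="ndarray")

    contacts = []
    n_clashes = 0
    for i, j in pairs:
        if i >= n_primary and j >= n_primary:
            continue  # partner-partner pair
        a, b = allg[i], allg[j]
        # refine prefilter with per-pair bounding radii
        if np.linalg.norm(a.centroid - b.centroid) > criteria.vdw_cutoff + a.radius + b.radius:
            continue
        if (a.copy_label is not None) != (b.copy_label is not None):
            if float(cdist(a.coords, b.coords).min()) < clash_cutoff:
                n_clashes += 1
                continue
        c = is_planar_pi_contact(a, b, criteria)
        if c is not None:
            contacts.append(c)

    contacts.sort(key=lambda c: (_ordered(c.group_a, c.group_b)[0].chain_id,
                                 c.group_a.residue_index, c.group_a.category,
                                 c.group_b.chain_id, c.group_b.residue_index,
                                 c.group_b.category))
    return DetectionResult(contacts, n_clashes)


def brute_force_contacts(groups, partner_groups=(),
                         criteria: ContactCriteria = DEFAULT_CRITERIA) -> list[PlanarContact]:
    """O(n^2) all-pairs evaluation, the reference oracle for detect_contacts."""
    groups = list(groups)
    partner_groups = list(partner_groups)
    allg = groups + partner_groups
    n_primary = len(groups)
    out = []
    for i in range(len(allg)):
        for j in range(i + 1, len(allg)):
            if i >= n_primary and j >= n_primary:
                continue
            a, b = allg[i], allg[j]
            if (a.copy_label is not None) != (b.copy_label is not None):
                if float(cdist(a.coords, b.coords).min()) < 1.0:
                    continue
            c = is_planar_pi_contact(a, b, criteria)
            if c is not None:
                out.append(c)
    out.sort(key=lambda c: (c.group_a.chain_id, c.group_a.residue_index,
                            c.group_a.category, c.group_b.chain_id,
                            c.group_b.residue_index, c.group_b.category))
    return out


def water_contact_count(residue_atoms, water_oxygens: np.ndarray,
                        cutoff: float = 4.9) -> int:
    """Number of water oxygens within ``cutoff`` of any residue heavy atom."""
    pts = np.asarray([a.coords for a in residue_atoms if not a.is_hydrogen],
                     dtype=float).reshape(-1, 3)
    waters = np.asarray(water_oxygens, dtype=float).reshape(-1, 3)
    if len(pts) == 0 or len(waters) == 0:
        return 0
    d = cdist(waters, pts)
    return int(np.count_nonzero(d.min(axis=1) <= cutoff))
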