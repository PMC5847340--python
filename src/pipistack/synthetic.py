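"""Synthetic fixtures: idealized geometries, annotation corpora with known
statistical structure, and sequence sets with controlled composition.

Everything here is seed-deterministic and returns its ground-truth
parameters alongside the data, so recovery tests can compare estimates with
the generating values.  The annotation corpora emulate the statistical shape
of a non-redundant folded-protein survey (per-opportunity contact rates,
composition-dependent rate modifiers); they do not emulate real packing
geometry, redundancy structure, or experimental noise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .structure_io import AtomRecord, StructureModel, build_model
from .sp2_model import Sp2GroupInstance, compute_plane_normal, _DEFS
from .contact_stats import ChainAnnotation, ContactRecord
from .frequency_predictor import (AA_INDEX, SHORT_MAX, STANDARD_AA,
                                  _one_hot_prefix, iter_sequence_groups)

# ------------------------------------------------------------------ geometry

RING_BOND = 1.39      # aromatic C-C, A
AMIDE_CN = 1.33       # peptide C-N, A

#: planar atom templates centered on their centroid, z = 0 plane
def _hexagon(names):
    r = RING_BOND
    pts = [(r * math.cos(k * math.pi / 3), r * math.sin(k * math.pi / 3), 0.0)
           for k in range(6)]
    return dict(zip(names, pts))


def _polygon(names, radius):
    n = len(names)
    return {nm: (radius * math.cos(2 * math.pi * k / n),
                 radius * math.sin(2 * math.pi * k / n), 0.0)
            for k, nm in enumerate(names)}


def _amide(names3):
    # trigonal planar: center atom at origin, two substituents at 120 deg
    c, o, n = names3
    return {c: (0.0, 0.0, 0.0),
            o: (1.23, 0.0, 0.0),
            n: (1.33 * math.cos(2 * math.pi / 3), 1.33 * math.sin(2 * math.pi / 3), 0.0)}


#: per supported identity: (residue name, {atom: xyz}, category)
def _templates():
    t = {}
    # hexagon in ring order, then reorder to the member-atom table
    hx = _hexagon(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"])
    t["F"] = ("PHE", hx, "sidechain")
    t["Y"] = ("TYR", dict(hx), "sidechain")
    t["H"] = ("HIS", _polygon(["CG", "ND1", "CE1", "NE2", "CD2"], 1.32), "sidechain")
    t["R"] = ("ARG", {"CZ": (0.0, 0.0, 0.0),
                      "NE": (1.33, 0.0, 0.0),
                      "NH1": (1.33 * math.cos(2 * math.pi / 3),
                              1.33 * math.sin(2 * math.pi / 3), 0.0),
                      "NH2": (1.33 * math.cos(-2 * math.pi / 3),
                              1.33 * math.sin(-2 * math.pi / 3), 0.0)},
              "sidechain")
    t["Q"] = ("GLN", _amide(["CD", "OE1", "NE2"]), "sidechain")
    t["N"] = ("ASN", _amide(["CG", "OD1", "ND2"]), "sidechain")
    # planar peptide unit: CA(i), C(i), O(i), N(i+1), CA(i+1)
    n_dir = (AMIDE_CN, 0.0, 0.0)
    t["PEPTIDE"] = ("GLY", {"CA": (-1.21, 0.91, 0.0),
                            "C": (0.0, 0.0, 0.0),
                            "O": (-0.51, -1.12, 0.0),
                            "N": n_dir,
                            "CA2": (2.02, 1.05, 0.0)}, "backbone")
    return t


TEMPLATES = _templates()


def _center(coords: dict) -> dict:
    arr = np.array(list(coords.values()))
    c = arr.mean(axis=0)
    return {k: np.asarray(v) - c for k, v in coords.items()}


def _rot_x(deg):
    a = math.radians(deg)
    return np.array([[1, 0, 0], [0, math.cos(a), -math.sin(a)],
                     [0, math.sin(a), math.cos(a)]])


def _place_group(identity, origin, rot, chain, resnum):
    """AtomRecords for one group template, rotated then translated."""
    resname, tpl, category = TEMPLATES[identity]
    tpl = _center(tpl)
    atoms = []
    for nm, xyz in tpl.items():
        pos = rot @ np.asarray(xyz, dtype=float) + origin
        if identity == "PEPTIDE":
            # split the unit over two residues
            if nm in ("N", "CA2"):
                rn, rnum = resname, resnum + 1
                nm_out = "CA" if nm == "CA2" else nm
            else:
                rn, rnum = resname, resnum
                nm_out = nm
        else:
            rn, rnum, nm_out = resname, resnum, nm
        atoms.append(AtomRecord(element=nm_out[0], name=nm_out,
                                coords=pos, residue_index=rnum,
                                author_seq=str(rnum), residue_name=rn,
                                chain_id=chain))
    return atoms


def make_stacked_pair(identity_a: str = "F", identity_b: str = "F",
                      gap: float = 3.5, offset: float = 0.0,
                      tilt_deg: float = 0.0, same_chain: bool = True,
                      residue_a: int = 10, residue_b: int = 30,
                      unit_cell=(60.0, 60.0, 60.0, 90.0, 90.0, 90.0),
                      spacegroup: str = "P 1") -> StructureModel:
    """Two planar groups at an exact inter-plane gap, in-plane offset and tilt.

    Group A lies in the z = 0 plane centered at the origin; group B is the
    same-template group tilted about x by ``tilt_deg`` and translated to
    (offset, 0, gap).  The groups are embedded in minimal residues and the
    model is writable as a PDB file.
    """
    if gap < 0:
        raise ValueError("inter-plane gap must be non-negative")
    chain_b = "A" if same_chain else "B"
    atoms = _place_group(identity_a, np.zeros(3), np.eye(3), "A", residue_a)
    atoms += _place_group(identity_b, np.array([offset, 0.0, gap]),
                          _rot_x(tilt_deg), chain_b, residue_b)
    return build_model(atoms, unit_cell=unit_cell, spacegroup=spacegroup,
                       resolution=1.5, name="stacked_pair")


def _instance_from_template(identity, center, rot, chain, ridx, copy_label=None):
    resname, tpl, category = TEMPLATES[identity]
    tpl = _center(tpl)
    names = list(tpl)
    coords = np.array([rot @ np.asarray(tpl[n]) + center for n in names])
    if identity == "PEPTIDE":
        plane_names = ("O", "C", "N")
        rindices = (ridx, ridx + 1)
        ident = "GG"
    else:
        d = _DEFS["sidechain"][identity]
        plane_names = tuple(d["plane"])
        rindices = (ridx,)
        ident = identity
    pidx = [names.index(n) for n in plane_names]
    normal = compute_plane_normal(*(coords[i] for i in pidx))
    keys = frozenset((copy_label, chain, ridx, n) for n in names)
    aromatic = identity in ("F", "Y", "H", "W")
    carbon = sum(1 for n in names if n[0] == "C")
    return Sp2GroupInstance(identity=ident, category=category, chain_id=chain,
                            residue_index=ridx, residue_indices=rindices,
                            atom_names=tuple(names), coords=coords,
                            normal=normal, aromatic=aromatic,
                            carbon_count=carbon, copy_label=copy_label,
                            atom_keys=keys)


def random_group_field(n_groups: int, box: float = 30.0, seed: int = 0,
                       identities=("F", "Y", "H", "R", "Q", "N", "PEPTIDE")):
    """Random planar groups in a box: the input for detector/oracle equivalence.

    Positions are uniform in the box and orientations uniform on the rotation
    group, so pairs straddle every criterion boundary.  Residue indices step
    by 3 so no two groups share atoms and peptide units never abut.
    """
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation
    groups = []
    for i in range(n_groups):
        ident = identities[rng.integers(0, len(identities))]
        center = rng.uniform(0, box, size=3)
        rot = Rotation.random(random_state=np.random.RandomState(
            int(rng.integers(0, 2**31)))).as_matrix()
        groups.append(_instance_from_template(ident, center, rot, "A", 3 * i))
    return groups


# ----------------------------------------------------- composition constants

#: folded-protein (UniProt-average) amino-acid frequencies
BACKGROUND_COMPOSITION = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: composition concentrated on backbone-flexible / pi-rich residue types
FLEXIBLE_COMPOSITION = {
    "G": 0.28, "S": 0.16, "T": 0.08, "P": 0.18, "R": 0.12, "Y": 0.04,
    "F": 0.04, "Q": 0.04, "N": 0.03, "E": 0.03,
}

FLEXIBLE_SET = frozenset("GSTP")

#: dipeptide repeats associated with high planar pi-contact frequency
POSITIVE_MOTIFS = ("PG", "FG", "SR", "YG", "RG")


def _comp_vector(comp: dict) -> np.ndarray:
    v = np.zeros(20)
    for aa, f in comp.items():
        v[AA_INDEX[aa]] = f
    return v / v.sum()


def random_sequence(length: int, comp: np.ndarray, rng) -> str:
    idx = rng.choice(20, size=length, p=comp)
    return "".join(STANDARD_AA[i] for i in idx)


# -------------------------------------------------------- annotation corpora

#: per (group category 0=sc,1=bb axis unused; keys are contacted category)
DEFAULT_RATE_TRUTH = {
    # per-opportunity Bernoulli rate:
    #   (base + slope * flex) * partner_weight[partner residue]
    # with flex the G/S/T/P fraction within +-40 of the group.  Scaled so
    # backbone units end up with a few percent contact involvement and
    # residues with ~10-20%, the scale seen in folded-protein surveys.
    "base_bb": {"short": 3.0e-3, "long": 8.0e-5},
    "slope_bb": {"short": 1.5e-3, "long": 5.0e-4},
    "base_sc": {"short": 1.5e-3, "long": 5.0e-5},
    "slope_sc": {"short": 5.0e-4, "long": 2.5e-4},
    # exposed-backbone / pi-rich partners attract contacts; buried
    # hydrophobics suppress them
    "partner_weights": {"G": 2.5, "P": 2.0, "S": 1.5, "R": 1.5, "T": 1.3,
                        "Y": 1.3, "F": 1.2, "Q": 1.2, "N": 1.1,
                        "A": 0.8, "L": 0.5, "I": 0.5, "V": 0.5, "M": 0.6,
                        "C": 0.6, "W": 1.0, "H": 1.0, "E": 1.0, "D": 1.0,
                        "K": 0.7},
}


def make_annotation_corpus(n_chains: int = 120, length=(180, 300),
                           seed: int = 0, truth: dict | None = None,
                           flex_mix_max: float = 0.6):
    """Sequence corpus with context-dependent per-opportunity contact rates.

    Each chain's composition mixes the folded background with the flexible
    composition at a chain-specific weight, so the corpus spans a range of
    Gly/Ser/Thr/Pro context fractions.  For every group and candidate
    partner residue, a contact to the partner's backbone (and, for sp2
    partners, sidechain) is drawn as a Bernoulli event whose probability is
    ``base + slope * flex`` with ``flex`` the G/S/T/P fraction within +-40
    of the group.  Returns (annotations, truth dict).
    """
    truth = dict(DEFAULT_RATE_TRUTH if truth is None else truth)
    rng = np.random.default_rng(seed)
    bg = _comp_vector(BACKGROUND_COMPOSITION)
    fx = _comp_vector(FLEXIBLE_COMPOSITION)
    annotations = []
    flex_idx = np.array([1.0 if a in FLEXIBLE_SET else 0.0 for a in STANDARD_AA])
    pw = np.array([truth["partner_weights"].get(a, 1.0) for a in STANDARD_AA])

    for ci in range(n_chains):
        L = int(rng.integers(length[0], length[1] + 1))
        m = rng.uniform(0.0, flex_mix_max)
        comp = (1 - m) * bg + m * fx
        seq = random_sequence(L, comp, rng)
        prefix = _one_hot_prefix(seq)
        is_sp2 = np.array([1.0 if a in "WFYHRQNED" else 0.0 for a in seq])
        w_seq = np.array([truth["partner_weights"].get(a, 1.0) for a in seq])

        contacts = []
        for ident, cat, anchor, positions in iter_sequence_groups(seq):
            lo = max(0, min(positions) - 40)
            hi = min(L, max(positions) + 41)
            ctx = prefix[hi] - prefix[lo]
            n_ctx = ctx.sum() - len(positions)
            flex = float(ctx @ flex_idx) / max(n_ctx, 1)

            q = np.arange(L)
            dist = np.min(np.abs(q[:, None] - np.array(positions)[None, :]), axis=1)
            valid = dist > 0
            sep_long = dist > SHORT_MAX

            p_bb = np.where(sep_long, truth["base_bb"]["long"]
                            + truth["slope_bb"]["long"] * flex,
                            truth["base_bb"]["short"]
                            + truth["slope_bb"]["short"] * flex)
            p_sc = np.where(sep_long, truth["base_sc"]["long"]
                            + truth["slope_sc"]["long"] * flex,
                            truth["base_sc"]["short"]
                            + truth["slope_sc"]["short"] * flex)
            p_bb = np.clip(p_bb * w_seq, 0, 0.9) * valid
            p_sc = np.clip(p_sc * w_seq, 0, 0.9) * valid * is_sp2

            hit_bb = rng.random(L) < p_bb
            hit_sc = rng.random(L) < p_sc
            for qpos in np.flatnonzero(hit_bb):
                if qpos >= L - 1:
                    continue
                contacts.append(ContactRecord(
                    type_a=ident, pos_a=anchor, cat_a=cat,
                    type_b=seq[qpos:qpos + 2], pos_b=int(qpos), cat_b="backbone",
                    seq_separation=float(dist[qpos]), chain_class="intra"))
            for qpos in np.flatnonzero(hit_sc):
                contacts.append(ContactRecord(
                    type_a=ident, pos_a=anchor, cat_a=cat,
                    type_b=seq[qpos], pos_b=int(qpos), cat_b="sidechain",
                    seq_separation=float(dist[qpos]), chain_class="intra"))
        annotations.append(ChainAnnotation(
            key=f"syn{ci:04d}_A", sequence=seq, contacts=contacts,
            resolution=float(np.round(rng.uniform(1.0, 2.5), 2)),
            r_factor=float(np.round(rng.uniform(0.12, 0.22), 3))))
    return annotations, truth


def _involvement_record(seq, i, cat, rng=None):
    """A one-sided record marking residue i (and i+1 for backbone) involved."""
    if cat == "backbone":
        typ = seq[i:i + 2] if i < len(seq) - 1 else seq[i - 1:i + 1]
        pos = i if i < len(seq) - 1 else i - 1
    else:
        typ, pos = seq[i], i
    return ContactRecord(type_a=typ, pos_a=pos, cat_a=cat,
                         type_b="GG", pos_b=0, cat_b="backbone",
                         seq_separation=math.inf, chain_class="inter_asu")


def make_solvation_corpus(n_chains: int = 60, length: int = 200,
                          base: float = 0.05, slope: float = 0.01,
                          water_mean: float = 4.0, seed: int = 0):
    """Chains whose involvement probability rises linearly with water contacts.

    Per residue, the water-contact count is Poisson(``water_mean``) and the
    probability of planar-contact involvement is ``base + slope * waters``
    for the sidechain track (half that effect for backbone).
    """
    rng = np.random.default_rng(seed)
    bg = _comp_vector(BACKGROUND_COMPOSITION)
    annotations = []
    for ci in range(n_chains):
        seq = random_sequence(length, bg, rng)
        waters = rng.poisson(water_mean, size=length)
        contacts = []
        for i, w in enumerate(waters):
            if rng.random() < base + slope * w:
                contacts.append(_involvement_record(seq, i, "sidechain"))
            if rng.random() < (base + slope * w) / 2:
                contacts.append(_involvement_record(seq, i, "backbone"))
        annotations.append(ChainAnnotation(
            key=f"wat{ci:04d}_A", sequence=seq, contacts=contacts,
            resolution=1.2, n_waters=int(waters.sum()),
            water_counts=[int(w) for w in waters]))
    return annotations, {"base": base, "slope": slope}


def ss_rate(distance: int, p_deep_ss: float = 0.095,
            p_deep_loop: float = 0.16, scale: float = 1.2) -> float:
    """Sigmoid contact rate vs signed distance from regular secondary structure."""
    s = 1.0 / (1.0 + math.exp(-distance / scale))
    return p_deep_ss + (p_deep_loop - p_deep_ss) * s


def make_ss_corpus(n_chains: int = 80, length: int = 240,
                   p_deep_ss: float = 0.095, p_deep_loop: float = 0.16,
                   seed: int = 0):
    """Chains with helix/strand/loop segments and an order-to-disorder sigmoid.

    Involvement probability follows :func:`ss_rate` on the signed distance
    from regular secondary structure (H/G/E), reaching ``p_deep_ss`` deep
    inside elements and ``p_deep_loop`` deep inside loops.
    """
    from .contact_stats import ss_signed_distance
    rng = np.random.default_rng(seed)
    bg = _comp_vector(BACKGROUND_COMPOSITION)
    annotations = []
    for ci in range(n_chains):
        seq = random_sequence(length, bg, rng)
        ss = []
        while len(ss) < length:
            ss.extend(["H" if rng.random() < 0.6 else "E"]
                      * int(rng.integers(8, 25)))
            ss.extend([" "] * int(rng.integers(4, 30)))
        ss = "".join(ss[:length])
        dist = ss_signed_distance(ss)
        contacts = []
        for i, d in enumerate(dist):
            if rng.random() < ss_rate(int(d), p_deep_ss, p_deep_loop):
                contacts.append(_involvement_record(seq, i, "sidechain"))
        annotations.append(ChainAnnotation(
            key=f"ss{ci:04d}_A", sequence=seq, contacts=contacts,
            resolution=1.5, ss=ss))
    return annotations, {"p_deep_ss": p_deep_ss, "p_deep_loop": p_deep_loop}


def make_interface_corpus(n_chains: int = 60, length: int = 200,
                          local_rate: float = 0.10, nonlocal_rate: float = 0.20,
                          exchange: float = 0.5, seed: int = 0):
    """Sidechain contact corpus with intra-to-inter exchange at interfaces.

    Non-interface sp2 residues draw local/non-local intra contacts at the
    stated rates; interface residues keep the same total but move
    ``exchange`` of the non-local rate to inter-chain contacts.
    """
    rng = np.random.default_rng(seed)
    bg = _comp_vector(BACKGROUND_COMPOSITION)
    annotations = []
    for ci in range(n_chains):
        seq = random_sequence(length, bg, rng)
        iface = "".join(rng.choice([".", "A", "S"], p=[0.7, 0.2, 0.1])
                        for _ in range(length))
        contacts = []
        for i, aa in enumerate(seq):
            if aa not in "WFYHRQNED":
                continue
            at_iface = iface[i] != "."
            nl_intra = nonlocal_rate * (1 - exchange if at_iface else 1.0)
            inter = nonlocal_rate * (exchange if at_iface else 0.0)
            for rate, kind in ((local_rate, "local"), (nl_intra, "nonlocal"),
                               (inter, "inter")):
                for _ in range(rng.poisson(rate)):
                    if kind == "inter":
                        contacts.append(ContactRecord(
                            type_a=aa, pos_a=i, cat_a="sidechain",
                            type_b="GG", pos_b=0, cat_b="backbone",
                            seq_separation=math.inf, chain_class="inter_asu"))
                    else:
                        sep = 2 if kind == "local" else 20
                        pos_b = i + sep if i + sep < length - 1 else i - sep
                        contacts.append(ContactRecord(
                            type_a=aa, pos_a=i, cat_a="sidechain",
                            type_b=seq[pos_b:pos_b + 2], pos_b=int(pos_b),
                            cat_b="backbone", seq_separation=float(sep),
                            chain_class="intra"))
        annotations.append(ChainAnnotation(
            key=f"ifc{ci:04d}_A", sequence=seq, contacts=contacts,
            resolution=1.6, interface=iface))
    return annotations, {"local_rate": local_rate, "nonlocal_rate": nonlocal_rate,
                         "exchange": exchange}


# ------------------------------------------------------------- sequence sets

def make_sequence_sets(n_positive: int = 30, n_background: int = 150,
                       length=(160, 320), noise: float = 0.15, seed: int = 0):
    """(positive-like, background) sequence sets for end-to-end recovery.

    Positives tile one of the high-pi-contact dipeptide repeats (Pro-Gly,
    Phe-Gly, Ser-Arg, Tyr-Gly, Arg-Gly) and then mutate a ``noise`` fraction
    of positions to background draws; background sequences are i.i.d. from
    the folded-protein composition.  All sequences are >= 140 residues.
    """
    rng = np.random.default_rng(seed)
    bg = _comp_vector(BACKGROUND_COMPOSITION)
    positives, background = [], []
    for i in range(n_positive):
        L = int(rng.integers(length[0], length[1] + 1))
        motif = POSITIVE_MOTIFS[int(rng.integers(0, len(POSITIVE_MOTIFS)))]
        seq = list((motif * (L // 2 + 1))[:L])
        n_mut = int(round(noise * L))
        for p in rng.choice(L, size=n_mut, replace=False):
            seq[p] = STANDARD_AA[rng.choice(20, p=bg)]
        positives.append((f"pos{i:03d}_{motif}", "".join(seq)))
    for i in range(n_background):
        L = int(rng.integers(length[0], length[1] + 1))
        background.append((f"bg{i:04d}", random_sequence(L, bg, rng)))
    return positives, background


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")


def read_fasta(path):
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
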