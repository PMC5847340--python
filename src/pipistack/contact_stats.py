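"""Survey statistics over planar pi-pi contact annotations.

The unit of observation is the :class:`ChainAnnotation`: one non-redundant
protein chain with its sequence, the planar contacts its groups make
(including to other chains of the same entry; symmetry contacts flagged and
excluded from default statistics), and optional per-residue water-contact
counts, secondary-structure assignments and interface flags.

Contact records here are geometry-free: sidechain groups are named by their
one-letter amino acid code, backbone peptide units by the ordered dipeptide
of the flanking residues i/i+1.  This is also the on-disk dialect
(tab-separated, one contact per line).

Error bars use the block bootstrap of the paper-style survey: whole PDB
entries are resampled with replacement, never individual residues, so
within-structure dependence is respected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .sp2_model import AROMATIC_IDENTITIES, SIDECHAIN_IDENTITIES
from .contact_engine import PlanarContact

ORDERED_SS = frozenset("HGE")   # helix, 3-10 helix, strand


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class ContactRecord:
    """One planar contact (or, when ``planar`` is False, a VDW-only contact)."""

    type_a: str        # one-letter sidechain code, dipeptide, CTERM, or sp3 code
    pos_a: int         # internal residue index of the group anchor
    cat_a: str         # sidechain | backbone | cterm | sp3
    type_b: str
    pos_b: int
    cat_b: str
    seq_separation: float      # residues or inf
    chain_class: str           # intra | inter_asu | symmetry
    planar: bool = True

    @property
    def range_class(self) -> str:
        return "short" if self.seq_separation <= 4 else "long"

    def residues_a(self) -> tuple[int, ...]:
        return (self.pos_a, self.pos_a + 1) if self.cat_a == "backbone" else (self.pos_a,)

    def residues_b(self) -> tuple[int, ...]:
        return (self.pos_b, self.pos_b + 1) if self.cat_b == "backbone" else (self.pos_b,)


@dataclass
class ChainAnnotation:
    key: str                    # PDB id + chain, e.g. "1abc_A"
    sequence: str
    contacts: list[ContactRecord] = field(default_factory=list)
    resolution: float | None = None
    r_factor: float | None = None
    n_waters: int | None = None             # solved waters in the entry
    water_counts: list[int] | None = None   # per-residue waters within 4.9 A
    ss: str | None = None                   # DSSP one-letter string
    interface: str | None = None            # per residue: '.', 'A' (asu), 'S' (sym)

    @property
    def pdb_id(self) -> str:
        return self.key.split("_")[0]

    def __len__(self):
        return len(self.sequence)


def contact_to_record(c: PlanarContact, primary_chain: str) -> ContactRecord:
    """Flatten an engine PlanarContact into the annotation dialect."""
    return ContactRecord(
        type_a=c.group_a.identity, pos_a=c.group_a.residue_index,
        cat_a=c.group_a.category,
        type_b=c.group_b.identity, pos_b=c.group_b.residue_index,
        cat_b=c.group_b.category,
        seq_separation=c.seq_separation, chain_class=c.chain_class)


def annotate_structure(model, criteria=None, expand_radius: float = 8.0,
                       include_vdw_records: bool = False,
                       include_sp3: bool = False) -> list[ChainAnnotation]:
    """Run contact detection on a structure and flatten to chain annotations.

    One annotation per chain; contacts of a chain include its intra-chain
    contacts, contacts to the other chains of the entry, and (flagged)
    contacts to crystal symmetry images within ``expand_radius``.  With
    ``include_vdw_records``, sidechain/sp3-plane VDW contacts to backbone
    units that fail the planar criterion are recorded with ``planar=False``
    (the denominator of the sp3 control enrichment).
    """
    from .contact_engine import (DEFAULT_CRITERIA, SHARED_ATOMS,
                                 count_vdw_pairs, detect_contacts,
                                 is_planar_pi_contact, water_contact_count)
    from .sp2_model import extract_sp2_groups, extract_sp3_controls
    from .structure_io import SymmetryUnavailableError, expand_symmetry

    criteria = criteria or DEFAULT_CRITERIA
    groups = list(extract_sp2_groups(model))
    partner = []
    try:
        for label, atoms in expand_symmetry(model, expand_radius):
            partner.extend(extract_sp2_groups(model, copy_label=label,
                                              atoms=atoms))
    except SymmetryUnavailableError:
        pass
    result = detect_contacts(groups, partner, criteria)

    extra: list[tuple] = []   # (chain, record) VDW-only records
    if include_vdw_records:
        probe = list(groups)
        if include_sp3:
            probe += list(extract_sp3_controls(model))
        backbones = [g for g in groups if g.category == "backbone"]
        for g in probe:
            if g.category not in ("sidechain", "sp3"):
                continue
            for bb in backbones:
                n = count_vdw_pairs(g, bb, criteria.vdw_cutoff)
                if n == SHARED_ATOMS or n < criteria.min_atom_pairs:
                    continue
                planar = is_planar_pi_contact(g, bb, criteria) is not None
                from .contact_engine import classify_pair
                sep, _, cls = classify_pair(g, bb)
                extra.append((g.chain_id, ContactRecord(
                    type_a=g.identity, pos_a=g.residue_index, cat_a=g.category,
                    type_b=bb.identity, pos_b=bb.residue_index,
                    cat_b=bb.category, seq_separation=sep, chain_class=cls,
                    planar=planar)))

    waters = model.water_oxygens()
    annotations = []
    for chain in model.chains:
        seq = model.chain_sequence(chain)
        if not seq:
            continue
        recs = []
        for c in result:
            if c.group_a.chain_id == chain and c.group_a.copy_label is None:
                recs.append(contact_to_record(c, chain))
            elif c.group_b.chain_id == chain and c.group_b.copy_label is None \
                    and c.group_a.chain_id != chain:
                # mirror so this chain's group sits on the A side
                recs.append(ContactRecord(
                    type_a=c.group_b.identity, pos_a=c.group_b.residue_index,
                    cat_a=c.group_b.category, type_b=c.group_a.identity,
                    pos_b=c.group_a.residue_index, cat_b=c.group_a.category,
                    seq_separation=c.seq_separation, chain_class=c.chain_class))
        recs += [r for ch, r in extra if ch == chain]
        wc = None
        if len(waters):
            wc = []
            for _, ridx, _, amap in model.residues(chain):
                wc.append(water_contact_count(list(amap.values()), waters))
        annotations.append(ChainAnnotation(
            key=f"{model.name}_{chain}", sequence=seq, contacts=recs,
            resolution=model.resolution, r_factor=model.r_factor,
            n_waters=int(len(waters)) if len(waters) else 0,
            water_counts=wc))
    return annotations


# ---------------------------------------------------------------- TSV dialect

_CONTACT_COLS = ["chain", "type_a", "pos_a", "cat_a", "type_b", "pos_b",
                 "cat_b", "separation", "chain_class", "planar"]


def write_annotations(annotations, contacts_path, chains_path) -> None:
    """Write the contact file and the per-chain residue-count file."""
    rows = []
    for ann in annotations:
        for c in ann.contacts:
            rows.append([ann.key, c.type_a, c.pos_a, c.cat_a, c.type_b, c.pos_b,
                         c.cat_b,
                         "inter" if math.isinf(c.seq_separation) else int(c.seq_separation),
                         c.chain_class, int(c.planar)])
    pd.DataFrame(rows, columns=_CONTACT_COLS).to_csv(contacts_path, sep="\t", index=False)

    crows = [{"chain": ann.key, "resolution": ann.resolution,
              "r_factor": ann.r_factor, "n_waters": ann.n_waters,
              "sequence": ann.sequence} for ann in annotations]
    pd.DataFrame(crows).to_csv(chains_path, sep="\t", index=False)


def read_annotations(contacts_path, chains_path) -> list[ChainAnnotation]:
    chains = pd.read_csv(chains_path, sep="\t", dtype={"chain": str})
    contacts = pd.read_csv(contacts_path, sep="\t", dtype={"chain": str})
    by_chain: dict[str, list[ContactRecord]] = {}
    for row in contacts.itertuples(index=False):
        sep = math.inf if row.separation == "inter" else float(row.separation)
        by_chain.setdefault(row.chain, []).append(ContactRecord(
            type_a=row.type_a, pos_a=int(row.pos_a), cat_a=row.cat_a,
            type_b=row.type_b, pos_b=int(row.pos_b), cat_b=row.cat_b,
            seq_separation=sep, chain_class=row.chain_class,
            planar=bool(row.planar)))
    out = []
    for row in chains.itertuples(index=False):
        res = None if pd.isna(row.resolution) else float(row.resolution)
        rf = None if pd.isna(row.r_factor) else float(row.r_factor)
        nw = None if pd.isna(row.n_waters) else int(row.n_waters)
        out.append(ChainAnnotation(key=row.chain, sequence=row.sequence,
                                   contacts=by_chain.get(row.chain, []),
                                   resolution=res, r_factor=rf, n_waters=nw))
    return out


# ------------------------------------------------------------- core statistics

def _usable(ann: ChainAnnotation, include_symmetry=False):
    for c in ann.contacts:
        if not c.planar:
            continue
        if c.chain_class == "symmetry" and not include_symmetry:
            continue
        yield c


def involved_residues(ann: ChainAnnotation, include_symmetry=False) -> set[int]:
    """Residues of the annotated chain contributing any atom to a planar contact.

    Backbone planar contacts involve both flanking residues.
    """
    out: set[int] = set()
    for c in _usable(ann, include_symmetry):
        out.update(c.residues_a())
        # the B side belongs to this chain only for intra-chain contacts
        if c.chain_class == "intra":
            out.update(c.residues_b())
    return {r for r in out if 0 <= r < len(ann.sequence)}


def involvement_frequency(annotations) -> pd.DataFrame:
    """Per-amino-acid fraction of residues involved in >= 1 planar contact.

    Returns a frame indexed by amino acid with columns ``involved``,
    ``total`` and ``frequency``; attrs carry the unweighted mean over types.
    """
    annotations = list(annotations)
    if not annotations:
        raise InsufficientDataError("no annotations")
    involved: dict[str, int] = {}
    total: dict[str, int] = {}
    for ann in annotations:
        inv = involved_residues(ann)
        for i, aa in enumerate(ann.sequence):
            total[aa] = total.get(aa, 0) + 1
            if i in inv:
                involved[aa] = involved.get(aa, 0) + 1
    rows = []
    for aa in sorted(total):
        n, k = total[aa], involved.get(aa, 0)
        rows.append({"amino_acid": aa, "involved": k, "total": n,
                     "frequency": k / n})
    df = pd.DataFrame(rows).set_index("amino_acid")
    df.attrs["mean_frequency"] = float(df["frequency"].mean())
    return df


def _pair_nature(c: ContactRecord) -> str:
    arom_a = c.cat_a == "sidechain" and c.type_a in AROMATIC_IDENTITIES
    arom_b = c.cat_b == "sidechain" and c.type_b in AROMATIC_IDENTITIES
    if arom_a and arom_b:
        return "aromatic-aromatic"
    if arom_a or arom_b:
        return "aromatic-nonaromatic"
    return "nonaromatic-nonaromatic"


def _participations(ann: ChainAnnotation, contact_class: str) -> int:
    n = 0
    for c in _usable(ann):
        nature = _pair_nature(c)
        if contact_class == "all":
            n += 2
        elif contact_class == "backbone-backbone":
            n += 2 if (c.cat_a == "backbone" and c.cat_b == "backbone") else 0
        elif nature == contact_class:
            n += 2
    return n


CONTACT_CLASSES = ("all", "aromatic-aromatic", "aromatic-nonaromatic",
                   "nonaromatic-nonaromatic", "backbone-backbone")


def contacts_per_100(annotations, contact_class: str = "all") -> float:
    """Group participations in planar contacts per 100 residues."""
    if contact_class not in CONTACT_CLASSES:
        raise ValueError(f"unknown contact class {contact_class!r}")
    annotations = list(annotations)
    residues = sum(len(a) for a in annotations)
    if residues == 0:
        raise InsufficientDataError("no residues")
    parts = sum(_participations(a, contact_class) for a in annotations)
    return 100.0 * parts / residues


def resolution_bins(annotations, min_count: int = 100,
                    max_span: float = 0.25) -> pd.DataFrame:
    """Bin structures by exact resolution, rolling small bins forward.

    Entries are first grouped by exact resolution value; any bin with fewer
    than ``min_count`` structures is rolled into the next bin, provided the
    accumulated bin spans no more than ``max_span`` A (otherwise the bin is
    closed undersized).  Bin label is the count-weighted mean resolution; the
    rate is the pooled contacts-per-100 within the bin.
    """
    annotations = [a for a in annotations if a.resolution is not None]
    if not annotations:
        raise InsufficientDataError("no resolutions present")
    by_pdb: dict[str, list[ChainAnnotation]] = {}
    for a in annotations:
        by_pdb.setdefault(a.pdb_id, []).append(a)
    entries = sorted(by_pdb.values(), key=lambda chs: chs[0].resolution)

    bins: list[list] = []
    current: list = []
    for chs in entries:
        if current and len(current) >= min_count and \
                chs[0].resolution != current[-1][0].resolution:
            bins.append(current)
            current = []
        if current and chs[0].resolution - current[0][0].resolution > max_span \
                and chs[0].resolution != current[-1][0].resolution:
            bins.append(current)   # close undersized bin: roll limit exceeded
            current = []
        current.append(chs)
    if current:
        bins.append(current)

    rows = []
    for b in bins:
        anns = [a for chs in b for a in chs]
        res = np.array([chs[0].resolution for chs in b])
        rows.append({
            "resolution": float(res.mean()),
            "n_structures": len(b),
            "n_residues": sum(len(a) for a in anns),
            "rate_per_100": contacts_per_100(anns, "all"),
        })
    return pd.DataFrame(rows)


def weighted_linear_fit(x, y, weights):
    """Weighted least squares of y on x; returns (slope, intercept, r).

    ``r`` is the weighted Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(weights, float)
    if len(x) < 2:
        raise InsufficientDataError("need >= 2 points for a fit")
    res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    intercept, slope = res.params
    mx, my = np.average(x, weights=w), np.average(y, weights=w)
    cov = np.average((x - mx) * (y - my), weights=w)
    sx = math.sqrt(np.average((x - mx) ** 2, weights=w))
    sy = math.sqrt(np.average((y - my) ** 2, weights=w))
    r = cov / (sx * sy) if sx > 0 and sy > 0 else 0.0
    return float(slope), float(intercept), float(r)


def block_bootstrap_sem(statistic, annotations, n_iter: int = 10000,
                        seed: int = 0) -> float:
    """SD of ``statistic`` over resamples of whole PDB entries.

    ``statistic`` is any callable on a list of annotations.  Resampling is
    with replacement over PDB identifiers, keeping each entry's chains
    together, so dependent observations stay in their blocks.
    """
    annotations = list(annotations)
    by_pdb: dict[str, list[ChainAnnotation]] = {}
    for a in annotations:
        by_pdb.setdefault(a.pdb_id, []).append(a)
    ids = sorted(by_pdb)
    if len(ids) < 2:
        warnings.warn("single-PDB input: bootstrap SEM is 0")
        return 0.0
    rng = np.random.default_rng(seed)
    vals = np.empty(n_iter)
    for it in range(n_iter):
        pick = rng.integers(0, len(ids), size=len(ids))
        sample = [a for k in pick for a in by_pdb[ids[k]]]
        vals[it] = statistic(sample)
    return float(vals.std(ddof=1))


# -------------------------------------------------------- profiled statistics

def solvation_profile(annotations, max_waters: int = 20,
                      min_waters_per_residue: float = 1.0) -> pd.DataFrame:
    """Contact frequency vs. water-contact count, sidechain and backbone apart.

    Only structures with more than ``min_waters_per_residue`` solved water
    oxygens per residue qualify.  Water counts above ``max_waters`` pool into
    the top bin.
    """
    qual = [a for a in annotations
            if a.water_counts is not None and a.n_waters is not None
            and len(a) > 0 and a.n_waters / len(a) > min_waters_per_residue]
    if not qual:
        raise InsufficientDataError("no structures pass the water threshold")
    n_bins = max_waters + 1
    sc_tot = np.zeros(n_bins); sc_hit = np.zeros(n_bins)
    bb_tot = np.zeros(n_bins); bb_hit = np.zeros(n_bins)
    for ann in qual:
        sc_inv, bb_inv = set(), set()
        for c in _usable(ann):
            for cat, pos_fn in ((c.cat_a, c.residues_a), (c.cat_b, c.residues_b)):
                if cat == "sidechain":
                    sc_inv.update(pos_fn())
                elif cat == "backbone":
                    bb_inv.update(pos_fn())
        for i, w in enumerate(ann.water_counts):
            b = min(int(w), max_waters)
            sc_tot[b] += 1
            bb_tot[b] += 1
            if i in sc_inv:
                sc_hit[b] += 1
            if i in bb_inv:
                bb_hit[b] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        df = pd.DataFrame({
            "waters": np.arange(n_bins),
            "n_residues": sc_tot.astype(int),
            "sidechain_frequency": np.where(sc_tot > 0, sc_hit / sc_tot, np.nan),
            "backbone_frequency": np.where(bb_tot > 0, bb_hit / bb_tot, np.nan),
        })
    return df


def ss_signed_distance(ss: str, cap: int = 7) -> np.ndarray:
    """Signed sequence distance from the order/disorder boundary per residue.

    Ordered residues (DSSP H/G/E) get minus their distance to the nearest
    loop/turn residue; loop residues get plus their distance to the nearest
    ordered residue.  Distances cap at ``+-cap``.  A chain with no boundary
    at all gets -cap everywhere (all ordered) or +cap (all loop).
    """
    n = len(ss)
    ordered = np.array([s in ORDERED_SS for s in ss])
    out = np.empty(n, dtype=int)
    ord_pos = np.flatnonzero(ordered)
    loop_pos = np.flatnonzero(~ordered)
    for i in range(n):
        if ordered[i]:
            d = cap if len(loop_pos) == 0 else int(np.abs(loop_pos - i).min())
            out[i] = -min(d, cap)
        else:
            d = cap if len(ord_pos) == 0 else int(np.abs(ord_pos - i).min())
            out[i] = min(d, cap)
    return out


def ss_distance_profile(annotations, cap: int = 7) -> pd.DataFrame:
    """Contact frequency per signed distance from regular secondary structure."""
    tot: dict[int, int] = {}
    hit: dict[int, int] = {}
    any_ss = False
    for ann in annotations:
        if ann.ss is None:
            continue
        if len(ann.ss) != len(ann.sequence):
            raise ValueError(f"{ann.key}: ss length != sequence length")
        any_ss = True
        dist = ss_signed_distance(ann.ss, cap)
        inv = involved_residues(ann)
        for i, d in enumerate(dist):
            tot[d] = tot.get(d, 0) + 1
            if i in inv:
                hit[d] = hit.get(d, 0) + 1
    if not any_ss:
        raise InsufficientDataError("no secondary-structure assignments")
    rows = [{"distance": d, "n_residues": tot[d],
             "frequency": hit.get(d, 0) / tot[d]} for d in sorted(tot)]
    return pd.DataFrame(rows)


def interface_breakdown(annotations) -> pd.DataFrame:
    """Per-sidechain-type contact frequencies split by interface class.

    Rows: 9 sp2 sidechain types x interface class (none / inter_asu /
    symmetry, from per-residue interface flags).  Columns split each bar
    into local intra (<= 4 residues), non-local intra, and inter-chain
    contact rates per residue.
    """
    acc: dict[tuple[str, str], np.ndarray] = {}
    tot: dict[tuple[str, str], int] = {}
    flag_to_class = {".": "none", "A": "inter_asu", "S": "symmetry"}
    for ann in annotations:
        flags = ann.interface or "." * len(ann)
        counts: dict[int, np.ndarray] = {}
        for c in _usable(ann, include_symmetry=True):
            for (cat, typ, positions) in ((c.cat_a, c.type_a, c.residues_a()),
                                          (c.cat_b, c.type_b, c.residues_b())):
                if cat != "sidechain":
                    continue
                if c.chain_class == "intra":
                    slot = 0 if c.seq_separation <= 4 else 1
                else:
                    slot = 2
                for p in positions:
                    counts.setdefault(p, np.zeros(3))[slot] += 1
        for i, aa in enumerate(ann.sequence):
            if aa not in SIDECHAIN_IDENTITIES:
                continue
            cls = flag_to_class.get(flags[i], "none")
            key = (aa, cls)
            tot[key] = tot.get(key, 0) + 1
            if i in counts:
                acc[key] = acc.get(key, np.zeros(3)) + counts[i]
    rows = []
    for (aa, cls), n in sorted(tot.items()):
        v = acc.get((aa, cls), np.zeros(3)) / n
        rows.append({"amino_acid": aa, "interface_class": cls, "n_residues": n,
                     "local_intra": v[0], "nonlocal_intra": v[1],
                     "inter_chain": v[2], "total": float(v.sum())})
    return pd.DataFrame(rows)


def sp3_control_enrichment(annotations) -> pd.DataFrame:
    """P(planar | VDW contact to a peptide unit), per plane identity.

    Annotations must include non-planar VDW records (``planar=False``) for
    sidechain/sp3-plane contacts to backbone groups; the conditional fraction
    compares sp2 sidechains against sp3 terminal planes.
    """
    vdw: dict[tuple[str, str], int] = {}
    planar: dict[tuple[str, str], int] = {}
    for ann in annotations:
        for c in ann.contacts:
            if c.chain_class == "symmetry":
                continue
            for (cat, typ, ocat) in ((c.cat_a, c.type_a, c.cat_b),
                                     (c.cat_b, c.type_b, c.cat_a)):
                if ocat != "backbone" or cat not in ("sidechain", "sp3"):
                    continue
                key = (cat, typ)
                vdw[key] = vdw.get(key, 0) + 1
                if c.planar:
                    planar[key] = planar.get(key, 0) + 1
    rows = []
    for (cat, typ), n in sorted(vdw.items()):
        if n == 0:
            warnings.warn(f"no VDW denominator for {typ}")
            continue
        rows.append({"category": cat, "identity": typ, "n_vdw": n,
                     "fraction_planar": planar.get((cat, typ), 0) / n})
    return pd.DataFrame(rows)
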