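"""Stage 1: expected planar pi-contact frequencies per sp2 group from sequence.

The predictor is an empirical statistical potential.  A frequency table is
tallied from contact annotations, keyed by

    (group identity, partner residue type, separation class, contacted category)

with 9 sidechain identities plus 400 ordered-dipeptide backbone identities,
separation classes short (<= 4 residues) and long (> 4 or inter-chain), and
the contacted category either a sidechain group or a backbone peptide unit.

For a query position, the raw expectation is the mean table frequency over
the sequence context (every residue within +-40 positions, the separation
class implied by the offset).  Raw expectations are then calibrated per
identity against the distribution of (raw, realized) pairs from the training
chains: 20 equal-population percentile bins, the prediction being the mean
realized frequency of the matching bin, post-smoothed with isotonic
regression so calibration is monotone.  The relative channel is the
prediction minus the identity mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .sp2_model import SIDECHAIN_IDENTITIES
from .contact_stats import ChainAnnotation

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(STANDARD_AA)}
SEP_CLASSES = ("short", "long")
CATEGORIES = ("sidechain", "backbone")
CONTEXT_WINDOW = 40
SHORT_MAX = 4

#: the four absolute channels, in fixed order
CHANNELS = ("short_sc", "short_bb", "long_sc", "long_bb")


class PredictorError(ValueError):
    pass


def iter_sequence_groups(seq: str):
    """Yield (identity, category, anchor position, residue positions) per group.

    Every bonded backbone unit (i, i+1) and every sp2 sidechain residue.
    Non-standard letters never form groups.
    """
    for i, aa in enumerate(seq):
        if aa in SIDECHAIN_IDENTITIES:
            yield aa, "sidechain", i, (i,)
    for i in range(len(seq) - 1):
        a, b = seq[i], seq[i + 1]
        if a in AA_INDEX and b in AA_INDEX:
            yield a + b, "backbone", i, (i, i + 1)


@dataclass
class ContactFrequencyTable:
    """Contact and opportunity counts per table cell.

    ``cells[identity]`` is a pair of (20, 2, 2) arrays: contacts and
    opportunities indexed by (partner type, separation class, contacted
    category).  Frequencies use add-one smoothing; cells whose opportunity
    count falls below ``floor`` back off to the partner-marginal for the
    identity, then to the identity-class marginal.
    """

    cells: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    floor: int = 50
    provenance: list[str] = field(default_factory=list)

    def _get(self, identity):
        if identity not in self.cells:
            self.cells[identity] = (np.zeros((20, 2, 2)), np.zeros((20, 2, 2)))
        return self.cells[identity]

    def _class_marginal(self, identity_len: int):
        # pooled over all identities of the same class (1 = sidechain, 2 = backbone)
        c = np.zeros((20, 2, 2)); o = np.zeros((20, 2, 2))
        for ident, (ci, oi) in self.cells.items():
            if len(ident) == identity_len:
                c += ci
                o += oi
        return c, o

    def frequency(self, identity: str, partner: str, sep: str, cat: str) -> float:
        pi = AA_INDEX.get(partner)
        if pi is None:
            raise PredictorError(f"non-standard partner {partner!r}")
        si = SEP_CLASSES.index(sep)
        ci = CATEGORIES.index(cat)
        return float(self.frequency_vector(identity)[pi, si, ci])

    def frequency_vector(self, identity: str) -> np.ndarray:
        """Smoothed (20, 2, 2) frequency array for an identity.

        Empirical-Bayes shrinkage: each cell is pulled toward a prior rate
        ``mu_identity * (partner rate of the identity class / class rate)``
        with ``floor`` pseudo-opportunities, so sparse cells inherit both the
        identity's overall level and the class-wide partner preference
        instead of collapsing to an additive-count artifact.
        """
        if not hasattr(self, "_cache"):
            self._cache = {}
        hit = self._cache.get(identity)
        if hit is not None:
            return hit
        contacts, opps = self.cells.get(identity,
                                        (np.zeros((20, 2, 2)), np.zeros((20, 2, 2))))
        mc, mo = self._class_marginal(len(identity))
        k = float(self.floor)
        out = np.empty((20, 2, 2))
        for si in range(2):
            for ci in range(2):
                c = contacts[:, si, ci]
                o = opps[:, si, ci]
                mu0 = (mc[:, si, ci].sum() + 1.0) / (mo[:, si, ci].sum() + 2.0)
                mu_class_p = (mc[:, si, ci] + k * mu0) / (mo[:, si, ci] + k)
                mu_ident = (c.sum() + k * mu0) / (o.sum() + k)
                prior = mu_ident * mu_class_p / mu0
                out[:, si, ci] = (c + k * prior) / (o + k)
        self._cache[identity] = out
        return out

    def invalidate_cache(self) -> None:
        self._cache = {}

    def identity_mean(self, identity: str, sep: str, cat: str) -> float:
        si = SEP_CLASSES.index(sep)
        ci = CATEGORIES.index(cat)
        contacts, opps = self.cells.get(identity,
                                        (np.zeros((20, 2, 2)), np.zeros((20, 2, 2))))
        mc, mo = self._class_marginal(len(identity))
        mu0 = (mc[:, si, ci].sum() + 1.0) / (mo[:, si, ci].sum() + 2.0)
        k = float(self.floor)
        return float((contacts[:, si, ci].sum() + k * mu0)
                     / (opps[:, si, ci].sum() + k))

    # ---- serialization (versioned TSV with header metadata)
    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# pipistack contact-frequency table v1\tfloor={self.floor}\n")
            for src in self.provenance:
                fh.write(f"# source\t{src}\n")
            fh.write("identity\tpartner\tseparation\tcategory\tcontacts\topportunities\n")
            for ident in sorted(self.cells):
                c, o = self.cells[ident]
                for pi, aa in enumerate(STANDARD_AA):
                    for si, sep in enumerate(SEP_CLASSES):
                        for ci, cat in enumerate(CATEGORIES):
                            if o[pi, si, ci] > 0 or c[pi, si, ci] > 0:
                                fh.write(f"{ident}\t{aa}\t{sep}\t{cat}\t"
                                         f"{c[pi, si, ci]:g}\t{o[pi, si, ci]:g}\n")

    @classmethod
    def read(cls, path) -> "ContactFrequencyTable":
        table = cls()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    if "floor=" in line:
                        table.floor = int(line.split("floor=")[1].split()[0])
                    continue
                if line.startswith("identity\t"):
                    continue
                ident, aa, sep, cat, c, o = line.rstrip("\n").split("\t")
                cc, oo = table._get(ident)
                cc[AA_INDEX[aa], SEP_CLASSES.index(sep), CATEGORIES.index(cat)] = float(c)
                oo[AA_INDEX[aa], SEP_CLASSES.index(sep), CATEGORIES.index(cat)] = float(o)
        return table


def split_chains(annotations, holdout_fraction: float = 0.2, seed: int = 0):
    """Seeded chain-level split into (training, holdout) lists."""
    annotations = list(annotations)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(annotations))
    n_hold = int(round(holdout_fraction * len(annotations)))
    hold = {int(i) for i in idx[:n_hold]}
    train = [a for i, a in enumerate(annotations) if i not in hold]
    test = [a for i, a in enumerate(annotations) if i in hold]
    return train, test


def _sep_class(dist: float) -> str:
    return "short" if dist <= SHORT_MAX else "long"


def _group_contact_counts(ann: ChainAnnotation):
    """Per group (keyed by (category, anchor)): contact counts per channel cell.

    Returns dict key -> (20,2,2) contact-count array aligned with table cells.
    Partner residues of backbone groups count at both flanking positions.
    """
    counts: dict[tuple[str, int], np.ndarray] = {}

    def add(cat, pos, partner_aa, sep, pcat):
        pi = AA_INDEX.get(partner_aa)
        if pi is None:
            return
        arr = counts.setdefault((cat, pos), np.zeros((20, 2, 2)))
        arr[pi, SEP_CLASSES.index(sep), CATEGORIES.index(pcat)] += 1

    seq = ann.sequence
    for c in ann.contacts:
        if not c.planar or c.chain_class == "symmetry":
            continue
        sep = _sep_class(c.seq_separation)
        if c.cat_a in CATEGORIES and c.cat_b in CATEGORIES:
            for p in c.residues_b():
                if c.chain_class == "intra" and 0 <= p < len(seq):
                    add(c.cat_a, c.pos_a, seq[p], sep, c.cat_b)
                elif c.chain_class != "intra":
                    add(c.cat_a, c.pos_a, c.type_b[0] if c.cat_b == "backbone"
                        else c.type_b, "long", c.cat_b)
            if c.chain_class == "intra":
                for p in c.residues_a():
                    if 0 <= p < len(seq):
                        add(c.cat_b, c.pos_b, seq[p], sep, c.cat_a)
    return counts


def _one_hot_prefix(seq: str) -> np.ndarray:
    """(L+1, 20) prefix sums of the one-hot amino-acid matrix."""
    onehot = np.zeros((len(seq), 20))
    for i, aa in enumerate(seq):
        k = AA_INDEX.get(aa)
        if k is not None:
            onehot[i, k] = 1.0
    return np.vstack([np.zeros(20), np.cumsum(onehot, axis=0)])


def _range_counts(prefix: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Amino-acid counts over positions [lo, hi) via the prefix matrix."""
    n = prefix.shape[0] - 1
    lo = max(0, min(lo, n))
    hi = max(0, min(hi, n))
    if hi <= lo:
        return np.zeros(20)
    return prefix[hi] - prefix[lo]


def _window_counts(seq_len: int, prefix: np.ndarray, positions: tuple[int, ...],
                   reach: int | None):
    """(short counts, long counts) of context residue types around a group.

    Short = within SHORT_MAX of the nearest anchor position; long = the rest
    of the ``reach`` window (whole chain when reach is None).  Anchor
    positions themselves are excluded.
    """
    lo_a, hi_a = min(positions), max(positions)
    s_lo, s_hi = lo_a - SHORT_MAX, hi_a + SHORT_MAX + 1
    short = _range_counts(prefix, s_lo, s_hi)
    short -= _range_counts(prefix, lo_a, hi_a + 1)
    if reach is None:
        total = _range_counts(prefix, 0, seq_len)
    else:
        total = _range_counts(prefix, lo_a - reach, hi_a + reach + 1)
    long = total - short - _range_counts(prefix, lo_a, hi_a + 1)
    return short, long


def _group_opportunities(seq: str, positions: tuple[int, ...],
                         prefix: np.ndarray | None = None) -> np.ndarray:
    """Opportunity counts (20, 2, 2) for a group anchored at ``positions``."""
    if prefix is None:
        prefix = _one_hot_prefix(seq)
    short, long = _window_counts(len(seq), prefix, positions, reach=None)
    arr = np.empty((20, 2, 2))
    arr[:, 0, 0] = arr[:, 0, 1] = short
    arr[:, 1, 0] = arr[:, 1, 1] = long
    return arr


def build_table(annotations, floor: int = 50) -> ContactFrequencyTable:
    """Tally the contact-frequency table from annotated chains."""
    annotations = list(annotations)
    if not annotations:
        raise PredictorError("no annotations to build the table from")
    table = ContactFrequencyTable(floor=floor)
    for ann in annotations:
        table.provenance.append(ann.key)
        counts = _group_contact_counts(ann)
        prefix = _one_hot_prefix(ann.sequence)
        for ident, cat, anchor, positions in iter_sequence_groups(ann.sequence):
            c, o = table._get(ident)
            o += _group_opportunities(ann.sequence, positions, prefix)
            got = counts.get((cat, anchor))
            if got is not None:
                c += got
    return table


def context_expectation(seq: str, positions: tuple[int, ...], identity: str,
                        table: ContactFrequencyTable,
                        prefix: np.ndarray | None = None) -> np.ndarray:
    """Raw expected frequencies, 4 absolute values in CHANNELS order.

    Mean over the context residues (within +-40 of the group, truncated at
    the termini) of the table frequency for (identity, context residue type,
    separation class implied by the offset, contacted category).
    """
    if prefix is None:
        prefix = _one_hot_prefix(seq)
    short, long = _window_counts(len(seq), prefix, tuple(positions),
                                 reach=CONTEXT_WINDOW)
    fv = table.frequency_vector(identity)   # (20, 2, 2)
    out = np.empty(4)
    for k, ch in enumerate(CHANNELS):
        sep, cat = ch.split("_")
        si = SEP_CLASSES.index(sep)
        ci = 0 if cat == "sc" else 1
        counts = short if sep == "short" else long
        n = counts.sum()
        if n > 0:
            out[k] = float(counts @ fv[:, si, ci]) / n
        else:
            cat_full = "sidechain" if cat == "sc" else "backbone"
            out[k] = table.identity_mean(identity, sep, cat_full)
    return out


@dataclass
class Calibration:
    """Per-identity monotone maps from raw expectation to realized frequency.

    Identities with fewer than ``min_samples`` calibration groups use the
    pooled map of their class (sidechain or backbone); identity-specific
    means are kept whenever available so the relative channel still centers
    per identity.
    """

    maps: dict[tuple[str, int], IsotonicRegression] = field(default_factory=dict)
    identity_means: dict[tuple[str, int], float] = field(default_factory=dict)
    pooled: dict[tuple[str, int], IsotonicRegression] = field(default_factory=dict)
    pooled_means: dict[tuple[str, int], float] = field(default_factory=dict)
    n_bins: int = 20
    min_samples: int = 2000

    def predict(self, identity: str, channel: int, raw: float) -> float:
        m = self.maps.get((identity, channel))
        if m is None:
            m = self.pooled[("sidechain" if len(identity) == 1 else "backbone",
                             channel)]
        return float(np.clip(m.predict([raw])[0], 0.0, 1.0))

    def mean(self, identity: str, channel: int) -> float:
        key = (identity, channel)
        if key in self.identity_means:
            return self.identity_means[key]
        return self.pooled_means[("sidechain" if len(identity) == 1 else
                                  "backbone", channel)]


def _fit_map(raws: np.ndarray, obs: np.ndarray, n_bins: int) -> IsotonicRegression:
    order = np.argsort(raws, kind="stable")
    raws, obs = raws[order], obs[order]
    edges = np.linspace(0, len(raws), n_bins + 1).astype(int)
    bx, by = [], []
    for b in range(n_bins):
        sl = slice(edges[b], edges[b + 1])
        if edges[b + 1] > edges[b]:
            bx.append(raws[sl].mean())
            by.append(obs[sl].mean())
    iso = IsotonicRegression(out_of_bounds="clip")
    iso.fit(bx, by)
    return iso


def _realized_channel_freqs(ann: ChainAnnotation):
    """Per group: realized contact frequency per channel (counts/opportunities)."""
    counts = _group_contact_counts(ann)
    prefix = _one_hot_prefix(ann.sequence)
    for ident, cat, anchor, positions in iter_sequence_groups(ann.sequence):
        opp = _group_opportunities(ann.sequence, positions, prefix)
        got = counts.get((cat, anchor), np.zeros((20, 2, 2)))
        freqs = np.empty(4)
        for k, ch in enumerate(CHANNELS):
            sep, pc = ch.split("_")
            si = SEP_CLASSES.index(sep)
            ci = 0 if pc == "sc" else 1
            o = opp[:, si, ci].sum()
            freqs[k] = min(got[:, si, ci].sum() / o, 1.0) if o > 0 else 0.0
        yield ident, cat, anchor, positions, freqs


def calibrate(annotations, table: ContactFrequencyTable, n_bins: int = 20,
              min_samples: int = 2000) -> Calibration:
    """Fit the percentile-bin calibration from training annotations."""
    raws: dict[tuple[str, int], list[float]] = {}
    obs: dict[tuple[str, int], list[float]] = {}
    for ann in annotations:
        prefix = _one_hot_prefix(ann.sequence)
        for ident, cat, anchor, positions, freqs in _realized_channel_freqs(ann):
            raw = context_expectation(ann.sequence, positions, ident, table, prefix)
            for k in range(4):
                raws.setdefault((ident, k), []).append(raw[k])
                obs.setdefault((ident, k), []).append(freqs[k])
    cal = Calibration(n_bins=n_bins, min_samples=min_samples)
    pooled_raws: dict[tuple[str, int], list[float]] = {}
    pooled_obs: dict[tuple[str, int], list[float]] = {}
    for (ident, k), r in raws.items():
        cls = "sidechain" if len(ident) == 1 else "backbone"
        pooled_raws.setdefault((cls, k), []).extend(r)
        pooled_obs.setdefault((cls, k), []).extend(obs[(ident, k)])
        if len(r) >= min_samples:
            cal.maps[(ident, k)] = _fit_map(np.array(r), np.array(obs[(ident, k)]),
                                            n_bins)
            cal.identity_means[(ident, k)] = float(np.mean(obs[(ident, k)]))
    for (cls, k), r in pooled_raws.items():
        cal.pooled[(cls, k)] = _fit_map(np.array(r), np.array(pooled_obs[(cls, k)]),
                                        n_bins)
        cal.pooled_means[(cls, k)] = float(np.mean(pooled_obs[(cls, k)]))
    return cal


def fit_predictor(annotations, floor: int = 50, n_bins: int = 20,
                  min_samples: int = 2000, seed: int = 0):
    """Fit (table, calibration) with split-half cross-fitting.

    The frequency table is tallied on one half of the chains and the
    calibration on the other, so a group's own contacts never inflate the
    raw expectation it is calibrated against.
    """
    annotations = list(annotations)
    if len(annotations) < 2:
        raise PredictorError("need at least two chains for cross-fitting")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(annotations))
    half = len(annotations) // 2
    part_a = [annotations[i] for i in idx[:half]]
    part_b = [annotations[i] for i in idx[half:]]
    table = build_table(part_a, floor=floor)
    cal = calibrate(part_b, table, n_bins=n_bins, min_samples=min_samples)
    return table, cal


def predict_profile(seq: str, table: ContactFrequencyTable,
                    calibration: Calibration) -> pd.DataFrame:
    """Predict the 8-channel ContactProfile for every sp2 group of a sequence.

    One row per group with columns ``abs_<channel>`` (calibrated frequency in
    [0, 1]) and ``rel_<channel>`` (signed difference from the identity mean).
    """
    if len(seq) < 2:
        raise PredictorError("sequence must have length >= 2")
    rows = []
    prefix = _one_hot_prefix(seq)
    for ident, cat, anchor, positions in iter_sequence_groups(seq):
        raw = context_expectation(seq, positions, ident, table, prefix)
        row = {"identity": ident, "category": cat, "position": anchor}
        for k, ch in enumerate(CHANNELS):
            pred = calibration.predict(ident, k, raw[k])
            row[f"abs_{ch}"] = pred
            row[f"rel_{ch}"] = pred - calibration.mean(ident, k)
        rows.append(row)
    return pd.DataFrame(rows)
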