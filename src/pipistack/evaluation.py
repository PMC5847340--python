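"""Benchmark machinery: empirical ROC/AUC, bootstrap errors, and the
sequence-similarity and complexity controls used around the predictor.

The ROC is the non-parametric step function of the two empirical score
distributions; the AUC is measured directly on it, without smoothing, and
equals the normalized Mann-Whitney U statistic with ties counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

EVIDENCE_CLASSES = ("in_vitro_sufficient", "in_vitro_insufficient",
                    "in_cellulo_associated", "synthetic_designed", "background")
MIN_LENGTH = 140

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class EvaluationError(ValueError):
    pass


@dataclass
class BenchmarkSet:
    """Named benchmark with per-member evidence class.

    Members shorter than 140 residues are dropped on load (removals logged
    in ``removed``) so scores are never extrapolated onto a length class the
    predictor was not built for.
    """

    name: str
    members: list[tuple[str, str, str]]   # (id, sequence, evidence class)
    source: str = ""
    removed: list[str] = field(default_factory=list)

    @classmethod
    def from_records(cls, name, records, source=""):
        members, removed = [], []
        for sid, seq, evidence in records:
            if evidence not in EVIDENCE_CLASSES:
                raise EvaluationError(f"unknown evidence class {evidence!r}")
            if len(seq) < MIN_LENGTH:
                removed.append(sid)
            else:
                members.append((sid, seq, evidence))
        return cls(name=name, members=members, source=source, removed=removed)

    @classmethod
    def from_tsv(cls, path, name=None):
        df = pd.read_csv(path, sep="\t")
        return cls.from_records(name or str(path),
                                df[["id", "sequence", "evidence"]].itertuples(index=False))

    def sequences(self, evidence=None):
        return [(sid, seq) for sid, seq, ev in self.members
                if evidence is None or ev == evidence]


def roc_curve(positive_scores, negative_scores):
    """Empirical step-function ROC points as (fpr, tpr) arrays."""
    pos = np.asarray(list(positive_scores), dtype=float)
    neg = np.asarray(list(negative_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both score sets must be nonempty")
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(np.r_[pos, neg]))[::-1]])
    tpr = [(pos >= t).mean() for t in thresholds]
    fpr = [(neg >= t).mean() for t in thresholds]
    return np.array(fpr), np.array(tpr)


def roc_auc(positive_scores, negative_scores, with_curve: bool = False):
    """AUC of the empirical ROC; ties count one half (Mann-Whitney).

    Computed from midranks: AUC = (R_pos - n_pos(n_pos+1)/2) / (n_pos n_neg).
    """
    pos = np.asarray(list(positive_scores), dtype=float)
    neg = np.asarray(list(negative_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both score sets must be nonempty")
    ranks = rankdata(np.r_[pos, neg], method="average")
    r_pos = ranks[:pos.size].sum()
    auc = (r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    if with_curve:
        return float(auc), roc_curve(pos, neg)
    return float(auc)


def bootstrap_auc_sem(positive_scores, negative_scores, n_iter: int = 10000,
                      seed: int = 0) -> float:
    """SD of the AUC over resamples (with replacement) of both score sets."""
    pos = np.asarray(list(positive_scores), dtype=float)
    neg = np.asarray(list(negative_scores), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise EvaluationError("both score sets must be nonempty")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_iter)
    for i in range(n_iter):
        p = pos[rng.integers(0, pos.size, pos.size)]
        n = neg[rng.integers(0, neg.size, neg.size)]
        vals[i] = roc_auc(p, n)
    return float(vals.std(ddof=1))


def dipeptide_profile(seq: str) -> np.ndarray:
    """Normalized frequencies of the 400 ordered i,i+1 residue pairs."""
    if len(seq) < 2:
        raise EvaluationError("sequence must have length >= 2")
    idx = {a: i for i, a in enumerate(STANDARD_AA)}
    prof = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        if a in idx and b in idx:
            prof[idx[a] * 20 + idx[b]] += 1
    total = prof.sum()
    if total == 0:
        raise EvaluationError("no standard dipeptides in sequence")
    return prof / total


def dipeptide_distance(query: str, reference_seqs) -> float:
    """Minimum block-L1 distance between dipeptide profiles (range [0, 2])."""
    refs = list(reference_seqs)
    if not refs:
        raise EvaluationError("empty reference set")
    q = dipeptide_profile(query)
    return min(float(np.abs(q - dipeptide_profile(r)).sum()) for r in refs)


def shannon_entropy(seq: str) -> float:
    """Shannon entropy of the amino-acid composition, in bits."""
    if not seq:
        raise EvaluationError("empty sequence")
    _, counts = np.unique(list(seq), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())
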