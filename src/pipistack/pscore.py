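"""Stage 2: the PScore — phase-separation propensity from pi-contact profiles.

A sequence's contact profile (8 channels per sp2 group) is flattened to
per-residue tracks: each sidechain group contributes its channel values to
its own residue, each backbone unit to both flanking residues, averaging
where several groups attach to the same residue.  Each scored component is
one channel track, optionally modulated by the carbon count of the
contributing group, aggregated over the sequence by a window statistic
(maximum window mean, or the mean over the top-60 residues expanded by +-5),
and combined as a weighted sum into a raw score.  The PScore is the raw
score in standard deviations above the mean of a PDB-like background set;
>= 4.0 is the standard confidence threshold.

Training is seeded stochastic hill climbing over weights and window lengths,
maximizing the z-unit gap between the lowest-scoring training positive and
the mean of the top 1% of the background.  Scoring is restricted to
sequences of at least 140 residues; shorter inputs raise, never score 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .frequency_predictor import (CHANNELS, Calibration, ContactFrequencyTable,
                                  predict_profile)

MIN_LENGTH = 140
#: per-channel variants: plain value and carbon-count-weighted value
COMPONENT_NAMES = tuple(f"{kind}_{ch}" for kind in ("abs", "rel") for ch in CHANNELS) \
    + tuple(f"carbon_{kind}_{ch}" for kind in ("abs", "rel") for ch in CHANNELS)
N_COMPONENTS = len(COMPONENT_NAMES)
DEFAULT_WINDOWS = (10, 20, 40, 60, 80, 100, 140)
PSCORE_THRESHOLD = 4.0


class SequenceTooShortError(ValueError):
    """Sequences below the 140-residue floor are refused, never scored 0."""


class TrainingError(RuntimeError):
    pass


@dataclass
class PScoreModel:
    weights: np.ndarray                  # (N_COMPONENTS,)
    window_lengths: np.ndarray           # (N_COMPONENTS,) ints
    aggregation: str = "max_window"      # max_window | top_k_expand
    background_mean: float = 0.0
    background_sd: float = 1.0
    metadata: dict = field(default_factory=dict)
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.window_lengths = np.asarray(self.window_lengths, dtype=int)
        if np.any(self.window_lengths < 1) or np.any(self.window_lengths > MIN_LENGTH):
            raise ValueError("window lengths must be in [1, 140]")

    def write(self, path) -> None:
        doc = {"format": "pipistack pscore model v1",
               "weights": self.weights.tolist(),
               "window_lengths": self.window_lengths.tolist(),
               "component_names": list(COMPONENT_NAMES),
               "aggregation": self.aggregation,
               "background_mean": self.background_mean,
               "background_sd": self.background_sd,
               "metadata": self.metadata,
               "objective_trace": self.objective_trace}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def read(cls, path) -> "PScoreModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(weights=np.array(doc["weights"]),
                   window_lengths=np.array(doc["window_lengths"]),
                   aggregation=doc["aggregation"],
                   background_mean=doc["background_mean"],
                   background_sd=doc["background_sd"],
                   metadata=doc.get("metadata", {}),
                   objective_trace=doc.get("objective_trace", []))


@dataclass
class ScoredSequence:
    id: str
    length: int
    raw_score: float
    pscore: float
    residue_track: np.ndarray | None = None


def component_values(profile: pd.DataFrame, seq_len: int,
                     include_carbon: bool = True) -> np.ndarray:
    """Per-residue value matrix, one row per component.

    Sidechain-group rows attach to their residue; backbone rows to both
    flanking residues.  Where several groups attach to one residue the
    values average.  Carbon components weight each group's contribution by
    its carbon count before averaging.
    """
    from .sp2_model import _DEFS
    n_plain = len(CHANNELS) * 2
    vals = np.zeros((N_COMPONENTS, seq_len))
    wsum = np.zeros((2, seq_len))    # attachment weights: [plain, carbon]

    carbon_counts = {"backbone": 3}
    for ident, d in _DEFS["sidechain"].items():
        carbon_counts[ident] = sum(1 for a in d["members"] if a[0] == "C")

    cols = [f"{kind}_{ch}" for kind in ("abs", "rel") for ch in CHANNELS]
    for row in profile.itertuples(index=False):
        if row.category == "sidechain":
            targets = (row.position,)
            cc = carbon_counts.get(row.identity, 1)
        elif row.category == "backbone":
            targets = (row.position, row.position + 1)
            cc = carbon_counts["backbone"]
        else:
            continue
        v = np.array([getattr(row, c) for c in cols])
        for t in targets:
            if 0 <= t < seq_len:
                vals[:n_plain, t] += v
                vals[n_plain:, t] += cc * v
                wsum[0, t] += 1
                wsum[1, t] += cc
    with np.errstate(invalid="ignore", divide="ignore"):
        vals[:n_plain] = np.where(wsum[0] > 0, vals[:n_plain] / wsum[0], 0.0)
        vals[n_plain:] = np.where(wsum[1] > 0, vals[n_plain:] / wsum[1], 0.0)
    if not include_carbon:
        vals = vals[:n_plain]
    return vals


def window_aggregate(values: np.ndarray, window: int,
                     mode: str = "max_window", top_k: int = 60,
                     expand: int = 5) -> float:
    """Aggregate a per-residue track to a scalar.

    ``max_window``: maximum over contiguous windows of length ``window`` of
    the window mean.  ``top_k_expand``: mean over the union of the top-k
    residues by value expanded by +-``expand`` positions.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < window:
        raise SequenceTooShortError(f"track length {n} < window {window}")
    if mode == "max_window":
        csum = np.concatenate([[0.0], np.cumsum(values)])
        means = (csum[window:] - csum[:-window]) / window
        return float(means.max())
    if mode == "top_k_expand":
        k = min(top_k, n)
        top = np.argsort(values, kind="stable")[::-1][:k]
        mask = np.zeros(n, dtype=bool)
        for t in top:
            mask[max(0, t - expand):min(n, t + expand + 1)] = True
        return float(values[mask].mean())
    raise ValueError(f"unknown aggregation mode {mode!r}")


def component_aggregates(values: np.ndarray, windows=DEFAULT_WINDOWS,
                         mode: str = "max_window") -> np.ndarray:
    """(N_COMPONENTS, len(windows)) aggregate matrix for one sequence."""
    out = np.empty((values.shape[0], len(windows)))
    for c in range(values.shape[0]):
        for wi, w in enumerate(windows):
            out[c, wi] = window_aggregate(values[c], w, mode=mode)
    return out


def sequence_component_tracks(seq: str, table: ContactFrequencyTable,
                              calibration: Calibration) -> np.ndarray:
    profile = predict_profile(seq, table, calibration)
    return component_values(profile, len(seq))


def raw_score(seq: str, model: PScoreModel, table: ContactFrequencyTable,
              calibration: Calibration,
              return_track: bool = False):
    """Weighted sum of per-component window aggregates for one sequence."""
    if len(seq) < MIN_LENGTH:
        raise SequenceTooShortError(
            f"sequence length {len(seq)} < minimum {MIN_LENGTH}")
    tracks = sequence_component_tracks(seq, table, calibration)
    total = 0.0
    for c in range(N_COMPONENTS):
        total += model.weights[c] * window_aggregate(
            tracks[c], int(model.window_lengths[c]), mode=model.aggregation)
    if return_track:
        return float(total), model.weights @ tracks
    return float(total)


def pscore(seq: str, model: PScoreModel, table: ContactFrequencyTable,
           calibration: Calibration, seq_id: str = "") -> ScoredSequence:
    """Score one sequence; PScore = (raw - background mean) / background SD."""
    raw, track = raw_score(seq, model, table, calibration, return_track=True)
    z = (raw - model.background_mean) / model.background_sd
    return ScoredSequence(id=seq_id, length=len(seq), raw_score=raw,
                          pscore=float(z), residue_track=track)


def _objective(raws_pos: np.ndarray, raws_bg: np.ndarray) -> float:
    """z(min positive) - z(mean of top-1% background), in background z units."""
    mu = raws_bg.mean()
    sd = raws_bg.std(ddof=0)
    if sd <= 0:
        return -np.inf
    n_top = max(1, int(round(0.01 * len(raws_bg))))
    top = np.sort(raws_bg)[-n_top:]
    return float((raws_pos.min() - mu) / sd - (top.mean() - mu) / sd)


def train(positive_tracks, background_tracks, seed: int = 0,
          windows=DEFAULT_WINDOWS, plateau: int = 2000,
          n_restarts: int = 3, aggregation: str = "max_window",
          step: float = 0.5) -> PScoreModel:
    """Fit weights and window lengths by seeded stochastic hill climbing.

    ``positive_tracks`` / ``background_tracks`` are per-sequence component
    matrices from :func:`sequence_component_tracks`.  Aggregates over the
    candidate window grid are precomputed once, so each proposal is a cheap
    re-weighting.  A proposal perturbs one weight (Gaussian) or moves one
    window index; it is accepted only if the objective improves, so the
    accepted-objective trace is non-decreasing.  Training stops after
    ``plateau`` consecutive rejected proposals.
    """
    if len(positive_tracks) < 1:
        raise TrainingError("need at least one training positive")
    if len(background_tracks) < 100:
        raise TrainingError(
            f"need >= 100 background sequences, got {len(background_tracks)}")
    windows = tuple(int(w) for w in windows)
    A_pos = np.stack([component_aggregates(t, windows, aggregation)
                      for t in positive_tracks])      # (n_pos, C, W)
    A_bg = np.stack([component_aggregates(t, windows, aggregation)
                     for t in background_tracks])     # (n_bg, C, W)
    if np.allclose(A_bg.std(axis=0), 0):
        raise TrainingError("degenerate background: zero variance")

    rng = np.random.default_rng(seed)
    n_c = A_pos.shape[1]
    best_obj, best_state = -np.inf, None
    best_trace: list[float] = []

    for _ in range(max(1, n_restarts)):
        w = rng.normal(0, 1, size=n_c)
        widx = rng.integers(0, len(windows), size=n_c)
        cols = np.arange(n_c)

        def raws(A, widx):
            return A[:, cols, widx]

        obj = _objective(raws(A_pos, widx) @ w, raws(A_bg, widx) @ w)
        trace = [obj]
        stale = 0
        while stale < plateau:
            w2, widx2 = w, widx
            if rng.random() < 0.8:
                w2 = w.copy()
                c = rng.integers(0, n_c)
                w2[c] += rng.normal(0, step)
            else:
                widx2 = widx.copy()
                c = rng.integers(0, n_c)
                widx2[c] = rng.integers(0, len(windows))
            cand = _objective(raws(A_pos, widx2) @ w2, raws(A_bg, widx2) @ w2)
            if cand > obj:
                w, widx, obj = w2, widx2, cand
                trace.append(obj)
                stale = 0
            else:
                stale += 1
        if obj > best_obj:
            best_obj, best_state, best_trace = obj, (w.copy(), widx.copy()), trace

    w, widx = best_state
    bg_raw = A_bg[:, np.arange(n_c), widx] @ w
    model = PScoreModel(weights=w,
                        window_lengths=np.array([windows[i] for i in widx]),
                        aggregation=aggregation,
                        background_mean=float(bg_raw.mean()),
                        background_sd=float(bg_raw.std(ddof=0)),
                        metadata={"seed": int(seed), "plateau": int(plateau),
                                  "n_restarts": int(n_restarts),
                                  "windows": list(windows),
                                  "objective": float(best_obj)},
                        objective_trace=[float(v) for v in best_trace])
    return model


def score_tracks(tracks, model: PScoreModel, as_z: bool = True) -> np.ndarray:
    """Score precomputed component tracks under a trained model.

    Returns raw scores, or PScores (background z units) when ``as_z``.
    """
    out = np.empty(len(tracks))
    for i, t in enumerate(tracks):
        total = 0.0
        for c in range(t.shape[0]):
            total += model.weights[c] * window_aggregate(
                t[c], int(model.window_lengths[c]), mode=model.aggregation)
        out[i] = total
    if as_z:
        out = (out - model.background_mean) / model.background_sd
    return out


def threshold_capture(pscores, threshold: float = PSCORE_THRESHOLD) -> float:
    """Fraction of scores at or above the confidence threshold (ties included)."""
    scores = np.asarray(list(pscores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty score set")
    return float(np.mean(scores >= threshold))
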