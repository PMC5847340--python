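"""PScore scoring and training: components, windows, z-normalization."""

import numpy as np
import pandas as pd
import pytest

from pipistack.pscore import (COMPONENT_NAMES, N_COMPONENTS, PScoreModel,
                              SequenceTooShortError, TrainingError,
                              component_values, pscore, raw_score,
                              score_tracks, sequence_component_tracks,
                              threshold_capture, train, window_aggregate)
from pipistack.frequency_predictor import CHANNELS
from pipistack.synthetic import make_sequence_sets


def _toy_profile(rows):
    cols = ["identity", "category", "position"]
    cols += [f"{k}_{c}" for k in ("abs", "rel") for c in CHANNELS]
    return pd.DataFrame(rows, columns=cols)


def test_repeat_dipeptide_gives_constant_tracks():
    rows = []
    for i in range(9):
        rows.append(["GA" if i % 2 == 0 else "AG", "backbone", i] + [0.1] * 8)
    vals = component_values(_toy_profile(rows), 10)
    plain = vals[:16 // 2]
    assert np.allclose(plain[:, 1:9], 0.1)


def test_carbon_channel_reduces_to_plain_when_disabled():
    rows = [["F", "sidechain", 0] + [0.2] * 8,
            ["GA", "backbone", 0] + [0.1] * 8]
    with_c = component_values(_toy_profile(rows), 2, include_carbon=True)
    without = component_values(_toy_profile(rows), 2, include_carbon=False)
    assert np.allclose(with_c[: without.shape[0]], without)


def test_attachment_rule_hand_assignment():
    """Sidechain rows mark their residue; backbone rows both flanks, averaged."""
    rows = [["F", "sidechain", 2] + [0.8] * 8,
            ["AG", "backbone", 0] + [0.2] * 8,
            ["GA", "backbone", 1] + [0.4] * 8]
    vals = component_values(_toy_profile(rows), 5, include_carbon=False)
    ch = 0
    assert vals[ch, 0] == pytest.approx(0.2)           # only unit (0,1)
    assert vals[ch, 1] == pytest.approx((0.2 + 0.4) / 2)
    assert vals[ch, 2] == pytest.approx((0.4 + 0.8) / 2)
    assert vals[ch, 3] == pytest.approx(0.0)
    # carbon weighting: F ring has 6 carbons, peptide unit 3
    full = component_values(_toy_profile(rows), 5, include_carbon=True)
    carbon_ch = 16 // 2
    assert full[carbon_ch, 2] == pytest.approx(
        (3 * 0.4 + 6 * 0.8) / (3 + 6))


def test_window_aggregate_constant_spike_and_topk():
    assert window_aggregate(np.full(140, 0.3), 10) == pytest.approx(0.3)
    assert window_aggregate(np.full(140, 0.3), 140) == pytest.approx(0.3)
    spike = np.zeros(140); spike[70] = 1.0
    assert window_aggregate(spike, 10) == pytest.approx(1.0 / 10)
    # top-k-expand equals brute-force enumeration on a toy track
    rng = np.random.default_rng(0)
    track = rng.random(200)
    got = window_aggregate(track, 1, mode="top_k_expand", top_k=60, expand=5)
    top = np.argsort(track, kind="stable")[::-1][:60]
    mask = np.zeros(200, bool)
    for t in top:
        mask[max(0, t - 5):t + 6] = True
    assert got == pytest.approx(track[mask].mean())
    with pytest.raises(SequenceTooShortError):
        window_aggregate(np.zeros(5), 10)


def _flat_model(**kw):
    return PScoreModel(weights=np.ones(N_COMPONENTS),
                       window_lengths=np.full(N_COMPONENTS, 20), **kw)


def test_short_sequence_refused(fitted_predictor):
    table, cal, _, _ = fitted_predictor
    with pytest.raises(SequenceTooShortError):
        raw_score("A" * 139, _flat_model(), table, cal)


def test_pscore_z_identity_and_determinism(fitted_predictor):
    table, cal, train_anns, _ = fitted_predictor
    seqs = [a.sequence for a in train_anns[:30]]
    tracks = [sequence_component_tracks(s, table, cal) for s in seqs]
    raws = score_tracks(tracks, _flat_model(), as_z=False)
    model = _flat_model(background_mean=float(raws.mean()),
                        background_sd=float(raws.std()))
    zs = score_tracks(tracks, model)
    assert zs.mean() == pytest.approx(0.0, abs=1e-9)
    assert zs.std() == pytest.approx(1.0, abs=1e-9)
    s1 = pscore(seqs[0], model, table, cal)
    s2 = pscore(seqs[0], model, table, cal)
    assert s1.pscore == s2.pscore
    assert s1.pscore == pytest.approx((s1.raw_score - model.background_mean)
                                      / model.background_sd)


def test_threshold_capture_boundary_inclusive():
    assert threshold_capture([5.0, 5.0, 5.0]) == 1.0
    assert threshold_capture([3.9, 4.0, 4.1]) == pytest.approx(2 / 3)
    scores = [3.0, 4.0, 4.5, 2.0]
    assert threshold_capture(scores) == \
        sum(1 for s in scores if s >= 4.0) / len(scores)
    with pytest.raises(ValueError):
        threshold_capture([])


@pytest.fixture(scope="module")
def toy_tracks():
    """Synthetic component tracks with an inflated long-bb channel in positives."""
    rng = np.random.default_rng(12)
    ch = COMPONENT_NAMES.index("abs_long_bb")
    def mk(n, boost):
        out = []
        for _ in range(n):
            t = rng.normal(0.01, 0.002, size=(N_COMPONENTS, 200))
            t[ch] += boost * rng.random(200)
            out.append(t)
        return out
    return mk(11, 0.05), mk(120, 0.0)


def test_train_separates_inflated_channel(toy_tracks):
    pos, bg = toy_tracks
    model = train(pos, bg, seed=0, plateau=400, n_restarts=1)
    zp = score_tracks(pos, model)
    zb = score_tracks(bg, model)
    n_top = max(1, len(zb) // 100)
    assert zp.min() > np.sort(zb)[-n_top:].mean()
    assert model.metadata["objective"] > 1.0
    trace = model.objective_trace
    assert all(a <= b + 1e-12 for a, b in zip(trace, trace[1:]))


def test_train_deterministic_under_seed(toy_tracks):
    pos, bg = toy_tracks
    m1 = train(pos, bg, seed=7, plateau=200, n_restarts=1)
    m2 = train(pos, bg, seed=7, plateau=200, n_restarts=1)
    assert np.array_equal(m1.weights, m2.weights)
    assert np.array_equal(m1.window_lengths, m2.window_lengths)
    assert m1.objective_trace == m2.objective_trace


def test_train_null_control(toy_tracks):
    """Positives drawn from the background distribution give no separation."""
    _, bg = toy_tracks
    model = train(bg[:11], bg[11:], seed=1, plateau=300, n_restarts=1)
    # min positive cannot clear the top percentile on matched distributions
    assert model.metadata["objective"] < 1.0


def test_train_input_validation(toy_tracks):
    pos, bg = toy_tracks
    with pytest.raises(TrainingError):
        train([], bg, seed=0)
    with pytest.raises(TrainingError):
        train(pos, bg[:10], seed=0)
    flat = [np.zeros((N_COMPONENTS, 200)) for _ in range(120)]
    with pytest.raises(TrainingError):
        train(pos[:1], flat, seed=0)


def test_model_roundtrip(tmp_path, toy_tracks):
    pos, bg = toy_tracks
    m = train(pos, bg, seed=3, plateau=100, n_restarts=1)
    m.write(tmp_path / "m.json")
    back = PScoreModel.read(tmp_path / "m.json")
    assert np.array_equal(m.weights, back.weights)
    assert np.array_equal(m.window_lengths, back.window_lengths)
    assert back.background_sd == m.background_sd
    assert score_tracks(bg[:5], m).tolist() == score_tracks(bg[:5], back).tolist()


def test_monotone_in_positive_channel(toy_tracks):
    """Raising values on a positively weighted component never lowers a score."""
    pos, bg = toy_tracks
    model = train(pos, bg, seed=0, plateau=200, n_restarts=1)
    c = int(np.argmax(model.weights))
    t = bg[0].copy()
    base = score_tracks([t], model)[0]
    t2 = t.copy(); t2[c] += 0.05
    assert score_tracks([t2], model)[0] >= base
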