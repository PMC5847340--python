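"""Sequence-based pi-contact frequency prediction: table, context, calibration."""

import math

import numpy as np
import pytest

from pipistack.contact_stats import ChainAnnotation, ContactRecord
from pipistack.frequency_predictor import (CHANNELS, ContactFrequencyTable,
                                           PredictorError, build_table,
                                           calibrate, context_expectation,
                                           fit_predictor, predict_profile,
                                           split_chains, _one_hot_prefix,
                                           _realized_channel_freqs,
                                           iter_sequence_groups)


def _rec(ta, pa, ca, tb, pb, cb, sep):
    return ContactRecord(type_a=ta, pos_a=pa, cat_a=ca, type_b=tb, pos_b=pb,
                         cat_b=cb, seq_separation=sep, chain_class="intra")


def test_single_contact_table_frequency_hand_count():
    """One long Phe-Phe sidechain contact in one chain tallies exactly."""
    seq = "F" + "A" * 18 + "F"
    ann = ChainAnnotation(key="t_A", sequence=seq, contacts=[
        _rec("F", 0, "sidechain", "F", 19, "sidechain", 19)])
    table = build_table([ann], floor=50)
    c, o = table.cells["F"]
    fidx = "ACDEFGHIKLMNPQRSTVWY".index("F")
    # the F at 0 contacted the F at 19 (long, sidechain) and vice versa
    assert c[fidx, 1, 0] == 2.0
    # opportunities vs partner F: each F group sees one F long partner
    assert o[fidx, 1, 0] == 2.0
    aidx = "ACDEFGHIKLMNPQRSTVWY".index("A")
    assert c[aidx, 1, 0] == 0 and o[aidx, 1, 0] > 0


def test_table_build_deterministic_and_serializable(tmp_path, survey_corpus):
    annotations, _ = survey_corpus
    sub = annotations[:15]
    t1 = build_table(sub)
    t2 = build_table(sub)
    for k in t1.cells:
        assert np.array_equal(t1.cells[k][0], t2.cells[k][0])
        assert np.array_equal(t1.cells[k][1], t2.cells[k][1])
    t1.write(tmp_path / "tab.tsv")
    t3 = ContactFrequencyTable.read(tmp_path / "tab.tsv")
    assert t3.floor == t1.floor
    for k in t1.cells:
        assert np.allclose(t1.cells[k][0], t3.cells[k][0])
    with pytest.raises(PredictorError):
        build_table([])


def test_zero_contact_table_falls_to_smoothing_floor():
    """With no contacts every frequency equals the shrinkage prior level."""
    ann = ChainAnnotation(key="t_A", sequence="AGAGAGAGAG" * 4, contacts=[])
    table = build_table([ann], floor=50)
    fv = table.frequency_vector("AG")
    assert (fv > 0).all()
    assert fv.max() < 0.05  # prior stays near the (empty) marginal, not 0.5


def test_homopolymer_context_equals_single_entry():
    """In a poly-G context the expectation is the single table frequency."""
    seq = "G" * 81
    ann = ChainAnnotation(key="t_A", sequence=seq, contacts=[])
    table = build_table([ann])
    mid = 40
    raw = context_expectation(seq, (mid, mid + 1), "GG", table)
    f_short_bb = table.frequency("GG", "G", "short", "backbone")
    f_long_bb = table.frequency("GG", "G", "long", "backbone")
    assert raw[CHANNELS.index("short_bb")] == pytest.approx(f_short_bb)
    assert raw[CHANNELS.index("long_bb")] == pytest.approx(f_long_bb)


def test_context_window_truncates_at_termini():
    """Near the N-terminus only the available context is averaged."""
    seq = "F" + "G" * 100
    table = ContactFrequencyTable(floor=1)
    c, o = table._get("F")
    gidx = "ACDEFGHIKLMNPQRSTVWY".index("G")
    o[gidx, :, :] = 100.0
    c[gidx, 0, :] = 10.0   # short freq ~ (10+k*prior)/(100+k)
    c[gidx, 1, :] = 2.0
    raw_edge = context_expectation(seq, (0,), "F", table)
    raw_mid = context_expectation("G" * 50 + "F" + "G" * 50, (50,), "F", table)
    # same homogeneous context values regardless of truncation
    assert np.allclose(raw_edge, raw_mid)


def test_context_expectation_matches_hand_average():
    """Tiny window with two residue types averages the two table entries."""
    seq = "FGA"
    table = ContactFrequencyTable(floor=2)
    for aa, val in (("G", 0.2), ("A", 0.4)):
        c, o = table._get("F")
        idx = "ACDEFGHIKLMNPQRSTVWY".index(aa)
        o[idx, :, :] = 1000.0
        c[idx, :, :] = val * 1000.0
    raw = context_expectation(seq, (0,), "F", table)
    fG = table.frequency("F", "G", "short", "sidechain")
    fA = table.frequency("F", "A", "short", "sidechain")
    assert raw[CHANNELS.index("short_sc")] == pytest.approx((fG + fA) / 2)


def test_calibration_monotone_and_centered(fitted_predictor):
    table, cal, train, test = fitted_predictor
    # monotone: higher raw never yields a lower prediction
    for key, iso in list(cal.pooled.items())[:4]:
        xs = np.linspace(0, 0.02, 50)
        ys = iso.predict(xs)
        assert (np.diff(ys) >= -1e-12).all()
    # relative channel roughly centers at zero over training groups
    rel_sum, n = 0.0, 0
    for ann in train[:20]:
        prof = predict_profile(ann.sequence, table, cal)
        rel_sum += prof[[f"rel_{c}" for c in CHANNELS]].to_numpy().sum()
        n += len(prof) * 4
    assert abs(rel_sum / n) < 5e-4


def test_profile_contents_and_determinism(fitted_predictor):
    table, cal, train, test = fitted_predictor
    seq = "AVLIAVLIAVLI"  # no sp2 sidechains
    prof = predict_profile(seq, table, cal)
    assert (prof["category"] == "backbone").all()
    prof2 = predict_profile(seq, table, cal)
    assert prof.equals(prof2)
    assert ((prof[[f"abs_{c}" for c in CHANNELS]] >= 0).all().all())
    assert ((prof[[f"abs_{c}" for c in CHANNELS]] <= 1).all().all())
    with pytest.raises(PredictorError):
        predict_profile("A", table, cal)


def test_heldout_reliability_slope(fitted_predictor):
    """Percentile-binned predicted vs realized total frequency tracks 1:1."""
    table, cal, train, test = fitted_predictor
    preds, obs = [], []
    for ann in test:
        prefix = _one_hot_prefix(ann.sequence)
        for ident, cat, anchor, positions, freqs in _realized_channel_freqs(ann):
            raw = context_expectation(ann.sequence, positions, ident, table,
                                      prefix)
            preds.append(sum(cal.predict(ident, k, raw[k]) for k in range(4)))
            obs.append(freqs.sum())
    preds = np.array(preds); obs = np.array(obs)
    order = np.argsort(preds, kind="stable")
    edges = np.linspace(0, len(preds), 21).astype(int)
    bx = np.array([preds[order[a:b]].mean() for a, b in zip(edges, edges[1:])])
    by = np.array([obs[order[a:b]].mean() for a, b in zip(edges, edges[1:])])
    slope = np.polyfit(bx, by, 1)[0]
    assert 0.8 <= slope <= 1.2


def test_flexible_context_raises_backbone_long_prediction(fitted_predictor):
    """Gly/Ser/Thr/Pro-rich contexts predict more long-range backbone contacts."""
    table, cal, _, _ = fitted_predictor
    flexible = "GSPTGSPTGS" * 10
    rigid = "LILVLILVLI" * 10
    pf = predict_profile(flexible, table, cal)
    pr = predict_profile(rigid, table, cal)
    assert pf["abs_long_bb"].mean() > pr["abs_long_bb"].mean()


def test_split_chains_partition(survey_corpus):
    annotations, _ = survey_corpus
    tr, te = split_chains(annotations, holdout_fraction=0.2, seed=0)
    assert len(tr) + len(te) == len(annotations)
    assert {a.key for a in tr}.isdisjoint({a.key for a in te})
    tr2, te2 = split_chains(annotations, holdout_fraction=0.2, seed=0)
    assert [a.key for a in te] == [a.key for a in te2]


def test_group_iteration_skips_nonstandard():
    groups = list(iter_sequence_groups("FXG"))
    idents = [g[0] for g in groups]
    assert "F" in idents          # sidechain at 0
    assert all(len(i) == 1 or "X" not in i for i in idents)
    assert not any(cat == "backbone" and "X" in ident
                   for ident, cat, _, _ in groups)
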