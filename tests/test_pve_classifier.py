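"""Intensity categories, window labeling rules, and the cascade network."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import colonseg as cs
from colonseg.pve_classifier import (
    CascadeNet,
    Category,
    NotTrainedError,
    build_training_set,
    categorize,
    detect_pve,
    extract_fluid,
    extract_windows,
    label_window,
    pixel_class,
    rule_targets,
    sigmoid,
    train,
    window_features,
)

A, PM, M, HI = Category.A, Category.PM, Category.M, Category.HI


def test_sigmoid_closed_forms():
    assert sigmoid(0.0) == 0.5
    assert sigmoid(np.log(3.0)) == pytest.approx(0.75)


@given(st.floats(-30, 30))
def test_sigmoid_symmetry_and_range(x):
    assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)
    assert 0.0 < sigmoid(x) < 1.0


def test_sigmoid_saturates():
    assert sigmoid(500.0) == pytest.approx(1.0)
    assert sigmoid(-500.0) == pytest.approx(0.0, abs=1e-200)


def test_sigmoid_monotone():
    xs = np.linspace(-20, 20, 201)
    assert (np.diff(sigmoid(xs)) > 0).all()


@pytest.mark.parametrize(
    "value,expected",
    [
        (5000, {A}),
        (40000, {M, PM}),
        (60000, {HI}),
        (64000, {HI}),      # bone saturating past the printed HI top
        (10000, {M}),
        (29999, {M}),
        (30000, {M, PM}),
    ],
)
def test_categorize_returns_all_containing_ranges(value, expected):
    assert categorize(value) == expected


def test_categorize_rejects_out_of_range():
    with pytest.raises(ValueError):
        categorize(70000)


def test_pixel_class_partitions_the_scale():
    v = np.array([0, 9999, 10000, 29999, 30000, 54999, 55000, 65535])
    assert pixel_class(v).tolist() == [0, 0, 1, 1, 2, 2, 3, 3]


@pytest.mark.parametrize(
    "present,expected",
    [
        ({A}, True),
        ({A, PM}, True),
        ({A, PM, HI}, True),
        ({M}, False),
        ({A, M}, False),
        ({HI}, False),
        ({PM}, False),
        ({A, HI}, False),        # not an enumerated active pattern
        ({A, PM, M, HI}, False),
        (set(), False),
    ],
)
def test_window_labeling_rules(present, expected):
    assert label_window(present) is expected


def test_window_labeling_prose_variant_switch():
    assert label_window({A, PM}, pm_with_air_active=False) is False
    assert label_window({A, PM, HI}, pm_with_air_active=False) is True


def test_rule_targets_match_label_window_on_all_combinations():
    combos = [(a, m, pm, hi) for a in (0, 1) for m in (0, 1) for pm in (0, 1) for hi in (0, 1)]
    presence = np.array(combos, dtype=bool)
    vec = rule_targets(presence)
    for row, got in zip(combos, vec):
        present = {c for c, flag in zip((A, M, PM, HI), row) if flag}
        assert bool(got) == label_window(present)


def test_uniform_air_tile_indicators():
    sl = np.full((8, 8), 5000, dtype=np.uint16)
    _, X, presence = window_features(sl, 8)
    assert presence.tolist() == [[True, False, False, False]]
    assert X[0, :4].tolist() == [1.0, 0.0, 0.0, 0.0]


def test_mixed_tile_indicators_use_disjoint_pixel_classes():
    sl = np.full((8, 8), 5000, dtype=np.uint16)
    sl[0, 1], sl[0, 2] = 40000, 60000
    _, _, presence = window_features(sl, 8)
    # 40000 is P/M evidence, not muscle-only evidence
    assert presence.tolist() == [[True, False, True, True]]


def test_full_slice_yields_4096_samples():
    sl = np.zeros((512, 512), dtype=np.uint16)
    samples = extract_windows(sl, 8)
    assert len(samples) == 4096


def test_window_larger_than_slice_is_an_error():
    with pytest.raises(ValueError):
        window_features(np.zeros((16, 16), dtype=np.uint16), 32)


def test_training_set_size_and_all_muscle_targets():
    vol = cs.CTVolume(np.full((7, 512, 512), 20000, dtype=np.uint16))
    samples = build_training_set(vol, window=8)
    assert len(samples) == 7 * 4096
    assert all(s.target == 0 for s in samples)


def test_training_set_truth_override():
    data = np.full((1, 16, 16), 20000, dtype=np.uint16)
    vol = cs.CTVolume(data)
    truth = np.zeros((1, 16, 16), bool)
    truth[0, :8, :8] = True
    samples = build_training_set(vol, window=8, truth=truth)
    assert [s.target for s in samples] == [1, 0, 0, 0]


def test_zero_network_outputs_one_half():
    net = CascadeNet(
        w_in_hidden=np.zeros((64, 10)),
        b_hidden=np.zeros(64),
        w_hidden_out=np.zeros(64),
        w_in_out=np.zeros(10),
        b_out=0.0,
    )
    out = net.forward(np.random.default_rng(0).random((5, 10)))
    assert np.allclose(out, 0.5)


def test_training_solves_separable_toy_problem():
    rng = np.random.default_rng(0)
    X = rng.random((400, 2))
    X = X[np.abs(X[:, 0] - X[:, 1]) > 0.05][:200]  # separable with a margin
    y = (X[:, 0] > X[:, 1]).astype(int)
    samples = [cs.PatternSample(x, t) for x, t in zip(X, y)]
    cfg = cs.TrainConfig(max_epochs=2000, error_tolerance=5e-3, n_hidden=16, seed=1)
    net, report = train(None, samples, cfg)
    assert report.final_mse < 5e-3
    assert (((net.forward(X) >= 0.5).astype(int)) == y).all()
    assert report.regression_r > 0.95


def test_training_is_deterministic():
    rng = np.random.default_rng(2)
    X = rng.random((50, 3))
    y = (X.sum(axis=1) > 1.5).astype(int)
    samples = [cs.PatternSample(x, t) for x, t in zip(X, y)]
    cfg = cs.TrainConfig(max_epochs=50, n_hidden=8, seed=7)
    n1, r1 = train(None, samples, cfg)
    n2, r2 = train(None, samples, cfg)
    assert np.array_equal(n1.w_in_hidden, n2.w_in_hidden)
    assert np.array_equal(n1.w_hidden_out, n2.w_hidden_out)
    assert r1.mse_history == r2.mse_history


def test_untrained_network_refuses_inference():
    net = CascadeNet.init(seed=0)
    with pytest.raises(NotTrainedError):
        detect_pve(np.zeros((16, 16), dtype=np.uint16), net)


def test_model_json_round_trip(tmp_path):
    net = CascadeNet.init(seed=5)
    net.trained = True
    net.to_json(tmp_path / "net.json")
    back = CascadeNet.from_json(tmp_path / "net.json")
    assert np.array_equal(net.w_in_hidden, back.w_in_hidden)
    assert np.array_equal(net.w_in_out, back.w_in_out)
    assert back.trained


def test_rule_trained_network_reproduces_rules_on_holdout(rule_net, rule_training):
    """The labeling rules are deterministic, so the network should
    approximate them almost perfectly on held-out tiles."""
    net, _ = rule_net
    _, holdout = rule_training
    X = np.array([s.features for s in holdout])
    y = np.array([s.target for s in holdout])
    acc = ((net.forward(X) >= 0.5) == y).mean()
    assert acc >= 0.95


def test_detect_pve_on_all_muscle_slice_is_empty(rule_net):
    net, _ = rule_net
    sl = np.full((64, 64), 20000, dtype=np.uint16)
    assert not detect_pve(sl, net).any()


def test_detect_pve_deterministic(rule_net, small_phantom):
    net, _ = rule_net
    _, volume, _ = small_phantom
    a = detect_pve(volume.data[0], net)
    b = detect_pve(volume.data[0], net)
    assert np.array_equal(a, b)


def test_detection_covers_active_anatomy(pipeline_run):
    """D0 covers nearly all colon air, fluid and boundary-band truth."""
    _, gt, states, _ = pipeline_run
    num = den = 0
    for s, t in zip(states, gt.colon_mask | gt.fluid_mask | gt.pve_mask):
        num += (s.D0 & t).sum()
        den += t.sum()
    assert num / den >= 0.90


def _layered_slice():
    """Air over a 3-row P/M band over a fluid pool, plus a distant bone blob."""
    sl = np.full((64, 64), 20000, dtype=np.uint16)
    sl[8:20, 8:40] = 4000          # air
    sl[20:23, 8:40] = 40000        # boundary band
    sl[23:32, 8:40] = 60000        # fluid pool
    sl[48:60, 48:60] = 60000       # bone, not under any air/P-M layering
    return sl


def test_extract_fluid_takes_pool_and_band_not_bone():
    sl = _layered_slice()
    out = extract_fluid(sl, np.ones_like(sl, dtype=bool), 8)
    assert out[23:32, 8:40].all()
    assert out[20:23, 8:40].all()
    assert not out[48:60, 48:60].any()
    assert not out[8:20, 8:40].any()


def test_extract_fluid_insensitive_to_window_alignment():
    base = _layered_slice()
    for shift in range(0, 8):
        sl = np.roll(base, shift, axis=0)
        out = extract_fluid(sl, np.ones_like(sl, dtype=bool), 8)
        assert out[23 + shift:32 + shift, 8:40].all()


def test_extract_fluid_empty_without_high_intensity():
    sl = np.full((32, 32), 4000, dtype=np.uint16)
    assert not extract_fluid(sl, np.ones_like(sl, dtype=bool), 8).any()
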