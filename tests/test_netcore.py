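"""Engine contracts: kWTA, settling, CHL updates, readout metrics."""

import numpy as np
import pytest

from hippoctx.netcore import (
    LayerSpec,
    LearningConfig,
    NetworkSpec,
    PhasePair,
    ProjectionSpec,
    SettleConfig,
    binarize,
    chl_update,
    init_network,
    kwta_threshold,
    kwta_winners,
    net_input,
    output_error,
    settle,
)


def two_layer_spec(n_in=8, n_out=6, rel=1.0, frac_out=0.5, bidirectional=False):
    return NetworkSpec(
        name="toy",
        layers=(
            LayerSpec("IN", n_in, 0.5, clampable=True),
            LayerSpec("OUT", n_out, frac_out, clampable=True),
        ),
        projections=(ProjectionSpec("IN", "OUT", rel, bidirectional=bidirectional),),
    )


class TestKwta:
    def test_midpoint_threshold(self):
        thr = kwta_threshold(np.array([0.9, 0.5, 0.1, 0.0]), 2)
        assert thr == pytest.approx(0.3, abs=1e-6)
        winners = kwta_winners(np.array([0.9, 0.5, 0.1, 0.0]), 2)
        assert list(np.flatnonzero(winners)) == [0, 1]

    def test_boundaries(self):
        d = np.array([0.2, 0.4, 0.1])
        assert not kwta_winners(d, 0).any()
        assert kwta_winners(d, 3).all()
        assert kwta_threshold(d, 0) > d.max()
        assert kwta_threshold(d, 3) < d.min()

    def test_ties_break_to_lowest_index(self):
        winners = kwta_winners(np.ones(5), 2)
        assert list(np.flatnonzero(winners)) == [0, 1]

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kwta_threshold(np.zeros(4), 5)

    @pytest.mark.parametrize("k", [1, 3, 7, 15])
    def test_exactly_k_winners_on_random_drives(self, k, rng):
        for _ in range(50):
            d = rng.normal(size=16)
            assert kwta_winners(d, k).sum() == k


class TestNetInput:
    def test_zero_senders_zero_drive(self, rng):
        state = init_network(two_layer_spec(), rng)
        assert np.allclose(net_input(state, "OUT"), 0.0)

    def test_linearity_in_rel_weight(self, rng):
        seed_state = np.random.default_rng(0)
        s1 = init_network(two_layer_spec(rel=1.0), np.random.default_rng(0))
        s2 = init_network(two_layer_spec(rel=2.0), np.random.default_rng(0))
        acts = {"IN": np.array([1.0, 1, 0, 0, 1, 0, 1, 0]), "OUT": np.zeros(6)}
        assert np.allclose(net_input(s2, "OUT", acts), 2 * net_input(s1, "OUT", acts))

    def test_mossy_style_ratio(self, rng):
        # two source layers with identical statistics; rel_weights 10 and 1
        spec = NetworkSpec(
            name="ratio",
            layers=(
                LayerSpec("A", 8, 0.5, clampable=True),
                LayerSpec("B", 8, 0.5, clampable=True),
                LayerSpec("OUT", 6, 0.5),
            ),
            projections=(
                ProjectionSpec("A", "OUT", 10.0),
                ProjectionSpec("B", "OUT", 1.0),
            ),
        )
        state = init_network(spec, np.random.default_rng(0))
        # give both projections the same weight table and the same senders
        state.weights[("B", "OUT")][...] = state.weights[("A", "OUT")]
        acts = {"A": np.ones(8), "B": np.zeros(8), "OUT": np.zeros(6)}
        a_only = net_input(state, "OUT", acts)
        acts = {"A": np.zeros(8), "B": np.ones(8), "OUT": np.zeros(6)}
        b_only = net_input(state, "OUT", acts)
        assert np.allclose(a_only, 10 * b_only)


class TestInitNetwork:
    def test_weight_range_and_determinism(self):
        spec = two_layer_spec(bidirectional=True)
        s1 = init_network(spec, np.random.default_rng(42))
        s2 = init_network(spec, np.random.default_rng(42))
        assert set(s1.weights) == {("IN", "OUT"), ("OUT", "IN")}
        for key, w in s1.weights.items():
            assert w.min() >= 0.25 and w.max() <= 0.75
            assert np.array_equal(w, s2.weights[key])
        # reciprocal tables are independent draws
        assert not np.array_equal(s1.weights[("IN", "OUT")].T, s1.weights[("OUT", "IN")])

    def test_dangling_projection_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(
                name="bad",
                layers=(LayerSpec("A", 4, 0.5),),
                projections=(ProjectionSpec("A", "GHOST"),),
            )


class TestSettle:
    def test_clamped_layer_is_fixed(self, rng):
        state = init_network(two_layer_spec(), rng)
        pattern = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=np.uint8)
        res = settle(state, {"IN": pattern}, SettleConfig(max_cycles=5))
        assert np.array_equal(res.activations["IN"], pattern.astype(float))

    def test_zero_input_activity_at_most_half(self, rng):
        state = init_network(two_layer_spec(), rng)
        res = settle(state, {"IN": np.zeros(8, dtype=np.uint8)}, SettleConfig())
        out = res.activations["OUT"]
        assert np.all(out <= 0.5 + 1e-9)
        assert (out > 0).sum() <= 3  # only the k winners are ever nonzero

    def test_sparse_layer_has_exactly_k_winners(self, rng):
        # 800-unit layer at 1.5% activity: exactly 12 units win each cycle
        spec = NetworkSpec(
            name="dg",
            layers=(
                LayerSpec("IN", 64, 0.25, clampable=True),
                LayerSpec("DG", 800, 0.015),
            ),
            projections=(ProjectionSpec("IN", "DG"),),
        )
        assert spec.layer("DG").k_active == 12
        state = init_network(spec, rng)
        pattern = np.zeros(64, dtype=np.uint8)
        pattern[:16] = 1
        res = settle(state, {"IN": pattern}, SettleConfig(step_size=1.0))
        drive = net_input(state, "DG", res.activations)
        assert kwta_winners(drive, 12).sum() == 12
        assert (res.activations["DG"] > 0).sum() == 12

    def test_rel_weight_scale_leaves_winners_unchanged(self):
        # doubling the multiplier on a single-projection path rescales drives
        # without reordering them, so the winner set is identical
        base = init_network(two_layer_spec(rel=1.0, frac_out=0.5), np.random.default_rng(9))
        doubled = init_network(two_layer_spec(rel=2.0, frac_out=0.5), np.random.default_rng(9))
        pattern = np.array([1, 1, 0, 0, 1, 0, 0, 1], dtype=np.uint8)
        r1 = settle(base, {"IN": pattern}, SettleConfig())
        r2 = settle(doubled, {"IN": pattern}, SettleConfig())
        assert np.array_equal(r1.activations["OUT"] > 0, r2.activations["OUT"] > 0)


class TestChlUpdate:
    def make_phases(self, spec, minus, plus):
        zeros = {l.name: np.zeros(l.size) for l in spec.layers}
        m, p = dict(zeros), dict(zeros)
        m.update(minus)
        p.update(plus)
        return PhasePair(minus=m, plus=p)

    def test_fixed_point_when_phases_agree(self, rng):
        spec = two_layer_spec()
        state = init_network(spec, rng)
        before = {k: w.copy() for k, w in state.weights.items()}
        acts = {"IN": rng.random(8), "OUT": rng.random(6)}
        phases = self.make_phases(spec, acts, acts)
        chl_update(state, phases, LearningConfig(learning_rate=0.1, hebbian_mix=0.0))
        for k in before:
            assert np.allclose(state.weights[k], before[k])

    def test_potentiation_from_zero_weight(self):
        spec = two_layer_spec(n_in=1, n_out=1)
        state = init_network(spec, np.random.default_rng(0))
        state.weights[("IN", "OUT")][...] = 0.0
        phases = self.make_phases(
            spec, {"IN": np.zeros(1), "OUT": np.zeros(1)}, {"IN": np.ones(1), "OUT": np.ones(1)}
        )
        chl_update(state, phases, LearningConfig(learning_rate=0.1, hebbian_mix=0.0))
        assert state.weights[("IN", "OUT")][0, 0] == pytest.approx(0.1)

    def test_depression_from_saturated_weight(self):
        spec = two_layer_spec(n_in=1, n_out=1)
        state = init_network(spec, np.random.default_rng(0))
        state.weights[("IN", "OUT")][...] = 1.0
        phases = self.make_phases(
            spec, {"IN": np.ones(1), "OUT": np.ones(1)}, {"IN": np.zeros(1), "OUT": np.zeros(1)}
        )
        chl_update(state, phases, LearningConfig(learning_rate=0.1, hebbian_mix=0.0))
        assert state.weights[("IN", "OUT")][0, 0] == pytest.approx(0.9)

    def test_weights_bounded_under_long_training(self, rng):
        # 10^4 random updates never push a weight out of [0, 1]
        spec = two_layer_spec(bidirectional=True)
        state = init_network(spec, rng)
        cfg = LearningConfig(learning_rate=0.5, hebbian_mix=0.05)
        for _ in range(10_000):
            phases = self.make_phases(
                spec,
                {"IN": rng.random(8), "OUT": rng.random(6)},
                {"IN": rng.random(8), "OUT": rng.random(6)},
            )
            chl_update(state, phases, cfg)
        for w in state.weights.values():
            assert w.min() >= 0.0 and w.max() <= 1.0


class TestReadout:
    def test_binarize_recovers_binary_target(self):
        target = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        assert np.array_equal(binarize(target.astype(float), 3), target)

    def test_binarize_boundaries_and_ties(self):
        assert binarize(np.array([0.2, 0.9, 0.9, 0.1]), 0).sum() == 0
        assert list(np.flatnonzero(binarize(np.array([0.2, 0.9, 0.9, 0.1]), 2))) == [1, 2]

    def test_output_error_extremes(self):
        target = np.array([1, 1, 0, 0], dtype=np.uint8)
        assert output_error(np.array([0.9, 0.8, 0.1, 0.0]), target) == 0.0
        assert output_error(np.array([0.0, 0.1, 0.8, 0.9]), target) == 1.0

    def test_output_error_partial_miss(self):
        target = np.zeros(64, dtype=np.uint8)
        target[:16] = 1
        acts = np.zeros(64)
        acts[:12] = 1.0   # recover 12 of 16
        acts[40:44] = 0.9  # 4 winners land off-target
        assert output_error(acts, target) == pytest.approx(0.25)

    def test_zero_active_target_rejected(self):
        with pytest.raises(ValueError):
            output_error(np.zeros(4), np.zeros(4, dtype=np.uint8))

    def test_sse_metric_variant(self):
        target = np.array([1, 0, 0, 0], dtype=np.uint8)
        acts = np.array([0.5, 0.5, 0.0, 0.0])
        assert output_error(acts, target, metric="sse") == pytest.approx(0.125)
        with pytest.raises(ValueError):
            output_error(acts, target, metric="nope")


class TestSparseConnectivity:
    def test_masked_synapses_stay_zero_through_learning(self, rng):
        spec = NetworkSpec(
            name="sparse",
            layers=(
                LayerSpec("IN", 20, 0.5, clampable=True),
                LayerSpec("OUT", 10, 0.5, clampable=True),
            ),
            projections=(ProjectionSpec("IN", "OUT", connectivity=0.3),),
        )
        state = init_network(spec, rng)
        mask = state.masks[("IN", "OUT")]
        assert 0 < mask.sum() < mask.size
        assert np.all(state.weights[("IN", "OUT")][~mask] == 0.0)
        zeros = {"IN": np.zeros(20), "OUT": np.zeros(10)}
        ones = {"IN": np.ones(20), "OUT": np.ones(10)}
        chl_update(state, PhasePair(minus=zeros, plus=ones), LearningConfig(learning_rate=0.5))
        w = state.weights[("IN", "OUT")]
        assert np.all(w[~mask] == 0.0)
        assert np.all(w[mask] > 0.0)
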