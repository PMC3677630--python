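"""Generator and corruption-operator contracts for the synthetic world."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippoctx.patterns import (
    BinaryPattern,
    CorruptionMode,
    CorruptionSpec,
    Role,
    build_association_set,
    build_test_battery,
    corrupt,
    generate_pattern,
    make_targets,
)


class TestGeneratePattern:
    @pytest.mark.parametrize("n_active", [16, 0, 64])
    def test_exact_active_count(self, n_active, rng):
        p = generate_pattern(64, n_active, rng)
        assert p.n_units == 64
        assert p.n_active == n_active

    def test_rejects_overfull(self, rng):
        with pytest.raises(ValueError):
            generate_pattern(64, 65, rng)

    def test_deterministic_under_seed(self):
        a = generate_pattern(64, 16, np.random.default_rng(3))
        b = generate_pattern(64, 16, np.random.default_rng(3))
        assert np.array_equal(a.values, b.values)


class TestAssociationSet:
    def test_default_world_counts(self, assoc):
        assert len(assoc.objects) == 120
        assert len(assoc.contexts) == 40
        for cid in range(40):
            assert len(assoc.objects_of_context(cid)) == 3
        assert all(p.n_active == 16 for p in assoc.objects + assoc.contexts)

    def test_all_patterns_distinct(self, assoc):
        # brute-force pairwise check over all 160 patterns
        everyone = [p.values.tobytes() for p in assoc.objects + assoc.contexts]
        assert len(set(everyone)) == len(everyone)

    def test_degenerate_single_context(self, rng):
        world = build_association_set(1, 3, 64, 16, rng)
        assert len(world.objects) == 3
        assert set(world.context_of.values()) == {0}

    def test_infeasible_uniqueness_rejected(self, rng):
        # only C(4,2)=6 distinct patterns exist; 3*2+2=8 are needed
        with pytest.raises(ValueError):
            build_association_set(2, 3, 4, 2, rng)


class TestMakeTargets:
    def test_matched_trial_contexts_agree(self, assoc):
        cid = assoc.context_of[5]
        bundle = make_targets(5, cid, assoc)
        assert bundle.OBCG == bundle.C
        assert bundle.O == assoc.object_by_id(5)

    def test_mismatch_splits_context_targets(self, assoc):
        trained = assoc.context_of[5]
        other = (trained + 1) % len(assoc.contexts)
        bundle = make_targets(5, other, assoc)
        assert bundle.OBCG == assoc.context_by_id(trained)
        assert bundle.C == assoc.context_by_id(other)
        # CBOG concatenates the PRESENTED context's objects, ascending ids
        slots = assoc.objects_of_context(other)
        assert bundle.cbog_slot_ids == tuple(o.id for o in slots)
        assert np.array_equal(
            bundle.CBOG, np.concatenate([o.values for o in slots])
        )

    def test_cbog_geometry(self, assoc):
        bundle = make_targets(0, assoc.context_of[0], assoc)
        assert bundle.CBOG.size == 192
        assert int(bundle.CBOG.sum()) == 48

    def test_unknown_id_raises(self, assoc):
        with pytest.raises(KeyError):
            make_targets(10_000, 0, assoc)


class TestCorrupt:
    @pytest.fixture
    def p16(self, rng):
        return generate_pattern(64, 16, rng)

    def test_additive_grows_active_count(self, p16, rng):
        out = corrupt(p16, CorruptionSpec(CorruptionMode.ADDITIVE, 0.30), rng)
        assert out.n_active == 21  # 16 + round(0.3 * 16)
        assert np.all(out.values >= p16.values)

    def test_partial_level_is_completeness(self, p16, rng):
        out = corrupt(p16, CorruptionSpec(CorruptionMode.PARTIAL, 0.40), rng)
        assert out.n_active == 6  # round(0.4 * 16) ones retained
        assert np.all(out.values <= p16.values)

    def test_nonadditive_preserves_count(self, p16, rng):
        out = corrupt(p16, CorruptionSpec(CorruptionMode.NONADDITIVE, 0.30), rng)
        assert out.n_active == 16
        assert int(np.sum(out.values != p16.values)) == 10  # 5 flips each way

    @pytest.mark.parametrize(
        "mode", [CorruptionMode.ADDITIVE, CorruptionMode.NONADDITIVE, CorruptionMode.MIXED]
    )
    def test_level_zero_noise_is_identity(self, mode, p16, rng):
        out = corrupt(p16, CorruptionSpec(mode, 0.0), rng)
        assert np.array_equal(out.values, p16.values)

    def test_full_completeness_is_identity(self, p16, rng):
        out = corrupt(p16, CorruptionSpec(CorruptionMode.PARTIAL, 1.0), rng)
        assert np.array_equal(out.values, p16.values)

    def test_infeasible_additive_rejected(self, rng):
        crowded = generate_pattern(16, 14, rng)
        with pytest.raises(ValueError):
            corrupt(crowded, CorruptionSpec(CorruptionMode.ADDITIVE, 0.5), rng)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(level=st.floats(min_value=0.0, max_value=1.0), seed=st.integers(0, 2**20))
    def test_count_contracts_over_levels(self, level, seed):
        rng = np.random.default_rng(seed)
        p = generate_pattern(64, 16, rng)
        n = CorruptionSpec(CorruptionMode.ADDITIVE, level).n_change(p)
        add = corrupt(p, CorruptionSpec(CorruptionMode.ADDITIVE, level), rng)
        assert add.n_active == 16 + n
        non = corrupt(p, CorruptionSpec(CorruptionMode.NONADDITIVE, level), rng)
        assert non.n_active == 16
        assert int(np.sum(non.values != p.values)) == 2 * n
        part = corrupt(p, CorruptionSpec(CorruptionMode.PARTIAL, level), rng)
        assert part.n_active == n
        mix = corrupt(p, CorruptionSpec(CorruptionMode.MIXED, level), rng)
        assert mix.n_active == 16 + (n - n // 2)  # additive half gets the odd unit
        assert int(np.sum(mix.values != p.values)) == n + n // 2

    def test_total_units_basis(self, p16, rng):
        spec = CorruptionSpec(CorruptionMode.ADDITIVE, 0.25, basis="total_units")
        out = corrupt(p16, spec, rng)
        assert out.n_active == 16 + 16  # round(0.25 * 64) added


class TestBatteries:
    def test_mismatch_is_a_derangement(self, assoc, rng):
        trials = build_test_battery(assoc, "mismatch", rng=rng)
        assert len(trials) == 120
        for t in trials:
            oid = t.targets.O.id
            assert t.mec_input.id != assoc.context_of[oid]
            assert t.targets.OBCG.id == assoc.context_of[oid]
            assert t.targets.C.id == t.mec_input.id

    def test_full_completeness_battery_is_clean(self, assoc, rng):
        trials = build_test_battery(assoc, "partial_context", levels=[1.0], rng=rng)
        for t in trials:
            assert np.array_equal(t.mec_input.values, t.targets.C.values)
            assert np.array_equal(t.lec_input.values, t.targets.O.values)

    def test_context_only_clamps_lec_to_zero(self, assoc, rng):
        trials = build_test_battery(assoc, "cbog_context_only", rng=rng)
        assert len(trials) == 120
        assert all(t.lec_input.n_active == 0 for t in trials)
        assert all(t.mec_input == t.targets.C for t in trials)

    def test_sample_o_c_structure(self, assoc, rng):
        trials = build_test_battery(assoc, "sample_O_C", rng=rng)
        noise = [t for t in trials if t.tags["subtest"] == "noise"]
        partial = [t for t in trials if t.tags["subtest"] == "partial"]
        assert len(noise) == len(partial) == 120
        # mixed 15% noise: round(0.15*16)=2 changes -> 1 added + 1 swapped
        assert all(t.lec_input.n_active == 17 for t in noise)
        assert all(t.mec_input.n_active == 17 for t in noise)
        # 40% complete on both inputs
        assert all(t.lec_input.n_active == 6 for t in partial)
        assert all(t.mec_input.n_active == 6 for t in partial)

    def test_unknown_battery_rejected(self, assoc, rng):
        with pytest.raises(ValueError):
            build_test_battery(assoc, "nope", rng=rng)

    def test_batteries_deterministic_under_seed(self, assoc):
        def snapshot(seed):
            trials = build_test_battery(
                assoc, "additive_object", levels=[0.2], rng=np.random.default_rng(seed)
            )
            return [t.lec_input.values.tobytes() for t in trials]

        assert snapshot(5) == snapshot(5)
        assert snapshot(5) != snapshot(6)
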