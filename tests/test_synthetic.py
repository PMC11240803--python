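import pytest

from broilerseq import (
    CONDITION_LABELS,
    CapacityError,
    ConditionPreset,
    EnvironmentViolationError,
    InvalidPresetError,
    Pattern,
    SimConfig,
    bouts_to_windows,
    build_database,
    default_presets,
    load_presets_yaml,
    mine,
    plant_pattern,
    simulate_flock,
    support,
    write_presets_yaml,
)

PRESETS = default_presets()

# reduced grid: short windows keep bout streams small and mining fast
SMALL = dict(n_broilers=4, n_windows=3, window_s=60.0)


def small_config(label, seed=0, **kwargs):
    return SimConfig(PRESETS[label], seed=seed, **{**SMALL, **kwargs})


class TestPresets:
    def test_four_named_presets(self):
        assert set(PRESETS) == set(CONDITION_LABELS)

    def test_explore_allowed_only_when_enriched(self):
        for label, preset in PRESETS.items():
            assert ("Ex" in preset.allowed_codes) == label.endswith("enriched")

    def test_heat_reduces_activity_scale(self):
        assert PRESETS["heat_plain"].activity_scale < PRESETS["thermoneutral_plain"].activity_scale

    def test_lying_laterally_reachable_only_under_heat(self):
        for label, preset in PRESETS.items():
            into_ll = sum(row.get("Ll", 0.0) for row in preset.transition_weights.values())
            assert (into_ll > 0) == label.startswith("heat")

    def test_stretch_to_lateral_motif_elevated_without_enrichment(self):
        plain = PRESETS["heat_plain"].transition_weights["St"]["Ll"]
        enriched = PRESETS["heat_enriched"].transition_weights["St"]["Ll"]
        assert plain > enriched

    def test_self_transitions_are_zero(self):
        for preset in PRESETS.values():
            for src, row in preset.transition_weights.items():
                assert row.get(src, 0.0) == 0.0

    def test_unnormalizable_row_rejected(self):
        preset = PRESETS["thermoneutral_plain"]
        broken = ConditionPreset(
            label=preset.label,
            transition_weights={**dict(preset.transition_weights), "Ld": {}},
            dwell_mean_s=preset.dwell_mean_s,
            activity_scale=preset.activity_scale,
            allowed_codes=preset.allowed_codes,
        )
        with pytest.raises(InvalidPresetError):
            simulate_flock(SimConfig(broken, **SMALL))

    def test_yaml_registry_roundtrip(self, tmp_path):
        path = tmp_path / "presets.yaml"
        write_presets_yaml(PRESETS, path)
        loaded = load_presets_yaml(path)
        assert set(loaded) == set(PRESETS)
        again = loaded["heat_plain"]
        assert again.activity_scale == PRESETS["heat_plain"].activity_scale
        assert again.transition_weights == {
            s: dict(r) for s, r in PRESETS["heat_plain"].transition_weights.items()
        }


class TestSimulateFlock:
    def test_seeded_determinism(self):
        config = small_config("thermoneutral_enriched", seed=5)
        assert simulate_flock(config) == simulate_flock(config)

    def test_environment_closure_over_many_seeds(self):
        """Non-enriched presets never emit the enriched-only behavior."""
        for label in ("thermoneutral_plain", "heat_plain"):
            for seed in range(50):
                bouts = simulate_flock(
                    SimConfig(PRESETS[label], n_broilers=1, n_windows=1, window_s=60.0, seed=seed)
                )
                assert all(b.behavior != "Ex" for b in bouts)

    def test_bout_legality_except_final_truncations(self):
        config = small_config("heat_enriched", seed=9)
        bouts = simulate_flock(config)
        last_per_window = {}
        for b in bouts:
            last_per_window[(b.broiler_id, b.window_index)] = b
        for b in bouts:
            if last_per_window[(b.broiler_id, b.window_index)] is not b:
                assert b.duration_s >= config.min_bout_s
            assert b.onset_s + b.duration_s <= config.window_s + 1e-9

    def test_windowed_output_satisfies_database_invariants(self):
        config = small_config("thermoneutral_plain", seed=3)
        seqs = bouts_to_windows(
            simulate_flock(config),
            window_s=config.window_s,
            n_windows=config.n_windows,
        )
        assert len(seqs) == config.n_broilers
        for seq in seqs:
            assert len(seq.elements) == config.n_windows
            for el in seq.elements:
                assert all(a != b for a, b in zip(el, el[1:]))  # merged repeats

    def test_thermoneutral_more_active_than_heat(self):
        """Mean bouts per window strictly higher at comfort temperature."""
        def mean_bouts(label):
            total = 0
            for seed in range(10):
                config = small_config(label, seed=seed)
                total += len(simulate_flock(config))
            return total / (10 * SMALL["n_broilers"] * SMALL["n_windows"])

        assert mean_bouts("thermoneutral_plain") > mean_bouts("heat_plain")


class TestPlantPattern:
    PATTERN = Pattern.of(["St", "Ll"])

    def _mined_support(self, config, carrier_fraction, plant_seed=17):
        bouts = simulate_flock(config)
        planted = plant_pattern(bouts, self.PATTERN, carrier_fraction, config, seed=plant_seed)
        db = build_database(
            bouts_to_windows(planted, window_s=config.window_s, n_windows=config.n_windows)
        )
        return support(self.PATTERN, db).support

    def test_all_carriers_give_full_support(self):
        config = SimConfig(PRESETS["heat_plain"], n_broilers=5, n_windows=3,
                           window_s=60.0, seed=2)
        assert self._mined_support(config, 1.0) == 1.0

    def test_recovered_support_at_least_carrier_fraction(self):
        config = SimConfig(PRESETS["heat_plain"], n_broilers=10, n_windows=4,
                           window_s=60.0, seed=4)
        assert self._mined_support(config, 0.4) >= 0.4

    def test_exact_recovery_when_codes_disjoint_from_preset(self):
        # lying laterally is unreachable at thermoneutral temperature, so
        # non-carriers can never contain the pattern spontaneously
        config = SimConfig(PRESETS["thermoneutral_plain"], n_broilers=10,
                           n_windows=4, window_s=60.0, seed=6)
        for fraction in (0.2, 0.5, 1.0):
            assert self._mined_support(config, fraction) == fraction

    def test_planted_pattern_appears_in_mined_output(self):
        config = SimConfig(PRESETS["thermoneutral_plain"], n_broilers=10,
                           n_windows=6, window_s=60.0, seed=8)
        bouts = plant_pattern(simulate_flock(config), self.PATTERN, 0.4, config, seed=19)
        db = build_database(
            bouts_to_windows(bouts, window_s=config.window_s, n_windows=config.n_windows)
        )
        hits = [fp for fp in mine(db, 0.2) if fp.pattern == self.PATTERN]
        assert len(hits) == 1 and hits[0].support == 0.4

    def test_pattern_with_too_many_elements_rejected(self):
        config = small_config("heat_plain")
        too_long = Pattern.of(*(["Ld"] if i % 2 == 0 else ["P"] for i in range(20)))
        with pytest.raises(CapacityError):
            plant_pattern(simulate_flock(config), too_long, 0.5, config, seed=1)

    def test_element_exceeding_window_capacity_rejected(self):
        config = small_config("heat_plain", window_s=60.0)
        wide = Pattern.of(["Ld", "P", "F", "W", "E", "D", "St"])  # 7 x 10 s > 60 s
        with pytest.raises(CapacityError):
            plant_pattern(simulate_flock(config), wide, 0.5, config, seed=1)

    def test_enriched_only_code_cannot_be_planted_in_plain_pen(self):
        config = small_config("heat_plain")
        with pytest.raises(EnvironmentViolationError):
            plant_pattern(simulate_flock(config), Pattern.of(["Ex"]), 0.5, config, seed=1)
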