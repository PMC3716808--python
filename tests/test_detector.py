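"""Detector Monte-Carlo: geometry, event statistics, bank recovery."""

import math

import numpy as np
import pytest

from patternsieve import (
    DetectorConfig,
    Event,
    PatternDistribution,
    ResourceBudget,
    budget_for_bank,
    enumerate_valid_bank,
    match_patterns,
    pattern_frequencies,
    simulate_event,
    simulate_events,
    validate_selection,
)
from patternsieve.detector import (
    _track_bins,
    live_bank,
    mask_dead_channels,
    read_bank,
    read_events,
    write_bank,
    write_events,
)


def _event(*layers):
    return Event(hits=tuple(np.array(sorted(h), dtype=np.int64) for h in layers), truth=[])


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(bins_per_layer=1)
        with pytest.raises(ValueError):
            DetectorConfig(noise_rate=1.5)
        with pytest.raises(ValueError):
            DetectorConfig(dead_bins=((0, 999),))

    def test_dead_bins_fixed_by_seed(self):
        a, b = DetectorConfig(seed=4), DetectorConfig(seed=4)
        assert a.dead_bins == b.dead_bins
        assert len(a.dead_bins) == 4

    def test_json_round_trip(self, tmp_path):
        cfg = DetectorConfig(seed=3, bins_per_layer=16)
        cfg.to_json(tmp_path / "cfg.json")
        assert DetectorConfig.from_json(tmp_path / "cfg.json") == cfg


class TestSimulation:
    def test_only_dead_channels_fire_without_tracks_or_noise(self):
        cfg = DetectorConfig(mean_tracks=0.0, noise_rate=0.0, seed=2)
        ev = simulate_event(cfg, np.random.default_rng(0))
        fired = {(layer, int(b)) for layer, h in enumerate(ev.hits) for b in h}
        assert fired == set(cfg.dead_bins)

    def test_straight_perpendicular_track_hits_same_bin_on_each_layer(self):
        cfg = DetectorConfig(mean_tracks=0.0, noise_rate=0.0, n_dead_bins=0, dead_bins=())
        bins = _track_bins(cfg, 10.3, 0.0, 0.0)
        assert bins.tolist() == [10, 10, 10, 10]

    def test_noise_rate_reproduced_in_expectation(self):
        cfg = DetectorConfig(
            mean_tracks=0.0, noise_rate=0.01, bins_per_layer=100, n_dead_bins=0, dead_bins=()
        )
        rng = np.random.default_rng(11)
        n_ev = 10_000
        hits = [len(h) for _ in range(n_ev) for h in simulate_event(cfg, rng).hits]
        mean = np.mean(hits)
        se = math.sqrt(100 * 0.01 * 0.99 / len(hits))
        assert abs(mean - 1.0) < 3 * se

    def test_event_stream_deterministic_in_seed(self):
        cfg = DetectorConfig(seed=5)
        a = simulate_events(cfg, 20)
        b = simulate_events(cfg, 20)
        for ea, eb in zip(a, b):
            for ha, hb in zip(ea.hits, eb.hits):
                assert np.array_equal(ha, hb)

    def test_event_csv_round_trip(self, tmp_path):
        events = simulate_events(DetectorConfig(seed=8), 5)
        write_events(events, tmp_path / "ev.csv")
        back = read_events(tmp_path / "ev.csv")
        assert len(back) == 5
        for ea, eb in zip(events, back):
            for ha, hb in zip(ea.hits, eb.hits):
                assert np.array_equal(ha, hb)


class TestMatching:
    def test_empty_event_matches_nothing(self):
        assert match_patterns(_event([], [1], [2], [3])) == set()

    def test_single_hit_per_layer_single_pattern(self):
        assert match_patterns(_event([4], [5], [6], [7])) == {(4, 5, 6, 7)}

    def test_combination_count_is_product_of_layer_hits(self):
        ev = _event([1, 2], [3, 4], [5, 6], [7, 8])
        matches = match_patterns(ev)
        assert len(matches) == 16
        rng = np.random.default_rng(0)
        ev2 = _event(*[rng.choice(50, size=n, replace=False) for n in (3, 1, 4, 2)])
        assert len(match_patterns(ev2)) == 3 * 1 * 4 * 2


class TestBank:
    def test_straight_tracks_give_diagonal_bank(self):
        cfg = DetectorConfig(
            bins_per_layer=16, slope_range=(0.0, 0.0), curvature_range=(0.0, 0.0),
            n_dead_bins=0, dead_bins=(),
        )
        bank = enumerate_valid_bank(cfg, efficiency=1.0)
        assert bank.patterns == {(b, b, b, b) for b in range(16)}

    def test_every_bank_pattern_resimulates(self):
        cfg = DetectorConfig(seed=1)
        bank = enumerate_valid_bank(cfg)
        for pat, (x0, s, k) in bank.examples.items():
            assert tuple(_track_bins(cfg, x0, s, k).tolist()) == pat

    def test_bank_is_tiny_fraction_of_pattern_space(self):
        cfg = DetectorConfig(seed=1)
        bank = enumerate_valid_bank(cfg)
        assert len(bank) < 0.001 * cfg.bins_per_layer**4

    def test_empty_parameter_range_rejected(self):
        cfg = DetectorConfig(slope_range=(0.5, -0.5))
        with pytest.raises(ValueError):
            enumerate_valid_bank(cfg)

    def test_bank_csv_round_trip(self, tmp_path):
        cfg = DetectorConfig(seed=1, bins_per_layer=16)
        bank = enumerate_valid_bank(cfg)
        write_bank(bank, tmp_path / "bank.csv")
        back = read_bank(tmp_path / "bank.csv")
        assert back.patterns == bank.patterns
        assert back.geometry_hash == bank.geometry_hash


class TestFrequencies:
    def test_repeated_single_pattern_has_unit_probability(self):
        events = [_event([1], [2], [3], [4])] * 5
        dist = pattern_frequencies(events, bins_per_layer=8)
        assert dist.probs == {(1, 2, 3, 4): 1.0}

    def test_two_equally_common_patterns_split_mass(self):
        events = [_event([1], [1], [1], [1])] * 3 + [_event([2], [2], [2], [2])] * 3
        dist = pattern_frequencies(events, bins_per_layer=8)
        assert dist.probs[(1, 1, 1, 1)] == pytest.approx(0.5)
        assert dist.probs[(2, 2, 2, 2)] == pytest.approx(0.5)

    def test_split_sample_frequency_consistency(self):
        """Empirical pattern probabilities agree between independent halves."""
        cfg = DetectorConfig(seed=13)
        bank = live_bank(enumerate_valid_bank(cfg), cfg)
        d1 = pattern_frequencies(
            mask_dead_channels(simulate_events(cfg, 1500, seed=101), cfg), cfg.bins_per_layer
        )
        d2 = pattern_frequencies(
            mask_dead_channels(simulate_events(cfg, 1500, seed=202), cfg), cfg.bins_per_layer
        )
        # a well-populated bank pattern in run 1
        pat = max(bank.patterns, key=lambda p: d1.probs.get(p, 0.0))
        c1, c2 = d1.counts[pat], d2.counts.get(pat, 0)
        p1, p2 = c1 / d1.total_units, c2 / d2.total_units
        se = math.sqrt(c1) / d1.total_units + math.sqrt(max(c2, 1)) / d2.total_units
        assert abs(p1 - p2) < 3 * se


class TestValidation:
    def test_forced_recall_and_precision(self):
        """Bank patterns placed at the cusp must be selected perfectly."""
        bank_patterns = [(i, i, i, i) for i in range(5)]
        budget = ResourceBudget(5, 0.01)
        cusp = budget.cusp
        probs = {p: cusp for p in bank_patterns}
        probs[(7, 7, 7, 7)] = 1.0 - 5 * cusp  # overwhelming background pattern
        dist = PatternDistribution(probs=probs)
        from patternsieve.detector import PatternBank

        bank = PatternBank(patterns=frozenset(bank_patterns), geometry_hash="x")
        rep = validate_selection(bank, dist, budget)
        assert rep.recall == 1.0
        assert rep.precision == 1.0

    def test_raw_frequency_structure_noise_bank_dead(self):
        """Raw frequencies: bank intermediate, noise rare, dead combos on top.

        The most probable combination is built on an always-on channel and
        exceeds every valid-track pattern; valid-track patterns in turn are
        typically far more probable than accidental combinations.  (Most
        *distinct* dead-involving combinations are rare mixtures, so the
        high-p claim is about the top of the distribution, not the group
        median.)
        """
        cfg = DetectorConfig(seed=3)
        bank = enumerate_valid_bank(cfg)
        events = simulate_events(cfg, 1500, seed=33)
        dist = pattern_frequencies(events, cfg.bins_per_layer)
        dead = set(cfg.dead_bins)
        groups = {"dead": [], "bank": [], "other": []}
        for pat, p in dist.probs.items():
            if any((layer, b) in dead for layer, b in enumerate(pat)):
                groups["dead"].append(p)
            elif pat in bank.patterns:
                groups["bank"].append(p)
            else:
                groups["other"].append(p)
        top = max(dist.probs, key=dist.probs.get)
        assert any((layer, b) in dead for layer, b in enumerate(top))
        assert max(groups["dead"]) > max(groups["bank"])
        assert np.median(groups["bank"]) > np.median(groups["other"])

    def test_masked_stream_recovers_live_bank(self):
        """Scaled-down end-to-end recovery check (full size in acceptance)."""
        cfg = DetectorConfig(seed=17)
        bank = live_bank(enumerate_valid_bank(cfg), cfg)
        events = mask_dead_channels(simulate_events(cfg, 2500, seed=18), cfg)
        dist = pattern_frequencies(events, cfg.bins_per_layer)
        rep = validate_selection(bank, dist, budget_for_bank(bank, dist))
        assert rep.recall > 0.8
        assert rep.precision > 0.8
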