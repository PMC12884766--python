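import numpy as np
import pytest

from sferlab.spatial import (RateMap, SessionScene, bayes_decode,
                             binarize_events, compute_rate_map,
                             cross_session_decode, field_statistics_fits,
                             identify_fields, place_cell_tests, snr,
                             spatial_information, synthetic_scene,
                             within_session_stability)


def uniform_scene(n=8, repeats=30, n_cells=1, rng=None):
    """Every bin visited equally, no events unless set by the caller."""
    bins = np.tile(np.arange(n * n), repeats)
    if rng is not None:
        rng.shuffle(bins)
    pos = np.stack([(bins % n) * 2 + 1.0, (bins // n) * 2 + 1.0], axis=1)
    T = len(bins)
    ev = np.zeros((n_cells, T), dtype=np.uint8)
    return SessionScene(positions=pos, events=ev, n_bins=n,
                        speeds=np.full(T, 10.0),
                        laps=np.arange(T) // (T // 4)), bins


class TestBinarize:
    def test_constant_trace_no_events(self):
        assert binarize_events(np.ones(100)).sum() == 0

    def test_single_large_spike_detected(self):
        tr = np.zeros(200)
        tr[50] = 10.0
        ev = binarize_events(tr)
        assert ev.sum() == 1 and ev[0, 50] == 1

    def test_slow_frames_dropped(self):
        tr = np.zeros(100)
        tr[10] = 10.0
        tr[20] = 10.0
        speeds = np.full(100, 10.0)
        speeds[20] = 1.0
        ev = binarize_events(tr, speeds=speeds)
        assert ev[0, 10] == 1 and ev[0, 20] == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binarize_events(np.array([]))


class TestRateMap:
    def test_no_events_all_zero(self):
        scene, _ = uniform_scene()
        m = compute_rate_map(scene, 0)
        assert np.nansum(m.raw_rate) == 0
        assert np.nansum(m.smoothed_rate) == 0

    def test_single_event_peaks_at_its_bin(self):
        scene, bins = uniform_scene()
        k = np.flatnonzero(bins == 27)[0]
        scene.events[0, k] = 1
        m = compute_rate_map(scene, 0)
        assert np.nanargmax(m.smoothed_rate) == 27
        assert np.nanargmax(m.raw_rate) == 27

    def test_zero_occupancy_rejected(self):
        scene, _ = uniform_scene()
        scene.speeds[:] = 0.0
        with pytest.raises(ValueError):
            compute_rate_map(scene, 0)

    def test_smoothing_respects_walls(self):
        """A full-height wall splits the arena; events on one side leak no
        rate mass to the other."""
        n = 8
        scene, bins = uniform_scene(n=n)
        wall_right = np.zeros((n, n), dtype=bool)
        wall_right[:, 3] = True   # wall between columns 3 and 4
        scene.wall_right = wall_right
        left = np.flatnonzero(bins % n <= 3)
        scene.events[0, left[::3]] = 1
        m = compute_rate_map(scene, 0)
        grid = np.nan_to_num(m.smoothed_rate).reshape(n, n)
        assert grid[:, 4:].sum() == 0
        assert grid[:, :4].sum() > 0

    def test_geodesic_distance_goes_around_walls(self):
        n = 8
        scene, _ = uniform_scene(n=n)
        wall_right = np.zeros((n, n), dtype=bool)
        wall_right[:7, 3] = True  # wall with a gap at the bottom row
        scene.wall_right = wall_right
        D = scene.distance_matrix("geodesic")
        a = 0 * n + 3   # row 0, col 3
        b = 0 * n + 4   # row 0, col 4 (across the wall)
        assert D[a, b] > 2.0   # must detour; adjacent would be 2 cm
        De = scene.distance_matrix("euclidean")
        assert De[a, b] == pytest.approx(2.0)


class TestSpatialInformation:
    def test_uniform_rate_zero_information(self):
        scene, bins = uniform_scene()
        scene.events[0, :] = 1   # every frame, every bin equally
        m = compute_rate_map(scene, 0)
        assert spatial_information(m) == pytest.approx(0.0, abs=1e-9)

    def test_one_of_four_bins_two_bits(self):
        """All activity in one of 4 equally occupied bins -> log2(4) bits
        per event."""
        occ = np.array([1.0, 1.0, 1.0, 1.0])
        rate = np.array([4.0, 0.0, 0.0, 0.0])
        m = RateMap(occupancy_s=occ, raw_rate=rate, smoothed_rate=rate,
                    valid=np.ones(4, bool), n_bins=2)
        assert spatial_information(m) == pytest.approx(2.0)

    def test_invariant_to_rate_scaling(self):
        rng = np.random.default_rng(0)
        occ = rng.uniform(0.5, 2.0, 16)
        rate = rng.uniform(0, 3.0, 16)
        m1 = RateMap(occ, rate, rate, np.ones(16, bool), 4)
        m2 = RateMap(occ, 7 * rate, 7 * rate, np.ones(16, bool), 4)
        assert spatial_information(m1) == pytest.approx(spatial_information(m2))

    def test_zero_rate_rejected(self):
        m = RateMap(np.ones(4), np.zeros(4), np.zeros(4), np.ones(4, bool), 2)
        with pytest.raises(ValueError):
            spatial_information(m)


class TestPlaceCellTests:
    def test_planted_field_passes(self, small_scene):
        res = place_cell_tests(small_scene, 0, n_shuffles=80, seed=0)
        assert res["passed"]

    def test_seeded_reproducibility(self, small_scene):
        a = place_cell_tests(small_scene, 1, n_shuffles=40, seed=3)
        b = place_cell_tests(small_scene, 1, n_shuffles=40, seed=3)
        np.testing.assert_allclose(a["nulls"]["temporal_shift"],
                                   b["nulls"]["temporal_shift"])

    def test_false_positive_rate_calibrated(self):
        """Homogeneous cells (no place coding) pass each test at roughly
        the nominal 5% rate."""
        rng = np.random.default_rng(42)
        scene, bins = uniform_scene(n=8, repeats=40, n_cells=40, rng=rng)
        scene.events[:] = (rng.random(scene.events.shape) < 0.02)
        fails = {"temporal_shift": 0, "interval_shuffle": 0,
                 "random_shuffle": 0}
        n_cells = 0
        for c in range(40):
            try:
                res = place_cell_tests(scene, c, n_shuffles=60, seed=c)
            except ValueError:
                continue
            n_cells += 1
            for name, null in res["nulls"].items():
                fails[name] += res["si"] > np.percentile(null, 95)
        for name, k in fails.items():
            # binomial bound at p = 0.05 (3 sigma, small-sample slack)
            assert k <= 0.05 * n_cells + 3 * np.sqrt(0.05 * 0.95 * n_cells) + 1

    def test_too_few_events_rejected(self, small_scene):
        scene = SessionScene(positions=small_scene.positions,
                             events=np.zeros_like(small_scene.events),
                             speeds=small_scene.speeds, laps=small_scene.laps,
                             n_bins=small_scene.n_bins)
        with pytest.raises(ValueError):
            place_cell_tests(scene, 0, n_shuffles=10, seed=0)


def _two_bump_map(n=16, saddle_ratio=0.3):
    x = np.arange(n)
    X, Y = np.meshgrid(x, x)
    peak1 = np.exp(-(((X - 4) ** 2 + (Y - 8) ** 2) / 4.0))
    peak2 = np.exp(-(((X - 12) ** 2 + (Y - 8) ** 2) / 4.0))
    rate = peak1 + peak2
    bridge = saddle_ratio * np.exp(-((Y - 8) ** 2) / 4.0) * \
        ((X > 4) & (X < 12))
    rate = np.maximum(rate, bridge)
    return RateMap(occupancy_s=np.ones(n * n), raw_rate=rate.ravel(),
                   smoothed_rate=rate.ravel(), valid=np.ones(n * n, bool),
                   n_bins=n)


class TestFieldIdentification:
    def test_deep_saddle_splits(self):
        fields = identify_fields(_two_bump_map(saddle_ratio=0.3))
        assert len(fields) == 2

    def test_shallow_saddle_merges(self):
        fields = identify_fields(_two_bump_map(saddle_ratio=0.7))
        assert len(fields) == 1

    def test_subthreshold_map_empty(self):
        n = 8
        rate = np.full(n * n, 0.05)
        m = RateMap(np.ones(n * n), rate, rate, np.ones(n * n, bool), n)
        assert identify_fields(m) == []

    def test_event_and_lap_requirements(self):
        m = _two_bump_map(saddle_ratio=0.3)
        field_bins = np.flatnonzero(m.smoothed_rate > 0.2)
        few_events = field_bins[:3]
        out = identify_fields(m, event_bins=few_events,
                              lap_of_event=np.arange(3))
        assert out == []   # fewer than 5 events per candidate field

    def test_planted_scene_field_recovered(self, small_scene):
        m = compute_rate_map(small_scene, 0)
        fields = identify_fields(m)
        n = small_scene.n_bins
        truth = small_scene.truth["centers_cm"][0, 0]
        centers = [np.array([f.center_bin % n * 2 + 1,
                             f.center_bin // n * 2 + 1]) for f in fields]
        assert min(np.linalg.norm(c - truth) for c in centers) < 8.0


class TestStability:
    def test_identical_halves_perfect(self):
        scene, bins = uniform_scene(repeats=40)
        # same event pattern in both halves
        k = np.flatnonzero(bins == 20)
        scene.events[0, k] = 1
        r = within_session_stability(scene, 0)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_planted_cell_stable(self, small_scene):
        assert within_session_stability(small_scene, 0) > 0.5

    def test_field_restriction_pads_to_minimum(self, small_scene):
        r = within_session_stability(small_scene, 0, field_bins=[100],
                                     min_field_bins=16)
        assert -1.0 <= r <= 1.0


class TestSNR:
    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            snr(np.ones(100))

    def test_spike_only_trace_rejected(self):
        with pytest.raises(ValueError):
            snr(np.array([0.0, 0.0, 0.0, 1.0]))

    def test_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 0.1, 1000)
        trace[500] = 3.0
        k = int(0.75 * len(trace))
        expected = trace.max() / np.sort(trace)[:k].std()
        assert snr(trace) == pytest.approx(expected)


class TestFieldStatistics:
    def test_negbinom_counts_not_rejected(self):
        rng = np.random.default_rng(0)
        counts = rng.negative_binomial(5, 0.5, 600)
        out = field_statistics_fits(field_counts=counts, B=60, seed=1)
        assert out["counts_negbinom"]["p_value"] > 0.05

    def test_lognormal_sizes_preferred(self):
        rng = np.random.default_rng(1)
        sizes = rng.lognormal(3.0, 0.5, 2000)
        out = field_statistics_fits(field_sizes=sizes, B=60, seed=2)
        assert out["sizes_lognormal"]["statistic"] < out["sizes_gamma"]["statistic"]

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        sizes = rng.lognormal(3.0, 0.4, 300)
        a = field_statistics_fits(field_sizes=sizes, B=30, seed=9)
        b = field_statistics_fits(field_sizes=sizes, B=30, seed=9)
        assert a["sizes_lognormal"]["p_value"] == b["sizes_lognormal"]["p_value"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            field_statistics_fits(field_sizes=np.arange(5))


class TestDecoding:
    def test_perfectly_selective_cells_zero_error(self):
        n = 6
        scene, bins = uniform_scene(n=n, repeats=20, n_cells=n * n)
        scene.events[bins, np.arange(len(bins))] = 1
        out = bayes_decode(scene)
        assert out["median_error_cm"] == 0.0

    def test_three_bin_hand_example(self):
        """Hand-computable posterior on 3 linear bins: decoded bin is the
        expected-distance argmin."""
        from sferlab.spatial import _decode_frames
        n = 4
        scene, bins = uniform_scene(n=n, repeats=10, n_cells=2)
        probs = np.array([[0.9, 0.1, 0.1, 0.1] + [0.1] * (n * n - 4),
                          [0.1, 0.1, 0.9, 0.1] + [0.1] * (n * n - 4)])
        prior = np.full(n * n, 1.0 / (n * n))
        scene.events[:, 0] = [1, 0]   # frame 0: cell 0 fired only
        frames = np.zeros(len(bins), dtype=bool)
        frames[0] = True
        D = scene.distance_matrix("euclidean")
        idx, decoded = _decode_frames(scene, probs, prior, [0, 1], frames, D)
        post = np.array([probs[0, y] * (1 - probs[1, y]) * prior[y]
                         for y in range(n * n)])
        post /= post.sum()
        expected = np.argmin(D @ post)
        assert decoded[0] == expected

    def test_uniform_posterior_minimizes_mean_distance(self):
        n = 6
        scene, bins = uniform_scene(n=n, repeats=10, n_cells=1)
        from sferlab.spatial import _decode_frames
        probs = np.full((1, n * n), 0.5)
        prior = np.full(n * n, 1.0 / (n * n))
        frames = np.zeros(len(bins), dtype=bool)
        frames[0] = True
        D = scene.distance_matrix("euclidean")
        idx, decoded = _decode_frames(scene, probs, prior, [0], frames, D)
        # brute force: a bin minimizing the mean distance to all bins
        # (the central bins tie by symmetry)
        m = D.mean(axis=1)
        minimizers = np.flatnonzero(np.isclose(m, m.min()))
        assert decoded[0] in minimizers

    def test_single_lap_rejected(self):
        scene, _ = uniform_scene()
        scene.laps[:] = 0
        with pytest.raises(ValueError):
            bayes_decode(scene)


class TestCrossSessionDecode:
    def test_self_decoding_beats_scrambled(self, small_scene):
        cells = np.arange(small_scene.n_cells)
        with pytest.warns(UserWarning):
            good = cross_session_decode(small_scene, small_scene, cells,
                                        cells, seed=0)
        rng = np.random.default_rng(1)
        scrambled = rng.permutation(cells)
        with pytest.warns(UserWarning):
            bad = cross_session_decode(small_scene, small_scene, cells,
                                       scrambled, seed=0)
        assert good["mean_loss_cm"] <= bad["mean_loss_cm"]

    def test_seeded_reproducibility(self, small_scene):
        cells = np.arange(small_scene.n_cells)
        with pytest.warns(UserWarning):
            a = cross_session_decode(small_scene, small_scene, cells, cells,
                                     seed=4)
        with pytest.warns(UserWarning):
            b = cross_session_decode(small_scene, small_scene, cells, cells,
                                     seed=4)
        assert a["mean_loss_cm"] == b["mean_loss_cm"]

    def test_misaligned_lists_rejected(self, small_scene):
        with pytest.raises(ValueError):
            cross_session_decode(small_scene, small_scene, [0, 1], [0], seed=0)
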