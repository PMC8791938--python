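import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from conftest import criterion_phantom_config, flat_config
from octlayers import (
    Polarity,
    SearchConfig,
    ValidationError,
    accumulate,
    axial_gradient,
    boundary_enhance,
    denoise,
    generate_bscan,
    hysteresis_select,
    large_scale_smooth,
    nonmax_suppress_axial,
    select_seeds,
    trace_channel,
    trace_path,
    trace_paths,
)
from octlayers.enhance import EnhancedImage, PeakMap
from octlayers.trace import ProbabilityMap, Seed, TracedPath
from scipy import ndimage

D2B = Polarity.DARK_TO_BRIGHT


def _enh(pixels):
    return EnhancedImage(np.asarray(pixels, dtype=float), D2B)


def _ridge_image(h=40, w=100, row=20, value=1.0):
    img = np.zeros((h, w))
    img[row] = value
    return _enh(img)


class TestSelectSeeds:
    def _peaks(self, flags):
        return PeakMap(flags, D2B)

    def test_empty_peakmap_gives_no_seeds(self):
        flags = np.zeros((40, 100), dtype=bool)
        assert select_seeds(self._peaks(flags), SearchConfig()) == []

    def test_flags_in_both_bands_returned(self):
        # coherence vote disabled: this checks the pure banding rule
        flags = np.zeros((40, 512), dtype=bool)
        flags[10, 5] = True
        flags[20, 500] = True
        cfg = SearchConfig(seed_coherence_frac=0.0)
        seeds = select_seeds(self._peaks(flags), cfg)
        assert [(s.row, s.col) for s in seeds] == [(10, 5), (20, 500)]

    def test_center_flags_excluded(self):
        flags = np.zeros((40, 512), dtype=bool)
        flags[10, 256] = True
        cfg = SearchConfig(seed_coherence_frac=0.0)
        assert select_seeds(self._peaks(flags), cfg) == []

    def test_too_narrow_image_rejected(self):
        flags = np.zeros((40, 50), dtype=bool)
        with pytest.raises(ValidationError):
            select_seeds(self._peaks(flags), SearchConfig(seed_band_width=30))

    def test_coherence_filter_drops_scattered_peaks(self):
        flags = np.zeros((60, 512), dtype=bool)
        flags[30, :] = True          # a real, laterally coherent ridge
        rng = np.random.default_rng(0)
        for j in rng.choice(30, size=6, replace=False):
            flags[int(rng.integers(5, 20)), j] = True  # scattered speckle flags
        enh = _enh(np.where(flags, 0.5, 0.0))
        seeds = select_seeds(PeakMap(flags, D2B), SearchConfig(), enhanced=enh)
        assert {s.row for s in seeds} == {30}


class TestTracePath:
    def test_follows_constant_ridge(self):
        enh = _ridge_image()
        path = trace_path(Seed(20, 5, D2B), enh, SearchConfig())
        assert np.all(path.rows == 20)

    def test_crosses_zeroed_gap_straight(self):
        enh = _ridge_image()
        enh.pixels[:, 40:46] = 0.0
        path = trace_path(Seed(20, 5, D2B), enh, SearchConfig())
        assert np.all(path.rows[40:46] == 20)
        assert np.all(path.rows == 20)  # re-acquires the ridge after the gap

    def test_border_seed_spans_full_width(self):
        enh = _ridge_image()
        path = trace_path(Seed(20, 0, D2B), enh, SearchConfig())
        assert path.rows.shape == (100,)
        assert np.all(path.rows == 20)

    def test_seed_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            trace_path(Seed(99, 0, D2B), _ridge_image(h=40), SearchConfig())

    @pytest.mark.parametrize("neighborhood", [3, 5])
    def test_continuity_bound_on_noisy_phantom(self, noisy_phantom, neighborhood):
        bscan, _ = noisy_phantom
        den = denoise(bscan)
        enh = boundary_enhance(
            axial_gradient(den, D2B), large_scale_smooth(den, (9, 9))
        )
        peaks = nonmax_suppress_axial(enh)
        cfg = SearchConfig(neighborhood=neighborhood)
        seeds = select_seeds(peaks, cfg, enhanced=enh)
        paths = trace_paths(seeds[::7], enh, cfg)
        bound = neighborhood // 2
        for p in paths:
            assert np.all(np.abs(np.diff(p.rows)) <= bound)
            assert p.rows.min() >= 0 and p.rows.max() < bscan.shape[0]


class TestAccumulate:
    def _path(self, rows, w):
        rows = np.asarray(rows, dtype=np.int64)
        return TracedPath(rows, Seed(int(rows[0]), 0, D2B))

    def test_unanimity_gives_exactly_100(self):
        paths = [self._path([3] * 10, 10) for _ in range(7)]
        pm = accumulate(paths, (6, 10))
        assert np.all(pm.values[3] == 100.0)
        assert pm.values.sum() == pytest.approx(100.0 * 10)

    def test_half_agreement_gives_50(self):
        paths = [self._path([2] * 8, 8) for _ in range(5)]
        paths += [self._path([4] * 8, 8) for _ in range(5)]
        pm = accumulate(paths, (6, 8))
        assert np.all(pm.values[2] == 50.0)
        assert np.all(pm.values[4] == 50.0)

    def test_distinct_paths_split_column_mass(self):
        paths = [self._path([r] * 8, 8) for r in range(4)]
        pm = accumulate(paths, (6, 8))
        assert np.all(pm.values[:4] == 25.0)
        assert np.allclose(pm.values.sum(axis=0), 100.0)

    def test_empty_path_list_rejected(self):
        with pytest.raises(ValidationError):
            accumulate([], (6, 8))

    def test_column_sums_conserved_on_phantom(self, noisy_phantom):
        bscan, _ = noisy_phantom
        den = denoise(bscan)
        enh = boundary_enhance(
            axial_gradient(den, D2B), large_scale_smooth(den, (9, 9))
        )
        peaks = nonmax_suppress_axial(enh)
        result = trace_channel(enh, peaks, SearchConfig(), full=True)
        sums = result.probability.values.sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)


small_prob_maps = arrays(
    dtype=float,
    shape=st.tuples(st.integers(3, 40), st.integers(3, 40)),
    elements=st.floats(0, 100, width=32),
)


class TestHysteresis:
    def _pm(self, values):
        return ProbabilityMap(np.asarray(values, dtype=float), 1, D2B)

    def test_all_below_low_gives_empty_mask(self):
        pm = self._pm(np.full((5, 5), 3.0))
        cfg = SearchConfig(low_threshold=10, high_threshold=40)
        assert not hysteresis_select(pm, cfg).flags.any()

    def test_strong_ridge_fully_kept(self):
        vals = np.zeros((7, 9))
        vals[3] = 80.0
        mask = hysteresis_select(self._pm(vals), SearchConfig(low_threshold=10, high_threshold=40))
        assert np.array_equal(mask.flags, vals >= 40)

    def test_weak_dip_kept_isolated_weak_removed(self):
        vals = np.zeros((7, 12))
        vals[3] = 80.0
        vals[3, 5:8] = 15.0   # dip, connected to strong pixels
        vals[0, 0] = 15.0     # isolated weak pixel
        mask = hysteresis_select(self._pm(vals), SearchConfig(low_threshold=10, high_threshold=40))
        assert mask.flags[3].all()
        assert not mask.flags[0, 0]

    @given(small_prob_maps)
    def test_matches_bfs_oracle(self, values):
        cfg = SearchConfig(low_threshold=10, high_threshold=40)
        got = hysteresis_select(self._pm(values), cfg).flags
        expected = oracles.bf_hysteresis(values, 10, 40)
        assert np.array_equal(got, expected)

    @given(small_prob_maps)
    def test_raising_thresholds_never_adds_pixels(self, values):
        lo = hysteresis_select(self._pm(values), SearchConfig(low_threshold=5, high_threshold=30)).flags
        hi = hysteresis_select(self._pm(values), SearchConfig(low_threshold=10, high_threshold=40)).flags
        assert not (hi & ~lo).any()


class TestTraceChannel:
    def _channel(self, bscan, pol=D2B, cfg=None):
        den = denoise(bscan)
        enh = boundary_enhance(
            axial_gradient(den, pol), large_scale_smooth(den, (9, 9))
        )
        peaks = nonmax_suppress_axial(enh)
        return trace_channel(enh, peaks, cfg or SearchConfig(), full=True)

    def _n_components(self, mask):
        labels, n = ndimage.label(mask.flags, np.ones((3, 3), int))
        full = 0
        for k in range(1, n + 1):
            if (labels == k).any(axis=0).sum() >= 0.9 * mask.flags.shape[1]:
                full += 1
        return full

    def test_flat_phantom_yields_six_full_width_ridges(self, flat_phantom):
        bscan, _ = flat_phantom
        result = self._channel(bscan)
        assert self._n_components(result.mask) == 6

    def test_vessel_shadow_does_not_break_the_ridges(self):
        cfg = flat_config(rng_seed=8, vessel_shadows=((170, 8, 0.3),))
        bscan, _ = generate_bscan(cfg)
        result = self._channel(bscan)
        assert self._n_components(result.mask) == 6

    def test_empty_peak_map_warns_and_returns_empty_mask(self):
        peaks = PeakMap(np.zeros((40, 100), dtype=bool), D2B)
        enh = _enh(np.zeros((40, 100)))
        with pytest.warns(UserWarning):
            mask = trace_channel(enh, peaks, SearchConfig())
        assert not mask.flags.any()

    def test_mask_tracks_truth_under_speckle(self):
        """Under speckle, each detected full-width candidate stays
        within 1 px of its truth boundary in at least 95% of columns."""
        cfg = criterion_phantom_config(
            seed=13, speckle_level=0.2, vessel_shadows=(), pvf_offset=None
        )
        bscan, truth = generate_bscan(cfg)
        den = denoise(bscan)
        enh = boundary_enhance(
            axial_gradient(den, D2B), large_scale_smooth(den, (9, 9))
        )
        peaks = nonmax_suppress_axial(enh)
        result = trace_channel(enh, peaks, SearchConfig(), full=True)
        from octlayers import extract_components

        cands = extract_components(
            result.mask,
            result.probability,
            signal=enh,
            lost_fraction=result.lost_fraction,
        )
        # The rendered image only contains the rasterised boundary
        # (the first pixel row at or below the fractional truth), so
        # that is the curve a detector can be held to.
        d2b_truth = [
            np.ceil(truth.boundaries[n])
            for n in ("ILM", "o-GCL", "o-INL", "o-ONL", "o-IS", "o-OS")
        ]
        assert len(cands) == 6
        for cand in cands:
            dev = np.min([np.abs(cand - tr) for tr in d2b_truth], axis=0)
            assert (dev <= 1.0).mean() >= 0.95
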