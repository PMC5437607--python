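import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meniscoq import (
    ImageSeries,
    RoiMask,
    compute_map,
    exclude_invalid,
    fit_monoexp,
    fit_pixels,
)
from meniscoq.phantom import TSL_MS, TE_MS, add_rician_noise

TSL = np.asarray(TSL_MS)
TE = np.asarray(TE_MS)


def grid_search_oracle(signal, times, t_range=(10.0, 500.0), s0_range=(1.0, 1000.0)):
    """Brute-force least-squares oracle: three zoom levels of an (S0, T)
    lattice, final spacing ~1e-4 in T."""
    t_lo, t_hi = t_range
    s_lo, s_hi = s0_range
    best = None
    for _ in range(4):
        Ts = np.linspace(t_lo, t_hi, 61)
        S0s = np.linspace(s_lo, s_hi, 61)
        model = S0s[:, None, None] * np.exp(-times[None, None, :] / Ts[None, :, None])
        rss = ((model - signal[None, None, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(rss.argmin(), rss.shape)
        best = (S0s[i], Ts[j])
        ds = (s_hi - s_lo) / 60
        dt = (t_hi - t_lo) / 60
        s_lo, s_hi = best[0] - 2 * ds, best[0] + 2 * ds
        t_lo, t_hi = max(best[1] - 2 * dt, 1e-3), best[1] + 2 * dt
    return best


class TestFitMonoexp:
    @pytest.mark.parametrize("times", [TSL, TE], ids=["TSL", "TE"])
    @pytest.mark.parametrize("t_true", [10.0, 40.0, 80.0, 120.0, 300.0, 500.0])
    def test_noiseless_exact_recovery(self, times, t_true):
        signal = 100.0 * np.exp(-times / t_true)
        fit = fit_monoexp(signal, times)
        assert fit.valid
        assert fit.t_relax == pytest.approx(t_true, rel=1e-6)
        assert fit.s0 == pytest.approx(100.0, rel=1e-6)

    def test_all_zero_signal_is_invalid_with_zero_sentinel(self):
        fit = fit_monoexp(np.zeros(4), TSL)
        assert not fit.valid
        assert fit.t_relax == 0.0

    def test_single_positive_sample_invalid(self):
        fit = fit_monoexp(np.array([50.0, 0.0, 0.0, 0.0]), TSL)
        assert not fit.valid

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            fit_monoexp(np.ones(3), TSL)

    def test_noisy_fit_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            t_true = rng.uniform(40, 150)
            signal = add_rician_noise(300.0 * np.exp(-TSL / t_true), 6.0, rng=rng)
            fit = fit_monoexp(signal, TSL)
            assert fit.valid
            s0_o, t_o = grid_search_oracle(signal, TSL, s0_range=(100.0, 600.0))
            assert fit.t_relax == pytest.approx(t_o, abs=2e-3)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        t_true=st.floats(10.0, 500.0),
        c=st.floats(0.01, 1000.0),
    )
    def test_scale_invariance(self, t_true, c):
        signal = 50.0 * np.exp(-TSL / t_true)
        base = fit_monoexp(signal, TSL)
        scaled = fit_monoexp(c * signal, TSL)
        assert scaled.t_relax == pytest.approx(base.t_relax, rel=1e-9)
        assert scaled.s0 == pytest.approx(c * base.s0, rel=1e-9)

    def test_runaway_t_declared_invalid(self):
        # nearly flat signal: fitted T blows past the physiologic bound
        signal = np.array([100.0, 99.999, 99.998, 99.997])
        fit = fit_monoexp(signal, TSL)
        assert not fit.valid
        assert fit.t_relax == 0.0


class TestFitBias:
    def test_rician_bias_below_2pct_at_snr50(self, rng):
        n = 10_000
        t_true = 80.0
        clean = 500.0 * np.exp(-TSL[None, :] / t_true)
        signals = add_rician_noise(np.broadcast_to(clean, (n, 4)), 10.0, rng=rng)
        _, T, _, valid = fit_pixels(signals, TSL)
        bias = T[valid].mean() - t_true
        assert abs(bias) / t_true < 0.02

    def test_rmse_degrades_monotonically_with_snr(self, rng):
        t_true = 80.0
        rmses = []
        for snr in (100, 50, 25, 10):
            clean = 500.0 * np.exp(-TSL[None, :] / t_true)
            signals = add_rician_noise(
                np.broadcast_to(clean, (5000, 4)), 500.0 / snr, rng=rng
            )
            _, T, _, valid = fit_pixels(signals, TSL)
            rmses.append(np.sqrt(np.mean((T[valid] - t_true) ** 2)))
        assert all(b >= a for a, b in zip(rmses, rmses[1:]))


class TestComputeMap:
    def _series(self, t_map, times=TSL, s0=200.0):
        tissue = t_map > 0
        frames = [
            np.where(tissue, s0 * np.exp(-t / np.where(tissue, t_map, 1.0)), 0.0)
            for t in times
        ]
        return ImageSeries(frames=np.stack(frames), weight_times=times, modality="T1RHO")

    def test_uniform_phantom_uniform_map(self):
        t_map = np.full((10, 10), 90.0)
        series = self._series(t_map)
        roi = RoiMask(mask=np.ones((10, 10), bool), side="LM", segment="BD")
        pmap = compute_map(series, roi)
        assert pmap.valid_mask.all()
        np.testing.assert_allclose(pmap.values, 90.0, rtol=1e-9)

    def test_two_region_phantom_exact(self):
        t_map = np.full((8, 8), 80.0)
        t_map[:, 4:] = 100.0
        series = self._series(t_map)
        roi = RoiMask(mask=np.ones((8, 8), bool), side="LM", segment="BD")
        pmap = compute_map(series, roi)
        np.testing.assert_allclose(pmap.values[:, :4], 80.0, rtol=1e-9)
        np.testing.assert_allclose(pmap.values[:, 4:], 100.0, rtol=1e-9)

    def test_pixels_outside_roi_are_zero_invalid(self):
        t_map = np.full((6, 6), 70.0)
        series = self._series(t_map)
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        pmap = compute_map(series, RoiMask(mask=mask, side="MM", segment="AH"))
        assert pmap.valid_mask.sum() == 4
        assert np.all(pmap.values[~mask] == 0)

    def test_rician_phantom_mean_within_2pct(self, rng):
        t_true = 85.0
        t_map = np.full((40, 40), t_true)  # 1600 pixels
        series = self._series(t_map, s0=500.0)
        noisy = ImageSeries(
            frames=np.stack(
                [add_rician_noise(f, 10.0, rng=rng) for f in series.frames]
            ),
            weight_times=series.weight_times,
            modality="T1RHO",
        )
        roi = RoiMask(mask=np.ones((40, 40), bool), side="MM", segment="BD")
        pmap = exclude_invalid(compute_map(noisy, roi))
        mean = pmap.values[pmap.valid_mask].mean()
        assert mean == pytest.approx(t_true, rel=0.02)

    def test_empty_roi_warns(self):
        series = self._series(np.full((5, 5), 60.0))
        with pytest.warns(UserWarning):
            roi = RoiMask(mask=np.zeros((5, 5), bool), side="LM", segment="PH")
        with pytest.warns(UserWarning, match="empty ROI"):
            pmap = compute_map(series, roi)
        assert not pmap.valid_mask.any()


class TestExcludeInvalid:
    def test_zero_sentinel_pixels_excluded(self):
        from meniscoq.relaxometry import ParameterMap

        values = np.array([[0.0, 10.0, 20.0]])
        pmap = ParameterMap(
            values=values,
            s0_map=np.ones_like(values),
            valid_mask=np.ones_like(values, bool),
            modality="T2",
        )
        out = exclude_invalid(pmap)
        assert out.valid_mask.sum() == 2
        # idempotent
        again = exclude_invalid(out)
        np.testing.assert_array_equal(again.valid_mask, out.valid_mask)

    def test_all_valid_map_unchanged(self):
        from meniscoq.relaxometry import ParameterMap

        values = np.array([[10.0, 20.0]])
        pmap = ParameterMap(
            values=values,
            s0_map=np.ones_like(values),
            valid_mask=np.ones_like(values, bool),
            modality="T2",
        )
        out = exclude_invalid(pmap)
        np.testing.assert_array_equal(out.valid_mask, pmap.valid_mask)
        np.testing.assert_array_equal(out.values, pmap.values)

    def test_forced_invalid_count_matches_generator_record(self):
        from meniscoq.phantom import PhantomSpec, generate_phantom

        spec = PhantomSpec(seed=11, n_slices=1, invalid_fraction=0.1)
        study = generate_phantom(spec)
        gt = study.ground_truth
        seq, sl = "bFFE_T1rho", 0
        series = study.series[(seq, sl)]
        mask = gt.side_masks[("MM", sl)]
        roi = RoiMask(mask=mask, side="MM", segment="BD")
        pmap = exclude_invalid(compute_map(series, roi))
        forced = gt.forced_invalid[(seq, sl)] & mask
        assert forced.sum() > 0
        # every forced pixel is invalid, and the valid count matches
        assert not pmap.valid_mask[forced].any()
        assert pmap.valid_mask.sum() == mask.sum() - forced.sum()
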