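"""gCNR, depth-SNR and PSF metric correctness and invariances."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pocusqa as pq
from pocusqa.synthetic_phantom import apply_gain


def gcnr_bruteforce(fg, bg, edges):
    """Independent min-sum oracle: explicit per-bin counting on shared edges."""
    fg, bg = np.asarray(fg, float), np.asarray(bg, float)
    overlap = 0.0
    for lo, hi, last in zip(
        edges[:-1], edges[1:], [False] * (len(edges) - 2) + [True]
    ):
        inside_f = (fg >= lo) & ((fg <= hi) if last else (fg < hi))
        inside_b = (bg >= lo) & ((bg <= hi) if last else (bg < hi))
        overlap += min(inside_f.sum() / fg.size, inside_b.sum() / bg.size)
    return 1.0 - overlap


class TestGcnr:
    def test_identical_sets_give_zero(self, rng):
        x = rng.integers(0, 256, size=1000).astype(float)
        assert pq.gcnr(x, x, n_bins=64) == 0.0

    def test_disjoint_sets_give_one(self, rng):
        fg = rng.uniform(0, 50, 500)
        bg = rng.uniform(200, 250, 500)
        assert pq.gcnr(fg, bg, n_bins=64, value_range=(0, 250)) == 1.0

    def test_partial_overlap_hand_example(self):
        # fg {0,0,1,1}, bg {1,1,2,2} on unit bins: shared mass 0.5
        value = pq.gcnr([0, 0, 1, 1], [1, 1, 2, 2], n_bins=[0, 1, 2, 3])
        assert value == pytest.approx(0.5)

    def test_degenerate_range_single_value(self):
        assert pq.gcnr([5.0, 5.0], [5.0, 5.0, 5.0]) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pq.gcnr([], [1.0])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        data=st.data(),
        n_fg=st.integers(2, 40),
        n_bg=st.integers(2, 40),
        n_bins=st.integers(1, 32),
    )
    def test_matches_bruteforce_oracle(self, data, n_fg, n_bg, n_bins):
        """Implementation equals the explicit min-sum to machine precision."""
        vals = st.floats(0, 255, allow_nan=False)
        fg = np.array(data.draw(st.lists(vals, min_size=n_fg, max_size=n_fg)))
        bg = np.array(data.draw(st.lists(vals, min_size=n_bg, max_size=n_bg)))
        pooled = np.concatenate([fg, bg])
        if pooled.min() == pooled.max():
            return
        edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
        got = pq.gcnr(fg, bg, n_bins=n_bins)
        expected = gcnr_bruteforce(fg, bg, edges)
        assert got == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= got <= 1.0

    def test_monotone_map_invariance_with_quantile_bins(self, rng):
        fg = rng.rayleigh(1.0, 4000)
        bg = rng.rayleigh(1.6, 4000)
        base = pq.gcnr(fg, bg, n_bins=32, binning="quantile")
        mapped = pq.gcnr(np.log1p(fg) ** 2, np.log1p(bg) ** 2, n_bins=32, binning="quantile")
        assert mapped == pytest.approx(base, abs=1e-12)


class TestGcnrForTarget:
    def test_contrast_ordering_minus9_vs_minus3(self, triplicate):
        _, images, mask, _ = triplicate
        by_db = {}
        for tid in mask.ids_of_kind("contrast_target"):
            vals = [pq.gcnr_for_target(img, mask, tid).value for img in images]
            by_db[mask.legend[tid].contrast_db] = np.mean(vals)
        assert by_db[-9.0] > by_db[-3.0]

    def test_zero_db_target_small_gcnr(self):
        spec = dataclasses.replace(
            pq.default_spec(seed=4),
            contrast_targets=[pq.ContrastTargetSpec(20.0, 40.0, contrast_db=0.0)],
        )
        img, mask, _ = pq.generate_phantom(spec)
        tid = mask.ids_of_kind("contrast_target")[0]
        assert pq.gcnr_for_target(img, mask, tid, n_bins=64).value < 0.15

    def test_empty_background_rejected(self):
        img = pq.PhantomImage(np.ones((10, 10)), 0.1, 0.1)
        labels = np.zeros((10, 10), dtype=int)
        labels[2:6, 2:6] = 7  # label fills its tight box exactly
        mask = pq.LabelMask(labels, {7: pq.LabelEntry(kind="contrast_target")})
        with pytest.raises(ValueError, match="background"):
            pq.gcnr_for_target(img, mask, 7, pad_mm=0.0)


class TestGainSweep:
    def test_single_replicate_mean_is_identity(self):
        res = [pq.GcnrResult(0.4, target_contrast_db=-3.0, gain_setting=0.5)]
        mean_table, best = pq.gain_sweep_summary(res)
        assert mean_table["mean_gcnr"].tolist() == [0.4]
        assert best["best_gain"].tolist() == [0.5]

    def test_blank_images_at_zero_gain_give_zero(self, triplicate):
        _, images, mask, _ = triplicate
        blank = apply_gain(images[0], 0.0)
        for tid in mask.ids_of_kind("contrast_target"):
            assert pq.gcnr_for_target(blank, mask, tid).value == 0.0

    def test_saturation_moves_optimum_to_interior_gain(self, triplicate):
        """Deep clipping at full gain degrades the +3 dB target, so the
        best mean gCNR sits at an intermediate gain setting."""
        _, images, mask, _ = triplicate
        results = []
        for gain in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            for rep, img in enumerate(images):
                out = apply_gain(img, gain)
                for tid in mask.ids_of_kind("contrast_target"):
                    results.append(
                        pq.gcnr_for_target(
                            out, mask, tid, replicate_id=rep, gain_setting=gain
                        )
                    )
        _, best = pq.gain_sweep_summary(results)
        row = best[best["target_contrast_db"] == 3.0]
        assert 0.0 < row["best_gain"].iloc[0] < 1.0


class TestSnrCurve:
    def test_hand_example_row(self):
        img = pq.PhantomImage(np.array([[8.0, 12.0, 8.0, 12.0]]), 0.1, 0.1)
        sig, noi, snr = pq.snr_curve(img, pq.RoiBox(0, 1, 0, 4))
        assert sig.value[0] == 10.0
        assert noi.value[0] == 2.0  # population std
        assert snr.value[0] == 5.0

    def test_constant_row_flagged_undefined(self):
        img = pq.PhantomImage(np.array([[10.0, 10.0, 10.0], [1.0, 2.0, 3.0]]), 0.1, 0.1)
        _, _, snr = pq.snr_curve(img, pq.RoiBox(0, 2, 0, 3))
        assert np.isnan(snr.value[0]) and np.isfinite(snr.value[1])
        assert snr.defined.tolist() == [False, True]

    def test_scale_invariance(self, rng):
        arr = rng.rayleigh(30, size=(50, 20))
        img = pq.PhantomImage(arr, 0.1, 0.1)
        img2 = pq.PhantomImage(3.0 * arr, 0.1, 0.1)
        box = pq.RoiBox(0, 50, 0, 20)
        s1, n1, r1 = pq.snr_curve(img, box)
        s2, n2, r2 = pq.snr_curve(img2, box)
        np.testing.assert_allclose(s2.value, 3 * s1.value)
        np.testing.assert_allclose(n2.value, 3 * n1.value)
        np.testing.assert_allclose(r2.value, r1.value)

    def test_narrow_box_rejected(self):
        img = pq.PhantomImage(np.ones((5, 5)), 0.1, 0.1)
        with pytest.raises(ValueError):
            pq.snr_curve(img, pq.RoiBox(0, 5, 2, 3))

    def test_structures_in_box_rejected(self, triplicate):
        _, images, mask, _ = triplicate
        box = pq.RoiBox(100, 200, 200, 280)  # overlaps the -9 dB disc
        with pytest.raises(ValueError, match="structure"):
            pq.snr_curve(images[0], box, mask=mask)

    def test_rayleigh_speckle_recovery(self):
        spec = dataclasses.replace(pq.default_spec(seed=6), decay_per_mm=0.0)
        img = pq.simulate_speckle(spec)
        box = pq.RoiBox(0, 450, 660, 690)  # 3 mm wide at 0.1 mm spacing
        _, _, snr = pq.snr_curve(img, box)
        assert np.nanmean(snr.value) == pytest.approx(pq.RAYLEIGH_SNR, rel=0.05)


class TestWindowAverage:
    def test_single_window_mean(self):
        c = pq.DepthCurve(np.arange(1.0, 6.0), np.arange(1.0, 6.0), "snr")
        out = pq.window_average(c, window_mm=5.0)
        assert out.value.tolist() == [3.0]
        assert out.depth_mm.tolist() == [3.5]

    def test_constant_curve_idempotent(self):
        c = pq.DepthCurve(np.arange(0.0, 20.0, 0.1), np.full(200, 7.0), "signal")
        out = pq.window_average(c)
        np.testing.assert_allclose(out.value, 7.0)

    def test_undefined_rows_excluded_from_window_mean(self):
        c = pq.DepthCurve(np.arange(4.0), np.array([1.0, 2.0, np.nan, 4.0]), "snr")
        out = pq.window_average(c, window_mm=5.0)
        assert out.value.tolist() == [pytest.approx((1 + 2 + 4) / 3)]


class TestLineProfile:
    def test_constant_rows_give_constant_profile(self):
        arr = np.tile(np.arange(40.0)[:, None], (1, 40))
        img = pq.PhantomImage(arr, 0.1, 0.1)
        offs, ints = pq.extract_line_profile(img, (20.0, 20.0), "horizontal", 3.0)
        np.testing.assert_allclose(ints, arr[20, 0])

    def test_sample_count_3mm_at_0p1mm(self):
        img = pq.PhantomImage(np.zeros((60, 60)), 0.1, 0.1)
        offs, ints = pq.extract_line_profile(img, (30.0, 30.0), "vertical", 3.0)
        assert offs.size == 31  # 2*15 + 1
        assert offs[0] == pytest.approx(-1.5) and offs[-1] == pytest.approx(1.5)

    def test_wire_profile_peaks_at_centroid(self):
        img = pq.render_wire(
            pq.PhantomImage(np.zeros((200, 200)), 0.1, 0.1), (10.0, 10.0), 0.2, 0.3
        )
        offs, ints = pq.extract_line_profile(img, (100.0, 100.0), "horizontal", 3.0)
        assert abs(offs[np.argmax(ints)]) <= 0.1 + 1e-12

    def test_centroid_outside_image(self):
        img = pq.PhantomImage(np.zeros((10, 10)), 0.1, 0.1)
        with pytest.raises(ValueError):
            pq.extract_line_profile(img, (20.0, 5.0), "horizontal")


def _gaussian_profile(sigma=0.3, spacing=0.05, half_mm=1.5, shift=0.0, noise=0.0, rng=None):
    offs = np.arange(-half_mm, half_mm + spacing / 2, spacing)
    ints = 100.0 * np.exp(-0.5 * ((offs - shift) / sigma) ** 2)
    if noise:
        ints = ints + rng.normal(0, noise, offs.size)
    return offs, ints


class TestAlignAndAverage:
    def test_shift_cancellation(self):
        p0 = _gaussian_profile()
        p1 = _gaussian_profile(shift=0.05)  # one sample to the right
        mean = pq.align_and_average_psf([p0, p1])
        interp = np.interp(mean.offsets_mm, p0[0], p0[1])
        np.testing.assert_allclose(mean.intensities, interp, atol=1e-9)
        assert mean.offsets_mm[np.argmax(mean.intensities)] == pytest.approx(0.0)

    def test_single_profile_identity(self):
        p0 = _gaussian_profile()
        mean = pq.align_and_average_psf([p0])
        assert mean.n_replicates == 1
        assert mean.offsets_mm[np.argmax(mean.intensities)] == pytest.approx(0.0)
        np.testing.assert_allclose(mean.intensities, p0[1], atol=1e-9)

    def test_flat_profile_names_replicate(self):
        p0 = _gaussian_profile()
        flat = (p0[0], np.full_like(p0[1], 5.0))
        with pytest.raises(ValueError, match="replicate 1"):
            pq.align_and_average_psf([p0, flat])

    def test_noisy_triplicate_width_within_10pct(self, rng):
        profiles = [
            _gaussian_profile(noise=5.0, rng=rng, shift=s) for s in (0.0, 0.05, -0.05)
        ]
        mean = pq.align_and_average_psf(profiles)
        assert pq.psf_width(mean) == pytest.approx(pq.gaussian_fwhm(0.3), rel=0.10)


class TestPsfWidth:
    def test_exact_gaussian(self):
        assert pq.psf_width(_gaussian_profile()) == pytest.approx(
            pq.gaussian_fwhm(0.3), rel=0.01
        )

    def test_rectangular_pulse(self):
        offs = np.arange(-2.0, 2.0 + 0.025, 0.05)
        ints = np.where(np.abs(offs) <= 0.5, 80.0, 0.0)
        assert pq.psf_width((offs, ints)) == pytest.approx(1.0, abs=0.05)

    def test_baseline_and_scale_invariance(self):
        offs, ints = _gaussian_profile()
        w = pq.psf_width((offs, ints))
        assert pq.psf_width((offs, ints + 50.0)) == pytest.approx(w, rel=1e-6)
        assert pq.psf_width((offs, ints * 7.0)) == pytest.approx(w, rel=1e-6)

    @pytest.mark.parametrize("sigmas", [(0.1, 0.2), (0.2, 0.5), (0.5, 1.0)])
    def test_monotone_in_sigma(self, sigmas):
        lo, hi = sigmas
        w_lo = pq.psf_width(_gaussian_profile(sigma=lo, half_mm=4.0))
        w_hi = pq.psf_width(_gaussian_profile(sigma=hi, half_mm=4.0))
        assert w_hi > w_lo

    def test_uncrossed_half_max_rejected(self):
        # peak at the window edge: the left crossing cannot exist
        offs = np.arange(0.0, 1.0, 0.05)
        ints = 100.0 * np.exp(-0.5 * (offs / 0.2) ** 2)
        with pytest.raises(ValueError):
            pq.psf_width((offs, ints))
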