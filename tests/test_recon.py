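"""Reconstruction chain: preprocessing, k-linearization, dispersion,
mirror-peak oracles."""

import numpy as np
import pytest
from scipy.signal.windows import hann

from limbusoct.phantom import (
    ScattererColumn,
    SourceSpectrumModel,
    build_source_spectrum,
    synthesize_interferogram,
)
from limbusoct.recon import (
    BackgroundSpectrum,
    DispersionModel,
    KMap,
    SpectralFrame,
    apply_dispersion_correction,
    apply_window,
    estimate_dispersion,
    k_linearize,
    normalize_by_background,
    reconstruct_bscan,
    subtract_background,
    transform_to_depth,
    upsample_2x,
)


def linear_aline(image, col=0):
    return 10 ** (image.data[:, col] / 20)


def fwhm_rows(profile):
    p = np.asarray(profile, dtype=float)
    p = p / p.max()
    i = int(np.argmax(p))

    def cross(side):
        j = i
        while 0 < j < p.size - 1 and p[j] > 0.5:
            j += side
        a, b = p[j - side], p[j]
        return (j - side) + side * (a - 0.5) / (a - b)

    return cross(+1) - cross(-1)


class TestPreprocessing:
    def test_subtract_background_identity_cases(self, background):
        bg = background.counts
        frame = SpectralFrame(np.tile(bg[:, None], (1, 3)), np.linspace(0.78, 0.92, bg.size))
        assert np.allclose(subtract_background(frame, background), 0.0)
        # an (effectively) zero background leaves the frame unchanged
        zero_bg = BackgroundSpectrum(np.full(bg.size, 1e-12))
        assert np.allclose(subtract_background(frame, zero_bg), frame.data, atol=1e-9)

    def test_subtract_background_shape_mismatch(self, background):
        frame = SpectralFrame(np.zeros((100, 2)), np.linspace(0.78, 0.92, 100))
        with pytest.raises(ValueError):
            subtract_background(frame, background)

    def test_normalize_flat_background_is_identity(self):
        bg = BackgroundSpectrum(np.full(64, 7.0))
        m = np.random.default_rng(0).normal(size=(64, 4))
        assert np.allclose(normalize_by_background(m, bg), m)

    def test_normalize_flattens_gaussian_envelope(self, wavelength_grid, source_spectrum, background):
        fr = synthesize_interferogram(
            ScattererColumn([400.0], [0.0]), source_spectrum, wavelength_grid
        )  # zero-amplitude scatterer: pure envelope
        out = normalize_by_background(fr.data, background)[:, 0]
        band = source_spectrum > 0.3 * source_spectrum.max()
        ratio = out[band] / out[band].max()
        assert np.all(ratio > 0.999)

    def test_normalize_clamps_below_floor(self):
        bg = BackgroundSpectrum(np.concatenate([[1e-9], np.ones(63)]))
        m = np.ones((64, 1))
        out = normalize_by_background(m, bg)
        assert np.all(np.isfinite(out))
        assert out[0, 0] == pytest.approx(1.0 / 1e-3)

    def test_window_is_elementwise_hann(self):
        m = np.ones((128, 2))
        out = apply_window(m)
        w = hann(128, sym=True)
        assert np.allclose(out, np.tile(w[:, None], (1, 2)))
        assert out[0, 0] == 0.0 and out[-1, 0] == 0.0

    def test_windowed_mirror_sidelobes_below_minus_31db(self, uniform_k_grid):
        flat = np.full(uniform_k_grid.size, 100.0)
        bg = BackgroundSpectrum(flat)
        km = KMap(uniform_k_grid)
        dz = km.upsampled().depth_pixel_um
        # worst-case half-bin offsets included
        for zbins in (400.0, 400.5, 611.25):
            fr = synthesize_interferogram(
                ScattererColumn([zbins * dz], [0.05]), flat, uniform_k_grid
            )
            img = reconstruct_bscan(fr, bg, km)
            a = linear_aline(img)
            pk = int(np.argmax(a))
            rel = 20 * np.log10(a / a.max())
            mask = np.ones(a.size, bool)
            mask[max(0, pk - 4): pk + 5] = False
            assert rel[mask].max() < -31.0


class TestUpsampling:
    def test_output_length_doubles(self):
        m = np.random.default_rng(1).normal(size=(256, 3))
        assert upsample_2x(m).shape == (512, 3)

    def test_band_limited_samples_recovered_at_even_indices(self):
        n = 256
        i = np.arange(n)
        m = (np.cos(2 * np.pi * 20 * i / n) + 0.3 * np.sin(2 * np.pi * 7 * i / n))[:, None]
        up = upsample_2x(m)
        assert np.allclose(up[::2].real, m, atol=1e-10)
        assert np.allclose(up.imag, 0.0, atol=1e-10)

    def test_odd_length_rejected(self):
        with pytest.raises(ValueError):
            upsample_2x(np.zeros((255, 1)))

    def test_peak_depth_unchanged_by_upsampling(self, wavelength_grid, source_spectrum, background, kmap):
        z = 700.0
        fr = synthesize_interferogram(
            ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid
        )
        with_up = reconstruct_bscan(fr, background, kmap, upsample=True)
        without = reconstruct_bscan(fr, background, kmap, upsample=False)
        for img in (with_up, without):
            row = int(np.argmax(img.data[:, 0]))
            assert abs(img.depth_of_row(row) - z) <= img.axial_pitch_um


class TestKLinearize:
    def test_identity_on_uniform_k_input(self, uniform_k_grid):
        km = KMap(uniform_k_grid)
        rng = np.random.default_rng(2)
        m = rng.normal(size=(uniform_k_grid.size, 2))
        out = k_linearize(m, km)
        # data sorted by ascending k = reversed wavelength order
        assert np.allclose(out, m[::-1], atol=1e-8)

    def test_extrapolation_rejected(self, wavelength_grid):
        km = KMap(wavelength_grid)
        km.k_out = km.k_out + 0.1  # push the grid outside the source range
        with pytest.raises(ValueError):
            k_linearize(np.zeros((wavelength_grid.size, 1)), km)

    def test_chirped_fringe_recovers_transform_limited_width(
        self, wavelength_grid, source_spectrum, background, kmap, uniform_k_grid
    ):
        # uniform-lambda sampling chirps the fringe; after k-linearization
        # the PSF width must be within 10% of a natively uniform-k synthesis
        z = 900.0
        fr = synthesize_interferogram(
            ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid
        )
        img = reconstruct_bscan(fr, background, kmap)
        src_k = build_source_spectrum(SourceSpectrumModel(), uniform_k_grid)
        fr_k = synthesize_interferogram(
            ScattererColumn([z], [0.05]), src_k, uniform_k_grid
        )
        img_k = reconstruct_bscan(fr_k, BackgroundSpectrum(src_k), KMap(uniform_k_grid))
        w = fwhm_rows(linear_aline(img))
        w_k = fwhm_rows(linear_aline(img_k))
        assert w == pytest.approx(w_k, rel=0.10)


class TestDispersion:
    def test_zero_coefficients_identity(self, kmap):
        up = kmap.upsampled()
        m = np.random.default_rng(0).normal(size=(up.k_out.size, 2)).astype(complex)
        model = DispersionModel(k0=float(up.k_out.mean()))
        assert np.allclose(apply_dispersion_correction(m, model, up), m)

    def test_real_input_signals_pipeline_order_bug(self, kmap):
        up = kmap.upsampled()
        model = DispersionModel(k0=float(up.k_out.mean()), c2=1.0)
        with pytest.raises(TypeError):
            apply_dispersion_correction(np.ones((up.k_out.size, 1)), model, up)

    def test_forward_inverse_restores_psf_width(
        self, wavelength_grid, source_spectrum, background, kmap
    ):
        z = 800.0
        k0 = float(kmap.upsampled().k_out.mean())
        true = DispersionModel(k0=k0, c2=30.0, c3=10.0)
        fr0 = synthesize_interferogram(
            ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid
        )
        fr = synthesize_interferogram(
            ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid, dispersion=true
        )
        w_limit = fwhm_rows(linear_aline(reconstruct_bscan(fr0, background, kmap)))
        w_corr = fwhm_rows(
            linear_aline(reconstruct_bscan(fr, background, kmap, dispersion=true))
        )
        w_unc = fwhm_rows(linear_aline(reconstruct_bscan(fr, background, kmap)))
        w_wrong = fwhm_rows(
            linear_aline(
                reconstruct_bscan(
                    fr, background, kmap,
                    dispersion=DispersionModel(k0=k0, c2=-30.0, c3=-10.0),
                )
            )
        )
        assert w_corr == pytest.approx(w_limit, rel=0.05)
        assert w_unc > 2 * w_limit
        assert w_wrong > w_unc  # wrong sign doubles the phase error

    def test_null_recovery_on_dispersion_free_mirror(
        self, wavelength_grid, source_spectrum, background, kmap
    ):
        fr = synthesize_interferogram(
            ScattererColumn([600.0], [0.05]), source_spectrum, wavelength_grid
        )
        est = estimate_dispersion([fr], background, kmap)
        assert abs(est.c2) < 0.5
        assert abs(est.c3) < 0.5

    def test_known_coefficients_recovered_within_5pct(
        self, wavelength_grid, source_spectrum, background, kmap
    ):
        k0 = float(kmap.upsampled().k_out.mean())
        true = DispersionModel(k0=k0, c2=30.0, c3=10.0)
        frames = [
            synthesize_interferogram(
                ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid,
                dispersion=true, frame_id=i,
            )
            for i, z in enumerate((500.0, 1100.0))
        ]
        est = estimate_dispersion(frames, background, kmap)
        assert est.c2 == pytest.approx(30.0, rel=0.05)
        assert est.c3 == pytest.approx(10.0, rel=0.05)

    def test_estimates_depth_independent(
        self, wavelength_grid, source_spectrum, background, kmap
    ):
        k0 = float(kmap.upsampled().k_out.mean())
        true = DispersionModel(k0=k0, c2=30.0, c3=10.0)
        ests = []
        for z in (400.0, 1400.0):
            fr = synthesize_interferogram(
                ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid,
                dispersion=true,
            )
            ests.append(estimate_dispersion([fr], background, kmap))
        assert ests[0].c2 == pytest.approx(ests[1].c2, rel=0.02)
        assert ests[0].c3 == pytest.approx(ests[1].c3, rel=0.05)


class TestReconstruct:
    def test_mirror_peak_localized_within_one_row(
        self, wavelength_grid, source_spectrum, background, kmap
    ):
        for z in np.linspace(100.0, 1900.0, 21):
            fr = synthesize_interferogram(
                ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid
            )
            img = reconstruct_bscan(fr, background, kmap)
            row = int(np.argmax(img.data[:, 0]))
            assert abs(img.depth_of_row(row) - z) <= img.axial_pitch_um

    def test_degenerate_path_equals_windowed_fft(self, uniform_k_grid):
        # uniform-in-k input, identity resampling, zero dispersion: the
        # pipeline must match a plain zero-padded windowed FFT oracle
        n = uniform_k_grid.size
        src = build_source_spectrum(SourceSpectrumModel(), uniform_k_grid)
        bg = BackgroundSpectrum(src)
        fr = synthesize_interferogram(
            ScattererColumn([800.0], [0.05]), src, uniform_k_grid
        )
        img = reconstruct_bscan(fr, bg, KMap(uniform_k_grid))
        pipeline = 10 ** (img.data[:, 0] / 20)

        d = (fr.data[:, 0] - src) / np.maximum(bg.normalized, 1e-3)
        d = (d * hann(n, sym=True))[::-1]  # ascending-k order
        spec = np.fft.fft(d)
        pad = np.zeros(2 * n, dtype=complex)
        pad[: n // 2] = spec[: n // 2]
        pad[n // 2] = 0.5 * spec[n // 2]
        pad[2 * n - n // 2] = 0.5 * spec[n // 2]
        pad[2 * n - n // 2 + 1:] = spec[n // 2 + 1:]
        # the pipeline keeps 2n-1 upsampled samples (the trailing
        # half-pixel is wrap-contaminated and dropped by the k map)
        u = 2 * np.fft.ifft(pad)
        m = 2 * n - 1
        oracle = np.abs(np.fft.fft(u[:m]))[: m // 2][::-1]
        assert np.max(np.abs(pipeline - oracle)) < 1e-6 * pipeline.max()

    def test_pure_background_frame_is_flat_noise_floor(
        self, wavelength_grid, source_spectrum, background
    ):
        rng = np.random.default_rng(5)
        data = source_spectrum[:, None] + 0.001 * source_spectrum.max() * rng.standard_normal(
            (wavelength_grid.size, 16)
        )
        fr = SpectralFrame(data, wavelength_grid)
        img = reconstruct_bscan(fr, background, KMap(wavelength_grid))
        # no depth has structure: within the raw unambiguous band (the
        # bottom half of the frame; the upsampled extension above it is
        # band-limited and carries no noise energy) the laterally averaged
        # intensity stays within 6 dB of the median row.  DC rows excluded.
        n_rows = img.data.shape[0]
        lin = 10 ** (img.data[n_rows // 2: -8] / 10)  # intensity
        row_db = 10 * np.log10(lin.mean(axis=1))
        assert row_db.max() - np.median(row_db) < 6.0
        # and the extended band stays below that floor
        ext_db = 10 * np.log10((10 ** (img.data[: n_rows // 2] / 10)).mean(axis=1))
        assert ext_db.max() <= np.median(row_db) + 6.0

    def test_orientation_flip_invariance(self, wavelength_grid, source_spectrum, background, kmap):
        z = 650.0
        fr = synthesize_interferogram(
            ScattererColumn([z], [0.05]), source_spectrum, wavelength_grid
        )
        img = reconstruct_bscan(fr, background, kmap)
        flipped = SpectralFrame(fr.data[::-1], wavelength_grid[::-1])
        img_f = reconstruct_bscan(
            flipped, BackgroundSpectrum(background.counts[::-1]), KMap(wavelength_grid[::-1])
        )
        # compare in the linear domain: the log map amplifies meaningless
        # differences deep in the numerical noise floor
        a = 10 ** (img.data / 20)
        b = 10 ** (img_f.data / 20)
        assert np.max(np.abs(a - b)) < 1e-6 * a.max()

    def test_stage_errors_carry_stage_name(self, wavelength_grid, background, kmap):
        bad = SpectralFrame(np.zeros((100, 1)), np.linspace(0.78, 0.92, 100))
        with pytest.raises(ValueError, match="subtract_background"):
            reconstruct_bscan(bad, background, kmap)

    def test_provenance_records_the_chain(self, wavelength_grid, source_spectrum, background, kmap):
        fr = synthesize_interferogram(
            ScattererColumn([500.0], [0.05]), source_spectrum, wavelength_grid
        )
        img = reconstruct_bscan(fr, background, kmap)
        assert img.provenance == [
            "subtract_background", "normalize_by_background", "apply_window",
            "upsample_2x", "k_linearize", "apply_dispersion_correction",
            "transform_to_depth(log)",
        ]
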