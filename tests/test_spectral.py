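"""Spectral processing: baseline, denoising, normalisation, detection,
annotation and envelope deconvolution."""

from __future__ import annotations

import numpy as np
import pytest

from abmsi.masslist import make_variant
from abmsi.spectral import (
    AmbiguityError,
    InvalidConfigError,
    ProcessingConfig,
    Spectrum,
    annotate_matrix,
    annotate_peptides,
    deconvolve_envelopes,
    detect_peaks,
    estimate_noise,
    process_matrix,
    subtract_baseline,
    tic_normalize,
    weak_denoise,
)
from conftest import gaussian_peak

MZ = np.arange(3950.0, 4600.0, 0.1)
FWHM = 0.625


def envelope_signal(mz, variant, amplitude, fwhm=FWHM):
    """Unit-apex-per-probability envelope rendering (generator convention)."""
    out = np.zeros_like(mz)
    for p, pos in zip(variant.envelope.probabilities, variant.envelope.mz_positions):
        if p >= 1e-4:
            out += gaussian_peak(mz, pos, fwhm, amplitude * p)
    return out


class TestBaseline:
    def test_constant_spectrum_removed(self):
        s = Spectrum(MZ, np.full_like(MZ, 7.5))
        out = subtract_baseline(s, 15.0)
        assert np.allclose(out.intensities, 0.0)

    def test_peak_on_ramp_preserved(self):
        ramp = 0.01 * (MZ - MZ[0])
        peak = gaussian_peak(MZ, 4200.0, 0.8, 100.0)
        out = subtract_baseline(Spectrum(MZ, ramp + peak), 15.0)
        apex = out.intensities[np.argmin(np.abs(MZ - 4200.0))]
        assert apex >= 0.95 * 100.0
        assert (out.intensities >= 0).all()

    def test_idempotent(self):
        signal = gaussian_peak(MZ, 4100.0, 0.8, 50.0) + gaussian_peak(MZ, 4300.0, 0.8, 20.0)
        once = subtract_baseline(Spectrum(MZ, signal + 3.0), 15.0)
        twice = subtract_baseline(once, 15.0)
        assert np.allclose(once.intensities, twice.intensities, atol=1e-9)

    def test_window_wider_than_span_rejected(self):
        with pytest.raises(InvalidConfigError):
            subtract_baseline(Spectrum(MZ, np.zeros_like(MZ)), 1e4)


class TestTicNormalize:
    def test_sum_equals_target(self):
        s = Spectrum(MZ, np.abs(np.sin(MZ)))
        out = tic_normalize(s, 1.0)
        assert out.intensities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        y = np.abs(np.cos(MZ)) + 0.1
        a = tic_normalize(Spectrum(MZ, y), 1.0)
        b = tic_normalize(Spectrum(MZ, 2 * y), 1.0)
        assert np.allclose(a.intensities, b.intensities)

    def test_all_zero_flagged(self):
        with pytest.raises(ValueError, match="empty pixel"):
            tic_normalize(Spectrum(MZ, np.zeros_like(MZ)), 1.0)

    def test_generator_shares_preserved(self, narrow_masslist):
        """Noiseless phantom pixel scaled by a TIC factor of 1.7 keeps
        per-peptide shares after normalisation."""
        v1, v2 = narrow_masslist[0], narrow_masslist[-1]
        y = envelope_signal(MZ, v1, 60.0) + envelope_signal(MZ, v2, 40.0)
        plain = tic_normalize(Spectrum(MZ, y), 1.0)
        scaled = tic_normalize(Spectrum(MZ, 1.7 * y), 1.0)
        assert np.allclose(plain.intensities, scaled.intensities, atol=1e-6)


class TestWeakDenoise:
    def test_zeros_stay_zero(self):
        out = weak_denoise(Spectrum(MZ, np.zeros_like(MZ)))
        assert np.allclose(out.intensities, 0.0)

    def test_fwhm_broadening_bounded(self):
        peak = gaussian_peak(MZ, 4200.0, FWHM, 100.0)
        out = weak_denoise(Spectrum(MZ, peak))

        def fwhm_of(y):
            above = MZ[y >= y.max() / 2]
            return above[-1] - above[0]

        assert fwhm_of(out.intensities) <= 1.10 * fwhm_of(peak)

    def test_batch_equals_per_pixel(self):
        rng = np.random.default_rng(3)
        Y = rng.gamma(2.0, 1.0, size=(2, len(MZ)))
        cfg = ProcessingConfig()
        batch, _ = process_matrix(Y, MZ, cfg)
        singles = np.vstack([process_matrix(Y[i : i + 1], MZ, cfg)[0] for i in range(2)])
        assert np.allclose(batch, singles)


class TestNoiseEstimate:
    def test_iid_gaussian_recovered(self):
        rng = np.random.default_rng(7)
        mz = np.arange(0.0, 1000.0, 0.1)
        y = rng.normal(0.0, 2.0, size=len(mz))
        sigma = estimate_noise(Spectrum(mz, y), window=50.0)
        assert 1.8 <= np.median(sigma) <= 2.2

    def test_zero_away_from_peak(self):
        y = gaussian_peak(MZ, 4200.0, FWHM, 100.0)
        sigma = estimate_noise(Spectrum(MZ, y), window=50.0)
        far = np.abs(MZ - 4200.0) > 100
        assert np.median(sigma[far]) == pytest.approx(0.0, abs=1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        y = np.abs(rng.normal(0, 1, len(MZ)))
        s1 = estimate_noise(Spectrum(MZ, y))
        s2 = estimate_noise(Spectrum(MZ, 2 * y))
        assert np.allclose(s2, 2 * s1)


class TestDetectPeaks:
    def _noisy_peak(self, snr, seed=5):
        """Peak of exactly ``snr`` times the surrounding noise level.

        The apex region itself is left noise-free so the constructed SNR is
        exact rather than a draw-dependent realisation.
        """
        rng = np.random.default_rng(seed)
        noise_sd = 1.0
        peak = gaussian_peak(MZ, 4212.3, FWHM, snr * noise_sd)
        noise = rng.normal(0, noise_sd, len(MZ))
        noise[np.abs(MZ - 4212.3) < 3.0] = 0.0
        return Spectrum(MZ, peak + noise)

    def test_snr10_peak_found_near_apex(self):
        peaks = detect_peaks(self._noisy_peak(10.0))
        near = [p for p in peaks if abs(p.mz - 4212.3) < 0.05]
        assert len(near) >= 1

    def test_snr2_peak_rejected(self):
        peaks = detect_peaks(self._noisy_peak(2.0))
        assert not any(abs(p.mz - 4212.3) < 0.05 and p.snr > 3 for p in peaks)

    def test_zero_spectrum_empty(self):
        assert detect_peaks(Spectrum(MZ, np.zeros_like(MZ))) == []

    def test_sorted_by_mz(self):
        rng = np.random.default_rng(1)
        y = sum(
            gaussian_peak(MZ, c, FWHM, 50.0) for c in (4000.0, 4100.0, 4350.0)
        ) + rng.normal(0, 1, len(MZ))
        peaks = detect_peaks(Spectrum(MZ, y))
        assert [p.mz for p in peaks] == sorted(p.mz for p in peaks)


class TestAnnotation:
    def test_pure_species_detected_exclusively(self, narrow_masslist):
        rng = np.random.default_rng(9)
        v142 = next(v for v in narrow_masslist if v.name == "Abeta1-42")
        y = envelope_signal(MZ, v142, 10.0) + rng.normal(0, 1.0, len(MZ))
        s = Spectrum(MZ, y)
        ann = annotate_peptides(detect_peaks(s), s, narrow_masslist)
        det = dict(zip(ann.variant_names, ann.detected[0]))
        assert det["Abeta1-42"]
        others = [n for n, d in det.items() if d and n != "Abeta1-42"]
        assert others == []

    def test_low_snr_species_not_detected(self, narrow_masslist):
        rng = np.random.default_rng(9)
        v142 = next(v for v in narrow_masslist if v.name == "Abeta1-42")
        y = envelope_signal(MZ, v142, 2.0) + rng.normal(0, 1.0, len(MZ))
        s = Spectrum(MZ, y)
        ann = annotate_peptides(detect_peaks(s), s, narrow_masslist)
        k = ann.variant_names.index("Abeta1-42")
        assert not ann.detected[0, k]
        assert ann.abundance[0, k] == 0.0

    def test_empty_spectrum_nothing_detected(self, narrow_masslist):
        s = Spectrum(MZ, np.zeros_like(MZ))
        ann = annotate_peptides([], s, narrow_masslist)
        assert not ann.detected.any()
        assert (ann.abundance == 0).all()

    def test_abundance_nonnegative_and_consistent(self, narrow_masslist):
        rng = np.random.default_rng(21)
        v = narrow_masslist[3]
        y = envelope_signal(MZ, v, 20.0) + rng.normal(0, 1.0, len(MZ))
        ann = annotate_matrix(y, MZ, narrow_masslist, ProcessingConfig())
        assert (ann.abundance >= 0).all()
        positive = ann.abundance[0] > 0
        assert positive[ann.variant_names.index(v.name)]

    def test_scaling_invariance_after_normalisation(self, narrow_masslist):
        """Post-normalisation abundances ignore any positive raw scaling."""
        rng = np.random.default_rng(2)
        v = narrow_masslist[5]
        raw = envelope_signal(MZ, v, 30.0) + rng.gamma(1.0, 1.0, len(MZ)) + 5.0
        cfg = ProcessingConfig()
        for scale in (1.0, 7.3):
            P, empty = process_matrix(scale * raw[None, :], MZ, cfg)
            ann = annotate_matrix(P, MZ, narrow_masslist, cfg, empty_pixels=empty)
            if scale == 1.0:
                ref = ann.abundance.copy()
        assert np.allclose(ann.abundance, ref, rtol=1e-6, atol=1e-12)


@pytest.fixture(scope="module")
def overlapping_pair():
    # the classic reflector-mode showcase: envelopes ~3 Da apart
    return make_variant(1, 36), make_variant(4, 40)


class TestDeconvolution:

    def test_noiseless_70_30_recovery(self, overlapping_pair):
        v136, v440 = overlapping_pair
        y = envelope_signal(MZ, v136, 70.0) + envelope_signal(MZ, v440, 30.0)
        result, residual = deconvolve_envelopes(Spectrum(MZ, y), [v136, v440])
        total = sum(result.values())
        assert result["Abeta1-36"] / total == pytest.approx(0.70, abs=0.01)
        assert result["Abeta4-40"] / total == pytest.approx(0.30, abs=0.01)

    def test_single_component_second_zero(self, overlapping_pair):
        v136, v440 = overlapping_pair
        y = envelope_signal(MZ, v136, 50.0)
        result, _ = deconvolve_envelopes(Spectrum(MZ, y), [v136, v440])
        assert result["Abeta4-40"] <= 1e-6 * max(result.values())

    def test_snr10_monte_carlo_median_within_5_points(self, overlapping_pair):
        v136, v440 = overlapping_pair
        clean = envelope_signal(MZ, v136, 70.0) + envelope_signal(MZ, v440, 30.0)
        noise_sd = clean.max() / 10.0
        rng = np.random.default_rng(17)
        errors = []
        for _ in range(100):
            y = np.clip(clean + rng.normal(0, noise_sd, len(MZ)), 0, None)
            result, _ = deconvolve_envelopes(Spectrum(MZ, y), [v136, v440])
            share = result["Abeta1-36"] / sum(result.values())
            errors.append(abs(share - 0.70))
        assert np.median(errors) <= 0.05

    def test_identical_envelopes_raise_ambiguity(self):
        # A-beta 2-41 and 3-42 have identical elemental composition
        a, b = make_variant(2, 41), make_variant(3, 42)
        y = envelope_signal(MZ, a, 10.0)
        with pytest.raises(AmbiguityError, match="Abeta"):
            deconvolve_envelopes(Spectrum(MZ, y), [a, b])

    def test_agrees_with_annotation_for_isolated_species(self, narrow_masslist):
        v = next(v for v in narrow_masslist if v.name == "Abeta1-42")
        y = envelope_signal(MZ, v, 40.0)
        s = Spectrum(MZ, y)
        result, _ = deconvolve_envelopes(s, [v])
        ann = annotate_matrix(y, MZ, [v], ProcessingConfig(denoise="none"))
        assert result["Abeta1-42"] == pytest.approx(ann.abundance[0, 0], rel=0.02)
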