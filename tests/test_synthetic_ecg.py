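"""Generator-level tests: rhythm semantics, determinism, pool bookkeeping."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from ecgfewshot.synthetic_ecg import (
    CLASS_NAMES,
    ConfigurationError,
    GenerationError,
    LeadProjection,
    RhythmClass,
    RhythmParams,
    default_params,
    generate_labeled_set,
    generate_rr_series,
    generate_unlabeled_pool,
    synthesize_record,
)
from dataclasses import replace


def test_rhythm_classes_are_the_five_rhythms_in_fixed_order():
    assert CLASS_NAMES == ("SR", "AFIB", "STACH", "SARRH", "SBRAD")
    assert [int(c) for c in RhythmClass] == [0, 1, 2, 3, 4]


class TestRrSeries:
    def test_stach_realized_rate_is_tachycardic(self):
        rr = generate_rr_series(RhythmClass.STACH, 10.0, np.random.default_rng(1))
        assert 60.0 / rr.mean() > 100.0

    def test_zero_cv_gives_identical_intervals(self):
        params = replace(default_params(RhythmClass.SR), rr_cv=0.0)
        rr = generate_rr_series(RhythmClass.SR, 10.0, np.random.default_rng(2), params)
        assert np.allclose(rr, rr[0])

    def test_afib_is_more_irregular_than_sr_at_same_seed(self):
        rr_af = generate_rr_series(RhythmClass.AFIB, 10.0, np.random.default_rng(3))
        rr_sr = generate_rr_series(RhythmClass.SR, 10.0, np.random.default_rng(3))
        cv = lambda x: x.std() / x.mean()
        assert cv(rr_af) > cv(rr_sr)

    @pytest.mark.parametrize("cls", list(RhythmClass))
    @pytest.mark.parametrize("seed", [0, 11, 42])
    def test_mean_rate_within_class_range_and_cv_near_target(self, cls, seed):
        params = default_params(cls)
        rr = generate_rr_series(cls, 10.0, np.random.default_rng(seed), params)
        lo, hi = params.hr_range_bpm
        assert lo <= 60.0 / rr.mean() <= hi
        assert rr.sum() >= 10.0
        if len(rr) >= 8 and params.rr_cv > 0 and cls is not RhythmClass.SARRH:
            realized = rr.std() / rr.mean()
            assert 0.5 * params.rr_cv <= realized <= 1.5 * params.rr_cv

    def test_sarrh_rr_modulation_sits_in_respiratory_band(self):
        # long record so the respiratory oscillation is resolvable in the
        # beat-time spectrum
        params = replace(default_params(RhythmClass.SARRH), rr_cv=0.0)
        rr = generate_rr_series(RhythmClass.SARRH, 120.0, np.random.default_rng(5), params)
        t = np.cumsum(rr)
        grid = np.arange(0, t[-1], 0.25)
        rr_t = np.interp(grid, t, rr)
        rr_detrended = rr_t - rr_t.mean()
        freqs = np.fft.rfftfreq(len(grid), d=0.25)
        spectrum = np.abs(np.fft.rfft(rr_detrended))
        peak_freq = freqs[np.argmax(spectrum)]
        assert 0.1 <= peak_freq <= 0.45
        # relative modulation amplitude near the configured depth
        rel_amp = (rr_t.max() - rr_t.min()) / (2 * rr_t.mean())
        assert rel_amp == pytest.approx(params.resp_mod_depth, rel=0.5)

    def test_infeasible_rate_for_duration_raises(self):
        params = replace(default_params(RhythmClass.SBRAD), hr_range_bpm=(21, 22))
        with pytest.raises(GenerationError):
            generate_rr_series(RhythmClass.SBRAD, 0.5, np.random.default_rng(0), params)

    def test_invalid_class_raises_configuration_error(self):
        with pytest.raises((ConfigurationError, ValueError)):
            default_params(99)


class TestSynthesizeRecord:
    def test_record_shape_is_12_by_1000_at_100hz(self):
        rec = synthesize_record(RhythmClass.SR, np.random.default_rng(7), fs=100, duration_s=10)
        assert rec.signal.shape == (12, 1000)
        assert rec.label is RhythmClass.SR
        assert np.all(np.isfinite(rec.signal))

    def test_afib_suppresses_p_wave_relative_to_sr(self):
        # project a zero-mean P-wave template onto the noise-free base
        # waveform at the expected P offsets; matched rates keep the windows
        # clear of the preceding beat's T wave
        proj = LeadProjection(weights=np.ones(12), per_lead_noise_sd=0.0)

        def p_score(rec):
            base = rec.signal[0]
            tpl_t = np.arange(-0.21, -0.11, 1 / rec.fs)
            g = np.exp(-0.5 * ((tpl_t + 0.16) / 0.025) ** 2)
            g -= g.mean()
            g /= np.dot(g, g)
            scores = []
            for bt in rec.meta["beat_times"]:
                idx = np.round((bt + tpl_t) * rec.fs).astype(int)
                if idx.min() >= 0 and idx.max() < rec.n_samples:
                    scores.append(np.dot(base[idx], g))
            return np.mean(scores)

        scores = {}
        for cls in (RhythmClass.SR, RhythmClass.AFIB):
            params = replace(default_params(cls), hr_range_bpm=(60, 75))
            scores[cls] = [
                p_score(
                    synthesize_record(
                        cls, np.random.default_rng(seed), params=params, projection=proj
                    )
                )
                for seed in range(10)
            ]
        sr_mean = np.mean(scores[RhythmClass.SR])
        afib_mean_abs = np.mean(np.abs(scores[RhythmClass.AFIB]))
        # SR recovers its configured P amplitude; AFIB is near zero
        assert sr_mean == pytest.approx(0.15, rel=0.15)
        assert sr_mean > 3 * afib_mean_abs

    def test_equal_gains_without_noise_give_identical_leads(self):
        proj = LeadProjection(weights=np.full(12, 0.8), per_lead_noise_sd=0.0)
        rec = synthesize_record(RhythmClass.SR, np.random.default_rng(3), projection=proj)
        assert np.allclose(rec.signal, rec.signal[0][None, :])

    def test_determinism_same_seed_bit_identical(self):
        a = synthesize_record(RhythmClass.SARRH, np.random.default_rng(11))
        b = synthesize_record(RhythmClass.SARRH, np.random.default_rng(11))
        assert np.array_equal(a.signal, b.signal)

    def test_unsupported_sampling_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            synthesize_record(RhythmClass.SR, np.random.default_rng(0), fs=123)


class TestSets:
    @pytest.mark.parametrize("n_per_class,total", [(14, 70), (1, 5)])
    def test_labeled_set_is_balanced_with_unique_ids(self, n_per_class, total):
        records = generate_labeled_set(n_per_class, np.random.default_rng(0))
        assert len(records) == total
        labels = [r.label for r in records]
        for cls in RhythmClass:
            assert labels.count(cls) == n_per_class
        assert len({r.record_id for r in records}) == total

    def test_unlabeled_pool_strips_labels(self):
        pool = generate_unlabeled_pool(50, (1, 0, 0, 0, 0), np.random.default_rng(1))
        assert len(pool) == 50
        assert all(r.label is None for r in pool)

    def test_hidden_mixture_counts_near_multinomial_expectation(self):
        mixture = np.array([0.6, 0.1, 0.1, 0.1, 0.1])
        n = 500
        pool = generate_unlabeled_pool(
            n, mixture, np.random.default_rng(21), strip_labels=False
        )
        counts = np.bincount([int(r.label) for r in pool], minlength=5)
        sigma = np.sqrt(n * mixture * (1 - mixture))
        assert np.all(np.abs(counts - n * mixture) <= 3 * sigma)

    def test_bad_mixture_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_unlabeled_pool(10, (0.5, 0.5, 0.5, 0, 0), np.random.default_rng(0))


def _recover_hr(rec):
    base = rec.signal[0]
    peaks, _ = find_peaks(base, height=0.5 * base.max())
    assert len(peaks) >= 2
    return 60.0 / np.mean(np.diff(peaks) / rec.fs)


@pytest.mark.parametrize("cls", [RhythmClass.SR, RhythmClass.STACH, RhythmClass.SBRAD])
def test_naive_peak_detection_recovers_configured_rate(cls):
    proj = LeadProjection(weights=np.ones(12), per_lead_noise_sd=0.0)
    for seed in range(10):
        rec = synthesize_record(cls, np.random.default_rng(seed), projection=proj)
        configured = 60.0 / np.diff(rec.meta["beat_times"]).mean()
        assert abs(_recover_hr(rec) - configured) <= 5.0
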