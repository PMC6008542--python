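"""Morlet CWT, relative-change statistic, bootstrap CI, band bins."""

import numpy as np
import pytest
from scipy import stats as sstats

import scclfp as s
from scclfp.errors import ConfigError, DegenerateBaselineError, ShortEpochWarning
from scclfp.spectral import BAND_NAMES, Spectrogram, _boot_medians, _boot_medians_resample

FS = 128.0


def _spec(rows, freqs=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    freqs = np.asarray([10.0] * len(rows) if freqs is None else freqs, dtype=float)
    return Spectrogram(freqs, np.arange(rows.shape[1], dtype=float), rows)


class TestMorletCwt:
    def test_zero_epoch_gives_zero_magnitudes(self):
        spec = s.morlet_cwt(np.zeros(int(10 * FS)), FS)
        assert spec.magnitudes.shape == (200, int(10 * FS))
        assert np.allclose(spec.magnitudes, 0)

    def test_sine_peak_at_own_frequency(self):
        t = np.arange(60 * FS) / FS
        spec = s.morlet_cwt(np.sin(2 * np.pi * 10 * t), FS)
        peak = spec.freqs_hz[np.argmax(spec.magnitudes.mean(axis=1))]
        step = spec.freqs_hz[1] - spec.freqs_hz[0]
        assert abs(peak - 10.0) <= step
        # unit amplitude maps to modulus ~1
        assert abs(spec.magnitudes.mean(axis=1).max() - 1.0) < 0.05

    def test_two_tones_two_local_maxima(self):
        t = np.arange(60 * FS) / FS
        x = np.sin(2 * np.pi * 6 * t) + np.sin(2 * np.pi * 40 * t)
        prof = s.morlet_cwt(x, FS).magnitudes.mean(axis=1)
        freqs = s.default_grid()
        for f0 in (6.0, 40.0):
            sel = np.abs(freqs - f0) < 2.0
            assert prof[sel].max() > 0.8 * prof.max()

    def test_peak_location_matches_mne_reference(self):
        """Cross-check against an independent Morlet implementation."""
        from mne.time_frequency import tfr_array_morlet

        t = np.arange(20 * FS) / FS
        x = np.sin(2 * np.pi * 22 * t)
        freqs = np.linspace(5, 45, 81)
        ours = s.morlet_cwt(x, FS, freqs).magnitudes.mean(axis=1)
        theirs = np.abs(
            tfr_array_morlet(
                x[None, None, :], FS, freqs, n_cycles=6.0, output="complex", verbose="error"
            )[0, 0]
        ).mean(axis=1)
        step = freqs[1] - freqs[0]
        assert abs(freqs[np.argmax(ours)] - freqs[np.argmax(theirs)]) <= step

    def test_short_epoch_warns_but_computes(self):
        with pytest.warns(ShortEpochWarning):
            spec = s.morlet_cwt(np.ones(int(1.5 * FS)), FS)
        assert spec.magnitudes.shape[1] == int(1.5 * FS)


class TestRelativeChange:
    def test_identity_is_zero(self, rng):
        v = rng.lognormal(size=50)
        assert s.relative_change(v, v) == 0.0

    def test_doubling_gives_plus_one(self, rng):
        v = rng.lognormal(size=51)
        assert s.relative_change(2 * v, v) == pytest.approx(1.0)

    def test_worked_example(self):
        assert s.relative_change([1, 2, 3], [4, 4, 8]) == pytest.approx(-0.5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DegenerateBaselineError):
            s.relative_change([1.0, 2.0], [0.0, 0.0, 0.0])

    def test_scale_invariance(self, rng):
        for _ in range(100):
            pre = rng.lognormal(size=rng.integers(3, 40))
            post = rng.lognormal(size=rng.integers(3, 40))
            c = rng.uniform(1e-3, 1e3)
            assert s.relative_change(c * post, c * pre) == pytest.approx(
                s.relative_change(post, pre), rel=1e-12
            )


class TestBootstrap:
    def test_constant_rows_give_degenerate_exact_ci(self):
        ci = s.bootstrap_relative_change(
            _spec(np.full(100, 4.0)), _spec(np.full(100, 2.0)), n_boot=200, seed=0
        )
        assert ci.ci_min[0] == ci.ci_mid[0] == ci.ci_max[0] == -0.5

    def test_midpoint_is_mean_of_endpoints(self, rng):
        ci = s.bootstrap_relative_change(
            _spec(rng.lognormal(size=500)), _spec(rng.lognormal(size=400)),
            n_boot=300, seed=1,
        )
        assert np.array_equal(ci.ci_mid, (ci.ci_min + ci.ci_max) / 2)

    def test_reproducible_given_seed(self, rng):
        pre, post = _spec(rng.lognormal(size=300)), _spec(rng.lognormal(size=300))
        a = s.bootstrap_relative_change(pre, post, n_boot=200, seed=7)
        b = s.bootstrap_relative_change(pre, post, n_boot=200, seed=7)
        assert np.array_equal(a.ci_min, b.ci_min) and np.array_equal(a.ci_max, b.ci_max)

    def test_n_boot_floor(self, rng):
        pre = _spec(rng.lognormal(size=50))
        with pytest.raises(ConfigError):
            s.bootstrap_relative_change(pre, pre, n_boot=10)

    def test_null_row_ci_contains_zero(self, rng):
        """Post identical in law to pre: CI straddles 0 in most seeds."""
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            pre = _spec(r.lognormal(size=400))
            post = _spec(r.lognormal(size=400))
            ci = s.bootstrap_relative_change(pre, post, n_boot=300, seed=seed)
            hits += ci.ci_min[0] <= 0 <= ci.ci_max[0]
        assert hits >= 34  # ~95% nominal coverage

    @pytest.mark.parametrize("n", [101, 300, 256])
    def test_orderstat_sampler_matches_naive_resampling(self, n, rng):
        """Dual route: the exact order-statistic draw of the bootstrap
        median must agree in distribution with materialised resampling
        (odd and even sample sizes)."""
        x = rng.lognormal(size=n)
        fast = _boot_medians(np.sort(x), 4000, np.random.default_rng(1))
        naive = _boot_medians_resample(x, 4000, np.random.default_rng(2))
        assert sstats.ks_2samp(fast, naive).pvalue > 0.01

    def test_resample_method_end_to_end(self, rng):
        pre, post = _spec(rng.lognormal(size=200)), _spec(rng.lognormal(size=200))
        ci = s.bootstrap_relative_change(pre, post, n_boot=300, seed=3, method="resample")
        assert ci.ci_min[0] < ci.ci_max[0]

    def test_lognormal_median_ratio_recovered(self):
        r = np.random.default_rng(42)
        pre = _spec(r.lognormal(mean=0.0, size=7680))
        post = _spec(r.lognormal(mean=np.log(0.5), size=7680))
        ci = s.bootstrap_relative_change(pre, post, n_boot=1000, seed=5)
        assert ci.ci_mid[0] == pytest.approx(-0.5, abs=0.03)


class TestBandAggregate:
    def _ci(self, mids, freqs=None):
        freqs = s.default_grid() if freqs is None else freqs
        mids = np.asarray(mids, dtype=float)
        return s.FrequencyCI(freqs, mids, mids, mids, 0.95, 1000, 0)

    def test_constant_midpoints(self):
        bc = s.band_aggregate(self._ci(np.full(200, 0.3)))
        assert all(v == pytest.approx(0.3) for v in bc.as_dict().values())

    def test_alpha_only_change(self):
        freqs = s.default_grid()
        mids = np.where((freqs >= 8) & (freqs < 15), -0.5, 0.0)
        bc = s.band_aggregate(self._ci(mids))
        assert bc.alpha == pytest.approx(-0.5)
        for name in ("delta", "theta", "beta", "gamma"):
            assert getattr(bc, name) == 0.0

    def test_identity_midpoints_give_band_mean_frequencies(self):
        freqs = s.default_grid()
        bc = s.band_aggregate(self._ci(freqs))
        for name, (lo, hi) in s.BANDS.items():
            member = (freqs >= lo) & ((freqs <= hi) if hi == 50 else (freqs < hi))
            assert getattr(bc, name) == pytest.approx(freqs[member].mean())

    def test_every_grid_point_in_exactly_one_band(self):
        freqs = s.default_grid()
        counts = np.zeros(len(freqs), dtype=int)
        for lo, hi in s.BANDS.values():
            counts += (freqs >= lo) & ((freqs <= hi) if hi == 50 else (freqs < hi))
        assert np.array_equal(counts, np.ones(200, dtype=int))


class TestAnalyzeCycle:
    def _pair(self, theta_mult, seed, artifact_rate=1.0):
        spec = s.SyntheticCycleSpec(
            post_multipliers={"delta": 1, "theta": theta_mult, "alpha": 1, "beta": 1, "gamma": 1},
            artifact_rate_per_min=artifact_rate,
            seed=seed,
        )
        syn = s.synthesize_cycle(spec)
        rec = s.preprocess_recording(syn.recording)
        diff = s.derive_differential(rec, "L2", syn.artifacts)
        return s.extract_epoch_pair(diff, syn.cycle)

    def test_clean_null_cycle_changes_small(self):
        """Artifact-free null cycle: residual band change is bootstrap
        noise only."""
        pair = self._pair(1.0, seed=0, artifact_rate=0.0)
        res = s.analyze_cycle(pair, s.SpectralConfig(n_boot=300, seed=1))
        assert all(abs(v) < 0.05 for v in res.band_change.as_dict().values())

    def test_null_cycle_with_artifacts_small_over_seeds(self):
        """With artifact transients present, splice energy from the
        discard-not-blank concatenation adds low-frequency scatter;
        the typical (median over seeds) deviation stays small."""
        devs = []
        for seed in range(6):
            pair = self._pair(1.0, seed=seed)
            res = s.analyze_cycle(pair, s.SpectralConfig(n_boot=200, seed=seed + 50))
            devs.append(max(abs(v) for v in res.band_change.as_dict().values()))
        assert np.median(devs) < 0.08

    def test_theta_suppression_recovered(self):
        pair = self._pair(0.5, seed=2)
        res = s.analyze_cycle(pair, s.SpectralConfig(n_boot=300, seed=1))
        bands = res.band_change.as_dict()
        assert bands["theta"] == pytest.approx(-0.5, abs=0.1)
        assert abs(bands["delta"]) < 0.1 and abs(bands["gamma"]) < 0.1

    def test_deterministic_given_seed(self):
        pair = self._pair(0.8, seed=3)
        cfg = s.SpectralConfig(n_boot=200, seed=9)
        a = s.analyze_cycle(pair, cfg).band_change.as_dict()
        b = s.analyze_cycle(pair, cfg).band_change.as_dict()
        assert a == b

    def test_scale_equivariance_of_band_change(self):
        pair = self._pair(0.7, seed=4)
        scaled = s.EpochPair(
            pre=37.0 * pair.pre, post=37.0 * pair.post, cycle=pair.cycle,
            lost_fraction_pre=0.0, lost_fraction_post=0.0,
        )
        cfg = s.SpectralConfig(n_boot=200, seed=11)
        a = s.analyze_cycle(pair, cfg).band_change.as_dict()
        b = s.analyze_cycle(scaled, cfg).band_change.as_dict()
        for name in BAND_NAMES:
            assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_monotone_in_multiplier(self):
        values = []
        for m in (0.5, 0.75, 1.0, 1.25):
            spec = s.SyntheticCycleSpec(
                post_multipliers={"delta": 1, "theta": m, "alpha": 1, "beta": 1, "gamma": 1},
                artifact_rate_per_min=0.0,
                seed=6,
            )
            syn = s.synthesize_cycle(spec)
            rec = s.preprocess_recording(syn.recording)
            diff = s.derive_differential(rec, "L2")
            pair = s.extract_epoch_pair(diff, syn.cycle)
            res = s.analyze_cycle(pair, s.SpectralConfig(n_boot=200, seed=2))
            values.append(res.band_change.theta)
        assert values == sorted(values)
        assert values[0] < 0 < values[-1]
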