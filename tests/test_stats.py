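"""Exact nonparametric tests against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sstats

import scclfp as s
from scclfp.errors import (
    AllZeroError,
    DegenerateSampleError,
    InsufficientDataError,
)


def brute_force_signed_rank_p(x):
    """Oracle: enumerate all 2^n sign patterns on the observed
    mid-ranks; two-sided p = min(1, 2 min(P(W<=w), P(W>=w)))."""
    d = np.asarray(x, dtype=float)
    d = d[d != 0]
    ranks = sstats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    n = len(d)
    sums = [
        sum(r for r, sign in zip(ranks, pattern) if sign)
        for pattern in itertools.product([False, True], repeat=n)
    ]
    sums = np.asarray(sums)
    tol = 1e-9
    p_le = np.mean(sums <= w + tol)
    p_ge = np.mean(sums >= w - tol)
    return min(1.0, 2 * min(p_le, p_ge))


def brute_force_rank_sum_p(x):
    """Oracle: enumerate all C(2n, n) assignments of the combined
    mid-ranks (x against an equal-length zero pseudo-sample)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    combined = np.concatenate([x, np.zeros(n)])
    ranks = sstats.rankdata(combined)
    w = ranks[:n].sum()
    sums = np.asarray(
        [sum(ranks[list(c)]) for c in itertools.combinations(range(2 * n), n)]
    )
    tol = 1e-9
    p_le = np.mean(sums <= w + tol)
    p_ge = np.mean(sums >= w - tol)
    return min(1.0, 2 * min(p_le, p_ge))


class TestSignedRank:
    def test_all_positive_six(self):
        res = s.signed_rank_exact([1, 2, 3, 4, 5, 6])
        assert res.statistic_W == 21
        assert res.p_two_sided == pytest.approx(2 / 64)
        assert res.n == 6 and res.method == "signed_rank"

    def test_symmetric_pair_p_one(self):
        res = s.signed_rank_exact([-3.0, 3.0])
        assert res.p_two_sided == 1.0

    def test_zeros_dropped(self):
        res = s.signed_rank_exact([0.0, 0.0, 5.0])
        assert res.n == 1 and res.statistic_W == 1.0 and res.p_two_sided == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(AllZeroError):
            s.signed_rank_exact([0.0, 0.0])

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 11))
            x = rng.normal(size=n)
            if rng.random() < 0.5:  # inject ties in magnitude
                x = np.round(x, 1)
                x = x[x != 0]
                if len(x) == 0:
                    continue
            assert s.signed_rank_exact(x).p_two_sided == pytest.approx(
                brute_force_signed_rank_p(x), abs=1e-12
            )

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(4, 12)))
            ours = s.signed_rank_exact(x)
            ref = sstats.wilcoxon(x, alternative="two-sided", mode="exact")
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_monte_carlo_branch_close_to_exact(self, rng):
        """n just above the enumeration limit: MC agrees with the
        normal-free exact DP run manually."""
        x = rng.normal(loc=0.4, size=30)
        mc = s.signed_rank_exact(x, seed=0).p_two_sided
        ref = sstats.wilcoxon(x, alternative="two-sided", mode="exact").pvalue
        assert mc == pytest.approx(ref, abs=0.02)

    def test_shift_away_from_zero_never_raises_p(self, rng):
        x = np.abs(rng.normal(size=8)) + 0.1
        p_values = [
            s.signed_rank_exact(x * scale).p_two_sided for scale in (1.0, 2.0, 5.0)
        ]
        assert p_values[0] == p_values[1] == p_values[2]  # ranks unchanged
        mixed = np.concatenate([x[:4], -x[4:] * 0.01])  # mostly positive
        p_mixed = s.signed_rank_exact(mixed).p_two_sided
        assert p_mixed >= p_values[0]


class TestRankSumVsZero:
    def test_three_positives_vs_zeros(self):
        res = s.rank_sum_vs_zero_exact([1, 2, 3])
        assert res.statistic_W == 15.0
        assert res.p_two_sided == pytest.approx(2 / math.comb(6, 3))

    def test_all_zero_complete_tie(self):
        res = s.rank_sum_vs_zero_exact([0.0, 0.0, 0.0])
        assert res.p_two_sided == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 8))
            x = rng.normal(size=n)
            if rng.random() < 0.3:
                x[rng.integers(0, n)] = 0.0  # tie with the pseudo-sample
            assert s.rank_sum_vs_zero_exact(x).p_two_sided == pytest.approx(
                brute_force_rank_sum_p(x), abs=1e-12
            )

    def test_signed_rank_null_p_values_valid(self, rng):
        """Under a symmetric-about-zero null the (default) signed-rank
        p-values are valid: P(p <= t) <= t plus the null atom size."""
        n_sim, n = 400, 8
        ps = np.array(
            [
                s.signed_rank_exact(rng.normal(size=n)).p_two_sided
                for _ in range(n_sim)
            ]
        )
        for t in (0.05, 0.1, 0.2, 0.5):
            atom = 2 / 2**n
            assert (ps <= t).mean() <= t + atom + 3 * np.sqrt(t * (1 - t) / n_sim)


class TestEffectSizes:
    def test_worked_example(self):
        assert s.hedges_g([2, 4, 6]) == pytest.approx(8 / 7)

    def test_zero_mean_gives_zero(self):
        assert s.hedges_g([-1.0, 0.0, 1.0]) == 0.0

    def test_antisymmetry(self, rng):
        x = rng.normal(loc=1, size=9)
        assert s.hedges_g(-x) == pytest.approx(-s.hedges_g(x))

    def test_paired_equals_one_sample_of_differences(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert s.hedges_g_paired(x, y) == pytest.approx(s.hedges_g(x - y))

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            s.hedges_g([2.0, 2.0, 2.0])
        with pytest.raises(InsufficientDataError):
            s.hedges_g([1.0])


class TestKsAdvisory:
    def test_normal_sample_not_flagged(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert s.ks_nongaussianity(x) > 0.05

    def test_exponential_sample_flagged(self):
        x = np.random.default_rng(1).exponential(size=1000)
        assert s.ks_nongaussianity(x) < 0.01

    def test_too_small_rejected(self):
        with pytest.raises(InsufficientDataError):
            s.ks_nongaussianity([1.0, 2.0, 3.0])

    def test_constant_sample_is_na(self):
        assert np.isnan(s.ks_nongaussianity([2.0] * 10))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected", [(0.05, 5, 0.01), (0.07, 1, 0.07), (0.05, 10, 0.005)]
    )
    def test_threshold(self, alpha, m, expected):
        assert s.bonferroni_threshold(alpha, m) == pytest.approx(expected)


class TestOutcomeCorrelation:
    def test_perfect_linear(self):
        x = np.arange(6, dtype=float)
        res = s.correlate_with_outcome(x, 3 * x + 1)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_antimonotone(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 12.0])
        res = s.correlate_with_outcome(x, -(x**3))
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_na_pairs_excluded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, np.nan, 6.0, 8.0, 10.0])
        assert s.correlate_with_outcome(x, y).n == 4

    def test_spearman_recovery(self, rng):
        """Monte-Carlo: bivariate normal with rho=0.6 at n=11 recovers
        the rank correlation on average."""
        est = []
        for _ in range(400):
            cov = [[1, 0.6], [0.6, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=11)
            est.append(s.correlate_with_outcome(xy[:, 0], xy[:, 1]).spearman_rho)
        assert np.mean(est) == pytest.approx(0.58, abs=0.05)  # rank rho of rho=0.6

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InsufficientDataError):
            s.correlate_with_outcome([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestTestTable:
    def _rows(self, rng, effects, n_patients=11, noise=0.03):
        import pandas as pd

        rows = []
        for p in range(n_patients):
            for (hemi, role), bands in effects.items():
                for band, mu in bands.items():
                    rows.append(
                        {
                            "patient_id": f"{p:02d}",
                            "hemisphere": hemi,
                            "role": role,
                            "band": band,
                            "value": mu + noise * rng.standard_normal(),
                            "responder": True,
                        }
                    )
        return pd.DataFrame(rows)

    def test_designed_pattern_flagged_exactly(self):
        """Direct simulation from ground-truth band effects: the cells
        with real decreases (left theta-gamma, right beta/gamma) are
        the ones flagged after Bonferroni in >= 9/10 seeds."""
        target = {
            ("L", "effective"): {"theta": True, "alpha": True, "beta": True, "gamma": True},
            ("R", "effective"): {"beta": True, "gamma": True},
        }
        effects = {
            ("L", "effective"): {"delta": 0.0, "theta": -0.35, "alpha": -0.45,
                                 "beta": -0.3, "gamma": -0.25},
            ("R", "effective"): {"delta": 0.0, "theta": 0.0, "alpha": 0.0,
                                 "beta": -0.3, "gamma": -0.35},
        }
        hits = 0
        for seed in range(10):
            table = s.build_test_table(self._rows(np.random.default_rng(seed), effects))
            ok = True
            for _, row in table[table.contrast == "effective"].iterrows():
                expected = target.get((row.hemisphere, "effective"), {}).get(row.band, False)
                ok &= bool(row.significant) == expected
            hits += ok
        assert hits >= 9

    def test_null_cohort_rarely_flags(self):
        effects = {("L", "effective"): {b: 0.0 for b in s.spectral.BAND_NAMES}}
        n_flags = 0
        n_cells = 0
        for seed in range(40):
            table = s.build_test_table(self._rows(np.random.default_rng(100 + seed), effects))
            sub = table[table.contrast == "effective"]
            sub = sub[sub.hemisphere == "L"]
            n_flags += int(sub.significant.sum())
            n_cells += len(sub)
        assert n_flags / n_cells <= 0.02  # nominal per-cell rate is 0.01

    def test_missing_patients_reduce_n(self, rng):
        effects = {("L", "effective"): {"theta": -0.4}}
        df = self._rows(rng, effects, n_patients=11)
        df = df[df.patient_id != "00"]  # e.g. an edge-contact patient
        table = s.build_test_table(df)
        row = table[
            (table.hemisphere == "L") & (table.contrast == "effective") & (table.band == "theta")
        ].iloc[0]
        assert row.n == 10 and row.n_missing == 0  # cohort itself shrank

    def test_nonresponders_excluded(self, rng):
        effects = {("L", "effective"): {"theta": -0.4}}
        df = self._rows(rng, effects, n_patients=12)
        df.loc[df.patient_id == "00", "responder"] = False
        table = s.build_test_table(df)
        row = table[(table.contrast == "effective") & (table.band == "theta")].iloc[0]
        assert row.n == 11
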