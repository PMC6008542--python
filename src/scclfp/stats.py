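"""Exact nonparametric inference on band-limited power changes.

Samples here are small (around eleven responders), so p-values come
from exact enumeration of the permutation null rather than normal
approximations: the signed-rank null enumerates all 2^n sign patterns
(via a subset-sum convolution over the observed, possibly tied,
mid-ranks) and the rank-sum null enumerates all group assignments.
Above the exact-enumeration limits a seeded Monte Carlo with at least
1e5 draws takes over.  Hedges' g (small-sample corrected standardized
mean difference) accompanies every test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import (
    AllZeroError,
    DegenerateSampleError,
    InsufficientDataError,
)
from .spectral import BAND_NAMES

EXACT_SIGNED_RANK_N = 25
EXACT_RANK_SUM_COMBINED_N = 20
MC_DRAWS = 100_000


@dataclass
class TestResult:
    """Outcome of one exact nonparametric test."""

    statistic_W: float
    p_two_sided: float
    n: int
    g: float
    method: str


def _two_sided_from_dist(
    support: np.ndarray, probs: np.ndarray, w: float
) -> float:
    """Two-sided p = min(1, 2 * min(P(W <= w), P(W >= w)))."""
    tol = 1e-9
    p_le = float(probs[support <= w + tol].sum())
    p_ge = float(probs[support >= w - tol].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _doubled_ranks(abs_values: np.ndarray) -> np.ndarray:
    """Mid-ranks of |values| doubled to exact integers (ties give .5s)."""
    r = sstats.rankdata(abs_values)  # mid-ranks
    doubled = np.rint(2 * r).astype(np.int64)
    return doubled


def _signed_rank_null(doubled_ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the positive-rank sum W (doubled
    scale) over all 2^n equiprobable sign patterns, by convolution."""
    total = int(doubled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in doubled_ranks:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    return np.arange(total + 1), dist


def signed_rank_exact(
    x: np.ndarray, mu: float = 0.0, seed: int = 0
) -> TestResult:
    """Exact two-tailed Wilcoxon signed-rank test of ``x`` against ``mu``.

    Zeros are dropped; tied magnitudes receive mid-ranks and the null
    is enumerated over the observed tie structure.  For n > 25 the
    p-value is a seeded Monte Carlo estimate over >= 1e5 sign patterns.
    """
    x = np.asarray(x, dtype=float)
    d = x[np.isfinite(x)] - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise AllZeroError("all observations equal the null value")
    doubled = _doubled_ranks(np.abs(d))
    w_doubled = int(doubled[d > 0].sum())
    if n <= EXACT_SIGNED_RANK_N:
        support, probs = _signed_rank_null(doubled)
        p = _two_sided_from_dist(support, probs, w_doubled)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.integers(0, 2, size=(MC_DRAWS, n))
        sims = signs @ doubled
        p = min(
            1.0,
            2.0 * min(float((sims <= w_doubled).mean()), float((sims >= w_doubled).mean())),
        )
    g = _safe_g(d)
    return TestResult(
        statistic_W=w_doubled / 2.0,
        p_two_sided=p,
        n=n,
        g=g,
        method="signed_rank",
    )


def _rank_sum_null(doubled_ranks: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null of the sum of k ranks drawn without replacement from
    ``doubled_ranks`` (all C(n, k) subsets equiprobable): DP over
    (items, chosen count, sum) counting subsets."""
    total = int(doubled_ranks.sum())
    counts = np.zeros((k + 1, total + 1))
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        for c in range(min(k, len(doubled_ranks)), 0, -1):
            counts[c, r:] += counts[c - 1, : total + 1 - r]
    probs = counts[k]
    probs = probs / probs.sum()
    return np.arange(total + 1), probs


def rank_sum_vs_zero_exact(x: np.ndarray, seed: int = 0) -> TestResult:
    """Exact two-tailed rank-sum test of ``x`` against an equal-length
    all-zero pseudo-sample.

    The massive tie at zero gets mid-ranks; the null enumerates all
    C(2n, n) group assignments exactly for combined n <= 20, otherwise
    a seeded Monte Carlo over >= 1e5 permutations.  Provided as the
    alternate one-sample test; the signed-rank test is the default.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n == 0:
        raise InsufficientDataError("empty sample")
    combined = np.concatenate([x, np.zeros(n)])
    doubled = np.rint(2 * sstats.rankdata(combined)).astype(np.int64)
    w_doubled = int(doubled[:n].sum())
    if 2 * n <= EXACT_RANK_SUM_COMBINED_N:
        support, probs = _rank_sum_null(doubled, n)
        p = _two_sided_from_dist(support, probs, w_doubled)
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((MC_DRAWS, 2 * n)), axis=1)[:, :n]
        sims = doubled[idx].sum(axis=1)
        p = min(
            1.0,
            2.0 * min(float((sims <= w_doubled).mean()), float((sims >= w_doubled).mean())),
        )
    nz = x[x != 0]
    g = _safe_g(x) if len(nz) else float("nan")
    return TestResult(
        statistic_W=w_doubled / 2.0,
        p_two_sided=p,
        n=n,
        g=g,
        method="rank_sum_vs_zero",
    )


def _safe_g(x: np.ndarray) -> float:
    try:
        return hedges_g(x)
    except (DegenerateSampleError, InsufficientDataError):
        return float("nan")


def hedges_g(x: np.ndarray, mu: float = 0.0) -> float:
    """One-sample Hedges' g: ``J * (mean(x) - mu) / sd(x)`` with the
    small-sample correction ``J = 1 - 3 / (4n - 5)``."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 2:
        raise InsufficientDataError("Hedges' g needs n >= 2")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("zero-variance sample")
    j = 1.0 - 3.0 / (4.0 * n - 5.0)
    return j * (float(np.mean(x)) - mu) / sd


def hedges_g_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Paired Hedges' g: the one-sample g of the differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return hedges_g(x - y)


def ks_nongaussianity(sample: np.ndarray) -> float:
    """Advisory one-sample Kolmogorov-Smirnov p-value against a normal
    with the sample's own mean and sd.

    Low p flags non-gaussianity (motivating the rank tests, which are
    used regardless).  A constant sample is degenerate: returns NaN.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 4:
        raise InsufficientDataError("KS check needs n >= 4")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return float("nan")
    return float(sstats.kstest(x, "norm", args=(float(np.mean(x)), sd)).pvalue)


def bonferroni_threshold(alpha: float = 0.05, m: int = 5) -> float:
    """Per-test significance threshold alpha / m (m = 5 bands)."""
    if m < 1 or not (0 < alpha < 1):
        raise ValueError("need m >= 1 and 0 < alpha < 1")
    return alpha / m


@dataclass
class OutcomeCorrelation:
    """Pearson and Spearman correlation with a clinical outcome."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def correlate_with_outcome(
    band_changes: np.ndarray, times_to_response: np.ndarray
) -> OutcomeCorrelation:
    """Correlate per-patient band changes with time to stable response.

    NA times are excluded pairwise; both Pearson and Spearman are
    reported.
    """
    x = np.asarray(band_changes, dtype=float)
    y = np.asarray(times_to_response, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors required")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise InsufficientDataError("correlation needs n >= 4 complete pairs")
    pr = sstats.pearsonr(x, y)
    sr = sstats.spearmanr(x, y)
    return OutcomeCorrelation(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
        n=len(x),
    )


def build_test_table(
    band_rows: pd.DataFrame,
    alpha: float = 0.05,
    responders_only: bool = True,
    method: str = "signed_rank",
    seed: int = 0,
) -> pd.DataFrame:
    """Group-level test table over per-cycle band changes.

    ``band_rows`` columns: ``patient_id, hemisphere, role, band, value,
    responder``.  Per (hemisphere, role, band) a one-sample test against
    zero is run over patients; per (hemisphere, band) a paired
    signed-rank contrasts effective vs ineffective within patients
    contributing both.  Statistics are restricted to 6-month responders
    by default; the Bonferroni family is the 5 bands of each contrast.
    Patients missing a differential (edge contacts) simply contribute no
    row; ``n_missing`` counts them against the responder cohort size.
    """
    df = band_rows.copy()
    if responders_only and "responder" in df.columns:
        df = df[df["responder"].astype(bool)]
    one_sample = signed_rank_exact if method == "signed_rank" else rank_sum_vs_zero_exact
    threshold = bonferroni_threshold(alpha, m=5)
    n_cohort = df["patient_id"].nunique()
    out = []

    def _append(hemisphere, contrast, band, values, result, n_missing):
        out.append(
            {
                "hemisphere": hemisphere,
                "contrast": contrast,
                "band": band,
                "n": result.n if result else len(values),
                "W": result.statistic_W if result else float("nan"),
                "p": result.p_two_sided if result else float("nan"),
                "g": result.g if result else float("nan"),
                "significant": bool(result and result.p_two_sided < threshold),
                "method": result.method if result else "none",
                "n_missing": n_missing,
            }
        )

    for hemisphere in ("L", "R"):
        for role in ("effective", "ineffective"):
            sub = df[(df.hemisphere == hemisphere) & (df.role == role)]
            for band in BAND_NAMES:
                vals = sub[sub.band == band]["value"].to_numpy()
                missing = n_cohort - len(vals)
                try:
                    res = one_sample(vals, seed=seed)
                except (AllZeroError, InsufficientDataError):
                    res = None
                _append(hemisphere, role, band, vals, res, missing)
        # paired effective vs ineffective within patients having both
        eff = df[(df.hemisphere == hemisphere) & (df.role == "effective")]
        ine = df[(df.hemisphere == hemisphere) & (df.role == "ineffective")]
        for band in BAND_NAMES:
            merged = pd.merge(
                eff[eff.band == band][["patient_id", "value"]],
                ine[ine.band == band][["patient_id", "value"]],
                on="patient_id",
                suffixes=("_eff", "_ine"),
            )
            diffs = (merged["value_eff"] - merged["value_ine"]).to_numpy()
            missing = n_cohort - len(diffs)
            try:
                res = signed_rank_exact(diffs, seed=seed)
                res.method = "paired_signed_rank"
            except (AllZeroError, InsufficientDataError):
                res = None
            _append(hemisphere, "effective_vs_ineffective", band, diffs, res, missing)
    table = pd.DataFrame(out)
    table.attrs["alpha"] = alpha
    table.attrs["family_size"] = 5
    table.attrs["threshold"] = threshold
    return table
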