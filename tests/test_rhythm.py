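"""Rhythm detection: umbrella test, ANOVA, damped cosine, fold change."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, special

from circaturn.errors import InsufficientDesignError, TransformError
from circaturn.rhythm import (
    TimeSeries,
    umbrella_test,
    anova_rhythm_test,
    fit_line,
    fit_damped_cosine,
    compare_fits_f_test,
    peak_trough_fold_change,
    analyze_series,
    _candidate_weights,
    _weighted_moments,
    _weighted_statistic,
    _pairwise_counts,
    _exact_tail_table,
)

TIMES8 = np.arange(0, 48, 6.0)


# ---------------------------------------------------------------------------
# Umbrella test
# ---------------------------------------------------------------------------


def brute_force_candidate_pmf(sizes, weights):
    """Null distribution of the two-arm statistic by raw permutation of ranks."""
    n = sum(sizes)
    labels = []
    for i, s in enumerate(sizes):
        labels += [i] * s
    stats_seen = {}
    total = 0
    for perm in set(itertools.permutations(labels)):
        groups = [np.array([r for r, l in zip(range(n), perm) if l == i]) for i in range(len(sizes))]
        u = _pairwise_counts(groups)
        s = _weighted_statistic(u, weights)
        stats_seen[s] = stats_seen.get(s, 0) + 1
        total += 1
    return {k: v / total for k, v in stats_seen.items()}


@pytest.mark.parametrize("sizes,peak,trough", [((2, 2, 2), 1, 0), ((2, 2, 2, 2), 2, 0), ((1, 2, 3), 2, 1)])
def test_exact_tail_table_matches_raw_permutation_enumeration(sizes, peak, trough):
    weights = _candidate_weights(len(sizes), peak, trough)
    support, tail = _exact_tail_table(sizes, weights)
    pmf = brute_force_candidate_pmf(sizes, weights)
    for s, t in zip(support, tail):
        expected = sum(v for k, v in pmf.items() if k >= s - 1e-9)
        assert t == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("sizes,peak,trough", [((2, 2, 2, 2), 2, 0), ((3, 2, 4), 0, 2), ((2, 3, 2, 3), 1, 3)])
def test_permutation_moments_match_enumerated_distribution(sizes, peak, trough):
    """The closed-form mean/variance equal the enumerated distribution's."""
    weights = _candidate_weights(len(sizes), peak, trough)
    mean, var = _weighted_moments(sizes, weights)
    pmf = brute_force_candidate_pmf(sizes, weights)
    e = sum(k * v for k, v in pmf.items())
    v2 = sum((k - e) ** 2 * v for k, v in pmf.items())
    assert mean == pytest.approx(e, abs=1e-9)
    assert var == pytest.approx(v2, rel=1e-9)


def test_umbrella_detects_peak_with_exact_enumeration():
    """The worked example: groups {1,2},{3,4},{7,8},{3,4} peak at phase 12.

    Exact enumeration over the 2520 assignments of the tied values gives
    a best-candidate p of 6/2520; Bonferroni over the 12 candidate
    (peak, trough) placements yields 0.02857.
    """
    series = TimeSeries(TIMES8, np.array([1, 3, 7, 3, 2, 4, 8, 4], float), 24.0)
    res = umbrella_test(series)
    assert res.p_value == pytest.approx(6 / 2520 * 12, rel=1e-9)
    assert res.phase_h == 12.0


def test_umbrella_constant_series_is_null_by_convention():
    res = umbrella_test(TimeSeries(TIMES8, np.full(8, 3.3), 24.0))
    assert res.p_value == 1.0


def test_umbrella_requires_three_phase_groups():
    with pytest.raises(InsufficientDesignError):
        umbrella_test(TimeSeries(np.array([0.0, 12.0, 24.0, 36.0]), np.arange(4.0), 24.0))


def test_umbrella_invariant_under_monotone_transform():
    rng = np.random.default_rng(3)
    vals = rng.lognormal(0, 0.4, TIMES8.size)
    p1 = umbrella_test(TimeSeries(TIMES8, vals, 24.0)).p_value
    p2 = umbrella_test(TimeSeries(TIMES8, np.log(vals), 24.0)).p_value
    p3 = umbrella_test(TimeSeries(TIMES8, vals**3, 24.0)).p_value
    assert p1 == p2 == p3


def test_umbrella_longitudinal_mode_ranks_within_replicates():
    times = np.concatenate([TIMES8, TIMES8])
    reps = np.array([1] * 8 + [2] * 8)
    # replicate 2 on a much higher scale: pooling would garble ranks,
    # longitudinal mode ranks within each culture
    base = np.array([1, 2, 8, 2, 1, 2, 8, 2], float)
    vals = np.concatenate([base, base * 100 + 3])
    res = umbrella_test(
        TimeSeries(times, vals, 24.0, replicate_ids=reps), mode="longitudinal"
    )
    assert res.phase_h == 12.0
    assert res.p_value < 0.05


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------


def closed_form_oneway(groups):
    """Textbook one-way fixed-effects ANOVA from explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = special.betainc(df_w / 2.0, df_b / 2.0, df_w / (df_w + df_b * f))
    return f, p


def test_anova_matches_closed_form_to_1e_10():
    rng = np.random.default_rng(8)
    vals = rng.lognormal(2.0, 0.5, 16)
    times = np.concatenate([TIMES8, TIMES8])
    res = anova_rhythm_test(TimeSeries(times, vals, 24.0))
    logs = np.log(vals)
    phases = np.mod(times, 24.0)
    groups = [logs[phases == p] for p in np.unique(phases)]
    f, p = closed_form_oneway(groups)
    assert res.f_statistic == pytest.approx(f, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_anova_degenerate_cases():
    assert anova_rhythm_test(TimeSeries(np.concatenate([TIMES8, TIMES8]), np.full(16, 5.0), 24.0)).p_value == 1.0
    # zero within-group variance with real between-group differences: F -> inf
    vals = np.array([1, 1, 150, 1] * 4, float)
    times = np.concatenate([TIMES8, TIMES8])
    res = anova_rhythm_test(TimeSeries(times, vals, 24.0))
    assert res.p_value <= 1e-300
    with pytest.raises(TransformError):
        anova_rhythm_test(TimeSeries(TIMES8, np.array([1, -1, 1, 1, 1, 1, 1, 1.0]), 24.0))
    with pytest.raises(InsufficientDesignError):
        # one observation per circadian group
        anova_rhythm_test(TimeSeries(np.arange(0, 24, 6.0), np.ones(4), 24.0))


def test_anova_scale_invariance():
    rng = np.random.default_rng(9)
    vals = rng.lognormal(0, 0.3, 16)
    times = np.concatenate([TIMES8, TIMES8])
    f1 = anova_rhythm_test(TimeSeries(times, vals, 24.0)).f_statistic
    f2 = anova_rhythm_test(TimeSeries(times, 7.25 * vals, 24.0)).f_statistic
    assert f1 == pytest.approx(f2, rel=1e-12)


# ---------------------------------------------------------------------------
# Damped cosine and F test
# ---------------------------------------------------------------------------


def model(x, m, c, a, k, peak, p=24.0):
    return m * x + c + a * np.exp(k * x) * np.cos((2 * np.pi * x - 2 * np.pi * peak) / p)


def test_noiseless_cosine_recovery_to_1e_6():
    x = np.arange(16) * 3.0
    y = model(x, 0.0, 10.0, 3.0, 0.0, 6.0)
    fit = fit_damped_cosine(x, y, 24.0)
    assert fit.m == pytest.approx(0.0, abs=1e-6)
    assert fit.c == pytest.approx(10.0, abs=1e-6)
    assert fit.a == pytest.approx(3.0, abs=1e-6)
    assert fit.k == pytest.approx(0.0, abs=1e-6)
    assert fit.peak_time_h == pytest.approx(6.0, abs=0.01)
    assert fit.df == len(x) - 5


def test_phase_conventions_agree_on_peak_time():
    x = np.arange(16) * 3.0
    y = model(x, 0.1, 5.0, 2.0, -0.02, 15.0)
    printed = fit_damped_cosine(x, y, 24.0, convention="printed")
    conventional = fit_damped_cosine(x, y, 24.0, convention="conventional")
    assert printed.peak_time_h == pytest.approx(conventional.peak_time_h, abs=0.02)
    # damping shifts the envelope peak by atan(k/omega)/omega
    w = 2 * np.pi / 24.0
    expected = 15.0 + np.arctan(-0.02 / w) / w
    assert printed.peak_time_h == pytest.approx(expected, abs=0.05)


def test_noisy_cosine_recovery_over_seeds():
    """5% multiplicative noise: median |phase error| <= 1 h, amplitude within 10%."""
    x = np.arange(16) * 3.0
    truth_a, truth_peak = 3.0, 6.0
    phase_err, amp_err = [], []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        y = model(x, 0.0, 10.0, truth_a, 0.0, truth_peak) * rng.lognormal(0, 0.05, x.size)
        fit = fit_damped_cosine(x, y, 24.0)
        d = abs(fit.peak_time_h - truth_peak)
        phase_err.append(min(d, 24.0 - d))
        amp_err.append(abs(fit.a - truth_a) / truth_a)
    assert np.median(phase_err) <= 1.0
    assert np.median(amp_err) <= 0.10


def test_f_statistic_arithmetic_and_degenerate_cases():
    null = fit_line(np.arange(12.0), np.arange(12.0))
    null.rss, null.df = 100.0, 10
    alt = fit_damped_cosine(np.arange(12.0) * 4, model(np.arange(12.0) * 4, 0, 1, 1, 0, 0), 24.0)
    alt.rss, alt.df = 50.0, 7
    f, p = compare_fits_f_test(null, alt)
    assert f == pytest.approx(7.0 / 3.0)
    alt.rss = 100.0
    f, p = compare_fits_f_test(null, alt)
    assert (f, p) == (0.0, 1.0)
    alt.rss = 120.0
    with pytest.warns(RuntimeWarning):
        f, p = compare_fits_f_test(null, alt)
    assert f == 0.0


def test_f_to_p_mapping_against_numerical_integration():
    """p at (3, 7) df matches direct integration of the F density to 1e-8."""
    dfn, dfd = 3, 7

    def f_pdf(x):
        return (
            math.gamma((dfn + dfd) / 2)
            / (math.gamma(dfn / 2) * math.gamma(dfd / 2))
            * (dfn / dfd) ** (dfn / 2)
            * x ** (dfn / 2 - 1)
            * (1 + dfn * x / dfd) ** (-(dfn + dfd) / 2)
        )

    null = fit_line(np.arange(12.0), np.arange(12.0))
    null.rss, null.df = 100.0, 10
    alt = fit_damped_cosine(np.arange(12.0) * 4, model(np.arange(12.0) * 4, 0, 1, 1, 0, 0), 24.0)
    alt.df = 7
    for rss_alt in (50.0, 80.0, 20.0):
        alt.rss = rss_alt
        f, p = compare_fits_f_test(null, alt)
        expected, _ = integrate.quad(f_pdf, f, np.inf)
        assert p == pytest.approx(expected, abs=1e-8)


# ---------------------------------------------------------------------------
# Fold change
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "values,expected",
    [
        ([10, 20, 40, 20, 10, 20, 40, 20], 4.0),
        ([5] * 8, 1.0),
        ([10, 20, 40, 20, 10, 20, 80, 20], 6.0),
    ],
)
def test_peak_trough_fold_change(values, expected):
    fc = peak_trough_fold_change(TimeSeries(TIMES8, np.array(values, float), 24.0))
    assert fc == pytest.approx(expected)
    assert fc >= 1.0


def test_fold_change_non_positive_trough_is_undefined():
    with pytest.warns(RuntimeWarning):
        fc = peak_trough_fold_change(TimeSeries(TIMES8, np.array([0, 1, 2, 1, 0, 1, 2, 1.0]), 24.0))
    assert np.isnan(fc)


@pytest.mark.parametrize("amp", [0.2, 1 / 3, 0.5])
def test_fold_change_matches_cosine_amplitude_at_aligned_sampling(amp):
    """Noiseless cosine with peak/trough on the grid: FC = (1+A)/(1-A) within 10%."""
    vals = 10.0 * (1 + amp * np.cos(2 * np.pi * (TIMES8 - 6.0) / 24.0))
    fc = peak_trough_fold_change(TimeSeries(TIMES8, vals, 24.0))
    assert fc == pytest.approx((1 + amp) / (1 - amp), rel=0.10)


def test_analyze_series_combines_detectors():
    vals = np.array([1, 3, 9, 3, 1.1, 3.2, 8.8, 3.1])
    res = analyze_series(TimeSeries(TIMES8, vals, 24.0))
    assert res.p_umbrella < 0.05
    assert res.p_anova < 0.05
    assert res.phase_h == 12.0
    assert res.fold_change > 2
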