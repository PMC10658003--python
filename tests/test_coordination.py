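import math

import numpy as np
import pytest

from convosync.bayes_stats import grade_evidence
from convosync.coordination import (
    WclcConfig,
    compare_to_pseudo,
    fill_missing,
    pseudoadaptation,
    pseudosynchrony,
    shuffle_segments,
    surrogate_null,
    turn_adaptation,
    wclc_synchrony,
    wclc_synchrony_reference,
)
from convosync.errors import ConfigError, UndefinedStatisticError
from convosync.prosody import TurnProsody

STEP = 0.01


def test_wclc_config_invariants():
    with pytest.raises(ConfigError):
        WclcConfig(window_s=3.0, max_lag_s=2.0)
    with pytest.raises(ConfigError):
        WclcConfig(step_s=20.0)


def test_identical_series_peak_one_at_lag_zero(rng):
    a = rng.normal(0, 1, 6400)  # 64 s
    res = wclc_synchrony(a, a, STEP)
    assert res.summary == pytest.approx(1.0)
    assert np.allclose(res.per_window_peak, 1.0)
    assert np.allclose(res.per_window_lag_s, 0.0)


def test_shifted_copy_recovered_at_shift_lag(rng):
    a = rng.normal(0, 1, 6400)
    b = np.concatenate([np.full(100, 0.0), a[:-100]])  # b follows a by 1 s
    res = wclc_synchrony(a, b, STEP)
    assert res.summary > 0.99
    assert np.allclose(res.per_window_lag_s, 1.0)


def test_fast_equals_naive_reference_with_missing_frames(rng):
    n = 12000  # 120 s at 10 ms
    a = rng.normal(0, 1, n)
    b = 0.4 * np.concatenate([np.zeros(80), a[:-80]]) + rng.normal(0, 1, n)
    a[rng.random(n) < 0.15] = np.nan
    b[rng.random(n) < 0.15] = np.nan
    for rule in ("max_signed", "max_abs"):
        cfg = WclcConfig(peak_rule=rule)
        fast = wclc_synchrony(a, b, STEP, cfg)
        ref = wclc_synchrony_reference(a, b, STEP, cfg)
        assert np.max(np.abs(fast.per_window_peak - ref.per_window_peak)) < 1e-10
        assert abs(fast.summary - ref.summary) < 1e-10


def test_single_window_lag_symmetry(rng):
    # on one fully-finite window, wclc(a, b) at lag L equals wclc(b, a) at -L
    n = 1600
    a = rng.normal(0, 1, n)
    b = rng.normal(0, 1, n)
    cfg = WclcConfig(window_s=16.0, step_s=16.0, max_lag_s=2.0)
    ab = wclc_synchrony(a, b, STEP, cfg)
    ba = wclc_synchrony(b, a, STEP, cfg)
    assert ab.per_window_peak[0] == pytest.approx(ba.per_window_peak[0], abs=1e-12)
    assert ab.per_window_lag_s[0] == pytest.approx(-ba.per_window_lag_s[0])


def test_affine_invariance_and_bounds(rng):
    a = rng.normal(0, 1, 6400)
    b = rng.normal(0, 1, 6400)
    base = wclc_synchrony(a, b, STEP)
    scaled = wclc_synchrony(3.7 * a + 12.0, 0.5 * b - 4.0, STEP)
    assert np.allclose(base.per_window_peak, scaled.per_window_peak, atol=1e-9)
    assert -1.0 <= base.summary <= 1.0
    abs_res = wclc_synchrony(a, b, STEP, WclcConfig(peak_rule="max_abs"))
    assert 0.0 <= abs_res.summary <= 1.0
    assert abs_res.summary >= base.summary - 1e-12


def test_constant_series_is_undefined():
    with pytest.raises(UndefinedStatisticError):
        wclc_synchrony(np.ones(6400), np.ones(6400), STEP)
    with pytest.raises(UndefinedStatisticError):
        wclc_synchrony(np.ones(100), np.ones(100), STEP)  # shorter than a window


def test_fill_missing_bridges_gaps():
    x = np.array([np.nan, 1.0, np.nan, 3.0, np.nan])
    assert np.allclose(fill_missing(x), [1.0, 1.0, 2.0, 3.0, 3.0])
    with pytest.raises(UndefinedStatisticError):
        fill_missing(np.full(5, np.nan))


# ---------------------------------------------------------------------------
# adaptation


def _tp(values_a, values_b):
    out = []
    for va, vb in zip(values_a, values_b):
        out.append(TurnProsody("A", va, va, 1, va))
        out.append(TurnProsody("B", vb, vb, 1, vb))
    return out


def test_copied_previous_turn_gives_perfect_adaptation():
    a_vals = [100.0, 120.0, 90.0, 115.0, 105.0]
    b_vals = a_vals  # B copies A's previous turn exactly
    tp = _tp(a_vals, b_vals)
    assert turn_adaptation(tp, "B")["adapt_pitch"] == pytest.approx(1.0)


def test_constant_own_values_are_undefined():
    tp = _tp([100.0, 120.0, 90.0, 115.0], [50.0, 50.0, 50.0, 50.0])
    with pytest.raises(UndefinedStatisticError):
        turn_adaptation(tp, "B")


def test_too_few_turn_pairs_is_an_error():
    tp = _tp([100.0, 120.0], [90.0, 95.0])
    with pytest.raises(UndefinedStatisticError):
        turn_adaptation(tp, "B")


def test_planted_adaptation_gain_recovered(small_corpus):
    """Default adaptation gain 0.3 yields clearly positive adaptation."""
    from convosync.prosody import turn_prosody
    from convosync.turn_structure import segment_turns

    records, _ = small_corpus
    vals = []
    for rec in records:
        turns = segment_turns(rec.annotations)
        tp = turn_prosody(turns, rec.tracks)
        for spk in rec.annotations.speakers:
            vals.append(turn_adaptation(tp, spk)["adapt_intensity"])
    assert 0.1 < np.mean(vals) < 0.9


# ---------------------------------------------------------------------------
# surrogates


def test_segment_shuffle_preserves_values_and_tail(rng):
    x = np.arange(35.0)
    out = shuffle_segments(x, 10, rng)
    assert sorted(out) == sorted(x)
    assert np.array_equal(out[30:], x[30:])  # trailing partial chunk in place
    chunks = {tuple(out[i : i + 10]) for i in range(0, 30, 10)}
    assert chunks == {tuple(x[i : i + 10]) for i in range(0, 30, 10)}


def test_surrogate_null_is_deterministic_given_seed(rng):
    a = rng.normal(0, 1, 4000)
    b = rng.normal(0, 1, 4000)
    r1 = pseudosynchrony(a, b, STEP, n_surrogates=15, seed=9)
    r2 = pseudosynchrony(a, b, STEP, n_surrogates=15, seed=9)
    assert np.array_equal(r1.surrogates, r2.surrogates)
    assert r1.observed == r2.observed
    assert len(r1.surrogates) == 15
    assert r1.surrogate_mean == pytest.approx(np.mean(r1.surrogates))


def test_surrogate_null_error_when_statistic_mostly_undefined():
    def stat(_):
        raise UndefinedStatisticError("nope")

    def stat_obs(x):
        if x is marker:
            return 0.0
        raise UndefinedStatisticError("nope")

    marker = object()
    with pytest.raises(UndefinedStatisticError):
        surrogate_null(stat_obs, marker, lambda x, rng: None, n_surrogates=10, seed=0)


def test_pseudoadaptation_shuffles_partner_only(small_corpus):
    from convosync.prosody import turn_prosody
    from convosync.turn_structure import segment_turns

    records, _ = small_corpus
    rec = records[0]
    tp = turn_prosody(segment_turns(rec.annotations), rec.tracks)
    spk = rec.annotations.speakers[0]
    res = pseudoadaptation(tp, spk, "adapt_intensity", n_surrogates=20, seed=4)
    assert len(res.surrogates) == 20
    assert math.isfinite(res.observed)


# ---------------------------------------------------------------------------
# paired Bayes factor


def test_zero_differences_favour_the_null():
    assert compare_to_pseudo(np.zeros(30), np.zeros(30)) < 0


def test_large_effect_is_decisive():
    rng = np.random.default_rng(0)
    d = rng.normal(0, 1, 40)
    d = (d - d.mean()) / d.std(ddof=1) + 1.0  # exact standardized effect 1
    log_bf = compare_to_pseudo(d, np.zeros(40))
    assert log_bf > 4.6
    assert grade_evidence(log_bf).strength == "decisive"


def _oracle_one_sided_bf(diffs):
    """Independent quadrature oracle: two-sided JZS BF via the Rouder
    g-integral, converted to one-sided by the posterior mass on delta > 0."""
    from scipy import integrate, stats

    r = math.sqrt(2) / 2
    n = diffs.size
    nu = n - 1
    t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(n))

    def g_integrand(g):
        c = 1.0 + n * g * r * r
        return (
            c ** -0.5
            * (1.0 + t * t / (c * nu)) ** (-(nu + 1) / 2.0)
            * (2 * math.pi) ** -0.5
            * g ** -1.5
            * math.exp(-1.0 / (2 * g))
        )

    num, _ = integrate.quad(g_integrand, 0, np.inf, limit=400)
    bf_two = num / (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    # posterior P(delta > 0 | data, H1) on a fixed fine grid
    delta = np.linspace(-8, 8, 16001)
    post = stats.cauchy.pdf(delta, 0, r) * stats.nct.pdf(t, nu, delta * math.sqrt(n))
    p_pos = np.trapezoid(post[delta >= 0], delta[delta >= 0]) / np.trapezoid(post, delta)
    return bf_two * 2.0 * p_pos


def test_paired_bf_matches_independent_quadrature_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(10, 50))
        diffs = rng.normal(rng.uniform(-0.8, 0.8), rng.uniform(0.5, 2.0), n)
        mine = math.exp(compare_to_pseudo(diffs, np.zeros(n)))
        oracle = _oracle_one_sided_bf(diffs)
        assert mine == pytest.approx(oracle, rel=0.01)
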