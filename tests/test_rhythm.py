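"""Cosinor fitting, waveform comparison, differential rhythmicity and BH."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chillrhythm import rhythm
from chillrhythm.errors import InsufficientDataError, ValidationError

TIMES8 = np.arange(0.0, 24.0, 3.0)


def cosinor(t, mesor, amp, phase, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / period)


@pytest.mark.parametrize("mesor,amp,phase", [(5.0, 2.0, 8.0), (10.0, 0.5, 0.0),
                                             (3.0, 1.0, 23.5)])
def test_noiseless_recovery(mesor, amp, phase):
    fit = rhythm.fit_cosinor(TIMES8, cosinor(TIMES8, mesor, amp, phase))
    assert fit.mesor == pytest.approx(mesor, abs=1e-8)
    assert fit.amplitude == pytest.approx(amp, abs=1e-8)
    assert rhythm.wrap_phase_delta(fit.phase_h - phase) == pytest.approx(
        0.0, abs=1e-8)
    assert fit.p_rhythm < 1e-10


def test_constant_series_has_zero_amplitude_and_p_one():
    fit = rhythm.fit_cosinor(TIMES8, np.full(8, 4.2))
    assert fit.amplitude == 0.0
    assert fit.p_rhythm == 1.0


def test_too_few_distinct_times_rejected():
    with pytest.raises(InsufficientDataError):
        rhythm.fit_cosinor([0, 8, 16, 0, 8, 16], np.arange(6.0))


def test_reparameterization_identity(rng):
    """(M, A, phi) polar form reproduces the sin/cos linear fit exactly."""
    t = np.repeat(TIMES8, 3)
    y = cosinor(t, 7, 3, 14) + rng.normal(0, 1, t.size)
    fit = rhythm.fit_cosinor(t, y)
    w = 2 * np.pi / 24.0
    X = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(fit.predict(t), X @ beta, atol=1e-10)


def test_phase_shift_equivariance(rng):
    t = np.repeat(TIMES8, 2)
    y = cosinor(t, 5, 2, 6) + rng.normal(0, 0.3, t.size)
    base = rhythm.fit_cosinor(t, y)
    delta = 5.0
    shifted = rhythm.fit_cosinor(t + delta, y)
    assert shifted.phase_h == pytest.approx((base.phase_h + delta) % 24, abs=1e-8)
    assert shifted.mesor == pytest.approx(base.mesor, abs=1e-10)
    assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-10)


def test_phase_recovery_accuracy(rng):
    """Median absolute phase error stays below 1 h at amplitude/noise >= 2."""
    errors = []
    t = np.repeat(TIMES8, 3)
    for _ in range(200):
        phase = rng.uniform(0, 24)
        y = cosinor(t, 10, 2, phase) + rng.normal(0, 1.0, t.size)
        fit = rhythm.fit_cosinor(t, y)
        errors.append(abs(rhythm.wrap_phase_delta(fit.phase_h - phase)))
    assert np.median(errors) <= 1.0


# --- compare_cosinor --------------------------------------------------------

def test_compare_identical_groups_all_null():
    y = cosinor(TIMES8, 5, 2, 8)
    cc = rhythm.compare_cosinor(TIMES8, y, TIMES8, y)
    assert cc.delta_mesor == pytest.approx(0, abs=1e-10)
    assert cc.delta_amplitude == pytest.approx(0, abs=1e-10)
    assert cc.delta_phase_h == pytest.approx(0, abs=1e-10)
    assert cc.p_mesor > 0.99 and cc.p_amplitude > 0.99 and cc.p_phase > 0.99


def test_compare_recovers_planted_mesor_shift():
    y = cosinor(TIMES8, 5, 2, 8)
    cc = rhythm.compare_cosinor(TIMES8, y, TIMES8, y + 1.0)
    assert cc.delta_mesor == pytest.approx(1.0, abs=1e-8)


def test_compare_phase_delta_wraps_across_midnight():
    a = cosinor(TIMES8, 5, 2, 23.0)
    b = cosinor(TIMES8, 5, 2, 1.0)
    cc = rhythm.compare_cosinor(TIMES8, a, TIMES8, b)
    assert cc.delta_phase_h == pytest.approx(2.0, abs=1e-8)


def test_compare_flat_group_phase_unidentifiable(rng):
    a = cosinor(TIMES8, 5, 2, 8) + rng.normal(0, 0.05, 8)
    b = np.full(8, 5.0) + rng.normal(0, 0.05, 8)
    with pytest.warns(UserWarning):
        cc = rhythm.compare_cosinor(TIMES8, a, TIMES8, b)
    assert not cc.phase_identifiable
    assert cc.p_phase == 1.0


# --- BH adjustment ----------------------------------------------------------

def bh_stepup_oracle(p):
    """Textbook step-up computation, independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def test_bh_matches_hand_stepup_on_spec_example():
    assert np.allclose(rhythm.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert rhythm.bh_adjust([0.2])[0] == pytest.approx(0.2)
    assert np.all(rhythm.bh_adjust([1.0, 1.0, 1.0]) == 1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_oracle_and_is_monotone(ps):
    q = rhythm.bh_adjust(ps)
    assert np.allclose(q, bh_stepup_oracle(ps), atol=1e-12)
    assert np.all(q >= np.asarray(ps) - 1e-15)
    order = np.argsort(ps)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        rhythm.bh_adjust([0.5, 1.5])
    with pytest.raises(ValidationError):
        rhythm.bh_adjust([np.nan])


# --- differential rhythmicity ----------------------------------------------

def _gene_frame(gene, cond_params, noise, rng, n_rep=3):
    rows = []
    for cond, (mesor, amp, phase) in cond_params.items():
        for t in TIMES8[:6]:
            for _ in range(n_rep):
                rows.append((gene, cond,
                             t, cosinor(t, mesor, amp, phase) + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["gene", "condition", "time_h", "value"])


def test_diff_rhythm_same_waveform_not_flagged(rng):
    df = _gene_frame("g1", {"control": (5, 2, 8), "chilled": (5, 2, 8)},
                     0.0, rng)
    res = rhythm.diff_rhythm(df)
    assert res.loc["g1", "p_diff_rhythm"] > 0.99


def test_diff_rhythm_detects_lost_rhythm(rng):
    """Rhythmic in control, flat under chilling: q at or below 0.05."""
    df = _gene_frame("g1", {"control": (5, 2, 8), "chilled": (5, 0, 8)},
                     0.1, rng)
    res = rhythm.diff_rhythm(df)
    assert res.loc["g1", "q_diff_rhythm"] <= 0.05
    assert res.loc["g1", "p_rhythm_control"] < 0.01


def test_diff_rhythm_null_batch_controls_fdr(rng):
    frames = [_gene_frame(f"g{i}", {"control": (5, 0, 0), "chilled": (5, 0, 0)},
                          0.5, rng) for i in range(100)]
    res = rhythm.diff_rhythm(pd.concat(frames, ignore_index=True))
    assert int(res["diff_rhythmic"].sum()) <= 2
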