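"""Cosinor rhythmicity analysis for diel time courses.

A single-component cosinor models a series sampled over one or more 24-h
cycles as

    y(t) = M + A * cos(2*pi*(t - phi) / P) + e,

where M is the *mesor* (rhythm-adjusted mean), A >= 0 the amplitude (half the
peak-to-trough height), phi the *phase* (peak time in hours within the
period) and P the period, fixed at 24 h for a diel design.  The model is
linear in the equivalent parameters (M, b_cos, b_sin) with

    b_cos = A * cos(2*pi*phi/P),   b_sin = A * sin(2*pi*phi/P),

so fitting is ordinary least squares on cos/sin regressors followed by a
polar back-transform.  Rhythmicity is the joint F-test that both
trigonometric coefficients are zero; waveform differences between two groups
are tested on a joint design with group interactions; differential
rhythmicity across many series uses the same sin/cos basis with a
condition x (sin, cos) interaction F-test and Benjamini-Hochberg q-values.

Replicates enter every regression as independent observations; no replicate
random effect is used for rhythm fits.  The period is never estimated: a
six-point single-cycle design cannot support period estimation, and fits on
data spanning less than one full period are flagged in the log.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import logger
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "CosinorFit",
    "CosinorComparison",
    "fit_cosinor",
    "compare_cosinor",
    "diff_rhythm",
    "bh_adjust",
    "wrap_phase_delta",
]


@dataclass
class CosinorFit:
    """Single-group cosinor fit at a fixed period."""

    mesor: float
    amplitude: float
    phase_h: float
    period_h: float
    p_rhythm: float
    se_mesor: float
    se_amplitude: float
    se_phase_h: float
    n: int
    #: True when the sampled span covers less than one full period.
    single_cycle_flagged: bool = False

    def predict(self, times_h) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        w = 2.0 * np.pi / self.period_h
        return self.mesor + self.amplitude * np.cos(w * (t - self.phase_h))


@dataclass
class CosinorComparison:
    """Two-group cosinor comparison on a joint design."""

    period_h: float
    fit_a: CosinorFit
    fit_b: CosinorFit
    delta_mesor: float
    delta_amplitude: float
    delta_phase_h: float
    p_mesor: float
    p_amplitude: float
    p_phase: float
    phase_identifiable: bool = True
    warnings: list = field(default_factory=list)


def _design(times: np.ndarray, period: float) -> np.ndarray:
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(times), np.cos(w * times), np.sin(w * times)])


def _polar(b_cos: float, b_sin: float, period: float) -> tuple[float, float]:
    amp = float(np.hypot(b_cos, b_sin))
    phase = float((np.arctan2(b_sin, b_cos) * period / (2.0 * np.pi)) % period)
    return amp, phase


def fit_cosinor(times_h, values, period: float = 24.0) -> CosinorFit:
    """Fit a fixed-period cosinor by least squares.

    Parameters
    ----------
    times_h : array-like
        Sampling times in hours.  Replicates repeat the same time value.
    values : array-like
        Observations (any response unit: FPKM, mole %, unsaturation index).
    period : float
        Fixed period in hours (default 24, the diel cycle).

    Returns
    -------
    CosinorFit
        Mesor / amplitude / phase with delta-method standard errors and the
        joint-F rhythmicity p-value.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValidationError("times_h and values must be 1-D arrays of equal length")
    if not (np.isfinite(t).all() and np.isfinite(y).all()):
        raise ValidationError("times_h and values must be finite")
    distinct = np.unique(t)
    if distinct.size < 4:
        raise InsufficientDataError(
            f"cosinor fit needs >=4 distinct time points, got {distinct.size}"
        )
    single_cycle = bool(np.ptp(distinct) < period)
    if single_cycle:
        logger.info(
            "cosinor fit on a span (%.3g h) shorter than one period (%.3g h); "
            "single-cycle design flagged, statistical adequacy not asserted",
            np.ptp(distinct), period,
        )
    n = y.size
    if np.ptp(y) == 0.0:
        # All-constant series: amplitude 0 by convention, nothing to test.
        return CosinorFit(float(y[0]), 0.0, 0.0, period, 1.0,
                          0.0, 0.0, np.nan, n, single_cycle)

    X = _design(t, period)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - 3
    if df_resid <= 0:
        raise InsufficientDataError("cosinor fit needs n > 3 observations")
    sigma2 = rss1 / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)

    b0, bc, bs = beta
    amp, phase = _polar(bc, bs, period)
    # Delta method for (A, phi) as functions of (b_cos, b_sin).
    if amp > 0:
        g_amp = np.array([0.0, bc / amp, bs / amp])
        w = 2.0 * np.pi / period
        g_phase = np.array([0.0, -bs / amp**2, bc / amp**2]) / w
        se_amp = float(np.sqrt(g_amp @ cov @ g_amp))
        se_phase = float(np.sqrt(g_phase @ cov @ g_phase))
    else:  # pragma: no cover - amp == 0 with non-constant y is measure-zero
        se_amp = float(np.sqrt(cov[1, 1]))
        se_phase = np.nan

    if rss1 <= 0.0:
        p_rhythm = 0.0 if amp > 0 else 1.0
    else:
        f = ((rss0 - rss1) / 2.0) / (rss1 / df_resid)
        p_rhythm = float(stats.f.sf(f, 2, df_resid))
    return CosinorFit(float(b0), amp, phase, period, p_rhythm,
                      float(np.sqrt(cov[0, 0])), se_amp, se_phase, n, single_cycle)


def wrap_phase_delta(delta_h: float, period: float = 24.0) -> float:
    """Wrap a phase difference into ``(-period/2, period/2]``."""
    d = (float(delta_h) + period / 2.0) % period - period / 2.0
    if d == -period / 2.0:
        d = period / 2.0
    return d


def _p_from_z(est: float, se: float, atol: float = 1e-12) -> float:
    # Degenerate noiseless fits have se ~ 0; report certainty accordingly.
    if not np.isfinite(se) or se <= atol:
        return 1.0 if abs(est) <= max(atol, 1e3 * se) else 0.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


def compare_cosinor(times_a, values_a, times_b, values_b,
                    period: float = 24.0,
                    amplitude_tol: float = 1e-8) -> CosinorComparison:
    """Compare two groups' cosinor waveforms on a joint design.

    Fits ``y ~ 1 + g + cos + sin + g:cos + g:sin`` (g the group indicator)
    and reports mesor, amplitude and phase differences with Wald p-values
    (delta method for the polar parameters).  The phase difference is wrapped
    into ``(-period/2, period/2]``.  When either group's amplitude is not
    distinguishable from zero the phase difference is unidentifiable: it is
    flagged and its p-value set to 1.
    """
    fit_a = fit_cosinor(times_a, values_a, period)
    fit_b = fit_cosinor(times_b, values_b, period)

    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ya = np.asarray(values_a, dtype=float)
    yb = np.asarray(values_b, dtype=float)
    t = np.concatenate([ta, tb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros_like(ta), np.ones_like(tb)])
    w = 2.0 * np.pi / period
    X = np.column_stack([
        np.ones_like(t), g, np.cos(w * t), np.sin(w * t),
        g * np.cos(w * t), g * np.sin(w * t),
    ])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = y.size - 6
    if df_resid <= 0:
        raise InsufficientDataError("joint cosinor comparison needs n > 6")
    sigma2 = float(resid @ resid) / df_resid
    # Numerically-exact fits leave ~eps residuals; treat them as noiseless so
    # z statistics do not become ratios of rounding errors.
    scale = max(1.0, float(np.abs(y).max()))
    atol = 1e-10 * scale
    if sigma2 < atol**2:
        sigma2 = 0.0
    cov = sigma2 * np.linalg.pinv(X.T @ X)

    _, bg, bc, bs, bgc, bgs = beta
    amp_a, phase_a = _polar(bc, bs, period)
    amp_b, phase_b = _polar(bc + bgc, bs + bgs, period)

    d_mesor = float(bg)
    d_amp = amp_b - amp_a
    d_phase = wrap_phase_delta(phase_b - phase_a, period)

    p_mesor = _p_from_z(d_mesor, float(np.sqrt(cov[1, 1])), atol)

    # Delta-method gradients of d_amp and d_phase w.r.t. (bc, bs, bgc, bgs).
    idx = [2, 3, 4, 5]
    sub = cov[np.ix_(idx, idx)]
    msgs: list[str] = []
    # The phase delta is identifiable only when both amplitudes are clearly
    # non-zero (beyond ~2 standard errors of a single-group amplitude).
    se_amp_single = float(np.sqrt(max(cov[2, 2] + cov[3, 3], 0.0)))
    amp_floor = max(amplitude_tol, 2.0 * se_amp_single)
    if amp_a > amp_floor and amp_b > amp_floor:
        ca, sa = bc, bs
        cb, sb = bc + bgc, bs + bgs
        g_amp = np.array([cb / amp_b - ca / amp_a, sb / amp_b - sa / amp_a,
                          cb / amp_b, sb / amp_b])
        p_amp = _p_from_z(d_amp, float(np.sqrt(g_amp @ sub @ g_amp)), atol)
        g_phase = np.array([-sb / amp_b**2 + sa / amp_a**2,
                            cb / amp_b**2 - ca / amp_a**2,
                            -sb / amp_b**2, cb / amp_b**2]) / w
        p_phase = _p_from_z(d_phase, float(np.sqrt(g_phase @ sub @ g_phase)),
                            atol)
        identifiable = True
    else:
        g_amp = np.zeros(4)
        p_amp = _p_from_z(d_amp, float(np.sqrt(sub[0, 0] + sub[1, 1])), atol)
        p_phase = 1.0
        identifiable = False
        msgs.append("phase delta unidentifiable: a group amplitude is ~0")
        warnings.warn(msgs[-1], stacklevel=2)
        logger.warning(msgs[-1])

    return CosinorComparison(period, fit_a, fit_b, d_mesor, d_amp, d_phase,
                             p_mesor, p_amp, p_phase, identifiable, msgs)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving).

    Shared by the rhythmicity and cross-species pipelines.  Raises
    :class:`ValidationError` for p-values outside [0, 1] or non-finite.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def diff_rhythm(data: pd.DataFrame, period: float = 24.0,
                q_threshold: float = 0.05,
                series_col: str = "gene", condition_col: str = "condition",
                time_col: str = "time_h", value_col: str = "value") -> pd.DataFrame:
    """Differential rhythmicity across many series between two conditions.

    For each series a linear model with a sin/cos basis, a condition main
    effect and a condition x (sin, cos) interaction is fitted on the
    replicate-level observations.  The interaction-pair F-test p-value is the
    differential-rhythmicity p; per-condition rhythmicity p-values come from
    the sin/cos pair within each condition.  All three p-value families are
    BH-adjusted across series into q-values.

    Returns a DataFrame indexed like the input series with columns
    ``p_rhythm_<cond>``, ``q_rhythm_<cond>``, ``p_diff_rhythm``,
    ``q_diff_rhythm``, ``diff_rhythmic`` and ``note``.
    """
    required = {series_col, condition_col, time_col, value_col}
    missing = required - set(data.columns)
    if missing:
        raise ValidationError(f"diff_rhythm input missing columns: {sorted(missing)}")
    conds = sorted(data[condition_col].unique())
    if len(conds) != 2:
        raise ValidationError(f"diff_rhythm needs exactly 2 conditions, got {conds}")

    rows = []
    for gene, sub in data.groupby(series_col, sort=True):
        rec: dict = {series_col: gene, "note": ""}
        try:
            ok = True
            for cond in conds:
                cs = sub[sub[condition_col] == cond]
                if np.unique(cs[time_col]).size < 4:
                    raise InsufficientDataError(
                        f"condition {cond!r} has <4 distinct times")
            t = sub[time_col].to_numpy(float)
            y = sub[value_col].to_numpy(float)
            g = (sub[condition_col] == conds[1]).to_numpy(float)
            w = 2.0 * np.pi / period
            X = np.column_stack([np.ones_like(t), g, np.cos(w * t), np.sin(w * t),
                                 g * np.cos(w * t), g * np.sin(w * t)])
            if np.linalg.matrix_rank(X) < 6 or y.size <= 6:
                raise InsufficientDataError("rank-deficient joint design")
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            rss1 = float(resid @ resid)
            df_resid = y.size - 6
            X0 = X[:, :4]  # drop the interaction pair
            beta0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
            rss0 = float(np.sum((y - X0 @ beta0) ** 2))
            tss = float(np.sum((y - y.mean()) ** 2))
            if rss1 <= 1e-12 * max(tss, 1e-300):
                # numerically perfect joint fit: flag only a real gain
                p_diff = 1.0 if rss0 - rss1 <= 1e-12 * max(tss, 1e-300) else 0.0
            else:
                f = ((rss0 - rss1) / 2.0) / (rss1 / df_resid)
                p_diff = float(stats.f.sf(max(f, 0.0), 2, df_resid))
            rec["p_diff_rhythm"] = p_diff
            for cond in conds:
                cs = sub[sub[condition_col] == cond]
                fit = fit_cosinor(cs[time_col], cs[value_col], period)
                rec[f"p_rhythm_{cond}"] = fit.p_rhythm
            ok = True
        except InsufficientDataError as exc:
            logger.warning("diff_rhythm: series %r skipped: %s", gene, exc)
            rec["note"] = str(exc)
            rec["p_diff_rhythm"] = np.nan
            for cond in conds:
                rec[f"p_rhythm_{cond}"] = np.nan
            ok = False
        rec["_ok"] = ok
        rows.append(rec)

    out = pd.DataFrame(rows).set_index(series_col)
    for col in [f"p_rhythm_{c}" for c in conds] + ["p_diff_rhythm"]:
        qcol = col.replace("p_", "q_", 1)
        q = np.full(len(out), np.nan)
        mask = out[col].notna().to_numpy()
        if mask.any():
            q[mask] = bh_adjust(out.loc[mask, col].to_numpy())
        out[qcol] = q
    out["diff_rhythmic"] = out["q_diff_rhythm"] <= q_threshold
    return out.drop(columns="_ok")
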