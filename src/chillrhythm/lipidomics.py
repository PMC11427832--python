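"""Membrane glycerolipid composition statistics.

Quantities
----------
mole percent
    Each lipid class's share of the total measured fatty-acid-containing
    lipid in a sample, ``100 * class_total / all_class_total``; sums to 100
    per sample.  Fatty-acid mole percents are computed analogously within
    the 16:n / 18:n acyl pool.
double bond index (DBI)
    ``((X:1)*1 + (X:2)*2 + (X:3)*3) / 100`` where X:n is the summed mole %
    of 16- and 18-carbon fatty acids carrying n double bonds.  Range [0, 3].
unsaturation index
    Amount-weighted mean double-bond count per fatty acid over any acyl
    pool; restricted to 16:n/18:n with n <= 3 it coincides with the DBI.

Outlier handling is two-staged, mirroring common lipidomics practice:
a robust replicate-level screen on fatty-acid abundances (an FDR-style
reimplementation of robust-regression-and-outlier-removal at Q = 10%; exact
numerical agreement with the GraphPad original is not claimed), then a
median +/- k*IQR screen on mole percents within each
lipid class x genotype x temperature stratum (k = 1 by default, the literal
"one interquartile distance from the median"; quartiles by linear
interpolation, configurable via ``iqr_k``).
"""
from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import logger
from .errors import DegenerateSampleError, FormatError, ValidationError
from .rhythm import bh_adjust

__all__ = [
    "LipidComposition",
    "OutlierConfig",
    "parse_fatty_acid",
    "mole_percent",
    "compute_dbi",
    "unsaturation_index",
    "rout_mask",
    "iqr_mask",
    "screen_outliers",
    "screen_table",
    "compare_groups",
]

LIPID_COLUMNS = ("sample_id", "species", "condition", "time_h", "replicate",
                 "lipid_class", "fatty_acid", "amount")
SAMPLE_KEYS = ["sample_id", "species", "condition", "time_h", "replicate"]

_FA_RE = re.compile(r"^(\d+):(\d+)$")


def parse_fatty_acid(label: str) -> tuple[int, int]:
    """Parse a 'carbon:double_bonds' label such as '18:3' into integers."""
    m = _FA_RE.match(str(label).strip())
    if m is None:
        raise FormatError(f"fatty acid label {label!r} is not 'carbon:double_bonds'")
    return int(m.group(1)), int(m.group(2))


@dataclass
class OutlierConfig:
    """Thresholds for the two-stage outlier screen."""

    rout_q: float = 0.10   # false-discovery level of the robust replicate screen
    iqr_k: float = 1.0     # window half-width in IQR units around the median

    def __post_init__(self):
        if not (0.0 < self.rout_q < 0.5):
            raise ValidationError(f"rout_q must be in (0, 0.5), got {self.rout_q}")
        if self.iqr_k <= 0:
            raise ValidationError(f"iqr_k must be > 0, got {self.iqr_k}")


@dataclass
class LipidComposition:
    """Per-sample composition summaries derived from raw amounts.

    Attributes
    ----------
    class_mole_percent : pandas.DataFrame
        One row per sample (index = sample keys), one column per lipid
        class; rows sum to 100.
    fa_mole_percent : pandas.DataFrame
        One row per sample, one column per fatty acid, mole % within the
        16:n/18:n pool; rows sum to 100.
    summary : pandas.DataFrame
        One row per sample with ``dbi`` and ``unsaturation_index`` (all
        detected fatty acids) columns.
    class_unsaturation : pandas.DataFrame
        One row per sample, one column per lipid class: amount-weighted mean
        double bonds within that class (NaN when the class is absent).
    """

    class_mole_percent: pd.DataFrame
    fa_mole_percent: pd.DataFrame
    summary: pd.DataFrame
    class_unsaturation: pd.DataFrame


def _validate_lipid_table(raw: pd.DataFrame) -> pd.DataFrame:
    missing = set(LIPID_COLUMNS) - set(raw.columns)
    if missing:
        raise ValidationError(f"lipid table missing columns: {sorted(missing)}")
    if (raw["amount"] < 0).any():
        raise ValidationError("lipid amounts must be non-negative")
    for label in raw["fatty_acid"].unique():
        parse_fatty_acid(label)
    return raw


def mole_percent(raw: pd.DataFrame) -> LipidComposition:
    """Normalize raw lipid amounts to per-sample mole percentages.

    Class mole % = 100 * class total / all-class total per sample; the
    fatty-acid breakdown is normalized within the 16:n/18:n pool.  A sample
    whose amounts are all zero raises :class:`DegenerateSampleError`.
    """
    raw = _validate_lipid_table(raw)
    carbons = raw["fatty_acid"].map(lambda s: parse_fatty_acid(s)[0])
    dbs = raw["fatty_acid"].map(lambda s: parse_fatty_acid(s)[1])
    work = raw.assign(_carbon=carbons, _db=dbs)

    totals = work.groupby(SAMPLE_KEYS, sort=True)["amount"].sum()
    dead = totals[totals <= 0]
    if len(dead):
        raise DegenerateSampleError(
            f"sample(s) with zero total amount: {list(dead.index[:5])}")

    cls = work.pivot_table(index=SAMPLE_KEYS, columns="lipid_class",
                           values="amount", aggfunc="sum", fill_value=0.0)
    class_pct = cls.div(cls.sum(axis=1), axis=0) * 100.0

    pool = work[(work["_carbon"].isin((16, 18)))]
    fa = pool.pivot_table(index=SAMPLE_KEYS, columns="fatty_acid",
                          values="amount", aggfunc="sum", fill_value=0.0)
    fa = fa.reindex(class_pct.index, fill_value=0.0)
    fa_tot = fa.sum(axis=1)
    if (fa_tot <= 0).any():
        bad = list(fa_tot.index[fa_tot <= 0][:5])
        raise DegenerateSampleError(f"sample(s) with empty 16:n/18:n pool: {bad}")
    fa_pct = fa.div(fa_tot, axis=0) * 100.0

    dbi = fa_pct.apply(lambda row: compute_dbi(row.to_dict()), axis=1)
    ui = work.groupby(SAMPLE_KEYS).apply(
        lambda g: unsaturation_index(dict(zip(g["fatty_acid"], g["amount"]))),
        include_groups=False)
    summary = pd.DataFrame({"dbi": dbi, "unsaturation_index": ui})

    def _class_ui(g):
        try:
            return unsaturation_index(dict(zip(g["fatty_acid"], g["amount"])))
        except DegenerateSampleError:
            return np.nan

    class_ui = (work.groupby(SAMPLE_KEYS + ["lipid_class"])
                .apply(_class_ui, include_groups=False)
                .unstack("lipid_class"))
    return LipidComposition(class_pct, fa_pct, summary, class_ui)


def compute_dbi(fa_mole_percents, tol: float = 1e-6) -> float:
    """Double bond index from mole % of the 16:n/18:n fatty-acid pool.

    ``fa_mole_percents`` maps 'carbon:double_bonds' labels to mole percents
    that must sum to 100 (within ``tol``, relative).  Only 16- and 18-carbon
    species with at most three double bonds are admissible.
    """
    items = dict(fa_mole_percents)
    total = float(sum(items.values()))
    if not np.isclose(total, 100.0, rtol=tol, atol=tol * 100):
        raise ValidationError(
            f"fatty-acid mole percents must sum to 100, got {total:.6g}")
    acc = 0.0
    for label, pct in items.items():
        carbon, db = parse_fatty_acid(label)
        if carbon not in (16, 18):
            raise ValidationError(f"DBI pool admits only 16:n/18:n, got {label!r}")
        if db > 3:
            raise ValidationError(f"DBI pool admits n <= 3 double bonds, got {label!r}")
        acc += float(pct) * db
    return acc / 100.0


def unsaturation_index(fa_distribution) -> float:
    """Amount-weighted mean double bonds per fatty acid over any acyl pool."""
    items = dict(fa_distribution)
    total = float(sum(items.values()))
    if not items or total <= 0:
        raise DegenerateSampleError("empty fatty-acid pool")
    acc = sum(float(v) * parse_fatty_acid(k)[1] for k, v in items.items())
    return acc / total


def rout_mask(values: np.ndarray, q: float) -> np.ndarray:
    """Robust replicate-level screen: keep-mask at FDR-style level ``q``.

    Fits the robust location (median), scales residuals by the normalized
    MAD, converts to two-sided t-tail p-values (df = n - 1) and drops points
    flagged by a BH pass at level ``q``.  This approximates robust-fit
    outlier removal; it is not a numerical clone of any vendor tool.
    """
    n = values.size
    if n < 3:
        return np.ones(n, dtype=bool)
    center = np.median(values)
    resid = values - center
    scale = stats.median_abs_deviation(values, scale="normal")
    if scale == 0:
        return np.ones(n, dtype=bool)
    p = 2.0 * stats.t.sf(np.abs(resid) / scale, df=n - 1)
    qvals = bh_adjust(p)
    return qvals > q


def iqr_mask(values: np.ndarray, k: float) -> np.ndarray:
    """Keep-mask for the median +/- k*IQR screen (type-7 quartiles)."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    return (values >= med - k * iqr) & (values <= med + k * iqr)


def screen_outliers(values, cfg: OutlierConfig | None = None,
                    stratum: str = "") -> np.ndarray:
    """Two-stage keep/drop mask for one stratum of replicate values.

    The robust replicate-level screen runs first; the median +/- k*IQR
    window (recomputed on the survivors) runs second.  Strata with fewer
    than three values are passed through untouched with a logged warning.
    """
    cfg = cfg or OutlierConfig()
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        logger.warning("outlier screen skipped for stratum %r: <3 values", stratum)
        return np.ones(v.size, dtype=bool)
    keep = rout_mask(v, cfg.rout_q)
    if keep.sum() >= 3:
        inner = iqr_mask(v[keep], cfg.iqr_k)
        keep[np.flatnonzero(keep)] = inner
    return keep


def screen_table(table: pd.DataFrame, value_col: str,
                 strata: list[str], cfg: OutlierConfig | None = None) -> pd.Series:
    """Apply :func:`screen_outliers` within each stratum of a long table.

    Returns a boolean keep-mask aligned to ``table``'s index.
    """
    cfg = cfg or OutlierConfig()
    keep = pd.Series(True, index=table.index)
    for key, sub in table.groupby(strata, sort=False):
        keep.loc[sub.index] = screen_outliers(sub[value_col].to_numpy(), cfg,
                                              stratum=str(key))
    return keep


def _pooled_lsd(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Pooled within-group variance, its df, and the omnibus ANOVA p."""
    k = len(groups)
    n_tot = sum(g.size for g in groups)
    df_err = n_tot - k
    ss_err = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    mse = ss_err / df_err if df_err > 0 else 0.0
    grand = np.concatenate(groups).mean()
    ss_trt = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    if mse <= 0:
        p_omni = 1.0 if ss_trt == 0 else 0.0
    else:
        f = (ss_trt / (k - 1)) / mse
        p_omni = float(stats.f.sf(f, k - 1, df_err))
    return mse, df_err, p_omni


def compare_groups(data: pd.DataFrame, value_col: str = "value",
                   group_col: str = "group", replicate_col: str = "replicate",
                   method: str = "lsd", alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise group comparisons at one time point.

    Methods
    -------
    ``lsd``
        Fisher's least significant difference: pairwise t-tests on the
        pooled within-group mean square, with contrasts flagged only when
        the omnibus ANOVA F is significant at ``alpha``.
    ``tukey``
        Tukey's HSD (studentized-range adjusted pairwise p-values).
    ``mixed_tukey``
        A mixed model with fixed group and a random replicate intercept,
        followed by studentized-range-adjusted pairwise Wald contrasts.

    Returns a tidy DataFrame (group_a, group_b, estimate, p, method,
    omnibus_p, significant).  Zero within-group variance throughout makes
    the fit singular; the comparison then degrades to an exact-equality
    test of group means, logged.
    """
    if method not in ("lsd", "tukey", "mixed_tukey"):
        raise ValidationError(f"unknown method {method!r}")
    labels = sorted(data[group_col].unique())
    if len(labels) < 2:
        raise ValidationError("compare_groups needs >=2 groups")
    groups = [data.loc[data[group_col] == g, value_col].to_numpy(float)
              for g in labels]
    if any(g.size < 2 for g in groups):
        raise ValidationError("compare_groups needs >=2 replicates per group")

    mse, df_err, p_omni = _pooled_lsd(groups)
    rows = []
    if mse <= 0:
        logger.warning("compare_groups: zero within-group variance; "
                       "falling back to exact equality test")
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            est = groups[j].mean() - groups[i].mean()
            p = 1.0 if est == 0.0 else 0.0
            rows.append((a, b, est, p))
    elif method in ("lsd", "tukey"):
        k = len(labels)
        for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
            est = groups[j].mean() - groups[i].mean()
            se = np.sqrt(mse * (1.0 / groups[i].size + 1.0 / groups[j].size))
            tstat = est / se
            if method == "lsd":
                p = float(2.0 * stats.t.sf(abs(tstat), df_err))
            else:
                p = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0),
                                                     k, df_err))
            rows.append((a, b, est, p))
    else:  # mixed_tukey
        rows = _mixed_tukey(data, value_col, group_col, replicate_col, labels)

    out = pd.DataFrame(rows, columns=["group_a", "group_b", "estimate", "p"])
    out["method"] = method
    out["omnibus_p"] = p_omni
    if method == "lsd":
        out["significant"] = (p_omni <= alpha) & (out["p"] <= alpha)
    else:
        out["significant"] = out["p"] <= alpha
    return out


def _mixed_tukey(data, value_col, group_col, replicate_col, labels):
    import statsmodels.formula.api as smf

    k = len(labels)
    df = data.rename(columns={value_col: "_y", group_col: "_g",
                              replicate_col: "_rep"})
    df["_g"] = pd.Categorical(df["_g"], categories=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm("_y ~ C(_g)", df, groups=df["_rep"]).fit(reml=True)
        except Exception as exc:  # singular / non-converged random effect
            logger.warning("mixed_tukey fit failed (%s); using fixed-effects HSD",
                           exc)
            groups = [df.loc[df["_g"] == g, "_y"].to_numpy(float) for g in labels]
            mse, df_err, _ = _pooled_lsd(groups)
            rows = []
            for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
                est = groups[j].mean() - groups[i].mean()
                se = np.sqrt(mse * (1 / groups[i].size + 1 / groups[j].size))
                p = float(stats.studentized_range.sf(abs(est / se) * np.sqrt(2),
                                                     k, df_err))
                rows.append((a, b, est, p))
            return rows
    params = fit.fe_params
    cov = fit.cov_params().iloc[:len(params), :len(params)]
    df_err = max(int(len(df) - k - df["_rep"].nunique()), 2)
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        contrast = np.zeros(len(params))
        if i > 0:
            contrast[i] = -1.0
        if j > 0:
            contrast[j] = 1.0
        est = float(contrast @ params.to_numpy())
        se = float(np.sqrt(contrast @ cov.to_numpy() @ contrast))
        if se == 0:
            p = 1.0 if est == 0 else 0.0
        else:
            p = float(stats.studentized_range.sf(abs(est / se) * np.sqrt(2.0),
                                                 k, df_err))
        rows.append((a, b, est, p))
    return rows
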