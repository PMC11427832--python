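"""Lipidome-transcriptome integration.

Correlates per-gene expression time courses with lipid abundance (or
unsaturation) time courses to nominate candidate genes for lipid buildup
and breakdown during chilling.  Correlations are Pearson's r on
per-time-point replicate means over an aligned time grid; a positive r
nominates the gene as a buildup candidate for that lipid, a negative r as
a breakdown candidate.  Expression and lipid sampling grids rarely agree
exactly (here they share length but not all values), so two alignment
strategies are provided: strict intersection of identical times, and
ordinal pairing of the i-th sampled time of each grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import logger
from .errors import AlignmentError, ValidationError

__all__ = [
    "AlignedGrid",
    "CorrelationResult",
    "align_timepoints",
    "lipid_gene_correlation",
    "candidate_table",
    "minmax_normalize",
]


@dataclass
class AlignedGrid:
    """Matched (expression time, lipid time) pairs and the strategy used."""

    expr_times: tuple
    lipid_times: tuple
    strategy: str

    @property
    def n(self) -> int:
        return len(self.expr_times)


@dataclass
class CorrelationResult:
    """Pearson correlation between one gene and one lipid series."""

    gene: str
    lipid: str
    species: str
    condition: str
    r: float
    p: float
    n: int
    direction: str          # 'buildup' (r > 0) or 'breakdown' (r < 0)
    note: str = ""


def align_timepoints(expr_times, lipid_times,
                     strategy: str = "ordinal") -> AlignedGrid:
    """Align the expression and lipid sampling grids.

    ``intersection`` keeps exactly-equal times; ``ordinal`` pairs the i-th
    sampled time of each grid and requires equal grid lengths.  The pairing
    used is recorded in the returned object.
    """
    et = tuple(sorted(float(t) for t in expr_times))
    lt = tuple(sorted(float(t) for t in lipid_times))
    if not et or not lt:
        raise AlignmentError("both time grids must be non-empty")
    if strategy == "intersection":
        shared = sorted(set(et) & set(lt))
        if not shared:
            raise AlignmentError("time grids share no common points; "
                                 "consider strategy='ordinal'")
        return AlignedGrid(tuple(shared), tuple(shared), strategy)
    if strategy == "ordinal":
        if len(et) != len(lt):
            raise AlignmentError(
                f"ordinal pairing needs equal grid lengths ({len(et)} vs "
                f"{len(lt)}); use strategy='intersection'")
        return AlignedGrid(et, lt, strategy)
    raise ValidationError(f"unknown alignment strategy {strategy!r}")


def lipid_gene_correlation(expr_series, lipid_series, alignment: AlignedGrid,
                           gene: str = "", lipid: str = "", species: str = "",
                           condition: str = "") -> CorrelationResult:
    """Pearson correlation of a gene's profile with a lipid's profile.

    ``expr_series`` and ``lipid_series`` map time (hours) to the
    per-time-point replicate mean.  The two-sided p-value uses the t
    transform with n - 2 degrees of freedom.  Zero variance in either
    series yields an NA result with a logged reason rather than an error.
    """
    if alignment.n < 3:
        raise ValidationError("correlation needs >= 3 aligned time points")
    x = np.array([float(expr_series[t]) for t in alignment.expr_times])
    y = np.array([float(lipid_series[t]) for t in alignment.lipid_times])
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("series must be finite at all aligned times")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("correlation undefined for gene=%s lipid=%s: "
                       "zero variance", gene, lipid)
        return CorrelationResult(gene, lipid, species, condition,
                                 np.nan, np.nan, alignment.n, "undefined",
                                 note="zero variance")
    r, p = stats.pearsonr(x, y)
    direction = "buildup" if r > 0 else "breakdown"
    return CorrelationResult(gene, lipid, species, condition,
                             float(r), float(p), alignment.n, direction)


def candidate_table(correlations, p_max: float = 0.05,
                    include_marginal: bool = True,
                    marginal_p: float = 0.10) -> pd.DataFrame:
    """Rank correlation results into a candidate gene table.

    Results are sorted by |r| descending within each (lipid, species)
    block; rows with p <= ``p_max`` are flagged significant and, when
    ``include_marginal`` is on, rows with p <= ``marginal_p`` are flagged
    marginal (near-threshold candidates stay visible instead of vanishing).
    """
    rows = []
    for c in correlations:
        rows.append({"gene": c.gene, "lipid": c.lipid, "species": c.species,
                     "condition": c.condition, "r": c.r, "p": c.p, "n": c.n,
                     "direction": c.direction, "note": c.note})
    out = pd.DataFrame(rows, columns=["gene", "lipid", "species", "condition",
                                      "r", "p", "n", "direction", "note"])
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        out["marginal"] = pd.Series(dtype=bool)
        return out
    out["_absr"] = out["r"].abs()
    out = (out.sort_values(["lipid", "species", "_absr"],
                           ascending=[True, True, False])
           .drop(columns="_absr").reset_index(drop=True))
    out["significant"] = out["p"] <= p_max
    out["marginal"] = include_marginal & (out["p"] <= marginal_p) & ~out["significant"]
    return out


def minmax_normalize(series) -> np.ndarray:
    """Linear rescale of a series to [0, 1] (min -> 0, max -> 1).

    Used for heatmap export.  A constant series has no defined rescale; it
    maps to all zeros with a warning so a batch export never aborts.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("series must be non-empty")
    if not np.isfinite(x).all():
        raise ValidationError("series must be finite")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("constant series min-max normalized to all zeros",
                      stacklevel=2)
        logger.warning("minmax_normalize: constant series mapped to zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)
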