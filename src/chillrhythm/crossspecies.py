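"""Cross-species differentially regulated ortholog (DRO) detection.

Given replicate-level FPKM time courses for syntenic ortholog pairs in two
species under paired control/chilled conditions, this module implements the
two complementary detection routes and their intersection:

1. **Per-gene linear mixed model.**  For gene i the treatment/control FPKM
   ratio y_ijkl (time j, species k, replicate l) is modeled as

       E[y_ijkl] = nu_i + alpha_ij + beta_ik + gamma_ijk + eta_ikl,
       eta_ikl ~ N(0, theta_i^2),  residual ~ N(0, sigma_i^2),

   with fixed time and species main effects, a time x species interaction
   and a random intercept per biological replicate unit (replicates nested
   in species; six units in the reference design).  A non-zero interaction
   gamma means the two species' ratio trajectories diverge; the joint Wald
   chi-square test of all identifiable interaction contrasts
   (df = (n_times - 1)(n_species - 1)) yields a per-gene p-value, and
   Benjamini-Hochberg FDR thresholds call pairs DRO (FDR < 0.001) or CRO
   (FDR > 0.01); the unnamed gap in between is labeled "ambiguous".

   For the balanced complete design the model is fitted by the closed-form
   ANOVA/GLS route (the balanced-design moment estimator of the variance
   components coincides with REML, truncated at zero); unbalanced data fall
   back to a numerical REML fit (statsmodels MixedLM).  When the replicate
   variance estimate truncates to zero the GLS fit *is* the OLS fit and the
   result is flagged ``ols_fallback``.

2. **Correlation clustering.**  Mean T/C ratio profiles of both species'
   genes are pooled and clustered by deterministic average-linkage
   agglomeration on the correlation distance (1 - Pearson r), cut at k
   clusters (k = 16 by default, re-derivable via the permutation
   calibration).  A pair whose two members land in the same cluster is a
   co-expressed ortholog (CEO); otherwise it is a CC-DRO.  The permutation
   calibration keeps each species-A gene fixed and re-pairs it with a
   random different species-B gene (100 permutations by default) to measure
   the null co-clustering rate against which k and the SD / r-squared
   pre-filters are chosen.

High-confidence DROs (HC-DROs) are the intersection of the CC-DRO and
LMM-DRO sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._util import child_rng, logger
from .errors import InsufficientDataError, ValidationError
from .rhythm import bh_adjust

__all__ = [
    "FilterConfig",
    "GeneLMMResult",
    "ClusterAssignment",
    "compute_tc_ratios",
    "mean_ratio_profiles",
    "filter_pairs",
    "cluster_profiles",
    "permutation_calibrate",
    "classify_pairs",
    "fit_gene_lmm",
    "fit_lmm_table",
    "classify_dro",
    "hc_dro_intersect",
]


@dataclass
class FilterConfig:
    """Expression-quality pair filter (reproducibility + pair signal).

    ``sd_metric='fpkm_log2'`` is the pooled between-replicate SD of
    log2(FPKM + 1) per gene; ``'ratio'`` pools replicate SDs of the T/C
    ratios instead.  ``r2_metric='ratio_profile'`` is the squared Pearson
    correlation between the two species' mean T/C time profiles (the
    quantity the permutation test operates on); ``'fpkm_profile'`` uses the
    chilled-condition mean FPKM profiles.
    """

    sd_max: float = 0.4
    r2_min: float = 0.1
    sd_metric: str = "fpkm_log2"
    r2_metric: str = "ratio_profile"

    def __post_init__(self):
        if self.sd_max <= 0:
            raise ValidationError(f"sd_max must be > 0, got {self.sd_max}")
        if not (0.0 <= self.r2_min < 1.0):
            raise ValidationError(f"r2_min must be in [0, 1), got {self.r2_min}")
        if self.sd_metric not in ("fpkm_log2", "ratio"):
            raise ValidationError(f"unknown sd_metric {self.sd_metric!r}")
        if self.r2_metric not in ("ratio_profile", "fpkm_profile"):
            raise ValidationError(f"unknown r2_metric {self.r2_metric!r}")


def compute_tc_ratios(expr: pd.DataFrame, pseudocount: float = 1.0,
                      pairing: str = "replicate",
                      control: str = "control") -> pd.DataFrame:
    """Treatment/control FPKM ratios per (gene, species, time, replicate).

    ``pairing='replicate'`` divides each treatment replicate by the control
    replicate with the same index; ``'control_mean'`` divides by the control
    time-point mean instead (the paper's replicate matching is unstated;
    this is the documented alternative).  A pseudocount (default 1.0 FPKM)
    is added to numerator and denominator, so ratios are strictly positive
    and division by zero cannot occur.  Treatment cells without a matched
    control are masked (dropped) with a logged count.
    """
    if pairing not in ("replicate", "control_mean"):
        raise ValidationError(f"unknown pairing {pairing!r}")
    conds = set(expr["condition"].unique())
    if control not in conds or len(conds) != 2:
        raise ValidationError(
            f"expected two conditions including {control!r}, got {sorted(conds)}")
    treatment = (conds - {control}).pop()
    trt = expr[expr["condition"] == treatment]
    ctl = expr[expr["condition"] == control]
    if pairing == "replicate":
        keys = ["gene", "species", "time_h", "replicate"]
        merged = trt.merge(ctl, on=keys, suffixes=("_trt", "_ctl"), how="left")
        denom = merged["fpkm_ctl"]
    else:
        keys = ["gene", "species", "time_h"]
        ctl_mean = (ctl.groupby(keys, as_index=False)["fpkm"].mean()
                    .rename(columns={"fpkm": "fpkm_ctl"}))
        merged = trt.rename(columns={"fpkm": "fpkm_trt"}).merge(
            ctl_mean, on=keys, how="left")
        denom = merged["fpkm_ctl"]
    n_masked = int(denom.isna().sum())
    if n_masked:
        logger.warning("compute_tc_ratios: %d treatment cells without matched "
                       "control were masked", n_masked)
        merged = merged[denom.notna()]
    ratio = (merged["fpkm_trt"] + pseudocount) / (merged["fpkm_ctl"] + pseudocount)
    out = merged[["gene", "species", "time_h", "replicate"]].copy()
    out["ratio"] = ratio.to_numpy()
    bad = ~np.isfinite(out["ratio"]) | (out["ratio"] <= 0)
    if bad.any():  # only possible with pseudocount == 0 and zero FPKM
        logger.warning("compute_tc_ratios: %d non-positive ratios masked",
                       int(bad.sum()))
        out = out[~bad]
    return out.reset_index(drop=True)


def mean_ratio_profiles(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean T/C ratio over replicates: genes x time matrix."""
    return ratios.pivot_table(index="gene", columns="time_h", values="ratio",
                              aggfunc="mean")


def _replicate_sd(expr: pd.DataFrame, metric: str,
                  ratios: pd.DataFrame | None) -> pd.Series:
    """Pooled between-replicate SD per gene under the configured metric."""
    if metric == "fpkm_log2":
        work = expr.assign(_v=np.log2(expr["fpkm"] + 1.0))
        cells = ["gene", "species", "condition", "time_h"]
    else:
        if ratios is None:
            raise ValidationError("sd_metric='ratio' requires ratios")
        work = ratios.assign(_v=ratios["ratio"])
        cells = ["gene", "species", "time_h"]
    var = work.groupby(cells)["_v"].var(ddof=1)
    return np.sqrt(var.groupby("gene").mean())


def filter_pairs(ratios: pd.DataFrame, expr: pd.DataFrame, pairs: pd.DataFrame,
                 cfg: FilterConfig | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain pairs passing the replicate-SD and pair-r-squared filters.

    Returns ``(retained_pairs, stats)`` where ``stats`` carries the per-pair
    audit columns (sd_a, sd_b, r2, retained).  An empty retained set is
    allowed (warned, not raised).
    """
    cfg = cfg or FilterConfig()
    sd = _replicate_sd(expr, cfg.sd_metric, ratios)
    if cfg.r2_metric == "ratio_profile":
        prof = mean_ratio_profiles(ratios)
    else:
        chilled = expr[expr["condition"] != "control"]
        prof = chilled.pivot_table(index="gene", columns="time_h",
                                   values="fpkm", aggfunc="mean")
    stats_rows = []
    for gene_a, gene_b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        sd_a = float(sd.get(gene_a, np.nan))
        sd_b = float(sd.get(gene_b, np.nan))
        r2 = np.nan
        if gene_a in prof.index and gene_b in prof.index:
            pa = prof.loc[gene_a].to_numpy(float)
            pb = prof.loc[gene_b].to_numpy(float)
            if np.std(pa) > 0 and np.std(pb) > 0:
                r2 = float(np.corrcoef(pa, pb)[0, 1] ** 2)
            else:
                r2 = 0.0
        retained = (np.isfinite(sd_a) and np.isfinite(sd_b) and np.isfinite(r2)
                    and sd_a < cfg.sd_max and sd_b < cfg.sd_max
                    and r2 > cfg.r2_min)
        stats_rows.append((gene_a, gene_b, sd_a, sd_b, r2, retained))
    audit = pd.DataFrame(stats_rows, columns=["gene_a", "gene_b", "sd_a",
                                              "sd_b", "r2", "retained"])
    retained = audit.loc[audit["retained"], ["gene_a", "gene_b"]].reset_index(drop=True)
    if retained.empty:
        logger.warning("filter_pairs: no pairs retained under sd_max=%g, r2_min=%g",
                       cfg.sd_max, cfg.r2_min)
    return retained, audit


@dataclass
class ClusterAssignment:
    """Gene -> cluster assignment from correlation clustering."""

    assignments: pd.Series          # gene -> cluster id (1..k, flat cluster last)
    k: int
    linkage: str = "average"
    metric: str = "1 - pearson"
    flat_cluster: int | None = None  # id of the zero-variance catch-all, if any

    def same_cluster(self, gene_a: str, gene_b: str) -> bool | None:
        a = self.assignments.get(gene_a)
        b = self.assignments.get(gene_b)
        if a is None or b is None:
            return None
        return bool(a == b)


def cluster_profiles(profiles: pd.DataFrame, k: int) -> ClusterAssignment:
    """Cluster pooled mean-ratio time profiles at k clusters.

    Distance is the correlation distance 1 - Pearson r between time
    profiles (scale- and offset-invariant), agglomerated with deterministic
    average linkage and cut at ``k`` clusters.  Zero-variance (flat)
    profiles cannot enter a correlation metric; they are assigned to a
    dedicated extra cluster and logged.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    if profiles.isna().any().any():
        raise ValidationError("profiles must be complete (no NaN)")
    X = profiles.to_numpy(float)
    variable = X.std(axis=1) > 0
    n_flat = int((~variable).sum())
    genes_var = profiles.index[variable]
    assign = pd.Series(np.nan, index=profiles.index)
    n_var = int(variable.sum())
    if n_var:
        k_eff = min(k, n_var)
        if n_var == 1:
            labels = np.array([1])
        else:
            d = pdist(X[variable], metric="correlation")
            Z = hierarchy.linkage(d, method="average")
            labels = hierarchy.fcluster(Z, t=k_eff, criterion="maxclust")
        # renumber contiguously in order of first appearance
        _, labels = np.unique(labels, return_inverse=True)
        assign.loc[genes_var] = labels + 1
    flat_id = None
    if n_flat:
        flat_id = int(assign.loc[genes_var].max() if n_var else 0) + 1
        assign.loc[profiles.index[~variable]] = flat_id
        logger.warning("cluster_profiles: %d flat (zero-variance) profiles "
                       "assigned to dedicated cluster %d", n_flat, flat_id)
    return ClusterAssignment(assign.astype(int), k, flat_cluster=flat_id)


def classify_pairs(pairs: pd.DataFrame,
                   assignment: ClusterAssignment) -> pd.DataFrame:
    """Label each pair CEO (same cluster) or CC-DRO (different clusters).

    Pairs with an unclustered member are excluded and counted in the log.
    """
    rows = []
    n_excluded = 0
    for gene_a, gene_b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        same = assignment.same_cluster(gene_a, gene_b)
        if same is None:
            n_excluded += 1
            continue
        rows.append((gene_a, gene_b,
                     int(assignment.assignments[gene_a]),
                     int(assignment.assignments[gene_b]),
                     "CEO" if same else "CC-DRO"))
    if n_excluded:
        logger.warning("classify_pairs: %d pairs excluded (unclustered member)",
                       n_excluded)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "cluster_a",
                                       "cluster_b", "label"])


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random permutation of range(n) without fixed points (n >= 2)."""
    perm = rng.permutation(n)
    fixed = np.flatnonzero(perm == np.arange(n))
    if fixed.size == 1:
        j = fixed[0]
        other = (j + 1) % n
        perm[j], perm[other] = perm[other], perm[j]
    elif fixed.size > 1:
        perm[fixed] = perm[np.roll(fixed, 1)]
    return perm


def permutation_calibrate(pairs: pd.DataFrame, profiles: pd.DataFrame,
                          n_perm: int = 100,
                          k_grid: Sequence[int] = (8, 12, 16, 20, 24),
                          seed: int = 0,
                          max_null_rate: float = 0.15) -> dict:
    """Choose the cluster count by a fixed-A / permuted-B null.

    For each candidate k the true pairing's co-clustering rate is compared
    with the rate over ``n_perm`` random re-pairings in which every
    species-A gene keeps its cluster but is matched to a *different*
    species-B gene (fixed-point-free permutation of the B column).  The
    report recommends the k maximizing the observed rate among candidates
    whose mean null rate stays below ``max_null_rate`` (falling back to the
    lowest-null k when none qualifies).  Fully seeded and deterministic.
    """
    if len(pairs) < 2:
        raise ValidationError("permutation_calibrate needs >= 2 pairs")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = child_rng(seed, "permutation")
    n_genes = profiles.shape[0]
    rows = []
    for k in k_grid:
        if k >= n_genes:
            logger.warning("permutation_calibrate: k=%d >= %d genes, skipped",
                           k, n_genes)
            continue
        assignment = cluster_profiles(profiles, k)
        lab = classify_pairs(pairs, assignment)
        observed = float((lab["label"] == "CEO").mean()) if len(lab) else np.nan
        a_cl = assignment.assignments.reindex(pairs["gene_a"]).to_numpy()
        b_cl = assignment.assignments.reindex(pairs["gene_b"]).to_numpy()
        null_rates = np.empty(n_perm)
        for p in range(n_perm):
            perm = _derangement(len(pairs), rng)
            null_rates[p] = float(np.mean(a_cl == b_cl[perm]))
        rows.append((k, observed, float(null_rates.mean()),
                     float(null_rates.std(ddof=1)) if n_perm > 1 else 0.0))
    report = pd.DataFrame(rows, columns=["k", "observed_rate", "null_rate_mean",
                                         "null_rate_sd"])
    if report.empty:
        raise ValidationError("no feasible k in k_grid")
    feasible = report[report["null_rate_mean"] <= max_null_rate]
    if feasible.empty:
        chosen = int(report.loc[report["null_rate_mean"].idxmin(), "k"])
        logger.warning("permutation_calibrate: no k met null rate <= %g; "
                       "choosing lowest-null k=%d", max_null_rate, chosen)
    else:
        best = feasible.sort_values(["observed_rate", "k"],
                                    ascending=[False, True]).iloc[0]
        chosen = int(best["k"])
    return {"chosen_k": chosen, "report": report, "n_perm": n_perm,
            "max_null_rate": max_null_rate, "seed": seed}


# ---------------------------------------------------------------------------
# Per-gene linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class GeneLMMResult:
    """Per-gene mixed-model fit and interaction Wald test."""

    gene: str
    intercept: float
    time_effects: np.ndarray        # alpha_j, treatment-coded (J-1)
    species_effect: float           # beta for the second species
    interaction_effects: np.ndarray  # gamma_jk contrasts ((J-1)(K-1))
    theta2: float                   # replicate random-intercept variance
    sigma2: float                   # residual variance
    wald: float
    df: int
    p: float
    method: str = "anova_reml"      # or "mixedlm"
    ols_fallback: bool = False      # theta2 truncated to zero -> GLS == OLS
    call: str = ""                  # filled by classify_dro
    fdr: float = np.nan


def _lmm_design(times: np.ndarray, species: np.ndarray,
                time_levels: np.ndarray, species_levels: np.ndarray
                ) -> tuple[np.ndarray, slice]:
    """Treatment-coded fixed-effect design; returns (X, interaction slice)."""
    J = time_levels.size
    t_dumm = np.column_stack([(times == t).astype(float)
                              for t in time_levels[1:]])
    s_dumm = (species == species_levels[1]).astype(float)[:, None]
    inter = t_dumm * s_dumm
    X = np.column_stack([np.ones(times.size), t_dumm, s_dumm, inter])
    p = X.shape[1]
    return X, slice(p - (J - 1), p)


def fit_gene_lmm(gene_df: pd.DataFrame, gene: str | None = None,
                 log_ratios: bool = False) -> GeneLMMResult:
    """Fit the per-gene mixed model and the joint interaction Wald test.

    ``gene_df`` holds one gene's ratios with columns (species, time_h,
    replicate, ratio).  Balanced complete designs take the exact ANOVA/GLS
    REML route; anything unbalanced falls back to a numerical REML fit.
    Set ``log_ratios=True`` to model log2 ratios instead of raw ratios.
    """
    gene = gene if gene is not None else str(gene_df["gene"].iloc[0]) \
        if "gene" in gene_df.columns else "?"
    df = gene_df.copy()
    y = df["ratio"].to_numpy(float)
    if log_ratios:
        y = np.log2(y)
    times = df["time_h"].to_numpy(float)
    species = df["species"].to_numpy()
    time_levels = np.unique(times)
    species_levels = np.unique(species)
    J, K = time_levels.size, species_levels.size
    if J < 2 or K != 2:
        raise InsufficientDataError(
            f"gene {gene}: need >=2 time points and exactly 2 species")
    reps = df["replicate"].to_numpy()
    # replicate unit = (species, replicate): the biological replicate pool
    unit = pd.Series([f"{s}|{r}" for s, r in zip(species, reps)])
    per_species_units = pd.DataFrame({"s": species, "u": unit}).groupby("s")["u"].nunique()
    if (per_species_units < 2).any():
        raise InsufficientDataError(f"gene {gene}: need >=2 replicates per species")

    counts = df.groupby([pd.Series(times), pd.Series(species), unit]).size()
    balanced = (counts.nunique() == 1
                and len(counts) == J * unit.nunique()
                and counts.iloc[0] == 1
                and unit.nunique() % K == 0)
    X, gamma_sl = _lmm_design(times, species, time_levels, species_levels)
    if balanced:
        return _fit_balanced(gene, y, X, gamma_sl, times, species, unit,
                             time_levels, species_levels)
    return _fit_mixedlm(gene, y, X, gamma_sl, unit)


def _fit_balanced(gene, y, X, gamma_sl, times, species, unit,
                  time_levels, species_levels) -> GeneLMMResult:
    J = time_levels.size
    n = y.size
    p = X.shape[1]
    # Cell means (time x species) and the nested replicate-unit decomposition.
    cell = pd.Series(y).groupby([pd.Series(times), pd.Series(species)]).transform("mean")
    resid_cell = y - cell.to_numpy()
    ss_resid = float(resid_cell @ resid_cell)
    unit_mean = pd.Series(y).groupby(unit).transform("mean")
    species_mean = pd.Series(y).groupby(pd.Series(species)).transform("mean")
    dev = (unit_mean - species_mean).to_numpy()
    ss_rep = float(dev @ dev)               # J obs per unit already summed
    n_units = unit.nunique()
    K = species_levels.size
    df_rep = n_units - K
    df_err = (n - J * K) - df_rep
    if df_err <= 0:
        raise InsufficientDataError(f"gene {gene}: no residual df for the LMM")
    ss_err = max(ss_resid - ss_rep, 0.0)
    sigma2 = ss_err / df_err
    ms_rep = ss_rep / df_rep if df_rep > 0 else 0.0
    theta2 = max(0.0, (ms_rep - sigma2) / J)
    ols_fallback = theta2 == 0.0

    # GLS with block compound-symmetry covariance per replicate unit.
    if sigma2 <= 0:
        # Noiseless data: OLS estimates are exact; covariance is zero.
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        gamma = beta[gamma_sl]
        wald = 0.0 if np.allclose(gamma, 0.0, atol=1e-10) else np.inf
        pval = 1.0 if wald == 0.0 else 0.0
        return GeneLMMResult(gene, float(beta[0]), beta[1:J], float(beta[J]),
                             gamma, theta2, sigma2, wald, gamma.size, pval,
                             "anova_reml", ols_fallback)
    rho = theta2 / sigma2
    codes = unit.astype("category").cat.codes.to_numpy()
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for u in np.unique(codes):
        idx = codes == u
        m = int(idx.sum())
        Xu, yu = X[idx], y[idx]
        # (I + rho J)^-1 = I - rho/(1+m rho) J   (all divided by sigma2)
        shrink = rho / (1.0 + m * rho)
        Xs = Xu - shrink * Xu.sum(axis=0)
        XtVX += Xu.T @ Xs / sigma2
        XtVy += Xs.T @ yu / sigma2
    cov = np.linalg.inv(XtVX)
    beta = cov @ XtVy
    gamma = beta[gamma_sl]
    cov_gamma = cov[gamma_sl, gamma_sl]
    wald = float(gamma @ np.linalg.solve(cov_gamma, gamma))
    pval = float(stats.chi2.sf(wald, gamma.size))
    return GeneLMMResult(gene, float(beta[0]), beta[1:J], float(beta[J]),
                         gamma, theta2, sigma2, wald, gamma.size, pval,
                         "anova_reml", ols_fallback)


def _fit_mixedlm(gene, y, X, gamma_sl, unit) -> GeneLMMResult:
    from statsmodels.regression.mixed_linear_model import MixedLM

    J = X[:, gamma_sl].shape[1] + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=unit.to_numpy())
        try:
            fit = model.fit(reml=True)
            theta2 = float(np.asarray(fit.cov_re)[0, 0])
            sigma2 = float(fit.scale)
            beta = np.asarray(fit.fe_params)
            cov = np.asarray(fit.cov_params())[:X.shape[1], :X.shape[1]]
            method, fallback = "mixedlm", theta2 <= 1e-10
        except Exception as exc:  # singular random effect -> plain OLS
            logger.warning("gene %s: MixedLM failed (%s); OLS fallback", gene, exc)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            dfres = y.size - X.shape[1]
            sigma2 = float(resid @ resid) / dfres
            cov = sigma2 * np.linalg.pinv(X.T @ X)
            theta2, method, fallback = 0.0, "mixedlm", True
    beta = np.asarray(beta, dtype=float)
    cov = np.asarray(cov, dtype=float)
    gamma = beta[gamma_sl]
    cov_gamma = cov[gamma_sl, gamma_sl]
    wald = float(gamma @ np.linalg.solve(cov_gamma, gamma))
    pval = float(stats.chi2.sf(wald, gamma.size))
    return GeneLMMResult(gene, float(beta[0]), beta[1:J], float(beta[J]),
                         gamma, theta2, sigma2, wald, gamma.size, pval,
                         method, fallback)


def fit_lmm_table(ratios: pd.DataFrame, pairs: pd.DataFrame | None = None,
                  log_ratios: bool = False) -> pd.DataFrame:
    """Fit the per-gene LMM for every pair and return a tidy result table.

    ``ratios`` must hold both members of each pair; when ``pairs`` is given
    the two species' ratio series of a pair are fitted jointly under the
    pair's identity (gene_a), which is the paper-faithful unit of testing.
    Without ``pairs``, each gene's own (single-species) table is rejected —
    the model is cross-species by construction.
    """
    if pairs is None:
        raise ValidationError("fit_lmm_table requires the ortholog pair list")
    by_gene = dict(tuple(ratios.groupby("gene", sort=False)))
    rows = []
    for gene_a, gene_b in pairs[["gene_a", "gene_b"]].itertuples(index=False):
        sub_a = by_gene.get(gene_a)
        sub_b = by_gene.get(gene_b)
        if sub_a is None or sub_b is None:
            logger.warning("fit_lmm_table: pair (%s, %s) missing ratios; skipped",
                           gene_a, gene_b)
            continue
        both = pd.concat([sub_a, sub_b], ignore_index=True)
        res = fit_gene_lmm(both, gene=gene_a, log_ratios=log_ratios)
        rows.append({
            "gene_a": gene_a, "gene_b": gene_b, "wald": res.wald,
            "df": res.df, "p": res.p, "theta2": res.theta2,
            "sigma2": res.sigma2, "method": res.method,
            "ols_fallback": res.ols_fallback,
            "max_abs_gamma": float(np.max(np.abs(res.interaction_effects))),
        })
    return pd.DataFrame(rows)


def classify_dro(results: pd.DataFrame, fdr_dro: float = 0.001,
                 fdr_cro: float = 0.01) -> pd.DataFrame:
    """BH-adjust the interaction p-values and call DRO / CRO / ambiguous.

    FDR < ``fdr_dro`` -> DRO; FDR > ``fdr_cro`` -> CRO; the in-between band,
    which the thresholds leave unnamed, is "ambiguous".
    """
    if "p" not in results.columns:
        raise ValidationError("results must carry a 'p' column")
    out = results.copy()
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["call"] = np.where(out["fdr"] < fdr_dro, "DRO",
                           np.where(out["fdr"] > fdr_cro, "CRO", "ambiguous"))
    return out


def _pair_key(df: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, df[["gene_a", "gene_b"]].itertuples(index=False)))


def hc_dro_intersect(cc_dro: Iterable[tuple], lmm_dro: Iterable[tuple],
                     universe: Iterable[tuple]) -> set[tuple]:
    """High-confidence DROs: intersection of the two detection routes.

    Both sets must be subsets of the same retained-pair universe; anything
    else indicates mismatched upstream filtering and raises.
    """
    cc, lmm, uni = set(cc_dro), set(lmm_dro), set(universe)
    if not cc <= uni or not lmm <= uni:
        raise ValidationError("CC-DRO and LMM-DRO sets must index the same "
                              "pair universe")
    return cc & lmm
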