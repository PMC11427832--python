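"""Pipeline driver: configuration, stage orchestration and the run manifest.

Stages run in order synthdata (optional) -> lipidomics -> rhythm ->
crossspecies -> integrate.  Every stage persists its outputs as TSV under
the output directory, so any stage can be re-run from the persisted
intermediates through the corresponding CLI subcommand.  Each run emits
exactly one manifest recording the tool version, a config snapshot, the
seed, input checksums and per-stage row counts and warnings.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, crossspecies, integrate, lipidomics, rhythm, synthdata
from ._util import config_hash, file_checksum, logger
from .errors import ChillRhythmError, ConfigError
from .io import read_expression, read_lipids, read_pairs, write_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline",
           "lipid_stats_stage", "lipid_rhythm_stage", "dro_stage",
           "integrate_stage"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs.

    Paths may be None, in which case the corresponding table is simulated
    (expression/pairs via the expression simulator, lipids via the lipid
    simulator).  Module parameter blocks mirror the module-level configs.
    """

    expression_path: str | None = None
    pairs_path: str | None = None
    lipid_path: str | None = None
    out_dir: str = "chillrhythm_out"
    seed: int = 0

    simulate_expression: bool = True
    simulate_lipids: bool = True
    expression_sim: dict = field(default_factory=dict)
    lipid_sim: dict = field(default_factory=dict)

    filter: dict = field(default_factory=dict)       # FilterConfig kwargs
    outliers: dict = field(default_factory=dict)     # OutlierConfig kwargs
    apply_filter: bool = True
    period_h: float = 24.0
    k_clusters: int = 16
    calibrate_k: bool = False
    n_perm: int = 100
    fdr_dro: float = 0.001
    fdr_cro: float = 0.01
    pseudocount: float = 1.0
    ratio_pairing: str = "replicate"
    log_ratios: bool = False
    group_method: str = "lsd"
    alignment_strategy: str = "ordinal"
    integrate_max_genes: int = 50
    rhythm_q_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def snapshot(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    version: str
    config: dict
    config_hash: str
    seed: int
    input_checksums: dict
    counts: dict
    warnings: int
    stages: dict                    # stage name -> 'ok' | 'skipped: ...' | 'failed: ...'

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record):
        self.count += 1


# ---------------------------------------------------------------------------
# Stage functions (also backing the CLI subcommands)
# ---------------------------------------------------------------------------

def lipid_stats_stage(lipids: pd.DataFrame, outlier_cfg=None,
                      method: str = "lsd") -> dict:
    """Composition, outlier screen and per-timepoint species contrasts."""
    cfg = outlier_cfg or lipidomics.OutlierConfig()
    comp = lipidomics.mole_percent(lipids)
    long_pct = (comp.class_mole_percent.stack().rename("mole_percent")
                .reset_index())
    keep = lipidomics.screen_table(long_pct, "mole_percent",
                                   ["lipid_class", "species", "condition"], cfg)
    screened = long_pct[keep]
    contrasts = []
    for (cls, cond, t), sub in screened.groupby(
            ["lipid_class", "condition", "time_h"]):
        if sub["species"].nunique() < 2:
            continue
        if sub.groupby("species")["mole_percent"].count().min() < 2:
            continue
        res = lipidomics.compare_groups(
            sub.rename(columns={"species": "group", "mole_percent": "value"}),
            method=method)
        res.insert(0, "time_h", t)
        res.insert(0, "condition", cond)
        res.insert(0, "lipid_class", cls)
        contrasts.append(res)
    contrast_df = (pd.concat(contrasts, ignore_index=True)
                   if contrasts else pd.DataFrame())
    return {"composition": comp, "mole_percent_long": long_pct,
            "screen_keep": keep, "contrasts": contrast_df,
            "n_dropped": int((~keep).sum())}


def lipid_rhythm_stage(lipids: pd.DataFrame, period_h: float = 24.0,
                       q_threshold: float = 0.05) -> dict:
    """Cosinor fits per (class, species, condition) and condition contrasts."""
    comp = lipidomics.mole_percent(lipids)
    long_pct = (comp.class_mole_percent.stack().rename("mole_percent")
                .reset_index())
    fits = []
    for (cls, sp, cond), sub in long_pct.groupby(
            ["lipid_class", "species", "condition"]):
        fit = rhythm.fit_cosinor(sub["time_h"], sub["mole_percent"], period_h)
        fits.append({"lipid_class": cls, "species": sp, "condition": cond,
                     "mesor": fit.mesor, "amplitude": fit.amplitude,
                     "phase_h": fit.phase_h, "p_rhythm": fit.p_rhythm,
                     "n": fit.n})
    fit_df = pd.DataFrame(fits)
    fit_df["q_rhythm"] = rhythm.bh_adjust(fit_df["p_rhythm"].to_numpy())
    fit_df["rhythmic"] = fit_df["q_rhythm"] <= q_threshold

    comps = []
    for (cls, sp), sub in long_pct.groupby(["lipid_class", "species"]):
        conds = sorted(sub["condition"].unique())
        if len(conds) != 2:
            continue
        a = sub[sub["condition"] == conds[0]]
        b = sub[sub["condition"] == conds[1]]
        cc = rhythm.compare_cosinor(a["time_h"], a["mole_percent"],
                                    b["time_h"], b["mole_percent"], period_h)
        comps.append({"lipid_class": cls, "species": sp,
                      "delta_mesor": cc.delta_mesor,
                      "delta_amplitude": cc.delta_amplitude,
                      "delta_phase_h": cc.delta_phase_h,
                      "p_mesor": cc.p_mesor, "p_amplitude": cc.p_amplitude,
                      "p_phase": cc.p_phase,
                      "phase_identifiable": cc.phase_identifiable})
    return {"fits": fit_df, "comparisons": pd.DataFrame(comps)}


def dro_stage(expr: pd.DataFrame, pairs: pd.DataFrame, *,
              pseudocount: float = 1.0, ratio_pairing: str = "replicate",
              filter_cfg=None, apply_filter: bool = True, k: int = 16,
              calibrate_k: bool = False, n_perm: int = 100, seed: int = 0,
              fdr_dro: float = 0.001, fdr_cro: float = 0.01,
              log_ratios: bool = False) -> dict:
    """The full cross-species route: ratios, filter, clustering, LMM, HC."""
    ratios = crossspecies.compute_tc_ratios(expr, pseudocount, ratio_pairing)
    if apply_filter:
        retained, audit = crossspecies.filter_pairs(
            ratios, expr, pairs, filter_cfg or crossspecies.FilterConfig())
    else:
        retained = pairs[["gene_a", "gene_b"]].reset_index(drop=True)
        audit = retained.assign(retained=True)
    genes_used = pd.unique(retained[["gene_a", "gene_b"]].to_numpy().ravel())
    profiles = crossspecies.mean_ratio_profiles(
        ratios[ratios["gene"].isin(genes_used)])
    calibration = None
    if calibrate_k and len(retained) >= 2:
        calibration = crossspecies.permutation_calibrate(
            retained, profiles, n_perm=n_perm, seed=seed)
        k = calibration["chosen_k"]
    if len(retained):
        assignment = crossspecies.cluster_profiles(profiles, k)
        pair_labels = crossspecies.classify_pairs(retained, assignment)
        lmm = crossspecies.fit_lmm_table(ratios, retained, log_ratios=log_ratios)
        lmm = crossspecies.classify_dro(lmm, fdr_dro, fdr_cro)
        universe = set(map(tuple,
                           retained[["gene_a", "gene_b"]].itertuples(index=False)))
        cc_dro = set(map(tuple, pair_labels.loc[pair_labels["label"] == "CC-DRO",
                                                ["gene_a", "gene_b"]]
                         .itertuples(index=False)))
        lmm_dro = set(map(tuple, lmm.loc[lmm["call"] == "DRO",
                                         ["gene_a", "gene_b"]]
                          .itertuples(index=False)))
        hc = crossspecies.hc_dro_intersect(cc_dro, lmm_dro, universe)
        pair_labels["hc_dro"] = [
            (ga, gb) in hc for ga, gb in
            pair_labels[["gene_a", "gene_b"]].itertuples(index=False)]
    else:
        assignment, pair_labels = None, pd.DataFrame(
            columns=["gene_a", "gene_b", "cluster_a", "cluster_b", "label",
                     "hc_dro"])
        lmm = pd.DataFrame(columns=["gene_a", "gene_b", "p", "fdr", "call"])
        hc = set()
    counts = {
        "pairs_input": int(len(pairs)),
        "pairs_retained": int(len(retained)),
        "ceo": int((pair_labels["label"] == "CEO").sum()),
        "cc_dro": int((pair_labels["label"] == "CC-DRO").sum()),
        "lmm_dro": int((lmm["call"] == "DRO").sum()),
        "cro": int((lmm["call"] == "CRO").sum()),
        "ambiguous": int((lmm["call"] == "ambiguous").sum()),
        "hc_dro": int(len(hc)),
        "k_used": int(k),
    }
    return {"ratios": ratios, "retained": retained, "audit": audit,
            "assignment": assignment, "pair_labels": pair_labels, "lmm": lmm,
            "hc_dro": hc, "calibration": calibration, "counts": counts}


def integrate_stage(expr: pd.DataFrame, lipids: pd.DataFrame,
                    genes: list[str], *, strategy: str = "ordinal",
                    condition: str = "chilled") -> dict:
    """Correlate selected genes' chilled profiles with lipid mole percents."""
    comp = lipidomics.mole_percent(lipids)
    long_pct = (comp.class_mole_percent.stack().rename("mole_percent")
                .reset_index())
    lipid_means = (long_pct[long_pct["condition"] == condition]
                   .groupby(["species", "lipid_class", "time_h"])
                   ["mole_percent"].mean())
    expr_means = (expr[(expr["condition"] == condition)
                       & (expr["gene"].isin(genes))]
                  .groupby(["species", "gene", "time_h"])["fpkm"].mean())
    expr_times = sorted(expr["time_h"].unique())
    lipid_times = sorted(lipids["time_h"].unique())
    grid = integrate.align_timepoints(expr_times, lipid_times, strategy)
    results = []
    for (sp, gene), series in expr_means.groupby(["species", "gene"]):
        e = series.droplevel(["species", "gene"]).to_dict()
        if sp not in lipid_means.index.get_level_values("species"):
            continue
        for cls in lipid_means.loc[sp].index.get_level_values("lipid_class").unique():
            lseries = lipid_means.loc[(sp, cls)].to_dict()
            if any(t not in e for t in grid.expr_times) or \
               any(t not in lseries for t in grid.lipid_times):
                continue
            results.append(integrate.lipid_gene_correlation(
                e, lseries, grid, gene=gene, lipid=cls, species=sp,
                condition=condition))
    table = integrate.candidate_table(results)
    norm_rows = []
    for (sp, gene), series in expr_means.groupby(["species", "gene"]):
        vals = series.droplevel(["species", "gene"]).sort_index()
        norm_rows.append(pd.Series(integrate.minmax_normalize(vals.to_numpy()),
                                   index=vals.index, name=f"{sp}:{gene}"))
    heatmap = pd.DataFrame(norm_rows)
    return {"candidates": table, "alignment": grid, "heatmap": heatmap}


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages and write outputs plus one manifest to out_dir."""
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    logger.addHandler(counter)
    snapshot = cfg.snapshot()
    checksums: dict = {}
    counts: dict = {}
    stages: dict = {}
    manifest = RunManifest(__version__, snapshot, config_hash(snapshot),
                           cfg.seed, checksums, counts, 0, stages)

    def _finish_fail(stage, exc):
        stages[stage] = f"failed: {exc}"
        manifest.warnings = counter.count
        manifest.write(out / "manifest.yaml")
        logger.removeHandler(counter)
        raise ChillRhythmError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- inputs / synthdata -------------------------------------------------
    expr = pairs = lipid_table = None
    try:
        if cfg.expression_path:
            expr = read_expression(cfg.expression_path)
            checksums["expression"] = file_checksum(cfg.expression_path)
        elif cfg.simulate_expression:
            sim_cfg = synthdata.ExpressionSimConfig(seed=cfg.seed,
                                                    **cfg.expression_sim)
            expr, truth = synthdata.generate_expression(sim_cfg)
            pairs = truth.pairs()
            write_table(expr, out / "expression.tsv", snapshot)
            write_table(truth.genes, out / "truth_genes.tsv", snapshot)
            write_table(pairs, out / "pairs.tsv", snapshot)
        if cfg.pairs_path:
            pairs = read_pairs(cfg.pairs_path)
            checksums["pairs"] = file_checksum(cfg.pairs_path)
        if cfg.lipid_path:
            lipid_table = read_lipids(cfg.lipid_path)
            checksums["lipids"] = file_checksum(cfg.lipid_path)
        elif cfg.simulate_lipids:
            lsim = synthdata.LipidSimConfig(seed=cfg.seed, **cfg.lipid_sim)
            lipid_table, ltruth = synthdata.generate_lipids(lsim)
            write_table(lipid_table, out / "lipids.tsv", snapshot)
            write_table(ltruth.lipids, out / "truth_lipids.tsv", snapshot)
        stages["synthdata"] = "ok"
    except Exception as exc:
        _finish_fail("synthdata", exc)

    # --- lipidomics ----------------------------------------------------------
    if lipid_table is not None:
        try:
            lip = lipid_stats_stage(lipid_table,
                                    lipidomics.OutlierConfig(**cfg.outliers),
                                    cfg.group_method)
            write_table(lip["composition"].class_mole_percent.reset_index(),
                        out / "composition.tsv", snapshot)
            write_table(lip["composition"].summary.reset_index(),
                        out / "lipid_summary.tsv", snapshot)
            write_table(lip["contrasts"], out / "lipid_contrasts.tsv", snapshot)
            counts["lipid_samples"] = int(len(lip["composition"].summary))
            counts["lipid_outliers_dropped"] = lip["n_dropped"]
            stages["lipidomics"] = "ok"
        except Exception as exc:
            _finish_fail("lipidomics", exc)

        # --- rhythm (lipids) -------------------------------------------------
        try:
            rhy = lipid_rhythm_stage(lipid_table, cfg.period_h,
                                     cfg.rhythm_q_threshold)
            write_table(rhy["fits"], out / "lipid_rhythms.tsv", snapshot)
            write_table(rhy["comparisons"], out / "lipid_rhythm_comparisons.tsv",
                        snapshot)
            counts["rhythmic_lipid_series"] = int(rhy["fits"]["rhythmic"].sum())
            stages["rhythm"] = "ok"
        except Exception as exc:
            _finish_fail("rhythm", exc)
    else:
        stages["lipidomics"] = "skipped: no lipid input"
        stages["rhythm"] = "skipped: no lipid input"

    # --- crossspecies --------------------------------------------------------
    dro = None
    if expr is not None and pairs is not None:
        try:
            dro = dro_stage(
                expr, pairs, pseudocount=cfg.pseudocount,
                ratio_pairing=cfg.ratio_pairing,
                filter_cfg=crossspecies.FilterConfig(**cfg.filter),
                apply_filter=cfg.apply_filter, k=cfg.k_clusters,
                calibrate_k=cfg.calibrate_k, n_perm=cfg.n_perm, seed=cfg.seed,
                fdr_dro=cfg.fdr_dro, fdr_cro=cfg.fdr_cro,
                log_ratios=cfg.log_ratios)
            write_table(dro["lmm"], out / "lmm_results.tsv", snapshot)
            write_table(dro["pair_labels"], out / "pair_classification.tsv",
                        snapshot)
            if dro["assignment"] is not None:
                write_table(dro["assignment"].assignments.rename("cluster")
                            .rename_axis("gene").reset_index(),
                            out / "clusters.tsv", snapshot)
            if dro["calibration"] is not None:
                write_table(dro["calibration"]["report"],
                            out / "calibration.tsv", snapshot)
            counts.update(dro["counts"])
            stages["crossspecies"] = "ok"
        except Exception as exc:
            _finish_fail("crossspecies", exc)
    else:
        stages["crossspecies"] = "skipped: no expression/pairs input"

    # --- integrate -----------------------------------------------------------
    if dro is not None and lipid_table is not None and len(dro["pair_labels"]):
        try:
            hc_pairs = dro["pair_labels"][dro["pair_labels"]["hc_dro"]]
            pool = hc_pairs if len(hc_pairs) else dro["pair_labels"]
            genes = pd.unique(pool[["gene_a", "gene_b"]].to_numpy().ravel()
                              )[: cfg.integrate_max_genes]
            res = integrate_stage(expr, lipid_table, list(genes),
                                  strategy=cfg.alignment_strategy)
            write_table(res["candidates"], out / "lipid_gene_correlations.tsv",
                        snapshot)
            write_table(res["heatmap"].reset_index(names="series"),
                        out / "heatmap_matrix.tsv", snapshot)
            counts["correlation_candidates"] = int(
                res["candidates"]["significant"].sum())
            stages["integrate"] = "ok"
        except Exception as exc:
            _finish_fail("integrate", exc)
    else:
        stages["integrate"] = "skipped: needs crossspecies and lipid outputs"

    manifest.warnings = counter.count
    logger.removeHandler(counter)
    manifest.write(out / "manifest.yaml")
    return manifest
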