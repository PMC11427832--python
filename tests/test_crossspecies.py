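"""T/C ratios, pair filtering, clustering, the per-gene LMM and DRO calls."""
import numpy as np
import pandas as pd
import pytest

from chillrhythm import crossspecies, synthdata
from chillrhythm.errors import ValidationError

TIMES = [0.5, 1.0, 3.0, 6.0, 16.0, 24.0]


def expr_frame(records):
    return pd.DataFrame(records, columns=["gene", "species", "condition",
                                          "time_h", "replicate", "fpkm"])


def ratio_frame(gene, values, species=("A", "B"), reps=3):
    """values[(species, time, rep)] -> long ratio frame."""
    rows = [{"gene": gene, "species": sp, "time_h": t, "replicate": r,
             "ratio": values(sp, t, r)}
            for sp in species for t in TIMES for r in range(1, reps + 1)]
    return pd.DataFrame(rows)


# --- T/C ratios -------------------------------------------------------------

def test_equal_treatment_and_control_gives_unit_ratios():
    rows = [(g, "s", c, t, r, 5.0) for g in ("g1",) for c in ("control", "chilled")
            for t in TIMES for r in (1, 2, 3)]
    ratios = crossspecies.compute_tc_ratios(expr_frame(rows))
    assert np.allclose(ratios["ratio"], 1.0)


def test_pseudocount_arithmetic():
    rows = [("g1", "s", "chilled", 0.5, 1, 9.0),
            ("g1", "s", "control", 0.5, 1, 4.0)]
    ratios = crossspecies.compute_tc_ratios(expr_frame(rows), pseudocount=1.0)
    assert ratios["ratio"].iloc[0] == pytest.approx(2.0)


def test_zero_control_without_pseudocount_is_masked():
    rows = [("g1", "s", "chilled", 0.5, 1, 9.0),
            ("g1", "s", "control", 0.5, 1, 0.0)]
    ratios = crossspecies.compute_tc_ratios(expr_frame(rows), pseudocount=0.0)
    assert ratios.empty


def test_unmatched_treatment_cell_is_masked():
    rows = [("g1", "s", "chilled", 0.5, 1, 9.0),
            ("g1", "s", "chilled", 1.0, 1, 9.0),
            ("g1", "s", "control", 0.5, 1, 4.0)]
    ratios = crossspecies.compute_tc_ratios(expr_frame(rows))
    assert len(ratios) == 1


# --- pair filter ------------------------------------------------------------

def _paired_expression(profile_b=None, noise=0.0, rng=None):
    """Two genes, one per species, sharing (or not) a ratio profile."""
    rows = []
    base = {0.5: 1.0, 1.0: 2.0, 3.0: 0.5, 6.0: 1.5, 16.0: 3.0, 24.0: 1.0}
    prof = {"gA": base, "gB": profile_b or base}
    for gene, sp in (("gA", "A"), ("gB", "B")):
        for t in TIMES:
            for r in (1, 2, 3):
                eps = rng.normal(0, noise) if noise else 0.0
                rows.append((gene, sp, "control", t, r, 10.0))
                rows.append((gene, sp, "chilled", t, r,
                             10.0 * prof[gene][t] + eps))
    return expr_frame(rows)


def test_identical_profiles_pass_filter():
    expr = _paired_expression()
    ratios = crossspecies.compute_tc_ratios(expr)
    pairs = pd.DataFrame({"gene_a": ["gA"], "gene_b": ["gB"]})
    retained, audit = crossspecies.filter_pairs(ratios, expr, pairs)
    assert len(retained) == 1
    assert audit["r2"].iloc[0] == pytest.approx(1.0)
    assert audit["sd_a"].iloc[0] == pytest.approx(0.0)


def test_unrelated_noise_profile_is_dropped(rng):
    """A white-noise partner profile has expected r^2 below the 0.1 cut."""
    dropped = 0
    for _ in range(20):
        prof_b = {t: rng.uniform(0.5, 3.0) for t in TIMES}
        expr = _paired_expression(profile_b=prof_b)
        ratios = crossspecies.compute_tc_ratios(expr)
        pairs = pd.DataFrame({"gene_a": ["gA"], "gene_b": ["gB"]})
        _, audit = crossspecies.filter_pairs(ratios, expr, pairs)
        dropped += int(audit["r2"].iloc[0] <= 0.1)
    assert dropped >= 10  # r^2 of independent 6-point profiles: E ~ 0.2


def test_wide_open_thresholds_retain_everything(small_expression):
    expr, truth = small_expression
    ratios = crossspecies.compute_tc_ratios(expr)
    cfg = crossspecies.FilterConfig(sd_max=1e6, r2_min=0.0)
    retained, _ = crossspecies.filter_pairs(ratios, expr, truth.pairs(), cfg)
    assert len(retained) == len(truth.pairs())


# --- clustering -------------------------------------------------------------

def _profile_matrix():
    t = np.array(TIMES)
    up = np.exp(t / 24.0)
    down = np.exp(-t / 24.0)
    rows = {"a1": up, "a2": up * 3.0, "b1": down, "b2": down + 0.1}
    return pd.DataFrame(rows, index=TIMES).T


def test_identical_and_scaled_profiles_cocluster():
    prof = _profile_matrix()
    assignment = crossspecies.cluster_profiles(prof, k=2)
    assert assignment.same_cluster("a1", "a2")      # scale invariance
    assert not assignment.same_cluster("a1", "b1")


def test_k_equal_to_n_separates_distinct_profiles():
    prof = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 6)),
                        index=list("abcde"), columns=TIMES)
    assignment = crossspecies.cluster_profiles(prof, k=5)
    assert assignment.assignments.nunique() == 5


def test_flat_profile_gets_dedicated_cluster():
    prof = _profile_matrix()
    prof.loc["flat"] = 1.0
    assignment = crossspecies.cluster_profiles(prof, k=2)
    assert assignment.flat_cluster is not None
    assert assignment.assignments["flat"] == assignment.flat_cluster


def test_anticorrelated_pair_is_ccdro_and_k1_makes_all_ceo():
    t = np.array(TIMES)
    prof = pd.DataFrame({"gA": np.sin(t / 4), "gB": -np.sin(t / 4),
                         "gC": np.sin(t / 4) + 0.01},
                        index=TIMES).T
    pairs = pd.DataFrame({"gene_a": ["gA"], "gene_b": ["gB"]})
    lab2 = crossspecies.classify_pairs(pairs,
                                       crossspecies.cluster_profiles(prof, 2))
    assert (lab2["label"] == "CC-DRO").all()
    lab1 = crossspecies.classify_pairs(pairs,
                                       crossspecies.cluster_profiles(prof, 1))
    assert (lab1["label"] == "CEO").all()


# --- permutation calibration ------------------------------------------------

def test_permutation_calibration_is_seed_deterministic(small_expression):
    expr, truth = small_expression
    ratios = crossspecies.compute_tc_ratios(expr)
    profiles = crossspecies.mean_ratio_profiles(ratios)
    pairs = truth.pairs()
    r1 = crossspecies.permutation_calibrate(pairs, profiles, n_perm=10,
                                            k_grid=(4, 8), seed=9)
    r2 = crossspecies.permutation_calibrate(pairs, profiles, n_perm=10,
                                            k_grid=(4, 8), seed=9)
    assert r1["chosen_k"] == r2["chosen_k"]
    pd.testing.assert_frame_equal(r1["report"], r2["report"])


def test_noiseless_coexpressed_pairs_score_observed_rate_one(rng):
    t = np.array(TIMES)
    shapes = [np.sin(t / 4), np.cos(t / 5), t / 24.0, np.exp(-t / 10)]
    profs, pairs = {}, []
    for i in range(12):
        shape = shapes[i % 4] + rng.normal(0, 0.01, t.size)
        profs[f"A{i}"] = shape
        profs[f"B{i}"] = shape * rng.uniform(1.5, 2.5)
        pairs.append((f"A{i}", f"B{i}"))
    profiles = pd.DataFrame(profs, index=TIMES).T
    pairs = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
    rep = crossspecies.permutation_calibrate(pairs, profiles, n_perm=20,
                                             k_grid=(4,), seed=1)
    row = rep["report"].iloc[0]
    assert row["observed_rate"] == pytest.approx(1.0)
    assert row["null_rate_mean"] < 1.0


# --- per-gene LMM -----------------------------------------------------------

def test_identical_noiseless_trajectories_give_null_wald():
    traj = {0.5: 1.0, 1.0: 2.0, 3.0: 0.5, 6.0: 1.5, 16.0: 3.0, 24.0: 1.0}
    df = ratio_frame("g", lambda sp, t, r: traj[t])
    res = crossspecies.fit_gene_lmm(df)
    assert res.wald == pytest.approx(0.0, abs=1e-10)
    assert res.p == 1.0
    assert np.allclose(res.interaction_effects, 0.0, atol=1e-10)


def test_zero_replicate_variance_reduces_to_ols(rng):
    """With no between-replicate spread the GLS fit equals plain OLS."""
    cell = {(sp, t): rng.normal(1.0, 0.5) for sp in "AB" for t in TIMES}
    df = ratio_frame("g", lambda sp, t, r: cell[(sp, t)] + 0.01 * r * 0)
    # add within-cell noise that is identical across replicate units per cell
    df["ratio"] += rng.normal(0, 1e-3, len(df))
    res = crossspecies.fit_gene_lmm(df)
    X, gsl = crossspecies._lmm_design(df["time_h"].to_numpy(float),
                                      df["species"].to_numpy(),
                                      np.unique(df["time_h"]),
                                      np.unique(df["species"]))
    beta_ols, *_ = np.linalg.lstsq(X, df["ratio"].to_numpy(), rcond=None)
    if res.theta2 == 0.0:
        assert res.ols_fallback
    assert res.interaction_effects == pytest.approx(beta_ols[gsl], abs=1e-6)


def test_balanced_fit_matches_statsmodels_mixedlm(rng):
    """Closed-form ANOVA/GLS REML equals the numerical REML fit."""
    for _ in range(3):
        unit_eff = {(sp, r): rng.normal(0, 0.3) for sp in "AB" for r in (1, 2, 3)}
        df = ratio_frame("g", lambda sp, t, r:
                         1.0 + 0.2 * t / 24 + unit_eff[(sp, r)]
                         + rng.normal(0, 0.2))
        mine = crossspecies.fit_gene_lmm(df)
        sm = crossspecies._fit_mixedlm(
            "g", df["ratio"].to_numpy(),
            *crossspecies._lmm_design(df["time_h"].to_numpy(float),
                                      df["species"].to_numpy(),
                                      np.unique(df["time_h"]),
                                      np.unique(df["species"])),
            pd.Series([f"{s}|{r}" for s, r in zip(df["species"],
                                                  df["replicate"])]))
        assert mine.theta2 == pytest.approx(sm.theta2, abs=1e-5)
        assert mine.sigma2 == pytest.approx(sm.sigma2, rel=1e-4)
        assert mine.wald == pytest.approx(sm.wald, rel=1e-3, abs=1e-6)


def test_planted_interaction_detected_at_small_noise(rng):
    """Ratio +1 at three late times, noise 0.1: p < 1e-4 in >= 95% of runs."""
    hits = 0
    n_sim = 200
    late = {6.0, 16.0, 24.0}
    for _ in range(n_sim):
        df = ratio_frame("g", lambda sp, t, r:
                         1.0 + (1.0 if (sp == "B" and t in late) else 0.0)
                         + rng.normal(0, 0.1))
        res = crossspecies.fit_gene_lmm(df)
        hits += int(res.p < 1e-4)
    assert hits >= 0.95 * n_sim


def test_interaction_df_is_five_for_reference_design():
    df = ratio_frame("g", lambda sp, t, r: 1.0 + 0.01 * r)
    res = crossspecies.fit_gene_lmm(df)
    assert res.df == 5


# --- DRO calls and intersection --------------------------------------------

def test_all_unit_pvalues_are_cro():
    res = pd.DataFrame({"gene_a": list("abc"), "gene_b": list("xyz"),
                        "p": [1.0, 1.0, 1.0]})
    out = crossspecies.classify_dro(res)
    assert (out["call"] == "CRO").all()


def test_fdr_in_gap_is_ambiguous():
    res = pd.DataFrame({"gene_a": ["a"], "gene_b": ["x"], "p": [0.005]})
    out = crossspecies.classify_dro(res)
    assert out["fdr"].iloc[0] == pytest.approx(0.005)
    assert out["call"].iloc[0] == "ambiguous"


def test_hc_intersection_set_arithmetic():
    uni = {("a", "x"), ("b", "y"), ("c", "z"), ("d", "w")}
    assert crossspecies.hc_dro_intersect({("a", "x")}, {("b", "y")}, uni) == set()
    s = {("a", "x"), ("b", "y")}
    assert crossspecies.hc_dro_intersect(s, s, uni) == s
    assert crossspecies.hc_dro_intersect(
        {("a", "x"), ("b", "y"), ("c", "z")},
        {("b", "y"), ("c", "z"), ("d", "w")}, uni) == {("b", "y"), ("c", "z")}
    with pytest.raises(ValidationError):
        crossspecies.hc_dro_intersect({("q", "q")}, s, uni)


def test_recovery_on_small_low_noise_batch():
    """Planted interactions at low replicate noise are nearly all recovered."""
    cfg = synthdata.ExpressionSimConfig(n_pairs=40, frac_dro=0.25,
                                        noise_sd=0.1, seed=13)
    expr, truth = synthdata.generate_expression(cfg)
    ratios = crossspecies.compute_tc_ratios(expr)
    lmm = crossspecies.fit_lmm_table(ratios, truth.pairs())
    lmm = crossspecies.classify_dro(lmm, fdr_dro=0.05, fdr_cro=0.1)
    merged = lmm.merge(truth.genes[["gene_a", "is_dro"]], on="gene_a")
    sens = (merged.loc[merged["is_dro"], "call"] == "DRO").mean()
    assert sens >= 0.8
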