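"""Synthetic chilling time-course data with known ground truth.

Two generators emulate the study design that the downstream statistics
expect, so the whole pipeline is testable without any external download:

* :func:`generate_expression` — replicate-level FPKM tables for two species
  (a chilling-sensitive and a chilling-tolerant grass) under paired control
  and chilled conditions at six time points with three biological
  replicates.  Every syntenic pair shares a treatment/control ratio
  trajectory across species; a configurable fraction of pairs carry a
  planted species x time interaction (an additive shift of the ratio at the
  late time points, mimicking late-time divergence of differentially
  regulated orthologs), and a configurable fraction carry a 24-h cosinor in
  their control expression.  Replicate noise is multiplicative log-normal,
  the natural model for right-skewed counts-derived abundances.

* :func:`generate_lipids` — raw per-class/per-fatty-acid amounts whose
  normalized mole-percent composition follows planted cosinor trajectories
  exactly in the noiseless case.  Class cosinors are constructed to sum to
  100 mole % at every instant (the largest class absorbs the residual
  oscillation), so normalization never distorts the planted waveforms.
  Noise is Dirichlet-like: per-class log-normal jitter followed by
  renormalization, keeping compositions on the simplex.

Randomness: one root seed fans out into named child streams
(parameters vs noise, expression vs lipids) in a fixed documented order, so
identical configs give byte-identical tables and a single table can be
regenerated without disturbing the others.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import child_rng
from .errors import ConfigError
from .lipidomics import parse_fatty_acid

__all__ = [
    "ExpressionSimConfig",
    "LipidSimConfig",
    "SyntheticTruth",
    "generate_expression",
    "generate_lipids",
    "DEFAULT_CLASS_MESORS",
    "DEFAULT_FA_WEIGHTS",
]

EXPRESSION_TIMEPOINTS = (0.5, 1.0, 3.0, 6.0, 16.0, 24.0)
LIPID_TIMEPOINTS = (0.17, 3.0, 6.0, 12.0, 16.0, 24.0)

#: Default baseline composition (mole %) over the 11 measured lipid classes,
#: a realistic leaf-tissue profile dominated by the chloroplast galactolipids.
DEFAULT_CLASS_MESORS: dict[str, float] = {
    "MGDG": 32.0, "DGDG": 20.0, "PC": 16.0, "PE": 8.0, "PG": 7.0,
    "SQDG": 5.0, "PI": 4.0, "TAG": 4.0, "PS": 2.0, "LPC": 1.0, "DPG": 1.0,
}

#: Default within-class fatty-acid weights (arbitrary units, normalized at
#: use).  Plastid galactolipids are strongly 18:3/16:3-enriched; extra-
#: plastidic phospholipids carry more 16:0/18:2; TAG is the least
#: unsaturated pool.
DEFAULT_FA_WEIGHTS: dict[str, dict[str, float]] = {
    "MGDG": {"16:0": 2, "16:3": 20, "18:2": 8, "18:3": 70},
    "DGDG": {"16:0": 10, "16:3": 5, "18:2": 15, "18:3": 70},
    "PC":   {"16:0": 25, "18:0": 3, "18:1": 10, "18:2": 40, "18:3": 22},
    "PE":   {"16:0": 30, "18:1": 8, "18:2": 42, "18:3": 20},
    "PG":   {"16:0": 30, "16:1": 20, "18:2": 20, "18:3": 30},
    "SQDG": {"16:0": 40, "18:2": 20, "18:3": 40},
    "PI":   {"16:0": 45, "18:2": 35, "18:3": 20},
    "TAG":  {"16:0": 30, "18:0": 5, "18:1": 25, "18:2": 30, "18:3": 10},
    "PS":   {"16:0": 35, "18:2": 40, "18:3": 25},
    "LPC":  {"16:0": 40, "18:2": 45, "18:3": 15},
    "DPG":  {"16:0": 20, "18:1": 15, "18:2": 55, "18:3": 10},
}

_DEFAULT_FALLBACK_FA = {"16:0": 30, "18:1": 10, "18:2": 35, "18:3": 25}


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


@dataclass
class ExpressionSimConfig:
    """Design of the synthetic two-species expression experiment."""

    n_pairs: int = 2000
    timepoints_h: Sequence[float] = EXPRESSION_TIMEPOINTS
    n_replicates: int = 3
    species: Sequence[str] = ("sorghum", "foxtail_millet")
    conditions: Sequence[str] = ("control", "chilled")
    frac_dro: float = 0.1
    interaction_effect: float = 1.0       # additive shift on the T/C ratio scale
    interaction_timepoints: Sequence[float] | None = None  # default: last three
    frac_rhythmic: float = 0.5
    amplitude_range: tuple[float, float] = (1.0, 5.0)
    mesor_range: tuple[float, float] = (10.0, 100.0)
    phase_range: tuple[float, float] = (0.0, 24.0)
    period_h: float = 24.0
    ratio_sd: float = 0.3                 # log-SD of the shared T/C trajectory
    noise_sd: float = 0.3                 # replicate log-normal SD (natural log)
    seed: int = 0

    def __post_init__(self):
        _require(int(self.n_pairs) >= 1, "n_pairs", "must be a positive integer")
        t = tuple(float(x) for x in self.timepoints_h)
        _require(len(t) >= 2 and all(b > a for a, b in zip(t, t[1:])),
                 "timepoints_h", "must be strictly increasing with >=2 points")
        self.timepoints_h = t
        _require(int(self.n_replicates) >= 1, "n_replicates", "must be >= 1")
        _require(len(self.species) == 2, "species", "exactly two species required")
        _require(len(self.conditions) == 2, "conditions",
                 "exactly two conditions (control first) required")
        _require(0.0 <= self.frac_dro <= 1.0, "frac_dro", "must be in [0, 1]")
        _require(0.0 <= self.frac_rhythmic <= 1.0, "frac_rhythmic",
                 "must be in [0, 1]")
        _require(self.noise_sd >= 0.0, "noise_sd", "must be >= 0")
        _require(self.ratio_sd >= 0.0, "ratio_sd", "must be >= 0")
        _require(self.mesor_range[0] > 0, "mesor_range", "must be positive")
        _require(self.amplitude_range[0] >= 0, "amplitude_range", "must be >= 0")
        _require(self.period_h > 0, "period_h", "must be > 0")
        if self.interaction_timepoints is None:
            self.interaction_timepoints = self.timepoints_h[-3:]
        else:
            bad = set(self.interaction_timepoints) - set(self.timepoints_h)
            _require(not bad, "interaction_timepoints",
                     f"not in timepoints_h: {sorted(bad)}")
            self.interaction_timepoints = tuple(self.interaction_timepoints)


@dataclass
class LipidSimConfig:
    """Design of the synthetic lipid composition experiment."""

    lipid_classes: Sequence[str] = tuple(DEFAULT_CLASS_MESORS)
    class_mesors: Mapping[str, float] | None = None
    fa_weights: Mapping[str, Mapping[str, float]] | None = None
    timepoints_h: Sequence[float] = LIPID_TIMEPOINTS
    n_replicates: int = 3
    species: Sequence[str] = ("foxtail_millet", "sorghum", "urochloa")
    conditions: Sequence[str] = ("control", "chilled")
    #: explicit planted cosinors {(class, species, condition): (mesor, amp, phase)};
    #: when None, parameters are auto-generated (sum-preserving) from the ranges.
    rhythm_params: Mapping[tuple, tuple] | None = None
    frac_rhythmic: float = 0.8
    rel_amplitude_range: tuple[float, float] = (0.05, 0.25)
    phase_range: tuple[float, float] = (0.0, 24.0)
    period_h: float = 24.0
    species_effect_sd: float = 0.10       # log-scale spread of class mesors
    total_amount: float = 100.0           # nominal nmol per sample
    noise_sd: float = 0.10                # per-class log-normal jitter
    seed: int = 0

    def __post_init__(self):
        _require(len(self.lipid_classes) >= 1, "lipid_classes", "must be non-empty")
        t = tuple(float(x) for x in self.timepoints_h)
        _require(len(t) >= 2 and all(b > a for a, b in zip(t, t[1:])),
                 "timepoints_h", "must be strictly increasing with >=2 points")
        self.timepoints_h = t
        _require(int(self.n_replicates) >= 1, "n_replicates", "must be >= 1")
        _require(0.0 <= self.frac_rhythmic <= 1.0, "frac_rhythmic",
                 "must be in [0, 1]")
        _require(self.noise_sd >= 0.0, "noise_sd", "must be >= 0")
        _require(self.total_amount > 0, "total_amount", "must be > 0")
        _require(self.period_h > 0, "period_h", "must be > 0")
        weights = self.fa_weights or DEFAULT_FA_WEIGHTS
        for cls in self.lipid_classes:
            for label in weights.get(cls, _DEFAULT_FALLBACK_FA):
                parse_fatty_acid(label)  # FormatError on bad labels


@dataclass
class SyntheticTruth:
    """Ground-truth records for every simulated series.

    ``genes`` has one row per syntenic pair (flags and planted cosinor
    parameters); ``interactions`` one row per planted (pair, species, time)
    ratio shift; ``lipids`` one row per (class, species, condition) with the
    realized planted cosinor.  Exactly one truth record exists per simulated
    gene pair / lipid series.
    """

    genes: pd.DataFrame | None = None
    interactions: pd.DataFrame | None = None
    lipids: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def pairs(self) -> pd.DataFrame:
        """Ortholog pair list (gene_a, gene_b) for the simulated genes."""
        if self.genes is None:
            raise ValueError("no expression truth present")
        return self.genes[["gene_a", "gene_b"]].reset_index(drop=True)


def _gene_ids(cfg: ExpressionSimConfig) -> tuple[list[str], list[str]]:
    width = max(5, len(str(cfg.n_pairs)))
    a = [f"geneA_{i:0{width}d}" for i in range(cfg.n_pairs)]
    b = [f"geneB_{i:0{width}d}" for i in range(cfg.n_pairs)]
    return a, b


def generate_expression(config: ExpressionSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate the paired two-species chilling expression experiment.

    Returns ``(expression, truth)``: a long-format table with columns
    (gene, species, condition, time_h, replicate, fpkm) covering every
    (species, condition, time, replicate) cell for each of ``n_pairs``
    syntenic pairs, and the ground-truth record set.
    """
    cfg = config
    rng_par = child_rng(cfg.seed, "expression_params")
    rng_noise = child_rng(cfg.seed, "expression_noise")
    n = int(cfg.n_pairs)
    times = np.asarray(cfg.timepoints_h)
    n_t = times.size
    reps = np.arange(1, int(cfg.n_replicates) + 1)

    # --- planted per-pair parameters (parameter stream, fixed draw order) ---
    mesor = rng_par.uniform(*cfg.mesor_range, size=n)
    n_rhythmic = int(round(cfg.frac_rhythmic * n))
    rhythmic_idx = rng_par.choice(n, size=n_rhythmic, replace=False)
    is_rhythmic = np.zeros(n, dtype=bool)
    is_rhythmic[rhythmic_idx] = True
    amplitude = np.where(
        is_rhythmic,
        np.minimum(rng_par.uniform(*cfg.amplitude_range, size=n), 0.8 * mesor),
        0.0)
    phase = rng_par.uniform(*cfg.phase_range, size=n)
    n_dro = int(round(cfg.frac_dro * n))
    dro_idx = rng_par.choice(n, size=n_dro, replace=False)
    is_dro = np.zeros(n, dtype=bool)
    is_dro[dro_idx] = True
    # Shared treatment/control ratio trajectory (log-normal per time point).
    log_ratio = rng_par.normal(0.0, cfg.ratio_sd, size=(n, n_t))
    base_ratio = np.exp(log_ratio)

    interaction_mask = np.isin(times, np.asarray(cfg.interaction_timepoints))
    w = 2.0 * np.pi / cfg.period_h
    control_mean = mesor[:, None] + amplitude[:, None] * np.cos(
        w * (times[None, :] - phase[:, None]))          # (n, n_t), > 0 by cap

    genes_a, genes_b = _gene_ids(cfg)
    species_a, species_b = cfg.species
    cond_ctl, cond_trt = cfg.conditions

    frames = []
    inter_rows = []
    for k, (sp, genes) in enumerate(((species_a, genes_a), (species_b, genes_b))):
        ratio = base_ratio.copy()
        if k == 1:  # planted interaction on the second species' ratio
            ratio[np.ix_(is_dro, interaction_mask)] += cfg.interaction_effect
        for cond, mean in ((cond_ctl, control_mean),
                           (cond_trt, control_mean * ratio)):
            # noise stream: one block per (species, condition), fixed order
            eps = rng_noise.normal(0.0, cfg.noise_sd,
                                   size=(n, n_t, reps.size)) if cfg.noise_sd > 0 \
                else np.zeros((n, n_t, reps.size))
            fpkm = mean[:, :, None] * np.exp(eps)
            frames.append(pd.DataFrame({
                "gene": np.repeat(genes, n_t * reps.size),
                "species": sp,
                "condition": cond,
                "time_h": np.tile(np.repeat(times, reps.size), n),
                "replicate": np.tile(reps, n * n_t),
                "fpkm": fpkm.reshape(-1),
            }))
    for i in np.flatnonzero(is_dro):
        for t in times[interaction_mask]:
            inter_rows.append((i, species_b, float(t), cfg.interaction_effect))

    expr = pd.concat(frames, ignore_index=True)
    genes_df = pd.DataFrame({
        "pair_id": np.arange(n),
        "gene_a": genes_a, "gene_b": genes_b,
        "is_dro": is_dro,
        "is_rhythmic_control": is_rhythmic,
        # treatment = control x (non-cosinor ratio): rhythmicity carries over
        "is_rhythmic_treated": is_rhythmic,
        "mesor": mesor, "amplitude": amplitude, "phase_h": phase % cfg.period_h,
    })
    interactions = pd.DataFrame(inter_rows,
                                columns=["pair_id", "species", "time_h", "effect"])
    truth = SyntheticTruth(genes=genes_df, interactions=interactions,
                           meta={"config": "expression", "seed": cfg.seed})
    return expr, truth


def _auto_lipid_params(cfg: LipidSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw sum-preserving cosinor parameters per (class, species, condition).

    Amplitude/phase pairs are drawn per class, then the class with the
    largest mesor absorbs the negated vector sum of all other classes'
    cosine/sine components, so the planted trajectories sum to exactly 100
    mole % at every instant and survive normalization unchanged.
    """
    classes = list(cfg.lipid_classes)
    mesors0 = cfg.class_mesors or DEFAULT_CLASS_MESORS
    base = np.array([float(mesors0.get(c, 1.0)) for c in classes])
    rows = []
    for sp in cfg.species:
        # species-specific composition shift, renormalized to 100
        shift = np.exp(rng.normal(0.0, cfg.species_effect_sd, size=len(classes)))
        mes_sp = base * shift
        mes_sp = mes_sp / mes_sp.sum() * 100.0
        buffer_i = int(np.argmax(mes_sp))
        for cond in cfg.conditions:
            rhythmic = rng.random(len(classes)) < cfg.frac_rhythmic
            amp = np.where(rhythmic,
                           rng.uniform(*cfg.rel_amplitude_range,
                                       size=len(classes)) * mes_sp, 0.0)
            phi = rng.uniform(*cfg.phase_range, size=len(classes))
            theta = 2.0 * np.pi * phi / cfg.period_h
            a = amp * np.cos(theta)
            b = amp * np.sin(theta)
            a[buffer_i] = -(a.sum() - a[buffer_i])
            b[buffer_i] = -(b.sum() - b[buffer_i])
            amp_adj = np.hypot(a, b)
            phi_adj = (np.arctan2(b, a) * cfg.period_h / (2 * np.pi)) % cfg.period_h
            for c, m, A, P in zip(classes, mes_sp, amp_adj, phi_adj):
                rows.append((c, sp, cond, float(m), float(A), float(P)))
    return pd.DataFrame(rows, columns=["lipid_class", "species", "condition",
                                       "mesor", "amplitude", "phase_h"])


def generate_lipids(config: LipidSimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate raw lipid amounts with planted cosinor mole-% trajectories.

    Returns ``(lipids, truth)``: a long table with columns (sample_id,
    species, condition, time_h, replicate, lipid_class, fatty_acid, amount)
    and the realized planted cosinor per (class, species, condition).
    """
    cfg = config
    rng_par = child_rng(cfg.seed, "lipid_params")
    rng_noise = child_rng(cfg.seed, "lipid_noise")
    classes = list(cfg.lipid_classes)
    times = np.asarray(cfg.timepoints_h)
    w = 2.0 * np.pi / cfg.period_h
    weights = cfg.fa_weights or DEFAULT_FA_WEIGHTS

    if cfg.rhythm_params is not None:
        rows = [(c, sp, cond, *map(float, v))
                for (c, sp, cond), v in cfg.rhythm_params.items()]
        params = pd.DataFrame(rows, columns=["lipid_class", "species",
                                             "condition", "mesor", "amplitude",
                                             "phase_h"])
    else:
        params = _auto_lipid_params(cfg, rng_par)

    lut = params.set_index(["lipid_class", "species", "condition"])
    records = []
    for sp in cfg.species:
        for cond in cfg.conditions:
            mes = np.array([lut.loc[(c, sp, cond), "mesor"] for c in classes])
            amp = np.array([lut.loc[(c, sp, cond), "amplitude"] for c in classes])
            phi = np.array([lut.loc[(c, sp, cond), "phase_h"] for c in classes])
            for t in times:
                target = mes + amp * np.cos(w * (t - phi))   # mole %
                target = np.clip(target, 1e-9, None)
                frac = target / target.sum()                 # sums to 1 pre-noise
                for rep in range(1, int(cfg.n_replicates) + 1):
                    jitter = np.exp(rng_noise.normal(0.0, cfg.noise_sd,
                                                     size=len(classes))) \
                        if cfg.noise_sd > 0 else np.ones(len(classes))
                    amounts = cfg.total_amount * frac * jitter
                    sid = f"{sp}_{cond}_t{t:g}_r{rep}"
                    for c, amt in zip(classes, amounts):
                        fa = weights.get(c, _DEFAULT_FALLBACK_FA)
                        fa_tot = float(sum(fa.values()))
                        for label, wgt in fa.items():
                            records.append((sid, sp, cond, float(t), rep, c,
                                            label, float(amt * wgt / fa_tot)))
    lipids = pd.DataFrame(records, columns=["sample_id", "species", "condition",
                                            "time_h", "replicate", "lipid_class",
                                            "fatty_acid", "amount"])
    params = params.assign(is_rhythmic=params["amplitude"] > 0)
    truth = SyntheticTruth(lipids=params,
                           meta={"config": "lipids", "seed": cfg.seed})
    return lipids, truth
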