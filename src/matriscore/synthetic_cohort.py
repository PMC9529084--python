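"""Synthetic multi-cancer cohorts with planted ground truth.

Generates the five inputs the prioritization pipeline consumes — per-cancer
GISTIC call matrices, a pooled expression matrix with tumour/normal
annotations, a clinical table, an interaction edge list — together with a
record of the effects actually planted, so that every downstream screen can be
validated against a known answer without any external data.

Data model
----------
* **Copy number.** Each gene acquires a deep event (+2 amplification or -2 deep
  deletion) independently per tumour sample: driver genes at their configured
  ``amp_prob``/``del_prob`` (within their active cancers), background genes at a
  low symmetric rate. Unaffected cells may carry shallow +/-1 calls so that
  deep-event-only counting rules are non-trivially exercised.
* **Expression.** Generated directly on the log2(TPM+1)-like scale. Normal
  samples: per-gene baseline + Gaussian noise. Tumour samples additionally
  receive the driver shift, a copy-number coupling (log2 units per GISTIC
  step) and a linear stage trend; values are floored at 0.
* **Survival.** Exponential event times with per-sample hazard
  ``baseline_hazard * exp(sum_d gamma_d * z_d)`` where ``z_d`` is the within-
  cancer z-score of driver ``d``'s tumour expression; censoring is independent
  uniform over a study window sized to hit the requested censoring rate under
  the baseline hazard.
* **Co-occurrence.** Listed gene pairs have their amplification events drawn
  from the unique 2x2 joint distribution with the configured marginals and
  odds ratio.
* **Edges.** A planted clique over the driver genes plus random background
  edges, so hub-recovery has a known answer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import (
    ClinicalTable,
    EdgeList,
    ExpressionMatrix,
    GisticMatrix,
    MISSING,
    write_clinical_table,
    write_edge_list,
    write_expression_matrix,
    write_gistic_matrix,
)


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class DriverEffect:
    """Effect block for one planted driver gene.

    All expression effects are in log2 units; ``log_hazard_ratio`` is per unit
    z-score of the driver's tumour expression; ``stage_trend`` is log2 units
    per stage step (I -> IV).
    """

    amp_prob: float = 0.0
    del_prob: float = 0.0
    expression_shift: float = 0.0
    cna_coupling: float = 0.0
    log_hazard_ratio: float = 0.0
    stage_trend: float = 0.0
    cancers: Optional[Tuple[str, ...]] = None  # None = active in every cancer

    def __post_init__(self) -> None:
        for p in (self.amp_prob, self.del_prob):
            if not 0 <= p <= 1:
                raise ConfigError("alteration probabilities must lie in [0,1]")
        if self.amp_prob + self.del_prob > 1:
            raise ConfigError("amp_prob + del_prob must not exceed 1")

    def active_in(self, cancer: str) -> bool:
        return self.cancers is None or cancer in self.cancers


@dataclass
class SimConfig:
    """Study conditions for one simulated multi-cancer cohort."""

    n_cancers: int = 5
    n_tumour: int = 100
    n_normal: int = 40
    n_genes: int = 200
    drivers: Dict[str, DriverEffect] = field(default_factory=dict)
    cooccurring_pairs: List[Tuple[str, str, float]] = field(default_factory=list)
    background_alteration_prob: float = 0.02
    shallow_alteration_prob: float = 0.05
    baseline_hazard: float = 1.0 / 1000.0  # per day; median survival ~693 days
    censoring_rate: float = 0.3
    noise_sd: float = 0.5
    stage_probs: Tuple[float, float, float, float] = (0.30, 0.30, 0.25, 0.15)
    n_background_edges: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must lie in [0,1)")
        if not 0 <= self.background_alteration_prob <= 1:
            raise ConfigError("background_alteration_prob must lie in [0,1]")
        universe = set(self.gene_ids)
        for g in self.drivers:
            if g not in universe:
                raise ConfigError(f"driver gene {g!r} absent from gene universe")
        for a, b, orr in self.cooccurring_pairs:
            if a not in universe or b not in universe:
                raise ConfigError(f"co-occurrence pair ({a},{b}) outside gene universe")
            if orr <= 0:
                raise ConfigError("target odds ratio must be > 0")

    @property
    def gene_ids(self) -> List[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def cancer_labels(self) -> List[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_cancers)]


@dataclass
class SimTruth:
    """Planted and realized effects, one record per driver and per pair."""

    drivers: pd.DataFrame  # gene, cancer, amp_prob, del_prob, realized_amp_freq,
    #                        realized_del_freq, expression_shift, log_hazard_ratio, stage_trend
    pairs: pd.DataFrame  # gene_a, gene_b, target_odds_ratio, realized 2x2 counts, realized OR

    def to_json(self, path) -> None:
        payload = {
            "drivers": self.drivers.to_dict(orient="records"),
            "pairs": self.pairs.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class Cohort:
    gistic: Dict[str, GisticMatrix]
    expression: ExpressionMatrix
    clinical: ClinicalTable
    edges: EdgeList
    truth: SimTruth

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cancer, matrix in self.gistic.items():
            write_gistic_matrix(matrix, out / f"gistic_{cancer}.tsv")
        write_expression_matrix(self.expression, out / "expression.tsv", out / "annotations.tsv")
        write_clinical_table(self.clinical, out / "clinical.tsv")
        write_edge_list(self.edges, out / "edges.tsv")
        self.truth.to_json(out / "truth.json")


def _joint_cells(p_a: float, p_b: float, odds_ratio: float) -> Tuple[float, float, float, float]:
    """Joint 2x2 cell probabilities with given marginals and odds ratio.

    Solves OR = p11*p00 / (p10*p01) subject to the marginals; the quadratic in
    p11 has a unique admissible root (Plackett construction).
    """
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    else:
        s = 1.0 + (p_a + p_b) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_a * p_b
        if disc < 0:
            raise ConfigError("no admissible joint distribution for the requested odds ratio")
        p11 = (s - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p_a - p_b + p11
    eps = 1e-12
    if min(p11, p10, p01, p00) < -eps:
        raise ConfigError("no admissible joint distribution for the requested odds ratio")
    cells = tuple(max(0.0, p) for p in (p11, p10, p01, p00))
    total = sum(cells)
    return tuple(c / total for c in cells)  # type: ignore[return-value]


def simulate_cooccurrence_pair(
    n: int,
    p_a: float,
    p_b: float,
    odds_ratio: float,
    seed: int | np.random.Generator = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw paired i.i.d. binary alteration vectors with a target odds ratio.

    Returns two length-``n`` 0/1 arrays whose joint distribution has marginals
    ``p_a``, ``p_b`` and odds ratio ``odds_ratio``.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ConfigError("marginals must lie strictly inside (0,1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p11, p10, p01, p00 = _joint_cells(p_a, p_b, odds_ratio)
    draws = rng.choice(4, size=n, p=[p11, p10, p01, p00])
    a = np.isin(draws, (0, 1)).astype(int)
    b = np.isin(draws, (0, 2)).astype(int)
    return a, b


def _censoring_window(baseline_hazard: float, censoring_rate: float) -> float:
    """Study-window length w such that C ~ U(0,w) censors the requested fraction
    of Exp(baseline_hazard) event times: P(E > C) = 1 - (1 - (1-e^{-hw})/(hw))."""
    if censoring_rate == 0:
        return math.inf
    h = baseline_hazard

    def censored_frac(w: float) -> float:
        return 1.0 - (1.0 - (1.0 - math.exp(-h * w)) / (h * w)) - censoring_rate

    # censored fraction decreases from 1 (w->0) to 0 (w->inf)
    return brentq(censored_frac, 1e-9 / h, 1e6 / h)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate one cohort; byte-identical outputs for identical config + seed."""
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids
    cancers = config.cancer_labels
    gene_index = {g: i for i, g in enumerate(genes)}
    paired_genes = {g for a, b, _ in config.cooccurring_pairs for g in (a, b)}

    baseline = rng.uniform(3.0, 8.0, size=config.n_genes)

    gistic: Dict[str, GisticMatrix] = {}
    expr_blocks: List[pd.DataFrame] = []
    ann_rows: List[dict] = []
    clin_rows: List[dict] = []
    truth_driver_rows: List[dict] = []
    truth_pair_rows: List[dict] = []

    window = _censoring_window(config.baseline_hazard, config.censoring_rate)
    bg = config.background_alteration_prob

    for cancer in cancers:
        tumour_ids = [f"{cancer}-T{i + 1:03d}" for i in range(config.n_tumour)]
        normal_ids = [f"{cancer}-N{i + 1:03d}" for i in range(config.n_normal)]
        nt, nn = config.n_tumour, config.n_normal

        # --- copy-number calls (tumour samples only) -----------------------
        calls = np.zeros((config.n_genes, nt), dtype=int)
        for i, g in enumerate(genes):
            if g in paired_genes:
                continue  # drawn jointly below
            eff = config.drivers.get(g)
            if eff is not None and eff.active_in(cancer):
                p_amp, p_del = eff.amp_prob, eff.del_prob
            else:
                p_amp = p_del = bg / 2.0
            u = rng.uniform(size=nt)
            calls[i, u < p_amp] = 2
            calls[i, (u >= p_amp) & (u < p_amp + p_del)] = -2
        for a, b, orr in config.cooccurring_pairs:
            pa = _amp_prob(config, a, cancer, bg)
            pb = _amp_prob(config, b, cancer, bg)
            va, vb = simulate_cooccurrence_pair(nt, pa, pb, orr, rng)
            calls[gene_index[a]] = 2 * va
            calls[gene_index[b]] = 2 * vb
            n11 = int(np.sum((va == 1) & (vb == 1)))
            n10 = int(np.sum((va == 1) & (vb == 0)))
            n01 = int(np.sum((va == 0) & (vb == 1)))
            n00 = nt - n11 - n10 - n01
            num, den = n11 * n00, n10 * n01
            truth_pair_rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "cancer": cancer,
                    "target_odds_ratio": orr,
                    "n11": n11,
                    "n10": n10,
                    "n01": n01,
                    "n00": n00,
                    "realized_odds_ratio": (num / den) if den else math.inf,
                }
            )
        # shallow +/-1 background on untouched cells
        shallow = (calls == 0) & (
            rng.uniform(size=calls.shape) < config.shallow_alteration_prob
        )
        signs = rng.choice((-1, 1), size=calls.shape)
        calls[shallow] = signs[shallow]
        gistic[cancer] = GisticMatrix(pd.DataFrame(calls, index=genes, columns=tumour_ids))

        # --- clinical covariates -------------------------------------------
        stage_idx = rng.choice(4, size=nt, p=config.stage_probs)
        race = rng.choice(["white", "black", "asian", MISSING], size=nt, p=[0.55, 0.20, 0.15, 0.10])
        gender = rng.choice(["male", "female", MISSING], size=nt, p=[0.50, 0.48, 0.02])

        # --- expression ------------------------------------------------------
        tumour_expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, nt))
        for g, eff in config.drivers.items():
            if not eff.active_in(cancer):
                continue
            i = gene_index[g]
            tumour_expr[i] += (
                eff.expression_shift
                + eff.cna_coupling * calls[i]
                + eff.stage_trend * stage_idx
            )
        normal_expr = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_genes, nn))
        tumour_expr = np.maximum(tumour_expr, 0.0)
        normal_expr = np.maximum(normal_expr, 0.0)
        expr_blocks.append(
            pd.DataFrame(
                np.concatenate([tumour_expr, normal_expr], axis=1),
                index=genes,
                columns=tumour_ids + normal_ids,
            )
        )
        for s in tumour_ids:
            ann_rows.append({"sample": s, "cancer_type": cancer, "is_tumour": True})
        for s in normal_ids:
            ann_rows.append({"sample": s, "cancer_type": cancer, "is_tumour": False})

        # --- survival --------------------------------------------------------
        log_hr = np.zeros(nt)
        for g, eff in config.drivers.items():
            if eff.log_hazard_ratio == 0.0 or not eff.active_in(cancer):
                continue
            x = tumour_expr[gene_index[g]]
            sd = x.std(ddof=0)
            z = (x - x.mean()) / sd if sd > 0 else np.zeros(nt)
            log_hr += eff.log_hazard_ratio * z
        hazard = config.baseline_hazard * np.exp(log_hr)
        event_time = rng.exponential(1.0 / hazard)
        if math.isinf(window):
            time, event = event_time, np.ones(nt, dtype=int)
        else:
            censor_time = rng.uniform(0.0, window, size=nt)
            time = np.minimum(event_time, censor_time)
            event = (event_time <= censor_time).astype(int)
        for j, s in enumerate(tumour_ids):
            clin_rows.append(
                {
                    "sample": s,
                    "cancer_type": cancer,
                    "time_days": float(time[j]),
                    "event": int(event[j]),
                    "stage": ("I", "II", "III", "IV")[stage_idx[j]],
                    "race": race[j],
                    "gender": gender[j],
                }
            )

        for g, eff in config.drivers.items():
            if not eff.active_in(cancer):
                continue
            i = gene_index[g]
            truth_driver_rows.append(
                {
                    "gene": g,
                    "cancer": cancer,
                    "amp_prob": eff.amp_prob,
                    "del_prob": eff.del_prob,
                    "realized_amp_freq": float(np.mean(calls[i] == 2)),
                    "realized_del_freq": float(np.mean(calls[i] == -2)),
                    "expression_shift": eff.expression_shift,
                    "cna_coupling": eff.cna_coupling,
                    "log_hazard_ratio": eff.log_hazard_ratio,
                    "stage_trend": eff.stage_trend,
                }
            )

    expression = ExpressionMatrix(
        pd.concat(expr_blocks, axis=1),
        pd.DataFrame(ann_rows).set_index("sample"),
    )
    clinical = ClinicalTable(pd.DataFrame(clin_rows).set_index("sample"))

    # --- edge list: driver clique + random background ----------------------
    driver_list = sorted(config.drivers)
    edge_records: dict[tuple[str, str], float] = {}
    for i, a in enumerate(driver_list):
        for b in driver_list[i + 1 :]:
            edge_records[(a, b)] = 0.95
    non_drivers = [g for g in genes if g not in config.drivers]
    attempts = 0
    while len(edge_records) < len(driver_list) * (len(driver_list) - 1) // 2 + config.n_background_edges:
        attempts += 1
        if attempts > 50 * (config.n_background_edges + 1):
            break
        a, b = rng.choice(non_drivers, size=2, replace=False)
        key = (a, b) if a < b else (b, a)
        if key in edge_records:
            continue
        edge_records[key] = float(rng.uniform(0.0, 1.0))
    edges = EdgeList(
        pd.DataFrame(
            [(a, b, c) for (a, b), c in sorted(edge_records.items())],
            columns=["gene_a", "gene_b", "confidence"],
        )
    )

    driver_cols = [
        "gene", "cancer", "amp_prob", "del_prob", "realized_amp_freq",
        "realized_del_freq", "expression_shift", "cna_coupling",
        "log_hazard_ratio", "stage_trend",
    ]
    pair_cols = [
        "gene_a", "gene_b", "cancer", "target_odds_ratio",
        "n11", "n10", "n01", "n00", "realized_odds_ratio",
    ]
    truth = SimTruth(
        drivers=pd.DataFrame(truth_driver_rows, columns=driver_cols),
        pairs=pd.DataFrame(truth_pair_rows, columns=pair_cols),
    )
    return Cohort(gistic, expression, clinical, edges, truth)


def _amp_prob(config: SimConfig, gene: str, cancer: str, background: float) -> float:
    eff = config.drivers.get(gene)
    if eff is not None and eff.active_in(cancer):
        return eff.amp_prob if eff.amp_prob > 0 else background / 2.0
    return background / 2.0
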