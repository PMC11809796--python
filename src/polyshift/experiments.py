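"""End-to-end benchmark experiments under the package's study conditions.

Each routine here runs the full pipeline — synthetic cohort generation,
harmonization, LD pruning, bin matching, resampling — and measures a
calibration, power, or recovery property of the tests. The study conditions
are fixed: 12 populations in 4 regions (drift covariance 0.02 shared within
region + 0.01 private), 50,000 SNPs, 100 trait SNPs, GWAS sample size
100,000, effect-size s.d. 0.5, selection thresholds and bin widths as in the
analysis modules, 1,000 control sets per test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io_harmonize, matched_null
from .containers import FrequencyPanel, TraitSnpSet
from .genetic_values import estimate_population_covariance, regional_outlier_test
from .pairwise_shift import mean_frequency_difference, pairwise_shift_test
from .simulate import (
    CovarianceModel,
    SimConfig,
    build_population_structure,
    inject_directional_shift,
    simulate_frequency_panel,
    simulate_gwas_trait,
)

N_REGIONS = 4
POPS_PER_REGION = 3
BETWEEN_VAR = 0.02
WITHIN_VAR = 0.01
P_THRESHOLD = 1e-6
FOCAL_REGION = "R1"
TARGET_POP = "R1P1"
REFERENCE_POP = "R2P1"


def default_structure() -> CovarianceModel:
    return build_population_structure(
        N_REGIONS, POPS_PER_REGION, BETWEEN_VAR, WITHIN_VAR
    )


def default_config(seed: int, n_snps: int = 50_000, n_trait_snps: int = 100) -> SimConfig:
    return SimConfig(n_snps=n_snps, n_trait_snps=n_trait_snps, seed=seed)


def _child_seeds(seed: int, label: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(label,))
    return [int(s) for s in (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF)]


@dataclass
class CohortAnalysis:
    """One synthetic cohort pushed through both tests."""

    panel: FrequencyPanel
    trait_snps: TraitSnpSet
    pairwise_p: float
    pairwise_d: float
    outlier_p: float
    outlier_z: float
    null_z_sd: float


def _prepare_trait_snps(panel, ann, gwas) -> TraitSnpSet:
    harmonized, _ = io_harmonize.harmonize(gwas, panel)
    return io_harmonize.select_trait_snps(
        harmonized, P_THRESHOLD, ann.ld_block_series()
    )


def analyze_cohort(
    seed: int,
    s: float = 0.0,
    n_sets: int = 1_000,
    n_snps: int = 50_000,
    n_trait_snps: int = 100,
    run_outlier: bool = True,
    pool_target: int = 20_000,
) -> CohortAnalysis:
    """Simulate one cohort at shift strength ``s`` and run both tests.

    The same ``seed`` with different ``s`` reuses the identical neutral panel
    and GWAS draw (common random numbers), so power is monotone in ``s``
    replicate by replicate up to matching noise.
    """
    model = default_structure()
    cfg = default_config(seed, n_snps=n_snps, n_trait_snps=n_trait_snps)
    panel, ann = simulate_frequency_panel(model, cfg)
    gwas = simulate_gwas_trait(panel, cfg)
    if s > 0:
        targets = [p for p in panel.populations if panel.region_of[p] == FOCAL_REGION]
        panel = inject_directional_shift(panel, gwas, targets, s)
    trait_snps = _prepare_trait_snps(panel, ann, gwas)

    seeds = _child_seeds(seed, 1, 3)
    binned = matched_null.assign_bins(
        panel, ann.bvalue_series(), (TARGET_POP, REFERENCE_POP), TARGET_POP
    )
    idx_pair = matched_null.build_match_index(
        binned, trait_snps, mode=matched_null.MODE_MAF, on_empty="lenient"
    )
    sets_pair = matched_null.sample_control_sets(idx_pair, n_sets, seeds[0])
    ts_pair = _restrict(trait_snps, idx_pair.trait_snp_ids)
    pw = pairwise_shift_test(ts_pair, panel, TARGET_POP, REFERENCE_POP, sets_pair)

    outlier_p = outlier_z = null_sd = float("nan")
    if run_outlier:
        idx_out = matched_null.build_match_index(
            binned, trait_snps, mode=matched_null.MODE_MAF_BVALUE, on_empty="lenient"
        )
        pool = matched_null.sample_control_pool(idx_out, 2_000, pool_target, seeds[1])
        F_hat = estimate_population_covariance(pool, panel)
        sets_out = matched_null.sample_control_sets(idx_out, n_sets, seeds[2])
        ts_out = _restrict(trait_snps, idx_out.trait_snp_ids)
        gv = regional_outlier_test(ts_out, panel, F_hat, FOCAL_REGION, sets_out)
        outlier_p, outlier_z, null_sd = gv.p_empirical, gv.regional_z, gv.null_z_sd
    return CohortAnalysis(
        panel=panel, trait_snps=trait_snps,
        pairwise_p=pw.p_empirical, pairwise_d=pw.d_obs,
        outlier_p=outlier_p, outlier_z=outlier_z, null_z_sd=null_sd,
    )


def _restrict(trait_snps: TraitSnpSet, kept_ids) -> TraitSnpSet:
    if len(kept_ids) == len(trait_snps):
        return trait_snps
    table = trait_snps.table[trait_snps.table["snp_id"].isin(kept_ids)]
    return TraitSnpSet(table.reset_index(drop=True), trait_snps.trait,
                       trait_snps.threshold)


def pairwise_null_calibration(
    n_reps: int = 200, seed: int = 1, n_sets: int = 1_000,
    n_snps: int = 50_000, n_trait_snps: int = 100,
) -> np.ndarray:
    """Empirical pairwise p-values across neutral (s = 0) replicate cohorts."""
    seeds = _child_seeds(seed, 11, n_reps)
    out = np.empty(n_reps)
    for i, rs in enumerate(seeds):
        res = analyze_cohort(rs, s=0.0, n_sets=n_sets, n_snps=n_snps,
                             n_trait_snps=n_trait_snps, run_outlier=False)
        out[i] = res.pairwise_p
    return out


def power_curve(
    s_values=(0.0, 0.1, 0.25, 0.5),
    n_reps: int = 20,
    seed: int = 1,
    alpha: float = 0.05,
    n_sets: int = 1_000,
    n_snps: int = 50_000,
    n_trait_snps: int = 100,
) -> pd.DataFrame:
    """Rejection frequency of both tests along a shift-strength grid.

    Common random numbers across ``s_values``: each replicate seed generates
    one neutral cohort, and each s injects its shift into that same cohort.
    """
    seeds = _child_seeds(seed, 13, n_reps)
    rows = []
    for s in s_values:
        pair_rej = out_rej = 0
        for rs in seeds:
            res = analyze_cohort(rs, s=s, n_sets=n_sets, n_snps=n_snps,
                                 n_trait_snps=n_trait_snps, run_outlier=True)
            pair_rej += res.pairwise_p <= alpha
            out_rej += res.outlier_p < alpha
        rows.append({
            "s": s,
            "pairwise_rejection": pair_rej / n_reps,
            "outlier_rejection": out_rej / n_reps,
        })
    return pd.DataFrame(rows)


def covariance_recovery(
    n_reps: int = 20, seed: int = 1, n_snps: int = 50_000,
    pool_target: int = 20_000,
) -> dict:
    """Frobenius error of F_hat against the centered generating covariance.

    Centering projector P = I - 11'/M: the pool estimator standardizes
    around the cross-population mean, so it recovers P F_true P, not F_true.
    """
    model = default_structure()
    m = len(model.population_labels)
    P = np.eye(m) - np.ones((m, m)) / m
    target = P @ model.F_true @ P
    norm_f = float(np.linalg.norm(model.F_true))
    seeds = _child_seeds(seed, 17, n_reps)
    errors = []
    f_hats = []
    for rs in seeds:
        cfg = default_config(rs, n_snps=n_snps)
        panel, ann = simulate_frequency_panel(model, cfg)
        gwas = simulate_gwas_trait(panel, cfg)
        trait_snps = _prepare_trait_snps(panel, ann, gwas)
        binned = matched_null.assign_bins(
            panel, ann.bvalue_series(), (TARGET_POP, REFERENCE_POP), TARGET_POP
        )
        idx = matched_null.build_match_index(
            binned, trait_snps, mode=matched_null.MODE_MAF_BVALUE, on_empty="lenient"
        )
        pool = matched_null.sample_control_pool(idx, 2_000, pool_target, rs)
        F_hat = estimate_population_covariance(pool, panel)
        f_hats.append(F_hat.to_numpy())
        errors.append(float(np.linalg.norm(F_hat.to_numpy() - target)))
    return {
        "mean_frobenius_error": float(np.mean(errors)),
        "relative_error": float(np.mean(errors)) / norm_f,
        "norm_F_true": norm_f,
        "mean_F_hat": np.mean(f_hats, axis=0),
        "target": target,
    }


# ---------------------------------------------------------------------------
# toy instance with an exhaustively enumerable null

def toy_two_snp_instance() -> tuple[FrequencyPanel, TraitSnpSet]:
    """2 trait SNPs, each with exactly 3 mean-MAF-bin-matched candidates."""
    freqs_t = [0.10, 0.11, 0.12, 0.10, 0.30, 0.31, 0.32, 0.30]
    freqs_r = [0.12, 0.11, 0.10, 0.10, 0.32, 0.31, 0.30, 0.30]
    ids = [f"t{i}" for i in range(8)]
    snps = pd.DataFrame(
        {
            "chrom": ["1"] * 8,
            "pos": np.arange(1, 9) * 100,
            "allele1": ["A"] * 8,
            "allele2": ["G"] * 8,
        },
        index=pd.Index(ids, name="snp_id"),
    )
    freqs = pd.DataFrame({"T": freqs_t, "R": freqs_r}, index=snps.index)
    panel = FrequencyPanel(snps, freqs, {"T": "focal", "R": "rest"}).validate()
    table = pd.DataFrame(
        {
            "snp_id": ["t1", "t5"],
            "trait_increasing_allele": ["A", "A"],
            "beta_abs": [0.5, 0.5],
            "p": [1e-9, 1e-9],
            "ld_block_id": ["b0", "b1"],
        }
    )
    return panel, TraitSnpSet(table, trait="toy", threshold=1e-6)


def toy_enumeration_gap(n_sets: int = 10_000, seed: int = 1) -> dict:
    """Exhaustive-null vs sampled-null empirical p on the toy instance."""
    panel, trait_snps = toy_two_snp_instance()
    binned = matched_null.assign_bins(panel, None, ("T", "R"), "T")
    index = matched_null.build_match_index(
        binned, trait_snps, mode=matched_null.MODE_MAF
    )
    d_obs = mean_frequency_difference(trait_snps, panel, "T", "R")

    # exhaustive null: every candidate combination x both orientations
    per_slot = []
    for tid in index.trait_snp_ids:
        diffs = []
        for cid in index.candidates[tid]:
            d = float(panel.freqs.loc[cid, "T"] - panel.freqs.loc[cid, "R"])
            diffs.extend([d, -d])
        per_slot.append(diffs)
    d_null_exact = np.array([np.mean(c) for c in itertools.product(*per_slot)])
    p_exact = float(np.mean(d_null_exact >= d_obs))

    sets = matched_null.sample_control_sets(index, n_sets, seed)
    result = pairwise_shift_test(trait_snps, panel, "T", "R", sets)
    return {
        "p_exact": p_exact,
        "p_sampled": result.p_empirical,
        "gap": abs(p_exact - result.p_empirical),
        "d_obs": d_obs,
        "n_exact": len(d_null_exact),
    }
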