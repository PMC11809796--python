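"""Multi-population genetic values and the regional outlier test.

A population's genetic value for a trait is the weighted sum of its allele
frequencies at the trait SNPs, the weights being the GWAS effect sizes
(trait-increasing orientation, no diploid factor — any constant cancels in
standardization). Under neutral drift the vector of centered, scaled genetic
values is approximately multivariate normal with covariance F, the
among-population allele-frequency covariance, estimated here from a
MAF+B-value-matched control pool. The regional outlier test asks whether the
focal region's mean value deviates from its expectation conditional on the
other regions under that normal model; significance also comes from an
empirical null of matched control sets.

Conditioning detail: F estimated with the cross-population mean as the
per-SNP reference makes the all-population-centered system exactly
degenerate (the focal value is a linear function of the others). The
conditional z is therefore computed with leave-focal-out centering — values
are re-centered on the mean of the non-focal populations before
conditioning — and the remaining rank deficiency among the conditioning
coordinates is handled by pseudo-inverse. This keeps the statistic
region-label-invariant and approximately N(0, 1) under the null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import (
    ControlPool,
    ControlSets,
    FrequencyPanel,
    GeneticValueResult,
    TraitSnpSet,
)
from .pairwise_shift import increasing_allele_frequencies

_PINV_RTOL = 1e-8
_MAX_NULL_BLOCK = 20_000_000  # floats per chunk when evaluating control sets


class SingularCovarianceError(RuntimeError):
    """Conditional variance vanished beyond pseudo-inverse tolerance."""


def compute_genetic_values(
    trait_snps: TraitSnpSet, panel: FrequencyPanel
) -> pd.Series:
    """Z_m = sum_l beta_abs_l * f_m(trait-increasing allele at l), per population.

    Returns an all-NaN series for an empty trait SNP set (NA convention).
    """
    pops = panel.populations
    if len(trait_snps) == 0:
        return pd.Series(np.nan, index=pops, name=trait_snps.trait)
    beta = trait_snps.table["beta_abs"].to_numpy()
    vals = np.empty(len(pops))
    finc = _increasing_freq_matrix(trait_snps, panel)
    vals = beta @ finc
    return pd.Series(vals, index=pops, name=trait_snps.trait)


def _increasing_freq_matrix(trait_snps: TraitSnpSet, panel: FrequencyPanel) -> np.ndarray:
    """(L, M) matrix of trait-increasing-allele frequencies."""
    ids = trait_snps.table["snp_id"]
    idx = panel.freqs.index.get_indexer(ids)
    if (idx < 0).any():
        missing = ids.to_numpy()[idx < 0][:5].tolist()
        raise ValueError(f"trait SNPs absent from panel: {missing}")
    f1 = panel.freqs.to_numpy()[idx]
    is_a1 = (
        trait_snps.table["trait_increasing_allele"].to_numpy()
        == panel.snps["allele1"].to_numpy()[idx]
    )
    return np.where(is_a1[:, None], f1, 1.0 - f1)


def estimate_population_covariance(
    pool: ControlPool, panel: FrequencyPanel, min_snps: int = 100
) -> pd.DataFrame:
    """Among-population covariance F_hat from a matched control pool.

    Each pool SNP contributes the outer product of its standardized centered
    frequency vector x_m = (f_m - eps) / sqrt(eps(1-eps)), eps being the
    unweighted cross-population mean; SNPs fixed across the panel (eps in
    {0, 1}) are dropped. F_hat estimates the centered drift covariance.
    """
    if len(pool) == 0:
        raise ValueError("control pool is empty")
    idx = panel.freqs.index.get_indexer(pool.snp_ids)
    if (idx < 0).any():
        raise ValueError("control pool contains SNPs absent from panel")
    f = panel.freqs.to_numpy()[idx]
    eps = f.mean(axis=1)
    keep = (eps > 0.0) & (eps < 1.0)
    f = f[keep]
    eps = eps[keep]
    if len(f) < min_snps:
        warnings.warn(
            f"only {len(f)} usable pool SNPs (< {min_snps}); "
            "covariance estimate may be unstable",
            stacklevel=2,
        )
    if len(f) == 0:
        raise ValueError("no usable (segregating) SNPs in control pool")
    x = (f - eps[:, None]) / np.sqrt(eps * (1.0 - eps))[:, None]
    F = x.T @ x / len(x)
    pops = panel.populations
    return pd.DataFrame(F, index=pops, columns=pops)


def _group_matrix(groups: list[list[int]], m: int) -> np.ndarray:
    A = np.zeros((len(groups), m))
    for g, members in enumerate(groups):
        A[g, members] = 1.0 / len(members)
    return A


def _conditional_z_weights(
    F: np.ndarray,
    groups: list[list[int]],
    focal: int,
    pinv_rtol: float = _PINV_RTOL,
) -> tuple[np.ndarray, float]:
    """Linear functional g and conditional sd for the focal group's z.

    Returns (g, sd) such that z = g @ x / sd for a population-level vector x
    (any constant shift of x is annihilated). sd = 0 signals the degenerate
    all-zero-covariance case, where z is defined as 0 for a zero residual.
    """
    m = F.shape[0]
    members = set(groups[focal])
    others = [i for i in range(m) if i not in members]
    if not others:
        raise ValueError("focal group contains every population")
    # leave-focal-out centering
    w = np.zeros(m)
    w[others] = 1.0 / len(others)
    B = np.eye(m) - np.outer(np.ones(m), w)
    A = _group_matrix(groups, m)
    T = A @ B                      # group values of leave-out-centered x
    S = T @ F @ T.T
    o = [g for g in range(len(groups)) if g != focal]
    Soo = S[np.ix_(o, o)]
    Sro = S[focal, o]
    if len(o) and np.abs(Soo).max() > 0:
        Soo_pinv = np.linalg.pinv(Soo, rcond=pinv_rtol, hermitian=True)
    else:
        Soo_pinv = np.zeros_like(Soo)
    coef = Sro @ Soo_pinv          # regression of focal on other groups
    var = float(S[focal, focal] - coef @ Sro)
    # residual functional: focal group value minus its conditional mean
    gvec = T[focal] - coef @ T[[g for g in o], :] if len(o) else T[focal]
    scale = float(np.abs(np.diag(S)).max()) if S.size else 0.0
    if var <= max(1e-12 * scale, 0.0) or var <= 0.0:
        return gvec, 0.0
    return gvec, float(np.sqrt(var))


def _apply_z(gvec: np.ndarray, sd: float, x: np.ndarray, zero_tol: float) -> float:
    resid = float(gvec @ x)
    if sd == 0.0:
        if abs(resid) <= zero_tol:
            return 0.0
        raise SingularCovarianceError(
            "conditional variance is singular beyond pseudo-inverse tolerance "
            "for the requested region partition"
        )
    return resid / sd


def regional_outlier_test(
    trait_snps: TraitSnpSet,
    panel: FrequencyPanel,
    F_hat: pd.DataFrame,
    focal_region: str,
    control_sets: ControlSets | None = None,
    pinv_rtol: float = _PINV_RTOL,
) -> GeneticValueResult:
    """Test whether the focal region's genetic value is an outlier.

    Computes per-population genetic values, centers and scales them by
    sqrt(sum_l beta_l^2 eps_l (1 - eps_l)) so their null covariance is
    approximately ``F_hat``, then standardizes the focal region's mean value
    against its conditional distribution given the other regions. When
    ``control_sets`` (maf+bvalue-matched) are supplied, an empirical p-value
    is the fraction of control sets whose focal regional \\|z\\| is >= the
    observed \\|z\\|; otherwise the analytic z alone is reported.
    """
    pops = panel.populations
    m = len(pops)
    region_names = panel.regions
    if focal_region not in region_names:
        raise ValueError(f"unknown focal region {focal_region!r}")
    if len(region_names) < 2:
        raise ValueError("need at least 2 regions")
    result = GeneticValueResult(
        trait=trait_snps.trait, focal_region=focal_region,
        n_snps=len(trait_snps), threshold=trait_snps.threshold,
        seed=None if control_sets is None else control_sets.seed,
    )
    if len(trait_snps) == 0:
        return result  # NA

    members = panel.region_members()
    pop_pos = {p: i for i, p in enumerate(pops)}
    groups = [[pop_pos[p] for p in members[r]] for r in region_names]
    focal = region_names.index(focal_region)

    Z = compute_genetic_values(trait_snps, panel)
    finc = _increasing_freq_matrix(trait_snps, panel)
    beta = trait_snps.table["beta_abs"].to_numpy()
    eps = finc.mean(axis=1)
    scale = float(np.sqrt(np.sum(beta**2 * eps * (1.0 - eps))))
    Zc = Z - Z.mean()
    result.Z = Z
    result.Z_centered = Zc
    A_plain = _group_matrix(groups, m)
    result.regional_values = pd.Series(A_plain @ Zc.to_numpy(), index=region_names)
    result.F_hat = F_hat

    if scale <= 0.0:
        # every trait SNP fixed panel-wide: no information, report NA z
        return result

    F = F_hat.loc[pops, pops].to_numpy()
    xs = Zc.to_numpy() / scale
    zero_tol = 1e-9 * (1.0 + float(np.abs(xs).max()))

    gvec, sd = _conditional_z_weights(F, groups, focal, pinv_rtol)
    result.regional_z = _apply_z(gvec, sd, xs, zero_tol)

    pop_groups = [[i] for i in range(m)]
    pz = np.empty(m)
    for i in range(m):
        gv, s_i = _conditional_z_weights(F, pop_groups, i, pinv_rtol)
        pz[i] = _apply_z(gv, s_i, xs, zero_tol)
    result.population_z = pd.Series(pz, index=pops)

    if control_sets is not None and control_sets.n_sets > 0:
        z_null = _null_regional_z(
            control_sets, panel, beta, gvec, sd, zero_tol
        )
        result.n_sets = len(z_null)
        result.null_z_sd = float(np.std(z_null, ddof=1)) if len(z_null) > 1 else float("nan")
        result.p_empirical = float(
            np.mean(np.abs(z_null) >= abs(result.regional_z))
        )
    return result


def _null_regional_z(
    control_sets: ControlSets,
    panel: FrequencyPanel,
    beta: np.ndarray,
    gvec: np.ndarray,
    sd: float,
    zero_tol: float,
) -> np.ndarray:
    """Focal regional z for each control set (matched beta, pre-drawn orientation)."""
    n_sets, L = control_sets.ids.shape
    if L != len(beta):
        raise ValueError("control sets and trait SNP set have different sizes")
    m = len(panel.populations)
    freqs = panel.freqs.to_numpy()
    idx_all = panel.freqs.index.get_indexer(control_sets.ids.ravel())
    if (idx_all < 0).any():
        raise ValueError("control set contains SNPs absent from panel")
    idx_all = idx_all.reshape(n_sets, L)

    chunk = max(1, _MAX_NULL_BLOCK // max(1, L * m))
    out = np.empty(n_sets)
    for start in range(0, n_sets, chunk):
        stop = min(start + chunk, n_sets)
        f = freqs[idx_all[start:stop]]                      # (c, L, M) allele1 freq
        flags = control_sets.use_allele1[start:stop]        # (c, L)
        fo = np.where(flags[:, :, None], f, 1.0 - f)        # oriented
        Zs = np.einsum("l,clm->cm", beta, fo)
        eps_s = f.mean(axis=2)                              # eps(1-eps) orientation-invariant
        scale_s = np.sqrt(np.einsum("l,cl->c", beta**2, eps_s * (1.0 - eps_s)))
        Zc = Zs - Zs.mean(axis=1, keepdims=True)
        ok = scale_s > 0
        xs = np.zeros_like(Zc)
        xs[ok] = Zc[ok] / scale_s[ok, None]
        resid = xs @ gvec
        if sd == 0.0:
            out[start:stop] = 0.0
        else:
            out[start:stop] = resid / sd
    return out


def write_genetic_value_result(result: GeneticValueResult, prefix) -> None:
    """JSON record plus a tidy per-population TSV suitable for plotting."""
    import json

    with open(f"{prefix}.json", "w") as fh:
        json.dump(result.to_json_dict(), fh, indent=2)
    if result.Z is None:
        return
    tidy = pd.DataFrame(
        {
            "population": result.Z.index,
            "region": [None] * len(result.Z),
            "genetic_value": result.Z.to_numpy(),
            "genetic_value_centered": result.Z_centered.to_numpy(),
            "population_z": (
                result.population_z.to_numpy()
                if result.population_z is not None
                else np.nan
            ),
        }
    )
    tidy.to_csv(f"{prefix}.tsv", sep="\t", index=False, na_rep="NA")


def plot_regional_values(result: GeneticValueResult, panel: FrequencyPanel, path) -> None:
    """Optional bar-and-circle rendering of regional and population values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    regions = list(result.regional_values.index)
    members = panel.region_members()
    for i, r in enumerate(regions):
        ax.bar(i, result.regional_values[r], width=0.6, alpha=0.5,
               label=r if i == 0 else None)
        for p in members[r]:
            size = 20.0
            if result.population_z is not None and np.isfinite(result.population_z[p]):
                size = 20.0 + 30.0 * abs(result.population_z[p])
            ax.scatter(i, result.Z_centered[p], s=size, zorder=3)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xticks(range(len(regions)), regions)
    ax.set_ylabel("centered genetic value")
    title = f"{result.trait}  regional z={result.regional_z:.2f}"
    if np.isfinite(result.p_empirical):
        title += f"  p={result.p_empirical:.3g}"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
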