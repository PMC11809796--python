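"""Synthetic cohort generator.

Produces every input the analysis consumes — hierarchically structured
population allele frequencies, GWAS summary statistics, optional directional
frequency shifts at trait SNPs, LD-block and B-value annotations, and paired
differential-expression contrast tables — so the full pipeline is testable
without restricted cohort data.

The frequency model is a multivariate-normal drift approximation: each SNP
has an ancestral frequency eps drawn uniformly, and population frequencies
are drawn around eps with covariance eps*(1-eps)*F_true, where F_true is a
block matrix encoding shared within-region drift. Frequencies are clipped to
[0, 1], mimicking fixation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationSet, FrequencyPanel, GWAS_COLUMNS

logger = logging.getLogger(__name__)

# Strand-unambiguous allele pairs only, so harmonization (which drops A/T and
# C/G pairs) retains every simulated SNP.
_ALLELE_PAIRS = [
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("C", "T"), ("T", "C"), ("G", "T"), ("T", "G"),
]


@dataclass
class CovarianceModel:
    """Among-population drift covariance with region labels."""

    population_labels: list[str]
    region_of: dict[str, str]
    F_true: np.ndarray

    def validate(self) -> "CovarianceModel":
        F = np.asarray(self.F_true, dtype=float)
        m = len(self.population_labels)
        if F.shape != (m, m):
            raise ValueError(f"F_true shape {F.shape} != ({m}, {m})")
        if not np.allclose(F, F.T):
            raise ValueError("F_true is not symmetric")
        w = np.linalg.eigvalsh(F)
        if w.min() < -1e-10:
            raise ValueError(f"F_true not positive semidefinite (min eigenvalue {w.min():g})")
        missing = [p for p in self.population_labels if p not in self.region_of]
        if missing:
            raise ValueError(f"populations without a region: {missing}")
        return self


@dataclass
class SimConfig:
    """Simulation knobs standing in for the study's unavailable cohort data.

    ``shift_strength`` is the selection-differential coefficient s of the
    directional alternative: trait-increasing-allele frequencies in the target
    populations move by s*|beta|*p*(1-p).
    """

    n_snps: int = 50_000
    n_trait_snps: int = 100
    maf_floor: float = 0.05
    maf_ceiling: float = 0.95
    beta_sd: float = 0.5
    gwas_n: int = 100_000
    shift_strength: float = 0.0
    target_populations: list[str] | None = None
    seed: int = 0
    ld_block_size: int = 25
    n_chromosomes: int = 22
    pos_spacing: int = 1000

    def validate(self) -> "SimConfig":
        if not (0.0 < self.maf_floor < self.maf_ceiling < 1.0):
            raise ValueError("require 0 < maf_floor < maf_ceiling < 1")
        if self.n_trait_snps > self.n_snps:
            raise ValueError("n_trait_snps must be <= n_snps")
        if self.shift_strength < 0:
            raise ValueError("shift_strength must be >= 0")
        if self.n_snps < 1 or self.n_trait_snps < 0:
            raise ValueError("counts must be positive")
        if self.ld_block_size < 1 or self.n_chromosomes < 1:
            raise ValueError("ld_block_size and n_chromosomes must be >= 1")
        if self.gwas_n < 1:
            raise ValueError("gwas_n must be >= 1")
        if self.beta_sd < 0:
            raise ValueError("beta_sd must be >= 0")
        return self


def build_population_structure(
    n_regions: int,
    pops_per_region: int,
    between_var: float,
    within_var: float,
) -> CovarianceModel:
    """Block drift covariance: shared within-region drift plus private drift.

    Entry (m, m') of ``F_true`` is ``between_var`` for two distinct
    populations of the same region, ``between_var + within_var`` on the
    diagonal, and 0 across regions.
    """
    if n_regions < 2 or pops_per_region < 1:
        raise ValueError("need n_regions >= 2 and pops_per_region >= 1")
    if between_var < 0 or within_var < 0:
        raise ValueError("variance components must be >= 0")
    labels, region_of = [], {}
    for r in range(1, n_regions + 1):
        region = f"R{r}"
        for p in range(1, pops_per_region + 1):
            pop = f"R{r}P{p}"
            labels.append(pop)
            region_of[pop] = region
    m = len(labels)
    F = np.zeros((m, m))
    for r in range(n_regions):
        sl = slice(r * pops_per_region, (r + 1) * pops_per_region)
        F[sl, sl] = between_var
    F[np.diag_indices(m)] = between_var + within_var
    return CovarianceModel(labels, region_of, F).validate()


def _synthetic_map(config: SimConfig) -> pd.DataFrame:
    """Deterministic chromosome/position layout; LD blocks never cross chromosomes."""
    n = config.n_snps
    per_chrom = -(-n // config.n_chromosomes)  # ceil
    idx = np.arange(n)
    chrom_i = idx // per_chrom
    within = idx % per_chrom
    chrom = (chrom_i + 1).astype(str)
    pos = within * config.pos_spacing + 1  # 1-based
    block_i = within // config.ld_block_size
    ld_block = pd.Series(chrom).str.cat(block_i.astype(str), sep="_b")
    return pd.DataFrame({"chrom": chrom, "pos": pos, "_block": ld_block.to_numpy()})


def simulate_frequency_panel(
    model: CovarianceModel, config: SimConfig
) -> tuple[FrequencyPanel, AnnotationSet]:
    """Draw a structured allele-frequency panel plus annotations.

    Ancestral frequency eps_l ~ U[maf_floor, maf_ceiling]; population
    frequencies ~ MVN(eps_l, eps_l(1-eps_l) * F_true), clipped to [0, 1].
    Fully reproducible from ``config.seed``.
    """
    model.validate()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_snps, len(model.population_labels)

    eps = rng.uniform(config.maf_floor, config.maf_ceiling, size=n)
    # eigen factor handles singular F_true (e.g. the zero matrix) exactly
    w, V = np.linalg.eigh(np.asarray(model.F_true, dtype=float))
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    noise = rng.standard_normal((n, m)) @ factor.T
    freqs = eps[:, None] + np.sqrt(eps * (1.0 - eps))[:, None] * noise
    np.clip(freqs, 0.0, 1.0, out=freqs)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    alleles = np.array(_ALLELE_PAIRS, dtype=object)[pair_idx]
    bvalues = rng.integers(0, 1001, size=n)

    gmap = _synthetic_map(config)
    snp_ids = pd.Index([f"snp{i:07d}" for i in range(n)], name="snp_id")
    snps = pd.DataFrame(
        {
            "chrom": gmap["chrom"].to_numpy(),
            "pos": gmap["pos"].to_numpy(),
            "allele1": alleles[:, 0],
            "allele2": alleles[:, 1],
        },
        index=snp_ids,
    )
    freq_df = pd.DataFrame(freqs, index=snp_ids, columns=model.population_labels)
    panel = FrequencyPanel(snps, freq_df, dict(model.region_of)).validate()
    ann = AnnotationSet(
        pd.DataFrame(
            {"bvalue": bvalues, "ld_block": gmap["_block"].to_numpy()}, index=snp_ids
        )
    )
    return panel, ann


def simulate_gwas_trait(
    panel: FrequencyPanel, config: SimConfig, trait: str = "trait1"
) -> pd.DataFrame:
    """Simulate GWAS summary statistics for a random subset of panel SNPs.

    beta ~ N(0, beta_sd^2); se = 1/sqrt(2 * gwas_n * q(1-q)) with q the first
    population's allele frequency; p from the two-sided normal test of
    beta/se. SNPs with q in {0, 1} are resampled (and logged) because their
    standard error is undefined.
    """
    config.validate()
    if config.n_trait_snps > len(panel.snp_ids):
        raise ValueError("n_trait_snps exceeds panel size")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    q_all = panel.freqs.iloc[:, 0].to_numpy()
    usable = np.flatnonzero((q_all > 0.0) & (q_all < 1.0))
    degenerate = len(panel.snp_ids) - len(usable)
    if degenerate and config.n_trait_snps > 0:
        logger.info("simulate_gwas_trait: %d SNPs with fixed frequency excluded "
                    "from trait-SNP draw", degenerate)
    if len(usable) < config.n_trait_snps:
        raise ValueError("not enough segregating SNPs to place trait SNPs")
    chosen = np.sort(rng.choice(usable, size=config.n_trait_snps, replace=False))

    beta = rng.normal(0.0, config.beta_sd, size=config.n_trait_snps)
    q = q_all[chosen]
    se = 1.0 / np.sqrt(2.0 * config.gwas_n * q * (1.0 - q))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)  # p must lie in (0, 1]

    meta = panel.snps.iloc[chosen]
    # randomize which allele is reported as the effect allele (content-neutral)
    report_a1 = rng.random(config.n_trait_snps) < 0.5
    eff = np.where(report_a1, meta["allele1"], meta["allele2"])
    oth = np.where(report_a1, meta["allele2"], meta["allele1"])
    beta_rep = np.where(report_a1, beta, -beta)
    gwas = pd.DataFrame(
        {
            "snp_id": meta.index.to_numpy(),
            "chrom": meta["chrom"].to_numpy(),
            "pos": meta["pos"].to_numpy(),
            "effect_allele": eff,
            "other_allele": oth,
            "beta": beta_rep,
            "se": se,
            "p": p,
        }
    )
    gwas.attrs["trait"] = trait
    return gwas


def inject_directional_shift(
    panel: FrequencyPanel,
    gwas: pd.DataFrame,
    targets: list[str],
    s: float,
) -> FrequencyPanel:
    """Apply the polygenic alternative: shift trait-increasing alleles.

    For each GWAS SNP and target population, the trait-increasing-allele
    frequency p becomes p + s*|beta|*p*(1-p), clipped to [0, 1] — the
    classical directional-selection differential, proportional to effect size
    and to standing variation. s = 0 is the identity.
    """
    if s < 0:
        raise ValueError("shift strength s must be >= 0")
    unknown = [t for t in targets if t not in panel.populations]
    if unknown:
        raise ValueError(f"unknown target populations: {unknown}")
    out = panel.copy()
    if len(gwas) == 0 or not targets:
        return out
    idx = out.freqs.index.get_indexer(gwas["snp_id"])
    if (idx < 0).any():
        missing = gwas["snp_id"].to_numpy()[idx < 0][:5].tolist()
        raise ValueError(f"GWAS SNPs absent from panel: {missing}")
    a1 = out.snps["allele1"].to_numpy()[idx]
    inc_is_a1 = np.where(
        gwas["beta"].to_numpy() >= 0,
        gwas["effect_allele"].to_numpy() == a1,
        gwas["other_allele"].to_numpy() == a1,
    )
    beta_abs = np.abs(gwas["beta"].to_numpy())
    cols = out.freqs.columns.get_indexer(targets)
    vals = out.freqs.to_numpy()
    # update on the allele1 scale: moving the trait-increasing allele up by
    # s*|beta|*p*(1-p) moves allele1 by +/- s*|beta|*f1*(1-f1)
    sign = np.where(inc_is_a1, 1.0, -1.0)
    for c in cols:
        f1 = vals[idx, c]
        vals[idx, c] = np.clip(f1 + sign * s * beta_abs * f1 * (1.0 - f1), 0.0, 1.0)
    out.freqs = pd.DataFrame(vals, index=out.freqs.index, columns=out.freqs.columns)
    return out


def simulate_contrast_table(
    n_genes: int,
    n_sig_both: int,
    n_discordant: int,
    seed: int,
    padj_threshold: float = 0.1,
) -> pd.DataFrame:
    """Paired DE contrast table with controlled sign concordance.

    Exactly ``n_sig_both`` genes pass both adjusted-p thresholds; of those,
    exactly ``n_discordant`` have opposite-signed logFC pairs (blunted under
    the downstream sign rule) and the rest same-signed (enhanced). Remaining
    genes draw both adjusted p values above the threshold.
    """
    if not (0 <= n_discordant <= n_sig_both <= n_genes):
        raise ValueError("require 0 <= n_discordant <= n_sig_both <= n_genes")
    if not (0.0 < padj_threshold < 1.0):
        raise ValueError("padj_threshold must be in (0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    sig = rng.choice(n_genes, size=n_sig_both, replace=False)
    discordant = set(sig[:n_discordant].tolist())
    sig_set = set(sig.tolist())

    def _nonzero_lfc(size):
        mag = np.maximum(np.abs(rng.normal(0.0, 1.0, size=size)), 1e-6)
        return mag

    lfc_cond = _nonzero_lfc(n_genes) * np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    lfc_pop = _nonzero_lfc(n_genes)
    padj_pop = np.empty(n_genes)
    padj_cond = np.empty(n_genes)
    for i in range(n_genes):
        if i in sig_set:
            padj_pop[i] = rng.uniform(0.0, padj_threshold)
            padj_cond[i] = rng.uniform(0.0, padj_threshold)
            sign = -1.0 if i in discordant else 1.0
            lfc_pop[i] = lfc_pop[i] * sign * np.sign(lfc_cond[i])
        else:
            padj_pop[i] = rng.uniform(padj_threshold, 1.0)
            padj_cond[i] = rng.uniform(padj_threshold, 1.0)
            lfc_pop[i] *= np.where(rng.random() < 0.5, 1.0, -1.0)
    padj_pop = np.clip(padj_pop, np.finfo(float).tiny, 1.0)
    padj_cond = np.clip(padj_cond, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "logFC_pop": lfc_pop,
            "padj_pop": padj_pop,
            "logFC_cond": lfc_cond,
            "padj_cond": padj_cond,
        }
    )


# ---------------------------------------------------------------------------
# text writers (tab-separated contracts; BED for intervals)

def write_frequency_panel(panel: FrequencyPanel, path) -> None:
    out = panel.snps.reset_index()[["snp_id", "chrom", "pos", "allele1", "allele2"]]
    out = pd.concat([out, panel.freqs.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def write_region_map(panel: FrequencyPanel, path) -> None:
    pd.DataFrame(
        {"population": panel.populations,
         "region": [panel.region_of[p] for p in panel.populations]}
    ).to_csv(path, sep="\t", index=False)


def write_gwas_table(gwas: pd.DataFrame, path) -> None:
    gwas[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def write_ld_blocks_bed(panel: FrequencyPanel, annotations: AnnotationSet, path) -> None:
    """One 0-based half-open interval per LD block, spanning its member SNPs."""
    df = pd.DataFrame(
        {
            "chrom": panel.snps["chrom"].to_numpy(),
            "pos0": panel.snps["pos"].to_numpy() - 1,
            "block": annotations.table["ld_block"].to_numpy(),
        }
    )
    agg = df.groupby("block", sort=False).agg(
        chrom=("chrom", "first"), start=("pos0", "min"), end=("pos0", "max")
    )
    agg["end"] = agg["end"] + 1
    agg = agg.sort_values(["chrom", "start"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s)
    agg[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def _chrom_sort_key(c):
    try:
        return int(c)
    except (TypeError, ValueError):
        return 10**9


def write_bvalues_bed(panel: FrequencyPanel, annotations: AnnotationSet, path) -> None:
    """One interval per SNP with its integer B-value in column 4."""
    pd.DataFrame(
        {
            "chrom": panel.snps["chrom"].to_numpy(),
            "start": panel.snps["pos"].to_numpy() - 1,
            "end": panel.snps["pos"].to_numpy(),
            "value": annotations.table["bvalue"].to_numpy(),
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def write_contrast_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
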