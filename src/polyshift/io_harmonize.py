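"""Reading, allele harmonization, thresholding and LD-block pruning.

Turns raw GWAS summary statistics plus a multi-population frequency panel
into a :class:`~polyshift.containers.TraitSnpSet`: SNPs below the p-value
threshold, oriented to the trait-increasing allele, one per LD block.

Positions are 1-based in tables; BED intervals are 0-based half-open; block
membership uses pos-1 in [start, end).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    FormatError,
    FrequencyPanel,
    GWAS_COLUMNS,
    IntervalSet,
    TRAIT_SNP_COLUMNS,
    TraitSnpSet,
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def read_gwas_table(path, trait: str | None = None) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-statistics table.

    Malformed rows (unparseable numerics, p outside (0, 1], identical
    alleles) raise a :class:`FormatError` citing 1-based file line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    df = df[GWAS_COLUMNS].copy()
    lines = df.index.to_numpy() + 2  # header is line 1

    bad_lines: list[int] = []
    for col in ("pos", "beta", "se", "p"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend(lines[vals.isna().to_numpy()].tolist())
        df[col] = vals
    bad_p = (~df["p"].isna()) & ((df["p"] <= 0.0) | (df["p"] > 1.0))
    bad_lines.extend(lines[bad_p.to_numpy()].tolist())
    same_allele = df["effect_allele"] == df["other_allele"]
    bad_lines.extend(lines[same_allele.to_numpy()].tolist())
    if bad_lines:
        uniq = sorted(set(bad_lines))
        raise FormatError(
            f"{path}: {len(uniq)} malformed row(s) at line(s) {uniq[:20]}"
            + ("..." if len(uniq) > 20 else "")
            + " (p must lie in (0,1], numerics must parse, alleles must differ)"
        )
    df["pos"] = df["pos"].astype(np.int64)
    if trait is not None:
        df.attrs["trait"] = trait
    return df


def read_region_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"population", "region"}.issubset(df.columns):
        raise FormatError(f"{path}: region map needs columns population, region")
    if df["population"].duplicated().any():
        raise FormatError(f"{path}: duplicate population in region map")
    return dict(zip(df["population"], df["region"]))


def read_frequency_panel(path, region_map_path) -> FrequencyPanel:
    """Read a frequency panel TSV plus its population→region map."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "allele1", "allele2"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise FormatError(f"{path}: duplicated snp_id {dup!r}")
    pop_cols = [c for c in df.columns if c not in meta_cols]
    if not pop_cols:
        raise FormatError(f"{path}: no population frequency columns found")
    region_of = read_region_map(region_map_path)
    uncovered = [p for p in pop_cols if p not in region_of]
    if uncovered:
        raise FormatError(f"{path}: populations missing from region map: {uncovered}")
    snps = df.set_index("snp_id")[["chrom", "pos", "allele1", "allele2"]]
    freqs = df.set_index("snp_id")[pop_cols].astype(float)
    return FrequencyPanel(snps, freqs, region_of).validate()


@dataclass
class HarmonizeReport:
    """Per-category drop counts from allele harmonization."""

    n_input: int = 0
    n_matched: int = 0
    n_strand_flipped: int = 0
    n_ambiguous_dropped: int = 0
    n_mismatch_dropped: int = 0
    n_multiallelic_dropped: int = 0
    n_unjoined: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def harmonize(
    gwas: pd.DataFrame, panel: FrequencyPanel
) -> tuple[pd.DataFrame, HarmonizeReport]:
    """Orient GWAS effects to the panel's allele1.

    SNPs are joined on (chrom, pos) and reconciled by allele set, directly or
    via strand complement. Where the effect allele is the panel's allele2 the
    beta is negated and the alleles swapped, so that in the output
    ``effect_allele`` always equals panel ``allele1`` and ``snp_id`` is the
    panel's id. Strand-ambiguous (A/T, C/G) pairs, irreconcilable pairs and
    multi-allelic positions are dropped and counted in the report; drops are
    never fatal. Idempotent.
    """
    rep = HarmonizeReport(n_input=len(gwas))
    pmeta = panel.snps.reset_index()[["snp_id", "chrom", "pos", "allele1", "allele2"]]
    dup_panel = pmeta.duplicated(subset=["chrom", "pos"], keep=False)
    pmeta = pmeta[~dup_panel]

    g = gwas.copy()
    dup_gwas = g.duplicated(subset=["chrom", "pos"], keep=False)
    rep.n_multiallelic_dropped += int(dup_gwas.sum())
    g = g[~dup_gwas]

    merged = g.merge(pmeta, on=["chrom", "pos"], how="left", suffixes=("", "_panel"))
    joined = merged["snp_id_panel"].notna()
    rep.n_unjoined = int((~joined).sum())
    merged = merged[joined]

    eff = merged["effect_allele"].to_numpy(dtype=object)
    oth = merged["other_allele"].to_numpy(dtype=object)
    a1 = merged["allele1"].to_numpy(dtype=object)
    a2 = merged["allele2"].to_numpy(dtype=object)

    ambiguous = np.array(
        [frozenset((e, o)) in _AMBIGUOUS_PAIRS for e, o in zip(eff, oth)]
    )
    direct = (~ambiguous) & (((eff == a1) & (oth == a2)) | ((eff == a2) & (oth == a1)))
    ceff = np.array([_COMPLEMENT.get(e, "?") for e in eff], dtype=object)
    coth = np.array([_COMPLEMENT.get(o, "?") for o in oth], dtype=object)
    flipped = (~ambiguous) & (~direct) & (
        ((ceff == a1) & (coth == a2)) | ((ceff == a2) & (coth == a1))
    )
    rep.n_ambiguous_dropped = int(ambiguous.sum())
    rep.n_mismatch_dropped = int((~ambiguous & ~direct & ~flipped).sum())
    rep.n_strand_flipped = int(flipped.sum())

    keep = direct | flipped
    merged = merged[keep]
    eff_k = np.where(flipped[keep], ceff[keep], eff[keep])
    flip_sign = eff_k == merged["allele2"].to_numpy(dtype=object)
    beta = merged["beta"].to_numpy() * np.where(flip_sign, -1.0, 1.0)

    out = pd.DataFrame(
        {
            "snp_id": merged["snp_id_panel"].to_numpy(),
            "chrom": merged["chrom"].to_numpy(),
            "pos": merged["pos"].to_numpy(),
            "effect_allele": merged["allele1"].to_numpy(),
            "other_allele": merged["allele2"].to_numpy(),
            "beta": beta,
            "se": merged["se"].to_numpy(),
            "p": merged["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    rep.n_matched = len(out)
    out.attrs["trait"] = gwas.attrs.get("trait", "trait")
    out.attrs["harmonized"] = True
    return out, rep


def assign_ld_blocks(
    gwas: pd.DataFrame, ld_blocks: "IntervalSet | pd.Series"
) -> pd.Series:
    """LD-block id per GWAS row; SNPs outside every block form singletons."""
    if isinstance(ld_blocks, pd.Series):
        labels = ld_blocks.reindex(gwas["snp_id"]).to_numpy(dtype=object)
        missing = pd.isna(labels)
    else:
        row = ld_blocks.lookup(
            gwas["chrom"].to_numpy(dtype=object), gwas["pos"].to_numpy() - 1
        )
        all_labels = ld_blocks.labels().to_numpy(dtype=object)
        labels = np.where(row >= 0, all_labels[np.clip(row, 0, None)], None)
        missing = row < 0
    singleton = np.array([f"singleton:{s}" for s in gwas["snp_id"]], dtype=object)
    return pd.Series(np.where(missing, singleton, labels), index=gwas.index)


def select_trait_snps(
    gwas: pd.DataFrame,
    p_threshold: float,
    ld_blocks: "IntervalSet | pd.Series",
    trait: str | None = None,
) -> TraitSnpSet:
    """Threshold, orient and LD-prune a harmonized GWAS table.

    Rows with ``p < p_threshold`` are retained; within each LD block the SNP
    with the smallest p survives (ties: smallest position, then lexicographic
    snp_id). The trait-increasing allele is the effect allele when beta > 0,
    the other allele otherwise; beta exactly 0 leaves no trait-increasing
    allele and the SNP is dropped. An empty result is legal.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    trait = trait or gwas.attrs.get("trait", "trait")
    sub = gwas[(gwas["p"] < p_threshold) & (gwas["beta"] != 0.0)].copy()
    if len(sub) == 0:
        empty = pd.DataFrame(columns=TRAIT_SNP_COLUMNS)
        return TraitSnpSet(empty, trait=trait, threshold=p_threshold)
    sub["ld_block_id"] = assign_ld_blocks(sub, ld_blocks)
    sub = sub.sort_values(["p", "pos", "snp_id"], kind="mergesort")
    pruned = sub.groupby("ld_block_id", sort=False).head(1)
    beta = pruned["beta"].to_numpy()
    tia = np.where(beta > 0, pruned["effect_allele"], pruned["other_allele"])
    table = pd.DataFrame(
        {
            "snp_id": pruned["snp_id"].to_numpy(),
            "trait_increasing_allele": tia,
            "beta_abs": np.abs(beta),
            "p": pruned["p"].to_numpy(),
            "ld_block_id": pruned["ld_block_id"].to_numpy(),
        }
    )
    table = table.sort_values("snp_id", kind="mergesort").reset_index(drop=True)
    return TraitSnpSet(table, trait=trait, threshold=p_threshold).validate()


def write_trait_snp_set(ts: TraitSnpSet, path) -> None:
    out = ts.table.copy()
    out.insert(0, "trait", ts.trait)
    out["threshold"] = ts.threshold
    out.to_csv(path, sep="\t", index=False)


def read_trait_snp_set(path) -> TraitSnpSet:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "trait": str})
    missing = [c for c in TRAIT_SNP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    trait = str(df["trait"].iloc[0]) if "trait" in df.columns and len(df) else "trait"
    thr = float(df["threshold"].iloc[0]) if "threshold" in df.columns and len(df) else float("nan")
    return TraitSnpSet(df[TRAIT_SNP_COLUMNS].copy(), trait=trait, threshold=thr).validate()
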