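"""Independent brute-force oracles used to check the vectorized implementations.

These deliberately use naive loops / O(n^2) scans and never share code with
the package internals they verify.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def loop_mean_frequency_difference(trait_snps, panel, target, reference) -> float:
    """Per-SNP loop version of the pairwise statistic."""
    total = 0.0
    n = 0
    for _, row in trait_snps.table.iterrows():
        sid = row["snp_id"]
        a1 = panel.snps.loc[sid, "allele1"]
        ft = panel.freqs.loc[sid, target]
        fr = panel.freqs.loc[sid, reference]
        if row["trait_increasing_allele"] != a1:
            ft, fr = 1.0 - ft, 1.0 - fr
        total += ft - fr
        n += 1
    return total / n


def loop_genetic_values(trait_snps, panel) -> dict[str, float]:
    """Per-SNP, per-population loop version of the genetic value."""
    out = {pop: 0.0 for pop in panel.populations}
    for _, row in trait_snps.table.iterrows():
        sid = row["snp_id"]
        a1 = panel.snps.loc[sid, "allele1"]
        for pop in panel.populations:
            f = panel.freqs.loc[sid, pop]
            if row["trait_increasing_allele"] != a1:
                f = 1.0 - f
            out[pop] += row["beta_abs"] * f
    return out


def brute_force_select(gwas: pd.DataFrame, p_threshold: float,
                       block_of: pd.Series) -> pd.DataFrame:
    """filter -> group -> argmin reimplementation of trait-SNP selection.

    ``block_of`` maps snp_id to LD block label (NaN = outside every block).
    """
    rows = []
    for _, row in gwas.iterrows():
        if row["p"] >= p_threshold or row["beta"] == 0.0:
            continue
        block = block_of.get(row["snp_id"])
        if block is None or (isinstance(block, float) and np.isnan(block)):
            block = f"singleton:{row['snp_id']}"
        rows.append({**row.to_dict(), "block": block})
    best: dict = {}
    for row in rows:
        key = row["block"]
        cand = (row["p"], row["pos"], row["snp_id"])
        if key not in best or cand < (best[key]["p"], best[key]["pos"], best[key]["snp_id"]):
            best[key] = row
    out = []
    for row in best.values():
        inc = row["effect_allele"] if row["beta"] > 0 else row["other_allele"]
        out.append({
            "snp_id": row["snp_id"],
            "trait_increasing_allele": inc,
            "beta_abs": abs(row["beta"]),
            "ld_block_id": row["block"],
            "p": row["p"],
        })
    return pd.DataFrame(out).sort_values("snp_id").reset_index(drop=True)


def brute_force_candidates(bins: pd.DataFrame, trait_ids: list[str],
                           mode: str) -> dict[str, set]:
    """O(n^2) double loop over SNP pairs comparing bin labels."""
    trait_set = set(trait_ids)
    out: dict[str, set] = {}
    for tid in trait_ids:
        trow = bins.loc[tid]
        cands = set()
        for sid in bins.index:
            if sid in trait_set:
                continue
            srow = bins.loc[sid]
            if mode == "maf":
                if srow["maf_bin_pairwise"] == trow["maf_bin_pairwise"]:
                    cands.add(sid)
            else:
                if (
                    srow["b_bin"] >= 0
                    and trow["b_bin"] >= 0
                    and srow["maf_bin_focal"] == trow["maf_bin_focal"]
                    and srow["b_bin"] == trow["b_bin"]
                ):
                    cands.add(sid)
        out[tid] = cands
    return out
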