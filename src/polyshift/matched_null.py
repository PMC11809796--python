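"""MAF / B-value binning and matched-control resampling.

Controls for allele-frequency ascertainment of GWAS SNPs by resampling
random SNPs from the same minor-allele-frequency bin (width 0.02) — and,
for the multi-population test, the same B-value bin (width 100 on the
0–1000 background-selection scale) — as each trait SNP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ControlPool, ControlSets, FrequencyPanel, IntervalSet, TraitSnpSet

logger = logging.getLogger(__name__)

MAF_BIN_WIDTH = 0.02
N_MAF_BINS = 25      # MAF in [0, 0.5]
B_BIN_WIDTH = 100
N_B_BINS = 10        # B-value in [0, 1000]; 1000 maps into the top bin

MODE_MAF = "maf"
MODE_MAF_BVALUE = "maf+bvalue"


class MatchingError(RuntimeError):
    """Raised when a trait SNP has no bin-matched candidate controls (strict mode)."""


@dataclass
class BinnedPanel:
    """Integer bin indices per panel SNP.

    ``maf_bin_pairwise`` bins the mean MAF of the designated population pair;
    ``maf_bin_focal`` bins the MAF of the focal population; ``b_bin`` is -1
    for SNPs with no B-value annotation (flagged unmatched-for-B).
    """

    bins: pd.DataFrame  # index snp_id; columns maf_bin_pairwise, maf_bin_focal, b_bin
    pop_pair: tuple[str, str]
    focal_pop: str


def _bin_index(values: np.ndarray, width: float, n_bins: int) -> np.ndarray:
    """floor(value/width), with the exact upper boundary mapped into the top bin."""
    idx = np.floor(values / width).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def assign_bins(
    panel: FrequencyPanel,
    bvalues: "IntervalSet | pd.Series | None",
    pop_pair: tuple[str, str],
    focal_pop: str,
) -> BinnedPanel:
    """Assign mean-MAF, focal-MAF and B-value bins to every panel SNP.

    ``bvalues`` may be a valued :class:`IntervalSet` (BED-derived), a per-SNP
    Series indexed by snp_id, or None (all SNPs flagged unannotated).
    """
    for p in (*pop_pair, focal_pop):
        if p not in panel.populations:
            raise ValueError(f"unknown population {p!r}")
    f = panel.freqs
    maf_a = np.minimum(f[pop_pair[0]].to_numpy(), 1.0 - f[pop_pair[0]].to_numpy())
    maf_b = np.minimum(f[pop_pair[1]].to_numpy(), 1.0 - f[pop_pair[1]].to_numpy())
    mean_maf = 0.5 * (maf_a + maf_b)
    maf_focal = np.minimum(f[focal_pop].to_numpy(), 1.0 - f[focal_pop].to_numpy())

    n = len(f)
    if bvalues is None:
        b_bin = np.full(n, -1, dtype=np.int64)
    elif isinstance(bvalues, pd.Series):
        b = bvalues.reindex(panel.snp_ids)
        b_bin = np.where(
            b.isna(), -1, _bin_index(b.fillna(0).to_numpy(dtype=float), B_BIN_WIDTH, N_B_BINS)
        ).astype(np.int64)
    else:
        row = bvalues.lookup(
            panel.snps["chrom"].to_numpy(dtype=object), panel.snps["pos"].to_numpy() - 1
        )
        vals = bvalues.df["value"].to_numpy(dtype=float)
        b_bin = np.where(
            row >= 0, _bin_index(vals[np.clip(row, 0, None)], B_BIN_WIDTH, N_B_BINS), -1
        ).astype(np.int64)
    n_unann = int((b_bin < 0).sum())
    if n_unann:
        logger.debug("assign_bins: %d SNPs without B-value annotation", n_unann)

    bins = pd.DataFrame(
        {
            "maf_bin_pairwise": _bin_index(mean_maf, MAF_BIN_WIDTH, N_MAF_BINS),
            "maf_bin_focal": _bin_index(maf_focal, MAF_BIN_WIDTH, N_MAF_BINS),
            "b_bin": b_bin,
        },
        index=panel.snp_ids,
    )
    return BinnedPanel(bins, tuple(pop_pair), focal_pop)


@dataclass
class MatchIndex:
    """Candidate control SNPs per trait SNP, sharing the required bin(s)."""

    trait_snp_ids: list[str]
    candidates: dict[str, np.ndarray]  # trait snp_id -> array of candidate snp_ids
    mode: str
    excluded_trait_snps: list[str] = field(default_factory=list)


def build_match_index(
    binned: BinnedPanel,
    trait_snps: TraitSnpSet,
    mode: str = MODE_MAF,
    on_empty: str = "strict",
) -> MatchIndex:
    """Index candidate controls for each trait SNP.

    In ``maf`` mode candidates share the pairwise mean-MAF bin; in
    ``maf+bvalue`` mode they share both the focal MAF bin and the B-value bin
    (SNPs without a B-value are never candidates). Every trait SNP of the
    tested trait is excluded from every candidate list. A trait SNP with zero
    candidates raises :class:`MatchingError` in strict mode and is excluded
    with a warning in lenient mode.
    """
    if mode not in (MODE_MAF, MODE_MAF_BVALUE):
        raise ValueError(f"unknown matching mode {mode!r}")
    if on_empty not in ("strict", "lenient"):
        raise ValueError("on_empty must be 'strict' or 'lenient'")
    bins = binned.bins
    trait_ids = trait_snps.snp_ids
    missing = [t for t in trait_ids if t not in bins.index]
    if missing:
        raise ValueError(f"trait SNPs absent from binned panel: {missing[:5]}")

    is_trait = bins.index.isin(trait_ids)
    pool = bins[~is_trait]
    if mode == MODE_MAF:
        key_pool = pool["maf_bin_pairwise"].to_numpy()
        key_trait = bins.loc[trait_ids, "maf_bin_pairwise"].to_numpy()
        groups: dict = {}
        ids_pool = pool.index.to_numpy(dtype=object)
        order = np.argsort(key_pool, kind="stable")
        sorted_keys = key_pool[order]
        bounds = np.searchsorted(sorted_keys, np.arange(N_MAF_BINS + 1))
        for b in range(N_MAF_BINS):
            groups[b] = ids_pool[order[bounds[b]:bounds[b + 1]]]
        keys = [int(k) for k in key_trait]
    else:
        usable = pool[pool["b_bin"] >= 0]
        grouped = usable.groupby(["maf_bin_focal", "b_bin"], sort=False)
        groups = {k: g.index.to_numpy(dtype=object) for k, g in grouped}
        tb = bins.loc[trait_ids]
        keys = [
            (int(m), int(b)) if b >= 0 else None
            for m, b in zip(tb["maf_bin_focal"], tb["b_bin"])
        ]

    candidates: dict[str, np.ndarray] = {}
    empty_ids: list[str] = []
    for tid, key in zip(trait_ids, keys):
        cand = groups.get(key, np.empty(0, dtype=object)) if key is not None \
            else np.empty(0, dtype=object)
        if len(cand) == 0:
            empty_ids.append(tid)
        else:
            candidates[tid] = cand
    if empty_ids:
        if on_empty == "strict":
            raise MatchingError(
                f"no bin-matched candidates for trait SNP(s) {empty_ids[:10]} in mode {mode}"
            )
        warnings.warn(
            f"excluding {len(empty_ids)} trait SNP(s) with no matched candidates",
            stacklevel=2,
        )
    kept = [t for t in trait_ids if t not in set(empty_ids)]
    return MatchIndex(kept, candidates, mode, excluded_trait_snps=empty_ids)


def sample_control_sets(index: MatchIndex, n_sets: int, seed: int) -> ControlSets:
    """Draw ``n_sets`` matched control sets, uniformly with replacement.

    For each set and each trait SNP slot, one candidate is drawn uniformly;
    each draw also records a fair-coin allele-orientation flag from the same
    seeded stream, so the pairwise and genetic-value nulls consume identical
    randomness given one seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    L = len(index.trait_snp_ids)
    ids = np.empty((n_sets, L), dtype=object)
    flags = np.empty((n_sets, L), dtype=bool)
    for l, tid in enumerate(index.trait_snp_ids):
        cand = index.candidates[tid]
        ids[:, l] = cand[rng.integers(0, len(cand), size=n_sets)]
        flags[:, l] = rng.random(n_sets) < 0.5
    return ControlSets(list(index.trait_snp_ids), ids, flags, index.mode, seed)


def sample_control_pool(
    index: MatchIndex, per_snp_cap: int, target_total: int, seed: int
) -> ControlPool:
    """Assemble a deduplicated pool of matched controls of roughly target size.

    Up to ``per_snp_cap`` distinct candidates are reserved per trait SNP, then
    consumed round-robin (one per trait SNP per round) until ``target_total``
    distinct SNPs are collected or every reservation is exhausted.
    """
    if per_snp_cap < 1 or target_total < 1:
        raise ValueError("per_snp_cap and target_total must be >= 1")
    rng = np.random.default_rng(seed)
    reservations: list[tuple[str, np.ndarray]] = []
    for tid in index.trait_snp_ids:
        cand = index.candidates[tid]
        take = min(per_snp_cap, len(cand))
        reservations.append((tid, rng.permutation(cand)[:take]))

    seen: set = set()
    out_ids: list = []
    out_trait: list = []
    depth = max((len(r) for _, r in reservations), default=0)
    for k in range(depth):
        for tid, res in reservations:
            if len(out_ids) >= target_total:
                break
            if k < len(res) and res[k] not in seen:
                seen.add(res[k])
                out_ids.append(res[k])
                out_trait.append(tid)
        if len(out_ids) >= target_total:
            break
    if len(out_ids) < 0.1 * target_total:
        warnings.warn(
            f"control pool has only {len(out_ids)} SNPs "
            f"(< 10% of target {target_total})",
            stacklevel=2,
        )
    table = pd.DataFrame({"snp_id": out_ids, "matched_trait_snp": out_trait})
    return ControlPool(table, target_total)
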