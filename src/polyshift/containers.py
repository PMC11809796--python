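"""Core in-memory containers shared across the pipeline.

The containers are thin, validated wrappers around pandas objects: a
:class:`FrequencyPanel` holds the SNP-by-population allele-frequency matrix,
:class:`IntervalSet` holds genomic interval annotations (LD blocks, B-values),
:class:`TraitSnpSet` the harmonized, pruned, trait-increasing-oriented GWAS
SNPs, and :class:`ControlSets` / :class:`ControlPool` the resampled matched
controls that realize the null distributions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]

PANEL_META_COLUMNS = ["chrom", "pos", "allele1", "allele2"]

TRAIT_SNP_COLUMNS = ["snp_id", "trait_increasing_allele", "beta_abs", "p", "ld_block_id"]


class FormatError(ValueError):
    """Raised when an input file or table violates its format contract."""


@dataclass
class FrequencyPanel:
    """SNP-by-population allele-frequency matrix with region labels.

    Parameters
    ----------
    snps
        Per-SNP metadata indexed by ``snp_id`` with columns ``chrom`` (str),
        ``pos`` (1-based int), ``allele1``, ``allele2``. Frequencies refer to
        ``allele1``.
    freqs
        Frequency of ``allele1`` per population, indexed by ``snp_id`` with one
        column per population label.
    region_of
        Mapping of every population label to its region label.
    """

    snps: pd.DataFrame
    freqs: pd.DataFrame
    region_of: dict[str, str]

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.columns)

    @property
    def regions(self) -> list[str]:
        """Region labels in order of first appearance along the population axis."""
        seen: list[str] = []
        for pop in self.populations:
            r = self.region_of[pop]
            if r not in seen:
                seen.append(r)
        return seen

    @property
    def snp_ids(self) -> pd.Index:
        return self.snps.index

    def region_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pop in self.populations:
            out.setdefault(self.region_of[pop], []).append(pop)
        return out

    def validate(self) -> "FrequencyPanel":
        if not self.snps.index.is_unique:
            dup = self.snps.index[self.snps.index.duplicated()][:5].tolist()
            raise FormatError(f"duplicate snp_id in panel: {dup}")
        if not self.snps.index.equals(self.freqs.index):
            raise FormatError("panel snps and freqs are not aligned on snp_id")
        same = self.snps["allele1"] == self.snps["allele2"]
        if bool(same.any()):
            bad = self.snps.index[same][:5].tolist()
            raise FormatError(f"allele1 == allele2 at SNPs: {bad}")
        vals = self.freqs.to_numpy()
        bad_mask = ~((vals >= 0.0) & (vals <= 1.0))
        if bad_mask.any():
            i = int(np.argwhere(bad_mask)[0, 0])
            raise FormatError(
                f"frequency outside [0,1] at SNP {self.freqs.index[i]!r}"
            )
        missing = [p for p in self.populations if p not in self.region_of]
        if missing:
            raise FormatError(f"populations missing from region map: {missing}")
        return self

    def copy(self) -> "FrequencyPanel":
        return FrequencyPanel(self.snps.copy(), self.freqs.copy(), dict(self.region_of))


@dataclass
class IntervalSet:
    """Genomic intervals (0-based, half-open), optionally valued (e.g. B-values).

    Intervals must be non-overlapping within a chromosome for membership
    lookups to be well defined; this is checked lazily by :meth:`lookup`.
    """

    df: pd.DataFrame  # columns: chrom, start, end [, value]

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.df.columns):
            raise FormatError(f"IntervalSet requires columns {sorted(need)}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None

    @property
    def has_values(self) -> bool:
        return "value" in self.df.columns

    @classmethod
    def from_bed(cls, path, valued: bool = False) -> "IntervalSet":
        names = ["chrom", "start", "end"] + (["value"] if valued else [])
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=range(len(names)), names=names,
            dtype={"chrom": str},
        )
        if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
            raise FormatError(f"malformed BED intervals in {path}")
        return cls(df)

    def to_bed(self, path) -> None:
        self.df.to_csv(path, sep="\t", header=False, index=False)

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        if self._by_chrom is None:
            by: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
            for chrom, g in self.df.groupby("chrom", sort=False):
                g = g.sort_values("start")
                starts = g["start"].to_numpy()
                ends = g["end"].to_numpy()
                if (starts[1:] < ends[:-1]).any():
                    raise FormatError(f"overlapping intervals on chromosome {chrom}")
                by[str(chrom)] = (starts, ends, g.index.to_numpy())
            self._by_chrom = by
        return self._by_chrom

    def lookup(self, chrom: np.ndarray, pos0: np.ndarray) -> np.ndarray:
        """Row index in ``df`` of the interval containing each 0-based position.

        Returns -1 where no interval contains the position.
        """
        chrom = np.asarray(chrom, dtype=object)
        pos0 = np.asarray(pos0)
        out = np.full(len(pos0), -1, dtype=np.int64)
        index = self._index()
        for c in pd.unique(chrom):
            tab = index.get(str(c))
            if tab is None:
                continue
            starts, ends, rows = tab
            mask = chrom == c
            p = pos0[mask]
            i = np.searchsorted(starts, p, side="right") - 1
            ok = (i >= 0) & (p < ends[np.clip(i, 0, None)])
            res = np.where(ok, rows[np.clip(i, 0, None)], -1)
            out[mask] = res
        return out

    def labels(self) -> pd.Series:
        """Canonical 'chrom:start-end' label per interval row."""
        d = self.df
        return d["chrom"].astype(str) + ":" + d["start"].astype(str) + "-" + d["end"].astype(str)


@dataclass
class AnnotationSet:
    """Per-SNP annotations produced by the simulator: B-value and LD block id."""

    table: pd.DataFrame  # index snp_id; columns: bvalue (int), ld_block (str)

    def bvalue_series(self) -> pd.Series:
        return self.table["bvalue"]

    def ld_block_series(self) -> pd.Series:
        return self.table["ld_block"]


@dataclass
class TraitSnpSet:
    """Thresholded, LD-pruned GWAS SNPs oriented to the trait-increasing allele."""

    table: pd.DataFrame  # columns TRAIT_SNP_COLUMNS
    trait: str = "trait"
    threshold: float = float("nan")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def validate(self) -> "TraitSnpSet":
        t = self.table
        missing = [c for c in TRAIT_SNP_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"trait SNP set missing columns: {missing}")
        if (t["beta_abs"] < 0).any():
            raise FormatError("beta_abs must be >= 0")
        if t["ld_block_id"].duplicated().any():
            raise FormatError("more than one SNP per LD block in trait SNP set")
        if np.isfinite(self.threshold) and (t["p"] >= self.threshold).any():
            raise FormatError("trait SNP with p >= threshold")
        return self


@dataclass
class ControlSets:
    """Resampled sets of bin-matched control SNPs (the resampling null).

    ``ids[s, l]`` is the control SNP replacing trait SNP ``trait_snp_ids[l]``
    in set ``s``; ``use_allele1[s, l]`` is the pre-drawn fair-coin allele
    orientation (True: panel allele1 plays the trait-increasing role).
    """

    trait_snp_ids: list[str]
    ids: np.ndarray          # (n_sets, L), dtype=object
    use_allele1: np.ndarray  # (n_sets, L), dtype=bool
    mode: str                # "maf" or "maf+bvalue"
    seed: int

    @property
    def n_sets(self) -> int:
        return int(self.ids.shape[0])

    def write(self, tsv_path, sidecar_path=None) -> None:
        n_sets, L = self.ids.shape
        df = pd.DataFrame({
            "set": np.repeat(np.arange(n_sets), L),
            "trait_snp": np.tile(np.asarray(self.trait_snp_ids, dtype=object), n_sets),
            "control_snp": self.ids.ravel(),
            "use_allele1": self.use_allele1.ravel().astype(int),
        })
        df.to_csv(tsv_path, sep="\t", index=False)
        if sidecar_path is not None:
            meta = {"n_sets": n_sets, "n_trait_snps": L, "mode": self.mode, "seed": self.seed}
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def read(cls, tsv_path, sidecar_path) -> "ControlSets":
        with open(sidecar_path) as fh:
            meta = json.load(fh)
        df = pd.read_csv(tsv_path, sep="\t", dtype={"trait_snp": str, "control_snp": str})
        n_sets, L = meta["n_sets"], meta["n_trait_snps"]
        trait_ids = df["trait_snp"].iloc[:L].tolist()
        ids = df["control_snp"].to_numpy(dtype=object).reshape(n_sets, L)
        flags = df["use_allele1"].to_numpy(dtype=bool).reshape(n_sets, L)
        return cls(trait_ids, ids, flags, meta["mode"], meta["seed"])


@dataclass
class ControlPool:
    """Flat, deduplicated list of matched control SNPs for covariance estimation."""

    table: pd.DataFrame  # columns: snp_id, matched_trait_snp
    target_total: int

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    def write(self, tsv_path) -> None:
        self.table.to_csv(tsv_path, sep="\t", index=False)

    @classmethod
    def read(cls, tsv_path, target_total: int = 0) -> "ControlPool":
        df = pd.read_csv(tsv_path, sep="\t", dtype=str)
        return cls(df, target_total)


@dataclass
class PairwiseResult:
    """Result of the pairwise trait-increasing-allele frequency-shift test."""

    trait: str
    target: str
    reference: str
    n_snps: int
    d_obs: float = float("nan")
    null_mean: float = float("nan")
    null_sd: float = float("nan")
    p_empirical: float = float("nan")
    signed_p: float = float("nan")
    n_sets: int = 0
    threshold: float = float("nan")
    seed: int | None = None

    @property
    def is_na(self) -> bool:
        return self.n_snps < 1

    def to_record(self) -> dict:
        rec = dataclasses.asdict(self)
        if self.is_na:
            for k in ("d_obs", "null_mean", "null_sd", "p_empirical", "signed_p"):
                rec[k] = "NA"
        return rec


@dataclass
class GeneticValueResult:
    """Result of the multi-population genetic-value regional outlier test."""

    trait: str
    focal_region: str
    n_snps: int
    Z: pd.Series | None = None                # raw genetic value per population
    Z_centered: pd.Series | None = None       # Z minus cross-population mean
    regional_values: pd.Series | None = None  # per-region mean of Z_centered
    F_hat: pd.DataFrame | None = None
    regional_z: float = float("nan")
    population_z: pd.Series | None = None
    p_empirical: float = float("nan")
    null_z_sd: float = float("nan")
    n_sets: int = 0
    threshold: float = float("nan")
    seed: int | None = None

    @property
    def is_na(self) -> bool:
        return self.n_snps < 1

    def to_json_dict(self) -> dict:
        def ser(x):
            if x is None:
                return None
            if isinstance(x, pd.Series):
                return {str(k): float(v) for k, v in x.items()}
            if isinstance(x, pd.DataFrame):
                return {str(k): {str(j): float(v) for j, v in row.items()}
                        for k, row in x.iterrows()}
            return x

        return {
            "trait": self.trait,
            "focal_region": self.focal_region,
            "n_snps": int(self.n_snps),
            "Z": ser(self.Z),
            "Z_centered": ser(self.Z_centered),
            "regional_values": ser(self.regional_values),
            "F_hat": ser(self.F_hat),
            "regional_z": None if np.isnan(self.regional_z) else float(self.regional_z),
            "population_z": ser(self.population_z),
            "p_empirical": None if np.isnan(self.p_empirical) else float(self.p_empirical),
            "null_z_sd": None if np.isnan(self.null_z_sd) else float(self.null_z_sd),
            "n_sets": int(self.n_sets),
            "threshold": self.threshold if np.isfinite(self.threshold) else None,
            "seed": self.seed,
        }


@dataclass
class ResponseClassification:
    """Blunted/enhanced labels for genes passing both contrast thresholds."""

    table: pd.DataFrame  # per qualifying gene: gene_id, logFC_pop, logFC_cond, label
    n_blunted: int
    n_enhanced: int
    n_zero_excluded: int
    threshold: float

    @property
    def n_total(self) -> int:
        return self.n_blunted + self.n_enhanced

    @property
    def proportions(self) -> dict[str, float]:
        if self.n_total == 0:
            return {"blunted": float("nan"), "enhanced": float("nan")}
        return {
            "blunted": self.n_blunted / self.n_total,
            "enhanced": self.n_enhanced / self.n_total,
        }

    def summary_dict(self) -> dict:
        prop = self.proportions
        return {
            "threshold": self.threshold,
            "n_total": self.n_total,
            "n_blunted": self.n_blunted,
            "n_enhanced": self.n_enhanced,
            "n_zero_logfc_excluded": self.n_zero_excluded,
            "prop_blunted": prop["blunted"],
            "prop_enhanced": prop["enhanced"],
        }
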