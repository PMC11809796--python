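"""Blunted vs enhanced transcriptional-response classification.

Given paired differential-expression contrasts per gene — the
between-population log fold change under hypoxia and the hypoxia-response
(hypoxia minus normoxia) log fold change — genes significant in both
contrasts are classified by the sign product of the two logFCs: opposite
signs mean the population difference opposes the hypoxia response (a
blunted response), same signs mean it reinforces it (enhanced). The module
consumes generic contrast tables; it does not fit any expression model.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .containers import FormatError, ResponseClassification

CONTRAST_COLUMNS = ["gene_id", "logFC_pop", "padj_pop", "logFC_cond", "padj_cond"]


def read_contrast_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in CONTRAST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    return validate_contrast_table(df[CONTRAST_COLUMNS].copy())


def validate_contrast_table(table: pd.DataFrame) -> pd.DataFrame:
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene_id {dup!r} in contrast table")
    for col in ("padj_pop", "padj_cond"):
        v = table[col].to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any() or np.isnan(v).any():
            raise FormatError(f"{col} must lie in [0, 1]")
    for col in ("logFC_pop", "logFC_cond"):
        if not np.isfinite(table[col].to_numpy(dtype=float)).all():
            raise FormatError(f"{col} must be finite")
    return table


def classify_response(
    table: pd.DataFrame, padj_threshold: float = 0.1
) -> ResponseClassification:
    """Label qualifying genes blunted or enhanced.

    Qualifying genes have both adjusted p-values strictly below
    ``padj_threshold``. A gene is blunted when sign(logFC_pop) *
    sign(logFC_cond) < 0 and enhanced when > 0; genes with either logFC
    exactly 0 carry no sign and are excluded (counted separately). An empty
    qualifying set is a valid result with zero counts.
    """
    if not (0.0 < padj_threshold <= 1.0):
        raise ValueError("padj_threshold must lie in (0, 1]")
    table = validate_contrast_table(table)
    sig = table[
        (table["padj_pop"] < padj_threshold) & (table["padj_cond"] < padj_threshold)
    ].copy()
    sign_prod = np.sign(sig["logFC_pop"].to_numpy()) * np.sign(
        sig["logFC_cond"].to_numpy()
    )
    zero = sign_prod == 0
    labeled = sig[~zero].copy()
    labeled["label"] = np.where(
        sign_prod[~zero] < 0, "blunted", "enhanced"
    )
    labeled = labeled[
        ["gene_id", "logFC_pop", "padj_pop", "logFC_cond", "padj_cond", "label"]
    ].reset_index(drop=True)
    return ResponseClassification(
        table=labeled,
        n_blunted=int((labeled["label"] == "blunted").sum()),
        n_enhanced=int((labeled["label"] == "enhanced").sum()),
        n_zero_excluded=int(zero.sum()),
        threshold=padj_threshold,
    )


def write_classification(result: ResponseClassification, prefix) -> None:
    """Per-gene labeled TSV plus a JSON summary of counts and proportions."""
    result.table.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(result.summary_dict(), fh, indent=2)
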