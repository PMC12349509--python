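"""Expression summaries for the genes harbouring deleterious SNPs.

From a genes x samples TPM matrix restricted to dSNP-associated genes, two
per-sample estimates feed the association battery: the expressed gene count
(genes with TPM above the expression floor) and the mean TPM across those
expressed genes. Per-gene sample-presence tallies (in how many samples is a
gene expressed?) support the presence/absence summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("gburden")


@dataclass
class ExpressionSummary:
    """Per-sample expression estimates and per-gene presence counts.

    ``per_sample.mean_tpm`` is NaN (undefined) for a sample expressing no
    gene; the expression floor is recorded for auditability.
    """

    per_sample: pd.DataFrame     # expressed_gene_count, mean_tpm
    per_gene: pd.Series          # n_samples_expressed, indexed by gene_id
    floor: float

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)


def read_tpm(path) -> pd.DataFrame:
    """Read a genes-in-rows TPM matrix TSV (first column = gene_id)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    mat.index = mat.index.astype(str)
    return mat


def summarize_expression(mat: pd.DataFrame, floor: float = 0.0) -> ExpressionSummary:
    """Summarise a TPM matrix into per-sample counts/means and per-gene presence.

    A gene is "expressed" in a sample when its TPM is strictly above
    ``floor`` (default 0: any detected abundance counts). Raising the floor
    can only shrink the expressed-gene count.
    """
    if not mat.index.is_unique or not mat.columns.is_unique:
        raise ValueError("TPM matrix gene and sample IDs must be unique")
    vals = mat.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("TPM values must be non-negative")

    expressed = vals > floor
    counts = expressed.sum(axis=0)
    with np.errstate(invalid="ignore"):
        sums = np.where(expressed, vals, 0.0).sum(axis=0)
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if (counts == 0).any():
        n0 = int((counts == 0).sum())
        logger.warning("summarize_expression: %d sample(s) express no gene "
                       "(mean TPM undefined)", n0)

    per_sample = pd.DataFrame(
        {"expressed_gene_count": counts.astype(int), "mean_tpm": means},
        index=pd.Index(mat.columns, name="sample_id"))
    per_gene = pd.Series(expressed.sum(axis=1).astype(int),
                         index=mat.index.rename("gene_id"),
                         name="n_samples_expressed")
    return ExpressionSummary(per_sample=per_sample, per_gene=per_gene,
                             floor=float(floor))


def map_genes_to_dsnps(dset: pd.DataFrame,
                       gene_index: pd.Series | dict | None = None) -> pd.DataFrame:
    """List the unique genes associated with a deleterious set, with dSNP counts.

    ``gene_index`` optionally overrides/supplies the per-variant gene mapping
    (keyed however the caller joined it; values are gene IDs). dSNPs with no
    gene assignment are tallied under ``unassigned`` rather than dropped.
    """
    genes = dset["gene_id"].copy() if "gene_id" in dset.columns else \
        pd.Series(index=dset.index, dtype=object)
    if gene_index is not None:
        genes = genes.where(genes.notna(), pd.Series(gene_index))
    genes = genes.fillna("unassigned").replace("", "unassigned")
    out = (genes.value_counts().rename_axis("gene_id")
           .reset_index(name="n_dsnps"))
    return out.sort_values(["n_dsnps", "gene_id"],
                           ascending=[False, True]).reset_index(drop=True)
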