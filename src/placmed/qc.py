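"""Nucleus/gene quality filters, normalization, and pseudobulk aggregation.

Filters follow the strict-inequality reading of the usual droplet thresholds:
a nucleus is kept iff detected genes > ``min_genes``, UMI sum > ``min_umi``
and mitochondrial percentage < ``max_mito_pct``. Gene filtering on pseudobulk
is stratum-local: within each (cell_type, side) stratum a gene needs at least
``min_total`` summed counts across that stratum's samples.

Normalization is log1p of counts-per-10,000 (CP10K): x = ln(1 + 1e4 * c / L).
It is scale-invariant per nucleus and preserves the sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import EmptyResultError, ValidationError
from .io import CountMatrix

__all__ = [
    "PseudobulkMatrix",
    "qc_metrics",
    "filter_nuclei",
    "normalize_log1p_cp10k",
    "pseudobulk",
    "filter_genes_pseudobulk",
    "mito_gene_ids_by_prefix",
]


def mito_gene_ids_by_prefix(cm: CountMatrix, prefix: str = "MT-") -> list[str]:
    """Mitochondrial gene ids by the conventional name prefix."""
    return [g for g, n in zip(cm.gene_ids, cm.gene_names) if n.startswith(prefix) or g.startswith(prefix)]


def qc_metrics(cm: CountMatrix, mito_gene_ids: list[str]) -> pd.DataFrame:
    """Per-nucleus detected genes, total UMIs, and mito percentage."""
    unknown = set(mito_gene_ids) - set(cm.gene_ids)
    if unknown:
        raise ValidationError(f"mito gene ids not in matrix: {sorted(unknown)[:5]}")
    csc = cm.counts.tocsc()
    n_genes_det = np.asarray((csc > 0).sum(axis=0)).ravel()
    total_umi = np.asarray(csc.sum(axis=0)).ravel()
    if mito_gene_ids:
        pos = {g: i for i, g in enumerate(cm.gene_ids)}
        mito_rows = [pos[g] for g in mito_gene_ids]
        mito_umi = np.asarray(csc[mito_rows, :].sum(axis=0)).ravel()
    else:
        mito_umi = np.zeros_like(total_umi)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_pct = np.where(total_umi > 0, 100.0 * mito_umi / total_umi, 0.0)
    return pd.DataFrame(
        {
            "n_genes_detected": n_genes_det,
            "total_umi": total_umi,
            "mito_pct": mito_pct,
        },
        index=pd.Index(cm.barcodes, name="barcode"),
    )


def filter_nuclei(
    cm: CountMatrix,
    min_genes: int = 200,
    min_umi: int = 500,
    max_mito_pct: float = 5.0,
    mito_gene_ids: list[str] | None = None,
) -> CountMatrix:
    """Keep nuclei with detected genes > min_genes, UMIs > min_umi and
    mito% < max_mito_pct (all strict). Column order is preserved."""
    mito_gene_ids = mito_gene_ids or []
    metrics = qc_metrics(cm, mito_gene_ids)
    pass_genes = metrics["n_genes_detected"].to_numpy() > min_genes
    pass_umi = metrics["total_umi"].to_numpy() > min_umi
    pass_mito = metrics["mito_pct"].to_numpy() < max_mito_pct
    keep = pass_genes & pass_umi & pass_mito
    if not keep.any():
        raise EmptyResultError(
            "all nuclei removed by QC: "
            f"{int((~pass_genes).sum())} failed genes>{min_genes}, "
            f"{int((~pass_umi).sum())} failed umi>{min_umi}, "
            f"{int((~pass_mito).sum())} failed mito<{max_mito_pct}%"
        )
    return cm.subset_nuclei(keep)


def normalize_log1p_cp10k(cm: CountMatrix) -> sp.csr_matrix:
    """x_gj = ln(1 + 1e4 * c_gj / sum_g c_gj); zeros stay zero."""
    totals = np.asarray(cm.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValidationError(
            f"zero-UMI nuclei present (should have been filtered): "
            f"{[cm.barcodes[i] for i in zero[:5]]}"
        )
    x = cm.counts.tocsc().astype(float)
    x.data *= np.repeat(1e4 / totals, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return x.tocsr()


@dataclass
class PseudobulkMatrix:
    """Per-stratum genes x samples count sums plus group sizes.

    ``strata`` maps (cell_type, side) -> genes x samples integer DataFrame;
    ``group_sizes`` maps (cell_type, side) -> per-sample nucleus counts.
    Only groups with at least one nucleus are present.
    """

    strata: dict[tuple[str, str], pd.DataFrame]
    group_sizes: dict[tuple[str, str], pd.Series]

    def total_counts(self) -> int:
        return int(sum(df.to_numpy().sum() for df in self.strata.values()))

    def total_nuclei(self) -> int:
        return int(sum(s.sum() for s in self.group_sizes.values()))


def pseudobulk(cm: CountMatrix) -> PseudobulkMatrix:
    """Sum counts over (sample, cell_type, side) groups."""
    meta = cm.nucleus_meta
    empty = meta.index[meta["cell_type"].astype(str) == ""]
    if len(empty):
        raise ValidationError(
            f"nuclei with empty cell_type label: {list(empty[:5])}"
            + ("..." if len(empty) > 5 else "")
        )
    csc = cm.counts.tocsc()
    strata: dict[tuple[str, str], pd.DataFrame] = {}
    sizes: dict[tuple[str, str], pd.Series] = {}
    for (ct, side), sub in meta.groupby(["cell_type", "side"], sort=True):
        cols = {}
        n = {}
        for sample_id, sub2 in sub.groupby("sample_id", sort=True):
            idx = meta.index.get_indexer(sub2.index)
            cols[sample_id] = np.asarray(csc[:, idx].sum(axis=1)).ravel()
            n[sample_id] = len(idx)
        df = pd.DataFrame(cols, index=pd.Index(cm.gene_ids, name="gene_id")).astype(np.int64)
        strata[(ct, side)] = df
        sizes[(ct, side)] = pd.Series(n, name="n_nuclei")
    return PseudobulkMatrix(strata=strata, group_sizes=sizes)


def filter_genes_pseudobulk(pb: PseudobulkMatrix, min_total: int = 10) -> PseudobulkMatrix:
    """Within each stratum, keep genes with >= min_total summed counts."""
    strata = {}
    sizes = {}
    for key, df in pb.strata.items():
        keep = df.sum(axis=1) >= min_total
        strata[key] = df.loc[keep].copy()
        sizes[key] = pb.group_sizes[key].copy()
    return PseudobulkMatrix(strata=strata, group_sizes=sizes)
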