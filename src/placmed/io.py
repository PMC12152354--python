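"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* 10x-style count triplets: ``matrix.mtx`` (Matrix Market coordinate, 1-based)
  + ``features.tsv`` (gene id, gene name) + ``barcodes.tsv`` + ``nucleus_meta.csv``.
* Long-format signed gene weights: TSV with columns ``program, gene, weight``.
* Sample / phenotype metadata: CSV. Bulk expression: TSV, genes x subjects.

All readers validate and raise typed errors naming the offending records;
none silently coerces. Internal matrices are 0-based; Matrix Market files use
the standard 1-based indices.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .errors import FormatError, SchemaError, ValidationError

SIDES = ("maternal", "fetal")

NUCLEUS_META_COLUMNS = ("barcode", "sample_id", "cell_type", "side")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x nuclei integer counts plus per-nucleus annotations.

    ``counts`` is a scipy CSR matrix (genes in rows, nuclei in columns);
    ``nucleus_meta`` is indexed by barcode with columns
    ``sample_id, cell_type, side``. ``cell_type`` may be empty at read time
    (annotation is upstream of this pipeline); per-cell-type operations
    reject empty labels.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    gene_names: list[str]
    barcodes: list[str]
    nucleus_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_g, n_b = self.counts.shape
        if n_g != len(self.gene_ids) or n_b != len(self.barcodes):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.barcodes)} barcodes"
            )
        if len(self.gene_names) != len(self.gene_ids):
            raise ValidationError("gene_names and gene_ids differ in length")
        dup = _duplicates(self.gene_ids)
        if dup:
            raise ValidationError(f"duplicate gene ids: {dup[:5]}")
        dup = _duplicates(self.barcodes)
        if dup:
            raise ValidationError(f"duplicate barcodes: {dup[:5]}")
        if self.counts.nnz and self.counts.data.min() < 0:
            bad = int(np.argmax(self.counts.data < 0))
            raise ValidationError(f"negative count entry (data index {bad})")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if data.size and np.any(data != np.round(data)):
                raise ValidationError("non-integral count entries present")
            self.counts = self.counts.astype(np.int64)
        if list(self.nucleus_meta.index) != list(self.barcodes):
            raise ValidationError("nucleus_meta index must equal barcodes, in order")
        missing = set(("sample_id", "cell_type", "side")) - set(self.nucleus_meta.columns)
        if missing:
            raise SchemaError(f"nucleus_meta missing columns: {sorted(missing)}")
        bad_side = self.nucleus_meta.loc[~self.nucleus_meta["side"].isin(SIDES)]
        if len(bad_side):
            raise ValidationError(
                f"invalid side for barcodes {list(bad_side.index[:5])}; must be one of {SIDES}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_nuclei(self) -> int:
        return self.counts.shape[1]

    def subset_nuclei(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx].tocsr(),
            gene_ids=list(self.gene_ids),
            gene_names=list(self.gene_names),
            barcodes=[self.barcodes[i] for i in idx],
            nucleus_meta=self.nucleus_meta.iloc[idx].copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            counts=self.counts[idx, :].tocsr(),
            gene_ids=[self.gene_ids[i] for i in idx],
            gene_names=[self.gene_names[i] for i in idx],
            barcodes=list(self.barcodes),
            nucleus_meta=self.nucleus_meta.copy(),
        )


@dataclass
class WeightMatrix:
    """Programs x genes signed weights, stored long (absent pair = 0)."""

    table: pd.DataFrame  # columns: program, gene, weight

    def __post_init__(self) -> None:
        missing = {"program", "gene", "weight"} - set(self.table.columns)
        if missing:
            raise SchemaError(f"weight table missing columns: {sorted(missing)}")
        dup = self.table.duplicated(["program", "gene"])
        if dup.any():
            first = self.table.loc[dup, ["program", "gene"]].iloc[0]
            raise ValidationError(
                f"duplicate (program, gene) pair: ({first['program']}, {first['gene']})"
            )
        if not np.issubdtype(self.table["weight"].dtype, np.number):
            raise FormatError("non-numeric weight column")
        counts = self.table.groupby("program")["weight"].apply(lambda w: int((w != 0).sum()))
        empty = counts[counts < 1]
        if len(empty):
            raise ValidationError(f"programs with no nonzero weight: {list(empty.index)}")

    @property
    def programs(self) -> list[str]:
        return list(dict.fromkeys(self.table["program"]))

    def genes(self, program: str | None = None) -> list[str]:
        t = self.table if program is None else self.table[self.table["program"] == program]
        return list(dict.fromkeys(t["gene"]))

    def program_weights(self, program: str) -> pd.Series:
        t = self.table[self.table["program"] == program]
        if not len(t):
            raise KeyError(program)
        return pd.Series(t["weight"].to_numpy(), index=t["gene"].to_numpy(), name=program)

    def to_wide(self, genes: Sequence[str] | None = None) -> pd.DataFrame:
        """Genes x programs dense frame; absent pairs are 0."""
        wide = self.table.pivot(index="gene", columns="program", values="weight").fillna(0.0)
        wide = wide[self.programs]
        if genes is not None:
            wide = wide.reindex(genes, fill_value=0.0)
        return wide

    def n_genes_per_program(self) -> pd.Series:
        return self.table.groupby("program")["gene"].nunique()


# ---------------------------------------------------------------------------
# BMI grouping
# ---------------------------------------------------------------------------


def derive_bmi_group(bmi: float) -> str:
    """Lean for BMI in [18.5, 25], MO (maternal obesity) above 35, else other."""
    if not (10 < bmi < 80):
        raise ValidationError(f"bmi {bmi} outside plausible range (10, 80)")
    if 18.5 <= bmi <= 25:
        return "lean"
    if bmi > 35:
        return "MO"
    return "other"


# ---------------------------------------------------------------------------
# 10x-style triplet reader/writer
# ---------------------------------------------------------------------------


def read_10x_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    nucleus_meta_path: str | Path | None = None,
) -> CountMatrix:
    """Read a Matrix Market triplet directory into a validated CountMatrix.

    Real-valued entries that are integral are accepted and cast; row/column
    order is preserved from the files.
    """
    matrix_path = Path(matrix_path)
    header = _read_mtx_header(matrix_path)
    if header["format"] != "coordinate" or header["field"] not in ("integer", "real"):
        raise FormatError(
            f"{matrix_path}: expected coordinate integer/real matrix, "
            f"got {header['format']} {header['field']}"
        )
    try:
        mat = sp.coo_matrix(mmread(str(matrix_path)))
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: {exc}") from exc

    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    if features.shape[1] < 2:
        raise FormatError(f"{features_path}: features TSV needs >= 2 columns (id, name)")
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0].tolist()

    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix header declares {mat.shape} but features/barcodes give "
            f"({len(features)}, {len(barcodes)})"
        )

    if nucleus_meta_path is not None:
        meta = read_nucleus_meta(nucleus_meta_path, barcodes)
    else:
        meta = pd.DataFrame(
            {"sample_id": "", "cell_type": "", "side": "maternal"},
            index=pd.Index(barcodes, name="barcode"),
        )
    return CountMatrix(
        counts=mat.tocsr(),
        gene_ids=features[0].tolist(),
        gene_names=features[1].tolist(),
        barcodes=barcodes,
        nucleus_meta=meta,
    )


def read_nucleus_meta(path: str | Path, barcodes: Sequence[str]) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str).fillna("")
    missing = set(NUCLEUS_META_COLUMNS) - set(meta.columns)
    if missing:
        raise SchemaError(f"{path}: nucleus meta missing columns {sorted(missing)}")
    meta = meta.set_index("barcode")
    absent = [b for b in barcodes if b not in meta.index]
    if absent:
        raise ValidationError(f"{path}: no metadata for barcodes {absent[:5]}")
    return meta.loc[list(barcodes), ["sample_id", "cell_type", "side"]]


def write_10x_mtx(cm: CountMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx / features.tsv / barcodes.tsv / nucleus_meta.csv.

    ``read_10x_mtx`` inverts this exactly (ids, order, values).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
        "nucleus_meta": out_dir / "nucleus_meta.csv",
    }
    coo = cm.counts.tocoo()
    buf = _io.StringIO()
    buf.write("%%MatrixMarket matrix coordinate integer general\n")
    buf.write(f"{cm.n_genes} {cm.n_nuclei} {coo.nnz}\n")
    if coo.nnz:
        trip = pd.DataFrame(
            {"r": coo.row + 1, "c": coo.col + 1, "v": coo.data.astype(np.int64)}
        ).sort_values(["c", "r"], kind="stable")
        trip.to_csv(buf, sep=" ", header=False, index=False)
    paths["matrix"].write_text(buf.getvalue())
    pd.DataFrame({"id": cm.gene_ids, "name": cm.gene_names}).to_csv(
        paths["features"], sep="\t", header=False, index=False
    )
    pd.Series(cm.barcodes).to_csv(paths["barcodes"], sep="\t", header=False, index=False)
    cm.nucleus_meta.rename_axis("barcode").to_csv(paths["nucleus_meta"])
    return paths


def _read_mtx_header(path: Path) -> dict[str, str]:
    with open(path) as fh:
        first = fh.readline()
    parts = first.strip().split()
    if len(parts) < 5 or parts[0] != "%%MatrixMarket":
        raise FormatError(f"{path}: missing MatrixMarket banner")
    return {"object": parts[1], "format": parts[2], "field": parts[3], "symmetry": parts[4]}


# ---------------------------------------------------------------------------
# Weight matrices
# ---------------------------------------------------------------------------


def read_weights(tsv_path: str | Path) -> WeightMatrix:
    """Long TSV with header ``program, gene, weight`` -> WeightMatrix."""
    table = pd.read_csv(
        tsv_path, sep="\t", dtype={"program": str, "gene": str}, float_precision="round_trip"
    )
    missing = {"program", "gene", "weight"} - set(table.columns)
    if missing:
        raise SchemaError(f"{tsv_path}: missing columns {sorted(missing)}")
    try:
        table["weight"] = pd.to_numeric(table["weight"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{tsv_path}: non-numeric weight: {exc}") from exc
    return WeightMatrix(table[["program", "gene", "weight"]].copy())


def write_weights(wm: WeightMatrix, tsv_path: str | Path) -> Path:
    tsv_path = Path(tsv_path)
    tsv_path.parent.mkdir(parents=True, exist_ok=True)
    wm.table.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    return tsv_path


# ---------------------------------------------------------------------------
# Sample / phenotype / bulk tables
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ("sample_id", "bmi", "maternal_age", "fetal_sex", "delivery_mode", "batch", "side")


def read_sample_table(csv_path: str | Path) -> pd.DataFrame:
    """Sample-level exposures/covariates; derives the BMI group column."""
    df = pd.read_csv(csv_path)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{csv_path}: sample table missing columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{csv_path}: duplicate sample_id {dup.iloc[0]!r}")
    df["group"] = [derive_bmi_group(b) for b in df["bmi"]]
    bad = df.loc[~df["side"].isin(SIDES), "sample_id"]
    if len(bad):
        raise ValidationError(f"{csv_path}: invalid side for samples {list(bad[:5])}")
    return df.set_index("sample_id", drop=False)


def standardize(x: pd.Series) -> pd.Series:
    """Center and scale to unit sd (ddof=1, the convention of R's scale())."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValidationError(f"cannot standardize constant column {x.name!r}")
    return (x - x.mean()) / sd


def read_phenotype_table(
    csv_path: str | Path,
    outcome_names: Sequence[str],
    standardize_outcomes: bool = False,
    standardize_age: bool = False,
) -> pd.DataFrame:
    """Subject-level outcome scores and covariates.

    Standardized columns have mean 0 / sd 1 (ddof=1) exactly up to float error.
    """
    df = pd.read_csv(csv_path)
    if "subject_id" not in df.columns:
        raise SchemaError(f"{csv_path}: missing subject_id column")
    if not outcome_names:
        raise ValidationError("outcome name set must be non-empty")
    missing = set(outcome_names) - set(df.columns)
    if missing:
        raise SchemaError(f"{csv_path}: missing outcome columns {sorted(missing)}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{csv_path}: duplicate subject_id {dup.iloc[0]!r}")
    df = df.set_index("subject_id", drop=False)
    if standardize_outcomes:
        for name in outcome_names:
            df[name] = standardize(df[name])
    if standardize_age and "maternal_age" in df.columns:
        df["maternal_age"] = standardize(df["maternal_age"])
    return df


def read_bulk_matrix(tsv_path: str | Path) -> pd.DataFrame:
    """Genes x subjects matrix of non-negative integer counts."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise FormatError(f"{tsv_path}: non-numeric entries in bulk matrix")
    if np.any(vals < 0):
        g, s = np.argwhere(vals < 0)[0]
        raise ValidationError(f"{tsv_path}: negative count at gene {df.index[g]}, subject {df.columns[s]}")
    if np.any(vals != np.round(vals)):
        g, s = np.argwhere(vals != np.round(vals))[0]
        raise ValidationError(f"{tsv_path}: non-integral count at gene {df.index[g]}, subject {df.columns[s]}")
    dup = _duplicates(list(df.index))
    if dup:
        raise ValidationError(f"{tsv_path}: duplicate gene ids {dup[:5]}")
    return df.astype(np.int64)


def write_bulk_matrix(df: pd.DataFrame, tsv_path: str | Path) -> Path:
    tsv_path = Path(tsv_path)
    tsv_path.parent.mkdir(parents=True, exist_ok=True)
    df.rename_axis("gene_id").to_csv(tsv_path, sep="\t")
    return tsv_path


def _duplicates(items: Sequence[str]) -> list[str]:
    s = pd.Series(items)
    return s[s.duplicated()].unique().tolist()
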