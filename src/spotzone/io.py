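"""Readers, writers, QC metrics and normalization.

Handles the Space Ranger tissue-positions dialects (headerless v1 and
headered v2), Visium HD coordinate-encoding barcodes, the 10x-style
MatrixMarket counts triplet (gzip-transparent), per-spot feature-set
percentages, the protocol's QC filter and log-normalization, and the
pipeline's CSV outputs.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .params import QCParams

__all__ = [
    "CountsMatrix",
    "NormalizedMatrix",
    "read_tissue_positions",
    "read_labels",
    "parse_hd_barcode",
    "emit_hd_barcode",
    "read_counts_mtx",
    "read_signatures",
    "percent_feature_set",
    "qc_metrics",
    "qc_filter",
    "log_normalize",
    "write_outputs",
]


@dataclass
class CountsMatrix:
    """Genes x spots raw counts (sparse), with name vectors."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_spots(self) -> int:
        return len(self.barcodes)


@dataclass
class NormalizedMatrix:
    """Genes x spots log-normalized expression (sparse)."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


# ---------------------------------------------------------------------------
# tissue positions & labels

_V1_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def read_tissue_positions(path: str | Path) -> pd.DataFrame:
    """Read a Space Ranger tissue-positions CSV (v1 or v2, auto-detected).

    v1 is headerless with 6 columns; v2 carries a header line starting
    with ``barcode``.  Returns columns barcode, in_tissue, array_row,
    array_col.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().lower() == "barcode"
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 6:
        raise ValueError(
            f"{path}: expected 6 tissue-positions columns, found {df.shape[1]}"
        )
    if has_header:
        df = df.rename(
            columns={
                df.columns[0]: "barcode",
                df.columns[1]: "in_tissue",
                df.columns[2]: "array_row",
                df.columns[3]: "array_col",
            }
        )
    else:
        df.columns = _V1_COLUMNS
    df = df[["barcode", "in_tissue", "array_row", "array_col"]].copy()
    for col in ("in_tissue", "array_row", "array_col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not (vals == np.floor(vals)).all():
            raise ValueError(f"{path}: non-integer values in column {col}")
        df[col] = vals.astype(int)
    return df


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read the per-spot label CSV (header barcode,sample,group,ift)."""
    df = pd.read_csv(path)
    required = {"barcode", "sample", "group", "ift"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing label columns {sorted(missing)}")
    out = df.rename(columns={"sample": "sample_id", "ift": "tissue_class"})
    if not out["tissue_class"].isin([0, 1]).all():
        raise ValueError(f"{path}: ift must be 0 or 1")
    return out[["barcode", "sample_id", "group", "tissue_class"]]


# ---------------------------------------------------------------------------
# Visium HD barcodes

_HD_FIELDS = re.compile(r"^(\d+)_(\d+)(?:-\d+)?$")


def parse_hd_barcode(barcode: str, prefix: str = "s_016um_") -> tuple[int, int]:
    """Extract (array_row, array_col) from an HD coordinate barcode.

    HD barcodes look like ``s_016um_00042_00007-1``: after the bin-size
    prefix, the first numeric field is the column and the second the
    row; a trailing ``-<n>`` suffix is ignored.
    """
    if not barcode.startswith(prefix):
        raise ValueError(f"barcode {barcode!r} does not start with prefix {prefix!r}")
    m = _HD_FIELDS.match(barcode[len(prefix):])
    if m is None:
        raise ValueError(f"barcode {barcode!r} has no <digits>_<digits> fields")
    col, row = int(m.group(1)), int(m.group(2))
    return row, col


def emit_hd_barcode(
    row: int, col: int, prefix: str = "s_016um_", suffix: str = "-1"
) -> str:
    """Inverse of :func:`parse_hd_barcode` (column field first)."""
    return f"{prefix}{col:05d}_{row:05d}{suffix}"


# ---------------------------------------------------------------------------
# counts

def _find_file(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem}[.gz] in {directory}")


def _dedup(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}.{seen[n]}")
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_counts_mtx(directory: str | Path) -> CountsMatrix:
    """Read a 10x-style MatrixMarket triplet directory.

    Expects ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (or
    ``genes.tsv``), each optionally gzipped.  Output is genes x spots;
    a transposed matrix is flipped when the name-vector lengths make
    the orientation unambiguous.  Duplicate gene symbols get ``.1``,
    ``.2`` suffixes in file order.
    """
    directory = Path(directory)
    mtx_path = _find_file(directory, "matrix.mtx")
    barcodes_path = _find_file(directory, "barcodes.tsv")
    try:
        features_path = _find_file(directory, "features.tsv")
    except FileNotFoundError:
        features_path = _find_file(directory, "genes.tsv")

    mat = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise ValueError(f"{mtx_path}: empty matrix")
    barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str).tolist()
    feats = pd.read_csv(features_path, header=None, sep="\t")
    symbol_col = 1 if feats.shape[1] >= 2 else 0
    genes = feats[symbol_col].astype(str).tolist()

    if mat.shape == (len(genes), len(barcodes)):
        pass
    elif mat.shape == (len(barcodes), len(genes)):
        mat = sp.csr_matrix(mat.T)
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} barcodes nor its transpose"
        )
    return CountsMatrix(mat, _dedup(genes), barcodes)


def read_signatures(path: str | Path) -> dict[str, list[str]]:
    """Read a name -> gene-list mapping from a YAML/JSON file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of signature name to gene list")
    return {str(k): [str(g) for g in v] for k, v in data.items()}


# ---------------------------------------------------------------------------
# QC and normalization

def percent_feature_set(counts: CountsMatrix, pattern: str) -> np.ndarray:
    """Percent of each spot's counts falling on genes matching ``pattern``.

    The pattern is anchored at the start of the gene symbol (so
    ``"mt-"`` matches ``mt-Co1`` but not ``Tmt-x``).  Spots with zero
    total counts score 0 with a warning.
    """
    rx = re.compile(pattern)
    mask = np.array([rx.match(g) is not None for g in counts.genes])
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel()
    matched = (
        np.asarray(counts.matrix[mask].sum(axis=0)).ravel()
        if mask.any()
        else np.zeros(counts.n_spots)
    )
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} spot(s) have zero total counts; percent set to 0")
    out = np.zeros(counts.n_spots)
    np.divide(matched, totals, out=out, where=~zero)
    return 100.0 * out


def qc_metrics(counts: CountsMatrix, params: QCParams | None = None) -> pd.DataFrame:
    """Per-spot QC table: totals, detected genes, percent mito/hb."""
    params = params or QCParams()
    nnz = np.diff(counts.matrix.tocsc().indptr)
    return pd.DataFrame(
        {
            "barcode": counts.barcodes,
            "n_counts": np.asarray(counts.matrix.sum(axis=0)).ravel().astype(int),
            "n_features": nnz,
            "percent_mito": percent_feature_set(counts, params.mito_pattern),
            "percent_hb": percent_feature_set(counts, params.hb_pattern),
        }
    )


def qc_filter(
    spots: pd.DataFrame,
    counts: CountsMatrix,
    params: QCParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter spots on detected genes and mitochondrial fraction.

    Keeps spots with n_features strictly above ``min_features`` and
    percent_mito strictly below ``max_pct_mito`` (``inclusive=True``
    relaxes both to non-strict).  Returns (kept spots with QC columns
    attached, report of removed barcodes with reasons).
    """
    params = params or QCParams()
    metrics = qc_metrics(counts, params)
    merged = spots.merge(metrics, on="barcode", how="left")
    if merged["n_features"].isna().any():
        missing = merged.loc[merged["n_features"].isna(), "barcode"].tolist()
        raise ValueError(f"spots absent from the counts matrix: {missing}")
    if params.inclusive:
        ok_feat = merged["n_features"] >= params.min_features
        ok_mito = merged["percent_mito"] <= params.max_pct_mito
    else:
        ok_feat = merged["n_features"] > params.min_features
        ok_mito = merged["percent_mito"] < params.max_pct_mito
    keep = ok_feat & ok_mito
    reasons = np.where(
        ~ok_feat & ~ok_mito,
        "low_features;high_mito",
        np.where(~ok_feat, "low_features", "high_mito"),
    )
    report = merged.loc[~keep, ["barcode", "n_features", "percent_mito"]].copy()
    report["reason"] = reasons[~np.asarray(keep)]
    if keep.sum() == 0:
        raise ValueError(
            "QC removed every spot; review min_features/max_pct_mito thresholds"
        )
    return merged[keep].reset_index(drop=True), report.reset_index(drop=True)


def log_normalize(counts: CountsMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Library-size log-normalization: ln(1 + scale * c / spot_total)."""
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel()
    if (totals == 0).any():
        bad = [counts.barcodes[i] for i in np.where(totals == 0)[0]]
        raise ValueError(f"spots with zero total counts (QC-filter first): {bad}")
    x = counts.matrix.tocsc().astype(float)
    per_entry_totals = np.repeat(totals, np.diff(x.indptr))
    x.data = np.log1p(scale * x.data / per_entry_totals)
    return NormalizedMatrix(sp.csr_matrix(x), list(counts.genes), list(counts.barcodes))


# ---------------------------------------------------------------------------
# outputs

def _write_gzip_csv(df: pd.DataFrame, path: Path) -> None:
    # fixed mtime/filename so identical inputs give byte-identical files
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
            gz.write(df.to_csv(index=False, lineterminator="\n").encode())


def write_outputs(
    spots: pd.DataFrame,
    zone_tables: Mapping[str, pd.DataFrame],
    summaries: Mapping[str, pd.DataFrame] | None,
    out_dir: str | Path,
) -> list[Path]:
    """Write the annotated metadata, per-sample zone CSVs and summaries.

    Metadata goes to ``metadata.csv.gz`` with deterministic row order
    (sample, then barcode); each sample's zone table to
    ``zones_<sample>.csv``; each summary to ``<name>.csv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    md = spots.sort_values(["sample_id", "barcode"], kind="stable").reset_index(drop=True)
    md_path = out_dir / "metadata.csv.gz"
    _write_gzip_csv(md, md_path)
    written.append(md_path)

    for sample in sorted(zone_tables):
        table = zone_tables[sample]
        if len(table) == 0:
            warnings.warn(f"sample {sample!r} has no zonated spots; writing header only")
        path = out_dir / f"zones_{sample}.csv"
        cols = ["barcode", "zone", "row", "col"]
        table.reindex(columns=cols).sort_values(
            ["row", "col"], kind="stable"
        ).to_csv(path, index=False, lineterminator="\n")
        written.append(path)

    for name, df in (summaries or {}).items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written
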