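"""Synthetic Visium-like datasets with known geometry and expression.

The generator emulates the study conditions of a mouse liver-metastasis
Visium section: a hex-packed array of ~5,000 in-tissue spots at 100 um
pitch with a contiguous tumor region, tumor/parenchyma marker programs,
mitochondrially-encoded genes at a target count fraction, and genes
whose mean expression follows the true distance from the tissue
boundary.  Everything is reproducible from (spec, seed) and is written
in exactly the dialects the readers in :mod:`spotzone.io` consume.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.ndimage
import scipy.sparse as sp

from .io import CountsMatrix, emit_hd_barcode

__all__ = [
    "HalfPlane",
    "Disk",
    "MultiDisk",
    "RandomBlob",
    "SimulationSpec",
    "make_labeled_lattice",
    "simulate_counts",
    "emit_dataset",
    "load_dataset",
]

TUMOR_MARKERS = (
    "Epcam", "Cdh1", "Cldn7", "Actb", "S100a6",
    "Tmsb10", "Timp1", "Bgn", "Col3a1", "Saa3", "Spp1",
)
PARENCHYMA_MARKERS = (
    "Alb", "Fabp1", "Apob", "Car3", "Apoa2",
    "Ttr", "Serpina1a", "Gnmt", "Bhmt", "Ass1",
)
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


@dataclass(frozen=True)
class HalfPlane:
    """Tumor occupies coordinates strictly below ``cut`` on ``axis``."""

    axis: str = "col"  # "row" or "col"
    cut: int = 0

    def membership(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        coord = rows if self.axis == "row" else cols
        return coord < self.cut


@dataclass(frozen=True)
class Disk:
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 1.0

    def membership(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        return dr * dr + dc * dc <= self.radius * self.radius


@dataclass(frozen=True)
class MultiDisk:
    disks: tuple[Disk, ...] = ()

    def membership(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        out = np.zeros(rows.shape, dtype=bool)
        for d in self.disks:
            out |= d.membership(rows, cols)
        return out


@dataclass(frozen=True)
class RandomBlob:
    """Contiguous random region grown from a seed cell by lattice accretion."""

    seed: int = 0
    size: int = 100

    def membership(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        r0, r1 = int(rows.min()), int(rows.max())
        c0, c1 = int(cols.min()), int(cols.max())
        shape = (r1 - r0 + 1, c1 - c0 + 1)
        rng = np.random.default_rng(self.seed)
        grid = np.zeros(shape, dtype=bool)
        start = (shape[0] // 2, shape[1] // 2)
        grid[start] = True
        frontier = {start}
        while grid.sum() < min(self.size, grid.size):
            cell = tuple(sorted(frontier)[rng.integers(len(frontier))])
            neighbors = [
                (cell[0] + dr, cell[1] + dc)
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= cell[0] + dr < shape[0] and 0 <= cell[1] + dc < shape[1]
            ]
            free = [n for n in neighbors if not grid[n]]
            if not free:
                frontier.discard(cell)
                if not frontier:
                    break
                continue
            new = free[rng.integers(len(free))]
            grid[new] = True
            frontier.add(new)
        return grid[rows - r0, cols - c0]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic sample.

    Defaults mimic a Visium capture area: hex layout (row + col even)
    on a 78 x 128 coordinate box (4,992 occupied positions, close to
    the ~5,000 spots of a full slide) at 100 um pitch, a half-plane
    tumor region, and a modest negative-binomial expression model.
    """

    n_rows: int = 78
    n_cols: int = 128
    layout: str = "hex"  # "hex" or "full"
    pitch_um: float = 100.0
    region: HalfPlane | Disk | MultiDisk | RandomBlob = HalfPlane(axis="col", cut=64)
    label_flip_prob: float = 0.0
    sample_id: str = "Sample1"
    group: str = "Ctrl"
    hd: bool = False
    bin_um: int = 16
    n_gradient: int = 5
    n_background: int = 80
    marker_fold: float = 8.0
    gradient_fold: float = 6.0
    mito_fraction: float = 0.05
    library_size_mean: float = 8000.0
    library_size_sigma: float = 0.35
    nb_dispersion: float = 2.0  # NB size parameter theta; larger = less noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_flip_prob < 0.5:
            raise ValueError("label_flip_prob must be in [0, 0.5)")
        if self.layout not in ("hex", "full"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice extent must be positive")

    @property
    def hd_prefix(self) -> str:
        return f"s_{self.bin_um:03d}um_"

    def gene_names(self) -> list[str]:
        gradient = [f"Grad{i + 1}" for i in range(self.n_gradient)]
        background = [f"Gene{i + 1:04d}" for i in range(self.n_background)]
        return (
            list(TUMOR_MARKERS)
            + list(PARENCHYMA_MARKERS)
            + list(MITO_GENES)
            + gradient
            + background
        )


def _signed_boundary_distance(member: np.ndarray) -> np.ndarray:
    """Signed Chebyshev lattice distance to the region boundary.

    Negative inside the region (tumor), positive outside; the layers
    adjacent to the boundary are -1 and +1.
    """
    if member.all() or (~member).all():
        return np.zeros(member.shape)
    to_tumor = scipy.ndimage.distance_transform_cdt(~member, metric="chessboard")
    to_paren = scipy.ndimage.distance_transform_cdt(member, metric="chessboard")
    return to_tumor.astype(float) - to_paren.astype(float)


def make_labeled_lattice(spec: SimulationSpec) -> pd.DataFrame:
    """Generate one sample's labeled spot table.

    Columns: barcode, sample_id, group, array_row, array_col,
    in_tissue, tissue_class (= region membership XOR flip noise),
    true_class and boundary_distance (signed lattice layers, ground
    truth before noise).
    """
    rr, cc = np.meshgrid(
        np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij"
    )
    member_grid = np.asarray(spec.region.membership(rr, cc), dtype=bool)
    if spec.layout == "hex":
        occupied = (rr + cc) % 2 == 0
    else:
        occupied = np.ones_like(member_grid)
    dist_grid = _signed_boundary_distance(member_grid)

    rows = rr[occupied]
    cols = cc[occupied]
    true_class = member_grid[occupied].astype(int)
    rng = np.random.default_rng([spec.seed, 0])
    flips = rng.random(len(rows)) < spec.label_flip_prob
    tissue_class = np.where(flips, 1 - true_class, true_class)

    if spec.hd:
        barcodes = [
            emit_hd_barcode(int(r), int(c), spec.hd_prefix) for r, c in zip(rows, cols)
        ]
    else:
        barcodes = [f"{spec.sample_id}-r{r:03d}c{c:03d}-1" for r, c in zip(rows, cols)]
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "sample_id": spec.sample_id,
            "group": spec.group,
            "array_row": rows,
            "array_col": cols,
            "in_tissue": 1,
            "tissue_class": tissue_class,
            "true_class": true_class,
            "boundary_distance": dist_grid[occupied],
        }
    )


def simulate_counts(spots: pd.DataFrame, spec: SimulationSpec) -> CountsMatrix:
    """Negative-binomial counts with planted expression programs.

    Tumor/parenchyma markers are up by ``marker_fold`` in their own
    tissue (by true class), mitochondrial genes take a
    ``mito_fraction`` share of every spot's rate, and gradient genes
    increase monotonically with the true boundary distance by a total
    factor of ``gradient_fold`` across the section.  Library sizes are
    lognormal; sampling is fully determined by the spec seed.
    """
    genes = spec.gene_names()
    n_spots = len(spots)
    rng = np.random.default_rng([spec.seed, 1])

    n_t, n_p, n_m = len(TUMOR_MARKERS), len(PARENCHYMA_MARKERS), len(MITO_GENES)
    base = rng.gamma(shape=2.0, scale=1.0, size=len(genes)) + 0.05

    rates = np.tile(base[:, None], (1, n_spots))
    tumor = spots["true_class"].to_numpy() == 1
    rates[:n_t, tumor] *= spec.marker_fold
    rates[n_t : n_t + n_p, ~tumor] *= spec.marker_fold

    dist = spots["boundary_distance"].to_numpy().astype(float)
    span = np.abs(dist).max() or 1.0
    grad = np.exp((dist / span) * (np.log(spec.gradient_fold) / 2.0))
    sl = slice(n_t + n_p + n_m, n_t + n_p + n_m + spec.n_gradient)
    rates[sl, :] *= grad[None, :]

    # mitochondrial share: fixed fraction of each spot's total rate
    non_mito = np.ones(len(genes), dtype=bool)
    non_mito[n_t + n_p : n_t + n_p + n_m] = False
    other_total = rates[non_mito].sum(axis=0)
    f = spec.mito_fraction
    mito_total = other_total * f / (1.0 - f)
    rates[~non_mito, :] = mito_total[None, :] / n_m

    libsize = rng.lognormal(
        mean=np.log(spec.library_size_mean), sigma=spec.library_size_sigma, size=n_spots
    )
    mu = rates / rates.sum(axis=0, keepdims=True) * libsize[None, :]
    theta = spec.nb_dispersion
    counts = rng.negative_binomial(n=theta, p=theta / (theta + mu))
    return CountsMatrix(sp.csr_matrix(counts), genes, spots["barcode"].tolist())


def emit_dataset(
    spots: pd.DataFrame,
    counts: CountsMatrix | None,
    out_dir: str | Path,
    spec: SimulationSpec | None = None,
    positions_dialect: str = "v2",
) -> dict[str, Path]:
    """Write a dataset in the dialects the pipeline ingests.

    One tissue-positions CSV per sample (v2 headered by default, v1
    headerless on request), a merged label CSV, a MatrixMarket triplet
    under ``counts/`` when counts are given, and a JSON manifest
    recording the spec and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for sample, group in spots.groupby("sample_id", sort=False):
        pos = pd.DataFrame(
            {
                "barcode": group["barcode"],
                "in_tissue": group["in_tissue"],
                "array_row": group["array_row"],
                "array_col": group["array_col"],
                "pxl_row_in_fullres": group["array_row"] * 100,
                "pxl_col_in_fullres": group["array_col"] * 100,
            }
        )
        path = out_dir / f"{sample}_tissue_positions.csv"
        if positions_dialect == "v2":
            pos.to_csv(path, index=False, lineterminator="\n")
        elif positions_dialect == "v1":
            pos.to_csv(path, index=False, header=False, lineterminator="\n")
        else:
            raise ValueError(f"unknown positions dialect {positions_dialect!r}")
        written[f"positions_{sample}"] = path

    labels = spots.rename(
        columns={"sample_id": "sample", "tissue_class": "ift"}
    )[["barcode", "sample", "group", "ift"]]
    labels_path = out_dir / "labels.csv"
    labels.to_csv(labels_path, index=False, lineterminator="\n")
    written["labels"] = labels_path

    if counts is not None:
        counts_dir = out_dir / "counts"
        counts_dir.mkdir(exist_ok=True)
        scipy.io.mmwrite(str(counts_dir / "matrix.mtx"), counts.matrix)
        (counts_dir / "barcodes.tsv").write_text(
            "".join(b + "\n" for b in counts.barcodes)
        )
        (counts_dir / "features.tsv").write_text(
            "".join(f"{g}\t{g}\tGene Expression\n" for g in counts.genes)
        )
        written["counts"] = counts_dir

    if spec is not None:
        manifest = dataclasses.asdict(spec)
        manifest["region"] = {
            "type": type(spec.region).__name__,
            **dataclasses.asdict(spec.region),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
        written["manifest"] = manifest_path
    return written


def load_dataset(out_dir: str | Path) -> tuple[pd.DataFrame, CountsMatrix | None]:
    """Re-ingest a dataset written by :func:`emit_dataset`."""
    from .io import read_counts_mtx, read_labels, read_tissue_positions

    out_dir = Path(out_dir)
    labels = read_labels(out_dir / "labels.csv")
    frames = []
    for path in sorted(out_dir.glob("*_tissue_positions.csv")):
        sample = path.name[: -len("_tissue_positions.csv")]
        pos = read_tissue_positions(path)
        pos["sample_id"] = sample
        frames.append(pos)
    if not frames:
        raise FileNotFoundError(f"no *_tissue_positions.csv under {out_dir}")
    positions = pd.concat(frames, ignore_index=True)
    spots = positions.merge(labels, on=["barcode", "sample_id"], how="inner")
    counts_dir = out_dir / "counts"
    counts = read_counts_mtx(counts_dir) if counts_dir.exists() else None
    return spots, counts
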