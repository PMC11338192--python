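"""Occupancy lattices, missing-aware moving averages and zone assignment.

The zonation works on dense 2-D lattices spanning the bounding box of
the observed array coordinates of one sample.  Occupied cells hold a
binary tissue indicator (1 = tumor/metastasis, 0 = parenchyma); every
other lattice position — off-tissue spots and, on the hex-packed Visium
array, the unoccupied checkerboard positions — is missing (NaN).  A
spot's boundary-distance score is a weighted sum of two square-window
moving averages of the indicator, masked to the spot's own tissue, and
zones are the ordinal intervals of that score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .params import ZonationParams

__all__ = [
    "Grid",
    "BarcodeGrid",
    "build_label_grids",
    "moving_average",
    "composite_score",
    "assign_zones",
    "annotate_spots_with_zones",
    "zonate_sample",
    "zonate",
    "delta_sweep",
]


@dataclass
class Grid:
    """A real-valued lattice with missing cells (NaN).

    ``row_offset``/``col_offset`` map lattice index (i, j) back to array
    coordinates (i + row_offset, j + col_offset), so that 0-based Visium
    coordinates round-trip exactly.
    """

    values: np.ndarray
    row_offset: int = 0
    col_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.values)

    def same_frame(self, other: "Grid | BarcodeGrid") -> bool:
        return (
            self.shape == other.values.shape
            and self.row_offset == other.row_offset
            and self.col_offset == other.col_offset
        )


@dataclass
class BarcodeGrid:
    """Lattice of barcode strings; unoccupied cells hold None."""

    values: np.ndarray
    row_offset: int = 0
    col_offset: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def occupied(self) -> np.ndarray:
        return self.values != None  # noqa: E711  -- elementwise on object array


def build_label_grids(
    spots: pd.DataFrame,
) -> tuple[Grid, Grid, BarcodeGrid]:
    """Build tumor/parenchyma indicator grids and the barcode grid.

    ``spots`` needs columns ``barcode``, ``array_row``, ``array_col`` and
    ``tissue_class`` (one sample's worth).  The tumor grid holds the
    tissue class, the parenchyma grid its complement (1 - class), and
    the barcode grid the spot identifier; all three are missing at
    lattice positions with no spot.
    """
    if len(spots) == 0:
        raise ValueError("no spots given")
    rows = np.asarray(spots["array_row"])
    cols = np.asarray(spots["array_col"])
    for name, arr in (("array_row", rows), ("array_col", cols)):
        if arr.dtype.kind == "f":
            if not (np.isfinite(arr).all() and (arr == np.floor(arr)).all()):
                raise ValueError(f"non-integer {name} coordinates")
        elif arr.dtype.kind not in "iu":
            raise ValueError(f"non-integer {name} coordinates")
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    tc = np.asarray(spots["tissue_class"])
    if not np.isin(tc, [0, 1]).all():
        raise ValueError("tissue_class must be 0 or 1")

    dup = pd.DataFrame({"r": rows, "c": cols}).duplicated(keep=False)
    if dup.any():
        bad = spots.loc[np.asarray(dup), "barcode"].tolist()
        raise ValueError(f"duplicate (row, col) coordinates for barcodes: {bad}")

    r0, c0 = int(rows.min()), int(cols.min())
    shape = (int(rows.max()) - r0 + 1, int(cols.max()) - c0 + 1)
    tumor = np.full(shape, np.nan)
    ri, ci = rows - r0, cols - c0
    tumor[ri, ci] = tc
    parenchyma = np.full(shape, np.nan)
    parenchyma[ri, ci] = 1 - tc
    barcodes = np.full(shape, None, dtype=object)
    barcodes[ri, ci] = np.asarray(spots["barcode"], dtype=object)
    return (
        Grid(tumor, r0, c0),
        Grid(parenchyma, r0, c0),
        BarcodeGrid(barcodes, r0, c0),
    )


def _window_sum(a: np.ndarray, delta: int) -> np.ndarray:
    """Sum over the (2*delta+1)-square window, clipped at the borders."""
    n, m = a.shape
    p = np.zeros((n + 1, m + 1))
    np.cumsum(np.cumsum(a, axis=0), axis=1, out=p[1:, 1:])
    r0 = np.clip(np.arange(n) - delta, 0, n)
    r1 = np.clip(np.arange(n) + delta + 1, 0, n)
    c0 = np.clip(np.arange(m) - delta, 0, m)
    c1 = np.clip(np.arange(m) + delta + 1, 0, m)
    return (
        p[np.ix_(r1, c1)] - p[np.ix_(r0, c1)] - p[np.ix_(r1, c0)] + p[np.ix_(r0, c0)]
    )


def moving_average(grid: Grid, delta: int, edge_policy: str = "clip") -> Grid:
    """Missing-aware square-window moving average.

    Each cell becomes the arithmetic mean of the non-missing cells in
    the Chebyshev ball of radius ``delta`` (window side 2*delta+1).
    With ``edge_policy="clip"`` the window is intersected with the
    lattice at the borders; with ``"missing"`` every cell within
    ``delta`` of an edge becomes missing.  A cell whose whole window is
    missing stays missing.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if edge_policy not in ("clip", "missing"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    v = grid.values
    if v.size == 0:
        raise ValueError("empty grid")
    finite = np.isfinite(v)
    sums = _window_sum(np.where(finite, v, 0.0), delta)
    counts = _window_sum(finite.astype(float), delta)
    out = np.full(v.shape, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    if edge_policy == "missing":
        out[:delta, :] = np.nan
        out[-delta:, :] = np.nan
        out[:, :delta] = np.nan
        out[:, -delta:] = np.nan
    return Grid(out, grid.row_offset, grid.col_offset)


def composite_score(
    indicator: Grid,
    mask: Grid,
    weights: tuple[float, float] = (2.0, 1.0),
    deltas: tuple[int, int] = (2, 3),
    edge_policy: str = "clip",
) -> Grid:
    """Weighted two-scale moving-average score, masked to one tissue.

    Returns ``w_small * MA(indicator, delta_small) + w_large *
    MA(indicator, delta_large)`` multiplied elementwise by ``mask``
    (the tissue's own indicator), so spots of the other tissue score
    exactly 0 and missing cells stay missing.
    """
    if not indicator.same_frame(mask):
        raise ValueError("indicator and mask grids do not share shape/offsets")
    w_small, w_large = weights
    d_small, d_large = deltas
    ma_small = moving_average(indicator, d_small, edge_policy)
    ma_large = moving_average(indicator, d_large, edge_policy)
    comp = w_small * ma_small.values + w_large * ma_large.values
    return Grid(comp * mask.values, indicator.row_offset, indicator.col_offset)


def _interval_ordinal(scores: np.ndarray, cuts: tuple[float, ...]) -> np.ndarray:
    """Count of cuts strictly below each positive score (0 for score 0).

    With descending cuts this realises the half-open intervals
    (cut_k, cut_{k-1}]: a score in (cuts[i], cuts[i-1]] gets ordinal
    len(cuts) - i.
    """
    ordinal = np.zeros(scores.shape, dtype=int)
    positive = scores > 0
    for cut in cuts:
        ordinal += (positive & (scores > cut)).astype(int)
    return ordinal


def assign_zones(
    tumor_score: Grid,
    parenchyma_score: Grid,
    barcodes: BarcodeGrid,
    params: ZonationParams | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Threshold the two score grids into ordinal zones.

    Tumor scores map to negative ordinals (score above the first cut ->
    the innermost tumor zone), parenchyma scores to non-negative ones;
    their sum indexes ``params.zone_names`` from inner tumor outwards.
    Returns the zone label grid (object array, None when missing) and
    the assignment table with one row per occupied cell: columns
    ``barcode``, ``zone``, ``row``, ``col`` in array coordinates.
    """
    params = params or ZonationParams()
    if not tumor_score.same_frame(parenchyma_score) or not tumor_score.same_frame(barcodes):
        raise ValueError("score and barcode grids do not share shape/offsets")
    ts, ps = tumor_score.values, parenchyma_score.values
    occupied = np.isfinite(ts) & np.isfinite(ps)
    if np.any(np.isfinite(ts) != np.isfinite(ps)):
        raise ValueError("tumor and parenchyma scores disagree on missing cells")
    both = occupied & (ts > 0) & (ps > 0)
    if both.any():
        i, j = np.argwhere(both)[0]
        raise ValueError(
            f"cell ({i + tumor_score.row_offset}, {j + tumor_score.col_offset}) "
            "has positive tumor and parenchyma scores; masks were not applied"
        )

    k_t = len(params.tumor_cuts)
    ord_t = -(_interval_ordinal(np.nan_to_num(ts), params.tumor_cuts) + (np.nan_to_num(ts) > 0))
    ord_p = _interval_ordinal(np.nan_to_num(ps), params.parenchyma_cuts)
    combined = ord_t + ord_p
    index = combined + k_t + 1
    if occupied.any() and (
        index[occupied].min() < 0 or index[occupied].max() >= len(params.zone_names)
    ):
        raise ValueError("combined ordinal outside the configured zone names")

    names = np.asarray(params.zone_names, dtype=object)
    zone_grid = np.full(ts.shape, None, dtype=object)
    zone_grid[occupied] = names[index[occupied]]

    ij = np.argwhere(occupied)
    table = pd.DataFrame(
        {
            "barcode": barcodes.values[occupied],
            "zone": zone_grid[occupied],
            "row": ij[:, 0] + tumor_score.row_offset,
            "col": ij[:, 1] + tumor_score.col_offset,
        }
    )
    table = table.sort_values(["row", "col"], kind="stable").reset_index(drop=True)
    return zone_grid, table


def annotate_spots_with_zones(
    spots: pd.DataFrame, tables: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Attach zone labels to a multi-sample spot table.

    The join is by (sample_id, barcode) — never by row order — so
    permuting either table leaves the result unchanged and barcodes
    shared between samples cannot cross-assign.  A spot whose barcode
    is absent from its sample's table raises.
    """
    out = spots.copy()
    out["zone"] = pd.Series([None] * len(out), index=out.index, dtype=object)
    for sample, group in spots.groupby("sample_id", sort=False):
        if sample not in tables:
            raise KeyError(f"no zone table for sample {sample!r}")
        table = tables[sample]
        mapping = dict(zip(table["barcode"], table["zone"]))
        missing = [b for b in group["barcode"] if b not in mapping]
        if missing:
            raise KeyError(
                f"barcodes missing from zone table of sample {sample!r}: {missing}"
            )
        out.loc[group.index, "zone"] = [mapping[b] for b in group["barcode"]]
    return out


def zonate_sample(
    spots: pd.DataFrame,
    params: ZonationParams | None = None,
    edge_policy: str = "clip",
) -> tuple[pd.DataFrame, dict[str, Grid]]:
    """Run the full zonation for one sample's spot table.

    Returns the zone assignment table and the intermediate grids
    (``tumor``, ``parenchyma``, ``tumor_score``, ``parenchyma_score``).
    """
    params = params or ZonationParams()
    tumor, parenchyma, barcodes = build_label_grids(spots)
    ts = composite_score(
        tumor, tumor, params.tumor_weights,
        (params.delta_small, params.delta_large), edge_policy,
    )
    ps = composite_score(
        parenchyma, parenchyma, params.parenchyma_weights,
        (params.delta_small, params.delta_large), edge_policy,
    )
    _, table = assign_zones(ts, ps, barcodes, params)
    grids = {
        "tumor": tumor,
        "parenchyma": parenchyma,
        "tumor_score": ts,
        "parenchyma_score": ps,
    }
    return table, grids


def zonate(
    spots: pd.DataFrame,
    params: ZonationParams | None = None,
    edge_policy: str = "clip",
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Zonate every sample independently and merge the labels back.

    Windows never cross sample borders: each sample's lattice is built
    and scored on its own, then zones are joined onto the input table
    by (sample_id, barcode).
    """
    tables: dict[str, pd.DataFrame] = {}
    for sample, group in spots.groupby("sample_id", sort=False):
        table, _ = zonate_sample(group, params, edge_policy)
        tables[str(sample)] = table
    annotated = annotate_spots_with_zones(spots, tables)
    return annotated, tables


def delta_sweep(
    tumor: Grid,
    deltas: tuple[int, ...] = (1, 2, 4, 8),
    weights: tuple[float, float] = (2.0, 1.0),
    edge_policy: str = "clip",
) -> dict[int, Grid]:
    """Tumor composite score at several window sizes, unmasked.

    For each delta ``d`` the score pairs windows of half-width ``d`` and
    ``d + 1`` with the given weights, mirroring the published window
    sweep; grids are returned without tissue masking so the smoothing
    behaviour at every lattice position is visible.
    """
    out: dict[int, Grid] = {}
    for d in deltas:
        ma_s = moving_average(tumor, d, edge_policy)
        ma_l = moving_average(tumor, d + 1, edge_policy)
        out[d] = Grid(
            weights[0] * ma_s.values + weights[1] * ma_l.values,
            tumor.row_offset,
            tumor.col_offset,
        )
    return out
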