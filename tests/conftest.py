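import numpy as np
import pandas as pd
import pytest

from spotzone import Grid


def brute_force_moving_average(values, delta, edge_policy="clip"):
    """Literal double-loop windowed mean, the independent oracle."""
    v = np.asarray(values, dtype=float)
    n, m = v.shape
    out = np.full((n, m), np.nan)
    for i in range(n):
        for j in range(m):
            if edge_policy == "missing" and (
                i < delta or j < delta or i >= n - delta or j >= m - delta
            ):
                continue
            window = v[max(i - delta, 0): i + delta + 1, max(j - delta, 0): j + delta + 1]
            vals = window[np.isfinite(window)]
            if vals.size:
                out[i, j] = vals.mean()
    return out


def spots_from_class_grid(class_grid, sample_id="s1", group="Ctrl"):
    """Spot table from a 2-D array of {0, 1, nan}; nan = no spot."""
    cg = np.asarray(class_grid, dtype=float)
    rows, cols = np.where(np.isfinite(cg))
    return pd.DataFrame(
        {
            "barcode": [f"{sample_id}-r{r}c{c}" for r, c in zip(rows, cols)],
            "sample_id": sample_id,
            "group": group,
            "array_row": rows,
            "array_col": cols,
            "tissue_class": cg[rows, cols].astype(int),
        }
    )


def full_grid_spots(n_rows, n_cols, tissue_class, **kwargs):
    """Fully occupied lattice; tissue_class is scalar or callable(r, c)."""
    cg = np.empty((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            cg[r, c] = tissue_class(r, c) if callable(tissue_class) else tissue_class
    return spots_from_class_grid(cg, **kwargs)


def half_plane_spots(n=40, cut=20, **kwargs):
    """Fully occupied square with tumor in columns < cut."""
    return full_grid_spots(n, n, lambda r, c: int(c < cut), **kwargs)


def random_class_grid(rng, max_side=15, missing_frac=0.3):
    n = rng.integers(3, max_side + 1)
    m = rng.integers(3, max_side + 1)
    cg = rng.integers(0, 2, size=(n, m)).astype(float)
    cg[rng.random((n, m)) < missing_frac] = np.nan
    if not np.isfinite(cg).any():
        cg[0, 0] = 1.0
    return cg


@pytest.fixture
def grid_factory():
    def make(values, **kwargs):
        return Grid(np.asarray(values, dtype=float), **kwargs)

    return make
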