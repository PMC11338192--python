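"""Parameter containers for zonation and QC.

Defaults reproduce the published protocol for mouse liver metastasis
sections profiled with Visium: window half-widths (delta) of 2 and 3
lattice layers, composite weights of (2, 1) on the tumor side and
(2, 0.1) on the parenchyma side, and score cuts chosen so that each
zone is roughly one spot layer (~100 um) thick.
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_ZONE_NAMES = (
    "Zone_A",  # inner tumor
    "Zone_B",
    "Zone_C",
    "Zone_D",  # tumor at the boundary
    "Zone_E",  # parenchyma at the boundary
    "Zone_F",
    "Zone_G",
    "Zone_H",  # distant parenchyma
)


@dataclass(frozen=True)
class ZonationParams:
    """Parameters of the moving-average zonation.

    The composite boundary-distance score of a spot is

        w_small * MA(indicator, delta_small) + w_large * MA(indicator, delta_large)

    masked to the spot's own tissue, where ``MA`` is the missing-aware
    mean over a square window of side ``2*delta + 1``.  The tumor score
    lies in (0, w_small + w_large] on tumor spots; the parenchyma score
    in (0, w_small + w_large] on parenchyma spots (2.1 with defaults).

    Cuts are descending score thresholds splitting each side into
    ``len(cuts) + 1`` ordinal zones; ``zone_names`` runs from the inner
    tumor outwards to the distant parenchyma and must have
    ``len(tumor_cuts) + len(parenchyma_cuts) + 2`` entries.  More zones
    can be introduced by supplying more cuts and names.
    """

    delta_small: int = 2
    delta_large: int = 3
    tumor_weights: tuple[float, float] = (2.0, 1.0)
    parenchyma_weights: tuple[float, float] = (2.0, 0.1)
    tumor_cuts: tuple[float, ...] = (2.96, 2.7, 2.3)
    parenchyma_cuts: tuple[float, ...] = (2.095, 1.91, 1.7)
    zone_names: tuple[str, ...] = DEFAULT_ZONE_NAMES

    def __post_init__(self) -> None:
        if self.delta_small < 1 or self.delta_large < 1:
            raise ValueError("deltas must be >= 1")
        for cuts, side in ((self.tumor_cuts, "tumor"), (self.parenchyma_cuts, "parenchyma")):
            if len(cuts) < 1:
                raise ValueError(f"{side}_cuts must not be empty")
            if any(c <= 0 for c in cuts):
                raise ValueError(f"{side}_cuts must be positive")
            if any(a <= b for a, b in zip(cuts, cuts[1:])):
                raise ValueError(f"{side}_cuts must be strictly decreasing")
        expected = len(self.tumor_cuts) + len(self.parenchyma_cuts) + 2
        if len(self.zone_names) != expected:
            raise ValueError(
                f"need {expected} zone names for "
                f"{len(self.tumor_cuts)} tumor and {len(self.parenchyma_cuts)} "
                f"parenchyma cuts, got {len(self.zone_names)}"
            )
        if len(set(self.zone_names)) != len(self.zone_names):
            raise ValueError("zone names must be unique")

    @property
    def n_tumor_zones(self) -> int:
        return len(self.tumor_cuts) + 1

    @property
    def n_parenchyma_zones(self) -> int:
        return len(self.parenchyma_cuts) + 1

    @property
    def tumor_score_max(self) -> float:
        return sum(self.tumor_weights)

    @property
    def parenchyma_score_max(self) -> float:
        return sum(self.parenchyma_weights)


@dataclass(frozen=True)
class QCParams:
    """Spot quality-control thresholds.

    ``min_features``/``max_pct_mito`` follow the protocol's defaults
    (more than 500 detected genes, less than 20% mitochondrial counts,
    strict inequalities as in the original filter expression; set
    ``inclusive`` to admit spots sitting exactly on a threshold).
    Patterns are anchored at the start of the gene symbol.
    """

    min_features: int = 500
    max_pct_mito: float = 20.0
    mito_pattern: str = "mt-"
    hb_pattern: str = "Hb.*-"
    inclusive: bool = False

    def __post_init__(self) -> None:
        if self.min_features < 0:
            raise ValueError("min_features must be >= 0")
        if not 0.0 <= self.max_pct_mito <= 100.0:
            raise ValueError("max_pct_mito must be in [0, 100]")
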