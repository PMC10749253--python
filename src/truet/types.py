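"""Shared containers passed between pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MARKERS = ("CD3", "CD4", "CD8")


@dataclass
class AnnotatedPatch:
    """One RGB IHC patch with its binary positive-cell mask.

    ``image`` is (H, W, 3) uint8; ``mask`` is (H, W) with values in {0, 1}.
    ``n_cells`` is the generator's ground-truth count of rendered positive
    cells (-1 when unknown, e.g. for patches read from disk).
    """

    image: np.ndarray
    mask: np.ndarray
    marker: str
    patient_id: str
    institution_id: str = ""
    n_cells: int = -1

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask shapes disagree")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        bad = np.setdiff1d(np.unique(self.mask), [0, 1])
        if bad.size:
            raise ValueError("mask values must be in {0, 1}")


@dataclass
class DensityRecord:
    """Per patient x marker cell count and density in cells/mm^2."""

    patient_id: str
    marker: str
    total_cells: int
    n_patches: int
    patch_height_px: int
    patch_width_px: int
    um_per_px: float
    density: float

    def __post_init__(self):
        if self.total_cells < 0 or self.n_patches < 1:
            raise ValueError("invalid counts")
        if (self.density == 0) != (self.total_cells == 0):
            raise ValueError("density must be zero iff total_cells is zero")


@dataclass
class StratificationResult:
    """Output of threshold/majority-vote survival stratification."""

    thresholds: dict
    status: "object"            # pandas Series: patient_id -> "High"/"Low"
    group_sizes: dict
    km_curves: dict             # group -> (times, survival) step arrays
    logrank_statistic: float | None
    logrank_p: float | None
    n_undetermined: int = 0
    flags: list = field(default_factory=list)
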