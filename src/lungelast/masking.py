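"""Parenchyma masking and per-lobe value extraction.

Vessels and tumors do not expand during respiration and are far stiffer
than parenchyma, so lung voxels at or above the attenuation threshold
(-700 HU by default; strictly-below convention) are excluded before any
elasticity statistic is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phantom import LOBE_LABELS, PARENCHYMA_HU_THRESHOLD

logger = logging.getLogger(__name__)


@dataclass
class ParenchymaMask:
    mask: np.ndarray       # 3D bool, subset of lung voxels
    threshold_hu: float
    n_excluded: int        # lung voxels removed by the threshold


def parenchyma_mask(
    hu_exhale: np.ndarray,
    lobe_labels: np.ndarray,
    threshold_hu: float = PARENCHYMA_HU_THRESHOLD,
) -> ParenchymaMask:
    """Keep lung voxels with HU strictly below the threshold.

    Voxels exactly at the threshold are excluded (strict ``<``).
    """
    hu = np.asarray(hu_exhale)
    labels = np.asarray(lobe_labels)
    if hu.shape != labels.shape:
        raise ValueError(
            f"grid mismatch: HU {hu.shape} vs lobe labels {labels.shape}"
        )
    lung = labels > 0
    mask = lung & (hu < threshold_hu)
    return ParenchymaMask(
        mask=mask,
        threshold_hu=float(threshold_hu),
        n_excluded=int(lung.sum() - mask.sum()),
    )


@dataclass
class LobarDistribution:
    """Multiset of parenchymal values (kPa) within one lobe, with summaries.

    Sample (n-1) standard deviation; 95th percentile by linear
    interpolation between order statistics. An empty lobe is flagged via
    ``n == 0`` (summaries are NaN) and is excluded downstream.
    """

    lobe_label: int
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def is_empty(self) -> bool:
        return self.n == 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.n else float("nan")

    @property
    def sd(self) -> float:
        if self.n < 2:
            return 0.0 if self.n == 1 else float("nan")
        return float(np.std(self.values, ddof=1))

    @property
    def p95(self) -> float:
        return float(np.percentile(self.values, 95)) if self.n else float("nan")


def lobar_values(
    value_map: np.ndarray,
    mask: ParenchymaMask,
    lobe_labels: np.ndarray,
) -> list[LobarDistribution]:
    """Partition masked voxel values by lobe label (labels 1-5)."""
    values = np.asarray(value_map)
    labels = np.asarray(lobe_labels)
    if values.shape != labels.shape or values.shape != mask.mask.shape:
        raise ValueError("grid mismatch between value map, mask and labels")
    out = []
    for lb in LOBE_LABELS:
        sel = mask.mask & (labels == lb)
        dist = LobarDistribution(lobe_label=lb, values=values[sel])
        if dist.is_empty:
            logger.warning(
                "lobe %d has no masked parenchymal voxels; flagged empty", lb
            )
        out.append(dist)
    return out
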