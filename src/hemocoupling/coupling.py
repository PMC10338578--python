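"""Hemodynamics-connectivity coupling: overlay masks and regional percentages.

A voxel is classified by combining its time-shift value with its
connectivity status:

* hemodynamic *lead*: lag < lead_threshold (default < -1 TR, strict);
* hemodynamic *lag*: lag > lag_threshold (default > +1 TR, strict);
* *high* / *low* connectivity: membership in the per-subject significantly
  high / low ICC masks.

The concordant combinations — lead∧high and lag∧low — index **coupling**
between hemodynamics and connectivity; the discordant ones — lag∧high and
lead∧low — index **uncoupling**.  On the default integer grid with a +/-3 TR
span, lead means lag_tr in {-3, -2} and lag means {+2, +3}: the +/-1 values
themselves are neutral because the inequalities are strict.  Each region's
index is the percentage of its gray-matter voxels falling in each class
(denominator: region ∩ GM voxel count), reported at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import IccMap
from .io import ParcellationAtlas, PipelineConfig, ValidationError
from .tsa import LagMap

__all__ = ["OverlayMasks", "COUPLING_CLASSES", "overlay_masks", "coupling_table"]

#: Class names in the order they appear in every output table.
COUPLING_CLASSES = ("pct_lead_hi", "pct_lag_lo", "pct_lag_hi", "pct_lead_lo")


@dataclass
class OverlayMasks:
    """Four disjoint boolean voxel classes on the TSA x ICC overlay."""

    lead_hi: np.ndarray   # coupled: lead + high connectivity
    lag_lo: np.ndarray    # coupled: lag + low connectivity
    lag_hi: np.ndarray    # uncoupled
    lead_lo: np.ndarray   # uncoupled

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"pct_lead_hi": self.lead_hi, "pct_lag_lo": self.lag_lo,
                "pct_lag_hi": self.lag_hi, "pct_lead_lo": self.lead_lo}

    def __post_init__(self) -> None:
        total = (self.lead_hi.astype(int) + self.lag_lo + self.lag_hi
                 + self.lead_lo)
        if total.max(initial=0) > 1:
            raise ValidationError("overlay classes must be disjoint")


def overlay_masks(lag: LagMap, icc: IccMap,
                  config: PipelineConfig) -> OverlayMasks:
    """Intersect lead/lag status with the high/low connectivity masks."""
    if lag.lag_tr.shape != icc.icc.shape:
        raise ValidationError(
            f"lag grid {lag.lag_tr.shape} and ICC grid {icc.icc.shape} differ"
        )
    if icc.hi_mask is None or icc.lo_mask is None:
        raise ValidationError("ICC map has no hi/lo masks; run threshold_icc first")
    base = lag.valid & icc.defined
    lead = base & (lag.lag_tr < config.lead_threshold_tr)
    lagging = base & (lag.lag_tr > config.lag_threshold_tr)
    return OverlayMasks(
        lead_hi=lead & icc.hi_mask,
        lag_lo=lagging & icc.lo_mask,
        lag_hi=lagging & icc.hi_mask,
        lead_lo=lead & icc.lo_mask,
    )


def coupling_table(masks: OverlayMasks, atlas: ParcellationAtlas,
                   gm_mask: np.ndarray | None = None,
                   subject_id: str | None = None) -> pd.DataFrame:
    """Per-ROI percentages of voxels in each overlay class.

    One row per region of the atlas ROI subset, columns
    ``pct_lead_hi, pct_lag_lo, pct_lag_hi, pct_lead_lo`` plus the
    region's GM voxel count ``n_voxels``.  Regions without GM voxels get
    NaN percentages and are flagged in the ``defined`` column.
    """
    gm = atlas.gm_mask if gm_mask is None else (gm_mask.astype(bool))
    class_masks = masks.as_dict()
    rows = []
    for rid in atlas.roi_subset:
        region = atlas.region_mask(rid) & gm
        n = int(region.sum())
        row: dict = {"region": rid, "n_voxels": n, "defined": n > 0}
        if subject_id is not None:
            row["subject_id"] = subject_id
        for name, cmask in class_masks.items():
            row[name] = 100.0 * int((cmask & region).sum()) / n if n else np.nan
        rows.append(row)
    cols = (["subject_id"] if subject_id is not None else []) + \
        ["region", "n_voxels", "defined", *COUPLING_CLASSES]
    return pd.DataFrame(rows)[cols]
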