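"""Domain types and on-disk artifact handling.

All volumes are NIfTI-1 (.nii / .nii.gz) read through nibabel; tabular
artifacts are tab-separated text with a header row; configuration is YAML or
JSON.  Voxel grids are addressed with 0-based integer indices everywhere in
the package; world (MNI mm) coordinates are derived from the affine only for
reporting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("hemocoupling")

#: Bounds of the symptom scales (scale minimum, scale maximum).
FSS_RANGE = (9.0, 63.0)
HADS_D_RANGE = (0.0, 21.0)

REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "fss", "hads_d", "tiv")
VALID_GROUPS = ("CIS", "RRMS", "HC")


class FormatError(ValueError):
    """An on-disk artifact does not have the expected structure."""


class ConfigError(ValueError):
    """A configuration value is missing or inconsistent."""


class ValidationError(ValueError):
    """Input contents violate a declared invariant."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable constants of the analysis.

    Defaults mirror the study protocol: a lag grid of +/-3 TR, coupling
    thresholds at +/-1 TR (strict inequalities), connectivity significance at
    p < .001 within subject, voxel-wise statistics at p < .001 uncorrected
    with 20-voxel cluster extent, region statistics at p < .01, a
    0.008-0.09 Hz passband and five noise principal components.
    """

    lag_max_tr: int = 3
    lead_threshold_tr: float = -1.0
    lag_threshold_tr: float = 1.0
    icc_p_threshold: float = 0.001
    voxel_p: float = 0.001
    cluster_min: int = 20
    region_p: float = 0.01
    band: tuple[float, float] = (0.008, 0.09)
    n_confound_pcs: int = 5
    graph_density: float | Sequence[float] = 0.15
    seed: int = 0
    n_discard: int = 5
    tr: float | None = None  # explicit TR overrides the NIfTI header
    rmax_min: float | None = None  # optional gate on the peak lag correlation
    cluster_connectivity: int = 18  # 6, 18 or 26
    icc_standardization: str = "gaussian"  # or "rank"
    eloc_weighted: bool = False
    subgroup_test: str = "welch"  # or "mannwhitney"

    def __post_init__(self) -> None:
        if self.lag_max_tr < 1:
            raise ConfigError("lag_max_tr must be >= 1")
        low, high = self.band
        if not (0.0 < low < high):
            raise ConfigError(f"band must satisfy 0 < low < high, got {self.band}")
        if not (self.lead_threshold_tr < self.lag_threshold_tr):
            raise ConfigError("lead_threshold_tr must be < lag_threshold_tr")
        if self.cluster_connectivity not in (6, 18, 26):
            raise ConfigError("cluster_connectivity must be one of 6, 18, 26")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        raw = raw or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["band"] = list(self.band)
        return out


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------

@dataclass
class BoldSeries:
    """One subject's 4D BOLD time series after volume discarding.

    ``data`` has shape (x, y, z, t); ``tr`` is seconds per volume;
    ``n_discard`` records how many leading volumes were dropped at load time
    (they are absent from ``data``); ``mask`` marks the analyzed voxels.
    """

    data: np.ndarray
    tr: float
    affine: np.ndarray
    mask: np.ndarray
    n_discard: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise FormatError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise FormatError("need at least 2 time points after discarding")
        if self.tr <= 0:
            raise ConfigError(f"TR must be positive, got {self.tr}")
        if self.mask.shape != self.data.shape[:3]:
            raise FormatError(
                f"mask shape {self.mask.shape} != spatial shape {self.data.shape[:3]}"
            )
        self.mask = self.mask.astype(bool)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return a (T, V) matrix of the series inside ``mask`` (default: own mask)."""
        m = self.mask if mask is None else (mask.astype(bool) & self.mask)
        return self.data[m].T

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return BoldSeries(data=data, tr=self.tr, affine=self.affine,
                          mask=self.mask, n_discard=self.n_discard)


@dataclass
class ParcellationAtlas:
    """Integer-labelled parcellation; 0 is background."""

    labels: np.ndarray
    region_ids: list[int]
    region_names: Mapping[int, str] = field(default_factory=dict)
    roi_subset: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        present = set(np.unique(self.labels[self.labels > 0]).astype(int).tolist())
        declared = set(int(i) for i in self.region_ids)
        if not present <= declared:
            raise ValidationError(
                f"labels present in image but not declared: {sorted(present - declared)}"
            )
        missing = [int(r) for r in self.roi_subset if int(r) not in declared]
        if missing:
            raise ValidationError(f"roi_subset ids absent from atlas: {missing}")
        self.region_ids = sorted(int(i) for i in self.region_ids)
        self.roi_subset = [int(i) for i in self.roi_subset]

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    @property
    def gm_mask(self) -> np.ndarray:
        """Union of all regions — the gray-matter analysis mask."""
        return self.labels > 0


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------

def load_bold(path: str | Path, config: PipelineConfig,
              mask: np.ndarray | None = None) -> BoldSeries:
    """Load a 4D NIfTI, drop the leading ``config.n_discard`` volumes.

    TR precedence: an explicit ``config.tr`` overrides the header pixdim.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {img.ndim}D")
    tr = config.tr
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ConfigError(
            f"{path}: TR missing or non-positive in header and no config override"
        )
    data = np.asarray(img.dataobj, dtype=np.float64)
    n = config.n_discard
    if n >= data.shape[3] - 1:
        raise FormatError(f"{path}: discarding {n} of {data.shape[3]} volumes leaves <2")
    data = data[..., n:]
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    series = BoldSeries(data=data, tr=tr, affine=np.asarray(img.affine),
                        mask=mask, n_discard=n)
    logger.info("loaded %s: shape %s, TR %.4f s, discarded %d volumes",
                path, data.shape, tr, n)
    return series


def save_bold(series: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float64), series.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = series.tr
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {img.ndim}D")
    return np.asarray(img.dataobj) > 0


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_atlas(path: str | Path, roi_list: Sequence[int] | None = None,
               region_names: Mapping[int, str] | None = None) -> ParcellationAtlas:
    """Load an integer-labelled parcellation and validate the ROI subset."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D atlas, got {img.ndim}D")
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"{path}: atlas labels are not integer-valued")
    labels = np.round(data).astype(np.int32)
    region_ids = sorted(int(v) for v in np.unique(labels) if v > 0)
    roi_subset = list(roi_list) if roi_list is not None else list(region_ids)
    missing = [r for r in roi_subset if r not in region_ids]
    if missing:
        raise ValidationError(f"{path}: roi ids absent from atlas image: {missing}")
    return ParcellationAtlas(labels=labels, region_ids=region_ids,
                             region_names=dict(region_names or {}),
                             roi_subset=roi_subset)


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Load the subject covariate table (TSV).

    Columns: subject_id, group (CIS/RRMS/HC), fss, hads_d, tiv, and optional
    gm_volume / lesion_volume.  Missing numeric cells stay missing (NaN);
    control rows without symptom scores are legal and are excluded listwise
    from symptom models downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    missing_cols = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"{path}: duplicate subject ids {dupes}")
    bad_groups = sorted(set(df["group"]) - set(VALID_GROUPS))
    if bad_groups:
        raise ValidationError(f"{path}: unknown group labels {bad_groups}")
    for col in ("fss", "hads_d", "tiv", "gm_volume", "lesion_volume"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col, (lo, hi) in (("fss", FSS_RANGE), ("hads_d", HADS_D_RANGE)):
        vals = df[col].dropna()
        bad = vals[(vals < lo) | (vals > hi)]
        if len(bad):
            raise ValidationError(
                f"{path}: {col} values outside scale [{lo}, {hi}]: {bad.tolist()}"
            )
    if (df["tiv"].dropna() <= 0).any():
        raise ValidationError(f"{path}: non-positive tiv values")
    return df


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def voxel_to_world(affine: np.ndarray, ijk: Sequence[int]) -> np.ndarray:
    """Map a 0-based voxel index to world (mm) coordinates."""
    v = np.asarray([*ijk, 1.0], dtype=float)
    return (np.asarray(affine) @ v)[:3]
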