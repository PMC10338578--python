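"""Time shift analysis: voxel-wise hemodynamic lag by lagged cross-correlation.

Each voxel series is correlated with a venous reference signal at every
integer lag on a symmetric grid (default +/-3 TR) and assigned the lag of the
highest correlation.  Sign convention: **positive lag = the voxel series is
delayed relative to the venous reference** ("hemodynamic lag"); negative
values index hemodynamic lead.  Correlations are computed on the truncated
overlap of the shifted series — never circularly — so temporally unrelated
samples are never paired.

Tie-breaking when two lags give exactly equal correlation: the smaller
absolute lag wins; among equal magnitudes the negative one.  This biases
toward the null value 0 and is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BoldSeries, PipelineConfig, ValidationError

__all__ = ["LagMap", "reference_signal", "lagged_correlation", "lag_map",
           "VALID_OK", "INVALID_ZERO_VARIANCE", "INVALID_LOW_RMAX"]

VALID_OK = 0
INVALID_ZERO_VARIANCE = 1
INVALID_LOW_RMAX = 2


@dataclass
class LagMap:
    """Per-voxel integer time shifts (TR units) and their peak correlations."""

    lag_tr: np.ndarray          # int grid; defined only where valid
    rmax: np.ndarray            # correlation at the selected lag
    valid: np.ndarray           # bool grid
    reason: np.ndarray          # per-voxel invalidity code (0 = valid)
    lag_max_tr: int = 3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.abs(self.lag_tr[self.valid]).max(initial=0) > self.lag_max_tr:
            raise ValidationError("lag values exceed the configured grid bound")

    @property
    def lag_seconds(self) -> np.ndarray:
        tr = self.meta.get("tr")
        if tr is None:
            raise ValidationError("no TR recorded in LagMap metadata")
        return self.lag_tr * float(tr)


def reference_signal(bold: BoldSeries, venous_mask: np.ndarray) -> np.ndarray:
    """Mean series over the venous-sinus mask, variance-normalized."""
    m = venous_mask.astype(bool) & bold.mask
    if not m.any():
        raise ValidationError("venous mask does not intersect the analysis mask")
    ref = bold.data[m].mean(axis=0)
    ref = ref - ref.mean()
    sd = ref.std()
    if sd == 0:
        raise ValidationError("venous reference signal has zero variance")
    return ref / sd


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return np.nan
    return float((a @ b) / denom)


def lagged_correlation(x: np.ndarray, ref: np.ndarray, lag: int,
                       min_overlap: int = 10) -> float:
    """Pearson r between ``x`` shifted by ``lag`` TR and ``ref``.

    Positive ``lag`` treats ``x`` as delayed: ``x[lag:]`` is paired with
    ``ref[:-lag]``.  Only the overlapping samples enter the correlation.
    Returns NaN when either side has zero variance on the overlap.
    """
    x = np.asarray(x, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if x.shape != ref.shape:
        raise ValidationError("series and reference must have equal length")
    t = len(x)
    if t - abs(lag) < min_overlap:
        raise ValidationError(
            f"overlap {t - abs(lag)} below minimum {min_overlap} for lag {lag}"
        )
    if lag > 0:
        return _pearson(x[lag:], ref[:t - lag])
    if lag < 0:
        return _pearson(x[:t + lag], ref[-lag:])
    return _pearson(x, ref)


def _lag_order(lag_max: int) -> list[int]:
    """Lag evaluation order implementing the tie-break: |lag| asc, negative first."""
    return sorted(range(-lag_max, lag_max + 1), key=lambda l: (abs(l), l))


def lag_map(bold: BoldSeries, ref: np.ndarray, config: PipelineConfig,
            mask: np.ndarray | None = None,
            refine_parabolic: bool = False) -> LagMap:
    """Assign every masked voxel the lag of its peak correlation with ``ref``.

    The whole lag grid is evaluated for every voxel (vectorized over voxels,
    one pass per lag).  Voxels whose series has zero variance on any overlap
    window are marked invalid with a reason code; an optional ``rmax_min``
    gate (off by default) invalidates voxels whose peak correlation is weak.
    """
    m = bold.mask if mask is None else (mask.astype(bool) & bold.mask)
    t = bold.n_timepoints
    lmax = config.lag_max_tr
    if t - lmax < 10:
        raise ValidationError(f"series too short ({t}) for lag grid +/-{lmax}")
    y = bold.data[m].T.astype(np.float64)  # (T, V)
    n_vox = y.shape[1]

    best_r = np.full(n_vox, -np.inf)
    best_lag = np.zeros(n_vox, dtype=np.int16)
    degenerate = np.zeros(n_vox, dtype=bool)
    r_by_lag = {} if refine_parabolic else None

    for lag in _lag_order(lmax):
        if lag > 0:
            xs, rs = y[lag:], ref[:t - lag]
        elif lag < 0:
            xs, rs = y[:t + lag], ref[-lag:]
        else:
            xs, rs = y, ref
        xc = xs - xs.mean(axis=0)
        rc = rs - rs.mean()
        xnorm = np.sqrt(np.einsum("tv,tv->v", xc, xc))
        rnorm = np.sqrt(rc @ rc)
        bad = (xnorm == 0) | (rnorm == 0)
        degenerate |= bad
        denom = np.where(bad, 1.0, xnorm * rnorm)
        r = (rc @ xc) / denom
        r[bad] = -np.inf
        if r_by_lag is not None:
            r_by_lag[lag] = r
        better = r > best_r  # strict: ties keep the earlier (null-ward) lag
        best_r[better] = r[better]
        best_lag[better] = lag

    valid_flat = ~degenerate
    reason_flat = np.where(degenerate, INVALID_ZERO_VARIANCE, VALID_OK)
    if config.rmax_min is not None:
        weak = valid_flat & (best_r < config.rmax_min)
        valid_flat &= ~weak
        reason_flat[weak] = INVALID_LOW_RMAX

    shape = bold.spatial_shape
    lag_grid = np.zeros(shape, dtype=np.int16)
    r_grid = np.zeros(shape, dtype=np.float64)
    valid = np.zeros(shape, dtype=bool)
    reason = np.zeros(shape, dtype=np.int8)
    lag_grid[m] = np.where(valid_flat, best_lag, 0)
    r_grid[m] = np.where(valid_flat, best_r, 0.0)
    valid[m] = valid_flat
    reason[m] = reason_flat
    out = LagMap(lag_tr=lag_grid, rmax=r_grid, valid=valid, reason=reason,
                 lag_max_tr=lmax,
                 meta={"tr": bold.tr,
                       "sign_convention":
                           "positive = voxel delayed vs venous reference"})
    if refine_parabolic:
        refined = best_lag.astype(np.float64)
        interior = valid_flat & (np.abs(best_lag) < lmax)
        idx = np.flatnonzero(interior)
        for i in idx:
            l0 = int(best_lag[i])
            rm, r0, rp = r_by_lag[l0 - 1][i], r_by_lag[l0][i], r_by_lag[l0 + 1][i]
            denom_p = rm - 2.0 * r0 + rp
            if denom_p < 0:  # proper concave peak
                refined[i] = l0 + 0.5 * (rm - rp) / denom_p
        grid = np.zeros(shape, dtype=np.float64)
        grid[m] = np.where(valid_flat, refined, 0.0)
        out.meta["lag_refined"] = grid
    return out
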