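"""Denoising of the BOLD series: detrend, confound regression, bandpass.

Two variants feed the two downstream branches:

* ``full`` — aCompCor-style: the leading principal components of the
  combined white-matter + CSF compartment, plus their first-order
  derivatives, are regressed out.  Used before intrinsic-connectivity
  mapping.
* ``csf_only`` — only the mean CSF signal is removed, so that genuine
  gray-matter and venous timing information survives for the lag analysis.

The filter is a 4th-order Butterworth applied forward-backward (zero-phase):
the lag analysis measures timing, and a causal filter would inject a phase
delay of its own.  Processing order is detrend -> confound regression ->
bandpass, so the regression cannot reintroduce out-of-band energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import BoldSeries, ConfigError, ValidationError

__all__ = [
    "ConfoundSet",
    "extract_compcor",
    "mean_signal_confound",
    "regress_confounds",
    "detrend_bandpass",
    "denoise",
]


@dataclass
class ConfoundSet:
    """A T x k matrix of nuisance regressors with per-column labels."""

    regressors: np.ndarray
    names: list[str]
    variant: str  # "full" or "csf_only"

    def __post_init__(self) -> None:
        if self.regressors.ndim != 2:
            raise ValidationError("regressors must be a 2D (T, k) matrix")
        if self.regressors.shape[1] != len(self.names):
            raise ValidationError("one name per confound column required")
        if self.variant not in ("full", "csf_only"):
            raise ValidationError(f"unknown confound variant {self.variant!r}")
        centered = self.regressors - self.regressors.mean(axis=0)
        rank = np.linalg.matrix_rank(centered, tol=1e-10)
        if rank < centered.shape[1]:
            raise ValidationError(
                f"confound columns linearly dependent after centering "
                f"(rank {rank} < {centered.shape[1]})"
            )

    @property
    def n_timepoints(self) -> int:
        return self.regressors.shape[0]


def _backward_difference(columns: np.ndarray) -> np.ndarray:
    """First-order backward difference, leading element zero-padded."""
    deriv = np.zeros_like(columns)
    deriv[1:] = np.diff(columns, axis=0)
    return deriv


def _fix_sign(components: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (deterministic sign)."""
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def extract_compcor(bold: BoldSeries, noise_mask: np.ndarray,
                    n_pcs: int = 5, include_derivatives: bool = True) -> ConfoundSet:
    """Principal components of the noise-compartment series (aCompCor).

    Each voxel series inside ``noise_mask`` is mean-centered and scaled to
    unit variance; the left singular vectors of the resulting (T, V) matrix
    are the component time courses.  With derivatives the set has
    ``2 * n_pcs`` columns; all columns are unit-normalized.
    """
    m = noise_mask.astype(bool) & bold.mask
    n_vox = int(m.sum())
    if n_vox == 0:
        raise ValidationError("noise mask is empty (no overlap with analysis mask)")
    t = bold.n_timepoints
    if n_pcs >= min(t, n_vox):
        raise ValidationError(
            f"n_pcs={n_pcs} must be < min(T={t}, voxels={n_vox})"
        )
    x = bold.data[m].T.astype(np.float64)  # (T, V)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    achievable = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if achievable < n_pcs:
        raise ValidationError(
            f"noise compartment rank {achievable} < requested {n_pcs} components"
        )
    comps = _fix_sign(u[:, :n_pcs])
    cols = [comps]
    names = [f"compcor_{i + 1}" for i in range(n_pcs)]
    if include_derivatives:
        deriv = _backward_difference(comps)
        norms = np.linalg.norm(deriv, axis=0)
        norms[norms == 0] = 1.0
        cols.append(deriv / norms)
        names += [f"compcor_{i + 1}_deriv" for i in range(n_pcs)]
    regs = np.column_stack(cols)
    regs = regs / np.linalg.norm(regs, axis=0)
    return ConfoundSet(regressors=regs, names=names, variant="full")


def mean_signal_confound(bold: BoldSeries, mask: np.ndarray,
                         name: str = "csf_mean") -> ConfoundSet:
    """Mean time series of a compartment as a single confound column."""
    m = mask.astype(bool) & bold.mask
    if not m.any():
        raise ValidationError("compartment mask is empty")
    ts = bold.data[m].mean(axis=0)
    ts = ts - ts.mean()
    norm = np.linalg.norm(ts)
    if norm == 0:
        raise ValidationError("compartment mean signal has zero variance")
    return ConfoundSet(regressors=(ts / norm)[:, None], names=[name],
                       variant="csf_only")


def regress_confounds(bold: BoldSeries, confounds: ConfoundSet) -> BoldSeries:
    """Replace every voxel series with its residual against [1 | confounds]."""
    if confounds.n_timepoints != bold.n_timepoints:
        raise ValidationError(
            f"confound rows {confounds.n_timepoints} != time points {bold.n_timepoints}"
        )
    design = np.column_stack([np.ones(bold.n_timepoints), confounds.regressors])
    y = bold.data[bold.mask].T  # (T, V)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    out = np.zeros_like(bold.data)
    out[bold.mask] = resid.T
    return bold.with_data(out)


def detrend_bandpass(bold: BoldSeries, band: tuple[float, float]) -> BoldSeries:
    """Linear detrend then zero-phase Butterworth bandpass, per voxel."""
    low, high = band
    nyquist = 0.5 / bold.tr
    if not (0.0 < low < high < nyquist):
        raise ConfigError(
            f"band {band} must lie inside (0, Nyquist={nyquist:.4f} Hz)"
        )
    y = bold.data[bold.mask]  # (V, T)
    y = signal.detrend(y, axis=1, type="linear")
    b, a = signal.butter(4, [low, high], btype="bandpass", fs=1.0 / bold.tr)
    # Gustafsson initial conditions minimize forward-backward edge
    # transients, which matter because downstream lag estimation is a
    # timing measurement.
    filtered = signal.filtfilt(b, a, y, axis=1, method="gust")
    out = np.zeros_like(bold.data)
    out[bold.mask] = filtered
    return bold.with_data(out)


def denoise(bold: BoldSeries, wm_mask: np.ndarray | None,
            csf_mask: np.ndarray, variant: str,
            band: tuple[float, float], n_pcs: int = 5) -> BoldSeries:
    """Full denoising chain for one variant.

    ``full`` builds aCompCor confounds from WM ∪ CSF; ``csf_only`` uses the
    mean CSF signal alone and never touches WM or GM compartments.
    """
    detrended = bold.with_data(
        _detrend_only(bold)
    )
    if variant == "full":
        if wm_mask is None:
            raise ValidationError("full variant requires a WM mask")
        noise_mask = wm_mask.astype(bool) | csf_mask.astype(bool)
        confounds = extract_compcor(detrended, noise_mask, n_pcs=n_pcs)
    elif variant == "csf_only":
        confounds = mean_signal_confound(detrended, csf_mask)
    else:
        raise ConfigError(f"unknown denoising variant {variant!r}")
    regressed = regress_confounds(detrended, confounds)
    return detrend_bandpass(regressed, band)


def _detrend_only(bold: BoldSeries) -> np.ndarray:
    out = np.zeros_like(bold.data)
    out[bold.mask] = signal.detrend(bold.data[bold.mask], axis=1, type="linear")
    return out
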