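"""Synthetic resting-state cohorts with planted ground truth.

Every pipeline stage is exercised against data whose answers are known by
construction:

* a band-limited latent drives the venous compartment and, shifted by each
  region's planted lag, the gray-matter voxels (the lag analysis must
  recover the shifts);
* regions share per-block latent signals plus a global component, which
  controls intrinsic connectivity; "high" blocks share more, planted
  *uncoupled-class* voxels share almost nothing while still carrying a
  delayed copy of the venous latent (so they are classified lag + low-ICC);
* WM and CSF compartments carry independent nuisance latents, so confound
  regression removes something real without touching the gray-matter
  signals;
* symptom scores follow the score distributions of an early-MS cohort, and
  planted region-metric associations realize the requested sample
  correlation exactly (score component plus orthogonalized noise, both
  orthogonal to the intracranial-volume nuisance) before pipeline
  measurement noise.

Latents are continuous sums of sinusoids with frequencies strictly inside
the analysis passband, so planted timing survives filtering and non-integer
lags are possible even though the estimator is integer-valued.  All
randomness flows through numpy Generators seeded from a single root seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import BoldSeries, ParcellationAtlas, ValidationError, save_bold, save_cohort, save_volume
from .stats import _ols_residuals, residualized_scores

__all__ = ["RegionSpec", "EffectSpec", "SimSpec", "SubjectData", "CohortSim",
           "simulate_subject", "simulate_cohort", "build_geometry",
           "gaussian_smooth"]


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """One parcel: its planted lag (TR units), connectivity block and level."""

    id: int
    lag_tr: float = 0.0
    block: int | None = None           # defaults to own id
    icc_level: str = "normal"          # low | normal | high

    def __post_init__(self) -> None:
        if self.block is None:
            self.block = self.id
        if self.icc_level not in ("low", "normal", "high"):
            raise ValidationError(f"bad icc_level {self.icc_level!r}")


@dataclass
class EffectSpec:
    """A planted linear association between a regional metric and a score."""

    region: int
    metric: str                         # pct_lag_lo | lag | icc | bc
    rho: float
    score: str = "fss_resid"            # fss_resid | hads_resid
    group: str = "CIS"

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValidationError("|rho| must be < 1")
        if self.metric not in ("pct_lag_lo", "lag", "icc", "bc"):
            raise ValidationError(f"unsupported planted metric {self.metric!r}")
        if self.score not in ("fss_resid", "hads_resid"):
            raise ValidationError(f"unsupported score {self.score!r}")


def default_regions(n: int = 12) -> list[RegionSpec]:
    """Parcels with a moderate lag structure spanning +/-1 TR.

    Keeping normal-tissue lags within +/-1 TR leaves the > +1 TR range free
    for the planted delayed-and-disconnected voxel class, whose detectability
    would otherwise be diluted by whole regions sharing its timing.
    """
    lags = [0, -1, 1] * ((n + 2) // 3)
    return [RegionSpec(id=i + 1, lag_tr=float(lags[i])) for i in range(n)]


@dataclass
class SimSpec:
    """Full description of a synthetic cohort.

    The default geometry is desk-scale: a 24 x 24 x 16 grid, 150 volumes at
    TR 2.3 s (145 analyzed after discarding), 12 parcels of which 6 form the
    ROI subset, and group sizes matching an early-MS study cohort
    (24 CIS, 29 RR-MS, 39 controls).  Amplitudes are expressed relative to
    the venous latent (amplitude 1): the default white-noise level 0.28
    makes the structured-to-noise amplitude ratio ~5 for a normal
    gray-matter voxel.
    """

    shape: tuple[int, int, int] = (24, 24, 16)
    region_grid: tuple[int, int] = (3, 4)   # x-blocks x y-blocks of parcels
    tr: float = 2.3
    n_volumes: int = 150
    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"CIS": 24, "RRMS": 29, "HC": 39})
    regions: list[RegionSpec] = field(default_factory=default_regions)
    roi_subset: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    effects: list[EffectSpec] = field(default_factory=list)
    band: tuple[float, float] = (0.012, 0.078)
    noise_sd: float = 0.28
    amp_ref: float = 1.0               # venous latent in GM voxels
    amp_block: float = 1.0             # shared block signal, "normal" level
    amp_global: float = 0.8            # global GM component
    icc_high_global: float = 1.3       # global-share multiplier, "high" blocks
    icc_low_global: float = 0.2        # global-share multiplier, "low" blocks
    amp_block_high: float = 0.3        # private block signal in "high" blocks
    amp_block_low: float = 2.0         # private block signal in "low" blocks
    alpha_uncoupled: float = 0.65      # delayed-reference share in planted class voxels
    uncoupled_lag_tr: float = 3.0      # planted lag of the lag+low-ICC class
    q_base: float = 0.03               # mean planted-class fraction per region
    q_sd: float = 0.015                # between-subject spread of the fraction
    q_base_effect: float = 0.07        # mean fraction in a planted-effect region
    q_sd_effect: float = 0.022         # spread of the fraction in that region
    q_max: float = 0.14                # per-region cap; the GM-wide planted mass
                                       # must stay well under ~9.5% (Chebyshev bound
                                       # on the |z|>3.09 tail), which the small
                                       # q_base keeps true
    n_sinusoids: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValidationError("region ids must be unique")
        n_parcels = self.region_grid[0] * self.region_grid[1]
        if len(ids) != n_parcels:
            raise ValidationError(
                f"region_grid {self.region_grid} implies {n_parcels} parcels "
                f"but {len(ids)} region specs given")
        if not set(self.roi_subset) <= set(ids):
            raise ValidationError("roi_subset must be a subset of region ids")
        for r in self.regions:
            if abs(r.lag_tr) * self.tr >= self.n_volumes * self.tr / 4:
                raise ValidationError(f"planted lag of region {r.id} too large")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_subjects"] = dict(self.n_subjects)
        d["shape"] = list(self.shape)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimSpec":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        d["band"] = tuple(d["band"])
        d["regions"] = [RegionSpec(**r) for r in d["regions"]]
        d["effects"] = [EffectSpec(**e) for e in d["effects"]]
        return cls(**d)

    @classmethod
    def compact(cls, **overrides) -> "SimSpec":
        """Small geometry for fast simulation studies (12 x 12 x 8 grid)."""
        defaults: dict = {"shape": (12, 12, 8)}
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def coupling_cohort(cls, rho: float = -0.55, n: int = 24,
                        region: int = 4, score: str = "fss_resid",
                        seed: int = 0, **overrides) -> "SimSpec":
        """Patient cohort with one region's delayed+disconnected percentage
        tracking a residualized symptom score.

        Six large parcels on a compact grid, homogeneous normal-tissue lags
        (all 0) so the planted +3 TR class is the only delayed population,
        and an exact-sample-correlation effect in ``region``.
        """
        defaults: dict = dict(
            shape=(12, 12, 8), region_grid=(2, 3),
            regions=[RegionSpec(id=i + 1, lag_tr=0.0) for i in range(6)],
            roi_subset=[1, 2, 3, 4, 5, 6],
            n_subjects={"CIS": n},
            effects=[EffectSpec(region=region, metric="pct_lag_lo", rho=rho,
                                score=score, group="CIS")],
            seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def build_geometry(spec: SimSpec) -> dict:
    """Deterministic masks and atlas for a grid shape.

    Bottom z-slabs are CSF then WM; the remainder is gray matter except a
    small corner column acting as the venous sinus.  GM is partitioned into
    rectangular parcels (``region_grid`` x-blocks x y-blocks).
    """
    nx, ny, nz = spec.shape
    bx, by = spec.region_grid
    if nx < 2 * bx or ny < 2 * by or nz < 4:
        raise ValidationError(f"grid {spec.shape} too small for the geometry")
    z1 = max(1, nz // 8)
    z2 = 2 * z1
    csf = np.zeros(spec.shape, bool)
    wm = np.zeros(spec.shape, bool)
    venous = np.zeros(spec.shape, bool)
    csf[:, :, :z1] = True
    wm[:, :, z1:z2] = True
    venous[:2, :2, z2:] = True

    labels = np.zeros(spec.shape, np.int32)
    xb = np.minimum(np.arange(nx) * bx // nx, bx - 1)
    yb = np.minimum(np.arange(ny) * by // ny, by - 1)
    region_of = xb[:, None] * by + yb[None, :] + 1
    labels[:, :, z2:] = region_of[:, :, None]
    labels[venous] = 0

    ids = sorted(int(v) for v in np.unique(labels) if v > 0)
    spec_ids = [r.id for r in spec.regions]
    if ids != sorted(spec_ids):
        raise ValidationError(
            f"geometry produced regions {ids} but spec declares {sorted(spec_ids)}"
        )
    atlas = ParcellationAtlas(
        labels=labels, region_ids=ids,
        region_names={i: f"parcel_{i:02d}" for i in ids},
        roi_subset=list(spec.roi_subset))
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    return {"atlas": atlas, "gm": labels > 0, "wm": wm, "csf": csf,
            "venous": venous, "affine": affine}


# ---------------------------------------------------------------------------
# Band-limited latents
# ---------------------------------------------------------------------------

class BandLimitedSignal:
    """Continuous random signal with all spectral mass inside a band.

    A sum of ``n`` sinusoids with frequencies drawn uniformly inside the
    band, unit-variance on average; evaluable at arbitrary (shifted) times,
    which is how non-integer planted lags are realized.
    """

    def __init__(self, rng: np.random.Generator, band: tuple[float, float],
                 n: int = 40):
        self.freqs = rng.uniform(band[0], band[1], n)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, n)
        self.amps = rng.rayleigh(1.0, n)
        self.amps *= np.sqrt(2.0 / (self.amps @ self.amps))

    def __call__(self, t: np.ndarray) -> np.ndarray:
        arg = 2.0 * np.pi * self.freqs[:, None] * t[None, :] + self.phases[:, None]
        return self.amps @ np.cos(arg)


# ---------------------------------------------------------------------------
# Subject simulation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    bold: BoldSeries
    atlas: ParcellationAtlas
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    venous: np.ndarray
    truth: dict


def simulate_subject(spec: SimSpec, seed: int,
                     q_by_region: Mapping[int, float] | None = None,
                     lag_overrides: Mapping[int, float] | None = None,
                     block_amp_overrides: Mapping[int, float] | None = None,
                     global_share_overrides: Mapping[int, float] | None = None,
                     block_mixing: Mapping[int, float] | None = None
                     ) -> SubjectData:
    """Generate one subject's 4D volume and masks; fully seed-determined.

    ``q_by_region`` plants, per region, the fraction of voxels in the
    delayed + disconnected class; the overrides adjust region lag, block
    amplitude, or cross-block mixing (for the planted-effect machinery).
    """
    rng = np.random.default_rng(seed)
    geo = build_geometry(spec)
    atlas: ParcellationAtlas = geo["atlas"]
    t = np.arange(spec.n_volumes) * spec.tr
    band, n_sin = spec.band, spec.n_sinusoids

    s_ref = BandLimitedSignal(rng, band, n_sin)
    h_global = BandLimitedSignal(rng, band, n_sin)
    blocks = sorted({r.block for r in spec.regions})
    g_block = {b: BandLimitedSignal(rng, band, n_sin) for b in blocks}
    wm_latent = BandLimitedSignal(rng, band, n_sin)
    csf_latent = BandLimitedSignal(rng, band, n_sin)

    data = np.zeros((*spec.shape, spec.n_volumes))
    data[geo["venous"]] = s_ref(t) + 0.05 * rng.standard_normal(
        (int(geo["venous"].sum()), spec.n_volumes))
    for comp, latent in (("wm", wm_latent), ("csf", csf_latent)):
        m = geo[comp]
        n_vox = int(m.sum())
        data[m] = (latent(t)[None, :]
                   + spec.noise_sd * rng.standard_normal((n_vox, spec.n_volumes)))

    h_t = h_global(t)
    truth_q: dict[int, float] = {}
    truth_planted: dict[int, int] = {}
    for region in spec.regions:
        m = atlas.region_mask(region.id)
        n_vox = int(m.sum())
        if n_vox == 0:
            continue
        lag = float((lag_overrides or {}).get(region.id, region.lag_tr))
        # Connectivity level works mostly through dilution: a region with a
        # big *private* block signal correlates weakly with the rest of gray
        # matter (low ICC); a region with little private signal rides the
        # shared components and correlates broadly (high ICC).
        amp_b = {"low": spec.amp_block_low, "normal": spec.amp_block,
                 "high": spec.amp_block_high}[region.icc_level]
        amp_b = float((block_amp_overrides or {}).get(region.id, amp_b))
        c_mult = {"low": spec.icc_low_global, "normal": 1.0,
                  "high": spec.icc_high_global}[region.icc_level]
        c_mult = float((global_share_overrides or {}).get(region.id, c_mult))
        base = (spec.amp_ref * s_ref(t - lag * spec.tr)
                + amp_b * g_block[region.block](t)
                + c_mult * spec.amp_global * h_t)
        mix = float((block_mixing or {}).get(region.id, 0.0))
        if mix > 0:  # couple this region into every other block's signal
            others = [b for b in blocks if b != region.block]
            base = base + mix * np.mean([g_block[b](t) for b in others], axis=0)
        vox = np.tile(base, (n_vox, 1))

        q = float((q_by_region or {}).get(region.id, 0.0))
        n_planted = int(round(np.clip(q, 0.0, 1.0) * n_vox))
        if n_planted:
            chosen = rng.choice(n_vox, size=n_planted, replace=False)
            alpha = spec.alpha_uncoupled
            shifted = s_ref(t - spec.uncoupled_lag_tr * spec.tr)
            for c in chosen:
                private = BandLimitedSignal(rng, band, n_sin)
                vox[c] = alpha * shifted + np.sqrt(1 - alpha ** 2) * private(t)
        truth_q[region.id] = n_planted / n_vox
        truth_planted[region.id] = n_planted
        vox += spec.noise_sd * rng.standard_normal((n_vox, spec.n_volumes))
        data[m] = vox

    mask = geo["gm"] | geo["wm"] | geo["csf"] | geo["venous"]
    bold = BoldSeries(data=data, tr=spec.tr, affine=geo["affine"], mask=mask,
                      n_discard=0)
    truth = {"seed": int(seed),
             "region_lags": {r.id: float((lag_overrides or {}).get(r.id, r.lag_tr))
                             for r in spec.regions},
             "planted_fraction": truth_q,
             "planted_count": truth_planted,
             "uncoupled_lag_tr": spec.uncoupled_lag_tr}
    return SubjectData(bold=bold, atlas=atlas, gm=geo["gm"], wm=geo["wm"],
                       csf=geo["csf"], venous=geo["venous"], truth=truth)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

_SCORE_PARAMS = {  # group -> (fss mean, fss sd, hads mean, hads sd, tiv mean, tiv sd)
    "CIS": (33.1, 15.9, 4.6, 3.1, 1333.7, 146.4),
    "RRMS": (42.6, 15.0, 5.8, 2.6, 1356.4, 123.4),
    "HC": (np.nan, np.nan, np.nan, np.nan, 1387.5, 140.4),
}
_VOLUME_PARAMS = {  # group -> (gm mean, gm sd, lesion mean, lesion sd)
    "CIS": (668.0, 83.0, 4.5, 6.1),
    "RRMS": (659.9, 62.1, 11.6, 15.9),
    "HC": (684.1, 60.2, 0.0, 0.0),
}
_SYMPTOM_CORR = 0.4  # generative correlation between raw FSS and HADS-D


def _draw_covariates(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for group, n in spec.n_subjects.items():
        fm, fs, hm, hs, tm, ts = _SCORE_PARAMS[group]
        gm_m, gm_s, le_m, le_s = _VOLUME_PARAMS[group]
        for i in range(n):
            sid = f"{group.lower()}{i + 1:03d}"
            if np.isnan(fm):
                fss = hads = np.nan
            else:
                z1, z2 = rng.standard_normal(2)
                z2 = _SYMPTOM_CORR * z1 + np.sqrt(1 - _SYMPTOM_CORR ** 2) * z2
                fss = float(np.clip(np.round(fm + fs * z1), 9, 63))
                hads = float(np.clip(np.round(hm + hs * z2), 0, 21))
            rows.append({
                "subject_id": sid, "group": group, "fss": fss, "hads_d": hads,
                "tiv": float(rng.normal(tm, ts)),
                "gm_volume": float(rng.normal(gm_m, gm_s)),
                "lesion_volume": float(max(0.0, rng.normal(le_m, le_s))),
            })
    return pd.DataFrame(rows)


def _exact_corr_construct(score: np.ndarray, tiv: np.ndarray, rho: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-variance vector whose sample partial correlation with ``score``
    (controlling TIV) is exactly ``rho``."""
    z1 = _ols_residuals(score, tiv)
    z1 = z1 / z1.std()
    noise = rng.standard_normal(len(score))
    z2 = _ols_residuals(noise, np.column_stack([tiv, score]))
    sd = z2.std()
    if sd == 0:
        raise ValidationError("degenerate noise draw in effect construction")
    z2 = z2 / sd
    return rho * z1 + np.sqrt(1.0 - rho ** 2) * z2


@dataclass
class CohortSim:
    spec: SimSpec
    cohort: pd.DataFrame
    subjects: dict[str, SubjectData]
    manifest: dict


def simulate_cohort(spec: SimSpec, outdir: str | Path | None = None,
                    keep_in_memory: bool = True) -> CohortSim:
    """Generate a full cohort with planted symptom-metric associations.

    Per-subject volumes are seed-determined from the root seed; the returned
    manifest (also written as JSON when ``outdir`` is given) records every
    planted quantity, so any expected value downstream is recomputable from
    it alone.  Regenerating from the manifest's spec reproduces the cohort
    bit for bit.
    """
    root = np.random.SeedSequence(spec.seed)
    cov_rng = np.random.default_rng(root.spawn(1)[0])
    cohort = _draw_covariates(spec, cov_rng)

    # Per-region planted-class fractions: independent jitter everywhere ...
    n_total = len(cohort)
    q_table = {
        r.id: np.clip(cov_rng.normal(spec.q_base, spec.q_sd, n_total),
                      0.0, spec.q_max)
        for r in spec.regions
    }
    lag_over: dict[int, np.ndarray] = {}
    amp_over: dict[int, np.ndarray] = {}
    share_over: dict[int, np.ndarray] = {}
    mix_over: dict[int, np.ndarray] = {}

    # ... except effect regions, where the fraction (or another knob) tracks
    # the residualized score with the requested correlation.
    resid_cache = {}
    for eff in spec.effects:
        if eff.group not in resid_cache:
            resid_cache[eff.group] = residualized_scores(cohort, eff.group)
        scores = resid_cache[eff.group].table.set_index("subject_id")[eff.score]
        idx = cohort.index[cohort["group"] == eff.group]
        svec = scores.reindex(cohort.loc[idx, "subject_id"]).to_numpy()
        tvec = cohort.loc[idx, "tiv"].to_numpy()
        u = _exact_corr_construct(svec, tvec, eff.rho, cov_rng)
        if eff.metric == "pct_lag_lo":
            q = spec.q_base_effect + spec.q_sd_effect * u
            clipped = np.clip(q, 0.002, spec.q_max)
            if not np.allclose(q, clipped):
                lo = (0.002 - spec.q_base_effect) / spec.q_sd_effect
                hi = (spec.q_max - spec.q_base_effect) / spec.q_sd_effect
                warnings.warn(
                    f"planted fraction clipped to [0.002, {spec.q_max}] for "
                    f"region {eff.region}; achievable |rho| is reduced "
                    f"(u range [{lo:.2f}, {hi:.2f}])")
            q_table[eff.region][idx] = clipped
        elif eff.metric == "lag":
            vals = np.clip(1.0 * u, -3.0, 3.0)
            arr = np.full(n_total, np.nan)
            arr[idx] = vals
            lag_over[eff.region] = arr
        elif eff.metric == "icc":
            # less private block signal -> less dilution -> higher ICC
            vals = np.clip(spec.amp_block * (1.0 - 0.4 * u), 0.2, 2.2)
            arr = np.full(n_total, np.nan)
            arr[idx] = vals
            amp_over[eff.region] = arr
        elif eff.metric == "bc":
            vals = np.clip(0.4 + 0.25 * u, 0.0, 1.2)
            arr = np.full(n_total, np.nan)
            arr[idx] = vals
            mix_over[eff.region] = arr

    subject_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in root.spawn(1 + n_total)[1:]]
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        outpath.mkdir(parents=True, exist_ok=True)

    subjects: dict[str, SubjectData] = {}
    manifest_subjects = {}
    for pos, (_, row) in enumerate(cohort.iterrows()):
        sid = row["subject_id"]
        q_by_region = {rid: float(q_table[rid][pos]) for rid in q_table}
        kwargs = {}
        for name, table in (("lag_overrides", lag_over),
                            ("block_amp_overrides", amp_over),
                            ("global_share_overrides", share_over),
                            ("block_mixing", mix_over)):
            vals = {rid: float(arr[pos]) for rid, arr in table.items()
                    if np.isfinite(arr[pos])}
            if vals:
                kwargs[name] = vals
        sub = simulate_subject(spec, subject_seeds[pos],
                               q_by_region=q_by_region, **kwargs)
        manifest_subjects[sid] = sub.truth
        if outpath is not None:
            save_bold(sub.bold, outpath / f"{sid}_bold.nii.gz")
        if keep_in_memory:
            subjects[sid] = sub

    manifest = {
        "spec": spec.to_dict(),
        "subject_seeds": {sid: subject_seeds[pos]
                          for pos, sid in enumerate(cohort["subject_id"])},
        "subjects": manifest_subjects,
        "effects": [dataclasses.asdict(e) for e in spec.effects],
    }
    if outpath is not None:
        geo = build_geometry(spec)
        save_volume(geo["atlas"].labels.astype(np.int16), geo["affine"],
                    outpath / "atlas.nii.gz")
        for name in ("gm", "wm", "csf", "venous"):
            save_volume(geo[name].astype(np.uint8), geo["affine"],
                        outpath / f"mask_{name}.nii.gz")
        save_cohort(cohort, outpath / "cohort.tsv")
        with open(outpath / "ground_truth.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
    return CohortSim(spec=spec, cohort=cohort, subjects=subjects,
                     manifest=manifest)


def gaussian_smooth(bold: BoldSeries, fwhm_mm: float) -> BoldSeries:
    """Volume-wise Gaussian smoothing (synthetic path only; real inputs are
    assumed already smoothed upstream)."""
    voxdim = np.abs(np.diag(bold.affine)[:3])
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxdim
    out = ndimage.gaussian_filter(bold.data, sigma=(*sigma, 0.0))
    return bold.with_data(out)
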