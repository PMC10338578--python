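# Methods

## Overview

`hemocoupling` implements a resting-state BOLD analysis with four stages:

1. **Denoising** — per-voxel linear detrend, nuisance regression, and
   zero-phase bandpass filtering (0.008–0.09 Hz), in two variants.  The
   *full* variant regresses the five leading principal components of the
   combined white-matter + CSF compartment plus their first-order
   derivatives (aCompCor) and feeds the connectivity branch.  The
   *CSF-only* variant removes just the mean CSF signal and feeds the lag
   branch: gray-matter and venous timing information is signal there, not
   noise, so it must not be regressed away.
2. **Time shift analysis (TSA)** — each gray-matter voxel is assigned the
   integer lag (in TR units, grid ±3) at which its series best correlates
   with the mean signal of a venous-sinus mask.  Positive lag = the voxel
   is delayed relative to venous outflow ("hemodynamic lag"); negative =
   lead.
3. **Intrinsic connectivity contrast (ICC)** — each gray-matter voxel's
   mean squared Pearson correlation with every other gray-matter voxel, a
   weighted-degree summary of global connectivity.  Within subject, ICC is
   z-standardized over gray matter and thresholded one-sided at p < .001
   (z ≈ ±3.09) into significantly-high / significantly-low masks.  A
   region-level graph (mean parcel series → Pearson matrix → negatives
   zeroed → proportional threshold) yields nodal betweenness centrality
   (distances 1/w, normalized by (n−1)(n−2)/2) and local efficiency
   (binarized neighborhood subgraph by default).
4. **Coupling index and group statistics** — voxels are cross-classified
   by timing (lead: lag < −1 TR; lag: > +1 TR; strict inequalities, so ±1
   itself is neutral) and connectivity (high/low masks).  Lead∧high and
   lag∧low are *coupled* classes; lag∧high and lead∧low are *uncoupled*.
   Each region's index is the percentage of its gray-matter voxels in each
   class.  Group models relate per-subject maps and region metrics to
   mutually residualized symptom scores (fatigue adjusted for depression
   and vice versa, ordinary least squares within patient group) by partial
   correlation controlling total intracranial volume; voxel-wise maps are
   thresholded at an uncorrected voxel p with a cluster-extent filter,
   region metrics at p < .01; a median-split contrast compares high- vs
   low-scoring patients and each subgroup against healthy-control values.

## Statistical model and assumptions

* The voxel-wise model is a partial correlation (map value vs score,
  controlling intracranial volume).  With one covariate and one nuisance
  this is equivalent to the corresponding GLM contrast; p-values come from
  the t transform with n−3 degrees of freedom and are exact under
  Gaussian errors.
* Partial correlations are computed by double residualization, which is
  algebraically identical to the precision-matrix formula; the test suite
  enforces agreement to 1e−12.
* "Significantly high/low ICC" requires a null model the measurement does
  not supply; the package operationalizes it as a within-subject Gaussian
  z threshold over gray-matter voxels (a rank-quantile alternative is
  selectable via `icc_standardization="rank"`).  A consequence worth
  remembering: the |z| > 3.09 tail can never hold more than ~9.5% of
  gray-matter mass (Chebyshev), so coupling percentages are intrinsically
  small numbers.
* Missing symptom scores (healthy controls) are excluded listwise per
  model, never imputed.
* Tests are two-sided throughout.  No correction beyond the stated
  uncorrected thresholds and cluster extent is applied by default; a
  Benjamini–Hochberg helper exists but is off.

## Key parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `lag_max_tr` | 3 | TR | half-width of the lag search grid |
| `lead_threshold_tr` / `lag_threshold_tr` | −1 / +1 | TR | strict coupling-class cutoffs |
| `band` | (0.008, 0.09) | Hz | bandpass corners |
| `n_confound_pcs` | 5 | — | aCompCor components (doubled by derivatives) |
| `icc_p_threshold` | 0.001 | — | within-subject high/low ICC tail |
| `voxel_p` / `cluster_min` | 0.001 / 20 | — / voxels | voxel-wise threshold and extent filter |
| `region_p` | 0.01 | — | region-level significance |
| `graph_density` | 0.15 | — | retained edge fraction (list → sweep average) |
| `n_discard` | 5 | volumes | leading volumes dropped at load |
| `tr` | header | s | explicit value overrides the NIfTI header |

## Numerical choices

* **Filter**: 4th-order Butterworth applied forward-backward.  Zero phase
  is mandatory because TSA measures timing and a causal filter would
  inject a lag of its own.  We use Gustafsson initial conditions
  (`filtfilt(..., method="gust")`), which minimize forward-backward edge
  transients — again a timing concern.  Note the passband is flat to
  <0.5% only away from the −3 dB corners; repeated filtering moves
  content near 0.09 Hz by more than 1%.
* **Order of steps**: discard → detrend → confound regression → bandpass,
  so regression cannot reintroduce out-of-band energy.
* **Derivatives**: backward difference with a leading zero.
* **PC sign**: fixed by making each component's largest-magnitude loading
  positive (deterministic across platforms).
* **Lag ties**: argmax ties choose the smaller |lag|, then the negative
  one — biased toward the null and deterministic.  Correlations use the
  truncated overlap only (never circular).  Voxels with zero variance on
  any overlap window are invalidated with a reason code.  An optional
  parabolic refinement of the peak exists but is off by default; the
  estimator is integer-valued as specified.
* **ICC**: computed blockwise (matrix products over row blocks) but
  numerically identical to the pairwise definition (checked to 1e−10);
  zero-variance voxels are excluded from both the map and the pool.
* **Graph**: negative inter-region correlations are zeroed before
  thresholding because the graph distance 1/w is undefined for w ≤ 0;
  proportional thresholding resolves weight ties by index for
  determinism; disconnected nodes score 0 on both metrics.
* **Clusters**: 18-connectivity by default (6/26 configurable), labeled
  with `scipy.ndimage`; validated against a flood-fill reference.
* **TR**: treated as data (config overrides header); the package never
  assumes a fixed scanner TR.

## The synthetic cohort generator

Real patient data are not distributable, so every test runs on synthetic
cohorts with planted ground truth (`hemocoupling.simulate`).

* **Geometry**: a small grid (default 24×24×16, 3 mm voxels; the compact
  test geometry is 12×12×8) with CSF and WM slabs, a venous corner
  column, and gray matter partitioned into rectangular parcels
  (`region_grid`, default 3×4 = 12; the effect-cohort factory uses 2×3 =
  6 larger parcels).  150 volumes at TR 2.3 s; the pipeline discards the
  first five, analyzing 145.
* **Signals**: continuous sums of ~40 random sinusoids confined to
  0.012–0.078 Hz, evaluable at arbitrary shifted times — planted lags
  (including non-integer ones) are exact and survive the bandpass.  A
  venous latent *s* drives the reference; each gray-matter voxel carries
  *s* delayed by its region's lag, a private per-region block signal, a
  shared global component, and white noise (default amplitudes 1 / 1 /
  0.8 / 0.28, i.e. structured-to-noise ≈ 5).  WM and CSF carry
  independent latents, so confound regression removes something real
  without touching gray matter.
* **Connectivity levels work by dilution**: a region with a large private
  signal correlates weakly with the rest of gray matter (low ICC); one
  with little private signal rides the shared components (high ICC).
* **The delayed + disconnected class** (the lag∧low coupling class) is
  planted per voxel: a 0.65-weighted copy of *s* delayed by +3 TR plus a
  private band-limited latent.  Normal parcels stay within ±1 TR so the
  planted class is the only population beyond the +1 TR threshold.
  Planted fractions are kept small (background regions ≈ 3%, effect
  region ≈ 7%) because of the Chebyshev ceiling above.
* **Planted associations** realize the requested *sample* correlation
  exactly: the per-subject fraction is built from the standardized score
  component plus orthogonalized noise, both orthogonalized against
  intracranial volume, so a cohort's planted partial correlation equals ρ
  before pipeline measurement noise.  Covariate tables mimic an early-MS
  cohort (FSS 33±16 / 43±15, HADS-D 4.6±3.1 / 5.8±2.6, TIV ≈ 1330–1390
  cm³ by group; controls carry no symptom scores).
* **Not emulated**: head motion and scrubbing, spatial autocorrelation
  and smoothing (a Gaussian smoother exists for the synthetic path only),
  registration error, physiological aliasing, lesions, and realistic
  anatomy.  Passing tests therefore demonstrate algorithmic correctness
  and statistical calibration under the generative model, not robustness
  to real-scanner artifacts.

## Problem sizes used by the test and acceptance runs

The validation studies run at deliberately compact sizes chosen so the
whole suite completes in minutes while keeping the temporal structure
(145 analyzed volumes at TR 2.3 s) intact: 12×12×8 grids (~840 gray-matter
voxels), 20 subjects for lag recovery, 24-patient cohorts × 100 replicates
for the end-to-end power study, 100 simulations for the null calibration
of the voxel-wise model.  `scripts/acceptance.py` repeats the same studies
at 10 subjects / 30 replicates / 60 null simulations.

## Known limitations

* The integer-lag estimator quantizes true hemodynamic delays; sub-TR
  structure is only visible through the optional parabolic refinement.
* Shared structured signals (e.g. a block signal that happens to
  correlate with the venous reference in a finite sample) can bias a whole
  region's lag coherently by ±1 TR; this is a property of the method on
  short series, not an implementation artifact, and it is why the lag
  recovery study uses additive white noise as its stated condition.
* With ~45 effective samples in the passband, per-pair correlation
  estimates are noisy; ICC inherits a positive floor of roughly 1/(T−1)
  plus band-limitation effects.
* The within-subject ICC z-threshold makes coupling percentages
  compositional (they compete for a bounded tail); comparisons across
  subjects assume similar gray-matter ICC distributions.
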