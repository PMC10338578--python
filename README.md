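# hemocoupling

Voxel-wise hemodynamic lag mapping, intrinsic connectivity, and their
regional coupling for resting-state BOLD fMRI — with the group statistics
to relate those measures to clinical symptom scores, and a synthetic-cohort
generator that makes every stage testable against planted ground truth.

## The problem

In early multiple sclerosis and related conditions, symptoms such as
fatigue and depression may reflect not only *where* the brain is
functionally connected but *when* blood-oxygenation signals arrive.  Two
voxel-wise measures capture these axes on ordinary resting-state scans:

* **Time shift analysis (TSA).**  Each voxel's BOLD series is correlated
  with the mean signal of the major venous sinuses at integer lags
  τ ∈ {−3, …, +3} TR; the voxel's time shift is
  `argmax_τ corr(x(t − τ), ref(t))`.  Negative values index hemodynamic
  *lead* (accelerated drainage), positive values *lag*.
* **Intrinsic connectivity contrast (ICC).**  A voxel's ICC is
  `mean_{j≠i} r_ij²`, the average squared correlation with every other
  gray-matter voxel — a weighted-degree measure of global functional
  connectivity.  For independent noise E[ICC] = 1/(T−1).

The **coupling index** cross-classifies voxels with |lag| beyond ±1 TR
against significantly high/low ICC (within-subject z at p < .001).
Lead∧high and lag∧low are *coupled* (timing and connectivity agree);
lag∧high and lead∧low are *uncoupled*.  Per atlas region, the percentage
of gray-matter voxels in each class becomes a subject-level dependent
variable.  Group models then ask whether those percentages — or voxel
maps, or nodal graph metrics (betweenness centrality, local efficiency) —
track fatigue after adjusting for depression (and vice versa), as partial
correlations controlling total intracranial volume.

The package is for methods-oriented neuroimaging researchers who want a
tested, scriptable implementation of this analysis chain, with explicit
null calibration and parameter-recovery evidence on synthetic cohorts.

## Worked example

A synthetic patient cohort (n = 24) in which region 4's percentage of
delayed + disconnected voxels is built to correlate ρ = −0.55 with
depression-adjusted fatigue:

```python
from hemocoupling import PipelineConfig
from hemocoupling.simulate import SimSpec, simulate_cohort
from hemocoupling.pipeline import run_group_sim

cfg = PipelineConfig()
sim = simulate_cohort(SimSpec.coupling_cohort(seed=11))
results, groups = run_group_sim(cfg, sim, group="CIS")

print(results["cis001"].coupling.to_string(index=False))
g = next(x for x in groups if x.covariate == "fss_resid")
print(g.region_stats[g.region_stats.metric == "pct_lag_lo"].to_string(index=False))
```

Subject-level coupling table (one subject):

```
subject_id  region  n_voxels  defined  pct_lead_hi  pct_lag_lo  pct_lag_hi  pct_lead_lo
    cis001       1       120     True          0.0    3.333333         0.0          0.0
    cis001       2       144     True          0.0    1.388889         0.0          0.0
    cis001       3       144     True          0.0    1.388889         0.0          0.0
    cis001       4       144     True          0.0    6.250000         0.0          0.0
    cis001       5       144     True          0.0    3.472222         0.0          0.0
    cis001       6       144     True          0.0    3.472222         0.0          0.0
```

`pct_lag_lo` is the percentage of the region's gray-matter voxels with a
time shift > +1 TR *and* significantly low connectivity — the coupled
"delayed and disconnected" class.  Region 4 (the planted one) carries the
largest share for this subject.  Group level:

```
covariate  region     metric         r        p  n  significant
fss_resid       4 pct_lag_lo -0.551654 0.006356 24         True
fss_resid       6 pct_lag_lo -0.380032 0.073658 24        False
fss_resid       5 pct_lag_lo -0.257618 0.235325 24        False
fss_resid       3 pct_lag_lo  0.222896 0.306642 24        False
fss_resid       1 pct_lag_lo -0.123969 0.573052 24        False
fss_resid       2 pct_lag_lo  0.011802 0.957376 24        False
```

The planted region is recovered at r = −0.55 (p = .006, flagged at the
p < .01 region threshold); the five null regions are not.

There is also a command-line front end for on-disk cohorts:

```bash
hemocoupling simulate --seed 9 --out cohort/ --compact
hemocoupling subject --bold cohort/cis001_bold.nii.gz --atlas cohort/atlas.nii.gz \
    --venous-mask cohort/mask_venous.nii.gz --wm-mask cohort/mask_wm.nii.gz \
    --csf-mask cohort/mask_csf.nii.gz --out out/
hemocoupling group --cohort-dir cohort/ --group CIS --out stats/
```

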