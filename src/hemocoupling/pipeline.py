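"""End-to-end orchestration: subject-level maps, group-level statistics.

Two preprocessing branches per subject, mirroring the analysis design:

* CSF-only confound regression -> time shift analysis (gray-matter timing
  must not be regressed away);
* full aCompCor denoising -> intrinsic connectivity -> regional graph.

The overlay of the two maps gives the coupling table.  Group-level models
relate lag and ICC maps, coupling percentages and nodal graph metrics to the
mutually residualized symptom scores, controlling intracranial volume.

Every run writes a JSON manifest (config snapshot, input hashes, package
version, seed, timestamps, output paths); numeric TSV outputs are
timestamp-free so reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import IccMap, RegionGraph, icc_map, region_graph, threshold_icc
from .coupling import COUPLING_CLASSES, coupling_table, overlay_masks
from .io import (BoldSeries, ParcellationAtlas, PipelineConfig, ValidationError,
                 load_atlas, load_bold, load_cohort, load_mask, save_volume)
from .preprocess import denoise
from .simulate import CohortSim, SubjectData
from .stats import (StatMap, region_partial_corr, residualized_scores,
                    voxelwise_covariate_map)
from .tsa import LagMap, lag_map, reference_signal

logger = logging.getLogger("hemocoupling")

__all__ = ["SubjectResult", "GroupResult", "run_subject", "run_subject_arrays",
           "run_group", "run_group_sim", "write_subject_outputs"]


@dataclass
class SubjectResult:
    subject_id: str
    lag: LagMap
    icc: IccMap
    graph: RegionGraph
    coupling: pd.DataFrame


def run_subject_arrays(subject_id: str, bold: BoldSeries,
                       atlas: ParcellationAtlas, venous: np.ndarray,
                       wm: np.ndarray, csf: np.ndarray,
                       config: PipelineConfig,
                       gm: np.ndarray | None = None) -> SubjectResult:
    """Subject-level pipeline on in-memory arrays."""
    gm_mask = atlas.gm_mask if gm is None else gm.astype(bool)
    for name, m in (("venous", venous), ("wm", wm), ("csf", csf)):
        if m is None or not np.asarray(m).any():
            raise ValidationError(f"subject {subject_id}: missing or empty "
                                  f"{name} mask is required")

    tsa_bold = denoise(bold, wm_mask=None, csf_mask=csf, variant="csf_only",
                       band=config.band, n_pcs=config.n_confound_pcs)
    ref = reference_signal(tsa_bold, venous)
    lag = lag_map(tsa_bold, ref, config, mask=gm_mask)

    icc_bold = denoise(bold, wm_mask=wm, csf_mask=csf, variant="full",
                       band=config.band, n_pcs=config.n_confound_pcs)
    icc = icc_map(icc_bold, gm_mask)
    icc = threshold_icc(icc, config.icc_p_threshold,
                        method=config.icc_standardization)
    graph = region_graph(icc_bold, atlas, density=config.graph_density,
                         eloc_weighted=config.eloc_weighted)

    masks = overlay_masks(lag, icc, config)
    table = coupling_table(masks, atlas, gm_mask=gm_mask, subject_id=subject_id)
    return SubjectResult(subject_id=subject_id, lag=lag, icc=icc, graph=graph,
                         coupling=table)


def run_subject(config: PipelineConfig, bold_path: str | Path,
                atlas_path: str | Path, venous_path: str | Path,
                wm_path: str | Path, csf_path: str | Path,
                subject_id: str | None = None,
                roi_list: list[int] | None = None,
                outdir: str | Path | None = None) -> SubjectResult:
    """Subject-level pipeline from files, optionally writing all outputs."""
    sid = subject_id or Path(bold_path).stem.split(".")[0]
    atlas = load_atlas(atlas_path, roi_list=roi_list)
    bold = load_bold(bold_path, config)
    venous, wm, csf = (load_mask(p) for p in (venous_path, wm_path, csf_path))
    result = run_subject_arrays(sid, bold, atlas, venous, wm, csf, config)
    if outdir is not None:
        paths = write_subject_outputs(result, bold.affine, Path(outdir))
        _write_manifest(Path(outdir) / f"{sid}_manifest.json", config,
                        inputs={"bold": bold_path, "atlas": atlas_path,
                                "venous": venous_path, "wm": wm_path,
                                "csf": csf_path},
                        outputs=paths)
    return result


def write_subject_outputs(result: SubjectResult, affine: np.ndarray,
                          outdir: Path) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    sid = result.subject_id
    paths = {}
    vols = {
        "lag_tr": result.lag.lag_tr.astype(np.float32),
        "rmax": result.lag.rmax.astype(np.float32),
        "lag_valid": result.lag.valid.astype(np.uint8),
        "icc": result.icc.icc.astype(np.float32),
        "icc_z": result.icc.z.astype(np.float32),
        "icc_hi": result.icc.hi_mask.astype(np.uint8),
        "icc_lo": result.icc.lo_mask.astype(np.uint8),
    }
    for name, vol in vols.items():
        p = outdir / f"{sid}_{name}.nii.gz"
        save_volume(vol, affine, p)
        paths[name] = str(p)
    cpath = outdir / f"{sid}_coupling.tsv"
    result.coupling.to_csv(cpath, sep="\t", index=False, float_format="%.10g")
    paths["coupling"] = str(cpath)
    gpath = outdir / f"{sid}_graph_metrics.tsv"
    pd.DataFrame({
        "region": result.graph.nodes,
        "bc": [result.graph.bc[r] for r in result.graph.nodes],
        "eloc": [result.graph.eloc[r] for r in result.graph.nodes],
    }).to_csv(gpath, sep="\t", index=False, float_format="%.10g")
    paths["graph_metrics"] = str(gpath)
    return paths


# ---------------------------------------------------------------------------
# Group level
# ---------------------------------------------------------------------------

@dataclass
class GroupResult:
    group: str
    covariate: str                     # fss_resid or hads_resid
    stat_maps: dict[str, StatMap]      # "lag", "icc_z"
    region_stats: pd.DataFrame
    n: int


def _collect_metric_table(results: dict[str, SubjectResult]) -> pd.DataFrame:
    """Coupling percentages plus nodal metrics, one row per subject-region."""
    frames = []
    for sid, res in results.items():
        t = res.coupling.copy()
        t["bc"] = t["region"].map(res.graph.bc)
        t["eloc"] = t["region"].map(res.graph.eloc)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def run_group(config: PipelineConfig, results: dict[str, SubjectResult],
              cohort: pd.DataFrame, group: str,
              affine: np.ndarray | None = None,
              extra_nuisance_cols: list[str] | None = None
              ) -> list[GroupResult]:
    """Both covariate models for one patient group.

    ``results`` maps subject id -> SubjectResult for at least the group's
    subjects.  Voxel-wise models relate the lag map and the ICC z map to
    each residualized score controlling TIV; region models cover the four
    coupling classes plus betweenness centrality and local efficiency.
    """
    sub = cohort[cohort["group"] == group].dropna(subset=["fss", "hads_d", "tiv"])
    ids = [s for s in sub["subject_id"] if s in results]
    if len(ids) < 5:
        raise ValidationError(
            f"group {group}: need >= 5 subjects with complete covariates and "
            f"maps, got {len(ids)}")
    sub = sub[sub["subject_id"].isin(ids)].set_index("subject_id").loc[ids]
    resid = residualized_scores(cohort, group)
    rtab = resid.table.set_index("subject_id").loc[ids]
    tiv = sub["tiv"]

    lag_stack = np.stack([results[s].lag.lag_tr.astype(float) for s in ids])
    icc_stack = np.stack([results[s].icc.z for s in ids])
    common_valid = np.all(np.stack([results[s].lag.valid for s in ids]), axis=0)
    common_defined = np.all(np.stack([results[s].icc.defined for s in ids]), axis=0)

    metric_table = _collect_metric_table({s: results[s] for s in ids})
    extra = None
    if extra_nuisance_cols:
        extra = sub[extra_nuisance_cols]

    out = []
    for cov_name in ("fss_resid", "hads_resid"):
        cov = rtab[cov_name]
        maps = {
            "lag": voxelwise_covariate_map(lag_stack, cov.to_numpy(),
                                           tiv.to_numpy(), config,
                                           mask=common_valid, affine=affine),
            "icc_z": voxelwise_covariate_map(icc_stack, cov.to_numpy(),
                                             tiv.to_numpy(), config,
                                             mask=common_defined, affine=affine),
        }
        stats_rows = region_partial_corr(
            metric_table, [*COUPLING_CLASSES, "bc", "eloc"],
            covariate=cov, nuisance=tiv, config=config,
            extra_nuisances=extra)
        df = pd.DataFrame([dataclasses.asdict(r) for r in stats_rows])
        df.insert(0, "covariate", cov_name)
        df = df.sort_values(["metric", "p"], kind="stable").reset_index(drop=True)
        out.append(GroupResult(group=group, covariate=cov_name, stat_maps=maps,
                               region_stats=df, n=len(ids)))
    return out


def run_group_sim(config: PipelineConfig, sim: CohortSim, group: str = "CIS",
                  extra_nuisance_cols: list[str] | None = None
                  ) -> tuple[dict[str, SubjectResult], list[GroupResult]]:
    """Subject pipeline over a simulated cohort, then the group models."""
    results = {}
    ids = sim.cohort.loc[sim.cohort["group"] == group, "subject_id"]
    for sid in ids:
        sub: SubjectData = sim.subjects[sid]
        bold = _discard(sub.bold, config.n_discard)
        results[sid] = run_subject_arrays(sid, bold, sub.atlas, sub.venous,
                                          sub.wm, sub.csf, config, gm=sub.gm)
    groups = run_group(config, results, sim.cohort, group,
                       affine=next(iter(sim.subjects.values())).bold.affine,
                       extra_nuisance_cols=extra_nuisance_cols)
    return results, groups


def _discard(bold: BoldSeries, n: int) -> BoldSeries:
    if n <= 0:
        return bold
    return BoldSeries(data=bold.data[..., n:], tr=bold.tr, affine=bold.affine,
                      mask=bold.mask, n_discard=n)


# ---------------------------------------------------------------------------
# Reporting and manifests
# ---------------------------------------------------------------------------

def write_group_outputs(groups: list[GroupResult], affine: np.ndarray,
                        outdir: Path) -> dict[str, str]:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for g in groups:
        tag = f"{g.group}_{g.covariate}"
        tpath = outdir / f"region_stats_{tag}.tsv"
        g.region_stats.to_csv(tpath, sep="\t", index=False, float_format="%.10g")
        paths[f"region_stats_{tag}"] = str(tpath)
        for name, smap in g.stat_maps.items():
            p = outdir / f"statmap_{tag}_{name}_r.nii.gz"
            save_volume(smap.effect.astype(np.float32), affine, p)
            save_volume(smap.surviving.astype(np.uint8), affine,
                        outdir / f"statmap_{tag}_{name}_surviving.nii.gz")
            paths[f"statmap_{tag}_{name}"] = str(p)
            cpath = outdir / f"clusters_{tag}_{name}.tsv"
            pd.DataFrame(smap.clusters or [],
                         columns=["label", "size", "peak_voxel", "peak_effect",
                                  "peak_mm"]).to_csv(
                cpath, sep="\t", index=False, float_format="%.10g")
            paths[f"clusters_{tag}_{name}"] = str(cpath)
    return paths


def write_report(groups: list[GroupResult], path: Path) -> None:
    """Plain-markdown summary: per model, the region table and cluster list."""
    lines = ["# Group analysis report", ""]
    for g in groups:
        lines += [f"## {g.group} — covariate {g.covariate} (n={g.n})", ""]
        sig = g.region_stats[g.region_stats["significant"] == True]  # noqa: E712
        lines.append(f"Significant region metrics (p < configured threshold): "
                     f"{len(sig)}")
        lines.append("")
        lines.append("```")
        lines.append(g.region_stats.to_string(index=False))
        lines.append("```")
        lines.append("")
        for name, smap in g.stat_maps.items():
            lines.append(f"### Voxel-wise map: {name} — "
                         f"{len(smap.clusters)} surviving cluster(s)")
            for c in smap.clusters:
                mm = c.get("peak_mm")
                mm_txt = (" at MNI " + ", ".join(f"{v:.0f}" for v in mm)
                          if mm else "")
                lines.append(f"- cluster of {c['size']} voxels, peak r = "
                             f"{c['peak_effect']:.3f}{mm_txt}")
            lines.append("")
    path.write_text("\n".join(lines))


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(path: Path, config: PipelineConfig, inputs: dict,
                    outputs: dict) -> None:
    manifest = {
        "config": config.to_dict(),
        "inputs": {k: {"path": str(v), "sha256": _hash_file(v)}
                   for k, v in inputs.items()},
        "outputs": outputs,
        "version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
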