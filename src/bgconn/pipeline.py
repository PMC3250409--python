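"""End-to-end orchestration of the connectome analysis.

``run_connectome`` executes: input acquisition (phantom simulation or file
loading) -> tensor/FA estimation -> fiber substrate -> pairwise probabilistic
tractography over all 21 unordered structure pairs per hemisphere -> pathway
masks -> connectivity-based parcellation -> probability-of-connection
matrices -> volumetry/agreement statistics -> seed-based functional
connectivity and structure-function overlap. Every stage is reproducible
from the global seed; outputs are NIfTI volumes, CSV matrices and a JSON
run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as bio
from .fibers import estimate_fiber_orientations, fit_tensor
from .funcconn import (FCParams, overlap_structure_function, preprocess_bold,
                       seed_fc_map, threshold_activation)
from .phantom import (DWIProtocol, LabelVolume, PhantomSpec, STRUCTURES,
                      build_fiber_field, build_label_volume,
                      perturb_segmentation, simulate_bold, simulate_dwi)
from .quantify import (ConnectionMatrix, extract_pathway, matrix_from_profiles,
                       parcellate_roi, subterritory_volumes)
from .stats import agreement_table, roi_volumes
from .tracking import TrackingParams, track_all_pairs

__all__ = ["RunConfig", "RunReport", "run_connectome"]

log = logging.getLogger("bgconn")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``phantom`` (simulate inputs) or ``input_paths`` (load
    NIfTI + bval/bvec files with keys ``labels``, ``dwi``, ``bval``,
    ``bvec`` and optionally ``bold``) must be provided.
    """

    phantom: PhantomSpec | None = None
    input_paths: dict[str, str] | None = None
    out_dir: str | Path = "bgconn_out"
    seed: int = 0
    tracking: TrackingParams = field(default_factory=TrackingParams)
    pathway_threshold: float = 0.10
    parcellation_threshold: float = 0.50
    fc: FCParams = field(default_factory=FCParams)
    #: tractography substrate: "truth" (phantom fiber field) or "estimated"
    #: (ball-and-stick NLLS from the DWI volumes)
    fiber_source: str = "truth"
    #: seed structures for functional connectivity maps
    fc_seed_structures: tuple[str, ...] = ("SN",)
    perturb_flip_rate: float = 0.1
    do_tracking: bool = True
    do_stats: bool = True
    do_fc: bool = True
    write_outputs: bool = True

    def __post_init__(self):
        if (self.phantom is None) == (self.input_paths is None):
            raise ValueError("provide exactly one of phantom spec or "
                             "input paths")
        if self.fiber_source not in ("truth", "estimated"):
            raise ValueError("fiber_source must be 'truth' or 'estimated'")
        if self.fiber_source == "truth" and self.phantom is None:
            raise ValueError("fiber_source='truth' requires a phantom spec")


@dataclass
class RunReport:
    stages: dict[str, dict] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    manifest: list[str] = field(default_factory=list)
    summaries: dict = field(default_factory=dict)

    # in-memory artifacts for library users (not serialized)
    labels: LabelVolume | None = None
    matrices: dict[str, ConnectionMatrix] = field(default_factory=dict)
    pairs: dict = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)
    parcellations: dict = field(default_factory=dict)
    pathway_masks: dict = field(default_factory=dict)
    activation_maps: dict = field(default_factory=dict)
    fa: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages,
                           "parameters": self.parameters,
                           "manifest": self.manifest,
                           "summaries": self.summaries}, indent=2,
                          default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _stage(report: RunReport, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is None:
                report.stages[name] = {"status": "ok", "seconds": round(dt, 3)}
                log.info("stage %s: done in %.2fs", name, dt)
                return False
            report.stages[name] = {"status": "failed", "seconds": round(dt, 3),
                                   "error": str(exc)}
            log.error("stage %s: FAILED (%s)", name, exc)
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return _Ctx()


def run_connectome(config: RunConfig) -> RunReport:
    """Execute the full pipeline described in the module docstring."""
    report = RunReport()
    report.parameters = {
        "seed": config.seed,
        "tracking": vars(config.tracking).copy(),
        "pathway_threshold": config.pathway_threshold,
        "parcellation_threshold": config.parcellation_threshold,
        "fiber_source": config.fiber_source,
    }
    out = Path(config.out_dir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    # ---- inputs -----------------------------------------------------------
    with _stage(report, "inputs"):
        if config.phantom is not None:
            spec = config.phantom
            labels = build_label_volume(spec)
            fiber_truth = build_fiber_field(spec, labels)
            protocol = DWIProtocol.uniform()
            dwi = simulate_dwi(fiber_truth, protocol,
                               noise_sigma=spec.noise_sigma_dwi,
                               seed=config.seed)
            bold = simulate_bold(spec, labels, seed=config.seed + 1) \
                if config.do_fc else None
            labels_day2 = perturb_segmentation(labels, config.perturb_flip_rate,
                                               seed=config.seed + 2)
            voxel_size = spec.voxel_size
        else:
            paths = config.input_paths
            lab_arr, voxel_size, _ = bio.read_nifti(paths["labels"])
            table_path = paths.get("label_table")
            if table_path:
                table = {int(k): tuple(v) for k, v in
                         json.loads(Path(table_path).read_text()).items()}
            else:
                # conventional ordering: L then R, structures in fixed order
                table = {i + 1: (s, h) for i, (h, s) in enumerate(
                    (h, s) for h in ("L", "R") for s in STRUCTURES)}
            labels = LabelVolume(lab_arr.astype(np.int16), table, voxel_size)
            dwi, _, _ = bio.read_nifti(paths["dwi"])
            protocol = bio.read_bvals_bvecs(paths["bval"], paths["bvec"])
            bold = None
            if config.do_fc and "bold" in paths:
                from .phantom import BoldSeries
                bold_arr, _, _ = bio.read_nifti(paths["bold"])
                bold = BoldSeries(bold_arr.astype(float),
                                  float(paths.get("tr", 2.0)))
            fiber_truth = None
            labels_day2 = None
        report.labels = labels
        hemispheres = sorted({h for _, h in labels.keys()})

    # ---- diffusion modelling ---------------------------------------------
    with _stage(report, "fiber_model"):
        brain = np.ones(labels.labels.shape, dtype=bool)
        tensor = fit_tensor(dwi, protocol, brain)
        report.fa = tensor.fa
        if config.fiber_source == "estimated":
            est_mask = tensor.fa > 0.1
            substrate = estimate_fiber_orientations(
                dwi, protocol, est_mask, seed=config.seed + 3,
                voxel_size=voxel_size)
        else:
            substrate = fiber_truth

    # ---- tractography and quantification ---------------------------------
    if config.do_tracking:
        with _stage(report, "tractography"):
            n_pairs = {}
            for hemi in hemispheres:
                pairs, profiles = track_all_pairs(substrate, labels, hemi,
                                                  config.tracking)
                report.pairs[hemi] = pairs
                report.profiles[hemi] = profiles
                n_pairs[hemi] = len(pairs)
            report.summaries["pairs_per_hemisphere"] = n_pairs

        with _stage(report, "quantification"):
            for hemi in hemispheres:
                for pair, dist in report.pairs[hemi].items():
                    report.pathway_masks[(hemi, pair)] = extract_pathway(
                        dist, config.pathway_threshold)
                parcs = {}
                volumes = {}
                for s, prof in report.profiles[hemi].items():
                    parc = parcellate_roi(prof, config.parcellation_threshold)
                    parcs[s] = parc
                    volumes[s] = subterritory_volumes(parc)
                report.parcellations[hemi] = parcs
                report.matrices[hemi] = matrix_from_profiles(
                    report.profiles[hemi], hemi,
                    config.parcellation_threshold)
                report.summaries.setdefault("subterritory_volumes", {})[hemi] \
                    = volumes
            report.summaries["connection_matrices"] = {
                h: m.values for h, m in report.matrices.items()}

    # ---- volumetry and agreement -----------------------------------------
    if config.do_stats:
        with _stage(report, "stats"):
            vols = roi_volumes(labels)
            report.summaries["roi_volumes_mm3"] = {
                f"{s}_{h}": v for (s, h), v in vols.items()}
            if labels_day2 is not None:
                ai = agreement_table(labels, labels_day2)
                report.summaries["agreement_index"] = {
                    f"{r.key[0]}_{r.key[1]}": r.ai for r in ai}
                report.summaries["agreement_index_mean"] = float(
                    np.mean([r.ai for r in ai]))

    # ---- functional connectivity -----------------------------------------
    if config.do_fc and bold is not None:
        with _stage(report, "functional_connectivity"):
            pre = preprocess_bold(bold, config.fc, voxel_size)
            overlaps = {}
            for hemi in hemispheres:
                for s in config.fc_seed_structures:
                    if (s, hemi) not in labels.key_to_label:
                        continue
                    amap = seed_fc_map(pre, labels.mask((s, hemi)),
                                       params=config.fc,
                                       seed_name=f"{s}_{hemi}")
                    threshold_activation(amap, config.fc)
                    report.activation_maps[(s, hemi)] = amap
                    if config.do_tracking:
                        for pair, pw in report.pathway_masks.items():
                            if pair[0] != hemi or s not in pair[1]:
                                continue
                            other = next(x for x in pair[1] if x != s)
                            roi = labels.mask((other, hemi))
                            ov = overlap_structure_function(
                                pw.mask, amap.thresholded, roi)
                            overlaps[f"{s}-{other}_{hemi}"] = ov.dice
            report.summaries["structure_function_dice"] = overlaps

    # ---- outputs ----------------------------------------------------------
    if config.write_outputs:
        with _stage(report, "outputs"):
            vs = voxel_size
            p = bio.write_nifti(out / "labels.nii", labels.labels, vs)
            report.manifest.append(str(p))
            if report.fa is not None:
                p = bio.write_nifti(out / "fa.nii", report.fa, vs)
                report.manifest.append(str(p))
            for hemi, m in report.matrices.items():
                path = out / f"connection_matrix_{hemi}.csv"
                m.to_frame().to_csv(path)
                report.manifest.append(str(path))
            for hemi, parcs in report.parcellations.items():
                for s, parc in parcs.items():
                    path = out / f"parcellation_{s}_{hemi}.nii"
                    bio.write_nifti(path, parc.dominant_label_volume(
                        labels.labels.shape), vs)
                    report.manifest.append(str(path))
            for (hemi, pair), pw in report.pathway_masks.items():
                a, b = sorted(pair)
                path = out / f"pathway_{a}-{b}_{hemi}.nii"
                bio.write_nifti(path, pw.mask.astype(np.uint8), vs)
                report.manifest.append(str(path))
            for (s, hemi), amap in report.activation_maps.items():
                path = out / f"fc_{s}_{hemi}_t.nii"
                bio.write_nifti(path, amap.t, vs)
                report.manifest.append(str(path))
                if amap.thresholded is not None:
                    path = out / f"fc_{s}_{hemi}_mask.nii"
                    bio.write_nifti(path, amap.thresholded.astype(np.uint8), vs)
                    report.manifest.append(str(path))
            (out / "report.json").write_text(report.to_json())
            report.manifest.append(str(out / "report.json"))
    return report
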