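"""NIfTI, gradient-table and config file I/O."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import (BoldSpec, BundleDef, DWIProtocol, PhantomSpec, ROIDef)

__all__ = ["read_nifti", "write_nifti", "read_bvals_bvecs",
           "write_bvals_bvecs", "read_phantom_spec", "write_phantom_spec"]


def write_nifti(path, data: np.ndarray,
                voxel_size: tuple[float, float, float]) -> Path:
    """Write a 3-D or 4-D array as NIfTI-1 with a diagonal affine."""
    path = Path(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite volume")
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, path)
    return path


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float], np.ndarray]:
    """Read a NIfTI-1 file; returns (data, voxel_size, affine)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
    except Exception as exc:  # corrupted header or non-NIfTI content
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    if np.issubdtype(data.dtype, np.floating) and not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite values")
    zooms = img.header.get_zooms()[:3]
    return data, tuple(float(z) for z in zooms), img.affine


def write_bvals_bvecs(protocol: DWIProtocol, bval_path, bvec_path) -> None:
    """FSL-dialect gradient table: one whitespace row of b-values, three
    rows of gradient components."""
    np.savetxt(bval_path, protocol.bvals[None, :], fmt="%g")
    np.savetxt(bvec_path, protocol.bvecs.T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> DWIProtocol:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    return DWIProtocol(bvals, bvecs)


def write_phantom_spec(spec: PhantomSpec, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(spec), indent=2))
    return path


def read_phantom_spec(path) -> PhantomSpec:
    raw = json.loads(Path(path).read_text())
    rois = tuple(ROIDef(r["structure"], r["hemisphere"],
                        tuple(r["center_mm"]), tuple(r["radii_mm"]))
                 for r in raw["roi_defs"])
    bundles = tuple(BundleDef(tuple(b["roi_a"]), tuple(b["roi_b"]),
                              b["radius_mm"], b["stick_fraction"], b["kappa"],
                              tuple(tuple(p) for p in b["points_mm"])
                              if b.get("points_mm") else None)
                    for b in raw["bundle_defs"])
    bs = raw["bold_spec"]
    bold = BoldSpec(bs["n_frames"], bs["tr"],
                    tuple((tuple(a), tuple(b), rho)
                          for a, b, rho in bs["correlations"]),
                    bs["drift_amplitude"], bs["noise_sd"], bs["baseline"])
    return PhantomSpec(tuple(raw["grid_shape"]), tuple(raw["voxel_size"]),
                       rois, bundles, raw["noise_sigma_dwi"], bold,
                       raw["rng_seed"])
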