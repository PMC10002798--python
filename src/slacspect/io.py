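"""File interfaces: NIfTI volumes, YAML sidecars, projection archives.

Volumes travel as NIfTI-1 with the voxel size in the affine; phantom and
reconstruction metadata as YAML; projection sets as compressed ``.npz``
archives with a YAML geometry header alongside.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .forward_model import AcquisitionGeometry, ProjectionSet
from .phantom import PhantomInstance, VolumeGrid

__all__ = [
    "save_volume",
    "load_volume",
    "save_phantom",
    "save_projections",
    "load_projections",
]


def save_volume(path, volume: np.ndarray, voxel_size_cm=0.68) -> None:
    vs = np.broadcast_to(np.asarray(voxel_size_cm, dtype=float), (3,))
    affine = np.diag([*(vs * 10.0), 1.0])  # NIfTI spacing is mm
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    vox_mm = np.sqrt((img.affine[:3, :3] ** 2).sum(axis=0))
    return np.asarray(img.dataobj), vox_mm / 10.0


def save_phantom(directory, phantom: PhantomInstance, stem: str = "phantom") -> None:
    """Write activity/mu/label volumes plus a YAML sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vs = phantom.grid.voxel_size_cm
    save_volume(directory / f"{stem}_activity.nii.gz", phantom.activity, vs)
    save_volume(directory / f"{stem}_mu.nii.gz", phantom.mu, vs)
    save_volume(directory / f"{stem}_labels.nii.gz",
                phantom.labels.astype(np.int16), vs)
    meta = {
        "seed": phantom.seed,
        "grid": {"shape": list(phantom.grid.shape),
                 "voxel_size_cm": list(vs)},
        "heart": {
            "center_cm": [float(v) for v in phantom.heart.center_cm],
            "long_axis": [float(v) for v in phantom.heart.long_axis],
            "r_outer_cm": float(phantom.heart.r_outer_cm),
            "r_inner_cm": float(phantom.heart.r_inner_cm),
        },
        "class_mu": {int(k): float(v) for k, v in phantom.class_mu.items()},
    }
    (directory / f"{stem}.yaml").write_text(yaml.safe_dump(meta))


def save_projections(path, pset: ProjectionSet) -> None:
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        photopeak=pset.photopeak,
        scatter=pset.scatter if pset.scatter is not None else np.array([]),
    )
    header = dataclasses.asdict(pset.geometry)
    header["window_bounds_kev"] = [list(w) for w in pset.window_bounds_kev]
    header["is_noisy"] = bool(pset.is_noisy)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(header))


def load_projections(path) -> ProjectionSet:
    path = Path(path)
    arrs = np.load(path.with_suffix(".npz"))
    header = yaml.safe_load(path.with_suffix(".yaml").read_text())
    windows = tuple(tuple(w) for w in header.pop("window_bounds_kev"))
    noisy = header.pop("is_noisy")
    header["n_bins"] = tuple(header["n_bins"])
    geom = AcquisitionGeometry(**header)
    scatter = arrs["scatter"] if arrs["scatter"].size else None
    return ProjectionSet(geom, arrs["photopeak"], scatter,
                         window_bounds_kev=windows, is_noisy=noisy)
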