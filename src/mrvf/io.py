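"""NIfTI and config round-tripping shared by the command-line entry points."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "read_volume",
    "write_volume",
    "check_same_grid",
    "load_yaml",
    "dump_yaml",
    "write_json",
]


def read_volume(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    """Load a NIfTI volume; non-finite voxels are rejected with a count."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    bad = int(np.sum(~np.isfinite(data)))
    if bad:
        raise ValueError(f"{path}: {bad} non-finite voxel value(s)")
    return data, img


def write_volume(data: np.ndarray, path, like: nib.Nifti1Image | None = None, affine=None) -> None:
    """Write a NIfTI-1 volume, passing the reference header geometry through."""
    if like is not None:
        affine = like.affine
        header = like.header.copy()
        header.set_data_shape(data.shape)
    else:
        affine = np.eye(4) if affine is None else affine
        header = None
    img = nib.Nifti1Image(np.asarray(data), affine, header=header)
    nib.save(img, str(path))


def check_same_grid(named_images: dict[str, nib.Nifti1Image]) -> None:
    """Fail before any compute if spatial grids or affines disagree."""
    items = list(named_images.items())
    ref_name, ref = items[0]
    for name, img in items[1:]:
        if img.shape[:3] != ref.shape[:3]:
            raise ValueError(
                f"volume {name!r} grid {img.shape[:3]} does not match "
                f"{ref_name!r} grid {ref.shape[:3]}"
            )
        if not np.allclose(img.affine, ref.affine, atol=1e-4):
            raise ValueError(f"volume {name!r} affine does not match {ref_name!r}")


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
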