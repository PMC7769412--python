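"""Disk formats: slice images, masks, dataset directories with manifests.

Datasets are directories of 16-bit TIFF slices (HU as int16) plus boolean
PNG masks and a deterministic JSON manifest recording the generating specs,
seeds and split membership, so a dataset is reproducible and
self-describing.  Single slices can also be read from PNG, NIfTI (via
nibabel) and DICOM (via pydicom, read-only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import tifffile

from .phantom_sim import (
    ArtifactSpec,
    DeformationSpec,
    PairedSlice,
    PhantomSpec,
    SliceDataset,
)

__all__ = [
    "read_slice",
    "write_slice",
    "write_dataset",
    "read_dataset",
    "manifest_hash",
]


def read_slice(path) -> np.ndarray:
    """Read a 2-D HU slice from TIFF/PNG/NIfTI/DICOM by extension."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        return np.asarray(tifffile.imread(path), dtype=np.float64)
    if suffix.endswith(".png"):
        import imageio.v3 as iio

        return np.asarray(iio.imread(path), dtype=np.float64)
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        return np.asarray(np.squeeze(data), dtype=np.float64)
    if suffix.endswith(".dcm"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept
    raise ValueError(f"unsupported image format: {path.name}")


def write_slice(path, image: np.ndarray) -> None:
    """Write a 2-D HU slice; TIFF stores rounded int16 HU, NIfTI float."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.round(image).astype(np.int16))
        return
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(image, np.float32), np.eye(4)), str(path))
        return
    raise ValueError(f"unsupported output format: {path.name}")


def _write_mask(path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def _read_mask(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path)) > 127


def write_dataset(dataset: SliceDataset, out_dir, specs: Dict | None = None) -> dict:
    """Write a dataset directory with a deterministic manifest; returns it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries: List[dict] = []
    i = 0
    for split in ("train", "val", "test"):
        for s in getattr(dataset, split):
            stem = f"s{i:04d}"
            files = {
                "input": f"{stem}_input.tif",
                "label": f"{stem}_label.tif",
                "truth": f"{stem}_truth.tif",
                "body": f"{stem}_body.png",
            }
            write_slice(out / files["input"], s.input_image)
            write_slice(out / files["label"], s.label_image)
            write_slice(out / files["truth"], s.clean_truth)
            _write_mask(out / files["body"], s.body_mask)
            for name, m in s.roi_masks.items():
                files[f"roi_{name}"] = f"{stem}_roi_{name}.png"
                _write_mask(out / files[f"roi_{name}"], m)
            entries.append({"id": stem, "split": split, "files": files})
            i += 1
    manifest = {
        "format": "cxct-dataset-v1",
        "master_seed": dataset.master_seed,
        "n": i,
        "specs": specs or {},
        "slices": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_dataset(in_dir) -> SliceDataset:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    if manifest.get("format") != "cxct-dataset-v1":
        raise ValueError(f"{in_dir} is not a cxct dataset directory")
    splits: Dict[str, List[PairedSlice]] = {"train": [], "val": [], "test": []}
    for entry in manifest["slices"]:
        files = entry["files"]
        rois = {
            key[len("roi_"):]: _read_mask(src / fname)
            for key, fname in files.items() if key.startswith("roi_")
        }
        splits[entry["split"]].append(PairedSlice(
            input_image=read_slice(src / files["input"]),
            label_image=read_slice(src / files["label"]),
            clean_truth=read_slice(src / files["truth"]),
            body_mask=_read_mask(src / files["body"]),
            roi_masks=rois,
        ))
    return SliceDataset(master_seed=manifest["master_seed"], **splits)


def manifest_hash(manifest: dict) -> str:
    """Stable content hash of a manifest (for reproducibility checks)."""
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode("utf-8")
    ).hexdigest()


def specs_to_dict(phantom: PhantomSpec, artifact: ArtifactSpec,
                  deformation: DeformationSpec) -> dict:
    return {
        "phantom": dataclasses.asdict(phantom),
        "artifact": dataclasses.asdict(artifact),
        "deformation": dataclasses.asdict(deformation),
    }
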