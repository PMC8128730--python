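"""File formats: NIfTI image stacks, JSON ground truth and noise sidecars.

Image stacks are stored as NIfTI volumes with voxel order (slice, row,
col); in-plane pixel spacing and the slice center-to-center distance go in
the header zooms, and slice thickness / gap are recorded in the header
description so the split survives a round trip. Ground truth is a plain
JSON document: per-slice contour vertex lists, ROI pixel lists, the true
scar mask as per-slice pixel-index lists, and the true scar percentage.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .datatypes import ContourSet, GroundTruth, ImageStack, NoiseField, ROI


def save_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an image stack as NIfTI with spacing metadata in the header."""
    sr, sc = stack.pixel_spacing_mm
    affine = np.diag([stack.slice_spacing_mm, sr, sc, 1.0])
    img = nib.Nifti1Image(np.asarray(stack.voxels, dtype=np.float64), affine)
    img.header.set_zooms((stack.slice_spacing_mm, sr, sc))
    img.header["descrip"] = f"th={stack.slice_thickness_mm};gap={stack.slice_gap_mm}".encode()
    nib.save(img, str(path))


def load_stack(path: str | Path) -> ImageStack:
    """Read an image stack written by :func:`save_stack`."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(errors="replace")
    thickness, gap = zooms[0], 0.0
    for part in descrip.split(";"):
        if part.startswith("th="):
            thickness = float(part[3:])
        elif part.startswith("gap="):
            gap = float(part[4:])
    return ImageStack(
        voxels=np.asarray(img.dataobj, dtype=float),
        pixel_spacing_mm=(float(zooms[1]), float(zooms[2])),
        slice_thickness_mm=float(thickness),
        slice_gap_mm=float(gap),
    )


def save_noise(noise: NoiseField, path: str | Path) -> None:
    """Write a noise field as NIfTI plus a JSON sidecar with sigma and seed."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(noise.values, dtype=np.float64), np.eye(4))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps({"sigma": noise.sigma, "seed": noise.seed}))


def load_noise(path: str | Path) -> NoiseField:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return NoiseField(
        values=np.asarray(img.dataobj, dtype=float),
        sigma=float(meta["sigma"]),
        seed=int(meta["seed"]),
    )


def _roi_to_json(roi: ROI) -> dict:
    return {"slice_index": int(roi.slice_index), "pixels": roi.pixels.tolist()}


def _roi_from_json(obj: dict) -> ROI:
    return ROI(int(obj["slice_index"]), np.asarray(obj["pixels"], dtype=int))


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize ground truth (contours, ROIs, scar mask, scar %) to JSON."""
    mask = truth.true_scar_mask
    doc = {
        "format": "lgequant-ground-truth-v1",
        "contours": {
            str(i): {"epi": epi.tolist(), "endo": endo.tolist()}
            for i, (epi, endo) in truth.contours.contours.items()
        },
        "rois": {
            "remote": _roi_to_json(truth.remote_roi),
            "scar": _roi_to_json(truth.scar_roi),
            "air": _roi_to_json(truth.air_roi),
        },
        "mask_shape": list(mask.shape),
        "true_scar_mask": {
            str(i): np.argwhere(mask[i]).tolist()
            for i in range(mask.shape[0])
            if mask[i].any()
        },
        "true_scar_percent": float(truth.true_scar_percent),
    }
    Path(path).write_text(json.dumps(doc))


def load_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "lgequant-ground-truth-v1":
        raise ValueError(f"{path}: not an lgequant ground-truth document")
    contours = ContourSet(
        {
            int(i): (np.asarray(c["epi"], float), np.asarray(c["endo"], float))
            for i, c in doc["contours"].items()
        }
    )
    mask = np.zeros(tuple(doc["mask_shape"]), dtype=bool)
    for i, idx in doc["true_scar_mask"].items():
        idx = np.asarray(idx, dtype=int)
        mask[int(i), idx[:, 0], idx[:, 1]] = True
    return GroundTruth(
        contours=contours,
        remote_roi=_roi_from_json(doc["rois"]["remote"]),
        scar_roi=_roi_from_json(doc["rois"]["scar"]),
        air_roi=_roi_from_json(doc["rois"]["air"]),
        true_scar_mask=mask,
        true_scar_percent=float(doc["true_scar_percent"]),
    )
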