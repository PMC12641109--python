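"""File I/O: NIfTI volumes/masks, lossless multi-frame clips, sidecars."""

from __future__ import annotations

import json
import os

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .preprocessing import (BoundingBox, Modality, MRIVolume, PreprocessedSubject,
                            SegmentationMask, VideoClip)


def save_volume_nifti(vol: MRIVolume, path) -> None:
    affine = np.diag([*vol.spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), path)


def load_volume_nifti(path, modality: Modality | str) -> MRIVolume:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return MRIVolume(np.asarray(img.dataobj, dtype=np.float64), spacing,
                     Modality(modality))


def save_mask_nifti(mask: SegmentationMask, path,
                    spacing_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing_mm, 1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), path)


def load_mask_nifti(path) -> SegmentationMask:
    img = nib.load(path)
    return SegmentationMask((np.asarray(img.dataobj) > 0.5).astype(np.uint8))


def save_phantom_subject(out_dir, subject_id: str, volumes: dict,
                         mask: SegmentationMask,
                         spacing_mm=(1.0, 1.0, 1.0)) -> None:
    """Write one subject as <id>_<modality>.nii.gz files plus <id>_seg."""
    os.makedirs(out_dir, exist_ok=True)
    for modality, vol in volumes.items():
        save_volume_nifti(vol, os.path.join(out_dir,
                          f"{subject_id}_{Modality(modality).value}.nii.gz"))
    save_mask_nifti(mask, os.path.join(out_dir, f"{subject_id}_seg.nii.gz"),
                    spacing_mm)


def save_clip(clip: VideoClip, path) -> None:
    """Lossless 8-bit multi-frame TIFF, one page per frame."""
    iio.imwrite(path, clip.frames, extension=".tif")


def load_clip(path, modality: Modality | str) -> VideoClip:
    frames = iio.imread(path)
    return VideoClip(np.asarray(frames, dtype=np.uint8), Modality(modality))


def save_preprocessed_subject(pp: PreprocessedSubject, out_dir,
                              subject_id: str) -> None:
    """Write the five clips plus a JSON sidecar (bbox, percentiles)."""
    os.makedirs(out_dir, exist_ok=True)
    for modality, clip in pp.clips.items():
        save_clip(clip, os.path.join(out_dir,
                  f"{subject_id}_{modality.value}.tif"))
    sidecar = {
        "subject_id": subject_id,
        "bounding_box": {"row0": pp.box.row0, "col0": pp.box.col0,
                         "height": pp.box.height, "width": pp.box.width},
        "percentiles": pp.percentiles,
    }
    with open(os.path.join(out_dir, f"{subject_id}_preprocess.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_preprocessed_subject(out_dir, subject_id: str) -> PreprocessedSubject:
    with open(os.path.join(out_dir, f"{subject_id}_preprocess.json")) as fh:
        sidecar = json.load(fh)
    clips = {}
    for modality in Modality:
        path = os.path.join(out_dir, f"{subject_id}_{modality.value}.tif")
        if os.path.exists(path):
            clips[modality] = load_clip(path, modality)
    bb = sidecar["bounding_box"]
    return PreprocessedSubject(clips,
                               BoundingBox(bb["row0"], bb["col0"],
                                           bb["height"], bb["width"]),
                               {k: tuple(v) for k, v in
                                sidecar["percentiles"].items()})
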