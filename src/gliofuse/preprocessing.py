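"""mpMRI preprocessing: geometry standardization, intensity normalization,
tumor bounding boxes, volume-to-video conversion and the delta (T1wCE - T1)
contrast-enhancement volume.

The pipeline assumes volumes arrive co-registered and skull-stripped (as in
curated glioma collections); what remains here is the deterministic geometry
and intensity plumbing that turns a registered volume + whole-tumor mask into
the 150-frame 128x128 8-bit clips consumed by video feature extractors.

Pipeline order is fixed: standardize -> (delta) -> normalize -> bbox -> video.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage

TARGET_SHAPE = (240, 240, 150)
TARGET_SPACING = 1.0
BOX_SIZE = 128
N_FRAMES = TARGET_SHAPE[2]


class Modality(str, Enum):
    """Imaging modality of a volume; DELTA is the voxelwise T1wCE - T1 image."""

    T1 = "t1"
    T1WCE = "t1wce"
    T2 = "t2"
    FLAIR = "flair"
    DELTA = "delta"


@dataclass
class MRIVolume:
    """A registered 3D intensity grid (rows x cols x slices)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: Modality = Modality.T1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if not isinstance(self.modality, Modality):
            self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SegmentationMask:
    """Binary whole-tumor mask aligned with its volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError("mask must be 3D")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True)
class BoundingBox:
    """Fixed-size axial crop window shared by all frames of one subject.

    ``row0``/``col0`` are 0-based indices of the top-left corner; the window
    is always ``height`` x ``width`` (128 x 128 by default).
    """

    row0: int
    col0: int
    height: int = BOX_SIZE
    width: int = BOX_SIZE

    def __post_init__(self) -> None:
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("bounding box corner must be non-negative")


@dataclass
class VideoClip:
    """A 150-frame 128x128 grayscale clip, one frame per axial slice."""

    frames: np.ndarray
    source_modality: Modality

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3 or frames.shape[0] != N_FRAMES:
            raise ValueError(
                f"clip must have exactly {N_FRAMES} frames, got shape {frames.shape}"
            )
        if frames.shape[1:] != (BOX_SIZE, BOX_SIZE):
            raise ValueError(f"frames must be {BOX_SIZE}x{BOX_SIZE}")
        if frames.dtype != np.uint8:
            if frames.min() < 0 or frames.max() > 255:
                raise ValueError("frame values must lie in [0, 255]")
            frames = frames.astype(np.uint8)
        self.frames = frames
        if not isinstance(self.source_modality, Modality):
            self.source_modality = Modality(self.source_modality)


def _center_crop_pad(data: np.ndarray, target: tuple[int, int, int],
                     constant: float = 0.0) -> np.ndarray:
    """Center-crop or zero-pad each axis to `target`.

    Crop start is (in-out)//2; pad-before is (out-in)//2, so a voxel at the
    input center lands at the output center.
    """
    out = data
    for ax, (n_in, n_out) in enumerate(zip(out.shape, target)):
        if n_in > n_out:
            start = (n_in - n_out) // 2
            sl = [slice(None)] * out.ndim
            sl[ax] = slice(start, start + n_out)
            out = out[tuple(sl)]
        elif n_in < n_out:
            before = (n_out - n_in) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, n_out - n_in - before)
            out = np.pad(out, pad, mode="constant", constant_values=constant)
    return out


def standardize_geometry(
    vol: MRIVolume,
    mask: SegmentationMask | None = None,
    target_shape: tuple[int, int, int] = TARGET_SHAPE,
    target_spacing: float = TARGET_SPACING,
):
    """Resample to isotropic 1 mm voxels and center-crop/pad to 240x240x150.

    Intensities use trilinear interpolation; the mask (if given) uses
    nearest-neighbour so it stays binary. A volume already at target spacing
    and shape is returned bit-identical (modulo a copy).

    Returns the standardized volume, or ``(volume, mask)`` when a mask is
    supplied.
    """
    zoom = tuple(s / target_spacing for s in vol.spacing_mm)
    if all(abs(z - 1.0) < 1e-9 for z in zoom):
        data = vol.data.copy()
        mdata = mask.data.copy() if mask is not None else None
    else:
        data = ndimage.zoom(vol.data.astype(np.float64), zoom, order=1,
                            mode="nearest", grid_mode=True)
        mdata = None
        if mask is not None:
            mdata = ndimage.zoom(mask.data, zoom, order=0,
                                 mode="nearest", grid_mode=True)
    data = _center_crop_pad(data, target_shape)
    out_vol = MRIVolume(data, (target_spacing,) * 3, vol.modality)
    if mask is None:
        return out_vol
    mdata = _center_crop_pad(mdata, target_shape)
    return out_vol, SegmentationMask(mdata)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half-to-even; the pipeline pins half-away-from-zero
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_intensity(vol: MRIVolume, low_pct: float = 1.0,
                        high_pct: float = 99.0) -> MRIVolume:
    """Map the 1st-99th intensity percentile window linearly onto 0-255.

    Percentiles are computed over all voxels (linear-interpolation
    definition); values at or below p1 map to 0, at or above p99 to 255, and
    the result is rounded half-away-from-zero to 8 bits. A constant volume
    (p99 == p1) yields all zeros with a warning rather than an error, so one
    degenerate subject cannot abort a cohort run.
    """
    data = vol.data.astype(np.float64)
    p_lo, p_hi = np.percentile(data, [low_pct, high_pct])
    if p_hi <= p_lo:
        warnings.warn(
            "degenerate intensity window (p99 <= p1); emitting all-zero volume",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.zeros(data.shape, dtype=np.uint8)
    else:
        scaled = np.clip((data - p_lo) / (p_hi - p_lo), 0.0, 1.0)
        out = _round_half_away(255.0 * scaled).astype(np.uint8)
    return MRIVolume(out, vol.spacing_mm, vol.modality)


def compute_bounding_box(mask: SegmentationMask, size: int = BOX_SIZE) -> BoundingBox:
    """Anchor a fixed 128x128 box at the tumor's top-left extreme.

    ``row0`` is the minimum row index containing foreground in ANY slice and
    ``col0`` the minimum column index likewise; the same box is applied to
    every frame. If anchor + 128 would overrun the image, the corner is
    clamped to ``dim - 128`` (anchor-and-clamp; a tumor wider than the box is
    truncated on its far side).
    """
    fg = mask.data != 0
    if not fg.any():
        raise ValueError("empty mask")
    n_rows, n_cols = mask.shape[:2]
    if n_rows < size or n_cols < size:
        raise ValueError(f"image smaller than {size}x{size} bounding box")
    rows = np.flatnonzero(fg.any(axis=(1, 2)))
    cols = np.flatnonzero(fg.any(axis=(0, 2)))
    row0 = min(int(rows[0]), n_rows - size)
    col0 = min(int(cols[0]), n_cols - size)
    return BoundingBox(row0=row0, col0=col0, height=size, width=size)


def volume_to_video(vol8: MRIVolume, box: BoundingBox) -> VideoClip:
    """Crop every axial slice to the box; slice k becomes frame k (lossless)."""
    n_rows, n_cols, n_slices = vol8.shape
    if n_slices != N_FRAMES:
        raise ValueError(f"expected {N_FRAMES} slices, got {n_slices}")
    if box.row0 + box.height > n_rows or box.col0 + box.width > n_cols:
        raise ValueError("bounding box extends outside the volume")
    sub = vol8.data[box.row0:box.row0 + box.height,
                    box.col0:box.col0 + box.width, :]
    frames = np.moveaxis(sub, 2, 0)
    return VideoClip(np.ascontiguousarray(frames), vol8.modality)


def compute_delta_volume(t1wce: MRIVolume, t1: MRIVolume) -> MRIVolume:
    """Voxelwise contrast-enhancement image T1wCE - T1.

    Computed on geometry-standardized, *pre-normalization* intensities; the
    difference image then passes through :func:`normalize_intensity` like any
    modality, receiving its own 0-255 window.
    """
    if t1wce.shape != t1.shape:
        raise ValueError(f"shape mismatch: {t1wce.shape} vs {t1.shape}")
    if t1wce.spacing_mm != t1.spacing_mm:
        raise ValueError("spacing mismatch between T1wCE and T1")
    return MRIVolume(t1wce.data.astype(np.float64) - t1.data.astype(np.float64),
                     t1.spacing_mm, Modality.DELTA)


@dataclass
class PreprocessedSubject:
    """The five clips for one subject plus provenance of the preprocessing."""

    clips: dict[Modality, VideoClip]
    box: BoundingBox
    percentiles: dict[str, tuple[float, float]] = field(default_factory=dict)


def preprocess_subject(volumes: dict[Modality | str, MRIVolume],
                       mask: SegmentationMask) -> PreprocessedSubject:
    """Run the full pipeline for one subject.

    Expects the four acquired modalities (T1, T1wCE, T2, FLAIR) plus the
    whole-tumor mask on the same grid; emits exactly five clips (the four
    modalities and the delta image), each 150 x 128 x 128.
    """
    vols = {Modality(k): v for k, v in volumes.items()}
    required = {Modality.T1, Modality.T1WCE, Modality.T2, Modality.FLAIR}
    if set(vols) != required:
        raise ValueError(f"need exactly modalities {sorted(m.value for m in required)}")

    first = next(iter(vols.values()))
    std_mask = None
    std = {}
    for mod, vol in vols.items():
        if vol.shape != first.shape or vol.spacing_mm != first.spacing_mm:
            raise ValueError("all modalities of a subject must share one grid")
        if std_mask is None:
            std[mod], std_mask = standardize_geometry(vol, mask)
        else:
            std[mod] = standardize_geometry(vol)
    std[Modality.DELTA] = compute_delta_volume(std[Modality.T1WCE], std[Modality.T1])

    box = compute_bounding_box(std_mask)
    clips: dict[Modality, VideoClip] = {}
    percentiles: dict[str, tuple[float, float]] = {}
    for mod, vol in std.items():
        p_lo, p_hi = np.percentile(vol.data.astype(np.float64), [1.0, 99.0])
        percentiles[mod.value] = (float(p_lo), float(p_hi))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vol8 = normalize_intensity(vol)
        clips[mod] = volume_to_video(vol8, box)
    return PreprocessedSubject(clips=clips, box=box, percentiles=percentiles)
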