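"""From co-registered volumes to normalized, padded 2D slice samples.

Each modality volume is z-normalized to zero mean / unit variance; QSM is
first truncated to ±k standard deviations (k = 5 by default) because QSM
reconstructions carry high-intensity noise near the brain boundary that
would otherwise dominate the normalization.  Volumes are then sliced along
the axial axis and edge-padded to a fixed in-plane size (256 x 256 by
default) to form the training/inference unit, :class:`SliceSample`.

Normalization is per 3D volume, not per slice: slice-wise scaling would
distort lesion contrast between slices of the same brain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_types import (
    CLASS_CMB,
    CLASS_IRON,
    DegenerateInputError,
    ExperimentConfig,
    LabelVolume,
    MODALITIES,
    MultiModalVolume,
    ValidationError,
)


@dataclass
class SliceSample:
    """One multi-channel axial slice with its label slice.

    ``image`` is (C, target, target); channel order is the canonical
    (SWI, QSM, T2w) restricted to the modalities in use.  ``pad_offsets``
    and ``orig_shape`` record the geometry needed to undo the padding when
    stacking per-slice predictions back into a 3D volume.
    """

    image: np.ndarray  # (C, H, W) float32
    label: np.ndarray  # (H, W) int16
    participant_id: str
    slice_index: int
    has_lesion: dict  # class -> bool
    pad_offsets: tuple = (0, 0)
    orig_shape: tuple = None

    def __post_init__(self) -> None:
        if self.image.ndim != 3:
            raise ValidationError("SliceSample.image must be (C, H, W)")
        if self.image.shape[1:] != self.label.shape:
            raise ValidationError(
                f"image spatial shape {self.image.shape[1:]} != label {self.label.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.image.shape[0]


def znormalize(grid: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance normalization of a whole grid."""
    grid = np.asarray(grid, dtype=np.float64)
    sd = grid.std()
    if sd == 0:
        raise DegenerateInputError("cannot z-normalize a constant grid")
    return (grid - grid.mean()) / sd


def truncate_qsm(grid: np.ndarray, k: float = 5.0,
                 mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Clip QSM values to ±k·σ, with σ from the full grid (or *mask*).

    Applied *before* z-normalization.  Idempotent only in the sense that
    re-clipping with the σ of the first pass changes nothing; the clipped
    grid has a smaller σ of its own.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    grid = np.asarray(grid, dtype=np.float64)
    sigma = grid[mask].std() if mask is not None else grid.std()
    return np.clip(grid, -k * sigma, k * sigma)


def _pad_or_crop_2d(arr: np.ndarray, target: int, mode: str):
    """Edge-pad (or center-crop) a 2D array to target x target.

    Returns the array and the (row, col) offsets of the original top-left
    corner inside the output (negative when cropped).
    """
    out = arr
    offsets = []
    for axis in range(2):
        n = out.shape[axis]
        diff = target - n
        if diff >= 0:
            lo = diff // 2  # extra voxel goes to the high side
            hi = diff - lo
            pad = [(0, 0), (0, 0)]
            pad[axis] = (lo, hi)
            if mode == "edge":
                out = np.pad(out, pad, mode="edge")
            else:
                out = np.pad(out, pad, mode="constant", constant_values=0)
            offsets.append(lo)
        else:
            start = (-diff) // 2
            sl = [slice(None), slice(None)]
            sl[axis] = slice(start, start + target)
            out = out[tuple(sl)]
            offsets.append(-start)
    return out, tuple(offsets)


def unpad_2d(arr: np.ndarray, orig_shape: Sequence[int], offsets: Sequence[int]):
    """Undo :func:`_pad_or_crop_2d` (exact for padded, partial for cropped)."""
    sls = []
    for axis in range(2):
        off = offsets[axis]
        if off >= 0:
            sls.append(slice(off, off + orig_shape[axis]))
        else:
            sls.append(slice(0, arr.shape[axis]))
    return arr[tuple(sls)]


def slice_and_pad(
    volume: MultiModalVolume,
    labels: Optional[LabelVolume],
    target: int = 256,
    modalities: Optional[Sequence[str]] = None,
) -> list:
    """Cut a volume into padded axial :class:`SliceSample`\\ s.

    Image channels are edge-padded (replicating border values); label
    padding uses background.  No intensity normalization is performed here.
    """
    modalities = tuple(modalities or volume.available_modalities)
    grids = [np.moveaxis(volume.modality(m), volume.axial_axis, 0) for m in modalities]
    if labels is not None:
        if labels.shape != volume.shape:
            raise ValidationError(
                f"label shape {labels.shape} != volume shape {volume.shape}"
            )
        lab = np.moveaxis(labels.labels, volume.axial_axis, 0)
    samples = []
    for k in range(grids[0].shape[0]):
        chans = []
        for g in grids:
            padded, offsets = _pad_or_crop_2d(g[k], target, mode="edge")
            chans.append(padded)
        image = np.stack(chans).astype(np.float32)
        if labels is not None:
            lab_p, _ = _pad_or_crop_2d(lab[k], target, mode="zero")
            lab_p = lab_p.astype(np.int16)
        else:
            lab_p = np.zeros((target, target), dtype=np.int16)
        has_lesion = {
            CLASS_CMB: bool((lab_p == CLASS_CMB).any()),
            CLASS_IRON: bool((lab_p == CLASS_IRON).any()),
        }
        samples.append(
            SliceSample(
                image=image,
                label=lab_p,
                participant_id=volume.participant_id,
                slice_index=k,
                has_lesion=has_lesion,
                pad_offsets=offsets,
                orig_shape=g[k].shape,
            )
        )
    return samples


def normalize_volume(volume: MultiModalVolume, config: ExperimentConfig) -> MultiModalVolume:
    """Apply QSM truncation + z-normalization to the configured modalities."""
    grids = {}
    for m in config.modalities:
        g = volume.modality(m)
        if m == "qsm":
            g = truncate_qsm(g, config.qsm_truncation_k)
        grids[m] = znormalize(g).astype(np.float32)
    return MultiModalVolume(
        participant_id=volume.participant_id,
        swi=grids["swi"],
        qsm=grids.get("qsm"),
        t2w=grids.get("t2w"),
        voxel_dims=volume.voxel_dims,
        axial_axis=volume.axial_axis,
    )


def assemble_channels(
    volume: MultiModalVolume,
    labels: Optional[LabelVolume],
    config: ExperimentConfig,
) -> list:
    """Normalized, stacked slice samples in canonical channel order.

    Channel order is (SWI, QSM, T2w) restricted to ``config.modalities``;
    the QSM channel is truncated (±kσ) then z-normalized, the others only
    z-normalized.
    """
    for m in config.modalities:
        if getattr(volume, m) is None:
            raise ValidationError(
                f"modality {m!r} requested but absent for {volume.participant_id}"
            )
    ordered = tuple(m for m in MODALITIES if m in config.modalities)
    normalized = normalize_volume(volume, config)
    return slice_and_pad(normalized, labels, target=config.slice_size,
                         modalities=ordered)
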