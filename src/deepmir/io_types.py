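"""Domain types, NIfTI I/O, dataset manifests and experiment configuration.

The central objects are :class:`MultiModalVolume` (co-registered SWI/QSM/T2w
grids for one participant), :class:`LabelVolume` (the integer lesion
annotation sharing that geometry), :class:`DatasetManifest` (which files
belong to which participant) and :class:`ExperimentConfig` (every knob of a
segmentation experiment, serialisable to YAML).

Lesion classes are encoded as 0 = background, 1 = cerebral microbleed (CMB),
2 = non-hemorrhage iron deposit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

CLASS_BACKGROUND = 0
CLASS_CMB = 1
CLASS_IRON = 2

DEFAULT_CLASS_MAP = {
    CLASS_BACKGROUND: "background",
    CLASS_CMB: "cmb",
    CLASS_IRON: "iron_deposit",
}

#: Modalities in canonical channel order.  SWI is mandatory in every
#: experiment; QSM and T2w are optional extras.
MODALITIES = ("swi", "qsm", "t2w")

#: Default voxel dimensions in mm.  The phantom uses 1.0 x 1.0 x 1.5 mm,
#: i.e. a 1.5 mm^3 voxel volume.
DEFAULT_VOXEL_DIMS = (1.0, 1.0, 1.5)


class ValidationError(ValueError):
    """A contract violation in user-supplied data or configuration."""


class FormatError(ValueError):
    """A file exists but does not have the expected structure."""


class DegenerateInputError(ValueError):
    """An input is numerically degenerate (e.g. constant image)."""


def _check_grid(name: str, grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValidationError(f"{name} must be a 3D grid, got ndim={grid.ndim}")
    return grid


@dataclass
class MultiModalVolume:
    """Co-registered 3D scalar grids for one participant.

    Parameters
    ----------
    participant_id : str
        Unique participant identifier.
    swi : ndarray
        Susceptibility-weighted image, arbitrary units.  Always present.
    qsm : ndarray, optional
        Quantitative susceptibility map (ppm-like a.u.); paramagnetic
        tissue positive, diamagnetic negative.
    t2w : ndarray, optional
        T2-weighted image, arbitrary units.
    voxel_dims : tuple of float
        Voxel edge lengths in mm.
    axial_axis : int
        Index of the axis along which axial slices are taken.
    """

    participant_id: str
    swi: np.ndarray
    qsm: Optional[np.ndarray] = None
    t2w: Optional[np.ndarray] = None
    voxel_dims: tuple = DEFAULT_VOXEL_DIMS
    axial_axis: int = 2

    def __post_init__(self) -> None:
        self.swi = _check_grid("swi", self.swi)
        for name in ("qsm", "t2w"):
            grid = getattr(self, name)
            if grid is not None:
                grid = _check_grid(name, grid)
                if grid.shape != self.swi.shape:
                    raise ValidationError(
                        f"{name} shape {grid.shape} != swi shape {self.swi.shape}"
                    )
                setattr(self, name, grid)
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)
        if len(self.voxel_dims) != 3 or any(v <= 0 for v in self.voxel_dims):
            raise ValidationError(f"voxel_dims must be 3 positive lengths, got {self.voxel_dims}")
        if self.axial_axis not in (0, 1, 2):
            raise ValidationError(f"axial_axis must be 0, 1 or 2, got {self.axial_axis}")

    @property
    def shape(self) -> tuple:
        return self.swi.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_dims))

    def modality(self, name: str) -> np.ndarray:
        grid = getattr(self, name.lower())
        if grid is None:
            raise ValidationError(f"modality {name!r} absent for participant {self.participant_id}")
        return grid

    @property
    def available_modalities(self) -> tuple:
        return tuple(m for m in MODALITIES if getattr(self, m) is not None)


@dataclass
class LabelVolume:
    """Integer lesion-class grid paired with a :class:`MultiModalVolume`."""

    labels: np.ndarray
    class_map: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    voxel_dims: tuple = DEFAULT_VOXEL_DIMS

    def __post_init__(self) -> None:
        self.labels = _check_grid("labels", self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValidationError("labels must be integer-valued")
            self.labels = self.labels.astype(np.int16)
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.class_map)
        if unknown:
            raise ValidationError(f"labels contain values outside class_map: {sorted(unknown)}")
        self.voxel_dims = tuple(float(v) for v in self.voxel_dims)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def class_mask(self, cls: int) -> np.ndarray:
        return self.labels == cls


@dataclass
class ManifestEntry:
    participant_id: str
    swi: str
    qsm: Optional[str] = None
    t2w: Optional[str] = None
    labels: Optional[str] = None


@dataclass
class DatasetManifest:
    """List of participants and the file paths of their modalities/labels."""

    entries: list
    modalities_used: tuple = ("swi",)
    root: Optional[Path] = None

    def __post_init__(self) -> None:
        ids = [e.participant_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate participant_id(s): {dupes}")
        for m in self.modalities_used:
            if m not in MODALITIES:
                raise ValidationError(f"unknown modality {m!r}")
        if "swi" not in self.modalities_used:
            raise ValidationError("SWI is mandatory in every experiment")
        for e in self.entries:
            if not e.swi:
                raise ValidationError(f"participant {e.participant_id}: missing SWI path")
            for m in self.modalities_used:
                if not getattr(e, m):
                    raise ValidationError(
                        f"participant {e.participant_id}: modality {m!r} required but absent"
                    )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def participant_ids(self) -> list:
        return [e.participant_id for e in self.entries]

    def resolve(self, path: str) -> Path:
        p = Path(path)
        if not p.is_absolute() and self.root is not None:
            p = self.root / p
        return p


@dataclass
class ExperimentConfig:
    """All knobs of one segmentation experiment.

    The defaults reproduce the study conditions: QSM values truncated at
    k = 5 standard deviations, at most 30 training epochs, a 75/25
    train/validation split of the non-test participants, centroid-matching
    tolerances of 3 voxels for CMBs and 5 for iron deposits, and a 0.5
    acceptance threshold on the single-class probability map.
    """

    task: str = "single_class_cmb"  # single_class_cmb | single_class_iron | multiclass
    modalities: tuple = ("swi",)
    qsm_truncation_k: float = 5.0
    max_epochs: int = 30
    val_fraction: float = 0.25
    tolerance_cmb: float = 3.0
    tolerance_iron: float = 5.0
    threshold: float = 0.5
    seed: int = 0
    # network / optimisation knobs (unstated in the source study; configurable)
    slice_size: int = 256
    n_resolutions: int = 6
    base_width: int = 64
    learning_rate: float = 1e-4
    batch_size: int = 16
    # cap on training samples drawn per epoch; None = use all
    max_train_samples_per_epoch: Optional[int] = None
    max_val_samples: Optional[int] = None
    # keyword arguments for the augmentation policy (see
    # deepmir.augment.AugmentationPolicy); None = policy defaults
    augmentation: Optional[dict] = None

    _TASKS = ("single_class_cmb", "single_class_iron", "multiclass")

    def __post_init__(self) -> None:
        if self.task not in self._TASKS:
            raise ValidationError(f"task must be one of {self._TASKS}, got {self.task!r}")
        self.modalities = tuple(m.lower() for m in self.modalities)
        for m in self.modalities:
            if m not in MODALITIES:
                raise ValidationError(f"unknown modality {m!r}")
        if "swi" not in self.modalities:
            raise ValidationError("SWI is mandatory in every experiment")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValidationError("val_fraction must be in (0, 1)")
        if self.tolerance_cmb <= 0 or self.tolerance_iron <= 0:
            raise ValidationError("matching tolerances must be positive")
        if not (0.0 < self.threshold < 1.0):
            raise ValidationError("threshold must be in (0, 1)")
        if self.qsm_truncation_k <= 0:
            raise ValidationError("qsm_truncation_k must be positive")

    @property
    def n_classes(self) -> int:
        return 3 if self.task == "multiclass" else 2

    @property
    def target_classes(self) -> tuple:
        """Lesion classes this task predicts (background excluded)."""
        return {
            "single_class_cmb": (CLASS_CMB,),
            "single_class_iron": (CLASS_IRON,),
            "multiclass": (CLASS_CMB, CLASS_IRON),
        }[self.task]

    def tolerance_for(self, cls: int) -> float:
        return self.tolerance_cmb if cls == CLASS_CMB else self.tolerance_iron

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "modalities" in raw:
            raw["modalities"] = tuple(raw["modalities"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["modalities"] = list(self.modalities)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_volume(path) -> tuple:
    """Read one NIfTI volume.

    Returns
    -------
    grid : ndarray
        The 3D image data.
    voxel_dims : tuple of float
        Voxel edge lengths (mm) from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3D image, got shape {img.shape}")
    grid = np.asarray(img.dataobj)
    voxel_dims = tuple(float(z) for z in img.header.get_zooms()[:3])
    return grid, voxel_dims


def write_volume(grid: np.ndarray, voxel_dims: Sequence[float], path) -> Path:
    """Write a 3D grid as NIfTI-1, preserving dtype and voxel dimensions."""
    grid = _check_grid("grid", np.asarray(grid))
    voxel_dims = tuple(float(v) for v in voxel_dims)
    if len(voxel_dims) != 3 or any(v <= 0 for v in voxel_dims):
        raise ValidationError(f"voxel_dims must be 3 positive lengths, got {voxel_dims}")
    affine = np.diag(list(voxel_dims) + [1.0])
    img = nib.Nifti1Image(grid, affine)
    img.header.set_zooms(voxel_dims)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Manifest

MANIFEST_COLUMNS = ["participant_id", "swi", "qsm", "t2w", "labels"]


def load_manifest(path, modalities_used: Optional[Sequence[str]] = None) -> DatasetManifest:
    """Load a CSV manifest (columns ``participant_id,swi,qsm,t2w,labels``).

    If *modalities_used* is omitted it is inferred as SWI plus every optional
    modality with a path in every row.  Requesting a modality that is missing
    for some participants raises :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype=str).fillna("")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty manifest") from exc
    missing_cols = [c for c in ("participant_id", "swi") if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required column(s) {missing_cols}")
    if len(df) == 0:
        raise ValidationError(f"{path}: manifest has no rows")
    for c in MANIFEST_COLUMNS:
        if c not in df.columns:
            df[c] = ""
    entries = [
        ManifestEntry(
            participant_id=row.participant_id,
            swi=row.swi,
            qsm=row.qsm or None,
            t2w=row.t2w or None,
            labels=row.labels or None,
        )
        for row in df.itertuples(index=False)
    ]
    if modalities_used is None:
        modalities_used = ["swi"] + [
            m for m in ("qsm", "t2w") if all(getattr(e, m) for e in entries)
        ]
    return DatasetManifest(
        entries=entries, modalities_used=tuple(modalities_used), root=path.parent
    )


def save_manifest(manifest: DatasetManifest, path) -> Path:
    rows = [
        {
            "participant_id": e.participant_id,
            "swi": e.swi,
            "qsm": e.qsm or "",
            "t2w": e.t2w or "",
            "labels": e.labels or "",
        }
        for e in manifest.entries
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


def load_volume_set(manifest: DatasetManifest, entry: ManifestEntry):
    """Load one participant's volumes (and labels, if listed) from disk."""
    grids = {}
    voxel_dims = None
    for m in manifest.modalities_used:
        p = getattr(entry, m)
        grid, dims = read_volume(manifest.resolve(p))
        grids[m] = grid
        voxel_dims = voxel_dims or dims
    vol = MultiModalVolume(
        participant_id=entry.participant_id,
        swi=grids["swi"],
        qsm=grids.get("qsm"),
        t2w=grids.get("t2w"),
        voxel_dims=voxel_dims,
    )
    labels = None
    if entry.labels:
        lab_grid, lab_dims = read_volume(manifest.resolve(entry.labels))
        labels = LabelVolume(labels=lab_grid.astype(np.int16), voxel_dims=lab_dims)
        if labels.shape != vol.shape:
            raise ValidationError(
                f"{entry.participant_id}: label shape {labels.shape} != image shape {vol.shape}"
            )
    return vol, labels
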