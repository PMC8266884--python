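"""Synthetic multi-modal brain phantoms with known lesion ground truth.

Real cohort data for this problem (SWI/QSM/T2w volumes with expert CMB and
iron-deposit annotations) cannot be redistributed, so this module generates
volumes that emulate the relevant statistics of such a cohort:

* **CMBs** — small near-spherical clusters (mean ~4.2 voxels, ~6 mm^3 at a
  1.5 mm^3 voxel volume), hypointense on SWI, paramagnetic (positive) on
  QSM, anywhere in the brain foreground.
* **Iron deposits** — larger irregular clusters (mean ~17.4 voxels) grown by
  a seeded random walk, hypointense on SWI, strongly positive on QSM,
  confined to a central "basal ganglia" ellipsoid.
* **Calcification mimics** — SWI-hypointense like the lesions but
  *diamagnetic* (negative) on QSM; they are deliberately absent from the
  label volume, so a model can only avoid them by exploiting QSM.
* **Vessels** — tubular SWI-hypointense curves, also unlabeled.

Per-participant lesion counts follow the cohort mixture observed in the
study population: most participants carry 0-2 CMBs, a minority 3-8, and an
optional single high-burden outlier (>100 CMBs).

Intensities are arbitrary units (everything is z-normalized downstream);
lesion contrast is several noise standard deviations so that a small network
can learn from a desk-scale cohort.  This is an *appearance* phantom, not a
physical MR simulation: there is no dipole convolution, k-space sampling or
skull/CSF anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_types import (
    CLASS_CMB,
    CLASS_IRON,
    DEFAULT_VOXEL_DIMS,
    DatasetManifest,
    LabelVolume,
    ManifestEntry,
    MultiModalVolume,
    save_manifest,
    write_volume,
)


class GenerationError(RuntimeError):
    """Requested lesion configuration could not be placed without overlap."""


@dataclass
class LesionRecord:
    cls: int
    centroid: tuple  # voxel coordinates (unweighted mean of member voxels)
    n_voxels: int


@dataclass
class MimicRecord:
    kind: str  # "calcification" | "vessel"
    centroid: tuple


@dataclass
class PhantomConfig:
    """Parameters of one phantom volume.

    Lesion mean sizes default to the cohort statistics the phantom emulates
    (CMBs 4.18 voxels, iron deposits 17.43 voxels); sizes are drawn from a
    clipped log-normal around those means.  SWI lesion contrast is ~12 noise
    standard deviations by default.
    """

    shape: tuple = (96, 96, 48)
    n_cmb: int = 2
    n_iron: int = 4
    n_calcification: int = 1
    n_vessels: int = 3
    cmb_mean_voxels: float = 4.18
    cmb_sd_voxels: float = 1.6
    iron_mean_voxels: float = 17.43
    iron_sd_voxels: float = 8.0
    voxel_dims: tuple = DEFAULT_VOXEL_DIMS
    # contrast parameters, arbitrary units
    tissue_mean: float = 100.0
    smooth_field_sd: float = 8.0
    noise_sd: float = 5.0
    qsm_noise_sd: float = 0.01
    swi_lesion_contrast: float = 60.0
    vessel_swi_contrast: float = 40.0
    cmb_qsm_shift: float = 0.12
    iron_qsm_shift: float = 0.30
    calcification_qsm_shift: float = -0.25
    lesion_t2w_shift: float = -25.0
    # QSM maps carry high-intensity noise along the brain boundary (the
    # reason the +/-5 sigma truncation step exists); the phantom reproduces
    # it as a noisy shell at the foreground edge
    qsm_boundary_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cmb", "n_iron", "n_calcification", "n_vessels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cmb_mean_voxels < 1 or self.iron_mean_voxels < 1:
            raise ValueError("mean lesion sizes must be >= 1 voxel")
        if self.noise_sd < 0 or self.qsm_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError("shape must be 3D with every dimension >= 8")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated phantom volume."""

    labels: LabelVolume
    lesion_records: list = field(default_factory=list)
    mimic_records: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipsoid_mask(shape, semi_factors) -> np.ndarray:
    coords = np.indices(shape, dtype=float)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [max(f * s, 1.0) for f, s in zip(semi_factors, shape)]
    r2 = sum(((c - m) / a) ** 2 for c, m, a in zip(coords, center, semi))
    return r2 <= 1.0


def brain_foreground(shape) -> np.ndarray:
    """Ellipsoidal brain-like foreground mask."""
    return _ellipsoid_mask(shape, (0.42, 0.42, 0.42))


def basal_ganglia_region(shape) -> np.ndarray:
    """Central ellipsoid standing in for the basal ganglia."""
    return _ellipsoid_mask(shape, (0.24, 0.24, 0.24))


def _draw_size(rng, mean, sd, lo=1, hi=None) -> int:
    """Clipped log-normal integer size with the requested mean/SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    s = int(np.round(rng.lognormal(mu, np.sqrt(sigma2))))
    hi = hi if hi is not None else int(np.ceil(mean * 5))
    return int(np.clip(s, lo, hi))


def _spherical_cluster(center, size, shape, voxel_dims) -> list:
    """The *size* voxels nearest to *center* in physical (mm) distance."""
    rad = int(np.ceil((size * 3 / (4 * np.pi)) ** (1 / 3) * 3 + 2))
    lo = [max(0, int(c) - rad) for c in center]
    hi = [min(s, int(c) + rad + 1) for c, s in zip(center, shape)]
    coords = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
    d2 = np.sum(((coords - np.asarray(center)) * np.asarray(voxel_dims)) ** 2, axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
    return [tuple(coords[i]) for i in order[:size]]


_NEIGHBORS6 = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)


def _walk_cluster(rng, start, size, allowed, max_tries=2000) -> Optional[list]:
    """Grow an irregular 6-connected cluster by a seeded random walk."""
    voxels = [tuple(start)]
    members = {tuple(start)}
    tries = 0
    while len(voxels) < size and tries < max_tries:
        tries += 1
        base = voxels[rng.integers(len(voxels))]
        step = _NEIGHBORS6[rng.integers(6)]
        cand = (base[0] + step[0], base[1] + step[1], base[2] + step[2])
        if cand in members:
            continue
        if not all(0 <= c < s for c, s in zip(cand, allowed.shape)):
            continue
        if not allowed[cand]:
            continue
        voxels.append(cand)
        members.add(cand)
    return voxels if len(voxels) == size else None


def _vessel_path(rng, start, allowed, length) -> list:
    """Tubular curve: a smooth random walk with persistent direction."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pos = np.asarray(start, dtype=float)
    voxels = []
    for _ in range(length):
        ivox = tuple(int(round(c)) for c in pos)
        if not all(0 <= c < s for c, s in zip(ivox, allowed.shape)):
            break
        if not allowed[ivox]:
            break
        if ivox not in voxels:
            voxels.append(ivox)
        direction = direction + 0.3 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + direction
    return voxels


def _centroid(voxels) -> tuple:
    arr = np.asarray(voxels, dtype=float)
    return tuple(arr.mean(axis=0))


def _smooth_field(rng, shape, sd, smoothing=6.0) -> np.ndarray:
    """Low-frequency Gaussian random field with the requested SD."""
    raw = rng.normal(size=shape)
    sm = ndimage.gaussian_filter(raw, smoothing)
    s = sm.std()
    return sm * (sd / s) if s > 0 else sm


# ---------------------------------------------------------------------------
# phantom generation


def generate_phantom(config: PhantomConfig):
    """Generate one phantom participant.

    Returns a ``(MultiModalVolume, PhantomTruth)`` pair.  Identical config
    (including seed) gives identical output.  Lesions are placed with a
    minimum 2-voxel separation so that every generated lesion is a distinct
    connected component of the label volume.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.shape
    fg = brain_foreground(shape)
    bg_region = basal_ganglia_region(shape) & fg
    # keep lesions away from the foreground boundary
    interior = ndimage.binary_erosion(fg, iterations=2)

    blocked = np.zeros(shape, dtype=bool)  # occupied + separation margin
    sep = np.ones((5, 5, 5), dtype=bool)  # Chebyshev radius 2

    def _claim(voxels):
        m = np.zeros(shape, dtype=bool)
        for v in voxels:
            m[v] = True
        nonlocal blocked
        blocked |= ndimage.binary_dilation(m, structure=sep)

    def _place(region, builder, n, what):
        out = []
        candidates = np.argwhere(region)
        if n > 0 and len(candidates) == 0:
            raise GenerationError(f"no room for {what}: placement region empty")
        for _ in range(n):
            placed = None
            for _attempt in range(200):
                center = tuple(candidates[rng.integers(len(candidates))])
                if blocked[center]:
                    continue
                voxels = builder(center)
                if voxels is None:
                    continue
                if any(blocked[v] or not region[v] for v in voxels):
                    continue
                placed = voxels
                break
            if placed is None:
                raise GenerationError(f"could not place {what} without overlap")
            _claim(placed)
            out.append(placed)
        return out

    cmb_clusters = _place(
        interior,
        lambda c: _spherical_cluster(
            c,
            _draw_size(rng, config.cmb_mean_voxels, config.cmb_sd_voxels),
            shape,
            config.voxel_dims,
        ),
        config.n_cmb,
        "CMB",
    )
    # clusters grow around already-placed lesions; cap the size draw so a
    # single cluster cannot exhaust a small region
    bg_voxels = int(np.count_nonzero(bg_region))
    size_cap = max(2, bg_voxels // 8)

    def _grown_cluster(center):
        size = _draw_size(rng, config.iron_mean_voxels, config.iron_sd_voxels,
                          lo=2, hi=size_cap)
        return _walk_cluster(rng, center, size, bg_region & ~blocked)

    iron_clusters = _place(bg_region, _grown_cluster, config.n_iron, "iron deposit")
    calc_clusters = _place(bg_region, _grown_cluster, config.n_calcification,
                           "calcification")
    vessel_paths = _place(
        interior,
        lambda c: (lambda v: v if len(v) >= 5 else None)(
            _vessel_path(rng, c, interior, length=int(rng.integers(15, 35)))
        ),
        config.n_vessels,
        "vessel",
    )

    # --- intensities -------------------------------------------------------
    swi = np.zeros(shape, dtype=np.float32)
    t2w = np.zeros(shape, dtype=np.float32)
    qsm = np.zeros(shape, dtype=np.float32)
    swi[fg] = config.tissue_mean
    t2w[fg] = config.tissue_mean
    swi += _smooth_field(rng, shape, config.smooth_field_sd) * fg
    t2w += _smooth_field(rng, shape, config.smooth_field_sd) * fg
    qsm += _smooth_field(rng, shape, config.qsm_noise_sd * 2.0) * fg
    if config.qsm_boundary_sd > 0:
        shell = fg & ~interior
        qsm += rng.normal(0, config.qsm_boundary_sd, shape) * shell

    def _apply(clusters, swi_shift, qsm_shift, t2w_shift):
        for voxels in clusters:
            for v in voxels:
                swi[v] -= swi_shift
                qsm[v] += qsm_shift
                t2w[v] += t2w_shift

    _apply(cmb_clusters, config.swi_lesion_contrast, config.cmb_qsm_shift,
           config.lesion_t2w_shift)
    _apply(iron_clusters, config.swi_lesion_contrast, config.iron_qsm_shift,
           config.lesion_t2w_shift)
    _apply(calc_clusters, config.swi_lesion_contrast, config.calcification_qsm_shift,
           config.lesion_t2w_shift)
    _apply(vessel_paths, config.vessel_swi_contrast, 0.0, 0.0)

    if config.noise_sd > 0:
        swi += rng.normal(0, config.noise_sd, shape).astype(np.float32)
        t2w += rng.normal(0, config.noise_sd, shape).astype(np.float32)
    if config.qsm_noise_sd > 0:
        qsm += rng.normal(0, config.qsm_noise_sd, shape).astype(np.float32)

    # --- labels & truth ----------------------------------------------------
    labels = np.zeros(shape, dtype=np.int16)
    records = []
    for voxels in cmb_clusters:
        for v in voxels:
            labels[v] = CLASS_CMB
        records.append(LesionRecord(CLASS_CMB, _centroid(voxels), len(voxels)))
    for voxels in iron_clusters:
        for v in voxels:
            labels[v] = CLASS_IRON
        records.append(LesionRecord(CLASS_IRON, _centroid(voxels), len(voxels)))
    mimics = [MimicRecord("calcification", _centroid(v)) for v in calc_clusters]
    mimics += [MimicRecord("vessel", _centroid(v)) for v in vessel_paths]

    vol = MultiModalVolume(
        participant_id=f"phantom-{config.seed}",
        swi=swi,
        qsm=qsm,
        t2w=t2w,
        voxel_dims=config.voxel_dims,
    )
    truth = PhantomTruth(
        labels=LabelVolume(labels=labels, voxel_dims=config.voxel_dims),
        lesion_records=records,
        mimic_records=mimics,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# cohort generation


def draw_lesion_counts(rng, outlier: bool = False, n_participants: int = 24):
    """Per-participant (n_cmb, n_iron) counts from the cohort mixture.

    Non-outlier CMB counts: 0 with probability 4/23, 1-2 with 13/23, 3-8
    with 6/23 (uniform within each band).  Iron deposits: none with
    probability 5/24, else 2-13 lesions.  With *outlier* enabled, exactly
    one participant receives 120 CMBs.
    """
    counts = []
    for _ in range(n_participants):
        u = rng.random()
        if u < 4 / 23:
            n_cmb = 0
        elif u < 17 / 23:
            n_cmb = int(rng.integers(1, 3))
        else:
            n_cmb = int(rng.integers(3, 9))
        n_iron = 0 if rng.random() < 5 / 24 else int(rng.integers(2, 14))
        counts.append((n_cmb, n_iron))
    if outlier:
        idx = int(rng.integers(n_participants))
        counts[idx] = (120, counts[idx][1])
    return counts


def _placement_capacity(shape, mean_size: float) -> int:
    """Rough number of clusters of *mean_size* voxels that fit a region.

    Each placed cluster blocks roughly its 2-voxel-dilated footprint; the
    estimate is deliberately conservative.  Only binding for the small
    volumes used in unit tests — full-size phantoms have ample room.
    """
    region = int(np.count_nonzero(basal_ganglia_region(shape)))
    blocked = (mean_size ** (1 / 3) + 4) ** 3
    return max(1, int(region / blocked))


def build_cohort(
    n_participants: int,
    seed: int = 0,
    template: Optional[PhantomConfig] = None,
    outlier: bool = False,
) -> list:
    """In-memory phantom cohort: ``[(pid, MultiModalVolume, PhantomTruth)]``.

    Per-participant lesion counts are drawn from the cohort mixture and
    clipped to the placement capacity of the configured volume shape (which
    only matters for deliberately tiny test volumes).
    """
    if n_participants < 2:
        raise ValueError("n_participants must be >= 2")
    template = template or PhantomConfig()
    rng = np.random.default_rng(seed)
    counts = draw_lesion_counts(rng, outlier=outlier, n_participants=n_participants)
    iron_cap = _placement_capacity(template.shape, template.iron_mean_voxels)
    out = []
    for i, (n_cmb, n_iron) in enumerate(counts):
        pid = f"P{i:03d}"
        n_iron = min(n_iron, iron_cap)
        cfg_kwargs = asdict(template)
        cfg_kwargs.update(
            n_cmb=n_cmb,
            n_iron=n_iron,
            n_calcification=min(int(rng.integers(0, 3)), max(0, iron_cap - n_iron)),
            n_vessels=int(rng.integers(2, 6)),
            seed=int(rng.integers(2**31 - 1)),
        )
        cfg_kwargs["shape"] = tuple(cfg_kwargs["shape"])
        cfg_kwargs["voxel_dims"] = tuple(cfg_kwargs["voxel_dims"])
        cfg = PhantomConfig(**cfg_kwargs)
        vol, truth = generate_phantom(cfg)
        vol.participant_id = pid
        out.append((pid, vol, truth))
    return out


def generate_cohort(
    n_participants: int,
    out_dir,
    seed: int = 0,
    template: Optional[PhantomConfig] = None,
    outlier: bool = False,
) -> DatasetManifest:
    """Generate a phantom cohort on disk: NIfTI volumes, manifest, truth.

    Writes ``<pid>_{swi,qsm,t2w,labels}.nii.gz`` per participant plus
    ``manifest.csv`` and ``truth.json`` under *out_dir*.
    """
    template = template or PhantomConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(n_participants, seed=seed, template=template,
                          outlier=outlier)

    entries = []
    truth_json = {}
    truths = {}
    for pid, vol, truth in cohort:
        cfg = template
        paths = {}
        for mod in ("swi", "qsm", "t2w"):
            p = out_dir / f"{pid}_{mod}.nii.gz"
            write_volume(getattr(vol, mod), cfg.voxel_dims, p)
            paths[mod] = p.name
        lp = out_dir / f"{pid}_labels.nii.gz"
        write_volume(truth.labels.labels, cfg.voxel_dims, lp)
        entries.append(
            ManifestEntry(participant_id=pid, swi=paths["swi"], qsm=paths["qsm"],
                          t2w=paths["t2w"], labels=lp.name)
        )
        truths[pid] = truth
        truth_json[pid] = {
            "lesions": [
                {"class": r.cls, "centroid": list(r.centroid), "n_voxels": r.n_voxels}
                for r in truth.lesion_records
            ],
            "mimics": [
                {"kind": m.kind, "centroid": list(m.centroid)}
                for m in truth.mimic_records
            ],
        }

    manifest = DatasetManifest(entries=entries, modalities_used=("swi", "qsm", "t2w"),
                               root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    manifest.truths = truths  # in-memory convenience; not part of the CSV
    return manifest


# ---------------------------------------------------------------------------
# raw echo (magnitude/phase) pairs for testing SWI composition


@dataclass
class EchoLesionSpec:
    """One focal phase lesion: Gaussian dip of *depth* radians (negative)."""

    center: tuple
    radius_vox: float = 2.0
    depth: float = -np.pi / 2


def generate_echo_pair(
    shape=(64, 64, 8),
    lesions=(),
    background_phase_amplitude: float = 0.0,
    seed: int = 0,
):
    """Smooth positive magnitude plus a wrapped phase image.

    The phase is a low-frequency background field (amplitude
    *background_phase_amplitude* radians, zero by default) plus focal
    negative-phase lesions, wrapped to (-pi, pi].
    """
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    fg = _ellipsoid_mask(shape, (0.45, 0.45, 0.48)) if len(shape) == 3 else None
    mag = np.full(shape, 1.0, dtype=np.float64)
    if fg is not None:
        mag = np.where(fg, 100.0, 1.0)
        mag += _smooth_field(rng, shape, 5.0) * fg
    phase = np.zeros(shape, dtype=np.float64)
    if background_phase_amplitude > 0:
        field = _smooth_field(rng, shape, 1.0, smoothing=max(shape) / 4.0)
        phase += field * background_phase_amplitude / max(np.abs(field).max(), 1e-12)
        if fg is not None:
            phase *= fg
    coords = np.indices(shape, dtype=float)
    for les in lesions:
        d2 = sum((c - m) ** 2 for c, m in zip(coords, les.center))
        phase += les.depth * np.exp(-d2 / (2 * les.radius_vox**2))
    # wrap to (-pi, pi]
    phase = -(np.mod(-phase + np.pi, 2 * np.pi) - np.pi)
    return mag, phase
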