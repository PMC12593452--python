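"""Multi-modal volume containers, NIfTI I/O, preprocessing and augmentation.

The in-memory contract used throughout the package: a case is a 4-channel
float32 grid in ``(channel, x, y, z)`` order with channels T1, T2, FLAIR,
T1CE, a boolean brain mask on the same grid, per-axis voxel spacing in mm
and a NIfTI affine. Labels are 0 background, 1 necrotic core (NCR),
2 peritumoral edema (ED), 3 enhancing tumor (ET); raw BraTS-style masks
that use label 4 for ET are remapped on read.

Preprocessing mirrors the standard pipeline for this task: resampling to a
common voxel spacing (trilinear for intensities, nearest for labels),
center pad/crop to a fixed grid, and per-channel z-score normalization over
brain-mask statistics with the background zeroed. Skull-stripping and bias
correction are intentionally out of scope: inputs are expected stripped and
bias-controlled (the synthetic phantoms are by construction).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger("causalseg")

#: Fixed modality channel order.
MODALITIES: tuple[str, ...] = ("t1", "t2", "flair", "t1ce")
MODALITY_INDEX: dict[str, int] = {m: i for i, m in enumerate(MODALITIES)}

#: Class ids.
BACKGROUND, NCR, ED, ET = 0, 1, 2, 3
CLASS_NAMES: tuple[str, ...] = ("background", "ncr", "ed", "et")
#: Raw BraTS label convention uses 4 for enhancing tumor.
RAW_LABEL_REMAP = {4: ET}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MultiModalVolume:
    """4-channel 3D image with brain mask, spacing and orientation."""

    data: np.ndarray                      # (4, X, Y, Z) float32
    brain_mask: np.ndarray                # (X, Y, Z) bool
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    missing: frozenset = frozenset()      # modality names flagged absent

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITIES):
            raise ValueError(
                f"expected ({len(MODALITIES)}, X, Y, Z) data, got {self.data.shape}")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[1:]:
            raise ValueError("brain_mask shape does not match data grid")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def copy(self) -> "MultiModalVolume":
        return MultiModalVolume(self.data.copy(), self.brain_mask.copy(),
                                self.spacing_mm, self.affine.copy(),
                                self.missing)


@dataclass
class SegmentationMask:
    """Integer voxel labels in [0, n_classes)."""

    labels: np.ndarray
    n_classes: int = 4

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        bad = np.setdiff1d(np.unique(self.labels),
                           np.arange(self.n_classes))
        if bad.size:
            raise ValueError(f"labels outside [0, {self.n_classes}): {bad}")

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(self.labels.copy(), self.n_classes)


@dataclass
class AugmentParams:
    """Training-time augmentation configuration.

    Spatial transforms couple the image (trilinear) and labels (nearest);
    intensity transforms act per channel. Defaults follow common practice
    for this task: rotations up to ±15°, coarse-grid elastic deformation,
    additive Gaussian noise, gamma and global intensity scaling, and whole
    modality dropout with probability 0.2.
    """

    rotation_max_deg: float = 15.0
    elastic_grid_spacing: float = 8.0      # control-grid spacing, voxels
    elastic_sigma: float = 0.0             # displacement std, voxels (0 = off)
    noise_sigma: float = 0.0
    gamma_range: tuple[float, float] = (1.0, 1.0)
    intensity_scale_range: tuple[float, float] = (1.0, 1.0)
    modality_dropout_prob: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")
        if not 0.0 <= self.modality_dropout_prob <= 1.0:
            raise ValueError("modality_dropout_prob must be in [0, 1]")

    @classmethod
    def identity(cls) -> "AugmentParams":
        return cls(rotation_max_deg=0.0, elastic_sigma=0.0, noise_sigma=0.0,
                   gamma_range=(1.0, 1.0), intensity_scale_range=(1.0, 1.0),
                   modality_dropout_prob=0.0)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_nifti(path: Path):
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def read_case(paths: Mapping[str, str | Path],
              mask_path: str | Path | None = None,
              allow_missing: bool = False,
              ) -> tuple[MultiModalVolume, SegmentationMask | None]:
    """Read co-registered modality NIfTIs (+ optional label mask).

    ``paths`` maps modality names (t1, t2, flair, t1ce) to files. A missing
    modality raises unless ``allow_missing``; then its channel is
    zero-filled and flagged in ``MultiModalVolume.missing`` so downstream
    causal components can treat it as absent. Raw masks using label 4 for
    enhancing tumor are remapped to 3 (logged).
    """
    arrays: dict[str, np.ndarray] = {}
    affine = None
    missing = []
    for m in MODALITIES:
        if m not in paths or paths[m] is None:
            if not allow_missing:
                raise FileNotFoundError(
                    f"missing modality '{m}'; pass allow_missing=True to "
                    f"zero-fill")
            missing.append(m)
            continue
        p = Path(paths[m])
        if not p.exists():
            if not allow_missing:
                raise FileNotFoundError(f"modality '{m}' file not found: {p}")
            missing.append(m)
            continue
        arr, aff = _load_nifti(p)
        arrays[m] = np.asarray(arr, dtype=np.float32)
        affine = affine if affine is not None else aff
    if not arrays:
        raise FileNotFoundError("no modality files could be read")
    shapes = {m: a.shape for m, a in arrays.items()}
    if len(set(shapes.values())) > 1:
        raise ValueError(f"modalities are not co-registered, shapes differ: "
                         f"{shapes}")
    grid = next(iter(shapes.values()))
    data = np.zeros((len(MODALITIES),) + grid, dtype=np.float32)
    for m, a in arrays.items():
        data[MODALITY_INDEX[m]] = a
    spacing = tuple(float(s) for s in
                    np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    brain = np.any(data != 0, axis=0)
    volume = MultiModalVolume(data, brain, spacing, affine,
                              missing=frozenset(missing))
    mask = None
    if mask_path is not None:
        labels, _ = _load_nifti(Path(mask_path))
        labels = np.asarray(labels)
        if labels.shape != grid:
            raise ValueError(
                f"mask shape {labels.shape} does not match modality grid {grid}")
        labels = np.rint(labels).astype(np.int16)
        for raw, new in RAW_LABEL_REMAP.items():
            if (labels == raw).any():
                logger.info("remapping raw label %d -> %d", raw, new)
                labels[labels == raw] = new
        mask = SegmentationMask(labels)
    return volume, mask


def write_volume(volume: MultiModalVolume, out_dir: str | Path,
                 stem: str = "case") -> dict[str, Path]:
    """Write one NIfTI per modality; returns the paths written."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for i, m in enumerate(MODALITIES):
        p = out_dir / f"{stem}_{m}.nii.gz"
        nib.save(nib.Nifti1Image(volume.data[i], volume.affine), str(p))
        paths[m] = p
    return paths


def write_mask(mask: SegmentationMask, path: str | Path,
               affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    aff = affine if affine is not None else np.eye(4)
    nib.save(nib.Nifti1Image(mask.labels.astype(np.int16), aff), str(path))
    return path


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _center_pad_crop(arr: np.ndarray, target: Sequence[int],
                     is_channelled: bool) -> np.ndarray:
    """Zero-pad and/or crop the trailing 3 axes to ``target``, centered."""
    spatial = arr.shape[1:] if is_channelled else arr.shape
    pads, crops = [], []
    for s, t in zip(spatial, target):
        if t >= s:
            before = (t - s) // 2
            pads.append((before, t - s - before))
            crops.append(slice(0, t))
        else:
            start = (s - t) // 2
            pads.append((0, 0))
            crops.append(slice(start, start + t))
    if is_channelled:
        arr = np.pad(arr, [(0, 0)] + pads)
        return arr[(slice(None),) + tuple(crops)]
    arr = np.pad(arr, pads)
    return arr[tuple(crops)]


def preprocess(volume: MultiModalVolume,
               mask: SegmentationMask | None = None,
               target_spacing: float | Sequence[float] | None = None,
               target_shape: Sequence[int] | None = None,
               variance_epsilon: float | None = None,
               ) -> tuple[MultiModalVolume, SegmentationMask | None]:
    """Resample, pad/crop and z-score a case.

    After this call each channel has mean 0 and unit variance over the
    brain mask (to float32 rounding) and the background is exactly 0. A
    constant-intensity channel raises unless ``variance_epsilon`` is given,
    in which case the divisor is guarded by that epsilon.
    """
    data = volume.data
    brain = volume.brain_mask
    labels = mask.labels if mask is not None else None
    spacing = np.asarray(volume.spacing_mm, dtype=float)

    if target_spacing is not None:
        tgt = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,))
        if np.any(tgt <= 0):
            raise ValueError("target spacing must be positive")
        factors = spacing / tgt
        if not np.allclose(factors, 1.0):
            data = np.stack([ndi.zoom(c, factors, order=1) for c in data])
            brain = ndi.zoom(brain.astype(np.uint8), factors, order=0) > 0
            if labels is not None:
                labels = ndi.zoom(labels, factors, order=0)
        spacing = tgt

    if target_shape is not None:
        target_shape = tuple(int(t) for t in target_shape)
        data = _center_pad_crop(data, target_shape, is_channelled=True)
        brain = _center_pad_crop(brain, target_shape, is_channelled=False)
        if labels is not None:
            labels = _center_pad_crop(labels, target_shape,
                                      is_channelled=False)

    if not brain.any():
        raise ValueError("empty brain mask: cannot compute z-score statistics")

    data = data.astype(np.float32).copy()
    for c in range(data.shape[0]):
        vals = data[c][brain]
        mu = float(vals.mean())
        sd = float(vals.std())
        if sd < 1e-12:
            if variance_epsilon is None:
                raise ValueError(
                    f"channel {MODALITIES[c]} is constant over the brain "
                    f"mask; pass variance_epsilon to guard")
            sd = variance_epsilon
        data[c] = (data[c] - mu) / sd
    data[:, ~brain] = 0.0

    new_affine = np.diag(list(spacing) + [1.0])
    out_vol = MultiModalVolume(data, brain, tuple(spacing), new_affine,
                               volume.missing)
    out_mask = None
    if labels is not None:
        out_mask = SegmentationMask(labels, mask.n_classes)
    return out_vol, out_mask


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _rotation_matrix(angle_deg: float, axes: tuple[int, int]) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    r = np.eye(3)
    a, b = axes
    r[a, a] = np.cos(th)
    r[a, b] = -np.sin(th)
    r[b, a] = np.sin(th)
    r[b, b] = np.cos(th)
    return r


def augment(volume: MultiModalVolume, mask: SegmentationMask,
            params: AugmentParams, seed: int | None = None,
            ) -> tuple[MultiModalVolume, SegmentationMask]:
    """Apply one seeded draw of the augmentation stack.

    The same spatial transform is applied to image (trilinear) and labels
    (nearest), so augmented label sets are subsets of the originals.
    All-zero parameter ranges yield the identity bit-for-bit.
    """
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)
    data = volume.data
    labels = mask.labels
    brain = volume.brain_mask
    shape = data.shape[1:]

    angle = float(rng.uniform(-params.rotation_max_deg,
                              params.rotation_max_deg))
    axes = tuple(sorted(rng.choice(3, size=2, replace=False).tolist()))
    do_rot = params.rotation_max_deg > 0 and abs(angle) > 0
    do_elastic = params.elastic_sigma > 0

    if do_rot or do_elastic:
        coords = np.stack(np.meshgrid(*[np.arange(s, dtype=np.float32)
                                        for s in shape], indexing="ij"))
        center = (np.asarray(shape, dtype=np.float32) - 1) / 2.0
        pts = coords.reshape(3, -1) - center[:, None]
        rot = _rotation_matrix(angle, axes) if do_rot else np.eye(3)
        src = rot.T @ pts + center[:, None]
        src = src.reshape(coords.shape)
        if do_elastic:
            n_ctrl = [max(2, int(np.ceil(s / params.elastic_grid_spacing)) + 1)
                      for s in shape]
            disp = rng.normal(0.0, params.elastic_sigma, size=(3, *n_ctrl))
            for d in range(3):
                src[d] += ndi.zoom(disp[d],
                                   [s / n for s, n in zip(shape, n_ctrl)],
                                   order=1, mode="nearest")
        data = np.stack([ndi.map_coordinates(c, src, order=1,
                                             mode="constant")
                         for c in data]).astype(np.float32)
        labels = ndi.map_coordinates(labels, src, order=0, mode="constant")
        brain = ndi.map_coordinates(brain.astype(np.uint8), src, order=0,
                                    mode="constant") > 0
    else:
        data = data.copy()
        labels = labels.copy()
        brain = brain.copy()

    lo_s, hi_s = params.intensity_scale_range
    lo_g, hi_g = params.gamma_range
    for c in range(data.shape[0]):
        scale = float(rng.uniform(lo_s, hi_s))
        gamma = float(rng.uniform(lo_g, hi_g))
        ch = data[c]
        if gamma != 1.0 and brain.any():
            vals = ch[brain]
            vmin, vmax = float(vals.min()), float(vals.max())
            if vmax > vmin:
                norm = np.clip((ch - vmin) / (vmax - vmin), 0.0, 1.0)
                ch = np.where(brain, norm ** gamma * (vmax - vmin) + vmin, ch)
        if scale != 1.0:
            ch = ch * scale
        data[c] = ch
    if params.noise_sigma > 0:
        data = data + rng.normal(0.0, params.noise_sigma,
                                 size=data.shape).astype(np.float32)

    out_vol = MultiModalVolume(data, brain, volume.spacing_mm,
                               volume.affine.copy(), volume.missing)
    if params.modality_dropout_prob > 0:
        out_vol, _ = modality_dropout(out_vol, params.modality_dropout_prob,
                                      seed=int(rng.integers(2 ** 31 - 1)))
    return out_vol, SegmentationMask(labels, mask.n_classes)


def modality_dropout(volume: MultiModalVolume, p: float,
                     seed: int | None = None,
                     max_redraws: int = 100,
                     ) -> tuple[MultiModalVolume, tuple[str, ...]]:
    """Independently zero whole modality channels with probability ``p``.

    The all-dropped event is resampled (never fewer than one channel
    survives); if resampling cannot avoid it (p close to 1), one surviving
    channel is chosen uniformly instead.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("dropout probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(MODALITIES)
    drop = np.zeros(n, dtype=bool)
    if p > 0:
        for _ in range(max_redraws):
            drop = rng.random(n) < p
            if not drop.all():
                break
        if drop.all():
            drop[rng.integers(n)] = False
    if not drop.any():
        return volume.copy(), ()
    data = volume.data.copy()
    data[drop] = 0.0
    dropped = tuple(MODALITIES[i] for i in np.flatnonzero(drop))
    out = MultiModalVolume(data, volume.brain_mask.copy(), volume.spacing_mm,
                           volume.affine.copy(),
                           volume.missing | frozenset(dropped))
    return out, dropped
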