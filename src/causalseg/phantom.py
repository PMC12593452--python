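"""Synthetic multi-modal MRI phantoms with a known modality→tissue graph.

Each phantom is a skull-stripped brain ellipsoid carrying a nested tumor
(enhancing tumor ⊂ tumor core ⊂ whole tumor, realised as concentric
ellipsoids with Gaussian-smoothed boundaries), imaged in four channels
(T1, T2, FLAIR, T1CE). The generative causal structure is explicit: the
signal of tumor class c appears in modality m if and only if the ground
truth adjacency has the edge m→c. The canonical edges mirror radiological
contrast behaviour — FLAIR-hyperintense edema, T1CE-hyperintense enhancing
tumor, T1-hypointense necrosis — so a causal layer trained on these cases
has a known graph to recover. Shared smooth anatomy texture, multiplicative
bias fields and Rician noise provide nuisance structure common to all
modalities.

The module also implements the acquisition-artifact stress perturbations
used by the robustness harness: Rician noise at a target SNR, smooth
multiplicative intensity bias, sub-voxel linear motion blur and whole
modality ablation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from .io_prep import (MODALITIES, MODALITY_INDEX, NCR, ED, ET,
                      MultiModalVolume, SegmentationMask, write_mask,
                      write_volume)

#: Tumor classes carried by the adjacency (columns), in label order 1..3.
TUMOR_CLASSES: tuple[int, ...] = (NCR, ED, ET)

#: Canonical modality→class edges: T1→NCR, FLAIR→ED, T1CE→ET.
CANONICAL_EDGES: tuple[tuple[str, int], ...] = (
    ("t1", NCR), ("flair", ED), ("t1ce", ET))

#: Mean intensity offsets (arbitrary units on a base signal of 1.0) for the
#: canonical contrasts; necrosis is hypointense on T1.
DEFAULT_CONTRASTS: dict[tuple[str, int], float] = {
    ("t1", NCR): -0.65,
    ("flair", ED): 1.2,
    ("t1ce", ET): 1.5,
}


def canonical_adjacency() -> np.ndarray:
    """(4 modalities × 3 tumor classes) binary matrix with the canonical
    edges set."""
    adj = np.zeros((len(MODALITIES), len(TUMOR_CLASSES)), dtype=np.int8)
    for m, c in CANONICAL_EDGES:
        adj[MODALITY_INDEX[m], TUMOR_CLASSES.index(c)] = 1
    return adj


@dataclass
class TumorGeometry:
    """Ranges for the nested ellipsoid compartments, as fractions of the
    smallest grid axis (whole tumor) or of the parent radius."""

    wt_radius_frac: tuple[float, float] = (0.27, 0.35)
    tc_frac: tuple[float, float] = (0.62, 0.75)
    ncr_frac: tuple[float, float] = (0.55, 0.72)
    center_jitter_frac: float = 0.06
    anisotropy: tuple[float, float] = (0.85, 1.18)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic cohort (the study conditions)."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_classes: int = 4
    truth_adjacency: np.ndarray = field(default_factory=canonical_adjacency)
    signal_contrasts: dict = field(default_factory=dict)
    noise_sigma: float = 0.10
    bias_amplitude: float = 0.015
    anatomy_amplitude: float = 0.02
    boundary_sigma: float = 0.7
    tumor_geometry: TumorGeometry = field(default_factory=TumorGeometry)
    seed: int = 0

    def __post_init__(self):
        self.truth_adjacency = np.asarray(self.truth_adjacency, dtype=np.int8)
        if self.truth_adjacency.shape != (len(MODALITIES), len(TUMOR_CLASSES)):
            raise ValueError(
                f"truth_adjacency must be {len(MODALITIES)}x"
                f"{len(TUMOR_CLASSES)}, got {self.truth_adjacency.shape}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0.0 <= self.bias_amplitude < 1.0:
            raise ValueError("bias_amplitude must be in [0, 1)")
        # every edge present in the adjacency needs a contrast value
        contrasts = dict(DEFAULT_CONTRASTS)
        contrasts.update({(m, int(c)): float(v)
                          for (m, c), v in self.signal_contrasts.items()})
        for mi, m in enumerate(MODALITIES):
            for ci, c in enumerate(TUMOR_CLASSES):
                if self.truth_adjacency[mi, ci] and (m, c) not in contrasts:
                    contrasts[(m, c)] = 1.0
        self.signal_contrasts = contrasts
        g = self.tumor_geometry
        rmax = (g.wt_radius_frac[1] * (1.0 + g.anisotropy[1] - 1.0)
                + g.center_jitter_frac)
        if g.wt_radius_frac[1] * g.anisotropy[1] + g.center_jitter_frac > 0.5:
            raise ValueError(
                "degenerate tumor geometry: whole-tumor radius plus jitter "
                "exceeds the grid half-extent")

    def canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["truth_adjacency"] = self.truth_adjacency.tolist()
        d["signal_contrasts"] = sorted(
            (m, int(c), float(v)) for (m, c), v in self.signal_contrasts.items())
        return d

    def hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PhantomCase:
    volume: MultiModalVolume
    mask: SegmentationMask
    truth_graph: np.ndarray
    provenance: dict

    def __post_init__(self):
        if self.volume.grid_shape != self.mask.labels.shape:
            raise ValueError("volume and mask grids differ")


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    """Zero-mean unit-std smooth Gaussian random field."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def generate_case(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Generate one phantom; deterministic for fixed (spec, seed)."""
    rng = np.random.default_rng([int(spec.seed), int(seed)])
    shape = tuple(spec.grid_shape)
    min_ax = min(shape)
    geo = spec.tumor_geometry

    center0 = (np.asarray(shape, dtype=float) - 1) / 2.0
    brain_radii = 0.46 * np.asarray(shape, dtype=float)
    brain = _ellipsoid(shape, center0, brain_radii)

    jitter = rng.uniform(-1.0, 1.0, size=3) * geo.center_jitter_frac * min_ax
    center = center0 + jitter
    anis = rng.uniform(*geo.anisotropy, size=3)
    r_wt = rng.uniform(*geo.wt_radius_frac) * min_ax
    r_tc = r_wt * rng.uniform(*geo.tc_frac)
    r_ncr = r_tc * rng.uniform(*geo.ncr_frac)
    if np.any(r_wt * anis + np.abs(jitter) > np.asarray(shape) / 2.0):
        raise ValueError("degenerate tumor geometry: radii exceed the grid")

    wt = _ellipsoid(shape, center, r_wt * anis) & brain
    tc = _ellipsoid(shape, center, r_tc * anis) & brain
    ncr = _ellipsoid(shape, center, r_ncr * anis) & brain

    labels = np.zeros(shape, dtype=np.int16)
    labels[wt] = ED
    labels[tc] = ET
    labels[ncr] = NCR

    anatomy = _smooth_field(rng, shape, sigma=1.5) * spec.anatomy_amplitude
    # smoothing is label-respecting: the contrast tapers toward each class
    # boundary but is exactly zero outside its own class, so absent edges
    # carry no leaked signal
    class_fields = {
        c: ndi.gaussian_filter((labels == c).astype(np.float64),
                               spec.boundary_sigma) * (labels == c)
        for c in TUMOR_CLASSES
    }

    data = np.zeros((len(MODALITIES),) + shape, dtype=np.float64)
    for mi, m in enumerate(MODALITIES):
        signal = 1.0 + anatomy
        for ci, c in enumerate(TUMOR_CLASSES):
            if spec.truth_adjacency[mi, ci]:
                signal = signal + spec.signal_contrasts[(m, c)] * class_fields[c]
        if spec.bias_amplitude > 0:
            bias = _smooth_field(rng, shape, sigma=min_ax / 3.0)
            bias = bias / max(np.abs(bias).max(), 1e-12)
            signal = signal * (1.0 + spec.bias_amplitude * bias)
        if spec.noise_sigma > 0:
            n1 = rng.normal(0.0, spec.noise_sigma, shape)
            n2 = rng.normal(0.0, spec.noise_sigma, shape)
            signal = np.sqrt((signal + n1) ** 2 + n2 ** 2)
        data[mi] = np.where(brain, signal, 0.0)

    volume = MultiModalVolume(data.astype(np.float32), brain,
                              spec.voxel_spacing_mm)
    mask = SegmentationMask(labels, spec.n_classes)
    return PhantomCase(volume=volume, mask=mask,
                       truth_graph=spec.truth_adjacency.copy(),
                       provenance={"seed": int(seed),
                                   "spec_hash": spec.hash()})


def generate_cohort(spec: PhantomSpec, n: int, seed: int,
                    out_dir: str | Path) -> dict:
    """Write ``n`` independent cases as NIfTI pairs plus a JSON manifest."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cohort directory not writable: {out_dir}") from exc

    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    cases = []
    for i, cseed in enumerate(case_seeds):
        case = generate_case(spec, int(cseed))
        stem = f"case_{i:04d}"
        paths = write_volume(case.volume, out_dir, stem=stem)
        mask_path = write_mask(case.mask, out_dir / f"{stem}_seg.nii.gz",
                               affine=case.volume.affine)
        cases.append({
            "id": stem,
            "seed": int(cseed),
            "modalities": {m: p.name for m, p in paths.items()},
            "mask": mask_path.name,
        })
    manifest = {
        "spec": spec.canonical_dict(),
        "spec_hash": spec.hash(),
        "seed": int(seed),
        "n": int(n),
        "cases": cases,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    return manifest


def generate_cases(spec: PhantomSpec, n: int, seed: int) -> list[PhantomCase]:
    """In-memory cohort with the same per-case seed derivation as
    :func:`generate_cohort`."""
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    return [generate_case(spec, int(s)) for s in case_seeds]


# ---------------------------------------------------------------------------
# Stress perturbations
# ---------------------------------------------------------------------------

PERTURB_KINDS = ("rician_snr", "intensity_bias", "motion_blur",
                 "ablate_modality")


def _blur_kernel(extent: float) -> np.ndarray:
    """1-D linear motion kernel of sub-voxel ``extent`` (box of that length
    sampled on the voxel grid with fractional end taps)."""
    half = extent / 2.0
    n = int(np.ceil(half - 0.5))
    taps = np.arange(-n, n + 1)
    w = np.clip(np.minimum(taps + 0.5, half) - np.maximum(taps - 0.5, -half),
                0.0, 1.0)
    w = w[w > 0]
    return (w / w.sum()).astype(np.float64)


def perturb(volume: MultiModalVolume, kind: str, level,
            seed: int | None = None) -> MultiModalVolume:
    """Apply one acquisition-artifact perturbation; brain mask unchanged.

    ``rician_snr``: Rician corruption with sigma = mean in-brain signal /
    level. ``intensity_bias``: smooth per-channel multiplicative field in
    [1−level, 1+level]. ``motion_blur``: linear kernel of ``level`` voxels
    along a random axis. ``ablate_modality``: zero the named channel.
    """
    if kind not in PERTURB_KINDS:
        raise ValueError(f"unknown perturbation '{kind}'; "
                         f"valid kinds: {PERTURB_KINDS}")
    rng = np.random.default_rng(seed)
    data = volume.data.astype(np.float64).copy()
    brain = volume.brain_mask

    if kind == "ablate_modality":
        m = level if isinstance(level, str) else MODALITIES[int(level)]
        if m not in MODALITY_INDEX:
            raise ValueError(f"unknown modality '{m}'; valid: {MODALITIES}")
        out = volume.data.copy()
        out[MODALITY_INDEX[m]] = 0.0
        return MultiModalVolume(out, brain.copy(), volume.spacing_mm,
                                volume.affine.copy(),
                                volume.missing | frozenset([m]))

    level = float(level)
    if kind == "rician_snr":
        if level <= 0:
            raise ValueError("SNR level must be > 0")
        mean_signal = float(data[:, brain].mean()) if brain.any() else 1.0
        sigma = mean_signal / level
        n1 = rng.normal(0.0, sigma, data.shape)
        n2 = rng.normal(0.0, sigma, data.shape)
        data = np.sqrt((data + n1) ** 2 + n2 ** 2)
    elif kind == "intensity_bias":
        if not 0.0 <= level < 1.0:
            raise ValueError("bias fraction must be in [0, 1)")
        if level > 0:
            for c in range(data.shape[0]):
                f = _smooth_field(rng, data.shape[1:],
                                  sigma=min(data.shape[1:]) / 3.0)
                f = f / max(np.abs(f).max(), 1e-12)
                data[c] *= 1.0 + level * f
    elif kind == "motion_blur":
        if level < 0:
            raise ValueError("blur extent must be >= 0")
        if level > 0:
            kernel = _blur_kernel(level)
            axis = int(rng.integers(3))
            if kernel.size > 1:
                data = ndi.convolve1d(data, kernel, axis=1 + axis,
                                      mode="constant")
    return MultiModalVolume(data.astype(np.float32), brain.copy(),
                            volume.spacing_mm, volume.affine.copy(),
                            volume.missing)
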