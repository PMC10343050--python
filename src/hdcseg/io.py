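"""NIfTI case I/O, intensity normalization, region mapping and augmentation.

A *case* is a directory ``<case>/<case>_{t1,t1ce,t2,flair[,seg]}.nii.gz``
holding four co-registered MRI modalities and an optional integer label
volume with values in {0, 1, 2, 4} (BraTS convention: 1 = necrotic /
non-enhancing core, 2 = peritumoral edema, 4 = enhancing tumor). The
evaluation regions are nested unions of the raw labels:
whole tumor = {1, 2, 4}, tumor core = {1, 4}, enhancing tumor = {4}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "MODALITIES", "VALID_LABELS", "REGION_LABELS",
    "MultimodalVolume", "LabelVolume", "RegionMasks",
    "load_case", "save_case", "normalize", "labels_to_regions",
    "crop_patch", "pad_depth_for_inference", "augment",
]

MODALITIES = ("t1", "t1ce", "t2", "flair")
VALID_LABELS = frozenset({0, 1, 2, 4})

#: default (standard BraTS) region <- raw-label mapping
REGION_LABELS = {"wt": (1, 2, 4), "tc": (1, 4), "et": (4,)}


@dataclass
class MultimodalVolume:
    """Four co-registered modalities stacked channel-first: (4, X, Y, Z)."""

    data: np.ndarray
    modality_names: tuple[str, ...] = MODALITIES
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(self.modality_names):
            raise ValueError(
                f"expected ({len(self.modality_names)}, X, Y, Z) data, got {self.data.shape}")
        if len(self.modality_names) != 4:
            raise ValueError("exactly 4 modalities are required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class LabelVolume:
    """Integer label volume, values restricted to {0, 1, 2, 4}."""

    labels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label array, got shape {self.labels.shape}")
        _check_label_values(self.labels)


@dataclass
class RegionMasks:
    """Nested binary evaluation masks: et ⊆ tc ⊆ wt."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __iter__(self):
        yield from (("wt", self.wt), ("tc", self.tc), ("et", self.et))


def _check_label_values(labels: np.ndarray, source: str = "") -> None:
    found = set(np.unique(labels).tolist())
    extra = sorted(found - VALID_LABELS)
    if extra:
        where = f" in {source}" if source else ""
        raise ValueError(f"unexpected label {', '.join(map(str, extra))}{where}; "
                         f"allowed values are {sorted(VALID_LABELS)}")


def _modality_paths(case_dir: Path) -> dict[str, Path]:
    case_dir = Path(case_dir)
    name = case_dir.name
    paths = {m: case_dir / f"{name}_{m}.nii.gz" for m in MODALITIES}
    seg = case_dir / f"{name}_seg.nii.gz"
    if seg.exists():
        paths["seg"] = seg
    return paths


def load_case(case, load_labels: bool = True) -> tuple[MultimodalVolume, LabelVolume | None]:
    """Load a case from a directory or an explicit {modality: path} mapping.

    The channel order is fixed to (T1, T1ce, T2, FLAIR) regardless of the
    mapping order. Spatial shapes must agree across files; label values are
    validated against {0, 1, 2, 4}.
    """
    paths = dict(case) if isinstance(case, dict) else _modality_paths(Path(case))
    missing = [m for m in MODALITIES if m not in paths]
    if missing:
        raise FileNotFoundError(f"missing modalities {missing} for case {case}")
    imgs = {}
    for m in MODALITIES:
        p = Path(paths[m])
        if not p.exists():
            raise FileNotFoundError(f"modality file not found: {p}")
        imgs[m] = nib.load(str(p))
    shapes = {m: imgs[m].shape for m in MODALITIES}
    ref = shapes[MODALITIES[0]]
    for m, s in shapes.items():
        if s != ref:
            raise ValueError(
                f"shape mismatch: {paths[m]} has shape {s}, expected {ref} "
                f"(from {paths[MODALITIES[0]]})")
    first = imgs[MODALITIES[0]]
    data = np.stack([np.asarray(imgs[m].dataobj, dtype=np.float32) for m in MODALITIES])
    spacing = tuple(float(z) for z in first.header.get_zooms()[:3])
    vol = MultimodalVolume(data, MODALITIES, spacing, np.asarray(first.affine))

    lab = None
    if load_labels and "seg" in paths:
        seg_img = nib.load(str(paths["seg"]))
        if seg_img.shape != ref:
            raise ValueError(f"shape mismatch: {paths['seg']} has shape "
                             f"{seg_img.shape}, expected {ref}")
        seg = np.asarray(seg_img.dataobj)
        seg = np.rint(seg).astype(np.int16)
        _check_label_values(seg, source=str(paths["seg"]))
        lab = LabelVolume(seg, affine=np.asarray(seg_img.affine))
    return vol, lab


def save_case(case_dir, vol: MultimodalVolume, lab: LabelVolume | None = None) -> Path:
    """Write a case in the canonical directory layout; returns the directory."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    name = case_dir.name
    for i, m in enumerate(vol.modality_names):
        nib.save(nib.Nifti1Image(vol.data[i].astype(np.float32), vol.affine),
                 str(case_dir / f"{name}_{m}.nii.gz"))
    if lab is not None:
        nib.save(nib.Nifti1Image(lab.labels.astype(np.int16), lab.affine),
                 str(case_dir / f"{name}_seg.nii.gz"))
    return case_dir


def save_prediction(path, labels: np.ndarray, affine: np.ndarray | None = None) -> None:
    """Write a predicted label map as NIfTI in the input geometry."""
    _check_label_values(labels)
    nib.save(nib.Nifti1Image(labels.astype(np.int16),
                             np.eye(4) if affine is None else affine), str(path))


def normalize(vol: MultimodalVolume) -> MultimodalVolume:
    """Per-modality z-score over nonzero voxels; background stays exactly 0.

    A constant nonzero region maps to 0 (zero-variance guard) and an
    all-zero modality is returned unchanged.
    """
    out = vol.data.copy()
    for i in range(out.shape[0]):
        chan = out[i]
        mask = chan != 0
        if not mask.any():
            continue
        vals = chan[mask]
        mu = vals.mean()
        sd = vals.std()
        chan[mask] = (vals - mu) / sd if sd > 0 else 0.0
    return MultimodalVolume(out, vol.modality_names, vol.voxel_spacing, vol.affine)


def labels_to_regions(lab: LabelVolume | np.ndarray,
                      mapping: dict[str, tuple[int, ...]] = REGION_LABELS) -> RegionMasks:
    """Derive the nested WT/TC/ET evaluation masks from raw labels."""
    labels = lab.labels if isinstance(lab, LabelVolume) else np.asarray(lab)
    masks = {r: np.isin(labels, vals) for r, vals in mapping.items()}
    return RegionMasks(**masks)


def crop_patch(vol: MultimodalVolume, lab: LabelVolume | None,
               size: tuple[int, int, int] = (128, 128, 128),
               rng: np.random.Generator | None = None,
               foreground_prob: float = 0.0
               ) -> tuple[MultimodalVolume, LabelVolume | None]:
    """Crop an identical random window from all modalities and the labels.

    With probability ``foreground_prob`` (and labels present containing
    tumor) the window is centered on a random tumor voxel, clamped to the
    volume; otherwise the window is uniform over valid positions.
    """
    rng = rng or np.random.default_rng()
    shape = vol.spatial_shape
    size = tuple(size)
    if any(s < p for s, p in zip(shape, size)):
        raise ValueError(f"volume {shape} smaller than patch {size}")
    max_start = [s - p for s, p in zip(shape, size)]
    start = None
    if (lab is not None and foreground_prob > 0
            and rng.random() < foreground_prob):
        fg = np.argwhere(lab.labels > 0)
        if len(fg):
            center = fg[rng.integers(len(fg))]
            start = [int(np.clip(c - p // 2, 0, m))
                     for c, p, m in zip(center, size, max_start)]
    if start is None:
        start = [int(rng.integers(m + 1)) for m in max_start]
    sl = tuple(slice(s, s + p) for s, p in zip(start, size))
    pvol = MultimodalVolume(vol.data[(slice(None),) + sl], vol.modality_names,
                            vol.voxel_spacing, vol.affine)
    plab = None if lab is None else LabelVolume(lab.labels[sl], affine=lab.affine)
    return pvol, plab


def pad_depth_for_inference(vol: MultimodalVolume, multiple: int = 8) -> MultimodalVolume:
    """Append zero slices on the depth axis up to the next multiple (155 -> 160)."""
    d = vol.spatial_shape[-1]
    target = -(-d // multiple) * multiple
    if target == d:
        return vol
    pad = [(0, 0)] * 3 + [(0, target - d)]
    return MultimodalVolume(np.pad(vol.data, pad), vol.modality_names,
                            vol.voxel_spacing, vol.affine)


def augment(vol: MultimodalVolume, lab: LabelVolume, rng: np.random.Generator,
            flip_prob: float = 0.5, max_rotation_deg: float = 10.0,
            intensity_shift: float = 0.1, intensity_scale: float = 0.1
            ) -> tuple[MultimodalVolume, LabelVolume]:
    """Training-time augmentation applied jointly to image and labels.

    (1) independent mirror flips of each spatial plane with probability
    0.5; (2) an in-plane (axial) rotation by a uniform angle in
    [-10°, 10°] — trilinear resampling for intensities, nearest-neighbour
    for labels so the alphabet {0, 1, 2, 4} is preserved; (3) per-modality
    affine intensity jitter x -> x*s + b with s in [0.9, 1.1] and b in
    [-0.1, 0.1].
    """
    data = vol.data.copy()
    labels = lab.labels.copy()
    for axis in range(3):
        if rng.random() < flip_prob:
            data = np.flip(data, axis=axis + 1)
            labels = np.flip(labels, axis=axis)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    if angle != 0.0:
        data = ndimage.rotate(data, angle, axes=(1, 2), reshape=False,
                              order=1, mode="constant", cval=0.0)
        labels = ndimage.rotate(labels, angle, axes=(0, 1), reshape=False,
                                order=0, mode="constant", cval=0)
    scale = rng.uniform(1.0 - intensity_scale, 1.0 + intensity_scale, size=(4, 1, 1, 1))
    shift = rng.uniform(-intensity_shift, intensity_shift, size=(4, 1, 1, 1))
    data = data * scale.astype(np.float32) + shift.astype(np.float32)
    return (MultimodalVolume(np.ascontiguousarray(data), vol.modality_names,
                             vol.voxel_spacing, vol.affine),
            LabelVolume(np.ascontiguousarray(labels), affine=lab.affine))
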