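"""Synthetic multimodal brain-tumor phantoms.

Each phantom emulates the structure of a BraTS case: a brain ellipsoid on
a zero background, with a tumor built from three nested ellipsoidal
compartments — an outer edema shell (label 2), a middle necrotic /
non-enhancing shell (label 1) and an enhancing core (label 4). Every
modality assigns each compartment a mean intensity from a contrast table
(e.g. edema is bright on FLAIR/T2, the enhancing core is bright on T1ce)
plus i.i.d. Gaussian noise. The phantoms exercise every pipeline stage
with no download; they do not model MRI physics (bias fields, partial
volume, multi-focal disease).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import MODALITIES, LabelVolume, MultimodalVolume, save_case

__all__ = ["PhantomSpec", "make_case", "make_dataset", "DEFAULT_CONTRAST"]

#: per-modality mean intensity of (brain, edema, necrotic core, enhancing) tissue
DEFAULT_CONTRAST = {
    "t1":    {"brain": 1.0, "edema": 0.8, "ncr": 0.6, "et": 0.9},
    "t1ce":  {"brain": 1.0, "edema": 0.9, "ncr": 0.7, "et": 1.8},
    "t2":    {"brain": 1.0, "edema": 1.5, "ncr": 1.2, "et": 1.3},
    "flair": {"brain": 1.0, "edema": 1.7, "ncr": 1.3, "et": 1.4},
}

#: compartment -> raw label (standard BraTS convention)
COMPARTMENT_LABELS = {"edema": 2, "ncr": 1, "et": 4}


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    n_cases: int = 4
    tumor_radius_range: tuple[float, float] = (0.18, 0.30)  # fraction of min dim
    radius_ratios: tuple[float, float] = (0.65, 0.35)       # tc/wt, et/wt radii
    noise_sd: float = 0.1
    contrast_table: dict = field(default_factory=lambda: DEFAULT_CONTRAST)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("tumor radii must be fractions in (0, 0.5)")
        r_tc, r_et = self.radius_ratios
        if not (0 < r_et < r_tc < 1):
            raise ValueError("radius ratios must satisfy 0 < et < tc < 1 "
                             "so the compartments nest")
        if min(self.shape) * lo * r_et < 1.5:
            raise ValueError(f"shape {self.shape} too small to host a nested tumor")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def make_case(spec: PhantomSpec, rng: np.random.Generator
              ) -> tuple[MultimodalVolume, LabelVolume]:
    """Draw one phantom case: 4-channel float volume + label volume."""
    shape = tuple(spec.shape)
    mind = min(shape)
    brain_radii = [0.45 * s for s in shape]
    brain_center = [s / 2 for s in shape]
    brain = _ellipsoid(shape, brain_center, brain_radii)

    wt_r = rng.uniform(*spec.tumor_radius_range) * mind
    # per-axis jitter makes the lesion a proper ellipsoid, not a sphere
    wt_radii = wt_r * rng.uniform(0.8, 1.2, size=3)
    lo = [r for r in wt_radii]
    center = [rng.uniform(c - (br - r) * 0.6, c + (br - r) * 0.6)
              for c, br, r in zip(brain_center, brain_radii, lo)]
    wt = _ellipsoid(shape, center, wt_radii) & brain
    tc = _ellipsoid(shape, center, wt_radii * spec.radius_ratios[0]) & brain
    et = _ellipsoid(shape, center, wt_radii * spec.radius_ratios[1]) & brain

    labels = np.zeros(shape, dtype=np.int16)
    labels[wt] = COMPARTMENT_LABELS["edema"]
    labels[tc] = COMPARTMENT_LABELS["ncr"]
    labels[et] = COMPARTMENT_LABELS["et"]

    data = np.zeros((4,) + shape, dtype=np.float32)
    for i, m in enumerate(MODALITIES):
        tab = spec.contrast_table[m]
        chan = np.zeros(shape, dtype=np.float32)
        chan[brain] = tab["brain"]
        chan[wt] = tab["edema"]
        chan[tc] = tab["ncr"]
        chan[et] = tab["et"]
        if spec.noise_sd > 0:
            chan[brain] += rng.normal(0.0, spec.noise_sd,
                                      size=int(brain.sum())).astype(np.float32)
        data[i] = chan
    return MultimodalVolume(data), LabelVolume(labels)


def make_dataset(spec: PhantomSpec, out_dir) -> list[Path]:
    """Write ``spec.n_cases`` phantoms as NIfTI case directories."""
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    dirs = []
    for i in range(spec.n_cases):
        vol, lab = make_case(spec, rng)
        dirs.append(save_case(out_dir / f"phantom_{i:03d}", vol, lab))
    return dirs
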