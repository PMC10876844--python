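"""Synthetic Jacobian-determinant-like volumes for testing the pipeline.

Tensor-based morphometry summarises a non-linear registration warp as a
Jacobian-determinant (JD) map: a smooth, brain-masked scalar field whose
values encode local volume change. In Alzheimer's disease the dominant
morphometric signal is ventricular enlargement, so the generator plants a
class-dependent intensity offset inside a "ventricle" sub-region of an
ellipsoidal brain mask. Each subject is

    base field (smoothed white noise)
    + label * effect_size * (1 + subject-level variability), inside ventricles
    + voxel noise,

masked, then min-max normalised to [0, 1] with dataset-global extremes —
mirroring how real JD maps are masked and globally normalised before
classification. A tunable fraction of subjects is "ambiguous": their effect
magnitude is shrunk to near zero, which makes them genuinely hard to
classify and is what the uncertainty-based rejection stage should detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SynthConfig",
    "Volume",
    "LabeledDataset",
    "make_brain_mask",
    "make_ventricle_mask",
    "generate_dataset",
    "split_dataset",
    "center_crop",
]

# Fraction of the ellipsoid semi-axes relative to the volume sides.
_BRAIN_SEMIAXIS = 0.45
_VENTRICLE_SEMIAXIS = 0.15
# Ambiguous subjects get their effect multiplied by U(0, AMBIGUOUS_SHRINK_MAX).
AMBIGUOUS_SHRINK_MAX = 0.1


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic morphometric cohort.

    Defaults are the desk-scale study conditions used throughout the test
    suite: 120 subjects at 32 voxels per side with a 0.4 fractional effect
    and a quarter of the cohort ambiguous.
    """

    n_subjects: int = 120
    shape: tuple[int, int, int] = (32, 32, 32)
    effect_size: float = 0.4
    subject_sd: float = 0.2
    noise_sd: float = 0.05
    ambiguous_fraction: float = 0.25
    smoothness: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError(f"shape must be a triple with entries >= 8, got {self.shape}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise ValueError("ambiguous_fraction must lie in [0, 1]")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


@dataclass
class Volume:
    """One 3D image with spatial metadata; the unit of classification."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass
class LabeledDataset:
    """Volumes with binary labels (0 = healthy, 1 = AD-like) and split tags.

    ``meta`` carries per-subject bookkeeping (subject_id, label, split,
    ambiguous flag, realised effect magnitude); the ambiguity flags let the
    uncertainty stage be validated against ground truth.
    """

    volumes: list[Volume]
    labels: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.volumes) != len(self.labels):
            raise ValueError("labels and volumes must have equal length")
        if self.meta.empty:
            self.meta = pd.DataFrame(
                {
                    "subject_id": [f"sub-{i:04d}" for i in range(len(self.volumes))],
                    "label": self.labels,
                    "split": [""] * len(self.volumes),
                }
            )

    def __len__(self) -> int:
        return len(self.volumes)

    @property
    def split(self) -> np.ndarray:
        return self.meta["split"].to_numpy()

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            volumes=[self.volumes[i] for i in idx],
            labels=self.labels[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def partition(self, tag: str) -> "LabeledDataset":
        """Return the subset whose split tag equals ``tag`` ('train'/'test')."""
        idx = np.flatnonzero(self.split == tag)
        return self.subset(idx)

    def stack(self) -> np.ndarray:
        """All volumes as a (n, 1, D, H, W) array (single channel)."""
        return np.stack([v.data for v in self.volumes])[:, None]


def _ellipsoid(shape: tuple[int, int, int], semiaxis_frac: float) -> np.ndarray:
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError(f"shape must be a positive triple, got {shape}")
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    r2 = np.zeros(shape)
    for g, s in zip(grids, shape):
        center = (s - 1) / 2.0
        semi = semiaxis_frac * s
        r2 += ((g - center) / semi) ** 2
    return r2 <= 1.0


def make_brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic ellipsoidal 'brain' mask inscribed in the volume.

    Semi-axes are 0.45 of each side, centred on the voxel grid; the result
    is symmetric under reflection of any axis and bit-reproducible.
    """
    if any(int(s) < 8 for s in shape):
        raise ValueError(f"shape entries must be >= 8, got {shape}")
    return _ellipsoid(shape, _BRAIN_SEMIAXIS)


def make_ventricle_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Interior 'ventricle' ellipsoid where the class effect is planted."""
    if any(int(s) < 8 for s in shape):
        raise ValueError(f"shape entries must be >= 8, got {shape}")
    return _ellipsoid(shape, _VENTRICLE_SEMIAXIS)


def generate_dataset(config: SynthConfig) -> LabeledDataset:
    """Generate a balanced labelled cohort of JD-like volumes.

    Labels alternate 0/1 (balanced to within one subject). Class 1 receives
    a positive offset of magnitude ``effect_size * (1 + N(0, subject_sd))``
    inside the ventricle region — ventricular enlargement as the disease
    signature. The first ``round(ambiguous_fraction * n)`` subjects of a
    seeded permutation have that magnitude multiplied by U(0, 0.1). After
    masking, all volumes are jointly min-max normalised so the dataset
    minimum is 0 and maximum is 1.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    shape = tuple(int(s) for s in config.shape)

    labels = np.array([i % 2 for i in range(n)], dtype=np.int64)
    n_ambiguous = int(round(config.ambiguous_fraction * n))
    ambiguous = np.zeros(n, dtype=bool)
    ambiguous[rng.permutation(n)[:n_ambiguous]] = True

    brain = make_brain_mask(shape)
    ventricle = make_ventricle_mask(shape)

    raws = np.empty((n,) + shape)
    magnitudes = np.empty(n)
    for i in range(n):
        base = gaussian_filter(rng.standard_normal(shape), config.smoothness, mode="reflect")
        magnitude = config.effect_size * (1.0 + rng.normal(0.0, config.subject_sd))
        if ambiguous[i]:
            magnitude *= rng.uniform(0.0, AMBIGUOUS_SHRINK_MAX)
        vol = base.copy()
        if labels[i] == 1:
            vol[ventricle] += magnitude
        vol += rng.normal(0.0, config.noise_sd, shape)
        vol *= brain
        raws[i] = vol
        magnitudes[i] = magnitude if labels[i] == 1 else 0.0

    lo, hi = raws.min(), raws.max()
    if hi > lo:
        raws = (raws - lo) / (hi - lo)
    else:  # degenerate all-constant dataset
        raws = np.zeros_like(raws)

    volumes = [Volume(raws[i]) for i in range(n)]
    meta = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "label": labels,
            "split": [""] * n,
            "ambiguous": ambiguous,
            "effect_magnitude": magnitudes,
        }
    )
    return LabeledDataset(volumes=volumes, labels=labels, meta=meta)


def split_dataset(dataset: LabeledDataset, train_fraction: float, seed: int) -> LabeledDataset:
    """Stratified train/test split; returns a dataset with split tags set."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    split = np.array([""] * len(dataset), dtype=object)
    for cls in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 members; cannot split")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both partitions non-empty
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"
    meta = dataset.meta.copy()
    meta["split"] = split.astype(str)
    return replace(dataset, meta=meta)


def center_crop(data: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Central block of ``target_shape`` from an equal-or-larger array."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("center_crop expects a 3D array")
    if any(t > s for t, s in zip(target_shape, data.shape)):
        raise ValueError(f"target {target_shape} exceeds input shape {data.shape}")
    slices = tuple(
        slice((s - t) // 2, (s - t) // 2 + t) for s, t in zip(data.shape, target_shape)
    )
    return data[slices]
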