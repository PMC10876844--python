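"""NIfTI volume I/O and on-disk dataset layout.

A dataset directory holds one ``<subject_id>.nii.gz`` per subject plus a
``labels.csv`` sidecar with columns subject_id, label, split (and, when the
data came from the synthetic generator, the ambiguity bookkeeping).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .synthetic import LabeledDataset, Volume

__all__ = ["read_volume", "write_volume", "save_dataset", "load_dataset"]


def write_volume(volume: Volume, path) -> None:
    affine = np.diag(list(volume.voxel_size) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
    except Exception as exc:  # malformed/truncated files must not crash callers
        raise FormatError(f"could not read NIfTI volume {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise FormatError(f"{path!r}: expected a 3D volume, got ndim={data.ndim}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, voxel_size=voxel_size)


def save_dataset(dataset: LabeledDataset, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    for vol, sid in zip(dataset.volumes, dataset.meta["subject_id"]):
        write_volume(vol, os.path.join(out_dir, f"{sid}.nii.gz"))
    dataset.meta.to_csv(os.path.join(out_dir, "labels.csv"), index=False)


def load_dataset(data_dir) -> LabeledDataset:
    csv_path = os.path.join(data_dir, "labels.csv")
    if not os.path.exists(csv_path):
        raise FormatError(f"no labels.csv in {data_dir!r}")
    meta = pd.read_csv(csv_path, keep_default_na=False)
    volumes = [
        read_volume(os.path.join(data_dir, f"{sid}.nii.gz")) for sid in meta["subject_id"]
    ]
    return LabeledDataset(
        volumes=volumes, labels=meta["label"].to_numpy(), meta=meta
    )
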