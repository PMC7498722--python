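"""Volume loading, normalization, slice selection and RGB fusion.

Pipeline: each modality volume is min-max rescaled to 8-bit over the whole
volume, a contiguous window of axial slices (default indexes 37-68, i.e. 32
slices) is extracted, and same-index slices of the three modalities are
stacked into the channels of one RGB composite, so that a three-channel
network ingests all modalities at once.  Channel order is FA -> R, MD -> G,
sMRI -> B by default.  Single-modality experiments replicate one modality
into all three channels (pseudo-RGB).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import MODALITIES, Subject, Volume

#: default inclusive slice window (0-based along the slicing axis)
DEFAULT_WINDOW = (37, 68)
DEFAULT_AXIS = 2
#: channel order of the fused composite: (R, G, B)
DEFAULT_CHANNELS = ("FA", "MD", "sMRI")


def load_volume(path: str | Path, expected_shape=None, modality: str = "sMRI") -> Volume:
    """Read a NIfTI volume, optionally verifying its voxel grid shape."""
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if expected_shape is not None and tuple(data.shape) != tuple(expected_shape):
        raise ValueError(
            f"volume {path} has shape {tuple(data.shape)}, expected {tuple(expected_shape)}"
        )
    return Volume(data=data, modality=modality, affine=np.asarray(img.affine))


def normalize_modality(volume: Volume) -> Volume:
    """Min-max rescale a whole volume to 8-bit [0, 255].

    Statistics are volume-global (not per slice) so inter-slice intensity
    relationships are preserved.  A constant volume maps to all zeros.
    """
    data = volume.data
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot normalize a volume with non-finite values")
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        scaled = np.zeros(volume.shape, dtype=np.uint8)
    else:
        scaled = np.rint((data.astype(np.float64) - lo) * (255.0 / (hi - lo))).astype(np.uint8)
    return Volume(data=scaled, modality=volume.modality, affine=volume.affine)


def extract_slices(
    volume: Volume, window: tuple[int, int] = DEFAULT_WINDOW, axis: int = DEFAULT_AXIS
) -> list[np.ndarray]:
    """Extract the inclusive window of 2D slices along ``axis``, ascending."""
    lo, hi = window
    extent = volume.shape[axis]
    if not (0 <= lo <= hi < extent):
        raise ValueError(f"window {window} out of bounds for axis {axis} of extent {extent}")
    return [np.take(volume.data, k, axis=axis) for k in range(lo, hi + 1)]


@dataclass(frozen=True)
class FusedSlice:
    """An 8-bit RGB composite of same-index slices from the three modalities."""

    pixels: np.ndarray  # (H, W, 3) uint8
    slice_index: int
    subject_id: str
    label: int

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"fused slice must be HxWx3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"fused slice must be uint8, got {self.pixels.dtype}")


def fuse_rgb(fa_slice: np.ndarray, md_slice: np.ndarray, smri_slice: np.ndarray) -> np.ndarray:
    """Stack three normalized same-index slices into (FA, MD, sMRI) channels.

    Pure channel stacking: no cross-channel mixing, lossless at 8 bits.
    """
    slices = (fa_slice, md_slice, smri_slice)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise ValueError(f"slices to fuse must share shape, got {shapes}")
    for s in slices:
        if s.min() < 0 or s.max() > 255:
            raise ValueError("slices must already be normalized to [0, 255]")
    return np.stack([np.asarray(s, dtype=np.uint8) for s in slices], axis=-1)


def split_rgb(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """De-interleave a fused composite back into its three channel slices."""
    return pixels[..., 0], pixels[..., 1], pixels[..., 2]


def fuse_subject(
    subject: Subject,
    window: tuple[int, int] = DEFAULT_WINDOW,
    axis: int = DEFAULT_AXIS,
    channels: tuple[str, str, str] = DEFAULT_CHANNELS,
) -> list[FusedSlice]:
    """Normalize, slice and fuse one subject into its ordered RGB composites.

    ``channels`` names the modality feeding each of R, G, B; a repeated name
    (e.g. ``('sMRI',) * 3``) yields the pseudo-RGB single-modality input.
    """
    unknown = set(channels) - set(MODALITIES)
    if unknown:
        raise ValueError(f"unknown channel modalities {unknown}")
    normalized = {m: normalize_modality(subject.volumes[m]) for m in set(channels)}
    per_channel = {m: extract_slices(normalized[m], window, axis) for m in normalized}
    fused = []
    for offset, index in enumerate(range(window[0], window[1] + 1)):
        pixels = fuse_rgb(*(per_channel[m][offset] for m in channels))
        fused.append(
            FusedSlice(pixels=pixels, slice_index=index, subject_id=subject.subject_id, label=subject.label)
        )
    return fused


@dataclass
class SliceDataset:
    """Slice-level dataset with a seeded train/validation partition."""

    items: list[FusedSlice]
    partition: list[str]  # "train" / "val", parallel to items
    split_ratio: tuple[float, float] = (0.8, 0.2)

    def __post_init__(self) -> None:
        if len(self.items) != len(self.partition):
            raise ValueError("partition must be parallel to items")

    @property
    def train_items(self) -> list[FusedSlice]:
        return [s for s, p in zip(self.items, self.partition) if p == "train"]

    @property
    def val_items(self) -> list[FusedSlice]:
        return [s for s, p in zip(self.items, self.partition) if p == "val"]

    def counts(self) -> dict[str, int]:
        return {
            "total": len(self.items),
            "train": sum(p == "train" for p in self.partition),
            "val": sum(p == "val" for p in self.partition),
        }


@dataclass
class SubjectEntry:
    subject_id: str
    label: int
    slices: list[FusedSlice]  # ascending slice_index


@dataclass
class SubjectDataset:
    """One ordered stack of fused slices per subject, for subject-level models."""

    entries: list[SubjectEntry]

    def __len__(self) -> int:
        return len(self.entries)


def build_slice_dataset(
    cohort: Sequence[Subject],
    split_seed: int = 0,
    window: tuple[int, int] = DEFAULT_WINDOW,
    axis: int = DEFAULT_AXIS,
    channels: tuple[str, str, str] = DEFAULT_CHANNELS,
    ratio: float = 0.8,
    grouped: bool = True,
) -> SliceDataset:
    """Fuse every subject and partition slices 8:2 into train/validation.

    By default the split is grouped by subject: all of one subject's slices
    land in the same partition, so no subject identity leaks from train into
    validation.  ``grouped=False`` reproduces a literal ungrouped slice-level
    split (same expected ratio, subject slices may straddle partitions).
    """
    items: list[FusedSlice] = []
    for subject in cohort:
        items.extend(fuse_subject(subject, window, axis, channels))
    rng = np.random.default_rng(split_seed)
    if grouped:
        ids = [s.subject_id for s in cohort]
        order = rng.permutation(len(ids))
        n_train = round(ratio * len(ids))
        train_ids = {ids[i] for i in order[:n_train]}
        partition = ["train" if s.subject_id in train_ids else "val" for s in items]
    else:
        order = rng.permutation(len(items))
        n_train = round(ratio * len(items))
        train_set = set(order[:n_train].tolist())
        partition = ["train" if i in train_set else "val" for i in range(len(items))]
    return SliceDataset(items=items, partition=partition, split_ratio=(ratio, 1.0 - ratio))


def build_subject_dataset(
    cohort: Sequence[Subject],
    window: tuple[int, int] = DEFAULT_WINDOW,
    axis: int = DEFAULT_AXIS,
    channels: tuple[str, str, str] = DEFAULT_CHANNELS,
) -> SubjectDataset:
    """One entry per subject, each holding its full ordered slice stack."""
    entries = []
    for subject in cohort:
        slices = fuse_subject(subject, window, axis, channels)
        entries.append(SubjectEntry(subject_id=subject.subject_id, label=subject.label, slices=slices))
    return SubjectDataset(entries=entries)


def slice_label_counts(dataset: SliceDataset) -> dict[int, int]:
    counts: dict[int, int] = {}
    for item in dataset.items:
        counts[item.label] = counts.get(item.label, 0) + 1
    return counts


def write_composites(dataset: SubjectDataset, out_dir: str | Path, fmt: str = "png") -> pd.DataFrame:
    """Persist composites as ``<subject>_<index>.png`` (lossless by default).

    ``fmt='jpeg'`` writes quality-95 JPEGs instead; JPEG is lossy, so
    round-trip identity only holds for PNG.
    """
    from PIL import Image

    if fmt not in ("png", "jpeg"):
        raise ValueError(f"format must be png or jpeg, got {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for entry in dataset.entries:
        for fused in entry.slices:
            name = f"{entry.subject_id}_{fused.slice_index}.{ 'png' if fmt == 'png' else 'jpg'}"
            img = Image.fromarray(fused.pixels, mode="RGB")
            if fmt == "png":
                img.save(out_dir / name)
            else:
                img.save(out_dir / name, quality=95)
            rows.append(
                {
                    "subject_id": entry.subject_id,
                    "label": entry.label,
                    "slice_index": fused.slice_index,
                    "path": name,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "slices.csv", index=False)
    return manifest
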