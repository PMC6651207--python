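"""Encode 1-s EEG segments as small RGB images.

Three channels form one pixel row: their [0, 1] values at each sample
become the red, green and blue intensities of one pixel, one image column
per sample. At 128 samples/s a 1-s segment becomes a 128-pixel-wide image;
the 14 montage channels form ceil(14/3) = 5 rows, the last row padded
with a null (all-zero) channel. Intensities are quantized to 8 bits with
round-half-up, so decoding recovers each value within 1/255.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import Segment, segment as cut_segments
from .recording import Recording
from .task import ANALYSIS_SUBTASKS

#: Placeholder label for the padding slots of an incomplete final triplet.
NULL_CHANNEL = None


@dataclass
class EncodedImage:
    """RGB raster of one segment plus its provenance labels."""

    pixels: np.ndarray          # (height, width, 3) uint8
    label: str                  # task
    subject_id: str
    segment_index: int
    subtask: str = ""


@dataclass
class ImageDatasetManifest:
    """Labeled image collection: a manifest table plus the images.

    ``entries`` columns: path (empty when kept in memory), subject_id,
    task, subtask, segment_index. ``images`` holds the EncodedImage
    objects in row order.
    """

    entries: pd.DataFrame
    images: list[EncodedImage]

    @property
    def class_counts(self) -> dict[str, int]:
        return self.entries["task"].value_counts().to_dict()


def group_channels(channel_names: tuple[str, ...]) -> list[tuple[str | None, ...]]:
    """Consecutive channel triplets in montage order, null-padded at the end."""
    if not channel_names:
        raise ValueError("empty channel list")
    names = list(channel_names)
    while len(names) % 3:
        names.append(NULL_CHANNEL)
    return [tuple(names[i:i + 3]) for i in range(0, len(names), 3)]


def encode_segment(seg: Segment) -> EncodedImage:
    """Map a normalized segment to an RGB image (one triplet per row)."""
    data = np.asarray(seg.data, dtype=np.float64)
    if data.min() < 0 or data.max() > 1:
        raise ValueError("segment values must lie in [0, 1]; normalize first")
    n_ch, width = data.shape
    triplets = group_channels(tuple(range(n_ch)))  # index triplets
    pixels = np.zeros((len(triplets), width, 3), dtype=np.uint8)
    for row, trip in enumerate(triplets):
        for color, ch in enumerate(trip):
            if ch is not None:
                # round-half-up 8-bit quantization
                pixels[row, :, color] = np.floor(data[ch] * 255.0 + 0.5).astype(np.uint8)
    return EncodedImage(
        pixels=pixels,
        label=seg.task,
        subject_id=seg.subject_id,
        segment_index=seg.index,
        subtask=seg.subtask,
    )


def decode_image(image: EncodedImage | np.ndarray,
                 montage: tuple[str, ...]) -> np.ndarray:
    """Recover channel x sample values in [0, 1] from an encoded image.

    Exact up to the 8-bit quantization step (max error 1/(2*255) per
    value, bounded by 1/255).
    """
    pixels = image.pixels if isinstance(image, EncodedImage) else image
    n_ch = len(montage)
    n_rows = (n_ch + 2) // 3
    if pixels.ndim != 3 or pixels.shape[0] != n_rows or pixels.shape[2] != 3:
        raise ValueError(
            f"image height {pixels.shape[0]} does not match the "
            f"{n_ch}-channel montage (expected {n_rows} rows)"
        )
    flat = pixels.transpose(0, 2, 1).reshape(n_rows * 3, -1)
    return flat[:n_ch].astype(np.float64) / 255.0


def build_image_dataset(recordings: list[Recording],
                        analysis_subtasks: tuple[str, ...] = ANALYSIS_SUBTASKS,
                        out_dir: str | Path | None = None) -> ImageDatasetManifest:
    """Encode every 1-s segment of the analysis sub-tasks of a cohort.

    Recordings must already be preprocessed (filtered + normalized).
    With ``out_dir`` given, one PNG per segment is written and the
    manifest CSV is saved alongside; otherwise images stay in memory.
    """
    rows = []
    images: list[EncodedImage] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        for seg in cut_segments(rec):
            if seg.subtask not in analysis_subtasks:
                continue
            img = encode_segment(seg)
            path = ""
            if out is not None:
                path = str(out / f"{rec.subject_id}_{rec.task}_{seg.index:04d}.png")
                Image.fromarray(img.pixels, mode="RGB").save(path)
            rows.append({
                "path": path,
                "subject_id": rec.subject_id,
                "task": rec.task,
                "subtask": seg.subtask,
                "segment_index": seg.index,
            })
            images.append(img)
    if not rows:
        raise ValueError(
            f"no segments matched analysis sub-tasks {analysis_subtasks}"
        )
    entries = pd.DataFrame(rows)
    if out is not None:
        entries.to_csv(out / "manifest.csv", index=False)
    return ImageDatasetManifest(entries=entries, images=images)


def load_image_dataset(manifest_csv: str | Path) -> ImageDatasetManifest:
    """Reload a written dataset from its manifest CSV (paths relative OK)."""
    manifest_csv = Path(manifest_csv)
    entries = pd.read_csv(manifest_csv)
    images = []
    for row in entries.itertuples():
        p = Path(row.path)
        if not p.is_absolute() and not p.exists():
            p = manifest_csv.parent / p.name
        pixels = np.asarray(Image.open(p).convert("RGB"), dtype=np.uint8)
        images.append(EncodedImage(
            pixels=pixels, label=row.task, subject_id=row.subject_id,
            segment_index=int(row.segment_index),
            subtask=getattr(row, "subtask", ""),
        ))
    return ImageDatasetManifest(entries=entries, images=images)
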