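"""Encode 1-s segments as 5 x 128 RGB images and decode them back.

Three consecutive montage channels form one pixel row (their [0, 1]
values are the R, G, B intensities); 128 samples/s gives 128 columns.
The encoding is invertible up to 8-bit quantization (error <= 1/255).
"""

import numpy as np

from leansense import build_image_dataset, decode_image, encode_segment, group_channels, make_cohort, segment
from leansense.montage import CHANNELS
from leansense.preprocess import preprocess

print("channel triplets (one per pixel row):")
for row, trip in enumerate(group_channels(CHANNELS)):
    print(f"  row {row}: {trip}")

cohort = [preprocess(r) for r in make_cohort(1, 128, seed=6)]
seg = segment(cohort[0])[100]
img = encode_segment(seg)
back = decode_image(img, CHANNELS)
print(f"\nimage shape: {img.pixels.shape} (rows x samples x RGB)")
print(f"round-trip max error: {np.abs(back - seg.data).max():.5f} "
      f"(quantization bound 1/255 = {1 / 255:.5f})")

dataset = build_image_dataset(cohort)
print(f"dataset from one subject: {len(dataset.images)} images, "
      f"class counts {dataset.class_counts}")
print("""
250 KATA-III + 250 Plan segments per subject -> 500 images; a 24-subject
cohort therefore yields the full 12,000-image training corpus.""")
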