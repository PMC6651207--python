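"""The 14-channel AES electrode montage used throughout the package.

Channel order is fixed; every matrix, image row and feature vector in the
package indexes channels in this order.
"""

from __future__ import annotations

#: The 14 AES electrode labels in device listing order.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Six frontal sensors over the prefrontal cortex.
FRONTAL: tuple[str, ...] = ("AF3", "F7", "F3", "AF4", "F4", "F8")

#: Cortical-region annotations for the sensors the hypotheses name.
REGIONS: dict[str, str] = {
    "F7": "vmPFC-L",
    "F3": "dlPFC-L",
    "F4": "vmPFC-R",
    "F8": "dlPFC-R",
    "P7": "TPJ-L",
    "P8": "TPJ-R",
}

#: Default sampling rate of the recording device, samples per second.
FS_DEFAULT: int = 128


def channel_index(name: str) -> int:
    """Index of a channel in montage order; raises on unknown labels."""
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise KeyError(
            f"unknown channel {name!r}; montage channels are {', '.join(CHANNELS)}"
        ) from None
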