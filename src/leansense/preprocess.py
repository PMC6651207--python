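"""Causal filtering, [0, 1] normalization and 1-s segmentation.

The preprocessing chain deliberately uses *causal* (forward-only) IIR
filters: sample t of the output depends only on samples <= t of the input,
at the cost of a phase shift. A 5th-order Butterworth high-pass at 1 Hz
removes DC offsets and slow drifts; a 5th-order Butterworth low-pass at
50 Hz removes high-frequency noise (and subsumes the mains notch). Each
channel is then independently rescaled to [0, 1] over the whole recording
— amplitude is anonymized while rank order and inter-channel correlation
structure are preserved. Finally the session is cut into non-overlapping
1-s segments, each labeled with the sub-task interval containing its
start sample.

The pipeline order is always filter -> normalize -> segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Recording


@dataclass(frozen=True)
class PreprocessConfig:
    """Filter and normalization settings.

    Attributes
    ----------
    highpass_cutoff
        High-pass cut-off in Hz (default 1): removes DC and drift.
    lowpass_cutoff
        Low-pass cut-off in Hz (default 50).
    filter_order
        Butterworth order for each filter (default 5).
    causal
        Forward-only filtering (always true in this pipeline; kept
        explicit because the choice changes the science).
    """

    highpass_cutoff: float = 1.0
    lowpass_cutoff: float = 50.0
    filter_order: int = 5
    causal: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.highpass_cutoff < self.lowpass_cutoff):
            raise ValueError("need 0 < highpass_cutoff < lowpass_cutoff")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if not self.causal:
            raise ValueError("this pipeline is defined for causal filtering only")


@dataclass
class Segment:
    """One 1-s (or ``window_s``-s) slice of a preprocessed recording."""

    subject_id: str
    task: str
    subtask: str
    index: int
    fs: float
    data: np.ndarray  # (n_channels, fs * window_s), values in [0, 1]


def design_filters(config: PreprocessConfig, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Second-order-section coefficients for the high- and low-pass stages."""
    nyq = fs / 2
    if config.lowpass_cutoff >= nyq:
        raise ValueError(
            f"low-pass cutoff {config.lowpass_cutoff} Hz >= Nyquist {nyq} Hz"
        )
    hp = signal.butter(config.filter_order, config.highpass_cutoff,
                       btype="highpass", fs=fs, output="sos")
    lp = signal.butter(config.filter_order, config.lowpass_cutoff,
                       btype="lowpass", fs=fs, output="sos")
    return hp, lp


def apply_filters(recording: Recording,
                  config: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Causal high-pass + low-pass filtering of every channel."""
    if recording.duration < 2.0:
        raise ValueError("recording shorter than the 2-s filter warm-up")
    hp, lp = design_filters(config, recording.fs)
    y = signal.sosfilt(hp, recording.data, axis=-1)
    y = signal.sosfilt(lp, y, axis=-1)
    return recording.with_data(y)


def normalize01(recording: Recording) -> Recording:
    """Rescale each channel to [min, max] -> [0, 1] over the whole recording."""
    lo = recording.data.min(axis=-1, keepdims=True)
    hi = recording.data.max(axis=-1, keepdims=True)
    flat = (hi - lo).ravel() == 0
    if np.any(flat):
        bad = [recording.channel_names[i] for i in np.nonzero(flat)[0]]
        raise ValueError(f"constant channel(s) cannot be normalized: {', '.join(bad)}")
    return recording.with_data((recording.data - lo) / (hi - lo))


def preprocess(recording: Recording,
               config: PreprocessConfig = PreprocessConfig()) -> Recording:
    """Filter then normalize (the canonical order)."""
    return normalize01(apply_filters(recording, config))


def segment(recording: Recording, window_s: float = 1.0) -> list[Segment]:
    """Cut into non-overlapping windows labeled by sub-task at window start.

    Returns ``floor(duration / window_s)`` segments; a trailing partial
    window is dropped. A window straddling a sub-task boundary takes the
    label of the interval containing its start.
    """
    n_win = window_s * recording.fs
    if abs(n_win - round(n_win)) > 1e-9:
        raise ValueError("window_s x fs must be an integral sample count")
    n_win = int(round(n_win))
    out: list[Segment] = []
    for k in range(recording.n_samples // n_win):
        start = k * n_win
        out.append(Segment(
            subject_id=recording.subject_id,
            task=recording.task,
            subtask=recording.script.label_at(start / recording.fs),
            index=k,
            fs=recording.fs,
            data=recording.data[:, start:start + n_win],
        ))
    return out
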