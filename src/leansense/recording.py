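"""The in-memory container for one multichannel EEG session."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .task import TaskScript


@dataclass
class Recording:
    """One subject-task EEG session: channel x time matrix plus metadata.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    task
        Task label ("KATA" or "CPDnA"; "control" for null sessions).
    fs
        Sampling rate, samples per second.
    data
        ``(n_channels, n_samples)`` array of signal values (arbitrary units
        before normalization, [0, 1] after).
    channel_names
        Ordered channel labels matching the rows of ``data``.
    script
        The session's sub-task timing script.
    """

    subject_id: str
    task: str
    fs: float
    data: np.ndarray
    channel_names: tuple[str, ...]
    script: TaskScript

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channel x time array")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows for "
                f"{len(self.channel_names)} channel names"
            )
        expected = self.fs * self.script.total_duration
        if abs(self.data.shape[1] - expected) > 0.5:
            raise ValueError(
                f"data length {self.data.shape[1]} does not match script "
                f"duration ({expected:.0f} samples at fs={self.fs})"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """One channel's time series by label."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None
        return self.data[idx]

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with ``data`` replaced."""
        return replace(self, data=data)

    def subtask_window(self, label: str) -> "Recording":
        """Restrict to the samples of one sub-task interval.

        The returned recording keeps fs and channels; its script is a
        single-interval script covering just that sub-task.
        """
        start_s = 0.0
        for lab, dur in self.script.intervals:
            if lab == label:
                i0 = int(round(start_s * self.fs))
                i1 = min(int(round((start_s + dur) * self.fs)), self.n_samples)
                sub = TaskScript(self.task, ((lab, (i1 - i0) / self.fs),))
                return replace(self, data=self.data[:, i0:i1], script=sub)
            start_s += dur
        raise KeyError(f"sub-task {label!r} not in script for task {self.task!r}")
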