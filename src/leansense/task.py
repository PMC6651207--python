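"""Task scripts: the timed sub-task structure of each behavioral session.

Both problem-solving routines run 300 s. The KATA routine spends 10 s on
target-condition framing (KATA-I), 40 s on current-condition analysis
(KATA-II) and 250 s on the iterative experimentation step (KATA-III).
The (CPD)nA routine spends 10 s on Check, 250 s on Plan and 40 s on Do.
The long 250-s window of each task is the analysis window for both the
connectivity analysis and the image dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

TASK_KATA = "KATA"
TASK_CPDNA = "CPDnA"
TASKS = (TASK_KATA, TASK_CPDNA)

#: Sub-task labels of the long analysis window of each task.
ANALYSIS_SUBTASKS = ("KATA-III", "Plan")


@dataclass(frozen=True)
class TaskScript:
    """Ordered sub-task intervals of one behavioral session.

    Parameters
    ----------
    task
        Task label, ``"KATA"`` or ``"CPDnA"``.
    intervals
        Ordered ``(label, duration_s)`` pairs.
    """

    task: str
    intervals: tuple[tuple[str, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("a task script needs at least one interval")
        for label, dur in self.intervals:
            if dur <= 0:
                raise ValueError(f"interval {label!r} has non-positive duration {dur}")

    @property
    def total_duration(self) -> float:
        """Session length in seconds."""
        return float(sum(d for _, d in self.intervals))

    def label_at(self, t: float) -> str:
        """Sub-task label of the interval containing time ``t`` (seconds).

        Interval starts are inclusive; a time at or beyond the session end
        takes the last label (segments never start there in practice).
        """
        if t < 0:
            raise ValueError("time before session start")
        edge = 0.0
        for label, dur in self.intervals:
            edge += dur
            if t < edge:
                return label
        return self.intervals[-1][0]


def kata_script() -> TaskScript:
    """The 300-s KATA session preset: 10 s / 40 s / 250 s."""
    return TaskScript(
        TASK_KATA, (("KATA-I", 10.0), ("KATA-II", 40.0), ("KATA-III", 250.0))
    )


def cpdna_script() -> TaskScript:
    """The 300-s (CPD)nA session preset: Check 10 s, Plan 250 s, Do 40 s."""
    return TaskScript(
        TASK_CPDNA, (("Check", 10.0), ("Plan", 250.0), ("Do", 40.0))
    )


def script_for(task: str) -> TaskScript:
    """Session preset for a task label."""
    if task == TASK_KATA:
        return kata_script()
    if task == TASK_CPDNA:
        return cpdna_script()
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
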