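"""Channel-pair cross-correlation and the four coupling hypotheses.

The synchrony measure is the normalized cross-correlation: at zero lag it
is the Pearson correlation coefficient of the two (mean-removed) series;
with ``max_lag > 0`` it is the maximum-magnitude coefficient over integer
lags in ``[-max_lag, +max_lag]``. Zero lag is the default throughout.

Four hypotheses about lean-management problem solving are encoded:

* H1 — executive engagement: every pair among the six frontal sensors
  (AF3, F7, F3, AF4, F4, F8) correlates >= 0.45 in both tasks.
* H2 — goal-driven coordination: the ventromedial-dorsolateral pairs
  (F7, F3) and (F4, F8) correlate >= 0.85 in both tasks.
* H3 — context independence of KATA: temporoparietal-frontal pairs
  (P7-{F7, F3}, P8-{F4, F8}) correlate <= 0.34 during KATA.
* H4 — context dependence of (CPD)nA: the same pairs correlate >= 0.68
  during (CPD)nA.

Correlations are computed over the full 250-s analysis window of each
task (KATA-III, Plan), one coefficient per pair per task.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .montage import FRONTAL, REGIONS
from .recording import Recording


@dataclass
class CorrelationMatrix:
    """Symmetric channel-pair correlation coefficients."""

    channel_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.channel_names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match channel count")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("correlation coefficients must lie in [-1, 1]")

    def pair(self, a: str, b: str) -> float:
        i = self.channel_names.index(a)
        j = self.channel_names.index(b)
        return float(self.values[i, j])


@dataclass(frozen=True)
class HypothesisSpec:
    """One coupling hypothesis: a pair set, a comparator and a threshold."""

    id: str
    pair_sets: tuple[tuple[str, str], ...]
    comparator: str                      # "all_ge" or "all_le"
    threshold: float
    tasks: tuple[str, ...]               # tasks the hypothesis is tested on
    region_annotation: str = ""

    def __post_init__(self) -> None:
        if self.comparator not in ("all_ge", "all_le"):
            raise ValueError("comparator must be 'all_ge' or 'all_le'")
        if not 0 <= self.threshold <= 1:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class HypothesisReport:
    spec: HypothesisSpec
    per_pair: list[tuple[str, tuple[str, str], float]] = field(default_factory=list)
    verdict: str = "not_supported"


def cross_correlation(a: np.ndarray, b: np.ndarray, max_lag: int = 0) -> float:
    """Normalized cross-correlation of two equal-length series.

    At ``max_lag=0`` this is the Pearson correlation coefficient. For
    ``max_lag>0`` the Pearson coefficient of the overlapping parts is
    computed at every integer lag in ``[-max_lag, +max_lag]`` and the
    coefficient of maximum magnitude (with its sign) is returned.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("inputs must be equal-length 1-D series of length >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input")
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")

    def pearson(x: np.ndarray, y: np.ndarray) -> float:
        x = x - x.mean()
        y = y - y.mean()
        denom = np.linalg.norm(x) * np.linalg.norm(y)
        if denom == 0:
            return 0.0
        return float(np.dot(x, y) / denom)

    best = pearson(a, b)
    for lag in range(1, max_lag + 1):
        if lag >= a.size - 1:
            break
        for r in (pearson(a[lag:], b[:-lag]), pearson(a[:-lag], b[lag:])):
            if abs(r) > abs(best):
                best = r
    return best


def correlation_matrix(recording: Recording, channels: tuple[str, ...] | None = None,
                       max_lag: int = 0) -> CorrelationMatrix:
    """Pairwise cross-correlations over the recording's analysis window."""
    if channels is None:
        channels = recording.channel_names
    for c in channels:
        if c not in recording.channel_names:
            raise KeyError(f"channel {c!r} not in recording")
    rows = np.stack([recording.channel(c) for c in channels])
    n = len(channels)
    if max_lag == 0:
        values = np.corrcoef(rows)
        sd = rows.std(axis=-1)
        if np.any(sd == 0):
            bad = channels[int(np.argmin(sd))]
            raise ValueError(f"zero-variance channel {bad!r}")
        np.fill_diagonal(values, 1.0)
        values = np.clip((values + values.T) / 2, -1.0, 1.0)
    else:
        values = np.eye(n)
        for i, j in itertools.combinations(range(n), 2):
            values[i, j] = values[j, i] = cross_correlation(
                rows[i], rows[j], max_lag=max_lag
            )
    return CorrelationMatrix(tuple(channels), values)


def default_hypotheses() -> list[HypothesisSpec]:
    """The four coupling hypotheses with their literature-derived bounds."""
    frontal_pairs = tuple(itertools.combinations(FRONTAL, 2))
    pf_pairs = (("P7", "F7"), ("P7", "F3"), ("P8", "F4"), ("P8", "F8"))
    annot = ", ".join(f"{ch}->{reg}" for ch, reg in REGIONS.items())
    return [
        HypothesisSpec("H1", frontal_pairs, "all_ge", 0.45,
                       tasks=("KATA", "CPDnA"),
                       region_annotation="prefrontal executive block"),
        HypothesisSpec("H2", (("F7", "F3"), ("F4", "F8")), "all_ge", 0.85,
                       tasks=("KATA", "CPDnA"),
                       region_annotation="vmPFC-dlPFC goal coordination"),
        HypothesisSpec("H3", pf_pairs, "all_le", 0.34, tasks=("KATA",),
                       region_annotation=annot),
        HypothesisSpec("H4", pf_pairs, "all_ge", 0.68, tasks=("CPDnA",),
                       region_annotation=annot),
    ]


def _passes(value: float, spec: HypothesisSpec) -> bool:
    # Inclusive comparisons: boundary equality counts as a pass.
    return value >= spec.threshold if spec.comparator == "all_ge" \
        else value <= spec.threshold


def evaluate_hypotheses(kata: CorrelationMatrix, cpdna: CorrelationMatrix,
                        specs: list[HypothesisSpec] | None = None
                        ) -> list[HypothesisReport]:
    """Evaluate each hypothesis on the task matrices it applies to.

    H1/H2 must hold on both tasks; H3 is tested on the KATA matrix and H4
    on the (CPD)nA matrix. A hypothesis is supported iff its comparator
    holds for every (task, pair) coefficient.
    """
    if specs is None:
        specs = default_hypotheses()
    matrices = {"KATA": kata, "CPDnA": cpdna}
    reports: list[HypothesisReport] = []
    for spec in specs:
        rep = HypothesisReport(spec=spec)
        ok = True
        for t in spec.tasks:
            mat = matrices[t]
            for pair in spec.pair_sets:
                for c in pair:
                    if c not in mat.channel_names:
                        raise KeyError(f"channel {c!r} missing from {t} matrix")
                r = mat.pair(*pair)
                rep.per_pair.append((t, pair, r))
                ok = ok and _passes(r, spec)
        rep.verdict = "supported" if ok else "not_supported"
        reports.append(rep)
    return reports


def report_to_json(reports: list[HypothesisReport],
                   matrices: dict[str, CorrelationMatrix]) -> str:
    """Serialize hypothesis verdicts + full matrices for the run report."""
    payload = {
        "matrices": {
            t: {"channels": list(m.channel_names), "values": m.values.tolist()}
            for t, m in matrices.items()
        },
        "hypotheses": [
            {
                "id": r.spec.id,
                "comparator": r.spec.comparator,
                "threshold": r.spec.threshold,
                "verdict": r.verdict,
                "pairs": [
                    {"task": t, "pair": list(p), "coefficient": v}
                    for t, p, v in r.per_pair
                ],
            }
            for r in reports
        ],
    }
    return json.dumps(payload, indent=2)
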