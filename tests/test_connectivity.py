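"""Cross-correlation measure and the four coupling hypotheses."""

import itertools

import numpy as np
import pytest

from leansense import (
    CorrelationMatrix,
    correlation_matrix,
    cross_correlation,
    default_hypotheses,
    evaluate_hypotheses,
)
from leansense.montage import CHANNELS, FRONTAL
from leansense.recording import Recording
from leansense.task import TaskScript

IDX = {c: i for i, c in enumerate(CHANNELS)}


def brute_force_max_lag(a, b, max_lag):
    """Independent oracle: Pearson coefficient at every lag, max magnitude."""
    def pearson(x, y):
        x = x - x.mean(); y = y - y.mean()
        return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    best = pearson(a, b)
    for lag in range(1, max_lag + 1):
        for r in (pearson(a[lag:], b[:len(b) - lag]),
                  pearson(a[:len(a) - lag], b[lag:])):
            if abs(r) > abs(best):
                best = r
    return best


class TestCrossCorrelation:
    def test_identical_series(self, rng):
        x = rng.standard_normal(100)
        assert cross_correlation(x, x) == pytest.approx(1.0)

    def test_negated_series(self, rng):
        x = rng.standard_normal(100)
        assert cross_correlation(x, -x) == pytest.approx(-1.0)

    def test_max_lag_matches_brute_force(self, rng):
        a = rng.standard_normal(200)
        b = np.roll(a, 3) + 0.5 * rng.standard_normal(200)
        got = cross_correlation(a, b, max_lag=5)
        assert got == pytest.approx(brute_force_max_lag(a, b, 5))
        assert abs(got) >= abs(cross_correlation(a, b, max_lag=0))

    def test_symmetry_and_affine_invariance_at_zero_lag(self, rng):
        a = rng.standard_normal(150)
        b = rng.standard_normal(150)
        r = cross_correlation(a, b)
        assert cross_correlation(b, a) == pytest.approx(r)
        assert cross_correlation(3.0 * a + 7.0, b) == pytest.approx(r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            cross_correlation(np.ones(10), np.arange(10.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation(np.arange(5.0), np.arange(6.0))


class TestCorrelationMatrix:
    def _recording(self, rng, n=512):
        data = rng.standard_normal((14, n))
        return Recording("S01", "KATA", 128.0, data, CHANNELS,
                         TaskScript("KATA", (("all", n / 128.0),)))

    def test_matches_pairwise_calls(self, rng):
        rec = self._recording(rng)
        mat = correlation_matrix(rec, channels=("AF3", "F7", "P8"))
        for a, b in itertools.combinations(("AF3", "F7", "P8"), 2):
            assert mat.pair(a, b) == pytest.approx(
                cross_correlation(rec.channel(a), rec.channel(b)), abs=1e-10)

    def test_duplicated_channel_gives_unit_offdiagonal(self, rng):
        rec = self._recording(rng)
        rec.data[IDX["F7"]] = rec.data[IDX["AF3"]]
        mat = correlation_matrix(rec, channels=("AF3", "F7"))
        assert mat.pair("AF3", "F7") == pytest.approx(1.0)

    def test_unknown_channel_rejected_by_name(self, rng):
        with pytest.raises(KeyError, match="Cz"):
            correlation_matrix(self._recording(rng), channels=("AF3", "Cz"))

    def test_symmetric_unit_diagonal(self, rng):
        mat = correlation_matrix(self._recording(rng))
        assert np.allclose(mat.values, mat.values.T, atol=1e-12)
        assert np.allclose(np.diag(mat.values), 1.0)

    def test_frontal_block_exceeds_bound_on_synthetic_regime(self, regime_windows):
        _, window = regime_windows["CPDnA"]
        mat = correlation_matrix(window, channels=FRONTAL)
        off = mat.values[~np.eye(6, dtype=bool)]
        assert off.min() >= 0.45


class TestHypotheses:
    def test_default_structure(self):
        specs = {s.id: s for s in default_hypotheses()}
        assert len(specs["H1"].pair_sets) == 15          # C(6,2)
        assert len(specs["H2"].pair_sets) == 2
        assert specs["H3"].pair_sets == specs["H4"].pair_sets
        assert specs["H3"].comparator == "all_le" and specs["H3"].tasks == ("KATA",)
        assert specs["H4"].comparator == "all_ge" and specs["H4"].tasks == ("CPDnA",)
        assert specs["H1"].threshold == 0.45 and specs["H2"].threshold == 0.85
        assert specs["H3"].threshold == 0.34 and specs["H4"].threshold == 0.68

    def _matrix(self, fill=0.9, pairs=None):
        values = np.full((14, 14), fill)
        np.fill_diagonal(values, 1.0)
        for (a, b), v in (pairs or {}).items():
            values[IDX[a], IDX[b]] = values[IDX[b], IDX[a]] = v
        return CorrelationMatrix(CHANNELS, values)

    def _weak_parietal(self, fill=0.9):
        pf = {(a, b): 0.25 for a, b in
              (("P7", "F7"), ("P7", "F3"), ("P8", "F4"), ("P8", "F8"))}
        return self._matrix(fill, pf)

    def test_all_supported_on_conforming_matrices(self):
        kata = self._weak_parietal()
        cpdna = self._matrix(0.9)  # parietal pairs at 0.9 >= 0.68
        verdicts = {r.spec.id: r.verdict
                    for r in evaluate_hypotheses(kata, cpdna)}
        assert verdicts == {h: "supported" for h in ("H1", "H2", "H3", "H4")}

    def test_synthetic_regime_presets_support_all_hypotheses(self, regime_windows):
        kata = correlation_matrix(regime_windows["KATA"][1])
        cpdna = correlation_matrix(regime_windows["CPDnA"][1])
        reports = evaluate_hypotheses(kata, cpdna)
        assert all(r.verdict == "supported" for r in reports)

    def test_control_matrix_fails_h4(self):
        pf = {(a, b): 0.0 for a, b in
              (("P7", "F7"), ("P7", "F3"), ("P8", "F4"), ("P8", "F8"))}
        cpdna = self._matrix(0.9, pf)
        reports = {r.spec.id: r for r in
                   evaluate_hypotheses(self._weak_parietal(), cpdna)}
        assert reports["H4"].verdict == "not_supported"
        assert reports["H3"].verdict == "supported"

    def test_threshold_minus_epsilon_not_supported(self):
        kata = self._weak_parietal()
        kata.values[IDX["AF3"], IDX["F7"]] = kata.values[IDX["F7"], IDX["AF3"]] = \
            0.45 - 1e-9
        reports = {r.spec.id: r for r in
                   evaluate_hypotheses(kata, self._matrix(0.9))}
        assert reports["H1"].verdict == "not_supported"

    def test_boundary_equality_counts_as_pass(self):
        kata = self._weak_parietal()
        kata.values[IDX["AF3"], IDX["F7"]] = kata.values[IDX["F7"], IDX["AF3"]] = 0.45
        reports = {r.spec.id: r for r in
                   evaluate_hypotheses(kata, self._matrix(0.9))}
        assert reports["H1"].verdict == "supported"

    def test_threshold_monotonicity(self):
        """Raising an all_ge threshold can only flip supported -> not."""
        kata = self._weak_parietal()
        cpdna = self._matrix(0.9)
        base = default_hypotheses()
        for bump in (0.0, 0.2, 0.4):
            specs = [s for s in default_hypotheses()]
            raised = []
            for s in specs:
                thr = min(1.0, s.threshold + bump) if s.comparator == "all_ge" \
                    else s.threshold
                raised.append(type(s)(s.id, s.pair_sets, s.comparator, thr,
                                      s.tasks, s.region_annotation))
            low = {r.spec.id: r.verdict for r in evaluate_hypotheses(kata, cpdna, base)}
            high = {r.spec.id: r.verdict
                    for r in evaluate_hypotheses(kata, cpdna, raised)}
            for h in low:
                if low[h] == "not_supported":
                    assert high[h] == "not_supported"

    def test_missing_channel_rejected(self):
        small = CorrelationMatrix(("AF3", "F7"), np.eye(2))
        with pytest.raises(KeyError):
            evaluate_hypotheses(small, self._matrix(0.9))
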