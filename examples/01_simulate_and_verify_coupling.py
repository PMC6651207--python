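"""Simulate one subject per behavioral regime and verify the coupling.

Builds the KATA and (CPD)nA coupling models, simulates a 300-s session
for each, and compares the correlation measured on the 250-s analysis
window (after preprocessing) with the closed-form value implied by the
mixing weights. The two regimes share a strong frontal block and differ
only in temporoparietal-frontal coupling.
"""

from leansense import (
    analytic_channel_correlation,
    correlation_matrix,
    make_regime_config,
    simulate_recording,
)
from leansense.montage import CHANNELS
from leansense.preprocess import preprocess
from leansense.task import script_for

for regime, window_label in (("KATA", "KATA-III"), ("CPDnA", "Plan")):
    model = make_regime_config(regime, seed=1)
    rec = simulate_recording(model, script_for(regime), fs=128, seed=1)
    window = preprocess(rec).subtask_window(window_label)
    measured = correlation_matrix(window)
    analytic = analytic_channel_correlation(model)

    print(f"\n{regime} ({window_label}, {window.duration:.0f} s)")
    for a, b in (("F7", "F3"), ("F4", "F8"), ("P8", "F4"), ("P8", "F8")):
        i, j = CHANNELS.index(a), CHANNELS.index(b)
        print(f"  corr({a},{b}): measured {measured.pair(a, b):+.3f}  "
              f"analytic {analytic[i, j]:+.3f}")

print("""
The F7-F3 / F4-F8 pairs (ventromedial-dorsolateral PFC) are ~0.88 in both
regimes; the P8-F4 / P8-F8 pairs (TPJ-PFC) are ~0.27 under KATA but ~0.71
under (CPD)nA -- the coupling difference the soft sensor must detect.
Measured values track the closed form within ~0.02.""")
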