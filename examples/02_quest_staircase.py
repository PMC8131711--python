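"""Calibrate per-image contrast thresholds with interleaved QUEST processes.

Twenty simulated Weibull observers (one per image) are staircased with one
40-trial QUEST process each, interleaved into an 800-trial session targeting
55% recognition; a Day-2 style 80-trial validation block then checks that
the thresholds still produce a rate in the (30%, 80%] acceptance band.
"""

import numpy as np

from liminal import staircase

rng = np.random.default_rng(1)

true_thresholds = np.geomspace(0.03, 0.3, 20)
observers = {
    f"img{i:02d}": staircase.PsychometricObserver(t, target_p=0.55)
    for i, t in enumerate(true_thresholds)
}

cfg = staircase.StaircaseConfig()  # 20 processes x 40 trials, target 55%
session = staircase.run_interleaved_session(cfg, observers, rng)
rel_err = np.array(
    [abs(session.thresholds[k] - o.threshold) / o.threshold for k, o in observers.items()]
)
print(f"session: {len(session.trial_log)} trials")
print(f"median relative threshold error: {100 * np.median(rel_err):.1f}%")
for k in list(observers)[:5]:
    print(f"  {k}: true {observers[k].threshold:.4f}  recovered {session.thresholds[k]:.4f}")

validation = staircase.validate_and_adjust(session.thresholds, observers, rng)
print(
    f"\nDay-2 validation: {len(validation.validation_log)} trials, "
    f"recognition rate {100 * validation.recognition_rate:.1f}% -> "
    f"{'pass' if validation.passed else f'adjust (gain {validation.gain:.2f})'}"
)
# a rate near 55% passes the (30%, 80%] band: the calibrated contrasts put
# each image close to its individual recognition threshold.
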