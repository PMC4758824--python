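"""Condition a recording and cut labeled 1-second epochs.

Common-average reference, 60 Hz notch (with harmonics) and downsampling to
the 436 Hz working rate, then the window-labeling rules: onsets rounded to
the nearest second, durations floored, and windows shared by two stimuli
discarded.
"""
import numpy as np

import mklband as m

cfg = m.SynthConfig(n_channels=4, sfreq_hz=1000.0, n_events_per_class=25,
                    seed=7)
rec, truth = m.generate_recording(cfg)

rec = m.preprocess(rec, line_hz=60.0, n_harmonics=3, target_hz=436.0)
print(f"after conditioning: {rec.sfreq_hz:.0f} Hz, "
      f"channel-mean |residual| {np.abs(rec.data.mean(axis=1)).max():.2e} "
      f"(zero by construction of the common average reference)")

epochs = m.label_windows(truth.event_table, rec.duration_s)
n_math = np.sum(epochs.labels == "math")
print(f"{len(truth.event_table)} events -> {len(epochs)} labeled 1 s windows "
      f"({n_math} math, {len(epochs) - n_math} non-math)")

balanced = m.balance_classes(epochs, seed=1)
print(f"after balancing: {len(balanced)} windows, "
      f"{np.sum(balanced.labels == 'math')} per class")

tensor = m.extract_epochs(rec, balanced, window_ms=(-200, 1200))
print(f"epoch tensor: {tensor.shape} (epochs x channels x samples); "
      f"{tensor.shape[-1]} samples = round(1.4 s x 436 Hz)")
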