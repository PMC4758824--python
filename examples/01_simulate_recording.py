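"""Generate a synthetic self-paced experiment and inspect its ground truth.

Builds an 8-channel recording in which the high-gamma (70-110 Hz)
component of channel 3 doubles in amplitude whenever a "math" stimulus is
on screen, then prints what was injected.
"""
import numpy as np

import mklband as m

cfg = m.SynthConfig(n_channels=8, sfreq_hz=512.0, n_events_per_class=30,
                    informative_pairs=((3, "high_gamma"),), effect_gain=2.0,
                    seed=42)
rec, truth = m.generate_recording(cfg)

ev = truth.event_table
print(f"recording: {rec.n_channels} channels, {rec.duration_s:.0f} s "
      f"at {rec.sfreq_hz:.0f} Hz")
print(f"events: {len(ev)} total, {np.sum(ev.condition == 'math')} math, "
      f"mean reaction time {ev.rt_s[ev.condition != 'rest'].mean():.2f} s")
print(f"injected effect: gain {truth.effect_gain} on {truth.informative_pairs}")

# the effect is visible as raised high-gamma variance during math stimuli
math_mask = np.zeros(rec.n_samples, dtype=bool)
for _, row in ev.frame[ev.frame.condition == "math"].iterrows():
    i0 = int(row.onset_s * rec.sfreq_hz)
    math_mask[i0:i0 + int(row.rt_s * rec.sfreq_hz)] = True
v_math = rec.data[math_mask, 3].var()
v_rest = rec.data[~math_mask, 3].var()
print(f"channel-3 variance during math vs elsewhere: {v_math:.2f} vs "
      f"{v_rest:.2f} (ratio {v_math / v_rest:.2f})")
print("the ratio exceeds 1 because the informative band carries the gain; "
      "the other five bands dilute it below gain^2.")
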