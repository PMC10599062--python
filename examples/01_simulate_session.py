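"""Simulate a hypnosis-like EEG session and write it as EDF + labels.

Builds a 19-channel 10-20 session that moves from wakefulness through a
gradual deepening ramp into deep hypnosis, and saves the recording with
its ground-truth label sidecar. The printed band powers show the injected
deep-state signature: more delta/theta, less posterior alpha.
"""

import numpy as np

import hypnobci as hb

script = hb.SessionScript(
    segments=[
        hb.Segment(120, "WAKE"),
        hb.Segment(30, "MIX", (0.0, 1.0)),  # deepening ramp
        hb.Segment(120, "DEEP"),
    ],
    fs=250.0,
    seed=11,
)
wake_sig, deep_sig = hb.default_signatures(script.montage)
rec, labels = hb.generate_session(script, wake_sig, deep_sig)

hb.write_edf(rec, "session1.edf")
hb.write_labels(labels, "session1.tsv")
print(f"wrote session1.edf: {rec.duration:.0f} s, {rec.n_channels} channels "
      f"at {rec.fs:g} Hz; labels: {[(a, b, s.value) for a, b, s in labels.intervals]}")

table = hb.band_power_difference(rec, labels)
print("\nband power, DEEP minus WAKE (µV²), three illustrative channels:")
print(table.loc[["Fz", "Pz", "O2"]].round(1))
print("\npositive delta/theta and negative alpha rows reproduce the "
      "slow-wave increase and posterior alpha suppression of deepening.")
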