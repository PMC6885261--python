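"""Simulate a labelled three-class EMG dataset and inspect the class contrast.

Builds a small set of synthetic needle-EMG recordings (summed motor-unit
action-potential trains + noise, band-limited 5 Hz-10 kHz) and prints the
mean rectified amplitude per class: neuropathic recordings (few, large,
long MUAPs) should be loudest, myopathic ones (small, short MUAPs) quietest.
"""

import numpy as np

import emgkit as ek

recordings = ek.simulate_dataset(
    ek.default_profiles(), n_recordings_per_class=3,
    config=ek.SimulationConfig(duration_s=1.0, seed=42),
)
print(f"{len(recordings)} recordings of {recordings[0].duration_s:.0f} s "
      f"at {recordings[0].sampling_rate_hz:.0f} Hz")
for cls in ek.CLASSES:
    amps = [np.mean(np.abs(r.samples)) for r in recordings if r.label == cls]
    print(f"  {cls:>10s}: mean rectified amplitude {np.mean(amps):.4f} mV")
print("Expected ordering: Neuropathy > Normal > Myopathy "
      "(MUAP size drives the rectified amplitude).")
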