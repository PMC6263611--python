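"""Generate a synthetic recording and recover its heartbeats.

Builds one 60 s fear-condition recording at 200 Hz, removes baseline wander
with a 7-level db5 undecimated decomposition, and detects R waves via
modulus-maxima pairs at dyadic scale 8. The printed recall compares detected
peak times against the generator's ground truth at a 25 ms tolerance.
"""

import numpy as np

from emophys import synthgen, wavedet

FS = 200.0
regime = synthgen.DEFAULT_REGIMES["fear"]

ecg, r_truth = synthgen.generate_ecg(60, FS, regime, drift_amp=0.3,
                                     noise_sd=0.02, seed=3)
detrended = wavedet.remove_baseline(ecg, "db5", 7)
r_detected = wavedet.detect_modulus_maxima_peaks(detrended, fs=FS) / FS

hits = sum(np.any(np.abs(r_detected - t) <= 0.025) for t in r_truth)
print(f"ground-truth beats : {r_truth.size}")
print(f"detected beats     : {r_detected.size}")
print(f"recall within 25 ms: {100 * hits / r_truth.size:.1f}%")
print(f"mean heart rate    : {60 / np.mean(np.diff(r_detected)):.1f} bpm")
# Recall at 100% with matching beat counts means every heartbeat was located
# despite the 0.3-unit baseline wander; the bpm estimate reflects the fear
# regime's elevated heart rate (~95 bpm).
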