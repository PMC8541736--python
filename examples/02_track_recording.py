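"""Track per-fish EODf traces from a raw multichannel recording.

Synthesizes 30 s of 15-electrode voltage data for two fish 12 Hz apart,
then runs the full chain: spectrogram (n_fft = 2**15, 80% overlap),
harmonic-group detection on the channel-summed spectrum, and
frequency+power-profile tracking.
"""

import numpy as np

from risetrack.core import EodfTrace
from risetrack.synthetic import ElectrodeGrid, generate_raw_recording
from risetrack.tracking import track_recording

t = np.arange(0.0, 30.0, 0.1)
truth = {"fish A": 700.0, "fish B": 712.0}
traces = tuple(EodfTrace(k, t, np.full(t.size, v)) for k, v in truth.items())
rec = generate_raw_recording(traces, ElectrodeGrid.regular(), noise_sd=0.02, seed=1)
print(f"recording: {rec.data.shape[0] / rec.rate_hz:.0f} s x "
      f"{rec.data.shape[1]} channels at {rec.rate_hz:.0f} Hz")

result = track_recording(rec)
print(f"tracked {len(result.traces)} traces over {result.n_windows} windows; "
      f"unresolvable={result.unresolvable}")
for tr in result.traces:
    med = np.nanmedian(tr.freq)
    target = min(truth.values(), key=lambda v: abs(v - med))
    rms = np.sqrt(np.nanmean((tr.freq - target) ** 2))
    print(f"  {tr.fish_id}: median {med:.2f} Hz "
          f"(truth {target:.0f} Hz, RMS error {rms:.3f} Hz)")
# RMS well below one spectrogram bin (0.61 Hz): parabolic peak
# interpolation plus the harmonic ladder refine the fundamental.
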