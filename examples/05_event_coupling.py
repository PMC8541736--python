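"""Event-triggered rise rates with permutation null and jackknife bands.

Aligns loser rises to agonistic-contact onsets, smooths the lag
histogram with a 1 s Gaussian kernel, and asks whether the observed
curve escapes the 1st/99th percentile band of 1000 interval-shuffled
surrogates.  With generator coupling at +0.7 s (rise precedes contact),
the excursion appears at negative lags.
"""

import numpy as np

from risetrack import coupling
from risetrack.synthetic import TrialConfig, generate_trial

trial = generate_trial(TrialConfig(seed=4, trigger_prob=0.3))
rise_times = trial.true_rises.query("fish_id == 'loser'")["onset_s"].to_numpy()
contacts = coupling.contact_onsets_from_events(trial.events)
print(f"{rise_times.size} loser rises, {contacts.size} contacts")

curve = coupling.rate_curve_with_bands(
    rise_times, contacts, n_perm=1000, n_resample=1000, seed=0
)
above = curve.rate > curve.null_hi
sig_lags = curve.lags[above]
print(f"{above.sum()} of {curve.lags.size} lags above the 99th percentile "
      f"null band; significant lags: {sig_lags}")
i_peak = int(np.argmax(curve.rate))
print(f"curve peaks at lag {curve.lags[i_peak]:+.1f} s "
      f"with {curve.rate[i_peak]:.3f} rises/s per event "
      f"(null mean {curve.null_mean[i_peak]:.3f})")

rf, tf = coupling.window_fractions(rise_times, contacts)
print(f"rises in 5 s pre-contact windows: {100 * rf:.1f}% "
      f"(expected from time alone: {100 * tf:.1f}%)")
# The planted 0.7 s rise->contact lag shows up as an excursion just
# below lag zero, and the pre-window rise fraction exceeds chance.
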