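"""Generate a synthetic lateralized-EEG cohort and inspect its ground truth.

Builds the default 6-subject cohort (10 Hz rhythm on left temporal channels
for class 0, right for class 1, over 1/f noise with blinks and line noise),
then verifies the planted band-power contrast directly from the data.
"""

import numpy as np
from scipy.signal import periodogram

import eegconcepts as ec

cfg = ec.lateralized_cohort_config(seed=0, n_subjects=3, n_epochs_per_class=8)
cohort = ec.generate_cohort(cfg)
truth = ec.ground_truth(cfg)

print(f"cohort: {cohort.n_epochs} epochs x {cohort.n_channels} channels x "
      f"{cohort.n_times} samples at {cohort.sfreq:g} Hz")
print("planted sources:", [s.name for s in truth.sources])

# alpha-band power contrast between the planted left and right channels
freqs, psd = periodogram(cohort.data, fs=cohort.sfreq, axis=-1)
alpha = psd[..., (freqs >= 8) & (freqs < 12)].sum(axis=-1)
chs = list(cohort.channels)
left = [chs.index(c) for c in ("FC5", "C5", "CP5", "T7")]
right = [chs.index(c) for c in ("FC6", "C6", "CP6", "T8")]
contrast = alpha[:, left].mean(axis=1) - alpha[:, right].mean(axis=1)
for cls in (0, 1):
    m = contrast[cohort.labels == cls].mean()
    print(f"class {cls}: mean left-minus-right alpha power = {m:8.2f} µV²"
          f"  ({'left' if m > 0 else 'right'}-dominant, as planted)")

# the generator is a linear source model: sources + noise reproduce the data
err = np.abs(truth.reconstruct() - cohort.data).max()
print(f"ground-truth reconstruction error: {err:.2e} µV (exact by design)")
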