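"""Frequency-domain attribution through the virtual inspection layer.

Trains one leave-one-out fold of the lateralized study cohort (about a
minute and a half on one CPU core), then reads the explanation out in the
frequency domain: relevance should concentrate in the alpha band that
carries the planted class difference.
"""

import numpy as np

import eegconcepts as ec

cfg = ec.lateralized_cohort_config(seed=0)
cohort = ec.generate_cohort(cfg)
pre = ec.preprocess_epochs(cohort)

held_out = 0
train = pre.select(pre.subjects != held_out)
test = pre.select(pre.subjects == held_out)
model = ec.build_eegnet(pre.n_channels, pre.n_times, seed=0)
ec.train_model(model, train.data, train.labels, epochs=200,
               rng=np.random.default_rng(0))
print("held-out accuracy:", ec.evaluate(model, test.data, test.labels))

vm = ec.attach_vil(ec.canonicalize(model))
xs = test.data[test.labels == 0]
fr = ec.relevance_in_frequency(vm, xs, pre.sfreq, class_y=0)
pos = np.maximum(fr.values.mean(axis=0), 0.0)
band, rest = ec.band_aggregate(ec.FreqRelevance(pos, fr.freqs))
shares = band.sum(axis=0) / pos.sum()
for name, share in zip(ec.BandScheme().names, shares):
    print(f"  {name:>5}: {100 * share:5.1f} % of positive relevance")
print("the alpha band spans 6 % of the spectrum's bins; its share above "
      "marks the planted 10 Hz rhythm as the model's main evidence")
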