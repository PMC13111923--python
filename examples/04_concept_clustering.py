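"""Concept clustering across constructed filter concepts.

Skips training: builds two families of concept activation maps directly
(an early-burst and a late-burst temporal profile, as two filter strategies
would produce) at the reference scale of 16 models x 16 filters, embeds
them with cosine UMAP, clusters with DBSCAN and tabulates which 'models'
contribute to which cluster.
"""

import numpy as np

import eegconcepts as ec
from eegconcepts.relmax import Concept

rng = np.random.default_rng(0)
t = np.linspace(0, 1, 96)
profiles = {
    "early": np.exp(-0.5 * ((t - 0.25) / 0.12) ** 2),
    "late": np.exp(-0.5 * ((t - 0.75) / 0.12) ** 2),
}

concepts = []
for model_id in range(16):
    for fid in range(16):
        kind = "early" if fid % 2 == 0 else "late"
        vec = profiles[kind] * rng.uniform(0.8, 1.25) \
            + 0.02 * rng.standard_normal(96)
        concepts.append(Concept(
            model_id=f"model{model_id}", layer_id="pointwise_conv",
            filter_id=fid, class_y=0, sample_ids=np.array([0]),
            sample_relevance=np.array([1.0]), mean_activation_map=vec))

ct = ec.cluster_concepts(concepts, class_y=0, seed=0)
print(ct.composition)
print("\nmodel coverage per cluster:")
print(ct.coverage)
print("\nTwo clusters, each drawing filters from (nearly) every model: "
      "both filter strategies generalize across models.")
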