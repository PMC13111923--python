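"""eegconcepts: concept-relevance propagation for compact EEG CNNs.

The package trains EEGNet-style models subject-independently, propagates
class evidence backwards with layer-wise / concept relevance propagation
(ε-α2-β1 composite), reads explanations out in the frequency domain through
a DFT virtual inspection layer, selects concept-representative samples by
relevance maximization, clusters filter concepts across models (cosine
UMAP + DBSCAN), and validates concepts against neuroscientific views:
band topographies, functional grouping, and ICA relevance projection.
"""

from .synthetic import (CohortConfig, EpochSet, SignalSpec, ArtifactSpec,
                        generate_cohort, ground_truth,
                        lateralized_cohort_config, two_concept_cohort_config,
                        DEFAULT_MONTAGE)
from .preprocessing import (PreprocConfig, filter_and_resample, make_windows,
                            common_average_reference, batch_standardize,
                            preprocess_epochs)
from .nn import (LayerGraph, build_eegnet, forward_activations,
                 LAST_CONV_LAYER, TrainRun, train_loo, train_model, evaluate)
from .crp import (Condition, RelevanceTensor, Composite, canonicalize,
                  propagate_layer, lrp, crp)
from .vil import (FreqRelevance, BandScheme, VILModel, attach_vil,
                  relevance_in_frequency, project_time_relevance,
                  band_aggregate)
from .relmax import (Concept, score_samples, select_top_k, build_concept,
                     concepts_for_model)
from .clustering import (ClusterTable, embed_concepts, cluster_embedding,
                         effective_min_samples, cluster_composition,
                         cluster_concepts)
from .views import (RegionMap, BandTopoData, DEFAULT_REGIONS,
                    channel_positions, psd_relevance_curves, band_topo,
                    functional_grouping)
from .ica import (ICADecomposition, fit_ica, project_relevance,
                  label_components, GroundTruthLabeler, ICLabelAdapter)
from .consistency import (ConsistencyReport, match_filters, pair_correlation,
                          mean_pairwise_correlation, consistency_report)
from .pipeline import (PipelineConfig, Pipeline, PipelineStageError,
                       run_pipeline, export_report)

__version__ = "0.1.0"
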