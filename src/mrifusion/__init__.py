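"""Multi-parametric MRI multi-sequence feature-fusion classification.

A reusable pipeline for subtype classification of ovarian-cancer MRI:
NIfTI I/O and cohort manifests, rigid template registration (intra-
modal correlation, cross-modal mutual information), gated 2D
augmentation, per-sequence MBConv feature extraction with late fusion
and per-branch auxiliary losses, weighted-sampling training with a
warm-up/cosine schedule, and threshold/ranking metrics with fold
aggregation.  A phantom generator provides synthetic cohorts with
class signal split complementarily across the two sequences.
"""

from .imaging_io import (VolumeImage, PatientRecord, CohortManifest,
                         read_volume, write_volume, load_manifest,
                         save_manifest, slice_select)
from .registration import (RigidTransform, RegistrationResult,
                           RegistrationSettings, select_template, ncc,
                           mutual_information, register, resample,
                           register_cohort)
from .augmentation import AugmentationConfig, apply_augment
from .fusion_net import (StageSpec, ExtractorConfig, FeatureVector,
                         BranchPredictions, ModelConfig, efficientnet_stages,
                         b2_extractor_config, reduced_extractor_config,
                         build_extractor, extract_features, fuse, predict,
                         MultiSequenceModel, build_model, FUSED)
from .training import (SamplerWeights, LossBreakdown, ScheduleConfig,
                       TrainConfig, SplitPlan, class_weights, sample_indices,
                       branch_loss, total_loss, lr_multiplier, split_cohort,
                       SliceDataset, train, predict_cohort)
from .evaluation import (ScoredCohort, MetricsReport, AggregateReport,
                         roc_auc, average_precision, threshold_metrics,
                         aggregate, export_roc)
from .synthetic_data import (PhantomConfig, generate_patient, generate_cohort,
                             make_registration_case, default_remap)
from .experiment import SyntheticExperimentConfig, run_synthetic_experiment

__version__ = "0.1.0"
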