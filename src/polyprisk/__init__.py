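"""polyprisk: KDE-transformed biomarker models for colorectal polyp risk.

The pipeline: per-sex health-checkup cohorts are labelled at a polyp-size
threshold, each feature is mapped through a KDE fit on the polyp-positive
class (optionally clamped into a monotone "sigmoid-like" curve and raised to
an integer exponent), a zoo of classifiers is searched with backward feature
elimination, and every selection is driven by the Matthews correlation
coefficient. Shapley attributions explain the winning model per feature and
per patient.
"""

from .schema import FeatureSchema, FeatureSpec, default_schema
from .cohort import (
    CohortFlow,
    LabeledDataset,
    PatientRecord,
    apply_discard_limits,
    apply_eligibility,
    make_labels,
    read_cohort_csv,
    split_train_test,
    write_cohort_csv,
)
from .synthetic import (
    FeatureLaw,
    SyntheticSpec,
    default_feature_laws,
    generate_cohort,
    reference_cohort_roster,
)
from .kde import (
    DensityModel,
    KDETransformer,
    fit_density,
    fit_feature_model,
    normalize_and_power,
    sigmoidize,
    silverman_bandwidth,
    transform_value,
)
from .estimator import ZOO, PolypRiskClassifier, cv_mcc, make_classifier
from .selection import (
    CandidateModel,
    backward_eliminate,
    optimize_bandwidth,
    prepare_threshold_data,
    predict_polyp_score,
    run_grid,
    select_best,
)
from .metrics import (
    MetricsReport,
    fit_baseline_metrics,
    kruskal_wallis,
    kruskal_wallis_screen,
    mcc,
    predictions_from_scores,
    roc_auc,
    score_distribution_summary,
)
from .attribution import (
    AttributionReport,
    format_patient_report,
    patient_risk_report,
    shapley_importance,
)

__version__ = "0.1.0"

__all__ = [
    "FeatureSchema",
    "FeatureSpec",
    "default_schema",
    "CohortFlow",
    "LabeledDataset",
    "PatientRecord",
    "apply_discard_limits",
    "apply_eligibility",
    "make_labels",
    "read_cohort_csv",
    "split_train_test",
    "write_cohort_csv",
    "FeatureLaw",
    "SyntheticSpec",
    "default_feature_laws",
    "generate_cohort",
    "reference_cohort_roster",
    "DensityModel",
    "KDETransformer",
    "fit_density",
    "fit_feature_model",
    "normalize_and_power",
    "sigmoidize",
    "silverman_bandwidth",
    "transform_value",
    "ZOO",
    "PolypRiskClassifier",
    "cv_mcc",
    "make_classifier",
    "CandidateModel",
    "backward_eliminate",
    "optimize_bandwidth",
    "prepare_threshold_data",
    "predict_polyp_score",
    "run_grid",
    "select_best",
    "MetricsReport",
    "fit_baseline_metrics",
    "kruskal_wallis",
    "kruskal_wallis_screen",
    "mcc",
    "predictions_from_scores",
    "roc_auc",
    "score_distribution_summary",
    "AttributionReport",
    "format_patient_report",
    "patient_risk_report",
    "shapley_importance",
    "__version__",
]
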