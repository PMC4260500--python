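"""wmlbci: synthetic-EEG working-memory-load classification pipeline.

A passive-BCI analysis stack: paradigm schedulers for controlled
working-memory tasks and realistic learning materials, a forward model
generating oscillatory EEG under a latent workload signature (frontal
theta synchronization, parietal alpha desynchronization), %ERD/ERS
feature extraction via Burg autoregressive spectra, subjective-rating
class calibration, and SVM-RBF within-task and cross-task evaluation.
"""

from .calibration import (CalibrationStats, ClassLabeling, assign_classes,
                          personal_cutoff, select_difficulty_levels, zscore_apply,
                          zscore_fit)
from .classify import (ClassifierModel, EvaluationResult, TaskResult,
                       cross_task_evaluate, crossval_10fold, permutation_test,
                       report, report_text, train_svm_rbf)
from .events import SessionSchedule, TaskSpec, TrialEvent
from .features import FeatureMatrix, build_crosstask_features, build_study1_features, erd_ers
from .forward import ForwardModel, inject_artifacts, simulate_session
from .pipeline import (Study1Config, Study2Config, run_study1_cohort,
                       run_study1_subject, run_study2_cohort, run_study2_subject)
from .preprocess import (Epoch, Interval, IntervalPair, extract_interval_pairs,
                         regress_out_eog, segment_study_windows)
from .recording import EEGRecording
from .schedules import (build_nback_block, build_readingspan_block,
                        build_study1_schedule, build_study2_session,
                        build_wordproblem_block, iter_trials)
from .spectral import BANDS, PowerSpectrum, ar_psd, band_power, burg_fit, epoch_spectrum
from .workload import (RatingModel, RatingRecord, WorkloadProfile,
                       simulate_latent_workload)

__version__ = "0.1.0"
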