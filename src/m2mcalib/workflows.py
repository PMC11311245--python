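"""Experiment procedures: calibration workflows, baselines, aggregation.

Two calibration procedures move data across the machine-domain gap:

- *Train-time calibration*: the training set is filtered into the test
  domain with the forward transfer function; z-score statistics are
  computed **from the transformed training set** and used both to train
  and to normalize incoming test patches at evaluation.
- *Test-time calibration*: the model is trained once in the training
  domain with training-set statistics; at evaluation incoming test
  patches are filtered into the training domain with the backward
  transfer function and normalized with the training statistics.

Neither procedure reads statistics (or anything else) from the raw
test-domain classification data before final scoring.

Baselines: three no-calibration variants differing only in the z-score
statistics applied to raw test patches at evaluation (train statistics /
calibrated statistics from the transformed training set / true test
statistics), fine-tuning of trailing layers on adaptation frames,
score-threshold re-selection by AUC analysis, and BN freezing (which
requires test statistics at evaluation).

Every experiment is repeated with seeds ``seed_base + r`` (run-to-run
variance comes from network initialization and batching); accuracy and
AUC are aggregated as mean and population standard deviation.  Paired
method comparisons use the two-sided Wilcoxon signed-rank test (exact
null distribution for n <= 25, zero differences dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .classify import (
    ClassifierConfig,
    EvalResult,
    SmallCNNClassifier,
    auc_threshold,
    build_model,
    evaluate_model,
    fine_tune,
)
from .errors import DegenerateInputError
from .patching import NormalizationStats, apply_zscore, compute_zscore_stats
from .transfer import TransferFunction, apply_transfer

__all__ = [
    "ExperimentSpec",
    "ExperimentReport",
    "PatchSet",
    "run_train_time_calibration",
    "run_test_time_calibration",
    "run_no_calibration",
    "run_fine_tune",
    "run_auc_analysis",
    "run_bn_freeze",
    "run_method_comparison",
    "repeat_and_aggregate",
    "wilcoxon_compare",
    "METHODS",
]

METHODS = (
    "train_time_calib",
    "test_time_calib",
    "no_calib_train_stats",
    "no_calib_calibrated_stats",
    "no_calib_test_stats",
    "fine_tune",
    "auc_analysis",
    "bn_freeze",
)

#: Paper-scale learning protocol (kept discoverable; the desk preset in
#: ClassifierConfig is what tests exercise).
PAPER_PROTOCOL = {
    "calibration": {"learning_rate": 1e-5, "epochs": 50, "batch_size": 2048},
    "no_calibration": {"learning_rate": 5e-6, "epochs": 25, "batch_size": 2048},
    "n_repetitions": 10,
}


@dataclass
class PatchSet:
    """A patch stack with its zone and label vectors."""

    X: np.ndarray  # (N, H, W)
    zones: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if not (len(self.X) == len(self.zones) == len(self.labels)):
            raise ValueError("X, zones and labels must have equal length")


@dataclass
class ExperimentSpec:
    """What to run and how often."""

    method: str = "test_time_calib"
    config: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_repetitions: int = 10
    seed_base: int = 0
    calibration_source: str = ""

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class ExperimentReport:
    """Per-run results plus aggregate statistics (population convention)."""

    method: str
    runs: List[EvalResult]
    mean_accuracy: float
    std_accuracy: float
    mean_auc: float
    std_auc: float
    eval_stats_tag: str = ""
    models: list = field(default_factory=list, repr=False)
    eval_stats: Optional[NormalizationStats] = field(default=None, repr=False)

    def accuracies(self) -> np.ndarray:
        return np.array([r.accuracy for r in self.runs])

    def aucs(self) -> np.ndarray:
        return np.array([r.auc for r in self.runs])


def repeat_and_aggregate(method: str, runs: Sequence[EvalResult], **extra) -> ExperimentReport:
    """Aggregate per-run results into a report (population std)."""
    if len(runs) < 1:
        raise ValueError("need at least one run")
    acc = np.array([r.accuracy for r in runs], dtype=float)
    auc = np.array([r.auc for r in runs], dtype=float)
    return ExperimentReport(
        method=method,
        runs=list(runs),
        mean_accuracy=float(acc.mean()),
        std_accuracy=float(acc.std()),
        mean_auc=float(auc.mean()),
        std_auc=float(auc.std()),
        **extra,
    )


def _train_one(train: PatchSet, stats: NormalizationStats, config: ClassifierConfig,
               seed: int) -> SmallCNNClassifier:
    cfg = replace(config, seed=seed)
    model = build_model(cfg)
    Xn = apply_zscore(train.X, stats)
    model.fit(Xn, train.labels, zones=train.zones)
    return model


def run_train_time_calibration(
    train: PatchSet,
    test: PatchSet,
    tf_fwd: TransferFunction,
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 3,
    seed_base: int = 0,
) -> ExperimentReport:
    """Train-time calibration: filter the training set into the test
    domain, train there, and evaluate test patches normalized with the
    transformed-training-set statistics."""
    if tf_fwd.direction != "train_to_test":
        raise ValueError("train-time calibration needs a train_to_test transfer function")
    X_cal = apply_transfer(train.X, tf_fwd, zones=train.zones)
    stats = compute_zscore_stats(X_cal, source_tag="calibrated(train->test)")
    X_eval = apply_zscore(test.X, stats)
    runs, models = [], []
    for r in range(n_repetitions):
        cfg = replace(config, seed=seed_base + r)
        model = build_model(cfg)
        model.fit(apply_zscore(X_cal, stats), train.labels, zones=train.zones)
        runs.append(evaluate_model(model, X_eval, test.labels))
        models.append(model)
    return repeat_and_aggregate(
        "train_time_calib", runs, eval_stats_tag=stats.source_tag,
        models=models, eval_stats=stats,
    )


def run_test_time_calibration(
    train: PatchSet,
    test: PatchSet,
    tf_bwd: TransferFunction,
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 3,
    seed_base: int = 0,
    pretrained: Optional[Sequence[SmallCNNClassifier]] = None,
) -> ExperimentReport:
    """Test-time calibration: train in the training domain, filter test
    patches back into it at evaluation.  Pretrained per-repetition models
    (e.g. shared with a no-calibration run) are reused without retraining."""
    if tf_bwd.direction != "test_to_train":
        raise ValueError("test-time calibration needs a test_to_train transfer function")
    stats = compute_zscore_stats(train.X, source_tag="train")
    X_ttc = apply_transfer(test.X, tf_bwd, zones=test.zones)
    X_eval = apply_zscore(X_ttc, stats)
    runs, models = [], []
    for r in range(n_repetitions):
        if pretrained is not None:
            model = pretrained[r]
        else:
            model = _train_one(train, stats, config, seed_base + r)
        runs.append(evaluate_model(model, X_eval, test.labels))
        models.append(model)
    return repeat_and_aggregate(
        "test_time_calib", runs, eval_stats_tag=stats.source_tag,
        models=models, eval_stats=stats,
    )


def run_no_calibration(
    train: PatchSet,
    test: PatchSet,
    stats_source: str = "train",
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 3,
    seed_base: int = 0,
    tf_fwd: Optional[TransferFunction] = None,
    pretrained: Optional[Sequence[SmallCNNClassifier]] = None,
    base_bn_mode: str = "running_stats",
) -> ExperimentReport:
    """No-calibration variants: a conventionally normalized model
    (running-statistics BN; the batch-statistics modification belongs to
    the calibration algorithms) trains on raw training patches with
    training statistics; raw test patches are evaluated under the selected
    normalization statistics (train / calibrated / test)."""
    config = replace(config, bn_mode=base_bn_mode)
    train_stats = compute_zscore_stats(train.X, source_tag="train")
    if stats_source == "train":
        eval_stats = train_stats
    elif stats_source == "calibrated":
        if tf_fwd is None:
            raise ValueError("stats_source='calibrated' requires a train_to_test transfer function")
        X_cal = apply_transfer(train.X, tf_fwd, zones=train.zones)
        eval_stats = compute_zscore_stats(X_cal, source_tag="calibrated(train->test)")
    elif stats_source == "test":
        eval_stats = compute_zscore_stats(test.X, source_tag="test")
    else:
        raise ValueError(f"unknown stats_source {stats_source!r}")
    X_eval = apply_zscore(test.X, eval_stats)
    runs, models = [], []
    for r in range(n_repetitions):
        if pretrained is not None:
            model = pretrained[r]
        else:
            model = _train_one(train, train_stats, config, seed_base + r)
        runs.append(evaluate_model(model, X_eval, test.labels))
        models.append(model)
    return repeat_and_aggregate(
        f"no_calib_{stats_source}_stats", runs, eval_stats_tag=eval_stats.source_tag,
        models=models, eval_stats=eval_stats,
    )


def run_fine_tune(
    train: PatchSet,
    test: PatchSet,
    adapt: PatchSet,
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 3,
    seed_base: int = 0,
    pretrained: Optional[Sequence[SmallCNNClassifier]] = None,
    ft_epochs: int = 2,
    ft_learning_rate: Optional[float] = None,
    base_bn_mode: str = "running_stats",
) -> ExperimentReport:
    """Fine-tuning baseline: pretrain in the training domain (conventional
    running-statistics BN), then adapt the trailing layers on labelled
    test-machine adaptation frames.  Adaptation-set statistics are used
    for the adaptation and evaluation normalization (this baseline assumes
    access to test-domain frames)."""
    import copy

    config = replace(config, bn_mode=base_bn_mode)
    train_stats = compute_zscore_stats(train.X, source_tag="train")
    adapt_stats = compute_zscore_stats(adapt.X, source_tag="adapt")
    X_ad = apply_zscore(adapt.X, adapt_stats)
    X_eval = apply_zscore(test.X, adapt_stats)
    runs, models = [], []
    for r in range(n_repetitions):
        if pretrained is not None:
            model = copy.deepcopy(pretrained[r])
        else:
            model = _train_one(train, train_stats, config, seed_base + r)
        fine_tune(model, X_ad, adapt.labels, zones=adapt.zones,
                  epochs=ft_epochs, learning_rate=ft_learning_rate)
        runs.append(evaluate_model(model, X_eval, test.labels))
        models.append(model)
    return repeat_and_aggregate(
        "fine_tune", runs, eval_stats_tag=adapt_stats.source_tag,
        models=models, eval_stats=adapt_stats,
    )


def run_auc_analysis(
    train: PatchSet,
    test: PatchSet,
    adapt: PatchSet,
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 3,
    seed_base: int = 0,
    pretrained: Optional[Sequence[SmallCNNClassifier]] = None,
    base_bn_mode: str = "running_stats",
) -> ExperimentReport:
    """AUC-analysis baseline: keep the pretrained (conventionally
    normalized) model, re-select the score threshold (Youden's J) on
    adaptation frames normalized with the training statistics."""
    config = replace(config, bn_mode=base_bn_mode)
    train_stats = compute_zscore_stats(train.X, source_tag="train")
    X_ad = apply_zscore(adapt.X, train_stats)
    X_eval = apply_zscore(test.X, train_stats)
    runs, models = [], []
    for r in range(n_repetitions):
        if pretrained is not None:
            model = pretrained[r]
        else:
            model = _train_one(train, train_stats, config, seed_base + r)
        thr = auc_threshold(model, X_ad, adapt.labels)
        runs.append(evaluate_model(model, X_eval, test.labels, threshold=thr))
        models.append(model)
    return repeat_and_aggregate(
        "auc_analysis", runs, eval_stats_tag=train_stats.source_tag,
        models=models, eval_stats=train_stats,
    )


def run_bn_freeze(
    train: PatchSet,
    test: PatchSet,
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 3,
    seed_base: int = 0,
) -> ExperimentReport:
    """BN-freezing baseline: train with frozen normalization statistics;
    evaluation uses true test statistics (this baseline's stated
    requirement)."""
    cfg = replace(config, bn_mode="frozen")
    train_stats = compute_zscore_stats(train.X, source_tag="train")
    test_stats = compute_zscore_stats(test.X, source_tag="test")
    X_eval = apply_zscore(test.X, test_stats)
    runs, models = [], []
    for r in range(n_repetitions):
        model = _train_one(train, train_stats, cfg, seed_base + r)
        runs.append(evaluate_model(model, X_eval, test.labels))
        models.append(model)
    return repeat_and_aggregate(
        "bn_freeze", runs, eval_stats_tag=test_stats.source_tag,
        models=models, eval_stats=test_stats,
    )


def run_method_comparison(
    train: PatchSet,
    test: PatchSet,
    adapt: PatchSet,
    tf_fwd: TransferFunction,
    tf_bwd: TransferFunction,
    config: ClassifierConfig = ClassifierConfig(),
    n_repetitions: int = 3,
    seed_base: int = 0,
    methods: Sequence[str] = METHODS,
    no_calib_config: Optional[ClassifierConfig] = None,
) -> Dict[str, ExperimentReport]:
    """Run the full method grid on one study.

    Two base-model pools are shared per repetition: batch-statistics-BN
    models (the calibration algorithms' BN mode) reused by test-time
    calibration, and conventional running-statistics-BN models reused by
    the no-calibration variants, AUC analysis, and as the fine-tuning
    pretraining stage.  The conventional pool trains on a shorter schedule
    (default: 4/5 of the calibration epochs), the desk-scale analogue of
    the original protocol's early-stopped no-calibration training.
    """
    reports: Dict[str, ExperimentReport] = {}
    train_stats = compute_zscore_stats(train.X, source_tag="train")
    if no_calib_config is None:
        no_calib_config = replace(
            config, bn_mode="running_stats",
            epochs=max(1, (config.epochs * 4) // 5),
        )
    batch_models = None
    if "test_time_calib" in methods:
        batch_models = [
            _train_one(train, train_stats, config, seed_base + r)
            for r in range(n_repetitions)
        ]
    conv_models = None
    needs_conv = {
        "no_calib_train_stats", "no_calib_calibrated_stats",
        "no_calib_test_stats", "fine_tune", "auc_analysis",
    }
    if needs_conv & set(methods):
        conv_models = [
            _train_one(train, train_stats, no_calib_config, seed_base + r)
            for r in range(n_repetitions)
        ]
    common = dict(config=config, n_repetitions=n_repetitions, seed_base=seed_base)
    for method in methods:
        if method == "train_time_calib":
            reports[method] = run_train_time_calibration(train, test, tf_fwd, **common)
        elif method == "test_time_calib":
            reports[method] = run_test_time_calibration(
                train, test, tf_bwd, pretrained=batch_models, **common)
        elif method.startswith("no_calib_"):
            source = method[len("no_calib_"):-len("_stats")]
            reports[method] = run_no_calibration(
                train, test, stats_source=source, tf_fwd=tf_fwd,
                pretrained=conv_models, **common)
        elif method == "fine_tune":
            reports[method] = run_fine_tune(
                train, test, adapt, pretrained=conv_models, **common)
        elif method == "auc_analysis":
            reports[method] = run_auc_analysis(
                train, test, adapt, pretrained=conv_models, **common)
        elif method == "bn_freeze":
            reports[method] = run_bn_freeze(train, test, **common)
        else:
            raise ValueError(f"unknown method {method!r}")
    return reports


def wilcoxon_compare(runs_a: Sequence[float], runs_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired repetitions.

    Exact null distribution for n <= 25; zero differences are dropped
    (classic convention).  All-tied inputs are degenerate.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("runs_a and runs_b must be 1-D with equal length")
    if a.size < 5:
        raise ValueError("need at least 5 paired repetitions")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        raise DegenerateInputError("all paired differences are zero")
    method = "exact" if nz.size <= 25 else "auto"
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)
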