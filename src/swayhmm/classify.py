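"""Two-model maximum-likelihood classification of balance recordings.

One Gaussian HMM is trained per class — H-HMM on healthy subjects, PD-HMM on
Parkinson's disease subjects — and a test recording is assigned to the class
whose model gives the higher total log-likelihood.  An exact tie goes to PD
(the clinically conservative call).  Both log-likelihoods are returned so a
decision can always be audited.

Channel handling: recordings carry medial-lateral (ML) and anterior-posterior
(AP) displacement channels; the classifier runs on ML alone, AP alone, or
both.  In the combined "MLAP" mode the default is a bivariate emission model
(d = 2, full covariances, so ML/AP correlation is modeled); an alternative
late-fusion mode trains one univariate HMM pair per channel and sums their
log-likelihoods.

Metric conventions (note the reversal of common clinical usage): sensitivity
is the percentage of healthy subjects classified healthy, specificity the
percentage of PD subjects classified PD, accuracy the overall percentage
correct.  Evaluation is stratified k-fold cross-validation (default k = 10)
with pooled confusion counts and the across-fold accuracy standard deviation
reported as a spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DimensionMismatchError, SequenceError
from .hmm import GaussianHMM, ObservationSequence, forward_log_likelihood
from .io import preprocess
from .learn import FitConfig, FitReport, baum_welch_fit, kmeans_init

CHANNEL_MODES = ("ML", "AP", "MLAP")


def select_channels(seq: ObservationSequence, mode: str) -> ObservationSequence:
    """Project a recording onto the requested channel set.

    ``ML``/``AP`` keep the single named column; ``MLAP`` keeps both in fixed
    (ML, AP) order regardless of the input column order.
    """
    if mode not in CHANNEL_MODES:
        raise ValueError(f"mode must be one of {CHANNEL_MODES}, got {mode!r}")
    wanted = ("ML", "AP") if mode == "MLAP" else (mode,)
    missing = [c for c in wanted if c not in seq.channels]
    if missing:
        raise SequenceError(
            f"subject {seq.subject_id!r}: channel(s) {missing} not present "
            f"(available: {list(seq.channels)})"
        )
    if seq.channels == wanted:
        return seq
    idx = [seq.channels.index(c) for c in wanted]
    return ObservationSequence(
        values=seq.values[:, idx],
        sampling_rate_hz=seq.sampling_rate_hz,
        channels=wanted,
        subject_id=seq.subject_id,
        label=seq.label,
    )


@dataclass
class ClassifierConfig:
    """Channel selection, preprocessing and training settings."""

    channel_mode: str = "MLAP"
    channel_fusion: bool = False  # MLAP only: per-channel HMM pairs, summed loglik
    decimate_factor: int = 1
    center: bool = False
    fit_config: FitConfig = field(default_factory=FitConfig)

    def __post_init__(self) -> None:
        if self.channel_mode not in CHANNEL_MODES:
            raise ValueError(
                f"channel_mode must be one of {CHANNEL_MODES}, got {self.channel_mode!r}"
            )
        if self.channel_fusion and self.channel_mode != "MLAP":
            raise ValueError("channel_fusion requires channel_mode='MLAP'")


@dataclass
class ClassifierModel:
    """A trained H-HMM / PD-HMM pair (one pair per channel in fusion mode)."""

    h_models: List[GaussianHMM]
    pd_models: List[GaussianHMM]
    config: ClassifierConfig
    h_report: Optional[FitReport] = None
    pd_report: Optional[FitReport] = None

    def __post_init__(self) -> None:
        if len(self.h_models) != len(self.pd_models):
            raise ValueError("h_models and pd_models must pair up")
        for h, p in zip(self.h_models, self.pd_models):
            if h.d != p.d:
                raise DimensionMismatchError(
                    f"H-HMM d={h.d} vs PD-HMM d={p.d}"
                )
        expect_d = 1 if (self.config.channel_mode != "MLAP" or self.config.channel_fusion) else 2
        for m in self.h_models + self.pd_models:
            if m.d != expect_d:
                raise DimensionMismatchError(
                    f"model d={m.d} inconsistent with channel_mode="
                    f"{self.config.channel_mode!r} (expected d={expect_d})"
                )

    @property
    def h_model(self) -> GaussianHMM:
        return self.h_models[0]

    @property
    def pd_model(self) -> GaussianHMM:
        return self.pd_models[0]


def _prepare(seq: ObservationSequence, config: ClassifierConfig) -> List[ObservationSequence]:
    """Channel-select and preprocess; returns one sequence per trained model."""
    sel = select_channels(seq, config.channel_mode)
    sel = preprocess(sel, config.decimate_factor, config.center)
    if config.channel_mode == "MLAP" and config.channel_fusion:
        return [select_channels(sel, ch) for ch in ("ML", "AP")]
    return [sel]


def train_classifier(
    healthy: Sequence[ObservationSequence],
    pd_subjects: Sequence[ObservationSequence],
    config: Optional[ClassifierConfig] = None,
) -> ClassifierModel:
    """Train the H-HMM and PD-HMM independently on the two class cohorts."""
    if config is None:
        config = ClassifierConfig()
    if not healthy or not pd_subjects:
        raise ValueError("both training cohorts must be nonempty")

    def fit_class(seqs, class_name):
        prepared = [_prepare(s, config) for s in seqs]
        models, reports = [], []
        for part in range(len(prepared[0])):
            train = [p[part] for p in prepared]
            try:
                init = kmeans_init(train, config.fit_config)
                model, report = baum_welch_fit(init, train, config.fit_config)
            except Exception as exc:
                raise type(exc)(f"[{class_name} model] {exc}") from exc
            models.append(model)
            reports.append(report)
        return models, reports

    h_models, h_reports = fit_class(healthy, "healthy")
    pd_models, pd_reports = fit_class(pd_subjects, "pd")
    return ClassifierModel(
        h_models=h_models,
        pd_models=pd_models,
        config=config,
        h_report=h_reports[0],
        pd_report=pd_reports[0],
    )


def classify_subject(
    model: ClassifierModel, seq: ObservationSequence
) -> Tuple[str, float, float]:
    """Label one recording: "healthy" iff the H-HMM log-likelihood is
    strictly greater, PD on ties.  Returns (label, loglik_H, loglik_PD)."""
    parts = _prepare(seq, model.config)
    ll_h = sum(forward_log_likelihood(m, p) for m, p in zip(model.h_models, parts))
    ll_pd = sum(forward_log_likelihood(m, p) for m, p in zip(model.pd_models, parts))
    label = "healthy" if ll_h > ll_pd else "pd"
    return label, float(ll_h), float(ll_pd)


@dataclass
class ConfusionCounts:
    """Two-class confusion table in the row layout
    (subjects / predicted H / predicted PD)."""

    n_healthy: int
    n_pd: int
    h_pred_h: int
    h_pred_pd: int
    pd_pred_h: int
    pd_pred_pd: int

    def __post_init__(self) -> None:
        if self.h_pred_h + self.h_pred_pd != self.n_healthy:
            raise ValueError("healthy row does not sum to n_healthy")
        if self.pd_pred_h + self.pd_pred_pd != self.n_pd:
            raise ValueError("PD row does not sum to n_pd")
        if min(self.h_pred_h, self.h_pred_pd, self.pd_pred_h, self.pd_pred_pd) < 0:
            raise ValueError("counts must be nonnegative")


def compute_metrics(c: ConfusionCounts) -> Tuple[float, float, float]:
    """(sensitivity %, specificity %, accuracy %).

    Healthy is treated as the positive class: sensitivity = healthy recall,
    specificity = PD recall.
    """
    if c.n_healthy == 0 or c.n_pd == 0:
        raise ValueError("both classes must be nonempty to compute metrics")
    sens = 100.0 * c.h_pred_h / c.n_healthy
    spec = 100.0 * c.pd_pred_pd / c.n_pd
    acc = 100.0 * (c.h_pred_h + c.pd_pred_pd) / (c.n_healthy + c.n_pd)
    return sens, spec, acc


@dataclass
class CVResult:
    k: int
    fold_assignments: Dict[str, int]
    pooled: ConfusionCounts
    sensitivity: float
    specificity: float
    accuracy: float
    accuracy_spread: float
    seed: int
    fold_accuracies: List[float] = field(default_factory=list)


def stratified_folds(
    cohort: Sequence[ObservationSequence], k: int, seed: int
) -> Dict[str, int]:
    """Seeded stratified fold assignment.

    Each class is shuffled independently; subjects are then dealt to folds in
    a single round-robin pass so class proportions are preserved as closely
    as integer counts allow, and k = n subjects degenerates to leave-one-out.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(cohort):
        raise ValueError(f"k={k} exceeds cohort size {len(cohort)}")
    rng = np.random.default_rng(seed)
    assignment: Dict[str, int] = {}
    cursor = 0
    for label in ("healthy", "pd"):
        ids = [s.subject_id for s in cohort if s.label == label]
        order = rng.permutation(len(ids))
        for j in order:
            assignment[ids[j]] = cursor % k
            cursor += 1
    return assignment


def kfold_cross_validate(
    cohort: Sequence[ObservationSequence],
    k: int = 10,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of the two-model classifier.

    Per fold: train H-HMM/PD-HMM on the other k-1 folds, classify the held
    out subjects; the confusion table is pooled over folds and the spread is
    the sample standard deviation of per-fold accuracies.
    """
    if config is None:
        config = ClassifierConfig()
    for s in cohort:
        if s.label not in ("healthy", "pd"):
            raise ValueError(f"subject {s.subject_id!r} has no class label")
    assignment = stratified_folds(cohort, k, seed)
    counts = {"hh": 0, "hp": 0, "ph": 0, "pp": 0}
    fold_accs: List[float] = []
    for fold in range(k):
        train_h = [s for s in cohort if assignment[s.subject_id] != fold and s.label == "healthy"]
        train_p = [s for s in cohort if assignment[s.subject_id] != fold and s.label == "pd"]
        test = [s for s in cohort if assignment[s.subject_id] == fold]
        if not test:
            continue
        if not train_h or not train_p:
            raise ValueError(
                f"fold {fold}: training split lost a class entirely; use a smaller k"
            )
        model = train_classifier(train_h, train_p, config)
        correct = 0
        for s in test:
            pred, _, _ = classify_subject(model, s)
            if s.label == "healthy":
                counts["hh" if pred == "healthy" else "hp"] += 1
            else:
                counts["ph" if pred == "healthy" else "pp"] += 1
            correct += pred == s.label
        fold_accs.append(100.0 * correct / len(test))
    pooled = ConfusionCounts(
        n_healthy=counts["hh"] + counts["hp"],
        n_pd=counts["ph"] + counts["pp"],
        h_pred_h=counts["hh"],
        h_pred_pd=counts["hp"],
        pd_pred_h=counts["ph"],
        pd_pred_pd=counts["pp"],
    )
    sens, spec, acc = compute_metrics(pooled)
    spread = float(np.std(fold_accs, ddof=1)) if len(fold_accs) > 1 else 0.0
    return CVResult(
        k=k,
        fold_assignments=assignment,
        pooled=pooled,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        accuracy_spread=spread,
        seed=seed,
        fold_accuracies=fold_accs,
    )


def hyperparameter_sweep(
    cohort: Sequence[ObservationSequence],
    states: Sequence[int],
    mixtures: Sequence[int],
    config: Optional[ClassifierConfig] = None,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """CV accuracy over a (n_states, n_components) grid with shared folds.

    Every grid point reuses the same seed, hence identical fold assignments,
    so rows are directly comparable.  A failing cell records NaN plus the
    error message and the sweep continues.
    """
    if not states or not mixtures:
        raise ValueError("state and mixture grids must be nonempty")
    if config is None:
        config = ClassifierConfig()
    rows = []
    for S in states:
        for C in mixtures:
            fc = FitConfig(**{**vars(config.fit_config), "n_states": S, "n_components": C})
            cell_cfg = ClassifierConfig(
                channel_mode=config.channel_mode,
                channel_fusion=config.channel_fusion,
                decimate_factor=config.decimate_factor,
                center=config.center,
                fit_config=fc,
            )
            try:
                res = kfold_cross_validate(cohort, k=k, config=cell_cfg, seed=seed)
                rows.append(
                    {
                        "n_states": S,
                        "n_components": C,
                        "accuracy": res.accuracy,
                        "sensitivity": res.sensitivity,
                        "specificity": res.specificity,
                        "accuracy_spread": res.accuracy_spread,
                        "error": "",
                    }
                )
            except Exception as exc:  # keep sweeping
                rows.append(
                    {
                        "n_states": S,
                        "n_components": C,
                        "accuracy": np.nan,
                        "sensitivity": np.nan,
                        "specificity": np.nan,
                        "accuracy_spread": np.nan,
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)


def render_confusion_table(result: CVResult) -> str:
    """Render pooled CV results in the standard two-row confusion layout."""
    c = result.pooled
    lines = [
        "\tSubjects\tPredicted H\tPredicted PD\tSensitivity/Specificity\tOverall Accuracy",
        f"Healthy\t{c.n_healthy}\t{c.h_pred_h}\t{c.h_pred_pd}\t{result.sensitivity:.1f}%\t"
        f"{result.accuracy:.1f}% ± {result.accuracy_spread:.1f}%",
        f"PD\t{c.n_pd}\t{c.pd_pred_h}\t{c.pd_pred_pd}\t{result.specificity:.1f}%\t",
    ]
    return "\n".join(lines)
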