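"""Leave-one-out cross-validation, confusion-matrix metrics, ROC/AUC, voting.

LOOCV holds each sample out of *both* training stages (encoder fitting and
fusion fitting) and of every training-dependent feature step: the prevalence
filter and the log transform are re-fit on the training fold and the held-out
sample is projected onto the fold's feature space.  Metrics follow the usual
confusion-matrix ratios; evaluation is repeated over several seeds and
averaged.  ROC thresholds are the midpoints between consecutive distinct
scores, and AUC is the trapezoid-rule area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .io_formats import FeatureMatrix
from .multimodal_model import (
    EncoderConfig,
    EncoderModel,
    MultimodalModel,
    predict,
    train_encoder,
    train_multimodal,
)
from .multimodal_model import DEFAULT_HIDDEN
from .taxonomic_features import filter_single_sample_taxa, log_transform

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def metrics(c: ConfusionCounts) -> tuple[float, float | None, float | None]:
    """(accuracy, precision, recall); None where the denominator is zero.

    accuracy = (TP+TN)/total, precision = TP/(TP+FP), recall = TP/(TP+FN).
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    accuracy = (c.TP + c.TN) / c.total
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) > 0 else None
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    return accuracy, precision, recall


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], positive_label: str
) -> ConfusionCounts:
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between truth and predictions")
    c = ConfusionCounts()
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            if p == positive_label:
                c.TP += 1
            else:
                c.FN += 1
        else:
            if p == positive_label:
                c.FP += 1
            else:
                c.TN += 1
    return c


@dataclass
class FoldResult:
    sample_id: str
    true_label: str
    predicted_label: str
    probabilities: dict[str, float]


@dataclass
class EvalResult:
    folds: list[FoldResult]
    confusion: ConfusionCounts | None
    accuracy: float
    precision: float | None
    recall: float | None
    roc_points: np.ndarray | None = None
    auc: float | None = None
    positive_label: str | None = None
    per_run: list["EvalResult"] | None = None
    models: list[object] | None = None


def _prepare_fold(
    m: FeatureMatrix,
    train_idx: list[int],
    test_idx: list[int],
    prevalence_filter: bool,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Fit training-dependent feature steps on the fold, project the test rows."""
    mtr = m.select_samples(train_idx)
    mte = m.select_samples(test_idx)
    if m.transform == "raw":
        if prevalence_filter and m.modality == "taxonomic":
            mtr = filter_single_sample_taxa(mtr)
        mte = mte.project(mtr.feature_ids)
        mtr = log_transform(mtr)
        mte = log_transform(mte)
    return mtr, mte


def loocv(
    matrices: Mapping[str, FeatureMatrix],
    labels: Sequence[str],
    seed: int = 0,
    positive_label: str | None = None,
    encoder_configs: Mapping[str, EncoderConfig] | None = None,
    fusion_config: EncoderConfig | None = None,
    prevalence_filter: bool = True,
    return_models: bool = False,
) -> EvalResult:
    """Leave-one-out evaluation of the (multi- or single-)modality classifier.

    Raw matrices are processed per fold (prevalence filter fitted on training
    samples only, then log transform); matrices passed in already
    log-transformed are used globally as-is.  With a single modality the
    encoder's own softmax output is the classifier; with several, the full
    two-stage model is trained per fold.  Per-fold seeds derive from ``seed``.
    """
    matrices = dict(matrices)
    if not matrices:
        raise ValueError("no modalities given")
    first = next(iter(matrices.values()))
    n = first.n_samples
    for name, m in matrices.items():
        if m.sample_ids != first.sample_ids:
            raise ValueError(f"sample ids of modality {name!r} disagree")
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for {n} samples")
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if positive_label is None:
        positive_label = classes[0]
    elif positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among classes {classes}")

    labels = list(labels)
    fold_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    folds: list[FoldResult] = []
    models: list[object] = []
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        y_train = [labels[j] for j in train_idx]
        if len(set(y_train)) < len(classes):
            warnings.warn(
                f"fold {i}: class absent from training fold; fold still run", stacklevel=2
            )
        prepared_tr: dict[str, FeatureMatrix] = {}
        prepared_te: dict[str, FeatureMatrix] = {}
        for name, m in matrices.items():
            prepared_tr[name], prepared_te[name] = _prepare_fold(
                m, train_idx, [i], prevalence_filter
            )
        fold_seed = int(fold_seeds[i])
        if len(matrices) == 1:
            name, mtr = next(iter(prepared_tr.items()))
            mte = prepared_te[name]
            if encoder_configs and name in encoder_configs:
                cfg = encoder_configs[name].with_seed(fold_seed)
            else:
                hidden = DEFAULT_HIDDEN.get(mtr.modality, (200, 100, 50))
                cfg = EncoderConfig(hidden_sizes=hidden, seed=fold_seed)
            model: object = train_encoder(mtr, y_train, cfg)
            proba = model.predict_proba(mte)
            model_classes = model.classes
        else:
            cfgs = (
                {
                    k: v.with_seed((fold_seed + j) % 2**31)
                    for j, (k, v) in enumerate(encoder_configs.items())
                }
                if encoder_configs
                else None
            )
            model = train_multimodal(
                prepared_tr, y_train, encoder_configs=cfgs,
                fusion_config=fusion_config.with_seed(fold_seed) if fusion_config else None,
                seed=fold_seed,
            )
            proba = predict(model, prepared_te)
            model_classes = model.classes
        pred = model_classes[int(np.argmax(proba[0]))]
        folds.append(
            FoldResult(
                sample_id=first.sample_ids[i],
                true_label=labels[i],
                predicted_label=pred,
                probabilities={c: float(p) for c, p in zip(model_classes, proba[0])},
            )
        )
        if return_models:
            models.append(model)

    confusion = confusion_from_predictions(
        [f.true_label for f in folds], [f.predicted_label for f in folds], positive_label
    )
    accuracy, precision, recall = metrics(confusion)
    roc_points, auc = None, None
    scores = [f.probabilities.get(positive_label, 0.0) for f in folds]
    truths = [f.true_label for f in folds]
    if len(set(truths)) >= 2:
        roc_points, auc = roc_auc(truths, scores, positive_label)
    return EvalResult(
        folds=folds,
        confusion=confusion,
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        roc_points=roc_points,
        auc=auc,
        positive_label=positive_label,
        models=models if return_models else None,
    )


MatrixFactory = Callable[[int], Mapping[str, FeatureMatrix]]


def repeat_eval(
    matrices: Mapping[str, FeatureMatrix] | MatrixFactory,
    labels: Sequence[str],
    runs: int = 5,
    base_seed: int = 0,
    **loocv_kwargs,
) -> EvalResult:
    """Average ``runs`` independent LOOCVs over derived seeds.

    ``matrices`` may be a callable seed -> matrices, letting each run rebuild
    feature matrices (e.g. redrawing the genomic reference samples).
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    run_seeds = np.random.SeedSequence(base_seed).generate_state(runs) % (2**31)
    results = []
    for r in range(runs):
        rs = int(run_seeds[r])
        mats = matrices(rs) if callable(matrices) else matrices
        results.append(loocv(mats, labels, seed=rs, **loocv_kwargs))
    if runs == 1:
        return results[0]

    def _mean(vals: list[float | None]) -> float | None:
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    total = ConfusionCounts(
        TP=sum(r.confusion.TP for r in results),
        FP=sum(r.confusion.FP for r in results),
        TN=sum(r.confusion.TN for r in results),
        FN=sum(r.confusion.FN for r in results),
    )
    return EvalResult(
        folds=[],
        confusion=total,
        accuracy=float(np.mean([r.accuracy for r in results])),
        precision=_mean([r.precision for r in results]),
        recall=_mean([r.recall for r in results]),
        auc=_mean([r.auc for r in results]),
        positive_label=results[0].positive_label,
        per_run=results,
    )


def roc_auc(
    y_true: Sequence[str], scores: Sequence[float], positive_label: str
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoid AUC with midpoint thresholds.

    Thresholds are the means between any two consecutive distinct observed
    scores, bracketed by sentinels below the minimum and above the maximum so
    the curve spans (0,0) to (1,1).  A sample is called positive when its
    score >= threshold.
    """
    y = np.asarray([t == positive_label for t in y_true], dtype=bool)
    s = np.asarray(scores, dtype=np.float64)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    distinct = np.unique(s)
    mids = (distinct[1:] + distinct[:-1]) / 2.0
    thresholds = np.concatenate([[distinct[0] - 1.0], mids, [distinct[-1] + 1.0]])
    points = []
    for thr in thresholds[::-1]:  # descending: (0,0) first
        called = s >= thr
        tpr = (called & y).sum() / n_pos
        fpr = (called & ~y).sum() / n_neg
        points.append((fpr, tpr))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def ensemble_vote(
    votes: Sequence[Sequence[str]],
    probabilities: Sequence[np.ndarray] | None = None,
    classes: Sequence[str] | None = None,
) -> list[str]:
    """Majority vote over classifiers per sample.

    ``votes``: one label sequence per classifier, aligned on samples.  Ties
    break to the tied label with the highest mean predicted probability (when
    ``probabilities`` per classifier over ``classes`` are given), then to the
    first label in sorted class order.
    """
    if len(votes) < 2:
        raise ValueError("ensemble needs at least 2 classifiers")
    n = len(votes[0])
    if any(len(v) != n for v in votes):
        raise ValueError("classifiers vote on different numbers of samples")
    if probabilities is not None:
        if classes is None:
            raise ValueError("classes order required with probabilities")
        probabilities = [np.asarray(p) for p in probabilities]
        for p in probabilities:
            if p.shape != (n, len(classes)):
                raise ValueError("probability array shape mismatch")
        mean_proba = np.mean(probabilities, axis=0)
        class_pos = {c: j for j, c in enumerate(classes)}
    out = []
    for i in range(n):
        counts: dict[str, int] = {}
        for v in votes:
            counts[v[i]] = counts.get(v[i], 0) + 1
        top = max(counts.values())
        tied = sorted(lab for lab, c in counts.items() if c == top)
        if len(tied) == 1:
            out.append(tied[0])
        elif probabilities is not None:
            # max returns the first of equally probable tied labels (sorted order)
            out.append(max(tied, key=lambda lab: mean_proba[i, class_pos[lab]]))
        else:
            out.append(tied[0])
    return out
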