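"""Case classification: features, LOOCV scoring, ROC and confusion metrics.

Profiles of window-maximum latencies are turned into fixed-length feature
vectors and classified MCI vs. NC with a small neural network, a Gaussian
discriminant or an RBF-kernel SVM under leave-one-out cross-validation;
a plain latency-threshold rule (median window-maximum <= 70 ms -> MCI) is
included as the non-learned baseline.  MCI is the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import ClassifierSpec
from .coupling import CaseLatencyProfile

MCI = "MCI"
NC = "NC"


@dataclass(frozen=True)
class FeatureVector:
    case_id: str
    values: np.ndarray
    low_coverage: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class CaseScore:
    case_id: str
    label: str
    score: float  # higher = more MCI-like
    fold: int


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def _ratio(self, num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    operating_threshold: float
    confusion: ConfusionMatrix
    degenerate: bool = False
    extras: Dict[str, float] = field(default_factory=dict)

    @property
    def sensitivity(self) -> Optional[float]:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> Optional[float]:
        return self.confusion.specificity

    @property
    def ppv(self) -> Optional[float]:
        return self.confusion.ppv

    @property
    def npv(self) -> Optional[float]:
        return self.confusion.npv


# ---------------------------------------------------------------------------
# features


def features_from_profile(profile: CaseLatencyProfile) -> FeatureVector:
    """Deterministic featurization: PDF bin densities plus summary stats."""
    if not profile.maxima_ms:
        raise ValueError(f"case {profile.case_id}: empty latency profile")
    m = np.asarray(profile.maxima_ms, dtype=float)
    summary = np.array(
        [
            float(np.median(m)),
            float(np.min(m)),
            float(np.max(m)),
            float(np.mean(m < 0.0)),
        ]
    )
    values = np.concatenate([profile.density, summary])
    return FeatureVector(
        case_id=profile.case_id, values=values, low_coverage=profile.low_coverage
    )


def latency_threshold_classify(
    profile: CaseLatencyProfile, threshold_ms: float = 70.0
) -> str:
    """Median window-maximum latency at or below the threshold -> MCI.

    Short/negative latencies are the MCI-like pattern, so the boundary value
    itself is assigned to MCI.
    """
    if not profile.maxima_ms:
        raise ValueError(f"case {profile.case_id}: empty latency profile")
    return MCI if float(np.median(profile.maxima_ms)) <= threshold_ms else NC


# ---------------------------------------------------------------------------
# models and LOOCV


def _build_model(spec: ClassifierSpec, features: np.ndarray):
    if spec.family == "neural_network":
        return MLPClassifier(
            hidden_layer_sizes=(spec.hidden_units,),
            activation="tanh",
            solver="lbfgs",
            max_iter=spec.max_iter,
            random_state=spec.seed,
        )
    if spec.family == "gaussian":
        # class-conditional Gaussians with shared covariance; shrinkage keeps
        # the covariance invertible when features outnumber cases
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    if spec.family == "kernel":
        # RBF bandwidth from the median pairwise distance
        d2 = np.sum((features[:, None, :] - features[None, :, :]) ** 2, axis=-1)
        med = float(np.sqrt(np.median(d2[np.triu_indices(len(features), k=1)])))
        gamma = 1.0 / (2.0 * med**2) if med > 0 else "scale"
        return SVC(kernel="rbf", gamma=gamma)
    raise ValueError(f"family {spec.family!r} has no trainable model")


def _score_one(model, x: np.ndarray) -> float:
    if hasattr(model, "predict_proba"):
        classes = list(model.classes_)
        return float(model.predict_proba(x.reshape(1, -1))[0][classes.index(1)])
    return float(model.decision_function(x.reshape(1, -1))[0])


def loocv_scores(
    features: Sequence[FeatureVector],
    labels: Sequence[str],
    spec: ClassifierSpec,
) -> List[CaseScore]:
    """Leave-one-out scores; each case scored by a model that never saw it.

    Feature standardization is fitted inside each fold (no leakage).  For the
    non-trained ``latency_threshold`` family the score is the negated median
    latency feature (higher = shorter latency = more MCI-like).
    """
    if len(features) != len(labels):
        raise ValueError("features and labels must align")
    labs = list(labels)
    bad = sorted(set(labs) - {MCI, NC})
    if bad:
        raise ValueError(f"unknown labels: {bad}")
    if len(set(labs)) < 2:
        raise ValueError("LOOCV needs both classes present")
    for lab in (MCI, NC):
        if labs.count(lab) < 2:
            raise ValueError(f"need >= 2 cases of class {lab}")
    x = np.stack([f.values for f in features])
    lengths = {f.values.shape[0] for f in features}
    if len(lengths) != 1:
        raise ValueError("feature vectors have inconsistent lengths")
    y = np.array([1 if lab == MCI else 0 for lab in labs])

    n_density = x.shape[1] - 4  # summary stats live in the last 4 slots
    if spec.family == "latency_threshold":
        return [
            CaseScore(features[i].case_id, labs[i], -float(x[i, n_density]), i)
            for i in range(len(labs))
        ]

    scores: List[CaseScore] = []
    for i in range(len(labs)):
        mask = np.ones(len(labs), dtype=bool)
        mask[i] = False
        scaler = StandardScaler().fit(x[mask])
        xt = scaler.transform(x[mask])
        model = _build_model(spec, xt)
        model.fit(xt, y[mask])
        s = _score_one(model, scaler.transform(x[i : i + 1])[0])
        scores.append(CaseScore(features[i].case_id, labs[i], s, i))
    return scores


# ---------------------------------------------------------------------------
# ROC / confusion


def confusion(predicted: Sequence[str], truth: Sequence[str]) -> ConfusionMatrix:
    """Counts with MCI as the positive class; derived rates guard div-by-0."""
    if len(predicted) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    for lab in list(predicted) + list(truth):
        if lab not in (MCI, NC):
            raise ValueError(f"label {lab!r} outside {{MCI, NC}}")
    tp = sum(1 for p, t in zip(predicted, truth) if p == MCI and t == MCI)
    tn = sum(1 for p, t in zip(predicted, truth) if p == NC and t == NC)
    fp = sum(1 for p, t in zip(predicted, truth) if p == MCI and t == NC)
    fn = sum(1 for p, t in zip(predicted, truth) if p == NC and t == MCI)
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)


def _confusion_at(scores: np.ndarray, y: np.ndarray, thr: float) -> ConfusionMatrix:
    pred = scores >= thr
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
        fn=int(np.sum(~pred & (y == 1))),
    )


def roc_metrics(
    scores: Sequence[CaseScore] | np.ndarray,
    labels: Optional[Sequence[str]] = None,
    operating_rule: str = "youden",
) -> ROCResult:
    """Empirical ROC over all score thresholds, trapezoidal AUC, and the
    Youden-optimal operating point (ties resolved toward higher specificity).
    """
    if labels is None:
        cs = list(scores)  # type: ignore[arg-type]
        s = np.array([c.score for c in cs], dtype=float)
        y = np.array([1 if c.label == MCI else 0 for c in cs])
    else:
        s = np.asarray(scores, dtype=float)
        y = np.array([1 if lab == MCI else 0 for lab in labels])
    if operating_rule != "youden":
        raise ValueError(f"unknown operating rule {operating_rule!r}")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    degenerate = bool(np.all(s == s[0]))
    # thresholds: descending unique scores; predict positive when score >= t
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], uniq))
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for k, t in enumerate(thresholds):
        pred = s >= t
        tpr[k] = np.sum(pred & (y == 1)) / n_pos
        fpr[k] = np.sum(pred & (y == 0)) / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    # ties -> higher specificity (lower FPR)
    pick = best[np.argmin(fpr[best])]
    thr = float(thresholds[pick]) if np.isfinite(thresholds[pick]) else float(uniq[0])
    cm = _confusion_at(s, y, thr)
    return ROCResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=0.5 if degenerate else auc,
        operating_threshold=thr,
        confusion=cm,
        degenerate=degenerate,
    )


def evaluate_family(
    features: Sequence[FeatureVector],
    labels: Sequence[str],
    spec: ClassifierSpec,
) -> Tuple[List[CaseScore], ROCResult]:
    """LOOCV scores plus ROC metrics at the pooled Youden operating point."""
    scores = loocv_scores(features, labels, spec)
    return scores, roc_metrics(scores)
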