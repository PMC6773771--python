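"""Detection metrics: ROC AUC, thresholded confusion metrics, the
validation-derived operating threshold, slide-level scores and bootstrap
confidence intervals.

Patch-level metrics treat every patch as one observation; slide-level
diagnosis assigns each slide the maximum patch probability and labels a
slide positive when its mask contains any cancer.  The operating threshold
is chosen on the validation group by maximizing Youden's J
(sensitivity + specificity - 1) and applied to the test group with the
strict rule "predict cancer iff score > threshold".  Bootstrap intervals
resample *slides* with replacement (patches within a slide are spatially
correlated) and report the 2.5/97.5 percentiles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

log = logging.getLogger(__name__)

N_BOOT_DEFAULT = 1000


@dataclass
class EvalReport:
    """Patch- and slide-level results with bootstrap confidence intervals."""

    patch_auc: float
    slide_auc: float | None
    f1: float
    accuracy: float
    sensitivity: float
    specificity: float
    threshold: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_patches: int = 0
    n_slides: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _check_two_classes(labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if not (labels > 0).any():
        raise ValueError("no positive (cancer) examples present")
    if not (labels <= 0).any():
        raise ValueError("no negative (normal) examples present")


def roc_auc(scores, labels) -> float:
    """Trapezoidal ROC AUC with midrank tie handling (Mann-Whitney)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = (np.asarray(labels) > 0).astype(int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def metrics_at(scores, labels, threshold: float):
    """(f1, accuracy, sensitivity, specificity) at a threshold.

    Positive prediction iff score > threshold (strict).  Undefined ratios
    (zero denominators) are returned as ``nan`` with a logged warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    scores = np.asarray(scores, dtype=np.float64)
    labels = (np.asarray(labels) > 0).astype(int)
    pred = scores > threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))

    def ratio(num, den, name):
        if den == 0:
            log.warning("%s undefined (zero denominator); reported as nan", name)
            return float("nan")
        return num / den

    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    accuracy = ratio(tp + tn, tp + fp + fn + tn, "accuracy")
    precision = ratio(tp, tp + fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        f1 = float("nan") if np.isnan(precision) or np.isnan(sensitivity) else 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return f1, accuracy, sensitivity, specificity


def select_threshold(scores, labels) -> float:
    """Operating threshold maximizing Youden's J on validation data.

    Candidate cuts are the observed scores; ties in J break toward the
    higher threshold.  The returned value is used downstream with the
    strict rule ``score > threshold``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = (np.asarray(labels) > 0).astype(int)
    _check_two_classes(labels)
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best_j, best_t = -np.inf, None
    for t in np.unique(scores):
        pred = scores > t
        sens = np.sum(pred & (labels == 1)) / n_pos
        spec = np.sum(~pred & (labels == 0)) / n_neg
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and (best_t is None or t > best_t)):
            best_j, best_t = j, float(t)
    return best_t


def slide_score(patch_probs) -> float:
    """Slide-level probability: the maximum patch probability on the slide."""
    arr = np.asarray(patch_probs, dtype=np.float64).ravel()
    if arr.size == 0:
        raise ValueError("slide has no patch predictions")
    return float(arr.max())


# ------------------------------------------------------------------ bootstrap

def bootstrap_ci(
    metric_fn,
    slide_data: list,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Nonparametric bootstrap percentile interval, resampling slides.

    ``slide_data`` is a list of per-slide payloads; ``metric_fn`` receives a
    resampled list (slides drawn with replacement) and returns the metric.
    A replicate on which ``metric_fn`` raises (e.g. a single-class resample)
    is redrawn up to 10 times, then dropped with a logged count.
    """
    if not slide_data:
        raise ValueError("no slide data to bootstrap")
    rng = np.random.default_rng(seed)
    n = len(slide_data)
    values = []
    dropped = 0
    for _ in range(n_boot):
        for _attempt in range(10):
            idx = rng.integers(0, n, size=n)
            try:
                values.append(float(metric_fn([slide_data[i] for i in idx])))
                break
            except ValueError:
                continue
        else:
            dropped += 1
    if dropped:
        log.warning("bootstrap: dropped %d of %d replicates (single-class resamples)", dropped, n_boot)
    if not values:
        raise ValueError("every bootstrap replicate failed")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


# ----------------------------------------------------------- report assembly

def _pooled(slides):
    scores = np.concatenate([s for s, _ in slides])
    labels = np.concatenate([l for _, l in slides])
    return scores, labels


def evaluate_cohort(
    patch_scores_by_slide: dict[str, tuple[np.ndarray, np.ndarray]],
    slide_labels: dict[str, int],
    threshold: float,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
) -> EvalReport:
    """Assemble an EvalReport for a test cohort.

    ``patch_scores_by_slide`` maps slide id -> (patch scores, patch labels);
    ``slide_labels`` maps slide id -> 1 if the slide contains any cancer.
    Patch metrics pool all patches; slide AUC uses the max patch probability
    per slide.  Bootstrap resamples slides for every interval.
    """
    ids = sorted(patch_scores_by_slide)
    per_slide = [
        (np.asarray(patch_scores_by_slide[i][0], float),
         np.asarray(patch_scores_by_slide[i][1], int))
        for i in ids
    ]
    scores, labels = _pooled(per_slide)
    patch_auc = roc_auc(scores, labels)
    f1, acc, sens, spec = metrics_at(scores, labels, threshold)

    slide_scores = np.array([slide_score(s) for s, _ in per_slide])
    slide_y = np.array([slide_labels[i] for i in ids])
    s_auc = None
    if (slide_y > 0).any() and (slide_y == 0).any():
        s_auc = roc_auc(slide_scores, slide_y)

    ci = {}
    ci["patch_auc"] = bootstrap_ci(
        lambda sl: roc_auc(*_pooled(sl)), per_slide, n_boot, seed
    )
    for k, name in enumerate(["f1", "accuracy", "sensitivity", "specificity"]):
        ci[name] = bootstrap_ci(
            lambda sl, k=k: metrics_at(*_pooled(sl), threshold)[k], per_slide, n_boot, seed + 1 + k
        )
    if s_auc is not None:
        slide_units = list(zip(slide_scores, slide_y))
        ci["slide_auc"] = bootstrap_ci(
            lambda units: roc_auc([u[0] for u in units], [u[1] for u in units]),
            slide_units, n_boot, seed + 5,
        )

    return EvalReport(
        patch_auc=patch_auc,
        slide_auc=s_auc,
        f1=f1,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        threshold=threshold,
        ci={k: (float(a), float(b)) for k, (a, b) in ci.items()},
        n_patches=int(len(labels)),
        n_slides=len(ids),
    )
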