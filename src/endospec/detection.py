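"""Detection-output evaluation: IoU matching with a background class,
confusion matrices, derived metrics, average precision, and YOLO-format I/O.

Conventions
-----------
Confusion matrices are (K+1) x (K+1) with rows = predicted, columns = true,
and the background class last; the background/background cell is fixed at 0.
Overall accuracy is the sum of correct real-class predictions divided by the
total number of real-class ground truths (background excluded from both
sums).  Specificity is one-vs-rest over the full table including background,
and kappa is Cohen's kappa on the full table; both are standard definitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CLASSES = ("scc", "dysplasia", "normal")
BACKGROUND = "background"

#: Names of the bundled reference confusion matrices (four detector/imaging
#: variants evaluated on an esophageal endoscopy test set).
REFERENCE_MATRICES = ("rgb-wli", "hsi-wli", "rgb-nbi", "hsi-nbi")


@dataclass(frozen=True)
class BoxAnnotation:
    """Normalized YOLO-style box: center/size as [0, 1] image fractions."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    confidence: float | None = None

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("degenerate box: width and height must be > 0")
        if not (
            0.0 <= self.cx - self.w / 2 + 1e-9
            and self.cx + self.w / 2 <= 1.0 + 1e-9
            and 0.0 <= self.cy - self.h / 2 + 1e-9
            and self.cy + self.h / 2 <= 1.0 + 1e-9
        ):
            raise ValueError("box must lie within the [0, 1] image square")
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def xyxy(self) -> tuple[float, float, float, float]:
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )


def iou(a: BoxAnnotation, b: BoxAnnotation) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ax0, ay0, ax1, ay1 = a.xyxy
    bx0, by0, bx1, by1 = b.xyxy
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


@dataclass
class ConfusionMatrix:
    """(K+1) x (K+1) contingency table; rows predicted, columns true,
    background last."""

    counts: np.ndarray
    class_names: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.class_names) + 1
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} for {len(self.class_names)} classes")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts[-1, -1] != 0:
            raise ValueError("background/background cell must be 0 by convention")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.class_names + (BACKGROUND,)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def match_detections(
    preds: list[BoxAnnotation],
    truths: list[BoxAnnotation],
    iou_threshold: float = 0.5,
    class_names: tuple[str, ...] = DEFAULT_CLASSES,
) -> ConfusionMatrix:
    """Greedy confidence-ordered matching of one image's detections.

    Each prediction (descending confidence, ties by input order) claims the
    unmatched truth with the highest IoU >= threshold.  Matched pairs count as
    (pred_class, true_class); unmatched predictions fall in the background
    column, unmatched truths in the background row.
    """
    k = len(class_names)
    counts = np.zeros((k + 1, k + 1), dtype=np.int64)
    if any(p.confidence is None for p in preds):
        raise ValueError("all predictions must carry a confidence for matching")
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    matched = [False] * len(truths)
    for i in order:
        p = preds[i]
        best_j, best_v = -1, 0.0
        for j, t in enumerate(truths):
            if matched[j]:
                continue
            v = iou(p, t)
            if v > best_v:
                best_j, best_v = j, v
        if best_j >= 0 and best_v >= iou_threshold:
            matched[best_j] = True
            counts[p.class_id, truths[best_j].class_id] += 1
        else:
            counts[p.class_id, k] += 1  # false positive vs background
    for j, t in enumerate(truths):
        if not matched[j]:
            counts[k, t.class_id] += 1  # missed truth
    return ConfusionMatrix(counts, class_names)


def accumulate_confusion(
    preds_by_image: dict,
    truths_by_image: dict,
    iou_threshold: float = 0.5,
    class_names: tuple[str, ...] = DEFAULT_CLASSES,
) -> ConfusionMatrix:
    """Sum per-image confusion matrices over a keyed collection of images."""
    k = len(class_names)
    total = np.zeros((k + 1, k + 1), dtype=np.int64)
    for key in sorted(set(preds_by_image) | set(truths_by_image)):
        cm = match_detections(
            preds_by_image.get(key, []),
            truths_by_image.get(key, []),
            iou_threshold,
            class_names,
        )
        total += cm.counts
    return ConfusionMatrix(total, class_names)


@dataclass
class MetricsTable:
    """Per-class and overall metrics derived from a confusion matrix.

    Undefined ratios (zero denominators) are reported as NaN, never as 0.
    """

    class_names: tuple[str, ...]
    sensitivity: np.ndarray
    precision: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    accuracy: float
    kappa: float

    @staticmethod
    def _nanmean(values: np.ndarray) -> float:
        finite = values[~np.isnan(values)]
        return float(finite.mean()) if finite.size else math.nan

    @property
    def mean_sensitivity(self) -> float:
        return self._nanmean(self.sensitivity)

    @property
    def mean_precision(self) -> float:
        return self._nanmean(self.precision)

    @property
    def mean_specificity(self) -> float:
        return self._nanmean(self.specificity)

    @property
    def mean_f1(self) -> float:
        return self._nanmean(self.f1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "sensitivity": self.sensitivity,
                "precision": self.precision,
                "specificity": self.specificity,
                "f1": self.f1,
            },
            index=list(self.class_names),
        )
        df.loc["mean"] = [
            self.mean_sensitivity,
            self.mean_precision,
            self.mean_specificity,
            self.mean_f1,
        ]
        df["accuracy"] = np.nan
        df["kappa"] = np.nan
        df.loc["mean", "accuracy"] = self.accuracy
        df.loc["mean", "kappa"] = self.kappa
        return df


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsTable:
    """Derive sensitivity, precision, specificity, F1, overall accuracy and
    Cohen's kappa from a background-augmented confusion matrix."""
    counts = cm.counts.astype(np.float64)
    k = len(cm.class_names)
    diag = np.diag(counts)[:k]
    true_tot = counts.sum(axis=0)[:k]
    pred_tot = counts.sum(axis=1)[:k]
    total = counts.sum()

    sens = np.array([_safe_div(diag[c], true_tot[c]) for c in range(k)])
    prec = np.array([_safe_div(diag[c], pred_tot[c]) for c in range(k)])
    f1 = np.array(
        [
            _safe_div(2 * sens[c] * prec[c], sens[c] + prec[c])
            if not (math.isnan(sens[c]) or math.isnan(prec[c]))
            else math.nan
            for c in range(k)
        ]
    )
    # one-vs-rest specificity over the full table, background included
    spec = np.empty(k)
    for c in range(k):
        fp = pred_tot[c] - diag[c]
        negatives = total - true_tot[c]
        spec[c] = _safe_div(negatives - fp, negatives)

    accuracy = _safe_div(diag.sum(), true_tot.sum())

    po = _safe_div(np.trace(counts), total)
    pe = _safe_div(
        float(counts.sum(axis=1) @ counts.sum(axis=0)), total * total if total else 0
    )
    kappa = _safe_div(po - pe, 1.0 - pe) if not math.isnan(po) else math.nan

    return MetricsTable(
        class_names=cm.class_names,
        sensitivity=sens,
        precision=prec,
        specificity=spec,
        f1=f1,
        accuracy=accuracy,
        kappa=kappa,
    )


def average_precision(
    preds_by_image: dict,
    truths_by_image: dict,
    iou_threshold: float = 0.5,
    class_names: tuple[str, ...] = DEFAULT_CLASSES,
) -> tuple[dict, float]:
    """101-point interpolated AP per class and the unweighted mAP.

    Classes with no ground truth get NaN AP and are excluded from the mAP.
    """
    k = len(class_names)
    aps: dict[str, float] = {}
    defined = []
    for c in range(k):
        rows = []  # (confidence, image_key, pred)
        n_truth = 0
        for key in sorted(set(preds_by_image) | set(truths_by_image)):
            n_truth += sum(1 for t in truths_by_image.get(key, []) if t.class_id == c)
            for p in preds_by_image.get(key, []):
                if p.class_id == c:
                    if p.confidence is None:
                        raise ValueError("average_precision requires confidences")
                    rows.append((p.confidence, key, p))
        if n_truth == 0:
            aps[class_names[c]] = math.nan
            continue
        rows.sort(key=lambda r: -r[0])
        matched: dict[str, set] = {}
        tp = np.zeros(len(rows))
        for i, (_, key, p) in enumerate(rows):
            truths = [t for t in truths_by_image.get(key, []) if t.class_id == c]
            taken = matched.setdefault(key, set())
            best_j, best_v = -1, 0.0
            for j, t in enumerate(truths):
                if j in taken:
                    continue
                v = iou(p, t)
                if v > best_v:
                    best_j, best_v = j, v
            if best_j >= 0 and best_v >= iou_threshold:
                taken.add(best_j)
                tp[i] = 1.0
        cum_tp = np.cumsum(tp)
        cum_fp = np.cumsum(1.0 - tp)
        recall = cum_tp / n_truth
        precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
        ap = 0.0
        for r in np.linspace(0.0, 1.0, 101):
            mask = recall >= r - 1e-12
            ap += float(precision[mask].max()) if mask.any() else 0.0
        aps[class_names[c]] = ap / 101.0
        defined.append(aps[class_names[c]])
    mean_ap = float(np.mean(defined)) if defined else math.nan
    return aps, mean_ap


def dedup_boxes(preds: list[BoxAnnotation], iou_threshold: float = 0.5):
    """Optional IoU de-duplication for raw prediction files: keep the highest
    confidence box among same-class mutual overlaps above the threshold."""
    if any(p.confidence is None for p in preds):
        raise ValueError("dedup_boxes requires confidences")
    keep: list[BoxAnnotation] = []
    for p in sorted(preds, key=lambda b: -b.confidence):
        if all(
            not (q.class_id == p.class_id and iou(p, q) >= iou_threshold) for q in keep
        ):
            keep.append(p)
    return keep


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_yolo_annotations(path) -> list[BoxAnnotation]:
    """Read one image's YOLO text file: rows ``class cx cy w h [conf]``."""
    boxes: list[BoxAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise ValueError(
                    f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}"
                )
            try:
                cls = int(parts[0])
                vals = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable field ({exc})") from None
            conf = vals[4] if len(vals) == 5 else None
            try:
                boxes.append(BoxAnnotation(cls, *vals[:4], confidence=conf))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return boxes


def write_yolo_annotations(boxes: list[BoxAnnotation], path) -> None:
    """Write YOLO rows at 6-decimal precision (lossless round trip)."""
    with open(path, "w") as fh:
        for b in boxes:
            row = f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
            if b.confidence is not None:
                row += f" {b.confidence:.6f}"
            fh.write(row + "\n")


def read_annotation_dir(directory) -> dict[str, list[BoxAnnotation]]:
    """Read every ``*.txt`` file in a directory, keyed by file stem."""
    directory = Path(directory)
    return {
        p.stem: read_yolo_annotations(p) for p in sorted(directory.glob("*.txt"))
    }


def write_confusion_csv(cm: ConfusionMatrix, path) -> None:
    df = cm.to_frame()
    df.index.name = "predicted"
    df.to_csv(path)


def read_confusion_csv(path) -> ConfusionMatrix:
    """Read a labeled confusion-matrix CSV (rows predicted, columns true,
    background last)."""
    df = pd.read_csv(path, index_col=0)
    labels = [str(c) for c in df.columns]
    if labels[-1] != BACKGROUND or [str(i) for i in df.index] != labels:
        raise ValueError(
            "confusion CSV must have identical row/column labels with "
            "'background' last"
        )
    return ConfusionMatrix(df.to_numpy(dtype=np.int64), tuple(labels[:-1]))


def load_reference_confusion(name: str) -> ConfusionMatrix:
    """Load one of the bundled reference matrices (see REFERENCE_MATRICES)."""
    if name not in REFERENCE_MATRICES:
        raise ValueError(f"unknown reference matrix {name!r}; choose from {REFERENCE_MATRICES}")
    ref = resources.files("endospec").joinpath(f"data/confusion_{name.replace('-', '_')}.csv")
    with resources.as_file(ref) as p:
        return read_confusion_csv(p)
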