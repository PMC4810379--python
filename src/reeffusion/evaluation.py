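"""Evaluation protocol: per-image accuracy, confusion, PR curves, paired test.

Accuracy is computed per test image as the fraction of its annotated points
classified in agreement with the expert, then summarized as mean ± SE over
images (SE = sample SD / sqrt(n_images)).  Confusion matrices are
row-normalized so the diagonal gives per-class recall; precision–recall curves
sweep a one-vs-rest threshold on each class's score.  Two classifiers are
compared with a Wilcoxon signed-rank test on the per-image accuracy
differences d(i) = a_A(i) - a_B(i): zero differences are discarded, tied
absolute differences receive average ranks, the null distribution is exact for
up to 25 nonzero differences and a tie-corrected normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_curve

from .datamodel import LabelSet, merge_coral_other

EXACT_WILCOXON_LIMIT = 25


# ------------------------------------------------------------- accuracy


def per_image_accuracy(
    images: Sequence[str], true: Sequence[str], pred: Sequence[str]
) -> dict[str, float]:
    """Fraction of correctly classified points per image."""
    if not (len(images) == len(true) == len(pred)):
        raise ValueError("images, true and pred must have equal length")
    hits: dict[str, list[int]] = {}
    for img, t, p in zip(images, true, pred):
        hits.setdefault(img, []).append(int(t == p))
    return {img: float(np.mean(v)) for img, v in hits.items()}


def summarize_accuracy(acc: Mapping[str, float]) -> tuple[float, float]:
    """Mean and standard error of per-image accuracies."""
    values = np.array(list(acc.values()), dtype=np.float64)
    if len(values) == 0:
        raise ValueError("no images to summarize")
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(values.mean()), se


# ------------------------------------------------------------- confusion


def confusion_matrix(
    true: Sequence[str], pred: Sequence[str], labelset: LabelSet | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized confusion matrix plus per-class truth counts.

    Entry (r, c) is the probability of classifying category r as category c;
    the diagonal is per-class recall.  Rows with zero truth count are left as
    zeros.
    """
    labelset = labelset or LabelSet()
    if len(true) != len(pred):
        raise ValueError("true and pred must have equal length")
    counts_matrix = _sk_confusion(true, pred, labels=list(labelset.labels)).astype(
        np.float64
    )
    row_counts = counts_matrix.sum(axis=1)
    norm = np.zeros_like(counts_matrix)
    nz = row_counts > 0
    norm[nz] = counts_matrix[nz] / row_counts[nz, None]
    return norm, row_counts.astype(np.int64)


# ------------------------------------------------------------- PR curves


def pr_curves(
    true: Sequence[str], scores: np.ndarray, labelset: LabelSet | None = None
) -> dict[str, dict[str, np.ndarray] | None]:
    """One-vs-rest precision–recall curve per class.

    Precision is the proportion of correct classifications among all samples
    classified as the class; recall the proportion among all samples from the
    class.  Classes absent from the truth get ``None`` (undefined recall).
    """
    labelset = labelset or LabelSet()
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if scores.shape != (len(true), len(labelset)):
        raise ValueError(
            f"scores must be ({len(true)}, {len(labelset)}), got {scores.shape}"
        )
    true = np.asarray(true)
    out: dict[str, dict[str, np.ndarray] | None] = {}
    for j, label in enumerate(labelset.labels):
        mask = true == label
        if not mask.any():
            out[label] = None
            continue
        precision, recall, thresholds = precision_recall_curve(mask, scores[:, j])
        out[label] = {
            "precision": precision,
            "recall": recall,
            "thresholds": thresholds,
        }
    return out


# ------------------------------------------------------------- Wilcoxon


@dataclass
class PairedComparison:
    """Result of a paired signed-rank comparison of two classifiers."""

    differences: np.ndarray
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n: int  # images compared
    n_nonzero: int
    alternative: str
    method: str  # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _signed_rank_exact_sf(double_ranks: np.ndarray, double_w: int) -> float:
    """P(W+ >= w) under the exact null, ranks doubled to integers.

    Dynamic programming over the generating polynomial prod (1 + x^{2 r_i});
    handles tied (half-integer) average ranks exactly.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)
        counts[r:] += counts[: total + 1 - r]
    tail = counts[double_w:].sum()
    return float(tail / counts.sum())


def wilcoxon_paired(
    a_a: Mapping[str, float],
    a_b: Mapping[str, float],
    alternative: str = "greater",
    zero_method: str = "wilcox",
) -> PairedComparison:
    """Wilcoxon signed-rank test on per-image accuracy differences.

    Tests whether classifier A's per-image accuracy exceeds B's
    (``alternative="greater"``, the default; ``"two-sided"`` available).
    Both maps must cover the same image set.
    """
    if set(a_a) != set(a_b):
        raise ValueError("the two accuracy maps must cover the same images")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    if zero_method != "wilcox":
        raise ValueError("only zero-discarding ('wilcox') is implemented")
    images = sorted(a_a)
    d = np.array([a_a[i] - a_b[i] for i in images], dtype=np.float64)
    n = len(d)

    nz = d[d != 0]
    m = len(nz)
    if m == 0:
        return PairedComparison(d, 0.0, 1.0, n, 0, alternative, "degenerate")

    ranks = stats.rankdata(np.abs(nz))  # average ranks for ties
    w_plus = float(ranks[nz > 0].sum())
    double_ranks = np.rint(2 * ranks).astype(np.int64)
    total = int(double_ranks.sum())  # == m (m + 1)

    if m <= EXACT_WILCOXON_LIMIT:
        dw = int(np.rint(2 * w_plus))
        p_greater = _signed_rank_exact_sf(double_ranks, dw)
        if alternative == "greater":
            p = p_greater
        else:
            # P(W+ <= w) via symmetry of the enumeration
            p_less = _signed_rank_exact_sf(double_ranks, 0) - _signed_rank_exact_sf(
                double_ranks, dw + 1
            )
            p = min(1.0, 2.0 * min(p_greater, p_less))
        method = "exact"
    else:
        mean = total / 4.0  # = sum(ranks) / 2
        var = float(np.sum(ranks**2)) / 4.0  # tie-corrected automatically
        z = (w_plus - mean - 0.5) / np.sqrt(var)
        p_greater = float(stats.norm.sf(z))
        if alternative == "greater":
            p = p_greater
        else:
            z2 = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
            p = min(1.0, 2.0 * float(stats.norm.sf(z2)))
        method = "normal"
    return PairedComparison(d, w_plus, p, n, m, alternative, method)


# ------------------------------------------------------------- arithmetic


def error_reduction(acc_a: float, acc_b: float) -> tuple[float, float]:
    """Absolute and relative error-rate reduction going from A to B.

    Accuracies are percentages.  absolute = error(A) - error(B); relative is
    the absolute reduction as a percentage of A's error rate (NaN when A has
    zero error but B does not).
    """
    for acc in (acc_a, acc_b):
        if not 0.0 <= acc <= 100.0:
            raise ValueError(f"accuracy {acc} outside [0, 100]")
    err_a, err_b = 100.0 - acc_a, 100.0 - acc_b
    absolute = err_a - err_b
    if err_a == 0.0:
        relative = 0.0 if err_b == 0.0 else float("nan")
    else:
        relative = absolute / err_a * 100.0
    return absolute, relative


# ------------------------------------------------------------- report


@dataclass
class EvaluationReport:
    """Full evaluation of one classifier on the test set."""

    per_image: dict[str, float]
    mean_accuracy: float
    se_accuracy: float
    confusion: np.ndarray
    confusion_counts: np.ndarray
    pr: dict[str, dict[str, np.ndarray] | None]
    binary_mean: float
    binary_se: float
    n_images: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_images = len(self.per_image)


def render_confusion_matrix(
    report: "EvaluationReport", path, labelset: LabelSet | None = None
) -> None:
    """Render the row-normalized confusion matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labelset = labelset or LabelSet()
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(report.confusion, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(labelset)), labelset.labels, rotation=90, fontsize=7)
    ax.set_yticks(
        range(len(labelset)),
        [f"{lab} ({int(n)})" for lab, n in zip(labelset.labels, report.confusion_counts)],
        fontsize=7,
    )
    ax.set_xlabel("predicted")
    ax.set_ylabel("true (count)")
    fig.colorbar(im, label="recall")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_pr_curves(report: "EvaluationReport", path) -> None:
    """Render the per-class precision-recall curves to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for label, curve in report.pr.items():
        if curve is None:
            continue
        ax.plot(curve["recall"], curve["precision"], label=label, lw=1)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1.02)
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=6, loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def build_report(
    images: Sequence[str],
    true: Sequence[str],
    pred: Sequence[str],
    scores: np.ndarray | None = None,
    labelset: LabelSet | None = None,
) -> EvaluationReport:
    """Assemble the standard evaluation report for one classifier."""
    labelset = labelset or LabelSet()
    acc = per_image_accuracy(images, true, pred)
    mean, se = summarize_accuracy(acc)
    conf, counts = confusion_matrix(true, pred, labelset)
    curves = (
        pr_curves(true, scores, labelset)
        if scores is not None
        else {lab: None for lab in labelset.labels}
    )
    bin_acc = per_image_accuracy(
        images, merge_coral_other(true, labelset), merge_coral_other(pred, labelset)
    )
    bin_mean, bin_se = summarize_accuracy(bin_acc)
    return EvaluationReport(acc, mean, se, conf, counts, curves, bin_mean, bin_se)
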