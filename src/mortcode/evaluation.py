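"""Reject-aware evaluation: accuracy with bootstrap confidence intervals,
per-chapter error/prevalence tables, chapter confusion restricted to
errors, top-k and second-choice accuracy, and confidence calibration.

A rule-based baseline that rejects complex certificates is scored twice:
once with rejects counted as errors (overall accuracy, the lower figure)
and once with rejects excluded (nonrejected accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .oracle import OracleResult
from .vocabulary import Vocabulary

__all__ = [
    "EvalReport",
    "BaselineComparison",
    "accuracy",
    "bootstrap_ci",
    "per_chapter_report",
    "chapter_confusion_on_errors",
    "topk_accuracy",
    "second_choice_accuracy_on_errors",
    "calibration_report",
    "compare_with_baseline",
    "evaluate",
]


def accuracy(preds: list[str], golds: list[str]) -> float:
    """Fraction of exact prediction/gold matches."""
    if len(preds) != len(golds):
        raise ValueError(f"length mismatch: {len(preds)} predictions vs {len(golds)} golds")
    if not preds:
        raise ValueError("empty prediction list")
    return sum(p == g for p, g in zip(preds, golds)) / len(preds)


def bootstrap_ci(
    correct_flags, B: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for an accuracy.

    Resamples the 0/1 correctness flags with replacement ``B`` times and
    returns the ``(1-level)/2`` and ``(1+level)/2`` percentiles of the
    resampled accuracies.
    """
    flags = np.asarray(correct_flags, dtype=np.float64)
    if flags.size == 0:
        raise ValueError("empty flag list")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    n = flags.size
    # resample in chunks to bound memory at large B*n
    chunk = max(1, int(2e7 // n))
    accs = np.empty(B)
    for lo in range(0, B, chunk):
        b = min(chunk, B - lo)
        idx = rng.integers(0, n, size=(b, n))
        accs[lo:lo + b] = flags[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo_v, hi_v = np.quantile(accs, [alpha, 1.0 - alpha])
    return float(lo_v), float(hi_v)


def _chapters_of(codes: list[str], vocab: Vocabulary) -> list[str]:
    return [vocab.chapter_of_index(vocab.index_of(c, strict=True)) for c in codes]


def per_chapter_report(preds: list[str], golds: list[str], vocab: Vocabulary) -> pd.DataFrame:
    """Per-chapter prevalence (gold share) and error rate.

    Chapters never observed as gold UCD appear with ``observed=False`` and
    NaN error rate; observed prevalences sum to 1.
    """
    if len(preds) != len(golds) or not golds:
        raise ValueError("predictions and golds must be aligned and non-empty")
    gold_ch = _chapters_of(golds, vocab)
    wrong = [p != g for p, g in zip(preds, golds)]
    df = pd.DataFrame({"chapter": gold_ch, "wrong": wrong})
    agg = df.groupby("chapter")["wrong"].agg(count="size", errors="sum")
    rows = []
    for ch in vocab.chapters():
        if ch in agg.index:
            cnt = int(agg.loc[ch, "count"])
            rows.append({
                "chapter": ch, "observed": True,
                "prevalence": cnt / len(golds),
                "error_rate": int(agg.loc[ch, "errors"]) / cnt,
                "count": cnt,
            })
        else:
            rows.append({
                "chapter": ch, "observed": False,
                "prevalence": 0.0, "error_rate": float("nan"), "count": 0,
            })
    return pd.DataFrame(rows).set_index("chapter")


def chapter_confusion_on_errors(
    preds: list[str], golds: list[str], vocab: Vocabulary
) -> pd.DataFrame:
    """Chapter-level confusion matrix over mispredicted cases only
    (rows: true chapter, columns: predicted chapter)."""
    if len(preds) != len(golds):
        raise ValueError("length mismatch")
    chapters = list(vocab.chapters())
    mat = pd.DataFrame(0, index=chapters, columns=chapters, dtype=int)
    for p, g in zip(preds, golds):
        if p != g:
            mat.loc[
                vocab.chapter_of_index(vocab.index_of(g, strict=True)),
                vocab.chapter_of_index(vocab.index_of(p, strict=True)),
            ] += 1
    return mat


def _topk_hits(distributions: np.ndarray, gold_idx: np.ndarray, k: int) -> np.ndarray:
    # ranking with the coder's tie-break: higher prob first, then lower index
    order = np.lexsort(
        (np.broadcast_to(np.arange(distributions.shape[1]), distributions.shape),
         -distributions),
        axis=1,
    )
    return (order[:, :k] == gold_idx[:, None]).any(axis=1)


def topk_accuracy(
    distributions: np.ndarray, golds: list[str], vocab: Vocabulary, k: int
) -> float:
    """Fraction of cases whose gold code sits among the k most probable."""
    if not 1 <= k <= distributions.shape[1]:
        raise ValueError(f"k={k} outside 1..{distributions.shape[1]}")
    if distributions.shape[0] != len(golds):
        raise ValueError("length mismatch")
    gold_idx = np.array([vocab.index_of(g, strict=True) for g in golds])
    return float(_topk_hits(distributions, gold_idx, k).mean())


def second_choice_accuracy_on_errors(
    distributions: np.ndarray, preds: list[str], golds: list[str], vocab: Vocabulary
) -> float:
    """Among mispredicted cases, the fraction whose second-most-probable
    code is the gold one.  Undefined (raises) when there are no errors."""
    if not (distributions.shape[0] == len(preds) == len(golds)):
        raise ValueError("length mismatch")
    wrong = np.array([p != g for p, g in zip(preds, golds)])
    if not wrong.any():
        raise ValueError("second-choice accuracy is undefined without errors")
    gold_idx = np.array([vocab.index_of(g, strict=True) for g in golds])
    order = np.lexsort(
        (np.broadcast_to(np.arange(distributions.shape[1]), distributions.shape),
         -distributions),
        axis=1,
    )
    second = order[:, 1]
    return float((second[wrong] == gold_idx[wrong]).mean())


def calibration_report(
    distributions: np.ndarray, preds: list[str], golds: list[str], n_bins: int = 10
) -> pd.DataFrame:
    """Histogram of argmax confidence, split by correctness.

    Returns one row per bin with counts for correct and incorrect
    predictions; mean group confidences are attached as ``DataFrame.attrs``
    (``mean_confidence_correct`` / ``mean_confidence_incorrect``).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    conf = distributions.max(axis=1)
    correct = np.array([p == g for p, g in zip(preds, golds)])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(conf, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        in_bin = which == b
        rows.append({
            "bin_lo": edges[b], "bin_hi": edges[b + 1],
            "count_correct": int((in_bin & correct).sum()),
            "count_incorrect": int((in_bin & ~correct).sum()),
        })
    out = pd.DataFrame(rows)
    out.attrs["mean_confidence_correct"] = (
        float(conf[correct].mean()) if correct.any() else float("nan")
    )
    out.attrs["mean_confidence_incorrect"] = (
        float(conf[~correct].mean()) if (~correct).any() else float("nan")
    )
    return out


@dataclass(frozen=True)
class BaselineComparison:
    """Dual accuracy of a rejecting rule-based coder, next to the model's
    accuracy on the identical certificates."""

    overall_accuracy: float
    nonrejected_accuracy: float
    reject_fraction: float
    model_accuracy: float
    n: int


def compare_with_baseline(
    model_preds: list[str],
    baseline_results: list[OracleResult],
    golds: list[str],
) -> BaselineComparison:
    """Score the baseline twice (rejects as errors vs. excluded) on the
    same certificates the model is scored on."""
    if not (len(model_preds) == len(baseline_results) == len(golds)):
        raise ValueError("length mismatch")
    n = len(golds)
    rejected = np.array([r.rejected for r in baseline_results])
    base_correct = np.array([
        (not r.rejected) and r.ucd == g for r, g in zip(baseline_results, golds)
    ])
    overall = float(base_correct.mean())
    if (~rejected).any():
        nonrej = float(base_correct[~rejected].mean())
    else:
        nonrej = float("nan")
    return BaselineComparison(
        overall_accuracy=overall,
        nonrejected_accuracy=nonrej,
        reject_fraction=float(rejected.mean()),
        model_accuracy=accuracy(model_preds, golds),
        n=n,
    )


@dataclass
class EvalReport:
    """The full metric surface for one test set."""

    n: int
    accuracy: float
    ci95: tuple[float, float]
    per_chapter: pd.DataFrame
    chapter_confusion: pd.DataFrame
    topk: dict[int, float]
    second_choice_on_errors: float | None
    calibration: pd.DataFrame
    mean_confidence_correct: float
    mean_confidence_incorrect: float

    def summary(self) -> str:
        lines = [
            f"n = {self.n}",
            f"accuracy = {self.accuracy:.4f}  (95% CI {self.ci95[0]:.4f}-{self.ci95[1]:.4f})",
        ]
        for k, v in sorted(self.topk.items()):
            lines.append(f"top-{k} accuracy = {v:.4f}")
        if self.second_choice_on_errors is not None:
            lines.append(f"second-choice accuracy on errors = {self.second_choice_on_errors:.4f}")
        lines.append(
            "mean argmax confidence: "
            f"correct {self.mean_confidence_correct:.4f}, "
            f"incorrect {self.mean_confidence_incorrect:.4f}"
        )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        d = {
            "n": self.n,
            "accuracy": self.accuracy,
            "ci95": list(self.ci95),
            "topk": {str(k): v for k, v in self.topk.items()},
            "second_choice_on_errors": self.second_choice_on_errors,
            "mean_confidence_correct": self.mean_confidence_correct,
            "mean_confidence_incorrect": self.mean_confidence_incorrect,
            "per_chapter": json.loads(self.per_chapter.reset_index().to_json(orient="records")),
            "chapter_confusion": self.chapter_confusion.to_dict(),
            "calibration": json.loads(self.calibration.to_json(orient="records")),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1)


def evaluate(
    distributions: np.ndarray,
    golds: list[str],
    vocab: Vocabulary,
    ks: tuple[int, ...] = (1, 2),
    bootstrap_B: int = 1000,
    bootstrap_seed: int = 0,
    n_bins: int = 10,
) -> EvalReport:
    """Assemble the full report from predicted distributions and gold codes."""
    pred_idx = np.lexsort(
        (np.broadcast_to(np.arange(distributions.shape[1]), distributions.shape),
         -distributions),
        axis=1,
    )[:, 0]
    preds = [vocab.code_at(int(i)) for i in pred_idx]
    acc = accuracy(preds, golds)
    flags = [int(p == g) for p, g in zip(preds, golds)]
    ci = bootstrap_ci(flags, B=bootstrap_B, seed=bootstrap_seed)
    topk = {k: topk_accuracy(distributions, golds, vocab, k) for k in ks}
    try:
        second = second_choice_accuracy_on_errors(distributions, preds, golds, vocab)
    except ValueError:
        second = None
    calib = calibration_report(distributions, preds, golds, n_bins)
    return EvalReport(
        n=len(golds),
        accuracy=acc,
        ci95=ci,
        per_chapter=per_chapter_report(preds, golds, vocab),
        chapter_confusion=chapter_confusion_on_errors(preds, golds, vocab),
        topk=topk,
        second_choice_on_errors=second,
        calibration=calib,
        mean_confidence_correct=calib.attrs["mean_confidence_correct"],
        mean_confidence_incorrect=calib.attrs["mean_confidence_incorrect"],
    )
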