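"""Residue- and segment-level evaluation of merged structure predictions.

Label alphabets
---------------
Predictions are 4-class strings over ``{M, H, C, E}`` (Q4).  Two coarser
views are obtained by projection: topology (Q2, transmembrane ``T`` vs not
``N``, with M -> T) and secondary structure (Q3, with both helix classes
merged: {M, H} -> H).

Metrics
-------
* ``q_accuracy`` — fraction of correctly labeled residues (Q2/Q3/Q4).
* ``mcc`` — Matthews correlation; the textbook binary formula for 2-letter
  alphabets, the Gorodkin R_K generalization of the contingency table
  otherwise.  Zero denominators yield 0 by convention.
* ``sov`` — Segment OVerlap score, SOV'99 definition (Zemla et al. 1999):
  per-class maximal segments, overlap ratio with the delta extension
  allowance, normalized by N_SOV, scaled to [0, 100].
* ``per_class_stats`` — one-vs-rest recall/precision/specificity/F1.
* ``tm_segments`` / ``correct_tm`` — per-protein count of transmembrane
  segments and the number of proteins whose predicted count is exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "project_labels",
    "q_accuracy",
    "mcc",
    "per_class_stats",
    "sov",
    "sov_per_class",
    "tm_segments",
    "correct_tm",
    "MetricsReport",
    "evaluate_predictions",
]

_Q2_MAP = {"M": "T", "H": "N", "C": "N", "E": "N"}
_Q3_MAP = {"M": "H", "H": "H", "C": "C", "E": "E"}

#: marker for one-vs-rest statistics whose denominator is empty
UNDEFINED = float("nan")


def project_labels(y4: str, target: str) -> str:
    """Project a Q4 string onto the Q2 (T/N) or Q3 (H/E/C) alphabet."""
    try:
        table = {"Q2": _Q2_MAP, "Q3": _Q3_MAP}[target]
    except KeyError:
        raise ValueError(f"target must be 'Q2' or 'Q3', got {target!r}") from None
    try:
        return "".join(table[c] for c in y4)
    except KeyError as e:
        raise ValueError(f"invalid Q4 label {e.args[0]!r}") from None


def _check_lengths(pred: str, true: str) -> None:
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: pred {len(pred)} vs true {len(true)}")


def q_accuracy(pred: str, true: str, alphabet: str | None = None) -> float:
    """Fraction of positions labeled correctly."""
    _check_lengths(pred, true)
    if not true:
        return 1.0
    return sum(p == t for p, t in zip(pred, true)) / len(true)


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class plus the multiclass contingency table."""

    alphabet: str
    table: np.ndarray  # (n_classes, n_classes); rows = true, cols = predicted
    per_class: dict[str, dict[str, int]]  # class -> {tp, fp, tn, fn}


def confusion_counts(pred: str, true: str, alphabet: str) -> ConfusionCounts:
    _check_lengths(pred, true)
    idx = {c: i for i, c in enumerate(alphabet)}
    C = np.zeros((len(alphabet), len(alphabet)), dtype=float)
    for p, t in zip(pred, true):
        C[idx[t], idx[p]] += 1
    n = int(C.sum())
    per = {}
    for c in alphabet:
        i = idx[c]
        tp = int(C[i, i])
        fp = int(C[:, i].sum()) - tp
        fn = int(C[i, :].sum()) - tp
        per[c] = {"tp": tp, "fp": fp, "fn": fn, "tn": n - tp - fp - fn}
    return ConfusionCounts(alphabet=alphabet, table=C, per_class=per)


def mcc(pred: str, true: str, alphabet: str) -> float:
    """Matthews correlation coefficient over the given alphabet.

    Two-letter alphabets use (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))
    with the first alphabet letter as the positive class; larger alphabets
    use the Gorodkin R_K statistic.  A zero denominator returns 0.
    """
    _check_lengths(pred, true)
    if len(alphabet) < 2:
        raise ValueError("alphabet must have at least 2 letters")
    if len(alphabet) == 2:
        c = confusion_counts(pred, true, alphabet).per_class[alphabet[0]]
        tp, tn, fp, fn = c["tp"], c["tn"], c["fp"], c["fn"]
        den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        return (tp * tn - fp * fn) / den if den > 0 else 0.0
    C = confusion_counts(pred, true, alphabet).table
    n = C.sum()
    trace = np.trace(C)
    t_row = C.sum(axis=1)  # true-class totals
    p_col = C.sum(axis=0)  # predicted-class totals
    num = trace * n - float(t_row @ p_col)
    den = math.sqrt(n * n - float(p_col @ p_col)) * math.sqrt(n * n - float(t_row @ t_row))
    return num / den if den > 0 else 0.0


def per_class_stats(pred: str, true: str, alphabet: str) -> dict[str, dict[str, float]]:
    """One-vs-rest recall/precision/specificity/F1 per class.

    Classes absent from both strings are reported with NaN markers rather
    than 0, so macro-averages cannot be silently deflated.
    """
    counts = confusion_counts(pred, true, alphabet)
    out: dict[str, dict[str, float]] = {}
    for c in alphabet:
        cc = counts.per_class[c]
        tp, fp, fn, tn = cc["tp"], cc["fp"], cc["fn"], cc["tn"]
        recall = tp / (tp + fn) if tp + fn else UNDEFINED
        precision = tp / (tp + fp) if tp + fp else UNDEFINED
        specificity = tn / (tn + fp) if tn + fp else UNDEFINED
        if not math.isnan(recall) and not math.isnan(precision) and (recall + precision) > 0:
            f1 = 2 * recall * precision / (recall + precision)
        elif tp + fn + fp == 0:
            f1 = UNDEFINED
        else:
            f1 = 0.0
        out[c] = {"recall": recall, "precision": precision, "specificity": specificity, "f1": f1}
    return out


def _segments(s: str) -> list[tuple[str, int, int]]:
    """Maximal same-letter runs as (letter, start, end) with inclusive ends."""
    segs = []
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        segs.append((s[i], i, j))
        i = j + 1
    return segs


def sov(pred: str, true: str, alphabet: str | None = None) -> float:
    """Segment OVerlap score (SOV'99), in percent.

    For every true segment S1 and overlapping same-class predicted segment
    S2 accumulate ``(minov + delta) / maxov * len(S1)`` with
    ``delta = min(maxov - minov, minov, len(S1)//2, len(S2)//2)``; true
    segments with no overlap add ``len(S1)`` to the normalizer only.
    """
    _check_lengths(pred, true)
    if not true:
        return 100.0
    letters = set(alphabet) if alphabet else set(true) | set(pred)
    total = 0.0
    n_sov = 0.0
    true_segs = [s for s in _segments(true) if s[0] in letters]
    pred_segs = [s for s in _segments(pred) if s[0] in letters]
    for cls, a1, b1 in true_segs:
        len1 = b1 - a1 + 1
        overlaps = [
            (a2, b2)
            for c2, a2, b2 in pred_segs
            if c2 == cls and not (b2 < a1 or a2 > b1)
        ]
        if not overlaps:
            n_sov += len1
            continue
        for a2, b2 in overlaps:
            len2 = b2 - a2 + 1
            minov = min(b1, b2) - max(a1, a2) + 1
            maxov = max(b1, b2) - min(a1, a2) + 1
            delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
            total += (minov + delta) / maxov * len1
            n_sov += len1
    if n_sov == 0:
        return 100.0
    return float(np.clip(100.0 * total / n_sov, 0.0, 100.0))


def sov_per_class(pred: str, true: str, alphabet: str) -> dict[str, float]:
    """SOV restricted to each class's segments separately.

    Classes with no true segment are reported as NaN.
    """
    out = {}
    for c in alphabet:
        has_true = any(s[0] == c for s in _segments(true))
        out[c] = sov(pred, true, alphabet=c) if has_true else UNDEFINED
    return out


def tm_segments(labels: str, min_length: int = 1) -> int:
    """Number of maximal transmembrane runs (letter M, or T on Q2 strings)."""
    return sum(
        1
        for cls, a, b in _segments(labels)
        if cls in ("M", "T") and (b - a + 1) >= min_length
    )


def correct_tm(preds: list[str], trues: list[str], min_length: int = 1) -> int:
    """Number of proteins whose predicted TM-segment count is exactly right."""
    if len(preds) != len(trues):
        raise ValueError("prediction and reference lists differ in length")
    return sum(
        tm_segments(p, min_length) == tm_segments(t, min_length)
        for p, t in zip(preds, trues)
    )


@dataclass
class MetricsReport:
    """Aggregate evaluation of a prediction set (concatenated residues)."""

    q4: float
    q3: float
    q2: float
    mcc_q4: float
    mcc_q3: float
    mcc_q2: float
    sov_q4: float
    sov_q3: float
    per_class: dict[str, dict[str, float]]
    tm_correct: int
    n_proteins: int
    n_residues: int
    per_protein: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=float)

    def to_tsv(self, path) -> None:
        cols = ["id", "length", "q4", "q2", "tm_pred", "tm_true"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.per_protein:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def evaluate_predictions(preds: list[str], trues: list[str], ids: list[str] | None = None) -> MetricsReport:
    """Full metric suite over parallel lists of Q4 prediction/reference strings."""
    if len(preds) != len(trues):
        raise ValueError("prediction and reference lists differ in length")
    ids = ids or [f"seq{i + 1}" for i in range(len(preds))]
    cat_p, cat_t = "".join(preds), "".join(trues)
    p3, t3 = project_labels(cat_p, "Q3"), project_labels(cat_t, "Q3")
    p2, t2 = project_labels(cat_p, "Q2"), project_labels(cat_t, "Q2")
    per_protein = [
        {
            "id": i,
            "length": len(t),
            "q4": q_accuracy(p, t),
            "q2": q_accuracy(project_labels(p, "Q2"), project_labels(t, "Q2")),
            "tm_pred": tm_segments(p),
            "tm_true": tm_segments(t),
        }
        for i, p, t in zip(ids, preds, trues)
    ]
    return MetricsReport(
        q4=q_accuracy(cat_p, cat_t),
        q3=q_accuracy(p3, t3),
        q2=q_accuracy(p2, t2),
        mcc_q4=mcc(cat_p, cat_t, "MHCE"),
        mcc_q3=mcc(p3, t3, "HEC"),
        mcc_q2=mcc(p2, t2, "TN"),
        # '|' separators keep segments from merging across protein boundaries
        sov_q4=sov("|".join(preds), "|".join(trues), "MHCE"),
        sov_q3=sov(
            "|".join(project_labels(p, "Q3") for p in preds),
            "|".join(project_labels(t, "Q3") for t in trues),
            "HEC",
        ),
        per_class=per_class_stats(cat_p, cat_t, "MHCE"),
        tm_correct=correct_tm(preds, trues),
        n_proteins=len(preds),
        n_residues=len(cat_t),
        per_protein=per_protein,
    )
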