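"""Evaluation: confusion matrix, per-class precision/recall/F1, one-vs-rest
ROC AUC, and extraction of discrete mutation calls from label tracks.

Per-class metrics follow the standard definitions
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R), with fixed
zero-denominator conventions: TP+FP = 0 gives precision 0, TP+FN = 0 gives
recall 0, P+R = 0 gives F1 0. The headline number is the macro F1 over the
mutation classes (SNV, insertion, deletion) that actually occur in the
truth labels; the normal class would otherwise dominate any pooled score,
and averaging in mutation classes with zero support would report an
artifact of the dataset composition rather than of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .encoding import LabelSequence, WindowSet
from .errors import InvalidInputError, UndefinedMetricError

CLASS_NAMES = ("normal", "SNV", "INS", "DEL")
_TYPE_OF_LABEL = {1: "SNV", 2: "INS", 3: "DEL"}


@dataclass
class EvalReport:
    confusion: np.ndarray                      # 4x4, rows true / cols predicted
    precision: dict = field(default_factory=dict)
    recall: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)    # per mutation class, None if absent
    macro_f1_mutations: float = 0.0            # mean F1 over supported classes 1-3
    macro_f1_mutations_all: float = 0.0        # strict mean over classes 1-3
    micro_f1: float = 0.0                      # pooled over classes 1-3
    n_positions: int = 0

    def to_tsv(self) -> str:
        lines = ["metric\tclass\tvalue"]
        for c in range(4):
            name = CLASS_NAMES[c]
            lines.append(f"precision\t{name}\t{self.precision[c]:.6f}")
            lines.append(f"recall\t{name}\t{self.recall[c]:.6f}")
            lines.append(f"f1\t{name}\t{self.f1[c]:.6f}")
        for c in (1, 2, 3):
            v = self.auc.get(c)
            lines.append(f"auc\t{CLASS_NAMES[c]}\t" +
                         ("NA" if v is None else f"{v:.6f}"))
        lines.append(f"macro_f1_mutations\t-\t{self.macro_f1_mutations:.6f}")
        lines.append(f"macro_f1_mutations_all\t-\t{self.macro_f1_mutations_all:.6f}")
        lines.append(f"micro_f1\t-\t{self.micro_f1:.6f}")
        lines.append(f"n_positions\t-\t{self.n_positions}")
        return "\n".join(lines) + "\n"

    def confusion_grid(self) -> str:
        head = "true\\pred\t" + "\t".join(CLASS_NAMES)
        rows = [head]
        for c in range(4):
            rows.append(CLASS_NAMES[c] + "\t" +
                        "\t".join(str(int(v)) for v in self.confusion[c]))
        return "\n".join(rows) + "\n"


def confusion_matrix_counts(true_seqs, pred_seqs, mask_padding=False,
                            codes_seqs=None) -> np.ndarray:
    """4x4 count matrix over all paired positions.

    With ``mask_padding`` on, positions whose input code is 0 are excluded;
    ``codes_seqs`` must then supply the aligned code vectors.
    """
    y_true, y_pred = [], []
    for i, (t, p) in enumerate(zip(true_seqs, pred_seqs)):
        tv = t.labels if isinstance(t, LabelSequence) else np.asarray(t)
        pv = p.labels if isinstance(p, LabelSequence) else np.asarray(p)
        if tv.shape[0] != pv.shape[0]:
            name = t.source_id if isinstance(t, LabelSequence) else f"pair {i}"
            raise InvalidInputError(
                f"length mismatch for {name}: {tv.shape[0]} vs {pv.shape[0]}")
        if mask_padding:
            if codes_seqs is None:
                raise InvalidInputError("mask_padding requires code vectors")
            keep = np.asarray(codes_seqs[i]) != 0
            tv, pv = tv[keep], pv[keep]
        y_true.append(tv)
        y_pred.append(pv)
    yt = np.concatenate(y_true) if y_true else np.zeros(0, dtype=int)
    yp = np.concatenate(y_pred) if y_pred else np.zeros(0, dtype=int)
    return _sk_confusion(yt, yp, labels=[0, 1, 2, 3]).astype(np.int64)


def precision_recall_f1(confusion: np.ndarray, c: int):
    """Per-class precision, recall and F1 from the count matrix."""
    if c not in (0, 1, 2, 3):
        raise InvalidInputError(f"class must be in 0..3, got {c}")
    tp = float(confusion[c, c])
    fp = float(confusion[:, c].sum() - tp)
    fn = float(confusion[c, :].sum() - tp)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


def roc_auc_ovr(true_labels, probs, c: int) -> float:
    """One-vs-rest ROC AUC for class c using probs[:, c] as the score.

    Equals the Mann-Whitney pairwise-concordance statistic. Raises
    UndefinedMetricError when class c is absent from the truth (never a
    silent 0).
    """
    y = np.asarray(true_labels)
    p = np.asarray(probs)
    pos = y == c
    if not pos.any() or pos.all():
        raise UndefinedMetricError(
            f"class {c} absent from truth (or the only class); AUC undefined")
    return float(roc_auc_score(pos.astype(int), p[:, c]))


def extract_calls(pred: LabelSequence, probs: np.ndarray):
    """Merge maximal runs of identical nonzero labels into discrete calls.

    Returns (start_1based, end_1based, type, mean_probability) tuples
    sorted by start, where the probability is the called class's mean over
    the run.
    """
    labels = pred.labels
    calls = []
    i, n = 0, labels.shape[0]
    while i < n:
        lab = int(labels[i])
        if lab == 0:
            i += 1
            continue
        j = i
        while j < n and labels[j] == lab:
            j += 1
        mean_p = float(np.asarray(probs)[i:j, lab].mean())
        calls.append((i + 1, j, _TYPE_OF_LABEL[lab], mean_p))
        i = j
    return calls


def evaluate(model, test: WindowSet, mask_padding: bool = True) -> EvalReport:
    """Predict on every test window and assemble the full report."""
    if len(test) == 0:
        raise InvalidInputError("empty test set")
    from .training import _assemble

    true_seqs, pred_seqs, codes_list, prob_rows, true_rows = [], [], [], [], []
    chunk = 256
    for start in range(0, len(test), chunk):
        batch = test.items[start : start + chunk]
        X, y, _ = _assemble(batch, model.cfg.in_dim)
        probs = model.predict_proba(X)                      # (B, 4, W)
        preds = probs.argmax(axis=1)
        for b, (codes, labels, sid, offset) in enumerate(batch):
            keep = codes != 0 if mask_padding else np.ones_like(codes, dtype=bool)
            true_seqs.append(labels)
            pred_seqs.append(preds[b])
            codes_list.append(codes)
            prob_rows.append(probs[b].T[keep])
            true_rows.append(labels[keep])
    cm = confusion_matrix_counts(true_seqs, pred_seqs,
                                 mask_padding=mask_padding,
                                 codes_seqs=codes_list)
    report = EvalReport(confusion=cm, n_positions=int(cm.sum()))
    for c in range(4):
        p, r, f = precision_recall_f1(cm, c)
        report.precision[c], report.recall[c], report.f1[c] = p, r, f
    supported = [c for c in (1, 2, 3) if cm[c].sum() > 0]
    report.macro_f1_mutations = (
        float(np.mean([report.f1[c] for c in supported])) if supported else 0.0)
    report.macro_f1_mutations_all = float(np.mean([report.f1[c] for c in (1, 2, 3)]))
    tp = sum(cm[c, c] for c in (1, 2, 3))
    fp = sum(cm[:, c].sum() - cm[c, c] for c in (1, 2, 3))
    fn = sum(cm[c, :].sum() - cm[c, c] for c in (1, 2, 3))
    micro_p = tp / (tp + fp) if tp + fp > 0 else 0.0
    micro_r = tp / (tp + fn) if tp + fn > 0 else 0.0
    report.micro_f1 = (2 * micro_p * micro_r / (micro_p + micro_r)
                       if micro_p + micro_r > 0 else 0.0)
    all_probs = np.concatenate(prob_rows) if prob_rows else np.zeros((0, 4))
    all_true = np.concatenate(true_rows) if true_rows else np.zeros(0, dtype=int)
    for c in (1, 2, 3):
        try:
            report.auc[c] = roc_auc_ovr(all_true, all_probs, c)
        except UndefinedMetricError:
            report.auc[c] = None
    return report
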