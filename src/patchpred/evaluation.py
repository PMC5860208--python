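"""Binary-classification performance measures.

Six measures are reported: accuracy, precision, specificity, sensitivity,
Matthews' correlation coefficient and the F-measure.  At patch level the
unlabelled rim (U) patches are excluded from scoring; at residue level every
surface residue counts, including the low-accessibility ones that are forced
non-interface.  Any measure with a zero denominator is undefined and reported
as NA, never as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    level: str = "patch"  # patch | residue

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    acc: float | None
    prec: float | None
    spec: float | None
    sens: float | None
    mcc: float | None
    f: float | None

    def as_dict(self) -> dict:
        return {
            "acc": self.acc, "prec": self.prec, "spec": self.spec,
            "sens": self.sens, "mcc": self.mcc, "f": self.f,
        }

    def __str__(self) -> str:
        def fmt(v):
            return "NA" if v is None else f"{v:.3f}"
        d = self.as_dict()
        return "  ".join(f"{k.upper()}={fmt(v)}" for k, v in d.items())


def confusion(
    predictions: dict,
    truth: dict,
    level: str = "patch",
    exclude_truth: tuple = ("U",),
) -> ConfusionCounts:
    """Tally the four outcomes over identically keyed predictions and truth.

    Labels are truthy = positive (interface).  At patch level, keys whose true
    label is in ``exclude_truth`` (the rim class U by default) are skipped.
    """
    counts = ConfusionCounts(level=level)
    for key, pred in predictions.items():
        if key not in truth:
            raise KeyError(f"prediction key {key!r} missing from truth")
        true = truth[key]
        if level == "patch" and true in exclude_truth:
            continue
        p = pred in ("I", "interface", 1, True)
        t = true in ("I", "interface", 1, True)
        if p and t:
            counts.tp += 1
        elif p and not t:
            counts.fp += 1
        elif not p and t:
            counts.fn += 1
        else:
            counts.tn += 1
    if counts.total == 0:
        warnings.warn("no scoreable cases (all excluded?)")
    return counts


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """The six measures; zero-denominator cases come back as None (NA)."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.total

    def ratio(num, den):
        return None if den == 0 else num / den

    acc = ratio(tp + tn, n)
    prec = ratio(tp, tp + fp)
    spec = ratio(tn, tn + fp)
    sens = ratio(tp, tp + fn)
    f = None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f = 2.0 * prec * sens / (prec + sens)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if mcc_den == 0 else (tp * tn - fp * fn) / math.sqrt(mcc_den)
    return MetricsReport(acc=acc, prec=prec, spec=spec, sens=sens, mcc=mcc, f=f)


def report_to_tsv(report: MetricsReport) -> str:
    d = report.as_dict()
    head = "\t".join(k.upper() for k in d)
    vals = "\t".join("NA" if v is None else f"{v:.6f}" for v in d.values())
    return head + "\n" + vals + "\n"
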