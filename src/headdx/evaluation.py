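"""Diagnostic-accuracy evaluation: multi-class agreement tables and
per-class accuracy indices.

Per-class indices come from the one-vs-rest collapse of the 13-class
agreement table (rows = system diagnosis, columns = reference/expert
diagnosis): sensitivity tp/(tp+fn), specificity tn/(tn+fp), predictive
values, Youden index, and a binary one-vs-rest Cohen's kappa
``(po - pe)/(1 - pe)``.

Two rate conventions are emitted side by side. The validation study
tabulates a "false negative rate" equal to ``1 - NPV`` and a "false
positive rate" equal to ``1 - PPV``; these nonstandard definitions are
reproduced verbatim under the explicit names ``fnr_paper``/``fpr_paper``,
while the textbook complements of sensitivity and specificity are reported
as ``fnr_standard``/``fpr_standard``.

The two published agreement matrices ship as packaged fixtures. Their
marginals and diagonal cells are exact (every published index depends only
on those); the off-diagonal cells are a constrained reconstruction and are
flagged as such in the fixture metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .records import DiagnosisLabel

__all__ = [
    "ConfusionMatrix", "ClassStats", "FixtureCorruptionError",
    "confusion_matrix", "collapse_binary", "class_stats", "cohens_kappa",
    "load_fixture", "accuracy_report", "format_report", "FIXTURE_NAMES",
]

ALL_CLASSES: tuple[DiagnosisLabel, ...] = tuple(DiagnosisLabel)

MIGRAINE_GROUP = (DiagnosisLabel.MO, DiagnosisLabel.MA, DiagnosisLabel.PM,
                  DiagnosisLabel.CM)
TTH_GROUP = (DiagnosisLabel.iETTH, DiagnosisLabel.fETTH, DiagnosisLabel.PTTH,
             DiagnosisLabel.CTTH)


class FixtureCorruptionError(RuntimeError):
    pass


@dataclass(frozen=True)
class ConfusionMatrix:
    """rows = system (index i), columns = reference (index j)"""

    classes: tuple[DiagnosisLabel, ...]
    counts: np.ndarray
    meta: dict = dc_field(default_factory=dict, compare=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be a classes x classes grid")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("empty agreement table")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def index(self, cls: DiagnosisLabel) -> int:
        return self.classes.index(cls)

    def to_frame(self) -> pd.DataFrame:
        names = [c.value for c in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(pred: Sequence[DiagnosisLabel],
                     ref: Sequence[DiagnosisLabel],
                     classes: Sequence[DiagnosisLabel] = ALL_CLASSES,
                     ) -> ConfusionMatrix:
    if len(pred) != len(ref) or not pred:
        raise ValueError("pred and ref must be equal-length, non-empty")
    classes = tuple(classes)
    pos = {cls: i for i, cls in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, r in zip(pred, ref):
        if p not in pos or r not in pos:
            raise ValueError(f"label outside class list: {p!r}/{r!r}")
        counts[pos[p], pos[r]] += 1
    return ConfusionMatrix(classes, counts)


def collapse_binary(cm: ConfusionMatrix, cls: DiagnosisLabel,
                    ) -> tuple[int, int, int, int]:
    """One-vs-rest 2x2 collapse: (tp, fp, fn, tn)."""
    i = cm.index(cls)
    tp = int(cm.counts[i, i])
    fp = int(cm.counts[i, :].sum()) - tp
    fn = int(cm.counts[:, i].sum()) - tp
    tn = cm.n - tp - fp - fn
    return tp, fp, fn, tn


def cohens_kappa(tp: int, fp: int, fn: int, tn: int) -> Optional[float]:
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fn + tn) * (fp + tn)) / n ** 2
    if pe == 1.0:
        return None
    return (po - pe) / (1 - pe)


@dataclass(frozen=True)
class ClassStats:
    cls: DiagnosisLabel
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    youden: Optional[float]
    fnr_paper: Optional[float]   # 1 - NPV, the published convention
    fpr_paper: Optional[float]   # 1 - PPV, the published convention
    fnr_standard: Optional[float]
    fpr_standard: Optional[float]
    kappa: Optional[float]
    po: float
    pe: float
    ci_sensitivity: Optional[tuple[float, float]]
    ci_specificity: Optional[tuple[float, float]]
    ci_ppv: Optional[tuple[float, float]]
    ci_npv: Optional[tuple[float, float]]
    ci_kappa: Optional[tuple[float, float]]
    undefined: dict[str, str] = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        out = {"class": self.cls.value, "tp": self.tp, "fp": self.fp,
               "fn": self.fn, "tn": self.tn}
        for name in ("sensitivity", "specificity", "ppv", "npv", "youden",
                     "fnr_paper", "fpr_paper", "fnr_standard", "fpr_standard",
                     "kappa", "po", "pe"):
            out[name] = getattr(self, name)
        for name in ("ci_sensitivity", "ci_specificity", "ci_ppv", "ci_npv",
                     "ci_kappa"):
            ci = getattr(self, name)
            out[name] = None if ci is None else list(ci)
        if self.undefined:
            out["undefined"] = dict(self.undefined)
        return out


_CI_METHODS = {"clopper_pearson": "beta", "wilson": "wilson"}


def _proportion(num: int, den: int, name: str, undefined: dict,
                ci_method: str) -> tuple[Optional[float], Optional[tuple]]:
    if den == 0:
        undefined[name] = "undefined: empty denominator (0/0)"
        return None, None
    lo, hi = proportion_confint(num, den, alpha=0.05,
                                method=_CI_METHODS[ci_method])
    return num / den, (float(lo), float(hi))


def class_stats(cm: ConfusionMatrix, cls: DiagnosisLabel,
                ci_method: str = "clopper_pearson") -> ClassStats:
    """All per-class accuracy indices for one diagnosis.

    Cells with an empty denominator are reported as undefined with a reason
    rather than as NaN. Proportion intervals are exact (Clopper-Pearson) by
    default; the kappa interval is the asymptotic normal one.
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    tp, fp, fn, tn = collapse_binary(cm, cls)
    n = cm.n
    undefined: dict[str, str] = {}
    sens, ci_sens = _proportion(tp, tp + fn, "sensitivity", undefined, ci_method)
    spec, ci_spec = _proportion(tn, tn + fp, "specificity", undefined, ci_method)
    ppv, ci_ppv = _proportion(tp, tp + fp, "ppv", undefined, ci_method)
    npv, ci_npv = _proportion(tn, tn + fn, "npv", undefined, ci_method)
    youden = None if sens is None or spec is None else sens + spec - 1
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (fn + tn) * (fp + tn)) / n ** 2
    kappa = cohens_kappa(tp, fp, fn, tn)
    if kappa is None:
        undefined["kappa"] = "undefined: expected agreement is 1"
        ci_kappa = None
    else:
        se = math.sqrt(po * (1 - po) / n) / (1 - pe) if pe < 1 else float("nan")
        ci_kappa = (max(-1.0, kappa - 1.96 * se), min(1.0, kappa + 1.96 * se))
    return ClassStats(
        cls=cls, tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, youden=youden,
        fnr_paper=None if npv is None else 1 - npv,
        fpr_paper=None if ppv is None else 1 - ppv,
        fnr_standard=None if sens is None else 1 - sens,
        fpr_standard=None if spec is None else 1 - spec,
        kappa=kappa, po=po, pe=pe,
        ci_sensitivity=ci_sens, ci_specificity=ci_spec,
        ci_ppv=ci_ppv, ci_npv=ci_npv, ci_kappa=ci_kappa,
        undefined=undefined)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("table2_comparisonA", "table4_comparisonB")

# integrity constants: (n, row totals, column totals, diagonal)
_FIXTURE_CHECKS = {
    "table2_comparisonA": (
        531,
        (116, 38, 91, 11, 11, 38, 68, 24, 10, 5, 28, 26, 65),
        (129, 32, 95, 10, 11, 45, 60, 25, 9, 5, 29, 45, 36),
        (115, 32, 77, 10, 11, 36, 53, 23, 8, 5, 28, 26, 36),
    ),
    "table4_comparisonB": (
        531,
        (116, 38, 91, 11, 11, 38, 68, 24, 10, 5, 28, 26, 65),
        (146, 26, 85, 10, 9, 44, 59, 23, 9, 5, 33, 50, 32),
        (111, 25, 64, 9, 8, 32, 47, 22, 7, 4, 28, 24, 30),
    ),
}


def load_fixture(name: str) -> ConfusionMatrix:
    """One of the packaged 531-patient agreement matrices.

    ``table2_comparisonA``: system versus the expert reference made from the
    auto-generated report alone. ``table4_comparisonB``: system versus the
    expert reference that also used outpatient medical records. Marginals
    and diagonals are verified against embedded integrity constants on
    every load.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    text = resources.files("headdx.data").joinpath(f"{name}.csv").read_text()
    lines = [line.split(",") for line in text.strip().splitlines()]
    header = [DiagnosisLabel(tok) for tok in lines[0][1:]]
    counts = np.array([[int(x) for x in row[1:]] for row in lines[1:]], dtype=int)
    cm = ConfusionMatrix(tuple(header), counts, meta={
        "fixture": name,
        "offdiagonal": "reconstructed under exact marginal/diagonal constraints",
    })
    n, rows, cols, diag = _FIXTURE_CHECKS[name]
    if (cm.n != n
            or tuple(cm.counts.sum(axis=1)) != rows
            or tuple(cm.counts.sum(axis=0)) != cols
            or tuple(np.diag(cm.counts)) != diag):
        raise FixtureCorruptionError(f"fixture {name} failed integrity check")
    return cm


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def _group_rate(cm: ConfusionMatrix, group: Sequence[DiagnosisLabel]) -> dict:
    correct = sum(int(cm.counts[cm.index(c), cm.index(c)]) for c in group)
    total = sum(int(cm.counts[:, cm.index(c)].sum()) for c in group)
    return {"correct": correct, "total": total,
            "rate": None if total == 0 else correct / total}


def accuracy_report(cm: ConfusionMatrix,
                    ci_method: str = "clopper_pearson") -> dict:
    """Per-class indices plus grouped recognition rates (exact-subtype
    matches over the reference group totals) as a JSON-ready dict."""
    per_class = {cls.value: class_stats(cm, cls, ci_method).as_dict()
                 for cls in cm.classes}
    return {
        "n": cm.n,
        "classes": [c.value for c in cm.classes],
        "per_class": per_class,
        "groups": {
            "migraine": _group_rate(cm, [c for c in MIGRAINE_GROUP
                                         if c in cm.classes]),
            "tension_type": _group_rate(cm, [c for c in TTH_GROUP
                                             if c in cm.classes]),
        },
        "meta": dict(cm.meta),
    }


_ROWS = (("Sensitivity", "sensitivity"), ("Specificity", "specificity"),
         ("PPV", "ppv"), ("NPV", "npv"), ("Youden index", "youden"),
         ("False negative rate (1-NPV)", "fnr_paper"),
         ("False positive rate (1-PPV)", "fpr_paper"),
         ("Cohen's kappa", "kappa"))


def format_report(report: dict, classes: Sequence[str] | None = None) -> str:
    """Human-readable table of the main indices."""
    classes = list(classes or report["classes"])
    width = max(len(name) for name, _ in _ROWS) + 2
    head = " " * width + " ".join(f"{c:>9}" for c in classes)
    lines = [f"n = {report['n']}", head]
    for name, key in _ROWS:
        cells = []
        for c in classes:
            value = report["per_class"][c][key]
            cells.append("      nan" if value is None else f"{value:9.4f}")
        lines.append(f"{name:<{width}}" + " ".join(cells))
    for gname, g in report["groups"].items():
        if g["rate"] is not None:
            lines.append(f"{gname} group: {g['correct']}/{g['total']} "
                         f"({100 * g['rate']:.2f}%)")
    return "\n".join(lines)
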