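"""Hold-out evaluation of verdicts against truth and an external predictor.

Verdicts are three-way (pathogenic / uncertain / benign); ground truth is
binary (pathogenic / benign).  The confusion table is therefore 2 x 3.
Reported metrics follow the conventions that reproduce the published worked
numbers:

* accuracy — correct pathogenic + correct benign over the total, with
  uncertain verdicts counted as incorrect;
* weighted F1 — support-weighted mean of the per-class F1 scores, with an
  uncertain verdict counted as a misclassification of the true class;
* MCC — Matthews correlation of the binarized calls.  The treatment of
  uncertain verdicts is not uniquely determined by published tables, so it
  is selectable: ``uncertain-as-benign`` (default: an uncertain verdict is a
  non-pathogenic call) or ``uncertain-as-pathogenic``; both are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

TRUTH_CLASSES = ("pathogenic", "benign")
VERDICT_CLASSES = ("pathogenic", "uncertain", "benign")
MCC_CONVENTIONS = ("uncertain-as-benign", "uncertain-as-pathogenic")

__all__ = [
    "ConfusionTable",
    "MetricReport",
    "holdout_split",
    "build_confusion",
    "compute_metrics",
    "read_predictor_table",
    "stratified_compare",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2 x 3 counts: rows = truth (pathogenic, benign), columns = verdict
    (pathogenic, uncertain, benign)."""

    values: tuple[tuple[int, int, int], tuple[int, int, int]]

    def __post_init__(self) -> None:
        for row in self.values:
            if any(v < 0 for v in row):
                raise ValueError("negative confusion cell")

    @property
    def n_total(self) -> int:
        return sum(sum(r) for r in self.values)

    @property
    def n_pathogenic(self) -> int:
        return sum(self.values[0])

    @property
    def n_benign(self) -> int:
        return sum(self.values[1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.values), index=list(TRUTH_CLASSES), columns=list(VERDICT_CLASSES)
        )


@dataclass
class MetricReport:
    accuracy: float
    weighted_f1: float
    mcc: float | None
    mcc_by_convention: dict[str, float | None]
    per_class: dict[str, dict[str, float]]
    n_total: int
    n_pathogenic: int
    n_benign: int
    stratification: str = "all"

    def __post_init__(self) -> None:
        if not (0.0 <= self.accuracy <= 1.0 and 0.0 <= self.weighted_f1 <= 1.0):
            raise ValueError("accuracy and F1 must lie in [0, 1]")
        if self.mcc is not None and not -1.0 <= self.mcc <= 1.0 + 1e-12:
            raise ValueError("MCC must lie in [-1, 1]")


def holdout_split(
    variants: Sequence, labels: Sequence[str], fraction: float = 0.2, seed: int = 0
) -> tuple[list, list]:
    """Stratified (working, evaluation) split, reproducible from the seed.

    Per truth class, floor(n * fraction) members are held out.  Held-out
    variants must not contribute to matrix building.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if len(variants) != len(labels):
        raise ValueError("variants and labels differ in length")
    for cls in TRUTH_CLASSES:
        if labels and cls not in labels:
            warnings.warn(f"class {cls!r} has no members; split proceeds without it")
    rng = np.random.default_rng(seed)
    held: set[int] = set()
    for cls in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        k = int(len(idx) * fraction)
        held.update(rng.choice(idx, size=k, replace=False).tolist())
    working = [v for i, v in enumerate(variants) if i not in held]
    evaluation = [v for i, v in enumerate(variants) if i in held]
    return working, evaluation


def build_confusion(
    verdicts: Mapping[object, str], truths: Mapping[object, str]
) -> ConfusionTable:
    """Count (truth, verdict) pairs over the evaluation variants.

    Every truth-labeled variant must carry a verdict (uncertain allowed).
    """
    counts = [[0, 0, 0], [0, 0, 0]]
    for key, truth in truths.items():
        if truth not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth label {truth!r}")
        if key not in verdicts:
            raise ValueError(f"variant {key!r} has no verdict")
        verdict = verdicts[key]
        if verdict not in VERDICT_CLASSES:
            raise ValueError(f"unknown verdict {verdict!r}")
        counts[TRUTH_CLASSES.index(truth)][VERDICT_CLASSES.index(verdict)] += 1
    return ConfusionTable(values=tuple(tuple(r) for r in counts))


def _binary_mcc(tp: int, fp: int, fn: int, tn: int) -> float | None:
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return None
    return (tp * tn - fp * fn) / denom


def compute_metrics(
    confusion: ConfusionTable,
    mcc_convention: str = "uncertain-as-benign",
    stratification: str = "all",
) -> MetricReport:
    """Accuracy, weighted F1 and MCC from a 2 x 3 confusion table.

    Uncertain verdicts count as incorrect for accuracy and as
    misclassifications of the true class for the per-class F1 scores.  MCC
    binarizes the verdicts under the selected uncertain-handling convention;
    the value under every convention is also reported.
    """
    (pp, pu, pb), (bp, bu, bb) = confusion.values
    n = confusion.n_total
    if n == 0:
        raise ValueError("empty confusion table")
    accuracy = (pp + bb) / n

    # Per-class precision/recall/F1; uncertain verdicts are errors and do
    # not count toward any predicted class.
    per_class: dict[str, dict[str, float]] = {}
    f1s, supports = [], []
    for cls, tp, fp, fn, support in [
        ("pathogenic", pp, bp, pu + pb, confusion.n_pathogenic),
        ("benign", bb, pb, bp + bu, confusion.n_benign),
    ]:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
        f1s.append(f1)
        supports.append(support)
    weighted_f1 = (
        sum(f * s for f, s in zip(f1s, supports)) / sum(supports) if sum(supports) else 0.0
    )

    mcc_by: dict[str, float | None] = {}
    for convention in MCC_CONVENTIONS:
        if convention == "uncertain-as-benign":
            tp, fn = pp, pu + pb
            fp, tn = bp, bu + bb
        else:
            tp, fn = pp + pu, pb
            fp, tn = bp + bu, bb
        mcc_by[convention] = _binary_mcc(tp, fp, fn, tn)
    if mcc_convention not in MCC_CONVENTIONS:
        raise ValueError(f"unknown MCC convention {mcc_convention!r}")

    return MetricReport(
        accuracy=accuracy,
        weighted_f1=weighted_f1,
        mcc=mcc_by[mcc_convention],
        mcc_by_convention=mcc_by,
        per_class=per_class,
        n_total=n,
        n_pathogenic=confusion.n_pathogenic,
        n_benign=confusion.n_benign,
        stratification=stratification,
    )


PREDICTOR_CLASS_MAP = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "pathogenic",
    "ambiguous": "uncertain",
    "uncertain": "uncertain",
    "benign": "benign",
    "likely benign": "benign",
}


def read_predictor_table(path) -> pd.DataFrame:
    """External predictor TSV: protein_id, position, ref_aa, alt_aa,
    predictor_class[, predictor_score]; classes mapped onto the three-way
    verdict vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    df["verdict"] = [
        PREDICTOR_CLASS_MAP[str(c).strip().lower()] for c in df["predictor_class"]
    ]
    return df


def stratified_compare(
    verdicts_by_method: Mapping[str, Mapping[object, str]],
    truths: Mapping[object, str],
    position_kinds: Mapping[object, str],
    mcc_convention: str = "uncertain-as-benign",
) -> dict[tuple[str, str], MetricReport]:
    """Metrics per method per position stratum (all / rigid / flexible).

    *position_kinds* labels every evaluation variant rigid or flexible from
    its motif position's pattern typing; a missing annotation is an error.
    A stratum holding a single truth class flags MCC as undefined while
    still reporting accuracy.
    """
    for key in truths:
        if key not in position_kinds:
            raise ValueError(f"variant {key!r} lacks a rigid/flexible annotation")
        if position_kinds[key] not in ("rigid", "flexible"):
            raise ValueError(f"bad position kind {position_kinds[key]!r}")
    out: dict[tuple[str, str], MetricReport] = {}
    for method, verdicts in verdicts_by_method.items():
        for stratum in ("all", "rigid", "flexible"):
            sub = {
                k: t
                for k, t in truths.items()
                if stratum == "all" or position_kinds[k] == stratum
            }
            if not sub:
                continue
            table = build_confusion(verdicts, sub)
            out[(method, stratum)] = compute_metrics(
                table, mcc_convention=mcc_convention, stratification=stratum
            )
    return out
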