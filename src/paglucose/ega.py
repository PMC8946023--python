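"""Clarke error-grid analysis and the clinical-accuracy post-processing.

Clarke's EGA partitions (reference, predicted) glucose pairs into five
zones: A (clinically accurate, within 20 % or both hypoglycemic), B (benign
deviation), C (over-correction), D (detection failure), E (erroneous,
opposite-extreme treatment).  Regulatory practice for glucose monitors
requires at least 99 % of predictions in zones A and B.

The zone boundaries follow the original piecewise formulation as commonly
implemented; points exactly on a boundary are assigned to the lower-risk
zone (A over B, B over C/D, D over E) so that the assignment is
deterministic and testable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EgaPoint",
    "EgaSummary",
    "clarke_zone",
    "confusion_to_ega",
    "majority_vote",
    "fda_check",
    "summarize_points",
    "plot_ega",
]

ZONES = ("A", "B", "C", "D", "E")


@dataclass(frozen=True)
class EgaPoint:
    """One (reference, predicted) glucose pair with a multiplicity count."""

    reference: float
    predicted: float
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.reference <= 0 or self.predicted <= 0:
            raise ValueError("glucose values must be positive")
        if self.multiplicity < 0:
            raise ValueError("multiplicity must be non-negative")


@dataclass(frozen=True)
class EgaSummary:
    """Zone counts/percentages and the >=99 % A∪B regulatory flag."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int
    fda_pass: bool

    def __post_init__(self) -> None:
        if set(self.counts) != set(ZONES) or set(self.percentages) != set(ZONES):
            raise ValueError("summary must cover zones A-E")
        if self.total > 0 and abs(sum(self.percentages.values()) - 100.0) > 1e-9:
            raise ValueError("zone percentages must sum to 100")


def clarke_zone(reference: float, predicted: float) -> str:
    """Clarke zone of a (reference, predicted) pair, in mg/dL.

    Zone A: within 20 % of the reference, or both values hypoglycemic
    (< 70).  Zone E: opposite-extreme errors.  Zones C and D per the
    published over-correction and detection-failure regions; everything else
    is zone B.
    """
    r, p = float(reference), float(predicted)
    if r <= 0 or p <= 0:
        raise ValueError("glucose values must be positive")
    if abs(p - r) <= 0.2 * r or (r < 70 and p < 70):
        return "A"
    if (r >= 180 and p <= 70) or (r <= 70 and p >= 180):
        return "E"
    if (70 <= r <= 290 and p >= r + 110) or (130 <= r <= 180 and p <= 7 * r / 5 - 182):
        return "C"
    if (r >= 240 and 70 <= p <= 180) or (r <= 175 / 3 and 70 <= p <= 180) or (
        175 / 3 <= r <= 70 and p >= 6 * r / 5
    ):
        return "D"
    return "B"


def summarize_points(points: list[EgaPoint]) -> EgaSummary:
    """Zone counts/percentages over a weighted point set."""
    counts = {z: 0 for z in ZONES}
    for pt in points:
        counts[clarke_zone(pt.reference, pt.predicted)] += pt.multiplicity
    total = sum(counts.values())
    if total == 0:
        pct = {z: 0.0 for z in ZONES}
        return EgaSummary(counts=counts, percentages=pct, total=0, fda_pass=False)
    pct = {z: 100.0 * counts[z] / total for z in ZONES}
    return EgaSummary(
        counts=counts,
        percentages=pct,
        total=total,
        fda_pass=pct["A"] + pct["B"] >= 99.0,
    )


def confusion_to_ega(
    confusion: np.ndarray, class_values
) -> tuple[list[EgaPoint], EgaSummary]:
    """Convert a confusion matrix into weighted EGA points and a zone summary.

    Cell (i, j) with count n becomes the point
    ``(reference=class_values[i], predicted=class_values[j])`` with
    multiplicity n, so the total EGA mass equals the confusion mass.
    """
    confusion = np.asarray(confusion)
    values = np.asarray(class_values, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square")
    if confusion.shape[0] != len(values):
        raise ValueError("class_values length must match the matrix dimension")
    if np.any(np.diff(values) <= 0):
        raise ValueError("class_values must be strictly ascending")
    points = [
        EgaPoint(reference=values[i], predicted=values[j], multiplicity=int(n))
        for i in range(len(values))
        for j in range(len(values))
        if (n := confusion[i, j]) > 0
    ]
    return points, summarize_points(points)


def majority_vote(predictions, group_keys) -> dict:
    """Modal predicted label per group of repeated predictions.

    Ties resolve to the tied label closest to the group's median predicted
    value, then to the lower concentration.
    """
    preds = np.asarray(predictions, dtype=float)
    if len(preds) != len(group_keys):
        raise ValueError("predictions and group_keys must align")
    if len(preds) == 0:
        raise ValueError("empty prediction set")
    out: dict = {}
    frame = pd.DataFrame({"pred": preds, "group": list(group_keys)})
    for group, sub in frame.groupby("group", sort=False):
        votes = Counter(sub["pred"])
        top = max(votes.values())
        tied = sorted(label for label, n in votes.items() if n == top)
        if len(tied) == 1:
            out[group] = tied[0]
        else:
            med = float(np.median(sub["pred"]))
            out[group] = min(tied, key=lambda lab: (abs(lab - med), lab))
    return out


def fda_check(summary: EgaSummary) -> tuple[bool, str]:
    """Regulatory criterion: >= 99 % of points in zones A and B."""
    ab = summary.percentages["A"] + summary.percentages["B"]
    flag = ab >= 99.0
    verdict = "PASS" if flag else "FAIL"
    line = (
        f"zones A+B = {ab:.2f}% "
        f"(A {summary.percentages['A']:.2f}%, B {summary.percentages['B']:.2f}%): "
        f"{verdict} (criterion: >= 99% in A and B)"
    )
    return flag, line


def plot_ega(points: list[EgaPoint], path=None, title: str = "Clarke error grid"):
    """Scatter the EGA points with zone boundary overlays (optional export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    lim = 400
    ax.plot([0, lim], [0, lim], "k:", lw=0.8)
    ax.plot([0, lim], [0, 1.2 * lim], "k-", lw=0.6)
    ax.plot([0, lim], [0, 0.8 * lim], "k-", lw=0.6)
    refs = [p.reference for p in points]
    pred = [p.predicted for p in points]
    size = [12 + 3 * p.multiplicity for p in points]
    ax.scatter(refs, pred, s=size, c="tab:blue", alpha=0.7, edgecolors="none")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference glucose (mg/dL)")
    ax.set_ylabel("predicted glucose (mg/dL)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
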