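"""Ranking and calibration metrics for scored edge sets.

AUROC uses the Mann-Whitney convention (ties get half credit); AUPRC is
average precision with step interpolation (trapezoidal PR interpolation
overestimates and is deliberately not used). Calibration is summarized by the
Brier score, the mean squared error between predicted probabilities and
binary outcomes, and by a reliability table of equal-width probability bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "auroc",
    "auprc",
    "brier_score",
    "reliability_curve",
    "EvalReport",
    "evaluate",
    "plot_reliability_diagram",
]


def _validate(scores, labels):
    s = np.asarray(scores, dtype=np.float64).ravel()
    y = np.asarray(labels).ravel().astype(np.int64)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if s.size == 0:
        raise ValueError("empty input")
    return s, y


def auroc(scores, labels) -> float:
    """P(score+ > score-) + 0.5 P(score+ = score-) over pos/neg pairs."""
    s, y = _validate(scores, labels)
    if y.min() == y.max():
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(y, s))


def auprc(scores, labels) -> float:
    """Average precision: sum_k (R_k - R_{k-1}) P_k over descending thresholds."""
    s, y = _validate(scores, labels)
    if y.sum() == 0:
        raise ValueError("AUPRC undefined: no positives")
    return float(average_precision_score(y, s))


def brier_score(probabilities, labels) -> float:
    """Mean squared error of predicted probability vs binary outcome."""
    p, y = _validate(probabilities, labels)
    return float(np.mean((p - y) ** 2))


def reliability_curve(probabilities, labels, n_bins: int = 10) -> list[dict]:
    """Per-bin (mean predicted probability, positive fraction, count).

    Probabilities fall into ``n_bins`` equal-width bins over [0, 1]; each bin
    is right-closed except the first, which also includes 0. Empty bins are
    omitted. Deviation of the positive fraction from the mean prediction
    measures miscalibration (the reliability-diagram diagonal is perfect).
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    p, y = _validate(probabilities, labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins: bin b covers (edges[b], edges[b+1]], first includes 0
    idx = np.clip(np.ceil(p * n_bins).astype(int) - 1, 0, n_bins - 1)
    table = []
    for b in range(n_bins):
        member = idx == b
        count = int(member.sum())
        if count == 0:
            continue
        table.append(
            {
                "bin_lower": float(edges[b]),
                "bin_upper": float(edges[b + 1]),
                "mean_predicted": float(p[member].mean()),
                "positive_fraction": float(y[member].mean()),
                "count": count,
            }
        )
    return table


@dataclass
class EvalReport:
    """Ranking + calibration summary for one scored edge set."""

    auprc: float
    auroc: float
    brier: float
    n_pairs: int
    reliability: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auprc": self.auprc,
            "auroc": self.auroc,
            "brier": self.brier,
            "n_pairs": self.n_pairs,
            "reliability": self.reliability,
        }


def evaluate(probabilities, labels, n_bins: int = 10) -> EvalReport:
    """Full report: AUPRC, AUROC, Brier score and a reliability table."""
    p, y = _validate(probabilities, labels)
    return EvalReport(
        auprc=auprc(p, y),
        auroc=auroc(p, y),
        brier=brier_score(p, y),
        n_pairs=int(p.size),
        reliability=reliability_curve(p, y, n_bins=n_bins),
    )


def plot_reliability_diagram(report: EvalReport, path: str) -> None:
    """Write a reliability diagram (positive fraction vs mean prediction)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    xs = [row["mean_predicted"] for row in report.reliability]
    ys = [row["positive_fraction"] for row in report.reliability]
    ax.plot(xs, ys, "o-", label=f"Brier = {report.brier:.3f}")
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("fraction of positives")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
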