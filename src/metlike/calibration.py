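"""ROC analysis and Youden-index threshold calibration.

All (drug, enzyme) relations over the gold-standard enzymes are scored by
the drug's maximal similarity to the enzyme's gold-standard substrates and
labelled positive iff the relation is itself in the gold standard.  The
similarity score then acts as a binary classifier (score >= t predicts
"modulator"); sweeping t over every observed score yields the ROC curve,
and the optimal operating threshold maximises Youden's index

    J(x) = Sp(x) + Se(x) - 1 = tpr(x) - fpr(x),

which weighs sensitivity and specificity equally.  On a J tie the higher
(more specific) threshold is chosen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .goldstandard import GSPRelation, UnknownCompoundError
from .simmatrix import SimilarityMatrix


class SingleClassError(ValueError):
    """ROC needs at least one positive and one negative label."""


@dataclass(frozen=True)
class LabeledScore:
    """One drug-enzyme relation with its score and gold-standard label."""

    drug_id: str
    enzyme_label: str
    score: float
    label: bool

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class ROCCurve:
    """Step-function ROC over every distinct score plus a top sentinel."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass
class YoudenProfile:
    """J(x) per threshold and the maximising operating point."""

    thresholds: np.ndarray
    j_values: np.ndarray
    optimal_threshold: float
    j_max: float


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's index J = Sp + Se - 1 at one operating point."""
    return sensitivity + specificity - 1.0


def label_relations(
    m: SimilarityMatrix,
    gsp: Sequence[GSPRelation],
    enzymes=None,
) -> list[LabeledScore]:
    """Score and label every (drug, gold-standard enzyme) relation.

    For each enzyme appearing in the gold standard, every drug of the
    matrix is scored by its maximal similarity over that enzyme's
    gold-standard substrates; the label is true iff (drug, enzyme) is a
    gold-standard relation.  Output is sorted by descending score with a
    deterministic tie-break (drug id, then enzyme label, ascending).

    ``enzymes`` (optional EnzymeRecords) only cross-checks that each
    gold-standard substrate is listed for its enzyme.
    """
    subs_by_enzyme: dict[str, set[str]] = {}
    positives: set[tuple[str, str]] = set()
    for r in gsp:
        subs_by_enzyme.setdefault(r.enzyme_label, set()).add(r.substrate_id)
        positives.add((r.drug_id, r.enzyme_label))

    if enzymes is not None:
        listed = {e.label: set(e.substrate_ids) for e in enzymes}
        for label, subs in subs_by_enzyme.items():
            unknown = subs - listed.get(label, set())
            if unknown:
                raise UnknownCompoundError(
                    f"substrates {sorted(unknown)} not listed for enzyme "
                    f"{label!r}"
                )

    for label, subs in subs_by_enzyme.items():
        for s in subs:
            if not m.has_metabolite(s):
                raise UnknownCompoundError(
                    f"gold-standard substrate {s!r} of {label!r} not in matrix"
                )

    scored = []
    for enzyme_label in sorted(subs_by_enzyme):
        subs = sorted(subs_by_enzyme[enzyme_label])
        block = np.column_stack([m.column(s) for s in subs]).max(axis=1)
        for drug_id, score in zip(m.drug_ids, block):
            scored.append(
                LabeledScore(
                    drug_id=drug_id,
                    enzyme_label=enzyme_label,
                    score=float(score),
                    label=(drug_id, enzyme_label) in positives,
                )
            )
    scored.sort(key=lambda s: (-s.score, s.drug_id, s.enzyme_label))
    return scored


def roc_curve(scores: Sequence[LabeledScore]) -> ROCCurve:
    """ROC over the threshold sweep of every distinct observed score.

    The classifier at threshold t predicts positive iff score >= t; the
    threshold grid is every distinct score plus a sentinel above the
    maximum, so the curve is the exact step function (no binning).  AUC is
    the trapezoidal area, which equals the Mann-Whitney concordant-pair
    statistic.
    """
    y = np.array([s.label for s in scores], dtype=bool)
    x = np.array([s.score for s in scores], dtype=float)
    if y.all() or not y.any():
        raise SingleClassError("need both positive and negative labels")
    fpr, tpr, thr = _skm.roc_curve(y, x, drop_intermediate=False)
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr,
                    auc=float(_skm.auc(fpr, tpr)))


def youden_optimal(roc: ROCCurve) -> YoudenProfile:
    """Youden profile of a ROC curve and its maximising threshold.

    ``j_values[i] = tpr[i] - fpr[i]``; ties on J resolve to the highest
    threshold (thresholds are stored in descending order, so the first
    argmax is the most specific operating point).
    """
    j = roc.tpr - roc.fpr
    best = int(np.argmax(j))
    return YoudenProfile(
        thresholds=roc.thresholds,
        j_values=j,
        optimal_threshold=float(roc.thresholds[best]),
        j_max=float(j[best]),
    )


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def roc_table(roc: ROCCurve, youden: YoudenProfile | None = None) -> pd.DataFrame:
    data = {"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}
    if youden is not None:
        data["j"] = youden.j_values
    return pd.DataFrame(data)


def labeled_score_table(scores: Sequence[LabeledScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"drug_id": s.drug_id, "enzyme_label": s.enzyme_label,
          "score": s.score, "label": int(s.label)} for s in scores],
        columns=["drug_id", "enzyme_label", "score", "label"],
    )


def plot_roc(roc: ROCCurve, youden: YoudenProfile, path) -> None:
    """Optional ROC + Youden profile rendering."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ax1.plot(roc.fpr, roc.tpr, drawstyle="steps-post")
    ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax1.set_xlabel("false positive rate")
    ax1.set_ylabel("true positive rate")
    ax1.set_title(f"AUC = {roc.auc:.3f}")
    finite = np.isfinite(youden.thresholds)
    ax2.plot(youden.thresholds[finite], youden.j_values[finite])
    ax2.axvline(youden.optimal_threshold, color="r", ls="--", lw=0.8)
    ax2.set_xlabel("similarity threshold")
    ax2.set_ylabel("Youden's J")
    ax2.set_title(f"J_max = {youden.j_max:.3f} "
                  f"at t = {youden.optimal_threshold:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
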