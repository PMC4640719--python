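"""ROC/AUC validation of inferred links against literature-known positives.

Scores here are shared-neighbor counts, so ties are the rule rather than
the exception: the ROC sweep emits one operating point per distinct score
value, which makes the trapezoidal area identical to the tie-corrected
Mann-Whitney rank statistic.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .inference import (
    MODES,
    Mode,
    ScoringWeights,
    candidate_evidence,
    combined_score,
)
from .netmodel import EntityClass, NodeRef, PharmNetwork

__all__ = [
    "LabeledScore",
    "ROCCurve",
    "NegativePolicy",
    "label_pairs",
    "roc",
    "compare_modes",
    "write_roc",
]

logger = logging.getLogger("herblink.evaluation")

Pair = tuple[NodeRef, NodeRef]
NegativePolicy = Literal["candidates_only", "all_pairs"]


@dataclass(frozen=True)
class LabeledScore:
    pair: Pair
    score: float
    label: bool  # True = known positive


@dataclass(frozen=True)
class ROCCurve:
    """Ordered ROC operating points from (0,0) to (1,1) plus the area under them."""

    points: tuple[tuple[float, float], ...]  # (fpr, tpr)
    thresholds: tuple[float, ...]
    auc: float
    n_pos: int
    n_neg: int


def label_pairs(
    links,
    known: set[Pair],
    policy: NegativePolicy = "candidates_only",
    net: Optional[PharmNetwork] = None,
) -> list[LabeledScore]:
    """Assign positive/negative labels to scored pairs for ROC analysis.

    The universe is restricted to TKMs that have at least one known positive
    (the analysis is only informative for medicines with literature ground
    truth).  Every known pair for such a TKM appears exactly once as a
    positive, with score 0 when it is not an enumerated candidate.
    Negatives are the remaining candidate pairs of those TKMs; under the
    ``all_pairs`` policy, score-0 non-candidate pairs with every network
    protein are added as negatives too.

    ``links`` may be a list of :class:`~herblink.inference.InferredLink` or a
    mapping ``pair -> score``.  Known pairs whose TKM is absent from the
    network (when ``net`` is given) are dropped with a warning.
    """
    if not known:
        raise ValueError("known-positives set is empty")
    if policy not in ("candidates_only", "all_pairs"):
        raise ValueError(f"unknown negative-set policy {policy!r}")
    if policy == "all_pairs" and net is None:
        raise ValueError("policy 'all_pairs' requires the network (protein universe)")

    if isinstance(links, dict):
        scores: dict[Pair, float] = dict(links)
    else:
        scores = {link.pair: link.score for link in links}

    usable_known = set(known)
    if net is not None:
        dropped = {(t, p) for (t, p) in usable_known if t not in net}
        if dropped:
            logger.warning(
                "dropping %d known pair(s) whose TKM is absent from the network", len(dropped)
            )
            usable_known -= dropped
    if not usable_known:
        raise ValueError("no known positive references a TKM present in the network")

    eval_tkms = {t for (t, _) in usable_known}
    labeled: list[LabeledScore] = []
    for pair in sorted(usable_known):
        labeled.append(LabeledScore(pair, scores.get(pair, 0.0), True))
    for pair in sorted(scores):
        if pair[0] in eval_tkms and pair not in usable_known:
            labeled.append(LabeledScore(pair, scores[pair], False))
    if policy == "all_pairs":
        assert net is not None
        candidate_or_known = set(scores) | usable_known
        for tkm in sorted(eval_tkms):
            for protein in net.nodes_of_class(EntityClass.PROTEIN):
                pair = (tkm, protein)
                if pair not in candidate_or_known:
                    labeled.append(LabeledScore(pair, 0.0, False))
    return labeled


def roc(labeled: Sequence[LabeledScore]) -> ROCCurve:
    """ROC curve by descending threshold sweep over distinct scores.

    Tied scores share one operating point; the area is the trapezoidal
    integral, which for this construction equals the tie-corrected
    Mann-Whitney statistic P(S+ > S-) + 0.5 P(S+ = S-).
    """
    y = np.array([ls.label for ls in labeled], dtype=bool)
    s = np.array([ls.score for ls in labeled], dtype=float)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise ValueError(f"ROC undefined: no {missing} examples in the labeled set")
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    return ROCCurve(
        points=tuple(zip(fpr.tolist(), tpr.tolist())),
        thresholds=tuple(thresholds.tolist()),
        auc=area,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def compare_modes(
    net: PharmNetwork,
    known: set[Pair],
    weights: Optional[ScoringWeights] = None,
    policy: NegativePolicy = "candidates_only",
    modes: Sequence[Mode] = MODES,
    min_disease: int = 1,
    min_drug: int = 1,
) -> pd.DataFrame:
    """AUC of each scoring mode on a shared labeled-pair universe.

    For cross-mode comparability the labeled universe is the union of the
    modes' candidate sets, and every mode's scoring function is evaluated on
    every pair of that universe: the disease count, the drug count, or the
    weighted combination.  A pair with no evidence in a channel naturally
    scores 0 there, so every mode sees the same n_pos and n_neg.  The
    two-category retention filter selects the final reported link set (see
    :func:`~herblink.inference.infer_links`); it does not truncate the ROC
    ranking, which orders the whole comparison universe.
    Returns a DataFrame with columns mode, auc, n_pos, n_neg.
    """
    for mode in modes:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    w = weights if weights is not None else ScoringWeights()
    evidence = candidate_evidence(net)
    universe = {
        pair: ev
        for pair, ev in evidence.items()
        if ev.shared_disease_count >= min_disease or ev.shared_drug_count >= min_drug
    }

    rows = []
    for mode in modes:
        if mode == "disease_only":
            scores = {p: float(ev.shared_disease_count) for p, ev in universe.items()}
        elif mode == "drug_only":
            scores = {p: float(ev.shared_drug_count) for p, ev in universe.items()}
        else:
            scores = {p: combined_score(ev, w) for p, ev in universe.items()}
        labeled = label_pairs(scores, known, policy=policy, net=net)
        curve = roc(labeled)
        rows.append(
            {"mode": mode, "auc": curve.auc, "n_pos": curve.n_pos, "n_neg": curve.n_neg}
        )
    return pd.DataFrame(rows, columns=["mode", "auc", "n_pos", "n_neg"])


ROC_COLUMNS = ("threshold", "tp", "fp", "fn", "tn", "tpr", "fpr")


def write_roc(curve: ROCCurve, path: Union[str, Path]) -> None:
    """Write one operating point per row: threshold, confusion counts, rates."""
    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ROC_COLUMNS)
        for (fpr, tpr), thr in zip(curve.points, curve.thresholds):
            tp = round(tpr * curve.n_pos)
            fp = round(fpr * curve.n_neg)
            writer.writerow(
                [
                    f"{thr:g}",
                    tp,
                    fp,
                    curve.n_pos - tp,
                    curve.n_neg - fp,
                    f"{tpr:.6f}",
                    f"{fpr:.6f}",
                ]
            )
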