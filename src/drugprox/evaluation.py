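"""ROC evaluation of predicted associations against a gold standard.

Predictions are ranked by ascending p-value (best first; ties broken by
descending normalized similarity, then lexicographically by pair) and each
pair is labelled 1 if it appears in the gold standard of known drug-disease
associations, 0 otherwise.  Sweeping a p-value threshold down the ranking
traces the ROC curve: TPR is the fraction of known associations recovered,
FPR the fraction of unknown associations admitted.  Equal-score groups
enter the curve together, the convention under which the trapezoidal AUC
equals the normalized Mann-Whitney U statistic (pairwise concordance
probability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["UndefinedROCError", "LabeledRanking", "RocCurve",
           "label_predictions", "roc_curve", "load_gold_standard",
           "write_roc_table"]


class UndefinedROCError(ValueError):
    """Raised when the labelled ranking contains a single class only."""


@dataclass(frozen=True)
class LabeledRanking:
    """Predictions sorted best-first with 0/1 known-association labels.

    ``items`` carries columns drug, disease, p_value, normalized_similarity
    and label, already in ranking order.  ``n_gold_unmatched`` counts gold
    pairs that referenced no prediction (logged, not an error).
    """

    items: pd.DataFrame
    n_gold_unmatched: int = 0

    @property
    def n_known(self) -> int:
        return int(self.items["label"].sum())

    @property
    def n_unknown(self) -> int:
        return int(len(self.items) - self.items["label"].sum())


@dataclass(frozen=True)
class RocCurve:
    """ROC points (starting at (0,0), ending at (1,1)) and trapezoidal AUC.

    ``thresholds`` holds, for every point after the origin, the p-value of
    the group admitted at that point.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def label_predictions(
    predictions: pd.DataFrame, gold_pairs: Iterable[tuple[str, str]]
) -> LabeledRanking:
    """Attach gold-standard labels and sort into ranking order.

    ``predictions`` needs columns drug, disease, p_value; a missing
    normalized_similarity column is treated as all-zero (ties then resolve
    lexicographically).
    """
    if len(predictions) == 0:
        raise ValueError("no predictions to label")
    required = {"drug", "disease", "p_value"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions missing columns {sorted(missing)}")
    df = predictions.copy()
    if "normalized_similarity" not in df.columns:
        df["normalized_similarity"] = 0.0
    gold = {(str(d), str(s)) for d, s in gold_pairs}
    pairs = list(zip(df["drug"].astype(str), df["disease"].astype(str)))
    df["label"] = [int(p in gold) for p in pairs]
    unmatched = gold - set(pairs)
    if unmatched:
        logger.info("%d gold pairs match no prediction", len(unmatched))
    df["_neg_sim"] = -df["normalized_similarity"]
    df = df.sort_values(
        ["p_value", "_neg_sim", "drug", "disease"], kind="mergesort"
    ).drop(columns="_neg_sim").reset_index(drop=True)
    return LabeledRanking(items=df, n_gold_unmatched=len(unmatched))


def roc_curve(ranking: LabeledRanking) -> RocCurve:
    """ROC curve and AUC from a labelled ranking.

    Ties on the composite ranking key (p-value, then similarity) are
    grouped: all equally-ranked items cross the threshold together, so the
    trapezoidal AUC equals the U-statistic concordance probability.
    """
    df = ranking.items
    labels = df["label"].to_numpy()
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError(
            "ROC undefined: ranking must contain both known (1) and unknown "
            f"(0) associations (got {n_pos} known, {n_neg} unknown)"
        )
    keys = list(zip(df["p_value"], -df["normalized_similarity"]))
    # group boundaries: last index of each run of equal keys
    fpr = [0.0]
    tpr = [0.0]
    thresholds = []
    tp = fp = 0
    for i, lab in enumerate(labels):
        if lab:
            tp += 1
        else:
            fp += 1
        if i + 1 == len(labels) or keys[i + 1] != keys[i]:
            fpr.append(fp / n_neg)
            tpr.append(tp / n_pos)
            thresholds.append(df["p_value"].iat[i])
    fpr_arr = np.asarray(fpr)
    tpr_arr = np.asarray(tpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(fpr=fpr_arr, tpr=tpr_arr,
                    thresholds=np.asarray(thresholds), auc=auc)


def load_gold_standard(path: str | Path) -> set[tuple[str, str]]:
    """Read a gold-standard TSV of (drug, disease) pairs with a header row."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (drug, disease)")
    return {
        (str(a).strip(), str(b).strip())
        for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    }


def write_roc_table(roc: RocCurve, path: str | Path) -> None:
    """Export (threshold_p, fpr, tpr) as TSV with a one-line AUC summary."""
    with open(path, "w") as fh:
        fh.write(f"# auc\t{roc.auc:.17g}\n")
        fh.write("threshold_p\tfpr\ttpr\n")
        fh.write(f"\t{roc.fpr[0]:.17g}\t{roc.tpr[0]:.17g}\n")
        for thr, x, y in zip(roc.thresholds, roc.fpr[1:], roc.tpr[1:]):
            fh.write(f"{thr:.17g}\t{x:.17g}\t{y:.17g}\n")
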