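"""Proximity-to-similarity transform, cluster reward, and sigmoid normalization.

Significant proximities are mapped to similarities in [0, 1] by

    similarity = (max(p) - p) / max(p)

so a pair at proximity 0 (targets inside the disease module) scores 1 and
the most distal retained pair scores 0.  Pairs whose drug and disease fall
in the same community of the bipartite association network are rewarded by
the community's quality score QC:

    similarity_adj = (1 + QC) * similarity       (same cluster)
    similarity_adj = similarity                  (different clusters)

and the adjusted scores are squashed onto (0, 1) by the logistic sigmoid

    f(x) = 1 / (1 + exp(-c * (x - d)))

with steepness c and midpoint d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

if TYPE_CHECKING:  # pragma: no cover
    from .clustering import Partition

from .proximity import ProximityRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DegenerateTransformError",
    "SimilarityParams",
    "AssociationNetwork",
    "proximity_to_similarity",
    "adjust_similarity",
    "sigmoid",
    "sigmoid_normalize",
]

#: Weight provenance stages, in pipeline order.
STAGES = ("proximity", "similarity", "adjusted", "normalized")

# open-interval clamp for sigmoid saturation
_EPS_LO = np.nextafter(0.0, 1.0)
_EPS_HI = np.nextafter(1.0, 0.0)


class DegenerateTransformError(RuntimeError):
    """All proximities are zero: every pair is maximally similar and the
    (max(p) - p)/max(p) transform is undefined."""


@dataclass
class SimilarityParams:
    """Sigmoid shape and the scope of the max(p) normalizer.

    ``sigmoid_midpoint=None`` resolves at normalization time to the median
    adjusted similarity of the run, centring the sigmoid on the score
    distribution.  ``max_p_scope`` controls whether max(p) is taken over
    the significant pairs entering the output network (default) or over
    all scored pairs.
    """

    sigmoid_steepness: float = 25.0
    sigmoid_midpoint: float | None = None
    max_p_scope: str = "significant_pairs"

    def __post_init__(self) -> None:
        if self.sigmoid_steepness <= 0:
            raise ValueError("sigmoid_steepness must be > 0")
        if self.max_p_scope not in ("significant_pairs", "all_pairs"):
            raise ValueError(f"unknown max_p_scope {self.max_p_scope!r}")


@dataclass
class AssociationNetwork:
    """Weighted bipartite drug-disease network with stage provenance.

    ``edges`` is a DataFrame with at least columns ``drug``, ``disease``
    and ``weight``; each pipeline stage appends its own column
    (``similarity``, ``adjusted_similarity``, ``normalized_similarity``,
    cluster assignments) so intermediate networks can be exported and
    audited.  ``stage`` names the meaning of the current ``weight``.
    """

    edges: pd.DataFrame
    stage: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        overlap = set(self.edges["drug"]) & set(self.edges["disease"])
        if overlap:
            raise ValueError(f"identifiers on both sides of the bipartition: {sorted(overlap)[:5]}")

    @property
    def drugs(self) -> set[str]:
        return set(self.edges["drug"])

    @property
    def diseases(self) -> set[str]:
        return set(self.edges["disease"])

    def __len__(self) -> int:
        return len(self.edges)


def proximity_to_similarity(
    records: Sequence[ProximityRecord],
    scope: str = "significant_pairs",
    all_records: Sequence[ProximityRecord] | None = None,
) -> AssociationNetwork:
    """Map proximities onto [0, 1] similarities (stage ``similarity``).

    ``max(p)`` is taken over *records* by default; with
    ``scope="all_pairs"`` and ``all_records`` given, over the full scored
    set instead, so that filtering does not change the normalizer.
    """
    if not records:
        raise ValueError("no records to transform")
    prox = np.array([r.proximity for r in records], dtype=float)
    if not np.all(np.isfinite(prox)) or np.any(prox < 0):
        raise ValueError("all proximities must be finite and >= 0")
    if scope == "all_pairs" and all_records:
        max_p = max(r.proximity for r in all_records)
    else:
        max_p = float(prox.max())
    if max_p == 0:
        raise DegenerateTransformError(
            "max(p) over the scope is 0: all pairs are maximally similar and "
            "the similarity transform cannot discriminate them"
        )
    sim = (max_p - prox) / max_p
    df = pd.DataFrame({
        "drug": [r.drug for r in records],
        "disease": [r.disease for r in records],
        "proximity": prox,
        "p_value": [r.p_value for r in records],
        "z": [r.z for r in records],
        "similarity": sim,
        "weight": sim,
    })
    return AssociationNetwork(df, "similarity", meta={"max_p": max_p, "max_p_scope": scope})


def adjust_similarity(net: AssociationNetwork, partition: "Partition") -> AssociationNetwork:
    """Reward same-cluster pairs: weight *= (1 + QC) of the shared cluster.

    Cross-cluster edges keep their similarity unchanged (their QC is taken
    as zero).  Every drug and disease in the network must be covered by the
    partition.
    """
    from .clustering import DISEASE, DRUG  # deferred: circular at import time

    df = net.edges.copy()
    cl_drug, cl_dis, factors = [], [], []
    for drug, disease, w in zip(df["drug"], df["disease"], df["weight"]):
        kd, ks = (DRUG, drug), (DISEASE, disease)
        if kd not in partition.cluster_of or ks not in partition.cluster_of:
            missing = drug if kd not in partition.cluster_of else disease
            raise ValueError(f"node {missing!r} missing from partition")
        cd, cs = partition.cluster_of[kd], partition.cluster_of[ks]
        cl_drug.append(cd)
        cl_dis.append(cs)
        factors.append(1.0 + partition.qc[cd] if cd == cs else 1.0)
    df["cluster_drug"] = cl_drug
    df["cluster_disease"] = cl_dis
    df["same_cluster"] = [a == b for a, b in zip(cl_drug, cl_dis)]
    df["adjusted_similarity"] = df["weight"] * np.asarray(factors)
    df["weight"] = df["adjusted_similarity"]
    meta = dict(net.meta, n_same_cluster=int(sum(df["same_cluster"])))
    return AssociationNetwork(df, "adjusted", meta=meta)


def sigmoid(x: float | np.ndarray, steepness: float, midpoint: float) -> float | np.ndarray:
    """Logistic sigmoid 1 / (1 + exp(-c (x - d))), saturated to (0, 1)."""
    if steepness <= 0:
        raise ValueError("steepness must be > 0")
    y = expit(steepness * (np.asarray(x, dtype=float) - midpoint))
    y = np.clip(y, _EPS_LO, _EPS_HI)
    return float(y) if np.isscalar(x) or np.ndim(x) == 0 else y


def sigmoid_normalize(net: AssociationNetwork, params: SimilarityParams) -> AssociationNetwork:
    """Squash adjusted similarities onto (0, 1) (stage ``normalized``).

    A ``None`` midpoint resolves to the median of the current weights; the
    resolved value is recorded in ``meta`` so the run is self-documenting.
    """
    df = net.edges.copy()
    d = params.sigmoid_midpoint
    if d is None:
        d = float(np.median(df["weight"]))
        logger.info("sigmoid midpoint resolved to run median %.6g", d)
    y = sigmoid(df["weight"].to_numpy(), params.sigmoid_steepness, d)
    df["normalized_similarity"] = y
    df["weight"] = y
    meta = dict(net.meta, sigmoid_steepness=params.sigmoid_steepness, sigmoid_midpoint=d)
    return AssociationNetwork(df, "normalized", meta=meta)
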