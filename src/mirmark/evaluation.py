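"""Candidate evaluation: per-miRNA ROC/AUC, sample clustering, precision.

The AUC of a single miRNA's expression as a classifier score equals the
Mann-Whitney probability that a random positive sample outranks a random
negative one (ties counted 1/2).  Down-regulated markers separate the
classes with the score reversed, so both the raw *directional* AUC and the
*folded* value ``max(auc, 1 - auc)`` are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn import metrics

from .diffexpr import Contrast, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROCResult:
    """Directional and folded AUC with the ROC curve points."""

    auc_directional: float
    auc_folded: float
    n_pos: int
    n_neg: int
    curve: tuple  # ordered (FPR, TPR) pairs


def roc_auc(scores, labels) -> ROCResult:
    """ROC/AUC for real-valued scores against binary labels (1 = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need both classes present, got labels {classes.tolist()}")
    auc = float(metrics.roc_auc_score(labels, scores))
    fpr, tpr, _ = metrics.roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(
        auc_directional=auc,
        auc_folded=max(auc, 1.0 - auc),
        n_pos=int((labels == labels.max()).sum()),
        n_neg=int((labels == labels.min()).sum()),
        curve=tuple(zip(fpr.tolist(), tpr.tolist())),
    )


def evaluate_candidates(
    matrix: ExpressionMatrix, candidates, contrast: Contrast
) -> pd.DataFrame:
    """Per-candidate AUC table for one contrast (group_b is the positive class).

    Candidates absent from the matrix are skipped with a logged count.
    Columns: ``contrast, auc_directional, auc_folded, n_pos, n_neg``.
    """
    present = [c for c in candidates if c in matrix.values.index]
    n_missing = len(list(candidates)) - len(present)
    if n_missing:
        logger.info("%d candidate(s) absent from the expression matrix skipped", n_missing)
    keep = matrix.groups.isin(contrast.group_a + contrast.group_b)
    labels = matrix.groups[keep].isin(contrast.group_b).astype(int).to_numpy()
    rows = []
    for c in present:
        scores = matrix.values.loc[c, keep.index[keep]].to_numpy(dtype=float)
        r = roc_auc(scores, labels)
        rows.append((c, contrast.name, r.auc_directional, r.auc_folded, r.n_pos, r.n_neg))
    return pd.DataFrame(
        rows,
        columns=["mirna", "contrast", "auc_directional", "auc_folded", "n_pos", "n_neg"],
    ).set_index("mirna")


@dataclass(frozen=True)
class ClusteringResult:
    linkage: np.ndarray        # scipy linkage matrix over samples
    leaf_order: tuple          # sample ids in dendrogram order
    assignments: dict          # sample id -> cluster label 1..k


def cluster_samples(
    matrix: ExpressionMatrix,
    candidates=None,
    n_clusters: int = 3,
    standardize: bool = True,
) -> ClusteringResult:
    """Hierarchical clustering of samples on candidate-miRNA expression.

    Average linkage on the distance 1 - Pearson correlation between samples,
    computed across per-feature standardized rows (set ``standardize=False``
    to correlate raw values).  Samples are processed in sorted-id order,
    which fixes the leaf ordering under input permutation.  Constant
    (zero-variance) features are dropped with a warning.
    """
    sub = matrix.values
    if candidates is not None:
        sub = sub.loc[[c for c in candidates if c in sub.index]]
    if sub.shape[1] < 3 or sub.shape[0] < 2:
        raise ValueError("need >= 3 samples and >= 2 features to cluster")
    sub = sub[sorted(sub.columns)]
    sd = sub.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant feature(s) dropped before clustering", int(constant.sum()))
        sub, sd = sub.loc[~constant], sd[~constant]
    if sub.shape[0] < 2:
        raise ValueError("fewer than 2 non-constant features")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0) if standardize else sub
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(z.to_numpy(dtype=float), rowvar=False)
    if not np.isfinite(corr).all():
        raise ValueError(
            "undefined correlation: some sample has zero variance across the "
            "candidate features"
        )
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(link)
    flat = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
    samples = list(sub.columns)
    return ClusteringResult(
        linkage=link,
        leaf_order=tuple(samples[i] for i in order),
        assignments={s: int(c) for s, c in zip(samples, flat)},
    )


def prediction_precision(predicted, known) -> float:
    """Percentage of the predicted miRNA set already reported in the
    literature, to one decimal: 100 * |predicted & known| / |predicted|."""
    predicted, known = set(predicted), set(known)
    if not predicted:
        raise ValueError("empty predicted set")
    return round(100.0 * len(predicted & known) / len(predicted), 1)


def write_roc_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="mirna", float_format="%.6g")
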