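"""Expression-signature HRD / PARPi-sensitivity classification.

Procedure: restrict the expression matrix to a signature gene list,
two-way hierarchically cluster the samples (average linkage, Euclidean
distance by default), cut at two clusters, label the cluster with the
lower mean signature expression DEFICIENT (repair down-regulation), and
train a k-nearest-neighbour classifier on those provisional labels.
All samples are then classified for each of the two signatures
independently; confidence is the nearest-neighbour vote fraction.

The published signature gene lists are not shipped; callers supply
their own lists (one gene per line) or use synthetic ones for testing.
Predictive value is computed by leave-one-out cross-validation.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, fcluster, linkage as scipy_linkage
from sklearn.neighbors import KNeighborsClassifier

from .errors import ValidationError
from .models import (
    GenePanel,
    HitCategory,
    HRDCall,
    HRDStatus,
    HR_SUPERGROUP,
    ParpiStatus,
    SecondHitResult,
)

logger = logging.getLogger(__name__)

HRD_SIGNATURE = "HRD_SIGNATURE"
PARPI_SIGNATURE = "PARPI_SIGNATURE"


@dataclass
class ExpressionMatrix:
    """Normalized (log-scale) expression, genes x samples."""

    values: pd.DataFrame
    signatures: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, signature_genes: Sequence[str]) -> pd.DataFrame:
        missing = [g for g in signature_genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"signature genes absent from matrix: {missing}")
        return self.values.loc[list(signature_genes)]


def read_expression_tsv(path, signatures: dict[str, list[str]] | None = None
                        ) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, signatures=signatures or {})


def read_signature_list(path) -> list[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")]


def cluster_two_way(
    matrix: ExpressionMatrix,
    signature_genes: Sequence[str],
    linkage: str = "average",
    distance: str = "euclidean",
) -> tuple[dict[str, int], list[str], list[str]]:
    """Two-way hierarchical clustering on the signature-restricted matrix.

    Returns (sample -> cluster id in {0, 1}, sample dendrogram order,
    gene dendrogram order).  Deterministic: scipy's linkage has a fixed
    tie-breaking rule and cluster ids are renumbered by first
    appearance in sample order.
    """
    sub = matrix.restrict(signature_genes)
    if sub.shape[1] < 2:
        raise ValidationError("clustering requires at least 2 samples")
    Z = scipy_linkage(sub.T.values, method=linkage, metric=distance)
    raw = fcluster(Z, t=2, criterion="maxclust")
    if len(set(raw)) < 2:
        # all samples identical at the cut; split by dendrogram halves
        raw = fcluster(Z, t=0, criterion="distance")
        raw = np.where(raw == raw[0], 1, 2)
    relabel: dict[int, int] = {}
    clusters: dict[str, int] = {}
    for sample, cid in zip(sub.columns, raw):
        if cid not in relabel:
            relabel[cid] = len(relabel)
        clusters[sample] = relabel[cid] % 2
    sample_order = [sub.columns[i] for i in
                    dendrogram(Z, no_plot=True)["leaves"]]
    if sub.shape[0] >= 2:
        Zg = scipy_linkage(sub.values, method=linkage, metric=distance)
        gene_order = [sub.index[i] for i in dendrogram(Zg, no_plot=True)["leaves"]]
    else:
        gene_order = list(sub.index)
    return clusters, sample_order, gene_order


def derive_labels(
    clusters: dict[str, int],
    matrix: ExpressionMatrix,
    signature_genes: Sequence[str],
) -> dict[str, HRDStatus]:
    """Label the cluster with the lower mean signature centroid DEFICIENT.

    Equal centroids break the tie toward NORMAL for both clusters, with
    a warning.
    """
    sub = matrix.restrict(signature_genes)
    members: dict[int, list[str]] = {0: [], 1: []}
    for sample, cid in clusters.items():
        members.setdefault(cid, []).append(sample)
    if any(len(v) == 0 for v in members.values()):
        raise ValidationError("degenerate cluster of size 0")
    centroids = {cid: float(sub[samples].values.mean())
                 for cid, samples in members.items()}
    if centroids[0] == centroids[1]:
        warnings.warn("equal cluster centroids; labeling all samples NORMAL")
        return {s: HRDStatus.NORMAL for s in clusters}
    deficient = min(centroids, key=centroids.get)
    return {s: (HRDStatus.DEFICIENT if cid == deficient else HRDStatus.NORMAL)
            for s, cid in clusters.items()}


@dataclass
class SignatureClassifier:
    """KNN over signature-restricted profiles with provisional labels."""

    signature_genes: list[str]
    train_profiles: pd.DataFrame  # samples x genes
    train_labels: list[HRDStatus]
    k: int = 5
    distance: str = "euclidean"
    _knn: KNeighborsClassifier | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        labels = set(self.train_labels)
        if len(labels) < 2:
            raise ValidationError("training set contains a single class")
        n = len(self.train_labels)
        if self.k >= n:
            raise ValidationError(f"k={self.k} must be < n={n}")
        if self.k % 2 == 0:
            raise ValidationError("k must be odd")
        self._knn = KNeighborsClassifier(
            n_neighbors=self.k, metric=self.distance)
        self._knn.fit(self.train_profiles.values,
                      [l.value for l in self.train_labels])

    def predict(self, matrix: ExpressionMatrix
                ) -> tuple[dict[str, HRDStatus], dict[str, float]]:
        sub = matrix.restrict(self.signature_genes).T  # samples x genes
        pred = self._knn.predict(sub.values)
        proba = self._knn.predict_proba(sub.values)
        classes = list(self._knn.classes_)
        labels, confidence = {}, {}
        for i, sample in enumerate(sub.index):
            labels[sample] = HRDStatus(pred[i])
            confidence[sample] = float(proba[i][classes.index(pred[i])])
        return labels, confidence

    def loo_accuracy(self) -> float:
        """Leave-one-out predictive value on the training samples."""
        X = self.train_profiles.values
        y = np.array([l.value for l in self.train_labels])
        correct = 0
        for i in range(len(y)):
            mask = np.ones(len(y), bool)
            mask[i] = False
            # k < n guarantees k <= n-1 training points remain
            knn = KNeighborsClassifier(n_neighbors=self.k, metric=self.distance)
            knn.fit(X[mask], y[mask])
            correct += int(knn.predict(X[i:i + 1])[0] == y[i])
        return correct / len(y)


def train_knn(
    matrix: ExpressionMatrix,
    labels: dict[str, HRDStatus],
    signature_genes: Sequence[str],
    k: int = 5,
    distance: str = "euclidean",
) -> SignatureClassifier:
    sub = matrix.restrict(signature_genes).T
    ordered = [labels[s] for s in sub.index]
    return SignatureClassifier(
        signature_genes=list(signature_genes),
        train_profiles=sub,
        train_labels=ordered,
        k=k,
        distance=distance,
    )


def fit_signature(
    matrix: ExpressionMatrix,
    signature_genes: Sequence[str],
    k: int = 5,
    linkage: str = "average",
    distance: str = "euclidean",
) -> SignatureClassifier:
    """Cluster -> derive labels -> train KNN, for one signature."""
    clusters, _, _ = cluster_two_way(matrix, signature_genes,
                                     linkage=linkage, distance=distance)
    labels = derive_labels(clusters, matrix, signature_genes)
    return train_knn(matrix, labels, signature_genes, k=k, distance=distance)


def classify_samples(
    hrd_classifier: SignatureClassifier,
    parpi_classifier: SignatureClassifier,
    matrix: ExpressionMatrix,
) -> list[HRDCall]:
    """One HRDCall per sample; the two signatures are applied independently."""
    hrd_labels, hrd_conf = hrd_classifier.predict(matrix)
    parpi_labels, parpi_conf = parpi_classifier.predict(matrix)
    calls = []
    for sample in matrix.samples:
        parpi = (ParpiStatus.SENSITIVE
                 if parpi_labels[sample] is HRDStatus.DEFICIENT
                 else ParpiStatus.INSENSITIVE)
        calls.append(HRDCall(
            sample_id=sample,
            hrd_status=hrd_labels[sample],
            parpi_status=parpi,
            hrd_confidence=hrd_conf[sample],
            parpi_confidence=parpi_conf[sample],
        ))
    return calls


def hrd_cooccurrence(
    calls: Iterable[HRDCall],
    second_hits: Iterable[SecondHitResult],
    panel: GenePanel,
) -> dict:
    """HRD / PARPi-sensitive fractions among tumors with LOH or a somatic
    second hit in an HR-super-group gene.

    Sample identifiers are matched to patient identifiers.  Returns a
    dict with denominator, numerators and fractions (None when the
    denominator is empty).
    """
    qualifying: set[str] = set()
    for r in second_hits:
        if r.gene not in panel or panel[r.gene].pathway not in HR_SUPERGROUP:
            continue
        if r.loh or r.category is HitCategory.SOMATIC_SECOND_HIT:
            qualifying.add(r.patient_id)
    by_sample = {c.sample_id: c for c in calls}
    evaluable = sorted(qualifying & by_sample.keys())
    n = len(evaluable)
    n_hrd = sum(1 for s in evaluable
                if by_sample[s].hrd_status is HRDStatus.DEFICIENT)
    n_parpi = sum(1 for s in evaluable
                  if by_sample[s].parpi_status is ParpiStatus.SENSITIVE)
    return {
        "n_evaluable": n,
        "n_hrd": n_hrd,
        "n_parpi_sensitive": n_parpi,
        "hrd_fraction": (n_hrd / n) if n else None,
        "parpi_fraction": (n_parpi / n) if n else None,
    }


def write_hrd_calls(calls: Sequence[HRDCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\thrd_status\thrd_confidence"
                 "\tparpi_status\tparpi_confidence\n")
        for c in calls:
            fh.write(f"{c.sample_id}\t{c.hrd_status.value}\t{c.hrd_confidence:g}"
                     f"\t{c.parpi_status.value}\t{c.parpi_confidence:g}\n")
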