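"""External clustering agreement indices from a contingency table.

Six indices comparing a predicted labelling against ground truth:
Rand index (RI), Hubert–Arabie adjusted Rand index (ARI), adjusted
mutual information (AMI, max normalizer), homogeneity, completeness,
and the Fowlkes–Mallows score (FMS).  All are computed from the
contingency counts ``n_ij`` alone and are invariant to renaming labels.

Conventions for degenerate partitions follow the standard literature:
homogeneity (completeness) is 1 when the truth (prediction) entropy is
zero; ARI and AMI are 1 when the adjustment denominator vanishes (both
partitions trivially agree).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .exceptions import DegenerateInputError, LengthMismatchError

__all__ = ["ContingencyTable", "MetricsReport", "contingency", "compute_indices"]


@dataclass
class ContingencyTable:
    counts: np.ndarray          # n_ij, shape (n_truth_classes, n_pred_classes)

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    ari: float
    ami: float
    ri: float
    homogeneity: float
    completeness: float
    fms: float

    def as_dict(self) -> dict:
        return {
            "ari": self.ari,
            "ami": self.ami,
            "ri": self.ri,
            "homogeneity": self.homogeneity,
            "completeness": self.completeness,
            "fms": self.fms,
        }


def contingency(truth, pred) -> ContingencyTable:
    """Cross-tabulate two labelings: ``n_ij = |truth==i & pred==j|``."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.size != pred.size:
        raise LengthMismatchError("labelings differ in length")
    if truth.size < 1:
        raise LengthMismatchError("labelings are empty")
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    counts = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ContingencyTable(counts=counts)


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def _entropy(marginals: np.ndarray, n: int) -> float:
    p = marginals[marginals > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: ContingencyTable) -> float:
    n = table.n
    nij = table.counts
    a = table.row_marginals
    b = table.col_marginals
    mask = nij > 0
    nz = nij[mask].astype(float)
    outer = np.outer(a, b)[mask].astype(float)
    return float((nz / n * (np.log(nz * n) - np.log(outer))).sum())


def _expected_mutual_information(table: ContingencyTable) -> float:
    """E[MI] over the hypergeometric model of fixed marginals."""
    n = table.n
    a = table.row_marginals.astype(int)
    b = table.col_marginals.astype(int)
    emi = 0.0
    lg = gammaln
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = nij / n * (np.log(n * nij) - np.log(ai * bj))
                lw = (
                    lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                    - lg(n + 1) - lg(nij + 1) - lg(ai - nij + 1)
                    - lg(bj - nij + 1) - lg(n - ai - bj + nij + 1)
                )
                emi += term * np.exp(lw)
    return float(emi)


def compute_indices(truth, pred) -> MetricsReport:
    """All six agreement indices between two labelings of the same items."""
    table = contingency(truth, pred)
    n = table.n
    if n < 2:
        raise DegenerateInputError("at least two observations are required")

    a = table.row_marginals
    b = table.col_marginals
    nij = table.counts

    # pair counts
    same_same = float(_comb2(nij).sum())
    same_truth = float(_comb2(a).sum())
    same_pred = float(_comb2(b).sum())
    total = float(_comb2(np.array([n])).sum())

    ri = (same_same + (total - same_truth - same_pred + same_same)) / total

    expected = same_truth * same_pred / total
    max_index = (same_truth + same_pred) / 2.0
    denom = max_index - expected
    ari = 1.0 if denom == 0 else (same_same - expected) / denom

    if same_truth == 0 or same_pred == 0:
        fms = 0.0
    else:
        fms = same_same / np.sqrt(same_truth * same_pred)

    h_truth = _entropy(a, n)
    h_pred = _entropy(b, n)
    mi = _mutual_information(table)
    homogeneity = 1.0 if h_truth == 0 else mi / h_truth
    completeness = 1.0 if h_pred == 0 else mi / h_pred

    if a.size == 1 and b.size == 1:
        ami = 1.0
    else:
        emi = _expected_mutual_information(table)
        normalizer = max(h_truth, h_pred)
        denom = normalizer - emi
        if abs(denom) < np.finfo(float).eps:
            denom = np.finfo(float).eps if denom >= 0 else -np.finfo(float).eps
        ami = (mi - emi) / denom

    return MetricsReport(
        ari=float(ari),
        ami=float(ami),
        ri=float(ri),
        homogeneity=float(homogeneity),
        completeness=float(completeness),
        fms=float(fms),
    )
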