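"""Clustering-comparison statistics, implemented from first principles.

Mutual information between two labelings is computed from their contingency
table in nats; the chance level is removed with the expected mutual
information (EMI) under the permutation model — averaging MI over all ways
of shuffling one labeling at fixed cluster sizes, which reduces to a
hypergeometric sum evaluated stably through log-factorials. The adjusted
mutual information is then

    AMI = (MI - EMI) / (norm(H_a, H_b) - EMI)

with ``norm`` one of the arithmetic / geometric mean, max or min of the two
marginal entropies. AMI is ~0 for random agreement and 1 for identical
partitions, which makes it meaningful even for small samples (here n = 25).

Also provided: the silhouette coefficient on a precomputed distance matrix,
used for selecting the number of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .labeling import Labeling, aligned_codes

__all__ = [
    "ContingencyTable",
    "MetricValue",
    "NORMALIZATIONS",
    "contingency",
    "entropy",
    "mutual_information",
    "expected_mutual_information",
    "adjusted_mutual_information",
    "ami_all_normalizations",
    "silhouette",
    "UndefinedMetricError",
]

NORMALIZATIONS = ("arithmetic", "max", "min", "geometric")


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. a single cluster)."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two labelings of the same n items."""

    counts: np.ndarray  # R x C non-negative integers
    row_labels: tuple
    col_labels: tuple

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float
    normalization: str | None = None


def contingency(a: Labeling, b: Labeling) -> ContingencyTable:
    """Contingency table counts[r][c] = |{id : a(id)=r, b(id)=c}|.

    Rows follow a's labels, columns b's labels, in first-appearance order
    of a's id sequence.
    """
    codes_a, codes_b = aligned_codes(a, b)
    r, c = codes_a.max() + 1, codes_b.max() + 1
    counts = np.zeros((r, c), dtype=np.int64)
    np.add.at(counts, (codes_a, codes_b), 1)

    def _names(lab: Labeling, codes: np.ndarray, order) -> tuple:
        mapping = lab.to_dict()
        names: dict[int, object] = {}
        for pos, item in enumerate(order):
            names.setdefault(int(codes[pos]), mapping[item])
        return tuple(names[i] for i in range(len(names)))

    return ContingencyTable(
        counts,
        row_labels=_names(a, codes_a, a.ids),
        col_labels=_names(b, codes_b, a.ids),
    )


def entropy(sizes: np.ndarray) -> float:
    """Shannon entropy (nats) of a partition given its cluster sizes."""
    sizes = np.asarray(sizes, dtype=float)
    sizes = sizes[sizes > 0]
    n = sizes.sum()
    if n == 0:
        return 0.0
    p = sizes / n
    return float(-(p * np.log(p)).sum())


def mutual_information(t: ContingencyTable) -> float:
    """MI (nats) of the joint distribution given by the contingency table."""
    n = t.n
    if n == 0:
        return 0.0
    counts = t.counts
    a = t.row_totals.astype(float)
    b = t.col_totals.astype(float)
    nz = counts > 0
    nij = counts[nz].astype(float)
    outer = np.outer(a, b)[nz]
    mi = float(((nij / n) * (np.log(n * nij) - np.log(outer))).sum())
    return max(mi, 0.0)


def expected_mutual_information(t: ContingencyTable) -> float:
    """EMI under the permutation (hypergeometric) model.

    At fixed marginals a_i, b_j the count n_ij of a random permutation is
    hypergeometric; summing (n_ij/n) log(n n_ij / (a_i b_j)) weighted by
    that distribution over the support max(1, a_i+b_j-n) .. min(a_i, b_j)
    gives the expectation. Log-factorials keep it stable up to n ~ 1e4.
    """
    n = t.n
    if n == 0:
        return 0.0
    a = t.row_totals.astype(np.int64)
    b = t.col_totals.astype(np.int64)
    a = a[a > 0]
    b = b[b > 0]
    log_n = np.log(n)
    gln_n = gammaln(n + 1)
    emi = 0.0
    for ai in a:
        gln_ai = gammaln(ai + 1) + gammaln(n - ai + 1)
        for bj in b:
            start = max(1, ai + bj - n)
            end = min(ai, bj)
            if end < start:
                continue
            nij = np.arange(start, end + 1, dtype=np.int64)
            term = (nij / n) * (log_n + np.log(nij) - np.log(ai) - np.log(bj))
            log_p = (
                gln_ai
                + gammaln(bj + 1)
                + gammaln(n - bj + 1)
                - gln_n
                - gammaln(nij + 1)
                - gammaln(ai - nij + 1)
                - gammaln(bj - nij + 1)
                - gammaln(n - ai - bj + nij + 1)
            )
            emi += float((term * np.exp(log_p)).sum())
    return emi


def _normalize(h_a: float, h_b: float, normalization: str) -> float:
    if normalization == "arithmetic":
        return 0.5 * (h_a + h_b)
    if normalization == "max":
        return max(h_a, h_b)
    if normalization == "min":
        return min(h_a, h_b)
    if normalization == "geometric":
        return float(np.sqrt(h_a * h_b))
    raise ValueError(f"unknown normalization {normalization!r}; choose from {NORMALIZATIONS}")


def adjusted_mutual_information(
    a: Labeling, b: Labeling, normalization: str = "arithmetic"
) -> MetricValue:
    """Chance-adjusted mutual information between two labelings.

    Symmetric in its arguments and invariant to relabeling of either side.
    Defined as 0 when the denominator vanishes with MI = EMI (both
    labelings carry no information).
    """
    t = contingency(a, b)
    mi = mutual_information(t)
    emi = expected_mutual_information(t)
    h_a = entropy(t.row_totals)
    h_b = entropy(t.col_totals)
    denom = _normalize(h_a, h_b, normalization) - emi
    numer = mi - emi
    if abs(denom) < np.finfo(float).eps:
        # avoid 0/0 blow-up for trivial labelings; tiny denominators from
        # round-off fall back to the sign-preserving ratio below
        value = 0.0 if abs(numer) < np.finfo(float).eps else numer / max(denom, np.finfo(float).eps)
    else:
        value = numer / denom
    return MetricValue("AMI", float(value), normalization)


def ami_all_normalizations(a: Labeling, b: Labeling) -> dict[str, float]:
    return {
        norm: adjusted_mutual_information(a, b, norm).value for norm in NORMALIZATIONS
    }


def silhouette(labels: Labeling | np.ndarray, dist: np.ndarray) -> float:
    """Mean silhouette coefficient on a precomputed distance matrix.

    For point i with within-cluster mean distance a(i) (self excluded) and
    b(i) = the smallest mean distance to any other cluster,
    s(i) = (b - a) / max(a, b); singletons and degenerate a = b = 0 both
    score 0. Returns the mean of s over all points.
    """
    if isinstance(labels, Labeling):
        codes = labels.codes()
    else:
        codes = np.asarray(labels, dtype=int)
    dist = np.asarray(dist, dtype=float)
    n = codes.size
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match label count")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(dist)) > 1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    uniq = np.unique(codes)
    if uniq.size < 2:
        raise UndefinedMetricError("silhouette requires at least 2 clusters")
    # sum of distances from each point to each cluster
    sums = np.stack([dist[:, codes == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(codes == c).sum() for c in uniq])
    s = np.zeros(n)
    for i in range(n):
        ci = np.searchsorted(uniq, codes[i])
        if sizes[ci] == 1:
            continue  # singleton convention: s = 0
        a_i = sums[i, ci] / (sizes[ci] - 1)
        other = [sums[i, j] / sizes[j] for j in range(uniq.size) if j != ci]
        b_i = min(other)
        top = max(a_i, b_i)
        s[i] = 0.0 if top == 0 else (b_i - a_i) / top
    return float(s.mean())
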