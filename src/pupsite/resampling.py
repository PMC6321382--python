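"""Training-set rebalancing.

Two complementary operations bring a ~1:12 site dataset toward 1:1:

* **KPCA oversampling** — the minority (positive) class is clustered by
  k-means; each cluster is standardized, its correlation matrix
  eigendecomposed, and every standardized member is projected onto the
  principal axes to synthesize a new sample, which is mapped back to
  feature scale.  Clustering is repeated several times and the pooled
  candidates are subsampled (seeded, without replacement) to the requested
  count.
* **Fuzzy undersampling (FUS)** — every majority (negative) sample is
  scored by Gaussian membership closeness to the positive class plus
  distance from the negative class, summed over features; the
  highest-scoring (most ambiguous) negatives are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .peptide_io import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """K-means result: 1-based cluster labels and k x Dim centers."""

    labels: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centers = np.asarray(self.centers, dtype=float)
        k = self.centers.shape[0]
        present = set(self.labels.tolist())
        if present - set(range(1, k + 1)):
            raise ValueError("labels must lie in {1..k}")
        if len(present) != k:
            raise ValueError("every cluster must be non-empty")

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


def kmeans_cluster(
    X: FeatureMatrix | np.ndarray, k: int, seed: int
) -> ClusterAssignment:
    """Lloyd's algorithm from k distinct randomly chosen samples.

    Assignment is by Euclidean distance; iteration stops when assignments
    stop changing or after 300 rounds.  An emptied cluster is reseeded to
    the sample farthest from its current center.
    """
    V = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n = V.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    rng = np.random.default_rng(seed)
    centers = V[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(300):
        d = cdist(V, centers)
        new_labels = d.argmin(axis=1)
        # reseed empty clusters with the farthest sample from its center
        for c in range(k):
            if not (new_labels == c).any():
                far = d[np.arange(n), new_labels].argmax()
                centers[c] = V[far]
                new_labels[far] = c
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centers[c] = V[labels == c].mean(axis=0)
    return ClusterAssignment(labels=labels + 1, centers=centers)


@dataclass
class ResamplingReport:
    """Counts, parameters and provenance of a resampling run."""

    n_pos_before: int = 0
    n_pos_after: int = 0
    n_neg_before: int = 0
    n_neg_after: int = 0
    k: int | None = None
    repeats: int | None = None
    seed: int | None = None
    retained_negative_ids: list[str] = field(default_factory=list)
    synthetic_provenance: list[tuple[int, int]] = field(default_factory=list)
    #: (repeat index, cluster index) per synthetic sample

    def write(self, path: str | Path) -> None:
        lines = [
            f"n_pos_before\t{self.n_pos_before}",
            f"n_pos_after\t{self.n_pos_after}",
            f"n_neg_before\t{self.n_neg_before}",
            f"n_neg_after\t{self.n_neg_after}",
            f"k\t{self.k}",
            f"repeats\t{self.repeats}",
            f"seed\t{self.seed}",
            "retained_negative_ids\t" + ",".join(self.retained_negative_ids),
            "synthetic_provenance\t"
            + ",".join(f"{r}:{c}" for r, c in self.synthetic_provenance),
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _eigvecs_desc(R: np.ndarray) -> np.ndarray:
    """Eigenvectors of a symmetric matrix, columns ordered by descending
    eigenvalue, with a deterministic sign: the first entry whose magnitude
    is within a relative 1e-6 of the column maximum is made positive (an
    exact argmax would tie-break on last-ulp noise)."""
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    V = V[:, order]
    return fix_eigvec_signs(V)


def fix_eigvec_signs(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    for j in range(V.shape[1]):
        col = np.abs(V[:, j])
        i = int(np.flatnonzero(col >= col.max() * (1.0 - 1e-6))[0])
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def standardized_correlation(Z: np.ndarray) -> np.ndarray:
    """Correlation-style matrix of a standardized cluster: cross-products
    over the product of column norms.  All-zero columns (a zero-variance
    feature) contribute identity rows/columns."""
    norms = np.sqrt((Z ** 2).sum(axis=0))
    safe = norms.copy()
    safe[safe == 0] = 1.0
    R = (Z.T @ Z) / np.outer(safe, safe)
    dead = np.flatnonzero(norms == 0)
    if dead.size:
        R[dead, :] = 0.0
        R[:, dead] = 0.0
        R[dead, dead] = 1.0
    return R


def kpca_oversample(
    pos: FeatureMatrix,
    target_total: int,
    k: int = 3,
    repeats: int = 4,
    seed: int = 0,
) -> tuple[FeatureMatrix, ResamplingReport]:
    """Synthesize minority-class samples by clusterwise PCA projection.

    Per repeat and cluster: standardize the cluster, eigendecompose its
    correlation matrix, and project every standardized member onto the
    principal axes; the projections are mapped back to feature scale
    (y * sigma + mu).  Candidates pooled over clusters and repeats are
    subsampled without replacement to exactly ``target_total - n_pos``.
    """
    n_pos = pos.n_samples
    if n_pos < k:
        raise ValueError(f"need at least k={k} positive samples, got {n_pos}")
    if target_total < n_pos:
        raise ValueError("target_total must be >= current positive count")
    n_extra = target_total - n_pos
    rng = np.random.default_rng(seed)
    candidates: list[np.ndarray] = []
    provenance: list[tuple[int, int]] = []
    for r in range(repeats):
        assign = kmeans_cluster(pos, k, seed=int(rng.integers(2 ** 31)))
        for c in range(1, k + 1):
            idx = assign.members(c)
            if idx.size < 2:
                logger.warning("repeat %d cluster %d has 1 sample; skipped", r, c)
                continue
            Xc = pos.values[idx]
            mu = Xc.mean(axis=0)
            sigma = Xc.std(axis=0, ddof=0)
            dead = sigma == 0
            if dead.any():
                logger.warning(
                    "repeat %d cluster %d: %d zero-variance features, sigma=1",
                    r, c, int(dead.sum()),
                )
                sigma = np.where(dead, 1.0, sigma)
            Z = (Xc - mu) / sigma
            A = _eigvecs_desc(standardized_correlation(Z))
            Y = Z @ A  # row i = standardized sample projected on the axes
            back = Y * sigma + mu
            candidates.append(back)
            provenance.extend((r, c) for _ in range(back.shape[0]))
    if not candidates:
        raise ValueError("no cluster of size >= 2: cannot synthesize")
    pool = np.vstack(candidates)
    if n_extra > pool.shape[0]:
        raise ValueError(
            f"pool of {pool.shape[0]} synthetic candidates cannot supply "
            f"{n_extra} samples; increase repeats"
        )
    chosen = np.sort(rng.choice(pool.shape[0], size=n_extra, replace=False))
    synth = FeatureMatrix(
        sample_ids=[
            f"synthetic:r{provenance[i][0]}c{provenance[i][1]}:{i}"
            for i in chosen
        ],
        feature_names=list(pos.feature_names),
        values=pool[chosen],
    )
    if not np.isfinite(synth.values).all():
        raise RuntimeError("synthetic samples contain non-finite values")
    report = ResamplingReport(
        n_pos_before=n_pos,
        n_pos_after=target_total,
        k=k,
        repeats=repeats,
        seed=seed,
        synthetic_provenance=[provenance[i] for i in chosen],
    )
    return synth, report


@dataclass
class FusScoreTable:
    """Per-negative ambiguity scores plus the class statistics behind them."""

    sample_ids: list[str]
    scores: np.ndarray
    c_pos: np.ndarray
    c_neg: np.ndarray
    sigma_pos: np.ndarray
    sigma_neg: np.ndarray


def _gauss_membership(
    X: np.ndarray, center: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """exp(-((x - c)/sigma)^2 / 2); the sigma->0 limit is the indicator of
    x == c (logged by the caller)."""
    out = np.empty_like(X)
    ok = sigma > 0
    out[:, ok] = np.exp(-0.5 * ((X[:, ok] - center[ok]) / sigma[ok]) ** 2)
    if (~ok).any():
        out[:, ~ok] = (X[:, ~ok] == center[~ok]).astype(float)
    return out


def fus_scores(pos: FeatureMatrix, neg: FeatureMatrix) -> FusScoreTable:
    """Score every negative: sum over features of
    u_pos(x) + (1 - u_neg(x)), with Gaussian memberships built from class
    means and population standard deviations."""
    if pos.feature_names != neg.feature_names:
        raise ValueError("positive/negative feature sets differ")
    if pos.n_samples == 0 or neg.n_samples == 0:
        raise ValueError("both classes must be non-empty")
    c_pos = pos.values.mean(axis=0)
    c_neg = neg.values.mean(axis=0)
    s_pos = pos.values.std(axis=0, ddof=0)
    s_neg = neg.values.std(axis=0, ddof=0)
    if (s_pos == 0).any() or (s_neg == 0).any():
        logger.warning(
            "zero-variance features (%d pos, %d neg): membership is the "
            "indicator of the class mean there",
            int((s_pos == 0).sum()), int((s_neg == 0).sum()),
        )
    u_pos = _gauss_membership(neg.values, c_pos, s_pos)
    u_neg = _gauss_membership(neg.values, c_neg, s_neg)
    fval = u_pos + (1.0 - u_neg)
    return FusScoreTable(
        sample_ids=list(neg.sample_ids),
        scores=fval.sum(axis=1),
        c_pos=c_pos,
        c_neg=c_neg,
        sigma_pos=s_pos,
        sigma_neg=s_neg,
    )


def fus_undersample(
    pos: FeatureMatrix, neg: FeatureMatrix, target_count: int
) -> tuple[list[str], ResamplingReport]:
    """Retain the ``target_count`` lowest-scoring (least ambiguous)
    negatives; ties broken by original index.  Positives are untouched."""
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    if target_count > neg.n_samples:
        raise ValueError(
            f"target_count={target_count} exceeds n_neg={neg.n_samples}"
        )
    table = fus_scores(pos, neg)
    order = np.argsort(table.scores, kind="stable")
    keep = np.sort(order[:target_count])  # original order
    retained = [neg.sample_ids[i] for i in keep]
    report = ResamplingReport(
        n_pos_before=pos.n_samples,
        n_pos_after=pos.n_samples,
        n_neg_before=neg.n_samples,
        n_neg_after=target_count,
        retained_negative_ids=retained,
    )
    return retained, report


def balance_dataset(
    pos: FeatureMatrix,
    neg: FeatureMatrix,
    target_pos: int,
    target_neg: int,
    k: int = 3,
    repeats: int = 4,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray, ResamplingReport]:
    """FUS-undersample the negatives, then KPCA-oversample the positives.

    Returns the stacked matrix (original positives, synthetic positives,
    retained negatives), binary labels (1 = positive), and a report.
    """
    if target_pos < pos.n_samples:
        raise ValueError("target_pos must be >= current positive count")
    retained, _ = fus_undersample(pos, neg, target_neg)
    keep_idx = [i for i, s in enumerate(neg.sample_ids) if s in set(retained)]
    neg_kept = neg.take(keep_idx)
    if target_pos > pos.n_samples:
        synth, over_report = kpca_oversample(
            pos, target_total=target_pos, k=k, repeats=repeats, seed=seed
        )
        values = np.vstack([pos.values, synth.values, neg_kept.values])
        ids = pos.sample_ids + synth.sample_ids + neg_kept.sample_ids
        provenance = over_report.synthetic_provenance
    else:
        values = np.vstack([pos.values, neg_kept.values])
        ids = pos.sample_ids + neg_kept.sample_ids
        provenance = []
    labels = np.concatenate(
        [np.ones(target_pos, dtype=int), np.zeros(target_neg, dtype=int)]
    )
    combined = FeatureMatrix(ids, list(pos.feature_names), values)
    report = ResamplingReport(
        n_pos_before=pos.n_samples,
        n_pos_after=target_pos,
        n_neg_before=neg.n_samples,
        n_neg_after=target_neg,
        k=k,
        repeats=repeats,
        seed=seed,
        retained_negative_ids=retained,
        synthetic_provenance=provenance,
    )
    return combined, labels, report
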