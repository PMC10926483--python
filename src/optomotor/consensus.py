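"""Monte-Carlo reference-based consensus clustering of behavioral responses.

Response types are discovered by subsampled k-means consensus clustering:
each iteration clusters a random subset of responses (rows) and features
(columns), and the frequency with which two responses co-cluster, given they
were co-sampled, fills a consensus matrix.  Stability of a candidate cluster
count k is scored by the PAC statistic (proportion of ambiguous clustering:
the fraction of consensus entries falling in an intermediate window).  To
decide the *optimal* k, the same procedure runs on structureless reference
datasets simulated from a multivariate normal matching the real data's
feature covariance; the relative cluster stability index
``RCSI(k) = ln(mean null PAC / real PAC)`` rewards k values whose stability
exceeds what covariance alone produces, and the chosen k maximizes it.
Final labels come from an average-linkage hierarchical cut of the consensus
dissimilarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from ._kmeans import kmeans_labels

logger = logging.getLogger(__name__)

__all__ = [
    "zscore",
    "consensus_run",
    "pac",
    "monte_carlo_reference",
    "select_k",
    "assign_clusters",
    "cluster_proportions",
    "KSelection",
    "ClusterAssignment",
]

#: PAC window bounds (ConsensusClusterPlus convention).
DEFAULT_PAC_WINDOW = (0.1, 0.9)
#: PAC values are floored here before the RCSI log ratio.
PAC_FLOOR = 1e-4
#: k-means restarts per subsample.
KMEANS_RESTARTS = 25


def zscore(features: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-wise z-scoring, (x - mean) / sd with sample sd (ddof=1).

    All responses are pooled across treatments before standardization.

    Raises
    ------
    ValueError
        Fewer than 2 rows, or a zero-variance column (named in the message).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("z-scoring requires a 2-D table with at least 2 rows")
    if np.isnan(X).any():
        raise ValueError("missing values must be removed before z-scoring")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        if isinstance(features, pd.DataFrame):
            bad = [c for c, s in zip(features.columns, sd) if s == 0]
        else:
            bad = list(np.nonzero(sd == 0)[0])
        raise ValueError(f"zero-variance column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    if isinstance(features, pd.DataFrame):
        return pd.DataFrame(Z, index=features.index, columns=features.columns)
    return Z




def consensus_run(
    X: np.ndarray,
    k: int,
    reps: int = 2000,
    item_frac: float = 0.9,
    feature_frac: float = 0.8,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Subsampled k-means consensus matrix at one cluster count.

    Each of ``reps`` iterations draws ``ceil(item_frac * n)`` rows and
    ``ceil(feature_frac * p)`` columns without replacement, runs k-means
    (k-means++, 25 restarts), and tallies co-clustering against co-sampling.
    Entry (i, j) of the result is co-cluster count / co-sample count (0 when
    never co-sampled).  Fully seeded: the same seed gives a bitwise-identical
    matrix.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not (0 < item_frac <= 1 and 0 < feature_frac <= 1):
        raise ValueError("subsampling fractions must lie in (0, 1]")
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    n_items = math.ceil(item_frac * n)
    n_feats = math.ceil(feature_frac * p)
    if k > n_items:
        raise ValueError(f"k={k} exceeds subsampled row count {n_items}")

    rng = np.random.default_rng(seed)
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.choice(n, size=n_items, replace=False)
        feats = rng.choice(p, size=n_feats, replace=False)
        labels = kmeans_labels(X[np.ix_(idx, feats)], k, rng, restarts=KMEANS_RESTARTS)
        same = (labels[:, None] == labels[None, :]).astype(float)
        co_cluster[np.ix_(idx, idx)] += same
        co_sample[np.ix_(idx, idx)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    return M


def pac(M: np.ndarray, lower: float = DEFAULT_PAC_WINDOW[0], upper: float = DEFAULT_PAC_WINDOW[1]) -> float:
    """Proportion of ambiguous clustering: the fraction of off-diagonal
    consensus entries strictly inside (lower, upper).  0 = perfectly stable,
    1 = maximally ambiguous."""
    if not (0 <= lower < upper <= 1):
        raise ValueError(f"require 0 <= lower < upper <= 1, got ({lower}, {upper})")
    M = np.asarray(M)
    iu = np.triu_indices_from(M, k=1)
    vals = M[iu]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > lower) & (vals < upper)))


def monte_carlo_reference(
    X: np.ndarray, B: int, seed: int | np.random.SeedSequence = 0, ridge: float = 1e-10
) -> list[np.ndarray]:
    """B structureless surrogate datasets matched to X's feature covariance.

    Surrogates are drawn from a zero-mean multivariate normal whose
    covariance equals the empirical covariance of X (principal-component-
    preserving simulation), so any clustering stability they show is
    attributable to covariance alone.  A degenerate covariance is
    ridge-regularized (logged).
    """
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    w, V = np.linalg.eigh(cov)
    if w.min() < ridge:
        logger.info("degenerate covariance (min eigenvalue %.3g); ridge-regularizing with %.1g", w.min(), ridge)
        w = np.maximum(w, ridge)
    A = V * np.sqrt(w)  # cov = A @ A.T
    rng = np.random.default_rng(seed)
    return [rng.standard_normal((n, p)) @ A.T for _ in range(B)]


@dataclass
class KSelection:
    """Outcome of Monte-Carlo reference-based optimal-k selection."""

    k_range: tuple[int, ...]
    pac: np.ndarray  # real-data PAC per k
    null_pac: np.ndarray  # (B, len(k_range)) reference PACs
    rcsi: np.ndarray  # per k
    p_value: np.ndarray  # per k, normal approximation on the null PAC spread
    chosen_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_range,
                "pac": self.pac,
                "null_pac_mean": self.null_pac.mean(axis=0),
                "rcsi": self.rcsi,
                "p_value": self.p_value,
            }
        )


def select_k(
    X: np.ndarray,
    k_range=range(2, 11),
    reps: int = 2000,
    B: int = 25,
    item_frac: float = 0.9,
    feature_frac: float = 0.8,
    pac_window: tuple[float, float] = DEFAULT_PAC_WINDOW,
    seed: int = 0,
) -> KSelection:
    """Choose the optimal cluster count by comparing real-data PAC with PAC
    under the Monte-Carlo covariance-matched reference.

    For each k, the real consensus PAC and B reference PACs are computed with
    identical settings; ``RCSI(k) = ln(mean null PAC / real PAC)`` (both
    floored at 1e-4) and a lower-tail p-value from a normal fit to the null
    PACs are reported.  ``chosen_k`` maximizes RCSI (ties -> smallest k).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    k_range = tuple(int(k) for k in k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    if max(k_range) > n - 1 or min(k_range) < 2:
        raise ValueError(f"k_range must lie within [2, n-1] = [2, {n - 1}]")

    root = np.random.SeedSequence(seed)
    ref_seed, *run_seeds = root.spawn(1 + len(k_range) * (1 + B))
    refs = monte_carlo_reference(X, B, seed=ref_seed)

    real_pac = np.empty(len(k_range))
    null_pac = np.empty((B, len(k_range)))
    seeds = iter(run_seeds)
    for j, k in enumerate(k_range):
        M = consensus_run(X, k, reps=reps, item_frac=item_frac, feature_frac=feature_frac, seed=next(seeds))
        real_pac[j] = pac(M, *pac_window)
        for b, ref in enumerate(refs):
            Mb = consensus_run(ref, k, reps=reps, item_frac=item_frac, feature_frac=feature_frac, seed=next(seeds))
            null_pac[b, j] = pac(Mb, *pac_window)

    real_fl = np.maximum(real_pac, PAC_FLOOR)
    null_mean = np.maximum(null_pac.mean(axis=0), PAC_FLOOR)
    rcsi = np.log(null_mean / real_fl)
    sd = null_pac.std(axis=0, ddof=1)
    sd = np.maximum(sd, 1e-12)
    p_value = norm.cdf((real_pac - null_pac.mean(axis=0)) / sd)
    chosen = k_range[int(np.argmax(rcsi))]
    return KSelection(
        k_range=k_range, pac=real_pac, null_pac=null_pac, rcsi=rcsi, p_value=p_value, chosen_k=int(chosen)
    )


@dataclass
class ClusterAssignment:
    """Final consensus labels, 1..k, renumbered by descending cluster size."""

    labels: np.ndarray
    k: int


def assign_clusters(M: np.ndarray, k: int) -> ClusterAssignment:
    """Cut the consensus dissimilarity (1 - M) with average-linkage
    agglomerative clustering at k clusters; labels are renumbered so that
    cluster 1 is the largest."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    M = np.asarray(M, dtype=float)
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # guard tiny asymmetries
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber by descending size; ties broken by first appearance
    sizes = pd.Series(raw).value_counts()
    order = sorted(sizes.index, key=lambda c: (-sizes[c], list(raw).index(c)))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[c] for c in raw], dtype=int)
    return ClusterAssignment(labels=labels, k=int(labels.max()))


def cluster_proportions(assignment: ClusterAssignment, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-(treatment, stimulus) cluster proportions with counts retained.

    ``metadata`` must carry one row per response, aligned with the
    assignment's label order, with ``treatment`` and ``stimulus_label``
    columns.
    """
    required = {"treatment", "stimulus_label"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    if len(metadata) != len(assignment.labels):
        raise ValueError(
            f"metadata rows ({len(metadata)}) do not match assigned responses ({len(assignment.labels)})"
        )
    df = metadata[["treatment", "stimulus_label"]].copy()
    df["cluster"] = assignment.labels
    counts = df.groupby(["treatment", "stimulus_label", "cluster"], observed=True).size().rename("count")
    out = counts.reset_index()
    totals = out.groupby(["treatment", "stimulus_label"], observed=True)["count"].transform("sum")
    out["proportion"] = out["count"] / totals
    return out
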