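"""Diversity, community distances, ordination, clustering and group tests.

Standard community-ecology machinery over abundance profiles: Shannon
diversity, Jaccard/Bray-Curtis distance matrices, principal-coordinate and
principal-component ordination, agglomerative clustering, canonical k-mer
composition distances between raw read sets, and the usual group-difference
hypothesis tests (delegated to scipy/statsmodels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from ._seq import CODE


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with a zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        finite = np.isfinite(d)
        if not np.allclose(d[finite], d.T[finite], atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.data = d

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


@dataclass
class OrdinationResult:
    """Sample coordinates on axes ordered by decreasing eigenvalue."""

    ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalues: list[float] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"axis_{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def shannon(abundances) -> float | None:
    """Shannon diversity H = -sum p ln p (natural log) over p > 0.

    Accepts a mapping clade -> abundance or an array; returns None for an
    empty profile (H undefined)."""
    vals = np.asarray(
        list(abundances.values()) if isinstance(abundances, Mapping) else abundances,
        dtype=float,
    )
    vals = vals[vals > 0]
    if vals.size == 0:
        return None
    if abs(vals.sum() - 1.0) > 1e-6:
        raise ValueError("abundances must sum to 1")
    return float(-np.sum(vals * np.log(vals)))


def distance_matrix(profiles: Sequence, rank: str, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Jaccard (presence/absence) or Bray-Curtis dissimilarities
    over the clade union at ``rank``. A pair of empty profiles yields an
    undefined (NaN) entry."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if metric not in ("jaccard", "bray_curtis"):
        raise ValueError(f"unknown metric {metric!r}")
    clades = sorted({c for p in profiles for c in p.at(rank)})
    X = np.array(
        [[p.at(rank).get(c, 0.0) for c in clades] for p in profiles], dtype=float
    )
    ids = [p.sample_id for p in profiles]
    n = len(profiles)
    D = np.zeros((n, n))
    empty = X.sum(axis=1) == 0
    if metric == "jaccard":
        D = squareform(pdist(X > 0, metric="jaccard"), checks=False)
    else:
        D = squareform(pdist(X, metric="braycurtis"), checks=False)
    for i in range(n):
        for j in range(n):
            if i != j and empty[i] and empty[j]:
                D[i, j] = float("nan")
    return DistanceMatrix(ids, D)


def pcoa(D: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-center -D**2/2, eigendecompose, scale eigenvectors by the square
    root of their eigenvalues. Negative eigenvalues (non-Euclidean input)
    are reported and their axes suppressed; requesting more axes than the
    positive rank truncates with a notice in ``negative_eigenvalues``
    semantics (coordinates simply have fewer columns).
    """
    d = D.data
    if np.isnan(d).any():
        raise ValueError("distance matrix contains undefined entries")
    n = d.shape[0]
    Jc = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * Jc @ (d ** 2) @ Jc
    w, V = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(abs(w[0]), 1.0) * 1e-10
    negative = [float(x) for x in w if x < -tol]
    pos = w > tol
    wp, Vp = w[pos], V[:, pos]
    if k is not None:
        wp, Vp = wp[:k], Vp[:, :k]
    coords = Vp * np.sqrt(wp)
    total = w[w > tol].sum()
    prop = wp / total if total > 0 else np.zeros_like(wp)
    return OrdinationResult(list(D.ids), coords, wp, prop, negative)


def pca(X, ids: Sequence[str] | None = None, k: int | None = None) -> OrdinationResult:
    """Column-centered principal components of a samples x features matrix
    (delegated to scikit-learn)."""
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    if ids is None:
        ids = [f"s{i}" for i in range(X.shape[0])]
    if np.allclose(X.var(axis=0), 0.0):
        z = np.zeros(0)
        return OrdinationResult(list(ids), np.zeros((X.shape[0], 0)), z, z)
    n_comp = min(X.shape[0] - 1, X.shape[1]) if k is None else min(k, X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_comp, svd_solver="full")
    scores = model.fit_transform(X)
    eig = model.explained_variance_ * (X.shape[0] - 1)
    prop = model.explained_variance_ratio_
    return OrdinationResult(list(ids), scores, eig, prop)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over lexicographically ordered samples."""

    ids: list[str]
    linkage_matrix: np.ndarray

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")
        return dict(zip(self.ids, (int(x) for x in labels)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node) -> str:
            if node.is_leaf():
                return self.ids[node.id]
            left, right = node.get_left(), node.get_right()
            bl_l = node.dist - left.dist
            bl_r = node.dist - right.dist
            return f"({walk(left)}:{bl_l:.6g},{walk(right)}:{bl_r:.6g})"

        return walk(tree) + ";"


def hierarchical_cluster(D: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering of a distance matrix.

    Samples are canonicalized to lexicographic id order first, so the tree
    is invariant to input order (deterministic tie-breaking). ``ward-like``
    applies the Ward update formula to the given (possibly non-Euclidean)
    dissimilarities.
    """
    if len(D.ids) < 2:
        raise ValueError("need at least two samples to cluster")
    method = {"average": "average", "complete": "complete", "ward-like": "ward"}.get(linkage)
    if method is None:
        raise ValueError(f"unknown linkage {linkage!r}")
    order = np.argsort(np.asarray(D.ids, dtype=object))
    ids = [D.ids[i] for i in order]
    d = D.data[np.ix_(order, order)]
    Z = hierarchy.linkage(squareform(d, checks=False), method=method)
    return Dendrogram(ids, Z)


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    codes = CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    valid = codes != 255
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    fwd = win @ powers
    rc_codes = (3 - codes[::-1]).astype(np.int64)
    rc_win = np.lib.stride_tricks.sliding_window_view(rc_codes, k)
    rev = (rc_win @ powers)[::-1]
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return np.minimum(fwd, rev)[ok]


def kmer_distance(
    reads_per_sample: Mapping[str, Sequence], k: int = 10, metric: str = "bray_curtis"
) -> DistanceMatrix:
    """Bray-Curtis distances between canonical k-mer frequency vectors.

    Each sample's reads are reduced to a normalized frequency vector over
    canonical k-mers (lexicographic minimum of a k-mer and its reverse
    complement), making the representation strand-invariant. Reads shorter
    than ``k`` are skipped; a sample with no usable reads yields undefined
    (NaN) entries.
    """
    ids = sorted(reads_per_sample)
    if not ids:
        raise ValueError("no samples given")
    vecs = np.zeros((len(ids), 4 ** k), dtype=np.float32)
    empty = np.zeros(len(ids), dtype=bool)
    for i, sid in enumerate(ids):
        counts = np.zeros(4 ** k, dtype=np.float64)
        for read in reads_per_sample[sid]:
            seq = read.sequence if hasattr(read, "sequence") else read
            codes = _canonical_kmer_codes(seq, k)
            if codes.size:
                np.add.at(counts, codes, 1.0)
        total = counts.sum()
        if total == 0:
            empty[i] = True
        else:
            vecs[i] = counts / total
    if metric == "bray_curtis":
        D = squareform(pdist(vecs, metric="braycurtis"), checks=False)
    elif metric == "jaccard":
        D = squareform(pdist(vecs > 0, metric="jaccard"), checks=False)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    for i in range(len(ids)):
        for j in range(len(ids)):
            if i != j and (empty[i] or empty[j]):
                D[i, j] = float("nan")
    return DistanceMatrix(ids, D)


def group_test(values, labels, test: str = "anova") -> tuple[float, float]:
    """Named standard group-difference test; numerics are delegated to
    scipy/statsmodels.

    values : 1-D per-sample values (2-D samples x features for ``manova``)
    labels : group label per sample
    test   : anova | kruskal_wallis | t | wilcoxon | manova
             (``wilcoxon`` is the two-sample rank-sum / Mann-Whitney U)
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    groups = [values[labels == g] for g in uniq]
    if test in ("anova", "t", "manova") and any(len(g) < 2 for g in groups):
        raise ValueError("parametric tests need at least two samples per group")
    if test in ("t", "wilcoxon") and len(uniq) != 2:
        raise ValueError(f"{test} test requires exactly two groups")
    if test == "anova":
        res = stats.f_oneway(*groups)
    elif test == "kruskal_wallis":
        res = stats.kruskal(*groups)
    elif test == "t":
        res = stats.ttest_ind(groups[0], groups[1])
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
    elif test == "manova":
        from statsmodels.multivariate.manova import MANOVA

        if values.ndim != 2:
            raise ValueError("manova requires a 2-D value matrix")
        df = pd.DataFrame(values, columns=[f"v{i}" for i in range(values.shape[1])])
        df["group"] = labels
        mv = MANOVA.from_formula(
            " + ".join(df.columns[:-1]) + " ~ group", data=df
        ).mv_test()
        tbl = mv.results["group"]["stat"]
        return float(tbl.loc["Wilks' lambda", "F Value"]), float(
            tbl.loc["Wilks' lambda", "Pr > F"]
        )
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def tukey_hsd(values, labels) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons after ANOVA (statsmodels)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(labels))
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return frame
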