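"""Similarity network fusion (SNF) across omics modalities.

Each modality yields a patient-similarity kernel from a scaled exponential of
squared Euclidean distances, with a locally adaptive bandwidth set by the K
nearest neighbours.  Cross-diffusion then iteratively propagates each
modality's full kernel through the other modalities' sparse local kernels,
converging to a single fused network that is clustered with normalized-
Laplacian spectral clustering.  Also provides modality-dominance
quantification (which modality a member is most similar to its cluster in)
and Kaplan-Meier survival stratification of the clusters.

Kernel conventions (pinned here and in the tests):
  * W(i,j) = exp(-d^2(i,j) / (mu * eps(i,j))),
    eps(i,j) = (mean_d(i, K-NN) + mean_d(j, K-NN) + d(i,j)) / 3
  * full kernel P: off-diagonal W(i,j) / (2 * sum_{k != i} W(i,k)),
    diagonal 1/2 (self-affinity one half after normalization)
  * sparse kernel S: K nearest neighbours only, rows renormalized to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans


@dataclass
class SnfParams:
    K: int = 20
    mu: float = 0.5
    t: int = 20
    k_clusters: int | str = "auto"
    eigengap_range: tuple[int, int] = (2, 10)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.t < 1:
            raise ValueError("t must be >= 1")


@dataclass
class AffinityMatrix:
    matrix: np.ndarray
    index: list[str]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.index):
            raise ValueError("affinity matrix/index shape mismatch")
        if not np.all(np.isfinite(m)):
            raise ValueError("affinity matrix has non-finite entries")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("affinity matrix is not symmetric")
        if (m < -1e-12).any():
            raise ValueError("affinity matrix has negative entries")


@dataclass
class ClusterAssignment:
    labels: dict[str, int]            # sample id -> cluster 1..k
    k: int

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.labels.values():
            out[c] = out.get(c, 0) + 1
        return out


# --------------------------------------------------------------------------
# Data preparation
# --------------------------------------------------------------------------

def prepare_block(block: pd.DataFrame) -> pd.DataFrame:
    """Standardize features (z-score) and median-impute remaining missing
    entries for distance computation.  Constant columns are dropped with a
    warning.  Samples missing the whole block should be dropped by the caller
    (only subjects with data across all modalities are clustered)."""
    X = block.copy()
    med = X.median(axis=0)
    X = X.fillna(med)
    sd = X.std(axis=0, ddof=0)
    const = sd[sd == 0].index
    if len(const):
        warnings.warn(f"dropping {len(const)} constant feature(s): "
                      f"{list(const[:5])}...")
        X = X.drop(columns=const)
        sd = sd.drop(const)
    return (X - X.mean(axis=0)) / sd


def complete_samples(blocks: dict[str, pd.DataFrame]) -> list[str]:
    """Ids with at least one observed value in every modality block."""
    keep = None
    for frame in blocks.values():
        has = frame.notna().any(axis=1)
        keep = has if keep is None else (keep & has)
    return list(keep[keep].index)


# --------------------------------------------------------------------------
# Affinity construction
# --------------------------------------------------------------------------

def build_affinity(block: pd.DataFrame, params: SnfParams) -> AffinityMatrix:
    """Scaled exponential similarity kernel with KNN-adaptive bandwidth."""
    n = block.shape[0]
    if n <= params.K:
        raise ValueError(f"n={n} samples <= K={params.K}")
    X = prepare_block(block).to_numpy(dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    # mean distance of each sample to its K nearest neighbours (self excluded)
    sortD = np.sort(D, axis=1)[:, 1:params.K + 1]
    mean_knn = sortD.mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + D) / 3.0
    eps = np.maximum(eps, 1e-12)
    W = np.exp(-(D ** 2) / (params.mu * eps))
    W = (W + W.T) / 2.0
    return AffinityMatrix(W, list(block.index))


def _full_kernel(W: np.ndarray) -> np.ndarray:
    """Row-normalized full kernel with self-affinity 1/2."""
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rows = off.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    P = off / (2.0 * rows)
    np.fill_diagonal(P, 0.5)
    return P


def _sparse_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Keep each row's K nearest neighbours (largest affinities, self
    excluded); renormalize rows to sum 1."""
    n = W.shape[0]
    S = np.zeros_like(W)
    off = W.copy()
    np.fill_diagonal(off, -np.inf)
    idx = np.argpartition(off, -K, axis=1)[:, -K:]
    rows = np.arange(n)[:, None]
    S[rows, idx] = W[rows, idx]
    np.fill_diagonal(S, 0.0)
    sums = S.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return S / sums


def fuse(affinities: list[AffinityMatrix], params: SnfParams) -> AffinityMatrix:
    """Cross-diffusion of >= 2 modality kernels: P_v <- S_v mean(P_w, w!=v)
    S_v^T for t iterations with symmetrization and renormalization each step;
    returns the average of the final kernels."""
    if len(affinities) < 2:
        raise ValueError("fusion needs at least two modalities")
    index = affinities[0].index
    for a in affinities[1:]:
        if a.index != index:
            raise ValueError("affinity matrices have mismatched sample indices")
    Ps = [_full_kernel(a.matrix) for a in affinities]
    Ss = [_sparse_kernel(a.matrix, params.K) for a in affinities]
    m = len(Ps)
    for _ in range(params.t):
        new = []
        for v in range(m):
            others = sum(Ps[w] for w in range(m) if w != v) / (m - 1)
            Pv = Ss[v] @ others @ Ss[v].T
            Pv = (Pv + Pv.T) / 2.0
            new.append(_full_kernel(Pv))
        Ps = new
    fused = sum(Ps) / m
    fused = (fused + fused.T) / 2.0
    return AffinityMatrix(fused, index)


# --------------------------------------------------------------------------
# Spectral clustering
# --------------------------------------------------------------------------

def _spectral_embedding(P: np.ndarray, k: int) -> np.ndarray:
    d = P.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    L = np.eye(P.shape[0]) - d_inv_sqrt[:, None] * P * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(L)
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return U / norms


def eigengap_k(P: np.ndarray, k_range: tuple[int, int] = (2, 10)) -> int:
    """Number of clusters from the largest gap in the normalized-Laplacian
    eigenvalue spectrum over the configured range."""
    d = P.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(d, 1e-12))
    L = np.eye(P.shape[0]) - d_inv_sqrt[:, None] * P * d_inv_sqrt[None, :]
    vals = np.sort(np.linalg.eigvalsh(L))
    lo, hi = k_range
    hi = min(hi, P.shape[0] - 1)
    gaps = {k: vals[k] - vals[k - 1] for k in range(lo, hi + 1)}
    return max(gaps, key=gaps.get)


def spectral_cluster(P: AffinityMatrix, k_clusters: int | str = "auto",
                     params: SnfParams | None = None,
                     seed: int = 0) -> ClusterAssignment:
    """Normalized-Laplacian spectral embedding + k-means partition of the
    fused network; ``"auto"`` selects k by the eigengap heuristic."""
    params = params or SnfParams()
    n = P.matrix.shape[0]
    if k_clusters == "auto":
        k = eigengap_k(P.matrix, params.eigengap_range)
    else:
        k = int(k_clusters)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k={k} outside [2, n-1] for n={n}")
    adj = P.matrix.copy()
    np.fill_diagonal(adj, 0.0)
    n_comp, _ = connected_components((adj > 0).astype(int), directed=False)
    if n_comp > k:
        raise ValueError(f"graph has {n_comp} connected components > k={k}")
    emb = _spectral_embedding(P.matrix, k)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(emb)
    # relabel clusters 1..k by decreasing size for stable reporting
    order = np.argsort([-(raw == c).sum() for c in range(k)])
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = {sid: remap[int(c)] for sid, c in zip(P.index, raw)}
    return ClusterAssignment(labels=labels, k=k)


# --------------------------------------------------------------------------
# Modality dominance
# --------------------------------------------------------------------------

def modality_dominance(affinities: dict[str, AffinityMatrix],
                       assignment: ClusterAssignment) -> pd.DataFrame:
    """Fraction of each cluster's members whose highest mean within-cluster
    affinity lies in each modality.

    Each modality's matrix is first scaled to unit mean off-diagonal affinity;
    ties go to the first modality in sorted order.  Singleton clusters are
    reported as missing.
    """
    mods = sorted(affinities)
    index = affinities[mods[0]].index
    for m in mods:
        if affinities[m].index != index:
            raise ValueError("dominance: mismatched sample indices")
    pos = {sid: i for i, sid in enumerate(index)}
    normed = {}
    for m in mods:
        W = affinities[m].matrix.copy()
        mask = ~np.eye(W.shape[0], dtype=bool)
        mean_off = W[mask].mean()
        normed[m] = W / (mean_off if mean_off > 0 else 1.0)

    clusters = sorted(set(assignment.labels.values()))
    rows = []
    for c in clusters:
        members = [sid for sid in index if assignment.labels[sid] == c]
        if len(members) < 2:
            rows.append({"cluster": c, **{m: np.nan for m in mods}})
            continue
        midx = np.array([pos[s] for s in members])
        counts = {m: 0 for m in mods}
        for s in members:
            i = pos[s]
            others = midx[midx != i]
            means = [normed[m][i, others].mean() for m in mods]
            counts[mods[int(np.argmax(means))]] += 1
        total = len(members)
        rows.append({"cluster": c, **{m: counts[m] / total for m in mods}})
    return pd.DataFrame(rows).set_index("cluster")


# --------------------------------------------------------------------------
# Survival by cluster
# --------------------------------------------------------------------------

def km_by_cluster(assignment: ClusterAssignment,
                  followup: dict[str, tuple[float, bool]]
                  ) -> dict[int, dict]:
    """Kaplan-Meier product-limit estimate and crude mortality per cluster.

    ``followup`` maps sample id -> (time_years, death flag).  Empty clusters
    are skipped with a warning.
    """
    out: dict[int, dict] = {}
    for c in sorted(set(assignment.labels.values())):
        members = [sid for sid, cc in assignment.labels.items() if cc == c]
        members = [sid for sid in members if sid in followup]
        if not members:
            warnings.warn(f"cluster {c}: no follow-up data, skipped")
            continue
        times = np.array([followup[s][0] for s in members], dtype=float)
        deaths = np.array([followup[s][1] for s in members], dtype=bool)
        if (times < 0).any():
            raise ValueError("negative follow-up time")
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=deaths)
        sf = kmf.survival_function_
        out[c] = {
            "n": len(members),
            "deaths": int(deaths.sum()),
            "mortality_fraction": float(deaths.mean()),
            "times": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        }
    return out
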