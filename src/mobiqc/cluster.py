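"""Kernel K-means clustering of standardized spectra.

The clustering stage works entirely from the Gram (kernel) matrix
``K[i, j] = k(x_i, x_j)`` of the N standardized 256-bin spectra:

* candidate kernels are the linear kernel, inhomogeneous polynomial kernels
  of degree 2 and 3, and Gaussian kernels
  ``k(x, y) = exp(-||x - y||^2 / (2 sigma^2))`` over a fixed sigma ladder;
  screening picks the kernel whose off-diagonal similarity values are most
  evenly distributed (maximum histogram entropy);
* the number of clusters is read off the eigendecomposition
  ``K = U L U^T``: with the uniform weight vector ``w = 1/N``, the mean
  kernel value decomposes as ``w^T K w = sum_i l_i (w^T u_i)^2`` and the
  count of dominant terms in that sum indicates k;
* Lloyd iterations run implicitly in feature space using
  ``d(i, c) = K_ii - 2/|c| sum_{j in c} K_ij + 1/|c|^2 sum_{j,l in c} K_jl``,
  restarted from 200 random assignments, keeping the restart with the least
  within-cluster variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest

__all__ = [
    "KernelSpec", "KernelMatrix", "EigenSelection", "ClusterModel",
    "DEFAULT_GAUSSIAN_SIGMAS", "default_kernel_specs",
    "compute_kernel", "eigen_terms", "select_k", "kernel_kmeans",
    "kernel_quality", "screen_kernels", "exhaustive_kernel_kmeans",
    "cluster_composition", "proportion_test", "objective_from_assignments",
]

#: Gaussian kernel widths screened for the spectral clustering
DEFAULT_GAUSSIAN_SIGMAS = (4, 12, 14, 20, 22, 24, 26, 28, 36, 44, 52, 60)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    ``kind`` is ``linear``, ``polynomial`` (degree 2 or 3, inhomogeneous
    form ``(x.y + 1)^d``) or ``gaussian``.  For the Gaussian kernel,
    ``sigma`` is the width in standardized-feature units and ``convention``
    selects the exponent denominator: ``"2sigma2"`` (default,
    ``exp(-d^2/(2 sigma^2))``) or ``"sigma2"``.
    """

    kind: str
    degree: int | None = None
    sigma: float | None = None
    convention: str = "2sigma2"

    def __post_init__(self) -> None:
        if self.kind == "polynomial":
            if self.degree not in (2, 3):
                raise ValueError("polynomial degree must be 2 or 3")
        elif self.kind == "gaussian":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("gaussian kernel needs sigma > 0")
            if self.convention not in ("2sigma2", "sigma2"):
                raise ValueError("convention must be '2sigma2' or 'sigma2'")
        elif self.kind != "linear":
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    def label(self) -> str:
        if self.kind == "linear":
            return "linear"
        if self.kind == "polynomial":
            return f"poly{self.degree}"
        return f"gauss(sigma={self.sigma:g})"


def default_kernel_specs() -> list[KernelSpec]:
    """The screened candidate set: linear, poly 2/3, Gaussian sigma ladder."""
    specs = [KernelSpec("linear"), KernelSpec("polynomial", degree=2),
             KernelSpec("polynomial", degree=3)]
    specs += [KernelSpec("gaussian", sigma=float(s))
              for s in DEFAULT_GAUSSIAN_SIGMAS]
    return specs


@dataclass
class KernelMatrix:
    """A symmetric PSD Gram matrix with its generating spec."""

    K: np.ndarray
    spec: KernelSpec

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2 or self.K.shape[0] != self.K.shape[1]:
            raise ValueError("K must be square")

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class EigenSelection:
    """Eigen decomposition terms for cluster-count selection.

    ``terms[i] = eigenvalues[i] * projections[i]`` where ``projections[i]``
    is ``(w^T u_i)^2`` for the uniform weight vector ``w`` (entries 1/N);
    the terms sum to the mean kernel value ``w^T K w``.
    """

    eigenvalues: np.ndarray   # descending
    projections: np.ndarray   # (w^T u_i)^2, same order
    terms: np.ndarray
    k_selected: int | None = None

    @property
    def total(self) -> float:
        return float(self.terms.sum())


@dataclass
class ClusterModel:
    assignments: np.ndarray
    k: int
    objective: float
    n_restarts: int
    best_restart: int
    spec: KernelSpec

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)


# ---------------------------------------------------------------------------
# kernels

def compute_kernel(X: np.ndarray, spec: KernelSpec) -> KernelMatrix:
    """Gram matrix of the rows of ``X`` under ``spec`` (symmetrized)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with N >= 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite features")
    G = X @ X.T
    if spec.kind == "linear":
        K = G
    elif spec.kind == "polynomial":
        K = (G + 1.0) ** spec.degree
    else:
        sq = np.diag(G)[:, None] + np.diag(G)[None, :] - 2 * G
        np.maximum(sq, 0.0, out=sq)
        denom = 2 * spec.sigma**2 if spec.convention == "2sigma2" else spec.sigma**2
        K = np.exp(-sq / denom)
    K = (K + K.T) / 2.0
    return KernelMatrix(K=K, spec=spec)


def eigen_terms(K: KernelMatrix | np.ndarray,
                rtol: float = 1e-8) -> EigenSelection:
    """Terms ``l_i (w^T u_i)^2`` of the mean-kernel-value decomposition.

    ``w`` is the uniform vector with entries 1/N.  The returned terms are in
    descending-eigenvalue order and satisfy ``sum(terms) == w^T K w`` to
    relative precision ``rtol``.
    """
    M = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    scale = np.abs(M).max() or 1.0
    if np.abs(M - M.T).max() > 1e-8 * scale:
        raise ValueError("kernel matrix is not symmetric")
    n = M.shape[0]
    vals, vecs = np.linalg.eigh(M)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    w = np.full(n, 1.0 / n)
    proj = (w @ vecs) ** 2
    terms = vals * proj
    total = float(w @ M @ w)
    # w^T K w can vanish identically (zero-mean features, linear kernel);
    # judge the identity on the kernel's natural scale in that case
    ref = max(abs(total), abs(np.trace(M)) / n, 1e-300)
    if abs(terms.sum() - total) > rtol * ref * 100:
        warnings.warn("eigen-term identity degraded beyond tolerance")
    return EigenSelection(eigenvalues=vals, projections=proj, terms=terms)


def select_k(sel: EigenSelection, rule: str = "largest-gap",
             k_max: int = 10, tau: float = 0.05) -> int:
    """Number of dominant terms in the eigen decomposition.

    ``largest-gap`` (default): k at the largest relative gap
    ``(t_k - t_{k+1}) / t_k`` of the descending-sorted terms, capped at
    ``k_max``.  ``threshold``: count of terms above ``tau`` times the
    largest term.
    """
    t = np.sort(np.maximum(sel.terms, 0.0))[::-1]
    if t.size == 0 or t[0] == 0:
        warnings.warn("all eigen terms vanish; returning k=1")
        sel.k_selected = 1
        return 1
    if rule == "threshold":
        k = int((t > tau * t[0]).sum())
        k = max(min(k, k_max), 1)
    elif rule == "largest-gap":
        upper = min(k_max, t.size - 1)
        if upper < 1:
            k = 1
        else:
            gaps = np.zeros(upper)
            for i in range(1, upper + 1):
                if t[i - 1] > 0:
                    gaps[i - 1] = (t[i - 1] - t[i]) / t[i - 1]
            if np.all(gaps == 0):
                warnings.warn("all eigen terms equal; returning k=1")
                k = 1
            else:
                k = int(np.argmax(gaps)) + 1
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    sel.k_selected = k
    return k


# ---------------------------------------------------------------------------
# kernel K-means

def objective_from_assignments(K: np.ndarray, assignments: np.ndarray) -> float:
    """Within-cluster variance in feature space implied by ``assignments``.

    ``sum_i d(i, c_i) = trace(K) - sum_c (1/|c|) sum_{i,j in c} K_ij``.
    """
    obj = float(np.trace(K))
    for c in np.unique(assignments):
        idx = np.flatnonzero(assignments == c)
        obj -= float(K[np.ix_(idx, idx)].sum()) / idx.size
    return obj


def _lloyd(K: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300) -> tuple[np.ndarray, float]:
    n = K.shape[0]
    assign = rng.integers(0, k, size=n)
    # guarantee non-empty start
    assign[rng.permutation(n)[:k]] = np.arange(k)
    diag = np.diag(K)
    for _ in range(max_iter):
        H = np.zeros((n, k))
        H[np.arange(n), assign] = 1.0
        sizes = H.sum(axis=0)
        if np.any(sizes == 0):
            # reseed each empty cluster with the point farthest from its
            # current centroid
            for c in np.flatnonzero(sizes == 0):
                S = K @ H
                safe = np.maximum(sizes, 1.0)
                within = S[np.arange(n), assign] / safe[assign]
                quad = np.einsum("nc,nc->c", H, S) / safe**2
                dist = diag - 2 * within + quad[assign]
                far = int(np.argmax(dist))
                assign[far] = c
                H = np.zeros((n, k))
                H[np.arange(n), assign] = 1.0
                sizes = H.sum(axis=0)
        S = K @ H  # S[i, c] = sum_{j in c} K_ij
        quad = np.einsum("nc,nc->c", H, S) / sizes**2
        cost = -2 * S / sizes[None, :] + quad[None, :]
        new_assign = np.argmin(cost, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return assign, objective_from_assignments(K, assign)


def kernel_kmeans(K: KernelMatrix | np.ndarray, k: int, n_init: int = 200,
                  seed: int = 0, max_iter: int = 300) -> ClusterModel:
    """Multi-restart Lloyd iterations in the kernel-induced feature space.

    The assignment is initialized randomly ``n_init`` times (default 200)
    and the restart with the least within-cluster variance wins; ties go to
    the lowest restart index, so results are deterministic given ``seed``.
    """
    M = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    spec = K.spec if isinstance(K, KernelMatrix) else KernelSpec("linear")
    n = M.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"need 1 <= k <= N; got k={k}, N={n}")
    best: tuple[np.ndarray, float, int] | None = None
    seeds = np.random.SeedSequence(seed).spawn(n_init)
    for r in range(n_init):
        rng = np.random.default_rng(seeds[r])
        assign, obj = _lloyd(M, k, rng, max_iter=max_iter)
        if best is None or obj < best[1] - 1e-12:
            best = (assign, obj, r)
    assign, obj, r = best
    return ClusterModel(assignments=assign, k=k, objective=obj,
                        n_restarts=n_init, best_restart=r, spec=spec)


def exhaustive_kernel_kmeans(K: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Global optimum by enumerating every assignment (tiny N).

    Independent of the Lloyd path: evaluates the within-cluster variance
    ``trace(K) - sum_c (1/|c|) sum_{i,j in c} K_ij`` on all ``k^(N-1)``
    labelings (the first point is anchored to cluster 0 to fix label
    permutation symmetry; labelings that leave a cluster empty are never
    better than the k-cluster optimum, so they need no special casing).
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if n > 12:
        raise ValueError("exhaustive enumeration is for N <= 12")
    grids = np.meshgrid(*([np.arange(k)] * (n - 1)), indexing="ij")
    A = np.zeros((k ** (n - 1), n), dtype=int)
    for j, g in enumerate(grids):
        A[:, j + 1] = g.ravel()
    obj = np.full(A.shape[0], float(np.trace(K)))
    for c in range(k):
        M = (A == c).astype(float)
        sums = np.einsum("bi,ij,bj->b", M, K, M)
        counts = M.sum(axis=1)
        nz = counts > 0
        obj[nz] -= sums[nz] / counts[nz]
    best = int(np.argmin(obj))
    return A[best], float(obj[best])


# ---------------------------------------------------------------------------
# kernel screening

def kernel_quality(K: KernelMatrix | np.ndarray, n_bins: int = 32) -> float:
    """Shannon entropy (bits) of the off-diagonal similarity histogram.

    Higher entropy means the kernel spreads its similarity values more
    evenly over their observed range; screening keeps the argmax.
    """
    M = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    n = M.shape[0]
    if n < 3:
        raise ValueError("kernel quality needs N >= 3")
    off = M[~np.eye(n, dtype=bool)]
    lo, hi = off.min(), off.max()
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(off, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def screen_kernels(X: np.ndarray,
                   specs: list[KernelSpec] | None = None,
                   ) -> tuple[KernelMatrix, pd.DataFrame]:
    """Evaluate candidate kernels and keep the best-distributed one.

    Returns the winning kernel matrix and a table of per-spec entropy
    scores (descending).
    """
    if specs is None:
        specs = default_kernel_specs()
    rows = []
    best: tuple[float, KernelMatrix] | None = None
    for spec in specs:
        Km = compute_kernel(X, spec)
        score = kernel_quality(Km)
        rows.append({"kernel": spec.label(), "entropy_bits": score})
        if best is None or score > best[0]:
            best = (score, Km)
    table = pd.DataFrame(rows).sort_values(
        "entropy_bits", ascending=False).reset_index(drop=True)
    return best[1], table


# ---------------------------------------------------------------------------
# composition and condition-enrichment testing

def cluster_composition(model: ClusterModel, table: pd.DataFrame,
                        facets: tuple[str, ...] = ("headset", "condition",
                                                   "gender"),
                        ) -> dict[str, pd.DataFrame]:
    """Per-cluster composition tables and PSD envelopes.

    ``table`` is the feature table aligned row-wise with the clustered
    samples (metadata columns; ``f0..f255`` PSD columns if envelopes are
    wanted).  Returns ``proportions`` (cluster x facet level shares, which
    sum to 1 per cluster and facet) and, when PSD columns are present,
    ``envelopes`` (per cluster and headset: bin-wise mean, 5th and 95th
    percentile of the normalized PSDs).
    """
    if len(table) != len(model.assignments):
        raise ValueError("metadata table must align with cluster assignments")
    df = table.copy().reset_index(drop=True)
    df["cluster"] = model.assignments

    prop_rows = []
    for cluster, grp in df.groupby("cluster"):
        for facet in facets:
            if facet not in df.columns:
                continue
            counts = grp[facet].value_counts()
            for level, cnt in counts.items():
                prop_rows.append({
                    "cluster": cluster, "facet": facet, "level": level,
                    "n": int(cnt), "proportion": cnt / len(grp)})
    out = {"proportions": pd.DataFrame(prop_rows)}

    fcols = [c for c in df.columns
             if c.startswith("f") and c[1:].isdigit()]
    if fcols:
        env_rows = []
        fcols = sorted(fcols, key=lambda c: int(c[1:]))
        for (cluster, headset), grp in df.groupby(["cluster", "headset"]):
            P = grp[fcols].to_numpy(dtype=float)
            env_rows.append(pd.DataFrame({
                "cluster": cluster, "headset": headset,
                "bin": np.arange(len(fcols)),
                "mean": P.mean(axis=0),
                "p5": np.percentile(P, 5, axis=0),
                "p95": np.percentile(P, 95, axis=0)}))
        out["envelopes"] = pd.concat(env_rows, ignore_index=True)
    return out


def proportion_test(cluster_counts: tuple[int, int], overall_p_baseline: float,
                    alpha: float = 0.01) -> tuple[float, bool]:
    """Exact two-sided binomial test of a cluster's baseline share.

    ``cluster_counts = (n_baseline, n_piece_viewing)`` within one cluster;
    the null is that baseline samples occur at the overall session share
    ``overall_p_baseline``.  Returns ``(p_value, significant at alpha)``
    (default 99% confidence).
    """
    n_b, n_pv = cluster_counts
    n = n_b + n_pv
    if n < 1:
        raise ValueError("cluster has no samples")
    if not (0 < overall_p_baseline < 1):
        raise ValueError("overall baseline proportion must be in (0, 1)")
    res = binomtest(n_b, n, overall_p_baseline, alternative="two-sided")
    return float(res.pvalue), bool(res.pvalue < alpha)
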