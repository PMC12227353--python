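"""Similarity analysis across correlation matrices.

Each symmetric ROI x ROI matrix is reduced to the vector of its strict
upper triangle (n(n-1)/2 values; 6,441 for 114 ROIs). Pairs of such vectors
are compared with Spearman's rank correlation; whether one matrix is more
strongly related to a reference than another is tested with Williams' test
for dependent correlations sharing one variable; and a stack of matrices is
summarized by PCA of the column-standardized upper-triangle stack, with
component scores reshaped back into a shared-structure matrix.

A caveat documented here once: treating the n(n-1)/2 matrix entries as
independent observations (as the Spearman p-values and Williams' test do)
ignores the dependence among entries sharing an ROI. The rho values
themselves are the informative quantity; ``williams_permutation`` offers a
stricter label-permutation alternative for the contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connmat import ConnMatrix

__all__ = [
    "TriVector",
    "WilliamsResult",
    "PcaReport",
    "SimilarityReport",
    "vectorize_upper",
    "matrix_from_upper",
    "spearman_similarity",
    "williams_test",
    "williams_permutation",
    "stack_and_pca",
    "similarity_report",
]


# ---------------------------------------------------------------------------
# Upper-triangle vectorization
# ---------------------------------------------------------------------------

@dataclass
class TriVector:
    """Strict upper triangle of a symmetric matrix, row-major order.

    Length is n(n-1)/2; the ordering is fixed by ``numpy.triu_indices(n, 1)``
    (row-major) and round-trips losslessly through
    :func:`matrix_from_upper`.
    """

    values: np.ndarray
    n_roi: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        m = self.n_roi * (self.n_roi - 1) // 2
        if v.shape != (m,):
            raise ValueError(
                f"upper triangle of a {self.n_roi}-ROI matrix has {m} "
                f"values, got shape {v.shape}")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


def vectorize_upper(m: ConnMatrix | np.ndarray) -> TriVector:
    """Extract the strict upper triangle of a symmetric matrix, row-major."""
    if isinstance(m, ConnMatrix):
        arr, prov = m.values, dict(m.provenance)
    else:
        arr, prov = np.asarray(m, dtype=float), {}
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"need a square matrix, got shape {arr.shape}")
    both = np.isfinite(arr) & np.isfinite(arr.T)
    if not np.allclose(arr[both], arr.T[both], atol=1e-8):
        raise ValueError("matrix is asymmetric beyond 1e-8")
    n = arr.shape[0]
    iu = np.triu_indices(n, k=1)
    return TriVector(arr[iu].copy(), n, prov)


def matrix_from_upper(tri: TriVector, diagonal: float = 1.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an upper-triangle vector."""
    n = tri.n_roi
    out = np.full((n, n), float(diagonal))
    iu = np.triu_indices(n, k=1)
    out[iu] = tri.values
    out[(iu[1], iu[0])] = tri.values
    return out


# ---------------------------------------------------------------------------
# Spearman similarity
# ---------------------------------------------------------------------------

def _pair_values(a: TriVector | np.ndarray,
                 b: TriVector | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = a.values if isinstance(a, TriVector) else np.asarray(a, dtype=float)
    y = b.values if isinstance(b, TriVector) else np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def spearman_similarity(a: TriVector | np.ndarray,
                        b: TriVector | np.ndarray) -> tuple[float, float]:
    """Spearman's rank correlation between two upper-triangle vectors.

    Ties get average (mid) ranks; the two-tailed p-value uses the large-n t
    approximation. Entries that are NaN in either vector (flagged ROI pairs)
    are dropped pairwise. With thousands of ROI pairs even tiny rho are
    "significant"; interpret the rho value, not the p.
    """
    x, y = _pair_values(a, b)
    if x.size < 4:
        raise ValueError(f"need >= 4 paired finite values, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho is undefined for a constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# Williams' test for dependent correlations
# ---------------------------------------------------------------------------

@dataclass
class WilliamsResult:
    """Williams' test of r_jk vs r_jh (two correlations sharing variable j),
    with r_kh the correlation between the non-shared variables and n the
    number of paired observations. df = n - 3; p is two-tailed. The sign of
    t reports the direction (positive when r_jk > r_jh)."""

    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    t: float
    df: int
    p: float


def williams_test(r_jk: float, r_jh: float, r_kh: float,
                  n: int) -> WilliamsResult:
    """Test whether two dependent correlations sharing one variable differ.

    t = (r_jk - r_jh) * sqrt( (n-1)(1+r_kh) /
        ( 2 (n-1)/(n-3) |R| + rbar^2 (1-r_kh)^3 ) ),
    with |R| = 1 - r_jk^2 - r_jh^2 - r_kh^2 + 2 r_jk r_jh r_kh and
    rbar = (r_jk + r_jh)/2, referred to Student's t with df = n - 3.
    """
    if n <= 3:
        raise ValueError(f"Williams' test needs n > 3, got {n}")
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not (-1.0 < r < 1.0):
            raise ValueError(f"{name} must lie in (-1, 1), got {r}")
    detR = 1.0 - r_jk ** 2 - r_jh ** 2 - r_kh ** 2 + 2.0 * r_jk * r_jh * r_kh
    if detR <= 0:
        raise ValueError(
            f"impossible correlation triple: |R| = {detR:.6g} <= 0")
    rbar = (r_jk + r_jh) / 2.0
    denom = 2.0 * (n - 1) / (n - 3) * detR + rbar ** 2 * (1.0 - r_kh) ** 3
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1.0 + r_kh) / denom)
    df = n - 3
    p = 2.0 * stats.t.sf(abs(t), df)
    return WilliamsResult(r_jk, r_jh, r_kh, n, float(t), df, float(p))


def williams_permutation(a: ConnMatrix, b: ConnMatrix, ref: ConnMatrix,
                         n_perm: int = 1000, seed: int = 0) -> dict:
    """Label-permutation alternative to Williams' test.

    Null distribution of d = rho(a, ref) - rho(b, ref) under joint row/column
    permutation of the reference matrix's ROI labels, which breaks the
    alignment with both comparands symmetrically while preserving each
    matrix's internal dependence structure.
    """
    ta, tb = vectorize_upper(a), vectorize_upper(b)
    tref = vectorize_upper(ref)
    d_obs = (spearman_similarity(ta, tref)[0]
             - spearman_similarity(tb, tref)[0])
    rng = np.random.default_rng(seed)
    n = ref.n_roi
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        shuffled = ref.values[np.ix_(perm, perm)]
        tp = vectorize_upper(shuffled)
        null[i] = (spearman_similarity(ta, tp)[0]
                   - spearman_similarity(tb, tp)[0])
    p = float((np.sum(np.abs(null) >= abs(d_obs)) + 1) / (n_perm + 1))
    return {"delta_rho": float(d_obs), "p_perm": p, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# PCA over stacked matrices
# ---------------------------------------------------------------------------

@dataclass
class PcaReport:
    """PCA of the column-standardized upper-triangle stack.

    ``explained_variance_ratio`` sums to 1 over all components;
    ``loadings[i, c]`` is matrix i's weight on component c (sign fixed so
    each component's mean loading is non-negative); ``score_matrices[c]`` is
    the component's score vector reshaped to a symmetric ROI x ROI matrix
    (zero diagonal — scores are not correlations)."""

    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    score_matrices: list[np.ndarray]
    labels: list[str]
    roi_names: list[str]


def stack_and_pca(matrices: list[ConnMatrix],
                  labels: list[str] | None = None) -> PcaReport:
    """PCA across matrices: z-transform each matrix's upper-triangle vector
    (sample sd, n-1), then singular value decomposition of the stacked
    pairs x matrices array. Variance fractions come from the squared
    singular values."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices for a PCA")
    n = matrices[0].n_roi
    roi_names = list(matrices[0].roi_names)
    labels = list(labels) if labels is not None else [
        m.provenance.get("mode", f"matrix_{i}") for i, m in enumerate(matrices)]
    cols = []
    for lab, m in zip(labels, matrices):
        if m.n_roi != n:
            raise ValueError(f"matrix {lab!r} has {m.n_roi} ROIs, expected {n}")
        v = vectorize_upper(m).values
        sd = v.std(ddof=1)
        if not sd > 0:
            raise ValueError(f"matrix {lab!r} has a constant upper triangle")
        cols.append((v - v.mean()) / sd)
    X = np.column_stack(cols)                       # pairs x matrices
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    evr = s ** 2 / np.sum(s ** 2)
    loadings = Vt.T.copy()                          # matrices x components
    scores = U * s                                  # pairs x components
    for c in range(loadings.shape[1]):
        if loadings[:, c].mean() < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0
    score_matrices = [
        matrix_from_upper(TriVector(scores[:, c], n), diagonal=0.0)
        for c in range(scores.shape[1])]
    return PcaReport(evr, loadings, score_matrices, labels, roi_names)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class SimilarityReport:
    """All-pairs Spearman rho matrix over a labeled set of correlation
    matrices, requested Williams contrasts, and the PCA report."""

    rho: pd.DataFrame
    p: pd.DataFrame
    williams: list[dict]
    pca: PcaReport | None
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "rho": self.rho.to_dict(),
            "p": self.p.to_dict(),
            "williams": self.williams,
            "provenance": self.provenance,
        }
        if self.pca is not None:
            payload["pca"] = {
                "explained_variance_ratio":
                    self.pca.explained_variance_ratio.tolist(),
                "loadings": self.pca.loadings.tolist(),
                "labels": self.pca.labels,
            }
        Path(path).write_text(
            json.dumps(payload, sort_keys=True, indent=2, default=str) + "\n")


def similarity_report(matrices: dict[str, ConnMatrix],
                      williams_contrasts: list[tuple[str, str, str]] | None = None,
                      do_pca: bool = True) -> SimilarityReport:
    """Compare a labeled set of correlation matrices.

    ``williams_contrasts`` lists (a, b, reference) label triples, each asking
    whether matrix a correlates more strongly with the reference than matrix
    b does (the two correlations share the reference, so Williams' test
    applies with n = number of ROI pairs).
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to compare")
    labels = list(matrices)
    tris = {lab: vectorize_upper(m) for lab, m in matrices.items()}
    k = len(labels)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r, p = spearman_similarity(tris[labels[i]], tris[labels[j]])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=labels, columns=labels)
    p_df = pd.DataFrame(pmat, index=labels, columns=labels)

    williams = []
    for a, b, ref in (williams_contrasts or []):
        res = williams_test(rho_df.loc[a, ref], rho_df.loc[b, ref],
                            rho_df.loc[a, b], len(tris[ref]))
        williams.append({
            "a": a, "b": b, "reference": ref,
            "rho_a_ref": res.r_jk, "rho_b_ref": res.r_jh,
            "rho_a_b": res.r_kh, "n_pairs": res.n,
            "t": res.t, "df": res.df, "p": res.p,
            "direction": a if res.t > 0 else b,
        })

    pca = stack_and_pca(list(matrices.values()), labels) if do_pca else None
    prov = {lab: m.provenance for lab, m in matrices.items()}
    return SimilarityReport(rho_df, p_df, williams, pca, prov)
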