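"""Identity-by-state relationships and classical multidimensional scaling.

IBS between samples i and j is mean allele sharing over the SNPs genotyped
in both:

    IBS_ij = 1 - sum_k |G_ik - G_jk| / (2 * N_ij)

with N_ij the number of SNPs non-missing in both samples.  IBS lies in
[0, 1], with 1 meaning identical genotypes.  Axes of genetic variation are
the principal coordinates of the distance matrix 1 - IBS (Torgerson double
centering followed by eigendecomposition), ordered by decreasing eigenvalue.

The pairwise Manhattan sums are computed through a two-bit genotype
encoding: with x1 = [G >= 1] and x2 = [G == 2],

    |G_i - G_j| = |x1_i - x1_j| + |x2_i - x2_j|

and for binary u, v:  |u - v| = u + v - 2uv, so everything reduces to a
single BLAS rank-k update.  All products involve only small integers, which
float32 represents exactly for panels up to ~8M SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import blas as _blas, eigh as _eigh

from .simulate import MISSING, GenotypeMatrix

__all__ = ["SimilarityMatrix", "MDSResult", "ibs_matrix", "classical_mds", "ld_thin"]


@dataclass
class SimilarityMatrix:
    """Pairwise IBS values plus per-pair shared-SNP counts."""

    values: np.ndarray       # (n, n) float64 in [0, 1], symmetric, diag 1
    pair_counts: np.ndarray  # (n, n) int64, N_ij >= 1

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("IBS values must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("IBS diagonal must be 1")
        counts = np.asarray(self.pair_counts)
        if counts.shape != v.shape:
            raise ValueError("pair_counts shape mismatch")
        if np.any(counts < 1):
            i, j = np.argwhere(counts < 1)[0]
            raise ValueError(f"samples {i} and {j} share no genotyped SNPs")
        self.values = v
        self.pair_counts = counts

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


@dataclass
class MDSResult:
    """Principal-coordinate scores (columns ordered by decreasing eigenvalue)."""

    scores: np.ndarray       # (n, T)
    eigenvalues: np.ndarray  # (T,), positive, non-increasing

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(ev) > 1e-9 * max(1.0, abs(ev[0]) if ev.size else 1.0)):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(ev <= 0):
            raise ValueError("only positive-eigenvalue axes are retained")
        self.eigenvalues = ev

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def _syrk_full(x: np.ndarray) -> np.ndarray:
    """x @ x.T via BLAS ssyrk (half the flops of a full GEMM), symmetrized."""
    s = _blas.ssyrk(1.0, np.ascontiguousarray(x, dtype=np.float32))
    # ssyrk fills one triangle; mirror it
    s = np.triu(s) + np.triu(s, 1).T
    return s


def ibs_matrix(G: GenotypeMatrix) -> SimilarityMatrix:
    """Pairwise IBS over all samples of a genotype matrix.

    SNPs missing in either member of a pair are excluded from both the
    allele-difference sum and N_ij for that pair.  A pair with no shared
    genotyped SNP is an error.
    """
    g = G.values
    n, m = g.shape
    if n < 2:
        raise ValueError("IBS needs at least two samples")

    any_missing = bool((g == MISSING).any())
    if not any_missing:
        x = np.empty((n, 2 * m), dtype=np.float32)
        np.greater_equal(g, 1, out=x[:, :m], casting="unsafe")
        np.equal(g, 2, out=x[:, m:], casting="unsafe")
        s = _syrk_full(x)
        r = x.sum(axis=1, dtype=np.float64)
        num = r[:, None] + r[None, :] - 2.0 * s
        counts = np.full((n, n), m, dtype=np.int64)
    else:
        x1 = (g >= 1).astype(np.float32)
        x2 = (g == 2).astype(np.float32)
        obs = (g != MISSING).astype(np.float32)
        x1 *= obs
        x2 *= obs
        counts_f = _syrk_full(obs)
        counts = np.rint(counts_f).astype(np.int64)
        if np.any(counts < 1):
            i, j = np.argwhere(counts < 1)[0]
            raise ValueError(
                f"samples {G.sample_ids[i]!r} and {G.sample_ids[j]!r} "
                "share no genotyped SNPs"
            )
        # sum over shared SNPs of u_i + u_j - 2 u_i u_j, for each bit plane
        num = np.zeros((n, n))
        for xb in (x1, x2):
            cross = xb.astype(np.float64) @ obs.astype(np.float64).T
            num += cross + cross.T - 2.0 * _syrk_full(xb)
    ibs = 1.0 - num / (2.0 * counts)
    np.fill_diagonal(ibs, 1.0)
    np.clip(ibs, 0.0, 1.0, out=ibs)
    return SimilarityMatrix(ibs, counts)


def classical_mds(S: SimilarityMatrix, t_max: int) -> MDSResult:
    """Principal coordinates of the distance matrix D = 1 - IBS.

    Torgerson double centering B = -1/2 * J (D*D) J is eigendecomposed; the
    top ``t_max`` positive-eigenvalue axes are returned with scores scaled
    by sqrt(eigenvalue).  Axes with non-positive eigenvalues (non-Euclidean
    noise) are dropped, so fewer than ``t_max`` columns may come back.
    """
    n = S.n_samples
    t_max = int(t_max)
    if not 1 <= t_max < n:
        raise ValueError(f"t_max must satisfy 1 <= t_max < n={n}, got {t_max}")
    d2 = (1.0 - S.values) ** 2
    row = d2.mean(axis=0)
    b = -0.5 * (d2 - row[:, None] - row[None, :] + row.mean())
    vals, vecs = _eigh(b, subset_by_index=[n - t_max, n - 1])
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(1.0, vals[0]) if vals.size else 0.0
    keep = vals > tol
    vals, vecs = vals[keep], vecs[:, keep]
    scores = vecs * np.sqrt(vals)[None, :]
    if scores.size:
        scores = scores - scores.mean(axis=0)  # exact zero-mean columns
    return MDSResult(scores, vals)


def ld_thin(G: GenotypeMatrix, r2_max: float, window: int = 50) -> GenotypeMatrix:
    """Greedy LD pruning: drop the later SNP of any pair with r^2 > ``r2_max``.

    Scans left to right; each kept SNP is compared (squared Pearson
    correlation of dosages, pairwise-complete) against the previous kept
    SNPs inside ``window``.  Intended for real genotype data; simulated
    panels here are unlinked.
    """
    if not 0.0 < r2_max <= 1.0:
        raise ValueError(f"r2_max must lie in (0, 1], got {r2_max}")
    g = np.where(G.values == MISSING, np.nan, G.values).astype(float)
    kept: list[int] = []
    for k in range(G.n_snps):
        ok = True
        for prev in reversed(kept):
            if k - prev > window:
                break
            both = ~np.isnan(g[:, k]) & ~np.isnan(g[:, prev])
            if both.sum() < 3:
                continue
            a, b = g[both, k], g[both, prev]
            if a.std() == 0 or b.std() == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(k)
    return GenotypeMatrix(
        G.values[:, kept],
        list(G.sample_ids),
        [G.snp_ids[k] for k in kept],
    )
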