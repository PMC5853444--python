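"""Population-structure summaries: PCA, IBS distance, NJ tree, kinship.

PCA operates on mean-centered dosages (missing calls imputed to the SNP
mean for the decomposition only).  The genetic distance is 1 minus the
identity-by-state proportion.  The Neighbor-Joining tree is the standard
Saitou-Nei agglomeration with negative branch lengths clamped to zero (the
deficit transferred to the sister branch).  Kinship is VanRaden method 1:
K = Z Z' / (2 sum p(1-p)) with Z the centered dosage matrix.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, ValidationError


@dataclass
class PcaResult:
    scores: pd.DataFrame                      # samples x PC1..PCk
    explained_variance_fraction: np.ndarray   # non-increasing, sums to <= 1


@dataclass
class DistanceMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]


@dataclass
class KinshipMatrix:
    samples: list[str]
    values: np.ndarray  # symmetric PSD


def _imputed_centered(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(centered dosage with mean-imputed missing, per-SNP allele freq p)."""
    d = g.dosage_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        mean = np.nanmean(d, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    d = np.where(np.isnan(d), mean, d)
    return d - mean, mean / 2.0


def pca(g: GenotypeMatrix, n_components: int = 10, standardize: bool = False) -> PcaResult:
    """Principal components of the centered (optionally standardized) dosages."""
    if g.n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    Z, p = _imputed_centered(g)
    if standardize:
        sd = np.sqrt(2.0 * p * (1.0 - p))
        Z = np.divide(Z, sd, out=np.zeros_like(Z), where=sd > 0)
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        warnings.warn(f"requested {n_components} components but rank is {rank}; truncating")
        n_components = rank
    total = float(np.sum(s**2))
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * s[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(pd.DataFrame(scores, index=list(g.samples), columns=cols), frac)


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS proportion over SNPs called in both samples of each pair.

    IBS similarity per SNP is 1 - |x_i - x_j| / 2, so identical genotypes
    score 1 and opposite homozygotes 0.
    """
    D = g.dosage
    n = g.n_samples
    # |a-b| summed over SNPs via one-hot matmuls (9 n x n products)
    hot = [(D == v).astype(np.float64) for v in (0, 1, 2)]
    called = (D != MISSING).astype(np.float64)
    shared = called @ called.T
    absdiff = np.zeros((n, n))
    for u in range(3):
        for v in range(3):
            if u == v:
                continue
            absdiff += abs(u - v) * (hot[u] @ hot[v].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = absdiff / (2.0 * shared)
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(g.samples), d)


def _quote_label(label: str) -> str:
    return label if re.fullmatch(r"[\w.\-]+", label) else "'" + label.replace("'", "''") + "'"


def nj_tree(dist: DistanceMatrix | np.ndarray, labels: list[str] | None = None) -> str:
    """Saitou-Nei Neighbor-Joining; returns an unrooted newick string.

    Exact on additive distances.  Negative branch lengths are clamped to
    zero with the length transferred to the sister branch.  Ties in the Q
    matrix break on the lowest index pair, so the output is deterministic.
    """
    if isinstance(dist, DistanceMatrix):
        D = np.array(dist.values, dtype=np.float64)
        labels = list(dist.samples)
    else:
        D = np.array(dist, dtype=np.float64)
        if labels is None:
            labels = [f"t{i}" for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 3:
        raise ValidationError("NJ needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    nodes = [_quote_label(l) for l in labels]
    active = list(range(n))

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return li, lj

    while len(active) > 3:
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        m = len(active)
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = idx[i_loc], idx[j_loc]
        dij = D[i, j]
        li = dij / 2.0 + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        new_row = 0.5 * (D[i, idx] + D[j, idx] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        D[u, idx] = new_row
        D[idx, u] = new_row
        D[u, u] = 0.0
        nodes.append(f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})")
        active = [k for k in active if k not in (i, j)] + [u]
    i, j, k = active
    # three-point formulas for the final star
    x = max(0.0, (D[i, j] + D[i, k] - D[j, k]) / 2.0)
    y = max(0.0, (D[i, j] + D[j, k] - D[i, k]) / 2.0)
    z = max(0.0, (D[i, k] + D[j, k] - D[i, j]) / 2.0)
    return f"({nodes[i]}:{x:.10g},{nodes[j]}:{y:.10g},{nodes[k]}:{z:.10g});"


def kinship_vanraden(g: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden (2008) method-1 genomic relationship matrix.

    Monomorphic SNPs contribute nothing and are excluded from the scaling
    denominator; missing calls are imputed to the SNP mean.
    """
    Z, p = _imputed_centered(g)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValidationError("kinship needs at least one polymorphic SNP")
    Z = Z[:, poly]
    p = p[poly]
    scale = 2.0 * np.sum(p * (1.0 - p))
    K = (Z @ Z.T) / scale
    return KinshipMatrix(list(g.samples), K)
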