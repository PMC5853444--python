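"""Linkage disequilibrium: pairwise r2, decay curves, weak/strong regions.

r2 on unphased diploids is the composite (Rogers-Huff) estimate: the squared
Pearson correlation of dosage vectors over samples non-missing at both SNPs.
It is deterministic, needs no phasing or EM, and converges to the haplotype
r2 under Hardy-Weinberg; an EM haplotype-frequency mode is available for
cross-checks.

Region classification follows the genome-wide empirical rule: within each
non-overlapping 10 kb window, mean r2 over adjacent SNP pairs is computed;
windows in the bottom 5% genome-wide are "weak" LD regions, the top 5%
"strong" (nearest-rank percentiles, ties on the threshold included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, ValidationError


def subgenome_of(chrom: str) -> str:
    """Subgenome letter from the chromosome name prefix (A01 -> 'A')."""
    c = chrom[:1].upper()
    return c if c in ("A", "C") else "?"


# ----------------------------------------------------------------------
# pairwise r2
# ----------------------------------------------------------------------

def r2_composite(dosage_i, dosage_j) -> float:
    """Composite r2: squared dosage correlation over shared non-missing samples.

    NaN when fewer than two shared calls or either SNP is monomorphic on the
    shared set.  Symmetric and invariant to allele relabeling.
    """
    x = np.asarray(dosage_i, dtype=np.float64)
    y = np.asarray(dosage_j, dtype=np.float64)
    ok = (x != MISSING) & (y != MISSING) & ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return float("nan")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def r2_em(dosage_i, dosage_j, n_iter: int = 64, tol: float = 1e-10) -> float:
    """Haplotype-frequency r2 via EM on unphased diploid pairs (cross-check mode)."""
    x = np.asarray(dosage_i, dtype=np.float64)
    y = np.asarray(dosage_j, dtype=np.float64)
    ok = (x != MISSING) & (y != MISSING) & ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.var() == 0 or y.var() == 0:
        return float("nan")
    n = x.size
    pA = x.mean() / 2
    pB = y.mean() / 2
    pAB = pA * pB  # start at linkage equilibrium
    for _ in range(n_iter):
        # double-het individuals are ambiguous: AB/ab vs Ab/aB
        pAb, paB = pA - pAB, pB - pAB
        pab = 1 - pA - pB + pAB
        denom = pAB * pab + pAb * paB
        frac = pAB * pab / denom if denom > 0 else 0.5
        het2 = (x == 1) & (y == 1)
        count_AB = (
            2.0 * np.sum((x == 2) & (y == 2))
            + np.sum((x == 2) & (y == 1)) + np.sum((x == 1) & (y == 2))
            + frac * np.sum(het2)
        )
        new = count_AB / (2 * n)
        if abs(new - pAB) < tol:
            pAB = new
            break
        pAB = new
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    return float(D * D / denom) if denom > 0 else float("nan")


def _pairwise_r2(g: GenotypeMatrix, ii: np.ndarray, jj: np.ndarray,
                 chunk: int = 65536) -> np.ndarray:
    """Composite r2 for many (i, j) SNP index pairs, missing-aware, chunked."""
    D = g.dosage
    out = np.empty(ii.size, dtype=np.float64)
    X = D.astype(np.float64)
    M = (D != MISSING).astype(np.float64)
    X = X * M  # zero out missing
    for s in range(0, ii.size, chunk):
        a = ii[s:s + chunk]
        b = jj[s:s + chunk]
        Xi, Xj = X[:, a], X[:, b]
        Mi, Mj = M[:, a], M[:, b]
        Mij = Mi * Mj
        n = Mij.sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sx = (Xi * Mij).sum(0)
            sy = (Xj * Mij).sum(0)
            sxx = (Xi * Xi * Mij).sum(0)
            syy = (Xj * Xj * Mij).sum(0)
            sxy = (Xi * Xj * Mij).sum(0)
            cov = sxy / n - sx * sy / n**2
            vx = sxx / n - (sx / n) ** 2
            vy = syy / n - (sy / n) ** 2
            r2 = cov * cov / (vx * vy)
        r2[(n < 2) | (vx <= 0) | (vy <= 0)] = np.nan
        out[s:s + chunk] = r2
    return out


# ----------------------------------------------------------------------
# decay curves
# ----------------------------------------------------------------------

@dataclass
class DecayCurve:
    """Binned mean r2 vs physical distance with its half-decay distance.

    ``half_decay_distance`` is the smallest bin midpoint where the
    monotone-smoothed curve drops to half of its maximum (NaN if it never
    does within range).
    """

    bins: pd.DataFrame = field(default_factory=pd.DataFrame)
    half_decay_distance: float = float("nan")

    @property
    def empty(self) -> bool:
        return self.bins.empty


def _half_decay(mids: np.ndarray, mean_r2: np.ndarray, weights: np.ndarray) -> float:
    from sklearn.isotonic import IsotonicRegression

    ok = ~np.isnan(mean_r2)
    if ok.sum() == 0:
        return float("nan")
    iso = IsotonicRegression(increasing=False)
    smooth = iso.fit_transform(mids[ok], mean_r2[ok], sample_weight=weights[ok])
    half = smooth.max() / 2.0
    below = np.flatnonzero(smooth <= half)
    return float(mids[ok][below[0]]) if below.size else float("nan")


def ld_decay(g: GenotypeMatrix, max_dist: int = 5_000_000, bin_width: int = 50_000,
             groupby: str = "subgenome") -> dict[str, DecayCurve]:
    """LD decay curves per subgenome (default) or per chromosome.

    All intra-chromosomal SNP pairs at distance <= ``max_dist`` enter; mean
    r2 is binned by distance and smoothed by decreasing isotonic regression
    before locating the half-decay distance.
    """
    if not (max_dist >= bin_width > 0):
        raise ValidationError("need max_dist >= bin_width > 0")
    n_bins = int(np.ceil(max_dist / bin_width))
    chrom_arr = g.snps["chrom"].to_numpy()
    acc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in dict.fromkeys(chrom_arr):
        key = subgenome_of(chrom) if groupby == "subgenome" else chrom
        sums, counts = acc.setdefault(key, (np.zeros(n_bins), np.zeros(n_bins, dtype=np.int64)))
        sel = np.flatnonzero(chrom_arr == chrom)
        pos = g.snps["pos"].to_numpy()[sel]
        m = sel.size
        if m < 2:
            continue
        hi = np.searchsorted(pos, pos + max_dist, side="right")
        counts_per = hi - np.arange(m) - 1
        tot = int(counts_per.sum())
        if tot == 0:
            continue
        ii_local = np.repeat(np.arange(m), counts_per)
        offsets = np.concatenate([[0], np.cumsum(counts_per)])[:-1]
        jj_local = np.arange(tot) - np.repeat(offsets, counts_per) + ii_local + 1
        dist = pos[jj_local] - pos[ii_local]
        keep = dist > 0
        ii_local, jj_local, dist = ii_local[keep], jj_local[keep], dist[keep]
        r2 = _pairwise_r2(g, sel[ii_local], sel[jj_local])
        ok = ~np.isnan(r2)
        b = np.minimum(dist[ok] // bin_width, n_bins - 1).astype(np.int64)
        sums += np.bincount(b, weights=r2[ok], minlength=n_bins)
        counts += np.bincount(b, minlength=n_bins)
    curves: dict[str, DecayCurve] = {}
    for key, (sums, counts) in acc.items():
        if counts.sum() == 0:
            curves[key] = DecayCurve()
            continue
        mids = (np.arange(n_bins) + 0.5) * bin_width
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_r2 = sums / counts
        bins = pd.DataFrame({
            "bin_lo": np.arange(n_bins) * bin_width,
            "bin_hi": (np.arange(n_bins) + 1) * bin_width,
            "mid": mids,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        })
        curves[key] = DecayCurve(bins, _half_decay(mids, mean_r2, counts.astype(float)))
    return curves


# ----------------------------------------------------------------------
# weak/strong LD regions
# ----------------------------------------------------------------------

def nearest_rank_low(values: np.ndarray, tail: float) -> float:
    """Largest value of the bottom `tail` fraction (nearest-rank percentile)."""
    v = np.sort(np.asarray(values))
    k = int(np.ceil(tail * v.size))
    return float(v[max(k - 1, 0)])


def nearest_rank_high(values: np.ndarray, tail: float) -> float:
    """Smallest value of the top `tail` fraction (nearest-rank percentile)."""
    v = np.sort(np.asarray(values))
    k = int(np.ceil(tail * v.size))
    return float(v[v.size - max(k, 1)])


def classify_ld_regions(g: GenotypeMatrix, window_size: int = 10_000,
                        tail: float = 0.05) -> pd.DataFrame:
    """Classify non-overlapping windows as weak/strong LD regions.

    Per window the score is mean composite r2 over adjacent SNP pairs lying
    fully inside the window; windows with no scoreable pair get class
    ``neither`` and a NaN score.  Thresholds are genome-wide nearest-rank
    percentiles with ties on the threshold included in the tail.
    """
    import warnings

    if not (0 < tail < 0.5):
        raise ValidationError("tail must be in (0, 0.5)")
    chrom_arr = g.snps["chrom"].to_numpy()
    pos0 = g.snps["pos"].to_numpy() - 1
    rows = []
    for chrom in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero(chrom_arr == chrom)
        p0 = pos0[sel]
        wid = p0 // window_size
        ii = sel[:-1]
        jj = sel[1:]
        same = wid[:-1] == wid[1:]
        r2 = np.full(ii.size, np.nan)
        if same.any():
            r2[same] = _pairwise_r2(g, ii[same], jj[same])
        pair_w = wid[:-1]
        # aggregate by window id over valid pairs
        valid = same & ~np.isnan(r2)
        n_snps_per_w = pd.Series(wid).value_counts().sort_index()
        sums: dict[int, float] = {}
        cnts: dict[int, int] = {}
        for w, v in zip(pair_w[valid], r2[valid]):
            sums[w] = sums.get(w, 0.0) + v
            cnts[w] = cnts.get(w, 0) + 1
        for w, n_snps in n_snps_per_w.items():
            score = sums[w] / cnts[w] if w in cnts else np.nan
            rows.append((chrom, int(w * window_size), int((w + 1) * window_size),
                         int(n_snps), score))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "mean_adjacent_r2"])
    regions["klass"] = "neither"
    scores = regions["mean_adjacent_r2"].to_numpy()
    scoreable = ~np.isnan(scores)
    n_sc = int(scoreable.sum())
    if n_sc < 20:
        warnings.warn(f"only {n_sc} scoreable LD windows; percentile thresholds are unstable")
    if n_sc:
        low = nearest_rank_low(scores[scoreable], tail)
        high = nearest_rank_high(scores[scoreable], tail)
        weak = scoreable & (scores <= low)
        strong = scoreable & (scores >= high) & ~weak
        regions.loc[weak, "klass"] = "weak"
        regions.loc[strong, "klass"] = "strong"
    regions["subgenome"] = [subgenome_of(c) for c in regions["chrom"]]
    return regions


def ld_region_summary(regions: pd.DataFrame, chrom_lengths: dict[str, int],
                      window_size: int = 10_000) -> pd.DataFrame:
    """Counts of weak/strong regions per subgenome and % of genome covered."""
    total_bp = float(sum(chrom_lengths.values()))
    rows = []
    for klass in ("weak", "strong"):
        sub = regions[regions["klass"] == klass]
        n = len(sub)
        for sg in sorted(sub["subgenome"].unique()):
            n_sg = int((sub["subgenome"] == sg).sum())
            rows.append((klass, sg, n_sg, 100.0 * n_sg / n if n else 0.0,
                         100.0 * n_sg * window_size / total_bp))
    return pd.DataFrame(rows, columns=["klass", "subgenome", "n_regions",
                                       "pct_of_class", "pct_genome_covered"])


def join_homoeology(regions: pd.DataFrame, table: pd.DataFrame) -> dict[str, int]:
    """Count homoeologous weak<->weak and strong<->strong region pairs.

    ``table`` maps A-subgenome intervals to their homoeologous C-subgenome
    intervals (columns ``a_chrom, a_start, a_end, c_chrom, c_start, c_end``,
    0-based half-open).  A region pair counts when each region overlaps its
    mapped interval by at least 1 bp; (A-region, C-region) pairs are counted
    once even if several mappings link them.
    """
    need = {"a_chrom", "a_start", "a_end", "c_chrom", "c_start", "c_end"}
    if not need.issubset(table.columns):
        raise ValidationError(f"homoeology table needs columns {sorted(need)}")
    if (table["a_start"] >= table["a_end"]).any() or (table["c_start"] >= table["c_end"]).any():
        raise ValidationError("malformed homoeology interval (start >= end)")
    counts = {"weak": 0, "strong": 0}
    for klass in counts:
        sub = regions[regions["klass"] == klass]
        pairs: set[tuple[int, int]] = set()
        for row in table.itertuples(index=False):
            a_hits = sub.index[(sub["chrom"] == row.a_chrom)
                               & (sub["start"] < row.a_end) & (sub["end"] > row.a_start)]
            if len(a_hits) == 0:
                continue
            c_hits = sub.index[(sub["chrom"] == row.c_chrom)
                               & (sub["start"] < row.c_end) & (sub["end"] > row.c_start)]
            for ai in a_hits:
                for ci in c_hits:
                    pairs.add((ai, ci))
        counts[klass] = len(pairs)
    return counts
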