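"""Sliding-window diversity and differentiation statistics.

Per 100 kb window (stepped every 10 kb by default) and per ecotype group the
scan reports nucleotide diversity pi (mean per-SNP unbiased heterozygosity),
the number of segregating sites S, Watterson's theta and Tajima's D; per
group contrast it reports the Weir-Cockerham FST (ratio of sums of variance
components across SNPs) and the pi ratio pi_A / pi_B.

Array panels carry no invariant sites, so pi is reported per SNP rather than
per bp; ``pi_sum`` (summed site pi) is kept alongside because Tajima's D is
defined on the windowed sum.

FST uses the two-population Weir & Cockerham (1984) moments estimator in its
allele-count (random-union-of-gametes) form: within groups, Hardy-Weinberg
proportions are assumed and the 2N called alleles are treated as the sample,
so no observed-heterozygote term enters.  Per window the components are
combined as a ratio of sums, the standard multi-locus estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable, ValidationError

GroupSet = tuple[str, ...]


def _as_groupset(side: str | Sequence[str]) -> GroupSet:
    if isinstance(side, str):
        return tuple(side.split("+"))
    return tuple(side)


def side_label(side: str | Sequence[str]) -> str:
    return "+".join(_as_groupset(side))


def contrast_label(a: str | Sequence[str], b: str | Sequence[str]) -> str:
    return f"{side_label(a)}_vs_{side_label(b)}"


# ----------------------------------------------------------------------
# windows
# ----------------------------------------------------------------------

def make_windows(chrom_lengths: dict[str, int], size: int = 100_000,
                 step: int = 10_000) -> pd.DataFrame:
    """Sliding windows over each chromosome (0-based half-open intervals).

    Starts run 0, step, 2*step, ... while they fall inside the chromosome;
    the trailing windows are truncated at the chromosome end, so the union of
    windows covers each chromosome exactly.
    """
    if not (size >= step > 0):
        raise ValidationError("need size >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(0, length, step)
        for s in starts:
            rows.append((chrom, int(s), int(min(s + size, length))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ----------------------------------------------------------------------
# site-level statistics
# ----------------------------------------------------------------------

def site_pi(alt_count, allele_n):
    """Unbiased per-site nucleotide diversity from allele counts.

    pi_site = n/(n-1) * 2 p (1-p) with p = alt_count / n; equals the mean
    pairwise difference among the n sampled alleles.  Undefined (NaN) when
    fewer than two alleles were called.
    """
    alt = np.asarray(alt_count, dtype=np.float64)
    n = np.asarray(allele_n, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        pi = n / (n - 1.0) * 2.0 * p * (1.0 - p)
    return np.where(n >= 2, pi, np.nan)


@dataclass(frozen=True)
class TajimaConstants:
    """The standard Tajima (1989) normalizing constants for n_seq sequences."""

    n_seq: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n_seq: int) -> TajimaConstants:
    if n_seq < 4:
        raise ValidationError("Tajima's D needs at least 4 sequences")
    n = float(n_seq)
    i = np.arange(1, n_seq)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n_seq, a1, a2, b1, b2, c1, c2, e1, e2)


def tajima_d(S, pi_sum, n_seq):
    """Tajima's D from segregating sites and summed site pi.

    D = (pi_sum - S/a1) / sqrt(e1 S + e2 S (S-1)); NaN when S = 0 (the
    variance is undefined) or n_seq < 4.
    """
    S = np.asarray(S, dtype=np.float64)
    pi_sum = np.asarray(pi_sum, dtype=np.float64)
    n = np.asarray(n_seq, dtype=np.int64)
    scalar = S.ndim == 0
    S, pi_sum, n = np.atleast_1d(S, pi_sum, n)
    out = np.full(S.shape, np.nan)
    ok = (S > 0) & (n >= 4)
    if ok.any():
        a1, e1, e2 = _tajima_e_vec(n[ok])
        var = e1 * S[ok] + e2 * S[ok] * (S[ok] - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[ok] = (pi_sum[ok] - S[ok] / a1) / np.sqrt(var)
    return float(out[0]) if scalar else out


def _tajima_e_vec(n_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (a1, e1, e2) for an array of sequence counts."""
    n_max = int(n_arr.max())
    inv = 1.0 / np.arange(1, n_max)
    H1 = np.concatenate([[0.0], np.cumsum(inv)])        # H1[k] = sum_{i<=k} 1/i
    H2 = np.concatenate([[0.0], np.cumsum(inv**2)])
    n = n_arr.astype(np.float64)
    a1 = H1[n_arr - 1]
    a2 = H2[n_arr - 1]
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return a1, c1 / a1, c2 / (a1**2 + a2)


def wc_fst_components(alt_counts, allele_ns):
    """Two-population Weir-Cockerham variance components from allele counts.

    Parameters are arrays of shape ``(2, ...)``: alternate-allele counts and
    called-allele totals for the two populations.  Returns ``(a, b, c)``
    where ``a`` is the among-population component and ``b + c`` the within
    component (``c`` is identically zero in this allele-count form); the
    per-site estimator is theta = a / (a + b + c).  Sites with fewer than two
    called alleles in either population yield NaN components.
    """
    alt = np.asarray(alt_counts, dtype=np.float64)
    n = np.asarray(allele_ns, dtype=np.float64)
    n1, n2 = n[0], n[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = alt[0] / n1
        p2 = alt[1] / n2
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * n1 * n2 / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        within = pbar * (1.0 - pbar) - s2 / 2.0
        a = (nbar / nc) * (s2 - within / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * within
    bad = (n1 < 2) | (n2 < 2)
    a = np.where(bad, np.nan, a)
    b = np.where(bad, np.nan, b)
    return a, b, np.zeros_like(a)


# ----------------------------------------------------------------------
# windowed scan
# ----------------------------------------------------------------------

def scan_windows(g: GenotypeMatrix, groups: SampleTable, windows: pd.DataFrame,
                 contrasts: Sequence[tuple[str | Sequence[str], str | Sequence[str]]],
                 min_snps: int = 3) -> pd.DataFrame:
    """Per-window diversity and differentiation table.

    ``contrasts`` is a list of (side A, side B) pairs; each side is a group
    name or a union of groups (e.g. ``("winter", "spring")`` or
    ``"winter+spring"``).  Windows with fewer than ``min_snps`` SNPs carrying
    data on a side get NaN statistics for that side (and for any contrast
    touching it); the pi ratio is NaN whenever the denominator pi is zero.
    """
    contrasts = [(_as_groupset(a), _as_groupset(b)) for a, b in contrasts]
    for a, b in contrasts:
        for side in (a, b):
            ids = groups.samples_in(side)
            if len(ids) < 2:
                raise ValidationError(f"contrast side {side_label(side)} has fewer than 2 samples")
    sides: list[GroupSet] = []
    for grp in dict.fromkeys(groups.table["group"]):
        sides.append((grp,))
    for a, b in contrasts:
        for side in (a, b):
            if side not in sides:
                sides.append(side)

    side_idx = {side: g.sample_index(groups.samples_in(side)) for side in sides}
    chrom_arr = g.snps["chrom"].to_numpy()
    pos0 = g.snps["pos"].to_numpy() - 1

    out = windows.reset_index(drop=True).copy()
    n_windows = len(out)
    per_side_cols = ("n_snps", "pi", "pi_sum", "S", "theta_w", "tajima_d")
    store: dict[str, np.ndarray] = {}
    for side in sides:
        lab = side_label(side)
        for c in per_side_cols:
            store[f"{c}_{lab}"] = np.full(n_windows, np.nan)
    for a, b in contrasts:
        lab = contrast_label(a, b)
        store[f"fst_{lab}"] = np.full(n_windows, np.nan)
        store[f"pi_ratio_{lab}"] = np.full(n_windows, np.nan)

    for chrom in out["chrom"].unique():
        snp_sel = chrom_arr == chrom
        m = int(snp_sel.sum())
        wmask = (out["chrom"] == chrom).to_numpy()
        widx = np.flatnonzero(wmask)
        starts = out.loc[wmask, "start"].to_numpy()
        ends = out.loc[wmask, "end"].to_numpy()
        if m == 0:
            continue
        p0 = pos0[snp_sel]
        lo = np.searchsorted(p0, starts, side="left")
        hi = np.searchsorted(p0, ends, side="left")

        side_stats: dict[GroupSet, dict[str, np.ndarray]] = {}
        for side in sides:
            idx = side_idx[side]
            d = g.dosage[np.ix_(idx, np.flatnonzero(snp_sel))]
            missing = d == MISSING
            alt = np.where(missing, 0, d).sum(axis=0, dtype=np.int64)
            an = 2 * (len(idx) - missing.sum(axis=0, dtype=np.int64))
            pi = site_pi(alt, an)
            valid = an >= 2
            poly = valid & (alt > 0) & (alt < an)
            c_pi = np.concatenate([[0.0], np.cumsum(np.where(valid, pi, 0.0))])
            c_valid = np.concatenate([[0], np.cumsum(valid)])
            c_poly = np.concatenate([[0], np.cumsum(poly)])
            n_snps_w = (c_valid[hi] - c_valid[lo]).astype(np.int64)
            pi_sum_w = c_pi[hi] - c_pi[lo]
            S_w = (c_poly[hi] - c_poly[lo]).astype(np.int64)
            # n_seq: 2 x samples with >=1 non-missing call in the window
            if missing.any():
                c_nm = np.zeros((m + 1, len(idx)), dtype=np.int32)
                np.cumsum(~missing.T, axis=0, out=c_nm[1:])
                present = (c_nm[hi] - c_nm[lo]) > 0
                n_seq_w = 2 * present.sum(axis=1)
            else:
                n_seq_w = np.full(len(widx), 2 * len(idx), dtype=np.int64)
            scored = n_snps_w >= min_snps
            pi_mean_w = np.where(scored, pi_sum_w / np.maximum(n_snps_w, 1), np.nan)
            theta_w = np.full(len(widx), np.nan)
            taj = np.full(len(widx), np.nan)
            ok = scored & (n_seq_w >= 4)
            if ok.any():
                a1, _, _ = _tajima_e_vec(n_seq_w[ok])
                theta_w[ok] = S_w[ok] / a1
                taj[ok] = tajima_d(S_w[ok], pi_sum_w[ok], n_seq_w[ok])
            lab = side_label(side)
            store[f"n_snps_{lab}"][widx] = n_snps_w
            store[f"pi_{lab}"][widx] = pi_mean_w
            store[f"pi_sum_{lab}"][widx] = np.where(scored, pi_sum_w, np.nan)
            store[f"S_{lab}"][widx] = np.where(scored, S_w, np.nan)
            store[f"theta_w_{lab}"][widx] = theta_w
            store[f"tajima_d_{lab}"][widx] = taj
            side_stats[side] = {"alt": alt, "an": an, "n_snps_w": n_snps_w,
                                "pi_mean_w": pi_mean_w, "scored": scored}

        for a, b in contrasts:
            sa, sb = side_stats[a], side_stats[b]
            comp_a, comp_b, _ = wc_fst_components(
                np.stack([sa["alt"], sb["alt"]]), np.stack([sa["an"], sb["an"]]))
            num = np.where(np.isnan(comp_a), 0.0, comp_a)
            den = np.where(np.isnan(comp_a), 0.0, comp_a + comp_b)
            c_num = np.concatenate([[0.0], np.cumsum(num)])
            c_den = np.concatenate([[0.0], np.cumsum(den)])
            num_w = c_num[hi] - c_num[lo]
            den_w = c_den[hi] - c_den[lo]
            scored = sa["scored"] & sb["scored"] & (den_w > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                fst = np.where(scored, num_w / den_w, np.nan)
                ratio = sa["pi_mean_w"] / sb["pi_mean_w"]
            ratio = np.where(sa["scored"] & sb["scored"] & (sb["pi_mean_w"] > 0), ratio, np.nan)
            lab = contrast_label(a, b)
            store[f"fst_{lab}"][widx] = fst
            store[f"pi_ratio_{lab}"][widx] = ratio

    for name, arr in store.items():
        out[name] = arr
    return out
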