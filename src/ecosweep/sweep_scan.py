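"""Selective-sweep calling from windowed statistics.

A window is called a sweep when it lies simultaneously in the top 5% of the
empirical FST distribution and in one of the 5% tails of the empirical pi
ratio distribution for a contrast.  The direction convention: with ratio
pi_A / pi_B, a value in the LEFT tail means diversity is reduced in the
numerator group A, so the sweep is attributed to A; the right tail
attributes it to B.  Called windows sharing a label are merged (overlap or
bookended) into sweep regions.

Significance of window FST is assessed by permuting group labels across
individuals (group sizes preserved), with the add-one permutation p-value
and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable, ValidationError
from .ld_structure import nearest_rank_high, nearest_rank_low
from .popgen_windows import _as_groupset, contrast_label, side_label, wc_fst_components


@dataclass(frozen=True)
class TailThresholds:
    """Empirical-tail cutoffs for one contrast (nearest-rank percentiles)."""

    pi_ratio_low: float
    pi_ratio_high: float
    fst_high: float
    tail: float
    contrast: str

    def __post_init__(self) -> None:
        if not self.pi_ratio_low < self.pi_ratio_high:
            raise ValidationError("degenerate pi-ratio tails (low >= high)")


def empirical_thresholds(stats: pd.DataFrame, contrast, tail: float = 0.05) -> TailThresholds:
    """5% left/right pi-ratio tails and the top-5% FST cutoff for a contrast."""
    if not (0 < tail < 0.5):
        raise ValidationError("tail must be in (0, 0.5)")
    lab = contrast_label(*_norm_contrast(contrast))
    ratio = stats[f"pi_ratio_{lab}"].to_numpy(dtype=float)
    fst = stats[f"fst_{lab}"].to_numpy(dtype=float)
    ratio = ratio[~np.isnan(ratio)]
    fst = fst[~np.isnan(fst)]
    if ratio.size < 20 or fst.size < 20:
        raise ValidationError("need at least 20 non-missing windows for empirical tails")
    return TailThresholds(
        pi_ratio_low=nearest_rank_low(ratio, tail),
        pi_ratio_high=nearest_rank_high(ratio, tail),
        fst_high=nearest_rank_high(fst, tail),
        tail=tail,
        contrast=lab,
    )


def _norm_contrast(contrast) -> tuple[tuple[str, ...], tuple[str, ...]]:
    a, b = contrast
    return _as_groupset(a), _as_groupset(b)


def call_sweep_windows(stats: pd.DataFrame, thresholds: TailThresholds,
                       contrast) -> pd.DataFrame:
    """Label windows by the intersection rule (ties on thresholds inclusive).

    Adds a ``selected_group`` column: side A's label where the pi ratio is in
    the left tail and FST in the top tail, side B's label for the right tail,
    empty string otherwise.
    """
    a, b = _norm_contrast(contrast)
    lab = contrast_label(a, b)
    if thresholds.contrast != lab:
        raise ValidationError(f"thresholds computed for {thresholds.contrast}, not {lab}")
    out = stats.copy()
    ratio = out[f"pi_ratio_{lab}"].to_numpy(dtype=float)
    fst = out[f"fst_{lab}"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        high_fst = fst >= thresholds.fst_high
        in_a = high_fst & (ratio <= thresholds.pi_ratio_low)
        in_b = high_fst & (ratio >= thresholds.pi_ratio_high)
    selected = np.where(in_a, side_label(a), np.where(in_b, side_label(b), ""))
    out["selected_group"] = selected
    out.attrs["contrast"] = lab
    return out


def merge_windows(called: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/bookended same-label sweep windows into regions.

    Region statistics aggregate over member windows: window count, maximum
    FST and the most extreme pi ratio in the label's direction (minimum for
    the numerator group's sweeps, maximum for the denominator group's).
    """
    lab = called.attrs.get("contrast")
    fst_col = f"fst_{lab}" if lab else None
    ratio_col = f"pi_ratio_{lab}" if lab else None
    sel = called[called["selected_group"] != ""].copy()
    regions = []
    a_label = lab.split("_vs_")[0] if lab else None
    for (group, chrom), sub in sel.groupby(["selected_group", "chrom"], sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        fsts = sub[fst_col].to_numpy(dtype=float) if fst_col else np.full(len(sub), np.nan)
        ratios_arr = sub[ratio_col].to_numpy(dtype=float) if ratio_col else np.full(len(sub), np.nan)
        cur = None
        for k in range(len(sub)):
            if cur is None or starts[k] > cur["end"]:  # bookended (start == end) merges
                if cur is not None:
                    regions.append(cur)
                cur = {"chrom": chrom, "start": int(starts[k]), "end": int(ends[k]),
                       "selected_group": group, "n_windows": 1,
                       "max_fst": fsts[k], "ratios": [ratios_arr[k]]}
            else:
                cur["end"] = max(cur["end"], int(ends[k]))
                cur["n_windows"] += 1
                cur["max_fst"] = np.nanmax([cur["max_fst"], fsts[k]])
                cur["ratios"].append(ratios_arr[k])
        if cur is not None:
            regions.append(cur)
    for r in regions:
        ratios = np.asarray(r.pop("ratios", []), dtype=float)
        if ratios.size:
            r["extreme_pi_ratio"] = float(np.nanmin(ratios) if r["selected_group"] == a_label
                                          else np.nanmax(ratios))
        else:
            r["extreme_pi_ratio"] = np.nan
        r["span_bp"] = r["end"] - r["start"]
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "selected_group",
                                         "n_windows", "max_fst", "extreme_pi_ratio", "span_bp"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def genes_in_regions(regions: pd.DataFrame, annotation: pd.DataFrame
                     ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Attach overlapping genes (>= 1 bp, half-open) to each region.

    Returns the regions with a ``genes`` list column plus, per selected
    group, the deduplicated union of gene ids across that group's regions.
    """
    out = regions.copy()
    gene_lists = []
    for row in out.itertuples(index=False):
        hits = annotation[(annotation["chrom"] == row.chrom)
                          & (annotation["start"] < row.end)
                          & (annotation["end"] > row.start)]
        gene_lists.append(sorted(dict.fromkeys(hits["gene_id"])))
    out["genes"] = gene_lists
    out["n_genes"] = [len(gl) for gl in gene_lists]
    by_group: dict[str, list[str]] = {}
    if "selected_group" in out.columns:
        for group, sub in out.groupby("selected_group", sort=False):
            seen: dict[str, None] = {}
            for gl in sub["genes"]:
                for gid in gl:
                    seen[gid] = None
            by_group[group] = sorted(seen)
    return out, by_group


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qq = np.empty(m)
    qq[order] = np.minimum(ranked, 1.0)
    q[ok] = qq
    return q


def _window_bounds(g: GenotypeMatrix, windows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Global SNP index [lo, hi) per window, using the genome-wide SNP order."""
    chrom_arr = g.snps["chrom"].to_numpy()
    pos0 = g.snps["pos"].to_numpy() - 1
    lo = np.empty(len(windows), dtype=np.int64)
    hi = np.empty(len(windows), dtype=np.int64)
    for chrom in windows["chrom"].unique():
        snp_sel = np.flatnonzero(chrom_arr == chrom)
        wmask = (windows["chrom"] == chrom).to_numpy()
        if snp_sel.size == 0:
            lo[wmask] = 0
            hi[wmask] = 0
            continue
        offset = snp_sel[0]
        p0 = pos0[snp_sel]
        lo[wmask] = offset + np.searchsorted(p0, windows.loc[wmask, "start"].to_numpy())
        hi[wmask] = offset + np.searchsorted(p0, windows.loc[wmask, "end"].to_numpy())
    return lo, hi


def _window_fst_from_counts(alt: np.ndarray, an: np.ndarray,
                            lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    a, b, _ = wc_fst_components(alt, an)
    num = np.where(np.isnan(a), 0.0, a)
    den = np.where(np.isnan(a), 0.0, a + b)
    c_num = np.concatenate([[0.0], np.cumsum(num)])
    c_den = np.concatenate([[0.0], np.cumsum(den)])
    num_w = c_num[hi] - c_num[lo]
    den_w = c_den[hi] - c_den[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den_w > 0, num_w / den_w, np.nan)


def permutation_fst(g: GenotypeMatrix, groups: SampleTable, windows: pd.DataFrame,
                    contrast, n_perm: int = 2000, seed: int = 0,
                    min_snps: int = 3) -> pd.DataFrame:
    """Label-permutation test of window FST for one contrast.

    Individuals of the two contrast sides are pooled and reassigned at
    random (side sizes preserved); per window the add-one estimator gives
    perm_p = (1 + #{permuted FST >= observed}) / (n_perm + 1), and q-values
    are Benjamini-Hochberg.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    a, b = _norm_contrast(contrast)
    ids_a = groups.samples_in(a)
    ids_b = groups.samples_in(b)
    idx_a = g.sample_index(ids_a)
    idx_b = g.sample_index(ids_b)
    pool = np.concatenate([idx_a, idx_b])
    n_a = idx_a.size

    lo, hi = _window_bounds(g, windows)
    D0 = np.where(g.dosage == MISSING, 0, g.dosage).astype(np.float32)
    NM = (g.dosage != MISSING).astype(np.float32)

    def counts_for(rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        alt = D0[rows].sum(0, dtype=np.float64)
        an = 2.0 * NM[rows].sum(0, dtype=np.float64)
        return alt, an

    alt_a, an_a = counts_for(idx_a)
    alt_b, an_b = counts_for(idx_b)
    observed = _window_fst_from_counts(np.stack([alt_a, alt_b]), np.stack([an_a, an_b]), lo, hi)
    # windows too sparse on either side are not tested
    valid_a = (an_a >= 2).astype(np.float64)
    c_cnt = np.concatenate([[0.0], np.cumsum(valid_a * (an_b >= 2))])
    n_informative = c_cnt[hi] - c_cnt[lo]
    observed = np.where(n_informative >= min_snps, observed, np.nan)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(windows), dtype=np.int64)
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        alt_pa, an_pa = counts_for(perm[:n_a])
        alt_pb, an_pb = counts_for(perm[n_a:])
        fst_p = _window_fst_from_counts(np.stack([alt_pa, alt_pb]), np.stack([an_pa, an_pb]), lo, hi)
        with np.errstate(invalid="ignore"):
            exceed += np.where(~np.isnan(fst_p) & ~np.isnan(observed), fst_p >= observed, 0)
    perm_p = np.where(np.isnan(observed), np.nan, (1.0 + exceed) / (n_perm + 1.0))
    out = windows.reset_index(drop=True).copy()
    out["observed_fst"] = observed
    out["perm_p"] = perm_p
    out["q_value"] = bh_qvalues(perm_p)
    out.attrs["seed"] = seed
    out.attrs["n_perm"] = n_perm
    out.attrs["contrast"] = contrast_label(a, b)
    return out
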