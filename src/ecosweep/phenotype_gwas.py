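"""Multi-year BLUP and kinship-corrected mixed-model GWAS for flowering time.

The multi-year phenotype is condensed to one value per accession by BLUP
under y_ij = mu + year_i + g_j + e_ij with year fixed and genotype random
(variance components by REML).  The association scan then fits, per SNP,

    y = X alpha + P beta + u + e,   u ~ N(0, sigma_g^2 K),

with X the SNP dosage, P principal-component covariates and K the kinship
matrix.  Variance components are estimated once on the null model through
the spectral decomposition of K (the P3D/EMMAX approximation) and every SNP
is then tested by generalized least squares with a Wald t-test.  Per-SNP
variance explained is reported as 2 p (1-p) beta^2 / var(y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix, ValidationError
from .ld_structure import r2_composite
from .population_structure import KinshipMatrix, pca


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV with columns sample_id, year, value."""
    df = pd.read_csv(path)
    need = {"sample_id", "year", "value"}
    if not need.issubset(df.columns):
        raise ValidationError(f"phenotype table needs columns {sorted(need)}")
    if df.duplicated(["sample_id", "year"]).any():
        raise ValidationError("duplicated (sample_id, year) rows in phenotype table")
    return df


def blup_trait(pheno: pd.DataFrame) -> pd.Series:
    """Per-sample BLUP of the trait across years (mu + predicted g_j).

    Year enters as a fixed effect, genotype as a random intercept; variance
    components come from REML (statsmodels MixedLM).  Samples observed in no
    year are simply absent from the result.
    """
    import statsmodels.api as sm

    pheno = pheno.dropna(subset=["value"])
    if pheno["year"].nunique() < 2:
        raise ValidationError("BLUP needs at least 2 years")
    if pheno["sample_id"].nunique() < 2:
        raise ValidationError("BLUP needs at least 2 samples")
    y = pheno["value"].to_numpy(dtype=float)
    year_d = pd.get_dummies(pheno["year"].astype("category"), drop_first=True, dtype=float)
    X = np.column_stack([np.ones(len(pheno)), year_d.to_numpy()])
    if np.ptp(y) == 0:
        # degenerate: all observations identical; every BLUP is the mean
        return pd.Series(y[0], index=pd.Index(sorted(pheno["sample_id"].unique()), name="sample_id"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=pheno["sample_id"].to_numpy())
        fit = model.fit(reml=True)
    fitted_fixed = X @ np.asarray(fit.fe_params)
    mu = float(np.mean(fitted_fixed))
    re = {k: float(np.asarray(v)[0]) for k, v in fit.random_effects.items()}
    out = pd.Series({s: mu + re.get(s, 0.0) for s in pheno["sample_id"].unique()})
    out.index.name = "sample_id"
    return out.sort_index()


@dataclass
class MlmFit:
    """Null-model variance components on the kinship eigenbasis."""

    delta: float          # sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float
    eigenvalues: np.ndarray
    loglik: float


def _reml_delta(y_r: np.ndarray, W_r: np.ndarray, S: np.ndarray) -> MlmFit:
    """Profile-REML over delta on the rotated (eigenbasis) model."""
    n, q = W_r.shape

    def neg_reml(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        w = S + delta
        Wt = W_r / np.sqrt(w)[:, None]
        yt = y_r / np.sqrt(w)
        A = Wt.T @ Wt
        try:
            beta = np.linalg.solve(A, Wt.T @ yt)
        except np.linalg.LinAlgError:
            return np.inf
        rss = float(np.sum((yt - Wt @ beta) ** 2))
        if rss <= 0:
            return np.inf
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        df = n - q
        return 0.5 * (df * np.log(rss / df) + np.sum(np.log(w)) + logdetA)

    grid = np.linspace(-5, 5, 21)
    vals = [neg_reml(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    delta = float(10.0 ** res.x)
    w = S + delta
    Wt = W_r / np.sqrt(w)[:, None]
    yt = y_r / np.sqrt(w)
    beta = np.linalg.lstsq(Wt, yt, rcond=None)[0]
    rss = float(np.sum((yt - Wt @ beta) ** 2))
    sigma_g2 = rss / (len(y_r) - W_r.shape[1])
    return MlmFit(delta, sigma_g2, sigma_g2 * delta, S, -float(res.fun))


def gwas_mlm(blups: pd.Series, g: GenotypeMatrix, K: KinshipMatrix,
             n_pcs: int = 3) -> pd.DataFrame:
    """Mixed-model association scan (P3D approximation).

    Samples are aligned on the intersection of phenotype, genotypes and K.
    Monomorphic SNPs are skipped (NaN results); missing dosages are imputed
    to the SNP mean for testing.
    """
    common = [s for s in g.samples if s in blups.index]
    if len(common) < 10:
        raise ValidationError("too few samples shared between phenotype and genotypes")
    gi = g.subset(samples=common)
    y = blups.loc[common].to_numpy(dtype=float)
    k_idx = [K.samples.index(s) for s in common]
    Kmat = K.values[np.ix_(k_idx, k_idx)]

    covar = [np.ones(len(common))]
    if n_pcs > 0:
        scores = pca(gi, n_components=n_pcs).scores.to_numpy()
        covar.extend(scores.T)
    W = np.column_stack(covar)

    S, U = np.linalg.eigh(Kmat)
    S = np.clip(S, 0.0, None)
    y_r = U.T @ y
    W_r = U.T @ W
    fit = _reml_delta(y_r, W_r, S)

    w = S + fit.delta
    sw = np.sqrt(w)
    Wt = W_r / sw[:, None]
    yt = y_r / sw

    d = gi.dosage_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(d), col_mean, d)
    p_freq = col_mean / 2.0
    mono = (p_freq <= 0) | (p_freq >= 1)

    Xt = (U.T @ X) / sw[:, None]
    A = Wt.T @ Wt
    Ainv = np.linalg.inv(A)
    b0 = Wt.T @ yt
    C = Wt.T @ Xt                               # q x M
    AinvC = Ainv @ C
    Sxx = np.einsum("ij,ij->j", Xt, Xt) - np.einsum("ij,ij->j", C, AinvC)
    Sxy = Xt.T @ yt - b0 @ AinvC
    rss0 = float(yt @ yt - b0 @ Ainv @ b0)
    n, q = Wt.shape
    df = n - q - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = Sxy / Sxx
        rss = np.maximum(rss0 - beta * Sxy, 1e-300)  # exact fits keep a finite t
        sigma2 = rss / df
        se = np.sqrt(sigma2 / Sxx)
        tstat = beta / se
    bad = mono | (Sxx <= 1e-10) | ~np.isfinite(tstat)
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval = np.where(bad, np.nan, np.clip(pval, np.finfo(float).tiny, 1.0))
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    var_y = float(np.var(y))
    pve = np.clip(2.0 * p_freq * (1.0 - p_freq) * beta**2 / var_y, 0.0, 1.0)

    out = gi.snps[["snp_id", "chrom", "pos"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p_value"] = pval
    out["pve"] = np.where(bad, np.nan, pve)
    out.attrs["delta"] = fit.delta
    out.attrs["sigma_g2"] = fit.sigma_g2
    out.attrs["sigma_e2"] = fit.sigma_e2
    out.attrs["n_samples"] = n
    return out


def significance_threshold(M: int) -> float:
    """Genome-wide p cutoff 1/M (one over the number of SNPs tested)."""
    if M < 1:
        raise ValidationError("M must be >= 1")
    return 1.0 / M


def genomic_inflation(p_values: np.ndarray) -> float:
    """Lambda_GC: median association chi-square over its null expectation."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def define_regions(results: pd.DataFrame, g: GenotypeMatrix, p_cutoff: float | None = None,
                   r2_min: float = 0.5, max_extension: int = 200_000) -> pd.DataFrame:
    """LD-based candidate regions around significant SNPs.

    From each peak (most significant unassigned hit) the region extends
    SNP-by-SNP in both directions while r2 with the peak stays >= ``r2_min``,
    capped at ``max_extension`` bp each side; overlapping regions are merged.
    Coordinates are 0-based half-open; an isolated peak yields the 1-bp
    interval of the peak SNP.
    """
    if p_cutoff is None:
        p_cutoff = significance_threshold(int((~results["p_value"].isna()).sum()))
    hits = results[results["p_value"] < p_cutoff].sort_values("p_value")
    if hits.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "peak_snp", "peak_p", "n_hits"])
    chrom_arr = g.snps["chrom"].to_numpy()
    pos_arr = g.snps["pos"].to_numpy()
    id_arr = g.snps["snp_id"].to_numpy()
    snp_pos = {sid: i for i, sid in enumerate(id_arr)}
    assigned: set[str] = set()
    regions = []
    for hit in hits.itertuples(index=False):
        if hit.snp_id in assigned:
            continue
        i = snp_pos[hit.snp_id]
        chrom = chrom_arr[i]
        peak_pos = pos_arr[i]
        left = i
        j = i - 1
        while j >= 0 and chrom_arr[j] == chrom and peak_pos - pos_arr[j] <= max_extension:
            r2 = r2_composite(g.dosage[:, i], g.dosage[:, j])
            if not (r2 >= r2_min):
                break
            left = j
            j -= 1
        right = i
        j = i + 1
        while j < len(pos_arr) and chrom_arr[j] == chrom and pos_arr[j] - peak_pos <= max_extension:
            r2 = r2_composite(g.dosage[:, i], g.dosage[:, j])
            if not (r2 >= r2_min):
                break
            right = j
            j += 1
        start, end = int(pos_arr[left] - 1), int(pos_arr[right])
        members = [sid for sid in hits["snp_id"]
                   if snp_pos[sid] >= left and snp_pos[sid] <= right and chrom_arr[snp_pos[sid]] == chrom]
        assigned.update(members)
        regions.append({"chrom": chrom, "start": start, "end": end,
                        "peak_snp": hit.snp_id, "peak_p": hit.p_value, "n_hits": len(members)})
    out = pd.DataFrame(regions).sort_values(["chrom", "start"]).reset_index(drop=True)
    # merge overlaps
    merged = []
    for row in out.itertuples(index=False):
        if merged and row.chrom == merged[-1]["chrom"] and row.start < merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], row.end)
            merged[-1]["n_hits"] += row.n_hits
            if row.peak_p < merged[-1]["peak_p"]:
                merged[-1]["peak_snp"], merged[-1]["peak_p"] = row.peak_snp, row.peak_p
        else:
            merged.append(dict(row._asdict()))
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "peak_snp", "peak_p", "n_hits"])


@dataclass
class HaplotypeBlock:
    """Genotype-combination classes over a set of linked SNPs."""

    snp_ids: list[str]
    classes: pd.DataFrame     # haplotype, n, mean_trait
    p_value: float | None
    note: str = ""


def haplotype_means(snp_ids: list[str], g: GenotypeMatrix, values: pd.Series,
                    min_class_n: int = 5) -> HaplotypeBlock:
    """Per-class trait means for the multi-SNP genotype combinations.

    Samples missing any block genotype are excluded.  Classes are the joint
    dosage tuples (heterozygote-containing combinations form their own
    classes); a Kruskal-Wallis test compares classes with n >= min_class_n.
    """
    if len(snp_ids) < 1:
        raise ValidationError("need at least one block SNP")
    cols = [int(np.flatnonzero(g.snps["snp_id"].to_numpy() == sid)[0]) for sid in snp_ids]
    sub = g.dosage[:, cols]
    rows = []
    for i, s in enumerate(g.samples):
        if s not in values.index or np.isnan(values.loc[s]):
            continue
        if (sub[i] < 0).any():
            continue
        key = "/".join(str(int(x)) for x in sub[i])
        rows.append((s, key, float(values.loc[s])))
    df = pd.DataFrame(rows, columns=["sample_id", "haplotype", "value"])
    classes = (df.groupby("haplotype")["value"].agg(["count", "mean"])
                 .rename(columns={"count": "n", "mean": "mean_trait"})
                 .reset_index().sort_values("n", ascending=False).reset_index(drop=True))
    testable = [grp["value"].to_numpy() for _, grp in df.groupby("haplotype")
                if len(grp) >= min_class_n]
    if len(testable) < 2:
        return HaplotypeBlock(list(snp_ids), classes, None,
                              note=f"fewer than 2 classes with n >= {min_class_n}; test skipped")
    stat = stats.kruskal(*testable)
    return HaplotypeBlock(list(snp_ids), classes, float(stat.pvalue))
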