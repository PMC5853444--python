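"""Synthetic ecotype panels with planted, recoverable ground truth.

The generator emulates the statistical structure of an array-genotyped
rapeseed diversity panel: three ecotype groups (semi-winter / winter /
spring, 196/71/60 accessions by default) differentiated under the
Balding-Nichols drift model, ~33 000 biallelic SNPs on 19 chromosomes
(A01-A10, C01-C09), block-structured LD built from a small number of
founder haplotypes per block, localized sweeps where one group's allele
frequencies are collapsed, and a multi-year flowering-time phenotype with
planted causal SNPs.

The Balding-Nichols model draws each group's allele frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral p ~ U(0.05, 0.95), so the
configured F is also the expected FST - an analytic oracle for the
differentiation statistics.  LD arises because every individual samples two
of K_h founder haplotypes per block: adjacent-pair r2 scales like 1/K_h,
giving direct control of weak/strong LD contrasts between subgenomes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SampleTable, ValidationError, write_genotypes


@dataclass
class ChromSpec:
    name: str
    length: int            # bp
    n_snps: int
    block_len: int = 100_000
    founders: int = 8      # K_h founder haplotypes per LD block; 0 = no LD (direct HWE draws)


@dataclass
class SweepSpec:
    chrom: str
    start: int             # 0-based half-open
    end: int
    target_group: tuple[str, ...]   # group(s) whose diversity collapses
    delta: float = 0.02    # residual diversity: frequency pinned to delta or 1-delta

    def __post_init__(self) -> None:
        if isinstance(self.target_group, str):
            self.target_group = tuple(self.target_group.split("+"))
        else:
            self.target_group = tuple(self.target_group)
        if not (0 < self.delta <= 0.1):
            raise ValidationError("sweep delta must be in (0, 0.1]")


@dataclass
class PhenotypeSpec:
    n_causal: int = 5
    effect_sizes: tuple[float, ...] = (8.0, -6.0, 5.0, -5.0, 4.0)  # days per allele
    group_offsets: dict = field(default_factory=lambda: {
        "winter": 25.0, "semi_winter": 0.0, "spring": -20.0})
    year_effects: dict = field(default_factory=lambda: {
        2012: -4.0, 2013: 1.0, 2014: 5.0, 2015: -2.0})
    residual_sd: float = 8.0  # days
    mu: float = 155.0         # days; with the offsets spans roughly 107-204 d


@dataclass
class SimConfig:
    seed: int = 0
    groups: tuple[tuple[str, int], ...] = (
        ("semi_winter", 196), ("winter", 71), ("spring", 60))
    chroms: tuple[ChromSpec, ...] = ()
    fst: dict = field(default_factory=lambda: {
        "semi_winter": 0.15, "winter": 0.15, "spring": 0.15})
    sweeps: tuple[SweepSpec, ...] = ()
    phenotype: PhenotypeSpec | None = field(default_factory=PhenotypeSpec)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        lengths = {c.name: c.length for c in self.chroms}
        for sw in self.sweeps:
            if sw.chrom not in lengths or not (0 <= sw.start < sw.end <= lengths[sw.chrom]):
                raise ValidationError(f"sweep interval outside chromosome bounds: {sw}")
        if self.chroms and sum(c.n_snps for c in self.chroms) <= 0:
            raise ValidationError("total SNP count must be positive")

    @property
    def group_names(self) -> list[str]:
        return [name for name, _ in self.groups]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chroms}


def paper_like_config(seed: int = 0) -> SimConfig:
    """The default study-scale panel: 327 accessions, 19 chromosomes, ~33k SNPs.

    SNP density and subgenome LD mirror the array design being emulated:
    denser, faster-decaying A chromosomes (more founder haplotypes) and
    sparser, long-LD C chromosomes.
    """
    chroms = []
    for i in range(1, 11):  # A01..A10: ~25 Mb, 8 SNPs / 100 kb, short LD
        chroms.append(ChromSpec(f"A{i:02d}", 25_000_000, 2000, block_len=100_000, founders=16))
    for i in range(1, 10):  # C01..C09: ~40 Mb, 4 SNPs / 100 kb, long LD
        chroms.append(ChromSpec(f"C{i:02d}", 40_000_000, 1450, block_len=400_000, founders=4))
    return SimConfig(seed=seed, chroms=tuple(chroms))


def tiny_config(seed: int = 0) -> SimConfig:
    """A minutes-scale scenario for smoke tests: 2 chromosomes, 500 SNPs, 60 samples."""
    return SimConfig(
        seed=seed,
        groups=(("semi_winter", 24), ("winter", 18), ("spring", 18)),
        chroms=(ChromSpec("A01", 2_000_000, 300, block_len=100_000, founders=8),
                ChromSpec("C01", 2_000_000, 200, block_len=200_000, founders=4)),
        sweeps=(SweepSpec("A01", 500_000, 600_000, ("semi_winter",)),),
        phenotype=PhenotypeSpec(n_causal=2, effect_sizes=(8.0, -6.0)),
    )


# ----------------------------------------------------------------------
# simulation stages
# ----------------------------------------------------------------------

def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator | None = None
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """SNP map plus per-group per-SNP allele frequencies.

    Returns (snp_df, freqs) with freqs of shape (n_groups, n_snps) in the
    order of ``cfg.group_names``; inside each sweep interval the target
    groups' frequencies are pinned to delta or 1 - delta (whichever is
    nearer the drifted frequency), collapsing local diversity.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    parts = []
    for c in cfg.chroms:
        pos = np.sort(rng.choice(np.arange(1, c.length + 1), size=c.n_snps, replace=False))
        parts.append(pd.DataFrame({
            "snp_id": [f"{c.name}_{p}" for p in pos],
            "chrom": c.name, "pos": pos,
        }))
    snps = pd.concat(parts, ignore_index=True)
    m = len(snps)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    freqs = np.empty((len(cfg.groups), m))
    for gi, name in enumerate(cfg.group_names):
        F = float(cfg.fst[name]) if isinstance(cfg.fst, dict) else float(cfg.fst)
        if F <= 0 or F >= 1:
            raise ValidationError("Balding-Nichols F must be in (0, 1)")
        freqs[gi] = rng.beta(p_anc * (1 - F) / F, (1 - p_anc) * (1 - F) / F)
    chrom_arr = snps["chrom"].to_numpy()
    pos0 = snps["pos"].to_numpy() - 1
    for sw in cfg.sweeps:
        in_sweep = (chrom_arr == sw.chrom) & (pos0 >= sw.start) & (pos0 < sw.end)
        for name in sw.target_group:
            gi = cfg.group_names.index(name)
            f = freqs[gi, in_sweep]
            freqs[gi, in_sweep] = np.where(f < 0.5, sw.delta, 1.0 - sw.delta)
    return snps, freqs


def simulate_genotypes(cfg: SimConfig, snps: pd.DataFrame, freqs: np.ndarray,
                       rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, SampleTable]:
    """Draw diploid genotypes with founder-block LD.

    Within each LD block of ``block_len`` bp, each group has K_h founder
    haplotypes drawn from its frequencies; every individual samples two
    founders per block independently, so within-block LD scales like 1/K_h
    and blocks recombine freely.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValidationError("frequencies must lie in [0, 1]")
    sample_ids, group_labels = [], []
    for name, n in cfg.groups:
        sample_ids += [f"{name}_{i:03d}" for i in range(n)]
        group_labels += [name] * n
    n_total = len(sample_ids)
    m = len(snps)
    dosage = np.zeros((n_total, m), dtype=np.int8)
    chrom_arr = snps["chrom"].to_numpy()
    pos0 = snps["pos"].to_numpy() - 1
    spec_by_name = {c.name: c for c in cfg.chroms}
    row0 = 0
    for name, n in cfg.groups:
        gi = cfg.group_names.index(name)
        for cname in dict.fromkeys(chrom_arr):
            c = spec_by_name[cname]
            sel = np.flatnonzero(chrom_arr == cname)
            if c.founders == 0:  # linkage-free sites: two independent gamete draws
                f = freqs[gi, sel]
                draws = rng.random((n, 2, sel.size)) < f
                dosage[row0:row0 + n, sel] = draws.sum(axis=1, dtype=np.int8)
                continue
            block_ids = pos0[sel] // c.block_len
            for blk in np.unique(block_ids):
                cols = sel[block_ids == blk]
                f = freqs[gi, cols]
                founders = (rng.random((c.founders, cols.size)) < f).astype(np.int8)
                pick = rng.integers(0, c.founders, size=(n, 2))
                dosage[row0:row0 + n, cols] = founders[pick[:, 0]] + founders[pick[:, 1]]
        row0 += n
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = -1
    snps = snps.copy()
    snps["ref"] = "A"
    snps["alt"] = "G"
    g = GenotypeMatrix(sample_ids, snps, dosage)
    table = SampleTable.from_frame(pd.DataFrame({
        "sample_id": sample_ids, "group": group_labels, "origin": "simulated"}))
    return g, table


def simulate_phenotype(cfg: SimConfig, g: GenotypeMatrix, samples: SampleTable,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-year flowering-time table plus the causal-SNP truth.

    FT_ijy = mu + group_offset + sum_c beta_c * dosage_c + year_y + N(0, sd^2).
    Causal SNPs are drawn among SNPs with overall MAF >= 0.1 so the planted
    per-SNP variance explained is stable.
    """
    spec = cfg.phenotype
    if spec is None:
        raise ValidationError("config has no phenotype block")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    alt, an = g.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / an
    maf = np.minimum(p, 1 - p)
    eligible = np.flatnonzero(maf >= 0.1)
    if spec.n_causal > eligible.size:
        raise ValidationError("requested more causal SNPs than eligible SNPs in the panel")
    causal = np.sort(rng.choice(eligible, size=spec.n_causal, replace=False))
    betas = np.asarray(spec.effect_sizes[:spec.n_causal], dtype=float)
    if betas.size < spec.n_causal:
        raise ValidationError("effect_sizes shorter than n_causal")
    dose = np.where(g.dosage[:, causal] < 0, 0, g.dosage[:, causal]).astype(float)
    genetic = dose @ betas
    group_of = samples.group_of()
    offsets = np.array([spec.group_offsets.get(group_of[s], 0.0) for s in g.samples])
    rows = []
    for year, yeff in sorted(spec.year_effects.items()):
        noise = rng.normal(0.0, spec.residual_sd, size=g.n_samples)
        vals = spec.mu + offsets + genetic + yeff + noise
        rows.append(pd.DataFrame({"sample_id": g.samples, "year": year, "value": vals}))
    pheno = pd.concat(rows, ignore_index=True)
    truth = g.snps.iloc[causal][["snp_id", "chrom", "pos"]].copy()
    truth["beta"] = betas
    return pheno, truth.reset_index(drop=True)


def split_pool(g: GenotypeMatrix, sizes: dict[str, int], seed: int = 0) -> SampleTable:
    """Assign ecotype labels at random to a panmictic pool (a no-structure null).

    ``sizes`` maps canonical group names to sample counts summing to the
    panel size; labels are shuffled deterministically from the seed.
    """
    if sum(sizes.values()) != g.n_samples:
        raise ValidationError("group sizes must sum to the number of samples")
    labels = np.array([name for name, n in sizes.items() for _ in range(n)])
    np.random.default_rng(seed).shuffle(labels)
    return SampleTable.from_frame(pd.DataFrame(
        {"sample_id": g.samples, "group": labels, "origin": "random split"}))


@dataclass
class Scenario:
    config: SimConfig
    genotypes: GenotypeMatrix
    samples: SampleTable
    phenotype: pd.DataFrame | None
    truth_sweeps: pd.DataFrame
    truth_causal: pd.DataFrame | None


def simulate_panel(cfg: SimConfig) -> Scenario:
    """Run all stages from one seed; bit-reproducible."""
    ss = np.random.SeedSequence(cfg.seed)
    r_freq, r_geno, r_pheno = [np.random.default_rng(s) for s in ss.spawn(3)]
    snps, freqs = simulate_frequencies(cfg, r_freq)
    g, samples = simulate_genotypes(cfg, snps, freqs, r_geno)
    pheno, truth_causal = (None, None)
    if cfg.phenotype is not None:
        pheno, truth_causal = simulate_phenotype(cfg, g, samples, r_pheno)
    truth_sweeps = pd.DataFrame(
        [{"chrom": sw.chrom, "start": sw.start, "end": sw.end,
          "target_group": "+".join(sw.target_group), "delta": sw.delta}
         for sw in cfg.sweeps],
        columns=["chrom", "start", "end", "target_group", "delta"])
    return Scenario(cfg, g, samples, pheno, truth_sweeps, truth_causal)


def write_scenario(cfg: SimConfig, outdir: str | Path, genotype_format: str = "table") -> Scenario:
    """Write a scenario to disk in formats genotype_io reads back unchanged.

    Emits genotypes.(csv|vcf), samples.csv, genes.bed (dummy 2 kb genes every
    50 kb), phenotype.csv and truth.json (schema_version 1).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = simulate_panel(cfg)
    gpath = outdir / ("genotypes.csv" if genotype_format == "table" else "genotypes.vcf")
    write_genotypes(sc.genotypes, gpath, format=genotype_format)
    sc.samples.table.to_csv(outdir / "samples.csv", index=False)
    with open(outdir / "genes.bed", "w") as fh:
        for c in cfg.chroms:
            for k, start in enumerate(range(0, c.length - 2000, 50_000)):
                fh.write(f"{c.name}\t{start}\t{start + 2000}\t{c.name}_g{k:04d}\t0\t+\n")
    if sc.phenotype is not None:
        sc.phenotype.to_csv(outdir / "phenotype.csv", index=False)
    truth = {
        "schema_version": 1,
        "seed": cfg.seed,
        "sweeps": sc.truth_sweeps.to_dict("records"),
        "causal_snps": sc.truth_causal.to_dict("records") if sc.truth_causal is not None else [],
        "chrom_lengths": cfg.chrom_lengths,
        "groups": {name: n for name, n in cfg.groups},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return sc
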