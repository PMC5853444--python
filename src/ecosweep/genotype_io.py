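"""Genotype, sample-group and annotation I/O plus SNP quality filtering.

The pipeline's universal input is a :class:`GenotypeMatrix`: an accessions x
SNPs dosage matrix (0/1/2 alternate-allele counts, ``-1`` for missing) with a
SNP map sorted by (chromosome, position).  Genotypes can be read from a
standard VCF (GT fields only) or from a delimited table as exported from SNP
arrays (calls coded ``AA``/``AB``/``BB``/``NA`` or ``0``/``1``/``2``/``NA``).

Internal coordinates are 0-based half-open; VCF and GFF3 (both 1-based) are
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call in dosage matrices.
MISSING = -1

#: The three canonical ecotype groups of the panel design.
CANONICAL_GROUPS = ("winter", "spring", "semi_winter")

_TABLE_CALL_CODES = {
    "AA": 0, "AB": 1, "BA": 1, "BB": 2,
    "0": 0, "1": 1, "2": 2,
    "NA": MISSING, "NN": MISSING, "--": MISSING, "": MISSING, ".": MISSING,
    "./.": MISSING,
}

_NUCLEOTIDES = frozenset("ACGT")


class GenotypeIOError(ValueError):
    """Raised when an input file cannot be parsed in the declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a structural invariant."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with a 1-based genomic position."""

    snp_id: str
    chrom: str
    pos: int  # 1-based bp
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class FilterReport:
    """Counts from :func:`filter_snps`.

    ``n_informative`` counts SNPs that pass the call-rate threshold and are
    polymorphic; ``n_pass_maf`` additionally requires MAF strictly above
    ``maf_min`` (frequencies over non-missing calls only).
    """

    n_input: int
    n_informative: int
    n_pass_maf: int
    maf_min: float
    call_rate_min: float

    def __post_init__(self) -> None:
        if not (self.n_pass_maf <= self.n_informative <= self.n_input):
            raise ValidationError("filter counts must satisfy n_pass_maf <= n_informative <= n_input")


class GenotypeMatrix:
    """Samples x SNPs dosage matrix with SNP map.

    Parameters
    ----------
    samples
        Ordered sample identifiers.
    snps
        DataFrame with columns ``snp_id, chrom, pos`` (1-based) and optional
        ``ref, alt``.  Rows are sorted by (chrom, pos) on construction, and
        the dosage columns are reordered alongside.
    dosage
        ``(n_samples, n_snps)`` integer array with entries in {0, 1, 2} or
        :data:`MISSING`.
    """

    def __init__(self, samples: Sequence[str], snps: pd.DataFrame, dosage: np.ndarray):
        samples = list(samples)
        if len(set(samples)) != len(samples):
            raise ValidationError("duplicated sample ids")
        snps = snps.reset_index(drop=True).copy()
        for col in ("snp_id", "chrom", "pos"):
            if col not in snps.columns:
                raise ValidationError(f"SNP map lacks required column {col!r}")
        if "ref" not in snps.columns:
            snps["ref"] = "A"
        if "alt" not in snps.columns:
            snps["alt"] = "G"
        if snps["snp_id"].duplicated().any():
            dups = snps.loc[snps["snp_id"].duplicated(), "snp_id"].tolist()
            raise ValidationError(f"duplicated snp_id(s): {dups[:5]}")
        dosage = np.asarray(dosage)
        if dosage.shape != (len(samples), len(snps)):
            raise ValidationError(
                f"dosage shape {dosage.shape} does not match {len(samples)} samples x {len(snps)} SNPs"
            )
        ok = np.isin(dosage, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValidationError("dosage entries must be in {0,1,2} or missing (-1)")
        order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
        self.snps = snps.iloc[order].reset_index(drop=True)
        self.dosage = np.ascontiguousarray(dosage[:, order], dtype=np.int8)
        self.samples = samples

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.snps["chrom"]))

    def positions0(self, chrom: str | None = None) -> np.ndarray:
        """0-based positions, optionally restricted to one chromosome."""
        pos = self.snps["pos"].to_numpy() - 1
        if chrom is None:
            return pos
        return pos[self.snps["chrom"].to_numpy() == chrom]

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with missing entries mapped to NaN."""
        d = self.dosage.astype(np.float64)
        d[self.dosage == MISSING] = np.nan
        return d

    def subset(self, samples: Sequence[str] | None = None,
               snp_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        rows = self.sample_index(samples) if samples is not None else np.arange(self.n_samples)
        cols = np.arange(self.n_snps) if snp_mask is None else np.flatnonzero(np.asarray(snp_mask))
        new_samples = [self.samples[i] for i in rows]
        return GenotypeMatrix(new_samples, self.snps.iloc[cols], self.dosage[np.ix_(rows, cols)])

    def allele_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (alt allele count, total called alleles) over a sample set."""
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        missing = d == MISSING
        alt = np.where(missing, 0, d).sum(axis=0, dtype=np.int64)
        allele_n = 2 * (d.shape[0] - missing.sum(axis=0, dtype=np.int64))
        return alt, allele_n

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.snps[["snp_id", "chrom", "pos"]].equals(other.snps[["snp_id", "chrom", "pos"]])
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class SampleTable:
    """Sample-to-ecotype assignment (winter / spring / semi_winter)."""

    table: pd.DataFrame  # columns: sample_id, group, origin

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleTable":
        df = df.copy()
        if "origin" not in df.columns:
            df["origin"] = ""
        missing_cols = {"sample_id", "group"} - set(df.columns)
        if missing_cols:
            raise ValidationError(f"sample table lacks columns {sorted(missing_cols)}")
        norm = df["group"].astype(str).str.strip().str.lower().str.replace(r"[-\s]+", "_", regex=True)
        bad = ~norm.isin(CANONICAL_GROUPS)
        if bad.any():
            rows = df.loc[bad, ["sample_id", "group"]].to_dict("records")
            raise ValidationError(f"unknown group label(s) in rows: {rows[:10]}")
        df["group"] = norm
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicated sample_id in sample table")
        return cls(df[["sample_id", "group", "origin"]].reset_index(drop=True))

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["group"]))

    def samples_in(self, groups: str | Sequence[str]) -> list[str]:
        if isinstance(groups, str):
            groups = (groups,)
        sel = self.table["group"].isin(groups)
        return self.table.loc[sel, "sample_id"].tolist()

    def counts(self) -> dict[str, int]:
        return self.table["group"].value_counts().to_dict()


# ----------------------------------------------------------------------
# readers / writers
# ----------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "vcf") -> GenotypeMatrix:
    """Read genotypes from a VCF or a delimited array-export table.

    Multiallelic or non-SNP records are dropped (count logged).  The result
    is sorted by (chrom, pos).
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeIOError(f"no such file: {path}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "table":
        return _read_table(path)
    raise GenotypeIOError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise GenotypeIOError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_dropped = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF.upper() not in _NUCLEOTIDES or v.ALT[0].upper() not in _NUCLEOTIDES:
            n_dropped += 1
            continue
        ids.append(v.ID if v.ID not in (None, ".") else f"snp_{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(gt_map[np.asarray(v.gt_types)])
    if n_dropped:
        logger.info("dropped %d multiallelic/non-SNP records from %s", n_dropped, path)
    if not rows:
        raise GenotypeIOError(f"no biallelic SNP records in {path}")
    snps = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    dosage = np.column_stack(rows).astype(np.int8)
    return GenotypeMatrix(samples, snps, dosage)


def _read_table(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise GenotypeIOError(f"cannot parse genotype table {path}: {exc}") from exc
    meta_cols = [c for c in ("snp_id", "chrom", "pos", "ref", "alt") if c in df.columns]
    if not {"snp_id", "chrom", "pos"}.issubset(meta_cols):
        raise GenotypeIOError("genotype table needs columns snp_id, chrom, pos before sample calls")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    if not sample_cols:
        raise GenotypeIOError("genotype table contains no sample columns")
    calls = df[sample_cols].to_numpy(dtype=object)
    flat = pd.Series(calls.ravel()).astype(str).str.strip().str.upper()
    mapped = flat.map(_TABLE_CALL_CODES)
    if mapped.isna().any():
        bad = sorted(set(flat[mapped.isna()]))[:5]
        raise GenotypeIOError(f"unrecognized genotype call code(s): {bad}")
    coded = mapped.to_numpy(dtype=np.int8).reshape(calls.shape)
    snps = df[meta_cols].copy()
    snps["pos"] = snps["pos"].astype(int)
    return GenotypeMatrix(sample_cols, snps, coded.T)


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str = "vcf") -> None:
    """Write a GenotypeMatrix back to VCF or the delimited table format.

    Round-trips bit-exactly with :func:`read_genotypes` for both formats.
    """
    path = Path(path)
    if format == "table":
        back = {0: "AA", 1: "AB", 2: "BB", MISSING: "NA"}
        out = g.snps[["snp_id", "chrom", "pos", "ref", "alt"]].copy()
        for j, s in enumerate(g.samples):
            out[s] = [back[int(x)] for x in g.dosage[j]]
        out.to_csv(path, index=False)
        return
    if format != "vcf":
        raise GenotypeIOError(f"unknown genotype format {format!r}")
    gt_back = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chrom_max = g.snps.groupby("chrom", sort=False)["pos"].max()
        for chrom, mx in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={int(mx) + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        snp_cols = g.snps.itertuples(index=True)
        for rec in snp_cols:
            gts = "\t".join(gt_back[int(x)] for x in g.dosage[:, rec.Index])
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.snp_id}\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def filter_snps(g: GenotypeMatrix, maf_min: float = 0.05,
                call_rate_min: float = 0.8) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the study's SNP quality filters.

    A SNP is *informative* when its call rate is at least ``call_rate_min``
    and it is polymorphic over non-missing calls.  It passes when its minor
    allele frequency is strictly greater than ``maf_min`` (the threshold
    itself is removed).
    """
    if not (0 <= maf_min < 0.5):
        raise ValidationError("maf_min must be in [0, 0.5)")
    if not (0 < call_rate_min <= 1):
        raise ValidationError("call_rate_min must be in (0, 1]")
    alt, allele_n = g.allele_counts()
    call_rate = allele_n / (2 * g.n_samples)
    polymorphic = (alt > 0) & (alt < allele_n)
    informative = (call_rate >= call_rate_min) & polymorphic
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(allele_n > 0, alt / np.maximum(allele_n, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = informative & (maf > maf_min)
    report = FilterReport(
        n_input=g.n_snps,
        n_informative=int(informative.sum()),
        n_pass_maf=int(keep.sum()),
        maf_min=maf_min,
        call_rate_min=call_rate_min,
    )
    if report.n_pass_maf == 0:
        raise ValidationError("all SNPs removed by the filters (empty panel)")
    return g.subset(snp_mask=keep), report


def read_sample_groups(path: str | Path) -> SampleTable:
    """Read a sample table CSV (sample_id, group[, origin]).

    Group labels are matched case-insensitively against the canonical names;
    anything else raises with the offending rows listed.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return SampleTable.from_frame(df)


def read_gene_annotation(path: str | Path, format: str = "bed") -> pd.DataFrame:
    """Read a gene annotation as BED4 (0-based half-open) or GFF3 (1-based).

    Returns a DataFrame ``gene_id, chrom, start, end, strand`` with 0-based
    half-open coordinates.
    """
    path = Path(path)
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] < 3:
            raise GenotypeIOError("BED needs at least 3 columns")
        out = pd.DataFrame({
            "gene_id": df[3] if df.shape[1] > 3 else [f"feat_{i}" for i in range(len(df))],
            "chrom": df[0],
            "start": df[1].astype(int),
            "end": df[2].astype(int),
            "strand": df[5] if df.shape[1] > 5 else "unknown",
        })
    elif format == "gff3":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                         names=["chrom", "source", "type", "start", "end",
                                "score", "strand", "phase", "attributes"])
        genes = df[df["type"].str.lower() == "gene"] if (df["type"].str.lower() == "gene").any() else df
        ids = genes["attributes"].str.extract(r"ID=([^;]+)")[0]
        ids = ids.fillna(pd.Series([f"feat_{i}" for i in range(len(genes))], index=genes.index))
        out = pd.DataFrame({
            "gene_id": ids,
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int) - 1,  # 1-based inclusive -> 0-based half-open
            "end": genes["end"].astype(int),
            "strand": genes["strand"].where(genes["strand"].isin(["+", "-"]), "unknown"),
        }).reset_index(drop=True)
    else:
        raise GenotypeIOError(f"unknown annotation format {format!r}")
    if (out["start"] >= out["end"]).any():
        raise ValidationError("gene annotation with start >= end")
    return out.reset_index(drop=True)
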