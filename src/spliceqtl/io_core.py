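"""Readers/writers and core containers for genotype, feature, and count data.

Coordinates are 1-based inclusive everywhere internally (Ensembl-style);
half-open BED input is converted at the boundary. Dosages are alt-allele
counts in {0,1,2}; missing genotypes are a hard error because the pipeline
assumes fully imputed sequence data and silent imputation would mask bugs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with its folded minor allele frequency."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.snp_id}: pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")


@dataclass(frozen=True)
class FeatureRecord:
    """A gene, exon, or intron with 1-based inclusive coordinates.

    ``tss`` is defined for genes only: start on the + strand, end on the
    - strand.
    """

    feature_id: str
    kind: str  # gene | exon | intron
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    tss: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "exon", "intron"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(
                f"{self.feature_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: bad strand {self.strand!r}")
        if self.kind == "gene" and self.tss is None:
            object.__setattr__(
                self, "tss", self.start if self.strand == "+" else self.end
            )


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with positional metadata."""

    samples: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray  # (n_samples, n_snps), values in {0,1,2}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError("dosage shape does not match samples x snps")
        if not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2} (missing not permitted)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "chrom": [s.chrom for s in self.snps],
                "pos": [s.pos for s in self.snps],
                "ref": [s.ref_allele for s in self.snps],
                "alt": [s.alt_allele for s in self.snps],
                "maf": [s.maf for s in self.snps],
            }
        )

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(
            samples=list(keep), snps=list(self.snps), dosages=self.dosages[idx, :]
        )


@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative integer counts."""

    features: list[FeatureRecord]
    samples: list[str]
    counts: np.ndarray  # (n_features, n_samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.features), len(self.samples)):
            raise ValueError("count shape does not match features x samples")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[f.feature_id for f in self.features],
            columns=self.samples,
        )


def folded_maf(dosage_col: np.ndarray) -> float:
    """Minor allele frequency min(f, 1-f) with f the mean alt dose / 2."""
    f = float(np.mean(dosage_col)) / 2.0
    return min(f, 1.0 - f)


def _attach_mafs(samples, snp_rows, dosages) -> GenotypeMatrix:
    snps = []
    for j, (snp_id, chrom, pos, ref, alt) in enumerate(snp_rows):
        snps.append(
            SnpRecord(snp_id, str(chrom), int(pos), ref, alt, folded_maf(dosages[:, j]))
        )
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def _maf_filter(gm: GenotypeMatrix, maf_min: float) -> GenotypeMatrix:
    mafs = np.array([s.maf for s in gm.snps])
    keep = mafs > maf_min
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("MAF filter: removed %d of %d SNPs (maf <= %g)",
                 n_removed, gm.n_snps, maf_min)
    out = gm.subset_snps(keep)
    order = np.lexsort(
        ([s.pos for s in out.snps], [s.chrom for s in out.snps])
    )
    return GenotypeMatrix(
        samples=out.samples,
        snps=[out.snps[i] for i in order],
        dosages=out.dosages[:, order],
    )


def read_genotypes(path: str | Path, maf_min: float = 0.01) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV dialect, applying a MAF filter.

    The TSV dialect has a header ``snp_id chrom pos ref alt <sample...>`` and
    one row per SNP. VCF input must carry GT fields; non-biallelic sites are
    skipped with a warning and missing genotypes raise.
    """
    path = Path(path)
    if path.suffix in (".vcf",) or str(path).endswith(".vcf.gz"):
        gm = _read_vcf(path)
    else:
        gm = _read_genotype_tsv(path)
    return _maf_filter(gm, maf_min)


def _read_genotype_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment=None)
    required = ["snp_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != required:
        raise ValueError(f"genotype TSV must start with columns {required}")
    if df["snp_id"].duplicated().any():
        dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"duplicate snp_id {dup!r}")
    samples = list(df.columns[5:])
    dosages = df[samples].to_numpy()
    if np.isnan(dosages.astype(float)).any():
        raise ValueError("missing genotype in TSV (imputation is out of scope)")
    dosages = dosages.astype(np.int16).T  # samples x snps
    rows = list(df[required].itertuples(index=False, name=None))
    return _attach_mafs(samples, rows, dosages)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, cols = [], []
    seen: set[str] = set()
    for var in vcf:
        if len(var.ALT) != 1:
            log.warning("skipping non-biallelic site %s:%d", var.CHROM, var.POS)
            continue
        gt = var.gt_types  # 0=hom-ref 1=het 2=hom-alt 3=unknown with gts012
        if (gt == 3).any():
            raise ValueError(
                f"missing genotype at {var.CHROM}:{var.POS} (imputation out of scope)"
            )
        snp_id = var.ID or f"{var.CHROM}:{var.POS}"
        if snp_id in seen:
            raise ValueError(f"duplicate snp_id {snp_id!r}")
        seen.add(snp_id)
        rows.append((snp_id, var.CHROM, var.POS, var.REF, var.ALT[0]))
        cols.append(gt.astype(np.int16))
    dosages = (
        np.stack(cols, axis=1) if cols else np.zeros((len(samples), 0), dtype=np.int16)
    )
    return _attach_mafs(samples, rows, dosages)


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.snp_frame().drop(columns="maf")
    body = pd.DataFrame(
        gm.dosages.T, columns=gm.samples, index=df.index
    )
    pd.concat([df, body], axis=1).to_csv(path, sep="\t", index=False)


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal biallelic-SNP VCF with GT fields."""
    code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(s.chrom for s in gm.snps):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, s in enumerate(gm.snps):
            gts = "\t".join(code[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# feature annotation


def read_features(path: str | Path) -> list[FeatureRecord]:
    """Read gene/exon/intron annotation from GFF3 or the 6-column BED dialect.

    Introns absent from the file are derived as the gaps between consecutive
    exons of each gene. BED (0-based half-open) coordinates are converted to
    the internal 1-based inclusive convention on read.
    """
    path = Path(path)
    if path.suffix in (".gff", ".gff3"):
        feats = _read_gff3(path)
    else:
        feats = _read_feature_bed(path)
    return finalize_features(feats)


def finalize_features(feats: list[FeatureRecord]) -> list[FeatureRecord]:
    """Validate parentage and derive missing introns from exon gaps."""
    genes = {f.feature_id for f in feats if f.kind == "gene"}
    for f in feats:
        if f.kind in ("exon", "intron") and f.gene_id not in genes:
            raise ValueError(
                f"{f.kind} {f.feature_id} has no parent gene {f.gene_id!r}"
            )
    have_introns = {f.gene_id for f in feats if f.kind == "intron"}
    derived: list[FeatureRecord] = []
    for gid in sorted(genes - have_introns):
        exons = sorted(
            (f for f in feats if f.kind == "exon" and f.gene_id == gid),
            key=lambda f: f.start,
        )
        for k in range(len(exons) - 1):
            lo, hi = exons[k].end + 1, exons[k + 1].start - 1
            if lo > hi:
                continue  # abutting exons leave no gap
            derived.append(
                FeatureRecord(
                    feature_id=f"{gid}_intron{k + 1}",
                    kind="intron",
                    chrom=exons[k].chrom,
                    start=lo,
                    end=hi,
                    strand=exons[k].strand,
                    gene_id=gid,
                )
            )
    return feats + derived


def _parse_gff_attrs(s: str) -> dict[str, str]:
    out = {}
    for part in s.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


_GFF_KIND = {"gene": "gene", "exon": "exon", "intron": "intron"}


def _read_gff3(path: Path) -> list[FeatureRecord]:
    feats: list[FeatureRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = (
                line.rstrip("\n").split("\t")
            )
            if ftype not in _GFF_KIND:
                continue
            a = _parse_gff_attrs(attrs)
            fid = a.get("ID")
            if fid is None:
                raise ValueError(f"GFF3 feature without ID: {line.strip()}")
            gene_id = fid if ftype == "gene" else a.get("Parent", "")
            feats.append(
                FeatureRecord(
                    feature_id=fid,
                    kind=_GFF_KIND[ftype],
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    gene_id=gene_id,
                )
            )
    return feats


def _read_feature_bed(path: Path) -> list[FeatureRecord]:
    """BED dialect: chrom start end name score strand kind gene_id (0-based half-open)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, name, _score, strand, kind, gene_id = parts[:8]
            feats.append(
                FeatureRecord(
                    feature_id=name,
                    kind=kind,
                    chrom=chrom,
                    start=int(start) + 1,  # BED -> 1-based inclusive
                    end=int(end),
                    strand=strand,
                    gene_id=gene_id if gene_id else name,
                )
            )
    return feats


def write_features_gff3(feats: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            attrs = f"ID={f.feature_id}"
            if f.kind != "gene":
                attrs += f";Parent={f.gene_id}"
            fh.write(
                f"{f.chrom}\tspliceqtl\t{f.kind}\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def tss_distance(snp: SnpRecord, gene: FeatureRecord) -> int:
    """Absolute distance in bp between a SNP and a gene's transcription start site."""
    if gene.kind != "gene":
        raise ValueError("tss_distance requires a gene feature")
    if snp.chrom != gene.chrom:
        raise ValueError(
            f"SNP {snp.snp_id} on {snp.chrom} but gene {gene.feature_id} on {gene.chrom}"
        )
    return abs(snp.pos - int(gene.tss))


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path: str | Path, features: list[FeatureRecord]) -> CountMatrix:
    """Read a TSV count matrix keyed by feature_id, matched against annotation."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    by_id = {f.feature_id: f for f in features}
    missing = [fid for fid in df.index if fid not in by_id]
    if missing:
        raise ValueError(f"count rows without annotation: {missing[:5]} ...")
    feats = [by_id[fid] for fid in df.index]
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError("non-numeric counts")
    return CountMatrix(features=feats, samples=list(df.columns), counts=counts)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="feature_id")
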