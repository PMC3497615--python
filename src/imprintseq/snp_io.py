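"""I/O for SNP references, gene models, count tables and prediction reports.

Coordinate conventions: SNP tables and count tables are 1-based (dbSNP
convention); gene-model exons are stored 0-based half-open (the BED
convention), with conversion from GTF's 1-based inclusive coordinates at
the parsing boundary only.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "SnpRecord",
    "GeneRecord",
    "SnpGeneMap",
    "SnpLoadResult",
    "ParseError",
    "load_snp_reference",
    "load_gene_models",
    "map_snps_to_genes",
    "read_counts_table",
    "write_counts_table",
    "write_predictions",
    "read_predictions",
]

_NUCS = {"A", "C", "G", "T"}

COUNT_COLUMNS = ["sample_id", "rs_id", "count_x", "count_y", "count_other"]
PREDICTION_COLUMNS = [
    "rs_id",
    "chrom",
    "position",
    "strand",
    "posterior",
    "gene_id",
    "symbol",
    "sample_size",
    "fdr",
]


class ParseError(ValueError):
    """Raised for malformed rows; message names the offending line."""


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic SNP with population frequency of allele X.

    The frequency of allele Y is always ``1 - freq_x`` and never stored.
    Alleles are recorded exactly as annotated (minus-strand SNPs are
    complemented to the mapped strand during counting, not here).
    """

    rs_id: str
    chrom: str
    position: int  # 1-based
    strand: str
    allele_x: str
    allele_y: str
    freq_x: float

    def __post_init__(self) -> None:
        if self.allele_x == self.allele_y:
            raise ValueError(f"{self.rs_id}: alleles must differ")
        if self.allele_x not in _NUCS or self.allele_y not in _NUCS:
            raise ValueError(f"{self.rs_id}: alleles must be single nucleotides")
        if not 0.0 <= self.freq_x <= 1.0:
            raise ValueError(f"{self.rs_id}: freq_x {self.freq_x} outside [0, 1]")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.rs_id}: strand must be '+' or '-'")
        if self.position < 1:
            raise ValueError(f"{self.rs_id}: position must be 1-based positive")

    @property
    def freq_y(self) -> float:
        return 1.0 - self.freq_x

    @property
    def minor_allele_frequency(self) -> float:
        return min(self.freq_x, 1.0 - self.freq_x)


@dataclass(frozen=True)
class GeneRecord:
    """A gene model as a set of merged exon intervals (0-based half-open)."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have at least one exon")
        merged = _merge_intervals(self.exons)
        object.__setattr__(self, "exons", merged)


def _merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if s < 0 or e <= s:
            raise ValueError(f"bad exon interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return tuple(out)


@dataclass(frozen=True)
class SnpGeneMap:
    """Unique (rs_id, gene_id) assignments; a SNP may map to several genes."""

    assignments: tuple[tuple[str, str], ...]

    def genes_for(self, rs_id: str) -> list[str]:
        return [g for r, g in self.assignments if r == rs_id]

    def snps_for(self, gene_id: str) -> list[str]:
        return [r for r, g in self.assignments if g == gene_id]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass
class SnpLoadResult:
    """SNP records plus a tally of rows dropped at load time."""

    records: list[SnpRecord]
    dropped_missing_freq: int = 0
    dropped_multiallelic: int = 0

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def load_snp_reference(path: str, format: str | None = None) -> SnpLoadResult:
    """Load a biallelic SNP reference from TSV or VCF.

    TSV columns: rs_id, chrom, position, strand, allele_x, allele_y,
    freq_x (header required, '#' comment lines ignored).  VCF records
    must be single-nucleotide and biallelic and carry an ``AF`` INFO
    field; allele X is the REF allele with ``freq_x = 1 - AF``.

    Records with more than two alleles and records lacking a frequency
    are dropped and tallied in the returned :class:`SnpLoadResult`.
    """
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "tsv":
        return _load_snp_tsv(path)
    if format == "vcf":
        return _load_snp_vcf(path)
    raise ValueError(f"unknown SNP reference format {format!r}")


def _load_snp_tsv(path: str) -> SnpLoadResult:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["rs_id", "chrom", "position", "strand", "allele_x", "allele_y", "freq_x"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    result = SnpLoadResult(records=[])
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        freq_raw = row["freq_x"]
        if pd.isna(freq_raw) or str(freq_raw).upper() in {"NA", "NAN", "."}:
            result.dropped_missing_freq += 1
            continue
        try:
            rec = SnpRecord(
                rs_id=str(row["rs_id"]),
                chrom=str(row["chrom"]),
                position=int(row["position"]),
                strand=str(row["strand"]),
                allele_x=str(row["allele_x"]).upper(),
                allele_y=str(row["allele_y"]).upper(),
                freq_x=float(freq_raw),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {line_no}: {exc}") from exc
        result.records.append(rec)
    return result


def _load_snp_vcf(path: str) -> SnpLoadResult:
    from cyvcf2 import VCF

    result = SnpLoadResult(records=[])
    for variant in VCF(path):
        if len(variant.ALT) != 1:
            result.dropped_multiallelic += 1
            continue
        ref, alt = variant.REF.upper(), variant.ALT[0].upper()
        if ref not in _NUCS or alt not in _NUCS:
            result.dropped_multiallelic += 1  # indels/symbolic are not SNPs
            continue
        af = variant.INFO.get("AF")
        if af is None:
            result.dropped_missing_freq += 1
            continue
        # cyvcf2 yields float32; round back to the text field's precision
        af = round(float(af[0] if isinstance(af, (tuple, list)) else af), 6)
        if not 0.0 <= af <= 1.0:
            raise ParseError(f"{path}: {variant.ID or variant.POS}: AF {af} outside [0, 1]")
        result.records.append(
            SnpRecord(
                rs_id=str(variant.ID) if variant.ID else f"{variant.CHROM}:{variant.POS}",
                chrom=variant.CHROM,
                position=variant.POS,
                strand="+",
                allele_x=ref,
                allele_y=alt,
                freq_x=1.0 - af,
            )
        )
    return result


def load_gene_models(path: str, format: str | None = None) -> list[GeneRecord]:
    """Load gene models from BED12 or GTF."""
    if format is None:
        lowered = path.lower()
        format = "gtf" if lowered.endswith((".gtf", ".gff", ".gtf.gz")) else "bed"
    if format == "bed":
        return _load_bed12(path)
    if format == "gtf":
        return _load_gtf(path)
    raise ValueError(f"unknown gene model format {format!r}")


def _load_bed12(path: str) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}, line {line_no}: BED12 needs 12 columns")
            chrom, start = fields[0], int(fields[1])
            name, strand = fields[3], fields[5]
            sizes = [int(s) for s in fields[10].rstrip(",").split(",")]
            starts = [int(s) for s in fields[11].rstrip(",").split(",")]
            if len(sizes) != len(starts):
                raise ParseError(f"{path}, line {line_no}: block size/start mismatch")
            exons = [(start + off, start + off + size) for off, size in zip(starts, sizes)]
            genes.append(
                GeneRecord(gene_id=name, symbol=name, chrom=chrom, strand=strand,
                           exons=tuple(exons))
            )
    return genes


def _load_gtf(path: str) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes.get("gene_id", [exon.id])[0]
        symbol = exon.attributes.get("gene_name", [gene_id])[0]
        entry = by_gene.setdefault(
            gene_id,
            {"symbol": symbol, "chrom": exon.seqid, "strand": exon.strand, "exons": []},
        )
        entry["exons"].append((exon.start - 1, exon.end))  # GTF is 1-based inclusive
    return [
        GeneRecord(
            gene_id=gid,
            symbol=info["symbol"],
            chrom=info["chrom"],
            strand=info["strand"] or "+",
            exons=tuple(info["exons"]),
        )
        for gid, info in by_gene.items()
    ]


def map_snps_to_genes(
    snps: Iterable[SnpRecord], genes: Iterable[GeneRecord]
) -> SnpGeneMap:
    """Assign each SNP to every gene with an exon containing its position.

    Intronic and intergenic SNPs receive no assignment; a SNP inside
    overlapping exons of several genes is assigned to each of them.
    """
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for start, end in gene.exons:
            tree[start:end] = gene.gene_id
    pairs = set()
    for snp in snps:
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for hit in tree[snp.position - 1]:
            pairs.add((snp.rs_id, hit.data))
    return SnpGeneMap(assignments=tuple(sorted(pairs)))


def read_counts_table(path: str) -> pd.DataFrame:
    """Read a per-sample allelic-count TSV (sample_id, rs_id, count_x, count_y, count_other)."""
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=COUNT_COLUMNS)
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"sample_id": str, "rs_id": str}
    )
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    df = df[COUNT_COLUMNS]
    for col in ("count_x", "count_y", "count_other"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals < 0).any():
            bad = int(np.argmax(vals.to_numpy() < 0))
            raise ValueError(f"{path}: negative {col} at data row {bad + 1}")
        df[col] = vals.astype(int)
    return df


def write_counts_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


def write_predictions(records: pd.DataFrame | Sequence[dict], path: str) -> None:
    """Write a prediction report TSV (one row per SNP-gene prediction)."""
    df = pd.DataFrame(records)
    missing = [c for c in PREDICTION_COLUMNS if c not in df.columns]
    if missing and len(df):
        raise ValueError(f"prediction report missing columns {missing}")
    if not len(df):
        df = pd.DataFrame(columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, columns=PREDICTION_COLUMNS)


def read_predictions(path: str) -> pd.DataFrame:
    if os.path.getsize(path) == 0:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    return pd.read_csv(path, sep="\t", dtype={"rs_id": str, "gene_id": str, "symbol": str})
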