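"""Per-(SNP, sample) allelic observations: pileup counting, QS, filters.

An observation at a SNP collects x (reads matching allele X), y (reads
matching allele Y) and e (reads showing either of the other two
nucleotides).  Reads of a third nucleotide indicate low base quality or a
wrong allele annotation, so each observation carries a quality score

    QS = (x + y) / (x + y + e)

and is *valid* — i.e. contributes to the model and counts toward a SNP's
"sample size" — only when QS exceeds a cutoff (default 0.9, exclusive)
and the total allelic count x + y is at least 3.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pysam

from .snp_io import SnpRecord

__all__ = [
    "AlleleObservation",
    "COMPLEMENT",
    "pileup_allele_counts",
    "derive_observation",
    "observations_from_counts",
    "observations_from_table",
]

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_NUCS = ("A", "C", "G", "T")

DEFAULT_QS_CUTOFF = 0.9
DEFAULT_MIN_TOTAL = 3


@dataclass(frozen=True)
class AlleleObservation:
    """Allelic counts for one SNP in one sample."""

    rs_id: str
    sample_id: str
    x: int
    y: int
    e: int
    qs: float
    valid: bool

    def __post_init__(self) -> None:
        if min(self.x, self.y, self.e) < 0:
            raise ValueError("counts must be non-negative")


def derive_observation(
    nucleotide_counts: Mapping[str, int],
    snp: SnpRecord,
    sample_id: str = "",
    qs_cutoff: float = DEFAULT_QS_CUTOFF,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> AlleleObservation:
    """Build a filtered observation from raw A/C/G/T counts at a SNP.

    SNP alleles annotated on the minus strand are complemented before
    matching against pileup counts, which are always reported on the
    mapped (plus) strand.  Validity requires ``x + y >= min_total`` and
    ``QS > qs_cutoff`` (strict); zero coverage yields ``valid=False``
    with QS reported as 0.
    """
    ax, ay = snp.allele_x, snp.allele_y
    if snp.strand == "-":
        ax, ay = COMPLEMENT[ax], COMPLEMENT[ay]
    x = int(nucleotide_counts.get(ax, 0))
    y = int(nucleotide_counts.get(ay, 0))
    total = sum(int(nucleotide_counts.get(n, 0)) for n in _NUCS)
    e = total - x - y
    qs = (x + y) / (x + y + e) if total > 0 else 0.0
    valid = (x + y >= min_total) and (qs > qs_cutoff)
    return AlleleObservation(
        rs_id=snp.rs_id, sample_id=sample_id, x=x, y=y, e=e, qs=qs, valid=valid
    )


def pileup_allele_counts(
    alignments: str,
    snps: Iterable[SnpRecord],
    min_base_quality: int = 0,
    min_mapping_quality: int = 0,
) -> dict[str, dict[str, int]]:
    """Count A/C/G/T read bases at each SNP position in one SAM/BAM file.

    Streams every mapped read once and tallies the aligned base at each
    SNP position, skipping deletions/reference skips (absent from the
    aligned pairs), bases below ``min_base_quality``, reads below
    ``min_mapping_quality``, and ambiguous (non-ACGT) bases.  SNPs with
    zero coverage are omitted from the result.

    Returns ``{rs_id: {"A": nA, "C": nC, "G": nG, "T": nT}}``.
    """
    wanted: dict[str, dict[int, list[str]]] = defaultdict(lambda: defaultdict(list))
    chroms = set()
    for snp in snps:
        wanted[snp.chrom][snp.position - 1].append(snp.rs_id)
        chroms.add(snp.chrom)

    counts: dict[str, dict[str, int]] = defaultdict(lambda: dict.fromkeys(_NUCS, 0))
    with pysam.AlignmentFile(alignments, check_sq=False) as af:
        refs = set(af.references or ())
        missing = chroms - refs
        if missing:
            warnings.warn(
                "chromosomes absent from alignment header (zero counts): "
                + ", ".join(sorted(missing)),
                stacklevel=2,
            )
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapping_quality:
                continue
            positions = wanted.get(read.reference_name)
            if not positions:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos not in positions:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                base = seq[qpos].upper()
                if base not in COMPLEMENT:
                    continue
                for rs_id in positions[rpos]:
                    counts[rs_id][base] += 1
    return dict(counts)


def observations_from_table(
    counts,
    qs_cutoff: float = DEFAULT_QS_CUTOFF,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> dict[str, list[AlleleObservation]]:
    """Observations grouped by SNP from a counts table.

    ``counts`` is a DataFrame with columns sample_id, rs_id, count_x,
    count_y, count_other (allele-oriented, so no strand handling is
    needed here).  Validity is derived with the standard QS and
    minimum-count filters.
    """
    out: dict[str, list[AlleleObservation]] = {}
    for row in counts.itertuples(index=False):
        x, y, e = int(row.count_x), int(row.count_y), int(row.count_other)
        total = x + y + e
        qs = (x + y) / total if total > 0 else 0.0
        valid = (x + y >= min_total) and (qs > qs_cutoff)
        out.setdefault(str(row.rs_id), []).append(
            AlleleObservation(
                rs_id=str(row.rs_id),
                sample_id=str(row.sample_id),
                x=x,
                y=y,
                e=e,
                qs=qs,
                valid=valid,
            )
        )
    return out


def observations_from_counts(
    counts_by_snp: Mapping[str, Mapping[str, int]],
    snps: Iterable[SnpRecord],
    sample_id: str,
    qs_cutoff: float = DEFAULT_QS_CUTOFF,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> list[AlleleObservation]:
    """Observations for one sample from a pileup result; uncovered SNPs skipped."""
    out = []
    for snp in snps:
        nuc = counts_by_snp.get(snp.rs_id)
        if nuc is None or sum(nuc.values()) == 0:
            continue
        out.append(
            derive_observation(
                nuc, snp, sample_id=sample_id, qs_cutoff=qs_cutoff, min_total=min_total
            )
        )
    return out
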