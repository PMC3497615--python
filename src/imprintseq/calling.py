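"""Gene-level imprinting calls and simulation-based FDR annotation.

A gene is called imprinted when at least one of its exonic SNPs has a
posterior above the call cutoff (default 0.2) and *none* of its SNPs
contradicts imprinting — every computed posterior must stay above the
contradiction cutoff (default 0.002, calibrated so that ~95% of truly
imprinted SNPs clear it in simulation).  Genes on the X chromosome are
excluded because X-inactivation mimics imprinting.

The FDR attached to a call is read off a simulated performance grid:

    FDR = (1 - specificity)(1 - prevalence)
          / [(1 - specificity)(1 - prevalence) + sensitivity * prevalence]

with prevalence the prior probability of imprinting (default 1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .model import PosteriorResult
from .snp_io import GeneRecord, SnpGeneMap

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PerformanceGrid

__all__ = [
    "GenePrediction",
    "call_imprinted_genes",
    "fdr_from_rates",
    "estimate_fdr",
    "DEFAULT_CALL_CUTOFF",
    "DEFAULT_CONTRADICTION_CUTOFF",
    "DEFAULT_EXCLUDE_CHROMS",
]

DEFAULT_CALL_CUTOFF = 0.2
DEFAULT_CONTRADICTION_CUTOFF = 0.002
DEFAULT_EXCLUDE_CHROMS = frozenset({"chrX", "X"})


@dataclass(frozen=True)
class GenePrediction:
    """Gene-level call aggregating the posteriors of its exonic SNPs."""

    gene_id: str
    symbol: str
    chrom: str
    snp_posteriors: tuple[tuple[str, float, int], ...]  # (rs_id, posterior, sample_size)
    max_posterior: float
    min_posterior: float
    best_snp: str
    called: bool
    fdr_estimate: float | None = None


def call_imprinted_genes(
    posteriors: Iterable[PosteriorResult],
    snp_gene_map: SnpGeneMap,
    genes: Iterable[GeneRecord],
    call_cutoff: float = DEFAULT_CALL_CUTOFF,
    contradiction_cutoff: float = DEFAULT_CONTRADICTION_CUTOFF,
    exclude_chroms: Iterable[str] = DEFAULT_EXCLUDE_CHROMS,
    grid: "PerformanceGrid | None" = None,
    snp_mafs: dict[str, float] | None = None,
    prevalence: float = 0.01,
) -> list[GenePrediction]:
    """Aggregate per-SNP posteriors into gene-level imprinting calls.

    A SNP mapped to several genes contributes its posterior to each.
    Genes with no mapped posterior are omitted.  When a performance
    ``grid`` and per-SNP minor allele frequencies are supplied, each
    called gene is annotated with the FDR at its best SNP's sample size
    and frequency.
    """
    excluded = set(exclude_chroms)
    by_rs = {p.rs_id: p for p in posteriors}
    gene_info = {g.gene_id: g for g in genes}
    per_gene: dict[str, list[PosteriorResult]] = {}
    for rs_id, gene_id in snp_gene_map:
        p = by_rs.get(rs_id)
        if p is not None:
            per_gene.setdefault(gene_id, []).append(p)

    out = []
    for gene_id in sorted(per_gene):
        results = sorted(per_gene[gene_id], key=lambda r: (-r.posterior, r.rs_id))
        gene = gene_info.get(gene_id)
        chrom = gene.chrom if gene else ""
        symbol = gene.symbol if gene else gene_id
        best = results[0]
        max_post = best.posterior
        min_post = min(r.posterior for r in results)
        called = (
            max_post > call_cutoff
            and min_post > contradiction_cutoff
            and chrom not in excluded
        )
        fdr = None
        if grid is not None and snp_mafs is not None and best.rs_id in snp_mafs:
            fdr = estimate_fdr(
                best.sample_size, snp_mafs[best.rs_id], grid, prevalence=prevalence
            )
        out.append(
            GenePrediction(
                gene_id=gene_id,
                symbol=symbol,
                chrom=chrom,
                snp_posteriors=tuple(
                    (r.rs_id, r.posterior, r.sample_size) for r in results
                ),
                max_posterior=max_post,
                min_posterior=min_post,
                best_snp=best.rs_id,
                called=called,
                fdr_estimate=fdr,
            )
        )
    return out


def fdr_from_rates(
    sensitivity: float, specificity: float, prevalence: float = 0.01
) -> float | None:
    """Expected FDR of a caller with the given class-conditional rates.

    Returns ``None`` (not computable) when neither class produces any
    positive calls, i.e. sensitivity = 0 and specificity = 1.
    """
    false_pos = (1.0 - specificity) * (1.0 - prevalence)
    true_pos = sensitivity * prevalence
    denom = false_pos + true_pos
    if denom == 0.0:
        return None
    return false_pos / denom


def estimate_fdr(
    sample_size: int,
    minor_allele_frequency: float,
    grid: "PerformanceGrid",
    prevalence: float = 0.01,
) -> float | None:
    """FDR at the nearest simulated grid cell.

    Sample size snaps to the nearest simulated size; a minor allele
    frequency outside the simulated range returns ``None`` (NA), as do
    grid cells whose FDR was not computable.
    """
    if grid.sample_sizes.size == 0 or grid.mafs.size == 0:
        raise ValueError("performance grid is empty")
    maf = min(minor_allele_frequency, 1.0 - minor_allele_frequency)
    tol = 1e-9
    if maf < grid.mafs.min() - tol or maf > grid.mafs.max() + tol:
        return None
    i = int(np.argmin(np.abs(grid.sample_sizes - sample_size)))
    j = int(np.argmin(np.abs(grid.mafs - maf)))
    sens = grid.sensitivity[i, j]
    spec = grid.specificity[i, j]
    return fdr_from_rates(float(sens), float(spec), prevalence)
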