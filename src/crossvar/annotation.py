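"""Indel post-filtering, functional characterization and region-based
density/enrichment statistics.

Short intra-read indels carry a high false-positive load, so candidate
lists are first intersected across two callers and then passed through a
six-criterion post-filter (per-strand support, base quality, depth bounds,
assembly-N exclusion).  Coding indels are characterized by frame effect
(size a multiple of three or not) and by relative position in the encoded
protein.  The generic density/enrichment operation compares variant density
inside a region set against the rest of the genome with a 2x2 chi-square.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .variant_model import GenomeLayout, GenomicInterval, VariantCall

__all__ = [
    "GeneModel",
    "IndelFilterParams",
    "EnrichmentResult",
    "intersect_indel_callers",
    "filter_indels",
    "classify_3n",
    "relative_protein_position",
    "snp_indel_ratio",
    "region_density_enrichment",
    "windowed_density_correlation",
]


@dataclass(frozen=True)
class GeneModel:
    """Protein-coding gene: ordered CDS intervals (0-based half-open,
    genomic order) on one strand.  ``protein_length`` excludes the stop
    codon."""

    gene_id: str
    chrom: str
    strand: str
    cds: tuple[GenomicInterval, ...]
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        total = sum(iv.length for iv in self.cds)
        if total % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {total} not divisible by 3")
        expected = total // 3 - 1
        if self.protein_length is None:
            object.__setattr__(self, "protein_length", expected)
        elif self.protein_length != expected:
            raise ValueError(
                f"{self.gene_id}: protein_length {self.protein_length} != CDS/3-1 {expected}"
            )

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    def cds_offset(self, pos: int) -> int:
        """Strand-aware offset of a genomic position within the coding
        sequence (0 = first base of the start codon)."""
        ordered = sorted(self.cds, key=lambda iv: iv.start)
        if not any(iv.start <= pos < iv.end for iv in ordered):
            raise ValueError(f"position {pos} outside CDS of {self.gene_id}")
        offset = 0
        for iv in ordered:
            if iv.start <= pos < iv.end:
                offset += pos - iv.start
                break
            offset += iv.length
        if self.strand == "-":
            offset = self.cds_length - 1 - offset
        return offset


@dataclass(frozen=True)
class IndelFilterParams:
    """Post-filter thresholds for intra-read indels.

    The mapping-quality downgrade coefficient applied during calling is a
    caller-time setting and is tracked only as upstream metadata here.
    """

    min_base_quality: int = 20
    min_depth: int = 4
    max_depth: int = 30
    require_both_strands: bool = True
    exclude_n_overlap: bool = True

    def __post_init__(self) -> None:
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")


def intersect_indel_callers(
    set_a: Iterable[VariantCall], set_b: Iterable[VariantCall]
) -> list[VariantCall]:
    """Indels called identically (chrom, pos, ref, alt) by both callers.

    Both inputs must already be left-normalized; records from ``set_a`` are
    returned for matches.
    """
    keys_b = {(c.chrom, c.pos, c.ref, c.alt) for c in set_b}
    return [c for c in set_a if (c.chrom, c.pos, c.ref, c.alt) in keys_b]


def _overlaps_any(call: VariantCall, trees: Mapping[str, IntervalTree]) -> bool:
    tree = trees.get(call.chrom)
    if tree is None:
        return False
    span = max(len(call.ref), 1)
    return bool(tree.overlap(call.pos, call.pos + span))


def filter_indels(
    indels: Iterable[VariantCall],
    params: IndelFilterParams | None = None,
    n_mask: Sequence[GenomicInterval] = (),
) -> tuple[list[VariantCall], dict[str, int]]:
    """Apply the indel post-filter; returns (survivors, per-rule drop counts).

    Each record's ``info`` must carry ``strand_support`` (fwd, rev reads for
    the non-reference allele) and ``base_quality``; records missing any
    required annotation are dropped and counted under ``missing``.
    """
    params = params or IndelFilterParams()
    trees: dict[str, IntervalTree] = {}
    for iv in n_mask:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept: list[VariantCall] = []
    drops = {
        "strand": 0,
        "base_quality": 0,
        "min_depth": 0,
        "max_depth": 0,
        "n_overlap": 0,
        "missing": 0,
    }
    for c in indels:
        support = c.info.get("strand_support")
        bq = c.info.get("base_quality")
        if c.depth is None or support is None or bq is None:
            drops["missing"] += 1
            continue
        fwd, rev = support
        if params.require_both_strands and (fwd < 1 or rev < 1):
            drops["strand"] += 1
            continue
        if bq < params.min_base_quality:
            drops["base_quality"] += 1
            continue
        if c.depth < params.min_depth:
            drops["min_depth"] += 1
            continue
        if c.depth > params.max_depth:
            drops["max_depth"] += 1
            continue
        if params.exclude_n_overlap and _overlaps_any(c, trees):
            drops["n_overlap"] += 1
            continue
        kept.append(c)
    return kept, drops


def classify_3n(
    coding_sizes: Sequence[int],
    genome_sizes: Sequence[int] | None = None,
    yates: bool = False,
) -> dict[str, object]:
    """Count frame-preserving (size % 3 == 0) vs frameshift indels and, when
    a genome-wide background is given, test enrichment with a 2x2
    chi-square (1 df, no continuity correction by default)."""
    if len(coding_sizes) == 0:
        raise ValueError("empty coding indel set")
    if any(s < 1 for s in coding_sizes):
        raise ValueError("indel sizes must be >= 1")
    c3 = sum(1 for s in coding_sizes if s % 3 == 0)
    result: dict[str, object] = {
        "coding_3n": c3,
        "coding_non_3n": len(coding_sizes) - c3,
        "coding_3n_fraction": c3 / len(coding_sizes),
    }
    if genome_sizes is not None:
        g3 = sum(1 for s in genome_sizes if s % 3 == 0)
        table = np.array(
            [
                [c3, len(coding_sizes) - c3],
                [g3, len(genome_sizes) - g3],
            ]
        )
        chi2, p, _, _ = stats.chi2_contingency(table, correction=yates)
        result.update(
            genome_3n=g3,
            genome_non_3n=len(genome_sizes) - g3,
            genome_3n_fraction=g3 / len(genome_sizes),
            chi2=float(chi2),
            p_value=float(p),
        )
    return result


def relative_protein_position(indel: VariantCall, gene: GeneModel) -> float:
    """Relative location of a coding indel in the protein: affected
    amino-acid index divided by protein length, in (0, 1].

    The indel's position is taken as its first affected codon (the base
    after the shared anchor for an anchored indel).
    """
    first_changed = indel.pos + 1 if len(indel.ref) != len(indel.alt) else indel.pos
    offset = gene.cds_offset(first_changed)
    aa_index = offset // 3 + 1
    assert gene.protein_length is not None
    rel = aa_index / gene.protein_length
    return min(rel, 1.0)


def snp_indel_ratio(n_snp: int, n_indel: int) -> float:
    """Ratio of SNP to indel counts (e.g. genome-wide vs coding regions)."""
    if n_indel <= 0:
        raise ValueError("n_indel must be > 0")
    return n_snp / n_indel


@dataclass
class EnrichmentResult:
    n_in: int
    n_out: int
    bases_in: int
    bases_out: int
    density_in: float
    density_out: float
    density_genome: float
    fold: float
    chi2: float
    p_value: float


def _merged_region_bases(regions: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    for t in trees.values():
        t.merge_overlaps()
    return trees


def region_density_enrichment(
    variants: Iterable[VariantCall],
    regions: Sequence[GenomicInterval],
    layout: GenomeLayout,
    per: int = 10_000,
    yates: bool = False,
) -> EnrichmentResult:
    """Variant density inside vs outside a region set, per ``per`` bases.

    The fold ratio is density_in / density_out; the chi-square contrasts the
    observed in/out variant split against the split expected from the base
    fractions alone (regions covering the whole genome or none of it are
    rejected).  Serves the CNV duplication/deletion, CpG-island,
    X-vs-autosome and imprinted-gene density contrasts alike.
    """
    for iv in regions:
        if iv.chrom not in layout:
            raise ValueError(f"region chromosome {iv.chrom!r} absent from layout")
    trees = _merged_region_bases(regions)
    bases_in = sum(
        int(iv.end - iv.begin) for t in trees.values() for iv in t
    )
    if bases_in == 0:
        raise ValueError("regions cover zero bases")
    bases_total = layout.total_length
    bases_out = bases_total - bases_in
    if bases_out <= 0:
        raise ValueError("regions cover the whole genome; no outside to compare")
    n_in = n_out = 0
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is not None and tree.overlap(v.pos, v.pos + 1):
            n_in += 1
        else:
            n_out += 1
    n_total = n_in + n_out
    density_in = n_in / (bases_in / per)
    density_out = n_out / (bases_out / per)
    density_genome = n_total / (bases_total / per)
    fold = density_in / density_out if density_out > 0 else math.inf
    expected_in = n_total * bases_in / bases_total
    expected_out = n_total - expected_in
    table = np.array([[n_in, n_out], [expected_in, expected_out]])
    if n_total == 0 or expected_in == 0:
        chi2, p = float("nan"), float("nan")
    else:
        # goodness-of-fit of the in/out split against base-fraction expectation
        chi2, p = stats.chisquare([n_in, n_out], [expected_in, expected_out])
        if yates:
            corr = [abs(n_in - expected_in) - 0.5, abs(n_out - expected_out) - 0.5]
            chi2 = sum(c * c / e for c, e in zip(corr, [expected_in, expected_out]))
            p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentResult(
        n_in=n_in,
        n_out=n_out,
        bases_in=bases_in,
        bases_out=bases_out,
        density_in=density_in,
        density_out=density_out,
        density_genome=density_genome,
        fold=fold,
        chi2=float(chi2),
        p_value=float(p),
    )


def windowed_density_correlation(
    snps: Iterable[VariantCall],
    indels: Iterable[VariantCall],
    layout: GenomeLayout,
    window: int = 20_000,
) -> dict[str, float]:
    """Pearson correlation between per-window SNP and indel counts.

    Windows are fixed and non-overlapping.  Returns r, R^2 and the p-value;
    zero variance in either count series leaves the result flagged NaN.
    """
    windows = list(layout.windows(window))
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    index = {
        (w.chrom, w.start // window): i for i, w in enumerate(windows)
    }
    snp_counts = np.zeros(len(windows))
    indel_counts = np.zeros(len(windows))
    for v in snps:
        i = index.get((v.chrom, v.pos // window))
        if i is not None:
            snp_counts[i] += 1
    for v in indels:
        i = index.get((v.chrom, v.pos // window))
        if i is not None:
            indel_counts[i] += 1
    if snp_counts.std() == 0 or indel_counts.std() == 0:
        warnings.warn("zero variance in one count series; correlation undefined")
        return {"r": float("nan"), "r_squared": float("nan"), "p_value": float("nan"),
                "n_windows": float(len(windows))}
    r, p = stats.pearsonr(snp_counts, indel_counts)
    return {
        "r": float(r),
        "r_squared": float(r * r),
        "p_value": float(p),
        "n_windows": float(len(windows)),
    }
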