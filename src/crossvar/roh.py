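"""Runs of homozygosity, IBD-based false-positive rates, and the
minimum-allele-percentage diagnostics.

A run of homozygosity (ROH) is detected with a sliding window (default
1 Mb window, 200 kb step): a window qualifies when it holds enough SNPs
and its heterozygote count is at most ``max_het_hom_ratio`` times its
homozygote count; overlapping qualifying windows merge into maximal
intervals.  Inside a trusted identical-by-descent (IBD) region every true
genotype is homozygous, so the observed heterozygote fraction there
estimates a caller's false-positive het rate directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .variant_model import GenomeLayout, GenomicInterval, VariantCall, Zygosity

__all__ = [
    "RohParams",
    "FprReport",
    "detect_roh",
    "roh_genome_fraction",
    "fpr_in_ibd",
    "map_value",
    "filter_het_calls",
]


@dataclass(frozen=True)
class RohParams:
    """Sliding-window ROH parameters.

    window/step in bp; a window qualifies iff it contains at least
    ``min_snps_per_window`` SNPs and ``n_het <= max_het_hom_ratio * n_hom``.
    The multiplicative form keeps all-homozygous windows (hom may be the
    whole window) well defined; sparse windows never qualify.
    """

    window: int = 1_000_000
    step: int = 200_000
    max_het_hom_ratio: float = 0.1
    min_snps_per_window: int = 20

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must be <= window")
        if not (0 < self.max_het_hom_ratio < 1):
            raise ValueError("max_het_hom_ratio must be in (0,1)")
        if self.min_snps_per_window < 1:
            raise ValueError("min_snps_per_window must be >= 1")


def _window_starts(chrom_length: int, params: RohParams) -> list[int]:
    # chromosome-end partial windows are evaluated if at least half a window
    # remains, avoiding both edge blindness and tiny unstable windows
    starts = []
    start = 0
    while start < chrom_length:
        if min(start + params.window, chrom_length) - start >= params.window / 2:
            starts.append(start)
        start += params.step
    return starts


def detect_roh(
    calls: Iterable[VariantCall],
    layout: GenomeLayout,
    params: RohParams | None = None,
) -> list[GenomicInterval]:
    """Detect runs of homozygosity from one individual's genotyped SNPs.

    Returns merged, sorted, non-overlapping intervals labelled ``ROH``;
    each spans from the first to the last qualifying window, so reported
    lengths are at least one window (up to end-of-chromosome clipping).
    """
    import bisect

    params = params or RohParams()
    by_chrom: dict[str, list[tuple[int, bool]]] = {}
    for call in calls:
        if call.chrom not in layout:
            raise ValueError(f"chromosome {call.chrom!r} absent from layout")
        by_chrom.setdefault(call.chrom, []).append(
            (call.pos, call.zygosity is Zygosity.HET)
        )
    out: list[GenomicInterval] = []
    for chrom in layout.chroms:
        sites = sorted(by_chrom.get(chrom, []))
        if not sites:
            continue
        positions = [p for p, _ in sites]
        het_prefix = [0]
        for _, is_het in sites:
            het_prefix.append(het_prefix[-1] + int(is_het))
        chrom_len = layout.lengths[chrom]
        qualifying: list[tuple[int, int]] = []
        for start in _window_starts(chrom_len, params):
            end = min(start + params.window, chrom_len)
            lo = bisect.bisect_left(positions, start)
            hi = bisect.bisect_left(positions, end)
            n = hi - lo
            if n < params.min_snps_per_window:
                continue
            n_het = het_prefix[hi] - het_prefix[lo]
            n_hom = n - n_het
            if n_het <= params.max_het_hom_ratio * n_hom:
                qualifying.append((start, end))
        # merge overlapping/adjacent qualifying windows into maximal runs
        for start, end in qualifying:
            if out and out[-1].chrom == chrom and start <= out[-1].end:
                out[-1] = GenomicInterval(chrom, out[-1].start, max(out[-1].end, end), "ROH")
            else:
                out.append(GenomicInterval(chrom, start, end, "ROH"))
    return out


def roh_genome_fraction(
    roh: Sequence[GenomicInterval], layout: GenomeLayout
) -> float:
    """Fraction of the genome inside ROH (intervals assumed non-overlapping)."""
    return sum(iv.length for iv in roh) / layout.total_length


@dataclass
class FprReport:
    """Heterozygous (and optionally homozygous) false-positive rate of one
    caller inside a trusted IBD region."""

    caller: str
    region: GenomicInterval
    n_het: int
    n_hom: int
    fpr_het: float | None
    n_hom_alt_in_ref_identical: int | None = None
    n_calls_in_ref_identical: int | None = None
    fpr_hom: float | None = None

    @property
    def undefined(self) -> bool:
        return self.fpr_het is None


def fpr_in_ibd(
    calls_by_caller: Mapping[str, Iterable[VariantCall]],
    ibd: GenomicInterval,
    ref_identical: Sequence[GenomicInterval] | None = None,
    per_mb: bool = False,
) -> dict[str, FprReport]:
    """Estimate each caller's false-positive het rate inside a trusted IBD
    region.

    ``fpr_het`` = het calls / all SNP calls in the region (or het calls per
    Mb when ``per_mb``).  If sub-intervals known to be identical to the
    reference are supplied, ``fpr_hom`` = hom-alt calls / all calls there.
    """
    reports: dict[str, FprReport] = {}
    for caller, calls in calls_by_caller.items():
        n_het = n_hom = 0
        n_ref_hom_alt = n_ref_total = 0
        for c in calls:
            if not c.is_snp:
                continue
            if ibd.contains(c.chrom, c.pos):
                if c.zygosity is Zygosity.HET:
                    n_het += 1
                else:
                    n_hom += 1
            if ref_identical and any(r.contains(c.chrom, c.pos) for r in ref_identical):
                n_ref_total += 1
                if c.zygosity is Zygosity.HOM_ALT:
                    n_ref_hom_alt += 1
        total = n_het + n_hom
        if per_mb:
            fpr = n_het / (ibd.length / 1e6)
        elif total > 0:
            fpr = n_het / total
        else:
            fpr = None
            warnings.warn(f"{caller}: no calls inside IBD region; FPR undefined")
        fpr_hom = (
            n_ref_hom_alt / n_ref_total
            if ref_identical is not None and n_ref_total > 0
            else None
        )
        reports[caller] = FprReport(
            caller=caller,
            region=ibd,
            n_het=n_het,
            n_hom=n_hom,
            fpr_het=fpr,
            n_hom_alt_in_ref_identical=n_ref_hom_alt if ref_identical else None,
            n_calls_in_ref_identical=n_ref_total if ref_identical else None,
            fpr_hom=fpr_hom,
        )
    return reports


def map_value(call: VariantCall) -> float:
    """Minimum allele percentage of a heterozygous call: the fraction of
    reads supporting the less-covered allele.  Low values flag hets created
    by misaligned reads rather than real polymorphism."""
    if call.zygosity is not Zygosity.HET:
        raise ValueError("MAP is defined for heterozygous calls only")
    if call.allele_depths is None:
        raise ValueError("call lacks allele depths")
    total = sum(call.allele_depths)
    if total == 0:
        raise ValueError("zero total allele depth")
    return min(call.allele_depths) / total


def filter_het_calls(
    calls: Iterable[VariantCall],
    min_coverage: int = 3,
    min_variant_frequency: float = 0.35,
) -> list[VariantCall]:
    """Post-hoc het filter: keep calls with coverage > ``min_coverage - 1``
    and non-reference read fraction > ``min_variant_frequency``.

    Removes most misalignment-driven false het calls (which show few
    variant-supporting reads) at some cost in sensitivity.  Calls missing
    depth annotations are dropped with a warning.
    """
    kept: list[VariantCall] = []
    dropped_missing = 0
    for c in calls:
        if c.depth is None or c.allele_depths is None:
            dropped_missing += 1
            continue
        if c.depth < min_coverage:
            continue
        total = sum(c.allele_depths)
        if total == 0:
            continue
        variant_fraction = c.allele_depths[1] / total
        if variant_fraction > min_variant_frequency:
            kept.append(c)
    if dropped_missing:
        warnings.warn(f"dropped {dropped_missing} het calls lacking depth annotations")
    return kept
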