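"""Multi-caller SNP set bookkeeping and chip-vs-sequencing concordance.

Venn partitions identify a SNP site by ``(chrom, pos)``; zygosity-stratified
partitions place a site in the subset of callers that agree on the zygosity
under consideration.  Concordance between an array genotype and a
sequencing call falls into exactly one of six categories; summary fractions
are computed over *detected* sites (sites the sequencing pipeline missed
enter the detection rate, not the percentage denominator), which is how the
published per-pipeline consistency percentages are defined.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .variant_model import (
    ChipGenotype,
    GenomeLayout,
    VariantCall,
    Zygosity,
)

__all__ = [
    "ConcordanceCategory",
    "VennPartition",
    "ConcordanceSummary",
    "venn_partition",
    "intersection_fraction",
    "classify_site",
    "concordance_summary",
    "chip_error_rate",
    "chip_filter_bookkeeping",
    "mutation_rate_estimate",
    "exclude_sex_het_calls",
    "exclude_sex_het_genotypes",
]


class ConcordanceCategory(str, enum.Enum):
    CONSISTENT = "consistent"
    HET_TO_HOM = "het_to_hom"
    HOM_TO_HET = "hom_to_het"
    AS_INDEL = "as_indel"
    INCONSISTENT = "inconsistent"
    NOT_DETECTED = "not_detected"


@dataclass
class VennPartition:
    """Counts of SNP sites per non-empty caller subset.

    ``by_subset`` covers site presence regardless of zygosity; ``het`` and
    ``hom`` stratify by each caller's zygosity at the site.
    """

    callers: tuple[str, ...]
    by_subset: dict[frozenset[str], int]
    het: dict[frozenset[str], int] = field(default_factory=dict)
    hom: dict[frozenset[str], int] = field(default_factory=dict)

    @property
    def union_size(self) -> int:
        return sum(self.by_subset.values())

    @property
    def core_size(self) -> int:
        """Sites called by every caller."""
        return self.by_subset.get(frozenset(self.callers), 0)

    def count(self, *callers: str) -> int:
        return self.by_subset.get(frozenset(callers), 0)


def venn_partition(callsets: Mapping[str, Iterable[VariantCall]]) -> VennPartition:
    """Partition the union of SNP sites by the exact subset of callers
    reporting each site."""
    if len(callsets) < 2:
        raise ValueError("need at least two callsets")
    site_maps: dict[str, dict[tuple[str, int], VariantCall]] = {}
    for caller, calls in callsets.items():
        m: dict[tuple[str, int], VariantCall] = {}
        for call in calls:
            if not call.is_snp:
                raise ValueError(f"non-SNP call in callset {caller!r}: {call}")
            if call.site in m:
                raise ValueError(f"duplicate site {call.site} in callset {caller!r}")
            m[call.site] = call
        site_maps[caller] = m
    callers = tuple(callsets)
    by_subset: Counter[frozenset[str]] = Counter()
    het: Counter[frozenset[str]] = Counter()
    hom: Counter[frozenset[str]] = Counter()
    union = set().union(*(m.keys() for m in site_maps.values()))
    for site in union:
        members = frozenset(c for c in callers if site in site_maps[c])
        by_subset[members] += 1
        het_members = frozenset(
            c for c in members if site_maps[c][site].zygosity is Zygosity.HET
        )
        if het_members:
            het[het_members] += 1
        hom_members = frozenset(
            c for c in members if site_maps[c][site].zygosity is not Zygosity.HET
        )
        if hom_members:
            hom[hom_members] += 1
    return VennPartition(callers, dict(by_subset), dict(het), dict(hom))


def intersection_fraction(n_intersection: int, n_union: int) -> float:
    """Fraction of the union of called sites shared by all callers."""
    if n_union <= 0:
        raise ValueError("union size must be positive")
    return n_intersection / n_union


def classify_site(
    chip: ChipGenotype, seq: VariantCall | None
) -> ConcordanceCategory:
    """Assign one concordance category to a chip marker given the sequencing
    call (or absence of one) at the same site."""
    if chip.call is None:
        raise ValueError("no-call chip genotypes must be excluded upstream")
    if seq is None:
        return ConcordanceCategory.NOT_DETECTED
    if seq.site != (chip.chrom, chip.pos):
        raise ValueError("chip and sequencing call refer to different sites")
    if not seq.is_snp:
        return ConcordanceCategory.AS_INDEL
    seq_alleles = seq.alleles
    if chip.call == seq_alleles:
        return ConcordanceCategory.CONSISTENT
    chip_het, seq_het = chip.is_het, seq.zygosity is Zygosity.HET
    if chip_het == seq_het:
        return ConcordanceCategory.INCONSISTENT
    # zygosity disagrees: only a genuine het/hom flip on a shared allele
    # counts as under/over-calling; allele-disjoint cases are inconsistent
    if not (chip.call & seq_alleles):
        return ConcordanceCategory.INCONSISTENT
    return (
        ConcordanceCategory.HET_TO_HOM if chip_het else ConcordanceCategory.HOM_TO_HET
    )


@dataclass
class ConcordanceSummary:
    counts: dict[ConcordanceCategory, int]
    fractions: dict[ConcordanceCategory, float]
    n_total: int
    n_detected: int
    detection_rate: float
    undefined: bool = False


def concordance_summary(
    categories: Iterable[ConcordanceCategory]
    | Mapping[ConcordanceCategory, int],
) -> ConcordanceSummary:
    """Tabulate categories; fractions are over detected sites only and the
    detection rate (detected / total chip SNPs) is reported separately."""
    if isinstance(categories, Mapping):
        counts = Counter({ConcordanceCategory(k): int(v) for k, v in categories.items()})
    else:
        counts = Counter(categories)
    n_total = sum(counts.values())
    if n_total == 0:
        raise ValueError("no categorized sites")
    n_detected = n_total - counts.get(ConcordanceCategory.NOT_DETECTED, 0)
    undefined = n_detected == 0
    fractions = {
        cat: (counts.get(cat, 0) / n_detected if not undefined else float("nan"))
        for cat in ConcordanceCategory
        if cat is not ConcordanceCategory.NOT_DETECTED
    }
    return ConcordanceSummary(
        counts=dict(counts),
        fractions=fractions,
        n_total=n_total,
        n_detected=n_detected,
        detection_rate=n_detected / n_total,
        undefined=undefined,
    )


def chip_error_rate(
    pairs: Iterable[tuple[ChipGenotype, ChipGenotype]],
) -> tuple[float, int, int]:
    """Discordance rate between two chips over markers genotyped on both.

    Any difference in the unordered allele pair counts as discordant
    (het/hom disagreements included).  Returns (rate, discordant, shared).
    """
    shared = discordant = 0
    for a, b in pairs:
        if a.call is None or b.call is None:
            continue
        shared += 1
        if a.call != b.call:
            discordant += 1
    if shared == 0:
        raise ValueError("no markers genotyped on both chips")
    return discordant / shared, discordant, shared


@dataclass
class ChipFilterReport:
    n_input: int
    n_no_call: int
    n_sex_het_removed: int
    n_polymorphic: int
    n_het: int
    n_hom: int


def chip_filter_bookkeeping(
    genotypes: Iterable[ChipGenotype],
    layout: GenomeLayout,
    male: bool = True,
) -> ChipFilterReport:
    """Count effective polymorphic sites after dropping no-calls and, for a
    male sample, heterozygous calls on the sex chromosomes."""
    n_input = n_no_call = n_sex_het = n_het = n_hom = 0
    for g in genotypes:
        n_input += 1
        if g.call is None:
            n_no_call += 1
            continue
        if male and g.is_het and g.chrom in layout.sex_chroms:
            n_sex_het += 1
            continue
        if g.is_het:
            n_het += 1
        else:
            n_hom += 1
    return ChipFilterReport(
        n_input=n_input,
        n_no_call=n_no_call,
        n_sex_het_removed=n_sex_het,
        n_polymorphic=n_het + n_hom,
        n_het=n_het,
        n_hom=n_hom,
    )


def mutation_rate_estimate(
    n_new_het: int,
    het_detection_rate: float,
    ploidy: int = 2,
    generations: int = 1,
    region_length: int = 0,
) -> float:
    """Per-base per-generation mutation rate from new heterozygotes observed
    in an identical-by-descent region.

    A region IBD since ``generations`` meioses ago accumulates new mutations
    on ``ploidy`` copies per generation; dividing the observed count by the
    het detection rate corrects for incomplete ascertainment.
    """
    if n_new_het < 0:
        raise ValueError("n_new_het must be >= 0")
    if het_detection_rate <= 0 or region_length <= 0 or ploidy <= 0 or generations <= 0:
        raise ValueError("detection rate, ploidy, generations and length must be > 0")
    return n_new_het / (het_detection_rate * ploidy * generations * region_length)


def exclude_sex_het_calls(
    calls: Iterable[VariantCall], layout: GenomeLayout, male: bool = True
) -> list[VariantCall]:
    """Drop het calls on sex chromosomes for a male (haploid-X) sample."""
    if not male:
        return list(calls)
    return [
        c
        for c in calls
        if not (c.zygosity is Zygosity.HET and c.chrom in layout.sex_chroms)
    ]


def exclude_sex_het_genotypes(
    genotypes: Iterable[ChipGenotype], layout: GenomeLayout, male: bool = True
) -> list[ChipGenotype]:
    if not male:
        return list(genotypes)
    return [
        g for g in genotypes if not (g.is_het and g.chrom in layout.sex_chroms)
    ]
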