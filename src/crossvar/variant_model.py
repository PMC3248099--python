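"""Core domain types and I/O for variant call sets, chip genotypes and intervals.

All internal coordinates are 0-based, half-open.  VCF (1-based) and the
1-based-inclusive TSV dialects convert at the I/O boundary and nowhere else.
A SNP site is identified by ``(chrom, pos)``; allele agreement is judged
separately by the concordance operations.  Indels are left-normalized before
any set arithmetic so that call sets from representationally different
callers can be intersected.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "Zygosity",
    "VariantType",
    "VariantCall",
    "ChipGenotype",
    "GenomicInterval",
    "GenomeLayout",
    "VcfParseError",
    "normalize_variant",
    "read_vcf",
    "write_vcf",
    "read_intervals",
    "write_bed",
    "read_layout",
    "write_layout",
    "read_chip_table",
    "write_chip_table",
]


class Zygosity(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"


class VariantType(str, enum.Enum):
    SNP = "snp"
    INSERTION = "insertion"
    DELETION = "deletion"


def _infer_vtype(ref: str, alt: str) -> VariantType:
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNP
    if len(alt) > len(ref):
        return VariantType.INSERTION
    return VariantType.DELETION


@dataclass(frozen=True)
class VariantCall:
    """One caller's call at one site.

    ``pos`` is 0-based.  ``allele_depths`` is (ref reads, alt reads) when
    available.  ``info`` carries optional caller annotations used by the
    indel post-filter (per-strand support, base quality, upstream-filter
    metadata).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: Zygosity
    depth: int | None = None
    allele_depths: tuple[int, int] | None = None
    caller: str | None = None
    info: Mapping[str, object] = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.allele_depths is not None and any(d < 0 for d in self.allele_depths):
            raise ValueError("allele_depths entries must be >= 0")
        if not self.ref or not self.alt:
            raise ValueError("empty allele")

    @property
    def vtype(self) -> VariantType:
        return _infer_vtype(self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return self.vtype is VariantType.SNP

    @property
    def indel_size(self) -> int:
        return abs(len(self.alt) - len(self.ref))

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def alleles(self) -> frozenset[str]:
        """Genotype allele set implied by zygosity (for SNPs)."""
        if self.zygosity is Zygosity.HET:
            return frozenset((self.ref, self.alt))
        if self.zygosity is Zygosity.HOM_ALT:
            return frozenset((self.alt,))
        return frozenset((self.ref,))


NO_CALL = None


@dataclass(frozen=True)
class ChipGenotype:
    """Array genotype at one marker; ``call`` is an unordered allele pair or
    ``None`` for a no-call."""

    marker_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    call: frozenset[str] | None
    chip: str = "HD"

    def __post_init__(self) -> None:
        if self.call is not None:
            allowed = {self.allele_a, self.allele_b}
            if not set(self.call) <= allowed:
                raise ValueError(
                    f"call {set(self.call)} outside marker alleles {allowed}"
                )

    @property
    def is_het(self) -> bool:
        return self.call is not None and len(self.call) == 2

    @property
    def is_hom(self) -> bool:
        return self.call is not None and len(self.call) == 1


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open region with a class label and optional numeric payload."""

    chrom: str
    start: int
    end: int
    label: str = ""
    value: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


class GenomeLayout:
    """Ordered chromosome names -> lengths, plus the sex-chromosome set.

    The sex-chromosome flag drives the male het exclusion used before the
    concordance summaries (a het on a haploid X is an error or
    pseudoautosomal).
    """

    def __init__(
        self,
        lengths: Mapping[str, int],
        sex_chroms: Iterable[str] = (),
    ) -> None:
        if len(set(lengths)) != len(lengths):
            raise ValueError("duplicate chromosome names")
        for name, ln in lengths.items():
            if ln <= 0:
                raise ValueError(f"non-positive length for {name}")
        self.lengths: dict[str, int] = dict(lengths)
        self.sex_chroms: frozenset[str] = frozenset(sex_chroms)
        unknown = self.sex_chroms - set(self.lengths)
        if unknown:
            raise ValueError(f"sex chromosomes not in layout: {sorted(unknown)}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.lengths if c not in self.sex_chroms]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeLayout):
            return NotImplemented
        return self.lengths == other.lengths and self.sex_chroms == other.sex_chroms

    def windows(
        self, window: int, step: int | None = None, chroms: Sequence[str] | None = None
    ) -> Iterable[GenomicInterval]:
        """Sliding windows clipped at chromosome ends."""
        step = step or window
        for chrom in chroms if chroms is not None else self.chroms:
            ln = self.lengths[chrom]
            start = 0
            while start < ln:
                yield GenomicInterval(chrom, start, min(start + window, ln))
                start += step


# ---------------------------------------------------------------------------
# Normalization


def normalize_variant(
    pos: int,
    ref: str,
    alt: str,
    sequence: str | None = None,
    seq_start: int = 0,
) -> tuple[int, str, str]:
    """Canonicalize a variant: trim shared bases, then left-shift indels.

    ``sequence`` is reference context (0-based, starting at ``seq_start``);
    without it only prefix/suffix trimming is applied.  Indels end up in
    anchored VCF form (shared leading base) shifted as far left as the
    flanking sequence allows — the convention required before intersecting
    call sets from callers that report the same event at different offsets.
    """
    ref, alt = ref.upper(), alt.upper()
    sequence = sequence.upper() if sequence is not None else None
    # trim common suffix, keeping at least one base per allele
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix down to the single anchor base of an indel
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if len(ref) == len(alt):
        return pos, ref, alt
    # reduce to the unpadded varied unit (pure insertion or pure deletion)
    if ref[0] == alt[0] and (len(ref) == 1 or len(alt) == 1):
        unit = ref[1:] or alt[1:]
        is_deletion = len(ref) > len(alt)
        cpos = pos + 1
    else:
        return pos, ref, alt  # complex substitution: no shift defined
    if sequence is not None:
        # rotate the varied unit leftward while the preceding reference
        # base matches its last base
        while cpos > seq_start and sequence[cpos - 1 - seq_start] == unit[-1]:
            unit = sequence[cpos - 1 - seq_start] + unit[:-1]
            cpos -= 1
    if cpos > seq_start and sequence is not None:
        anchor = sequence[cpos - 1 - seq_start]
    else:
        anchor = ref[0]  # no context to the left: keep the original anchor
        cpos = pos + 1
    if is_deletion:
        return cpos - 1, anchor + unit, anchor
    return cpos - 1, anchor, anchor + unit


# ---------------------------------------------------------------------------
# VCF I/O


class VcfParseError(ValueError):
    pass


_GT_ZYGOSITY = {
    (0, 0): Zygosity.HOM_REF,
    (0, 1): Zygosity.HET,
    (1, 0): Zygosity.HET,
    (1, 1): Zygosity.HOM_ALT,
    (1,): Zygosity.HOM_ALT,  # haploid call
    (0,): Zygosity.HOM_REF,
}


def read_vcf(
    path: str | Path,
    caller: str | None = None,
    reference: Mapping[str, str] | None = None,
) -> list[VariantCall]:
    """Read a VCF (subset: GT/DP/AD) into :class:`VariantCall` records.

    Positions convert to 0-based; multi-allelic records are split into one
    record per alternate allele (AD re-paired as ref vs that allele); indels
    are left-normalized when ``reference`` sequences are supplied.  Records
    with missing or unrecognized genotypes are skipped and counted in a
    warning.
    """
    calls: list[VariantCall] = []
    skipped = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        sample = next(iter(vf.header.samples), None)
        for rec in vf:
            if rec.alts is None:
                skipped += 1
                continue
            if sample is None:
                raise VcfParseError(f"{path}: no sample column")
            fmt = rec.samples[sample]
            gt = fmt.get("GT")
            depth = fmt.get("DP")
            ad = fmt.get("AD")
            for alt_index, alt in enumerate(rec.alts, start=1):
                if gt is None or any(a is None for a in gt):
                    skipped += 1
                    continue
                collapsed = tuple(0 if a == 0 else (1 if a == alt_index else None) for a in gt)
                if None in collapsed and len(rec.alts) > 1:
                    # genotype involves a different alt of this record
                    if all(a != alt_index for a in gt):
                        continue
                    collapsed = tuple(1 if a == alt_index else 0 for a in gt)
                zyg = _GT_ZYGOSITY.get(collapsed)  # type: ignore[arg-type]
                if zyg is None:
                    skipped += 1
                    continue
                if zyg is Zygosity.HOM_REF:
                    # not a variant call for this allele
                    continue
                allele_depths = None
                if ad is not None and ad[0] is not None and len(ad) > alt_index:
                    allele_depths = (int(ad[0]), int(ad[alt_index]))
                pos, ref_a, alt_a = rec.pos - 1, rec.ref, alt
                if len(ref_a) != len(alt_a) or len(ref_a) > 1:
                    seq = reference.get(rec.chrom) if reference else None
                    pos, ref_a, alt_a = normalize_variant(pos, ref_a, alt_a, seq)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=pos,
                        ref=ref_a,
                        alt=alt_a,
                        zygosity=zyg,
                        depth=int(depth) if depth is not None else None,
                        allele_depths=allele_depths,
                        caller=caller,
                    )
                )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} records with unusable genotypes")
    return calls


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    layout: GenomeLayout,
    sample: str = "SAMPLE",
) -> None:
    """Write calls as minimal VCF 4.2 with GT:DP:AD, sorted by position."""
    header = pysam.VariantHeader()
    for chrom, length in layout.lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    header.add_sample(sample)
    ordered = sorted(calls, key=lambda c: (layout.chroms.index(c.chrom), c.pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in ordered:
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                alleles=(call.ref, call.alt),
            )
            gt = (0, 1) if call.zygosity is Zygosity.HET else (1, 1)
            rec.samples[sample]["GT"] = gt
            if call.depth is not None:
                rec.samples[sample]["DP"] = call.depth
            if call.allele_depths is not None:
                rec.samples[sample]["AD"] = list(call.allele_depths)
            out.write(rec)


# ---------------------------------------------------------------------------
# Interval / table I/O


def read_intervals(
    path: str | Path,
    fmt: str = "bed",
    label: str = "",
) -> list[GenomicInterval]:
    """Read BED (0-based half-open) or ``tsv1`` (1-based inclusive) intervals.

    Records whose converted span is empty (start >= end) are rejected.
    """
    if fmt not in ("bed", "tsv1"):
        raise ValueError(f"unknown interval format {fmt!r}")
    out: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >=3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if fmt == "tsv1":
            start -= 1  # 1-based inclusive -> 0-based half-open
        name = fields[3] if len(fields) > 3 else label
        value = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        if start >= end:
            raise ValueError(f"{path}:{lineno}: empty interval after conversion")
        out.append(GenomicInterval(chrom, start, end, label=name, value=value))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.value is None else f"{iv.value:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{score}\n")


def read_layout(path: str | Path) -> GenomeLayout:
    """Layout TSV: ``chrom<TAB>length[<TAB>sex]`` (third column 'sex' flags
    sex chromosomes)."""
    lengths: dict[str, int] = {}
    sex: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        lengths[fields[0]] = int(fields[1])
        if len(fields) > 2 and fields[2].lower() in ("sex", "x", "y", "1", "true"):
            sex.add(fields[0])
    return GenomeLayout(lengths, sex)


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, ln in layout.lengths.items():
            flag = "\tsex" if chrom in layout.sex_chroms else ""
            fh.write(f"{chrom}\t{ln}{flag}\n")


_CHIP_COLUMNS = ["marker_id", "chrom", "pos", "allele_a", "allele_b", "call", "chip"]


def read_chip_table(path: str | Path) -> list[ChipGenotype]:
    """Chip genotype TSV with 1-based positions and call column ``A/G`` or
    ``--`` for no-call."""
    out: list[ChipGenotype] = []
    lines = Path(path).read_text().splitlines()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("marker_id"):
            continue
        mid, chrom, pos, a, b, call, chip = line.split("\t")
        parsed = None if call in ("--", ".", "NC") else frozenset(call.split("/"))
        out.append(
            ChipGenotype(
                marker_id=mid,
                chrom=chrom,
                pos=int(pos) - 1,
                allele_a=a,
                allele_b=b,
                call=parsed,
                chip=chip,
            )
        )
    return out


def write_chip_table(genotypes: Iterable[ChipGenotype], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_CHIP_COLUMNS) + "\n")
        for g in genotypes:
            call = "--" if g.call is None else "/".join(sorted(g.call))
            fh.write(
                f"{g.marker_id}\t{g.chrom}\t{g.pos + 1}\t{g.allele_a}\t{g.allele_b}"
                f"\t{call}\t{g.chip}\n"
            )
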