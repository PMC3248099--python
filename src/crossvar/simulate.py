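"""Synthetic diploid genome with planted truth for end-to-end testing.

The generator emulates the data structure of a single resequenced male
bovine genome analysed on several platforms at once: multiple SNP/indel
callers with caller-specific error processes, two genotyping arrays with a
small per-marker error rate, and window read counts for a test and a
reference animal.  Planted truth (IBD regions, CNVs with known copy
number, gene models, per-caller error records) makes every downstream
estimator checkable against known rates.

Error processes mirror the structure seen in real multi-pipeline data:
false heterozygotes arise from misalignment at a base rate that is
multiplied inside copy-number duplications, and carry a low minimum
allele percentage; true heterozygotes are under-called as homozygous when
read sampling covers only one allele at low depth; per-site depth is
negative-binomial (Poisson overdispersed); the X chromosome is haploid in
the male sample, so true X genotypes are homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotation import GeneModel
from .variant_model import (
    ChipGenotype,
    GenomeLayout,
    GenomicInterval,
    VariantCall,
    Zygosity,
    write_bed,
    write_chip_table,
    write_layout,
    write_vcf,
)

__all__ = ["CallerProfile", "SimConfig", "TruthSet", "SimResult", "simulate",
           "end_to_end_fixture", "PROFILES"]

_BASES = np.array(list("ACGT"))


def _default_layout() -> GenomeLayout:
    return GenomeLayout(
        {"chr1": 4_000_000, "chr2": 3_500_000, "chr3": 3_000_000, "chrX": 1_500_000},
        sex_chroms={"chrX"},
    )


@dataclass(frozen=True)
class CallerProfile:
    """Error process of one variant-calling pipeline.

    ``base_fp_het_rate`` is false-het sites per bp outside duplications;
    inside a duplication the rate is multiplied by ``dup_fp_multiplier``
    (paralogous reads pile onto one locus).  ``fp_map_beta`` parameterizes
    the Beta distribution of the variant-read fraction of false hets —
    misalignment FPs sit far below the 0.5 of a real heterozygote.  With
    ``het_undercall`` on, a true het whose sampled reads cover only one
    allele is reported homozygous (or missed entirely at the reference
    allele).
    """

    base_fp_het_rate: float = 0.0
    dup_fp_multiplier: float = 1.0
    het_undercall: bool = False
    fp_map_beta: tuple[float, float] = (1.0, 6.0)
    drop_rate: float = 0.0


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset; ``seed`` is mandatory."""

    seed: int
    layout: GenomeLayout = field(default_factory=_default_layout)
    snp_density: float = 1e-3          # true SNP sites per bp
    indel_density: float = 7e-5        # ~7 indels per 100 kb
    het_fraction: float = 0.6          # het share of true autosomal variants
    ibd_intervals: tuple[GenomicInterval, ...] = (
        GenomicInterval("chr1", 1_000_000, 2_600_000, "IBD"),
    )
    cnv_spec: tuple[tuple[GenomicInterval, int], ...] = (
        (GenomicInterval("chr2", 500_000, 700_000, "CNV"), 4),
        (GenomicInterval("chr3", 1_000_000, 1_150_000, "CNV"), 3),
        (GenomicInterval("chr2", 2_000_000, 2_200_000, "CNV"), 1),
    )
    n_genes: int = 300
    caller_profiles: Mapping[str, CallerProfile] = field(
        default_factory=lambda: {
            "bwa": CallerProfile(2e-6, 2.0, True),
            "smalt": CallerProfile(2e-6, 2.0, True),
            "clc": CallerProfile(1.6e-5, 5.0, True),
            "giga": CallerProfile(1.6e-5, 5.0, True),
        }
    )
    chip_error_rate: float = 5.52e-4
    chip_marker_spacing: int = 2_000   # ~1 polymorphic marker per 2 kb
    chip_lowdensity_fraction: float = 0.5  # share of markers also on the small chip
    coverage_mean: float = 15.0
    depth_overdispersion: float = 5.0   # per-site depth NB shape k (var = m + m^2/k)
    count_overdispersion: float = 100.0  # per-window Gamma-Poisson shape k
    rd_window: int = 10_000
    reads_per_window_mean: float = 500.0

    def __post_init__(self) -> None:
        if self.snp_density <= 0 or self.indel_density <= 0:
            raise ValueError("densities must be > 0")
        for (iv, cn) in self.cnv_spec:
            if cn not in (0, 1, 3, 4):
                raise ValueError(f"copy number {cn} not in {{0,1,3,4}}")
        ivs = sorted((iv for iv, _ in self.cnv_spec), key=lambda v: (v.chrom, v.start))
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError("overlapping CNVs in cnv_spec")


@dataclass
class TruthSet:
    variants: list[VariantCall]
    indels: list[VariantCall]
    ibd: tuple[GenomicInterval, ...]
    cnvs: tuple[tuple[GenomicInterval, int], ...]
    genes: list[GeneModel]
    planted_fp: dict[str, list[VariantCall]]


@dataclass
class SimResult:
    config: SimConfig
    truth: TruthSet
    callsets: dict[str, list[VariantCall]]
    chip_hd: list[ChipGenotype]
    chip_ld: list[ChipGenotype]
    window_counts: pd.DataFrame


def _draw_depth(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size)


def _copy_number_at(config: SimConfig, chrom: str, pos: int) -> int:
    for iv, cn in config.cnv_spec:
        if iv.contains(chrom, pos):
            return cn
    return 2


def _in_any(intervals: Sequence[GenomicInterval], chrom: str, pos: int) -> bool:
    return any(iv.contains(chrom, pos) for iv in intervals)


def _random_sites(rng: np.random.Generator, length: int, density: float) -> np.ndarray:
    n = rng.poisson(length * density)
    n = min(n, length)
    return np.sort(rng.choice(length, size=n, replace=False))


def _random_snp_alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _make_truth(config: SimConfig, rng: np.random.Generator) -> TruthSet:
    male_x = config.layout.sex_chroms
    variants: list[VariantCall] = []
    indels: list[VariantCall] = []
    for chrom, length in config.layout.lengths.items():
        positions = _random_sites(rng, length, config.snp_density)
        refs, alts = _random_snp_alleles(rng, len(positions))
        for pos, ref, alt in zip(positions, refs, alts):
            pos = int(pos)
            haploid = chrom in male_x
            in_ibd = _in_any(config.ibd_intervals, chrom, pos)
            if haploid or in_ibd:
                zyg = Zygosity.HOM_ALT
            else:
                zyg = Zygosity.HET if rng.random() < config.het_fraction else Zygosity.HOM_ALT
            variants.append(
                VariantCall(chrom, pos, str(ref), str(alt), zyg, caller=None)
            )
        snp_pos = set(int(p) for p in positions)
        ipos = _random_sites(rng, length - 10, config.indel_density)
        for pos in ipos:
            pos = int(pos)
            if pos in snp_pos:
                continue
            size = int(rng.geometric(0.45))
            size = min(size, 8)
            unit = "".join(rng.choice(_BASES, size=size))
            anchor = str(rng.choice(_BASES))
            if rng.random() < 0.5:
                ref, alt = anchor, anchor + unit  # insertion
            else:
                ref, alt = anchor + unit, anchor  # deletion
            haploid = chrom in male_x
            in_ibd = _in_any(config.ibd_intervals, chrom, pos)
            zyg = (
                Zygosity.HOM_ALT
                if haploid or in_ibd or rng.random() >= config.het_fraction
                else Zygosity.HET
            )
            indels.append(VariantCall(chrom, pos, ref, alt, zyg, caller=None))
    genes = _make_genes(config, rng)
    return TruthSet(
        variants=variants,
        indels=indels,
        ibd=config.ibd_intervals,
        cnvs=config.cnv_spec,
        genes=genes,
        planted_fp={},
    )


def _make_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    chroms = config.layout.chroms
    lengths = np.array([config.layout.lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    for i in range(config.n_genes):
        ci = rng.choice(len(chroms), p=probs)
        chrom = chroms[ci]
        n_codons = int(rng.integers(100, 500))
        cds_len = 3 * (n_codons + 1)  # coding codons + stop
        max_start = config.layout.lengths[chrom] - cds_len - 1
        start = int(rng.integers(0, max_start))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"gene{i:04d}",
                chrom=chrom,
                strand=strand,
                cds=(GenomicInterval(chrom, start, start + cds_len, "CDS"),),
            )
        )
    return genes


def _emit_caller(
    config: SimConfig,
    truth: TruthSet,
    name: str,
    profile: CallerProfile,
    rng: np.random.Generator,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Emit one caller's SNP call set: planted truth minus drop-outs and
    depth-driven under-calls, plus misalignment false hets."""
    calls: dict[tuple[str, int], VariantCall] = {}
    k = config.depth_overdispersion
    for v in truth.variants:
        if profile.drop_rate > 0 and rng.random() < profile.drop_rate:
            continue
        cn = _copy_number_at(config, v.chrom, v.pos)
        mean = config.coverage_mean * (cn / 2 if cn != 2 else 1.0)
        if v.chrom in config.layout.sex_chroms:
            mean *= 0.5  # haploid X: half the autosomal depth
        depth = int(_draw_depth(rng, mean, k, 1)[0])
        if v.zygosity is Zygosity.HET:
            if profile.het_undercall:
                alt_reads = int(rng.binomial(depth, 0.5)) if depth else 0
                if alt_reads == 0:
                    continue  # only reference allele sampled: site missed
                if alt_reads == depth:
                    zyg = Zygosity.HOM_ALT  # under-called as homozygous
                else:
                    zyg = Zygosity.HET
            else:
                depth = max(depth, 4)
                alt_reads = min(max(int(rng.binomial(depth, 0.5)), 1), depth - 1)
                zyg = Zygosity.HET
        else:
            depth = max(depth, 1) if not profile.het_undercall else depth
            if depth == 0:
                continue
            alt_reads = depth
            zyg = Zygosity.HOM_ALT
        calls[(v.chrom, v.pos)] = VariantCall(
            v.chrom, v.pos, v.ref, v.alt, zyg,
            depth=depth, allele_depths=(depth - alt_reads, alt_reads), caller=name,
        )
    # misalignment false hets: base rate outside duplications, multiplied inside
    fps: list[VariantCall] = []
    if profile.base_fp_het_rate > 0:
        dup_ivs = [iv for iv, cn in config.cnv_spec if cn > 2]
        for chrom, length in config.layout.lengths.items():
            positions = _random_sites(rng, length, profile.base_fp_het_rate)
            extra: list[int] = []
            for iv in dup_ivs:
                if iv.chrom != chrom:
                    continue
                n_extra = rng.poisson(
                    iv.length * profile.base_fp_het_rate * (profile.dup_fp_multiplier - 1)
                )
                extra.extend(int(p) for p in iv.start + rng.choice(iv.length, size=min(n_extra, iv.length), replace=False))
            all_pos = sorted(set(int(p) for p in positions) | set(extra))
            refs, alts = _random_snp_alleles(rng, len(all_pos))
            a, b = profile.fp_map_beta
            for pos, ref, alt in zip(all_pos, refs, alts):
                if (chrom, pos) in calls:
                    continue
                cn = _copy_number_at(config, chrom, pos)
                mean = config.coverage_mean * (cn / 2 if cn != 2 else 1.0)
                depth = max(int(_draw_depth(rng, mean, k, 1)[0]), 2)
                frac = rng.beta(a, b)
                alt_reads = min(max(int(rng.binomial(depth, frac)), 1), depth - 1)
                fp = VariantCall(
                    chrom, pos, str(ref), str(alt), Zygosity.HET,
                    depth=depth, allele_depths=(depth - alt_reads, alt_reads),
                    caller=name,
                )
                calls[(chrom, pos)] = fp
                fps.append(fp)
    ordered = sorted(calls.values(), key=lambda c: (config.layout.chroms.index(c.chrom), c.pos))
    return ordered, fps


def _emit_chips(
    config: SimConfig, truth: TruthSet, rng: np.random.Generator
) -> tuple[list[ChipGenotype], list[ChipGenotype]]:
    """Array genotypes at a subset of true SNP sites; each chip's call is the
    truth flipped with ``chip_error_rate`` (het <-> one of the homozygotes)."""
    hd: list[ChipGenotype] = []
    ld: list[ChipGenotype] = []
    spacing = config.chip_marker_spacing
    snp_density_bp = max(config.snp_density, 1e-9)
    keep_prob = min(1.0, 1.0 / (spacing * snp_density_bp))
    for i, v in enumerate(truth.variants):
        if rng.random() > keep_prob:
            continue
        marker = f"mk{i:07d}"

        def genotype(chip: str) -> ChipGenotype:
            call = (
                frozenset((v.ref, v.alt))
                if v.zygosity is Zygosity.HET
                else frozenset((v.alt,))
            )
            if rng.random() < config.chip_error_rate:
                if len(call) == 2:
                    call = frozenset((v.alt,)) if rng.random() < 0.5 else frozenset((v.ref,))
                else:
                    call = frozenset((v.ref, v.alt))
            return ChipGenotype(marker, v.chrom, v.pos, v.ref, v.alt, call, chip)

        hd.append(genotype("HD"))
        if rng.random() < config.chip_lowdensity_fraction:
            ld.append(genotype("SNP50"))
    return hd, ld


def _emit_window_counts(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gamma-Poisson window read counts for test and reference samples over
    the autosomes; the test sample's mean scales with planted copy number."""
    rows = []
    k = config.count_overdispersion
    for iv in config.layout.windows(config.rd_window, chroms=config.layout.autosomes):
        overlap_scaled = 0.0
        for cnv_iv, cn in config.cnv_spec:
            if cnv_iv.chrom != iv.chrom:
                continue
            ov = min(iv.end, cnv_iv.end) - max(iv.start, cnv_iv.start)
            if ov > 0:
                overlap_scaled += (cn / 2 - 1.0) * ov / iv.length
        base = config.reads_per_window_mean * iv.length / config.rd_window
        mean_test = base * (1.0 + overlap_scaled)
        lam_t = rng.gamma(k, mean_test / k) if mean_test > 0 else 0.0
        lam_r = rng.gamma(k, base / k)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "count_test": int(rng.poisson(lam_t)),
                "count_ref": int(rng.poisson(lam_r)),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count_test", "count_ref"])


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate a full synthetic dataset; deterministic given ``config.seed``.

    When ``out_dir`` is given, also writes one VCF per caller, the chip
    genotype tables, the window-count TSV, truth BEDs and the genome layout.
    """
    rng = np.random.default_rng(config.seed)
    truth = _make_truth(config, rng)
    callsets: dict[str, list[VariantCall]] = {}
    for name, profile in config.caller_profiles.items():
        calls, fps = _emit_caller(config, truth, name, profile, rng)
        callsets[name] = calls
        truth.planted_fp[name] = fps
    chip_hd, chip_ld = _emit_chips(config, truth, rng)
    window_counts = _emit_window_counts(config, rng)
    result = SimResult(config, truth, callsets, chip_hd, chip_ld, window_counts)
    if out_dir is not None:
        _write_bundle(result, Path(out_dir))
    return result


def _write_bundle(result: SimResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    layout = result.config.layout
    write_layout(layout, out / "genome.tsv")
    for name, calls in result.callsets.items():
        write_vcf(calls, out / f"{name}.vcf", layout, sample="SIM")
    write_chip_table(result.chip_hd, out / "chip_hd.tsv")
    write_chip_table(result.chip_ld, out / "chip_ld.tsv")
    result.window_counts.to_csv(out / "window_counts.tsv", sep="\t", index=False)
    write_bed(result.truth.ibd, out / "truth_ibd.bed")
    write_bed(
        [
            GenomicInterval(iv.chrom, iv.start, iv.end, f"CN{cn}", value=float(cn))
            for iv, cn in result.truth.cnvs
        ],
        out / "truth_cnv.bed",
    )
    write_bed(
        [g.cds[0] for g in result.truth.genes],
        out / "truth_genes.bed",
    )
    meta = {
        "seed": result.config.seed,
        "snp_density": result.config.snp_density,
        "indel_density": result.config.indel_density,
        "het_fraction": result.config.het_fraction,
        "chip_error_rate": result.config.chip_error_rate,
        "caller_profiles": {
            name: asdict(p) if not isinstance(p, dict) else p
            for name, p in result.config.caller_profiles.items()
        },
    }
    (out / "sim_config.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


PROFILES: dict[str, dict] = {
    # zero-error bundle: every caller's output equals the planted truth
    "clean": dict(
        caller_profiles={
            name: CallerProfile(0.0, 1.0, False) for name in ("bwa", "smalt", "clc", "giga")
        },
        chip_error_rate=0.0,
    ),
    # error structure mirroring a real multi-pipeline study: two pipelines
    # with low misalignment FP rates, two with 8x higher rates concentrated
    # in duplications, chip errors at the deduced array error rate
    "paperlike": dict(),
    # stress profile: heavy misalignment load with very low-MAP false hets
    "adversarial": dict(
        caller_profiles={
            "bwa": CallerProfile(4e-6, 2.0, True),
            "smalt": CallerProfile(4e-6, 2.0, True),
            "clc": CallerProfile(8e-5, 8.0, True, fp_map_beta=(1.0, 8.0)),
            "giga": CallerProfile(8e-5, 8.0, True, fp_map_beta=(1.0, 8.0)),
        },
        chip_error_rate=2e-3,
    ),
}


def end_to_end_fixture(
    profile: str, out_dir: str | Path | None = None, seed: int = 42
) -> SimResult:
    """Build one of the named fixture bundles (clean / paperlike /
    adversarial) and optionally write it to ``out_dir``."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    config = SimConfig(seed=seed, **PROFILES[profile])
    return simulate(config, out_dir)
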