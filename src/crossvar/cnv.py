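"""Read-depth CNV calling, cross-platform CNV comparison, cross-assembly
SV filtering, and permutation-based gene enrichment.

The read-depth caller compares normalized window read counts between a
test and a reference sample: windows with |log2 ratio| above a threshold
that form runs of at least ``min_consecutive`` same-sign windows become
duplication (log2 > 0) or deletion (log2 < 0) calls.  Cross-platform
comparison uses the at-least-1-bp overlap rule; the consensus set keeps
events seen by two or more platforms.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .variant_model import GenomeLayout, GenomicInterval

__all__ = [
    "CnvType",
    "CnvCall",
    "RdParams",
    "SvRecord",
    "WINDOW_COLUMNS",
    "read_window_counts",
    "readdepth_cnv_call",
    "overlap_compare",
    "cnv_summary",
    "cross_assembly_filter",
    "gene_enrichment_permutation",
    "validation_bookkeeping",
]


class CnvType(str, enum.Enum):
    DUPLICATION = "duplication"
    DELETION = "deletion"


@dataclass(frozen=True)
class CnvCall:
    interval: GenomicInterval
    cnv_type: CnvType
    platform: str
    mean_log2: float

    def __post_init__(self) -> None:
        if (self.cnv_type is CnvType.DUPLICATION) != (self.mean_log2 > 0):
            raise ValueError("duplication iff mean_log2 > 0")

    @property
    def estimated_copy_number(self) -> float:
        """Diploid-relative copy number implied by the mean log2 ratio."""
        return 2.0 * 2.0 ** self.mean_log2


@dataclass(frozen=True)
class RdParams:
    """Read-depth calling thresholds: |log2| > ``min_abs_log2`` over at
    least ``min_consecutive`` windows; low-count windows are skipped; a
    pseudocount keeps the log2 finite on zero counts."""

    min_abs_log2: float = 1.0
    min_consecutive: int = 5
    pseudocount: float = 0.5
    min_total_reads_per_window: int = 10

    def __post_init__(self) -> None:
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")
        if self.min_abs_log2 <= 0:
            raise ValueError("min_abs_log2 must be > 0")


WINDOW_COLUMNS = ["chrom", "start", "end", "count_test", "count_ref"]


def read_window_counts(path: str) -> pd.DataFrame:
    """Window-count TSV: chrom, start, end (0-based half-open), count_test,
    count_ref."""
    df = pd.read_csv(path, sep="\t", comment="#", names=WINDOW_COLUMNS, header=0)
    return df


def readdepth_cnv_call(
    windows: pd.DataFrame,
    params: RdParams | None = None,
    platform: str = "readdepth",
) -> list[CnvCall]:
    """Call CNVs from per-window read counts of a test and a reference
    sample on an identical window grid.

    Per window: log2(((c_t + q)/N_t) / ((c_r + q)/N_r)) with pseudocount q
    and library sizes N summed over all windows.  Runs of >=
    ``min_consecutive`` consecutive qualifying windows of consistent sign
    merge into one call spanning run start to run end; ``mean_log2`` is the
    mean over the run's windows.
    """
    params = params or RdParams()
    required = set(WINDOW_COLUMNS)
    if not required <= set(windows.columns):
        raise ValueError(f"window table must have columns {sorted(required)}")
    n_test = float(windows["count_test"].sum())
    n_ref = float(windows["count_ref"].sum())
    if n_ref <= 0:
        raise ValueError("all-zero reference counts")
    if n_test <= 0:
        raise ValueError("all-zero test counts")
    calls: list[CnvCall] = []
    for chrom, group in windows.groupby("chrom", sort=False):
        group = group.sort_values("start").reset_index(drop=True)
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping windows in grid")
        ct = group["count_test"].to_numpy(dtype=float)
        cr = group["count_ref"].to_numpy(dtype=float)
        log2 = np.log2(((ct + params.pseudocount) / n_test) / ((cr + params.pseudocount) / n_ref))
        usable = (ct + cr) >= params.min_total_reads_per_window
        sign = np.where(log2 > params.min_abs_log2, 1, np.where(log2 < -params.min_abs_log2, -1, 0))
        sign = np.where(usable, sign, 0)
        run_start = None
        run_sign = 0
        prev_end = None

        def close_run(idx: int) -> None:
            nonlocal run_start
            length = idx - run_start
            if length >= params.min_consecutive:
                seg = slice(run_start, idx)
                mean_log2 = float(log2[seg].mean())
                calls.append(
                    CnvCall(
                        interval=GenomicInterval(
                            str(chrom), int(starts[run_start]), int(ends[idx - 1]), "CNV"
                        ),
                        cnv_type=CnvType.DUPLICATION if run_sign > 0 else CnvType.DELETION,
                        platform=platform,
                        mean_log2=mean_log2,
                    )
                )
            run_start = None

        for i in range(len(group)):
            contiguous = prev_end is None or starts[i] == prev_end
            if run_start is not None and (sign[i] != run_sign or not contiguous):
                close_run(i)
            if run_start is None and sign[i] != 0:
                run_start, run_sign = i, sign[i]
            prev_end = ends[i]
        if run_start is not None:
            close_run(len(group))
    return calls


def _build_trees(calls: Sequence[CnvCall]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for c in calls:
        trees.setdefault(c.interval.chrom, IntervalTree()).addi(
            c.interval.start, c.interval.end, c
        )
    return trees


@dataclass
class OverlapComparison:
    shared_flags: dict[str, list[bool]]
    venn_counts: dict[frozenset[str], int]
    consensus: list[GenomicInterval]
    type_conflicts: list[GenomicInterval]


def overlap_compare(
    cnv_sets: Mapping[str, Sequence[CnvCall]],
) -> OverlapComparison:
    """Cross-platform CNV comparison under the >=1 bp overlap rule.

    For each call, records the set of platforms (including its own) whose
    calls it touches; Venn counts tabulate calls by that platform subset.
    The consensus set merges (interval union) all calls supported by at
    least two platforms; merged events mixing duplication and deletion
    labels are flagged as conflicts rather than resolved.
    """
    if len(cnv_sets) < 2:
        raise ValueError("need at least two platforms")
    trees = {p: _build_trees(calls) for p, calls in cnv_sets.items()}
    shared_flags: dict[str, list[bool]] = {}
    venn: Counter[frozenset[str]] = Counter()
    supported: list[CnvCall] = []
    for platform, calls in cnv_sets.items():
        flags = []
        for c in calls:
            members = {platform}
            for other, otrees in trees.items():
                if other == platform:
                    continue
                tree = otrees.get(c.interval.chrom)
                if tree is not None and tree.overlap(c.interval.start, c.interval.end):
                    members.add(other)
            shared = len(members) > 1
            flags.append(shared)
            venn[frozenset(members)] += 1
            if shared:
                supported.append(c)
        shared_flags[platform] = flags
    # merge overlapping multi-platform calls into consensus intervals
    consensus: list[GenomicInterval] = []
    conflicts: list[GenomicInterval] = []
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in supported:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        calls = sorted(by_chrom[chrom], key=lambda c: c.interval.start)
        cur_start, cur_end = calls[0].interval.start, calls[0].interval.end
        cur_types = {calls[0].cnv_type}
        for c in calls[1:]:
            if c.interval.start < cur_end:
                cur_end = max(cur_end, c.interval.end)
                cur_types.add(c.cnv_type)
            else:
                iv = GenomicInterval(chrom, cur_start, cur_end, "CNV_consensus")
                consensus.append(iv)
                if len(cur_types) > 1:
                    conflicts.append(iv)
                cur_start, cur_end, cur_types = c.interval.start, c.interval.end, {c.cnv_type}
        iv = GenomicInterval(chrom, cur_start, cur_end, "CNV_consensus")
        consensus.append(iv)
        if len(cur_types) > 1:
            conflicts.append(iv)
    return OverlapComparison(
        shared_flags=shared_flags,
        venn_counts=dict(venn),
        consensus=consensus,
        type_conflicts=conflicts,
    )


def cnv_summary(
    intervals: Sequence[GenomicInterval] | Sequence[CnvCall],
    layout: GenomeLayout | None = None,
) -> dict[str, float]:
    """Count, total bp, mean/min/max length and (given a layout) genome
    fraction of a CNV set."""
    ivs = [c.interval if isinstance(c, CnvCall) else c for c in intervals]
    if not ivs:
        out = {"count": 0, "total_bp": 0, "mean_length": 0.0, "min_length": 0.0,
               "max_length": 0.0, "empty": True}
        if layout is not None:
            out["genome_fraction"] = 0.0
        return out
    lengths = [iv.length for iv in ivs]
    out = {
        "count": len(ivs),
        "total_bp": int(sum(lengths)),
        "mean_length": sum(lengths) / len(lengths),
        "min_length": float(min(lengths)),
        "max_length": float(max(lengths)),
        "empty": False,
    }
    if layout is not None:
        out["genome_fraction"] = sum(lengths) / layout.total_length
    return out


@dataclass(frozen=True)
class SvRecord:
    """Structural variant with two breakpoints in assembly A coordinates."""

    sv_id: str
    sv_class: str  # e.g. inversion, intra_translocation, inter_translocation
    breakpoint1: tuple[str, int]
    breakpoint2: tuple[str, int]


@dataclass
class CrossAssemblyReport:
    kept: list[SvRecord]
    removed_discordant: list[SvRecord]
    removed_unmapped: list[SvRecord]
    before_by_class: dict[str, int]
    after_by_class: dict[str, int]
    reduction_fraction: float


def cross_assembly_filter(
    svs: Sequence[SvRecord],
    position_map: Mapping[tuple[str, int], tuple[str, int]],
) -> CrossAssemblyReport:
    """Keep SVs whose two breakpoints land on one and the same chromosome of
    the second assembly; report per-class before/after counts.

    ``position_map`` maps (chromA, posA) -> (chromB, posB), 0-based.  SVs
    with an unmapped breakpoint are removed and counted separately.
    """
    kept: list[SvRecord] = []
    discordant: list[SvRecord] = []
    unmapped: list[SvRecord] = []
    before: Counter[str] = Counter()
    after: Counter[str] = Counter()
    for sv in svs:
        before[sv.sv_class] += 1
        m1 = position_map.get(sv.breakpoint1)
        m2 = position_map.get(sv.breakpoint2)
        if m1 is None or m2 is None:
            unmapped.append(sv)
            continue
        if m1[0] == m2[0]:
            kept.append(sv)
            after[sv.sv_class] += 1
        else:
            discordant.append(sv)
    n_before = len(svs)
    reduction = (n_before - len(kept)) / n_before if n_before else 0.0
    return CrossAssemblyReport(
        kept=kept,
        removed_discordant=discordant,
        removed_unmapped=unmapped,
        before_by_class=dict(before),
        after_by_class=dict(after),
        reduction_fraction=reduction,
    )


def gene_enrichment_permutation(
    cnvs: Sequence[GenomicInterval] | Sequence[CnvCall],
    genes: Sequence[GenomicInterval],
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Gene-overlap enrichment of a CNV set against random placement.

    Observed = genes overlapped (>=1 bp) by any CNV.  Each permutation
    re-places every CNV uniformly at random (chromosome chosen with
    probability proportional to its length, among chromosomes that can hold
    the interval) and recounts.  fold = observed / mean(null);
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ivs = [c.interval if isinstance(c, CnvCall) else c for c in cnvs]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_trees: dict[str, IntervalTree] = {}
    for g in genes:
        gene_trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def count_genes(intervals: Sequence[GenomicInterval]) -> int:
        hit: set[tuple[str, int, int]] = set()
        for iv in intervals:
            tree = gene_trees.get(iv.chrom)
            if tree is None:
                continue
            for h in tree.overlap(iv.start, iv.end):
                hit.add((iv.chrom, h.begin, h.end))
        return len(hit)

    observed = count_genes(ivs)
    chrom_names = layout.chroms
    chrom_lengths = np.array([layout.lengths[c] for c in chrom_names], dtype=float)
    null = np.empty(n_perm)
    for k in range(n_perm):
        placed: list[GenomicInterval] = []
        for iv in ivs:
            fits = chrom_lengths >= iv.length
            if not fits.any():
                raise ValueError(f"interval of {iv.length} bp longer than every chromosome")
            probs = np.where(fits, chrom_lengths, 0.0)
            probs /= probs.sum()
            ci = rng.choice(len(chrom_names), p=probs)
            start = int(rng.integers(0, layout.lengths[chrom_names[ci]] - iv.length + 1))
            placed.append(GenomicInterval(chrom_names[ci], start, start + iv.length))
        null[k] = count_genes(placed)
    mean_null = float(null.mean())
    fold = observed / mean_null if mean_null > 0 else float("inf")
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return {
        "observed_genes": float(observed),
        "null_mean": mean_null,
        "fold": fold,
        "p_value": p,
        "n_perm": float(n_perm),
    }


def validation_bookkeeping(labels: Iterable[str]) -> dict[str, float]:
    """Confirmation rate of wet-lab CNV validation excluding assay failures.

    Labels are ``confirmed``, ``not_confirmed`` or ``assay_failed``;
    rate = confirmed / (tested - failed).
    """
    counts = Counter(labels)
    unknown = set(counts) - {"confirmed", "not_confirmed", "assay_failed"}
    if unknown:
        raise ValueError(f"unknown outcome labels: {sorted(unknown)}")
    tested = sum(counts.values())
    failed = counts.get("assay_failed", 0)
    informative = tested - failed
    if informative == 0:
        raise ValueError("all assays failed; confirmation rate undefined")
    confirmed = counts.get("confirmed", 0)
    return {
        "tested": float(tested),
        "assay_failed": float(failed),
        "confirmed": float(confirmed),
        "confirmation_rate": confirmed / informative,
    }
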