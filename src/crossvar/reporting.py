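"""Run-level summary reporting: the variation-overview table and a
structured run report.

The overview aggregates every variant class detected by the integrated
pipelines — consensus SNPs, intra-read indels, split-read/read-pair SVs
and multi-platform CNVs — into one table of counts, size ranges and total
bases affected.  Rows are per-method and deliberately not deduplicated
across classes; the "structurally variable bases" figure is the total
minus the SNP bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["OverviewRow", "VariationOverview", "RunReport", "variation_overview",
           "overview_from_rows"]


@dataclass(frozen=True)
class OverviewRow:
    method: str
    variant_type: str
    number: int
    min_size: int | None
    median_size: float | None
    max_size: int | None
    total_bases: int


@dataclass
class VariationOverview:
    rows: list[OverviewRow]

    @property
    def total_count(self) -> int:
        return sum(r.number for r in self.rows)

    @property
    def total_bases(self) -> int:
        return sum(r.total_bases for r in self.rows)

    @property
    def snp_bases(self) -> int:
        return sum(r.total_bases for r in self.rows if r.variant_type == "SNP")

    @property
    def structural_bases(self) -> int:
        """Bases affected by everything other than SNPs."""
        return self.total_bases - self.snp_bases

    def to_frame(self) -> pd.DataFrame:
        records = [dict(r.__dict__) for r in self.rows]
        mins = [r["min_size"] for r in records if r["min_size"] is not None]
        maxs = [r["max_size"] for r in records if r["max_size"] is not None]
        records.append(
            {
                "method": "Total",
                "variant_type": "",
                "number": self.total_count,
                "min_size": min(mins) if mins else None,
                "median_size": None,
                "max_size": max(maxs) if maxs else None,
                "total_bases": self.total_bases,
            }
        )
        return pd.DataFrame(records)

    def to_markdown(self) -> str:
        return self.to_frame().to_markdown(index=False)


def _row(method: str, vtype: str, sizes: Sequence[int]) -> OverviewRow:
    if not sizes:
        return OverviewRow(method, vtype, 0, None, None, None, 0)
    return OverviewRow(
        method=method,
        variant_type=vtype,
        number=len(sizes),
        min_size=int(min(sizes)),
        median_size=float(median(sizes)),
        max_size=int(max(sizes)),
        total_bases=int(sum(sizes)),
    )


def variation_overview(
    snp_count: int,
    indel_sizes: Sequence[int],
    sv_sizes: Mapping[str, Sequence[int]],
    cnv_sizes: Sequence[int],
    snp_method: str = "consensus SNPs",
    indel_method: str = "intra-read indels",
    cnv_method: str = "multi-platform CNVs",
) -> VariationOverview:
    """Build the overview table from raw size lists.

    SNPs affect one base each; indel size is |len(alt) - len(ref)|; SV and
    CNV sizes are interval lengths.  ``sv_sizes`` maps method name -> list
    of sizes (one row per SV method).
    """
    rows = [
        OverviewRow(snp_method, "SNP", snp_count, None, None, None, snp_count),
        _row(indel_method, "indel", list(indel_sizes)),
    ]
    for method, sizes in sv_sizes.items():
        rows.append(_row(method, "SV", list(sizes)))
    rows.append(_row(cnv_method, "CNV", list(cnv_sizes)))
    return VariationOverview(rows=rows)


def overview_from_rows(rows: Iterable[OverviewRow]) -> VariationOverview:
    """Overview from already-summarized per-method rows (counts and total
    bases taken as given), for integrating externally produced call sets."""
    return VariationOverview(rows=list(rows))


@dataclass
class RunReport:
    """Per-stage parameter record plus the summary blocks a run produced.

    Every number in ``blocks`` comes from an operation's returned summary;
    the report only collects, it never recomputes.
    """

    parameters: dict[str, dict] = field(default_factory=dict)
    input_files: dict[str, str] = field(default_factory=dict)
    blocks: dict[str, object] = field(default_factory=dict)

    def add_stage(self, name: str, params: Mapping[str, object], block: object) -> None:
        self.parameters[name] = dict(params)
        self.blocks[name] = block

    def to_markdown(self) -> str:
        lines = ["# Run report", ""]
        for name, block in self.blocks.items():
            lines.append(f"## {name}")
            params = self.parameters.get(name, {})
            if params:
                lines.append("parameters: " + ", ".join(f"{k}={v}" for k, v in params.items()))
            if isinstance(block, VariationOverview):
                lines.append(block.to_markdown())
            elif isinstance(block, pd.DataFrame):
                lines.append(block.to_markdown(index=False))
            elif isinstance(block, Mapping):
                lines.extend(f"- {k}: {v}" for k, v in block.items())
            else:
                lines.append(str(block))
            lines.append("")
        return "\n".join(lines)
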