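"""Gene-level case-overlap arithmetic against TCGA-style case counts.

For each candidate interactor, the fraction of its tumor cases that are also
NF1-altered cases is reported as a percentage (overlap / total, one decimal,
half-away-from-zero rounding — so 471/862 prints as 54.6). Case counts are
consumed as a user-supplied table; portal counts drift between data
releases, so a frozen snapshot of printed fractions ships as a package
fixture for reference and testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ParameterError


@dataclass
class CaseOverlap:
    gene: str
    overlap_cases: int
    total_cases: int
    percent: float

    def __post_init__(self) -> None:
        if self.overlap_cases > self.total_cases:
            raise ParameterError("overlap_cases", "overlap exceeds total cases")


def compute_overlap_percent(overlap_cases: int, total_cases: int) -> float:
    """100 * overlap / total, rounded half-away-from-zero to one decimal."""
    if total_cases < 1:
        raise ParameterError("total_cases", "must be >= 1")
    if overlap_cases < 0:
        raise ParameterError("overlap_cases", "must be >= 0")
    if overlap_cases > total_cases:
        raise ParameterError("overlap_cases", "overlap exceeds total cases")
    # exact decimal arithmetic: no float rounding surprises at the .x5 boundary
    pct = (Decimal(100 * overlap_cases) / Decimal(total_cases)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(pct)


def overlap_table(rows: list[tuple[str, int, int]]) -> list[CaseOverlap]:
    """One CaseOverlap per (gene, overlap, total) row, sorted by descending
    percent, ties broken by gene id. Duplicate genes are rejected."""
    genes = [g for g, _, _ in rows]
    dupes = {g for g in genes if genes.count(g) > 1}
    if dupes:
        raise ParameterError("gene", f"duplicate gene ids: {sorted(dupes)}")
    out = [
        CaseOverlap(
            gene=g, overlap_cases=o, total_cases=t, percent=compute_overlap_percent(o, t)
        )
        for g, o, t in rows
    ]
    out.sort(key=lambda c: (-c.percent, c.gene))
    return out


def overlaps_to_frame(overlaps: list[CaseOverlap]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in overlaps],
            "overlap_cases": [c.overlap_cases for c in overlaps],
            "total_cases": [c.total_cases for c in overlaps],
            "percent": [c.percent for c in overlaps],
        }
    )


def read_overlap_table(path: str | Path) -> list[CaseOverlap]:
    df = pd.read_csv(path, sep="\t")
    required = ["gene", "overlap_cases", "total_cases"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParameterError("overlap_table", f"missing columns {missing} in {path}")
    return overlap_table(
        list(zip(df["gene"].astype(str), df["overlap_cases"].astype(int), df["total_cases"].astype(int)))
    )


def write_overlap_table(overlaps: list[CaseOverlap], path: str | Path) -> None:
    overlaps_to_frame(overlaps).to_csv(path, sep="\t", index=False)


def reference_overlap_path() -> Path:
    """Path to the shipped snapshot of published per-gene case fractions."""
    return Path(str(resources.files("preycall").joinpath("data/table1_overlaps.tsv")))


def load_reference_overlaps() -> list[CaseOverlap]:
    return read_overlap_table(reference_overlap_path())
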