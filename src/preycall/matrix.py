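"""Protein-by-sample spectral-count matrices.

A :class:`CountMatrix` holds spectral counts (raw integers, or normalized
spectral counts — N-SC — after between-sample scaling) together with the
sample-to-group map distinguishing bait (WT) pulldowns from empty-vector (EV)
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ParameterError

GROUPS = ("WT", "EV")

#: relative tolerance for "per-sample totals equal" after normalization
NORMALIZED_RTOL = 1e-9


@dataclass
class CountMatrix:
    """Spectral counts for proteins (rows) across samples (columns).

    Parameters
    ----------
    counts
        DataFrame indexed by protein id with one column per sample id.
        Nonnegative; integers when raw, reals once normalized.
    groups
        Mapping of sample id to group label, ``"WT"`` or ``"EV"``.
    normalized
        True once between-sample normalization has been applied.
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ParameterError("groups", f"samples without a group label: {missing}")
        bad = {g for g in self.groups.values()} - set(GROUPS)
        if bad:
            raise ParameterError("groups", f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise ParameterError("counts", "negative spectral counts")

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    @property
    def wt_samples(self) -> list[str]:
        return self.samples_in_group("WT")

    @property
    def ev_samples(self) -> list[str]:
        return self.samples_in_group("EV")

    def to_tsv(self, counts_path: str | Path, groups_path: str | Path | None = None) -> None:
        """Write counts as TSV (rows = proteins) and, optionally, the sidecar group map."""
        df = self.counts.copy()
        df.index.name = "protein"
        df.to_csv(counts_path, sep="\t")
        if groups_path is not None:
            write_group_map(self.groups, groups_path)

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        groups_path: str | Path,
        normalized: bool = False,
    ) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        return cls(counts=counts, groups=read_group_map(groups_path), normalized=normalized)


def write_group_map(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(groups.keys()), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def read_group_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ParameterError("groups", f"expected columns [sample, group] in {path}")
    return dict(zip(df["sample"], df["group"]))
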