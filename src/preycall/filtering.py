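"""Evidence filtering, protein grouping, spectral counting, and normalization.

The filters mirror a Scaffold-style workflow for AP-MS identifications:
peptide-spectrum matches (PSMs) are kept only when the peptide is longer than
5 residues, is not a singly-charged (MH+1) species, and carries a peptide
probability above 80%; proteins are kept when supported by at least two
distinct peptide sequences and a protein probability above 99%. An aggregate
false-discovery-rate check (mean identification-error probability of the
retained proteins) guards the final list. Spectral counts are then tallied
per protein and sample, and normalized between samples by total-count scaling
so per-sample totals match the mean total (normalized spectral counts, N-SC).

All probability and length cutoffs are strict inequalities; the
peptides-per-protein minimum is inclusive (>= 2 distinct sequences, pooled
across samples).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError, PsmValidationError, UndefinedEstimateError
from .matrix import CountMatrix

logger = logging.getLogger(__name__)

_SEQUENCE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")


@dataclass
class FilterThresholds:
    """Evidence-filter cutoffs; defaults follow the Scaffold-style settings."""

    min_peptide_length_exclusive: int = 5
    excluded_charge: int = 1
    min_peptide_probability: float = 0.80
    min_peptides_per_protein: int = 2
    min_protein_probability: float = 0.99
    max_fdr: float = 0.01

    def __post_init__(self) -> None:
        if self.min_peptide_length_exclusive < 0:
            raise ParameterError("min_peptide_length_exclusive", "must be >= 0")
        if self.excluded_charge < 1:
            raise ParameterError("excluded_charge", "must be >= 1")
        for name in ("min_peptide_probability", "min_protein_probability", "max_fdr"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(name, "must be in [0, 1]")
        if self.min_peptides_per_protein < 1:
            raise ParameterError("min_peptides_per_protein", "must be >= 1")


def validate_psms(psms: pd.DataFrame) -> None:
    """Record-level validation; raises :class:`PsmValidationError` with the row index."""
    for row, seq in psms["peptide_sequence"].items():
        if not isinstance(seq, str) or not _SEQUENCE_RE.match(seq):
            raise PsmValidationError(row, f"malformed peptide sequence {seq!r}")
    for col in ("peptide_probability", "protein_probability"):
        bad = psms.index[(psms[col] < 0) | (psms[col] > 1)]
        if len(bad):
            raise PsmValidationError(int(bad[0]), f"{col} out of [0, 1]")


def filter_psms(psms: pd.DataFrame, thresholds: FilterThresholds | None = None) -> pd.DataFrame:
    """Retain PSMs passing the peptide-level filters; input order preserved.

    Keeps rows with peptide length strictly greater than
    ``min_peptide_length_exclusive``, charge different from
    ``excluded_charge``, and peptide probability strictly greater than
    ``min_peptide_probability``.
    """
    thresholds = thresholds or FilterThresholds()
    if psms.empty:
        return psms.copy()
    validate_psms(psms)
    keep = (
        (psms["peptide_sequence"].str.len() > thresholds.min_peptide_length_exclusive)
        & (psms["charge"] != thresholds.excluded_charge)
        & (psms["peptide_probability"] > thresholds.min_peptide_probability)
    )
    return psms.loc[keep].copy()


def group_to_proteins(
    psms: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Group filtered PSMs to proteins and apply the protein-level filters.

    A protein is retained when it has at least ``min_peptides_per_protein``
    DISTINCT peptide sequences pooled across all samples, and its protein
    probability is strictly greater than ``min_protein_probability``.

    Returns a DataFrame with columns ``protein_accession``,
    ``n_distinct_peptides``, ``protein_probability``, sorted by accession.
    """
    thresholds = thresholds or FilterThresholds()
    if psms.empty:
        return pd.DataFrame(
            columns=["protein_accession", "n_distinct_peptides", "protein_probability"]
        )
    grouped = psms.groupby("protein_accession", sort=True)
    n_prob = grouped["protein_probability"].nunique()
    conflicted = n_prob.index[n_prob > 1]
    if len(conflicted):
        raise PsmValidationError(
            -1, f"conflicting protein_probability values for accession {conflicted[0]!r}"
        )
    table = pd.DataFrame(
        {
            "protein_accession": list(grouped.groups),
            "n_distinct_peptides": grouped["peptide_sequence"].nunique().to_numpy(),
            "protein_probability": grouped["protein_probability"].first().to_numpy(),
        }
    )
    keep = (table["n_distinct_peptides"] >= thresholds.min_peptides_per_protein) & (
        table["protein_probability"] > thresholds.min_protein_probability
    )
    return table.loc[keep].reset_index(drop=True)


def estimate_fdr(proteins: pd.DataFrame) -> float:
    """Aggregate FDR estimate: mean of (1 - protein probability) over retained proteins.

    This is a probability-complement estimate used as a list-level check (the
    caller compares it against ``max_fdr``); it is not a per-protein filter.
    """
    if proteins.empty:
        raise UndefinedEstimateError("FDR is undefined for an empty protein table")
    return float((1.0 - proteins["protein_probability"]).mean())


def compute_spectral_counts(psms: pd.DataFrame, group_map: dict[str, str]) -> CountMatrix:
    """Tally retained PSM rows per (protein, sample) into a raw count matrix.

    Every sample in ``group_map`` appears as a column (zero-filled when
    absent from the PSMs); a PSM sample missing from ``group_map`` is an error.
    """
    samples = list(group_map)
    if not psms.empty:
        unknown = set(psms["sample_id"].astype(str)) - set(samples)
        if unknown:
            raise ParameterError("group_map", f"samples {sorted(unknown)} have no group label")
        counts = (
            psms.groupby(["protein_accession", "sample_id"], sort=True)
            .size()
            .unstack(fill_value=0)
            .reindex(columns=samples, fill_value=0)
            .astype("int64")
        )
    else:
        counts = pd.DataFrame(columns=samples, dtype="int64")
    counts.index.name = "protein"
    return CountMatrix(counts=counts, groups=dict(group_map), normalized=False)


def normalize_counts(matrix: CountMatrix) -> CountMatrix:
    """Total-count scaling: each sample's column is rescaled so per-sample
    totals equal the mean raw total (the N-SC convention).

    A sample whose raw total is zero is left unscaled (with a warning); the
    grand total is conserved whenever no column total is zero, and the
    operation is idempotent.
    """
    counts = matrix.counts.astype(float)
    if counts.empty or len(counts.columns) == 0:
        return CountMatrix(counts=counts, groups=dict(matrix.groups), normalized=True)
    totals = counts.sum(axis=0)
    mean_total = totals.mean()
    scaled = counts.copy()
    for sample in counts.columns:
        if totals[sample] == 0:
            logger.warning("sample %s has zero total spectral count; left unscaled", sample)
            continue
        scaled[sample] = counts[sample] * (mean_total / totals[sample])
    return CountMatrix(counts=scaled, groups=dict(matrix.groups), normalized=True)
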