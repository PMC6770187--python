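"""Species assignment of peptides between two ortholog proteins.

Closely related orthologs (e.g. human NF1 vs murine Nf1 neurofibromin, >98%
identical) differ at only a handful of residues. A peptide identified by MS
can be attributed to one species exactly when its sequence covers at least
one such discriminating residue — the human T2489, encoded by alanine in
mouse, is the canonical example. This module aligns the two orthologs
globally, enumerates the discriminating alignment columns, and assigns
peptides by exact substring matching.

Isoleucine and leucine are isobaric and indistinguishable by conventional
MS/MS, so I/L equivalence is ON by default in both site finding and peptide
matching.

Alignment is Needleman-Wunsch with match +1, mismatch -1, linear gap -2 and
deterministic tie-breaking (diagonal preferred over a gap in the second
sequence, preferred over a gap in the first). The inner dynamic program is
JIT-compiled so full-length (~2800 residue) neurofibromin-sized pairs align
in well under a second.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from numba import njit

from .errors import ParameterError

_SEQUENCE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")

MATCH, MISMATCH, GAP = 1, -1, -2
GAP_MARKER = "-"


@dataclass
class OrthologPair:
    """Two ortholog sequences and their global alignment (gapped strings)."""

    species_a_label: str
    species_b_label: str
    sequence_a: str
    sequence_b: str
    aligned_a: str
    aligned_b: str

    def __post_init__(self) -> None:
        assert self.aligned_a.replace(GAP_MARKER, "") == self.sequence_a
        assert self.aligned_b.replace(GAP_MARKER, "") == self.sequence_b
        assert len(self.aligned_a) == len(self.aligned_b)


@dataclass
class DiscriminatingSite:
    """An alignment column where the two orthologs differ.

    Positions are 1-based in each ungapped protein sequence (None on the
    gapped side of an indel column), matching the field's residue-numbering
    convention (e.g. "T2489").
    """

    column: int
    pos_a: int | None
    pos_b: int | None
    residue_a: str
    residue_b: str


@dataclass
class SpeciesCall:
    """Verdict for one peptide against an ortholog pair."""

    peptide: str
    verdict: Literal["species_a", "species_b", "ambiguous", "unmatched"]
    match_positions: list[tuple[str, int]]  # (species label, 1-based start)


def _validate_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ParameterError(name, "empty sequence")
    if not _SEQUENCE_RE.match(seq):
        raise ParameterError(name, "non-amino-acid character in sequence")


@njit
def _nw_fill(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:  # pragma: no cover
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    # pointers: 0 = diagonal, 1 = up (consume a), 2 = left (consume b)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        score[i, 0] = i * GAP
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        score[0, j] = j * GAP
        ptr[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            diag = score[i - 1, j - 1] + sub
            up = score[i - 1, j] + GAP
            left = score[i, j - 1] + GAP
            # tie-break preference: diagonal > up > left
            best, p = diag, 0
            if up > best:
                best, p = up, 1
            if left > best:
                best, p = left, 2
            score[i, j] = best
            ptr[i, j] = p
    return score, ptr


def align_orthologs(
    sequence_a: str,
    sequence_b: str,
    species_a_label: str = "species_a",
    species_b_label: str = "species_b",
) -> OrthologPair:
    """Global (Needleman-Wunsch) alignment of two ortholog sequences.

    Scoring: match +1, mismatch -1, linear gap -2; ties resolved
    deterministically preferring diagonal, then a gap in ``sequence_b``,
    then a gap in ``sequence_a``.
    """
    _validate_sequence(sequence_a, "sequence_a")
    _validate_sequence(sequence_b, "sequence_b")
    a = np.frombuffer(sequence_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(sequence_b.encode("ascii"), dtype=np.uint8)
    _, ptr = _nw_fill(a, b)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(sequence_a[i - 1])
            out_b.append(sequence_b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append(sequence_a[i - 1])
            out_b.append(GAP_MARKER)
            i -= 1
        else:
            out_a.append(GAP_MARKER)
            out_b.append(sequence_b[j - 1])
            j -= 1
    return OrthologPair(
        species_a_label=species_a_label,
        species_b_label=species_b_label,
        sequence_a=sequence_a,
        sequence_b=sequence_b,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
    )


def alignment_score(pair: OrthologPair) -> int:
    """Score of the stored alignment under the module's scoring scheme."""
    total = 0
    for ca, cb in zip(pair.aligned_a, pair.aligned_b):
        if ca == GAP_MARKER or cb == GAP_MARKER:
            total += GAP
        elif ca == cb:
            total += MATCH
        else:
            total += MISMATCH
    return total


def _collapse_il(seq: str) -> str:
    return seq.replace("I", "L")


def find_discriminating_sites(
    pair: OrthologPair, il_equivalent: bool = True
) -> list[DiscriminatingSite]:
    """All alignment columns whose residues differ, sorted by column (1-based).

    With ``il_equivalent`` (default) isoleucine and leucine are treated as
    the same residue, since MS cannot tell them apart. Indel columns count
    as discriminating, with the gap marker on the gapped side.
    """
    sites: list[DiscriminatingSite] = []
    pos_a = pos_b = 0
    for col, (ca, cb) in enumerate(zip(pair.aligned_a, pair.aligned_b), start=1):
        if ca != GAP_MARKER:
            pos_a += 1
        if cb != GAP_MARKER:
            pos_b += 1
        ea, eb = (_collapse_il(ca), _collapse_il(cb)) if il_equivalent else (ca, cb)
        if ea != eb:
            sites.append(
                DiscriminatingSite(
                    column=col,
                    pos_a=pos_a if ca != GAP_MARKER else None,
                    pos_b=pos_b if cb != GAP_MARKER else None,
                    residue_a=ca,
                    residue_b=cb,
                )
            )
    return sites


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of needle in haystack."""
    starts = []
    i = haystack.find(needle)
    while i != -1:
        starts.append(i + 1)
        i = haystack.find(needle, i + 1)
    return starts


def assign_species(
    peptide: str, pair: OrthologPair, il_equivalent: bool = True
) -> SpeciesCall:
    """Attribute one peptide to an ortholog by exact substring matching.

    A peptide matching only one of the two ungapped sequences is
    species-specific; matching both is ambiguous; matching neither is
    unmatched. Matching is exact (no error tolerance): a species call rests
    on exact residue identity at a discriminating site.
    """
    _validate_sequence(peptide, "peptide")
    if len(peptide) < 6:
        raise ParameterError("peptide", "peptide shorter than 6 residues cannot be assigned")
    if il_equivalent:
        pep = _collapse_il(peptide)
        seq_a, seq_b = _collapse_il(pair.sequence_a), _collapse_il(pair.sequence_b)
    else:
        pep, seq_a, seq_b = peptide, pair.sequence_a, pair.sequence_b

    hits_a = _find_all(seq_a, pep)
    hits_b = _find_all(seq_b, pep)
    positions = [(pair.species_a_label, s) for s in hits_a] + [
        (pair.species_b_label, s) for s in hits_b
    ]
    if hits_a and hits_b:
        verdict = "ambiguous"
    elif hits_a:
        verdict = "species_a"
    elif hits_b:
        verdict = "species_b"
    else:
        verdict = "unmatched"
    return SpeciesCall(peptide=peptide, verdict=verdict, match_positions=positions)


def read_ortholog_fasta(path: str | Path) -> OrthologPair:
    """Read a 2-record FASTA and align the pair (first record = species A)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ParameterError("fasta", f"expected exactly 2 records, found {len(records)}")
    return align_orthologs(
        str(records[0].seq).upper(),
        str(records[1].seq).upper(),
        species_a_label=records[0].id,
        species_b_label=records[1].id,
    )


def calls_to_frame(calls: list[SpeciesCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [c.peptide for c in calls],
            "verdict": [c.verdict for c in calls],
            "match_positions": [
                ";".join(f"{label}:{start}" for label, start in c.match_positions)
                for c in calls
            ],
        }
    )
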