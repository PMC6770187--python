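"""Interactor calling: the combined SAM / t-test / fold-change / rescue rule.

A prey protein is called a high-confidence interactor when either

* the statistical route passes — all three of
  (1) SAM-type weight ``|W| > 0.6`` with ``W = (mu1 - mu2) / (d1 - d2)``
  (group means and sample standard deviations of the normalized counts),
  (2) one-tailed unequal-variance (Welch) t-test with ``p < 0.1`` for the
  alternative WT mean > EV mean, and
  (3) fold change ``mu1 / mu2 >= 2`` — or

* the rescue route passes — the protein is detected only in the bait (WT)
  pulldowns (every EV raw count zero) with a total raw spectral count of at
  least 4.

Statistics run on NORMALIZED counts; the rescue rule reads RAW counts, since
it is a presence/absence criterion on the observed spectra. The printed SAM
denominator ``(d1 - d2)`` is implemented as the default (``as_printed``); a
``sum_denominator`` mode using the conventional ``(d1 + d2)`` is provided,
since the difference form is plausibly a transcription slip — neither is
guessed as the intent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientReplicatesError, MatrixMismatchError, ParameterError
from .matrix import CountMatrix


@dataclass
class GroupStats:
    """Means and sample (n-1) standard deviations of the WT and EV groups."""

    mu1: float  # WT mean
    mu2: float  # EV mean
    delta1: float  # WT sample SD
    delta2: float  # EV sample SD


@dataclass
class DecisionThresholds:
    """Cutoffs of the combined decision rule."""

    sam_cutoff: float = 0.6
    p_cutoff: float = 0.1
    fold_cutoff: float = 2.0
    rescue_min_total: int = 4
    sam_mode: Literal["as_printed", "sum_denominator"] = "as_printed"
    rescue_mode: Literal["total", "per_replicate", "mean"] = "total"
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        for name in ("sam_cutoff", "fold_cutoff", "epsilon"):
            if not getattr(self, name) > 0:
                raise ParameterError(name, "must be strictly positive")
        if not 0 <= self.p_cutoff <= 1:
            raise ParameterError("p_cutoff", "must be in [0, 1]")
        if self.rescue_min_total < 0:
            raise ParameterError("rescue_min_total", "must be >= 0")
        if self.sam_mode not in ("as_printed", "sum_denominator"):
            raise ParameterError("sam_mode", f"unknown mode {self.sam_mode!r}")
        if self.rescue_mode not in ("total", "per_replicate", "mean"):
            raise ParameterError("rescue_mode", f"unknown mode {self.rescue_mode!r}")


@dataclass
class DecisionRecord:
    """Per-protein test results and the verdict with its decision path."""

    protein: str
    W: float
    p_value: float | None
    fold_change: float | None
    stats_pass: bool
    rescue_pass: bool
    verdict: Literal["hit", "non_hit"]
    path: Literal["statistical", "rescue", "none"]


def group_stats(
    wt_values: Sequence[float], ev_values: Sequence[float]
) -> GroupStats:
    """Means and sample SDs (n-1 convention) for the two replicate groups."""
    wt = np.asarray(wt_values, dtype=float)
    ev = np.asarray(ev_values, dtype=float)
    if len(wt) < 2 or len(ev) < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicates per group, got {len(wt)} WT and {len(ev)} EV"
        )
    return GroupStats(
        mu1=float(wt.mean()),
        mu2=float(ev.mean()),
        delta1=float(wt.std(ddof=1)),
        delta2=float(ev.std(ddof=1)),
    )


def sam_weight(stats: GroupStats, thresholds: DecisionThresholds | None = None) -> float:
    """SAM-type weight W: mean difference over the SD combination.

    In ``as_printed`` mode the denominator is ``delta1 - delta2``; in
    ``sum_denominator`` mode it is ``delta1 + delta2``. When the denominator
    magnitude falls below ``epsilon``, W is 0 for equal means and a signed
    infinity otherwise (which passes any ``|W|`` cutoff).
    """
    thresholds = thresholds or DecisionThresholds()
    diff = stats.mu1 - stats.mu2
    if thresholds.sam_mode == "as_printed":
        denom = stats.delta1 - stats.delta2
    else:
        denom = stats.delta1 + stats.delta2
    if abs(denom) < thresholds.epsilon:
        if abs(diff) < thresholds.epsilon:
            return 0.0
        return math.copysign(math.inf, diff)
    return diff / denom


def welch_one_tailed_p(
    wt_values: Sequence[float], ev_values: Sequence[float]
) -> float | None:
    """One-tailed Welch p for the alternative WT mean > EV mean.

    Uses the unequal-variance statistic with Welch-Satterthwaite degrees of
    freedom. Returns None when both groups have zero variance (the statistic
    is undefined; such proteins are evaluated by the rescue rule only).
    """
    wt = np.asarray(wt_values, dtype=float)
    ev = np.asarray(ev_values, dtype=float)
    if len(wt) < 2 or len(ev) < 2:
        raise InsufficientReplicatesError("need >= 2 replicates per group")
    v1, v2 = wt.var(ddof=1), ev.var(ddof=1)
    if v1 == 0 and v2 == 0:
        return None
    n1, n2 = len(wt), len(ev)
    se2 = v1 / n1 + v2 / n2
    t = (wt.mean() - ev.mean()) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(sps.t.sf(t, df))


def fold_change(stats: GroupStats) -> float | None:
    """WT/EV mean ratio on normalized counts; None when the EV mean is zero
    (the protein is then evaluated via the rescue rule)."""
    if stats.mu2 > 0:
        return stats.mu1 / stats.mu2
    return None


def rescue_eligible(
    wt_raw: Sequence[int],
    ev_raw: Sequence[int],
    thresholds: DecisionThresholds | None = None,
) -> bool:
    """Presence/absence rescue rule on RAW counts.

    True iff every EV count is zero and the WT evidence reaches
    ``rescue_min_total`` — summed over replicates in ``total`` mode (the
    default), required of each replicate in ``per_replicate`` mode, or of the
    replicate mean in ``mean`` mode.
    """
    thresholds = thresholds or DecisionThresholds()
    wt = np.asarray(wt_raw)
    ev = np.asarray(ev_raw)
    if not (ev == 0).all():
        return False
    if thresholds.rescue_mode == "total":
        return bool(wt.sum() >= thresholds.rescue_min_total)
    if thresholds.rescue_mode == "per_replicate":
        return bool((wt >= thresholds.rescue_min_total).all())
    return bool(wt.mean() >= thresholds.rescue_min_total)


def call_interactors(
    raw: CountMatrix,
    normalized: CountMatrix,
    thresholds: DecisionThresholds | None = None,
) -> list[DecisionRecord]:
    """Apply the combined decision rule to every protein.

    The statistical route (|W| > sam_cutoff AND p < p_cutoff AND
    fold change >= fold_cutoff) runs on the normalized matrix; the rescue
    route runs on the raw matrix. Records are sorted by descending W, ties
    broken by protein id. When both routes pass, the statistical path is
    reported.
    """
    thresholds = thresholds or DecisionThresholds()
    if list(raw.counts.index) != list(normalized.counts.index) or list(
        raw.counts.columns
    ) != list(normalized.counts.columns):
        raise MatrixMismatchError("raw and normalized matrices must share proteins and samples")
    if not normalized.normalized:
        raise MatrixMismatchError("'normalized' matrix does not carry the normalized flag")
    if raw.normalized:
        raise MatrixMismatchError("'raw' matrix carries the normalized flag")

    wt_cols, ev_cols = normalized.wt_samples, normalized.ev_samples
    records: list[DecisionRecord] = []
    for protein in normalized.proteins:
        nrow = normalized.counts.loc[protein]
        rrow = raw.counts.loc[protein]
        stats = group_stats(nrow[wt_cols], nrow[ev_cols])
        W = sam_weight(stats, thresholds)
        p = welch_one_tailed_p(nrow[wt_cols], nrow[ev_cols])
        fc = fold_change(stats)
        stats_pass = (
            abs(W) > thresholds.sam_cutoff
            and p is not None
            and p < thresholds.p_cutoff
            and fc is not None
            and fc >= thresholds.fold_cutoff
        )
        rescue_pass = rescue_eligible(rrow[wt_cols], rrow[ev_cols], thresholds)
        verdict = "hit" if (stats_pass or rescue_pass) else "non_hit"
        path = "statistical" if stats_pass else ("rescue" if rescue_pass else "none")
        records.append(
            DecisionRecord(
                protein=protein,
                W=W,
                p_value=p,
                fold_change=fc,
                stats_pass=stats_pass,
                rescue_pass=rescue_pass,
                verdict=verdict,
                path=path,
            )
        )
    records.sort(key=lambda r: (-r.W, r.protein))
    return records


def decisions_to_frame(records: list[DecisionRecord]) -> pd.DataFrame:
    """Tabular view of decision records (None markers become NaN)."""
    return pd.DataFrame(
        {
            "protein": [r.protein for r in records],
            "W": [r.W for r in records],
            "p_value": [math.nan if r.p_value is None else r.p_value for r in records],
            "fold_change": [
                math.nan if r.fold_change is None else r.fold_change for r in records
            ],
            "stats_pass": [r.stats_pass for r in records],
            "rescue_pass": [r.rescue_pass for r in records],
            "verdict": [r.verdict for r in records],
            "path": [r.path for r in records],
        }
    )
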