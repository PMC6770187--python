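"""Synthetic AP-MS experiments with known ground truth.

Emulates the replicate design of a tandem-affinity-purification screen:
``n_wt_replicates`` bait (WT) pulldowns against ``n_ev_replicates``
empty-vector (EV) controls, a background of nonspecific binders present in
both groups, and a minority of true interactors that are either enriched in
WT or exclusive to it.

Spectral counts are drawn from a negative binomial in the mean/dispersion
parameterization (variance = mu + mu^2 / dispersion), the standard
overdispersed model for spectral-count data. PSM-level tables are produced by
expanding each count into individual peptide-spectrum matches with peptide
sequences, charges and identification probabilities, so every downstream
evidence filter is exercised.

All randomness flows from ``SimulationConfig.seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .matrix import CountMatrix

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

LABEL_BACKGROUND = "background"
LABEL_ENRICHED = "true_enriched"
LABEL_EXCLUSIVE = "true_exclusive"

PSM_COLUMNS = [
    "peptide_sequence",
    "charge",
    "peptide_probability",
    "protein_accession",
    "protein_probability",
    "sample_id",
]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic AP-MS experiment.

    Attributes
    ----------
    n_background
        Number of nonspecific binders, present in WT and EV alike.
    n_true
        Number of true interactors.
    n_wt_replicates, n_ev_replicates
        Replicate pulldowns per group (4 vs 4 by default).
    background_mean
        Mean spectral count per background protein per sample.
    dispersion
        Negative-binomial size parameter; smaller means more overdispersed.
    enrichment
        WT/EV mean ratio for true (enriched) interactors; >= 1.
    exclusive_fraction
        Fraction of true interactors with identically zero EV mean.
    noise_fraction
        Fraction of PSM rows drawn with a low (sub-threshold) peptide
        probability, emulating false identifications.
    n_sticky
        Optional extra high-abundance contaminants (10x background mean,
        equal in both groups) stressing the fold-change filter; 0 by default.
    seed
        RNG seed; the single entropy source for the experiment.
    """

    n_background: int = 200
    n_true: int = 20
    n_wt_replicates: int = 4
    n_ev_replicates: int = 4
    background_mean: float = 10.0
    dispersion: float = 2.0
    enrichment: float = 8.0
    exclusive_fraction: float = 0.5
    noise_fraction: float = 0.1
    n_sticky: int = 0
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_background", "n_true", "n_sticky"):
            if getattr(self, name) < 0:
                raise ParameterError(name, "must be >= 0")
        for name in ("n_wt_replicates", "n_ev_replicates"):
            if getattr(self, name) < 1:
                raise ParameterError(name, "must be >= 1")
        for name in ("background_mean", "dispersion"):
            if not getattr(self, name) > 0:
                raise ParameterError(name, "must be strictly positive")
        if not self.enrichment >= 1:
            raise ParameterError("enrichment", "must be >= 1")
        for name in ("exclusive_fraction", "noise_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(name, "must be in [0, 1]")

    @property
    def n_exclusive(self) -> int:
        return int(round(self.exclusive_fraction * self.n_true))

    @property
    def n_enriched(self) -> int:
        return self.n_true - self.n_exclusive

    def sample_ids(self) -> list[str]:
        wt = [f"WT{i + 1}" for i in range(self.n_wt_replicates)]
        ev = [f"EV{i + 1}" for i in range(self.n_ev_replicates)]
        return wt + ev

    def group_map(self) -> dict[str, str]:
        return {s: ("WT" if s.startswith("WT") else "EV") for s in self.sample_ids()}


#: truth table: protein id -> label, as a pandas Series
TruthTable = pd.Series


def _rngs(config: SimulationConfig) -> tuple[np.random.Generator, np.random.Generator]:
    # two independent child streams: counts, and PSM-level attributes —
    # so the matrix underlying a PSM table is identical to simulate_count_matrix's
    matrix_ss, psm_ss = np.random.SeedSequence(config.seed).spawn(2)
    return np.random.default_rng(matrix_ss), np.random.default_rng(psm_ss)


def _nbinom(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(np.int64)


def _protein_plan(config: SimulationConfig) -> pd.DataFrame:
    """Per-protein truth label and per-group negative-binomial means."""
    rows = []
    width = max(4, len(str(config.n_background + config.n_true + config.n_sticky)))
    idx = 0

    def pid() -> str:
        nonlocal idx
        idx += 1
        return f"PROT{idx:0{width}d}"

    for _ in range(config.n_background):
        rows.append((pid(), LABEL_BACKGROUND, config.background_mean, config.background_mean))
    for _ in range(config.n_sticky):
        sticky = 10.0 * config.background_mean
        rows.append((pid(), LABEL_BACKGROUND, sticky, sticky))
    for _ in range(config.n_enriched):
        rows.append(
            (pid(), LABEL_ENRICHED, config.enrichment * config.background_mean, config.background_mean)
        )
    for _ in range(config.n_exclusive):
        rows.append((pid(), LABEL_EXCLUSIVE, config.enrichment * config.background_mean, 0.0))
    return pd.DataFrame(rows, columns=["protein", "label", "wt_mean", "ev_mean"])


def simulate_count_matrix(config: SimulationConfig) -> tuple[CountMatrix, TruthTable]:
    """Draw a raw protein-by-sample spectral-count matrix plus its truth table.

    Background proteins share one count distribution across both groups;
    true-enriched proteins have WT mean = ``enrichment`` x EV mean;
    true-exclusive proteins have identically zero EV counts.
    """
    rng, _ = _rngs(config)
    plan = _protein_plan(config)
    samples = config.sample_ids()
    n_wt = config.n_wt_replicates

    data = np.zeros((len(plan), len(samples)), dtype=np.int64)
    for i, row in enumerate(plan.itertuples()):
        data[i, :n_wt] = _nbinom(rng, row.wt_mean, config.dispersion, n_wt)
        data[i, n_wt:] = _nbinom(rng, row.ev_mean, config.dispersion, config.n_ev_replicates)

    counts = pd.DataFrame(data, index=pd.Index(plan["protein"], name="protein"), columns=samples)
    truth = pd.Series(plan["label"].to_numpy(), index=counts.index, name="label")
    return CountMatrix(counts=counts, groups=config.group_map()), truth


def _peptide_repertoire(rng: np.random.Generator, n_peptides: int = 8) -> list[str]:
    """Random peptides over the 20 amino acids, lengths spanning 4-30."""
    lengths = rng.integers(4, 31, size=n_peptides)
    return ["".join(rng.choice(AMINO_ACIDS, size=ln)) for ln in lengths]


def simulate_psm_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, CountMatrix, TruthTable]:
    """Expand a simulated count matrix into a PSM-level evidence table.

    Returns ``(psms, matrix, truth)``. Aggregating the PSM table per
    (protein, sample) with no filtering reproduces ``matrix`` exactly; the
    matrix itself is identical to ``simulate_count_matrix(config)``.

    Peptide probabilities for non-noise rows are drawn high (mode near 1,
    floor 0.8); a ``noise_fraction`` of rows is drawn low (< 0.8), emulating
    false identifications that the evidence filters remove. Charges are in
    {1, 2, 3}; peptide lengths span 4-30, so every evidence filter is
    exercised on realistic inputs.
    """
    matrix, truth = simulate_count_matrix(config)
    _, rng = _rngs(config)

    records: list[tuple] = []
    for protein in matrix.proteins:
        repertoire = _peptide_repertoire(rng)
        protein_probability = float(rng.uniform(0.991, 0.9999))
        for sample in matrix.samples:
            n = int(matrix.counts.at[protein, sample])
            for _ in range(n):
                peptide = repertoire[rng.integers(len(repertoire))]
                charge = int(rng.choice([1, 2, 3], p=[0.10, 0.55, 0.35]))
                if rng.random() < config.noise_fraction:
                    pep_prob = float(rng.uniform(0.0, 0.8))
                else:
                    pep_prob = float(0.8 + 0.2 * rng.beta(5.0, 1.0))
                records.append(
                    (peptide, charge, pep_prob, protein, protein_probability, sample)
                )

    psms = pd.DataFrame(records, columns=PSM_COLUMNS)
    return psms, matrix, truth


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError("psm_table", f"missing columns {missing} in {path}")
    return df[PSM_COLUMNS]


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    truth.rename_axis("protein").to_frame().to_csv(path, sep="\t")


def read_truth_table(path: str | Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["label"]
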