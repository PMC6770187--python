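"""End-to-end orchestration: evidence table -> filters -> counts ->
normalization -> interactor calls, with optional species and case-overlap
reports, structured logging and a JSON run report."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import calling, filtering, simulate, species, tcga
from .errors import ParameterError, PreycallError, StageError
from .matrix import CountMatrix, read_group_map, write_group_map

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One pipeline run. Exactly one of ``psm_path`` / ``counts_path`` is the
    quantitative input; ``groups_path`` maps samples to WT/EV."""

    out_dir: str | Path
    groups_path: str | Path
    psm_path: str | Path | None = None
    counts_path: str | Path | None = None
    fasta_path: str | Path | None = None
    peptides_path: str | Path | None = None
    overlap_path: str | Path | None = None
    filter_thresholds: filtering.FilterThresholds = field(
        default_factory=filtering.FilterThresholds
    )
    decision_thresholds: calling.DecisionThresholds = field(
        default_factory=calling.DecisionThresholds
    )
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.psm_path is None) == (self.counts_path is None):
            raise ParameterError(
                "psm_path/counts_path", "exactly one quantitative input must be supplied"
            )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PreycallError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline and write all artifacts under ``config.out_dir``.

    Outputs: filtered PSM table (PSM input only), raw and normalized count
    matrices, the per-protein decision table, the hit list, and
    ``report.json`` with counts at every stage, the thresholds, seed and
    mode flags. Identical configs produce identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    report: dict = {
        "seed": config.seed,
        "filter_thresholds": dataclasses.asdict(config.filter_thresholds),
        "decision_thresholds": dataclasses.asdict(config.decision_thresholds),
        "stages": {},
    }
    groups = read_group_map(config.groups_path)

    if config.psm_path is not None:
        psms = _stage("read_psms")(simulate.read_psm_table)(config.psm_path)
        report["stages"]["input_psms"] = len(psms)
        logger.info("stage read_psms: %d rows", len(psms))

        kept = _stage("filter_psms")(filtering.filter_psms)(psms, config.filter_thresholds)
        report["stages"]["filtered_psms"] = len(kept)
        logger.info("stage filter_psms: %d rows retained", len(kept))

        proteins = _stage("group_to_proteins")(filtering.group_to_proteins)(
            kept, config.filter_thresholds
        )
        report["stages"]["proteins_before_grouping"] = int(kept["protein_accession"].nunique())
        report["stages"]["proteins_retained"] = len(proteins)
        logger.info("stage group_to_proteins: %d proteins retained", len(proteins))

        if len(proteins):
            fdr = filtering.estimate_fdr(proteins)
            report["fdr_estimate"] = fdr
            report["fdr_pass"] = bool(fdr < config.filter_thresholds.max_fdr)
            logger.info("stage estimate_fdr: %.5f (max %.5f)", fdr, config.filter_thresholds.max_fdr)

        kept = kept[kept["protein_accession"].isin(proteins["protein_accession"])]
        kept.to_csv(out / "filtered_psms.tsv", sep="\t", index=False)
        raw = _stage("compute_spectral_counts")(filtering.compute_spectral_counts)(kept, groups)
    else:
        raw = _stage("read_counts")(CountMatrix.from_tsv)(config.counts_path, config.groups_path)
        report["stages"]["input_psms"] = None
        report["stages"]["proteins_retained"] = len(raw.proteins)
        logger.info("stage read_counts: %d proteins x %d samples", len(raw.proteins), len(raw.samples))

    report["stages"]["proteins_counted"] = len(raw.proteins)
    raw.to_tsv(out / "counts_raw.tsv", out / "groups.tsv")

    normalized = _stage("normalize_counts")(filtering.normalize_counts)(raw)
    normalized.to_tsv(out / "counts_nsc.tsv")
    logger.info("stage normalize_counts: done")

    records = _stage("call_interactors")(calling.call_interactors)(
        raw, normalized, config.decision_thresholds
    )
    decisions = calling.decisions_to_frame(records)
    decisions.to_csv(out / "decisions.tsv", sep="\t", index=False)
    hits = [r.protein for r in records if r.verdict == "hit"]
    (out / "hits.txt").write_text("".join(h + "\n" for h in hits))
    report["stages"]["proteins_tested"] = len(records)
    report["stages"]["hits"] = len(hits)
    report["hits_by_path"] = {
        "statistical": sum(1 for r in records if r.path == "statistical"),
        "rescue": sum(1 for r in records if r.path == "rescue"),
    }
    logger.info("stage call_interactors: %d hits / %d proteins", len(hits), len(records))

    if config.fasta_path is not None and config.peptides_path is not None:
        pair = _stage("species")(species.read_ortholog_fasta)(config.fasta_path)
        peptides = [
            line.strip()
            for line in Path(config.peptides_path).read_text().splitlines()
            if line.strip()
        ]
        calls = [species.assign_species(p, pair) for p in peptides]
        species.calls_to_frame(calls).to_csv(out / "species_calls.tsv", sep="\t", index=False)
        report["stages"]["species_calls"] = len(calls)

    if config.overlap_path is not None:
        overlaps = _stage("overlap")(tcga.read_overlap_table)(config.overlap_path)
        tcga.write_overlap_table(overlaps, out / "case_overlaps.tsv")
        report["stages"]["overlap_rows"] = len(overlaps)

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def generate_fixture(config: simulate.SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete seeded demo dataset: PSM table, raw count matrix,
    group map, truth table, a synthetic ortholog FASTA pair with one planted
    discriminating site, and a case-overlap table."""
    import numpy as np

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    psms, matrix, truth = simulate.simulate_psm_table(config)
    paths = {
        "psms": out / "psms.tsv",
        "counts": out / "counts_raw.tsv",
        "groups": out / "groups.tsv",
        "truth": out / "truth.tsv",
        "fasta": out / "ortholog_pair.fa",
        "overlaps": out / "case_overlaps_input.tsv",
    }
    simulate.write_psm_table(psms, paths["psms"])
    matrix.to_tsv(paths["counts"])
    write_group_map(matrix.groups, paths["groups"])
    simulate.write_truth_table(truth, paths["truth"])

    # synthetic ortholog pair: identical 400-mers except one planted T<->A site
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    seq = "".join(rng.choice(simulate.AMINO_ACIDS, size=400))
    site = 250
    seq_a = seq[: site - 1] + "T" + seq[site:]
    seq_b = seq[: site - 1] + "A" + seq[site:]
    paths["fasta"].write_text(
        f">species_a synthetic ortholog, T at {site}\n{seq_a}\n"
        f">species_b synthetic ortholog, A at {site}\n{seq_b}\n"
    )

    pd.DataFrame(
        {"gene": ["GENE1", "GENE2", "GENE3"], "overlap_cases": [471, 189, 0], "total_cases": [862, 593, 100]}
    ).to_csv(paths["overlaps"], sep="\t", index=False)
    return paths
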