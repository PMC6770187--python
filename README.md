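# preycall

Interactor calling for affinity-purification mass spectrometry (AP-MS)
spectral-count experiments.

In a tandem-affinity-purification screen, a tagged bait protein (here
modelled on neurofibromin, the *NF1* gene product) is pulled down from cells
alongside its binding partners, and the purified mixture is identified by
MS/MS. The analytical problem is separating true prey from the large
background of nonspecific binders, using replicate bait (WT) pulldowns
against empty-vector (EV) controls. `preycall` implements that analysis end
to end for a small-replicate design (4 WT vs 4 EV):

1. **Evidence filtering** — Scaffold-style cutoffs on peptide-spectrum
   matches: peptide length > 5 residues, no singly-charged (MH+1) species,
   peptide probability > 80%; proteins need ≥ 2 distinct peptides and
   protein probability > 99%, with an aggregate FDR check (< 1%).
2. **Spectral counting and normalization** — per-protein, per-sample PSM
   tallies (SC), rescaled between samples by total-count scaling to the mean
   total (normalized spectral counts, N-SC).
3. **Interactor calling** — a protein is a high-confidence hit when all of
   - SAM-type weight |W| > 0.6, with W = (μ₁ − μ₂)/(δ₁ − δ₂)
     (group means and sample SDs of the N-SC values),
   - one-tailed unequal-variance (Welch) t-test, p < 0.1, and
   - fold change μ₁/μ₂ ≥ 2

   pass on the normalized counts, **or** the rescue rule fires: detected
   only in WT (all EV raw counts zero) with total raw spectral count ≥ 4.
4. **Species disambiguation** — peptides are attributed to one of two
   near-identical orthologs (e.g. human vs mouse neurofibromin, which differ
   at T2489 ↔ A) via global alignment, discriminating-residue detection, and
   exact substring matching with I/L equivalence.
5. **Case-overlap summaries** — per-gene TCGA-style overlap percentages
   (cases shared with *NF1* / total cases, one decimal).

A seeded synthetic-data generator produces PSM tables and count matrices
with known ground truth (negative-binomial counts, a minority of enriched or
WT-exclusive true interactors), so the whole pipeline is testable against
truth labels.

## Worked example

```bash
preycall simulate --out-dir demo --seed 7
preycall run --psms demo/psms.tsv --groups demo/groups.tsv --out-dir demo/out
```

prints

```
{"stages": {"filtered_psms": 16424, "hits": 22, "input_psms": 21926,
 "proteins_before_grouping": 220, "proteins_counted": 220,
 "proteins_retained": 220, "proteins_tested": 220}}
```

Of 21,926 simulated PSMs, 16,424 survive the evidence filters; all 220
simulated proteins retain ≥ 2 distinct peptides; and 22 proteins are called
high-confidence interactors (the generated truth table `demo/truth.tsv`
contains 20 true interactors). Full per-protein statistics are in
`demo/out/decisions.tsv` (W, p, fold change, decision path), the hit list in
`demo/out/hits.txt`, and stage counts with thresholds in
`demo/out/report.json`.

The same analysis is available as a library:

```python
from preycall import (SimulationConfig, simulate_count_matrix,
                      normalize_counts, call_interactors)

matrix, truth = simulate_count_matrix(SimulationConfig(seed=7))
records = call_interactors(matrix, normalize_counts(matrix))
hits = [r.protein for r in records if r.verdict == "hit"]   # 21 hits
```

Case-overlap arithmetic:

```python
from preycall import compute_overlap_percent
compute_overlap_percent(471, 862)   # 54.6
```

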