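# Methods

## The decision model

The calling procedure treats each protein's normalized spectral counts as
two small replicate groups — bait (WT) pulldowns and empty-vector (EV)
controls — and combines three tests conjunctively, with a presence/absence
rescue route for proteins invisible in the controls.

**SAM-type weight.** W = (μ₁ − μ₂)/(δ₁ − δ₂), where μ and δ are the group
means and *sample* (n−1) standard deviations. The difference-of-SDs
denominator is unusual — the conventional significance-analysis statistic
divides by a sum of deviations — but it is implemented literally as the
default (`sam_mode="as_printed"`), because that is the statistic this
pipeline models. A `sum_denominator` mode ((δ₁ + δ₂) denominator) is
provided for users who regard the difference as a transcription slip; both
modes are tested and neither is silently substituted for the other. The
denominator can vanish (equal SDs — e.g. two constant groups); below
`epsilon` (default 1e-12) W is defined as 0 when the means are also equal,
otherwise as a signed infinity, which deliberately passes the |W| > 0.6
cutoff: a mean difference with identical spreads is the statistic's limit of
perfect separation.

**Welch t-test.** One-tailed, alternative WT > EV — bait enrichment is the
only biologically sensible direction for an interaction screen. The
statistic and Welch–Satterthwaite degrees of freedom are computed directly;
only the t survival function comes from scipy. When both groups have zero
variance the p-value is undefined (returned as None) and the protein can
only be called through the rescue route. Spectral counts are discrete, so
null p-values are only approximately uniform; at the generator's default
count regime the approximation is good (the acceptance run checks this with
a Kolmogorov–Smirnov test on 2000 null proteins at α = 0.01).

**Fold change.** μ₁/μ₂ ≥ 2 on normalized counts, one-directional: depleted
proteins are never hits. μ₂ = 0 makes the ratio undefined (None), again
deferring to the rescue route rather than inventing a pseudocount.

**Rescue rule.** Evaluated on RAW counts — it reads as a statement about
observed spectra, not rescaled abundances: every EV count zero and total WT
count ≥ 4. The threshold's interpretation is configurable
(`rescue_mode`: total across replicates, per replicate, or replicate mean);
total is the default, as the natural reading of a summed spectral-count
requirement.

Statistics on normalized counts, rescue on raw, are both recorded in the run
report. Verdicts are `hit` iff either route passes; when both pass, the
statistical path is reported. Output is sorted by descending W (infinities
first), ties broken by protein id, so runs are byte-reproducible.

## Evidence filtering

All probability and length cutoffs are strict (>), mirroring their usual
statement as ">n" thresholds: peptide length > 5, peptide probability
> 0.80, protein probability > 0.99; charge 1 (MH+1) is excluded;
peptides-per-protein is inclusive (≥ 2) and counts *distinct* sequences
pooled across samples. Shared-peptide protein grouping is simplified to
unique-accession assignment. The FDR estimate is the mean identification
error probability, 1 − P(protein), over retained proteins — a list-level
check against `max_fdr` (default 1%), not a per-protein filter, since the
pipeline consumes externally computed probabilities and has no decoy set.

Normalization is total-count scaling: each sample column is multiplied by
(mean per-sample total)/(that sample's total). This conserves the grand
total when no column is empty, equalizes per-sample totals to within
1e-9 relative tolerance, and is idempotent. A zero-total sample is left
unscaled with a warning rather than producing NaNs.

## The synthetic generator

Counts are negative binomial in the mean/dispersion parameterization
(variance = μ + μ²/k), the standard overdispersed model for spectral
counts. Defaults define the simulated study conditions: 4 WT vs 4 EV
replicates; 200 background proteins at mean 10 counts/sample in both
groups; 20 true interactors with 8-fold WT enrichment, half of them
EV-exclusive (EV mean exactly 0, WT mean = enrichment × background mean);
dispersion k = 2 (strong overdispersion, typical of real spectral-count
data). The background mean and dispersion were fixed once from a pilot
over realistic count regimes before any acceptance measurement.

PSM tables are generated by expanding each count into individual rows, so
the unfiltered (protein, sample) tally reproduces the matrix exactly. Each
protein carries a repertoire of 8 random peptides (lengths 4–30 over the 20
amino acids — no real proteome is needed); charges are drawn from {1, 2, 3};
peptide probabilities are high (0.8 + 0.2·Beta(5,1), mode near 1) except
for a `noise_fraction` (default 10%) drawn uniformly below 0.8. Lengths,
charges and probabilities straddle every filter boundary, so filtering is
genuinely exercised — filtered counts are a thinned version of the matrix.

What the generator does **not** emulate: shared peptides between proteins,
correlated contaminant structure (beyond the optional equal-mean "sticky"
class), run-order or batch effects, and intensity-dependent identification
probability. Passing tests therefore demonstrate correctness of the
decision arithmetic and calibration under the stated model, not performance
on any particular real dataset.

## Species disambiguation

Global Needleman–Wunsch alignment (match +1, mismatch −1, linear gap −2)
with deterministic tie-breaking (diagonal > gap-in-B > gap-in-A); the fill
is JIT-compiled so full-length neurofibromin-sized pairs (~2800 residues)
align in well under a second. Discriminating sites are all alignment
columns whose residues differ; indel columns count, with a gap marker on
the gapped side; coordinates are 1-based in ungapped protein space (the
"T2489" convention). Peptide assignment is exact substring matching — a
species call rests on exact residue identity, so no error tolerance is
appropriate — and I/L are collapsed by default since they are isobaric and
indistinguishable by conventional MS/MS. A peptide matching only one
sequence is species-specific, both ambiguous, neither unmatched; by
construction a species-specific match must cover at least one
discriminating site.

## Case-overlap arithmetic

Percent = 100 × overlap/total, rounded half-away-from-zero to one decimal
using exact decimal arithmetic (no binary-float boundary surprises). Case
counts are consumed as a user-supplied table because portal counts drift
between data releases; the shipped `data/table1_overlaps.tsv` is a frozen
snapshot of published per-gene fractions used for reference and testing.
One published gene row prints no fraction and is omitted rather than
imputed.

## Numerical and design notes

- All randomness flows from a single integer seed; matrix and PSM-attribute
  streams are independent `SeedSequence` children so a PSM table's matrix is
  bit-identical to the directly simulated one.
- Degenerate inputs: empty PSM tables and empty matrices propagate as empty
  outputs; an FDR on an empty protein list is an error (undefined), not 0.
- The end-to-end regression test freezes the default-seed hit list
  byte-for-byte; problem sizes throughout (500 oracle matrices, 2000 null
  proteins, 100 normalization matrices, 2800-residue ortholog pair with
  exhaustive 8-mer scan) were chosen to give stable statistics while the
  whole suite runs in well under a minute.
- The pipeline itself is deterministic given its inputs; the seed recorded
  in run reports documents the generator provenance of synthetic inputs.
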