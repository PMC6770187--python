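"""Evidence filters, protein grouping, spectral counting and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from preycall import (
    CountMatrix,
    FilterThresholds,
    SimulationConfig,
    compute_spectral_counts,
    estimate_fdr,
    filter_psms,
    group_to_proteins,
    normalize_counts,
    simulate_psm_table,
)
from preycall.errors import ParameterError, PsmValidationError, UndefinedEstimateError
from preycall.simulate import PSM_COLUMNS


def psm_row(seq="PEPTIDE", charge=2, pep_prob=0.95, acc="P1", prot_prob=0.999, sample="WT1"):
    return (seq, charge, pep_prob, acc, prot_prob, sample)


def psm_frame(rows):
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


class TestFilterPsms:
    @pytest.mark.parametrize(
        "row, kept",
        [
            (psm_row(seq="PEPTI"), False),  # length 5: boundary, strict >5
            (psm_row(seq="PEPTID"), True),  # length 6 passes
            (psm_row(charge=1), False),  # MH+1 excluded
            (psm_row(charge=3), True),
            (psm_row(pep_prob=0.80), False),  # boundary, strict >0.80
            (psm_row(pep_prob=0.81), True),
        ],
    )
    def test_boundaries(self, row, kept):
        out = filter_psms(psm_frame([row]))
        assert len(out) == (1 if kept else 0)

    def test_empty_input(self):
        assert filter_psms(psm_frame([])).empty

    def test_order_preserved(self):
        rows = [psm_row(seq=f"PEPTID{aa}") for aa in "ACDEFG"]
        out = filter_psms(psm_frame(rows))
        assert list(out["peptide_sequence"]) == [r[0] for r in rows]

    def test_malformed_sequence_reports_row(self):
        frame = psm_frame([psm_row(), psm_row(seq="PEPT1DE")])
        with pytest.raises(PsmValidationError, match="row 1"):
            filter_psms(frame)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(PsmValidationError):
            filter_psms(psm_frame([psm_row(pep_prob=1.2)]))


class TestGroupToProteins:
    def test_one_distinct_peptide_in_many_psms_rejected(self):
        rows = [psm_row(seq="PEPTIDE", sample=f"WT{i%4+1}") for i in range(10)]
        assert group_to_proteins(psm_frame(rows)).empty

    def test_two_distinct_peptides_high_probability_retained(self):
        rows = [psm_row(seq="PEPTIDEA", prot_prob=0.995), psm_row(seq="PEPTIDEG", prot_prob=0.995)]
        out = group_to_proteins(psm_frame(rows))
        assert list(out["protein_accession"]) == ["P1"]
        assert out["n_distinct_peptides"].iloc[0] == 2

    def test_protein_probability_boundary_strict(self):
        rows = [psm_row(seq="PEPTIDEA", prot_prob=0.99), psm_row(seq="PEPTIDEG", prot_prob=0.99)]
        assert group_to_proteins(psm_frame(rows)).empty

    def test_distinct_peptides_pooled_across_samples(self):
        rows = [
            psm_row(seq="PEPTIDEA", sample="WT1"),
            psm_row(seq="PEPTIDEG", sample="EV1"),
        ]
        assert len(group_to_proteins(psm_frame(rows))) == 1

    def test_conflicting_protein_probability_raises(self):
        rows = [psm_row(prot_prob=0.999), psm_row(seq="PEPTIDEG", prot_prob=0.991)]
        with pytest.raises(PsmValidationError, match="conflicting"):
            group_to_proteins(psm_frame(rows))

    def test_empty_input(self):
        assert group_to_proteins(psm_frame([])).empty


class TestEstimateFdr:
    def proteins(self, probs):
        return pd.DataFrame(
            {
                "protein_accession": [f"P{i}" for i in range(len(probs))],
                "n_distinct_peptides": 2,
                "protein_probability": probs,
            }
        )

    def test_perfect_identifications(self):
        assert estimate_fdr(self.proteins([1.0, 1.0])) == 0.0

    def test_hand_arithmetic(self):
        assert estimate_fdr(self.proteins([0.99, 0.995])) == pytest.approx(0.0075)

    def test_boundary_fails_strict_check(self):
        fdr = estimate_fdr(self.proteins([0.99, 0.99, 0.99]))
        assert fdr == pytest.approx(0.01)
        assert not fdr < FilterThresholds().max_fdr

    def test_empty_table_is_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            estimate_fdr(self.proteins([]))


class TestSpectralCounts:
    GROUPS = {"s1": "WT", "s2": "EV"}

    def test_tally_definition(self):
        rows = [psm_row(sample="s1")] * 3 + [psm_row(sample="s2")]
        m = compute_spectral_counts(psm_frame(rows), self.GROUPS)
        assert m.counts.at["P1", "s1"] == 3
        assert m.counts.at["P1", "s2"] == 1
        assert not m.normalized

    def test_absent_sample_is_zero(self):
        m = compute_spectral_counts(psm_frame([psm_row(sample="s1")]), self.GROUPS)
        assert m.counts.at["P1", "s2"] == 0

    def test_unmapped_sample_raises(self):
        with pytest.raises(ParameterError, match="group_map"):
            compute_spectral_counts(psm_frame([psm_row(sample="s9")]), self.GROUPS)

    def test_brute_force_tally_on_simulated_table(self):
        config = SimulationConfig(n_background=10, n_true=3, seed=21)
        psms, _, _ = simulate_psm_table(config)
        m = compute_spectral_counts(psms, config.group_map())
        for protein in m.proteins:
            for sample in m.samples:
                expected = sum(
                    1
                    for r in psms.itertuples()
                    if r.protein_accession == protein and r.sample_id == sample
                )
                assert m.counts.at[protein, sample] == expected


def matrix_from(data, samples=("s1", "s2"), groups=None):
    groups = groups or {s: ("WT" if i % 2 == 0 else "EV") for i, s in enumerate(samples)}
    return CountMatrix(
        counts=pd.DataFrame(data, columns=list(samples)), groups=groups, normalized=False
    )


class TestNormalize:
    def test_hand_example_totals_100_200(self):
        m = matrix_from({"s1": [40, 60], "s2": [120, 80]})
        out = normalize_counts(m)
        assert out.normalized
        np.testing.assert_allclose(out.counts["s1"], [60.0, 90.0])  # scale 1.5
        np.testing.assert_allclose(out.counts["s2"], [90.0, 60.0])  # scale 0.75
        np.testing.assert_allclose(out.counts.sum(axis=0), [150.0, 150.0])

    def test_equal_totals_unchanged(self):
        m = matrix_from({"s1": [10, 20], "s2": [15, 15]})
        out = normalize_counts(m)
        np.testing.assert_allclose(out.counts.to_numpy(), m.counts.to_numpy())

    def test_single_sample_unchanged(self):
        m = CountMatrix(
            counts=pd.DataFrame({"s1": [3, 4]}), groups={"s1": "WT"}, normalized=False
        )
        out = normalize_counts(m)
        np.testing.assert_allclose(out.counts["s1"], [3.0, 4.0])

    def test_zero_total_sample_left_unscaled(self, caplog):
        m = matrix_from({"s1": [10, 10], "s2": [0, 0]})
        with caplog.at_level("WARNING"):
            out = normalize_counts(m)
        assert "zero total" in caplog.text
        np.testing.assert_allclose(out.counts["s2"], [0.0, 0.0])

    def test_conservation_and_idempotence_random(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n_p, n_s = rng.integers(1, 15), rng.integers(2, 9)
            counts = pd.DataFrame(
                rng.integers(1, 40, size=(n_p, n_s)),
                columns=[f"s{j}" for j in range(n_s)],
            )
            m = CountMatrix(
                counts=counts,
                groups={f"s{j}": ("WT" if j % 2 else "EV") for j in range(n_s)},
            )
            once = normalize_counts(m)
            assert once.counts.to_numpy().sum() == pytest.approx(
                m.counts.to_numpy().sum(), rel=1e-9
            )
            twice = normalize_counts(once)
            np.testing.assert_allclose(
                twice.counts.to_numpy(), once.counts.to_numpy(), rtol=1e-9
            )


@given(
    min_len=st.integers(4, 8),
    min_prob=st.floats(0.5, 0.95),
    seed=st.integers(0, 50),
)
def test_filter_monotonicity(min_len, min_prob, seed):
    """Raising any threshold never increases the number of retained PSMs."""
    config = SimulationConfig(n_background=6, n_true=2, seed=seed)
    psms, _, _ = simulate_psm_table(config)
    base = FilterThresholds(
        min_peptide_length_exclusive=min_len, min_peptide_probability=min_prob
    )
    n_base = len(filter_psms(psms, base))
    for stricter in (
        FilterThresholds(min_peptide_length_exclusive=min_len + 1, min_peptide_probability=min_prob),
        FilterThresholds(min_peptide_length_exclusive=min_len, min_peptide_probability=min(min_prob + 0.03, 1.0)),
    ):
        assert len(filter_psms(psms, stricter)) <= n_base


def test_composition_equals_naive_single_pass():
    """filter -> group -> count equals one naive pass over random PSM tables."""
    thresholds = FilterThresholds()
    for seed in range(100):
        config = SimulationConfig(n_background=4, n_true=2, noise_fraction=0.3, seed=seed)
        psms, _, _ = simulate_psm_table(config)
        kept = filter_psms(psms, thresholds)
        proteins = group_to_proteins(kept, thresholds)
        kept = kept[kept["protein_accession"].isin(proteins["protein_accession"])]
        m = compute_spectral_counts(kept, config.group_map())

        # naive single pass
        good = [
            r
            for r in psms.itertuples()
            if len(r.peptide_sequence) > 5 and r.charge != 1 and r.peptide_probability > 0.80
        ]
        per_protein: dict[str, set] = {}
        prob: dict[str, float] = {}
        for r in good:
            per_protein.setdefault(r.protein_accession, set()).add(r.peptide_sequence)
            prob[r.protein_accession] = r.protein_probability
        retained = {p for p, peps in per_protein.items() if len(peps) >= 2 and prob[p] > 0.99}
        assert set(m.proteins) == retained
        naive_tally: dict[tuple, int] = {}
        for r in good:
            if r.protein_accession in retained:
                k = (r.protein_accession, r.sample_id)
                naive_tally[k] = naive_tally.get(k, 0) + 1
        for protein in m.proteins:
            for sample in m.samples:
                assert m.counts.at[protein, sample] == naive_tally.get((protein, sample), 0)
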