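import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy import stats as sps

from preycall import CountMatrix, SimulationConfig, simulate_count_matrix
from preycall.filtering import normalize_counts

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    return SimulationConfig(n_background=30, n_true=6, seed=11)


@pytest.fixture
def recovery_config():
    """The frozen parameter-recovery scenario: 200 background + 20 true
    interactors (half exclusive), 8-fold enrichment, 4 vs 4 replicates."""
    return SimulationConfig(
        n_background=200,
        n_true=20,
        enrichment=8.0,
        exclusive_fraction=0.5,
        seed=7,
    )


def random_count_matrix(rng: np.random.Generator, n_proteins: int = 12) -> CountMatrix:
    """A small random 4-vs-4 raw matrix with edge-case rows mixed in:
    all-zero EV rows (rescue / undefined fold change), constant rows
    (zero-variance guards), and ordinary noisy rows."""
    samples = ["WT1", "WT2", "WT3", "WT4", "EV1", "EV2", "EV3", "EV4"]
    rows = []
    for i in range(n_proteins):
        kind = rng.integers(4)
        if kind == 0:  # EV-absent
            row = np.concatenate([rng.integers(0, 10, 4), np.zeros(4, dtype=int)])
        elif kind == 1:  # constant in both groups
            row = np.repeat(rng.integers(0, 8, 2), 4)
        else:
            row = rng.integers(0, 20, 8)
        rows.append(row)
    counts = pd.DataFrame(
        np.array(rows),
        index=[f"P{i:03d}" for i in range(n_proteins)],
        columns=samples,
    )
    groups = {s: ("WT" if s.startswith("WT") else "EV") for s in samples}
    return CountMatrix(counts=counts, groups=groups, normalized=False)


def naive_call(raw: CountMatrix) -> dict[str, str]:
    """Independent straight-line reimplementation of the decision rule,
    used as the verdict oracle. Deliberately written with plain loops and
    scipy's t-test, sharing no code with preycall.calling."""
    nsc = normalize_counts(raw)
    wt_cols = [s for s in raw.samples if raw.groups[s] == "WT"]
    ev_cols = [s for s in raw.samples if raw.groups[s] == "EV"]
    verdicts = {}
    for protein in raw.proteins:
        wt = nsc.counts.loc[protein, wt_cols].to_numpy(float)
        ev = nsc.counts.loc[protein, ev_cols].to_numpy(float)
        mu1, mu2 = wt.mean(), ev.mean()
        d1, d2 = wt.std(ddof=1), ev.std(ddof=1)
        denom = d1 - d2
        if abs(denom) < 1e-12:
            w = 0.0 if abs(mu1 - mu2) < 1e-12 else math.copysign(math.inf, mu1 - mu2)
        else:
            w = (mu1 - mu2) / denom
        if wt.var(ddof=1) == 0 and ev.var(ddof=1) == 0:
            p = None
        else:
            p = sps.ttest_ind(wt, ev, equal_var=False, alternative="greater").pvalue
        fc = mu1 / mu2 if mu2 > 0 else None
        stat = (
            abs(w) > 0.6
            and p is not None
            and p < 0.1
            and fc is not None
            and fc >= 2.0
        )
        wt_raw = raw.counts.loc[protein, wt_cols].to_numpy()
        ev_raw = raw.counts.loc[protein, ev_cols].to_numpy()
        rescue = bool((ev_raw == 0).all() and wt_raw.sum() >= 4)
        verdicts[protein] = "hit" if (stat or rescue) else "non_hit"
    return verdicts


@pytest.fixture
def make_random_matrix():
    return random_count_matrix


@pytest.fixture
def naive_caller():
    return naive_call


def simulated_recovery(config: SimulationConfig):
    """Run the calling pipeline on a simulated matrix; return (sensitivity,
    false-discovery proportion, n_hits)."""
    from preycall import call_interactors

    matrix, truth = simulate_count_matrix(config)
    records = call_interactors(matrix, normalize_counts(matrix))
    hits = {r.protein for r in records if r.verdict == "hit"}
    true = set(truth[truth != "background"].index)
    sensitivity = len(hits & true) / len(true) if true else float("nan")
    fdp = len(hits - true) / max(len(hits), 1)
    return sensitivity, fdp, len(hits)
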