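import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from apmsnet.io_formats import CONTROL_ID, PulldownMatrix
from apmsnet.synthetic_data import generate, study_design


def make_matrix(entries):
    """Build a PulldownMatrix from {(protein, bait, rep, frac): value}."""
    return PulldownMatrix(dict(entries))


@pytest.fixture
def simple_matrix():
    """One bait, 3 replicates, 2 fractions, plus a 3-replicate control.

    Bait protein 'B' is strong in every replicate; prey 'Y' is present in
    all three; 'Z' only in two; sticky 'S' matches the control exactly.
    """
    entries = {}
    for rep in (1, 2, 3):
        entries[("B", "B", rep, 1)] = 4.0
        entries[("B", "B", rep, 2)] = 1.0
        entries[("Y", "B", rep, 1)] = 2.0
        entries[("S", "B", rep, 1)] = 1.0
        entries[("S", CONTROL_ID, rep, 1)] = 1.0
    entries[("Z", "B", 1, 2)] = 3.0
    entries[("Z", "B", 2, 2)] = 3.0
    return PulldownMatrix(entries)


@pytest.fixture(scope="session")
def study_dataset():
    """Default study-scale synthetic dataset (noisy), fixed seed."""
    return generate(study_design(), np.random.default_rng(20240901))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Study-scale dataset in the noiseless limit with no sticky background."""
    cfg = study_design()
    cfg.noise_sigma = 0.0
    cfg.dropout = 0.0
    cfg.sticky_set = ()
    return generate(cfg, np.random.default_rng(11))


def random_matrix(rng, n_proteins=12, baits=("A", "B"), n_reps=3, n_fracs=4,
                  density=0.5, with_control=True):
    """Random sparse pull-down matrix for property tests."""
    proteins = [f"P{i}" for i in range(n_proteins)]
    runs = list(baits) + ([CONTROL_ID] if with_control else [])
    entries = {}
    for run in runs:
        for rep in range(1, n_reps + 1):
            for frac in range(1, n_fracs + 1):
                for p in proteins:
                    if rng.random() < density:
                        entries[(p, run, rep, frac)] = float(rng.uniform(0.05, 5.0))
    return PulldownMatrix(entries)
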