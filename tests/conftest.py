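"""Shared fixtures: small deterministic matrices and a session-scoped
study-scale synthetic cohort reused by the heavier analyses."""

import numpy as np
import pytest

import admixscope as ax
from admixscope.genotype_io import make_genotype_matrix


@pytest.fixture()
def small_gm():
    """12 samples x 20 SNPs over two chromosomes, with missing calls."""
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.05] = -1
    return make_genotype_matrix(
        calls, [f"rs{j:03d}" for j in range(20)],
        ["1"] * 10 + ["2"] * 10, list(range(100_000, 1_100_000, 100_000)) * 2,
        [f"S{i:02d}" for i in range(12)],
        populations=["CR"] * 6 + ["CEU"] * 6)


class StudyCohort:
    """Study-scale synthetic data bundle (built once per session)."""

    def __init__(self):
        self.freqs = ax.simulate_ancestral_freqs(
            2663, 3, 0.15, seed=101, populations=("CEU", "NA", "YRI"))
        self.design = ax.guanacaste_design(n=1245)
        self.cohort, self.truth = ax.simulate_cohort(
            self.design, self.freqs, seed=102)
        self.aim = ax.plant_aim(self.cohort, self.freqs, self.truth,
                                ancestry_index=0, seed=103)
        self.panels = ax.simulate_reference_panels(
            self.freqs, {"CEU": 60, "YRI": 59, "NA": 56}, seed=104)
        self.supervised = ax.supervised_admixture(self.cohort, self.freqs)
        self.labels, self.threshold, self.label_flags = \
            ax.assign_subpopulations(self.supervised.Q, 0)


@pytest.fixture(scope="session")
def study():
    return StudyCohort()
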