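"""Shared fixtures: published table counts and a small simulated study.

The count fixtures transcribe the genotype/allele/characteristics counts
of the motivating NR3C1 candidate-gene study, which are the desk-scale
substrate of the per-SNP statistics.
"""

import numpy as np
import pytest

import arhiscore as a

# Full-cohort genotype counts (hom-major, het, hom-minor): the HWE table.
HWE_COUNTS = {
    "rs6191": (0, 80, 780),
    "rs61757411": (494, 321, 45),
    "rs41400245": (685, 166, 10),
    "rs258751": (771, 88, 0),
    "rs6196": (769, 89, 1),
    "rs41423247": (551, 271, 35),
    "rs6877893": (523, 292, 44),
    "rs12655166": (658, 189, 11),
    "rs33388": (525, 288, 47),
}

# Case/control genotype counts (hom-major, het, hom-minor).
GENOTYPE_COUNTS = {
    "rs6191": {"case": (590, 68, 0), "control": (190, 12, 0)},
    "rs6877893": {"case": (408, 218, 31), "control": (115, 74, 13)},
    "rs33388": {"case": (411, 213, 34), "control": (114, 75, 13)},
}

# Case/control allele counts (major, minor).
ALLELE_COUNTS = {
    "rs41423247": {"case": (1074, 430), "control": (315, 87)},
    "rs6877893": {"case": (1034, 498), "control": (304, 100)},
}

# Characteristics-table counts: (control, case) per level.
SMOKING_COUNTS = {"no": (156, 416), "yes": (46, 243)}
SEX_COUNTS = {"male": (55, 290), "female": (147, 369)}


@pytest.fixture(scope="session")
def paper_study():
    """One paper-like simulated study (861 subjects, 9 SNPs, effects on)."""
    return a.simulate_study(a.paper_like_spec(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A quick 200-subject study for I/O and pipeline smoke tests."""
    return a.simulate_study(a.paper_like_spec(seed=5, n_subjects=200))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
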