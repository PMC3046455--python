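"""Shared fixtures: tiny catalogs and simulated cohorts.

All cohorts are generated at test time by the package's own simulator;
nothing is read from disk.
"""

import pytest
from hypothesis import settings

from gxescan.catalog import SnpCatalog, SnpDef

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")
from gxescan.simulate import SimConfig, StudyArm, sample_case_control


@pytest.fixture(scope="session")
def lsp1():
    return SnpDef("11p15-rs3817198", ("T", "C"), "C", 0.31, "LSP1", 1.08)


@pytest.fixture(scope="session")
def fgfr2():
    return SnpDef("10q26-rs2981582", ("C", "T"), "T", 0.38, "FGFR2", 1.22)


@pytest.fixture(scope="session")
def two_snp_catalog(lsp1, fgfr2):
    return SnpCatalog([fgfr2, lsp1])


@pytest.fixture(scope="session")
def null_config(two_snp_catalog):
    """Two studies, modest main effects, no interactions."""
    return SimConfig(
        studies=(StudyArm("STA", 800, 900), StudyArm("STB", 700, 800)),
        catalog=two_snp_catalog,
        main_effect_ors={"menarche": 0.96, "ever_birth": 0.84,
                         "n_births": 0.89},
    )


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return sample_case_control(null_config, seed=20260924)


@pytest.fixture(scope="session")
def messy_cohort(two_snp_catalog):
    """Cohort with realistic missingness for subset-rule tests."""
    config = SimConfig(
        studies=(StudyArm("STA", 600, 700), StudyArm("STB", 500, 600)),
        catalog=two_snp_catalog,
        missingness={"menarche_age": 0.2, "parous": 0.1, "n_live_births": 0.1,
                     "age_first_birth": 0.25, "bmi": 0.3, "dosage": 0.12},
    )
    return sample_case_control(config, seed=7)
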