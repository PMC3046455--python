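"""Generator correctness: Hardy-Weinberg draws, the generative logistic
model, case-control composition, determinism and structural invariants."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from gxescan.catalog import SnpCatalog, SnpDef
from gxescan.cohort import write_cohort
from gxescan.errors import ConfigError
from gxescan.simulate import (SimConfig, StudyArm, disease_logit,
                              draw_genotypes, sample_case_control,
                              study_intercepts)


class TestDrawGenotypes:
    def test_hwe_proportions_large_n(self):
        q = 0.38
        rng = np.random.default_rng(1)
        d = draw_genotypes(q, 100_000, rng)
        # mean dosage is Binomial(2, q)/draw: SE = sqrt(2q(1-q)/n)
        se = math.sqrt(2 * q * (1 - q) / 100_000)
        assert abs(d.mean() - 2 * q) < 3 * se
        props = np.bincount(d, minlength=3) / d.size
        expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        assert np.allclose(props, expected, atol=0.01)

    def test_boundary_frequencies(self):
        rng = np.random.default_rng(0)
        assert (draw_genotypes(0.0, 100, rng) == 0).all()
        assert (draw_genotypes(1.0, 100, rng) == 2).all()

    def test_invalid_frequency(self):
        with pytest.raises(ConfigError):
            draw_genotypes(1.2, 10, np.random.default_rng(0))


def _one_row(rsid, dosage, n_births=0, parous=0):
    return pd.DataFrame({
        "study": ["S1"], "is_case": [0], "age": [50], "menarche_age": [13],
        "parous": [parous], "n_live_births": [n_births or np.nan],
        "age_first_birth": [25 if parous else np.nan], "bmi": [25.0],
        "er": [None], "pr": [None], rsid: [dosage],
    })


class TestDiseaseLogit:
    def _config(self, snp_or=1.0, interaction=None, main=None):
        snp = SnpDef("10q26-rs2981582", ("C", "T"), "T", 0.38,
                     per_allele_or=snp_or)
        return SimConfig(
            studies=(StudyArm("S1", 10, 10),),
            catalog=SnpCatalog([snp]),
            main_effect_ors=main or {},
            interaction_ors=interaction or {},
        )

    def test_null_model_is_study_intercept(self):
        cfg = self._config()
        eta = disease_logit(_one_row("rs2981582", 2), cfg, {"S1": -1.7})
        assert eta[0] == pytest.approx(-1.7)

    def test_per_allele_main_effect(self):
        cfg = self._config(snp_or=1.22)
        eta = disease_logit(_one_row("rs2981582", 2), cfg, {"S1": -1.7})
        assert eta[0] == pytest.approx(-1.7 + 2 * math.log(1.22))

    def test_interaction_term_arithmetic(self):
        cfg = self._config(
            interaction={("10q26-rs2981582", "n_births"): 1.05})
        row = _one_row("rs2981582", 1, n_births=3, parous=1)
        eta = disease_logit(row, cfg, {"S1": -1.7})
        assert eta[0] == pytest.approx(-1.7 + 3 * math.log(1.05))

    def test_unknown_study_is_config_error(self):
        cfg = self._config()
        with pytest.raises(ConfigError):
            disease_logit(_one_row("rs2981582", 0), cfg, {"OTHER": 0.0})

    def test_multiplicative_joint_effect_without_interaction(self):
        """With OR_ge = 1 the joint OR factorises as OR_g^d * OR_e^e."""
        cfg = self._config(snp_or=1.2, main={"n_births": 0.9})
        base = disease_logit(_one_row("rs2981582", 0, 0, parous=1)
                             .assign(n_live_births=1), cfg, {"S1": 0.0})
        both = disease_logit(_one_row("rs2981582", 2, 0, parous=1)
                             .assign(n_live_births=4), cfg, {"S1": 0.0})
        assert both[0] - base[0] == pytest.approx(
            2 * math.log(1.2) + 3 * math.log(0.9))


class TestSampleCaseControl:
    def test_exact_composition(self, two_snp_catalog):
        cfg = SimConfig(
            studies=tuple(StudyArm(f"S{i}", 100, 150) for i in range(3)),
            catalog=two_snp_catalog)
        cohort = sample_case_control(cfg, seed=11)
        assert len(cohort) == 750
        by = cohort.groupby("study")["is_case"].agg(["sum", "count"])
        assert (by["sum"] == 100).all() and (by["count"] == 250).all()

    def test_same_seed_byte_identical_tsv(self, null_config):
        bufs = []
        for _ in range(2):
            cohort = sample_case_control(null_config, seed=123)
            buf = io.StringIO()
            write_cohort(cohort, buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_different_seed_differs(self, null_config):
        a = sample_case_control(null_config, seed=1)
        b = sample_case_control(null_config, seed=2)
        assert not a.equals(b)

    def test_structural_parity_invariants(self, null_cohort):
        nulli = null_cohort["parous"] == 0
        assert null_cohort.loc[nulli, "n_live_births"].isna().all()
        assert null_cohort.loc[nulli, "age_first_birth"].isna().all()
        parous = null_cohort["parous"] == 1
        afb = null_cohort.loc[parous, "age_first_birth"]
        assert (afb < null_cohort.loc[parous, "age"]).all()
        assert (null_cohort.loc[parous, "n_live_births"] >= 1).all()

    def test_er_pr_assigned_to_cases_only(self, null_cohort):
        cases = null_cohort["is_case"] == 1
        assert null_cohort.loc[cases, "er"].isin(["positive", "negative"]).all()
        assert null_cohort.loc[~cases, "er"].isna().all()
        frac_pos = (null_cohort.loc[cases, "er"] == "positive").mean()
        assert 0.65 < frac_pos < 0.85

    def test_adding_a_study_preserves_existing_draws(self, two_snp_catalog):
        cfg2 = SimConfig(studies=(StudyArm("STA", 200, 200),
                                  StudyArm("STB", 200, 200)),
                         catalog=two_snp_catalog)
        cfg3 = SimConfig(studies=(StudyArm("STA", 200, 200),
                                  StudyArm("STB", 200, 200),
                                  StudyArm("STC", 200, 200)),
                         catalog=two_snp_catalog)
        a = sample_case_control(cfg2, seed=5)
        b = sample_case_control(cfg3, seed=5)
        pd.testing.assert_frame_equal(a, b.iloc[:len(a)].reset_index(drop=True))

    def test_interaction_or_leaves_control_genotypes_unchanged(
            self, two_snp_catalog, lsp1):
        """Changing only OR_ge barely moves the control dosage margin."""
        base = SimConfig(studies=(StudyArm("STA", 500, 2000),),
                         catalog=two_snp_catalog)
        alt = SimConfig(studies=(StudyArm("STA", 500, 2000),),
                        catalog=two_snp_catalog,
                        interaction_ors={(lsp1.name, "n_births"): 1.05})
        a = sample_case_control(base, seed=3)
        b = sample_case_control(alt, seed=3)
        ma = a.loc[a.is_case == 0, lsp1.rsid].astype(float).mean()
        mb = b.loc[b.is_case == 0, lsp1.rsid].astype(float).mean()
        se = math.sqrt(2 * 0.31 * 0.69 / 2000)
        assert abs(ma - mb) < 3 * se

    def test_calibrated_prevalence_in_band(self, null_config):
        for label, c in study_intercepts(null_config, seed=9).items():
            assert -5.0 < c < 0.0  # prevalence target 0.125 => negative logit
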