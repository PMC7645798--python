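"""Synthetic cohort generator: design constants, binomial sampling, planted effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mechstrat as ms
from mechstrat.simulate import ConfigurationError, cyclic_signature


class TestConfig:
    def test_default_design_constants(self):
        cfg = ms.SyntheticConfig()
        assert cfg.n_discovery == 844
        assert cfg.n_snps == 148
        assert cfg.n_mechanisms == 15
        assert cfg.n_validation == 561
        assert cfg.k_true == 4

    def test_cyclic_signature_is_mechanism_mixture(self):
        sig = cyclic_signature(4, 15)
        assert sig.shape == (4, 15)
        assert (sig.sum(axis=0) == 1).all()  # each mechanism burdened once
        assert (sig.sum(axis=1) >= 3).all()  # each cluster mixes >= 3 mechanisms
        assert list(np.where(sig[0])[0]) == [0, 4, 8, 12]

    @pytest.mark.parametrize(
        "bad",
        [
            dict(cluster_proportions=(0.5, 0.5, 0.5, 0.5)),
            dict(effect_delta=0.7),  # 0.35 + 0.7 > 1
            dict(effect_delta=-0.1),
            dict(group_sizes=(0, 148)),
            dict(maf_range=(0.0, 0.3)),
            dict(snp_ids=("a", "b")),
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            ms.SyntheticConfig(**bad)


class TestGenerateCohort:
    def test_default_shapes(self, small_cohort):
        cfg = ms.SyntheticConfig()
        coh = ms.generate_cohort(cfg)
        assert coh.genotypes.dosages.shape == (844, 148)
        assert coh.config.n_mechanisms == 15
        vals = coh.genotypes.values()
        assert np.isin(vals, (0.0, 1.0, 2.0)).all()

    def test_determinism(self):
        cfg = ms.SyntheticConfig(n_patients_ad=30, n_patients_pd=20, seed=3)
        a = ms.generate_cohort(cfg)
        b = ms.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
        pd.testing.assert_series_equal(a.true_labels, b.true_labels)

    def test_zero_delta_no_cluster_signal(self):
        cfg = ms.SyntheticConfig(effect_delta=0.0, seed=4)
        coh = ms.generate_cohort(cfg)
        X = coh.genotypes.values()
        lab = coh.true_labels.to_numpy()
        mech_of = cfg.mechanism_of_snp
        for j in range(cfg.n_snps):
            burden_cluster = int(np.argmax(cfg.signature[:, mech_of[j]]))
            a = X[lab == burden_cluster, j]
            b = X[lab != burden_cluster, j]
            se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
            assert abs(a.mean() - b.mean()) <= 4 * se

    def test_binomial_allele_frequency(self):
        # one SNP, MAF fixed by a degenerate range, n = 10,000, no effect
        cfg = ms.SyntheticConfig(
            n_patients_ad=5000, n_patients_pd=5000, k_true=2,
            group_sizes=(1,), maf_range=(0.3, 0.3), effect_delta=0.0, seed=5,
        )
        coh = ms.generate_cohort(cfg)
        freq = coh.genotypes.values().mean() / 2.0
        n = 10_000
        assert abs(freq - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / (2 * n))

    def test_planted_mean_dosage_shift(self):
        cfg = ms.SyntheticConfig(seed=6)
        coh = ms.generate_cohort(cfg)
        X = coh.genotypes.values()
        lab = coh.true_labels.to_numpy()
        mech_of = cfg.mechanism_of_snp
        # pooled over all SNPs of mechanism 0 (burdened by cluster 0)
        snps = np.where(mech_of == 0)[0]
        a = X[np.ix_(lab == 0, snps)].ravel()
        b = X[np.ix_(lab != 0, snps)].ravel()
        diff = a.mean() - b.mean()
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        assert abs(diff - 2 * cfg.effect_delta) <= 3 * se

    def test_confounders_independent_of_cluster(self):
        # chi-square p-values for sex x cluster should look uniform over seeds
        pvals = []
        for seed in range(20):
            cfg = ms.SyntheticConfig(n_patients_ad=150, n_patients_pd=150, seed=seed)
            coh = ms.generate_cohort(cfg)
            tab = pd.crosstab(coh.covariates["sex"], coh.true_labels)
            pvals.append(sps.chi2_contingency(tab)[1])
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3

    def test_missingness_fraction(self):
        cfg = ms.SyntheticConfig(
            n_patients_ad=200, n_patients_pd=200, missing_fraction=0.1, seed=7
        )
        coh = ms.generate_cohort(cfg)
        frac = coh.genotypes.dosages.isna().to_numpy().mean()
        assert abs(frac - 0.1) < 0.01


class TestValidationCohort:
    def test_default_size(self):
        coh = ms.generate_validation_cohort(ms.SyntheticConfig())
        assert coh.genotypes.dosages.shape == (561, 148)

    def test_empty_cohort_valid(self):
        cfg = ms.SyntheticConfig(n_validation=0, n_patients_ad=10, n_patients_pd=10)
        coh = ms.generate_validation_cohort(cfg)
        assert coh.n_patients == 0

    def test_same_seed_identical(self):
        cfg = ms.SyntheticConfig(n_validation=50, seed=8)
        a = ms.generate_validation_cohort(cfg)
        b = ms.generate_validation_cohort(cfg)
        pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)

    def test_independent_of_discovery_stream(self):
        cfg = ms.SyntheticConfig(n_validation=561, seed=9)
        disc = ms.generate_cohort(cfg)
        val = ms.generate_validation_cohort(cfg)
        assert not np.array_equal(
            disc.genotypes.values()[:561], val.genotypes.values()
        )


class TestLongitudinal:
    def test_noiseless_construction_exact(self):
        outcomes = {
            "y": ms.simulate.OutcomeSpec(
                cluster_means=(0.0, 0.0), sd=0.0, slopes=(0.0, 1.0),
                random_intercept_sd=0.0, age_coef=0.0, sex_coef=0.0,
            )
        }
        cfg = ms.SyntheticConfig(
            n_patients_ad=20, n_patients_pd=20, k_true=2, outcomes=outcomes,
            n_visits=3, seed=10,
        )
        coh = ms.generate_cohort(cfg)
        tab = ms.generate_longitudinal(coh, cfg)
        wide = tab.pivot(index="patient_id", columns="visit", values="y")
        diffs = wide.diff(axis=1).iloc[:, 1:]
        lab = coh.true_labels.reindex(wide.index)
        assert np.allclose(diffs[lab == 0], 0.0)
        assert np.allclose(diffs[lab == 1], 1.0)

    def test_equal_slopes_no_difference(self):
        outcomes = {
            "y": ms.simulate.OutcomeSpec(
                cluster_means=(0.0, 0.0), sd=0.5, slopes=(0.3, 0.3),
                random_intercept_sd=0.2, age_coef=0.0, sex_coef=0.0,
            )
        }
        cfg = ms.SyntheticConfig(
            n_patients_ad=300, n_patients_pd=300, k_true=2, outcomes=outcomes,
            n_visits=4, seed=11,
        )
        coh = ms.generate_cohort(cfg)
        tab = ms.generate_longitudinal(coh, cfg)
        # OLS slope per cluster as the oracle
        lab = coh.true_labels
        slopes, ses = [], []
        for c in (0, 1):
            sub = tab[lab.reindex(tab["patient_id"]).to_numpy() == c]
            res = sps.linregress(sub["visit"], sub["y"])
            slopes.append(res.slope)
            ses.append(res.stderr)
        diff_se = np.hypot(*ses)
        assert abs(slopes[0] - slopes[1]) <= 3 * diff_se

    def test_row_count_and_visits(self, small_cohort, small_config):
        tab = ms.generate_longitudinal(small_cohort, small_config)
        assert len(tab) == small_cohort.n_patients * small_config.n_visits
        assert sorted(tab["visit"].unique()) == list(range(small_config.n_visits))

    def test_too_few_visits_rejected(self, small_cohort):
        cfg = ms.SyntheticConfig(n_visits=1)
        with pytest.raises(ConfigurationError):
            ms.generate_longitudinal(small_cohort, cfg)
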