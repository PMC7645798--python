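"""Association statistics: stepwise confounders, multinomial LRT/Wald, BH, mixed models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import mechstrat as ms
from mechstrat.stats import (
    ConfounderSelection,
    _design,
    _fit_mnlogit,
    longitudinal_association,
    outcome_association,
    progression_scores,
    select_confounders,
)


def brute_force_bh(p):
    """Independent step-up implementation: p(i)*m/i then cumulative minimum."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestAdjustBH:
    def test_hand_computed_example(self):
        assert np.allclose(ms.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(ms.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 20))
            assert np.allclose(ms.adjust_bh(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_and_order_invariant(self):
        rng = np.random.default_rng(1)
        p = rng.random(15)
        adj = ms.adjust_bh(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        perm = rng.permutation(15)
        assert np.allclose(ms.adjust_bh(p[perm]), adj[perm])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            ms.adjust_bh([0.1, np.nan])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_step_up_properties_hold_for_any_input(self, p):
        adj = ms.adjust_bh(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        assert np.allclose(adj, brute_force_bh(p), atol=1e-12)


class TestSelectConfounders:
    def test_matches_exhaustive_best_aic_subset(self):
        rng = np.random.default_rng(2)
        n = 500
        labels = rng.integers(0, 3, n)
        cand = pd.DataFrame({
            "inf": labels + rng.normal(0, 1.0, n),
            "n1": rng.normal(size=n),
            "n2": rng.normal(size=n),
        })
        sel = select_confounders(labels, cand)
        # brute-force enumeration over all subsets
        y = np.searchsorted(np.unique(labels), labels)
        best_aic, best_subset = np.inf, None
        for r in range(4):
            for subset in itertools.combinations(cand.columns, r):
                res = _fit_mnlogit(y, _design(cand, list(subset)))
                if res is not None and res.aic < best_aic:
                    best_aic, best_subset = res.aic, set(subset)
        assert set(sel.selected) == best_subset

    def test_pure_noise_mostly_empty(self):
        rng = np.random.default_rng(3)
        empty = 0
        n_seeds = 50
        for _ in range(n_seeds):
            labels = rng.integers(0, 4, 500)
            cand = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
            if not select_confounders(labels, cand).selected:
                empty += 1
        assert empty >= 0.7 * n_seeds

    def test_separation_guard_warns_and_skips(self):
        labels = np.repeat([0, 1, 2], 30)
        cand = pd.DataFrame({"copy": pd.Categorical(labels).astype(str)})
        with pytest.warns(UserWarning, match="skipped"):
            sel = select_confounders(labels, cand)
        assert sel.selected == []

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            select_confounders(np.zeros(10), pd.DataFrame({"a": np.arange(10)}))


class TestOutcomeAssociation:
    def test_planted_shift_detected(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 4, 400)
        out = pd.Series(rng.normal(size=400) + (labels == 1) * 1.0, name="y")
        res = outcome_association(out, labels)
        assert res.lrt_p < 0.01
        assert len(res.pairwise_wald_p) == 6
        # the shifted cluster drives the smallest pairwise p-values
        best_pair = min(res.pairwise_wald_p, key=res.pairwise_wald_p.get)
        assert 1 in best_pair

    def test_binary_case_equals_binary_logit_lrt(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, 300)
        out = pd.Series(rng.normal(size=300) + labels * 0.5, name="y")
        res = outcome_association(out, labels)
        X = np.column_stack([np.ones(300), out])
        llf_full = sm.Logit(labels, X).fit(disp=0).llf
        llf_null = sm.Logit(labels, np.ones((300, 1))).fit(disp=0).llf
        assert res.lrt_stat == pytest.approx(2 * (llf_full - llf_null), abs=1e-8)

    def test_confounder_adjustment_removes_false_positive(self):
        # outcome driven purely by a confounder that correlates with clusters
        rng = np.random.default_rng(6)
        rejections_raw = rejections_adj = 0
        n_sims = 100
        for _ in range(n_sims):
            n = 300
            conf = rng.normal(size=n)
            labels = (conf + rng.normal(0, 1.0, n) > 0).astype(int) + (
                rng.random(n) < 0.3
            )
            out = pd.Series(conf + rng.normal(0, 0.5, n), name="y")
            raw = outcome_association(out, labels)
            adj = outcome_association(out, labels, pd.DataFrame({"conf": conf}))
            rejections_raw += raw.lrt_p < 0.05
            rejections_adj += adj.lrt_p < 0.05
        assert rejections_raw / n_sims > 0.5  # confounding induces false positives
        assert rejections_adj / n_sims < 0.15  # adjustment restores near-nominal

    def test_degenerate_fit_flagged(self):
        labels = np.repeat([0, 1, 2], 20)
        out = pd.Series(labels.astype(float), name="y")  # perfect separation
        with pytest.warns(UserWarning, match="non-convergent"):
            res = outcome_association(out, labels)
        assert not res.converged


class TestLongitudinal:
    def test_baseline_progression_is_zero(self, small_cohort, small_config):
        tab = ms.generate_longitudinal(small_cohort, small_config)
        df = progression_scores(tab, "cognition")
        assert np.allclose(df.loc[df["visit"] == 0, "progression"], 0.0)

    def test_zero_random_intercept_matches_ols(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(7)
        n, visits = 150, 4
        labels = pd.Series(rng.integers(0, 2, n), index=[f"p{i}" for i in range(n)])
        rows = []
        for i, pid in enumerate(labels.index):
            # independent noise per visit, no shared patient effect, and a
            # baseline visit free of noise so progression has no induced
            # within-patient correlation
            base = 0.0
            for t in range(visits):
                eps = 0.0 if t == 0 else rng.normal(0, 0.5)
                rows.append(
                    {"patient_id": pid, "visit": t,
                     "y": base + 0.4 * labels.iloc[i] * t + eps}
                )
        tab = pd.DataFrame(rows)
        res = longitudinal_association(tab, labels, "y", (0, 1))
        assert res.random_intercept_var <= 0.05
        df = progression_scores(tab, "y")
        df = df[df["visit"] > 0].copy()
        df["cluster"] = (labels.reindex(df["patient_id"]).to_numpy() == 1).astype(float)
        df["time_num"] = df["visit"].astype(float)
        ols = smf.ols("progression ~ cluster * time_num", df).fit()
        if res.time_coding == "numeric" and not res.fallback_ols:
            for term in ("cluster", "time_num", "cluster:time_num"):
                assert res.fixed_effects[term] == pytest.approx(ols.params[term], abs=1e-3)

    def test_planted_slope_difference_detected(self):
        outcomes = {
            "y": ms.simulate.OutcomeSpec(
                cluster_means=(0.0, 0.0), sd=0.5, slopes=(0.0, 0.5),
                random_intercept_sd=0.0, age_coef=0.0, sex_coef=0.0,
            )
        }
        cfg = ms.SyntheticConfig(
            n_patients_ad=200, n_patients_pd=200, k_true=2, outcomes=outcomes,
            n_visits=3, seed=8,
        )
        coh = ms.generate_cohort(cfg)
        tab = ms.generate_longitudinal(coh, cfg)
        res = longitudinal_association(tab, coh.true_labels, "y", (0, 1))
        assert res.cluster_lrt_p < 0.05

    def test_missing_cluster_rejected(self, small_cohort, small_config):
        tab = ms.generate_longitudinal(small_cohort, small_config)
        with pytest.raises(ValueError):
            longitudinal_association(tab, small_cohort.true_labels, "cognition", (0, 99))
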