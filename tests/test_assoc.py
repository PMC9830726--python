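"""Spearman / partial-Spearman correlations and the clinical panels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabshape import (
    CohortConfig, IntensityMatrix, correlate_panel, generate_cohort,
    maternal_cord_correlation, partial_spearman, spearman,
)

from oracles import partial_corr_first_order


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = np.linspace(0, 3, 10)
        r, p = spearman(x, np.exp(x))
        assert r == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        r, _ = spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_tied_fixture_matches_rank_then_pearson(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])  # one tie
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0])
        r, _ = spearman(x, y)
        brute = stats.pearsonr(stats.rankdata(x), stats.rankdata(y))[0]
        assert r == pytest.approx(brute, abs=1e-12)

    def test_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r0, _ = spearman(x, y)
        r1, _ = spearman(np.exp(x), y**3)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_constant_vector_flagged(self):
        r, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman([1, 2, 3], [1, 2, 3])


class TestPartialSpearman:
    def test_no_covariates_equals_spearman(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 25))
        r0, p0 = spearman(x, y)
        r1, p1, k = partial_spearman(x, y, None)
        assert k == 0
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_y_equal_to_covariate_partials_to_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(30)
        c = rng.standard_normal(30)
        r, _, _ = partial_spearman(x, c, pd.DataFrame({"c": c}))
        assert abs(r) < 1e-8

    def test_matches_first_order_closed_form(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(20)
        x = 0.5 * z + rng.standard_normal(20)
        y = -0.7 * z + rng.standard_normal(20)
        r, _, k = partial_spearman(x, y, pd.DataFrame({"z": z}))
        assert k == 1
        assert r == pytest.approx(partial_corr_first_order(x, y, z), abs=1e-10)

    def test_collinear_covariates_warn(self):
        rng = np.random.default_rng(4)
        x, y, z = rng.standard_normal((3, 25))
        cov = pd.DataFrame({"z": z, "z2": 2 * z})
        with pytest.warns(UserWarning, match="collinear"):
            r, _, k = partial_spearman(x, y, cov)
        assert k == 1   # the redundant column carries no adjustment

    def test_categorical_covariates_dummy_coded(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 40))
        cov = pd.DataFrame({"parity": rng.choice(["first", "subsequent"], 40)})
        r, p, k = partial_spearman(x, y, cov)
        assert k == 1 and np.isfinite(r) and 0 <= p <= 1

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            partial_spearman([1, 2, 3, 4], [4, 3, 2, 1],
                             pd.DataFrame({"z": [1, 2, 3, 4]}))


def _link_cohort(seed, variable="gestational_age", slope=1.2):
    cfg = CohortConfig(
        group_sizes=(16, 28, 23),
        n_metabolites_per_class={"null": 10},
        transfer_rho=0.0, modes=("pos",), seed=seed,
        pheno_links=(("null_001", variable, slope),),
    )
    return generate_cohort(cfg)


class TestCorrelatePanel:
    def test_planted_link_detected_by_model1(self):
        hits = 0
        for seed in range(10):
            ph, mats, _ = _link_cohort(seed)
            tab = correlate_panel(mats[("maternal", "pos")], ph, ["null_001"],
                                  ["gestational_age"], model=1)
            rec = tab.iloc[0]
            hits += (rec["r"] > 0) and (rec["p"] < 0.05)
        assert hits >= 9

    def test_covariate_routed_link_attenuated_by_model2(self):
        # the link runs through gestational age, itself a Model-2 covariate:
        # adjustment must shrink the correlation toward zero
        r1s, r2s = [], []
        for seed in range(10):
            ph, mats, _ = _link_cohort(seed + 100)
            m1 = correlate_panel(mats[("maternal", "pos")], ph, ["null_001"],
                                 ["gestational_age"], model=1)
            m2 = correlate_panel(mats[("maternal", "pos")], ph, ["null_001"],
                                 ["gestational_age"], model=2)
            r1s.append(abs(m1.iloc[0]["r"]))
            r2s.append(abs(m2.iloc[0]["r"]))
        assert np.mean(r2s) < np.mean(r1s)

    def test_type_one_error_near_nominal_under_null(self):
        cfg = CohortConfig(
            group_sizes=(16, 28, 23), n_metabolites_per_class={"null": 100},
            transfer_rho=0.0, modes=("pos",), seed=12,
        )
        ph, mats, truth = generate_cohort(cfg)
        tab = correlate_panel(mats[("maternal", "pos")], ph,
                              list(truth.index), ["prepreg_bmi"], model=1)
        frac = float((tab["p"] < 0.05).mean())
        # binomial 95% band around 5% at 100 tests
        assert 0.0 <= frac <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / 100)

    def test_unknown_variable_lists_valid_names(self, tiny_cohort):
        ph, mats, truth = tiny_cohort
        with pytest.raises(ValueError, match="prepreg_bmi"):
            correlate_panel(mats[("maternal", "pos")], ph,
                            [truth.index[0]], ["nope"], model=1)

    def test_n_and_covariates_reported(self, tiny_cohort):
        ph, mats, truth = tiny_cohort
        tab = correlate_panel(mats[("maternal", "pos")], ph,
                              [truth.index[0]], ["prepreg_bmi"], model=2)
        rec = tab.iloc[0]
        assert rec["n"] == len(ph)
        assert "gdm" in rec["covariates"]

    def test_methods_preset_drops_gdm(self, tiny_cohort):
        ph, mats, truth = tiny_cohort
        tab = correlate_panel(mats[("maternal", "pos")], ph, [truth.index[0]],
                              ["prepreg_bmi"], model=2, covariate_preset="methods")
        assert "gdm" not in tab.iloc[0]["covariates"]


class TestMaternalCord:
    def test_identical_compartments_r_one(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.lognormal(size=(20, 5)),
                          index=[f"D{i}" for i in range(20)],
                          columns=[f"m{j}" for j in range(5)])
        mom = IntensityMatrix(df, "maternal", "pos")
        kid = IntensityMatrix(df.copy(), "cord", "pos")
        tab = maternal_cord_correlation(mom, kid)
        assert np.allclose(tab["r"], 1.0)

    def test_transfer_rho_recovered(self):
        rs = []
        for seed in range(10):
            cfg = CohortConfig(
                group_sizes=(16, 28, 23), n_metabolites_per_class={"null": 60},
                transfer_rho=0.7, modes=("pos",), seed=seed,
            )
            _, mats, _ = generate_cohort(cfg)
            tab = maternal_cord_correlation(mats[("maternal", "pos")],
                                            mats[("cord", "pos")])
            rs.append(float(tab["r"].mean()))
        assert np.mean(rs) == pytest.approx(0.7, abs=0.08)

    def test_zero_rho_mean_abs_r_small(self):
        cfg = CohortConfig(
            group_sizes=(16, 28, 23), n_metabolites_per_class={"null": 1000},
            transfer_rho=0.0, modes=("pos",), seed=8,
        )
        _, mats, _ = generate_cohort(cfg)
        tab = maternal_cord_correlation(mats[("maternal", "pos")],
                                        mats[("cord", "pos")])
        assert float(tab["r"].abs().mean()) < 0.1

    def test_unmatched_dyads_rejected(self):
        rng = np.random.default_rng(10)
        mk = lambda idx, comp: IntensityMatrix(
            pd.DataFrame(rng.lognormal(size=(len(idx), 3)), index=idx,
                         columns=["a", "b", "c"]), comp, "pos")
        with pytest.raises(ValueError, match="unmatched"):
            maternal_cord_correlation(mk(["D1", "D2", "D3"], "maternal"),
                                      mk(["D1", "D2", "D4"], "cord"))
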