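from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from facility_impact import psm_did as pm
from facility_impact import synthetic_data as sd
from facility_impact.diagnostics import build_analysis_panel
from facility_impact.errors import NoOverlapError, SeparationError


def _model(scores: dict, treated: dict) -> pm.PropensityModel:
    ids = list(scores)
    return pm.PropensityModel(
        coefficients={}, scores=pd.Series([scores[i] for i in ids], index=ids),
        treated=pd.Series([treated[i] for i in ids], index=ids),
        converged=True, n_iterations=1)


class TestFitPropensity:
    def test_intercept_only_equals_treated_fraction(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(index=[f"F{i}" for i in range(200)])
        y = pd.Series(rng.random(200) < 0.3, index=cov.index).astype(int)
        model = pm.fit_propensity(cov, y)
        assert np.allclose(model.scores, y.mean(), atol=1e-10)

    def test_null_covariates_give_null_slopes(self):
        rng = np.random.default_rng(1)
        n = 4000
        cov = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        y = pd.Series((rng.random(n) < 0.4).astype(int))
        model = pm.fit_propensity(cov, y)
        for c in ("x1", "x2"):
            assert abs(model.coefficients[c]) < 3 * model.standard_errors[c]

    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(2)
        n = 5000
        cov = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        eta = 0.8 * cov["x1"] - 0.5 * cov["x2"]
        y = pd.Series((rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int))
        model = pm.fit_propensity(cov, y)
        assert model.converged
        assert abs(model.coefficients["x1"] - 0.8) < 3 * model.standard_errors["x1"]
        assert abs(model.coefficients["x2"] + 0.5) < 3 * model.standard_errors["x2"]

    def test_one_class_rejected(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            pm.fit_propensity(cov, pd.Series([1, 1, 1]))

    def test_continuous_separation_raises(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        cov = pd.DataFrame({"x": x})
        y = pd.Series((x > 0).astype(int))
        with pytest.raises(SeparationError):
            pm.fit_propensity(cov, y)

    def test_perfectly_predicting_dummy_dropped_not_fatal(self):
        rng = np.random.default_rng(4)
        n = 400
        y = pd.Series((rng.random(n) < 0.4).astype(int))
        cov = pd.DataFrame({"x": rng.normal(size=n),
                            "dummy": (y == 1).astype(float)})  # perfect predictor
        model = pm.fit_propensity(cov, y)
        assert "dummy" not in model.coefficients
        assert model.converged


class TestCommonSupport:
    def test_identical_distributions_all_on_support(self):
        scores = {f"T{i}": s for i, s in enumerate([0.2, 0.4, 0.6])}
        scores |= {f"C{i}": s for i, s in enumerate([0.2, 0.4, 0.6])}
        treated = {k: int(k.startswith("T")) for k in scores}
        sup = pm.common_support(_model(scores, treated))
        assert sup["support_flags"].all()

    def test_min_max_rule_hand_fixture(self):
        scores = {"T1": 0.3, "T2": 0.5, "T3": 0.9, "C1": 0.1, "C2": 0.4, "C3": 0.6}
        treated = {"T1": 1, "T2": 1, "T3": 1, "C1": 0, "C2": 0, "C3": 0}
        sup = pm.common_support(_model(scores, treated))
        assert sup["interval"] == (0.3, 0.6)
        flags = sup["support_flags"]
        assert not flags["T3"] and not flags["C1"]
        assert flags[["T1", "T2", "C2", "C3"]].all()
        assert sup["n_off_support_treated"] == 1
        assert sup["n_off_support_control"] == 1

    def test_disjoint_ranges_raise(self):
        scores = {"T1": 0.8, "T2": 0.9, "C1": 0.1, "C2": 0.2}
        treated = {"T1": 1, "T2": 1, "C1": 0, "C2": 0}
        with pytest.raises(NoOverlapError):
            pm.common_support(_model(scores, treated))


class TestKernelWeights:
    def test_equal_scores_give_uniform_weights(self):
        w = pm.kernel_weights(0.5, np.full(4, 0.5))
        assert np.allclose(w, 0.25)

    def test_single_control_in_bandwidth(self):
        w = pm.kernel_weights(0.5, np.array([0.51, 0.9, 0.95]), bandwidth=0.06)
        assert w[0] == pytest.approx(1.0)
        assert w[1] == w[2] == 0.0

    def test_hand_evaluated_epanechnikov(self):
        # u = (-1/3, 5/6, >1); K(u) = 3/4 (1 - u^2)
        w = pm.kernel_weights(0.5, np.array([0.48, 0.55, 0.90]), bandwidth=0.06)
        k1 = Fraction(3, 4) * (1 - Fraction(1, 3) ** 2)
        k2 = Fraction(3, 4) * (1 - Fraction(5, 6) ** 2)
        tot = k1 + k2
        assert w[0] == pytest.approx(float(k1 / tot), abs=1e-12)
        assert w[1] == pytest.approx(float(k2 / tot), abs=1e-12)
        assert w[2] == 0.0

    def test_no_control_in_window_raises(self):
        with pytest.raises(ValueError):
            pm.kernel_weights(0.1, np.array([0.8, 0.9]), bandwidth=0.05)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        score=st.floats(0.05, 0.95),
        controls=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=30),
        bandwidth=st.floats(0.01, 0.5),
        kernel=st.sampled_from(["epanechnikov", "gaussian"]),
    )
    def test_weights_normalized_and_nonnegative(self, score, controls, bandwidth, kernel):
        try:
            w = pm.kernel_weights(score, np.array(controls), kernel, bandwidth)
        except ValueError:
            return  # no control in window: reported, not silent
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_support_monotone_in_bandwidth(self):
        rng = np.random.default_rng(7)
        scores = {f"T{i}": s for i, s in enumerate(rng.uniform(0.2, 0.8, 15))}
        scores |= {f"C{i}": s for i, s in enumerate(rng.uniform(0.25, 0.75, 20))}
        treated = {k: int(k.startswith("T")) for k in scores}
        model = _model(scores, treated)
        retained = [len(pm.build_match_weights(model, bandwidth=h).treated_ids)
                    for h in [0.02, 0.05, 0.1, 0.2, 0.5]]
        assert retained == sorted(retained)


def _fixture_panel():
    """Six facilities, printed pre/post values; changes T=(12,14,11), C=(4,2,1)."""
    vals = {"T1": (45, 57), "T2": (50, 64), "T3": (55, 66),
            "C1": (40, 44), "C2": (50, 52), "C3": (60, 61)}
    rows = [{"facility_id": f, "wave": w, "y": v[int(w == 2005)]}
            for f, v in vals.items() for w in (2000, 2005)]
    return pd.DataFrame(rows)


class TestPsmDidEstimate:
    SCORES = {"T1": 0.3, "T2": 0.5, "T3": 0.6, "C1": 0.3, "C2": 0.45, "C3": 0.6}
    TREATED = {k: int(k.startswith("T")) for k in SCORES}

    def _weights(self, bandwidth=0.25):
        return pm.build_match_weights(_model(self.SCORES, self.TREATED), bandwidth=bandwidth)

    def test_hand_computed_fixture(self):
        est = pm.psm_did_estimate(_fixture_panel(), 2000, 2005, "y", self._weights())
        # rational-arithmetic oracle for the matched-contrast formula
        h = Fraction(1, 4)
        p = {k: Fraction(v).limit_denominator(100) for k, v in self.SCORES.items()}
        dT = {"T1": 12, "T2": 14, "T3": 11}
        dC = {"C1": 4, "C2": 2, "C3": 1}

        def K(u):
            return Fraction(3, 4) * (1 - u * u) if abs(u) < 1 else Fraction(0)

        deltas = []
        for t in ("T1", "T2", "T3"):
            ks = {c: K((p[c] - p[t]) / h) for c in dC}
            tot = sum(ks.values())
            deltas.append(dT[t] - sum(ks[c] * dC[c] for c in dC) / tot)
        expected = sum(deltas) / 3
        assert est.estimate == pytest.approx(float(expected), abs=1e-12)

    def test_common_change_cancels(self):
        panel = _fixture_panel()
        panel.loc[panel["wave"] == 2005, "y"] = panel.loc[panel["wave"] == 2000, "y"].to_numpy() + 7.0
        est = pm.psm_did_estimate(panel, 2000, 2005, "y", self._weights())
        assert est.estimate == pytest.approx(0.0, abs=1e-12)

    def test_uniform_weights_degenerate_to_plain_did(self):
        w = pm.MatchWeights(
            treated_ids=["T1", "T2", "T3"], control_ids=["C1", "C2", "C3"],
            matrix=np.full((3, 3), 1 / 3),
            support_flags=pd.Series(True, index=list(self.SCORES)),
            support_interval=(0.0, 1.0))
        est = pm.psm_did_estimate(_fixture_panel(), 2000, 2005, "y", w)
        plain = np.mean([12, 14, 11]) - np.mean([4, 2, 1])
        assert est.estimate == pytest.approx(plain, abs=1e-12)

    def test_treated_missing_period_dropped(self):
        panel = _fixture_panel()
        panel = panel[~((panel["facility_id"] == "T3") & (panel["wave"] == 2005))]
        est = pm.psm_did_estimate(panel, 2000, 2005, "y", self._weights())
        assert est.n_clusters == 2  # two treated contrasts remain

    def test_identical_covariates_collapse_to_plain_did(self, small_panel):
        # degeneracy: no covariate variation => uniform scores => plain DiD
        panel, _, _ = small_panel
        panel = panel[panel["wave"].isin([2000, 2005])].copy()
        for col in sd.INDICATOR_COLUMNS:
            panel[col] = 0.5
        panel["region"] = "fully-urban"
        est, model, weights = pm.run_psm_did(panel, None, 2000, 2005, "anc_4plus_visits")
        pc = "pct_anc_4plus_visits"
        wide = panel.pivot_table(index="facility_id", columns="wave", values=pc, aggfunc="first")
        change = (wide[2005] - wide[2000]).dropna()
        acc = panel.groupby("facility_id")["policy"].max()
        plain = change[acc[change.index] == 1].mean() - change[acc[change.index] == 0].mean()
        assert est.estimate == pytest.approx(plain, abs=1e-10)


class TestBootstrap:
    def _null_panel(self):
        cfg = sd.TruthConfig(seed=21, women_per_facility_per_wave=15)
        data = sd.generate_dataset(n_districts=40, n_facilities=160,
                                   waves=[2000, 2005], rollout_waves=[2005], cfg=cfg)
        panel, _ = build_analysis_panel(data, use_truth_links=True)
        return panel, data["districts"]

    def test_reproducible_under_seed(self):
        panel, districts = self._null_panel()
        a = pm.bootstrap_se(panel, districts, 2000, 2005, "anc_4plus_visits", n_boot=60, seed=5)
        b = pm.bootstrap_se(panel, districts, 2000, 2005, "anc_4plus_visits", n_boot=60, seed=5)
        assert a == b

    def test_zero_variance_changes_give_zero_se(self):
        panel = _fixture_panel()
        panel["district_id"] = ["d" + f[-1] for f in panel["facility_id"]]
        panel["policy"] = [int(f.startswith("T") and w == 2005)
                          for f, w in zip(panel["facility_id"], panel["wave"])]
        for col in sd.INDICATOR_COLUMNS:
            panel[col] = panel["district_id"].str[-1].astype(float) / 10
        panel["region"] = "fully-urban"
        panel = panel.rename(columns={"y": "pct_anc_4plus_visits"})
        # make every facility's change identical
        base = panel[panel["wave"] == 2000].set_index("facility_id")["pct_anc_4plus_visits"]
        panel.loc[panel["wave"] == 2005, "pct_anc_4plus_visits"] = \
            base[panel.loc[panel["wave"] == 2005, "facility_id"]].to_numpy() + 5.0
        out = pm.bootstrap_se(panel, None, 2000, 2005, "anc_4plus_visits",
                              n_boot=50, seed=1, bandwidth=0.5)
        assert out["se"] == pytest.approx(0.0, abs=1e-10)

    def test_rejects_tiny_n_boot(self):
        panel, districts = self._null_panel()
        with pytest.raises(ValueError):
            pm.bootstrap_se(panel, districts, 2000, 2005, "anc_4plus_visits", n_boot=10)

    def test_stability_across_n_boot(self):
        panel, districts = self._null_panel()
        a = pm.bootstrap_se(panel, districts, 2000, 2005, "anc_4plus_visits", n_boot=199, seed=2)
        b = pm.bootstrap_se(panel, districts, 2000, 2005, "anc_4plus_visits", n_boot=399, seed=2)
        assert abs(a["se"] - b["se"]) / b["se"] < 0.25


class TestBalance:
    def test_identical_groups_balanced(self):
        rng = np.random.default_rng(8)
        ids = [f"F{i}" for i in range(40)]
        x = np.tile(rng.normal(size=20), 2)
        cov = pd.DataFrame({"x": x}, index=ids)
        treated = pd.Series([1] * 20 + [0] * 20, index=ids)
        w = pm.MatchWeights(treated_ids=ids[:20], control_ids=ids[20:],
                            matrix=np.eye(20), support_flags=pd.Series(True, index=ids),
                            support_interval=(0, 1))
        bal = pm.balance_tests(cov, treated, w)
        assert bal["smd_before"].abs().max() < 1e-12
        assert bal["smd_after"].abs().max() < 1e-12

    def test_zero_variance_covariate_safe(self):
        ids = [f"F{i}" for i in range(10)]
        cov = pd.DataFrame({"x": np.ones(10)}, index=ids)
        treated = pd.Series([1] * 5 + [0] * 5, index=ids)
        w = pm.MatchWeights(treated_ids=ids[:5], control_ids=ids[5:],
                            matrix=np.full((5, 5), 0.2),
                            support_flags=pd.Series(True, index=ids), support_interval=(0, 1))
        bal = pm.balance_tests(cov, treated, w)
        assert bal["smd_before"].iloc[0] == 0.0

    def test_matching_improves_balance_under_confounding(self):
        improvements = []
        for rep in range(12):
            cfg = sd.TruthConfig(targeting_strength=2.0, seed=500 + rep,
                                 women_per_facility_per_wave=12)
            data = sd.generate_dataset(n_districts=40, n_facilities=120,
                                       waves=[2000, 2005], rollout_waves=[2005], cfg=cfg)
            panel, _ = build_analysis_panel(data, use_truth_links=True)
            try:
                est, model, weights = pm.run_psm_did(panel, data["districts"], 2000, 2005,
                                                     "anc_4plus_visits")
            except (NoOverlapError, SeparationError):
                continue
            fac = panel.drop_duplicates("facility_id").set_index("facility_id")
            covs = fac[list(sd.INDICATOR_COLUMNS)]
            bal = pm.balance_tests(covs, model.treated, weights)
            improvements.append(bal["smd_before"].abs().mean() - bal["smd_after"].abs().mean())
        assert np.mean(improvements) > 0
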