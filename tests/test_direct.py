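import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fpsae
from fpsae import (
    DirectEstimator,
    NoDataError,
    boundary_adjust,
    design_variance,
    direct_estimates_table,
    logit_transform,
    weighted_prevalence,
)


def brute_weighted_mean(weights, ys):
    """Independent one-line oracle for the Hajek ratio."""
    return sum(w * y for w, y in zip(weights, ys)) / sum(weights)


def brute_psu_variance(df, outcome_col="uses_modern"):
    """Symbol-by-symbol between-PSU linearization variance oracle.

    Enumerates the formula directly: z_i = w_i (y_i - p_hat) / W, PSU totals
    within strata, n_h/(n_h-1) times squared deviations from the stratum
    mean, summed.
    """
    W = df["weight"].sum()
    p_hat = (df["weight"] * df[outcome_col]).sum() / W
    var = 0.0
    for _, stratum in df.groupby("stratum"):
        totals = []
        for _, psu in stratum.groupby("cluster"):
            z = (psu["weight"] * (psu[outcome_col] - p_hat) / W).sum()
            totals.append(z)
        n_h = len(totals)
        zbar = sum(totals) / n_h
        var += n_h / (n_h - 1) * sum((z - zbar) ** 2 for z in totals)
    return var


def make_cell(weights, ys, strata=None, clusters=None):
    n = len(ys)
    return pd.DataFrame({
        "survey_id": "s", "instrument_type": "DHS", "area": "A", "year": 2015,
        "stratum": strata if strata is not None else ["S1"] * n,
        "cluster": clusters if clusters is not None else [f"c{i}" for i in range(n)],
        "weight": weights, "age_group": "25+", "parity": "parous",
        "uses_modern": ys, "uses_traditional": 0, "unmet_need": 0,
    })


class TestWeightedPrevalence:
    def test_equal_weights_reduce_to_mean(self):
        cell = make_cell([1, 1, 1, 1], [1, 0, 1, 0])
        p, W = weighted_prevalence(cell, "modern")
        assert p == 0.5 and W == 4

    def test_unequal_weights(self):
        cell = make_cell([2, 1], [1, 0])
        p, _ = weighted_prevalence(cell, "modern")
        assert p == pytest.approx(2 / 3, abs=1e-15)

    def test_matches_oracle_on_toy(self, two_stratum_toy):
        p, _ = weighted_prevalence(two_stratum_toy, "modern")
        oracle = brute_weighted_mean(
            two_stratum_toy["weight"], two_stratum_toy["uses_modern"]
        )
        assert p == pytest.approx(oracle, abs=1e-15)

    def test_empty_input_signals_no_data(self):
        with pytest.raises(NoDataError):
            weighted_prevalence(make_cell([], []), "modern")

    @given(
        ys=st.lists(st.integers(0, 1), min_size=2, max_size=30),
        w0=st.floats(0.1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_equal_weight_invariance(self, ys, w0):
        # scaling all weights by any common factor leaves p_hat at the mean
        cell = make_cell([w0] * len(ys), ys)
        p, _ = weighted_prevalence(cell, "modern")
        assert p == pytest.approx(np.mean(ys), abs=1e-12)


class TestDesignVariance:
    def test_srs_collapse(self):
        # one PSU per observation, equal weights: matches the textbook
        # with-replacement SRS formula p(1-p) n/((n-1) n) = s^2/n
        ys = [1, 0, 1, 1, 0, 0, 1, 0, 1, 1]
        cell = make_cell([1.0] * 10, ys)
        var, _ = design_variance(cell, "modern")
        n, p = len(ys), np.mean(ys)
        assert var == pytest.approx(p * (1 - p) / (n - 1), abs=1e-12)

    def test_degenerate_outcomes_zero_variance(self):
        cell = make_cell([1, 2, 3, 4], [1, 1, 1, 1])
        var, _ = design_variance(cell, "modern")
        assert var == 0.0

    def test_matches_brute_force_oracle(self):
        # 2 strata x 3 clusters with unequal weights and mixed outcomes
        rng = np.random.default_rng(7)
        rows = []
        for h in ["S1", "S2"]:
            for c in range(3):
                for _ in range(5):
                    rows.append({
                        "survey_id": "s", "instrument_type": "DHS", "area": "A",
                        "year": 2015, "stratum": h, "cluster": f"{h}c{c}",
                        "weight": float(rng.uniform(0.5, 3.0)),
                        "age_group": "25+", "parity": "parous",
                        "uses_modern": int(rng.uniform() < 0.4),
                        "uses_traditional": 0, "unmet_need": 0,
                    })
        cell = pd.DataFrame(rows)
        var, _ = design_variance(cell, "modern")
        assert var == pytest.approx(brute_psu_variance(cell), abs=1e-15)

    def test_lone_psu_rules(self):
        strata = ["S1"] * 4 + ["S2"] * 2
        clusters = ["c1", "c1", "c2", "c2", "c3", "c3"]
        cell = make_cell([1.0] * 6, [1, 1, 0, 0, 1, 0], strata, clusters)
        var_collapse, adj = design_variance(cell, "modern", lone_psu="collapse")
        assert adj and var_collapse > 0
        var_cert, adj_cert = design_variance(cell, "modern", lone_psu="certainty")
        assert adj_cert
        with pytest.raises(ValueError, match="S2"):
            # all-lone case: collapse leaves a single merged stratum pair; for
            # "fail" the lone stratum is named
            design_variance(cell, "modern", lone_psu="fail")


class TestLogitTransform:
    def test_half_example(self):
        y, v = logit_transform(0.5, 0.01)
        assert y == 0.0
        assert v == pytest.approx(0.16, abs=1e-15)

    def test_inverse_logit_identity(self):
        y, _ = logit_transform(1 / (1 + np.e), 0.001)
        assert y == pytest.approx(-1.0, abs=1e-14)

    def test_delta_method_symmetry(self):
        _, v1 = logit_transform(0.3, 0.004)
        _, v2 = logit_transform(0.7, 0.004)
        assert v1 == pytest.approx(v2, rel=1e-14)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            logit_transform(0.0, 0.01)


class TestBoundaryAdjust:
    @pytest.mark.parametrize(
        "p, n_eff, expected, flagged",
        [(0.0, 99.0, 0.005, True), (1.0, 9.0, 0.95, True), (0.4, 50.0, 0.4, False)],
    )
    def test_rule(self, p, n_eff, expected, flagged):
        p_adj, flag = boundary_adjust(p, n_eff)
        assert p_adj == pytest.approx(expected, abs=1e-15)
        assert flag is flagged


class TestDirectEstimatesTable:
    def test_row_counting_all_women(self, two_stratum_toy):
        other = two_stratum_toy.assign(area="B")
        records = pd.concat([two_stratum_toy, other], ignore_index=True)
        est, dropped = direct_estimates_table(records, grouping="all")
        assert len(est) == 6  # 2 areas x 1 survey x 3 outcomes
        assert len(dropped) == 0

    def test_small_cells_dropped_and_logged(self, two_stratum_toy):
        tiny = two_stratum_toy.head(7).assign(area="tiny")
        records = pd.concat([two_stratum_toy, tiny], ignore_index=True)
        est, dropped = direct_estimates_table(records, n_min=10)
        assert "tiny" not in set(est["area"])
        assert list(dropped["area"]) == ["tiny"]
        assert dropped["n"].iloc[0] == 7

    def test_compositional_consistency(self, small_world):
        # every row of the table reproduces the single-cell operations
        records = small_world["records"]
        est, _ = direct_estimates_table(records, grouping="all")
        for _, row in est.sample(10, random_state=0).iterrows():
            cell = records[
                (records["area"] == row["area"])
                & (records["survey_id"] == row["survey_id"])
            ]
            p, _ = weighted_prevalence(cell, row["outcome"])
            var, _ = design_variance(cell, row["outcome"])
            assert row["p_hat"] == pytest.approx(p, abs=1e-12)
            assert row["var_p"] == pytest.approx(var, abs=1e-12)

    def test_age_parity_grouping_labels(self, small_world):
        est, _ = direct_estimates_table(
            small_world["records"], grouping="age-parity", n_min=5
        )
        assert set(est["subgroup"]) <= {
            "nulliparous 15-24", "parous 15-24", "nulliparous 25+", "parous 25+"
        }

    def test_unknown_grouping_rejected(self, two_stratum_toy):
        with pytest.raises(ValueError, match="grouping"):
            direct_estimates_table(two_stratum_toy, grouping="by-zodiac")


class TestIntervalCalibration:
    def test_wald_interval_coverage_against_frame_truth(self):
        # p_hat +- 1.96 sqrt(var_p) against the sampling-frame prevalence
        # over 500 replicate surveys: empirical coverage in [90%, 98%]
        import fpsae as fp

        g = fp.synthetic_graph(2, seed=3)
        surfaces = {
            o: fp.generate_true_surface(g, range(2010, 2013), seed=70 + i,
                                        outcome=o)
            for i, o in enumerate(["modern", "traditional", "unmet"])
        }
        frame = fp.build_sampling_frame(g, strata_per_area=2,
                                        clusters_per_stratum=20, seed=11)
        truth = fp.frame_prevalence(surfaces, frame, 2011)
        hits = []
        for r in range(500):
            rec = fp.simulate_survey(
                surfaces, frame,
                fp.SurveySpec("s", "DHS", 2011, g.areas, clusters_per_stratum=10,
                              women_per_cluster=15),
                seed=4000 + r,
            )
            est, _ = direct_estimates_table(rec, outcomes=("modern",))
            for _, row in est.iterrows():
                half = 1.96 * np.sqrt(row["var_p"])
                tr = truth.loc[row["area"], "modern"]
                hits.append(row["p_hat"] - half <= tr <= row["p_hat"] + half)
        coverage = np.mean(hits)
        assert 0.90 <= coverage <= 0.98, coverage


class TestDirectEstimator:
    def test_sklearn_contract(self, small_world):
        est = DirectEstimator(n_min=12)
        assert est.get_params()["n_min"] == 12
        est.set_params(n_min=10)
        out = est.fit_transform(small_world["records"])
        assert hasattr(est, "estimates_") and est.estimates_.equals(out)
        assert (out["v_logit"] > 0).all()
        assert out["p_hat"].between(0, 1).all()
        assert (out["var_p"] >= 0).all()
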