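"""Graded response model: probabilities, EAP scoring, error scores, EM fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from surveycog.irt import (
    GradedResponseModel,
    ItemParameters,
    category_probabilities,
    cumulative_probabilities,
    eap_theta,
    expected_score,
    response_error_score,
    score_all_scales,
)


def brute_force_probs(theta, a, b):
    """Independent direct evaluation of the two-logistic differences."""
    pstar = np.concatenate([[1.0], expit(a * (theta - np.asarray(b))), [0.0]])
    return pstar[:-1] - pstar[1:]


def brute_force_error(y, theta, a, b):
    p = brute_force_probs(theta, a, b)
    m = len(b) + 1
    e = np.sum(np.arange(1, m + 1) * p)
    return abs(y - e) / (m - 1)


ITEM = ItemParameters("i1", "s", 4, 1.5, (-1.0, 0.0, 1.0))
SYM5 = ItemParameters("i2", "s", 5, 1.5, (-1.5, -0.5, 0.5, 1.5))


class TestProbabilities:
    def test_normalization_on_grid(self):
        thetas = np.linspace(-5, 5, 41)
        for item in (ITEM, SYM5):
            p = category_probabilities(thetas, item)
            assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-10)
            assert np.all(p >= 0)

    def test_cumulative_midpoint_at_threshold(self):
        # at theta == b_k the cumulative curve for category k+1 is exactly 1/2
        for k, b in enumerate(ITEM.thresholds, start=1):
            pstar = cumulative_probabilities(b, ITEM)
            assert pstar[k] == pytest.approx(0.5, abs=1e-12)

    def test_matches_bruteforce_formula(self):
        p = category_probabilities(0.5, ITEM)
        assert np.allclose(p, brute_force_probs(0.5, 1.5, [-1, 0, 1]), atol=1e-12)

    def test_nonfinite_theta_rejected(self):
        with pytest.raises(ValueError):
            category_probabilities(np.nan, ITEM)

    def test_invalid_item_parameters_rejected(self):
        with pytest.raises(ValueError):
            ItemParameters("bad", "s", 4, 1.0, (0.0, 0.0, 1.0))  # tied thresholds
        with pytest.raises(ValueError):
            ItemParameters("bad", "s", 4, -1.0, (-1.0, 0.0, 1.0))  # a <= 0
        with pytest.raises(ValueError):
            ItemParameters("bad", "s", 4, 1.0, (-1.0, 1.0))  # wrong count


class TestExpectedAndErrorScores:
    def test_symmetric_midpoint(self):
        assert expected_score(0.0, SYM5) == pytest.approx(3.0, abs=1e-12)

    def test_limits(self):
        assert expected_score(12.0, SYM5) == pytest.approx(5.0, abs=1e-3)
        assert expected_score(-12.0, SYM5) == pytest.approx(1.0, abs=1e-3)

    def test_monotone_in_theta(self):
        grid = np.linspace(-6, 6, 201)
        for item in (ITEM, SYM5):
            e = expected_score(grid, item)
            assert np.all(np.diff(e) >= -1e-12)

    def test_oracle_equivalence_random_grid(self):
        # direct-summation oracle over random items, thetas and responses
        rng = np.random.default_rng(123)
        for _ in range(200):
            m = int(rng.integers(3, 8))
            a = float(rng.lognormal(0.4, 0.3))
            b = np.sort(rng.normal(0, 1.5, m - 1))
            b += np.arange(m - 1) * 1e-3  # guard exact ties
            item = ItemParameters("x", "s", m, a, tuple(b))
            theta = float(rng.normal(0, 2))
            y = int(rng.integers(1, m + 1))
            got = response_error_score(y, theta, item)
            assert got == pytest.approx(brute_force_error(y, theta, a, b), abs=1e-10)

    def test_zero_iff_observed_equals_expected(self):
        e = expected_score(0.0, SYM5)
        assert response_error_score(3, 0.0, SYM5) == pytest.approx(0.0, abs=1e-12)
        assert response_error_score(4, 0.0, SYM5) > 0

    def test_maximal_error_is_one(self):
        # expected -> m while observing y = 1
        item = ItemParameters("top", "s", 5, 2.0, (-6.0, -5.5, -5.0, -4.5))
        assert response_error_score(1, 8.0, item) == pytest.approx(1.0, abs=1e-4)

    def test_out_of_range_response_rejected(self):
        with pytest.raises(ValueError):
            response_error_score(6, 0.0, SYM5)


class TestEAP:
    def test_middle_response_symmetric_items_gives_zero(self):
        th, sd = eap_theta(np.array([[3, 3, 3]]), [SYM5] * 3)
        assert th[0] == pytest.approx(0.0, abs=1e-6)
        assert sd[0] > 0

    def test_monotone_in_responses(self):
        hi, _ = eap_theta(np.array([[5, 5, 5]]), [SYM5] * 3)
        lo, _ = eap_theta(np.array([[1, 1, 1]]), [SYM5] * 3)
        assert hi[0] > 0 > lo[0]

    def test_matches_dense_grid_oracle(self):
        # high-resolution trapezoid integration as the independent oracle
        item = ItemParameters("i", "s", 4, 2.0, (-1.0, 0.0, 1.0))
        y = 4
        grid = np.linspace(-8, 8, 2001)
        like = category_probabilities(grid, item)[:, y - 1]
        prior = np.exp(-0.5 * grid**2)
        post = like * prior
        oracle = np.trapezoid(grid * post, grid) / np.trapezoid(post, grid)
        th, _ = eap_theta(np.array([[y]]), [item], n_nodes=2001, bound=8.0)
        assert th[0] == pytest.approx(oracle, abs=1e-4)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            eap_theta(np.array([[0, 0]]), [SYM5, SYM5])


def _simulate_scale(n, items, rng):
    """GRM draws without contamination (local oracle generator)."""
    theta = rng.normal(size=n)
    cols = {}
    for it in items:
        pstar = np.column_stack([expit(it.discrimination * (theta - b))
                                 for b in it.thresholds])
        u = rng.random(n)
        cols[it.item_id] = 1 + (u[:, None] < pstar).sum(axis=1)
    return pd.DataFrame(cols)


class TestGRMFit:
    @pytest.fixture(scope="class")
    def clean_fit(self):
        rng = np.random.default_rng(7)
        items = [
            ItemParameters(f"i{j}", "s", 5, a, tuple(b))
            for j, (a, b) in enumerate([
                (1.2, (-1.5, -0.5, 0.5, 1.5)),
                (1.8, (-2.0, -1.0, 0.5, 1.2)),
                (0.9, (-1.0, -0.2, 0.8, 1.8)),
                (1.5, (-1.8, -0.4, 0.3, 1.0)),
                (2.2, (-1.2, -0.6, 0.6, 1.4)),
            ])
        ]
        wide = _simulate_scale(500, items, rng)
        model = GradedResponseModel(wide, "s")
        return items, model, model.fit(compute_se=True)

    def test_parameter_recovery_moderate_n(self, clean_fit):
        items, _, res = clean_fit
        p = res.params
        a_err = [abs(p.loc[it.item_id, "a"] - it.discrimination) for it in items]
        b_err = []
        for it in items:
            est = p.loc[it.item_id, [f"b{k}" for k in range(1, 5)]].to_numpy(float)
            b_err += list(np.abs(est - np.asarray(it.thresholds)))
        assert np.mean(a_err) < 0.25  # n = 500; the n = 2000 bound is 0.15
        assert np.mean(b_err) < 0.25

    def test_refit_deterministic(self, clean_fit):
        _, model, res = clean_fit
        res2 = model.fit(compute_se=False)
        assert res2.llf == pytest.approx(res.llf, abs=1e-6)

    def test_standard_errors_positive_and_shrinking(self, clean_fit):
        _, _, res = clean_fit
        for item_se in res.se.values():
            assert np.all(item_se > 0)
            assert np.all(item_se < 1.0)

    def test_srmr_small_for_well_specified_model(self, clean_fit):
        _, _, res = clean_fit
        assert 0 <= res.srmr() < 0.08

    def test_duplicate_items_get_near_equal_estimates(self):
        rng = np.random.default_rng(11)
        item = ItemParameters("i0", "s", 4, 1.4, (-1.0, 0.0, 1.0))
        n = 2500
        theta = rng.normal(size=n)
        pstar = np.column_stack([expit(1.4 * (theta - b)) for b in item.thresholds])
        wide = pd.DataFrame({
            "A": 1 + (rng.random(n)[:, None] < pstar).sum(axis=1),
            "B": 1 + (rng.random(n)[:, None] < pstar).sum(axis=1),
            "C": 1 + (rng.random(n)[:, None] < pstar).sum(axis=1),
        })
        res = GradedResponseModel(wide, "s").fit(compute_se=False)
        a = res.params["a"]
        assert abs(a["A"] - a["B"]) < 0.3 and abs(a["A"] - a["C"]) < 0.3

    def test_single_observed_category_rejected(self):
        wide = pd.DataFrame({"A": [1, 1, 1, 1], "B": [1, 2, 1, 2]})
        with pytest.raises(ValueError, match="A"):
            GradedResponseModel(wide, "s")

    def test_single_item_scale_rejected(self):
        with pytest.raises(ValueError):
            GradedResponseModel(pd.DataFrame({"A": [1, 2, 3]}), "s")

    def test_reverse_keyed_item_detected_and_flipped(self):
        rng = np.random.default_rng(13)
        items = [ItemParameters(f"i{j}", "s", 5, 1.5, (-1.5, -0.5, 0.5, 1.5))
                 for j in range(4)]
        wide = _simulate_scale(600, items, rng)
        flipped = wide.copy()
        flipped["i2"] = 6 - flipped["i2"]
        m = GradedResponseModel(flipped, "s")
        assert m.reverse_coded == ["i2"]
        res = m.fit(compute_se=False)
        base = GradedResponseModel(wide, "s").fit(compute_se=False)
        assert res.llf == pytest.approx(base.llf, abs=1e-6)

    def test_unused_category_collapsed_with_recorded_map(self):
        rng = np.random.default_rng(17)
        items = [ItemParameters(f"i{j}", "s", 3, 1.5, (-0.8, 0.8)) for j in range(3)]
        wide = _simulate_scale(300, items, rng)
        wide["i0"] = wide["i0"].replace({2: 1})  # category 2 never observed
        m = GradedResponseModel(wide, "s")
        assert m.category_maps["i0"] == {1: 1, 3: 2}
        assert m.m[0] == 2


class TestScoreAllScales:
    @pytest.fixture(scope="class")
    def scored(self, small_study):
        return score_all_scales(small_study.responses, small_study.items)

    def test_complete_data_yields_full_error_count(self, small_study, scored):
        err, thetas, fits = scored
        per_person = err.groupby("person_id").size()
        assert (per_person == small_study.config.n_items).all()
        assert len(fits) == 21
        assert err["error"].between(0, 1).all()

    def test_error_distribution_right_skewed(self, scored):
        from scipy.stats import skew
        err, *_ = scored
        assert skew(err["error"]) > 0

    def test_listwise_by_scale_rule_matches_bruteforce_recount(self, small_study):
        rng = np.random.default_rng(5)
        resp = small_study.responses.copy()
        resp = resp[rng.random(len(resp)) >= 0.05]  # 5% missing
        err, *_ = score_all_scales(resp, small_study.items)
        # brute-force recount: a person is scored on a scale iff they
        # answered every item of that scale
        items = small_study.items
        scale_size = items.groupby("scale_id")["item_id"].nunique()
        answered = resp.groupby(["person_id", "scale_id"]).size()
        expected = {
            pid: int(sum(scale_size[s] for s in scale_size.index
                         if answered.get((pid, s), 0) == scale_size[s]))
            for pid in resp["person_id"].unique()
        }
        got = err.groupby("person_id").size().to_dict()
        for pid, n_exp in expected.items():
            assert got.get(pid, 0) == n_exp

    def test_missing_one_item_drops_only_that_scale(self):
        rng = np.random.default_rng(23)
        items = [ItemParameters(f"a{j}", "SA", 4, 1.5, (-1.0, 0.0, 1.0)) for j in range(3)]
        items += [ItemParameters(f"b{j}", "SB", 4, 1.5, (-1.0, 0.0, 1.0)) for j in range(3)]
        frames = []
        theta = rng.normal(size=200)
        for it in items:
            pstar = np.column_stack([expit(1.5 * (theta - b)) for b in it.thresholds])
            y = 1 + (rng.random(200)[:, None] < pstar).sum(axis=1)
            frames.append(pd.DataFrame({
                "person_id": np.arange(200), "scale_id": it.scale_id,
                "item_id": it.item_id, "response": y}))
        resp = pd.concat(frames, ignore_index=True)
        drop = (resp["person_id"] == 0) & (resp["item_id"] == "a0")
        resp = resp[~drop]
        items_df = pd.DataFrame({"item_id": [it.item_id for it in items],
                                 "scale_id": [it.scale_id for it in items]})
        err, *_ = score_all_scales(resp, items_df)
        p0 = err[err["person_id"] == 0]
        assert set(p0["scale_id"]) == {"SB"}
        assert len(p0) == 3
        assert (err[err["person_id"] == 1].groupby("scale_id").size() == 3).all()

    def test_small_scale_rejected(self, small_study):
        items = small_study.items.copy()
        items.loc[items["scale_id"] == "S01", "scale_id"] = "S01X"
        items.loc[items["item_id"] == "S01I1", "scale_id"] = "LONE"
        with pytest.raises(ValueError, match="LONE"):
            score_all_scales(small_study.responses, items)
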