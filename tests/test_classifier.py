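"""Normalization, RD ranking and super-feature classifier construction."""

import numpy as np
import pandas as pd
import pytest

from aggrecyto import classifier as clf
from aggrecyto.classifier import (
    LinearClassifier,
    TruthSet,
    auto_truth,
    build_all_classifiers,
    build_classifier,
    fisher_rd,
    fit_normalization,
    normalize,
    rank_features,
    score_events,
)


def _truth(n=40):
    return TruthSet(members={
        "S": [f"s{i}" for i in range(n)],
        "SA": [f"a{i}" for i in range(n)],
        "LA": [f"l{i}" for i in range(n)],
    })


def _toy_table(rng, n=40, n_noise=9, shift=6.0):
    """One informative feature separating S from the rest + noise features."""
    truth = _truth(n)
    ids = truth.union()
    data = {"informative": np.concatenate([
        rng.normal(shift, 1.0, n), rng.normal(0.0, 1.0, 2 * n)])}
    for k in range(n_noise):
        data[f"noise{k}"] = rng.normal(0.0, 1.0, 3 * n)
    return pd.DataFrame(data, index=ids), truth


class TestNormalization:
    def test_hand_computed_z_scores(self):
        """{1,2,3} -> +/-1.2247 under the population-SD convention."""
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        params = fit_normalization(table, ["a", "b", "c"])
        z = normalize(table, params)["x"].to_numpy()
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(z, expected, atol=1e-12)

    def test_fitted_set_mean_zero_sd_one(self, rng):
        table = pd.DataFrame(rng.lognormal(2, 1, size=(50, 6)),
                             columns=[f"f{i}" for i in range(6)])
        table.index = table.index.map(str)
        params = fit_normalization(table, list(table.index))
        z = normalize(table, params)
        np.testing.assert_allclose(z.mean().to_numpy(), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(ddof=0).to_numpy(), 1.0, atol=1e-9)

    def test_idempotent_on_fitted_set(self, rng):
        table = pd.DataFrame({"x": rng.normal(0, 1, 30)})
        table.index = table.index.map(str)
        params = fit_normalization(table, list(table.index))
        z1 = normalize(table, params)
        params2 = fit_normalization(z1, list(z1.index))
        z2 = normalize(z1, params2)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)

    def test_constant_column_dropped(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]},
                             index=["a", "b", "c"])
        params = fit_normalization(table, ["a", "b", "c"])
        assert params.features == ["x"]


class TestFisherRD:
    def test_direct_substitution(self):
        # mu+=2 sigma+=1 (pop), mu-=0 sigma-=1 -> RD = 1
        assert fisher_rd([1.0, 3.0], [-1.0, 1.0]) == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        assert fisher_rd([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(2, 1, 20), rng.normal(0, 2, 25)
        assert fisher_rd(a, b) == pytest.approx(-fisher_rd(b, a))

    def test_degenerate_denominator_missing(self):
        assert np.isnan(fisher_rd([1.0, 1.0], [2.0, 2.0]))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            fisher_rd([1.0], [0.0, 1.0])


class TestRankFeatures:
    def test_matches_brute_force(self, rng):
        """Oracle: independent per-feature RD computation + exhaustive sort."""
        truth = _truth(20)
        table = pd.DataFrame(rng.normal(0, 1, size=(60, 8)),
                             columns=[f"f{i}" for i in range(8)], index=truth.union())
        ranked = rank_features(table, truth, "SA")
        pos, neg = truth.members["SA"], truth.negatives("SA")
        brute = []
        for col in table.columns:
            p, q = table.loc[pos, col], table.loc[neg, col]
            rd = (p.mean() - q.mean()) / (p.std(ddof=0) + q.std(ddof=0))
            brute.append((col, rd))
        brute.sort(key=lambda fr: (-abs(fr[1]), fr[0]))
        assert [f for f, _ in ranked] == [f for f, _ in brute]
        np.testing.assert_allclose([r for _, r in ranked], [r for _, r in brute])

    def test_uninformative_feature_ranked_last(self, rng):
        truth = _truth(10)
        table = pd.DataFrame({
            "good": np.concatenate([np.full(10, 5.0) + rng.normal(0, .1, 10),
                                    rng.normal(0, 1, 20)]),
            "flat_noise": np.tile(rng.normal(0, 1, 10), 3),
        }, index=truth.union())
        ranked = rank_features(table, truth, "S")
        assert ranked[0][0] == "good"

    def test_duplicate_columns_tie_broken_by_name(self, rng):
        truth = _truth(10)
        vals = np.concatenate([rng.normal(3, 1, 10), rng.normal(0, 1, 20)])
        table = pd.DataFrame({"b_copy": vals, "a_copy": vals}, index=truth.union())
        ranked = rank_features(table, truth, "S")
        assert [f for f, _ in ranked] == ["a_copy", "b_copy"]

    def test_empty_negative_set_errors(self, rng):
        truth = TruthSet(members={"S": [f"s{i}" for i in range(40)]})
        table = pd.DataFrame({"x": rng.normal(0, 1, 40)},
                             index=truth.members["S"])
        with pytest.raises(ValueError):
            rank_features(table, truth, "S")


class TestBuildClassifier:
    def test_informative_feature_selected_first_and_separates(self, rng):
        table, truth = _toy_table(rng)
        c = build_classifier(table, truth, "S")
        assert c.features[0] == "informative"
        assert not c.degenerate
        s = c.score_series(table)
        assert s[truth.members["S"]].min() > s[truth.negatives("S")].max()

    def test_all_noise_flagged_degenerate(self, rng):
        truth = _truth(40)
        table = pd.DataFrame(rng.normal(0, 1, size=(120, 10)),
                             columns=[f"n{i}" for i in range(10)], index=truth.union())
        c = build_classifier(table, truth, "S")
        assert c.degenerate

    def test_offset_signs(self, rng):
        table, truth = _toy_table(rng, shift=3.0)
        c = build_classifier(table, truth, "S")
        s = c.score_series(table)
        assert s[truth.members["S"]].mean() > 0 > s[truth.negatives("S")].mean()

    def test_greedy_matches_exhaustive_rederivation(self, rng):
        """Oracle: re-derive the greedy selection rule independently on a
        small table and compare subset and weights."""
        table, truth = _toy_table(rng, n_noise=5)
        c = build_classifier(table, truth, "SA", tol=1e-3, patience=5)

        params = fit_normalization(table, truth.union())
        z = normalize(table, params)
        ranked = rank_features(z.loc[truth.union()], truth, "SA")
        pos, neg = truth.members["SA"], truth.negatives("SA")

        def lda_w(sel):
            zp, zn = z.loc[pos, sel].to_numpy(), z.loc[neg, sel].to_numpy()
            S = 0.5 * (np.cov(zp.T, ddof=0) + np.cov(zn.T, ddof=0))
            S = np.atleast_2d(S) + 1e-4 * np.eye(len(sel))
            return np.linalg.solve(S, zp.mean(0) - zn.mean(0)), zp, zn

        sel, best, rej = [], -np.inf, 0
        for f, _rd in ranked:
            w, zp, zn = lda_w(sel + [f])
            sep = abs(fisher_rd(zp @ w, zn @ w))
            if sep > best + 1e-3:
                sel, best, rej = sel + [f], sep, 0
            else:
                rej += 1
                if rej >= 5:
                    break
        assert c.features == sel
        w, zp, zn = lda_w(sel)
        sp, sn = zp @ w, zn @ w
        scale = sp.std() + sn.std()
        np.testing.assert_allclose(c.weights, w / scale, rtol=1e-9)

    def test_affine_invariance_of_assignment(self, rng):
        """Rescaling any raw feature (a*x + b, a>0) leaves labels unchanged:
        truth-union normalization absorbs affine maps."""
        table, truth = _toy_table(rng)
        extra = pd.DataFrame(rng.normal(0, 1, size=(40, table.shape[1])),
                             columns=table.columns,
                             index=[f"q{i}" for i in range(40)])
        full = pd.concat([table, extra])
        cls1 = build_all_classifiers(full, truth)
        lab1 = score_events(cls1, full)["assigned"]
        warped = full.copy()
        warped["informative"] = 3.5 * warped["informative"] + 11.0
        warped["noise0"] = 0.2 * warped["noise0"] - 4.0
        cls2 = build_all_classifiers(warped, truth)
        lab2 = score_events(cls2, warped)["assigned"]
        assert (lab1 == lab2).all()

    def test_yaml_round_trip(self, rng, tmp_path):
        table, truth = _toy_table(rng)
        c = build_classifier(table, truth, "S")
        path = tmp_path / "c.yaml"
        c.to_yaml(path)
        back = LinearClassifier.from_yaml(path)
        np.testing.assert_allclose(back.score_series(table), c.score_series(table))


class TestScoreEvents:
    def _dummy(self, target, feature, weight):
        return LinearClassifier(
            target=target, features=[feature], weights=np.array([weight]),
            rd_scores=np.array([weight]),
            normalization=clf.NormalizationParams(
                means=pd.Series({feature: 0.0}), stds=pd.Series({feature: 1.0})),
            offset=0.0)

    def test_argmax_of_positive_scores(self):
        table = pd.DataFrame({"x": [1.2], "y": [-0.3], "z": [0.1]}, index=["e"])
        cls = {"S": self._dummy("S", "x", 1.0), "SA": self._dummy("SA", "y", 1.0),
               "LA": self._dummy("LA", "z", 1.0)}
        out = score_events(cls, table)
        assert out.loc["e", "assigned"] == "S"

    def test_no_positive_scores_unclassified(self):
        table = pd.DataFrame({"x": [-1.0], "y": [-2.0], "z": [-0.5]}, index=["e"])
        cls = {"S": self._dummy("S", "x", 1.0), "SA": self._dummy("SA", "y", 1.0),
               "LA": self._dummy("LA", "z", 1.0)}
        assert score_events(cls, table).loc["e", "assigned"] == "unclassified"

    def test_exact_tie_goes_to_class_order(self):
        table = pd.DataFrame({"x": [0.7], "y": [0.7], "z": [0.1]}, index=["e"])
        cls = {"S": self._dummy("S", "x", 1.0), "SA": self._dummy("SA", "y", 1.0),
               "LA": self._dummy("LA", "z", 1.0)}
        assert score_events(cls, table).loc["e", "assigned"] == "S"

    def test_missing_feature_unclassified(self):
        table = pd.DataFrame({"x": [np.nan], "y": [5.0], "z": [-1.0]}, index=["e"])
        cls = {"S": self._dummy("S", "x", 1.0), "SA": self._dummy("SA", "y", 1.0),
               "LA": self._dummy("LA", "z", 1.0)}
        assert score_events(cls, table).loc["e", "assigned"] == "SA"
        table2 = pd.DataFrame({"x": [np.nan], "y": [-5.0], "z": [-1.0]}, index=["e"])
        assert score_events(cls, table2).loc["e", "assigned"] == "unclassified"


class TestAutoTruth:
    def test_default_sizes_disjoint_and_deterministic(self, default_sample_1000):
        _, truths, table = default_sample_1000
        t1 = auto_truth(table, truths, n_per_class=40)
        t2 = auto_truth(table, truths, n_per_class=40)
        assert t1.members == t2.members
        all_ids = t1.union()
        assert len(all_ids) == len(set(all_ids)) == 120

    def test_zero_requested_rejected(self, small_sample):
        _, truths, table = small_sample
        with pytest.raises(ValueError):
            auto_truth(table, truths, n_per_class=0)

    def test_shortfall_reported(self, small_sample):
        _, truths, table = small_sample
        with pytest.raises(ValueError, match="shortfall"):
            auto_truth(table, truths, n_per_class=1000)

    def test_size_outside_range_warns(self, default_sample_1000):
        _, truths, table = default_sample_1000
        with pytest.warns(UserWarning, match="35-50"):
            auto_truth(table, truths, n_per_class=20)
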