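"""Perturbation benchmark metrics: sign/scale preparation, down-sampled
AUROC against a brute-force U-statistic oracle, scaled rank, P_Hit and
cross-run concordance."""

import numpy as np
import pandas as pd
import pytest

from kinactbench import (
    PerturbationAnnotation,
    auroc_downsampled,
    concordance_stats,
    p_hit,
    prepare_signed_scaled_scores,
    rank_auroc,
    scaled_rank,
)


def _ann(rows):
    return PerturbationAnnotation(records=pd.DataFrame(rows, columns=["experiment", "kinase", "sign"]))


def brute_force_auroc(pos, neg):
    """All-pairs U-statistic with half-credit for ties."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestPrepare:
    def test_inhibition_flips_sign_and_scales_to_unit_sd(self):
        acts = pd.DataFrame({"e1": [-2.0, 1.0, 0.5]}, index=["A", "B", "C"])
        ann = _ann([("e1", "A", -1)])
        prep = prepare_signed_scaled_scores(acts, ann)
        assert prep["e1"].std(ddof=1) == pytest.approx(1.0)
        assert prep.loc["A", "e1"] > 0  # inhibited kinase now ranks high

    def test_activation_keeps_sign(self):
        acts = pd.DataFrame({"e1": [2.0, -1.0, 0.0]}, index=["A", "B", "C"])
        prep = prepare_signed_scaled_scores(acts, _ann([("e1", "A", 1)]))
        assert prep.loc["A", "e1"] > 0 > prep.loc["B", "e1"]

    def test_experiment_without_scored_target_excluded(self):
        acts = pd.DataFrame(
            {"e1": [np.nan, 1.0, 0.5], "e2": [1.0, 0.2, np.nan]},
            index=["A", "B", "C"],
        )
        ann = _ann([("e1", "A", 1), ("e2", "A", 1)])
        with pytest.warns(UserWarning):
            prep = prepare_signed_scaled_scores(acts, ann)
        assert list(prep.columns) == ["e2"]

    def test_zero_spread_experiment_excluded(self):
        acts = pd.DataFrame({"e1": [1.0, 1.0, 1.0], "e2": [2.0, 1.0, 0.0]},
                            index=["A", "B", "C"])
        ann = _ann([("e1", "A", 1), ("e2", "A", 1)])
        with pytest.warns(UserWarning):
            prep = prepare_signed_scaled_scores(acts, ann)
        assert list(prep.columns) == ["e2"]

    def test_annotated_experiment_missing_from_matrix_errors(self):
        acts = pd.DataFrame({"e1": [1.0, 0.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            prepare_signed_scaled_scores(acts, _ann([("eX", "A", 1)]))

    def test_mixed_signs_within_experiment_rejected(self):
        with pytest.raises(ValueError):
            _ann([("e1", "A", 1), ("e1", "B", -1)])


class TestAuroc:
    def test_tied_scores_hand_value(self):
        # TP scores [1,0] vs TN scores [1,0]: U = (0.5+1+0+0.5)/4 = 0.5
        assert rank_auroc([1.0, 0.0], [1.0, 0.0]) == pytest.approx(0.5)

    def test_perfect_separation_every_repeat(self):
        acts = pd.DataFrame(
            np.array([[5.0, 5.0], [0.1, 0.3], [0.2, 0.1], [0.0, 0.2]]),
            index=["A", "B", "C", "D"],
            columns=["e1", "e2"],
        )
        ann = _ann([("e1", "A", 1), ("e2", "A", 1)])
        prep = prepare_signed_scaled_scores(acts, ann)
        res = auroc_downsampled(prep, ann, n_rep=50, seed=0)
        assert np.all(res.distribution == 1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0.5, 1, size=rng.integers(3, 30))
        neg = rng.normal(0, 1, size=rng.integers(3, 170))
        # inject ties
        if seed % 2:
            neg[: min(3, pos.size)] = pos[:3][: min(3, pos.size)]
        assert rank_auroc(pos, neg) == pytest.approx(
            brute_force_auroc(list(pos), list(neg)), abs=1e-12
        )

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(30, 40))
        acts = pd.DataFrame(
            scores, index=[f"K{i}" for i in range(30)],
            columns=[f"e{j}" for j in range(40)],
        )
        ann = _ann([(f"e{j}", f"K{rng.integers(30)}", 1) for j in range(40)])
        prep = prepare_signed_scaled_scores(acts, ann)
        res = auroc_downsampled(prep, ann, n_rep=400, seed=1)
        assert abs(res.distribution.mean() - 0.5) < 0.1

    def test_score_negation_flips_distribution(self):
        rng = np.random.default_rng(9)
        prep = pd.DataFrame(
            rng.normal(size=(12, 6)),
            index=[f"K{i}" for i in range(12)],
            columns=[f"e{j}" for j in range(6)],
        )
        ann = _ann([(f"e{j}", f"K{j}", 1) for j in range(6)])
        a = auroc_downsampled(prep, ann, n_rep=300, seed=5)
        b = auroc_downsampled(-prep, ann, n_rep=300, seed=5)
        assert np.allclose(np.sort(a.distribution), np.sort(1 - b.distribution))


class TestScaledRank:
    def test_top_of_ten(self):
        prep = pd.DataFrame({"e1": np.linspace(1, 0.1, 10)},
                            index=[f"K{i}" for i in range(10)])
        res = scaled_rank(prep, _ann([("e1", "K0", 1)]))
        assert res.value == pytest.approx(0.1)

    def test_last_of_four_is_one(self):
        prep = pd.DataFrame({"e1": [3.0, 2.0, 1.0, 0.0]},
                            index=["A", "B", "C", "D"])
        res = scaled_rank(prep, _ann([("e1", "D", 1)]))
        assert res.value == pytest.approx(1.0)

    def test_two_level_averaging(self):
        # K1 ranks 1/10 and 3/10 in its two experiments -> 0.2;
        # K2 ranks 5/10 in one -> 0.5; cross-kinase mean 0.35
        idx = [f"K{i}" for i in range(1, 11)]
        cols = {}
        cols["e1"] = pd.Series(np.linspace(1, 0.1, 10), index=idx)  # K1 first
        e2 = pd.Series(np.linspace(1, 0.1, 10), index=idx)
        e2["K1"], e2["K3"] = e2["K3"], e2["K1"]  # K1 third
        cols["e2"] = e2
        e3 = pd.Series(np.linspace(1, 0.1, 10), index=idx)
        e3["K2"], e3["K5"] = e3["K5"], e3["K2"]  # K2 fifth
        cols["e3"] = e3
        prep = pd.DataFrame(cols)
        ann = _ann([("e1", "K1", 1), ("e2", "K1", 1), ("e3", "K2", 1)])
        res = scaled_rank(prep, ann)
        assert res.per_kinase["K1"] == pytest.approx(0.2)
        assert res.per_kinase["K2"] == pytest.approx(0.5)
        assert res.value == pytest.approx(0.35)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        prep = pd.DataFrame(
            rng.normal(size=(15, 5)),
            index=[f"K{i}" for i in range(15)],
            columns=[f"e{j}" for j in range(5)],
        )
        ann = _ann([(f"e{j}", f"K{j}", 1) for j in range(5)])
        base = scaled_rank(prep, ann)
        transformed = scaled_rank(np.exp(prep * 0.5) + 3, ann)
        assert transformed.value == pytest.approx(base.value)

    def test_negation_maps_rank(self):
        rng = np.random.default_rng(3)
        prep = pd.DataFrame(
            rng.normal(size=(11, 4)),
            index=[f"K{i}" for i in range(11)],
            columns=[f"e{j}" for j in range(4)],
        )
        ann = _ann([(f"e{j}", f"K{j}", 1) for j in range(4)])
        a = scaled_rank(prep, ann).details["per_instance"]
        b = scaled_rank(-prep, ann).details["per_instance"]
        n = 11
        assert np.allclose(b["rank"].to_numpy(), n + 1 - a["rank"].to_numpy())


class TestPHit:
    def test_rank_seven_hits_ten_not_five(self):
        prep = pd.DataFrame({"e1": np.linspace(1, 0.1, 12)},
                            index=[f"K{i}" for i in range(12)])
        ann = _ann([("e1", "K6", 1)])  # rank 7
        assert p_hit(prep, ann, k=5).value == 0.0
        assert p_hit(prep, ann, k=10).value == 1.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(6)
        prep = pd.DataFrame(
            rng.normal(size=(25, 8)),
            index=[f"K{i}" for i in range(25)],
            columns=[f"e{j}" for j in range(8)],
        )
        ann = _ann([(f"e{j}", f"K{3 * j}", 1) for j in range(8)])
        vals = [p_hit(prep, ann, k=k).value for k in (5, 10, 20)]
        assert vals == sorted(vals)

    def test_two_level_averaging(self):
        idx = [f"K{i}" for i in range(12)]
        base = pd.Series(np.linspace(1, 0.1, 12), index=idx)
        e2 = base.copy()
        e2["K0"], e2["K11"] = e2["K11"], e2["K0"]  # K0 last
        prep = pd.DataFrame({"e1": base, "e2": e2, "e3": base})
        ann = _ann([("e1", "K0", 1), ("e2", "K0", 1), ("e3", "K1", 1)])
        res = p_hit(prep, ann, k=5)
        assert res.value == pytest.approx((0.5 + 1.0) / 2)


class TestConcordance:
    def _mats(self):
        rng = np.random.default_rng(7)
        base = pd.DataFrame(
            rng.normal(size=(30, 4)),
            index=[f"K{i}" for i in range(30)],
            columns=[f"e{j}" for j in range(4)],
        )
        return base

    def test_self_agreement(self):
        base = self._mats()
        out = concordance_stats({"a": base, "b": base.copy()})
        for key in ("pearson", "spearman", "jaccard_up", "jaccard_down"):
            assert out[key].loc["a", "b"] == pytest.approx(1.0)

    def test_negation_anticorrelates(self):
        base = self._mats()
        out = concordance_stats({"a": base, "b": -base})
        assert out["pearson"].loc["a", "b"] == pytest.approx(-1.0)
        assert out["jaccard_up"].loc["a", "b"] == 0.0  # 30 kinases > 2k

    def test_monotone_transform_preserves_spearman_only(self):
        base = self._mats()
        out = concordance_stats({"a": base, "b": np.exp(base)})
        assert out["spearman"].loc["a", "b"] == pytest.approx(1.0)
        assert out["pearson"].loc["a", "b"] < 1.0
        assert out["jaccard_up"].loc["a", "b"] == pytest.approx(1.0)
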