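import numpy as np
import pandas as pd
import pytest

import resq
from resq.config import FACTORS
from resq.subgroup import (
    SUBGROUP_COVARIATES,
    SubgroupTable,
    assign_subgroup_levels,
    interaction_model,
    sign_consistency,
    subgroup_lasso_ranks,
)

from conftest import orthogonal_config, pipeline_frame


def make_two_level_data(seed, n=600, slope_a=0.5, slope_b=1.5):
    rng = np.random.default_rng(seed)
    group = np.repeat(["a", "b"], n // 2)
    f = rng.normal(size=n)
    slope = np.where(group == "a", slope_a, slope_b)
    y = slope * f + rng.normal(size=n)
    return pd.DataFrame({"res": y, "f": f, "grp": group})


class TestLevelAssignment:
    def test_age_and_education_bins(self):
        df = pd.DataFrame(
            {
                "age_years": [18, 30, 31, 45, 46, 60, 61, 88],
                "education_years": [10, 12, 13, 16, 17, 20, 21, 25],
                "country": ["X"] * 8,
            }
        )
        out = assign_subgroup_levels(df, min_country_n=1)
        assert list(out["age_group"]) == [
            "18-30", "18-30", "31-45", "31-45", "46-60", "46-60", "61+", "61+",
        ]
        assert list(out["education_group"]) == [
            "<13", "<13", "13-16", "13-16", "17-20", "17-20", "21+", "21+",
        ]

    def test_small_countries_pooled(self):
        df = pd.DataFrame(
            {
                "age_years": [30] * 10,
                "education_years": [15] * 10,
                "country": ["Big"] * 8 + ["Tiny", "Tinier"],
            }
        )
        out = assign_subgroup_levels(df, min_country_n=5)
        assert set(out["country_group"]) == {"Big", "Other"}


class TestInteractionModel:
    def test_matches_stratified_fit_oracle(self):
        # with no shared base covariates the interaction model is exactly
        # equivalent to fitting each level separately, up to the pooled
        # error variance used for the standard errors
        data = make_two_level_data(0)
        fit = interaction_model(data, "res", "f", "grp")
        for lvl in ("a", "b"):
            chunk = data[data["grp"] == lvl]
            X = np.column_stack([np.ones(len(chunk)), chunk["f"]])
            beta = np.linalg.solve(X.T @ X, X.T @ chunk["res"].to_numpy())
            assert np.isclose(fit.slopes[lvl], beta[1], atol=1e-8), lvl

    def test_detects_strong_moderation(self):
        data = make_two_level_data(1, n=2000, slope_a=0.2, slope_b=2.0)
        fit = interaction_model(data, "res", "f", "grp")
        assert fit.p_interaction < 1e-6
        assert fit.slopes["b"] > fit.slopes["a"]

    def test_null_interaction_p_uniform_tail(self):
        data = make_two_level_data(2, n=4000, slope_a=0.8, slope_b=0.8)
        fit = interaction_model(data, "res", "f", "grp")
        assert fit.p_interaction > 0.01

    def test_lr_type_one_error_near_alpha(self):
        # under the null, the interaction LR test should reject at about
        # its nominal 5% rate when thresholded at p<0.05
        rng = np.random.default_rng(3)
        rejections = 0
        reps, n = 500, 400
        for _ in range(reps):
            group = np.repeat(["a", "b"], n // 2)
            f = rng.normal(size=n)
            y = 0.5 * f + rng.normal(size=n)
            data = pd.DataFrame({"res": y, "f": f, "grp": group})
            fit = interaction_model(data, "res", "f", "grp")
            rejections += int(fit.p_interaction < 0.05)
        assert 0.03 <= rejections / reps <= 0.07

    def test_excluded_levels_dropped(self):
        data = make_two_level_data(4)
        data.loc[:49, "grp"] = "diverse"
        data = data.rename(columns={"grp": "gender"})
        fit = interaction_model(data, "res", "f", "gender")
        assert "diverse" not in fit.levels
        assert fit.n == (data["gender"] != "diverse").sum()

    def test_single_level_rejected(self):
        data = make_two_level_data(5)
        data["grp"] = "a"
        with pytest.raises(ValueError, match="levels"):
            interaction_model(data, "res", "f", "grp")

    def test_small_levels_flagged(self):
        data = make_two_level_data(6)
        data.loc[data.index[:590], "grp"] = "a"
        data.loc[data.index[590:], "grp"] = "b"
        fit = interaction_model(data, "res", "f", "grp", min_level_size=30)
        assert fit.small_levels == ["b"]

    def test_generator_weight_modifier_recovered(self):
        # halving the planning-ability weight for the oldest age band
        # should roughly halve that band's estimated slope
        cfg = orthogonal_config(
            n_participants=10000,
            seed=7,
            weight_modifiers=[("age_band", "61+", "pac", 0.5)],
        )
        res = assign_subgroup_levels(pipeline_frame(cfg))
        fit = interaction_model(res, "res_c", "pac", "age_group")
        young = np.mean([fit.slopes[l] for l in ("18-30", "31-45", "46-60")])
        ratio = fit.slopes["61+"] / young
        assert 0.3 < ratio < 0.7
        assert fit.p_interaction < 0.05
        assert fit.slopes["61+"] == min(fit.slopes.values())


class TestSubgroupLasso:
    def test_small_level_skipped(self):
        rng = np.random.default_rng(8)
        n = 500
        data = pd.DataFrame({f: rng.normal(size=n) for f in FACTORS})
        data["res_c"] = data["rec"] + rng.normal(size=n)
        data["grp"] = ["big"] * (n - 5) + ["tiny"] * 5
        ranks, dev, skipped = subgroup_lasso_ranks(
            data, "res_c", "grp", random_state=0
        )
        assert skipped == ["tiny"]
        assert set(ranks) == {"big"}
        assert 0.0 <= dev["big"] <= 1.0

    def test_levels_partition_rows(self):
        rng = np.random.default_rng(9)
        n = 400
        data = pd.DataFrame({f: rng.normal(size=n) for f in FACTORS})
        data["res_c"] = data["opt"] + rng.normal(size=n)
        data["grp"] = rng.choice(["a", "b", "c"], size=n)
        ranks, _, skipped = subgroup_lasso_ranks(data, "res_c", "grp", random_state=1)
        assert sorted(list(ranks) + skipped) == sorted(data["grp"].unique())
        for lvl_ranks in ranks.values():
            assert sorted(lvl_ranks.values()) == list(range(1, len(FACTORS) + 1))


class TestSignConsistency:
    @staticmethod
    def table_from(coefs, lo, hi):
        idx = pd.MultiIndex.from_tuples(
            [("cov", f"l{i}") for i in range(len(coefs))], names=["covariate", "level"]
        )
        cols = [f"f{j}" for j in range(len(coefs[0]))]
        return SubgroupTable(
            coefficients=pd.DataFrame(coefs, index=idx, columns=cols),
            ci_low=pd.DataFrame(lo, index=idx, columns=cols),
            ci_high=pd.DataFrame(hi, index=idx, columns=cols),
            interaction_p=pd.DataFrame(),
        )

    def test_consistent_table_zero_flips(self):
        coefs = [[0.5, -0.3], [0.7, -0.2], [0.6, -0.4]]
        lo = [[0.1, -0.5], [0.2, -0.4], [0.1, -0.6]]
        hi = [[0.9, -0.1], [1.2, -0.05], [1.1, -0.2]]
        audit = sign_consistency(self.table_from(coefs, lo, hi))
        assert audit == {"sign_flips": 0, "ci_zero_crossings": 0, "n_cells": 6}

    def test_minority_sign_counted_once(self):
        coefs = [[0.5], [0.7], [-0.1]]
        lo = [[0.1], [0.2], [-0.4]]
        hi = [[0.9], [1.2], [0.2]]
        audit = sign_consistency(self.table_from(coefs, lo, hi))
        assert audit["sign_flips"] == 1
        assert audit["ci_zero_crossings"] == 1

    def test_full_grid_cell_count(self):
        # 29 levels x 9 factors
        coefs = [[0.5] * 9] * 29
        lo = [[0.1] * 9] * 29
        hi = [[0.9] * 9] * 29
        audit = sign_consistency(self.table_from(coefs, lo, hi))
        assert audit["n_cells"] == 261
        assert audit["sign_flips"] == 0


@pytest.fixture(scope="module")
def strong_table():
    weights = {f: 1.0 for f in FACTORS}
    weights["neu"] = -1.0
    cfg = orthogonal_config(n_participants=10000, seed=11, factor_weights=weights)
    res = assign_subgroup_levels(pipeline_frame(cfg))
    return resq.build_subgroup_table(
        res, "res_c", with_lasso=False,
        subgroup_covariates=["gender", "age_group", "diagnosis"],
    )


class TestFullTable:
    def test_zero_sign_flips_under_uniform_weights(self, strong_table):
        audit = sign_consistency(strong_table)
        assert audit["sign_flips"] == 0

    def test_rows_cover_all_levels(self, strong_table):
        covs = set(strong_table.coefficients.index.get_level_values("covariate"))
        assert covs == {"gender", "age_group", "diagnosis"}
        assert list(strong_table.coefficients.columns) == list(FACTORS)

    def test_homogeneous_generator_identical_rank_vectors(self):
        # with distinct, well-separated weights and no moderation, every
        # gender level should recover the same factor ranking
        weights = {
            f: s * (0.5 + 0.5 * i)
            for i, (f, s) in enumerate(
                (f, -1.0 if f == "neu" else 1.0) for f in FACTORS
            )
        }
        identical = 0
        for seed in range(5):
            cfg = orthogonal_config(
                n_participants=8000, seed=20 + seed, factor_weights=weights
            )
            res = pipeline_frame(cfg)
            ranks, _, skipped = subgroup_lasso_ranks(
                res, "res_c", "gender", random_state=seed
            )
            assert not skipped
            vectors = {tuple(sorted(r.items())) for r in ranks.values()}
            identical += int(len(vectors) == 1)
        assert identical >= 4

    def test_default_covariate_list(self):
        assert SUBGROUP_COVARIATES == (
            "gender", "age_group", "country_group", "income_band",
            "education_group", "diagnosis",
        )
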