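"""Censoring imputation, vernalization scoring and Q_ST variance components."""

import numpy as np
import pandas as pd
import pytest

from popgen.io import TraitTable
from popgen.quantgen import (
    QuantGenError,
    accession_means,
    compare_obligate_proportions,
    group_tukey,
    impute_censored,
    qst,
    trait_range_compare,
    vernalization_requirement,
)
from popgen.simulate import simulate_traits


def table_from_rows(rows):
    return TraitTable(pd.DataFrame(rows))


def plant(acc, pid, ft, ln, flowered=True, vern=False, **extra):
    return {
        "accession_id": acc,
        "plant_id": pid,
        "flowering_time": ft,
        "leaf_number": ln,
        "flowered": flowered,
        "vernalized": vern,
        **extra,
    }


class TestImputeCensored:
    def test_no_censoring_leaves_table_unchanged(self):
        t = table_from_rows([plant("a", "p1", 50, 40), plant("a", "p2", 60, 45)])
        out, rec = impute_censored(t)
        assert rec.n_imputed == 0
        pd.testing.assert_frame_equal(out.data, t.data, check_dtype=False)

    def test_exact_linear_relation_gives_150_at_200(self):
        # LN = 0.75 * FT exactly; a censored plant gets FT=200, LN=150
        rows = [plant("a", f"p{i}", ft, 0.75 * ft) for i, ft in enumerate((40, 80, 120, 160))]
        rows.append(plant("b", "px", np.nan, np.nan, flowered=False))
        out, rec = impute_censored(table_from_rows(rows), ft_limit=200)
        imputed = out.data[out.data["plant_id"] == "px"].iloc[0]
        assert imputed["flowering_time"] == 200
        assert imputed["leaf_number"] == pytest.approx(150.0)
        assert rec.ln_at_limit == pytest.approx(150.0)
        assert rec.n_imputed == 1

    def test_never_lowers_recorded_values(self):
        rows = [plant("a", f"p{i}", ft, 0.5 * ft + 10) for i, ft in enumerate((30, 90, 150))]
        rows.append(plant("a", "pc", np.nan, np.nan, flowered=False))
        t = table_from_rows(rows)
        out, _ = impute_censored(t, ft_limit=200)
        merged = t.data.merge(out.data, on="plant_id", suffixes=("_in", "_out"))
        recorded = merged["flowering_time_in"].notna()
        assert (merged.loc[recorded, "flowering_time_out"]
                >= merged.loc[recorded, "flowering_time_in"]).all()
        assert (merged.loc[recorded, "leaf_number_out"]
                >= merged.loc[recorded, "leaf_number_in"]).all()

    def test_all_censored_rejected(self):
        t = table_from_rows([plant("a", "p1", np.nan, np.nan, flowered=False)])
        with pytest.raises(QuantGenError):
            impute_censored(t)


class TestVernalization:
    def test_all_flowered_nothing_obligate(self):
        t = table_from_rows(
            [plant("a", "p1", 50, 40), plant("a", "p2", 55, 42), plant("b", "p3", 60, 44)]
        )
        summaries = vernalization_requirement(t)
        assert all(not s.obligate_vernalization for s in summaries)

    def test_obligate_requires_flowering_under_vernalization(self):
        rows = [
            plant("a", "p1", np.nan, np.nan, flowered=False),
            plant("a", "p2", np.nan, np.nan, flowered=False),
            plant("a", "pv", 90, 60, flowered=True, vern=True),
            plant("b", "p3", np.nan, np.nan, flowered=False),
            plant("b", "pv2", np.nan, np.nan, flowered=False, vern=True),
        ]
        summaries = {s.accession: s for s in vernalization_requirement(table_from_rows(rows))}
        assert summaries["a"].obligate_vernalization
        assert not summaries["b"].obligate_vernalization  # never flowered at all

    def test_proportion_comparison_fisher(self):
        def fake(n, k):
            rows = []
            for i in range(n):
                flowered = i >= k
                rows.append(
                    plant(f"x{i}", f"x{i}p", 50 if flowered else np.nan,
                          40 if flowered else np.nan, flowered=flowered)
                )
                rows.append(plant(f"x{i}", f"x{i}v", 80, 50, flowered=True, vern=True))
            return vernalization_requirement(table_from_rows(rows))

        pa, pb, p = compare_obligate_proportions(fake(20, 4), fake(25, 3))
        assert pa == pytest.approx(20.0)
        assert pb == pytest.approx(12.0)
        assert p > 0.05  # 20% vs 12% at these sizes is not significant


class TestQst:
    def test_identical_group_means_near_zero(self, rng):
        values = {f"a{i}": float(i % 5) for i in range(20)}
        grouping = {f"a{i}": "g1" if i < 10 else "g2" for i in range(20)}
        res = qst(values, grouping, method="anova_moments")
        assert res.Q_ST == pytest.approx(0.0, abs=0.05)

    def test_moments_and_reml_agree_on_balanced_design(self, rng):
        accs = [f"a{i}" for i in range(40)]
        grouping = {a: f"g{i // 10}" for i, a in enumerate(accs)}
        effects = {f"g{k}": rng.normal(0, 2) for k in range(4)}
        values = {a: effects[grouping[a]] + rng.normal(0, 1) for a in accs}
        m = qst(values, grouping, method="anova_moments")
        r = qst(values, grouping, method="reml")
        assert m.Q_ST == pytest.approx(r.Q_ST, abs=1e-4)
        assert m.V_W == pytest.approx(r.V_W, rel=1e-3)

    def test_equal_variances_give_half(self):
        ests = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            grouping = {f"a{i}": f"g{i // 10}" for i in range(200)}
            effects = {f"g{k}": rng.normal(0, 1) for k in range(20)}
            values = {a: effects[g] + rng.normal(0, 1) for a, g in grouping.items()}
            ests.append(qst(values, grouping, method="anova_moments").Q_ST)
        assert float(np.mean(ests)) == pytest.approx(0.5, abs=0.05)

    def test_single_accession_group_dropped(self, rng):
        values = {f"a{i}": float(rng.normal()) for i in range(7)}
        grouping = {f"a{i}": "g1" if i < 3 else "g2" for i in range(6)}
        grouping["a6"] = "lonely"
        res = qst(values, grouping, method="anova_moments")
        assert res.Q_ST >= 0.0  # lonely group silently dropped

    def test_fewer_than_two_groups_rejected(self, rng):
        values = {f"a{i}": float(rng.normal()) for i in range(4)}
        grouping = {f"a{i}": "g1" for i in range(4)}
        with pytest.raises(QuantGenError):
            qst(values, grouping)

    def test_permutation_p_small_for_strong_separation(self, rng):
        grouping = {f"a{i}": f"g{i // 8}" for i in range(24)}
        values = {a: 10.0 * int(g[1]) + rng.normal(0, 0.5) for a, g in grouping.items()}
        res = qst(values, grouping, method="anova_moments", n_perm=199, seed=4)
        assert res.Q_ST > 0.9
        assert res.p_value < 0.05


class TestGroupTukey:
    def test_identical_groups_share_letter(self):
        # every group holds exactly the same sample values: nothing to reject
        values = {f"a{i}": float(i // 3) for i in range(30)}
        grouping = {f"a{i}": f"g{i % 3}" for i in range(30)}
        letters = group_tukey(values, grouping)
        assert len(set(letters.values())) == 1

    def test_separated_groups_get_distinct_letters(self, rng):
        grouping = {f"a{i}": "g1" if i < 10 else "g2" for i in range(20)}
        values = {a: (0.0 if g == "g1" else 5.0) + rng.normal(0, 1) for a, g in grouping.items()}
        letters = group_tukey(values, grouping)
        assert letters["g1"] != letters["g2"]

    def test_one_outlier_group_among_three(self, rng):
        grouping = {f"a{i}": f"g{i // 10}" for i in range(30)}
        shift = {"g0": 0.0, "g1": 0.0, "g2": 8.0}
        values = {a: shift[g] + rng.normal(0, 1) for a, g in grouping.items()}
        letters = group_tukey(values, grouping)
        assert letters["g0"] == letters["g1"]
        assert letters["g2"] != letters["g0"]


class TestRangeCompare:
    def test_identical_sets_high_p(self, rng):
        a = rng.normal(0, 1, 15)
        res = trait_range_compare(a, a.copy(), n_perm=199, seed=1)
        assert res.p_value > 0.5
        assert res.range_a == res.range_b

    def test_nested_ranges_detected(self, rng):
        wide = np.concatenate([rng.uniform(0, 200, 40), [0.0, 200.0]])
        narrow = rng.uniform(90, 110, 42)
        res = trait_range_compare(narrow, wide, n_perm=499, seed=2)
        assert res.p_value < 0.05
        assert res.range_a < res.range_b


class TestSimulatedTraits:
    def test_censoring_flags_and_imputation_flow(self):
        t, _ = simulate_traits(["g1"] * 10 + ["g2"] * 10, V_B=400.0, V_W=25.0,
                               censor_at=120.0, seed=3)
        assert (~t.data["flowered"]).any()
        out, rec = impute_censored(t, ft_limit=120.0)
        assert out.data["flowering_time"].notna().all()

    def test_qst_recovery_from_trait_table(self):
        ests = []
        for seed in range(10):
            t, _ = simulate_traits(
                [f"g{i // 10}" for i in range(100)], V_B=1.0, V_W=1.0,
                seed=200 + seed, plants_per_accession=3, plant_sd=0.1,
            )
            means = accession_means(t, "flowering_time")
            grouping = (
                t.data.drop_duplicates("accession_id").set_index("accession_id")["group"].to_dict()
            )
            ests.append(qst(means, grouping, method="anova_moments").Q_ST)
        assert float(np.mean(ests)) == pytest.approx(0.5, abs=0.1)
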