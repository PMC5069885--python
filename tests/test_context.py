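"""Context statistics: state overlay, effect classification, rank tests
against enumeration oracles, matching, and invariances."""
import itertools

import numpy as np
import pandas as pd
import pytest

from tripkit import (
    ChromatinStateMap,
    assign_state,
    compute_effects,
    covariate_correlation,
    expression_matched_controls,
    mark_subset_test,
    memory_summary,
    rank_sum_test,
    state_vs_rest_test,
)


@pytest.fixture()
def two_interval_map():
    return ChromatinStateMap(
        pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [1000, 2000],
             "end": [2000, 3000], "state": [7, 3]}
        )
    )


def test_state_lookup_half_open(two_interval_map):
    sites = pd.DataFrame(
        {"chrom": ["chr1"] * 4, "position": [1500, 1999, 2000, 3000]},
        index=["a", "b", "c", "d"],
    )
    got = assign_state(sites, two_interval_map)
    assert got["a"] == 7 and got["b"] == 7
    assert got["c"] == 3                     # boundary joins the second interval
    assert pd.isna(got["d"])                 # past the segmentation end


def test_overlapping_intervals_rejected():
    with pytest.raises(ValueError, match="overlap"):
        ChromatinStateMap(
            pd.DataFrame(
                {"chrom": ["chr1", "chr1"], "start": [0, 500],
                 "end": [1000, 1500], "state": [1, 2]}
            )
        )


def test_bed_roundtrip(two_interval_map, tmp_path):
    path = tmp_path / "states.bed"
    two_interval_map.to_bed(path)
    back = ChromatinStateMap.from_bed(path)
    pd.testing.assert_frame_equal(back.intervals, two_interval_map.intervals)


def test_effect_classification_and_summary():
    ctrl = pd.Series({"a": 0.4, "b": 0.4, "c": 0.4, "d": 0.4, "e": 0.0})
    teth = pd.Series({"a": 0.1, "b": 0.0, "c": 0.5, "d": 1.2, "e": 0.0})
    eff, summary = compute_effects(ctrl, teth)
    assert eff.at["a", "fc"] == pytest.approx(0.25)
    assert eff.at["a", "effect_class"] == "down2x"
    assert eff.at["b", "effect_class"] == "silenced"
    assert eff.at["c", "effect_class"] == "within2x"
    assert eff.at["d", "effect_class"] == "up2x"
    assert pd.isna(eff.at["e", "fc"])        # undetectable control: no fold change
    assert summary["n_control_detectable"] == 4
    assert summary["frac_silenced"] == pytest.approx(0.25)
    assert summary["frac_down2x"] == pytest.approx(0.5)
    assert summary["n_up2x"] == 1
    assert summary["mean_fc_both_detectable"] == pytest.approx(np.mean([0.25, 1.25, 3.0]))


def _exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided p as the tail mass of the rank-sum
    distribution over all assignments."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[: len(x)].sum()
    sums = [
        sum(comb) for comb in itertools.combinations(ranks, len(x))
    ]
    mean = np.mean(sums)
    p = np.mean([abs(s - mean) >= abs(obs - mean) - 1e-9 for s in sums])
    return p


@pytest.mark.parametrize(
    "x,y",
    [
        ([0.1, 0.2, 0.3], [0.4, 0.5, 0.6]),
        ([0.1, 0.9, 0.3], [0.2, 0.5, 0.6, 0.7]),
        ([1.0, 2.0], [1.5, 2.5, 3.5]),
        ([0.05, 0.5, 0.22, 0.9], [0.4, 0.11]),
    ],
)
def test_rank_sum_matches_enumeration_oracle(x, y):
    assert rank_sum_test(x, y) == pytest.approx(_exact_rank_sum_p(x, y))


def _effects_frame(fc_by_state, expr=None):
    rows = []
    for state, fcs in fc_by_state.items():
        for i, fc in enumerate(fcs):
            rows.append((f"s{state}_{i}", state, fc))
    eff = pd.DataFrame(rows, columns=["barcode", "state", "fc"]).set_index("barcode")
    eff["control_expr"] = expr if expr is not None else 1.0
    eff["tethered_expr"] = eff["fc"] * eff["control_expr"]
    return eff


def test_state_vs_rest_null_gives_unit_ratio():
    fcs = list(np.linspace(0.05, 1.0, 40))
    eff = _effects_frame({7: fcs, 1: fcs})
    cmp_ = state_vs_rest_test(eff, 7)
    assert cmp_.median_ratio == pytest.approx(1.0)
    assert cmp_.pvalue > 0.5


def test_state_vs_rest_detects_enhanced_repression():
    rng = np.random.default_rng(1)
    eff = _effects_frame({7: list(rng.uniform(0.0, 0.2, 30)),
                          1: list(rng.uniform(0.2, 1.0, 100))})
    cmp_ = state_vs_rest_test(eff, 7)
    assert cmp_.direction == "enhanced_repression"
    assert cmp_.median_ratio > 2
    assert cmp_.pvalue < 1e-6


def test_state_vs_rest_requires_minimum_members():
    eff = _effects_frame({7: [0.1, 0.2], 1: [0.3] * 20})
    assert state_vs_rest_test(eff, 7) is None


def test_mark_subset_null_ratio_near_one():
    rng = np.random.default_rng(2)
    fcs = rng.lognormal(-1.5, 0.8, 2000)
    eff = _effects_frame({1: list(fcs)})
    mark = pd.Series(rng.random(len(eff)) < 0.3, index=eff.index)
    cmp_ = mark_subset_test(eff, mark)
    assert 0.85 < cmp_.median_ratio < 1.18
    assert cmp_.n_group == int(mark.sum())


def test_matching_picks_nearest_on_log_scale():
    eff = _effects_frame({7: [0.5], 1: [0.4, 0.6, 0.3]},)
    eff["control_expr"] = [1.0, 0.5, 1.1, 3.0]
    eff["tethered_expr"] = eff["fc"] * eff["control_expr"]
    m = expression_matched_controls(eff, focal_state=7, seed=0)
    assert list(m.pairs["matched_barcode"]) == ["s1_1"]      # expr 1.1 nearest to 1.0
    assert m.excluded == []


def test_matching_excludes_out_of_range_focal():
    eff = _effects_frame({7: [0.5, 0.5], 1: [0.4, 0.6, 0.3]})
    eff["control_expr"] = [1.0, 9.0, 0.5, 1.1, 3.0]          # 9.0 above pool max
    eff["tethered_expr"] = eff["fc"] * eff["control_expr"]
    m = expression_matched_controls(eff, focal_state=7, seed=0)
    assert m.excluded == ["s7_1"]
    assert len(m.pairs) == 1


def test_matching_identical_pool_gives_unit_ratio():
    fcs = list(np.linspace(0.1, 1.0, 15))
    eff = _effects_frame({7: fcs, 1: fcs + fcs})
    eff["control_expr"] = np.concatenate([fcs, fcs, fcs]) * 10   # matchable exactly
    m = expression_matched_controls(eff, focal_state=7, seed=3)
    assert m.median_ratio == pytest.approx(1.0)


def test_matching_rejects_undersized_pool():
    eff = _effects_frame({7: [0.1, 0.2, 0.3], 1: [0.5]})
    with pytest.raises(ValueError, match="pool"):
        expression_matched_controls(eff, focal_state=7)


def test_matching_reduces_expression_confounding():
    """When fold change is made to depend on expression, comparing against
    expression-matched controls recovers the true state effect far better
    than the raw state-vs-rest contrast."""
    rng = np.random.default_rng(5)
    true_state_effect = 2.0
    n_focal, n_pool = 60, 600
    expr_focal = rng.lognormal(-1.0, 0.3, n_focal)        # low-expression state
    expr_pool = rng.lognormal(1.0, 1.0, n_pool)
    fc_of = lambda e: 0.2 * e                             # strong confounding
    eff = pd.DataFrame(
        {
            "state": [7] * n_focal + [1] * n_pool,
            "control_expr": np.concatenate([expr_focal, expr_pool]),
            "fc": np.concatenate(
                [fc_of(expr_focal) / true_state_effect, fc_of(expr_pool)]
            ),
        },
        index=[f"r{i}" for i in range(n_focal + n_pool)],
    )
    eff["tethered_expr"] = eff["fc"] * eff["control_expr"]
    unmatched = state_vs_rest_test(eff, 7).median_ratio
    matched = expression_matched_controls(eff, 7, seed=0).median_ratio
    assert abs(matched - true_state_effect) < abs(unmatched - true_state_effect)


def test_covariate_correlation_edge_cases():
    eff = _effects_frame({1: list(np.linspace(0.1, 1.0, 30))})
    r, p, n = covariate_correlation(eff, eff["fc"].rename("cov"), method="spearman")
    assert r == pytest.approx(1.0)
    r, p, n = covariate_correlation(eff, pd.Series(1.0, index=eff.index))
    assert np.isnan(r)
    with pytest.raises(ValueError):
        covariate_correlation(eff, eff["fc"], method="kendall")


def test_memory_summary_trivial_cases():
    ctrl = pd.Series({"a": 0.5, "b": 1.0, "c": 2.0})
    same = memory_summary(ctrl, ctrl.copy())
    assert same.mean_fc == pytest.approx(1.0)
    assert same.sd_fc == pytest.approx(0.0)
    gone = memory_summary(ctrl, pd.Series(0.0, index=ctrl.index))
    assert gone.mean_fc == 0.0


def test_statistics_invariant_under_relabeling_and_order():
    rng = np.random.default_rng(8)
    eff = _effects_frame({7: list(rng.uniform(0, 0.5, 25)),
                          1: list(rng.uniform(0, 1, 60)),
                          2: list(rng.uniform(0, 1, 40))})
    base = state_vs_rest_test(eff, 7)
    shuffled = eff.sample(frac=1.0, random_state=1)
    shuffled.index = [f"x{i}" for i in range(len(shuffled))]
    again = state_vs_rest_test(shuffled, 7)
    assert again.median_ratio == base.median_ratio
    assert again.pvalue == base.pvalue
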