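"""Per-rail estimates, confidence intervals and ANOVA tests against
closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thalesarray import (
    InferenceError,
    NoiseModel,
    TargetSpec,
    angle_records,
    estimate_rail_deviations,
    generate_cdo_array,
    interaction_test,
    omnibus_rail_test,
    validate_intake_frame,
)


def records_frame(devs_by_rail, species="sp"):
    rows = [
        {"species": species, "rail": rail, "group": None,
         "beta_deg": 90.0 + d, "deviation_deg": float(d), "position": "on"}
        for rail, devs in devs_by_rail.items()
        for d in devs
    ]
    return pd.DataFrame(rows)


def pooled_cell_means_oracle(devs_by_rail, ci=0.95):
    """Hand-rolled cell-means model: group means + pooled residual variance."""
    k = len(devs_by_rail)
    n = sum(len(v) for v in devs_by_rail.values())
    ss = sum(
        float(np.sum((np.asarray(v) - np.mean(v)) ** 2)) for v in devs_by_rail.values()
    )
    df = n - k
    s2 = ss / df
    tcrit = stats.t.ppf(0.5 + ci / 2, df)
    out = {}
    for rail, v in devs_by_rail.items():
        m = float(np.mean(v))
        hw = tcrit * np.sqrt(s2 / len(v))
        out[rail] = (m, m - hw, m + hw)
    return out


def test_t_interval_textbook_case():
    """One rail with deviations {-10, 0, 10}: mean 0, CI half-width
    t(2, .975) * 10/sqrt(3) = 24.84."""
    est = estimate_rail_deviations(records_frame({"1:1": [-10, 0, 10]}))
    row = est.iloc[0]
    assert row["mean_beta_dev"] == pytest.approx(0.0, abs=1e-12)
    expected_hw = stats.t.ppf(0.975, 2) * 10 / np.sqrt(3)
    assert expected_hw == pytest.approx(24.84, abs=0.01)
    assert row["upr95"] == pytest.approx(expected_hw, abs=1e-8)
    assert row["lwr95"] == pytest.approx(-expected_hw, abs=1e-8)
    assert bool(row["consistent_with_cdo"])


def test_zero_variance_gives_zero_width_interval():
    est = estimate_rail_deviations(records_frame({"1:1": [5.0, 5.0, 5.0]}))
    row = est.iloc[0]
    assert row["mean_beta_dev"] == pytest.approx(5.0)
    assert row["upr95"] - row["lwr95"] == pytest.approx(0.0, abs=1e-10)
    assert not bool(row["consistent_with_cdo"])


def test_pooled_estimates_match_closed_form_oracle():
    rng = np.random.default_rng(11)
    devs = {
        "0:1": rng.normal(4, 3, 9).tolist(),
        "1:2": rng.normal(-2, 3, 14).tolist(),
        "1:1": rng.normal(0, 3, 11).tolist(),
        "2:1": rng.normal(1, 3, 8).tolist(),
    }
    est = estimate_rail_deviations(records_frame(devs)).set_index("ratio")
    oracle = pooled_cell_means_oracle(devs)
    for rail, (m, lo, hi) in oracle.items():
        assert est.loc[rail, "mean_beta_dev"] == pytest.approx(m, abs=1e-8)
        assert est.loc[rail, "lwr95"] == pytest.approx(lo, abs=1e-8)
        assert est.loc[rail, "upr95"] == pytest.approx(hi, abs=1e-8)
        assert est.loc[rail, "n"] == len(devs[rail])


def test_independent_per_rail_intervals_flag():
    rng = np.random.default_rng(5)
    devs = {"1:1": rng.normal(0, 1, 10).tolist(), "2:1": rng.normal(0, 6, 10).tolist()}
    pooled = estimate_rail_deviations(records_frame(devs)).set_index("ratio")
    indep = estimate_rail_deviations(records_frame(devs), pooled=False).set_index("ratio")
    # same means, but the quiet rail's own interval is narrower than pooled
    assert indep["mean_beta_dev"].to_dict() == pytest.approx(
        pooled["mean_beta_dev"].to_dict()
    )
    w = lambda df, r: df.loc[r, "upr95"] - df.loc[r, "lwr95"]
    assert w(indep, "1:1") < w(pooled, "1:1")
    x = np.asarray(devs["1:1"])
    hw = stats.t.ppf(0.975, 9) * x.std(ddof=1) / np.sqrt(10)
    assert w(indep, "1:1") == pytest.approx(2 * hw, abs=1e-8)


def test_estimates_order_invariant_and_duplication_shrinks_ci():
    rng = np.random.default_rng(2)
    devs = {"1:2": rng.normal(1, 2, 30).tolist(), "2:1": rng.normal(-1, 2, 30).tolist()}
    rec = records_frame(devs)
    shuffled = rec.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = estimate_rail_deviations(rec).set_index("ratio").sort_index()
    b = estimate_rail_deviations(shuffled).set_index("ratio").sort_index()
    pd.testing.assert_frame_equal(a, b)
    doubled = estimate_rail_deviations(
        pd.concat([rec, rec], ignore_index=True)
    ).set_index("ratio")
    for rail in devs:
        assert doubled.loc[rail, "mean_beta_dev"] == pytest.approx(
            a.loc[rail, "mean_beta_dev"], abs=1e-10
        )
        ratio = (a.loc[rail, "upr95"] - a.loc[rail, "lwr95"]) / (
            doubled.loc[rail, "upr95"] - doubled.loc[rail, "lwr95"]
        )
        assert ratio == pytest.approx(np.sqrt(2), rel=0.03)


def test_holm_adjustment_column():
    rng = np.random.default_rng(8)
    devs = {f"1:{k}": rng.normal(k, 1, 6).tolist() for k in (1, 2, 3)}
    est = estimate_rail_deviations(records_frame(devs), holm=True)
    assert "p_holm" in est.columns
    assert (est["p_holm"] >= est["p_value"] - 1e-15).all()


def test_single_observation_everywhere_is_an_error():
    with pytest.raises(InferenceError, match="residual degrees"):
        estimate_rail_deviations(records_frame({"1:1": [1.0], "2:1": [2.0]}))


def test_omnibus_f_closed_forms():
    """Equal group means give F = 0; {0,2} vs {10,12} gives F = 50 on (1, 2) df."""
    flat = omnibus_rail_test(records_frame({"1:1": [-1, 1], "2:1": [-1, 1]}))
    assert flat["F"] == pytest.approx(0.0, abs=1e-12)
    res = omnibus_rail_test(records_frame({"1:1": [0, 2], "2:1": [10, 12]}))
    # SSB = 100, SSW = 4, MSB/MSW = 100/2
    assert res["F"] == pytest.approx(50.0, abs=1e-8)
    assert (res["df1"], res["df2"]) == (1, 2)
    assert res["p"] == pytest.approx(stats.f.sf(50.0, 1, 2), abs=1e-12)


def test_omnibus_requires_two_levels():
    with pytest.raises(InferenceError, match="two rail levels"):
        omnibus_rail_test(records_frame({"1:1": [0, 1, 2]}))


def test_interaction_zero_for_identical_profiles():
    rng = np.random.default_rng(3)
    devs = {"1:2": rng.normal(3, 1, 12).tolist(), "2:1": rng.normal(-3, 1, 12).tolist()}
    rec = pd.concat(
        [records_frame(devs, species="a"), records_frame(devs, species="b")],
        ignore_index=True,
    )
    res = interaction_test(rec, ("a", "b"))
    assert res["F"] == pytest.approx(0.0, abs=1e-10)
    assert res["df1"] == 1  # (2 species - 1) * (2 shared rails - 1)


def test_interaction_matches_sequential_anova_oracle():
    """Hand-computed sequential sums of squares on a small unbalanced design."""
    rec = pd.concat(
        [
            records_frame({"1:1": [0.0, 2.0, 1.0], "2:1": [5.0, 7.0]}, species="a"),
            records_frame({"1:1": [1.0, 3.0], "2:1": [-1.0, 1.0, 0.0]}, species="b"),
        ],
        ignore_index=True,
    )
    res = interaction_test(rec, ("a", "b"))
    # full-cell-means RSS vs additive-model RSS, computed independently
    import statsmodels.formula.api as smf

    additive = smf.ols("deviation_deg ~ C(species) + C(rail)", data=rec).fit()
    cells = rec.groupby(["species", "rail"])["deviation_deg"].transform("mean")
    rss_full = float(((rec["deviation_deg"] - cells) ** 2).sum())
    df2 = len(rec) - 4
    f_expected = ((additive.ssr - rss_full) / 1) / (rss_full / df2)
    assert res["F"] == pytest.approx(f_expected, abs=1e-8)
    assert res["df2"] == df2


def test_interaction_requires_shared_rails():
    rec = pd.concat(
        [
            records_frame({"1:1": [0, 1, 2]}, species="a"),
            records_frame({"5:1": [0, 1, 2], "1:1": [1, 2, 0]}, species="b"),
        ],
        ignore_index=True,
    )
    with pytest.raises(InferenceError, match="share"):
        interaction_test(rec, ("a", "b"))


def test_angle_records_counts_and_exclusions(tiny_frame):
    ds = validate_intake_frame(tiny_frame)
    rec = angle_records(ds)
    assert len(rec) == 3  # choice rows excluded
    assert set(rec["rail"]) == {"1:1", "1:2", "2:1"}
    assert rec.attrs["targets"]["fly"] == (10.0, 40.0)
    with_choice = angle_records(ds, include_choice=True)
    assert len(with_choice) == 5
    assert (with_choice["rail"] == "choice").sum() == 2


def test_angle_records_on_cdo_feet_are_zero():
    ds = generate_cdo_array(target=(10, 40), n_per_rail=3, seed=0)
    rec = angle_records(ds, TargetSpec.explicit(10, 40))
    assert np.allclose(rec["deviation_deg"], 0.0, atol=1e-9)
    assert (rec["position"] == "on").all()


def test_degenerate_row_dropped_with_warning(tiny_frame):
    frame = tiny_frame.copy()
    frame.loc[0, ["protein", "carbohydrate"]] = (10.0, 40.0)  # exactly the target
    ds = validate_intake_frame(frame)
    with pytest.warns(UserWarning, match="degenerate"):
        rec = angle_records(ds, TargetSpec.explicit(10, 40))
    assert len(rec) == 2
    assert rec.attrs["n_dropped"] == 1


def test_noisy_cdo_array_recovers_zero_deviations():
    ds = generate_cdo_array(
        target=(30, 30), rails=("1:4", "1:3", "3:1", "4:1"), n_per_rail=40,
        noise=NoiseModel("gaussian", 1.0), seed=99,
    )
    rec = angle_records(ds, TargetSpec.explicit(30, 30))
    est = estimate_rail_deviations(rec)
    assert est["consistent_with_cdo"].all()
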