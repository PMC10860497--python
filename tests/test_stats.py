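"""Detection statistics against hand-computed and independent oracles."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from slowchange.errors import DegenerateError
from slowchange.stats import (
    aggregate_detection,
    detection_proportion,
    load_responses,
    paired_t,
    pearson_r,
    rm_anova_oneway,
    round_proportion,
    summarize,
    trial_position_rates,
    two_proportion_z,
)


# -- proportions ------------------------------------------------------------


@pytest.mark.parametrize(
    "detected,total,expected",
    [(4, 174, 0.023), (3, 410, 0.007), (1, 250, 0.004), (0, 99, 0.0)],
)
def test_detection_proportion_printed_counts(detected, total, expected):
    assert round_proportion(detection_proportion(detected, total)) == expected


def test_proportion_undefined_for_empty_denominator():
    with pytest.raises(DegenerateError):
        detection_proportion(0, 0)


# -- two-proportion z -------------------------------------------------------


def _z_oracle(x1, n1, x2, n2):
    """Textbook pooled formula, written out long-hand."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = math.erfc(abs(z) / math.sqrt(2.0))  # 2 * upper normal tail
    return z, p


def test_z_symmetry():
    z, p = two_proportion_z(5, 100, 5, 100)
    assert z == 0.0
    assert p == 1.0


def test_z_against_formula_oracle():
    z, p = two_proportion_z(10, 100, 5, 100)
    zo, po = _z_oracle(10, 100, 5, 100)
    assert z == pytest.approx(zo, abs=1e-14)
    assert p == pytest.approx(po, abs=1e-14)


@pytest.mark.parametrize("target_z", [0.5, 1.0, 2.0])
def test_z_pvalue_matches_normal_tail(target_z):
    p_tail = math.erfc(target_z / math.sqrt(2.0))
    assert 2 * sps.norm.sf(target_z) == pytest.approx(p_tail, abs=1e-12)
    # and our p for a computed z agrees with the same tail formula
    z, p = two_proportion_z(30, 200, 20, 200)
    assert p == pytest.approx(math.erfc(abs(z) / math.sqrt(2.0)), abs=1e-12)


def test_z_degenerate_pool():
    with pytest.raises(DegenerateError):
        two_proportion_z(0, 50, 0, 80)


# -- paired t ---------------------------------------------------------------


def test_paired_t_identical_vectors():
    t, df, p = paired_t([1, 2, 3, 4], [1, 2, 3, 4])
    assert (t, df, p) == (0.0, 3, 1.0)


def test_paired_t_hand_computed():
    # differences (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
    t, df, p = paired_t([1, 2, 3], [0, 0, 0])
    assert t == pytest.approx(2 * math.sqrt(3), abs=1e-12)
    assert df == 2
    assert p == pytest.approx(2 * sps.t.sf(2 * math.sqrt(3), 2), abs=1e-14)


def test_one_tail_is_half_of_two_tail():
    a = [0.1, 0.0, 0.2, 0.05, 0.0]
    b = [0.3, 0.2, 0.25, 0.15, 0.1]
    _, _, p2 = paired_t(a, b, tail="two")
    _, _, p1 = paired_t(a, b, tail="one")
    assert p1 == pytest.approx(p2 / 2, abs=1e-15)


def test_paired_t_constant_nonzero_difference_degenerate():
    with pytest.raises(DegenerateError):
        paired_t([2, 3, 4], [1, 2, 3])


# -- repeated-measures ANOVA -----------------------------------------------


def _rm_anova_oracle(y):
    """Independent long-hand sum-of-squares decomposition."""
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_level = sum(n * (y[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (y[i, :].mean() - grand) ** 2 for i in range(n))
    ss_res = ss_total - ss_level - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    f = (ss_level / df1) / (ss_res / df2)
    return f, df1, df2, float(sps.f.sf(f, df1, df2))


def test_anova_df_for_five_levels_eleven_subjects():
    rng = np.random.default_rng(4)
    f, df1, df2, p = rm_anova_oneway(rng.random((11, 5)))
    assert (df1, df2) == (4, 40)


def test_anova_no_level_effect_gives_zero_f():
    """Subject offsets plus level-mean-free noise: no level effect, F = 0."""
    rng = np.random.default_rng(0)
    noise = rng.normal(0, 1.0, (6, 4))
    noise -= noise.mean(axis=0, keepdims=True)  # equalize level means exactly
    y = np.arange(6, dtype=float)[:, None] + noise
    f, *_ = rm_anova_oneway(y)
    assert f == pytest.approx(0.0, abs=1e-20)


def test_anova_pure_subject_offsets_degenerate():
    y = np.repeat(np.arange(6, dtype=float)[:, None], 4, axis=1)
    with pytest.raises(DegenerateError):
        rm_anova_oneway(y)


def test_anova_two_levels_equals_paired_t_squared():
    rng = np.random.default_rng(8)
    a, b = rng.random(9), rng.random(9)
    f, df1, df2, p_f = rm_anova_oneway(np.column_stack([a, b]))
    t, df, p_t = paired_t(a, b)
    assert f == pytest.approx(t * t, abs=1e-10)
    assert p_f == pytest.approx(p_t, abs=1e-12)


def test_anova_matches_ss_oracle():
    rng = np.random.default_rng(12)
    y = rng.random((11, 5))
    got = rm_anova_oneway(y)
    want = _rm_anova_oracle(y)
    assert got[0] == pytest.approx(want[0], abs=1e-10)
    assert got[1:3] == want[1:3]
    assert got[3] == pytest.approx(want[3], abs=1e-12)


# -- Pearson ----------------------------------------------------------------


def _pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    r = cov / math.sqrt(vx * vy)
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, r * r, p


def test_pearson_perfect_correlation():
    x = np.arange(5.0)
    r, r2, _ = pearson_r(x, x)
    assert r == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    r, _, _ = pearson_r(x, -x)
    assert r == pytest.approx(-1.0)


def test_pearson_matches_formula_oracle():
    rng = np.random.default_rng(3)
    x = rng.random(11)
    y = 0.3 * x + rng.random(11)
    got = pearson_r(x, y)
    want = _pearson_oracle(list(x), list(y))
    assert got[0] == pytest.approx(want[0], abs=1e-12)
    assert got[1] == pytest.approx(want[1], abs=1e-12)
    assert got[2] == pytest.approx(want[2], abs=1e-10)


def test_pearson_constant_input_degenerate():
    with pytest.raises(DegenerateError):
        pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


# -- cross-validation against independent implementations -------------------


def test_hundred_random_datasets_agree_with_references():
    """All four tests agree with independent implementations (long-hand
    formula oracles, statsmodels, pingouin) to 1e-10 over 100 random small
    datasets."""
    import pingouin as pg
    from statsmodels.stats.proportion import proportions_ztest

    rng = np.random.default_rng(555)
    for trial in range(100):
        n = int(rng.integers(4, 12))
        a = rng.random(n)
        b = a + rng.normal(0, 0.5, n)
        t, df, p = paired_t(a, b)
        res = sps.ttest_rel(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(float(res.pvalue), abs=1e-12)

        x1, n1 = int(rng.integers(1, 40)), 50
        x2, n2 = int(rng.integers(1, 40)), 60
        z, pz = two_proportion_z(x1, n1, x2, n2)
        z_sm, p_sm = proportions_ztest([x1, x2], [n1, n2])
        assert z == pytest.approx(float(z_sm), abs=1e-10)
        assert pz == pytest.approx(float(p_sm), abs=1e-10)

        r, r2, pr = pearson_r(a, b)
        ro, r2o, po = _pearson_oracle(list(a), list(b))
        assert r == pytest.approx(ro, abs=1e-10)

        if trial % 10 == 0:  # pingouin is slow; spot-check the ANOVA
            y = rng.random((6, 4))
            f, df1, df2, pf = rm_anova_oneway(y)
            long = pd.DataFrame(
                {
                    "s": np.repeat(np.arange(6), 4),
                    "l": np.tile(np.arange(4), 6),
                    "y": y.ravel(),
                }
            )
            res = pg.rm_anova(data=long, dv="y", within="l", subject="s")
            assert f == pytest.approx(float(res["F"][0]), abs=1e-10)
            assert (df1, df2) == (int(res["ddof1"][0]), int(res["ddof2"][0]))
            assert pf == pytest.approx(float(res["p_unc"][0]), abs=1e-10)


# -- response-table ingestion ----------------------------------------------


CSV = """participant_id,trial_index,stimulus_id,noticed_any,free_text,slow_detected,quick1_detected,quick2_detected,quick3_detected,unidentified
p1,1,Img1_yellow-orange,yes,"floor changed color",1,1,,,0
p1,2,Img2_purple-blue,no,,0,0,,,0
p2,1,Img1_yellow-orange,yes,"a rocket flipped",0,1,1,,0
p2,2,Img2_purple-blue,yes,"something moved",0,0,,,1
p3,1,Img1_yellow-orange,no,,,,,,
"""


def _df():
    return load_responses(io.StringIO(CSV))


def test_load_and_aggregate():
    df = _df()
    table = aggregate_detection(df, by=["stimulus_id"])
    t1 = table[table.stimulus_id == "Img1_yellow-orange"].iloc[0]
    assert t1.n_trials == 3
    assert t1.n_slow_detected == 1
    # p1 coded one quick column, p2 two, p3 none
    assert t1.n_quick_change_opportunities == 1 + 2 + 0
    assert t1.n_quick_detected == 3


def test_marginals_conserved_under_regrouping():
    df = _df()
    by_stim = aggregate_detection(df, by=["stimulus_id"])
    by_part = aggregate_detection(df, by=["participant_id"])
    cols = ["n_trials", "n_slow_detected", "n_quick_change_opportunities", "n_quick_detected"]
    assert (by_stim[cols].sum() == by_part[cols].sum()).all()


def test_coding_inconsistency_rejected():
    bad = CSV + 'p4,1,Img1_yellow-orange,no,,1,,,,0\n'
    with pytest.raises(ValueError, match="noticed_any"):
        load_responses(io.StringIO(bad))


def test_trial_positions_never_double_count():
    df = _df()
    rates = trial_position_rates(df)
    assert rates[rates.trial_index == 1].iloc[0].n_trials == 3
    dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="more than once"):
        trial_position_rates(dup)


def test_summarize_rounds_to_three_decimals():
    df = _df()
    table = summarize(df, by=["stimulus_id"])
    assert ((table.slow_proportion * 1000) % 1 == 0).all()
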