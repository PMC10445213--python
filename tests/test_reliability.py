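import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trailgaze import bland_altman, classify_icc, icc_a2, reliability_report


def icc_a2_sums_of_squares(X):
    """Independent oracle: ICC(A,2) from explicit sums of squares."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    gm = X.mean()
    ss_rows = k * sum((X[i].mean() - gm) ** 2 for i in range(n))
    ss_cols = n * sum((X[:, j].mean() - gm) ** 2 for j in range(k))
    ss_tot = ((X - gm) ** 2).sum()
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (ms_cols - ms_err) / n)


def random_table(rng, n=None):
    n = n or int(rng.integers(5, 11))
    return rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))


# ---------------------------------------------------------------------------
# ICC


def test_icc_matches_explicit_anova_oracle():
    rng = np.random.default_rng(11)
    for _ in range(20):
        X = random_table(rng)
        assert icc_a2(X).estimate == pytest.approx(icc_a2_sums_of_squares(X), abs=1e-10)


def test_icc_known_small_matrix():
    X = np.array([[1, 2], [3, 4], [5, 6], [7, 8]], dtype=float)
    r = icc_a2(X)
    assert r.estimate == pytest.approx(icc_a2_sums_of_squares(X), abs=1e-12)
    assert r.estimate == pytest.approx(80 / 83, abs=1e-12)  # hand ANOVA: MSR=40/3, MSC=2, MSE=0


def test_perfect_agreement_is_exactly_one():
    X = np.array([[1.0, 1.0], [2.5, 2.5], [4.0, 4.0], [9.0, 9.0]])
    r = icc_a2(X)
    assert r.estimate == 1.0
    assert r.ci_low <= 1.0 <= r.ci_high


def test_constant_shift_breaks_absolute_agreement():
    rng = np.random.default_rng(5)
    a = rng.normal(size=12)
    X = np.column_stack([a, a + 2.0])
    r = icc_a2(X)
    assert np.corrcoef(X[:, 0], X[:, 1])[0, 1] == pytest.approx(1.0)
    assert r.estimate < 1.0


def test_icc_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    for _ in range(5):
        X = random_table(rng)
        n = X.shape[0]
        df = pd.DataFrame({"t": np.repeat(np.arange(n), 2), "r": np.tile([1, 2], n), "y": X.ravel()})
        row = pg.intraclass_corr(df, "t", "r", "y").set_index("Type").loc["ICC(A,k)"]
        mine = icc_a2(X)
        assert mine.estimate == pytest.approx(float(row["ICC"]), abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert mine.ci_low == pytest.approx(row["CI95"][0], abs=0.006)
        assert mine.ci_high == pytest.approx(row["CI95"][1], abs=0.006)


def test_icc_ci_brackets_estimate():
    rng = np.random.default_rng(2)
    for _ in range(10):
        r = icc_a2(random_table(rng))
        assert r.ci_low <= r.estimate <= r.ci_high
        assert r.estimate <= 1.0


def test_degenerate_tables_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        icc_a2([[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="zero total variance"):
        icc_a2(np.full((5, 2), 3.0))
    with pytest.raises(ValueError, match="missing"):
        icc_a2(np.array([[1.0, np.nan], [2, 2], [3, 3]]))


@pytest.mark.parametrize(
    "value,expected",
    [
        (0.85, "excellent"),
        (0.81, "excellent"),
        (0.80, "good"),  # boundary goes to the lower class
        (0.7, "good"),
        (0.60, "moderate"),
        (0.5, "moderate"),
        (0.40, "poor"),
        (0.39, "poor"),
        (-0.2, "poor"),
    ],
)
def test_icc_classification(value, expected):
    assert classify_icc(value) == expected


# ---------------------------------------------------------------------------
# Bland-Altman


def test_identical_sessions_give_zero_bias_and_zero_width_loas():
    a = np.array([1.0, 2.0, 5.0, 9.0])
    ba = bland_altman(np.column_stack([a, a]))
    assert ba.bias == 0.0
    assert ba.loa_low == ba.loa_high == 0.0


def test_constant_offset_sign_convention():
    # session 1 larger by 2 -> positive bias (session1 - session2)
    a = np.array([1.0, 2.0, 5.0, 9.0])
    ba = bland_altman(np.column_stack([a + 2.0, a]))
    assert ba.bias == pytest.approx(2.0)
    assert ba.loa_low == ba.loa_high == pytest.approx(2.0)
    assert ba.slope == 0.0


def test_column_swap_negates_bias_and_slope():
    rng = np.random.default_rng(3)
    X = random_table(rng, n=15)
    ba = bland_altman(X)
    sw = bland_altman(X[:, ::-1])
    assert sw.bias == pytest.approx(-ba.bias)
    assert sw.slope == pytest.approx(-ba.slope)
    assert sw.loa_high - sw.loa_low == pytest.approx(ba.loa_high - ba.loa_low)


def test_exact_proportional_bias_recovered():
    m = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    d = 0.5 * m
    # construct sessions with given mean and difference
    X = np.column_stack([m + d / 2, m - d / 2])
    ba = bland_altman(X)
    assert ba.slope == pytest.approx(0.5, abs=1e-12)
    assert ba.slope_p < 0.05


def test_bias_ci_uses_t_distribution():
    from scipy import stats as sps

    rng = np.random.default_rng(4)
    X = random_table(rng, n=10)
    d = X[:, 0] - X[:, 1]
    ba = bland_altman(X)
    half = sps.t.ppf(0.975, 9) * d.std(ddof=1) / np.sqrt(10)
    assert ba.bias_ci_high - ba.bias == pytest.approx(half, abs=1e-12)
    assert ba.loa_se == pytest.approx(d.std(ddof=1) * np.sqrt(3 / 10), abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.1, 20, allow_nan=False),
)
def test_location_scale_behavior(seed, shift, scale):
    """Adding a constant to both sessions changes nothing; scaling by c > 0
    scales bias/LOAs by c and leaves the ICC and slope p-value unchanged."""
    X = random_table(np.random.default_rng(seed), n=12)
    base_ba, base_icc = bland_altman(X), icc_a2(X)
    moved = bland_altman(X + shift)
    assert moved.bias == pytest.approx(base_ba.bias, abs=1e-8)
    assert moved.loa_low == pytest.approx(base_ba.loa_low, abs=1e-8)
    assert icc_a2(X + shift).estimate == pytest.approx(base_icc.estimate, rel=1e-8)
    scaled = bland_altman(X * scale)
    assert scaled.bias == pytest.approx(base_ba.bias * scale, rel=1e-8, abs=1e-10)
    assert scaled.loa_high == pytest.approx(base_ba.loa_high * scale, rel=1e-8, abs=1e-10)
    assert scaled.slope_p == pytest.approx(base_ba.slope_p, rel=1e-6, abs=1e-12)
    assert icc_a2(X * scale).estimate == pytest.approx(base_icc.estimate, rel=1e-8)


def test_column_swap_leaves_icc_unchanged():
    X = random_table(np.random.default_rng(9), n=20)
    assert icc_a2(X[:, ::-1]).estimate == pytest.approx(icc_a2(X).estimate, abs=1e-12)


# ---------------------------------------------------------------------------
# report


def test_report_has_one_row_per_score_and_condition():
    rng = np.random.default_rng(0)
    tables = {
        (score, part, instr): random_table(rng, n=10)
        for score in ["a", "b", "c"]
        for part in ["A", "B"]
        for instr in ["speed", "accuracy"]
    }
    rep = reliability_report(tables)
    assert len(rep) == 12
    assert set(rep["icc_class"]) <= {"excellent", "good", "moderate", "poor"}
    assert (rep["loa_low"] <= rep["bias"]).all() and (rep["bias"] <= rep["loa_high"]).all()


def test_report_rejects_empty_input():
    with pytest.raises(ValueError, match="no condition tables"):
        reliability_report({})
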