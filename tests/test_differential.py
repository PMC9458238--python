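"""Effect sizes, exact contingency tests, and their oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from msi_ith import (
    classify_magnitude,
    cohens_d,
    cohens_h,
    differential_components,
    fisher_exact,
    lhr_association,
    overlap_sets,
    students_t,
)


# ---------------------------------------------------------------------------
# Cohen's d
# ---------------------------------------------------------------------------


def test_cohens_d_identical_groups_zero():
    assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_cohens_d_hand_computed():
    # means 1 and 3, both SDs sqrt(2) -> d = -2 / sqrt(2)
    assert cohens_d([0.0, 2.0], [2.0, 4.0]) == pytest.approx(-np.sqrt(2))


def test_cohens_d_monte_carlo_recovers_half():
    rng = np.random.default_rng(0)
    a = rng.normal(0.5, 1.0, size=10_000)
    b = rng.normal(0.0, 1.0, size=10_000)
    assert cohens_d(a, b) == pytest.approx(0.5, abs=0.05)


def test_cohens_d_antisymmetric_and_scale_invariant():
    rng = np.random.default_rng(1)
    a, b = rng.normal(1, 2, 40), rng.normal(0, 1, 30)
    d = cohens_d(a, b)
    assert cohens_d(b, a) == pytest.approx(-d)
    assert cohens_d(3.7 * a, 3.7 * b) == pytest.approx(d)


def test_cohens_d_zero_pooled_sd_rejected():
    with pytest.raises(ValueError):
        cohens_d([2.0, 2.0], [2.0, 2.0])


# ---------------------------------------------------------------------------
# Cohen's h
# ---------------------------------------------------------------------------


def test_cohens_h_exact_values():
    assert cohens_h(0.3, 0.3) == 0.0
    assert cohens_h(1.0, 0.0) == pytest.approx(np.pi)
    assert cohens_h(0.25, 0.75) == pytest.approx(-np.pi / 3)


def test_cohens_h_out_of_range_rejected():
    with pytest.raises(ValueError):
        cohens_h(1.2, 0.5)


def test_magnitude_classes():
    assert classify_magnitude(0.1) == "negligible"
    assert classify_magnitude(-0.3) == "small"
    assert classify_magnitude(0.6) == "medium"
    assert classify_magnitude(-1.2) == "large"


# ---------------------------------------------------------------------------
# differential component selection
# ---------------------------------------------------------------------------


def test_self_contrast_selects_nothing():
    rng = np.random.default_rng(2)
    values = rng.lognormal(0, 1, size=(200, 50))
    idx = np.arange(100)
    table = differential_components(values, idx, idx)
    assert table["selected"].sum() == 0


def test_planted_shifted_components_detected():
    rng = np.random.default_rng(3)
    n = 2000
    null = rng.normal(10.0, 1.0, size=(2 * n, 500))
    values = np.clip(null, 0, None)
    shifted = rng.permutation(500)[:50]
    values[:n, shifted] += 1.0  # true d = 1.0
    table = differential_components(
        values, np.arange(n), np.arange(n, 2 * n), threshold_class="medium",
        direction="up",
    )
    selected = set(table.loc[table["selected"], "component_id"])
    sensitivity = len(selected & set(shifted)) / 50
    false_hits = len(selected - set(shifted))
    assert sensitivity >= 0.95
    assert false_hits <= 0.05 * 450


def test_contrast_swap_inverts_direction():
    rng = np.random.default_rng(4)
    values = rng.lognormal(0, 1, size=(100, 30))
    a, b = np.arange(50), np.arange(50, 100)
    t1 = differential_components(values, a, b)
    t2 = differential_components(values, b, a)
    np.testing.assert_allclose(t1["d"], -t2["d"], atol=1e-12)
    assert np.array_equal(
        t1["selected"].to_numpy(), t2["selected"].to_numpy()
    )  # |d| unchanged, direction="both"


# ---------------------------------------------------------------------------
# Venn overlaps
# ---------------------------------------------------------------------------


def test_overlap_disjoint_and_identical():
    assert overlap_sets({1, 2}, {3}, {4, 5}) == {
        "A": 2, "B": 1, "C": 2, "AB": 0, "AC": 0, "BC": 0, "ABC": 0
    }
    full = overlap_sets({1, 2}, {1, 2}, {1, 2})
    assert full["ABC"] == 2 and sum(full.values()) == 2


def test_overlap_matches_brute_force_membership():
    rng = np.random.default_rng(5)
    universe = np.arange(200)
    a, b, c = (set(rng.choice(universe, size=80, replace=False)) for _ in range(3))
    regions = overlap_sets(a, b, c)
    brute = {k: 0 for k in regions}
    for x in universe:
        key = "".join(
            n for n, s in zip("ABC", (a, b, c)) if x in s
        )
        if key:
            brute[key] += 1
    assert regions == brute
    assert sum(regions[k] for k in ("A", "AB", "AC", "ABC")) == len(a)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def all_tables_with_margins(rows, cols):
    """Exhaustive 2x2 enumeration oracle."""
    n = sum(rows)
    for a in range(0, min(rows[0], cols[0]) + 1):
        b = rows[0] - a
        c = cols[0] - a
        d = rows[1] - c
        if b < 0 or c < 0 or d < 0 or b > cols[1]:
            continue
        yield np.array([[a, b], [c, d]])


def test_fisher_2x2_matches_scipy_oracle():
    rng = np.random.default_rng(6)
    for _ in range(60):
        t = rng.integers(0, 11, size=(2, 2))
        if t.sum() == 0 or t.sum() > 40:
            continue
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            continue
        ours = fisher_exact(t)
        ref = stats.fisher_exact(t)[1]
        assert ours == pytest.approx(ref, rel=1e-9)


def test_fisher_2x2_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    for _ in range(30):
        t = rng.integers(0, 11, size=(2, 2))
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            continue
        rows, cols = t.sum(1), t.sum(0)
        logp = lambda m: (
            stats.hypergeom.logpmf(m[0, 0], m.sum(), rows[0], cols[0])
        )
        p_obs = logp(t)
        total = sum(
            np.exp(logp(m))
            for m in all_tables_with_margins(rows, cols)
            if logp(m) <= p_obs + 1e-7
        )
        assert fisher_exact(t) == pytest.approx(min(total, 1.0), rel=1e-7)


def test_fisher_zero_row_invariance():
    t = [[4, 6], [25, 11], [12, 16]]
    t_padded = [[4, 6], [0, 0], [25, 11], [12, 16]]
    assert fisher_exact(t_padded) == pytest.approx(fisher_exact(t))


def test_fisher_large_table_advises_monte_carlo():
    big = [[6000, 5000], [5000, 6000]]
    with pytest.raises(ValueError, match="monte_carlo"):
        fisher_exact(big)


def test_fisher_monte_carlo_close_to_exact():
    t = [[25, 16], [14, 12], [2, 8]]
    exact = fisher_exact(t)
    mc = fisher_exact(t, monte_carlo=True, n_draws=200_000, seed=1)
    assert mc == pytest.approx(exact, abs=0.01)


def test_fisher_rejects_negative_or_float():
    with pytest.raises(ValueError):
        fisher_exact([[1, -2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact([[0.5, 1], [2, 3]])


# ---------------------------------------------------------------------------
# Student's t
# ---------------------------------------------------------------------------


def test_students_t_closed_form():
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    res = students_t(a, b)
    # pooled SD = 1, se = sqrt(2/3), t = -1 / se
    expected_t = -1.0 / np.sqrt(2.0 / 3.0)
    assert res["statistic"] == pytest.approx(expected_t)
    assert res["p_value"] == pytest.approx(
        2 * stats.t.sf(abs(expected_t), df=4)
    )


# ---------------------------------------------------------------------------
# diversity vs LHR
# ---------------------------------------------------------------------------


def test_lhr_constant_diversity_rho_zero():
    lhr = ["weak"] * 10 + ["intermediate"] * 10 + ["strong"] * 10
    res = lhr_association(np.full(30, 0.5), lhr)
    assert res["spearman_rho"] == 0.0


def test_lhr_planted_trend_detected():
    rng = np.random.default_rng(8)
    lhr = ["weak"] * 25 + ["intermediate"] * 25 + ["strong"] * 25
    codes = np.array([0] * 25 + [1] * 25 + [2] * 25)
    d = 0.4 + 0.1 * codes + 0.08 * rng.standard_normal(75)
    res = lhr_association(d, lhr)
    assert res["spearman_rho"] > 0
    assert res["spearman_p"] < 0.05
    assert res["kruskal_p"] < 0.05


def test_lhr_permutation_null_calibrated():
    rng = np.random.default_rng(9)
    lhr = np.array(["weak"] * 25 + ["intermediate"] * 25 + ["strong"] * 25)
    d = 0.4 + 0.1 * rng.standard_normal(75)
    rejections = 0
    n_perm = 200
    for _ in range(n_perm):
        res = lhr_association(d, rng.permutation(lhr))
        rejections += res["spearman_p"] < 0.05
    assert 0.01 <= rejections / n_perm <= 0.10


def test_lhr_group_table_added():
    lhr = ["weak"] * 10 + ["strong"] * 10
    groups = ["NED"] * 5 + ["PD"] * 5 + ["NED"] * 8 + ["PD"] * 2
    d = np.linspace(0.2, 0.8, 20)
    res = lhr_association(d, lhr, groups)
    assert 0.0 <= res["fisher_lhr_group_p"] <= 1.0


def test_lhr_single_category_rejected():
    with pytest.raises(ValueError):
        lhr_association([0.1, 0.2], ["weak", "weak"])
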