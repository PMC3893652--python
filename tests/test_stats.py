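"""Trial selection, correlation t-test, ANOVAs and protected post-hocs."""

from __future__ import annotations

import math
from collections import namedtuple

import numpy as np
import pytest
from scipy import stats as sps

from swarmdim.stats import (TrialRecord, correlation_test, fisher_plsd,
                            load_trials, one_way_anova, save_trials,
                            select_reliable_trials, trials_from_frame,
                            trials_to_frame, two_way_anova)

Obs = namedtuple("Obs", ["condition", "dimensionality"])


def _trial(species, cond, tid, dim, a, b):
    return TrialRecord(species=species, condition=cond, trial_id=tid,
                       dimensionality=dim, cbm_a=a, cbm_b=b)


def _cell(species, cond, deltas):
    """Ten trials in one cell with the given |cbm_a - cbm_b| values."""
    out = []
    for i, d in enumerate(deltas):
        a = 6
        out.append(_trial(species, cond, f"{species}{cond}t{i:02d}", 5, a, a + d))
    return out


# ---------------------------------------------------------------------------
# trial selection

def test_selection_keeps_minimum_disagreement():
    trials = _cell("sp", 0, [0, 1, 5, 2, 0, 3, 4, 1, 2, 6])
    chosen = select_reliable_trials(trials, k=3)
    assert sorted(t.disagreement for t in chosen) == [0, 0, 1]


def test_selection_tie_broken_by_trial_id():
    trials = _cell("sp", 0, [2] * 10)
    chosen = select_reliable_trials(trials, k=3)
    assert [t.trial_id for t in chosen] == ["sp0t00", "sp0t01", "sp0t02"]


def test_selection_invariant_to_input_order():
    rng = np.random.default_rng(0)
    trials = _cell("a", 0, [3, 0, 4, 1, 2, 5, 0, 2, 1, 6]) + \
        _cell("a", 1, [1, 1, 0, 3, 2, 4, 5, 0, 2, 1])
    base = select_reliable_trials(trials, k=3)
    for _ in range(5):
        shuffled = list(trials)
        rng.shuffle(shuffled)
        assert select_reliable_trials(shuffled, k=3) == base


@pytest.mark.parametrize("seed", range(100))
def test_selection_matches_sort_oracle(seed):
    rng = np.random.default_rng(seed)
    deltas = rng.integers(0, 7, size=10).tolist()
    trials = _cell("x", 1, deltas)
    chosen = select_reliable_trials(trials, k=3)
    oracle = sorted(trials, key=lambda t: (t.disagreement, t.trial_id))[:3]
    assert chosen == oracle


def test_selection_errors_name_the_sparse_cell():
    trials = _cell("full", 0, [0] * 10) + _cell("thin", 1, [0, 1])
    with pytest.raises(ValueError, match="thin"):
        select_reliable_trials(trials, k=3)


# ---------------------------------------------------------------------------
# correlation

def _vectors_with_correlation(r, n, seed=0):
    """Construct x, y with *exact* sample correlation r."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonalize
    z /= z.std()
    y = r * x + math.sqrt(1 - r**2) * z
    return x, y


def test_perfect_linearity():
    x = np.arange(10.0)
    res = correlation_test(x, 2 * x + 1)
    assert res.r == pytest.approx(1.0)
    assert res.p == pytest.approx(0.0, abs=1e-12)


def test_t_statistic_formula():
    """r = 0.5 at n = 12 gives t = 0.5 * sqrt(10 / 0.75) ~= 1.826."""
    x, y = _vectors_with_correlation(0.5, 12)
    res = correlation_test(x, y)
    assert res.r == pytest.approx(0.5, abs=1e-12)
    assert res.t == pytest.approx(0.5 * math.sqrt(10 / 0.75), abs=1e-9)
    assert res.df == 10


def test_weak_correlation_significant_at_large_df():
    """r^2 = 0.11 with 44 degrees of freedom is significant at 0.05."""
    x, y = _vectors_with_correlation(math.sqrt(0.11), 46)
    res = correlation_test(x, y)
    assert res.r_squared == pytest.approx(0.11, abs=1e-9)
    assert res.df == 44
    assert res.p < 0.05


def test_correlation_matches_reference():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=(2, 20))
    res = correlation_test(x, y)
    ref = sps.pearsonr(x, y)
    assert res.r == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p == pytest.approx(ref.pvalue, abs=1e-12)


def test_correlation_symmetry_and_affine_invariance():
    rng = np.random.default_rng(6)
    x, y = rng.normal(size=(2, 15))
    a = correlation_test(x, y)
    assert correlation_test(y, x).r == pytest.approx(a.r)
    b = correlation_test(3.0 * x - 7.0, y)
    assert b.r == pytest.approx(a.r, abs=1e-12)
    assert b.p == pytest.approx(a.p, abs=1e-12)


def test_correlation_rejects_degenerate_input():
    with pytest.raises(ValueError):
        correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        correlation_test([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# one-way ANOVA

def test_two_group_f_equals_squared_t():
    rng = np.random.default_rng(1)
    obs = [Obs(0, v) for v in rng.normal(0, 1, 8)] + \
          [Obs(1, v) for v in rng.normal(1, 1, 8)]
    res = one_way_anova(obs)
    a = [o.dimensionality for o in obs[:8]]
    b = [o.dimensionality for o in obs[8:]]
    t, _ = sps.ttest_ind(a, b)
    assert res.f_statistic("condition") == pytest.approx(t**2, abs=1e-10)


def test_separated_groups_give_zero_within_ss():
    obs = [Obs(0, 1), Obs(0, 1), Obs(0, 1),
           Obs(1, 2), Obs(1, 2), Obs(1, 2),
           Obs(2, 3), Obs(2, 3), Obs(2, 3)]
    res = one_way_anova(obs)
    assert res.mse == 0.0
    assert math.isinf(res.f_statistic("condition"))
    assert res.p_value("condition") == 0.0


def test_one_way_matches_reference():
    rng = np.random.default_rng(2)
    groups = [rng.normal(m, 1, 7) for m in (0.0, 0.5, 1.5)]
    obs = [Obs(c, v) for c, g in enumerate(groups) for v in g]
    res = one_way_anova(obs)
    ref = sps.f_oneway(*groups)
    assert res.f_statistic("condition") == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value("condition") == pytest.approx(ref.pvalue, abs=1e-10)


def test_null_rejection_rate_calibrated():
    """Equal-mean groups: the 0.05-level rejection rate over seeded
    Monte-Carlo replicates sits near the nominal level."""
    rng = np.random.default_rng(99)
    rejections = 0
    reps = 500
    for _ in range(reps):
        obs = [Obs(c, v) for c in range(3) for v in rng.normal(0, 1, 10)]
        if one_way_anova(obs).p_value("condition") < 0.05:
            rejections += 1
    assert 0.03 <= rejections / reps <= 0.07


# ---------------------------------------------------------------------------
# two-way ANOVA

def _balanced_records(seed=0, reps=3, species=("a", "b", "c"), effects=None):
    rng = np.random.default_rng(seed)
    effects = effects or {}
    out = []
    for sp in species:
        for cond in (0, 1, 2):
            for i in range(reps):
                base = 5 + effects.get(sp, 0.0) + effects.get(cond, 0.0)
                dim = int(np.clip(round(base + rng.normal(0, 1)), 1, 12))
                out.append(_trial(sp, cond, f"{sp}{cond}{i}", dim, 5, 6))
    return out


def test_constant_response_gives_zero_f():
    recs = [_trial(sp, c, f"{sp}{c}{i}", 7, 5, 5)
            for sp in ("a", "b") for c in (0, 1, 2) for i in range(2)]
    res = two_way_anova(recs)
    assert res.f_statistic("species") == 0.0
    assert res.f_statistic("condition") == 0.0


def test_two_way_ss_matches_brute_force_oracle():
    """SS_A, SS_B and the residual match a direct mean-decomposition."""
    recs = _balanced_records(seed=3, effects={"a": -1.0, 2: 1.5})
    res = two_way_anova(recs)
    y = np.array([r.dimensionality for r in recs], dtype=float)
    sp = np.array([r.species for r in recs])
    cond = np.array([r.condition for r in recs])
    grand = y.mean()
    ss_a = sum((y[sp == s].size) * (y[sp == s].mean() - grand) ** 2
               for s in set(sp))
    ss_b = sum((y[cond == c].size) * (y[cond == c].mean() - grand) ** 2
               for c in set(cond))
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_a - ss_b
    df_a, df_b = 2, 2
    df_den = y.size - df_a - df_b - 1
    assert res.mse == pytest.approx(ss_err / df_den, abs=1e-10)
    assert res.f_statistic("species") == pytest.approx(
        (ss_a / df_a) / (ss_err / df_den), abs=1e-10)
    assert res.f_statistic("condition") == pytest.approx(
        (ss_b / df_b) / (ss_err / df_den), abs=1e-10)


def test_two_way_total_ss_decomposition():
    recs = _balanced_records(seed=8)
    res = two_way_anova(recs, interaction=True)
    y = np.array([r.dimensionality for r in recs], dtype=float)
    ss_tot = ((y - y.mean()) ** 2).sum()
    # reconstruct component SS from the reported F and MSE
    parts = sum((f * dfn) * res.mse for f, dfn, _ in res.factors.values())
    assert parts + res.mse * res.df_den == pytest.approx(ss_tot, abs=1e-8)


def test_two_way_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels")
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    recs = _balanced_records(seed=4, effects={"b": 2.0, 1: -1.0})
    res = two_way_anova(recs)
    df = trials_to_frame(recs)
    df["condition"] = df["condition"].astype(str)
    fit = ols("dimensionality ~ C(species) + C(condition)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    assert res.f_statistic("species") == pytest.approx(
        table.loc["C(species)", "F"], abs=1e-8)
    assert res.p_value("condition") == pytest.approx(
        table.loc["C(condition)", "PR(>F)"], abs=1e-8)


def test_relabeling_levels_preserves_f():
    recs = _balanced_records(seed=5, effects={"a": 1.0})
    res = two_way_anova(recs)
    renamed = [_trial({"a": "z", "b": "y", "c": "x"}[r.species], r.condition,
                      r.trial_id, r.dimensionality, r.cbm_a, r.cbm_b)
               for r in recs]
    res2 = two_way_anova(renamed)
    assert res2.f_statistic("species") == pytest.approx(res.f_statistic("species"))
    assert res2.p_value("species") == pytest.approx(res.p_value("species"))


def test_two_way_rejects_unbalanced_or_empty_cells():
    recs = _balanced_records(seed=6)
    with pytest.raises(ValueError, match="balanced"):
        two_way_anova(recs[:-1])
    no_cell = [r for r in recs if not (r.species == "a" and r.condition == 0)]
    with pytest.raises(ValueError):
        two_way_anova(no_cell)


# ---------------------------------------------------------------------------
# Fisher's protected LSD

def test_posthoc_gated_when_parent_not_significant():
    """A non-significant omnibus effect (like p = 0.23) yields no pairwise
    comparisons, only an explicit gate reason."""
    recs = _balanced_records(seed=7)  # no systematic effects
    res = two_way_anova(recs)
    assert res.p_value("condition") > 0.05
    table = fisher_plsd(res, recs, factor="condition")
    assert table.gated
    assert table.rows == []
    assert "not significant" in table.gate_reason


def test_posthoc_matches_pooled_t_oracle():
    recs = _balanced_records(seed=1, reps=5, effects={"a": -2.0, "c": 2.0})
    res = two_way_anova(recs)
    assert res.p_value("species") < 0.05
    table = fisher_plsd(res, recs, factor="species")
    assert not table.gated
    y = np.array([r.dimensionality for r in recs], dtype=float)
    sp = np.array([r.species for r in recs])
    for row in table.rows:
        yi, yj = y[sp == row.level_i], y[sp == row.level_j]
        se = math.sqrt(res.mse * (1 / yi.size + 1 / yj.size))
        t = (yi.mean() - yj.mean()) / se
        p = 2 * sps.t.sf(abs(t), res.df_den)
        assert row.t == pytest.approx(t, abs=1e-10)
        assert row.p == pytest.approx(p, abs=1e-10)
        assert row.significant == (p < 0.05)


def test_identical_means_give_null_comparisons():
    recs = [_trial(sp, c, f"{sp}{c}{i}", d, 5, 5)
            for sp in ("a", "b") for c in (0, 1, 2)
            for i, d in enumerate((4, 6))]
    res = two_way_anova(recs)
    # force past the protection gate to inspect the comparisons themselves
    table = fisher_plsd(res, recs, factor="species", alpha=1.5)
    assert all(row.t == 0.0 and row.p == 1.0 for row in table.rows)


def test_posthoc_unknown_factor_rejected():
    recs = _balanced_records(seed=2)
    res = two_way_anova(recs)
    with pytest.raises(ValueError):
        fisher_plsd(res, recs, factor="weight")


# ---------------------------------------------------------------------------
# persistence and validation

def test_trial_record_validation():
    with pytest.raises(ValueError):
        _trial("a", 3, "t", 5, 5, 5)
    with pytest.raises(ValueError):
        _trial("a", 0, "t", 5, 0, 5)
    with pytest.raises(ValueError):
        _trial("a", 0, "t", 0, 5, 5)


def test_trials_roundtrip(tmp_path):
    recs = _balanced_records(seed=9)
    path = tmp_path / "trials.csv"
    save_trials(recs, path)
    assert load_trials(path) == recs
    assert trials_from_frame(trials_to_frame(recs)) == recs
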