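"""Statistical machinery: Dice, Wilcoxon (vs brute force), Bonferroni,
Bland-Altman, fold aggregation and report building."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from fusionbench.stats import (BlandAltman, EvalTable, aggregate_folds,
                               bland_altman, bonferroni, build_report,
                               dice_score, median, nearest_rank_percentile,
                               wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# dice


class TestDiceScore:
    def test_examples(self):
        a = np.array([1, 1, 1, 0, 0, 0, 0], dtype=np.uint8)
        b = np.array([0, 1, 1, 1, 1, 0, 0], dtype=np.uint8)
        # |X|=3, |Y|=4, |X∩Y|=2 -> 4/7
        assert dice_score(a, b) == pytest.approx(4 / 7)
        assert dice_score(a, a) == 1.0
        assert dice_score(a, 1 - a) == 0.0
        assert dice_score(np.zeros(4, np.uint8), np.zeros(4, np.uint8)) == 1.0

    def test_matches_voxel_counting_oracle_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(120):
            shape = tuple(rng.integers(2, 7, size=3))
            x = (rng.random(shape) > rng.random()).astype(np.uint8)
            y = (rng.random(shape) > rng.random()).astype(np.uint8)
            inter = sum(1 for i in np.ndindex(shape) if x[i] and y[i])
            nx = sum(1 for i in np.ndindex(shape) if x[i])
            ny = sum(1 for i in np.ndindex(shape) if y[i])
            want = 1.0 if nx + ny == 0 else 2 * inter / (nx + ny)
            assert dice_score(x, y) == pytest.approx(want, abs=1e-12)

    def test_symmetric_and_monotone_under_true_positives(self):
        rng = np.random.default_rng(8)
        x = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        y = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        assert dice_score(x, y) == dice_score(y, x)
        # adding a true-positive voxel never decreases Dice
        miss = np.argwhere((y == 1) & (x == 0))
        if len(miss):
            x2 = x.copy()
            x2[tuple(miss[0])] = 1
            assert dice_score(x2, y) >= dice_score(x, y)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            dice_score(np.array([0, 2]), np.array([0, 1]))
        with pytest.raises(ValueError):
            dice_score(np.zeros(3), np.zeros(4))


# ---------------------------------------------------------------------------
# wilcoxon


def brute_force_wilcoxon_p(d: np.ndarray) -> float:
    """Independent oracle: enumerate all 2^n sign assignments of |d| and
    take twice the smaller-tail probability of W+ (symmetric null)."""
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    w_lo = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_lo + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / 2 ** n)


class TestWilcoxon:
    def test_all_equal_is_degenerate(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.degenerate and res.p == 1.0 and res.n_used == 0

    def test_five_positive_distinct_differences(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(x + np.array([1, 2, 3, 4, 5.0]), x)
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 32)

    def test_six_differences_with_one_negative(self):
        """Differences {+1..+5, -6}: W- = 6, exact two-sided p =
        2 * P(W <= 6) = 2 * 14/64 (enumerated by hand)."""
        y = np.zeros(6)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -6.0])
        res = wilcoxon_signed_rank(x, y)
        assert res.p == pytest.approx(28 / 64)

    def test_zero_differences_are_dropped(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 7, 7])
        y = np.array([0.0, 0, 0, 0, 0, 0, 0, 7, 7])
        res = wilcoxon_signed_rank(x, y)
        assert res.n_dropped == 2 and res.n_used == 7

    def test_too_few_nonzero_differences_rejected(self):
        x = np.array([1.0, 2, 3, 4])
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(x, np.zeros(4))
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(3), np.zeros(4))

    def test_exact_p_matches_brute_force_on_fuzzed_samples(self):
        """>= 200 fuzzed paired samples with n <= 10, ties included."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 200:
            n = int(rng.integers(5, 11))
            # small integer differences produce plenty of rank ties
            d = rng.integers(-5, 6, size=n).astype(float)
            if (d != 0).sum() < 5:
                continue
            res = wilcoxon_signed_rank(d, np.zeros(n))
            want = brute_force_wilcoxon_p(d)
            assert res.p == pytest.approx(want, abs=1e-12), d
            checked += 1

    def test_exact_matches_scipy_on_tie_free_data(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 20))
            x = rng.standard_normal(n)
            y = x + rng.standard_normal(n) * 0.5 + 0.2
            d = x - y
            if np.any(d == 0) or len(set(np.abs(d))) < n:
                continue
            ours = wilcoxon_signed_rank(x, y)
            ref = scipy_wilcoxon(x, y, mode="exact")
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60)
        y = x + 0.3 + rng.standard_normal(60) * 0.3
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal"
        from scipy.stats import wilcoxon as scipy_wilcoxon
        ref = scipy_wilcoxon(x, y, correction=False, mode="approx")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# bonferroni


class TestBonferroni:
    @pytest.mark.parametrize("raw,m,want_p,want_stars", [
        (0.008, 6, 0.048, "*"),
        (0.3, 6, 1.0, ""),
        (1e-5, 6, 6e-5, "***"),
        (0.0015, 6, 0.009, "**"),
        (0.05, 1, 0.05, ""),          # threshold is strict
        (0.0, 6, 0.0, "***"),
    ])
    def test_hand_arithmetic_grid(self, raw, m, want_p, want_stars):
        p, stars = bonferroni(raw, m)
        assert p == pytest.approx(want_p, abs=1e-15)
        assert stars == want_stars

    def test_monotone_in_raw_p(self):
        rng = np.random.default_rng(0)
        ps = np.sort(rng.random(50))
        cs = [bonferroni(p, 6)[0] for p in ps]
        assert all(a <= b for a, b in zip(cs, cs[1:]))

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


# ---------------------------------------------------------------------------
# bland-altman


class TestBlandAltman:
    def test_constant_difference(self):
        base = np.linspace(0.5, 0.9, 30)
        res = bland_altman(base + 0.07, base)
        assert (res.bias, res.loa_low, res.loa_high) == \
            (pytest.approx(0.07), pytest.approx(0.07), pytest.approx(0.07))

    def test_symmetric_differences_have_zero_bias(self):
        diffs = np.concatenate([np.arange(1, 11), -np.arange(1, 11)]) / 100
        base = np.full(20, 0.5)
        res = bland_altman(base + diffs, base)
        assert res.bias == pytest.approx(0.0)

    def test_rank_arithmetic_on_hundred_point_sequence(self):
        """diffs 0.01..1.00: nearest-rank 5th pct index ceil(5) = 5 ->
        0.05; 95th -> 0.95; median of even n -> 0.505."""
        diffs = np.arange(1, 101) / 100.0
        base = np.zeros(100)
        res = bland_altman(base + diffs, base)
        assert res.loa_low == pytest.approx(0.05)
        assert res.loa_high == pytest.approx(0.95)
        assert res.bias == pytest.approx(0.505)
        # nearest-rank limits leave exactly 89/100 strictly inside
        inside = np.sum((diffs > res.loa_low) & (diffs < res.loa_high))
        assert 0.88 <= inside / 100 <= 0.90

    def test_short_samples_warn_and_mismatch_rejected(self):
        with pytest.warns(UserWarning, match="unstable"):
            bland_altman(np.arange(5.0), np.zeros(5))
        with pytest.raises(ValueError):
            bland_altman(np.arange(21.0), np.zeros(20))


def test_percentile_and_median_conventions():
    v = np.arange(1, 11, dtype=float)
    assert nearest_rank_percentile(v, 25) == 3.0     # ceil(2.5) = 3
    assert nearest_rank_percentile(v, 75) == 8.0
    assert nearest_rank_percentile(v, 100) == 10.0
    assert median(v) == 5.5


# ---------------------------------------------------------------------------
# tables, aggregation, reports


def _table(config_names, n_pairs, score_fn, fold=0):
    rows = []
    for i in range(n_pairs):
        for cname in config_names:
            rows.append(dict(subject_id=f"s{fold}_{i}", session_id="e1",
                             config_name=cname, dice=score_fn(cname, i)))
    return EvalTable.from_rows(rows)


def test_aggregate_folds_concatenates_and_rejects_duplicates():
    f = lambda c, i: 0.5
    tables = [_table(["a"], n, f, fold=k)
              for k, n in enumerate([3, 3, 4])]
    agg = aggregate_folds(tables)
    assert len(agg.frame) == 10
    single = aggregate_folds([tables[0]])
    assert single.frame.equals(tables[0].frame)
    with pytest.raises(ValueError, match="duplicate"):
        aggregate_folds([tables[0], tables[0]])


def test_fold_order_does_not_change_report():
    rng = np.random.default_rng(2)
    tables = [_table(["baseline_ref", "fusion"], 8,
                     lambda c, i: float(rng.random()), fold=k)
              for k in range(3)]
    r1 = build_report(aggregate_folds(tables), m=2)
    r2 = build_report(aggregate_folds(tables[::-1]), m=2)
    for row1 in r1.rows:
        row2 = r2.row(row1["config_name"])
        assert row1["median_dice"] == pytest.approx(row2["median_dice"])
        assert row1["raw_p"] == pytest.approx(row2["raw_p"])


def test_eval_table_residuals_and_validation():
    t = _table(["baseline_ref", "fusion"], 6,
               lambda c, i: 0.6 + (0.1 if c == "fusion" else 0.0) + i / 100)
    df = t.with_residuals("baseline_ref")
    base_rows = df[df["config_name"] == "baseline_ref"]
    assert (base_rows["residual"] == 0).all()
    fus = df[df["config_name"] == "fusion"]
    np.testing.assert_allclose(fus["residual"], 0.1)
    with pytest.raises(ValueError, match="dice"):
        EvalTable.from_rows([dict(subject_id="a", session_id="b",
                                  config_name="c", dice=1.2)])


def test_build_report_full_shape_and_baseline_row():
    rng = np.random.default_rng(12)
    base_scores = 0.7 + 0.1 * rng.standard_normal(30).clip(-2, 2) / 10

    def score(c, i):
        bump = {"baseline_ref": 0.0, "up_cfg": 0.05, "down_cfg": -0.05}[c]
        return float(np.clip(base_scores[i] + bump
                             + 0.01 * rng.standard_normal(), 0, 1))

    table = _table(["baseline_ref", "up_cfg", "down_cfg"], 30, score)
    report = build_report(table, m=2)
    base = report.row("baseline_ref")
    assert base["degenerate"] and base["median_residual"] == 0.0
    up = report.row("up_cfg")
    down = report.row("down_cfg")
    assert up["direction"] == "up" and down["direction"] == "down"
    assert up["corrected_p"] == pytest.approx(min(1.0, 2 * up["raw_p"]))
    assert up["corrected_p"] < 0.05
    ranked = report.ranked()
    assert ranked[0]["config_name"] == "up_cfg"
    # serialization round-trip is parseable
    import json, tempfile, os
    with tempfile.TemporaryDirectory() as d:
        report.write(os.path.join(d, "r.csv"), os.path.join(d, "r.json"))
        loaded = json.load(open(os.path.join(d, "r.json")))
        assert loaded["m"] == 2
        assert {r["config_name"] for r in loaded["configs"]} == \
            {"baseline_ref", "up_cfg", "down_cfg"}
        assert len(pd.read_csv(os.path.join(d, "r.csv"))) == 3


def test_build_report_requires_pair_alignment():
    t1 = _table(["baseline_ref"], 6, lambda c, i: 0.5)
    t2 = _table(["fusion"], 5, lambda c, i: 0.6)
    merged = EvalTable(pd.concat([t1.frame, t2.frame], ignore_index=True))
    with pytest.raises(ValueError, match="paired"):
        build_report(merged)
    with pytest.raises(ValueError, match="absent"):
        build_report(t2)
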