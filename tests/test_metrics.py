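import numpy as np
import pandas as pd
import pytest

from gadseg.metrics import (CountConfusion, categorize_count, count_confusion,
                            dice_3d, evaluate_scans, format_report,
                            lesion_metrics, match_lesions, mean_dice_3d)


def _mask_with_blocks(shape, blocks):
    m = np.zeros(shape, dtype=np.uint8)
    for (z, y, x), (dz, dy, dx) in blocks:
        m[z:z + dz, y:y + dy, x:x + dx] = 1
    return m


def _brute_force_counts(pred, manual, min_size=5):
    """Exhaustive pairwise-overlap oracle for lesion-wise TP/FN/FP."""
    from gadseg.candidates import connected_components_6, filter_min_size
    _, pc = connected_components_6(pred)
    _, mc = connected_components_6(manual)
    pc, mc = filter_min_size(pc, min_size), filter_min_size(mc, min_size)
    psets = [set(map(tuple, c)) for c in pc]
    msets = [set(map(tuple, c)) for c in mc]
    tp = sum(1 for m in msets if any(m & p for p in psets))
    fn = len(msets) - tp
    fp = sum(1 for p in psets if not any(p & m for m in msets))
    return tp, fn, fp


class TestMatchLesions:
    def test_identical_masks_all_true_positive(self):
        m = _mask_with_blocks((10, 12, 12), [((1, 1, 1), (2, 2, 2)),
                                             ((5, 5, 5), (2, 3, 1)),
                                             ((8, 9, 2), (1, 2, 3))])
        t = match_lesions(m, m)
        assert (t["status"] == "TP").sum() == 3
        assert (t["status"] != "TP").sum() == 0

    def test_empty_prediction_gives_all_false_negative(self):
        manual = _mask_with_blocks((8, 10, 10), [((1, 1, 1), (2, 3, 1)),
                                                 ((5, 5, 5), (1, 2, 3))])
        t = match_lesions(np.zeros_like(manual), manual)
        assert (t["status"] == "FN").sum() == 2

    def test_one_voxel_overlap_counts_as_detection(self):
        manual = _mask_with_blocks((8, 10, 10), [((2, 2, 2), (1, 2, 3))])
        pred = _mask_with_blocks((8, 10, 10), [((2, 3, 4), (1, 5, 1))])
        assert manual.sum() >= 5 and pred.sum() >= 5
        assert (manual & pred).sum() == 1
        t = match_lesions(pred, manual)
        assert list(t["status"]) == ["TP"]

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        for _ in range(20):
            pred = (rng.random((12, 12, 12)) < 0.18).astype(np.uint8)
            manual = (rng.random((12, 12, 12)) < 0.18).astype(np.uint8)
            t = match_lesions(pred, manual)
            got = tuple((t["status"] == s).sum() for s in ("TP", "FN", "FP"))
            assert got == _brute_force_counts(pred, manual)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            match_lesions(np.zeros((4, 4, 4)), np.zeros((4, 4, 5)))

    def test_manual_lesion_partition_invariant(self, rng):
        pred = (rng.random((10, 10, 10)) < 0.2).astype(np.uint8)
        manual = (rng.random((10, 10, 10)) < 0.2).astype(np.uint8)
        from gadseg.candidates import connected_components_6, filter_min_size
        t = match_lesions(pred, manual)
        _, mc = connected_components_6(manual)
        n_manual = len(filter_min_size(mc))
        assert (t["status"].isin(["TP", "FN"])).sum() == n_manual


def _table(rows):
    return pd.DataFrame(rows, columns=["status", "size"])


class TestLesionMetrics:
    def test_stratified_ratios_from_counts(self):
        rows = ([{"status": "TP", "size": 7}] * 2
                + [{"status": "FN", "size": 8}] * 1
                + [{"status": "FP", "size": 30}] * 3
                + [{"status": "TP", "size": 120}] * 4)
        rep = lesion_metrics([_table(rows)])
        assert rep.row("5-10")["sensitivity"] == pytest.approx(2 / 3)
        assert rep.row("21-50")["fdr"] == pytest.approx(1.0)
        assert rep.row(">100")["sensitivity"] == pytest.approx(1.0)
        assert rep.sensitivity == pytest.approx(6 / 7)
        assert rep.fdr == pytest.approx(3 / 9)

    def test_totals_equal_sum_over_groups(self, rng):
        rows = [{"status": rng.choice(["TP", "FN", "FP"]),
                 "size": int(rng.integers(5, 200))} for _ in range(60)]
        rep = lesion_metrics([_table(rows)])
        groups = [g for g in rep.table.index if g != "total"]
        for col in ("tp", "fn", "fp"):
            assert rep.table.loc["total", col] == sum(rep.table.loc[g, col]
                                                      for g in groups)

    def test_undefined_ratios_are_nan_not_zero_or_one(self):
        rep = lesion_metrics([_table([{"status": "FN", "size": 7}])])
        assert np.isnan(rep.row("11-20")["sensitivity"])
        assert np.isnan(rep.row("11-20")["fdr"])
        assert np.isnan(rep.fdr)  # TP=0, FP=0
        assert rep.sensitivity == 0.0

    def test_ratios_recomputable_from_stored_counts(self, rng):
        rows = [{"status": rng.choice(["TP", "FN", "FP"]),
                 "size": int(rng.integers(5, 200))} for _ in range(40)]
        rep = lesion_metrics([_table(rows)])
        for _, r in rep.table.iterrows():
            if r["tp"] + r["fn"]:
                assert round(r["sensitivity"], 3) == round(
                    r["tp"] / (r["tp"] + r["fn"]), 3)
            if r["tp"] + r["fp"]:
                assert round(r["fdr"], 3) == round(r["fp"] / (r["fp"] + r["tp"]), 3)


class TestDice:
    def test_identical_and_disjoint(self):
        a = _mask_with_blocks((6, 6, 6), [((1, 1, 1), (2, 2, 2))])
        b = _mask_with_blocks((6, 6, 6), [((4, 4, 4), (2, 2, 2))])
        assert dice_3d(a, a) == 1.0
        assert dice_3d(a, b) == 0.0

    def test_partial_overlap_closed_form(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a.ravel()[:8] = 1
        b.ravel()[2:10] = 1  # overlap 6 of 8+8 -> 12/16
        assert dice_3d(a, b) == pytest.approx(0.75)

    def test_symmetry(self, rng):
        a = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        b = (rng.random((6, 6, 6)) < 0.3).astype(np.uint8)
        assert dice_3d(a, b) == dice_3d(b, a)

    def test_both_empty_is_nan(self):
        assert np.isnan(dice_3d(np.zeros((3, 3, 3)), np.zeros((3, 3, 3))))

    def test_group_restricted_dice(self):
        from gadseg.metrics import dice_by_size_group
        manual = _mask_with_blocks((12, 12, 12), [((1, 1, 1), (2, 2, 2)),   # 8 vox
                                                  ((6, 2, 2), (3, 3, 3))])  # 27 vox
        pred = _mask_with_blocks((12, 12, 12), [((1, 1, 1), (2, 2, 2)),
                                                ((9, 9, 9), (2, 2, 2))])  # FP
        d = dice_by_size_group(pred, manual)
        assert d["5-10"] == 1.0          # small lesion matched exactly
        assert d["21-50"] == 0.0         # 27-voxel lesion missed entirely
        assert np.isnan(d[">100"])       # no manual lesion in stratum
        # the disjoint false positive must not contaminate any stratum
        assert all(v in (0.0, 1.0) or np.isnan(v) for v in d.values())

    def test_mean_dice_excludes_lesion_free_images(self):
        a = _mask_with_blocks((6, 6, 6), [((1, 1, 1), (2, 2, 2))])
        empty = np.zeros_like(a)
        # second pair is lesion-free: must not drag the mean to NaN or 0
        assert mean_dice_3d([a, empty], [a, empty]) == 1.0


class TestCountCategories:
    @pytest.mark.parametrize("n,cat", [(0, "0"), (1, "1"), (2, ">=2"), (7, ">=2")])
    def test_categorization(self, n, cat):
        assert categorize_count(n) == cat

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            categorize_count(-1)


class TestCountConfusion:
    def test_perfect_predictions(self):
        cats = ["0"] * 3 + ["1"] * 2 + [">=2"] * 2
        conf = count_confusion(cats, cats)
        assert conf.accuracy == 100.0
        m = conf.matrix.to_numpy()
        assert np.trace(m) == 7 and m.sum() == 7

    def test_entries_sum_to_scan_count_and_columns_normalize(self, rng):
        cats = ["0", "1", ">=2"]
        pred = [cats[i] for i in rng.integers(0, 3, size=50)]
        true = [cats[i] for i in rng.integers(0, 3, size=50)]
        conf = count_confusion(pred, true)
        assert conf.n_scans == 50
        norm = conf.normalized.to_numpy()
        col_tot = conf.matrix.to_numpy().sum(axis=0)
        for j, tot in enumerate(col_tot):
            if tot:
                assert norm[:, j].sum() == pytest.approx(100.0)

    def test_subgroup_matrices(self):
        pred = ["0", "1", "0", ">=2"]
        true = ["0", "1", "1", ">=2"]
        by = ["1.5T", "1.5T", "3T", "3T"]
        out = count_confusion(pred, true, group_by=by)
        assert set(out) == {"1.5T", "3T"}
        assert out["1.5T"].accuracy == 100.0
        assert out["3T"].accuracy == 50.0

    def test_length_mismatch_and_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            count_confusion(["0"], ["0", "1"])
        with pytest.raises(ValueError):
            count_confusion(["two"], ["1"])


def test_format_report_renders_all_groups(rng):
    pred = (rng.random((10, 12, 12)) < 0.15).astype(np.uint8)
    manual = (rng.random((10, 12, 12)) < 0.15).astype(np.uint8)
    rep = evaluate_scans([pred], [manual])
    text = format_report(rep)
    for g in ("5-10", "11-20", "21-50", "51-100", ">100", "total"):
        assert g in text
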