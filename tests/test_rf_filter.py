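import numpy as np
import pytest

from gadseg.candidates import CandidateLesion, FEATURE_NAMES, extract_candidates
from gadseg.metrics import evaluate_scans
from gadseg.phantom import PhantomSpec, generate_phantom
from gadseg.rf_filter import RFConfig, apply_rf, fit_rf, label_candidates


def _fake_candidate(scan, cid, voxels, features):
    return CandidateLesion(scan_id=scan, component_id=cid,
                           voxels=np.asarray(voxels), features=np.asarray(features))


class TestLabeling:
    def test_overlap_rules(self):
        manual = np.zeros((6, 6, 6), dtype=np.uint8)
        manual[2:4, 2:4, 2:4] = 1
        inside = _fake_candidate("s", 0, [[2, 2, 2], [2, 2, 3]], np.zeros(75))
        touch = _fake_candidate("s", 1, [[3, 3, 3], [4, 4, 4]], np.zeros(75))
        disjoint = _fake_candidate("s", 2, [[0, 0, 0], [0, 0, 1]], np.zeros(75))
        out = label_candidates([inside, touch, disjoint], manual)
        assert [c.label for c in out] == [True, True, False]

    def test_out_of_grid_candidate_rejected(self):
        c = _fake_candidate("s", 0, [[9, 0, 0]], np.zeros(75))
        with pytest.raises(ValueError, match="grid"):
            label_candidates([c], np.zeros((4, 4, 4), dtype=np.uint8))


def _separable_candidates(n=40, seed=0):
    r = np.random.default_rng(seed)
    cands = []
    for i in range(n):
        label = i % 2 == 0
        f = r.normal(size=75)
        f[10] = 5.0 if label else -5.0  # size feature split
        c = _fake_candidate("s", i, [[0, 0, i % 4]], f)
        c.label = label
        cands.append(c)
    return cands


class TestFitting:
    def test_separable_features_reach_perfect_training_accuracy(self):
        cands = _separable_candidates()
        fitted = fit_rf(cands, RFConfig(seed=1))
        X = np.vstack([c.features for c in cands])
        y = np.array([c.label for c in cands])
        assert (fitted.model.predict(X) == y).all()
        assert list(fitted.importances.columns) == ["feature", "importance"]
        assert fitted.importances.iloc[0]["feature"] == FEATURE_NAMES[10]

    def test_single_class_training_set_rejected(self):
        cands = _separable_candidates()
        for c in cands:
            c.label = True
        with pytest.raises(ValueError, match="single class"):
            fit_rf(cands)

    def test_unlabeled_candidates_rejected(self):
        cands = _separable_candidates()
        cands[3].label = None
        with pytest.raises(ValueError, match="unlabeled"):
            fit_rf(cands)

    def test_deterministic_given_seed(self):
        cands = _separable_candidates()
        X = np.vstack([c.features for c in cands])
        a = fit_rf(cands, RFConfig(seed=7)).scores(X)
        b = fit_rf(cands, RFConfig(seed=7)).scores(X)
        np.testing.assert_array_equal(a, b)

    def test_persistence_round_trip(self, tmp_path):
        cands = _separable_candidates()
        fitted = fit_rf(cands, RFConfig(seed=2))
        p = tmp_path / "rf.pkl"
        fitted.save(p)
        from gadseg.rf_filter import FittedRF
        restored = FittedRF.load(p)
        X = np.vstack([c.features for c in cands])
        np.testing.assert_array_equal(restored.scores(X), fitted.scores(X))


class TestApplication:
    def test_threshold_extremes(self):
        cands = _separable_candidates(n=10)
        fitted = fit_rf(cands, RFConfig(seed=0))
        kept_all, mask_all = apply_rf(fitted, cands, (4, 4, 4), score_threshold=0.0)
        assert len(kept_all) == 10
        kept_none, mask_none = apply_rf(fitted, cands, (4, 4, 4),
                                        score_threshold=1.0 + 1e-9)
        assert kept_none == [] and mask_none.sum() == 0
        assert mask_all.sum() > 0

    def test_filtered_mask_is_subset_of_input(self):
        cands = _separable_candidates(n=10)
        fitted = fit_rf(cands, RFConfig(seed=0))
        from gadseg.candidates import candidates_mask
        full = candidates_mask(cands, (4, 4, 4))
        _, filtered = apply_rf(fitted, cands, (4, 4, 4))
        assert (filtered <= full).all()

    def test_layout_mismatch_rejected(self):
        cands = _separable_candidates(n=10)
        fitted = fit_rf(cands, RFConfig(seed=0))
        bad = _fake_candidate("s", 0, [[0, 0, 0]], np.zeros(10))
        with pytest.raises(ValueError, match="layout"):
            apply_rf(fitted, [bad], (4, 4, 4))


def _phantom_with_injected_fps(seed, n_fp=6):
    """Ground truth plus non-enhancing cortical blobs as the 'prediction'.

    The blobs are size-matched to real lesions and placed off the
    periventricular lesion prior, so the discriminating signal is the
    missing enhancement and the location, not the candidate size.
    """
    spec = PhantomSpec(shape=(24, 48, 48), n_lesions=2,
                       size_groups=(("21-50", 1), ("51-100", 1)), seed=seed)
    ph = generate_phantom(spec)
    pred = ph.mask.copy()
    wm_off_prior = ((ph.stack.channel("p_wm") > 0.8)
                    & (ph.stack.channel("p_lesion") < 0.05))
    r = np.random.default_rng(seed + 1000)
    sites = np.argwhere(wm_off_prior[2:-4, 2:-5, 2:-5]) + 2
    placed = 0
    for idx in r.permutation(len(sites)):
        z, y, x = sites[idx]
        dz, dy, dx = 2, int(r.integers(3, 6)), int(r.integers(3, 6))
        block = np.s_[z:z + dz, y:y + dy, x:x + dx]
        if ph.mask[block].any() or pred[block].any():
            continue
        pred[block] = 1
        placed += 1
        if placed == n_fp:
            break
    assert placed == n_fp
    return ph, pred


@pytest.fixture(scope="module")
def fitted_and_heldout():
    train_cands = []
    for seed in (21, 22, 23, 24, 25):
        ph, pred = _phantom_with_injected_fps(seed, n_fp=8)
        cands = extract_candidates(pred, ph.stack)
        train_cands += label_candidates(cands, ph.mask)
    fitted = fit_rf(train_cands, RFConfig(seed=5))
    held = _phantom_with_injected_fps(29)
    return fitted, held


class TestPhantomFalsePositiveReduction:
    """Paired before/after-filter evaluation on phantoms with injected
    false-positive blobs: the forest must not worsen the false detection
    ratio, and its important features should include the discriminative
    location/intensity descriptors."""

    def test_fdr_not_increased_by_filtering(self, fitted_and_heldout):
        fitted, (ph, pred) = fitted_and_heldout
        cands = extract_candidates(pred, ph.stack)
        _, filtered = apply_rf(fitted, cands, ph.mask.shape)
        before = evaluate_scans([pred], [ph.mask])
        after = evaluate_scans([filtered], [ph.mask])
        assert after.fdr <= before.fdr
        assert before.fdr > 0  # the injection really created false positives

    def test_sensitivity_never_rises_after_filtering(self, fitted_and_heldout):
        fitted, (ph, pred) = fitted_and_heldout
        cands = extract_candidates(pred, ph.stack)
        _, filtered = apply_rf(fitted, cands, ph.mask.shape)
        before = evaluate_scans([pred], [ph.mask])
        after = evaluate_scans([filtered], [ph.mask])
        assert after.sensitivity <= before.sensitivity

    def test_important_features_include_expected_discriminators(self, fitted_and_heldout):
        fitted, _ = fitted_and_heldout
        top = set(fitted.importances.head(10)["feature"])
        expected = {"centroid_z", "inside_mean_t1_post", "shell_sd_t1_post",
                    "inside_sum_p_lesion"}
        assert top & expected
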