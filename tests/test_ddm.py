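"""Window slicing, PCA reduction, the paired-holdout classifier and DDM
construction, including brute-force oracles and determinism."""

import numpy as np
import pytest

import telltale
from telltale import ddm
from telltale import preprocess as pp

from conftest import FAST_RT, make_epochset


class TestWindowSlice:
    cfg100 = ddm.DDMConfig(m_bins=100, bin_ms=10.0)

    def test_full_epoch_window(self):
        es = make_epochset(n_trials=6)
        x = ddm.window_slice(es, 0, 100, self.cfg100)
        assert x.shape == (6, 2000)
        assert np.array_equal(x, es.data)

    def test_final_bin_window(self):
        es = make_epochset(n_trials=6)
        x = ddm.window_slice(es, 99, 1, self.cfg100)
        assert x.shape == (6, 20)
        assert np.array_equal(x, es.data[:, -20:])

    def test_triangle_constraint_enforced(self):
        es = make_epochset(n_trials=6)
        with pytest.raises(ValueError):
            ddm.window_slice(es, 95, 10, self.cfg100)

    def test_binned_features(self):
        es = make_epochset(n_trials=5)
        x = ddm.window_slice(es, 2, 4, ddm.DDMConfig(m_bins=100, bin_ms=10.0,
                                                     features="binned"))
        assert x.shape == (5, 4)
        assert np.allclose(x[:, 0], es.data[:, 40:60].mean(axis=1))


class TestTriangle:
    @pytest.mark.parametrize("m", [1, 5, 20, 100])
    def test_defined_cells_match_enumeration(self, m):
        brute = {(i, j) for i in range(m) for j in range(1, m + 1) if i + j <= m}
        assert ddm.n_defined_cells(m) == len(brute)
        d = ddm.DDM(accuracy=np.full((m, m), np.nan), m=m, bin_ms=1000 / m)
        mask_cells = {(i, j + 1) for i, j in zip(*np.nonzero(d.defined_mask))}
        assert mask_cells == brute


class TestReduceDimensions:
    def test_rank_two_features_fully_explained(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 50))
        x = rng.normal(size=(30, 2)) @ basis + 5.0
        comps, ev = ddm.reduce_dimensions(x)
        assert comps.shape == (30, 2)
        assert ev == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_features_warn_and_match_eigen_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 20))
        with pytest.warns(ddm.LowVarianceWarning):
            comps, ev = ddm.reduce_dimensions(x)
        w = np.linalg.eigvalsh(np.cov(x, rowvar=False))
        assert ev == pytest.approx(w[-2:].sum() / w.sum(), abs=1e-10)
        assert 0.08 < ev < 0.30  # near 2/20, inflated by eigenvalue spread
        assert comps.shape[1] == 2

    def test_matches_sklearn_pca(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(2)
        x = rng.normal(size=(25, 40)) * np.linspace(1, 3, 40)
        comps, _ = ddm.reduce_dimensions(x, ev_floor=0.0)
        ref = PCA(n_components=2).fit_transform(x)
        for c in range(2):
            assert (np.allclose(comps[:, c], ref[:, c], atol=1e-8)
                    or np.allclose(comps[:, c], -ref[:, c], atol=1e-8))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ddm.reduce_dimensions(np.zeros((10, 5)))
        with pytest.raises(ValueError):
            ddm.reduce_dimensions(np.ones((2, 5)))


def brute_force_holdout(comps, labels, pairs=None):
    """Independent oracle: plain least squares (lstsq) refit per holdout
    pair, exhaustive over all (lie, truth) pairs by default."""
    comps = np.asarray(comps, float)
    labels = np.asarray(labels, bool)
    y = np.where(labels, 1.0, -1.0)
    Z = np.column_stack([comps, np.ones(len(labels))])
    lie = np.flatnonzero(labels)
    truth = np.flatnonzero(~labels)
    if pairs is None:
        pairs = [(a, b) for a in lie for b in truth]
    correct = []
    for a, b in pairs:
        mask = np.ones(len(labels), bool)
        mask[[a, b]] = False
        w, *_ = np.linalg.lstsq(Z[mask], y[mask], rcond=None)
        correct.append((Z[a] @ w) * y[a] > 0)
        correct.append((Z[b] @ w) * y[b] > 0)
    return float(np.mean(correct))


class TestClassifyWindow:
    def test_separable_classes(self):
        rng = np.random.default_rng(0)
        comps = np.vstack([rng.normal((10, 0), 0.1, (20, 2)),
                           rng.normal((-10, 0), 0.1, (20, 2))])
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        acc = ddm.classify_window(comps, labels, n_iterations=200, seed=1)
        assert acc >= 0.99

    def test_chance_on_permuted_labels(self):
        rng = np.random.default_rng(1)
        comps = rng.normal(size=(80, 2))
        labels = rng.permutation(np.arange(80) % 2 == 0)
        acc = ddm.classify_window(comps, labels, n_iterations=1000, seed=2)
        assert 0.40 <= acc <= 0.60

    def test_exhaustive_matches_brute_force_enumeration(self):
        # 3 lie + 3 truth trials: 9 holdout pairs, enumerated exactly
        rng = np.random.default_rng(3)
        comps = rng.normal(size=(6, 2)) + np.array([[1, 0]] * 3 + [[-1, 0]] * 3)
        labels = np.array([1, 1, 1, 0, 0, 0], bool)
        acc = ddm.classify_window(comps, labels, n_iterations=1000, seed=0,
                                  ridge=0.0)
        assert acc == pytest.approx(brute_force_holdout(comps, labels), abs=1e-12)

    def test_sampling_converges_to_exhaustive_mean(self):
        rng = np.random.default_rng(4)
        comps = np.vstack([rng.normal((0.8, 0), 1.0, (10, 2)),
                           rng.normal((-0.8, 0), 1.0, (10, 2))])
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        exact = ddm.classify_window(comps, labels, n_iterations=100, seed=0)
        sampled = np.mean([
            ddm.classify_window(comps, labels, n_iterations=60, seed=s)
            for s in range(40)])
        assert sampled == pytest.approx(exact, abs=0.03)

    def test_undefined_when_class_too_small(self):
        comps = np.random.default_rng(5).normal(size=(10, 2))
        labels = np.zeros(10, bool)
        labels[0] = True
        assert np.isnan(ddm.classify_window(comps, labels))

    def test_svm_classifier_on_separable_toy(self):
        rng = np.random.default_rng(6)
        comps = np.vstack([rng.normal((5, 0), 0.1, (6, 2)),
                           rng.normal((-5, 0), 0.1, (6, 2))])
        labels = np.r_[np.ones(6, bool), np.zeros(6, bool)]
        acc = ddm.classify_window(comps, labels, n_iterations=50, seed=0,
                                  classifier="svm")
        assert acc >= 0.99


class TestBuildDDM:
    cfg = ddm.DDMConfig(m_bins=5, bin_ms=200.0, n_iterations=50)

    def test_all_defined_cells_filled(self):
        es = make_epochset(n_trials=12, seed=1)
        d = ddm.build_ddm(es, self.cfg, seed=0)
        vals = d.defined_values
        assert vals.size == ddm.n_defined_cells(5) == 15
        assert np.all(np.isfinite(vals))
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(np.isnan(d.accuracy[~d.defined_mask]))

    def test_chance_level_on_unstructured_epochs(self):
        es = make_epochset(n_trials=80, seed=2)
        d = ddm.build_ddm(es, self.cfg, seed=1)
        assert 0.42 <= np.nanmean(d.defined_values) <= 0.58

    def test_seed_determinism(self):
        es = make_epochset(n_trials=20, seed=3)
        d1 = ddm.build_ddm(es, self.cfg, seed=5)
        d2 = ddm.build_ddm(es, self.cfg, seed=5)
        assert np.array_equal(d1.accuracy, d2.accuracy, equal_nan=True)
        d3 = ddm.build_ddm(es, self.cfg, seed=6)
        assert not np.array_equal(d1.accuracy, d3.accuracy, equal_nan=True)

    def test_joint_build_matches_separate_builds(self):
        es = make_epochset(n_trials=16, seed=4)
        real, shuf = ddm.build_real_and_shuffled(es, 5, seed=9, config=self.cfg)
        solo = ddm.build_ddm(es, self.cfg, seed=9)
        assert np.array_equal(real.accuracy, solo.accuracy, equal_nan=True)
        solo_shuf = ddm.build_shuffled_ddms(es, 5, seed=9, config=self.cfg)
        for a, b in zip(shuf, solo_shuf):
            assert np.array_equal(a.accuracy, b.accuracy, equal_nan=True)

    def test_fast_path_equals_reference_path(self):
        # dual route: vectorized Gram/downdate pipeline vs per-cell refits
        es = make_epochset(n_trials=12, seed=5)
        rows = np.vstack([es.labels, np.roll(es.labels, 1), np.roll(es.labels, 3)])
        tags = np.array([0, 1, 2])
        fast = ddm._build_ddms_multi(es, rows, tags, self.cfg, seed=3)
        slow = ddm._build_ddms_multi_slow(es, rows, tags, self.cfg, seed=3)
        assert np.array_equal(fast, slow, equal_nan=True)

    def test_fast_path_equals_reference_path_sampled(self):
        cfg = ddm.DDMConfig(m_bins=4, bin_ms=250.0, n_iterations=20)
        es = make_epochset(n_trials=30, seed=6)
        rows = np.vstack([es.labels, np.roll(es.labels, 2)])
        fast = ddm._build_ddms_multi(es, rows, np.array([0, 1]), cfg, seed=4)
        slow = ddm._build_ddms_multi_slow(es, rows, np.array([0, 1]), cfg, seed=4)
        assert np.array_equal(fast, slow, equal_nan=True)

    def test_cell_matches_classify_window_in_exhaustive_regime(self):
        es = make_epochset(n_trials=10, seed=7)
        d = ddm.build_ddm(es, self.cfg, seed=0)
        for (i, j) in [(0, 1), (1, 2), (0, 5)]:
            feats = ddm.window_slice(es, i, j, self.cfg)
            comps, _ = ddm.reduce_dimensions(feats, ev_floor=0.0)
            acc = ddm.classify_window(comps, es.labels, n_iterations=50, seed=0)
            assert d.cell(i, j) == pytest.approx(acc, abs=1e-12)

    def test_leakage_free_mode_runs(self):
        cfg = ddm.DDMConfig(m_bins=4, bin_ms=250.0, n_iterations=10,
                            leakage_free_pca=True)
        es = make_epochset(n_trials=10, seed=8)
        d = ddm.build_ddm(es, cfg, seed=0)
        vals = d.defined_values
        assert np.all((vals >= 0) & (vals <= 1))


class TestShuffles:
    def test_shuffles_preserve_class_counts(self):
        labels = np.r_[np.ones(7, bool), np.zeros(13, bool)]
        rows = ddm._shuffle_rows(labels, 50, seed=0)
        assert rows.shape == (50, 20)
        assert np.all(rows.sum(axis=1) == 7)
        assert any(not np.array_equal(rows[k], labels) for k in range(50))

    def test_shuffle_count(self):
        es = make_epochset(n_trials=10, seed=9)
        cfg = ddm.DDMConfig(m_bins=4, bin_ms=250.0, n_iterations=20)
        shuf = ddm.build_shuffled_ddms(es, 12, seed=1, config=cfg)
        assert len(shuf) == 12

    def test_shuffled_cells_centered_at_chance(self):
        es = make_epochset(n_trials=80, seed=10)
        cfg = ddm.DDMConfig(m_bins=4, bin_ms=250.0, n_iterations=200)
        shuf = ddm.build_shuffled_ddms(es, 30, seed=2, config=cfg)
        vals = np.concatenate([d.defined_values for d in shuf])
        assert abs(np.nanmean(vals) - 0.5) < 0.02


class TestSignalResponse:
    def test_accuracy_monotone_in_planted_effect(self):
        # mean ZM-speech DDM accuracy must rise with effect size
        # (10 simulated participants per level, one inversion allowed)
        cfg = ddm.DDMConfig(m_bins=10, bin_ms=100.0, n_iterations=50)
        means = []
        for k, effect in enumerate([0.0, 0.5, 1.0, 2.0]):
            accs = []
            for s in range(10):
                prof = telltale.ParticipantProfile(
                    id=f"e{k}s{s}", liar_type="ZM" if effect > 0 else "NULL",
                    effect_size=effect, effect_events=frozenset({"speech"}),
                    seed=7000 + 97 * k + s, **FAST_RT)
                rec, trials = telltale.generate_participant(prof, n_trials_per_stage=8)
                sel = pp.select_channels_from_recording(rec)
                env = pp.continuous_envelope(rec, sel.zm_pair)
                esets, _ = pp.epoch_trials(env, trials, "ZM", rec.fs,
                                           calibration_end_s=rec.calibration_marks[-1][2])
                data = np.vstack([esets[("speech", 1)].data, esets[("speech", 2)].data])
                labels = np.concatenate([esets[("speech", 1)].labels,
                                         esets[("speech", 2)].labels])
                if labels.sum() < 2 or (~labels).sum() < 2:
                    continue
                es = pp.EpochSet(data=data, labels=labels, muscle="ZM",
                                 event="speech", stage=2)
                d = ddm.build_ddm(es, cfg, seed=s)
                accs.append(np.nanmean(d.defined_values))
            means.append(np.mean(accs))
        inversions = sum(means[k + 1] < means[k] for k in range(3))
        assert inversions <= 1
        assert means[-1] > means[0]
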