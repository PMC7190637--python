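"""Marker prediction: tiling, bags, MIL head, AUC and cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tissuefp import biomarker as bm
from tissuefp import synthgen as sg
from tissuefp.nn import build_tiny_cnn


def solid_slide(px=2048, mpp=0.5, color=(180, 60, 120)):
    """Uniformly saturated slide: every grid square is foreground."""
    pixels = np.zeros((px, px, 3), dtype=np.uint8)
    pixels[:] = color
    # inject variation so Otsu has two classes in a corner strip only
    pixels[:16, :16] = (250, 250, 250)
    return bm.SlideRecord("solid", 1, pixels, mpp, {"ER": 1})


class TestTileSlide:
    def test_grid_arithmetic_at_target_scale(self):
        """2048 px at 0.5 um/px: 112 um = 224 px -> 9x9 = 81 squares."""
        tiles = bm.tile_slide(solid_slide(2048, 0.5), min_foreground=0.0)
        assert len(tiles) == 81
        assert tiles[0].pixels.shape == (224, 224, 3)

    def test_higher_resolution_resampled(self):
        """0.25 um/px: 448-px squares resampled down to 224."""
        tiles = bm.tile_slide(solid_slide(2048, 0.25), min_foreground=0.0)
        assert len(tiles) == (2048 // 448) ** 2
        assert tiles[0].pixels.shape == (224, 224, 3)

    def test_background_slide_empty_with_warning(self):
        white = bm.SlideRecord("blank", 1, np.full((1024, 1024, 3), 250, np.uint8),
                               0.5, {"ER": 1})
        with pytest.warns(UserWarning):
            assert bm.tile_slide(white) == []

    def test_missing_mpp_errors(self):
        rec = bm.SlideRecord("x", 1, np.zeros((1024, 1024, 3), np.uint8), 0.0, {})
        with pytest.raises(ValueError):
            bm.tile_slide(rec)

    def test_tissue_classes_attached(self):
        wsi = sg.make_wsi_cohort(1, slide_px=1024, seed=8)
        rec = bm.SlideRecord("s1", 1, wsi.slides[0], wsi.microns_per_pixel,
                             {"ER": 1}, tissue_mask=wsi.masks[0])
        tiles = bm.tile_slide(rec)
        assert tiles and all(t.tissue_class in (0, 1, 2, 3) for t in tiles)


class TestMakeBags:
    @pytest.fixture(scope="class")
    def slides(self):
        wsi = sg.make_wsi_cohort(3, slide_px=1024, seed=8)
        return [bm.SlideRecord(f"s{p.patient_id}", p.patient_id, px,
                               wsi.microns_per_pixel, {"ER": int(r.ER)},
                               tissue_mask=mk)
                for p, px, mk, (_, r) in zip(wsi.phenotypes, wsi.slides, wsi.masks,
                                             wsi.labels.iterrows())]

    def test_bag_size_and_replacement_warning(self, slides, tiny_model):
        with pytest.warns(UserWarning, match="replacement"):
            bags = bm.make_bags(slides, tiny_model, k=120,
                                rng=np.random.default_rng(0))
        for bag in bags.values():
            assert bag.fingerprints.shape == (120, tiny_model.fingerprint_dim)

    def test_no_replacement_when_enough(self, slides, tiny_model):
        bags = bm.make_bags(slides, tiny_model, k=5, rng=np.random.default_rng(0))
        for bag in bags.values():
            rows = bag.sources[["row", "col"]].apply(tuple, axis=1)
            assert rows.nunique() == 5

    def test_deterministic_given_seed(self, slides, tiny_model):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = bm.make_bags(slides, tiny_model, k=30, rng=np.random.default_rng(7))
            b = bm.make_bags(slides, tiny_model, k=30, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a[1].fingerprints, b[1].fingerprints)


class TestMarkerHead:
    def test_scores_inside_unit_interval(self, rng):
        head = bm.MarkerHead(in_dim=16, seed=0)
        s = head.scores(rng.normal(size=(50, 16)).astype(np.float32))
        assert (np.abs(s) < 1).all()
        # extreme inputs saturate but never exceed the bound
        s_big = head.scores(rng.normal(size=(50, 16)).astype(np.float32) * 100)
        assert (np.abs(s_big) <= 1).all()

    def test_predict_patient_is_mean(self, rng):
        head = bm.MarkerHead(in_dim=8, seed=1)
        fps = rng.normal(size=(40, 8)).astype(np.float32)
        bag = bm.PatchBag(1, fps, pd.DataFrame(index=range(40)))
        brute = float(np.mean([head.scores(fps[i : i + 1])[0] for i in range(40)]))
        assert bm.predict_patient(head, bag) == pytest.approx(brute, abs=1e-7)

    def test_empty_bag_errors(self):
        head = bm.MarkerHead(in_dim=8)
        bag = bm.PatchBag(1, np.zeros((0, 8), np.float32), pd.DataFrame())
        with pytest.raises(ValueError):
            bm.predict_patient(head, bag)

    def test_head_gradients_numeric(self, rng):
        head = bm.MarkerHead(in_dim=6, seed=2)
        fps = rng.normal(size=(5, 6)).astype(np.float32)
        s, cache = head.forward(fps)
        ds = rng.normal(size=5)
        grads = head.backward(ds, cache)
        eps = 1e-4
        for pi, (p, g) in enumerate(zip(head.params(), grads)):
            idx = (0,) * p.ndim
            orig = p[idx]
            p[idx] = orig + eps; lp = float(head.forward(fps)[0] @ ds)
            p[idx] = orig - eps; lm = float(head.forward(fps)[0] @ ds)
            p[idx] = orig
            assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-3), pi


def synthetic_bags(n_patients, rng, separation=3.0, d=8, k=20):
    """Bags whose mean feature encodes the label, for head-training tests."""
    bags, labels = {}, {}
    for pid in range(1, n_patients + 1):
        y = 1 if rng.uniform() < 0.5 else -1
        mu = np.zeros(d)
        mu[0] = y * separation / 2
        fps = rng.normal(size=(k, d)) + mu
        bags[pid] = bm.PatchBag(pid, fps.astype(np.float32),
                                pd.DataFrame(index=range(k)))
        labels[pid] = y
    return bags, labels


class TestHeadTraining:
    def test_learns_separable_bags(self, rng):
        bags, labels = synthetic_bags(40, rng)
        ids = list(bags)
        head, log = bm.train_marker_head(
            bags, labels, ids[:30], ids[30:],
            bm.HeadTrainConfig(steps=400, eval_interval=40, patience=5, seed=0))
        assert log.overfit_auc.dropna().max() >= 0.9

    def test_restores_best_weights(self, rng):
        bags, labels = synthetic_bags(30, rng)
        ids = list(bags)
        cfg = bm.HeadTrainConfig(steps=300, eval_interval=30, patience=3, seed=0)
        head, log = bm.train_marker_head(bags, labels, ids[:20], ids[20:], cfg)
        best = log.overfit_auc.dropna().max()
        scores = np.array([bm.predict_patient(head, bags[p]) for p in ids[20:]])
        got = bm.rank_auc(np.array([labels[p] for p in ids[20:]]), scores)
        assert got == pytest.approx(best, abs=1e-9)

    def test_single_class_overfit_group_errors(self, rng):
        bags, labels = synthetic_bags(20, rng)
        pos = [p for p in bags if labels[p] == 1]
        neg = [p for p in bags if labels[p] == -1]
        with pytest.raises(ValueError):
            bm.train_marker_head(bags, labels, neg, pos[:3],
                                 bm.HeadTrainConfig(steps=10))

    def test_shuffled_labels_near_half(self, rng):
        """Null contract: label-less bags give overfit AUC ~ 0.5."""
        bags, labels = synthetic_bags(40, rng, separation=0.0)
        ids = list(bags)
        _, log = bm.train_marker_head(
            bags, labels, ids[:28], ids[28:],
            bm.HeadTrainConfig(steps=200, eval_interval=40, patience=50, seed=1))
        finals = log.overfit_auc.dropna()
        # 12-patient overfit group: binomial spread is wide; just exclude signal
        assert finals.iloc[-1] == pytest.approx(0.5, abs=0.35)


class TestEvaluate:
    def test_perfect_separation(self):
        scores = {1: 0.9, 2: 0.8, 3: -0.5, 4: -0.9}
        labels = {1: 1, 2: 1, 3: -1, 4: -1}
        assert bm.evaluate(scores, labels)["auc"] == 1.0

    def test_pair_counting_oracle(self):
        scores = {1: 0.3, 2: 0.1, 3: -0.2, 4: 0.25, 5: -0.1, 6: 0.1}
        labels = {1: 1, 2: 1, 3: 1, 4: -1, 5: -1, 6: -1}
        pos = [scores[p] for p in (1, 2, 3)]
        neg = [scores[p] for p in (4, 5, 6)]
        oracle = np.mean([[1.0 if a > b else 0.5 if a == b else 0.0
                           for b in neg] for a in pos])
        assert bm.evaluate(scores, labels)["auc"] == pytest.approx(oracle, abs=1e-12)

    def test_random_scores_near_half(self):
        r = np.random.default_rng(0)
        labels = {i: (1 if i % 2 else -1) for i in range(200)}
        scores = {i: float(r.normal()) for i in range(200)}
        assert bm.evaluate(scores, labels)["auc"] == pytest.approx(0.5, abs=0.12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            bm.evaluate({1: 0.5, 2: 0.1}, {1: 1, 2: 1})

    def test_roc_endpoints(self):
        res = bm.evaluate({1: 0.9, 2: -0.2, 3: 0.4}, {1: 1, 2: -1, 3: 1})
        assert res["fpr"][0] == 0 and res["tpr"][0] == 0
        assert res["fpr"][-1] == 1 and res["tpr"][-1] == 1


class TestCrossValidation:
    def test_groups_partition_patients(self, rng):
        bags, labels = synthetic_bags(50, rng)
        split = bm.make_cv_split(labels, n_folds=5, seed=4)
        all_ids = np.concatenate(split.groups)
        assert sorted(all_ids.tolist()) == sorted(labels)
        for f in range(5):
            train, over, test = split.fold(f)
            assert not (set(train) & set(over) | set(train) & set(test)
                        | set(over) & set(test))

    def test_roles_rotate(self, rng):
        bags, labels = synthetic_bags(25, rng)
        split = bm.make_cv_split(labels, n_folds=5, seed=0)
        tests = [tuple(sorted(split.fold(f)[2].tolist())) for f in range(5)]
        assert len(set(tests)) == 5

    def test_same_seed_same_split(self, rng):
        bags, labels = synthetic_bags(30, rng)
        a = bm.make_cv_split(labels, 5, seed=9)
        b = bm.make_cv_split(labels, 5, seed=9)
        for ga, gb in zip(a.groups, b.groups):
            np.testing.assert_array_equal(ga, gb)

    def test_cv_recovers_separable_signal(self, rng):
        bags, labels = synthetic_bags(50, rng)
        res = bm.run_cross_validation(bags, labels, n_folds=5, seed=0,
                                      config=bm.HeadTrainConfig(steps=300,
                                                                eval_interval=50,
                                                                patience=3))
        assert len(res["fold_aucs"]) == 5
        assert res["mean_auc"] > 0.85

    def test_too_few_patients_errors(self, rng):
        bags, labels = synthetic_bags(6, rng)
        with pytest.raises(ValueError):
            bm.run_cross_validation(bags, labels)
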