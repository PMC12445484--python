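"""Evaluator: matching, precision/recall, AP integration, size bins."""

import numpy as np
import pytest

from canedet.boxgeom import Box, BoxFormat
from canedet.metrics import (MatchConfig, evaluate, match_detections,
                             precision_recall)
from canedet.suppress import Detection
from canedet.synth import SceneConfig, generate_scene

from oracles import cocoeval_ap


def B(xc, yc, w, h):
    return Box(xc, yc, w, h, format=BoxFormat.CENTER_PIXEL)


def D(xc, yc, w, h, s):
    return Detection(B(xc, yc, w, h), s)


class TestMatching:
    def test_perfect_duplicates(self):
        gts = [B(5, 5, 4, 4), B(20, 20, 6, 6)]
        preds = [D(5, 5, 4, 4, 0.9), D(20, 20, 6, 6, 0.8)]
        c = match_detections(preds, gts, MatchConfig())[0.5]
        assert (c["tp"], c["fp"], c["fn"]) == (2, 0, 0)

    def test_no_predictions(self):
        c = match_detections([], [B(1, 1, 2, 2)], MatchConfig())[0.5]
        assert (c["tp"], c["fp"], c["fn"]) == (0, 0, 1)

    def test_crafted_three_preds_two_gts_matches_exhaustive(self):
        """Greedy score-ordered matching equals the best assignment here."""
        gts = [B(10, 10, 8, 8), B(16, 10, 8, 8)]
        preds = [D(12, 10, 8, 8, 0.95),   # overlaps both, best with gt0
                 D(16, 10, 8, 8, 0.90),   # exact on gt1
                 D(10, 10, 8, 8, 0.85)]   # exact on gt0, arrives too late
        c = match_detections(preds, gts, MatchConfig())[0.5]
        assert (c["tp"], c["fp"], c["fn"]) == (2, 1, 0)
        # exhaustive assignment oracle: max #pairs with IoU >= .5, one-to-one
        from oracles import exact_iou
        best = 0
        P = [(12, 10, 8, 8), (16, 10, 8, 8), (10, 10, 8, 8)]
        G = [(10, 10, 8, 8), (16, 10, 8, 8)]
        import itertools
        for assign in itertools.permutations(range(3), 2):
            n = sum(exact_iou(P[p], G[g]) >= 0.5
                    for g, p in enumerate(assign))
            best = max(best, n)
        assert c["tp"] == best

    def test_each_gt_matched_at_most_once(self):
        gts = [B(5, 5, 4, 4)]
        preds = [D(5, 5, 4, 4, 0.9), D(5, 5, 4, 4, 0.8)]
        c = match_detections(preds, gts, MatchConfig())[0.5]
        assert (c["tp"], c["fp"]) == (1, 1)


class TestPrecisionRecall:
    def test_arithmetic(self):
        p, r = precision_recall({"tp": 9, "fp": 1, "fn": 1})
        assert p == pytest.approx(0.9)
        assert r == pytest.approx(0.9)

    def test_perfect(self):
        p, r = precision_recall({"tp": 4, "fp": 0, "fn": 0})
        assert p == 1.0 and r == 1.0

    def test_zero_over_zero_warns(self):
        with pytest.warns(UserWarning):
            p, r = precision_recall({"tp": 0, "fp": 0, "fn": 0})
        assert (p, r) == (0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            precision_recall({"tp": -1, "fp": 0, "fn": 0})


class TestAP:
    def test_all_correct_confident_gives_one(self):
        gts = [[B(5, 5, 4, 4)], [B(9, 9, 6, 6)]]
        preds = [[D(5, 5, 4, 4, 0.99)], [D(9, 9, 6, 6, 0.98)]]
        res = evaluate(preds, gts)
        assert res.map50 == pytest.approx(1.0)
        assert res.map50_95 == pytest.approx(1.0)

    def test_detection_order_irrelevant(self, rng):
        gts = [[B(5, 5, 4, 4), B(15, 15, 4, 4)]]
        dets = [D(5, 5, 4, 4, 0.9), D(15, 15, 4, 4, 0.6),
                D(25, 25, 4, 4, 0.7)]
        a = evaluate([dets], gts).map50
        b = evaluate([list(reversed(dets))], gts).map50
        assert a == pytest.approx(b)

    def test_five_detection_worked_example(self):
        """Hand-integrated step curve.

        2 gts; detections sorted by score: TP, FP, TP, FP, FP.
        precision after k: 1, 1/2, 2/3, 1/2, 2/5; recall: .5,.5,1,1,1.
        envelope: p(r<=0.5)=1, p(r<=1.0)=2/3 -> 101-pt AP:
        51 points at 1, 50 points at 2/3.
        """
        gts = [[B(5, 5, 4, 4), B(50, 50, 4, 4)]]
        preds = [[D(5, 5, 4, 4, 0.95),
                  D(90, 90, 4, 4, 0.9),
                  D(50, 50, 4, 4, 0.8),
                  D(70, 20, 4, 4, 0.7),
                  D(20, 70, 4, 4, 0.6)]]
        want = (51 * 1.0 + 50 * (2 / 3)) / 101
        assert evaluate(preds, gts).map50 == pytest.approx(want, abs=1e-9)

    def test_map50_dominates_map50_95(self, rng):
        gts, preds = _random_scene_sets(rng, 6)
        res = evaluate(preds, gts)
        assert res.map50 >= res.map50_95 - 1e-12

    def test_adding_confident_correct_detection_never_hurts(self, rng):
        gts, preds = _random_scene_sets(rng, 4)
        res0 = evaluate(preds, gts)
        # add one perfect, top-confidence detection for an unmatched gt
        g = gts[0][0]
        preds2 = [list(p) for p in preds]
        preds2[0] = preds2[0] + [Detection(g, 1.0)]
        res1 = evaluate(preds2, gts)
        assert res1.map50 >= res0.map50 - 1e-12

    def test_agrees_with_cocoeval_style_oracle(self, rng):
        """Cross-implementation agreement on 20 random synthetic scenes."""
        for trial in range(20):
            gts, preds = _random_scene_sets(rng, 3, seed=trial)
            mine = evaluate(preds, gts, MatchConfig()).map50
            pb = [([list(d.box.asarray()) for d in ps],
                   [d.score for d in ps]) for ps in preds]
            gb = [[list(g.asarray()) for g in gs] for gs in gts]
            ref = cocoeval_ap(pb, gb, thr=0.5)
            assert mine == pytest.approx(ref, abs=1e-4), trial


class TestSizeBins:
    def test_bins_scored_separately(self):
        small = B(5, 5, 4, 4)          # 16 px^2
        medium = B(30, 30, 50, 50)     # 2500
        large = B(200, 200, 120, 120)  # 14400
        gts = [[small, medium, large]]
        preds = [[Detection(small, 0.9), Detection(medium, 0.8)]]
        res = evaluate(preds, gts)
        assert res.per_bin_map50["small"] == pytest.approx(1.0)
        assert res.per_bin_map50["medium"] == pytest.approx(1.0)
        assert res.per_bin_map50["large"] == 0.0

    def test_synthetic_scenes_cover_all_bins(self):
        cfg = SceneConfig(image_size=640, seed=11, n_stalks=(6, 8),
                          occlusion_prob=0.0)
        bins = set()
        for s in range(6):
            _, boxes = generate_scene(SceneConfig(**{**cfg.__dict__, "seed": s}))
            from canedet.synth import size_bin
            bins |= {size_bin(b.w * b.h) for b in boxes}
        assert bins == {"small", "medium", "large"}


def _random_scene_sets(rng, n_images, seed=None, img=100.0):
    """Random gts with jittered/noisy predictions."""
    if seed is not None:
        rng = np.random.default_rng(1000 + seed)
    gts, preds = [], []
    for _ in range(n_images):
        n = int(rng.integers(1, 6))
        g = [B(*xy, *wh) for xy, wh in zip(rng.uniform(10, 90, (n, 2)),
                                           rng.uniform(3, 20, (n, 2)))]
        p = []
        for b in g:
            if rng.uniform() < 0.8:
                p.append(D(b.xc + rng.normal(0, 2), b.yc + rng.normal(0, 2),
                           max(b.w + rng.normal(0, 2), 1),
                           max(b.h + rng.normal(0, 2), 1),
                           float(rng.uniform(0.3, 1.0))))
        for _ in range(int(rng.integers(0, 3))):
            p.append(D(*rng.uniform(10, 90, 2),
                       *rng.uniform(3, 15, 2), float(rng.uniform(0.1, 0.8))))
        gts.append(g)
        preds.append(p)
    return gts, preds
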