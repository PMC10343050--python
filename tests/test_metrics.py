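"""Dice, HD95 and generalized Dice loss against brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from hdcseg.autograd import Tensor
from hdcseg.losses import generalized_dice_loss, one_hot_labels
from hdcseg.metrics import (ConfusionCounts, boundary_voxels, dice,
                            dice_from_counts, evaluate_cases, hd95)


def brute_force_hausdorff(p, t, percentile):
    """O(|dP|*|dT|) double-loop oracle over boundary voxel pairs."""
    bp = np.argwhere(boundary_voxels(p))
    bt = np.argwhere(boundary_voxels(t))
    d = cdist(bp, bt)
    d_pt = d.min(axis=1)   # inf over dT for each p
    d_tp = d.min(axis=0)
    pooled = np.concatenate([d_pt, d_tp])
    if percentile >= 100:
        return max(d_pt.max(), d_tp.max())
    return np.percentile(pooled, percentile)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        assert dice(m, m) == 1.0

    def test_disjoint_nonempty_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_formula_on_counts(self):
        assert dice_from_counts(ConfusionCounts(tp=2, fp=1, fn=1)) == pytest.approx(2 / 3)

    def test_empty_mask_policy(self):
        e = np.zeros((3, 3, 3), bool)
        f = np.ones((3, 3, 3), bool)
        assert dice(e, e) == 1.0
        assert dice(e, f) == 0.0

    def test_symmetric(self, rng):
        a = rng.random((6, 6, 6)) > 0.6
        b = rng.random((6, 6, 6)) > 0.6
        assert dice(a, b) == dice(b, a)


class TestHD95:
    def test_identical_masks_zero(self, rng):
        m = rng.random((6, 6, 6)) > 0.5
        m[2, 2, 2] = True
        val, flag = hd95(m, m)
        assert val == 0.0 and flag == ""

    def test_single_voxel_pair_full_hausdorff(self):
        p = np.zeros((6, 6, 6), bool)
        t = np.zeros((6, 6, 6), bool)
        p[0, 0, 0] = True
        t[3, 4, 0] = True
        val, _ = hd95(p, t, percentile=100)
        assert val == pytest.approx(5.0)

    @pytest.mark.parametrize("percentile", [95, 100])
    def test_matches_exhaustive_oracle_on_random_masks(self, percentile):
        rng = np.random.default_rng(77)
        for _ in range(10):
            p = ndimage.binary_dilation(rng.random((8, 8, 8)) > 0.9)
            t = ndimage.binary_dilation(rng.random((8, 8, 8)) > 0.9)
            if not p.any() or not t.any():
                continue
            got, flag = hd95(p, t, percentile=percentile)
            assert flag == ""
            want = brute_force_hausdorff(p, t, percentile)
            assert got == pytest.approx(want, abs=1e-9)

    def test_symmetric(self, rng):
        p = ndimage.binary_dilation(rng.random((8, 8, 8)) > 0.9)
        t = ndimage.binary_dilation(rng.random((8, 8, 8)) > 0.9)
        if p.any() and t.any():
            assert hd95(p, t)[0] == pytest.approx(hd95(t, p)[0])

    def test_full_hausdorff_dominates_95th(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            p = ndimage.binary_dilation(r.random((8, 8, 8)) > 0.88)
            t = ndimage.binary_dilation(r.random((8, 8, 8)) > 0.88)
            if not (p.any() and t.any()):
                continue
            assert hd95(p, t, percentile=100)[0] >= hd95(p, t, percentile=95)[0]

    def test_empty_mask_policy(self):
        e = np.zeros((4, 4, 4), bool)
        f = np.zeros((4, 4, 4), bool)
        f[1, 1, 1] = True
        val, flag = hd95(e, f)
        assert flag == "empty" and val == pytest.approx(np.sqrt(48))
        val, flag = hd95(e, e)
        assert val == 0.0 and flag == "both_empty"

    def test_spacing_scales_distances(self):
        p = np.zeros((4, 4, 4), bool)
        t = np.zeros((4, 4, 4), bool)
        p[0, 0, 0] = True
        t[0, 0, 2] = True
        val, _ = hd95(p, t, percentile=100, spacing=(1, 1, 2.5))
        assert val == pytest.approx(5.0)


class TestGDL:
    def test_perfect_prediction_zero_loss(self, rng):
        lab = rng.choice([0, 1, 2, 4], size=(4, 4, 4))
        t = one_hot_labels(lab)
        if not all(t[c].sum() > 0 for c in range(4)):
            lab[0, 0, :4] = [0, 1, 2, 4]
            t = one_hot_labels(lab)
        loss = generalized_dice_loss(Tensor(t), t)
        assert loss.item() == pytest.approx(0.0, abs=1e-7)

    def test_uniform_prediction_matches_hand_summation(self):
        """2-voxel, 4-class toy: p = 0.25 everywhere, t one-hot."""
        t = np.zeros((4, 2, 1, 1), dtype=np.float32)
        t[0, 0] = 1.0
        t[2, 1] = 1.0
        p = np.full_like(t, 0.25)
        # per class volumes: (1, 0, 1, 0); w = (1, cap, 1, cap)
        cap = 1e8
        w = np.array([1.0, cap, 1.0, cap])
        inter = np.array([0.25, 0.0, 0.25, 0.0])
        tot = np.array([0.5 + 1, 0.5, 0.5 + 1, 0.5])
        want = 1 - 2 * (w * inter).sum() / (w * tot).sum()
        got = generalized_dice_loss(Tensor(p), t).item()
        assert got == pytest.approx(want, rel=1e-6)

    def test_absent_class_keeps_loss_finite(self):
        lab = np.zeros((3, 3, 3), dtype=int)  # background only
        t = one_hot_labels(lab)
        p = np.full_like(t, 0.25)
        loss = generalized_dice_loss(Tensor(p), t).item()
        assert np.isfinite(loss) and 0.0 <= loss <= 1.0

    def test_rejects_non_one_hot_truth(self):
        t = np.full((4, 2, 2, 2), 0.5, dtype=np.float32)
        with pytest.raises(ValueError, match="one-hot"):
            generalized_dice_loss(Tensor(t), t)

    def test_monotone_decrease_toward_truth(self):
        """GDL falls as p moves linearly from uniform toward the one-hot
        truth, on 20 random toys."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            lab = rng.choice([0, 1, 2, 4], size=(3, 3, 3))
            t = one_hot_labels(lab)
            uniform = np.full_like(t, 0.25)
            prev = np.inf
            for alpha in (0.0, 0.25, 0.5, 0.75, 1.0):
                p = (1 - alpha) * uniform + alpha * t
                val = generalized_dice_loss(Tensor(p), t).item()
                assert val <= prev + 1e-9
                prev = val

    def test_differentiable_in_p(self, rng):
        lab = rng.choice([0, 1, 2, 4], size=(3, 3, 3))
        t = one_hot_labels(lab).astype(np.float64)
        logits = Tensor(rng.normal(size=t.shape), requires_grad=True)
        from hdcseg.autograd import softmax
        p = softmax(logits, axis=0)
        loss = generalized_dice_loss(p, t)
        loss.backward()
        assert logits.grad is not None and np.isfinite(logits.grad).all()


class TestEvaluateCases:
    def test_perfect_predictions(self, rng):
        from hdcseg.phantom import PhantomSpec, make_case
        spec = PhantomSpec(shape=(32, 32, 32), seed=6)
        labs = [make_case(spec, rng)[1] for _ in range(3)]
        report = evaluate_cases(labs, labs)
        body = report.table.iloc[:-1]
        for region in ("et", "wt", "tc"):
            assert (body[f"dice_{region}"] == 1.0).all()
            assert (body[f"hd95_{region}"] == 0.0).all()

    def test_row_count_is_cases_plus_mean(self, rng):
        from hdcseg.phantom import PhantomSpec, make_case
        spec = PhantomSpec(shape=(24, 24, 24), seed=6)
        labs = [make_case(spec, rng)[1] for _ in range(3)]
        report = evaluate_cases(labs, labs)
        assert len(report.table) == 4
        assert report.table.iloc[-1]["case_id"] == "mean"

    def test_eroded_prediction_bounded_by_voxel_diagonal(self, rng):
        """Eroding the truth by one 6-connected step moves every boundary by
        at most sqrt(3) voxels."""
        from hdcseg.phantom import PhantomSpec, make_case
        spec = PhantomSpec(shape=(32, 32, 32), seed=8)
        lab = make_case(spec, rng)[1]
        eroded = lab.labels.copy()
        keep = ndimage.binary_erosion(eroded > 0)
        eroded[~keep] = 0
        report = evaluate_cases([eroded], [lab])
        row = report.table.iloc[0]
        assert row["dice_wt"] < 1.0
        assert row["hd95_wt"] <= np.sqrt(3) + 1e-9

    def test_csv_roundtrip(self, tmp_path, rng):
        import pandas as pd
        lab = np.zeros((8, 8, 8), dtype=int)
        lab[2:5, 2:5, 2:5] = 4
        report = evaluate_cases([lab], [lab])
        out = tmp_path / "report.csv"
        report.to_csv(out)
        back = pd.read_csv(out)
        assert len(back) == 2 and back["dice_wt"].iloc[0] == 1.0
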