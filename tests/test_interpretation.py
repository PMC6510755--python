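"""Region masking and class-activation heatmaps."""

import numpy as np
import pytest
from scipy import ndimage

from petguard import nn
from petguard.aggregation import majority_vote
from petguard.augmentation import AugmentConfig
from petguard.errors import ConfigurationError
from petguard.interpretation import (
    MASK_REGIONS,
    REGION_BANDS,
    MaskSpec,
    apply_mask,
    band_heat_fraction,
    default_masks,
    grad_cam,
    masking_experiment,
)
from petguard.model import CNNModel, NetworkSpec, TrainingConfig, predict_batch
from petguard.projection import MIPImage


def _img(pixels, pid="P0"):
    return MIPImage(pixels=pixels.astype(np.float32), angle=0.0, patient_id=pid)


PELVIS = MaskSpec(region="pelvis", band=REGION_BANDS["pelvis"])


class TestApplyMask:
    def test_constant_image_unchanged(self):
        im = _img(np.full((64, 64), 0.4))
        out = apply_mask(im, PELVIS)
        assert np.allclose(out.pixels, 0.4)

    def test_band_filled_with_original_mean_outside_untouched(self):
        pix = np.zeros((64, 64))
        pix[38:55, :] = 0.8  # energy only inside the pelvic band
        im = _img(pix)
        out = apply_mask(im, PELVIS)
        mean = pix.mean()
        r0, r1 = round(0.60 * 64), round(0.85 * 64)
        assert np.allclose(out.pixels[r0:r1, :], np.float32(mean))
        assert np.array_equal(out.pixels[:r0, :], im.pixels[:r0, :])
        assert np.array_equal(out.pixels[r1:, :], im.pixels[r1:, :])
        assert out.pixels[r0:r1, :].var() < 1e-12  # constant fill (float32 accumulation)

    def test_idempotent_with_recorded_fill(self, rng):
        im = _img(rng.random((64, 64)))
        once = apply_mask(im, PELVIS)
        twice = apply_mask(once, PELVIS, fill_value=once.meta["mask_fill"])
        assert np.array_equal(once.pixels, twice.pixels)

    def test_bad_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            MaskSpec(region="x", band=(0.5, 0.4))
        with pytest.raises(ConfigurationError):
            apply_mask(_img(np.zeros((64, 64))), MaskSpec(region="thin", band=(0.501, 0.502)))


class TestMaskSet:
    def test_default_masks_cover_six_regions(self):
        masks = default_masks()
        assert [m.region for m in masks] == list(MASK_REGIONS)
        bands = {m.region: m.band for m in masks}
        assert bands["upper_body"] == (bands["head"][0], bands["chest"][1])
        assert bands["lower_body"] == (bands["abdomen"][0], bands["pelvis"][1])


class TestMaskingExperiment:
    def test_table_structure_and_error_marking(self, tiny_cohort):
        _, mips, truths = tiny_cohort
        regions = [
            MaskSpec(region="pelvis", band=REGION_BANDS["pelvis"]),
            MaskSpec(region="thin", band=(0.996, 0.999)),  # no pixel rows -> row marked failed
        ]
        table = masking_experiment(
            mips,
            truths,
            regions=regions,
            train_cfg=TrainingConfig(seed=5, max_epochs=1, patience=1),
            augment=AugmentConfig(factor=1, seed=5),
            seed=5,
        )
        assert list(table.index) == ["no_mask", "pelvis", "thin"]
        assert {"male_accuracy", "female_accuracy", "patient_accuracy"} <= set(table.columns)
        assert np.isnan(table.loc["thin", "patient_accuracy"])
        assert table.loc["thin", "error"] != ""
        assert np.isfinite(table.loc["no_mask", "patient_accuracy"])


def _toy_model(rng, zero_head=False):
    conv = nn.Conv3x3(1, 1, rng)
    dense = nn.Dense(64 * 64, 2, rng)
    if zero_head:
        dense.W[...] = 0.0
    net = nn.Sequential([conv, nn.ReLU(), nn.Flatten(), dense])
    model = CNNModel(NetworkSpec(), net, task="sex")
    model.trained = True
    return model, conv, dense


class TestGradCam:
    def test_heatmap_nonnegative_and_normalized(self, tiny_trained):
        model = tiny_trained["model"]
        pid = tiny_trained["test_ids"][0]
        hm = grad_cam(model, tiny_trained["mips"][pid][0])
        assert hm.values.min() >= 0.0
        # max-normalized to 1 whenever any heat survives the ReLU
        assert hm.values.max() in (0.0,) or hm.values.max() == pytest.approx(1.0)
        ew = grad_cam(model, tiny_trained["mips"][pid][0], method="elementwise")
        assert ew.values.min() >= 0.0
        assert ew.values.max() == pytest.approx(1.0)

    def test_zero_class_weights_give_zero_map(self, rng):
        model, *_ = _toy_model(rng, zero_head=True)
        im = _img(rng.random((64, 64)))
        hm = grad_cam(model, im, target_class="male")
        assert np.all(hm.values == 0.0)

    def test_single_conv_toy_matches_closed_form(self, rng):
        # independent oracle: conv via scipy.ndimage.correlate, gradient of the
        # class score w.r.t. the post-ReLU map is the dense weight column
        model, conv, dense = _toy_model(rng)
        pix = rng.random((64, 64)).astype(np.float32)
        im = _img(pix)
        K = conv.W.reshape(3, 3)
        A = np.maximum(ndimage.correlate(pix, K, mode="constant") + conv.b[0], 0.0)
        # gradient of the class score w.r.t. the *post-ReLU* map: no ReLU mask
        dA = dense.W[:, 0].reshape(64, 64)
        w = dA.mean()
        expected = np.maximum(w * A, 0.0)
        if expected.max() > 0:
            expected = expected / expected.max()
        hm = grad_cam(model, im, target_class="male")
        assert np.allclose(hm.values, expected, atol=1e-4)

    def test_elementwise_heat_concentrates_on_pelvic_signal(self, tiny_trained):
        model = tiny_trained["model"]
        mips, truths = tiny_trained["mips"], tiny_trained["truths"]
        fracs = {r: [] for r in ("head", "chest", "abdomen", "pelvis")}
        for p in tiny_trained["preds"]:
            t = truths[p.patient_id].sex
            if p.sex_label != t:
                continue
            for im in mips[p.patient_id][::6]:
                hm = grad_cam(model, im, target_class=t, method="elementwise")
                for r in fracs:
                    fracs[r].append(band_heat_fraction(hm, REGION_BANDS[r]))
        means = {r: np.mean(v) for r, v in fracs.items()}
        assert means["pelvis"] == max(means.values())

    def test_occlusion_probe_confirms_pelvic_dependence(self, tiny_trained):
        # masking the pelvic band at inference must hurt accuracy more than
        # masking any other single region
        model = tiny_trained["model"]
        mips, truths = tiny_trained["mips"], tiny_trained["truths"]

        def acc(region):
            ok = 0
            for pid in tiny_trained["test_ids"]:
                ims = mips[pid]
                if region:
                    m = MaskSpec(region=region, band=REGION_BANDS[region])
                    ims = [apply_mask(im, m) for im in ims]
                label, *_ = majority_vote(predict_batch(model, ims))
                ok += label == truths[pid].sex
            return ok / len(tiny_trained["test_ids"])

        accs = {r: acc(r) for r in ("head", "chest", "abdomen", "pelvis")}
        assert accs["pelvis"] == min(accs.values())
        assert accs["pelvis"] < acc(None)
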