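"""Where does the classifier look?  Masking ablation and Grad-CAM.

The masking experiment replaces one horizontal anatomical band of every
image (train *and* test) with the mean gray value of that image, retrains
the classifier from scratch under identical conditions, and tabulates
per-sex accuracy for each of six regions plus the unmasked baseline.  Band
locations are fixed in image coordinates and applied to all patients alike.

Grad-CAM weights the last convolutional block's feature maps by the
spatially averaged gradient of the target class score, rectifies the
weighted sum and upsamples it to the input resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .augmentation import AugmentConfig
from .errors import ConfigurationError, PredictionError
from .model import SEX_CLASSES, CNNModel, NetworkSpec, TrainingConfig
from .phantom import Demographics
from .projection import OUTPUT_SIZE, MIPImage

__all__ = [
    "MaskSpec",
    "HeatMap",
    "REGION_BANDS",
    "MASK_REGIONS",
    "default_masks",
    "apply_mask",
    "masking_experiment",
    "grad_cam",
    "band_heat_fraction",
]

#: Vertical band of each mask region as a fraction of image height
#: (0 = top of image).  upper_body = head + chest, lower_body = abdomen +
#: pelvis; the thighs (below 0.85) are never masked.
REGION_BANDS: dict[str, tuple[float, float]] = {
    "head": (0.00, 0.15),
    "chest": (0.15, 0.40),
    "abdomen": (0.40, 0.60),
    "pelvis": (0.60, 0.85),
    "upper_body": (0.00, 0.40),
    "lower_body": (0.40, 0.85),
}

MASK_REGIONS = ("head", "chest", "abdomen", "pelvis", "upper_body", "lower_body")


@dataclass(frozen=True)
class MaskSpec:
    region: str
    band: tuple[float, float]
    fill_policy: str = "image_mean"

    def __post_init__(self) -> None:
        top, bot = self.band
        if not (0.0 <= top < bot <= 1.0):
            raise ConfigurationError(f"mask band ({top}, {bot}) invalid")
        if self.fill_policy != "image_mean":
            raise ConfigurationError("only the image-mean fill policy is supported")


def default_masks() -> list[MaskSpec]:
    masks = [MaskSpec(region=r, band=REGION_BANDS[r]) for r in MASK_REGIONS]
    _validate_mask_set(masks)
    return masks


def _validate_mask_set(masks: list[MaskSpec]) -> None:
    bands = {m.region: m.band for m in masks}
    if "upper_body" in bands and {"head", "chest"} <= bands.keys():
        if not (
            np.isclose(bands["upper_body"][0], bands["head"][0])
            and np.isclose(bands["upper_body"][1], bands["chest"][1])
        ):
            raise ConfigurationError("upper_body band must equal head + chest")
    if "lower_body" in bands and {"abdomen", "pelvis"} <= bands.keys():
        if not (
            np.isclose(bands["lower_body"][0], bands["abdomen"][0])
            and np.isclose(bands["lower_body"][1], bands["pelvis"][1])
        ):
            raise ConfigurationError("lower_body band must equal abdomen + pelvis")


def _band_rows(band: tuple[float, float], height: int) -> tuple[int, int]:
    r0 = int(round(band[0] * height))
    r1 = int(round(band[1] * height))
    if r1 <= r0:
        raise ConfigurationError("mask band covers no pixel rows")
    return r0, r1


def apply_mask(image: MIPImage, mask: MaskSpec, fill_value: float | None = None) -> MIPImage:
    """Replace the band's pixels by the mean of the *original* entire image.

    ``fill_value`` overrides the computed mean; pass the value recorded in a
    previously masked image's ``meta['mask_fill']`` to re-apply a mask
    idempotently.
    """
    pix = image.pixels
    r0, r1 = _band_rows(mask.band, pix.shape[0])
    fill = float(pix.mean()) if fill_value is None else float(fill_value)
    out = pix.copy()
    out[r0:r1, :] = fill
    meta = {**image.meta, "mask_region": mask.region, "mask_fill": fill}
    return replace(image, pixels=out, meta=meta)


def masking_experiment(
    mips_by_patient: dict[str, list[MIPImage]],
    truths: dict[str, Demographics],
    regions: list[MaskSpec] | None = None,
    net_spec: NetworkSpec | None = None,
    train_cfg: TrainingConfig | None = None,
    augment: AugmentConfig | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
    fill: str = "cohort_mean",
) -> pd.DataFrame:
    """Train/test once per mask region (plus the unmasked baseline).

    The patient split, network initialization and training seeds are shared
    across all rows, so accuracy differences are attributable to the mask.
    Returns a table with one row per condition and per-sex patient-based
    accuracy columns (plus overall patient and image accuracy).  A row whose
    training fails is reported with NaN accuracies and the error message;
    the remaining rows still run.

    ``fill`` chooses the mask gray value: ``"cohort_mean"`` (default) uses
    one value for every image — the mean gray of the training-fold images —
    while ``"image_mean"`` uses each image's own mean.  The per-image fill
    is *not* a clean ablation: the image mean itself carries the regional
    signal (a bright pelvic feature raises it), so a classifier can read
    the class from the mask brightness; the shared fill removes that leak.
    """
    from .orchestration import run_sex_fold  # local import; orchestration owns the fold runner

    from .model import split_patients

    if fill not in ("cohort_mean", "image_mean"):
        raise ConfigurationError("fill must be 'cohort_mean' or 'image_mean'")
    regions = default_masks() if regions is None else regions
    _validate_mask_set(regions)
    train_ids, test_ids = split_patients(sorted(mips_by_patient), train_fraction, seed=seed)
    fill_value = None
    if fill == "cohort_mean":
        fill_value = float(
            np.mean([im.pixels.mean() for pid in train_ids for im in mips_by_patient[pid]])
        )

    rows = []
    for mask in [None, *regions]:
        name = "no_mask" if mask is None else mask.region
        try:
            if mask is None:
                data = mips_by_patient
            else:
                data = {
                    pid: [apply_mask(im, mask, fill_value=fill_value) for im in ims]
                    for pid, ims in mips_by_patient.items()
                }
            report, _ = run_sex_fold(
                data, truths, train_ids, test_ids, net_spec=net_spec,
                train_cfg=train_cfg, augment=augment, seed=seed,
            )
            rows.append(
                {
                    "mask": name,
                    "male_accuracy": report.per_sex_accuracy.get("male", np.nan),
                    "female_accuracy": report.per_sex_accuracy.get("female", np.nan),
                    "patient_accuracy": report.patient_accuracy,
                    "image_accuracy": report.image_accuracy,
                    "error": "",
                }
            )
        except Exception as exc:  # keep going; mark the failed row
            rows.append(
                {
                    "mask": name,
                    "male_accuracy": np.nan,
                    "female_accuracy": np.nan,
                    "patient_accuracy": np.nan,
                    "image_accuracy": np.nan,
                    "error": str(exc),
                }
            )
    return pd.DataFrame(rows).set_index("mask")


# --------------------------------------------------------------------------
# Grad-CAM
# --------------------------------------------------------------------------


@dataclass
class HeatMap:
    values: np.ndarray  # (64, 64), nonnegative, max 1 when nonzero
    image_id: str
    target_class: str


def grad_cam(
    model: CNNModel,
    image: MIPImage,
    target_class: str | int | None = None,
    method: str = "gradcam",
) -> HeatMap:
    """Class-activation heatmap of the last convolutional block.

    With ``method="gradcam"`` channel weights are the spatial average of
    d(class score)/d(feature map) and the heatmap is ReLU(sum_k w_k A_k).
    With ``method="elementwise"`` the heatmap is ReLU(sum_k dA_k * A_k)
    (no spatial pooling of the gradient), which preserves localization for
    very narrow networks where globally averaged channel weights smear the
    evidence.  Either way the map is bilinearly upsampled to the input size
    and normalized to max 1.  ``target_class`` defaults to the predicted
    class.
    """
    if method not in ("gradcam", "elementwise"):
        raise ConfigurationError("method must be 'gradcam' or 'elementwise'")
    if model.spec.head != "softmax":
        raise PredictionError("Grad-CAM requires a classification model with class scores")
    x = image.pixels.astype(np.float32)[None, ..., None]
    acts = model.net.activations(x)
    idx = model.last_conv_index()
    A = acts[idx]  # (1, h, w, C)

    logits = acts[-1]
    if target_class is None:
        target = int(np.argmax(logits[0]))
    elif isinstance(target_class, str):
        target = SEX_CLASSES.index(target_class)
    else:
        target = int(target_class)
    dlogits = np.zeros_like(logits)
    dlogits[0, target] = 1.0

    dA = model.net.backward(dlogits, stop_after=idx + 1)
    if method == "gradcam":
        weights = dA.mean(axis=(1, 2))  # (1, C)
        cam = np.maximum((A * weights[:, None, None, :]).sum(axis=-1)[0], 0.0)
    else:
        cam = np.maximum((dA * A).sum(axis=-1)[0], 0.0)

    h, w = cam.shape
    cam = ndimage.zoom(cam, (OUTPUT_SIZE / h, OUTPUT_SIZE / w), order=1, mode="nearest")
    cam = np.maximum(cam[:OUTPUT_SIZE, :OUTPUT_SIZE], 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    label = SEX_CLASSES[target] if target < len(SEX_CLASSES) else str(target)
    return HeatMap(values=cam.astype(np.float32), image_id=image.patient_id, target_class=label)


def band_heat_fraction(heatmap: HeatMap, band: tuple[float, float]) -> float:
    """Fraction of total heat inside a vertical image band."""
    vals = heatmap.values
    total = float(vals.sum())
    if total == 0:
        return 0.0
    r0, r1 = _band_rows(band, vals.shape[0])
    return float(vals[r0:r1, :].sum()) / total
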