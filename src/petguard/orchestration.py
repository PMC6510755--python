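"""Experiment designs: mixed-scanner split with repeats, cross-scanner
transfer, and the regression variants.

`run_sex_fold` / `run_regression_fold` are the single-fold building blocks
(train on one patient set, test on a disjoint one, aggregate per patient);
the experiment runners compose them.  Test images never pass through the
augmentation stage — only the training fold inside ``model.train`` does.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass

import numpy as np

from .aggregation import (
    MetricsReport,
    PatientPrediction,
    aggregate_regression,
    evaluate,
    majority_vote,
)
from .augmentation import AugmentConfig
from .errors import ConfigurationError, EmptyInputError
from .model import (
    SEX_CLASSES,
    NetworkSpec,
    TrainingConfig,
    build_model,
    predict_batch,
    split_patients,
    train,
)
from .phantom import CohortRecord, Demographics
from .projection import MIPImage, generate_mip_set

__all__ = [
    "ExperimentConfig",
    "project_cohort",
    "run_sex_fold",
    "run_regression_fold",
    "run_mixed_experiment",
    "run_cross_scanner",
    "spawn_seeds",
    "write_manifest",
    "plot_history",
]

logger = logging.getLogger("petguard")


@dataclass(frozen=True)
class ExperimentConfig:
    design: str = "mixed_split"  # or "cross_scanner"
    train_scanner: str | None = None
    test_scanner: str | None = None
    repeats: int = 5
    train_fraction: float = 0.7
    seeds: tuple[int, ...] | None = None
    tasks: tuple[str, ...] = ("sex",)
    net_spec: NetworkSpec | None = None
    regression_net_spec: NetworkSpec | None = None
    train_cfg: TrainingConfig | None = None
    augment: AugmentConfig | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("mixed_split", "cross_scanner"):
            raise ConfigurationError("design must be mixed_split or cross_scanner")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        if self.seeds is not None and len(self.seeds) != self.repeats:
            raise ConfigurationError("repeats must equal the number of seeds")
        if self.design == "cross_scanner":
            if not self.train_scanner or not self.test_scanner:
                raise ConfigurationError("cross_scanner needs train and test scanners")
            if self.train_scanner == self.test_scanner:
                raise ConfigurationError("cross_scanner scanners must differ")

    def seed_list(self) -> list[int]:
        if self.seeds is not None:
            return list(self.seeds)
        return spawn_seeds(self.master_seed, self.repeats)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        """Load an experiment config from YAML; nested ``net_spec``,
        ``train_cfg`` and ``augment`` mappings become their dataclasses."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, klass in (
            ("net_spec", NetworkSpec),
            ("regression_net_spec", NetworkSpec),
            ("train_cfg", TrainingConfig),
            ("augment", AugmentConfig),
        ):
            if isinstance(raw.get(key), dict):
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in raw[key].items()
                }
                raw[key] = klass(**sub)
        for key in ("seeds", "tasks"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic repeat seeds derived from one master seed."""
    return [
        int(np.random.SeedSequence([int(master_seed), k]).generate_state(1)[0] % (2**31))
        for k in range(n)
    ]


def project_cohort(records: list[CohortRecord]):
    """Render every patient's MIP view set.

    Returns ``(mips_by_patient, truths)``; view counts follow each patient's
    scanner profile.
    """
    if not records:
        raise EmptyInputError("empty cohort")
    t0 = time.perf_counter()
    mips = {}
    truths = {}
    for rec in records:
        mips[rec.patient_id] = generate_mip_set(rec.volume, rec.scanner)
        truths[rec.patient_id] = rec.demographics
    logger.info("projected %d patients in %.1f s", len(records), time.perf_counter() - t0)
    return mips, truths


def _gather(mips_by_patient, truths, ids, label_fn):
    images, labels = [], []
    for pid in ids:
        for im in mips_by_patient[pid]:
            images.append(im)
            labels.append(label_fn(truths[pid]))
    return images, labels


def run_sex_fold(
    mips_by_patient: dict[str, list[MIPImage]],
    truths: dict[str, Demographics],
    train_ids,
    test_ids,
    net_spec: NetworkSpec | None = None,
    train_cfg: TrainingConfig | None = None,
    augment: AugmentConfig | None = None,
    seed: int = 0,
):
    """Train the sex classifier on ``train_ids``, majority-vote ``test_ids``.

    Returns ``(MetricsReport, list[PatientPrediction])``.
    """
    if set(train_ids) & set(test_ids):
        raise ConfigurationError("train and test patients overlap")
    spec = net_spec or NetworkSpec()
    cfg = train_cfg or TrainingConfig(seed=seed)
    aug = augment if augment is not None else AugmentConfig(seed=seed)
    t0 = time.perf_counter()
    images, labels = _gather(mips_by_patient, truths, train_ids, lambda d: d.sex)
    model = build_model(spec, task="sex", seed=seed)
    train(model, images, labels, cfg, augment=aug)
    logger.info(
        "sex fold: trained %d epochs on %d images in %.1f s",
        len(model.history),
        len(images),
        time.perf_counter() - t0,
    )
    preds = []
    for pid in test_ids:
        probs = predict_batch(model, mips_by_patient[pid])
        label, frac, mean_p, tie = majority_vote(probs)
        preds.append(
            PatientPrediction(
                patient_id=pid,
                sex_label=label,
                vote_fraction=frac,
                mean_prob=mean_p,
                tie_broken=tie,
                n_images=len(probs),
                view_labels=[SEX_CLASSES[i] for i in probs.argmax(axis=1)],
            )
        )
    report = evaluate(preds, {pid: truths[pid] for pid in test_ids})
    report.model = model  # attached for interpretability follow-ups
    return report, preds


def run_regression_fold(
    mips_by_patient,
    truths,
    train_ids,
    test_ids,
    task: str,
    net_spec: NetworkSpec | None = None,
    train_cfg: TrainingConfig | None = None,
    augment: AugmentConfig | None = None,
    seed: int = 0,
    aggregate: str = "median",
):
    """Train an age or weight regressor and aggregate per-view estimates."""
    if task not in ("age", "weight"):
        raise ConfigurationError("task must be 'age' or 'weight'")
    spec = net_spec or NetworkSpec(head="linear", dropout_rate=0.2)
    cfg = train_cfg or TrainingConfig(seed=seed)
    aug = augment if augment is not None else AugmentConfig(seed=seed)
    attr = task
    images, labels = _gather(mips_by_patient, truths, train_ids, lambda d: getattr(d, attr))
    model = build_model(spec, task=task, seed=seed)
    train(model, images, labels, cfg, augment=aug)
    preds = []
    for pid in test_ids:
        est = predict_batch(model, mips_by_patient[pid])
        value = aggregate_regression(est, method=aggregate)
        kwargs = {f"{task}_estimate": value}
        preds.append(
            PatientPrediction(patient_id=pid, n_images=len(est), **kwargs)
        )
    report = evaluate(preds, {pid: truths[pid] for pid in test_ids})
    report.model = model
    return report, preds


def _merge_reports(reports: list[MetricsReport]) -> MetricsReport:
    merged = MetricsReport()
    for r in reports:
        if not np.isnan(r.patient_accuracy):
            merged.patient_accuracy = r.patient_accuracy
            merged.image_accuracy = r.image_accuracy
            merged.per_sex_accuracy = r.per_sex_accuracy
            merged.per_sex_image_accuracy = r.per_sex_image_accuracy
            merged.n_patients = r.n_patients
            merged.n_images = r.n_images
        merged.within_tolerance_fractions.update(r.within_tolerance_fractions)
        if r.age_confusion is not None:
            merged.age_confusion = r.age_confusion
        if r.weight_confusion is not None:
            merged.weight_confusion = r.weight_confusion
    return merged


def run_mixed_experiment(records: list[CohortRecord], cfg: ExperimentConfig):
    """Mixed-scanner design: per repeat, re-draw a 70/30 patient split, train
    each requested task, and summarize metrics as mean +- sample SD over
    repeats.

    Returns ``{"repeats": [MetricsReport...], "summary": {metric: {mean, sd}}}``.
    """
    mips, truths = project_cohort(records)
    seeds = cfg.seed_list()
    reports = []
    for k, seed in enumerate(seeds):
        train_ids, test_ids = split_patients(sorted(mips), cfg.train_fraction, seed=seed)
        task_reports = []
        for task in cfg.tasks:
            if task == "sex":
                rep, _ = run_sex_fold(
                    mips, truths, train_ids, test_ids,
                    net_spec=cfg.net_spec, train_cfg=cfg.train_cfg,
                    augment=cfg.augment, seed=seed,
                )
            else:
                rep, _ = run_regression_fold(
                    mips, truths, train_ids, test_ids, task,
                    net_spec=cfg.regression_net_spec, train_cfg=cfg.train_cfg,
                    augment=cfg.augment, seed=seed,
                )
            task_reports.append(rep)
        reports.append(_merge_reports(task_reports))
        logger.info("repeat %d/%d done", k + 1, len(seeds))
    return {"repeats": reports, "summary": summarize_metrics(reports)}


def summarize_metrics(reports: list[MetricsReport]) -> dict:
    """Mean and sample SD (ddof=1) per scalar metric; SD is None for one repeat."""
    scalars: dict[str, list[float]] = {}
    for r in reports:
        flat = {
            "image_accuracy": r.image_accuracy,
            "patient_accuracy": r.patient_accuracy,
            **{f"{s}_accuracy": v for s, v in r.per_sex_accuracy.items()},
            **r.within_tolerance_fractions,
        }
        for k, v in flat.items():
            if v is not None and np.isfinite(v):
                scalars.setdefault(k, []).append(float(v))
    out = {}
    for k, vals in scalars.items():
        out[k] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            "n_repeats": len(vals),
        }
    return out


def run_cross_scanner(records: list[CohortRecord], cfg: ExperimentConfig) -> MetricsReport:
    """Train on one scanner's patients, test on the other's.  No split."""
    by_scanner: dict[str, list[str]] = {}
    for r in records:
        by_scanner.setdefault(r.scanner.name, []).append(r.patient_id)
    for sc in (cfg.train_scanner, cfg.test_scanner):
        if not by_scanner.get(sc):
            raise ConfigurationError(f"scanner {sc!r} has no patients in the cohort")
    mips, truths = project_cohort(records)
    seed = cfg.seed_list()[0]
    rep, _ = run_sex_fold(
        mips, truths, by_scanner[cfg.train_scanner], by_scanner[cfg.test_scanner],
        net_spec=cfg.net_spec, train_cfg=cfg.train_cfg, augment=cfg.augment, seed=seed,
    )
    return rep


# --------------------------------------------------------------------------
# manifests and plots
# --------------------------------------------------------------------------


def write_manifest(path, config: dict, seeds: list[int], cohort_df=None) -> None:
    """Record everything needed to re-run an experiment bit-identically."""
    from . import __version__

    manifest = {
        "package_version": __version__,
        "config": config,
        "seeds": list(map(int, seeds)),
    }
    if cohort_df is not None:
        digest = hashlib.sha256(cohort_df.to_csv(index=False).encode()).hexdigest()
        manifest["cohort_sha256"] = digest
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def plot_history(history, path) -> None:
    """Training/validation loss curve as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(history["epoch"], history["train_loss"], label="training")
    ax.plot(history["epoch"], history["val_loss"], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
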