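"""Synthetic whole-body PET phantom cohorts.

This module generates stylized whole-body FDG-PET volumes (SUV units) whose
demographic structure mimics what a sex/age/weight classifier exploits in
clinical scans:

* a strong, low-variance sex signal in the **pelvic** band (broad gonadal /
  uterine uptake patterns that differ in shape and in regional mean),
* a weaker, high-variance sex signal in the **chest** band (breast/pectoral
  uptake with large inter-individual spread),
* **age** encoded as a linear drift of background soft-tissue SUV,
* **weight** encoded as habitus: transaxial body half-widths scale with
  ``sqrt(weight / 70 kg)``,
* a **brain** that sits above the display window maximum (SUV 10) so it
  saturates after windowing,
* Poisson-like noise (variance proportional to local mean) plus a small
  Gaussian floor, scaled per scanner.

The phantom is a stack of elliptical cross-sections (head, chest, abdomen,
pelvis, two thighs) in physical millimetre coordinates; it is deliberately
*not* anatomically realistic — only the regional statistical structure
matters for exercising the prediction pipeline.

Axis convention used everywhere in this package: volume arrays are indexed
``(z, y, x)`` with ``z`` the craniocaudal axis, slice 0 at the top of the
head; ``y`` is anterior-posterior and ``x`` left-right.  Voxel spacing is
stored as ``(dx, dy, dz)`` in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, EmptyInputError

__all__ = [
    "Demographics",
    "ScannerProfile",
    "Volume",
    "PhantomSpec",
    "CohortRecord",
    "SCANNER_1",
    "SCANNER_2",
    "DESK_SCANNER_1",
    "DESK_SCANNER_2",
    "DEFAULT_REGION_LAYOUT",
    "DEFAULT_SIGNALS",
    "DEFAULT_WEIGHT_MODEL",
    "DEFAULT_RATIO_MALE",
    "DEFAULT_SCANNER_MIX",
    "generate_phantom",
    "sample_demographics",
    "generate_cohort",
    "body_mask",
    "band_body_mean",
    "silhouette_max_width_mm",
    "save_volume",
    "load_volume",
    "save_cohort_metadata",
]

SEXES = ("male", "female")

#: Fraction of the cranio-caudal extent occupied by each anatomical band,
#: top of head = 0.0.  The remainder (0.85-1.0) is the thighs and stays
#: outside every mask region.
DEFAULT_REGION_LAYOUT: dict[str, tuple[float, float]] = {
    "head": (0.00, 0.15),
    "chest": (0.15, 0.40),
    "abdomen": (0.40, 0.60),
    "pelvis": (0.60, 0.85),
}

#: Amplitudes of the demographic signals, in SUV units.  ``pelvis_sex_amplitude``
#: is the exact difference in mean SUV over pelvic-band body voxels between a
#: male and a female phantom of otherwise identical demographics (noise off).
DEFAULT_SIGNALS: dict[str, float] = {
    "pelvis_sex_amplitude": 1.5,
    "pelvis_female_mean": 0.30,
    "chest_female_mean": 1.2,
    "chest_female_sd": 0.8,
    "chest_male_mean": 0.3,
    "chest_male_sd": 0.3,
    "soft_tissue_suv": 1.1,
    "age_slope": 0.006,
    "brain_suv": 12.0,
}

#: Sex-conditional body-weight model (normal, kg), clipped to a common range.
DEFAULT_WEIGHT_MODEL: dict[str, tuple[float, float]] = {
    "male": (66.0, 10.0),
    "female": (52.0, 8.0),
    "clip": (30.0, 120.0),
}

# Cohort sex ratio: 3,623 of 6,462 patients male.
DEFAULT_RATIO_MALE = 3623 / 6462
DEFAULT_AGE_MEAN_SD = (61.6, 16.2)
AGE_CLIP = (2.0, 92.0)

#: Scanner share observed clinically: 5,641 / 6,462 on scanner 1.
DEFAULT_SCANNER_MIX = {"scanner1": 5641 / 6462, "scanner2": 821 / 6462}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Demographics:
    """Ground-truth or claimed patient attributes."""

    sex: str
    age: float
    weight: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not 0.0 <= self.age <= 100.0:
            raise ConfigurationError(f"age {self.age} outside [0, 100] years")
        if not 20.0 <= self.weight <= 150.0:
            raise ConfigurationError(f"weight {self.weight} outside [20, 150] kg")


@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition geometry and the MIP view schedule of one scanner.

    ``view_angles`` are azimuth angles (degrees, counterclockwise viewed from
    superior) at which MIP views are rendered; their count defines the number
    of votes each patient contributes to the majority rule.
    """

    name: str
    voxel_size: tuple[float, float, float]  # (dx, dy, dz) mm
    volume_matrix: tuple[int, int]  # (nx, ny)
    view_angles: tuple[float, ...]
    noise_scale: float = 0.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel sizes must be positive")
        if any(m < 4 for m in self.volume_matrix):
            raise ConfigurationError("volume matrix too small")
        ang = np.asarray(self.view_angles, dtype=float)
        if ang.size == 0:
            raise ConfigurationError("view_angles must be nonempty")
        if np.any(ang < 0) or np.any(ang >= 360):
            raise ConfigurationError("view angles must lie in [0, 360)")
        if np.any(np.diff(ang) <= 0):
            raise ConfigurationError("view angles must be strictly increasing")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be nonnegative")

    @property
    def n_views(self) -> int:
        return len(self.view_angles)


def _uniform_angles(start: float, stop_inclusive: float, step: float) -> tuple[float, ...]:
    n = int(round((stop_inclusive - start) / step)) + 1
    return tuple(start + i * step for i in range(n))


# Clinical profiles.  Scanner 1: 168 x 168 matrix, 4.1 x 4.1 x 2.0 mm voxels,
# 19 MIP views; Scanner 2: 144 x 144, 4.0 mm isotropic, 36 views.  The view
# schedules are the only uniform-step schedules matching both view counts at
# a common 10 degree step: 0-180 deg inclusive and 0-350 deg.
SCANNER_1 = ScannerProfile(
    name="scanner1",
    voxel_size=(4.1, 4.1, 2.0),
    volume_matrix=(168, 168),
    view_angles=_uniform_angles(0.0, 180.0, 10.0),
    noise_scale=0.15,
)
SCANNER_2 = ScannerProfile(
    name="scanner2",
    voxel_size=(4.0, 4.0, 4.0),
    volume_matrix=(144, 144),
    view_angles=_uniform_angles(0.0, 350.0, 10.0),
    noise_scale=0.25,
)

# Desk-scale siblings: same fields of view, view counts and noise character,
# coarser voxels, so cohorts of hundreds of phantoms project in minutes on a
# single CPU.  Used as the default cohort profiles.
DESK_SCANNER_1 = ScannerProfile(
    name="scanner1",
    voxel_size=(14.3, 14.3, 12.0),
    volume_matrix=(48, 48),
    view_angles=SCANNER_1.view_angles,
    noise_scale=0.15,
)
DESK_SCANNER_2 = ScannerProfile(
    name="scanner2",
    voxel_size=(14.4, 14.4, 13.0),
    volume_matrix=(40, 40),
    view_angles=SCANNER_2.view_angles,
    noise_scale=0.25,
)


@dataclass
class Volume:
    """A 3-D nonnegative SUV grid.

    ``intensities`` is indexed ``(z, y, x)`` with z craniocaudal (slice 0 at
    the head); ``spacing`` is ``(dx, dy, dz)`` in mm.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise EmptyInputError("volume must be a nonempty 3-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ConfigurationError("volume contains non-finite intensities")
        if np.any(self.intensities < 0):
            raise ConfigurationError("SUV intensities must be nonnegative")


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to synthesize one phantom deterministically."""

    demographics: Demographics
    scanner: ScannerProfile
    seed: int = 0
    region_layout: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LAYOUT)
    )
    signal_strengths: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGNALS))
    body_length_mm: float = 960.0  # head to mid-thigh

    def __post_init__(self) -> None:
        _validate_layout(self.region_layout)
        sig = {**DEFAULT_SIGNALS, **self.signal_strengths}
        object.__setattr__(self, "signal_strengths", sig)
        if sig["pelvis_sex_amplitude"] <= 0:
            raise ConfigurationError(
                "pelvis_sex_amplitude must be positive: a sex difference is required"
            )
        if any(v < 0 for v in sig.values()):
            raise ConfigurationError("signal amplitudes must be nonnegative")
        if self.body_length_mm <= 0:
            raise ConfigurationError("body_length_mm must be positive")

    def to_dict(self) -> dict:
        return {
            "demographics": vars(self.demographics).copy(),
            "scanner": {
                "name": self.scanner.name,
                "voxel_size": list(self.scanner.voxel_size),
                "volume_matrix": list(self.scanner.volume_matrix),
                "view_angles": list(self.scanner.view_angles),
                "noise_scale": self.scanner.noise_scale,
            },
            "seed": self.seed,
            "region_layout": {k: list(v) for k, v in self.region_layout.items()},
            "signal_strengths": dict(self.signal_strengths),
            "body_length_mm": self.body_length_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        sc = d["scanner"]
        return cls(
            demographics=Demographics(**d["demographics"]),
            scanner=ScannerProfile(
                name=sc["name"],
                voxel_size=tuple(sc["voxel_size"]),
                volume_matrix=tuple(sc["volume_matrix"]),
                view_angles=tuple(sc["view_angles"]),
                noise_scale=sc.get("noise_scale", 0.0),
            ),
            seed=int(d.get("seed", 0)),
            region_layout={k: tuple(v) for k, v in d["region_layout"].items()}
            if "region_layout" in d
            else dict(DEFAULT_REGION_LAYOUT),
            signal_strengths=dict(d.get("signal_strengths", {})),
            body_length_mm=float(d.get("body_length_mm", 960.0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    demographics: Demographics
    scanner: ScannerProfile
    volume: Volume


def _validate_layout(layout: dict[str, tuple[float, float]]) -> None:
    required = set(DEFAULT_REGION_LAYOUT)
    if not required.issubset(layout):
        raise ConfigurationError(f"region_layout must define {sorted(required)}")
    bands = sorted(layout.values())
    for top, bot in bands:
        if not (0.0 <= top < bot <= 1.0):
            raise ConfigurationError(f"band ({top}, {bot}) not within [0, 1)")
    for (_, b0), (t1, _) in zip(bands, bands[1:]):
        if t1 < b0 - 1e-12:
            raise ConfigurationError("region bands overlap")


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

# Transaxial half-widths (x, y) in mm of each band's elliptical cross-section
# for a 70 kg reference habitus.
_BAND_HALFWIDTHS = {
    "head": (80.0, 95.0),
    "chest": (170.0, 110.0),
    "abdomen": (160.0, 105.0),
    "pelvis": (175.0, 110.0),
}
_THIGH_HALFWIDTHS = (70.0, 90.0)
_THIGH_OFFSET_X = 85.0
_REFERENCE_WEIGHT = 70.0


def _grids(spec: PhantomSpec):
    dx, dy, dz = spec.scanner.voxel_size
    nx, ny = spec.scanner.volume_matrix
    nz = max(int(round(spec.body_length_mm / dz)), 8)
    zf = (np.arange(nz) + 0.5) / nz  # craniocaudal fraction, 0 = head top
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    return zf, y[:, None], x[None, :]


def _habitus(weight: float) -> float:
    # cross-sectional area ~ mass at fixed height => linear half-width ~ sqrt
    return float(np.sqrt(weight / _REFERENCE_WEIGHT))


def body_mask(spec: PhantomSpec) -> np.ndarray:
    """Deterministic, noise-free body silhouette of the phantom, ``(z, y, x)``."""
    zf, y, x = _grids(spec)
    h = _habitus(spec.demographics.weight)
    nz, ny, nx = len(zf), y.shape[0], x.shape[1]
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for region, (top, bot) in spec.region_layout.items():
        rx, ry = _BAND_HALFWIDTHS[region]
        zsel = (zf >= top) & (zf < bot)
        ell = (x / (rx * h)) ** 2 + (y / (ry * h)) ** 2 <= 1.0
        mask[zsel] = ell
    # thighs: everything below the deepest configured band, two columns
    bottom = max(b for _, b in spec.region_layout.values())
    zsel = zf >= bottom
    if np.any(zsel):
        rx, ry = _THIGH_HALFWIDTHS
        off = _THIGH_OFFSET_X * h
        left = ((x + off) / (rx * h)) ** 2 + (y / (ry * h)) ** 2 <= 1.0
        right = ((x - off) / (rx * h)) ** 2 + (y / (ry * h)) ** 2 <= 1.0
        mask[zsel] = left | right
    return mask


def _band_slice(zf: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    return (zf >= band[0]) & (zf < band[1])


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Render one phantom volume from its spec; bit-deterministic in (spec, seed).

    The noise-free intensity model, by construction:

    * body soft tissue: ``soft_tissue_suv + age_slope * (age - 60)``;
    * brain (head band): constant ``brain_suv`` (>= 10 so it saturates after
      display windowing);
    * pelvic band: sex-specific feature scaled so the mean SUV over pelvic
      body voxels equals soft tissue + ``pelvis_female_mean`` for women and
      exactly ``pelvis_sex_amplitude`` more for men;
    * chest band: a breast/pectoral feature whose amplitude is drawn per
      patient (high variance, overlapping between sexes).

    Poisson-like noise (sigma = noise_scale * sqrt(SUV + 0.05)) is added when
    the scanner's ``noise_scale`` is positive; negative excursions clip to 0.
    """
    demo = spec.demographics
    sig = spec.signal_strengths
    rng = np.random.default_rng(spec.seed)

    zf, y, x = _grids(spec)
    mask = body_mask(spec)
    nz, ny, nx = mask.shape
    h = _habitus(demo.weight)
    L = spec.body_length_mm

    soft = sig["soft_tissue_suv"] + sig["age_slope"] * (demo.age - 60.0)
    soft = max(soft, 0.05)
    vol = np.where(mask, np.float64(soft), 0.0)

    z_mm = (np.arange(nz) + 0.5) / nz * L  # slice centres in mm from head top

    # brain: ellipsoid in the head band, assigned (not added)
    head = spec.region_layout["head"]
    head_len = (head[1] - head[0]) * L
    zc = (head[0] + 0.45 * (head[1] - head[0])) * L
    brain = (
        ((z_mm[:, None, None] - zc) / (0.38 * head_len)) ** 2
        + (y[None] / (70.0 * h)) ** 2
        + (x[None] / (62.0 * h)) ** 2
    ) <= 1.0
    brain &= mask
    vol[brain] = sig["brain_suv"]

    # pelvic sex feature -----------------------------------------------------
    pel = spec.region_layout["pelvis"]
    pz = _band_slice(zf, pel)
    band_body = mask & pz[:, None, None]
    n_band = int(band_body.sum())
    if n_band == 0:
        raise ConfigurationError("pelvic band contains no body voxels")
    rx, ry = _BAND_HALFWIDTHS["pelvis"]
    if demo.sex == "female":
        # broad uterine/adnexal ellipsoid mid-band
        zc = (pel[0] + 0.5 * (pel[1] - pel[0])) * L
        zlen = 0.38 * (pel[1] - pel[0]) * L
        feat = (
            ((z_mm[:, None, None] - zc) / zlen) ** 2
            + (y[None] / (0.55 * ry * h)) ** 2
            + (x[None] / (0.40 * rx * h)) ** 2
        ) <= 1.0
        target_mean = sig["pelvis_female_mean"]
    else:
        # broad gonadal/gluteal slab in the lower half of the band, inset
        # from the band boundary so the signal sits strictly inside it
        zsel = (zf >= pel[0] + 0.45 * (pel[1] - pel[0])) & (
            zf < pel[0] + 0.90 * (pel[1] - pel[0])
        )
        feat = (
            zsel[:, None, None]
            & (np.abs(x[None]) <= 0.55 * rx * h)
            & (np.abs(y[None]) <= 0.65 * ry * h)
        )
        target_mean = sig["pelvis_female_mean"] + sig["pelvis_sex_amplitude"]
    feat = feat & band_body
    n_feat = int(feat.sum())
    if n_feat == 0:
        raise ConfigurationError("pelvic sex feature is empty at this resolution")
    vol[feat] += target_mean * n_band / n_feat

    # chest sex feature: same anatomy, amplitude drawn per patient ------------
    chest = spec.region_layout["chest"]
    cz = _band_slice(zf, chest)
    crx, cry = _BAND_HALFWIDTHS["chest"]
    zc = (chest[0] + 0.55 * (chest[1] - chest[0])) * L
    zlen = 0.30 * (chest[1] - chest[0]) * L
    blob_l = (
        ((z_mm[:, None, None] - zc) / zlen) ** 2
        + ((y[None] - 0.45 * cry * h) / (0.40 * cry * h)) ** 2
        + ((x[None] + 0.40 * crx * h) / (0.30 * crx * h)) ** 2
    ) <= 1.0
    blob_r = (
        ((z_mm[:, None, None] - zc) / zlen) ** 2
        + ((y[None] - 0.45 * cry * h) / (0.40 * cry * h)) ** 2
        + ((x[None] - 0.40 * crx * h) / (0.30 * crx * h)) ** 2
    ) <= 1.0
    cfeat = (blob_l | blob_r) & mask & cz[:, None, None]
    mu, sd = (
        (sig["chest_female_mean"], sig["chest_female_sd"])
        if demo.sex == "female"
        else (sig["chest_male_mean"], sig["chest_male_sd"])
    )
    amp = max(float(rng.normal(mu, sd)), 0.0)
    if cfeat.any():
        vol[cfeat] += amp

    # noise --------------------------------------------------------------
    ns = spec.scanner.noise_scale
    if ns > 0:
        noise = rng.standard_normal(vol.shape) * (ns * np.sqrt(vol + 0.05))
        vol = np.maximum(vol + noise, 0.0)

    return Volume(
        intensities=vol.astype(np.float32),
        spacing=spec.scanner.voxel_size,
        patient_id="",
    )


def band_body_mean(volume: Volume, spec: PhantomSpec, region: str) -> float:
    """Mean SUV over body voxels within one anatomical band of a phantom."""
    zf, _, _ = _grids(spec)
    band = spec.region_layout[region]
    sel = body_mask(spec) & _band_slice(zf, band)[:, None, None]
    if not sel.any():
        raise EmptyInputError(f"no body voxels in band {region!r}")
    return float(volume.intensities[sel].mean())


def silhouette_max_width_mm(volume: Volume, suv_threshold: float = 0.2) -> float:
    """Widest left-right extent (mm) of the supra-threshold silhouette."""
    occ = volume.intensities > suv_threshold
    cols = occ.any(axis=1)  # (z, x)
    if not cols.any():
        return 0.0
    dx = volume.spacing[0]
    widths = []
    for row in cols:
        idx = np.flatnonzero(row)
        if idx.size:
            widths.append((idx[-1] - idx[0] + 1) * dx)
    return float(max(widths))


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------


def sample_demographics(
    ratio_male: float = DEFAULT_RATIO_MALE,
    age_mean_sd: tuple[float, float] = DEFAULT_AGE_MEAN_SD,
    weight_model: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> Demographics:
    """Draw one patient's demographics.

    Sex is Bernoulli(ratio_male); age is normal(mean, sd) clipped to the
    clinical range [2, 92] years; weight is a sex-conditional normal clipped
    to the model's range.
    """
    if not 0.0 <= ratio_male <= 1.0:
        raise ConfigurationError("ratio_male must lie in [0, 1]")
    wm = {**DEFAULT_WEIGHT_MODEL, **(weight_model or {})}
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sex = "male" if rng.random() < ratio_male else "female"
    age = float(np.clip(rng.normal(*age_mean_sd), *AGE_CLIP))
    mu, sd = wm[sex]
    weight = float(np.clip(rng.normal(mu, sd), *wm["clip"]))
    return Demographics(sex=sex, age=age, weight=weight)


def generate_cohort(
    n: int,
    scanner_mix: dict[str, float] | None = None,
    seed: int = 0,
    profiles: dict[str, ScannerProfile] | None = None,
    ratio_male: float = DEFAULT_RATIO_MALE,
    age_mean_sd: tuple[float, float] = DEFAULT_AGE_MEAN_SD,
    weight_model: dict | None = None,
    signal_strengths: dict[str, float] | None = None,
    noise: bool = True,
) -> list[CohortRecord]:
    """Generate ``n`` patients, one volume each, scanners drawn by ``scanner_mix``.

    Patient ids are unique; the whole cohort is a deterministic function of
    ``seed``.  Desk-scale scanner profiles are used unless ``profiles``
    overrides them.
    """
    if n < 1:
        raise EmptyInputError("cohort size must be >= 1")
    mix = scanner_mix or dict(DEFAULT_SCANNER_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-6:
        raise ConfigurationError("scanner_mix fractions must sum to 1")
    profs = profiles or {"scanner1": DESK_SCANNER_1, "scanner2": DESK_SCANNER_2}
    for name in mix:
        if name not in profs:
            raise ConfigurationError(f"no profile registered for scanner {name!r}")

    rng = np.random.default_rng(seed)
    names = sorted(mix)
    probs = np.array([mix[k] for k in names])
    assignments = rng.choice(len(names), size=n, p=probs)

    records: list[CohortRecord] = []
    for i in range(n):
        pid = f"P{i:05d}"
        child = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        demo = sample_demographics(ratio_male, age_mean_sd, weight_model, seed=child)
        prof = profs[names[assignments[i]]]
        if not noise:
            prof = replace(prof, noise_scale=0.0)
        pseed = int(np.random.SeedSequence([int(seed), i, 1]).generate_state(1)[0])
        spec = PhantomSpec(
            demographics=demo,
            scanner=prof,
            seed=pseed,
            signal_strengths=dict(signal_strengths or {}),
        )
        vol = generate_phantom(spec)
        vol.patient_id = pid
        records.append(CohortRecord(pid, demo, prof, vol))
    return records


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def save_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI; array transposed to (x, y, z), spacing in header."""
    dx, dy, dz = volume.spacing
    img = nib.Nifti1Image(
        volume.intensities.transpose(2, 1, 0), affine=np.diag([dx, dy, dz, 1.0])
    )
    nib.save(img, str(path))


def load_volume(path, patient_id: str = "") -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    return Volume(intensities=data, spacing=tuple(float(z) for z in zooms), patient_id=patient_id)


def save_cohort_metadata(records: list[CohortRecord], csv_path, json_path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "sex": [r.demographics.sex for r in records],
            "age": [r.demographics.age for r in records],
            "weight": [r.demographics.weight for r in records],
            "scanner": [r.scanner.name for r in records],
        }
    )
    df.to_csv(csv_path, index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=1)
    return df
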