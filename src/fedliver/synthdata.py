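"""Synthetic two-site ultrasound cohort generation.

Emulates a dual-center hepatic steatosis study: a large clinical-center-like
site and a smaller public-dataset-like site, each with a fixed patient count
per biopsy-proven steatosis grade (0-3), per-patient demographics, and ten
B-mode-like grayscale images per patient. The binary learning task is grade 0
(S0, no steatosis) versus grade 1 or higher (S1plus).

Images are synthesized as spatially correlated Rayleigh speckle with two
textbook sonographic signs of steatosis: echogenicity (mean brightness)
increasing with grade, and posterior (depth-dependent) attenuation whose rate
also grows with grade.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

PUBLIC = "public_like"
PRIVATE = "private_like"
SITES = (PUBLIC, PRIVATE)

S0 = "S0"
S1PLUS = "S1plus"
CLASSES = (S0, S1PLUS)

MANIFEST_COLUMNS = [
    "patient_id",
    "site",
    "grade",
    "binary_class",
    "sex",
    "age",
    "bmi",
    "image_path",
]


@dataclass(frozen=True)
class Demographics:
    """Site-level demographic summary used for sampling."""

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    male_fraction: float


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic two-site cohort.

    Defaults reproduce the dual-center study population: 153 clinical-center
    patients with grade counts (35, 51, 29, 38) and 55 public-like patients
    with grade counts (17, 20, 8, 10); demographics age 52±13 / BMI 30.8±8.0 /
    49% male (private-like) and age 40±9 / BMI 45.9±5.6 / 20% male
    (public-like).
    """

    per_site_grade_counts: dict[str, tuple[int, int, int, int]] = field(
        default_factory=lambda: {PRIVATE: (35, 51, 29, 38), PUBLIC: (17, 20, 8, 10)}
    )
    images_per_patient: int = 10
    image_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {PRIVATE: (960, 1280), PUBLIC: (434, 636)}
    )
    demographics: dict[str, Demographics] = field(
        default_factory=lambda: {
            PRIVATE: Demographics(52.0, 13.0, 30.8, 8.0, 0.49),
            PUBLIC: Demographics(40.0, 9.0, 45.9, 5.6, 0.20),
        }
    )
    base_echogenicity: float = 80.0
    echogenicity_slope: float = 15.0
    base_attenuation: float = 0.5
    attenuation_slope: float = 0.3
    speckle_scale: float = 3.0
    # acquisition gain per site: the two centers use different scanners and
    # presets, so overall image brightness differs by site independently of
    # steatosis grade (a domain shift the classifier must overcome)
    site_gain: dict[str, float] = field(
        default_factory=lambda: {PRIVATE: 1.0, PUBLIC: 1.2}
    )
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "CohortConfig":
        return cls(seed=seed)

    @classmethod
    def tiny(cls, seed: int = 0, size: int = 64, images_per_patient: int = 10) -> "CohortConfig":
        """Desk-scale profile: same patient structure, small square images."""
        return cls(
            image_sizes={PRIVATE: (size, size), PUBLIC: (size, size)},
            images_per_patient=images_per_patient,
            seed=seed,
        )

    def validate(self) -> None:
        if self.images_per_patient < 1:
            raise ValueError("images_per_patient must be >= 1")
        for site, counts in self.per_site_grade_counts.items():
            if len(counts) != 4:
                raise ValueError(f"per_site_grade_counts[{site!r}] must have 4 entries")
            for g, c in enumerate(counts):
                if int(c) != c or c <= 0:
                    raise ValueError(
                        f"per_site_grade_counts[{site!r}] grade {g}: counts must be "
                        f"strictly positive integers, got {c!r}"
                    )
        for site, (h, w) in self.image_sizes.items():
            if h <= 0 or w <= 0:
                raise ValueError(f"image_sizes[{site!r}] must be positive, got {(h, w)}")


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient; ``binary_class`` is S0 iff grade == 0."""

    patient_id: str
    site_of_origin: str
    grade: int
    binary_class: str
    sex: str
    age: float
    bmi: float

    @property
    def label(self) -> int:
        """Binary label: 1 for S1plus (any steatosis), 0 for S0."""
        return 0 if self.binary_class == S0 else 1


@dataclass(frozen=True)
class SplitResult:
    train_patients: list[PatientRecord]
    test_patients: list[PatientRecord]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float) -> float:
    # resampling beyond the truncation bound; bounds are several SDs from the
    # means so this terminates immediately in practice
    while True:
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the patient-level cohort (no images).

    Per-site per-grade counts are taken verbatim from the configuration
    (counts are never sampled). Age and BMI are truncated normal (age >= 18,
    BMI >= 15); sex is Bernoulli(male_fraction). Deterministic for a fixed
    config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    patients: list[PatientRecord] = []
    for site in sorted(config.per_site_grade_counts):
        demo = config.demographics[site]
        counts = config.per_site_grade_counts[site]
        k = 0
        for grade, count in enumerate(counts):
            for _ in range(count):
                pid = f"{site}_{k:04d}"
                k += 1
                patients.append(
                    PatientRecord(
                        patient_id=pid,
                        site_of_origin=site,
                        grade=grade,
                        binary_class=S0 if grade == 0 else S1PLUS,
                        sex="M" if rng.random() < demo.male_fraction else "F",
                        age=round(_truncated_normal(rng, demo.age_mean, demo.age_sd, 18.0), 1),
                        bmi=round(_truncated_normal(rng, demo.bmi_mean, demo.bmi_sd, 15.0), 1),
                    )
                )
    return patients


def _rayleigh_mean(speckle_scale: float) -> float:
    """Mean of |(gx, gy)| for unit white noise smoothed at ``speckle_scale``.

    The smoothed Gaussian fields have variance equal to the squared L2 norm
    of the 2-D smoothing kernel; the magnitude is Rayleigh with mean
    sigma * sqrt(pi / 2).
    """
    if speckle_scale <= 0:
        return float(np.sqrt(np.pi / 2))
    half = max(1, int(np.ceil(4 * speckle_scale)))
    impulse = np.zeros(2 * half + 1)
    impulse[half] = 1.0
    k = gaussian_filter(impulse, speckle_scale)
    sigma_f = float(np.sqrt((k**2).sum() ** 2))  # separable 2-D kernel
    return sigma_f * float(np.sqrt(np.pi / 2))


def render_image(
    grade: int,
    height: int,
    width: int,
    config: CohortConfig,
    seed: int,
    site: str | None = None,
) -> np.ndarray:
    """Render one grade-dependent B-mode-like image as uint8 (height, width).

    Model: base echogenicity ``base + slope * grade`` multiplied by a
    spatially correlated Rayleigh speckle field (two independent Gaussian
    fields smoothed at ``speckle_scale`` pixels, magnitude, normalized to unit
    mean) and by a depth-wise exponential attenuation with rate
    ``base_attenuation + attenuation_slope * grade`` over the full depth.
    Values are clipped to [0, 255]. Deterministic per seed.
    """
    if not 0 <= grade <= 3:
        raise ValueError(f"grade must be in 0..3, got {grade}")
    if height <= 0 or width <= 0:
        raise ValueError(f"image dimensions must be positive, got {(height, width)}")
    rng = np.random.default_rng(seed)
    gx = gaussian_filter(rng.standard_normal((height, width)), config.speckle_scale)
    gy = gaussian_filter(rng.standard_normal((height, width)), config.speckle_scale)
    speckle = np.hypot(gx, gy)
    # normalize by the theoretical Rayleigh mean of the smoothed field so the
    # per-image mean keeps its natural speckle fluctuation
    speckle /= _rayleigh_mean(config.speckle_scale)
    gain = config.site_gain.get(site, 1.0) if site is not None else 1.0
    level = gain * (config.base_echogenicity + config.echogenicity_slope * grade)
    rate = config.base_attenuation + config.attenuation_slope * grade
    depth = np.linspace(0.0, 1.0, height)[:, None]
    pixels = level * speckle * np.exp(-rate * depth)
    return np.clip(np.rint(pixels), 0, 255).astype(np.uint8)


def image_seed(config_seed: int, patient_id: str, acquisition_index: int) -> int:
    """Stable per-image seed derived from the cohort seed and patient id."""
    h = np.uint64(1469598103934665603)  # FNV-1a over the identifying tuple
    for b in f"{config_seed}|{patient_id}|{acquisition_index}".encode():
        h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % (1 << 31))


def render_patient_images(patient: PatientRecord, config: CohortConfig) -> list[np.ndarray]:
    """All images for one patient, deterministic given the config."""
    height, width = config.image_sizes[patient.site_of_origin]
    return [
        render_image(
            patient.grade,
            height,
            width,
            config,
            image_seed(config.seed, patient.patient_id, j),
            site=patient.site_of_origin,
        )
        for j in range(config.images_per_patient)
    ]


def make_test_split(
    cohort: list[PatientRecord], n_test_per_site: int = 10, seed: int = 0
) -> SplitResult:
    """Patient-level class-balanced test split.

    Per site, samples ``n_test_per_site/2`` S0 patients and the same number of
    S1plus patients uniformly without replacement; everyone else forms the
    training pool. The split is by patient, never by image.
    """
    if n_test_per_site % 2 != 0:
        raise ValueError("n_test_per_site must be even (half per binary class)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    sites = sorted({p.site_of_origin for p in cohort})
    test_ids: set[str] = set()
    for site in sites:
        for cls in CLASSES:
            members = [
                p for p in cohort if p.site_of_origin == site and p.binary_class == cls
            ]
            need = n_test_per_site // 2
            if len(members) < need:
                raise ValueError(
                    f"site {site!r} has only {len(members)} patients of class "
                    f"{cls!r}; {need} needed for the test split"
                )
            chosen = rng.choice(len(members), size=need, replace=False)
            test_ids.update(members[i].patient_id for i in chosen)
    test = [p for p in cohort if p.patient_id in test_ids]
    train = [p for p in cohort if p.patient_id not in test_ids]
    return SplitResult(train_patients=train, test_patients=test)


def write_dataset(
    cohort: list[PatientRecord],
    images: dict[str, list[np.ndarray]],
    directory: str,
) -> str:
    """Write images as 8-bit grayscale PNGs plus a CSV manifest.

    ``images`` maps patient_id to that patient's image list. Returns the
    manifest path. File naming: ``<patient_id>_<acquisition_index>.png``.
    """
    os.makedirs(directory, exist_ok=True)
    rows = []
    for patient in cohort:
        for j, pixels in enumerate(images[patient.patient_id]):
            fname = f"{patient.patient_id}_{j}.png"
            Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="L").save(
                os.path.join(directory, fname)
            )
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "site": patient.site_of_origin,
                    "grade": patient.grade,
                    "binary_class": patient.binary_class,
                    "sex": patient.sex,
                    "age": patient.age,
                    "bmi": patient.bmi,
                    "image_path": fname,
                }
            )
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_dataset(directory: str) -> tuple[list[PatientRecord], dict[str, list[np.ndarray]]]:
    """Inverse of :func:`write_dataset`; errors listing any missing files."""
    manifest = os.path.join(directory, "manifest.csv")
    df = pd.read_csv(manifest)
    missing = [
        p for p in df["image_path"] if not os.path.exists(os.path.join(directory, p))
    ]
    if missing:
        raise FileNotFoundError(f"manifest references missing image files: {missing}")
    cohort = []
    images: dict[str, list[np.ndarray]] = {}
    for pid, group in df.groupby("patient_id", sort=False):
        first = group.iloc[0]
        cohort.append(
            PatientRecord(
                patient_id=str(pid),
                site_of_origin=str(first["site"]),
                grade=int(first["grade"]),
                binary_class=str(first["binary_class"]),
                sex=str(first["sex"]),
                age=float(first["age"]),
                bmi=float(first["bmi"]),
            )
        )
        images[str(pid)] = [
            np.asarray(Image.open(os.path.join(directory, p)), dtype=np.uint8)
            for p in group["image_path"]
        ]
    return cohort, images
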