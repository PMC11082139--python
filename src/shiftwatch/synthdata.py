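"""Synthetic fundus-like image generator with controllable subgroup structure.

The generator emulates the population structure of a large multi-hospital
diabetic-retinopathy screening dataset: each image carries categorical
patient/image attributes (sex, ethnicity, image quality, a co-morbidity flag
and a 5-level DR grade), drawn from configurable marginal prevalences, and
the rendered appearance of the image is a deterministic-plus-noise function
of those attributes.  An extra "insufficient" quality level exists only in a
separate out-of-distribution (OOD) pool and is never sampled into the source
distribution.

Rendered images are stylised, not photorealistic: a circular bright fundus
field on a dark background, with lesion-like spots whose number and contrast
grow with DR grade, blur and noise growing as image quality drops, a diffuse
haze patch for co-morbidities, a global pigmentation offset per ethnicity and
a low-amplitude texture perturbation for patient sex.  The attribute-to-pixel
mappings for sex and ethnicity are stand-ins chosen for their statistical
detectability profile, not claims about retinal physiology.

Pixels are quantised to the 8-bit grid at render time so that the PNG + CSV
on-disk representation round-trips bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SEX_LEVELS",
    "ETHNICITY_LEVELS",
    "QUALITY_LEVELS",
    "DR_GRADES",
    "AttributeRecord",
    "GeneratorSpec",
    "LesionModel",
    "ImageSample",
    "LabeledDataset",
    "default_marginals",
    "sample_attributes",
    "render_image",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

SEX_LEVELS = ("female", "male", "other")
ETHNICITY_LEVELS = (
    "african",
    "asian",
    "white",
    "indian",
    "latin_american",
    "multiracial",
    "native_american",
)
# Ordered worst-to-best; "insufficient" belongs to the OOD pool only.
QUALITY_LEVELS = ("insufficient", "adequate", "good", "excellent")
DR_GRADES = (0, 1, 2, 3, 4)


def default_marginals() -> dict[str, dict]:
    """Default attribute prevalences, mirroring a large DR screening cohort.

    Sex is roughly 60/40 female/male with a sliver of "other"; image quality
    splits 18/41/40 excellent/good/adequate (no insufficient images in the
    source distribution); 10% of patients carry co-morbidities; DR grades
    are heavily imbalanced with 79% healthy.  Each table is normalised to
    sum to one.
    """
    raw = {
        "sex": {"female": 0.60, "male": 0.397, "other": 0.003},
        "ethnicity": {
            "african": 0.08,
            "asian": 0.06,
            "white": 0.11,
            "indian": 0.05,
            "latin_american": 0.69,
            "multiracial": 0.01,
            "native_american": 0.01,
        },
        "quality": {
            "insufficient": 0.0,
            "adequate": 0.40,
            "good": 0.41,
            "excellent": 0.18,
        },
        "comorbidity": {False: 0.90, True: 0.10},
        "dr_grade": {0: 0.79, 1: 0.07, 2: 0.13, 3: 0.01, 4: 0.01},
    }
    out = {}
    for attr, table in raw.items():
        total = sum(table.values())
        out[attr] = {k: v / total for k, v in table.items()}
    return out


# Pigmentation offset per ethnicity, in [-1, 1]; scaled by the ethnicity
# effect amplitude.  Chosen to spread the categories over a brightness axis.
_ETHNICITY_PIGMENT = {
    "african": -0.9,
    "asian": 0.15,
    "white": 0.85,
    "indian": -0.35,
    "latin_american": 0.0,
    "multiracial": 0.35,
    "native_american": -0.6,
}

# Sinusoidal texture phase per sex (the amplitude knob lives in
# effect_amplitudes["sex"] and defaults near the detection threshold).
_SEX_PHASE = {"female": 0.0, "male": np.pi / 2.0, "other": np.pi}

# Gaussian blur width in pixels at the 64-px reference size, per quality
# level; widths scale linearly with image size.  "insufficient" is strictly
# blurrier than any in-distribution level and additionally occluded.
QUALITY_BLUR_SIGMA = {
    "excellent": 0.0,
    "good": 0.5,
    "adequate": 1.1,
    "insufficient": 3.0,
}
QUALITY_EXTRA_NOISE = {
    "excellent": 0.0,
    "good": 0.01,
    "adequate": 0.025,
    "insufficient": 0.06,
}


@dataclass(frozen=True)
class AttributeRecord:
    """Patient/image attributes attached to one image.

    ``dr_grade`` may be ``None`` only for insufficient-quality (OOD) images,
    which were never gradable.
    """

    patient_id: str
    sex: str
    ethnicity: str
    quality: str
    comorbidity: bool
    dr_grade: int | None

    def __post_init__(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.ethnicity not in ETHNICITY_LEVELS:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if self.quality not in QUALITY_LEVELS:
            raise ValueError(f"unknown quality {self.quality!r}")
        if self.dr_grade is None:
            if self.quality != "insufficient":
                raise ValueError(
                    "dr_grade may be absent only for insufficient-quality images"
                )
        elif self.dr_grade not in DR_GRADES:
            raise ValueError(f"dr_grade must be in 0..4, got {self.dr_grade}")


@dataclass(frozen=True)
class LesionModel:
    """Maps DR grade to lesion-like spot count, size and contrast."""

    spots_per_grade: int = 5
    radius_frac: float = 0.06
    contrast: float = 0.55

    def n_spots(self, grade: int) -> int:
        return self.spots_per_grade * grade


@dataclass(frozen=True)
class GeneratorSpec:
    """Full configuration of the synthetic image distribution."""

    image_size: int = 64
    marginals: dict = field(default_factory=default_marginals)
    effect_amplitudes: dict = field(
        default_factory=lambda: {
            "sex": 0.005,
            "ethnicity": 0.10,
            "comorbidity": 0.18,
            "dr_grade": 1.0,
            "quality": 1.0,
        }
    )
    lesion_model: LesionModel = LesionModel()
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        for attr, table in self.marginals.items():
            probs = np.array(list(table.values()), dtype=float)
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-8):
                raise ValueError(
                    f"marginals for attribute {attr!r} must be nonnegative and sum to 1"
                )
        for attr, amp in self.effect_amplitudes.items():
            if amp < 0:
                raise ValueError(f"effect amplitude for {attr!r} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def with_amplitudes(self, **amps: float) -> "GeneratorSpec":
        merged = {**self.effect_amplitudes, **amps}
        return replace(self, effect_amplitudes=merged)


@dataclass(frozen=True)
class ImageSample:
    """One rendered image plus its attribute record."""

    pixels: np.ndarray  # (size, size, 3), float32 in [0, 1]
    attrs: AttributeRecord


@dataclass
class LabeledDataset:
    """An ordered image collection with its attribute sheet.

    ``images`` has shape (n, size, size, 3); ``attrs`` is a DataFrame with
    columns image_id, patient_id, sex, ethnicity, quality, comorbidity,
    dr_grade (nullable integer) and fold.
    """

    images: np.ndarray
    attrs: pd.DataFrame
    fold: str

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_ids(self) -> np.ndarray:
        return self.attrs["image_id"].to_numpy()

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            images=self.images[idx],
            attrs=self.attrs.iloc[idx].reset_index(drop=True),
            fold=self.fold,
        )


def sample_attributes(
    spec: GeneratorSpec, n: int, seed: int
) -> list[AttributeRecord]:
    """Draw ``n`` attribute records i.i.d. from the configured marginals.

    Attributes are sampled independently of each other.  Reproducible: the
    same (spec, n, seed) yields the identical record sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {}
    for attr in ("sex", "ethnicity", "quality", "comorbidity", "dr_grade"):
        if attr not in spec.marginals:
            raise ValueError(f"marginals missing attribute {attr!r}")
        table = spec.marginals[attr]
        values = list(table.keys())
        probs = np.array([table[v] for v in values], dtype=float)
        idx = rng.choice(len(values), size=n, p=probs)
        draws[attr] = [values[i] for i in idx]
    records = []
    for i in range(n):
        quality = draws["quality"][i]
        grade = None if quality == "insufficient" else int(draws["dr_grade"][i])
        records.append(
            AttributeRecord(
                patient_id=str(i),
                sex=draws["sex"][i],
                ethnicity=draws["ethnicity"][i],
                quality=quality,
                comorbidity=bool(draws["comorbidity"][i]),
                dr_grade=grade,
            )
        )
    return records


def _coordinate_grids(size: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = np.linspace(-1.0, 1.0, size, dtype=np.float32)
    xx, yy = np.meshgrid(ax, ax)
    rr = np.sqrt(xx**2 + yy**2)
    return xx, yy, rr


def render_image(
    attrs: AttributeRecord, spec: GeneratorSpec, seed: int
) -> ImageSample:
    """Render one image deterministically from (attrs, spec, seed).

    The composition order is: base fundus disc, ethnicity pigmentation, sex
    texture, co-morbidity haze, grade-dependent lesions, quality blur,
    additive noise, occlusion for insufficient quality, clipping to [0, 1]
    and 8-bit quantisation.
    """
    s = spec.image_size
    amps = spec.effect_amplitudes
    rng = np.random.default_rng(seed)
    xx, yy, rr = _coordinate_grids(s)
    disc = (rr <= 0.92).astype(np.float32)
    profile = disc * (1.0 - 0.35 * rr**2)

    base = np.array([0.62, 0.40, 0.20], dtype=np.float32)
    img = profile[:, :, None] * base[None, None, :]
    img += 0.04  # faint background level

    # Ethnicity: global pigmentation shift over the disc.
    pig = _ETHNICITY_PIGMENT[attrs.ethnicity] * amps.get("ethnicity", 0.0)
    img += (pig * profile)[:, :, None] * np.array(
        [0.6, 0.35, 0.15], dtype=np.float32
    )

    # Sex: low-amplitude sinusoidal texture on the green channel.
    sex_amp = amps.get("sex", 0.0)
    if sex_amp > 0:
        grating = np.sin(2.0 * np.pi * 3.0 * xx + _SEX_PHASE[attrs.sex])
        img[:, :, 1] += sex_amp * grating * disc

    # Co-morbidity: a diffuse haze patch, off-centre.
    if attrs.comorbidity:
        haze = np.exp(-(((xx - 0.30) ** 2 + (yy + 0.25) ** 2) / (2 * 0.30**2)))
        img += (amps.get("comorbidity", 0.0) * haze * disc)[:, :, None]

    # DR grade: lesion-like dark-red spots, count and contrast grow with grade.
    grade = attrs.dr_grade if attrs.dr_grade is not None else 0
    lesions = spec.lesion_model
    n_spots = lesions.n_spots(grade)
    if n_spots > 0 and amps.get("dr_grade", 0.0) > 0:
        radius = max(lesions.radius_frac, 1.5 / s)
        contrast = (
            amps["dr_grade"] * lesions.contrast * (0.55 + 0.15 * grade)
        )
        for _ in range(n_spots):
            theta = rng.uniform(0, 2 * np.pi)
            rad = 0.75 * np.sqrt(rng.uniform())
            cx, cy = rad * np.cos(theta), rad * np.sin(theta)
            blob = np.exp(
                -(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * radius**2))
            ).astype(np.float32)
            img[:, :, 1] -= contrast * blob
            img[:, :, 2] -= 0.6 * contrast * blob
            img[:, :, 0] += 0.15 * contrast * blob

    # Quality: blur scaled to image size, plus extra noise.
    q_amp = amps.get("quality", 0.0)
    sigma = QUALITY_BLUR_SIGMA[attrs.quality] * q_amp * (s / 64.0)
    if sigma > 0:
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))

    total_noise = spec.noise_sd + QUALITY_EXTRA_NOISE[attrs.quality] * q_amp
    if total_noise > 0:
        img += rng.normal(0.0, total_noise, size=img.shape).astype(np.float32)

    # Insufficient quality: heavy occlusion beyond any in-distribution level.
    if attrs.quality == "insufficient":
        occl = np.exp(
            -(((xx + 0.55) ** 2 + (yy - 0.55) ** 2) / (2 * 0.45**2))
        ).astype(np.float32)
        img *= 1.0 - 0.8 * q_amp * np.minimum(occl, 1.0)[:, :, None]

    img = np.clip(img, 0.0, 1.0)
    if np.all((img <= 0.0) | (img >= 1.0)):
        warnings.warn(
            "rendered image is fully saturated; consider lowering effect amplitudes",
            stacklevel=2,
        )
    # Quantise to the 8-bit grid so PNG round-trips are lossless.
    img = (np.round(img * 255.0) / 255.0).astype(np.float32)
    return ImageSample(pixels=img, attrs=attrs)


def generate_dataset(
    spec: GeneratorSpec, n: int, fold: str = "train", seed: int | None = None
) -> LabeledDataset:
    """Generate ``n`` samples for one fold.

    ``fold='ood'`` forces every record to insufficient quality with an absent
    DR grade, modelling an ungradable image pool outside the source support.
    All other folds draw quality from the source marginals (which exclude
    "insufficient").
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fold not in ("train", "val", "test", "ood"):
        raise ValueError(f"unknown fold {fold!r}")
    master = spec.seed if seed is None else seed
    ss = np.random.SeedSequence([master, _fold_tag(fold)])
    attr_seed, render_seed = ss.spawn(2)
    records = sample_attributes(spec, n, seed=attr_seed.generate_state(1)[0])
    if fold == "ood":
        records = [
            replace(r, quality="insufficient", dr_grade=None) for r in records
        ]
    image_seeds = render_seed.spawn(n)
    images = np.empty((n, spec.image_size, spec.image_size, 3), dtype=np.float32)
    rows = []
    for i, (rec, child) in enumerate(zip(records, image_seeds)):
        sample = render_image(rec, spec, seed=child.generate_state(1)[0])
        images[i] = sample.pixels
        rows.append(
            {
                "image_id": f"{fold}_{i:06d}",
                "patient_id": rec.patient_id,
                "sex": rec.sex,
                "ethnicity": rec.ethnicity,
                "quality": rec.quality,
                "comorbidity": rec.comorbidity,
                "dr_grade": rec.dr_grade,
                "fold": fold,
            }
        )
    attrs = pd.DataFrame(rows)
    attrs["dr_grade"] = attrs["dr_grade"].astype("Int64")
    return LabeledDataset(images=images, attrs=attrs, fold=fold)


def _fold_tag(fold: str) -> int:
    return {"train": 0, "val": 1, "test": 2, "ood": 3}[fold]


CSV_COLUMNS = [
    "image_id",
    "patient_id",
    "sex",
    "ethnicity",
    "quality",
    "comorbidity",
    "dr_grade",
    "fold",
]


def save_dataset(dataset: LabeledDataset, out_dir: str | Path) -> Path:
    """Write a dataset as PNG files plus ``attributes.csv``.

    dr_grade is written as an empty string when absent.  The pixel arrays
    are 8-bit-quantised at render time, so saving and re-loading round-trips
    bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for pixels, image_id in zip(dataset.images, dataset.attrs["image_id"]):
        arr = np.round(pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="RGB").save(out / f"{image_id}.png")
    dataset.attrs[CSV_COLUMNS].to_csv(out / "attributes.csv", index=False)
    return out


def load_dataset(in_dir: str | Path) -> LabeledDataset:
    """Read back a dataset written by :func:`save_dataset` (or hand-made)."""
    in_dir = Path(in_dir)
    attrs = pd.read_csv(
        in_dir / "attributes.csv",
        dtype={"image_id": str, "patient_id": str},
    )
    attrs["dr_grade"] = attrs["dr_grade"].astype("Int64")
    attrs["comorbidity"] = attrs["comorbidity"].astype(bool)
    images = []
    for image_id in attrs["image_id"]:
        arr = np.asarray(Image.open(in_dir / f"{image_id}.png"), dtype=np.float64)
        images.append((arr / 255.0).astype(np.float32))
    fold = str(attrs["fold"].iloc[0]) if len(attrs) else "train"
    return LabeledDataset(images=np.stack(images), attrs=attrs, fold=fold)
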