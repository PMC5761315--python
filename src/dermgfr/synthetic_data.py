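"""Stage-conditioned synthetic cohorts and skin-texture images.

No public cohort of forearm skin photographs with CKD labels exists, so the
pipeline is exercised on synthetic data built to mirror the study
conditions: 75 subjects (11 normal, 16 per CKD level 2–5), ages truncated
normal with mean 43.46 and SD 17.86 on [14, 75], and wrinkle texture whose
line density and depth increase with CKD level so that the per-level mean
of the texture random variables declines with stage.

Serum creatinine is synthesized by inverting the MDRD male form at a GFR
drawn uniformly inside the subject's stage band, which guarantees that
re-staging the MDRD estimate recovers the assigned level exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm
from skimage.draw import line_aa

from .imaging import SkinImage, ValidationError, save_image
from .texture import TextureFeatures, image_features
from . import imaging, sp_gfr

__all__ = [
    "SubjectRecord",
    "CohortConfig",
    "TextureConfig",
    "generate_cohort",
    "generate_skin_image",
    "attach_texture_features",
    "generate_labelled_cohort",
    "split_train_test",
    "cohort_frame",
    "write_cohort",
]

#: GFR sampling band per assigned CKD level, ml/min/1.73 m². Levels 2–5 use
#: the staging bands; level 1 is capped at 130 and level 5 floored at 2.
GFR_BANDS: dict[int, tuple[float, float]] = {
    1: (90.0, 130.0),
    2: (60.0, 90.0),
    3: (30.0, 60.0),
    4: (15.0, 30.0),
    5: (2.0, 15.0),
}


@dataclasses.dataclass
class SubjectRecord:
    """One subject: demographics, creatinine, stage label, and (once the
    imaging pipeline has run) texture features, Sp and mean-of-features."""

    subject_id: str
    age: float
    gender: int          # 1 = male, 2 = female
    height_cm: float
    weight_kg: float
    scr_mg_dl: float
    level: int
    features: TextureFeatures | None = None
    sp: float | None = None
    mean_features: float | None = None
    image_path: str | None = None


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Cohort composition: counts per group and the age distribution."""

    n_level1: int = 11
    n_per_ckd_level: int = 16
    age_mean: float = 43.46
    age_sd: float = 17.86
    age_range: tuple[float, float] = (14.0, 75.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_level1 < 1 or self.n_per_ckd_level < 1:
            raise ValidationError("group counts must be >= 1")
        lo, hi = self.age_range
        if not (0 < lo < hi < 120):
            raise ValidationError(f"age_range {self.age_range} must lie within (0, 120)")
        if self.age_sd <= 0:
            raise ValidationError("age_sd must be positive")

    @property
    def n_total(self) -> int:
        return self.n_level1 + 4 * self.n_per_ckd_level


@dataclasses.dataclass(frozen=True)
class TextureConfig:
    """Synthetic wrinkle-texture parameters.

    Expected line counts and line depths must strictly increase with level —
    CKD skin shows denser, more intense wrinkle lines than normal skin.
    """

    image_size: tuple[int, int] = (256, 256)
    base_noise_sd: float = 0.005
    lines_per_level: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {1: 24, 2: 56, 3: 96, 4: 144, 5: 200}
    )
    line_depth_per_level: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: {1: 0.22, 2: 0.30, 3: 0.38, 4: 0.46, 5: 0.54}
    )
    min_lines: int = 2
    background_mean: float = 0.7
    background_amplitude: float = 0.12
    background_scale_px: float = 16.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for mapping, name in (
            (self.lines_per_level, "lines_per_level"),
            (self.line_depth_per_level, "line_depth_per_level"),
        ):
            vals = [mapping[lv] for lv in range(1, 6)]
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValidationError(f"{name} must strictly increase with level")


def generate_cohort(cfg: CohortConfig = CohortConfig()) -> list[SubjectRecord]:
    """Draw a stage-labelled cohort with MDRD-consistent creatinine.

    For each subject a target GFR is drawn uniformly inside the stage band
    and creatinine obtained from Scr = (175 × age^−0.203 / GFR)^(1/1.154),
    so the MDRD (male, non-black) estimate re-stages to the assigned level.
    """
    rng = np.random.default_rng(cfg.seed)
    levels = [1] * cfg.n_level1 + [lv for lv in (2, 3, 4, 5) for _ in range(cfg.n_per_ckd_level)]
    lo, hi = cfg.age_range
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    ages = truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                         size=len(levels), random_state=rng)
    records = []
    for i, (level, age) in enumerate(zip(levels, ages)):
        gender = 1 if rng.random() < 0.5 else 2
        if gender == 1:
            height = rng.normal(170.0, 7.0)
            weight = rng.normal(70.0, 10.0)
        else:
            height = rng.normal(158.0, 6.0)
            weight = rng.normal(60.0, 9.0)
        g_lo, g_hi = GFR_BANDS[level]
        gfr = rng.uniform(g_lo, g_hi)
        scr = (175.0 * age**-0.203 / gfr) ** (1.0 / 1.154)
        records.append(
            SubjectRecord(
                subject_id=f"S{i:03d}",
                age=float(age),
                gender=gender,
                height_cm=float(np.clip(height, 140.0, 200.0)),
                weight_kg=float(np.clip(weight, 35.0, 130.0)),
                scr_mg_dl=float(scr),
                level=level,
            )
        )
    return records


def generate_skin_image(
    level: int,
    cfg: TextureConfig = TextureConfig(),
    seed: int | np.random.Generator = 0,
) -> SkinImage:
    """Render one synthetic forearm patch for a CKD level.

    A smooth low-frequency background stands in for illumination and skin
    tone; dark anti-aliased straight segments stand in for wrinkle lines,
    with Poisson-distributed count (floored at ``min_lines`` — even normal
    skin shows some line structure) and level-dependent depth; fine pixel
    noise models sensor grain, and a final Gaussian blur models the optical
    point-spread function. Intensities are clipped to [0, 1].
    """
    if level not in range(1, 6):
        raise ValidationError(f"level must be in 1..5, got {level}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = cfg.image_size
    field = gaussian_filter(rng.standard_normal((h, w)), cfg.background_scale_px)
    sd = field.std()
    if sd > 0:
        field = field / sd * cfg.background_amplitude
    img = cfg.background_mean + field

    n_lines = max(cfg.min_lines, rng.poisson(cfg.lines_per_level[level]))
    depth = cfg.line_depth_per_level[level]
    for _ in range(n_lines):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.25, 0.6) * min(h, w)
        r1 = int(np.clip(r0 + length * np.sin(angle), 0, h - 1))
        c1 = int(np.clip(c0 + length * np.cos(angle), 0, w - 1))
        rr, cc, val = line_aa(int(r0), int(c0), r1, c1)
        img[rr, cc] -= depth * val * rng.uniform(0.85, 1.0)

    img += rng.normal(0.0, cfg.base_noise_sd, size=(h, w))
    if cfg.blur_sigma > 0:
        img = gaussian_filter(img, cfg.blur_sigma)
    return SkinImage(np.clip(img, 0.0, 1.0))


def attach_texture_features(
    records: Sequence[SubjectRecord],
    cfg: TextureConfig = TextureConfig(),
    glcm_levels: int = 8,
    texture_source: str = "magnitude",
    selem_radius: int = 3,
) -> list[SubjectRecord]:
    """Run each record through the imaging pipeline on a freshly generated
    stage-conditioned image, filling features, Sp and mean-of-features.

    Per-record randomness is spawned from ``cfg.seed`` so the whole labelled
    cohort is a deterministic function of (config, seed).
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(len(records))
    out = []
    for rec, ss in zip(records, streams):
        img = generate_skin_image(rec.level, cfg, seed=np.random.default_rng(ss))
        proc = imaging.enhance(img, selem_radius=selem_radius)
        tex_img = imaging.gradient_texture_image(proc, source=texture_source)
        feats = image_features(tex_img, levels=glcm_levels)
        rec = dataclasses.replace(
            rec,
            features=feats,
            sp=sp_gfr.sp_from_features(feats, rec.age),
            mean_features=float(
                np.mean([feats.contrast, feats.correlation, feats.energy, feats.homogeneity])
            ),
        )
        out.append(rec)
    return out


def generate_labelled_cohort(
    cohort_cfg: CohortConfig = CohortConfig(),
    texture_cfg: TextureConfig | None = None,
) -> list[SubjectRecord]:
    """Complete synthetic cohort: demographics, creatinine, and texture
    features from stage-conditioned images (texture seed defaults to the
    cohort seed)."""
    if texture_cfg is None:
        texture_cfg = TextureConfig(seed=cohort_cfg.seed)
    return attach_texture_features(generate_cohort(cohort_cfg), texture_cfg)


def split_train_test(
    records: Sequence[SubjectRecord],
    n_train: int = 45,
    n_test: int = 30,
    n_normal_in_test: int = 5,
    seed: int = 0,
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Disjoint exhaustive train/test split with a fixed number of normal
    (level-1) subjects in the test partition."""
    if n_train + n_test != len(records):
        raise ValidationError(
            f"n_train + n_test = {n_train + n_test} != cohort size {len(records)}"
        )
    normals = [r for r in records if r.level == 1]
    ckd = [r for r in records if r.level != 1]
    if len(normals) < n_normal_in_test:
        raise ValidationError(
            f"only {len(normals)} level-1 records, need {n_normal_in_test} in test"
        )
    n_ckd_in_test = n_test - n_normal_in_test
    if len(ckd) < n_ckd_in_test:
        raise ValidationError("not enough CKD records for the requested test size")
    rng = np.random.default_rng(seed)
    normals = [normals[i] for i in rng.permutation(len(normals))]
    ckd = [ckd[i] for i in rng.permutation(len(ckd))]
    test = normals[:n_normal_in_test] + ckd[:n_ckd_in_test]
    train = normals[n_normal_in_test:] + ckd[n_ckd_in_test:]
    return train, test


def cohort_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Records as the cohort table (one row per subject)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age": r.age,
            "gender": r.gender,
            "height_cm": r.height_cm,
            "weight_kg": r.weight_kg,
            "scr_mg_dl": r.scr_mg_dl,
            "level": r.level,
            "image_path": r.image_path,
            "sp": r.sp,
            "mean_features": r.mean_features,
        }
        if r.features is not None:
            row.update(
                contrast=r.features.contrast,
                correlation=r.features.correlation,
                energy=r.features.energy,
                homogeneity=r.features.homogeneity,
                entropy=r.features.entropy,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    records: Sequence[SubjectRecord],
    out_dir: str | Path,
    cohort_cfg: CohortConfig,
    texture_cfg: TextureConfig,
    write_images: bool = True,
) -> Path:
    """Write cohort.csv, one PNG per subject, and a manifest recording the
    generating configuration; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = list(records)
    if write_images:
        streams = np.random.SeedSequence(texture_cfg.seed).spawn(len(records))
        for i, (rec, ss) in enumerate(zip(records, streams)):
            img = generate_skin_image(rec.level, texture_cfg, seed=np.random.default_rng(ss))
            png = out_dir / f"{rec.subject_id}.png"
            save_image(img, png)
            records[i] = dataclasses.replace(rec, image_path=png.name)
    csv_path = out_dir / "cohort.csv"
    cohort_frame(records).to_csv(csv_path, index=False)
    manifest = {
        "cohort_config": dataclasses.asdict(cohort_cfg),
        "texture_config": {
            k: (list(v) if isinstance(v, tuple) else dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(texture_cfg).items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return csv_path
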