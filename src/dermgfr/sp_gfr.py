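"""Skin parameter Sp, estimated GFR equations, and CKD staging.

The standard creatinine-based eGFR equations (MDRD, CKD-EPI) carry a
two-valued race multiplier. For populations that fit neither category, a
continuous per-subject value is derived instead from forearm skin texture:
the four texture random variables act as the constants of a four-parameter
logistic curve evaluated at the subject's age,

    Sp(x; a, b, c, d) = d + (a − d) / (1 + (x/c)^b)

with a = contrast (minimum asymptote), b = energy (hill slope),
c = correlation (inflection point), d = homogeneity (maximum asymptote)
and x = age in years. Sp then replaces the race factor in the MDRD form:

    GFR = 175 × Scr^−1.154 × age^−0.203 × Sp        [ml/min/1.73 m²]

Staging follows the usual GFR bands: ≥90 level 1, 60–89 level 2, 30–59
level 3, 15–29 level 4, <15 level 5.
"""

from __future__ import annotations

import dataclasses
import warnings

from .imaging import ValidationError
from .texture import TextureFeatures

__all__ = [
    "FourPMInputs",
    "GFRInputs",
    "GFRResult",
    "compute_sp",
    "sp_from_features",
    "mdrd_gfr",
    "ckd_epi_gfr",
    "proposed_gfr",
    "stage",
]

#: lower clamp for the inflection point c — the logistic form needs c > 0
#: but image correlation can be ≤ 0 on degenerate textures.
C_CLAMP_MIN = 1e-3
C_CLAMP_MAX = 1.0

_STUDY_AGE_RANGE = (14.0, 120.0)


@dataclasses.dataclass(frozen=True)
class FourPMInputs:
    """Arguments of the four-parameter model.

    a: minimum asymptote (contrast), d: maximum asymptote (homogeneity),
    b: hill slope (energy), c: inflection point (correlation, clamped
    positive), x: age in years.
    """

    a: float
    b: float
    c: float
    d: float
    x: float

    def __post_init__(self) -> None:
        if not self.x > 0:
            raise ValidationError(f"age x must be positive, got {self.x}")
        if not self.b > 0:
            raise ValidationError(f"hill slope b (energy) must be positive, got {self.b}")
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.d <= 1.0):
            raise ValidationError("asymptotes a (contrast) and d (homogeneity) must lie in [0, 1]")
        if self.c <= 0 or self.c > C_CLAMP_MAX:
            clamped = min(max(self.c, C_CLAMP_MIN), C_CLAMP_MAX)
            warnings.warn(
                f"inflection point c (correlation) = {self.c} outside "
                f"({0}, {C_CLAMP_MAX}]; clamped to {clamped}",
                stacklevel=3,
            )
            object.__setattr__(self, "c", clamped)


@dataclasses.dataclass(frozen=True)
class GFRInputs:
    """Demographic/biochemical arguments shared by the eGFR equations."""

    scr: float                 # serum creatinine, mg/dl
    age: float                 # years
    female: bool = False
    black: bool = False
    sp: float | None = None    # skin parameter, for the texture-based equation

    def __post_init__(self) -> None:
        if not self.scr > 0:
            raise ValidationError(f"serum creatinine must be positive, got {self.scr}")
        if not self.age > 0:
            raise ValidationError(f"age must be positive, got {self.age}")
        if not _STUDY_AGE_RANGE[0] <= self.age <= _STUDY_AGE_RANGE[1]:
            warnings.warn(
                f"age {self.age} outside the studied range "
                f"[{_STUDY_AGE_RANGE[0]}, {_STUDY_AGE_RANGE[1]}]",
                stacklevel=3,
            )

    @property
    def k(self) -> float:
        """CKD-EPI creatinine threshold: 0.7 (female) / 0.9 (male)."""
        return 0.7 if self.female else 0.9

    @property
    def alpha(self) -> float:
        """CKD-EPI low-creatinine exponent: −0.329 (female) / −0.411 (male)."""
        return -0.329 if self.female else -0.411


@dataclasses.dataclass(frozen=True)
class GFRResult:
    value: float   # ml/min/1.73 m²
    method: str    # "MDRD" | "CKD-EPI" | "proposed"
    level: int     # CKD stage 1–5


def compute_sp(inputs: FourPMInputs) -> float:
    """Evaluate the four-parameter model at the subject's age.

    The result is bounded between the two asymptotes:
    min(a, d) ≤ Sp ≤ max(a, d).
    """
    a, b, c, d, x = inputs.a, inputs.b, inputs.c, inputs.d, inputs.x
    return d + (a - d) / (1.0 + (x / c) ** b)


def sp_from_features(features: TextureFeatures, age: float) -> float:
    """Map an image's texture features and the subject's age to Sp."""
    inputs = FourPMInputs(
        a=features.contrast,
        b=features.energy,
        c=features.correlation,
        d=features.homogeneity,
        x=age,
    )
    return compute_sp(inputs)


def mdrd_gfr(g: GFRInputs) -> GFRResult:
    """MDRD estimate: 175 × Scr^−1.154 × age^−0.203, × 0.742 if female,
    × 1.212 if black."""
    value = 175.0 * g.scr**-1.154 * g.age**-0.203
    if g.female:
        value *= 0.742
    if g.black:
        value *= 1.212
    return GFRResult(value=value, method="MDRD", level=stage(value))


def ckd_epi_gfr(g: GFRInputs) -> GFRResult:
    """CKD-EPI estimate: 141 × min(Scr/k, 1)^α × max(Scr/k, 1)^−1.209 ×
    0.993^age, × 1.018 if female, × 1.159 if black."""
    r = g.scr / g.k
    value = 141.0 * min(r, 1.0) ** g.alpha * max(r, 1.0) ** -1.209 * 0.993**g.age
    if g.female:
        value *= 1.018
    if g.black:
        value *= 1.159
    return GFRResult(value=value, method="CKD-EPI", level=stage(value))


def proposed_gfr(g: GFRInputs, apply_female_factor: bool = False) -> GFRResult:
    """Texture-based estimate: the MDRD form with the race factor replaced
    by the continuous skin parameter Sp.

    The equation carries no sex multiplier; ``apply_female_factor`` adds the
    MDRD 0.742 factor for sensitivity analysis only.
    """
    if g.sp is None or not g.sp > 0:
        raise ValidationError(f"skin parameter sp must be positive, got {g.sp}")
    value = 175.0 * g.scr**-1.154 * g.age**-0.203 * g.sp
    if apply_female_factor and g.female:
        value *= 0.742
    return GFRResult(value=value, method="proposed", level=stage(value))


def stage(gfr_value: float) -> int:
    """CKD level of a GFR value (ml/min/1.73 m²): 1 for ≥90 down to 5 for <15."""
    if not gfr_value > 0:
        raise ValidationError(f"GFR must be positive, got {gfr_value}")
    if gfr_value >= 90:
        return 1
    if gfr_value >= 60:
        return 2
    if gfr_value >= 30:
        return 3
    if gfr_value >= 15:
        return 4
    return 5
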