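"""Skin texture as a random process: per-level ensemble statistics.

Each CKD level is treated as a random process whose realizations are the
subjects' texture-feature vectors (contrast, correlation, energy,
homogeneity). For each subject the mean of the four random variables is
taken; per level, the ensemble mean ± sample SD of that quantity and its
percent deviation from the level-1 (normal) baseline summarise how far the
skin texture of a stage departs from normal.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .imaging import ValidationError
from .texture import TextureFeatures

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import SubjectRecord

__all__ = ["EnsembleSummary", "mean_of_rvs", "deviation_from_baseline", "summarize_levels"]


@dataclasses.dataclass(frozen=True)
class EnsembleSummary:
    """Per-level mean ± sd of the subjects' mean-of-RVs, and the percent
    deviation of that mean from the level-1 baseline (None at level 1)."""

    level: int
    mean_of_process: float
    sd: float
    deviation_pct: float | None
    n: int


def mean_of_rvs(f: TextureFeatures) -> float:
    """Arithmetic mean of the four texture RVs (entropy excluded)."""
    vals = (f.contrast, f.correlation, f.energy, f.homogeneity)
    if not all(np.isfinite(v) for v in vals):
        raise ValidationError("non-finite texture feature")
    return float(np.mean(vals))


def deviation_from_baseline(mean_l1: float, mean_lk: float) -> float:
    """Percent deviation of a level's process mean from the level-1 mean:
    (mean₁ − mean_k) / mean₁ × 100."""
    if not mean_l1 > 0:
        raise ValidationError(f"level-1 mean must be positive, got {mean_l1}")
    return (mean_l1 - mean_lk) / mean_l1 * 100.0


def summarize_levels(records: Iterable["SubjectRecord"]) -> list[EnsembleSummary]:
    """Ensemble summary (mean, sample SD, deviation from level 1) per
    represented CKD level, ordered by level.

    Every record must carry texture features and a level in 1–5; the level-1
    group must be non-empty (it defines the baseline).
    """
    rows = []
    for rec in records:
        if rec.features is None:
            raise ValidationError(f"record {rec.subject_id} has no texture features")
        if rec.level not in range(1, 6):
            raise ValidationError(f"record {rec.subject_id} has invalid level {rec.level}")
        rows.append({"level": rec.level, "m": mean_of_rvs(rec.features)})
    df = pd.DataFrame(rows)
    if df.empty or 1 not in set(df["level"]):
        raise ValidationError("level-1 group is empty: baseline undefined")
    grouped = df.groupby("level")["m"].agg(["mean", "std", "count"])
    base = float(grouped.loc[1, "mean"])
    out = []
    for level, row in grouped.iterrows():
        sd = float(row["std"]) if row["count"] > 1 else 0.0
        out.append(
            EnsembleSummary(
                level=int(level),
                mean_of_process=float(row["mean"]),
                sd=sd,
                deviation_pct=None if level == 1 else deviation_from_baseline(base, float(row["mean"])),
                n=int(row["count"]),
            )
        )
    return out


def summary_frame(summaries: list[EnsembleSummary]) -> pd.DataFrame:
    """Summaries as a table (level, mean, sd, deviation_pct, n)."""
    return pd.DataFrame(
        {
            "level": [s.level for s in summaries],
            "mean_of_process": [s.mean_of_process for s in summaries],
            "sd": [s.sd for s in summaries],
            "deviation_pct": [s.deviation_pct for s in summaries],
            "n": [s.n for s in summaries],
        }
    )
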