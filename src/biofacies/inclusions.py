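"""Sulfide-inclusion population metrics.

Framboidal iron sulfides in reduced sediments are near-spherical, so a
sphericity filter separates putatively biogenic precipitates from
angular detrital grains. Inclusion volumes and surface areas arrive as
data (segmented upstream from tomographic reconstructions); this module
quantifies sphericity, the percent of sample volume occupied, and
between-facies volume ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .io import ValidationError


def sphericity(volume: float, surface_area: float) -> float:
    """Sphericity Psi = pi^(1/3) * (6V)^(2/3) / A.

    Equals 1 for a sphere and is < 1 for any other shape; values above 1
    violate the isoperimetric inequality and indicate a segmentation
    artifact (flagged by InclusionSet, not rejected here).
    """
    if volume <= 0 or surface_area <= 0:
        raise ValidationError("volume and surface area must be positive")
    return math.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / surface_area


@dataclass(frozen=True)
class InclusionSet:
    """All segmented inclusions within one imaged sample.

    Volumes in mm^3, areas in mm^2. The total inclusion volume may not
    exceed the sample volume.
    """

    sample_id: str
    facies: str
    sample_volume_mm3: float
    inclusions: tuple[tuple[float, float], ...]  # (volume, surface_area)

    def __post_init__(self):
        if self.sample_volume_mm3 <= 0:
            raise ValidationError("sample volume must be positive")
        for v, a in self.inclusions:
            if v <= 0 or a <= 0:
                raise ValidationError("inclusion volumes and areas must be positive")
        if sum(v for v, _ in self.inclusions) > self.sample_volume_mm3:
            raise ValidationError("inclusion volume exceeds sample volume")

    def sphericities(self) -> list[float]:
        return [sphericity(v, a) for v, a in self.inclusions]

    def nonphysical(self) -> list[int]:
        """Indices of inclusions with sphericity > 1 (artifact indicator)."""
        return [i for i, s in enumerate(self.sphericities()) if s > 1 + 1e-12]

    def filter_spherical(self, threshold: float = 0.8) -> "InclusionSet":
        """Keep inclusions at or above a sphericity threshold.

        Represents the qualitative high-sphericity criterion used to
        call microbially mediated framboids.
        """
        kept = tuple(
            (v, a) for (v, a) in self.inclusions if sphericity(v, a) >= threshold
        )
        return InclusionSet(self.sample_id, self.facies, self.sample_volume_mm3, kept)


def volume_fraction(
    inclusions: Sequence[tuple[float, float]] | InclusionSet,
    sample_volume: float | None = None,
) -> float:
    """Percent of the sample volume occupied by the inclusions."""
    if isinstance(inclusions, InclusionSet):
        total = sum(v for v, _ in inclusions.inclusions)
        sample_volume = inclusions.sample_volume_mm3
    else:
        total = sum(v for v, _ in inclusions)
        if sample_volume is None:
            raise ValidationError("sample_volume required")
    if sample_volume <= 0:
        raise ValidationError("sample volume must be positive")
    if total > sample_volume:
        raise ValidationError("inclusion volume exceeds sample volume")
    return 100.0 * total / sample_volume


def facies_volume_ratio(set_a: InclusionSet, set_b: InclusionSet) -> float:
    """Ratio of percent-volume occupancy between two samples."""
    fa = volume_fraction(set_a)
    fb = volume_fraction(set_b)
    if fb == 0:
        raise ValidationError("denominator sample has zero inclusion volume")
    return fa / fb


def read_inclusions(path: str | Path) -> list[InclusionSet]:
    """CSV with one inclusion per row: sample_id, facies,
    sample_volume_mm3, inclusion_volume_mm3, surface_area_mm2."""
    frame = pd.read_csv(path)
    required = (
        "sample_id", "facies", "sample_volume_mm3",
        "inclusion_volume_mm3", "surface_area_mm2",
    )
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"inclusion CSV missing columns: {missing}")
    sets = []
    for (sid, facies, sv), grp in frame.groupby(
        ["sample_id", "facies", "sample_volume_mm3"], sort=False
    ):
        sets.append(
            InclusionSet(
                sample_id=str(sid),
                facies=str(facies),
                sample_volume_mm3=float(sv),
                inclusions=tuple(
                    zip(grp["inclusion_volume_mm3"], grp["surface_area_mm2"])
                ),
            )
        )
    return sets
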