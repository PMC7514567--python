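"""Landmark-based vertebral measurements and the six-stage decision rules.

Each vertebral body carries five cephalometric landmarks (pixel coordinates,
y increasing downward):

- ``Clp`` / ``Cla``: lower-posterior / lower-anterior corners of the body;
- ``Cm``: midpoint of the lower border;
- ``Cup`` / ``Cua``: upper-posterior / upper-anterior corners.

Three measurements summarise a body's maturation-relevant shape:

- *concavity depth*: perpendicular distance of ``Cm`` below the chord
  ``Clp``-``Cla`` (0 when the lower border is flat or convex);
- *tapering ratio*: posterior height / anterior height,
  ``|Cup-Clp| / |Cua-Cla|`` (> 1 means the superior border slopes down
  toward the front, as in early stages);
- *lengthening ratio*: base length / anterior height,
  ``|Clp-Cla| / |Cua-Cla|`` (> 1 horizontal-rectangular, ~1 square,
  < 1 vertical-rectangular).

``stage_from_features`` turns the measurements of C2 (lower border), C3 and
C4 into one of the six stages via a deterministic most-mature-first cascade.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from cvmstage.stages import StageLabel

LANDMARK_NAMES = ("Cla", "Clp", "Cm", "Cua", "Cup")


class GeometryError(ValueError):
    """Raised for degenerate landmark configurations."""


@dataclasses.dataclass(frozen=True)
class LandmarkSet:
    """The five landmarks of one vertebral body, pixel coords, y downward."""

    Cla: tuple[float, float]
    Clp: tuple[float, float]
    Cm: tuple[float, float]
    Cua: tuple[float, float]
    Cup: tuple[float, float]

    def as_array(self) -> np.ndarray:
        """(5, 2) array in ``LANDMARK_NAMES`` order."""
        return np.array([getattr(self, n) for n in LANDMARK_NAMES], dtype=float)

    @classmethod
    def from_mapping(cls, m: Mapping[str, Sequence[float]]) -> "LandmarkSet":
        return cls(**{n: (float(m[n][0]), float(m[n][1])) for n in LANDMARK_NAMES})

    def scaled(self, s: float) -> "LandmarkSet":
        return LandmarkSet(
            **{
                n: (getattr(self, n)[0] * s, getattr(self, n)[1] * s)
                for n in LANDMARK_NAMES
            }
        )


@dataclasses.dataclass(frozen=True)
class CephFeatures:
    """The three shape measurements of one vertebral body."""

    concavity_depth: float
    tapering_ratio: float
    lengthening_ratio: float


@dataclasses.dataclass(frozen=True)
class StageRuleConfig:
    """Numeric thresholds quantising the qualitative stage descriptions.

    ``flat_threshold`` is in pixels at ``reference_side`` image scale and is
    rescaled linearly for other image sizes via :meth:`at_scale`. A lower
    border counts as concave when its concavity depth reaches
    ``flat_threshold`` and as deepened at ``deepened_factor`` times that. The
    lengthening-ratio bands separate horizontal-rectangular (above the square
    band), square (inside it) and vertical-rectangular (below
    ``vertical_ratio_threshold``) bodies.
    """

    flat_threshold: float = 1.0
    taper_threshold: float = 1.05
    square_band: tuple[float, float] = (0.95, 1.05)
    vertical_ratio_threshold: float = 0.95
    deepened_factor: float = 2.0
    reference_side: int = 256

    def __post_init__(self) -> None:
        if self.flat_threshold <= 0:
            raise ValueError("flat_threshold must be > 0")
        if self.square_band[0] > self.square_band[1]:
            raise ValueError("square_band bounds must be ordered")

    def at_scale(self, image_side: int) -> "StageRuleConfig":
        """Rules with pixel thresholds rescaled to an image of ``image_side``."""
        s = image_side / self.reference_side
        return dataclasses.replace(
            self, flat_threshold=self.flat_threshold * s, reference_side=image_side
        )


def concavity_depth(lm: LandmarkSet) -> float:
    """Perpendicular distance of Cm below the Clp-Cla chord, >= 0.

    Positive when Cm lies on the larger-y (lower) side of the chord; clamped
    to 0 when Cm is on or above it.
    """
    (xa, ya), (xp, yp) = lm.Cla, lm.Clp
    dx, dy = xa - xp, ya - yp
    norm = math.hypot(dx, dy)
    if norm == 0:
        raise GeometryError("Cla and Clp coincide")
    xm, ym = lm.Cm
    # cross product of chord direction with Clp->Cm; with y downward and the
    # anterior point to the right (dx > 0), positive values are below the chord
    signed = (dx * (ym - yp) - dy * (xm - xp)) / norm
    if dx < 0:
        signed = -signed
    return max(signed, 0.0)


def _anterior_height(lm: LandmarkSet) -> float:
    h = math.dist(lm.Cua, lm.Cla)
    if h == 0:
        raise GeometryError("zero anterior height (Cua == Cla)")
    return h


def tapering_ratio(lm: LandmarkSet) -> float:
    """Posterior-to-anterior body-height ratio |Cup-Clp| / |Cua-Cla|."""
    return math.dist(lm.Cup, lm.Clp) / _anterior_height(lm)


def lengthening_ratio(lm: LandmarkSet) -> float:
    """Base-length to anterior-height ratio |Clp-Cla| / |Cua-Cla|."""
    return math.dist(lm.Clp, lm.Cla) / _anterior_height(lm)


def features(lm: LandmarkSet) -> CephFeatures:
    """All three measurements of one body, computed consistently."""
    return CephFeatures(
        concavity_depth=concavity_depth(lm),
        tapering_ratio=tapering_ratio(lm),
        lengthening_ratio=lengthening_ratio(lm),
    )


def stage_from_features(
    c2: CephFeatures,
    c3: CephFeatures,
    c4: CephFeatures,
    rules: StageRuleConfig | None = None,
) -> StageLabel:
    """Map the feature triple (C2, C3, C4) to a maturation stage.

    The cascade evaluates the most mature stage first; the first match wins,
    so later-stage criteria subsume earlier ones:

    - CS6: all three lower borders concave, C3 and C4 concavities deepened,
      and at least one of C3/C4 vertical-rectangular (higher than wide);
    - CS5: all three concave and at least one of C3/C4 square;
    - CS4: all three concave (bodies horizontal-rectangular by default);
    - CS3: C2 and C3 concave;
    - CS2: C2 concave only;
    - CS1: no concavity (flat lower borders).

    The cascade is total: any finite feature triple maps to exactly one stage.
    """
    rules = rules or StageRuleConfig()
    flat = rules.flat_threshold
    deep = rules.deepened_factor * flat
    lo, hi = rules.square_band

    def concave(f: CephFeatures) -> bool:
        return f.concavity_depth >= flat

    def square(f: CephFeatures) -> bool:
        return lo <= f.lengthening_ratio <= hi

    def vertical(f: CephFeatures) -> bool:
        return f.lengthening_ratio < rules.vertical_ratio_threshold

    all_concave = concave(c2) and concave(c3) and concave(c4)
    if (
        all_concave
        and c3.concavity_depth >= deep
        and c4.concavity_depth >= deep
        and (vertical(c3) or vertical(c4))
    ):
        return StageLabel.CS6
    if all_concave and (square(c3) or square(c4)):
        return StageLabel.CS5
    if all_concave:
        return StageLabel.CS4
    if concave(c2) and concave(c3):
        return StageLabel.CS3
    if concave(c2):
        return StageLabel.CS2
    return StageLabel.CS1


def stage_from_landmarks(
    c2: LandmarkSet,
    c3: LandmarkSet,
    c4: LandmarkSet,
    rules: StageRuleConfig | None = None,
) -> StageLabel:
    """Convenience wrapper: measure three landmark sets and stage them."""
    return stage_from_features(features(c2), features(c3), features(c4), rules)
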