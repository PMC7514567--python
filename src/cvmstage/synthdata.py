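"""Synthetic vertebra-image generator with ground-truth landmarks.

The study's radiographs are private, so downstream stages are exercised on
synthetic images that emulate the cropped vertebral region of a lateral
cephalogram: three stacked bright vertebral bodies (the lower border and
partial body of C2, plus the full C3 and C4 bodies) on a darker, optionally
shaded and noisy background.

Per-stage geometry is drawn from a parameter table whose ranges follow the
six-stage morphology progression: flat lower borders and tapered superior
borders in CS1, a concavity appearing on C2 (CS2), then C2+C3 (CS3), then
all three (CS4+), with body shape moving from horizontal-rectangular (CS4)
through square (CS5) to vertical-rectangular with deepened concavities
(CS6). Every draw carries its exact landmark coordinates, so the rule-based
stager can be round-tripped against the generating stage.

Coordinates: origin top-left, x rightward, y downward, 0-based; the "lower"
border of a body has the larger y.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.draw import polygon as _polygon
from skimage.draw import polygon_perimeter as _polygon_perimeter

from cvmstage.cephalometrics import LANDMARK_NAMES, LandmarkSet, StageRuleConfig
from cvmstage.cephalometrics import features as ceph_features
from cvmstage.cephalometrics import stage_from_features
from cvmstage.stages import ALL_STAGES, StageLabel

#: Reference scale (pixels per side) at which the parameter table is written.
REFERENCE_SIDE = 256

VERTEBRAE = ("C2", "C3", "C4")


class ConfigurationError(ValueError):
    """Raised for malformed generator configurations."""


@dataclasses.dataclass(frozen=True)
class VertebraGeometry:
    """Ground-truth geometry of one rendered vertebral body."""

    landmarks: LandmarkSet
    concavity_depth_param: float
    posterior_height: float
    anterior_height: float
    base_length: float

    def __post_init__(self) -> None:
        if self.concavity_depth_param < 0:
            raise ValueError("concavity depth must be >= 0")
        for f in ("posterior_height", "anterior_height", "base_length"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


@dataclasses.dataclass(frozen=True)
class StageParams:
    """Per-stage parameter ranges, in pixels at ``REFERENCE_SIDE`` scale.

    Each range is an inclusive ``(low, high)`` interval sampled uniformly.
    ``depth_*`` are lower-border concavity depths; ``taper`` is the
    posterior/anterior height ratio shared by C3 and C4; ``lengthening_*``
    are base/anterior-height ratios.
    """

    depth_c2: tuple[float, float]
    depth_c3: tuple[float, float]
    depth_c4: tuple[float, float]
    taper: tuple[float, float]
    lengthening_c3: tuple[float, float]
    lengthening_c4: tuple[float, float]
    gap: float = 14.0  # vertical spacing between bodies


#: Default stage morphology table (pixels at 256-px scale). Ranges are chosen
#: so the rule cascade's default thresholds separate the stages with margin:
#: concavity depth is non-decreasing CS1 -> CS6, and the C3/C4 lengthening
#: ratio moves from horizontal-rectangular through square to vertical.
DEFAULT_STAGE_TABLE: dict[StageLabel, StageParams] = {
    StageLabel.CS1: StageParams(
        depth_c2=(0.0, 0.0), depth_c3=(0.0, 0.0), depth_c4=(0.0, 0.0),
        taper=(1.15, 1.30),
        lengthening_c3=(1.25, 1.45), lengthening_c4=(1.25, 1.45),
    ),
    StageLabel.CS2: StageParams(
        depth_c2=(2.5, 4.0), depth_c3=(0.0, 0.0), depth_c4=(0.0, 0.0),
        taper=(1.10, 1.25),
        lengthening_c3=(1.20, 1.40), lengthening_c4=(1.20, 1.40),
    ),
    StageLabel.CS3: StageParams(
        depth_c2=(2.5, 4.5), depth_c3=(2.5, 4.5), depth_c4=(0.0, 0.0),
        taper=(1.05, 1.18),
        lengthening_c3=(1.15, 1.35), lengthening_c4=(1.15, 1.35),
    ),
    StageLabel.CS4: StageParams(
        depth_c2=(3.0, 5.0), depth_c3=(3.0, 5.0), depth_c4=(3.0, 5.0),
        taper=(0.98, 1.08),
        lengthening_c3=(1.12, 1.32), lengthening_c4=(1.12, 1.32),
    ),
    StageLabel.CS5: StageParams(
        depth_c2=(3.5, 5.5), depth_c3=(3.5, 5.5), depth_c4=(3.5, 5.5),
        taper=(0.96, 1.06),
        lengthening_c3=(0.96, 1.04), lengthening_c4=(1.08, 1.20),
        gap=9.0,
    ),
    StageLabel.CS6: StageParams(
        depth_c2=(4.0, 6.0), depth_c3=(4.5, 6.5), depth_c4=(4.5, 6.5),
        taper=(0.95, 1.03),
        lengthening_c3=(0.80, 0.92), lengthening_c4=(0.82, 0.94),
        gap=9.0,
    ),
}


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines one synthetic dataset.

    Intensities are on the 8-bit scale (0..255): ``background_level`` and
    ``foreground_level`` fill the background and body interiors,
    ``border_level`` the one-pixel body rims (the bright cortical outline),
    ``gradient_amplitude`` the peak-to-peak span of a random-direction linear
    shading plane (exposure/illumination variation), and ``noise_sd`` the
    standard deviation of additive Gaussian noise. ``rotation_jitter``
    (degrees) and ``scale_jitter`` (fraction) perturb each sample's pose.
    """

    image_size: int = 64
    n_per_class: int = 100
    noise_sd: float = 8.0
    rotation_jitter: float = 3.0
    scale_jitter: float = 0.04
    seed: int = 0
    background_level: float = 60.0
    foreground_level: float = 190.0
    border_level: float = 235.0
    gradient_amplitude: float = 20.0
    gain_jitter: float = 0.0    # per-image multiplicative exposure spread
    offset_jitter: float = 0.0  # per-image additive offset spread (intensity)
    invert_prob: float = 0.0    # chance of per-image polarity inversion
    anterior_height: tuple[float, float] = (40.0, 52.0)
    c2_body_height: float = 22.0
    max_regenerate: int = 20
    supersample: int = 4
    stage_parameter_table: Mapping[StageLabel, StageParams] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_STAGE_TABLE)
    )

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.noise_sd < 0 or self.rotation_jitter < 0 or self.scale_jitter < 0:
            raise ConfigurationError("jitter/noise parameters must be >= 0")
        validate_stage_table(self.stage_parameter_table)

    @property
    def scale(self) -> float:
        return self.image_size / REFERENCE_SIDE

    def rules_at_scale(self, rules: StageRuleConfig | None = None) -> StageRuleConfig:
        return (rules or StageRuleConfig()).at_scale(self.image_size)


def easy_preset(**overrides) -> GeneratorConfig:
    """Benign imaging conditions: light noise, mild shading and pose jitter."""
    return GeneratorConfig(**overrides)


def hard_preset(**overrides) -> GeneratorConfig:
    """Degraded imaging: noise, strong random shading, per-image exposure
    gain/offset, mixed display polarity, and larger pose jitter.

    Emulates a heterogeneous radiograph archive whose absolute gray levels
    are unreliable (exposure variation, inverted display LUTs) while local
    structure (body outlines) is preserved -- the regime that motivates
    structure-sensitive preprocessing such as the entropy filter.
    """
    defaults = dict(
        noise_sd=25.0,
        gradient_amplitude=80.0,
        gain_jitter=0.4,
        offset_jitter=40.0,
        invert_prob=0.5,
        rotation_jitter=6.0,
        scale_jitter=0.08,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def validate_stage_table(
    table: Mapping[StageLabel, StageParams],
    rules: StageRuleConfig | None = None,
) -> None:
    """Check that every corner of every stage's ranges maps back to it.

    Because the rule cascade is monotone in each measurement, checking the
    2^3 corners of (depth, taper, lengthening) ranges guarantees the whole
    box is staged consistently. Raises :class:`ConfigurationError` otherwise.
    """
    rules = rules or StageRuleConfig()
    missing = [s for s in ALL_STAGES if s not in table]
    if missing:
        raise ConfigurationError(f"stage_parameter_table missing stages {missing}")
    from cvmstage.cephalometrics import CephFeatures

    for stage, p in table.items():
        for d2 in p.depth_c2:
            for d3, l3 in ((p.depth_c3[i], p.lengthening_c3[j])
                           for i in (0, 1) for j in (0, 1)):
                for d4, l4 in ((p.depth_c4[i], p.lengthening_c4[j])
                               for i in (0, 1) for j in (0, 1)):
                    for t in p.taper:
                        got = stage_from_features(
                            CephFeatures(d2, t, 1.3),
                            CephFeatures(d3, t, l3),
                            CephFeatures(d4, t, l4),
                            rules,
                        )
                        if got != stage:
                            raise ConfigurationError(
                                f"{stage.name} parameter corner maps to {got.name}: "
                                f"depths=({d2},{d3},{d4}) taper={t} "
                                f"lengthening=({l3},{l4})"
                            )


def _body_landmarks(cx: float, yb: float, base: float, ha: float,
                    hp: float, depth: float) -> LandmarkSet:
    """Landmarks of a body with a horizontal lower border at y = yb."""
    xp, xa = cx - base / 2.0, cx + base / 2.0
    return LandmarkSet(
        Cla=(xa, yb),
        Clp=(xp, yb),
        Cm=((xp + xa) / 2.0, yb + depth),
        Cua=(xa, yb - ha),
        Cup=(xp, yb - hp),
    )


def sample_geometry(
    stage: StageLabel,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, VertebraGeometry]:
    """Draw stage-consistent geometry for C2 (lower border + partial body),
    C3 and C4, in pixel coordinates at ``config.image_size``.

    At zero jitter the drawn geometry satisfies the generating stage's rule
    set exactly: flat vertebrae have concavity depth 0, tapered superior
    borders have posterior height > anterior height, and CS6 bodies are
    higher than wide.
    """
    stage = StageLabel.from_any(stage)
    p = config.stage_parameter_table[stage]
    u = rng.uniform

    s = config.scale
    ha3 = u(*config.anterior_height)
    ha4 = u(*config.anterior_height)
    t = u(*p.taper)
    geom_params = {
        "C2": dict(depth=u(*p.depth_c2), ha=config.c2_body_height,
                   taper=1.0, lengthening=None),
        "C3": dict(depth=u(*p.depth_c3), ha=ha3, taper=t,
                   lengthening=u(*p.lengthening_c3)),
        "C4": dict(depth=u(*p.depth_c4), ha=ha4, taper=t,
                   lengthening=u(*p.lengthening_c4)),
    }
    # C2's partial body spans slightly more than C3's base
    base3 = geom_params["C3"]["lengthening"] * ha3
    base4 = geom_params["C4"]["lengthening"] * ha4
    geom_params["C2"]["base"] = 1.05 * base3
    geom_params["C3"]["base"] = base3
    geom_params["C4"]["base"] = base4

    cx = REFERENCE_SIDE / 2.0
    yb2 = 70.0
    yb3 = yb2 + p.gap + max(geom_params["C3"]["taper"] * ha3, ha3)
    yb4 = yb3 + p.gap + max(geom_params["C4"]["taper"] * ha4, ha4)
    y_base = {"C2": yb2, "C3": yb3, "C4": yb4}

    out: dict[str, VertebraGeometry] = {}
    for v in VERTEBRAE:
        gp = geom_params[v]
        hp = gp["taper"] * gp["ha"]
        lm = _body_landmarks(cx, y_base[v], gp["base"], gp["ha"], hp, gp["depth"])
        out[v] = VertebraGeometry(
            landmarks=lm.scaled(s),
            concavity_depth_param=gp["depth"] * s,
            posterior_height=hp * s,
            anterior_height=gp["ha"] * s,
            base_length=gp["base"] * s,
        )
    return out


@dataclasses.dataclass(frozen=True)
class SyntheticSample:
    """One rendered image with its ground truth."""

    image: np.ndarray  # (H, W) uint8
    stage: StageLabel
    geometry: dict[str, VertebraGeometry]
    seed: int
    draw_index: int


def _transform_points(pts: np.ndarray, center: float, angle_deg: float,
                      scale: float) -> np.ndarray:
    """Rotate about the image center and scale; pts is (N, 2) as (x, y)."""
    th = math.radians(angle_deg)
    c, sn = math.cos(th), math.sin(th)
    rel = pts - center
    x = scale * (c * rel[:, 0] - sn * rel[:, 1]) + center
    y = scale * (sn * rel[:, 0] + c * rel[:, 1]) + center
    return np.stack([x, y], axis=1)


def _lower_border_curve(lm: LandmarkSet, n: int = 21) -> np.ndarray:
    """Sampled lower border from Cla to Clp: a quadratic dip through Cm."""
    (xa, ya), (xp, yp) = lm.Cla, lm.Clp
    depth = 2.0 * (lm.Cm[1] - (ya + yp) / 2.0)  # vertex offset of the parabola
    t = np.linspace(0.0, 1.0, n)
    x = xa + (xp - xa) * t
    y = ya + (yp - ya) * t + 2.0 * depth * t * (1.0 - t)
    return np.stack([x, y], axis=1)


def render_sample(
    geometry: Mapping[str, VertebraGeometry],
    stage: StageLabel,
    config: GeneratorConfig,
    rng: np.random.Generator,
    draw_index: int = 0,
) -> SyntheticSample:
    """Rasterise one sample: filled bright bodies with a brighter one-pixel
    rim on a darker background, optional shading plane, additive Gaussian
    noise, and pose jitter applied consistently to pixels and landmarks.

    If jitter pushes any landmark out of bounds the pose is redrawn, up to
    ``config.max_regenerate`` times, after which a :class:`ConfigurationError`
    is raised.
    """
    stage = StageLabel.from_any(stage)
    n = config.image_size
    center = (n - 1) / 2.0

    for _ in range(config.max_regenerate + 1):
        angle = rng.uniform(-config.rotation_jitter, config.rotation_jitter) \
            if config.rotation_jitter > 0 else 0.0
        pose_scale = 1.0 + (rng.uniform(-config.scale_jitter, config.scale_jitter)
                            if config.scale_jitter > 0 else 0.0)
        moved: dict[str, LandmarkSet] = {}
        polys: dict[str, np.ndarray] = {}
        ok = True
        for v, g in geometry.items():
            lm = g.landmarks
            curve = _lower_border_curve(lm)
            outline = np.concatenate(
                [np.array([lm.Cup, lm.Cua]), curve, np.array([lm.Cup])]
            )
            outline_t = _transform_points(outline, center, angle, pose_scale)
            pts_t = _transform_points(lm.as_array(), center, angle, pose_scale)
            if (pts_t < 0).any() or (pts_t > n - 1).any():
                ok = False
                break
            moved[v] = LandmarkSet(
                **{name: tuple(pts_t[i]) for i, name in enumerate(LANDMARK_NAMES)}
            )
            polys[v] = outline_t
        if ok:
            break
    else:
        raise ConfigurationError(
            "geometry out of bounds after jitter; increase image_size or "
            "reduce jitter"
        )

    # Rasterise at `supersample`x resolution and box-average down so that
    # sub-pixel geometry (the shallow early-stage concavities) survives as
    # intensity gradation instead of being lost to hard pixel boundaries.
    ss = max(1, int(config.supersample))
    nf = n * ss
    img_f = np.full((nf, nf), config.background_level, dtype=np.float64)
    for v, outline_t in polys.items():
        fine = outline_t * ss + (ss - 1) / 2.0
        rr, cc = _polygon(fine[:, 1], fine[:, 0], shape=(nf, nf))
        img_f[rr, cc] = config.foreground_level
        rim = np.zeros((nf, nf), dtype=bool)
        rr, cc = _polygon_perimeter(fine[:, 1], fine[:, 0], shape=(nf, nf),
                                    clip=True)
        rim[rr, cc] = True
        if ss > 1:
            rim = ndi.binary_dilation(rim, iterations=ss - 1)
        img_f[rim] = config.border_level
    img = img_f.reshape(n, ss, n, ss).mean(axis=(1, 3)) if ss > 1 else img_f

    # per-image exposure variation: multiplicative gain about mid-gray plus
    # an additive offset, emulating unreliable absolute gray levels
    if config.invert_prob > 0 and rng.random() < config.invert_prob:
        # mixed display polarity (film vs digital LUT): gray levels flip
        # about mid-gray while local structure is untouched
        img = 255.0 - img
    if config.gain_jitter > 0:
        gain = 1.0 + rng.uniform(-config.gain_jitter, config.gain_jitter)
        img = gain * (img - 128.0) + 128.0
    if config.offset_jitter > 0:
        img += rng.uniform(-config.offset_jitter, config.offset_jitter)
    if config.gradient_amplitude > 0:
        phi = rng.uniform(0.0, 2.0 * math.pi)
        yy, xx = np.mgrid[0:n, 0:n] / max(n - 1, 1)
        plane = math.cos(phi) * xx + math.sin(phi) * yy
        img += config.gradient_amplitude * (plane - plane.mean())
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)

    img = np.clip(img, 0.0, 255.0).round().astype(np.uint8)
    new_geometry = {
        v: dataclasses.replace(
            geometry[v],
            landmarks=moved[v],
            concavity_depth_param=geometry[v].concavity_depth_param * pose_scale,
            posterior_height=geometry[v].posterior_height * pose_scale,
            anterior_height=geometry[v].anterior_height * pose_scale,
            base_length=geometry[v].base_length * pose_scale,
        )
        for v in geometry
    }
    return SyntheticSample(
        image=img, stage=stage, geometry=new_geometry,
        seed=config.seed, draw_index=draw_index,
    )


def draw_sample(stage: StageLabel, config: GeneratorConfig,
                rng: np.random.Generator, draw_index: int = 0) -> SyntheticSample:
    """Sample geometry and render it in one step."""
    return render_sample(sample_geometry(stage, config, rng), stage, config,
                         rng, draw_index)


def _split_counts(n: int, fractions: tuple[float, ...]) -> list[int]:
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must be positive and sum to 1")
    counts = [int(round(n * f)) for f in fractions[:-1]]
    counts.append(n - sum(counts))
    if min(counts) < 0:
        raise ConfigurationError("split fractions leave an empty split")
    return counts


SPLIT_NAMES = ("train", "val", "test")


def generate_samples(
    config: GeneratorConfig,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> list[tuple[SyntheticSample, str]]:
    """Generate a balanced dataset in memory: ``n_per_class`` per stage,
    partitioned into disjoint train/val/test splits per class."""
    rng = np.random.default_rng(config.seed)
    counts = _split_counts(config.n_per_class, tuple(split_fractions))
    out: list[tuple[SyntheticSample, str]] = []
    idx = 0
    for stage in ALL_STAGES:
        for split_name, k in zip(SPLIT_NAMES, counts):
            for _ in range(k):
                out.append((draw_sample(stage, config, rng, idx), split_name))
                idx += 1
    return out


def samples_to_arrays(
    samples: list[tuple[SyntheticSample, str]], split: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stack one split into (images, labels): float32 in [0, 1], int labels 1..6."""
    sel = [s for s, sp in samples if sp == split]
    x = np.stack([s.image for s in sel]).astype(np.float32) / 255.0
    y = np.array([int(s.stage) for s in sel], dtype=np.int64)
    return x, y


def _manifest_row(path: str, split: str, sample: SyntheticSample) -> dict:
    row: dict[str, object] = {
        "path": path, "split": split, "stage": sample.stage.name,
        "seed": sample.seed, "draw_index": sample.draw_index,
    }
    for v in VERTEBRAE:
        lm = sample.geometry[v].landmarks
        for name in LANDMARK_NAMES:
            x, y = getattr(lm, name)
            row[f"{v}_{name}_x"] = x
            row[f"{v}_{name}_y"] = y
    return row


def landmarks_from_row(row: Mapping[str, float]) -> dict[str, LandmarkSet]:
    """Rebuild the three landmark sets from one manifest row."""
    return {
        v: LandmarkSet(**{
            name: (float(row[f"{v}_{name}_x"]), float(row[f"{v}_{name}_y"]))
            for name in LANDMARK_NAMES
        })
        for v in VERTEBRAE
    }


def generate_dataset(
    config: GeneratorConfig,
    out_dir: str | Path,
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> pd.DataFrame:
    """Write PNG images plus a ``manifest.csv`` and return the manifest.

    The manifest has one row per image: path (relative to ``out_dir``),
    split, stage name, and the 5 landmark coordinate pairs for each of the
    three vertebrae.
    """
    from PIL import Image

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for sample, split in generate_samples(config, split_fractions):
        fname = f"images/{sample.stage.name.lower()}_{sample.draw_index:05d}.png"
        Image.fromarray(sample.image, mode="L").save(out_dir / fname)
        rows.append(_manifest_row(fname, split, sample))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def stage_of_sample(sample: SyntheticSample, config: GeneratorConfig,
                    rules: StageRuleConfig | None = None) -> StageLabel:
    """Re-derive the stage of a sample from its stored landmarks."""
    f = {v: ceph_features(sample.geometry[v].landmarks) for v in VERTEBRAE}
    return stage_from_features(f["C2"], f["C3"], f["C4"],
                               config.rules_at_scale(rules))
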