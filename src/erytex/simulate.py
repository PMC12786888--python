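"""Synthetic cross-polarized-style facial study generator.

Renders greyscale faces in which erythema appears as clusters of darkened
Gaussian blobs plus thin curvilinear telangiectasia streaks inside four zone
masks (left cheek, right cheek, nose, chin).  Lesion geometry is fixed per
subject; the per-timepoint effect factor scales lesion amplitude, so a
treatment response is a proportional fading of the same lesions.  Noisy
ordinal grades from three raters are produced from the ground-truth severity.

Randomness: every stream is a ``numpy`` Generator seeded by an integer tuple
``(seed, stream-tag, subject, timepoint, ...)``, so outputs are byte-identical
for a fixed seed and independent of generation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from erytex.pipeline import TIMEPOINTS, ZONES, DEFAULT_WEIGHTS

# stream tags (arbitrary distinct constants)
_TAG_SUBJECT = 1
_TAG_NOISE = 2
_TAG_RATER_BIAS = 3
_TAG_RATER_NOISE = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study."""

    n_subjects: int = 20
    image_size: int = 512
    base_skin_level: float = 180.0
    shading_amplitude: float = 4.0
    lesion_count_range: tuple[int, int] = (2, 5)  # per zone, inclusive
    lesion_amplitude: float = 30.0  # grey-level depression per lesion at T0
    lesion_scale: float = 0.02  # Gaussian sigma as a fraction of image size
    telangiectasia_count: int = 3  # streaks per cheek
    effect_T1: float = 0.4  # multiplicative amplitude factor at T1
    effect_T2: float = 0.45
    noise_sd: float = 2.0  # additive grey-level noise
    cea_severity_max: float = 6.0  # severity mapped to the top grade (4)
    rater_bias_sd: float = 0.1  # per-rater constant offset, grade units
    rater_noise_sd: float = 0.18  # per-assessment noise, grade units
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.effect_T1 <= 1.0 and 0.0 <= self.effect_T2 <= 1.0):
            raise ValueError("effect factors must lie in [0, 1]")
        if self.n_subjects < 1 or self.image_size < 32:
            raise ValueError("need n_subjects >= 1 and image_size >= 32")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid lesion_count_range")

    def effect(self, timepoint: str) -> float:
        return {"T0": 1.0, "T1": self.effect_T1, "T2": self.effect_T2}[timepoint]


# Zone geometry in fractional image coordinates: (row, col, row-radius, col-radius).
_ZONE_GEOMETRY = {
    "left_cheek": (0.52, 0.26, 0.13, 0.13),
    "right_cheek": (0.52, 0.74, 0.13, 0.13),
    "nose": (0.50, 0.50, 0.15, 0.08),
    "chin": (0.84, 0.50, 0.09, 0.13),
}


def _zone_masks(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """Elliptical zone masks with small per-subject jitter; fixed across timepoints."""
    size = config.image_size
    rr, cc = np.mgrid[0:size, 0:size]
    masks = {}
    for zone in ZONES:
        fr, fc, frr, fcr = _ZONE_GEOMETRY[zone]
        jr, jc = rng.uniform(-0.01, 0.01, size=2)
        cy, cx = (fr + jr) * size, (fc + jc) * size
        ry, rx = frr * size, fcr * size
        masks[zone] = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    return masks


def _sample_in_mask(mask: np.ndarray, rng: np.random.Generator, n: int) -> np.ndarray:
    coords = np.argwhere(mask)
    idx = rng.integers(0, len(coords), size=n)
    return coords[idx]


def _lesion_field(config: SimulationConfig, masks: dict, rng: np.random.Generator) -> np.ndarray:
    """Unit-effect lesion depression field (grey levels), fixed per subject."""
    size = config.image_size
    rr, cc = np.mgrid[0:size, 0:size]
    field = np.zeros((size, size), dtype=float)
    sigma0 = max(1.0, config.lesion_scale * size)
    lo, hi = config.lesion_count_range
    for zone in ZONES:
        mask = masks[zone]
        n_lesions = int(rng.integers(lo, hi + 1))
        centers = _sample_in_mask(mask, rng, n_lesions) if n_lesions else []
        for cy, cx in centers:
            amp = config.lesion_amplitude * rng.uniform(0.6, 1.0)
            sigma = sigma0 * rng.uniform(0.7, 1.3)
            blob = amp * np.exp(-((rr - cy) ** 2 + (cc - cx) ** 2) / (2.0 * sigma**2))
            field += blob * mask  # lesion confined to its zone
    # thin dark random-walk streaks (telangiectasia) on the cheeks
    streak = np.zeros((size, size), dtype=float)
    for zone in ("left_cheek", "right_cheek"):
        mask = masks[zone]
        for _ in range(config.telangiectasia_count):
            (r, c), = _sample_in_mask(mask, rng, 1)
            r, c = float(r), float(c)
            heading = rng.uniform(0, 2 * np.pi)
            for _ in range(int(0.25 * size)):
                ri, ci = int(round(r)), int(round(c))
                if not (0 <= ri < size and 0 <= ci < size) or not mask[ri, ci]:
                    break
                streak[ri, ci] = 1.0
                heading += rng.normal(0, 0.35)
                r += np.sin(heading)
                c += np.cos(heading)
    field += 0.9 * config.lesion_amplitude * streak
    return field


def _base_field(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency skin shading, fixed per subject."""
    size = config.image_size
    rr, cc = np.mgrid[0:size, 0:size]
    phases = rng.uniform(0, 2 * np.pi, size=4)
    shade = (
        np.sin(2 * np.pi * rr / size + phases[0])
        + np.cos(2 * np.pi * cc / size + phases[1])
        + 0.5 * np.sin(4 * np.pi * (rr + cc) / (2 * size) + phases[2])
    )
    return config.base_skin_level + config.shading_amplitude * shade / 2.5


@dataclass(frozen=True)
class SubjectScene:
    """Per-subject geometry reused across the three timepoints."""

    masks: dict
    base: np.ndarray
    lesions: np.ndarray  # unit-effect depression field


def build_scene(config: SimulationConfig, subject: int) -> SubjectScene:
    rng = np.random.default_rng([config.seed, _TAG_SUBJECT, subject])
    masks = _zone_masks(config, rng)
    base = _base_field(config, rng)
    lesions = _lesion_field(config, masks, rng)
    return SubjectScene(masks=masks, base=base, lesions=lesions)


def severity_row(config: SimulationConfig, scene: SubjectScene, timepoint: str) -> dict:
    """Ground-truth severities: mean lesion depression inside each zone mask."""
    effect = config.effect(timepoint)
    per_zone = {
        zone: float(effect * scene.lesions[scene.masks[zone]].mean()) for zone in ZONES
    }
    face = sum(DEFAULT_WEIGHTS[z] * per_zone[z] for z in ZONES)
    row = {"true_severity": float(face)}
    row.update({f"sev_{z}": per_zone[z] for z in ZONES})
    return row


def render_face(
    config: SimulationConfig, subject: int, timepoint: str, scene: SubjectScene | None = None
) -> tuple[np.ndarray, dict, dict]:
    """One synthetic photograph: (grey image, zone masks, ground-truth row)."""
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    if scene is None:
        scene = build_scene(config, subject)
    tp_idx = TIMEPOINTS.index(timepoint)
    noise_rng = np.random.default_rng([config.seed, _TAG_NOISE, subject, tp_idx])
    pixels = scene.base - config.effect(timepoint) * scene.lesions
    pixels = pixels + noise_rng.normal(0.0, config.noise_sd, size=pixels.shape)
    image = np.clip(np.floor(pixels + 0.5), 0, 255).astype(np.uint8)
    truth = {"subject": f"S{subject:03d}", "timepoint": timepoint}
    truth.update(severity_row(config, scene, timepoint))
    return image, scene.masks, truth


def rater_biases(config: SimulationConfig) -> dict:
    """Fixed per-rater offsets for the whole study (grade units)."""
    rng = np.random.default_rng([config.seed, _TAG_RATER_BIAS])
    return {f"S{k + 1}": float(rng.normal(0.0, config.rater_bias_sd)) for k in range(3)}


def rate_cea(
    config: SimulationConfig,
    true_severity: float,
    subject: int,
    timepoint: str,
    biases: dict | None = None,
) -> dict:
    """Noisy ordinal grades from three raters: clamp(round(linear model), 0, 4)."""
    if biases is None:
        biases = rater_biases(config)
    tp_idx = TIMEPOINTS.index(timepoint)
    grades = {}
    for k, rater in enumerate(("S1", "S2", "S3")):
        rng = np.random.default_rng([config.seed, _TAG_RATER_NOISE, subject, tp_idx, k])
        raw = 4.0 * true_severity / config.cea_severity_max
        raw += biases[rater] + rng.normal(0.0, config.rater_noise_sd)
        grades[rater] = int(np.clip(np.floor(raw + 0.5), 0, 4))
    return grades


def simulate_feature_truth(config: SimulationConfig) -> pd.DataFrame:
    """Ground-truth severity table for all subjects x timepoints (no rendering)."""
    rows = []
    for subject in range(1, config.n_subjects + 1):
        scene = build_scene(config, subject)
        for tp in TIMEPOINTS:
            row = {"subject": f"S{subject:03d}", "timepoint": tp}
            row.update(severity_row(config, scene, tp))
            rows.append(row)
    return pd.DataFrame(rows)


def generate_study(config: SimulationConfig, output_dir: str | Path) -> dict:
    """Write the full synthetic study: images, masks, manifest, CEA and truth CSVs.

    Returns the paths of the three CSVs.  Deterministic under a fixed seed.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)

    biases = rater_biases(config)
    manifest_rows, cea_rows, truth_rows = [], [], []
    for subject in range(1, config.n_subjects + 1):
        sid = f"S{subject:03d}"
        scene = build_scene(config, subject)
        for tp in TIMEPOINTS:
            image, masks, truth = render_face(config, subject, tp, scene)
            img_path = out / "images" / f"{sid}_{tp}.png"
            Image.fromarray(image, mode="L").save(img_path)
            mask_paths = {}
            for zone in ZONES:
                mpath = out / "masks" / f"{sid}_{tp}_{zone}.png"
                Image.fromarray((masks[zone] * np.uint8(255)), mode="L").save(mpath)
                mask_paths[zone] = mpath
            manifest_rows.append(
                {
                    "subject": sid,
                    "timepoint": tp,
                    "image_path": str(img_path),
                    "mask_lc": str(mask_paths["left_cheek"]),
                    "mask_rc": str(mask_paths["right_cheek"]),
                    "mask_nose": str(mask_paths["nose"]),
                    "mask_chin": str(mask_paths["chin"]),
                }
            )
            truth_rows.append(truth)
            for rater, grade in rate_cea(
                config, truth["true_severity"], subject, tp, biases
            ).items():
                cea_rows.append(
                    {"subject": sid, "timepoint": tp, "rater": rater, "grade": grade}
                )

    paths = {
        "manifest": out / "manifest.csv",
        "cea": out / "cea.csv",
        "truth": out / "truth.csv",
    }
    pd.DataFrame(manifest_rows).to_csv(paths["manifest"], index=False)
    pd.DataFrame(cea_rows).to_csv(paths["cea"], index=False)
    pd.DataFrame(truth_rows).to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}


def config_defaults() -> dict:
    """Flat key -> default mapping (the `--print-defaults` payload)."""
    out = {}
    for f in dataclasses.fields(SimulationConfig):
        v = f.default
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a config from a flat key-value mapping (unknown keys rejected)."""
    valid = {f.name: f for f in dataclasses.fields(SimulationConfig)}
    unknown = set(mapping) - set(valid)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in mapping.items():
        if key == "lesion_count_range":
            kwargs[key] = tuple(int(x) for x in value)
        elif key in ("n_subjects", "image_size", "telangiectasia_count", "seed"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    return SimulationConfig(**kwargs)
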