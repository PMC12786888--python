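"""Photograph + four ROI masks -> per-zone features and whole-face scores.

Whole-face aggregation is the fixed weighted sum
``0.35*left_cheek + 0.35*right_cheek + 0.15*nose + 0.15*chin`` applied
independently to contrast and homogeneity.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from erytex.glcm import EmptyROIError, TextureFeatures, compute_glcm, texture_features

logger = logging.getLogger(__name__)

#: Zone order everywhere: left cheek, right cheek, nose, chin.
ZONES = ("left_cheek", "right_cheek", "nose", "chin")

#: Whole-face aggregation weights, summing to 1.
DEFAULT_WEIGHTS = {"left_cheek": 0.35, "right_cheek": 0.35, "nose": 0.15, "chin": 0.15}

#: Ordered study timepoints: baseline, 4 weeks post-treatment, 3 months post-treatment.
TIMEPOINTS = ("T0", "T1", "T2")

#: Manifest columns naming each zone's mask file.
MASK_COLUMNS = {
    "left_cheek": "mask_lc",
    "right_cheek": "mask_rc",
    "nose": "mask_nose",
    "chin": "mask_chin",
}


@dataclass(frozen=True)
class FaceFeatureRecord:
    subject_id: str
    timepoint: str
    per_zone: dict  # zone -> TextureFeatures
    per_zone_pairs: dict  # zone -> n_pairs
    face_contrast: float
    face_homogeneity: float


def validate_weights(weights: Mapping[str, float]) -> dict:
    w = {z: float(weights[z]) for z in ZONES}
    if abs(sum(w.values()) - 1.0) > 1e-9:
        raise ValueError(f"zone weights must sum to 1, got {sum(w.values())!r}")
    return w


def validate_timepoint(label: str) -> str:
    if label not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {label!r}; expected one of {TIMEPOINTS}")
    return label


def to_grey(rgb_image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit grey via 0.299 R + 0.587 G + 0.114 B.

    Rounds half-up to the nearest integer and clamps to [0, 255].  A 2-D
    input is already greyscale and passes through unchanged.
    """
    arr = np.asarray(rgb_image)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit channels, got dtype {arr.dtype}")
    lum = 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    return np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)


def load_grey_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF as an 8-bit grey array (RGB inputs are converted)."""
    with Image.open(path) as im:
        if im.mode == "L":
            return np.asarray(im, dtype=np.uint8)
        if im.mode == "RGB":
            return to_grey(np.asarray(im, dtype=np.uint8))
        if im.mode == "RGBA":
            return to_grey(np.asarray(im.convert("RGB"), dtype=np.uint8))
        raise ValueError(f"unsupported image mode {im.mode!r} in {path} (need 8-bit grey or RGB)")


def load_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG mask; nonzero pixels are inside the ROI."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr > 0


def extract_zone_features(
    image: np.ndarray,
    masks: Mapping[str, np.ndarray],
    d: int = 1,
    angle: float = 0.0,
    *,
    subject: str = "?",
    timepoint: str = "?",
) -> tuple[dict, dict]:
    """Per-zone (contrast, homogeneity) via the GLCM core.

    Returns ``(features, n_pairs)``, each keyed by zone.  A missing zone or an
    ROI with no valid pixel pair raises, naming subject, timepoint and zone.
    """
    missing = [z for z in ZONES if z not in masks]
    if missing:
        raise ValueError(
            f"subject {subject}, timepoint {timepoint}: missing zone masks {missing}"
        )
    features: dict[str, TextureFeatures] = {}
    n_pairs: dict[str, int] = {}
    for zone in ZONES:
        try:
            glcm = compute_glcm(image, masks[zone], d=d, angle=angle, zone=zone)
        except EmptyROIError as err:
            raise EmptyROIError(zone) from err
        features[zone] = texture_features(glcm)
        n_pairs[zone] = glcm.total_pairs
    return features, n_pairs


def aggregate_face(
    per_zone: Mapping[str, TextureFeatures],
    weights: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Weighted whole-face (contrast, homogeneity)."""
    w = validate_weights(weights if weights is not None else DEFAULT_WEIGHTS)
    missing = [z for z in ZONES if z not in per_zone]
    if missing:
        raise ValueError(f"missing zones for face aggregation: {missing}")
    face_contrast = sum(w[z] * per_zone[z].contrast for z in ZONES)
    face_homogeneity = sum(w[z] * per_zone[z].homogeneity for z in ZONES)
    return float(face_contrast), float(face_homogeneity)


def process_record(
    subject: str,
    timepoint: str,
    image_path: str | Path,
    mask_paths: Mapping[str, str | Path],
    weights: Mapping[str, float] | None = None,
    d: int = 1,
    angle: float = 0.0,
) -> FaceFeatureRecord:
    """One subject x timepoint: load, extract, aggregate."""
    validate_timepoint(timepoint)
    image = load_grey_image(image_path)
    masks = {z: load_mask(mask_paths[z]) for z in ZONES}
    features, n_pairs = extract_zone_features(
        image, masks, d=d, angle=angle, subject=subject, timepoint=timepoint
    )
    face_contrast, face_homogeneity = aggregate_face(features, weights)
    return FaceFeatureRecord(
        subject_id=str(subject),
        timepoint=timepoint,
        per_zone=features,
        per_zone_pairs=n_pairs,
        face_contrast=face_contrast,
        face_homogeneity=face_homogeneity,
    )


def _record_to_row(rec: FaceFeatureRecord) -> dict:
    row = {"subject": rec.subject_id, "timepoint": rec.timepoint}
    for zone in ZONES:
        feats = rec.per_zone[zone]
        row[f"contrast_{zone}"] = feats.contrast
        row[f"homogeneity_{zone}"] = feats.homogeneity
        row[f"n_pairs_{zone}"] = rec.per_zone_pairs[zone]
    row["face_contrast"] = rec.face_contrast
    row["face_homogeneity"] = rec.face_homogeneity
    return row


def run_batch(
    manifest: pd.DataFrame | str | Path,
    weights: Mapping[str, float] | None = None,
    d: int = 1,
    angle: float = 0.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Process every manifest row; failures are logged, the run continues.

    The manifest needs columns ``subject, timepoint, image_path, mask_lc,
    mask_rc, mask_nose, mask_chin``.  Returns the feature table, ordered by
    (subject, timepoint), plus a list of per-row error records.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, dtype={"subject": str})
    required = {"subject", "timepoint", "image_path"} | set(MASK_COLUMNS.values())
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest is missing columns {sorted(missing_cols)}")
    if manifest.empty:
        logger.warning("empty manifest: no rows to process")

    rows, errors = [], []
    for _, mrow in manifest.iterrows():
        subject, timepoint = str(mrow["subject"]), str(mrow["timepoint"])
        try:
            rec = process_record(
                subject,
                timepoint,
                mrow["image_path"],
                {z: mrow[col] for z, col in MASK_COLUMNS.items()},
                weights=weights,
                d=d,
                angle=angle,
            )
            rows.append(_record_to_row(rec))
        except Exception as err:  # per-row failure must not kill the batch
            logger.error("row (%s, %s) failed: %s", subject, timepoint, err)
            errors.append({"subject": subject, "timepoint": timepoint, "error": str(err)})

    columns = (
        ["subject", "timepoint"]
        + [f"{feat}_{zone}" for zone in ZONES for feat in ("contrast", "homogeneity", "n_pairs")]
        + ["face_contrast", "face_homogeneity"]
    )
    table = pd.DataFrame(rows, columns=columns)
    order = {t: k for k, t in enumerate(TIMEPOINTS)}
    table = table.sort_values(
        ["subject", "timepoint"], key=lambda s: s.map(order) if s.name == "timepoint" else s
    ).reset_index(drop=True)
    return table, errors


def write_features(
    table: pd.DataFrame,
    out_path: str | Path,
    config: dict | None = None,
) -> None:
    """Write the feature table as CSV plus a JSON sidecar with the run config."""
    out_path = Path(out_path)
    table.to_csv(out_path, index=False)
    sidecar = {"software": "erytex", "version": "0.1.0", "config": config or {}}
    out_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
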