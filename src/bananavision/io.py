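"""File formats and run configuration.

Interchange formats: 16-bit single-channel PNG for depth (value = sensor
units, millimeters under the default 0.001 depth scale), YOLO text files
for boxes (``class cx cy w h [conf]``, normalized to [0, 1]), and a single
JSON/YAML calibration document holding depth intrinsics, color intrinsics,
stereo baseline and the depth->color extrinsic [R|T].  Result files embed
the seed and a hash of the effective configuration so identical runs are
byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from PIL import Image

from . import __version__
from .geometry import CameraIntrinsics, DepthFrame, RigidTransform, StereoRig
from .localizer import BoundingBox, LocalizationResult, LocalizerConfig

__all__ = [
    "FormatError",
    "read_depth_png",
    "write_depth_png",
    "read_yolo_boxes",
    "write_yolo_boxes",
    "load_calibration",
    "save_calibration",
    "load_localizer_config",
    "config_hash",
    "write_results",
    "results_to_rows",
    "get_logger",
]

log = logging.getLogger("bananavision")


def get_logger() -> logging.Logger:
    return log


class FormatError(ValueError):
    """Input file does not match the expected format."""


# ---------------------------------------------------------------------------
# Depth PNG
# ---------------------------------------------------------------------------


def read_depth_png(path: str | Path, depth_scale: float = 0.001) -> DepthFrame:
    """Load a 16-bit single-channel PNG as a depth frame (values preserved).

    Raises :class:`FormatError` for 8-bit or multi-channel images.
    """
    img = Image.open(path)
    if img.mode not in ("I;16", "I;16B", "I"):
        raise FormatError(
            f"{path}: expected a 16-bit single-channel PNG, got mode {img.mode!r}"
        )
    values = np.asarray(img, dtype=np.uint16 if img.mode.startswith("I;16") else np.int64)
    if values.ndim != 2:
        raise FormatError(f"{path}: expected a single channel, got shape {values.shape}")
    return DepthFrame(values=values.astype(np.uint16), depth_scale=depth_scale)


def write_depth_png(frame: DepthFrame, path: str | Path) -> None:
    """Write a depth frame as a 16-bit PNG (lossless round trip)."""
    img = Image.fromarray(frame.values.astype(np.uint16))
    img.save(path, format="PNG")


# ---------------------------------------------------------------------------
# YOLO box text files
# ---------------------------------------------------------------------------


def read_yolo_boxes(path: str | Path, frame_size: tuple[int, int]) -> list[BoundingBox]:
    """Parse a YOLO text file into pixel-space boxes.

    Lines are ``class cx cy w h`` with an optional sixth confidence field;
    normalized values are scaled by ``frame_size`` = (width, height).
    Malformed lines raise :class:`FormatError` naming the line number.
    """
    W, H = frame_size
    boxes: list[BoundingBox] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise FormatError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}")
        try:
            cls = int(fields[0])
            cx, cy, w, h = (float(v) for v in fields[1:5])
            conf = float(fields[5]) if len(fields) == 6 else 1.0
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: {e}") from e
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not (0 <= v <= 1):
                raise FormatError(
                    f"{path}:{lineno}: normalized {name}={v} outside [0, 1]"
                )
        if not (0 <= conf <= 1):
            raise FormatError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
        boxes.append(
            BoundingBox(cx=cx * W, cy=cy * H, w=w * W, h=h * H, confidence=conf, class_id=cls)
        )
    return boxes


def write_yolo_boxes(
    boxes: Sequence[BoundingBox],
    path: str | Path,
    frame_size: tuple[int, int],
    with_confidence: bool = False,
) -> None:
    W, H = frame_size
    lines = []
    for b in boxes:
        parts = [str(b.class_id)] + [
            f"{v:.6f}" for v in (b.cx / W, b.cy / H, b.w / W, b.h / H)
        ]
        if with_confidence:
            parts.append(f"{b.confidence:.6f}")
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Calibration documents
# ---------------------------------------------------------------------------


def _intrinsics_to_dict(K: CameraIntrinsics) -> dict:
    return {"fx": K.fx, "fy": K.fy, "cx": K.cx, "cy": K.cy, "width": K.width, "height": K.height}


def _intrinsics_from_dict(d: dict) -> CameraIntrinsics:
    return CameraIntrinsics(
        fx=float(d["fx"]), fy=float(d["fy"]), cx=float(d["cx"]), cy=float(d["cy"]),
        width=int(d["width"]), height=int(d["height"]),
    )


def save_calibration(calib: dict, path: str | Path) -> None:
    """Write a calibration document (JSON or YAML by extension).

    Schema: ``depth_intrinsics``/``color_intrinsics`` (fx, fy, cx, cy in
    pixels; width/height), ``stereo`` (f in pixels, baseline_m),
    ``extrinsics`` (row-major 3x3 R, 3-vector T in meters), ``depth_scale``
    (meters per depth unit).
    """
    doc = {
        "depth_intrinsics": _intrinsics_to_dict(calib["depth_intrinsics"]),
        "color_intrinsics": _intrinsics_to_dict(calib["color_intrinsics"]),
        "stereo": {"f": calib["stereo"].f, "baseline_m": calib["stereo"].B},
        "extrinsics": {
            "R": np.asarray(calib["extrinsics"].R).reshape(3, 3).tolist(),
            "T": np.asarray(calib["extrinsics"].T).reshape(3).tolist(),
        },
        "depth_scale": calib["depth_scale"],
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    else:
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_calibration(path: str | Path) -> dict:
    """Load a calibration document (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    try:
        return {
            "depth_intrinsics": _intrinsics_from_dict(doc["depth_intrinsics"]),
            "color_intrinsics": _intrinsics_from_dict(doc["color_intrinsics"]),
            "stereo": StereoRig(f=float(doc["stereo"]["f"]), B=float(doc["stereo"]["baseline_m"])),
            "extrinsics": RigidTransform(
                np.asarray(doc["extrinsics"]["R"], dtype=float),
                np.asarray(doc["extrinsics"]["T"], dtype=float),
            ),
            "depth_scale": float(doc.get("depth_scale", 0.001)),
        }
    except KeyError as e:
        raise FormatError(f"{path}: missing calibration key {e}") from e


def load_localizer_config(path: Optional[str | Path] = None, seed: Optional[int] = None) -> LocalizerConfig:
    """Localizer settings from a YAML file; missing keys keep defaults."""
    kw: dict = {}
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        allowed = set(LocalizerConfig.__dataclass_fields__)
        unknown = set(doc) - allowed
        if unknown:
            raise FormatError(f"{path}: unknown localizer keys {sorted(unknown)}")
        kw.update(doc)
    if seed is not None:
        kw["rng_seed"] = seed
    return LocalizerConfig(**kw)


# ---------------------------------------------------------------------------
# Result files
# ---------------------------------------------------------------------------


def config_hash(cfg: LocalizerConfig) -> str:
    """Stable short hash of the effective localizer configuration."""
    payload = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def results_to_rows(
    boxes: Sequence[BoundingBox], results: Sequence[LocalizationResult]
) -> list[dict]:
    rows = []
    for b, r in zip(boxes, results):
        rows.append(
            {
                "class": b.class_id,
                "confidence": round(b.confidence, 6),
                "X": None if r.point is None else round(r.point.X, 6),
                "Y": None if r.point is None else round(r.point.Y, 6),
                "Z": None if r.point is None else round(r.point.Z, 6),
                "status": r.status.value,
                "n_valid_samples": r.n_valid_samples,
            }
        )
    return rows


def write_results(
    rows: Sequence[dict],
    path: str | Path,
    cfg: LocalizerConfig,
    csv_path: Optional[str | Path] = None,
) -> None:
    """Write localization rows as JSON (and optionally CSV).

    The JSON payload embeds the seed, the config hash and the library
    version but no timestamp, so identical runs produce identical bytes.
    """
    payload = {
        "version": __version__,
        "seed": cfg.rng_seed,
        "config_hash": config_hash(cfg),
        "config": asdict(cfg),
        "n_results": len(rows),
        "results": list(rows),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        fieldnames = ["class", "confidence", "X", "Y", "Z", "status", "n_valid_samples"]
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            for row in rows:
                writer.writerow({k: row.get(k) for k in fieldnames})
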