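"""Reading laser-induced-fluorescence RGB frames and enforcing a shared ROI.

The acquisition geometry imprints a fixed brightness gradient on every frame
(the camera sits close to the laser), so two images are only comparable over
the *same* pixel rectangle: the gradient then cancels from any histogram
comparison.  This module therefore treats the region of interest as a
first-class object applied with identical coordinates to every image in a
comparison set.

Coordinates are 0-based and half-open: ``RoiRect(x0, y0, x1, y1)`` selects
columns ``x0..x1-1`` and rows ``y0..y1-1``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from PIL import Image

from .errors import ImageFormatError, RoiBoundsError, ValidationError

logger = logging.getLogger(__name__)

SESSIONS = ("am", "pm")
SIDES = ("front", "back")


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition metadata for one frame.

    ``(position, side)`` jointly index the ten frames of one imaging
    session: five tray positions shot from the front, five from the back.
    """

    trial_id: str
    day: int
    session: str
    position: int
    side: str

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValidationError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.day < 1:
            raise ValidationError(f"day must be a positive integer, got {self.day}")

    @property
    def session_key(self) -> tuple[str, int, str]:
        """(trial_id, day, session) — the unit over which summaries are formed."""
        return (self.trial_id, self.day, self.session)


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned crop rectangle, 0-based, half-open upper bounds."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (0 <= self.x0 < self.x1 and 0 <= self.y0 < self.y1):
            raise ValidationError(
                f"ROI must satisfy 0 <= x0 < x1 and 0 <= y0 < y1, got {self}"
            )

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit RGB frame with its acquisition metadata.

    ``pixels`` has shape (height, width, 3), dtype uint8; values are raw
    decimal code values 0–255 and are never rescaled by this package.
    """

    pixels: np.ndarray
    meta: ImageMeta

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ImageFormatError(f"pixels must have shape (H, W, 3), got {p.shape}")
        if p.dtype != np.uint8:
            raise ImageFormatError(f"pixels must be uint8 decimal code values, got {p.dtype}")
        if p.shape[0] < 1 or p.shape[1] < 1:
            raise ImageFormatError("image must contain at least one pixel")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    def full_roi(self) -> RoiRect:
        return RoiRect(0, 0, self.width, self.height)


def read_image(path: str | os.PathLike, meta: ImageMeta) -> RgbImage:
    """Read an 8-bit RGB PNG or TIFF into an :class:`RgbImage`.

    An alpha channel, if present, is dropped with a logged warning (the
    analysis uses only R, G and B).  Higher bit depths and non-3-channel
    rasters are rejected with :class:`ImageFormatError`.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"image file not found: {path}")
    with Image.open(path) as im:
        mode = im.mode
        if mode == "RGBA":
            logger.warning("%s: dropping alpha channel", path)
            im = im.convert("RGB")
        elif mode != "RGB":
            raise ImageFormatError(
                f"{path}: expected an 8-bit 3-channel RGB raster, got mode {mode!r}"
            )
        arr = np.asarray(im)
    if arr.dtype != np.uint8:  # pragma: no cover - PIL RGB decodes to uint8
        raise ImageFormatError(f"{path}: bit depth exceeds 8 bits per channel ({arr.dtype})")
    return RgbImage(pixels=arr, meta=meta)


def crop_roi(image: RgbImage, roi: RoiRect) -> RgbImage:
    """Crop ``image`` to ``roi``; pixel values and metadata are unchanged."""
    if roi.x1 > image.width or roi.y1 > image.height:
        raise RoiBoundsError(
            f"ROI {roi} exceeds image bounds "
            f"RoiRect(x0=0, y0=0, x1={image.width}, y1={image.height})"
        )
    sub = image.pixels[roi.y0 : roi.y1, roi.x0 : roi.x1, :]
    return replace(image, pixels=np.ascontiguousarray(sub))


# ---------------------------------------------------------------------------
# Batch input: manifest CSV or organized directory layout
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["path", "trial_id", "day", "session", "position", "side"]


def load_manifest(manifest_path: str | os.PathLike) -> list[tuple[Path, ImageMeta]]:
    """Read a manifest CSV mapping image files to acquisition metadata.

    Relative paths are resolved against the manifest's own directory.
    Malformed rows raise :class:`ValidationError` naming the offending row.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {manifest_path} lacks columns {missing}")
    entries: list[tuple[Path, ImageMeta]] = []
    for idx, row in df.iterrows():
        try:
            meta = ImageMeta(
                trial_id=str(row["trial_id"]),
                day=int(row["day"]),
                session=str(row["session"]),
                position=int(row["position"]),
                side=str(row["side"]),
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(
                f"manifest {manifest_path} row {idx} ({row['path']}): {exc}"
            ) from exc
        p = Path(str(row["path"]))
        if not p.is_absolute():
            p = manifest_path.parent / p
        entries.append((p, meta))
    return entries


def discover_layout(root: str | os.PathLike) -> list[tuple[Path, ImageMeta]]:
    """Walk ``<root>/<trial_id>/day<D>/<session>/<position>_<side>.<ext>``.

    Only ``.png``/``.tif``/``.tiff`` files matching the naming convention are
    returned; anything else is ignored with a debug log line.
    """
    root = Path(root)
    entries: list[tuple[Path, ImageMeta]] = []
    for trial_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for day_dir in sorted(p for p in trial_dir.iterdir() if p.is_dir()):
            if not day_dir.name.startswith("day"):
                continue
            try:
                day = int(day_dir.name[3:])
            except ValueError:
                logger.debug("skipping non-day directory %s", day_dir)
                continue
            for sess_dir in sorted(p for p in day_dir.iterdir() if p.is_dir()):
                if sess_dir.name not in SESSIONS:
                    continue
                for f in sorted(sess_dir.iterdir()):
                    if f.suffix.lower() not in (".png", ".tif", ".tiff"):
                        continue
                    stem = f.stem
                    try:
                        pos_s, side = stem.split("_", 1)
                        meta = ImageMeta(
                            trial_id=trial_dir.name,
                            day=day,
                            session=sess_dir.name,
                            position=int(pos_s),
                            side=side,
                        )
                    except (ValueError, ValidationError):
                        logger.debug("skipping unrecognized file name %s", f)
                        continue
                    entries.append((f, meta))
    return entries


def iter_images(
    entries: list[tuple[Path, ImageMeta]], roi: RoiRect | None = None
) -> Iterator[RgbImage]:
    """Read and (optionally) crop every manifest entry, in manifest order."""
    for path, meta in entries:
        img = read_image(path, meta)
        if roi is not None:
            img = crop_roi(img, roi)
        yield img
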