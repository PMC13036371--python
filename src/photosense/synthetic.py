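"""Synthetic dermoscopy-like images and study metadata.

Generates small RGB images that mimic the photometric structure of
dermoscopic lesion photographs — a smooth skin-tone background, one
elliptical pigmented blob with a radial color gradient, and optional dark
hair strokes — together with a metadata table in the standard dermoscopy
archive schema (lesion_id, image_id, dx, dx_type, age, sex, localization).

The generator exists so the whole audit toolkit can be exercised without
any real dataset or trained network: images have controllable brightness,
saturation, hue and texture statistics with realistic magnitudes, and
melanoma-labelled lesions are drawn darker and more variegated.  It does
not emulate dermoscopy optics, calibration charts, or diagnostic
morphology; labels are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ImageRecord",
    "SyntheticDatasetSpec",
    "generate_synthetic_dataset",
    "read_metadata",
    "write_metadata",
    "load_images",
    "save_images",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("lesion_id", "image_id", "dx", "dx_type", "age", "sex", "localization")

#: Diagnosis codes of the 7-class dermoscopy archive vocabulary.
DX_CODES = ("akiec", "bcc", "bkl", "df", "mel", "nv", "vasc")
DX_TYPES = ("histo", "follow_up", "consensus", "confocal")
SEXES = ("male", "female")
LOCALIZATIONS = (
    "back", "lower extremity", "trunk", "upper extremity", "abdomen",
    "face", "chest", "foot", "neck", "scalp",
)
_BENIGN_DX = ("nv", "bkl", "bcc", "akiec", "df", "vasc")


@dataclass
class ImageRecord:
    """One study image: uint8 RGB pixels plus archive metadata."""

    image: np.ndarray
    lesion_id: str
    image_id: str
    dx: str
    dx_type: str
    age: float
    sex: str
    localization: str

    @property
    def label(self) -> int:
        """Binary target: 1 for melanoma (dx == 'mel'), 0 otherwise."""
        return 1 if self.dx == "mel" else 0


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of the synthetic dermoscopy generator.

    ``hue_center`` is the lesion hue on the normalized hue circle (skin and
    pigment live in the red-orange arc); ``brightness_base`` the background
    value-channel level in [0, 1].  Melanoma-labelled lesions get darker
    cores and more color variegation.
    """

    n_images: int = 8
    image_side: int = 128
    melanoma_fraction: float = 0.3
    seed: int = 2021
    hue_center: float = 0.055
    hue_spread: float = 0.012
    brightness_base: float = 0.72
    blob_eccentricity: tuple[float, float] = (0.6, 0.95)
    hair_strokes: tuple[int, int] = (0, 4)

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError(f"n_images must be >= 1, got {self.n_images}")
        if not (0.0 <= self.melanoma_fraction <= 1.0):
            raise ValueError(
                f"melanoma_fraction must be in [0, 1], got {self.melanoma_fraction}"
            )
        if self.image_side < 16:
            raise ValueError(f"image_side must be >= 16, got {self.image_side}")


def _hsv_to_rgb_float(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorized float HSV -> RGB on [0, 1] (generator internal)."""
    h6 = (h % 1.0) * 6.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def _render_image(spec: SyntheticDatasetSpec, rng: np.random.Generator, melanoma: bool) -> np.ndarray:
    side = spec.image_side
    yy, xx = np.mgrid[0:side, 0:side].astype(float) / (side - 1)

    # smooth skin background: base value with a random linear illumination ramp
    gx, gy = rng.uniform(-0.08, 0.08, size=2)
    v_bg = spec.brightness_base + gx * (xx - 0.5) + gy * (yy - 0.5)
    s_bg = rng.uniform(0.22, 0.30) * np.ones_like(v_bg)
    h_bg = spec.hue_center + rng.normal(0.0, spec.hue_spread / 2)

    # elliptical pigmented blob with a soft edge and radial darkening
    cx, cy = rng.uniform(0.35, 0.65, size=2)
    major = rng.uniform(0.18, 0.30)
    ecc = rng.uniform(*spec.blob_eccentricity)
    minor = major * ecc
    theta = rng.uniform(0, np.pi)
    dx = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    dy = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    r = np.sqrt((dx / major) ** 2 + (dy / minor) ** 2)
    mask = 1.0 / (1.0 + np.exp((r - 1.0) / 0.08))  # soft lesion boundary

    core_v = rng.uniform(0.18, 0.30) if melanoma else rng.uniform(0.34, 0.46)
    edge_v = core_v + rng.uniform(0.12, 0.2)
    v_blob = core_v + (edge_v - core_v) * np.clip(r, 0, 1)
    s_blob = (rng.uniform(0.5, 0.65) if melanoma else rng.uniform(0.38, 0.5)) * np.ones_like(v_bg)
    h_blob = h_bg + rng.normal(0.0, spec.hue_spread)

    # variegation: low-frequency mottling, stronger for melanoma
    n_waves = 3 if melanoma else 1
    texture = np.zeros_like(v_bg)
    for _ in range(n_waves):
        fx, fy = rng.uniform(2, 6, size=2)
        ph = rng.uniform(0, 2 * np.pi)
        texture += np.sin(2 * np.pi * (fx * xx + fy * yy) + ph)
    texture *= (0.05 if melanoma else 0.02)

    v = v_bg * (1 - mask) + (v_blob + texture) * mask
    s = s_bg * (1 - mask) + s_blob * mask
    h = np.full_like(v_bg, h_bg) * (1 - mask) + (h_blob + (texture if melanoma else 0)) * mask

    rgb = _hsv_to_rgb_float(h, np.clip(s, 0, 1), np.clip(v, 0.02, 1))

    # dark hair strokes: thin straight segments
    n_hairs = rng.integers(spec.hair_strokes[0], spec.hair_strokes[1] + 1)
    for _ in range(n_hairs):
        x0, y0 = rng.uniform(0, 1, size=2)
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.4, 0.9)
        tt = np.linspace(0, length, side * 2)
        hx = np.clip(((x0 + tt * np.cos(ang)) * (side - 1)).astype(int), 0, side - 1)
        hy = np.clip(((y0 + tt * np.sin(ang)) * (side - 1)).astype(int), 0, side - 1)
        rgb[hy, hx] *= rng.uniform(0.25, 0.45)

    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def generate_synthetic_dataset(
    spec: SyntheticDatasetSpec | None = None,
) -> tuple[list[ImageRecord], pd.DataFrame]:
    """Generate a deterministic synthetic dataset and its metadata table.

    The melanoma count is exactly ``round(n_images * melanoma_fraction)``;
    labels are shuffled among images by the seeded generator.  The same
    spec always yields byte-identical images and an identical table.
    """
    spec = spec or SyntheticDatasetSpec()
    rng = np.random.default_rng(spec.seed)
    n_mel = int(round(spec.n_images * spec.melanoma_fraction))
    labels = np.array([1] * n_mel + [0] * (spec.n_images - n_mel))
    rng.shuffle(labels)

    records: list[ImageRecord] = []
    for i, lab in enumerate(labels):
        img = _render_image(spec, rng, melanoma=bool(lab))
        dx = "mel" if lab else str(rng.choice(_BENIGN_DX, p=[0.6, 0.15, 0.1, 0.06, 0.05, 0.04]))
        records.append(
            ImageRecord(
                image=img,
                lesion_id=f"SYN_L{i:05d}",
                image_id=f"SYN_I{i:05d}",
                dx=dx,
                dx_type=str(rng.choice(DX_TYPES, p=[0.55, 0.25, 0.15, 0.05])),
                age=float(rng.choice(np.arange(20, 90, 5))),
                sex=str(rng.choice(SEXES)),
                localization=str(rng.choice(LOCALIZATIONS)),
            )
        )
    return records, records_to_frame(records)


def records_to_frame(records: Sequence[ImageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{col: getattr(r, col) for col in METADATA_COLUMNS} for r in records],
        columns=list(METADATA_COLUMNS),
    )


def write_metadata(records_or_frame, path: str | Path) -> None:
    """Write the 7-column metadata CSV."""
    frame = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else records_to_frame(records_or_frame)
    )
    missing = set(METADATA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"metadata frame missing required columns: {sorted(missing)}")
    frame[list(METADATA_COLUMNS)].to_csv(path, index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a metadata CSV in the archive schema, adding a binary ``label`` column.

    Unknown dx codes are preserved verbatim (label 0).  Missing required
    columns raise a schema error.
    """
    frame = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"metadata file {path} missing required columns: {sorted(missing)}")
    frame = frame[list(METADATA_COLUMNS)].copy()
    frame["label"] = (frame["dx"] == "mel").astype(int)
    return frame


def save_images(records: Sequence[ImageRecord], directory: str | Path) -> None:
    """Dump each record's pixels as ``<image_id>.png``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for r in records:
        Image.fromarray(r.image, mode="RGB").save(directory / f"{r.image_id}.png")


def load_images(directory: str | Path, metadata: pd.DataFrame) -> list[ImageRecord]:
    """Load ``<image_id>.png``/``.jpg`` files for every metadata row."""
    directory = Path(directory)
    records = []
    for row in metadata.itertuples(index=False):
        path = None
        for ext in (".png", ".jpg", ".jpeg"):
            cand = directory / f"{row.image_id}{ext}"
            if cand.exists():
                path = cand
                break
        if path is None:
            raise FileNotFoundError(f"no image file for image_id {row.image_id!r} in {directory}")
        img = np.asarray(Image.open(path).convert("RGB"))
        records.append(
            ImageRecord(
                image=img,
                lesion_id=str(row.lesion_id),
                image_id=str(row.image_id),
                dx=str(row.dx),
                dx_type=str(row.dx_type),
                age=float(row.age),
                sex=str(row.sex),
                localization=str(row.localization),
            )
        )
    return records
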