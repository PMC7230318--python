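"""I/O and geometry for en-face OCTA angiograms of the optic nerve head.

Images are single-channel TIFF/PNG exports of the device's per-plexus
en-face reconstructions (radial peripapillary capillaries RPC, superficial
SCP, deep DCP, choriocapillaris CC), centered on the optic disc.  A CSV
manifest carries per-image metadata; per-eye clinical values (RNFL
thickness, visual-field defect flags) travel in :class:`EyeRecord`.

Quadrants follow the clinical RNFL convention: the two ±45° diagonals
through the disc center split the image into superior (S), inferior (I),
nasal (N) and temporal (T) 90° sectors.  Which lateral sector is nasal
depends on eye laterality (OD: nasal is image-right; OS: image-left) and
can be overridden per manifest because vendor export orientations differ.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("octaquant")

PLEXUSES = ("RPC", "SCP", "DCP", "CC")
VT_PLEXUSES = ("RPC", "SCP", "DCP")  # the device's CC export has no usable VT
QUADRANT_PLEXUSES = ("RPC", "SCP")  # quadrant sub-analysis layers
QUADRANTS = ("S", "I", "N", "T")
GROUPS = ("AAION", "NAION", "CONTRA_AAION", "CONTRA_NAION", "CONTROL")
LATERALITIES = ("OD", "OS")

DEFAULT_QUALITY_MIN = 70


class ValidationError(ValueError):
    """Raised when inputs violate a documented contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AngioImage:
    """One en-face angiogram plus its geometry and clinical metadata.

    ``pixels`` are intensities normalized to [0, 1] (integer inputs are
    divided by their dtype maximum so the mean threshold keeps a common
    meaning across a cohort).  ``disc_center`` is a 0-based (row, col)
    pixel coordinate supplied by the operator.
    """

    pixels: np.ndarray
    scan_size_mm: float
    plexus: str
    laterality: str
    disc_center: tuple[int, int]
    quality_index: int
    patient_id: str
    group: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("pixels must be a non-empty 2-D array")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValidationError("pixel intensities must lie in [0, 1]")
        if self.plexus not in PLEXUSES:
            raise ValidationError(f"unknown plexus {self.plexus!r}")
        if self.laterality not in LATERALITIES:
            raise ValidationError(f"unknown laterality {self.laterality!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        r, c = self.disc_center
        h, w = self.pixels.shape
        if not (0 <= r < h and 0 <= c < w):
            raise ValidationError(
                f"disc_center {self.disc_center} outside {self.pixels.shape} grid"
            )
        if not 0 <= self.quality_index <= 100:
            raise ValidationError("quality_index must be in [0, 100]")

    @property
    def mm_per_px(self) -> float:
        return self.scan_size_mm / self.pixels.shape[0]


@dataclass
class QuadrantSet:
    """Four disjoint 90° sector masks about the disc center.

    ``masks`` maps quadrant label (S/I/N/T) to a boolean grid congruent
    with the source image; together the masks tile the grid.
    """

    masks: dict[str, np.ndarray]
    laterality: str
    nasal_side: str  # "left" or "right" in image coordinates

    def __post_init__(self) -> None:
        if set(self.masks) != set(QUADRANTS):
            raise ValidationError("masks must have exactly the keys S, I, N, T")
        total = sum(int(m.sum()) for m in self.masks.values())
        shape = next(iter(self.masks.values())).shape
        if total != int(np.prod(shape)):
            raise ValidationError("quadrant masks must partition the grid")


@dataclass
class EyeRecord:
    """Per-eye analysis row: clinical values plus computed VD/VT metrics.

    ``vf_defect`` flags live in visual-field space (Humphrey quadrants);
    use :func:`map_vf_defects_to_retinal_quadrants` before comparing them
    with retinal-quadrant impairment flags.
    """

    patient_id: str
    group: str
    laterality: str
    quality_index: int
    bcva_logmar: float = 0.0
    rnfl_um: dict[str, float] = field(default_factory=dict)  # S/I/N/T + "global"
    vf_defect: dict[str, bool] = field(default_factory=dict)
    vd: dict[str, float] = field(default_factory=dict)  # plexus -> [0,1]
    vt: dict[str, float] = field(default_factory=dict)  # plexus -> >= 1 scale-free
    quadrant_vd: dict[tuple[str, str], float] = field(default_factory=dict)
    quadrant_vt: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.vf_defect and set(self.vf_defect) != set(QUADRANTS):
            raise ValidationError("vf_defect must flag exactly 4 quadrants")
        for p, v in self.vd.items():
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"vd[{p}]={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# Manifest loading
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = (
    "path", "patient_id", "group", "laterality", "plexus",
    "scan_mm", "disc_row", "disc_col", "quality_index",
)


def read_image(path: Path) -> np.ndarray:
    """Read a single-channel 8/16-bit image, rescaled to [0, 1] by dtype max."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:  # tolerate grayscale saved with redundant channels
        raw = raw[..., 0]
    if np.issubdtype(raw.dtype, np.integer):
        return raw.astype(float) / float(np.iinfo(raw.dtype).max)
    arr = raw.astype(float)
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValidationError(f"float image {path} not in [0, 1]")
    return arr


def load_manifest(manifest_path: Path, image_root: Path | None = None) -> list[AngioImage]:
    """Load every valid manifest row as an :class:`AngioImage`.

    Rows that fail validation (missing file, unknown token, disc center
    outside the image) are rejected individually with an itemized log
    message; remaining rows load in manifest order.  An empty manifest is
    an error.
    """
    manifest_path = Path(manifest_path)
    root = Path(image_root) if image_root is not None else manifest_path.parent
    with open(manifest_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValidationError(f"manifest {manifest_path} has no data rows")
    missing = set(MANIFEST_COLUMNS) - set(rows[0])
    if missing:
        raise ValidationError(f"manifest missing columns: {sorted(missing)}")

    images: list[AngioImage] = []
    n_bad = 0
    for i, row in enumerate(rows):
        try:
            img_path = root / row["path"]
            if not img_path.exists():
                raise ValidationError(f"image file not found: {img_path}")
            pixels = read_image(img_path)
            images.append(
                AngioImage(
                    pixels=pixels,
                    scan_size_mm=float(row["scan_mm"]),
                    plexus=row["plexus"],
                    laterality=row["laterality"],
                    disc_center=(int(row["disc_row"]), int(row["disc_col"])),
                    quality_index=int(row["quality_index"]),
                    patient_id=row["patient_id"],
                    group=row["group"],
                )
            )
        except (ValidationError, ValueError, KeyError) as exc:
            n_bad += 1
            logger.warning("manifest row %d rejected: %s", i + 1, exc)
    logger.info("loaded %d images, rejected %d rows", len(images), n_bad)
    return images


def apply_quality_filter(records: Sequence, min_quality: int = DEFAULT_QUALITY_MIN) -> list:
    """Keep records whose Topcon-style quality index is >= ``min_quality``.

    Works on anything carrying ``quality_index`` (AngioImage or EyeRecord);
    order-preserving and idempotent.  The excluded count is logged.
    """
    kept = [r for r in records if r.quality_index >= min_quality]
    logger.info(
        "quality filter (>= %d): kept %d, excluded %d",
        min_quality, len(kept), len(records) - len(kept),
    )
    return kept


# ---------------------------------------------------------------------------
# Quadrant geometry
# ---------------------------------------------------------------------------

def default_nasal_side(laterality: str) -> str:
    """In upright en-face fundus orientation the nasal retina of a right
    eye (OD) lies on the image-right side, of a left eye (OS) on the left."""
    if laterality not in LATERALITIES:
        raise ValidationError(f"unknown laterality {laterality!r}")
    return "right" if laterality == "OD" else "left"


def quadrant_masks(
    shape: tuple[int, int],
    disc_center: tuple[int, int],
    laterality: str,
    nasal_side_override: str | None = None,
) -> QuadrantSet:
    """Partition the grid into S/I/N/T sectors by the ±45° diagonals.

    A pixel exactly on a diagonal goes to the vertical sector (S or I),
    which keeps the partition deterministic.  The disc-center pixel itself
    counts as superior.
    """
    h, w = shape
    r0, c0 = disc_center
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValidationError(f"disc_center {disc_center} outside grid {shape}")
    if nasal_side_override is not None and nasal_side_override not in ("left", "right"):
        raise ValidationError("nasal_side_override must be 'left' or 'right'")
    nasal = nasal_side_override or default_nasal_side(laterality)

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr = rr - r0  # image rows grow downward
    dc = cc - c0
    vertical = np.abs(dr) >= np.abs(dc)  # ties -> vertical sector
    s_mask = vertical & (dr <= 0)
    i_mask = vertical & (dr > 0)
    right = ~vertical & (dc > 0)
    left = ~vertical & (dc < 0)
    n_mask, t_mask = (right, left) if nasal == "right" else (left, right)
    return QuadrantSet(
        masks={"S": s_mask, "I": i_mask, "N": n_mask, "T": t_mask},
        laterality=laterality,
        nasal_side=nasal,
    )


def disc_exclusion_mask(
    shape: tuple[int, int],
    disc_center: tuple[int, int],
    radius_mm: float,
    scan_size_mm: float,
) -> np.ndarray:
    """Boolean mask of pixels *outside* a disc-centered circle.

    Optionally removes the optic-disc area from VD/VT computation; the
    default pipeline leaves it off (radius 0 -> all-true mask).
    """
    h, w = shape
    if radius_mm <= 0:
        return np.ones(shape, dtype=bool)
    radius_px = radius_mm * h / scan_size_mm
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    d2 = (rr - disc_center[0]) ** 2 + (cc - disc_center[1]) ** 2
    return d2 > radius_px**2


# ---------------------------------------------------------------------------
# Visual field <-> retina mapping
# ---------------------------------------------------------------------------

def map_vf_defects_to_retinal_quadrants(
    vf_defect: Mapping[str, bool], laterality: str = "OD"
) -> dict[str, bool]:
    """Map visual-field quadrant flags to the retinal quadrants they image.

    Optics invert the retinal projection vertically (superior field is
    seen by inferior retina) and horizontally (temporal field by nasal
    retina).  With quadrants named anatomically (nasal/temporal) the map
    is the same for both eyes, and it is an involution.
    """
    if set(vf_defect) != set(QUADRANTS):
        raise ValidationError("vf_defect must have exactly the keys S, I, N, T")
    if laterality not in LATERALITIES:
        raise ValidationError(f"unknown laterality {laterality!r}")
    return {
        "S": bool(vf_defect["I"]),
        "I": bool(vf_defect["S"]),
        "N": bool(vf_defect["T"]),
        "T": bool(vf_defect["N"]),
    }


# ---------------------------------------------------------------------------
# Metrics table round-trip
# ---------------------------------------------------------------------------

def _flatten(record: EyeRecord) -> dict:
    row: dict = {
        "patient_id": record.patient_id,
        "group": record.group,
        "laterality": record.laterality,
        "quality_index": record.quality_index,
        "bcva_logmar": record.bcva_logmar,
    }
    for q in QUADRANTS:
        row[f"rnfl_{q}"] = record.rnfl_um.get(q, math.nan)
    row["rnfl_global"] = record.rnfl_um.get("global", math.nan)
    for q in QUADRANTS:
        row[f"vf_{q}"] = int(bool(record.vf_defect.get(q, False)))
    for p in PLEXUSES:
        row[f"vd_{p}"] = record.vd.get(p, math.nan)
    for p in VT_PLEXUSES:
        row[f"vt_{p}"] = record.vt.get(p, math.nan)
    for p in QUADRANT_PLEXUSES:
        for q in QUADRANTS:
            row[f"vd_{p}_{q}"] = record.quadrant_vd.get((p, q), math.nan)
            row[f"vt_{p}_{q}"] = record.quadrant_vt.get((p, q), math.nan)
    return row


def _unflatten(row: Mapping) -> EyeRecord:
    def _f(key):
        v = float(row[key])
        return v

    rnfl = {q: _f(f"rnfl_{q}") for q in QUADRANTS}
    rnfl["global"] = _f("rnfl_global")
    return EyeRecord(
        patient_id=str(row["patient_id"]),
        group=str(row["group"]),
        laterality=str(row["laterality"]),
        quality_index=int(row["quality_index"]),
        bcva_logmar=_f("bcva_logmar"),
        rnfl_um=rnfl,
        vf_defect={q: bool(int(row[f"vf_{q}"])) for q in QUADRANTS},
        vd={p: _f(f"vd_{p}") for p in PLEXUSES},
        vt={p: _f(f"vt_{p}") for p in VT_PLEXUSES},
        quadrant_vd={
            (p, q): _f(f"vd_{p}_{q}") for p in QUADRANT_PLEXUSES for q in QUADRANTS
        },
        quadrant_vt={
            (p, q): _f(f"vt_{p}_{q}") for p in QUADRANT_PLEXUSES for q in QUADRANTS
        },
    )


def records_to_frame(records: Sequence[EyeRecord]) -> pd.DataFrame:
    if not records:
        raise ValidationError("no records to tabulate")
    return pd.DataFrame([_flatten(r) for r in records])


def write_metrics_table(records: Sequence[EyeRecord], path: Path) -> None:
    """Write one flattened CSV row per eye (6-decimal round-trip fidelity)."""
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.6f")


def read_metrics_table(path: Path) -> list[EyeRecord]:
    df = pd.read_csv(path)
    return [_unflatten(row) for _, row in df.iterrows()]
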