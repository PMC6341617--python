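"""Image and manifest I/O.

Fields are listed in a plate manifest CSV with header
``well_id,field_index,nuclei_path,lipid_path,rgb_path,pixel_pitch_um``;
each row is either a fluorescence field (nuclei_path + lipid_path) or an
RGB bright-field field (rgb_path), never both.  Pixel pitch always comes
from the manifest — TIFF resolution tags are ignored, because instrument
metadata is unreliable across export paths.  Supported image formats are
baseline single-channel/RGB TIFF and PNG; 16-bit data (including 12-bit
data stored in 16-bit containers) is used as-is without rescaling, since
the thresholding is relative and absolute scale is immaterial.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import (
    OPTIMAL_MAX_PITCH_UM,
    CalibrationError,
    InputError,
    ManifestError,
    PixelGrid,
    ResolutionWarning,
    RgbImage,
    TwoChannelImage,
)
from .unmix import unmix_oro_haematoxylin

MANIFEST_COLUMNS = (
    "well_id",
    "field_index",
    "nuclei_path",
    "lipid_path",
    "rgb_path",
    "pixel_pitch_um",
)


@dataclass(frozen=True)
class FieldRecord:
    """One manifest row: where a field's images live and its calibration."""

    well_id: str
    field_index: int
    pixel_pitch_um: float
    nuclei_path: Path | None = None
    lipid_path: Path | None = None
    rgb_path: Path | None = None

    def __post_init__(self) -> None:
        fluor = self.nuclei_path is not None and self.lipid_path is not None
        rgb = self.rgb_path is not None
        if fluor == rgb:
            raise ManifestError(
                f"field {self.well_id}/{self.field_index}: exactly one of "
                "(nuclei_path + lipid_path) or rgb_path must be set"
            )
        if self.field_index < 0:
            raise ManifestError("field_index must be non-negative")

    @property
    def mode(self) -> str:
        return "oro" if self.rgb_path is not None else "fluorescence"


def read_image(path: str | Path) -> np.ndarray:
    """Load a TIFF or PNG as a numpy array, preserving bit depth."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return tifffile.imread(path)
        return np.asarray(iio.imread(path))
    except InputError:
        raise
    except Exception as exc:  # decode failure
        raise InputError(f"could not decode image {path}: {exc}") from exc


def write_image(path: str | Path, values: np.ndarray) -> None:
    """Write an array as TIFF or PNG, losslessly."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, values)
    else:
        iio.imwrite(path, values)


def _check_pitch(pitch: float) -> None:
    if pitch >= OPTIMAL_MAX_PITCH_UM:
        warnings.warn(
            f"pixel pitch {pitch} um/px is at or above the "
            f"{OPTIMAL_MAX_PITCH_UM} um/px optimum; detection of nuclei "
            "and droplets may degrade",
            ResolutionWarning,
            stacklevel=3,
        )


def read_field(record: FieldRecord) -> TwoChannelImage:
    """Read one field as a TwoChannelImage, unmixing RGB rows on the fly."""
    _check_pitch(record.pixel_pitch_um)
    if record.mode == "oro":
        arr = read_image(record.rgb_path)
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise InputError(f"{record.rgb_path} is not a 3-channel RGB image")
        return unmix_oro_haematoxylin(
            RgbImage.from_array(arr[..., :3], record.pixel_pitch_um)
        )
    nuclei = read_image(record.nuclei_path)
    lipid = read_image(record.lipid_path)
    for name, arr in (("nuclei", nuclei), ("lipid", lipid)):
        if arr.ndim != 2:
            raise InputError(f"{name} channel is not single-channel")
    if nuclei.shape != lipid.shape:
        raise CalibrationError(
            f"channel shape mismatch for {record.well_id}/{record.field_index}: "
            f"{nuclei.shape} vs {lipid.shape}"
        )
    pitch = record.pixel_pitch_um
    return TwoChannelImage(
        nuclei=PixelGrid(nuclei, pitch), lipid=PixelGrid(lipid, pitch)
    )


def read_manifest(path: str | Path) -> list[FieldRecord]:
    """Parse and validate a plate manifest CSV.

    Records come back sorted by (well_id, field_index), so shuffled input
    rows yield identical output.
    """
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in MANIFEST_COLUMNS]
    if unknown:
        raise ManifestError(
            f"unknown manifest column(s) {unknown}; accepted columns are "
            f"{list(MANIFEST_COLUMNS)}"
        )
    missing = [c for c in ("well_id", "field_index", "pixel_pitch_um") if c not in df.columns]
    if missing:
        raise ManifestError(f"manifest missing required column(s) {missing}")
    base = path.parent

    def _path(cell: str) -> Path | None:
        if not cell.strip():
            return None
        p = Path(cell)
        return p if p.is_absolute() else base / p

    records = []
    for row in df.to_dict("records"):
        try:
            field_index = int(row["field_index"])
            pitch = float(row["pixel_pitch_um"])
        except ValueError as exc:
            raise ManifestError(f"malformed manifest row {row}: {exc}") from exc
        records.append(
            FieldRecord(
                well_id=row["well_id"],
                field_index=field_index,
                pixel_pitch_um=pitch,
                nuclei_path=_path(row.get("nuclei_path", "")),
                lipid_path=_path(row.get("lipid_path", "")),
                rgb_path=_path(row.get("rgb_path", "")),
            )
        )
    keys = [(r.well_id, r.field_index) for r in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ManifestError(f"duplicate (well_id, field_index) rows: {dupes}")
    records.sort(key=lambda r: (r.well_id, r.field_index))
    return records


def write_well_csv(results, path: str | Path, per_nucleus_path=None) -> None:
    """Write per-well results (and optionally a per-nucleus long table).

    Floats are written with ``repr``, which round-trips exactly through
    ``float()``.
    """
    if not results:
        raise InputError("refusing to write an empty well table")
    path = Path(path)

    def fmt(x):
        if x is None:
            return ""
        if isinstance(x, float):
            return repr(x)
        return str(x)

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "well_id",
                "n_nuclei",
                "n_differentiated",
                "mean_lipid_score",
                "adipogenic_score",
                "gate_threshold",
                "valid",
                "partial",
            ]
        )
        for r in results:
            writer.writerow(
                [
                    r.well_id,
                    r.n_nuclei,
                    r.n_differentiated,
                    fmt(r.mean_lipid_score),
                    fmt(r.adipogenic_score),
                    fmt(r.gate_threshold),
                    r.valid,
                    r.partial,
                ]
            )
    if per_nucleus_path is not None:
        with open(Path(per_nucleus_path), "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                [
                    "well_id",
                    "nucleus_label",
                    "centroid_row",
                    "centroid_col",
                    "p_t",
                    "i_s",
                    "s",
                    "differentiated",
                ]
            )
            for r in results:
                for s in r.scores:
                    writer.writerow(
                        [
                            r.well_id,
                            s.nucleus_label,
                            fmt(float(s.centroid[0])),
                            fmt(float(s.centroid[1])),
                            fmt(s.p_t),
                            fmt(s.i_s),
                            fmt(s.s),
                            s.differentiated,
                        ]
                    )


def write_summary_json(results, exclusions, path: str | Path) -> None:
    """JSON summary mirroring the per-well CSV plus exclusion accounting."""
    payload = {
        "wells": [
            {
                "well_id": r.well_id,
                "n_nuclei": r.n_nuclei,
                "n_differentiated": r.n_differentiated,
                "mean_lipid_score": r.mean_lipid_score,
                "adipogenic_score": r.adipogenic_score,
                "gate_threshold": r.gate_threshold,
                "valid": r.valid,
                "partial": r.partial,
            }
            for r in results
        ],
        "exclusions": exclusions,
    }
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
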