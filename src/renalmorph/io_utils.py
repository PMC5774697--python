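"""File formats: mask images, measurement tables, simulation configs.

The measurement table is a comma-separated UTF-8 CSV with a mandatory
header and "." decimal separator; units are fixed in the column names
(mm, mm², μg).  Missing values serialize as empty fields.  Numeric
fields are written at 6 significant digits, which round-trips all
measured quantities losslessly at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, EmptySectionError, SchemaError
from .geometry import CollagenModel
from .morphometry import BinarySectionImage
from .shape_synthesis import CohortRecord, CohortSpec, GroupShapeDistribution

__all__ = [
    "TABLE_COLUMNS",
    "read_mask",
    "write_mask",
    "read_table",
    "write_table",
    "cohort_to_table",
    "load_cohort_spec",
]

TABLE_COLUMNS: List[str] = [
    "kidney_id",
    "group",
    "a_mm",
    "b_mm",
    "be_mm",
    "A_mm2",
    "Ae_mm2",
    "Am_mm2",
    "collagen_ug",
    "collagen_est_ug",
    "mm_per_pixel",
]

PathLike = Union[str, Path]


def read_mask(path: PathLike, mm_per_pixel: float) -> BinarySectionImage:
    """Read a single-channel PNG/TIFF mask and apply standard preprocessing."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        # accept grayscale saved as identical channels (or with alpha)
        rgb = arr[..., :3]
        if rgb.shape[-1] == 1 or np.all(rgb == rgb[..., :1]):
            arr = rgb[..., 0]
        else:
            raise EmptySectionError(
                f"{path}: expected a single-channel mask, got shape {arr.shape}"
            )
    return BinarySectionImage.from_array(arr, pixel_size=mm_per_pixel)


def write_mask(path: PathLike, img: BinarySectionImage) -> None:
    """Write a mask as an 8-bit PNG/TIFF (foreground 255, background 0)."""
    iio.imwrite(path, (img.mask.astype(np.uint8) * 255))


def write_table(path: PathLike, table: pd.DataFrame) -> None:
    """Write a measurement table as CSV in the canonical column order."""
    out = table.copy()
    for col in TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[TABLE_COLUMNS]
    out.to_csv(path, index=False, float_format="%.6g")


def read_table(path: PathLike, require: Iterable[str] = ()) -> pd.DataFrame:
    """Read a measurement table, checking the header and required columns."""
    table = pd.read_csv(path)
    if "kidney_id" not in table.columns:
        raise SchemaError(f"{path}: not a measurement table (no kidney_id column)")
    missing = set(require) - set(table.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return table


def cohort_to_table(
    records: Iterable[CohortRecord], mm_per_pixel: Optional[float] = None
) -> pd.DataFrame:
    """Serialize simulated cohort records to the measurement-table schema."""
    rows = []
    for rec in records:
        rows.append(
            {
                "kidney_id": rec.kidney_id,
                "group": rec.group,
                "a_mm": rec.axes.a,
                "b_mm": rec.axes.b,
                "be_mm": rec.axes.b_e,
                "A_mm2": rec.areas.A,
                "Ae_mm2": rec.areas.A_e,
                "Am_mm2": rec.areas.A_m,
                "collagen_ug": rec.collagen_true,
                "collagen_est_ug": rec.collagen_est,
                "mm_per_pixel": mm_per_pixel,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def load_cohort_spec(path: PathLike, seed: Optional[int] = None) -> CohortSpec:
    """Load a cohort spec from YAML or JSON (auto-detected by extension).

    Recognized top-level keys mirror :class:`CohortSpec`; the
    ``healthy``/``diseased`` mappings mirror
    :class:`GroupShapeDistribution` and the ``collagen_model`` mapping
    takes ``slope``/``intercept``.  ``seed`` (if given) overrides the
    file.
    """
    path = Path(path)
    try:
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        elif path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            raise ConfigurationError(
                f"{path}: unknown config extension (use .yaml/.yml/.json)"
            )
    except (OSError, yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigurationError(f"{path}: cannot parse config: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    kwargs = dict(data)
    try:
        for group in ("healthy", "diseased"):
            if group in kwargs:
                kwargs[group] = GroupShapeDistribution(**kwargs[group])
        if "collagen_model" in kwargs:
            kwargs["collagen_model"] = CollagenModel(**kwargs["collagen_model"])
        if seed is not None:
            kwargs["seed"] = seed
        return CohortSpec(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: bad config field: {exc}") from exc
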