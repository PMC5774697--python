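"""Closed-form elliptical areas and the collagen calibration line.

A kidney coronal section is treated as an ellipse whose major axis ``a``
is the polar (pole-to-pole) distance and whose minor axis is the renal
width.  Two minor-axis conventions coexist:

* ``b``   — the standard minor axis, which stops at the parenchymal
  boundary and therefore excludes the pelvic cavity;
* ``b_e`` — the extended minor axis, continued across the renal pelvis
  to the line closing the hilar notch.

The standard elliptical area ``A = pi*a*b/4`` systematically
underestimates the measured parenchymal area because the pelvic notch
shortens ``b``; the modified area ``A_e = pi*a*b_e/4`` restores the lost
width and tracks the measured area closely.  Total kidney collagen is
then estimated from ``A_e`` through a linear calibration
``collagen = slope*A_e + intercept``.

All lengths are millimetres and areas mm**2; unit conversion happens
only at I/O boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .errors import CalibrationWarning, InvalidMeasurementError, MeasurementWarning

__all__ = [
    "AxialMeasurements",
    "AreaSet",
    "CollagenModel",
    "DEFAULT_COLLAGEN_MODEL",
    "ellipse_area",
    "extended_ellipse_area",
    "collagen_from_area",
    "estimate_collagen",
    "calibration_root",
]


@dataclass(frozen=True)
class AxialMeasurements:
    """The three linear measurements of one coronal section, in mm.

    Attributes
    ----------
    a
        Major-axis (polar) length.
    b
        Standard minor-axis length, excluding the pelvic cavity.
    b_e
        Extended minor-axis length, continued across the pelvis.

    Invariants: ``a > 0``, ``0 < b <= b_e`` (extending the minor axis
    across the pelvis can only lengthen it) and ``a >= b``.  ``b_e > a``
    is geometrically possible on squat sections and is permitted, but
    flagged with a :class:`MeasurementWarning`.
    """

    a: float
    b: float
    b_e: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.b_e > 0):
            raise InvalidMeasurementError(
                f"axes must be positive, got a={self.a}, b={self.b}, b_e={self.b_e}"
            )
        if self.b > self.b_e:
            raise InvalidMeasurementError(
                f"extended minor axis cannot be shorter than the minor axis "
                f"(b={self.b} > b_e={self.b_e})"
            )
        if self.a < self.b:
            raise InvalidMeasurementError(
                f"major axis must be the longer axis (a={self.a} < b={self.b})"
            )
        if self.a < self.b_e:
            warnings.warn(
                f"extended minor axis b_e={self.b_e} exceeds major axis a={self.a}",
                MeasurementWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class AreaSet:
    """Standard (A), modified (A_e) and measured (A_m) areas of one section, mm²."""

    A: float
    A_e: float
    A_m: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("A", "A_e", "A_m"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise InvalidMeasurementError(f"area {name}={value} must be positive")
        if self.A > self.A_e * (1 + 1e-12):
            raise InvalidMeasurementError(
                f"A={self.A} cannot exceed A_e={self.A_e} (b <= b_e)"
            )


@dataclass(frozen=True)
class CollagenModel:
    """Linear calibration of total kidney collagen (μg) on A_e (mm²).

    ``collagen = slope * A_e + intercept``.  Defaults are the murine
    chronic-kidney-disease calibration (slope 7.7 μg/mm², intercept
    −188.5 μg); both are configurable so the line can be refit for other
    species or disease models without code changes.
    """

    slope: float = 7.7
    intercept: float = -188.5

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise InvalidMeasurementError("collagen model slope must be nonzero")


DEFAULT_COLLAGEN_MODEL = CollagenModel()


def ellipse_area(m: AxialMeasurements) -> float:
    """Standard elliptical parenchymal area ``A = pi*a*b/4`` in mm²."""
    return math.pi * m.a * m.b / 4.0


def extended_ellipse_area(m: AxialMeasurements) -> float:
    """Modified elliptical area ``A_e = pi*a*b_e/4`` in mm².

    Equals :func:`ellipse_area` when ``b_e == b`` (convex section with no
    pelvic notch) and is strictly larger whenever ``b_e > b``.
    """
    return math.pi * m.a * m.b_e / 4.0


def collagen_from_area(
    A_e: float, model: CollagenModel = DEFAULT_COLLAGEN_MODEL
) -> float:
    """Total kidney collagen (μg) from the modified area via the calibration line.

    Areas below the calibration root (``-intercept/slope``, about
    24.48 mm² for the default model) yield negative estimates.  Those are
    returned as-is — clamping would hide calibration misuse — but tagged
    with a :class:`CalibrationWarning`.
    """
    if not A_e > 0:
        raise InvalidMeasurementError(f"area A_e={A_e} must be positive")
    collagen = model.slope * A_e + model.intercept
    if collagen < 0:
        warnings.warn(
            f"collagen estimate {collagen:.1f} μg is negative: A_e={A_e:.2f} mm² "
            f"lies below the calibration root {calibration_root(model):.2f} mm²",
            CalibrationWarning,
            stacklevel=2,
        )
    return collagen


def estimate_collagen(
    m: AxialMeasurements, model: CollagenModel = DEFAULT_COLLAGEN_MODEL
) -> float:
    """Collagen (μg/kidney) from the two axial measurements ``a`` and ``b_e``.

    Exactly the composition ``collagen_from_area(extended_ellipse_area(m))``:
    ``collagen = slope * pi*a*b_e/4 + intercept``.
    """
    return collagen_from_area(extended_ellipse_area(m), model)


def calibration_root(model: CollagenModel = DEFAULT_COLLAGEN_MODEL) -> float:
    """Area (mm²) at which the calibration line crosses zero collagen."""
    return -model.intercept / model.slope
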