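"""Visual-acuity unit conversions and display geometry.

The central unit is pixels per visual degree (ppd): the number of display
pixels that subtend one degree of visual angle at the observer's eye.  The
finest grating a display can show alternates every pixel, so the maximum
representable spatial frequency is half the ppd, in cycles per degree (cpd).
Clinical acuity units (minimum angle of resolution in arcminutes, Snellen
fractions) map onto ppd through the convention that one resolvable feature
corresponds to one pixel: an observer who resolves 1 arcmin of detail can use
a 60 ppd display fully.

All display geometry uses the exact arctangent of a single pixel's subtense
at the screen centre, measured along the display normal.  Small-angle
approximations are provided as documented helpers (they agree with the exact
forms to within 0.1% for ppd >= 20), but the exact forms are canonical
because they are analytically invertible.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "AngularResolution",
    "DisplaySpec",
    "POSTSCRIPT_POINT_MM",
    "TEX_POINT_MM",
    "mar_to_ppd",
    "ppd_to_mar",
    "ppd_to_cpd",
    "cpd_to_ppd",
    "parse_snellen",
    "snellen_to_ppd",
    "display_ppd",
    "display_ppd_small_angle",
    "min_viewing_distance",
    "ppi_distance_to_ppd",
    "required_ppi",
    "required_lines",
    "visual_angle_to_points",
    "visual_angle_to_size",
]

#: PostScript / DTP point in millimetres (1/72 inch).
POSTSCRIPT_POINT_MM = 25.4 / 72.0
#: TeX point in millimetres (1/72.27 inch).
TEX_POINT_MM = 25.4 / 72.27


@dataclass(frozen=True)
class AngularResolution:
    """Angular resolution expressed both as ppd and its Nyquist cpd.

    The two fields are locked together: ``cpd = ppd / 2`` exactly, the
    finest representable grating being one cycle per two pixels.
    """

    ppd: float

    def __post_init__(self) -> None:
        if not self.ppd > 0:
            raise ValueError(f"ppd must be positive, got {self.ppd}")

    @property
    def cpd(self) -> float:
        return self.ppd / 2.0

    @classmethod
    def from_cpd(cls, cpd: float) -> "AngularResolution":
        return cls(ppd=2.0 * cpd)


@dataclass(frozen=True)
class DisplaySpec:
    """Geometry of a flat display viewed along its normal.

    ``viewing_distance`` is tagged by ``distance_unit``: ``"m"`` (metres) or
    ``"H"`` (display heights).  ``ppi`` may be omitted when only
    height-relative geometry is needed.
    """

    vertical_lines: int
    aspect_ratio: float = 16.0 / 9.0
    ppi: float | None = None
    viewing_distance: float | None = None
    distance_unit: str = "H"

    def __post_init__(self) -> None:
        if int(self.vertical_lines) != self.vertical_lines or self.vertical_lines < 1:
            raise ValueError("vertical_lines must be an integer >= 1")
        if self.aspect_ratio <= 0:
            raise ValueError("aspect_ratio must be positive")
        if self.ppi is not None and self.ppi <= 0:
            raise ValueError("ppi must be positive")
        if self.viewing_distance is not None and self.viewing_distance <= 0:
            raise ValueError("viewing_distance must be positive")
        if self.distance_unit not in ("m", "H"):
            raise ValueError("distance_unit must be 'm' (metres) or 'H' (display heights)")

    def ppd(self) -> float:
        """Centre-of-screen ppd for the stored viewing distance."""
        if self.viewing_distance is None:
            raise ValueError("viewing_distance not set")
        if self.distance_unit == "H":
            return display_ppd(self.vertical_lines, self.viewing_distance)
        if self.ppi is None:
            raise ValueError("ppi required for a metric viewing distance")
        return ppi_distance_to_ppd(self.ppi, self.viewing_distance)


def mar_to_ppd(mar_arcmin: float) -> float:
    """Convert minimum angle of resolution (arcmin) to pixels per degree.

    One resolvable feature of ``mar`` arcmin corresponds to one pixel, so a
    MAR of 1 arcmin maps to 60 ppd.
    """
    if mar_arcmin <= 0:
        raise ValueError(f"MAR must be positive, got {mar_arcmin}")
    return 60.0 / mar_arcmin


def ppd_to_mar(ppd: float) -> float:
    """Inverse of :func:`mar_to_ppd`."""
    if ppd <= 0:
        raise ValueError(f"ppd must be positive, got {ppd}")
    return 60.0 / ppd


def ppd_to_cpd(ppd: float) -> float:
    """Nyquist pairing: the finest grating is one cycle per two pixels."""
    return ppd / 2.0


def cpd_to_ppd(cpd: float) -> float:
    return 2.0 * cpd


_SNELLEN_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*/\s*(\d+(?:\.\d+)?)\s*$")


def parse_snellen(text: str) -> tuple[float, float]:
    """Parse a Snellen fraction written as ``"N/D"`` (e.g. ``"20/20"``)."""
    m = _SNELLEN_RE.match(text)
    if m is None:
        raise ValueError(f"not a Snellen fraction: {text!r}")
    return float(m.group(1)), float(m.group(2))


def snellen_to_ppd(numerator: float | str, denominator: float | None = None) -> float:
    """Convert a Snellen fraction to ppd.

    The fraction is the testing distance over the distance at which a
    standard observer resolves the same optotype; the MAR in arcminutes is
    ``denominator / numerator``, so 20/20 (or the metric 6/6) gives 1 arcmin
    and hence 60 ppd.  Accepts either two numbers or a single ``"N/D"``
    string.
    """
    if isinstance(numerator, str):
        if denominator is not None:
            raise ValueError("pass either a string 'N/D' or two numbers, not both")
        numerator, denominator = parse_snellen(numerator)
    if denominator is None:
        raise ValueError("denominator missing")
    if numerator <= 0 or denominator <= 0:
        raise ValueError("Snellen distances must be positive")
    return mar_to_ppd(denominator / numerator)


def display_ppd(lines: float, distance_heights: float) -> float:
    """Centre-of-screen ppd of a display with ``lines`` vertical lines viewed
    from ``distance_heights`` display heights.

    One pixel has height ``1/lines`` display heights; its subtense at the
    screen centre is ``atan((1/lines)/d)``.  The result is the reciprocal of
    that angle in degrees, i.e. pixels per degree along the vertical at the
    display centre.
    """
    if lines < 1:
        raise ValueError("lines must be >= 1")
    if distance_heights <= 0:
        raise ValueError("distance must be positive")
    pixel_angle_deg = math.degrees(math.atan((1.0 / lines) / distance_heights))
    return 1.0 / pixel_angle_deg


def display_ppd_small_angle(lines: float, distance_heights: float) -> float:
    """Small-angle approximation of :func:`display_ppd`:
    ``ppd ~= lines * d * pi / 180``.  Documented helper; the arctangent form
    is canonical."""
    return lines * distance_heights * math.pi / 180.0


def min_viewing_distance(lines: float, target_ppd: float) -> float:
    """Closed-form inverse of :func:`display_ppd` in its distance argument:
    the distance (display heights) at which the display reaches
    ``target_ppd``."""
    if lines < 1:
        raise ValueError("lines must be >= 1")
    if target_ppd <= 0:
        raise ValueError("target_ppd must be positive")
    return (1.0 / lines) / math.tan(math.radians(1.0 / target_ppd))


def ppi_distance_to_ppd(ppi: float, distance_m: float) -> float:
    """ppd of a display with pixel density ``ppi`` viewed from
    ``distance_m`` metres (exact arctangent of one pixel pitch)."""
    if ppi <= 0 or distance_m <= 0:
        raise ValueError("ppi and distance must be positive")
    pitch_m = 0.0254 / ppi
    return 1.0 / math.degrees(math.atan(pitch_m / distance_m))


def required_ppi(target_ppd: float, distance_m: float) -> float:
    """Pixel density needed to reach ``target_ppd`` at ``distance_m`` metres
    (closed-form inverse of :func:`ppi_distance_to_ppd`)."""
    if target_ppd <= 0 or distance_m <= 0:
        raise ValueError("target_ppd and distance must be positive")
    pitch_m = distance_m * math.tan(math.radians(1.0 / target_ppd))
    return 0.0254 / pitch_m


def required_lines(target_ppd: float, distance_heights: float) -> float:
    """Vertical line count needed to reach ``target_ppd`` at a viewing
    distance in display heights (exact inverse of :func:`display_ppd` in its
    first argument; not rounded)."""
    if target_ppd <= 0 or distance_heights <= 0:
        raise ValueError("target_ppd and distance must be positive")
    return 1.0 / (distance_heights * math.tan(math.radians(1.0 / target_ppd)))


def visual_angle_to_size(angle_deg: float, distance_cm: float) -> float:
    """Physical extent (cm) subtending ``angle_deg`` at ``distance_cm``."""
    if angle_deg < 0:
        raise ValueError("angle must be non-negative")
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    return distance_cm * math.tan(math.radians(angle_deg))


def visual_angle_to_points(
    angle_deg: float,
    distance_cm: float,
    point_def_mm: float = POSTSCRIPT_POINT_MM,
) -> float:
    """Typographic size (points) of a feature subtending ``angle_deg`` at
    ``distance_cm``.

    The point definition is configurable: the PostScript point (1/72 inch,
    the default) and the TeX point (1/72.27 inch, :data:`TEX_POINT_MM`)
    differ by ~0.4%, which matters when matching printed font-size
    conventions.
    """
    size_mm = 10.0 * visual_angle_to_size(angle_deg, distance_cm)
    return size_mm / point_def_mm
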