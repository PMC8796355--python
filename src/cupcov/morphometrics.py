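"""True-acetabulum morphometrics: height, A-P diameter, volume proxy.

Acetabular height H is the perpendicular distance from the most superior
rim point to the horizontal plane through the acetabular lower edge
(|a p1 + b p2 + c p3 + d| / sqrt(a² + b² + c²) for the plane coefficients).
The A-P diameter R is the anterior-posterior extent of the socket surface
cut by the horizontal plane at half the acetabular height.  The acetabular
volume proxy is V = H·R·R, the printed planning formula for the roughly
conic Crowe-IV socket (no shape constant is applied).

The "most superior point" is taken from the digitized rim landmarks, not
searched over the whole bone mesh (on a full hemipelvis the global superior
extreme would be the iliac crest).  The half-height section is restricted
to the socket neighbourhood of the seated cup — within one cup radius
(+ margin) of the cup center and on the bone side of the cup opening plane
— which is the deterministic stand-in for the manual region selection of
the original workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import BoneModel, PelvicFrame
from .geometry import Plane, point_plane_distance

_DEGENERATE_HEIGHT_MM = 0.5


class MeasurementError(RuntimeError):
    """A morphometric measurement could not be taken."""


@dataclass(frozen=True)
class AcetabularMetrics:
    height_mm: float
    ap_diameter_mm: float
    volume_proxy_mm3: float
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            if self.height_mm <= 0 or self.ap_diameter_mm <= 0:
                raise ValueError("non-degenerate metrics must be positive")
            expected = self.height_mm * self.ap_diameter_mm**2
            if abs(self.volume_proxy_mm3 - expected) > 1e-6 * max(expected, 1.0):
                raise ValueError("volume proxy must equal H*R*R")


def acetabular_height(landmarks, frame: PelvicFrame) -> float:
    """Perpendicular distance from the most superior rim point to the
    horizontal plane through the acetabular lower edge."""
    rim = np.asarray(landmarks.rim, dtype=float)
    if len(rim) == 0:
        raise MeasurementError("rim landmark list is empty")
    sup = rim @ frame.superior_axis
    top = rim[int(np.argmax(sup))]
    plane = Plane.from_point_normal(landmarks.acetabular_lower_edge, frame.superior_axis)
    return point_plane_distance(plane, top)


def ap_diameter(
    bone: BoneModel,
    frame: PelvicFrame,
    height_mm: float,
    socket_center,
    socket_axis,
    socket_radius_mm: float,
    region_margin_mm: float = 0.3,
) -> float:
    """A-P extent of the socket surface at half the acetabular height.

    ``socket_center``/``socket_axis``/``socket_radius_mm`` delimit the
    socket neighbourhood (normally the seated cup's center, polar axis and
    outer radius).
    """
    if height_mm <= 0:
        raise MeasurementError("acetabular height must be positive")
    c = np.asarray(socket_center, dtype=float)
    axis = np.asarray(socket_axis, dtype=float)
    origin = bone.landmarks.acetabular_lower_edge + 0.5 * height_mm * frame.superior_axis
    section = bone.mesh.section(plane_origin=origin, plane_normal=frame.superior_axis)
    if section is None or len(section.vertices) == 0:
        raise MeasurementError(
            "the half-height horizontal plane does not intersect the bone "
            "(the slab missed the socket)"
        )
    pts = np.asarray(section.vertices, dtype=float)
    keep = (np.linalg.norm(pts - c, axis=1) <= socket_radius_mm + region_margin_mm) & (
        (pts - c) @ axis <= 0.0
    )
    if not keep.any():
        raise MeasurementError(
            "no socket surface found in the half-height section "
            "(the slab missed the socket)"
        )
    a = pts[keep] @ frame.anterior_axis
    return float(a.max() - a.min())


def volume_proxy(height_mm: float, ap_diameter_mm: float) -> float:
    """The planning volume proxy V = H * R * R (mm³)."""
    if height_mm <= 0 or ap_diameter_mm <= 0:
        raise ValueError("H and R must be positive")
    return float(height_mm * ap_diameter_mm * ap_diameter_mm)


def measure_hip(
    bone: BoneModel,
    frame: PelvicFrame,
    socket_center,
    socket_axis,
    socket_radius_mm: float,
    region_margin_mm: float = 0.3,
) -> AcetabularMetrics:
    """Height, A-P diameter and volume proxy for one hip."""
    h = acetabular_height(bone.landmarks, frame)
    if h < _DEGENERATE_HEIGHT_MM:
        return AcetabularMetrics(h, 0.0, 0.0, degenerate=True)
    r = ap_diameter(
        bone, frame, h, socket_center, socket_axis, socket_radius_mm, region_margin_mm
    )
    return AcetabularMetrics(h, r, volume_proxy(h, r))
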