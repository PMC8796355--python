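"""Pelvic landmarks and the anterior-pelvic-plane coordinate frame.

The standard planes are built the way CT-based hip planning does it: the
coronal plane passes through both anterior-superior iliac spines (ASIS) and
the midpoint of the pubic tubercles (the anterior pelvic plane, APP); the
sagittal plane is perpendicular to it through the tubercle midpoint with its
normal along the inter-ASIS direction; the horizontal plane is perpendicular
to both.  Pelvic tilt is deliberately not corrected: the APP itself is the
reference, which is the convention this pipeline measures in.

The four APP landmarks over-determine a plane; we reduce them to exactly
three points — ASIS left, ASIS right, and the pubic-tubercle *midpoint* — so
the construction is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .geometry import (
    DegenerateGeometryError,
    Plane,
    RigidTransform,
    as_point,
    plane_from_points,
    unit,
)

_LANDMARK_KEYS = (
    "asis_left",
    "asis_right",
    "pubic_tubercle_left",
    "pubic_tubercle_right",
    "transverse_ligament",
    "anterior_wall",
    "acetabular_lower_edge",
)


@dataclass(frozen=True)
class PelvicLandmarks:
    """Digitized pelvic landmark set for one hemipelvis (mm).

    ``rim`` is the ring of points digitized on the native acetabular rim;
    ``side`` names the hip under study ("left" or "right").
    """

    asis_left: np.ndarray
    asis_right: np.ndarray
    pubic_tubercle_left: np.ndarray
    pubic_tubercle_right: np.ndarray
    transverse_ligament: np.ndarray
    anterior_wall: np.ndarray
    acetabular_lower_edge: np.ndarray
    rim: np.ndarray
    side: str

    def __post_init__(self):
        for key in _LANDMARK_KEYS:
            object.__setattr__(self, key, as_point(getattr(self, key)))
        rim = np.asarray(self.rim, dtype=float)
        if rim.ndim != 2 or rim.shape[1] != 3 or len(rim) == 0:
            raise ValueError("rim must be a non-empty (n, 3) array of points")
        if not np.all(np.isfinite(rim)):
            raise ValueError("rim contains non-finite coordinates")
        object.__setattr__(self, "rim", rim)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if np.linalg.norm(self.asis_left - self.asis_right) < 1.0:
            raise DegenerateGeometryError(
                "ASIS landmarks are less than 1 mm apart"
            )

    @property
    def pubic_midpoint(self) -> np.ndarray:
        return 0.5 * (self.pubic_tubercle_left + self.pubic_tubercle_right)

    @property
    def asis_ipsilateral(self) -> np.ndarray:
        return self.asis_left if self.side == "left" else self.asis_right

    @property
    def rim_centroid(self) -> np.ndarray:
        return self.rim.mean(axis=0)

    def transformed(self, rt: RigidTransform) -> "PelvicLandmarks":
        return PelvicLandmarks(
            **{k: rt.apply(getattr(self, k)) for k in _LANDMARK_KEYS},
            rim=rt.apply(self.rim),
            side=self.side,
        )

    # -- JSON interface ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: [float(x) for x in getattr(self, k)] for k in _LANDMARK_KEYS}
        d["rim"] = [[float(x) for x in p] for p in self.rim]
        d["side"] = self.side
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PelvicLandmarks":
        missing = [k for k in (*_LANDMARK_KEYS, "rim", "side") if k not in d]
        if missing:
            raise KeyError(
                f"landmark file is missing required keys: {', '.join(missing)}"
            )
        unknown = set(d) - set(_LANDMARK_KEYS) - {"rim", "side"}
        if unknown:
            raise KeyError(
                f"landmark file has unknown keys: {', '.join(sorted(unknown))}"
            )
        return cls(**{k: d[k] for k in _LANDMARK_KEYS}, rim=d["rim"], side=d["side"])

    def save_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "PelvicLandmarks":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class BoneModel:
    """A hemipelvis surface model: watertight triangle mesh + landmarks."""

    mesh: trimesh.Trimesh
    landmarks: PelvicLandmarks

    def transformed(self, rt: RigidTransform) -> "BoneModel":
        return BoneModel(rt.apply_mesh(self.mesh), self.landmarks.transformed(rt))


@dataclass(frozen=True)
class PelvicFrame:
    """Orthonormal pelvic frame: origin at the pubic-tubercle midpoint.

    ``lateral_axis`` points toward the study side, ``anterior_axis``
    anteriorly, ``superior_axis`` cranially; the coronal/sagittal/horizontal
    planes have those axes as normals (positive side anterior / lateral /
    superior respectively).
    """

    origin: np.ndarray
    lateral_axis: np.ndarray
    anterior_axis: np.ndarray
    superior_axis: np.ndarray
    coronal_plane: Plane
    sagittal_plane: Plane
    horizontal_plane: Plane
    side: str

    def to_local(self, points) -> np.ndarray:
        """(lateral, anterior, superior) coordinates of world point(s)."""
        p = np.asarray(points, dtype=float) - self.origin
        M = np.vstack([self.lateral_axis, self.anterior_axis, self.superior_axis])
        return p @ M.T

    def from_local(self, coords) -> np.ndarray:
        c = np.asarray(coords, dtype=float)
        M = np.vstack([self.lateral_axis, self.anterior_axis, self.superior_axis])
        return c @ M + self.origin


def build_pelvic_frame(landmarks: PelvicLandmarks) -> PelvicFrame:
    """Standard planes and axes from the APP landmarks.

    Raises :class:`DegenerateGeometryError` when the APP points are
    (near-)collinear.
    """
    lm = landmarks
    origin = lm.pubic_midpoint
    toward_left = lm.asis_left - lm.asis_right
    if np.linalg.norm(toward_left) < 1e-9:
        raise DegenerateGeometryError("inter-ASIS vector has zero length")
    superior_raw = 0.5 * (lm.asis_left + lm.asis_right) - origin
    cross = np.cross(toward_left, superior_raw)
    if 0.5 * np.linalg.norm(cross) <= 1e-9:
        raise DegenerateGeometryError(
            "APP landmarks are collinear; coronal plane undefined"
        )
    left = unit(toward_left)
    superior = unit(superior_raw - (superior_raw @ left) * left)
    anterior = np.cross(superior, left)
    lateral = left if lm.side == "left" else -left

    coronal = Plane.from_point_normal(origin, anterior)
    sagittal = Plane.from_point_normal(origin, lateral)
    horizontal = Plane.from_point_normal(origin, superior)
    return PelvicFrame(
        origin=origin,
        lateral_axis=lateral,
        anterior_axis=anterior,
        superior_axis=superior,
        coronal_plane=coronal,
        sagittal_plane=sagittal,
        horizontal_plane=horizontal,
        side=lm.side,
    )


def signed_coordinates(frame: PelvicFrame, point) -> tuple[float, float, float]:
    """(lateral, anterior, superior) mm coordinates of a single point."""
    c = frame.to_local(as_point(point))
    return float(c[0]), float(c[1]), float(c[2])
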