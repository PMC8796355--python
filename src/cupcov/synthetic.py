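"""Parametric Crowe-IV-like hemipelvis phantoms with known coverage truth.

The generator does not attempt anatomical realism of the whole hemipelvis;
it builds a *socket block* whose carved geometry makes every downstream
measurement verifiable by construction:

* bone = block ∩ {below the cup opening plane} minus a cup-congruent
  spherical pocket (the pre-reamed seat for the 44-mm cup at 45°/20°),
* per-quadrant *deficiency windows* — radial wedges adjacent to the rim with
  a flat floor 3 mm behind the cup dome — remove a prescribed fraction
  ``f_Q`` of each quadrant segment's cup area, emulating dysplastic wall
  loss,
* rim landmarks are measurement fiducials placed so that the landmark-based
  acetabular height equals the target H and the half-height plane section of
  the pocket has anterior-posterior extent equal to the target R.  A 2-mm
  guard band of wall around that measurement ring is kept out of the windows
  so R stays measurable (dropped per-quadrant only when a requested ``f_Q``
  exceeds what the guarded quadrant can supply).

Because the windows are wedges of the sphere's direction space, the ground
truth segmental uncoverage ratios are known to the resolution of a 200k
quasi-uniform direction sample (~2e-3), independent of the meshing; meshes
are extracted from the implicit solid with marching cubes and are watertight.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import trimesh
from skimage import measure as _sk_measure

from .coverage import QuadrantUCRs, quadrant_labels, quadrant_planes
from .cup import CupPose, CupSpec, cup_axis_from_angles, cup_basis, rim_circle
from .frames import BoneModel, PelvicFrame, PelvicLandmarks, build_pelvic_frame
from .geometry import RigidTransform, unit
from .reference import REFERENCE_MOMENTS

_N_DIRS = 200_000
_N_PROBE = 50_000  # ground-truth / calibration direction probe
_CALIBRATION_EPS_MM = 0.1  # coverage eps the phantom is calibrated at
# Radius of the two protected wall patches around the anterior/posterior
# extremes of the A-P measurement ring (the only two points the extent
# measurement needs).  Large enough to survive the marching-cubes edge
# chamfer, small enough (~1% of a quadrant) not to constrain the windows.
_GUARD_PATCH_MM = 2.5
_WINDOW_FLOOR_MM = 3.0  # flat window floor this far behind the cup dome
_AXIS_MARGIN = 0.01  # A-P ring must sit this far (in direction cosine) below the opening plane

# hard feasibility ceiling for the A-P diameter target: above this the ring's
# anterior/posterior extremes rise to the cup opening plane and cannot be
# carved (see docs/methods.md)
AP_DIAMETER_MAX_MM = 38.5


class InfeasibleGeometryError(ValueError):
    """Requested phantom parameters cannot be realized as a watertight solid."""


@dataclass(frozen=True)
class SyntheticHipParams:
    """Targets for one synthetic hip.

    ``f_as``..``f_pi`` are the fractions of each quadrant segment's cup area
    left unsupported by bone (the per-quadrant deficiency fractions).
    """

    acetabular_height_mm: float = 31.99
    ap_diameter_mm: float = 25.23
    f_as: float = 0.2
    f_ai: float = 0.1
    f_ps: float = 0.3
    f_pi: float = 0.1
    socket_apex_depth_mm: float = 8.0
    bone_block_extent_mm: float = 76.0
    mesh_resolution_mm: float = 1.0
    cup_diameter_mm: float = 44.0
    abduction_deg: float = 45.0
    anteversion_deg: float = 20.0
    side: str = "left"
    seed: int = 0
    random_pose: bool = True

    def __post_init__(self):
        if not (15.0 <= self.acetabular_height_mm <= 50.0):
            raise InfeasibleGeometryError("acetabular height outside [15, 50] mm")
        if not (15.0 <= self.ap_diameter_mm <= 50.0):
            raise InfeasibleGeometryError("A-P diameter outside [15, 50] mm")
        for name in ("f_as", "f_ai", "f_ps", "f_pi"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InfeasibleGeometryError(f"{name}={v} outside [0, 1]")
        if self.mesh_resolution_mm <= 0 or self.mesh_resolution_mm > 3.0:
            raise InfeasibleGeometryError("mesh resolution must be in (0, 3] mm")
        if self.bone_block_extent_mm < 2.2 * self.cup_diameter_mm / 2 + 10:
            raise InfeasibleGeometryError("bone block too small for the cup")
        if self.cup_diameter_mm <= 0:
            raise InfeasibleGeometryError("cup diameter must be positive")
        if self.side not in ("left", "right"):
            raise InfeasibleGeometryError("side must be 'left' or 'right'")

    @property
    def deficiency_fractions(self) -> np.ndarray:
        return np.array([self.f_as, self.f_ai, self.f_ps, self.f_pi])


@dataclass(frozen=True)
class SyntheticHip:
    """A generated hip: bone model + construction ground truth."""

    bone: BoneModel
    ground_truth: QuadrantUCRs
    params: SyntheticHipParams
    true_cup_center: np.ndarray
    true_cup_axis: np.ndarray
    quadrant_weights: np.ndarray  # share of cup area per quadrant (sums to 1)
    guard_dropped: tuple[bool, bool, bool, bool]
    pose_transform: RigidTransform


@dataclass(frozen=True)
class CohortParams:
    """Sampling distributions for a synthetic Crowe-IV cohort."""

    n_hips: int = 30
    height_mean_mm: float = 31.99
    height_sd_mm: float = 4.09
    ap_mean_mm: float = 25.23
    ap_sd_mm: float = 4.82
    f_means: tuple = (0.33, 0.21, 0.40, 0.24)
    f_sds: tuple = (0.17, 0.10, 0.17, 0.19)
    ps_pi_corr: float = 0.5
    master_seed: int = 0
    mesh_resolution_mm: float = 1.0
    random_pose: bool = True

    def __post_init__(self):
        if self.n_hips < 1:
            raise ValueError("n_hips must be >= 1")
        for sd in (self.height_sd_mm, self.ap_sd_mm, *self.f_sds):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not (-1.0 <= self.ps_pi_corr <= 1.0):
            raise ValueError("ps_pi_corr must be in [-1, 1]")

    @classmethod
    def from_reference(
        cls, n_hips: int = 30, master_seed: int = 0, mesh_resolution_mm: float = 1.0,
        random_pose: bool = True,
    ) -> "CohortParams":
        """Calibrate the deficiency distributions to the reference cohort.

        Segment-Q's uncoverage ratio equals f_Q * w_Q where w_Q is the
        quadrant's share of cup area, so matching the reference segmental
        moments fixes the f distributions given the canonical weights.  The
        f draws are truncated to [0, 0.9]; the parent normal parameters are
        solved so that the *truncated* mean/SD equal the targets (the
        reference distributions are themselves bounded below by zero, so a
        naive untruncated parameterization would inflate the small-mean
        segments).
        """
        w = canonical_quadrant_weights()
        names = ("asucr", "aiucr", "psucr", "piucr")
        f_means, f_sds = [], []
        for i, n in enumerate(names):
            mu, sigma = _truncnorm_parent(
                REFERENCE_MOMENTS[n][0] / w[i], REFERENCE_MOMENTS[n][1] / w[i]
            )
            f_means.append(mu)
            f_sds.append(sigma)
        return cls(
            n_hips=n_hips,
            f_means=tuple(f_means),
            f_sds=tuple(f_sds),
            master_seed=master_seed,
            mesh_resolution_mm=mesh_resolution_mm,
            random_pose=random_pose,
        )


# Support of the cohort deficiency-fraction draws.  The ceiling keeps every
# cohort hip below the guarded-window capacity of its quadrant, so the A-P
# measurement guard band is never dropped for sampled hips.
_F_LO, _F_HI = 0.0, 0.8


def _trunc_moments(mu: float, sigma: float) -> tuple:
    from scipy import stats

    a, b = (_F_LO - mu) / sigma, (_F_HI - mu) / sigma
    m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
    return float(m), float(np.sqrt(v))


def _solve_mu_for_mean(target_mean: float, sigma: float) -> float:
    """Parent location whose [lo, hi]-truncated mean equals the target."""
    from scipy import optimize

    def resid(mu):
        return _trunc_moments(mu, sigma)[0] - target_mean

    grid = np.linspace(-3.0, 3.0, 61)
    vals = np.array([resid(g) for g in grid])
    sign_change = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if len(sign_change) == 0:
        return float(grid[int(np.argmin(np.abs(vals)))])
    i = int(sign_change[0])
    return float(optimize.brentq(resid, grid[i], grid[i + 1]))


@lru_cache(maxsize=32)
def _truncnorm_parent(target_mean: float, target_sd: float) -> tuple:
    """Parent normal (mu, sigma) whose truncation to [0, 0.8] matches the
    target moments; when the SD target is infeasible on that support, the
    mean is matched exactly and the SD as closely as the family allows."""
    from scipy import optimize

    def resid(x):
        m, s = _trunc_moments(x[0], abs(x[1]))
        return [m - target_mean, s - target_sd]

    sol, _, ier, _ = optimize.fsolve(
        resid, x0=[target_mean, target_sd], full_output=True
    )
    if ier == 1 and np.all(np.isfinite(sol)):
        m, s = _trunc_moments(sol[0], abs(sol[1]))
        if abs(m - target_mean) < 1e-6 and abs(s - target_sd) < 1e-6:
            return float(sol[0]), float(abs(sol[1]))
    best = None
    for sigma in (target_sd, 1.5 * target_sd, 2.0 * target_sd, 3.0 * target_sd):
        mu = _solve_mu_for_mean(target_mean, sigma)
        _, s = _trunc_moments(mu, sigma)
        if best is None or abs(s - target_sd) < abs(best[2] - target_sd):
            best = (mu, sigma, s)
    return float(best[0]), float(best[1])


# ---------------------------------------------------------------------------
# canonical landmark geometry (frame-local coordinates: lateral/anterior/superior)
# ---------------------------------------------------------------------------

_ASIS_HALFWIDTH = 115.0
_ASIS_HEIGHT = 85.0
_TUBERCLE_HALFWIDTH = 15.0
# Hip rotation center relative to the pubic-tubercle midpoint, in
# (lateral, anterior, superior) mm.
_CUP_CENTER_LOCAL = np.array([48.0, -22.0, 18.0])


def _app_points_local(side: str, scale: float = 1.0):
    """APP landmarks in frame-local coordinates; lateral = study side."""
    s = 1.0 if side == "left" else -1.0
    asis_ipsi = np.array([s * _ASIS_HALFWIDTH, 0.0, _ASIS_HEIGHT]) * scale
    asis_contra = np.array([-s * _ASIS_HALFWIDTH, 0.0, _ASIS_HEIGHT]) * scale
    tub_ipsi = np.array([s * _TUBERCLE_HALFWIDTH, 0.0, 0.0]) * scale
    tub_contra = np.array([-s * _TUBERCLE_HALFWIDTH, 0.0, 0.0]) * scale
    return asis_ipsi, asis_contra, tub_ipsi, tub_contra


def _axis_local(abduction_deg: float, anteversion_deg: float) -> np.ndarray:
    ri, ra = np.deg2rad(abduction_deg), np.deg2rad(anteversion_deg)
    return np.array([np.cos(ra) * np.sin(ri), np.sin(ra), -np.cos(ra) * np.cos(ri)])


def fibonacci_sphere(n: int = _N_DIRS) -> np.ndarray:
    """Quasi-uniform unit directions (deterministic golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _quadrant_signed(dirs_or_points, sag_n, sag_d, hor_n, hor_d):
    s_sag = dirs_or_points @ sag_n + sag_d
    s_hor = dirs_or_points @ hor_n + hor_d
    anterior = s_sag > -1e-9
    superior = s_hor < 1e-9
    labels = np.empty(len(dirs_or_points), dtype=np.int64)
    labels[anterior & superior] = 0
    labels[anterior & ~superior] = 1
    labels[~anterior & superior] = 2
    labels[~anterior & ~superior] = 3
    return labels


def _local_quadrant_geometry(side: str, scale: float, cup_center: np.ndarray):
    """Quadrant plane normals/offsets in local coordinates for a cup center."""
    asis_ipsi, asis_contra, _, _ = _app_points_local(side, scale)
    n_sag = np.cross(asis_ipsi - asis_contra, cup_center - asis_contra)
    n_sag = unit(n_sag)
    if n_sag[1] < 0:  # positive side anterior
        n_sag = -n_sag
    d_sag = -float(n_sag @ cup_center)
    n_hor = unit(cup_center - asis_ipsi)  # positive side inferior
    d_hor = -float(n_hor @ cup_center)
    return n_sag, d_sag, n_hor, d_hor


@lru_cache(maxsize=1)
def canonical_quadrant_weights() -> tuple:
    """Share of the cup hemisphere's area per quadrant, canonical geometry."""
    u = _axis_local(45.0, 20.0)
    dirs = fibonacci_sphere()
    hemi = dirs[dirs @ u <= 0.0]
    n_sag, d_sag, n_hor, d_hor = _local_quadrant_geometry(
        "left", 1.0, _CUP_CENTER_LOCAL
    )
    labels = _quadrant_signed(
        hemi + _CUP_CENTER_LOCAL, n_sag, d_sag, n_hor, d_hor
    )
    return tuple(np.bincount(labels, minlength=4) / len(hemi))


# ---------------------------------------------------------------------------
# hip generation
# ---------------------------------------------------------------------------


def _guard_dirs(r: float, z0_off: float) -> np.ndarray:
    """Unit directions of the A-P measurement ring's two extreme points."""
    rho = np.sqrt(max(0.0, r * r - z0_off * z0_off))
    return np.array([[0.0, rho, z0_off], [0.0, -rho, z0_off]]) / r


def _solve_windows(fractions, r, u, n_sag, d_sag, n_hor, d_hor,
                   cup_center, z0_off):
    """Choose window colatitude thresholds realizing the target fractions.

    Returns (alpha_thresholds, guard_dropped, quadrant counts, hemisphere
    count).  All angles in radians measured from the cup dome axis (-u);
    windows are {alpha >= threshold} within the quadrant, excluding the
    guard band unless it had to be dropped.
    """
    dirs = fibonacci_sphere()
    hemi = dirs[dirs @ u <= 0.0]
    labels = _quadrant_signed(hemi * r + cup_center, n_sag, d_sag, n_hor, d_hor)
    alpha = np.arccos(np.clip(-(hemi @ u), -1.0, 1.0))
    guard = np.zeros(len(hemi), dtype=bool)
    for e in _guard_dirs(r, z0_off):
        guard |= np.linalg.norm(hemi - e, axis=1) * r <= _GUARD_PATCH_MM

    thresholds = [None] * 4
    dropped = [False] * 4
    n_q = np.bincount(labels, minlength=4)
    for q in range(4):
        k = int(round(fractions[q] * n_q[q]))
        if k == 0:
            continue
        eligible = (labels == q) & ~guard
        if k > int(eligible.sum()):
            eligible = labels == q
            dropped[q] = True
        a = np.sort(alpha[eligible])[::-1]
        if k >= len(a):
            thresholds[q] = max(float(a[-1]) - 1e-6, 0.0)
        else:
            thresholds[q] = 0.5 * (float(a[k - 1]) + float(a[k]))
    return thresholds, tuple(dropped), n_q, len(hemi)


def _implicit_bone(points, params, cup_center, u, thresholds, dropped,
                   n_sag, d_sag, n_hor, d_hor, z0_off):
    """Signed field of the phantom solid: negative inside bone."""
    r = params.cup_diameter_mm / 2.0
    ext = params.bone_block_extent_mm / 2.0
    rel = points - cup_center
    dist = np.linalg.norm(rel, axis=1)

    box_sd = (np.abs(rel) - ext).max(axis=1)
    half_sd = rel @ u
    ball_sd = r - dist  # positive inside the carved pocket

    F = np.maximum(np.maximum(box_sd, half_sd), ball_sd)

    safe = np.maximum(dist, 1e-9)
    d_hat = rel / safe[:, None]
    alpha = np.arccos(np.clip(-(d_hat @ u), -1.0, 1.0))
    s_sag = points @ n_sag + d_sag
    s_hor = points @ n_hor + d_hor
    floor_term = -(r + _WINDOW_FLOOR_MM) - half_sd  # negative above the floor
    guard_in = np.full(len(points), -np.inf)
    for e in _guard_dirs(r, z0_off):
        guard_in = np.maximum(
            guard_in, _GUARD_PATCH_MM - np.linalg.norm(d_hat - e, axis=1) * safe
        )

    quadrant_terms = {
        0: (-s_sag, s_hor),
        1: (-s_sag, -s_hor),
        2: (s_sag, s_hor),
        3: (s_sag, -s_hor),
    }
    for q in range(4):
        if thresholds[q] is None:
            continue
        t_ang = (thresholds[q] - alpha) * safe
        t1, t2 = quadrant_terms[q]
        void = np.maximum(np.maximum(t_ang, floor_term), np.maximum(t1, t2))
        if not dropped[q]:
            void = np.maximum(void, guard_in)
        F = np.maximum(F, -void)
    return F


def _mesh_from_implicit(params, cup_center, field_fn) -> trimesh.Trimesh:
    res = params.mesh_resolution_mm
    ext = params.bone_block_extent_mm / 2.0
    pad = 2 * res
    # irrational sub-voxel offset so flat solid faces never coincide with
    # grid nodes (exact zeros there produce degenerate, occasionally
    # non-watertight marching-cubes output)
    lo = cup_center - ext - pad - res * 0.3183098861837907
    n = int(np.ceil((2 * (ext + pad)) / res)) + 1
    axes = [lo[i] + res * np.arange(n) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    F = field_fn(pts).reshape(n, n, n)
    verts, faces, _, _ = _sk_measure.marching_cubes(
        F, level=0.0, spacing=(res, res, res), allow_degenerate=False
    )
    mesh = trimesh.Trimesh(vertices=verts + lo, faces=faces, process=False)
    if not mesh.is_watertight:
        raise InfeasibleGeometryError(
            "marching cubes produced a non-watertight phantom; "
            "parameters are incompatible with the block extent/resolution"
        )
    return mesh


def generate_hip(params: SyntheticHipParams) -> SyntheticHip:
    """Build one synthetic hip with construction-known coverage truth."""
    rng = np.random.default_rng(params.seed)
    r = params.cup_diameter_mm / 2.0
    H = params.acetabular_height_mm
    R = params.ap_diameter_mm

    sgn = np.array([1.0 if params.side == "left" else -1.0, 1.0, 1.0])
    u = _axis_local(params.abduction_deg, params.anteversion_deg) * sgn
    cup_center = _CUP_CENTER_LOCAL * sgn

    # feasibility of the A-P measurement ring (see module docstring)
    if R >= 2 * r - 1.0:
        raise InfeasibleGeometryError(
            f"A-P diameter target {R} mm does not fit a {2 * r} mm socket"
        )
    z0_off = float(np.sqrt(r * r - (R / 2.0) ** 2))
    for sign in (+1.0, -1.0):
        extreme = np.array([0.0, sign * R / 2.0, z0_off]) / r
        if extreme @ u > -_AXIS_MARGIN:
            raise InfeasibleGeometryError(
                f"A-P diameter target {R} mm rises above the cup opening "
                f"plane (max feasible ~{AP_DIAMETER_MAX_MM} mm)"
            )

    n_sag, d_sag, n_hor, d_hor = _local_quadrant_geometry(
        params.side, 1.0, cup_center
    )

    # --- ground truth on a dense direction probe -------------------------
    probe = fibonacci_sphere(_N_PROBE)
    probe_hemi = probe[probe @ u <= 0.0]
    probe_labels = _quadrant_signed(
        probe_hemi * r + cup_center, n_sag, d_sag, n_hor, d_hor
    )
    n_q_probe = np.bincount(probe_labels, minlength=4)
    n_hemi_probe = len(probe_hemi)
    fs = params.deficiency_fractions
    gt_seg = np.round(fs * n_q_probe) / n_hemi_probe
    ground_truth = QuadrantUCRs(
        asucr=float(gt_seg[0]),
        aiucr=float(gt_seg[1]),
        psucr=float(gt_seg[2]),
        piucr=float(gt_seg[3]),
        tucr=float(gt_seg.sum()),
    )
    probe_points = cup_center + r * probe_hemi

    # --- carve, then calibrate the windows against the meshed solid ------
    # Marching cubes chamfers the sharp window edges by a fraction of a
    # voxel, slightly widening every window; one or two correction passes
    # (re-carving with adjusted window sizes so that the probe classified
    # against the actual mesh matches the requested fractions) remove the
    # bias.
    from .geometry import MeshQueries  # local import to avoid a cycle

    f_eff = fs.astype(float).copy()
    weights = None
    mesh = None
    dropped = (False,) * 4
    for _ in range(3):
        thresholds, dropped, n_q, n_hemi = _solve_windows(
            f_eff, r, u, n_sag, d_sag, n_hor, d_hor, cup_center, z0_off
        )
        weights = n_q / n_hemi
        mesh = _mesh_from_implicit(
            params,
            cup_center,
            lambda pts: _implicit_bone(
                pts, params, cup_center, u, thresholds, dropped,
                n_sag, d_sag, n_hor, d_hor, z0_off,
            ),
        )
        if not np.any(fs > 0):
            break
        queries = MeshQueries(mesh)
        uncov = ~queries.in_solid(probe_points, eps=_CALIBRATION_EPS_MM)
        realized = np.bincount(probe_labels[uncov], minlength=4) / n_hemi_probe
        err = realized - gt_seg
        if np.max(np.abs(err)) <= 0.0035:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            f_eff = np.clip(f_eff - err * n_hemi_probe / n_q_probe, 0.0, 1.0)

    # --- landmarks (frame-local coordinates) -----------------------------
    S = np.array([0.0, 0.0, 1.0])
    A = np.array([0.0, 1.0, 0.0])
    k_perp = float(np.sqrt(1.0 - (S @ u) ** 2))
    e1 = unit(S - (S @ u) * u)  # max-superior direction within planes ⊥ u
    e2 = np.cross(u, e1)
    r_ring = H / (2.0 * k_perp)
    ring_center = cup_center + (z0_off / (S @ u)) * u if abs(S @ u) > 1e-9 else cup_center
    phis = 2 * np.pi * np.arange(12) / 12  # phi=0 top, phi=pi bottom
    rim = ring_center + r_ring * (
        np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2
    )
    lower_edge = ring_center - r_ring * e1
    anterior_wall = cup_center + r * unit(A - (A @ u) * u)
    transverse_ligament = cup_center - r * e1

    asis_ipsi, asis_contra, tub_ipsi, tub_contra = _app_points_local(params.side)
    if params.side == "left":
        asis_l, asis_r = asis_ipsi, asis_contra
        tub_l, tub_r = tub_ipsi, tub_contra
    else:
        asis_l, asis_r = asis_contra, asis_ipsi
        tub_l, tub_r = tub_contra, tub_ipsi
    landmarks = PelvicLandmarks(
        asis_left=asis_l,
        asis_right=asis_r,
        pubic_tubercle_left=tub_l,
        pubic_tubercle_right=tub_r,
        transverse_ligament=transverse_ligament,
        anterior_wall=anterior_wall,
        acetabular_lower_edge=lower_edge,
        rim=rim,
        side=params.side,
    )

    if params.random_pose:
        rt = RigidTransform.random(rng, max_angle_deg=25.0, max_translation_mm=30.0)
    else:
        rt = RigidTransform.identity()
    bone = BoneModel(rt.apply_mesh(mesh), landmarks.transformed(rt))
    return SyntheticHip(
        bone=bone,
        ground_truth=ground_truth,
        params=params,
        true_cup_center=rt.apply(cup_center),
        true_cup_axis=rt.apply_vector(u),
        quadrant_weights=weights,
        guard_dropped=dropped,
        pose_transform=rt,
    )


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size):
    lo = max(lo, mean - 3 * sd)
    hi = min(hi, mean + 3 * sd)
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    out = np.empty(size)
    todo = np.ones(size, dtype=bool)
    while todo.any():
        draw = rng.normal(mean, sd, size=int(todo.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(todo)[ok]
        out[idx] = draw[ok]
        todo[idx] = False
    return out


def draw_cohort_params(cohort: CohortParams) -> list[SyntheticHipParams]:
    """Sample per-hip targets (no meshing); deterministic given master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(cohort.master_seed))
    n = cohort.n_hips
    seeds = rng.integers(0, 2**31 - 1, size=n)
    H = _truncated_normal(rng, cohort.height_mean_mm, cohort.height_sd_mm, 15.0, 50.0, n)
    R = _truncated_normal(
        rng, cohort.ap_mean_mm, cohort.ap_sd_mm, 15.0, AP_DIAMETER_MAX_MM, n
    )

    # Gaussian copula: correlated latent normals (P-S/P-I pair), each mapped
    # through its own truncated-normal marginal, so the marginals are exact
    # regardless of the correlation.
    from scipy import stats as sps

    means = np.asarray(cohort.f_means, dtype=float)
    sds = np.asarray(cohort.f_sds, dtype=float)
    rho = cohort.ps_pi_corr
    z = rng.standard_normal((n, 4))
    z[:, 3] = rho * z[:, 2] + np.sqrt(max(0.0, 1.0 - rho * rho)) * z[:, 3]
    q = sps.norm.cdf(z)
    f = np.empty((n, 4))
    for j in range(4):
        if sds[j] == 0:
            f[:, j] = np.clip(means[j], _F_LO, _F_HI)
        else:
            a, b = (_F_LO - means[j]) / sds[j], (_F_HI - means[j]) / sds[j]
            f[:, j] = sps.truncnorm.ppf(q[:, j], a, b, loc=means[j], scale=sds[j])

    out = []
    for i in range(n):
        out.append(
            SyntheticHipParams(
                acetabular_height_mm=float(H[i]),
                ap_diameter_mm=float(R[i]),
                f_as=float(f[i, 0]),
                f_ai=float(f[i, 1]),
                f_ps=float(f[i, 2]),
                f_pi=float(f[i, 3]),
                mesh_resolution_mm=cohort.mesh_resolution_mm,
                seed=int(seeds[i]),
                random_pose=cohort.random_pose,
            )
        )
    return out


def generate_cohort(cohort: CohortParams) -> list[SyntheticHip]:
    """Generate all hips of a cohort (meshes included)."""
    return [generate_hip(p) for p in draw_cohort_params(cohort)]


# ---------------------------------------------------------------------------
# analytic half-space fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HalfSpaceFixture:
    """A planar bone slab with closed-form cup coverage.

    ``gap_mm`` is the signed distance from the cup center to the slab face
    along the dome direction: 0 puts the face through the cup equator (whole
    dome buried, TUCR 0); +11 leaves a spherical zone of half the dome
    height uncovered (TUCR 0.5); r leaves the cup floating tangent to the
    face (TUCR 1).  The ``face_contains_axis`` variant rotates the face to
    contain the polar axis (mirror symmetry, TUCR 0.5).
    """

    bone: BoneModel
    frame: PelvicFrame
    pose: CupPose
    expected_tucr: float
    gap_mm: float
    face_contains_axis: bool


def spherical_zone_uncovered_fraction(gap_mm: float, radius_mm: float) -> float:
    """Closed-form uncovered fraction of a hemisphere against a planar wall.

    The zone of the hemisphere above the face plane has area 2*pi*r*gap
    (Archimedes), so the uncovered fraction is gap/r clipped to [0, 1].
    """
    return float(np.clip(gap_mm / radius_mm, 0.0, 1.0))


def half_space_fixture(
    gap_mm: float,
    side: str = "left",
    face_contains_axis: bool = False,
    cup: CupSpec | None = None,
) -> HalfSpaceFixture:
    """Planar-wall coverage fixture with landmarks and a nominal pose."""
    cup = cup or CupSpec.eggshell()
    r = cup.outer_radius_mm
    if abs(gap_mm) > r:
        raise ValueError(f"|gap| must be <= cup radius {r} mm")

    sgn = np.array([1.0 if side == "left" else -1.0, 1.0, 1.0])
    center = _CUP_CENTER_LOCAL * sgn
    u = _axis_local(45.0, 20.0) * np.array([sgn[0], 1.0, 1.0])

    asis_ipsi, asis_contra, tub_ipsi, tub_contra = _app_points_local(side)
    # rim fiducials on the cup opening circle (centroid = intended center)
    S = np.array([0.0, 0.0, 1.0])
    A = np.array([0.0, 1.0, 0.0])
    e1 = unit(S - (S @ u) * u)
    e2 = np.cross(u, e1)
    phis = 2 * np.pi * np.arange(12) / 12
    rim = center + r * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
    landmarks = PelvicLandmarks(
        asis_left=asis_ipsi if side == "left" else asis_contra,
        asis_right=asis_contra if side == "left" else asis_ipsi,
        pubic_tubercle_left=tub_ipsi if side == "left" else tub_contra,
        pubic_tubercle_right=tub_contra if side == "left" else tub_ipsi,
        transverse_ligament=center - r * e1,
        anterior_wall=center + r * unit(A - (A @ u) * u),
        acetabular_lower_edge=center - r * e1,
        rim=rim,
        side=side,
    )
    frame = build_pelvic_frame(landmarks)

    if face_contains_axis:
        normal = e1  # face contains the polar axis
        offset = 0.0
        expected = 0.5
    else:
        normal = -u  # dome direction
        offset = gap_mm
        expected = spherical_zone_uncovered_fraction(gap_mm, r)
    thickness = 40.0
    slab = trimesh.creation.box(extents=[140.0, 140.0, thickness])
    B = cup_basis(normal)
    T = np.eye(4)
    T[:3, :3] = B.T  # columns e1, e2, normal
    T[:3, 3] = center + (offset + thickness / 2.0) * normal
    slab.apply_transform(T)

    pose = CupPose(center=center, polar_axis=u)
    return HalfSpaceFixture(
        bone=BoneModel(slab, landmarks),
        frame=frame,
        pose=pose,
        expected_tucr=expected,
        gap_mm=float(gap_mm),
        face_contains_axis=face_contains_axis,
    )


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_hip(hip: SyntheticHip, directory, hip_id: str) -> dict:
    """Write STL + landmarks JSON + ground-truth CSV; return the file map."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    stl = d / f"{hip_id}.stl"
    lmk = d / f"{hip_id}.landmarks.json"
    gt = d / f"{hip_id}.ground_truth.csv"
    hip.bone.mesh.export(str(stl))
    hip.bone.landmarks.save_json(lmk)
    with open(gt, "w", encoding="utf-8") as fh:
        fh.write("quantity,value\n")
        for k, v in hip.ground_truth.as_dict().items():
            fh.write(f"{k},{v:.9g}\n")
        fh.write(f"height_mm,{hip.params.acetabular_height_mm:.9g}\n")
        fh.write(f"ap_diameter_mm,{hip.params.ap_diameter_mm:.9g}\n")
    return {"stl": str(stl), "landmarks": str(lmk), "ground_truth": str(gt)}


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
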