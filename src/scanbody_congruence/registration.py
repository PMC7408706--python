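"""Rigid registration of a scan mesh onto the reference library mesh.

Two stages, mirroring the clinical reverse-engineering workflow: a coarse
three-point landmark alignment (closed-form orthogonal Procrustes), then a
robust point-to-plane iterative closest point (ICP) refinement.  Points are
sampled from the moving scan; correspondences are exact nearest points on
the reference surface, signed along the reference outward normals.

Nearest-point queries use a KD-tree over triangle centroids with a
radius-bound candidate expansion that guarantees exactness: the accelerated
result always equals the brute-force minimum over all triangles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    EmptyMeshError,
    IllConditionedRegistrationError,
    ParameterError,
)
from .mesh_io import TriangleMesh

# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Rotation + translation mapping source into reference coordinates.

    ``rotation`` is a proper orthonormal 3x3 matrix (det +1); ``translation``
    is in mm.  Application is ``R p + t``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ParameterError(f"rotation is not orthonormal (|R'R - I| = {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ParameterError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation) -> "RigidTransform":
        """Build from an axis-angle vector in degrees and a translation in mm."""
        rot = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True)
        return cls(rot.as_matrix(), translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation_mm": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation_mm"]))

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _orthonormalize(matrix: np.ndarray) -> np.ndarray:
    """Nearest proper rotation to ``matrix`` (SVD projection)."""
    u, _, vt = np.linalg.svd(matrix)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


# ---------------------------------------------------------------------------
# landmark (Procrustes) alignment
# ---------------------------------------------------------------------------


@dataclass
class LandmarkPairs:
    """Matched landmark coordinates: ``source_points[i]`` corresponds to
    ``target_points[i]`` (both mm, >= 3 non-collinear points)."""

    source_points: np.ndarray
    target_points: np.ndarray

    def __post_init__(self) -> None:
        self.source_points = np.asarray(self.source_points, dtype=float).reshape(-1, 3)
        self.target_points = np.asarray(self.target_points, dtype=float).reshape(-1, 3)
        if len(self.source_points) != len(self.target_points):
            raise ParameterError("landmark point counts differ")
        if len(self.source_points) < 3:
            raise ParameterError("need at least 3 landmark pairs")
        centered = self.source_points - self.source_points.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] <= 1e-9:  # second singular value: collinear or coincident
            raise DegenerateGeometryError("landmarks are collinear or coincident")


def landmark_align(pairs: LandmarkPairs) -> RigidTransform:
    """Least-squares rigid transform (Kabsch/SVD, no scaling) minimising
    ``sum ||R s_i + t - d_i||^2``; the closed-form global optimum."""
    s = pairs.source_points
    d = pairs.target_points
    sc = s.mean(axis=0)
    dc = d.mean(axis=0)
    h = (s - sc).T @ (d - dc)
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    r = vt.T @ corr @ u.T
    t = dc - r @ sc
    return RigidTransform(r, t)


# ---------------------------------------------------------------------------
# point-triangle and point-surface queries
# ---------------------------------------------------------------------------


def _closest_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Pairwise closest point: ``points`` (n, 3) against ``triangles``
    (n, 3, 3).  Returns the (n, 3) foot points.

    The unconstrained plane projection is used when its barycentric
    coordinates are all non-negative; otherwise the minimum over the three
    clamped edge segments (which contains the constrained optimum).
    """
    a, b, c = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e0, e1 = b - a, c - a
    d = points - a
    d00 = np.einsum("ij,ij->i", e0, e0)
    d01 = np.einsum("ij,ij->i", e0, e1)
    d11 = np.einsum("ij,ij->i", e1, e1)
    d20 = np.einsum("ij,ij->i", d, e0)
    d21 = np.einsum("ij,ij->i", d, e1)
    denom = d00 * d11 - d01 * d01
    safe = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / safe
    w = (d00 * d21 - d01 * d20) / safe
    inside = (v >= 0) & (w >= 0) & (v + w <= 1) & (np.abs(denom) >= 1e-300)
    foot_plane = a + v[:, None] * e0 + w[:, None] * e1

    best = np.full(len(points), np.inf)
    foot_edge = np.zeros_like(points)
    for p0, p1 in ((a, b), (a, c), (b, c)):
        seg = p1 - p0
        L2 = np.einsum("ij,ij->i", seg, seg)
        t = np.einsum("ij,ij->i", points - p0, seg) / np.where(L2 == 0, 1.0, L2)
        t = np.clip(t, 0.0, 1.0)
        cand = p0 + t[:, None] * seg
        dist2 = np.einsum("ij,ij->i", points - cand, points - cand)
        better = dist2 < best
        best = np.where(better, dist2, best)
        foot_edge[better] = cand[better]

    return np.where(inside[:, None], foot_plane, foot_edge)


def closest_point_on_triangle(
    p: np.ndarray, tri: np.ndarray
) -> tuple[np.ndarray, float]:
    """Closest point on a single (non-degenerate) triangle to ``p``."""
    tri = np.asarray(tri, dtype=float).reshape(3, 3)
    area2 = np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
    if area2 <= 2 * 1e-12:
        raise DegenerateGeometryError("triangle is degenerate")
    foot = _closest_on_triangles(
        np.asarray(p, dtype=float).reshape(1, 3), tri[None, :, :]
    )[0]
    return foot, float(np.linalg.norm(np.asarray(p, dtype=float) - foot))


@dataclass
class Correspondence:
    """Vectorised nearest-surface correspondences for a batch of points."""

    source_points: np.ndarray  # (n, 3) query points, mm
    target_points: np.ndarray  # (n, 3) feet on the target surface, mm
    target_normals: np.ndarray  # (n, 3) unit face normals at the feet
    distances: np.ndarray  # (n,) unsigned Euclidean distances, mm
    face_indices: np.ndarray  # (n,) index of the nearest target face
    weights: np.ndarray  # (n,) in [0, 1]

    def barycentric(self, mesh: TriangleMesh) -> np.ndarray:
        """Barycentric coordinates of each foot in its face (rows sum to 1)."""
        tri = mesh.triangles[self.face_indices]
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        e0, e1 = b - a, c - a
        d = self.target_points - a
        d00 = np.einsum("ij,ij->i", e0, e0)
        d01 = np.einsum("ij,ij->i", e0, e1)
        d11 = np.einsum("ij,ij->i", e1, e1)
        denom = d00 * d11 - d01 * d01
        v = (d11 * np.einsum("ij,ij->i", d, e0) - d01 * np.einsum("ij,ij->i", d, e1)) / denom
        w = (d00 * np.einsum("ij,ij->i", d, e1) - d01 * np.einsum("ij,ij->i", d, e0)) / denom
        return np.column_stack([1 - v - w, v, w])


class SurfaceIndex:
    """Exact accelerated nearest-point queries on a triangle mesh.

    A KD-tree over face centroids proposes candidates; per-face bounding
    radii convert centroid distances into rigorous lower bounds on the true
    point-triangle distance (``d_tri >= d_centroid - radius``), so the
    search can certify that no unexamined triangle can beat the current
    best.  Results therefore match a brute-force scan over all faces
    exactly.

    Oversized faces (radius far above the median, e.g. cap fans) would make
    that bound uselessly loose, so they are kept out of the KD-tree and
    screened separately with their individual radii.
    """

    def __init__(self, mesh: TriangleMesh, leafsize: int = 16):
        if mesh.n_faces == 0:
            raise EmptyMeshError("cannot index an empty mesh")
        self.mesh = mesh
        self._tri = mesh.triangles
        self._centroids = mesh.face_centroids
        # max distance from a centroid to its own triangle's corners
        radii = np.linalg.norm(self._tri - self._centroids[:, None, :], axis=2).max(
            axis=1
        )
        cutoff = 2.5 * np.median(radii)
        big = radii > cutoff
        if big.sum() > 0.25 * mesh.n_faces:  # near-uniform mesh: no split
            big[:] = False
        self._small_idx = np.nonzero(~big)[0]
        self._big_idx = np.nonzero(big)[0]
        self._radii = radii
        self._r_small_max = float(radii[self._small_idx].max()) if len(self._small_idx) else 0.0
        self._tree = cKDTree(self._centroids[self._small_idx], leafsize=leafsize)

    def _exact(self, points: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        feet = _closest_on_triangles(points, self._tri[faces])
        return feet, np.linalg.norm(points - feet, axis=1)

    def query(self, points: np.ndarray, k_first: int = 8) -> Correspondence:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        m_small = len(self._small_idx)
        k = min(k_first, m_small)
        d_cent, pos = self._tree.query(points, k=k)
        if k == 1:
            d_cent = d_cent[:, None]
            pos = pos[:, None]
        idx = self._small_idx[pos]
        flat_pts = np.repeat(points, k, axis=0)
        feet, dist = self._exact(flat_pts, idx.ravel())
        feet = feet.reshape(n, k, 3)
        dist = dist.reshape(n, k)
        best_j = dist.argmin(axis=1)
        rows = np.arange(n)
        best_dist = dist[rows, best_j]
        best_face = idx[rows, best_j]
        best_foot = feet[rows, best_j]

        # oversized faces: evaluate only the (point, face) pairs whose lower
        # bound beats the current best
        if len(self._big_idx):
            cb = self._centroids[self._big_idx]
            rb = self._radii[self._big_idx]
            d_big = np.linalg.norm(points[:, None, :] - cb[None, :, :], axis=2)
            pi, fj = np.nonzero(d_big - rb[None, :] < best_dist[:, None])
            if len(pi):
                feet_b, dist_b = self._exact(points[pi], self._big_idx[fj])
                order = np.argsort(dist_b, kind="stable")
                for o in order[::-1]:  # ensure each point keeps its minimum
                    i = pi[o]
                    if dist_b[o] < best_dist[i]:
                        best_dist[i] = dist_b[o]
                        best_face[i] = self._big_idx[fj[o]]
                        best_foot[i] = feet_b[o]

        # certification for regular faces: any face outside the k candidates
        # has centroid distance >= the kth, hence distance >= that - r_small
        if k < m_small:
            unresolved = np.nonzero(best_dist > d_cent[:, -1] - self._r_small_max)[0]
            for i in unresolved:
                cand = self._tree.query_ball_point(
                    points[i], best_dist[i] + self._r_small_max
                )
                if not cand:
                    continue
                cand = self._small_idx[np.asarray(cand, dtype=np.int64)]
                feet_i, dist_i = self._exact(
                    np.repeat(points[i][None], len(cand), axis=0), cand
                )
                j = dist_i.argmin()
                if dist_i[j] < best_dist[i]:
                    best_dist[i] = dist_i[j]
                    best_face[i] = cand[j]
                    best_foot[i] = feet_i[j]

        return Correspondence(
            source_points=points,
            target_points=best_foot,
            target_normals=self.mesh.face_normals[best_face],
            distances=best_dist,
            face_indices=best_face,
            weights=np.ones(n),
        )


def closest_surface_point(
    p: np.ndarray, mesh: TriangleMesh, index: SurfaceIndex | None = None
) -> Correspondence:
    """Exact nearest point on ``mesh`` for a single query point."""
    if index is None:
        index = SurfaceIndex(mesh)
    return index.query(np.asarray(p, dtype=float).reshape(1, 3))


def brute_force_closest(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Reference implementation: unsigned distance minimised over *all*
    faces.  Used as the independent oracle for :class:`SurfaceIndex`."""
    points = np.atleast_2d(points)
    out = np.empty(len(points))
    tri = mesh.triangles
    for i, p in enumerate(points):
        feet = _closest_on_triangles(np.repeat(p[None], len(tri), axis=0), tri)
        out[i] = np.linalg.norm(p - feet, axis=1).min()
    return out


# ---------------------------------------------------------------------------
# robust weighting
# ---------------------------------------------------------------------------

TUKEY_C = 4.685  # 95% Gaussian efficiency tuning constant


def robust_weights(
    residuals: np.ndarray,
    scheme: str = "tukey",
    scale: str | float = "auto",
    tuning_c: float = TUKEY_C,
    center: bool = True,
    scale_floor: float = 0.0,
) -> np.ndarray:
    """Per-point weights in [0, 1], non-increasing in |residual|.

    ``scale="auto"`` uses 1.4826 * MAD of the (median-centred) residuals.
    Centring makes a uniform offset — the signature of a systematically
    grown or shrunken scan — count as consensus rather than outliers.
    ``scale_floor`` bounds the auto scale from below so that a nearly
    noise-free residual set (e.g. a pure offset surface) does not shrink
    the inlier band to numerical curvature jitter.  When the scale
    collapses to zero (all residuals equal) every weight is 1.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ParameterError("need at least one residual")
    if scheme == "none":
        return np.ones_like(r)
    if center:
        r = r - np.median(r)
    if scale == "auto":
        s = max(1.4826 * np.median(np.abs(r - np.median(r))), scale_floor)
    else:
        s = float(scale)
    if s <= 0:
        return np.ones_like(r)
    u = r / (tuning_c * s)
    if scheme == "tukey":
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    elif scheme == "huber":
        au = np.maximum(np.abs(r / s), 1e-300)
        w = np.minimum(1.0, tuning_c / au)
    else:
        raise ParameterError(f"unknown robust scheme {scheme!r}")
    return w


# ---------------------------------------------------------------------------
# point-to-plane ICP
# ---------------------------------------------------------------------------


@dataclass
class ICPConfig:
    """Settings for the point-to-plane refinement.

    ``min_iterations`` defaults to 100, matching the study protocol of at
    least 100 iterations per superimposition; ``convergence_tol`` is the RMS
    residual change (micrometres) below which iteration may stop once the
    minimum count is reached.

    The default robust scheme is Huber with a widened linear zone
    (``tuning_c = 2.0``): its bounded but never-vanishing influence keeps
    the weakly constrained axial/torsional modes of a rotationally
    near-symmetric scanbody anchored, where a hard-redescending weight
    (Tukey, also available) can reject the flat face and let the pose
    drift.  ``robust_scale_floor_um`` bounds the MAD scale from below so a
    nearly noise-free scan does not collapse the inlier band.
    """

    min_iterations: int = 100
    max_iterations: int = 500
    convergence_tol: float = 1e-4  # um change in RMS residual
    sample_count: int = 20_000
    robust_scheme: str = "huber"
    tuning_c: float = 2.0
    robust_scale_floor_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_iterations < 1:
            raise ParameterError("min_iterations must be >= 1")
        if self.max_iterations < self.min_iterations:
            raise ParameterError("max_iterations must be >= min_iterations")
        if self.sample_count < 6:
            raise ParameterError("sample_count must be >= 6")


def sample_surface(
    mesh: TriangleMesh, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Area-weighted uniform surface samples (mm)."""
    areas = mesh.face_areas
    probs = areas / areas.sum()
    faces = rng.choice(mesh.n_faces, size=count, p=probs)
    tri = mesh.triangles[faces]
    # uniform barycentric via the square-root trick
    r1 = np.sqrt(rng.random(count))
    r2 = rng.random(count)
    a = 1 - r1
    b = r1 * (1 - r2)
    c = r1 * r2
    return a[:, None] * tri[:, 0] + b[:, None] * tri[:, 1] + c[:, None] * tri[:, 2]


def icp_point_to_plane(
    source: TriangleMesh,
    target: TriangleMesh,
    init: RigidTransform | None = None,
    config: ICPConfig | None = None,
    index: SurfaceIndex | None = None,
) -> tuple[RigidTransform, list[float]]:
    """Register ``source`` onto ``target`` with robust point-to-plane ICP.

    Each iteration: transform the fixed area-weighted source samples, find
    exact nearest points on the target, robust-reweight the plane residuals,
    and solve the linearised 6x6 normal equations for the incremental twist
    (small-angle rotation + translation), re-orthonormalising the composed
    rotation.  Deterministic given ``config.seed``.

    Returns the final transform and the per-iteration weighted-RMS residual
    trace in micrometres.
    """
    if source.n_faces == 0 or target.n_faces == 0:
        raise EmptyMeshError("both meshes must be non-empty")
    config = config or ICPConfig()
    transform = init or RigidTransform.identity()
    rng = np.random.default_rng(config.seed)
    count = min(config.sample_count, max(6, 4 * source.n_vertices))
    samples = sample_surface(source, count, rng)
    if index is None:
        index = SurfaceIndex(target)

    trace: list[float] = []
    prev_rms = np.inf
    for iteration in range(config.max_iterations):
        p = transform.apply(samples)
        corr = index.query(p)
        r = np.einsum("ij,ij->i", p - corr.target_points, corr.target_normals)
        w = robust_weights(
            r,
            scheme=config.robust_scheme,
            scale="auto",
            tuning_c=config.tuning_c,
            scale_floor=config.robust_scale_floor_um / 1000.0,
        )
        if w.sum() < 6:
            w = np.ones_like(w)

        n = corr.target_normals
        jac = np.hstack([np.cross(p, n), n])  # (m, 6) rows [p x n, n]
        sw = np.sqrt(w)
        ata = (jac * sw[:, None]).T @ (jac * sw[:, None])
        atb = (jac * sw[:, None]).T @ (-r * sw)
        sv = np.linalg.svd(ata, compute_uv=False)
        if sv[-1] <= 1e-12 * sv[0]:
            # robust weighting can concentrate on a planar subset (e.g. the
            # flat face of an offset scanbody); retry unweighted before
            # declaring the geometry itself degenerate
            w = np.ones_like(w)
            ata = jac.T @ jac
            atb = jac.T @ (-r)
            sv = np.linalg.svd(ata, compute_uv=False)
            if sv[-1] <= 1e-12 * sv[0]:
                raise IllConditionedRegistrationError(
                    "normal equations rank-deficient (planar or degenerate source)"
                )
        x = np.linalg.solve(ata, atb)
        omega, t_inc = x[:3], x[3:]
        delta = RigidTransform(
            _orthonormalize(Rotation.from_rotvec(omega).as_matrix()), t_inc
        )
        transform = delta.compose(transform)
        transform = RigidTransform(
            _orthonormalize(transform.rotation), transform.translation
        )

        rms_um = 1000.0 * float(np.sqrt(np.sum(w * r**2) / np.sum(w)))
        trace.append(rms_um)
        if (
            iteration + 1 >= config.min_iterations
            and abs(prev_rms - rms_um) < config.convergence_tol
        ):
            break
        prev_rms = rms_um

    return transform, trace
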