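"""Synthetic scanbody geometry and simulated intraoral scans.

The reference "library file" is a parametric flat-faced cylinder: a PEEK-style
scanning post 13 mm tall with one or more planar reference faces and a
chamfered top, meshed at a controllable edge length.  Simulated scans start
from that exact geometry and accumulate the error sources the study design
cares about, in a fixed order:

1. manufacturing tolerance — a fixed signed offset along the surface normals,
   bounded by +/-20 um, shared by every scan of the same physical scanbody;
2. scanner signature — a mean normal offset (+ = the scan grows outward,
   - = it shrinks inward), optionally region dependent;
3. Laplacian smoothing — a surrogate for reconstruction post-processing,
   which slightly shrinks curved regions;
4. per-vertex Gaussian observation noise along the normals;
5. a random rigid jitter (the scan's arbitrary pose in scanner coordinates).

Every random stream is split per (scanner, model, scanbody) from the master
seed, so adding replicates never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import ParameterError, ScanbodyError
from .mesh_io import TriangleMesh, write_mesh
from .registration import RigidTransform

#: maximum admissible manufacturing offset magnitude, um
MANUFACTURING_TOL_UM = 20.0

SB_LABELS = ("S1", "S2", "S3", "S4", "S5", "S6")

REGION_FLAT_CENTRAL = "flat_central"
REGION_FLAT_LATERAL = "flat_lateral"
REGION_BACK = "back"
REGIONS = (REGION_FLAT_CENTRAL, REGION_FLAT_LATERAL, REGION_BACK)


# ---------------------------------------------------------------------------
# reference geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanbodySpec:
    """Parametric scanbody: cylinder + flat reference face(s) + chamfered top.

    Dimensions in mm.  The default height matches the 13 mm posts of the
    study design; radius, face width and chamfer are plausible values for a
    PEEK scanning post (exact manufacturer dimensions are proprietary — only
    the relative flat/cylindrical geometry matters for the analysis).
    """

    height: float = 13.0
    shaft_radius: float = 2.5
    flat_face_count: int = 1
    flat_face_width: float = 4.0
    top_chamfer: float = 0.6
    mesh_edge_length: float = 0.35

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ParameterError("height must be positive")
        if self.flat_face_count < 1:
            raise ParameterError("a scanbody needs at least one flat reference face")
        if not 0 < self.flat_face_width < 2 * self.shaft_radius:
            raise ParameterError("flat face must be narrower than the shaft diameter")
        alpha = np.arcsin(self.flat_face_width / (2 * self.shaft_radius))
        if self.flat_face_count * 2 * alpha >= 2 * np.pi:
            raise ParameterError("flat faces overlap around the shaft")
        if not 0 <= self.top_chamfer < min(self.height, self.shaft_radius):
            raise ParameterError("chamfer must fit within height and radius")
        if self.mesh_edge_length <= 0:
            raise ParameterError("mesh_edge_length must be positive")

    @property
    def flat_angles(self) -> np.ndarray:
        """Azimuths of the flat-face centres (first at +x)."""
        return 2 * np.pi * np.arange(self.flat_face_count) / self.flat_face_count

    @property
    def flat_half_angle(self) -> float:
        return float(np.arcsin(self.flat_face_width / (2 * self.shaft_radius)))

    @property
    def flat_offset(self) -> float:
        """Distance from the axis to the flat-face plane."""
        return float(np.sqrt(self.shaft_radius**2 - (self.flat_face_width / 2) ** 2))


def _cross_section(spec: ScanbodySpec) -> np.ndarray:
    """Ordered CCW 2D boundary points of the flat-cut circular section."""
    r = spec.shaft_radius
    h = spec.mesh_edge_length
    alpha = spec.flat_half_angle
    pts: list[np.ndarray] = []
    centres = spec.flat_angles
    for k, theta in enumerate(centres):
        # chord (flat face) from theta-alpha to theta+alpha
        a0, a1 = theta - alpha, theta + alpha
        p0 = r * np.array([np.cos(a0), np.sin(a0)])
        p1 = r * np.array([np.cos(a1), np.sin(a1)])
        n_seg = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / h)))
        for t in np.linspace(0.0, 1.0, n_seg, endpoint=False):
            pts.append((1 - t) * p0 + t * p1)
        # arc to the next flat
        next_start = centres[(k + 1) % len(centres)] - alpha
        if k + 1 == len(centres):
            next_start += 2 * np.pi
        arc = next_start - a1
        n_arc = max(2, int(np.ceil(arc * r / h)))
        for ang in np.linspace(a1, next_start, n_arc, endpoint=False):
            pts.append(r * np.array([np.cos(ang), np.sin(ang)]))
    return np.asarray(pts)


def build_library_mesh(spec: ScanbodySpec) -> TriangleMesh:
    """Build the closed, outward-oriented reference mesh for ``spec``.

    The bounding-box height along z equals ``spec.height`` exactly; the flat
    face(s) lie in planes at distance ``spec.flat_offset`` from the axis.
    """
    boundary = _cross_section(spec)
    nb = len(boundary)
    h, c = spec.height, spec.top_chamfer
    shaft_top = h - c
    n_shaft = max(2, int(np.ceil(shaft_top / spec.mesh_edge_length)) + 1)
    z_shaft = np.linspace(0.0, shaft_top, n_shaft)
    if c > 0:
        n_ch = max(2, int(np.ceil(c / (spec.mesh_edge_length / 2))) + 1)
        z_ch = np.linspace(shaft_top, h, n_ch)[1:]
    else:
        z_ch = np.array([])
    z_levels = np.concatenate([z_shaft, z_ch])

    rings = []
    for z in z_levels:
        # 45-degree chamfer: radial inset grows linearly above the shaft
        inset = max(0.0, z - shaft_top)
        scale = (spec.shaft_radius - inset) / spec.shaft_radius
        ring = np.column_stack(
            [boundary * scale, np.full(nb, z)]
        )
        rings.append(ring)
    vertices = np.vstack(rings)
    bottom_c = len(vertices)
    top_c = bottom_c + 1
    vertices = np.vstack([vertices, [0.0, 0.0, 0.0], [0.0, 0.0, h]])

    faces: list[tuple[int, int, int]] = []
    nz = len(z_levels)
    for i in range(nz - 1):
        base0, base1 = i * nb, (i + 1) * nb
        for j in range(nb):
            j1 = (j + 1) % nb
            p00, p01 = base0 + j, base0 + j1
            p10, p11 = base1 + j, base1 + j1
            faces.append((p00, p01, p11))
            faces.append((p00, p11, p10))
    for j in range(nb):  # bottom cap, normal -z
        j1 = (j + 1) % nb
        faces.append((bottom_c, j1, j))
    top_base = (nz - 1) * nb
    for j in range(nb):  # top cap, normal +z
        j1 = (j + 1) % nb
        faces.append((top_c, top_base + j, top_base + j1))

    mesh = TriangleMesh.from_arrays(vertices, np.asarray(faces), name="library")
    mesh.metadata["spec"] = spec
    if not is_closed(mesh):
        raise ScanbodyError("generated scanbody mesh is not closed")
    return mesh


def is_closed(mesh: TriangleMesh) -> bool:
    """True when every edge is shared by exactly two consistently wound faces."""
    edges = np.vstack(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    directed = edges[:, 0] * mesh.n_vertices + edges[:, 1]
    if len(np.unique(directed)) != len(directed):
        return False  # repeated directed edge: inconsistent winding
    undirected = np.sort(edges, axis=1)
    _, counts = np.unique(
        undirected[:, 0] * mesh.n_vertices + undirected[:, 1], return_counts=True
    )
    return bool(np.all(counts == 2))


def region_labels_for(spec: ScanbodySpec, mesh: TriangleMesh) -> np.ndarray:
    """Per-face region labels {flat_central, flat_lateral, back}.

    A face belongs to a flat face when its centroid lies on the chord plane
    (within a small tolerance).  The central band is the middle third of the
    face width; everything else — cylindrical shaft, chamfer and caps — is
    the posterior "back" region.  The partition is exhaustive by
    construction.
    """
    cent = mesh.face_centroids
    labels = np.full(mesh.n_faces, REGION_BACK, dtype=object)
    d = spec.flat_offset
    w = spec.flat_face_width
    tol = 1e-6
    for theta in spec.flat_angles:
        ct, st = np.cos(theta), np.sin(theta)
        x = cent[:, 0] * ct + cent[:, 1] * st  # toward the flat
        y = -cent[:, 0] * st + cent[:, 1] * ct  # along the face width
        on_flat = (np.abs(x - d) < tol) & (np.abs(y) <= w / 2 + tol)
        central = on_flat & (np.abs(y) <= w / 6)
        labels[on_flat] = REGION_FLAT_LATERAL
        labels[central] = REGION_FLAT_CENTRAL
    return labels


# ---------------------------------------------------------------------------
# error model and scan simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ErrorModel:
    """Controlled error signature of one scanner.

    Offsets and noise in micrometres; positive offsets grow the scan outward
    (the library ends up inside the mesh), negative shrink it inward.
    """

    normal_offset_mean_um: float = 0.0
    normal_offset_by_region_um: tuple[tuple[str, float], ...] | None = None
    surface_noise_sd_um: float = 0.0
    smoothing_iterations: int = 0
    smoothing_lambda: float = 0.1
    rigid_jitter_rotation_sd_deg: float = 0.0
    rigid_jitter_translation_sd_um: float = 0.0
    manufacturing_offset_um: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.manufacturing_offset_um) > MANUFACTURING_TOL_UM:
            raise ParameterError(
                f"|manufacturing offset| exceeds {MANUFACTURING_TOL_UM} um tolerance"
            )
        if self.surface_noise_sd_um < 0:
            raise ParameterError("surface_noise_sd_um must be >= 0")
        if self.smoothing_iterations < 0:
            raise ParameterError("smoothing_iterations must be >= 0")
        if not 0 <= self.smoothing_lambda <= 1:
            raise ParameterError("smoothing_lambda must be in [0, 1]")

    def region_offsets(self) -> dict[str, float]:
        return dict(self.normal_offset_by_region_um or ())


def _vertex_regions(mesh: TriangleMesh, face_labels: np.ndarray) -> np.ndarray:
    """Assign each vertex the label of its first incident face."""
    labels = np.empty(mesh.n_vertices, dtype=object)
    order = np.argsort(mesh.faces.ravel(), kind="stable")
    flat_faces = np.repeat(np.arange(mesh.n_faces), 3)
    verts_sorted = mesh.faces.ravel()[order]
    first = np.searchsorted(verts_sorted, np.arange(mesh.n_vertices))
    labels[:] = face_labels[flat_faces[order][first]]
    return labels


def _laplacian_smooth(
    vertices: np.ndarray, faces: np.ndarray, iterations: int, lam: float = 0.5
) -> np.ndarray:
    if iterations == 0:
        return vertices
    n = len(vertices)
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    v = vertices.copy()
    deg = np.zeros(n)
    np.add.at(deg, edges[:, 0], 1)
    np.add.at(deg, edges[:, 1], 1)
    deg[deg == 0] = 1
    for _ in range(iterations):
        acc = np.zeros_like(v)
        np.add.at(acc, edges[:, 0], v[edges[:, 1]])
        np.add.at(acc, edges[:, 1], v[edges[:, 0]])
        v = v + lam * (acc / deg[:, None] - v)
    return v


def simulate_scan(
    library: TriangleMesh,
    model: ErrorModel,
    seed: int | None = None,
    region_labels: np.ndarray | None = None,
) -> TriangleMesh:
    """Simulate one scan of ``library`` under ``model``.

    Deterministic given ``(model, seed)``.  The applied rigid jitter is
    recorded in ``metadata["applied_transform"]`` so ground truth is always
    recoverable.  Requires a closed, outward-oriented library mesh.
    """
    if not is_closed(library):
        raise ScanbodyError("library mesh must be closed and consistently oriented")
    if seed is None:
        seed = model.seed if model.seed is not None else 0
    rng = np.random.default_rng(seed)

    v = library.vertices.copy()
    normals = library.vertex_normals
    offset_um = np.full(len(v), model.manufacturing_offset_um + model.normal_offset_mean_um)
    by_region = model.region_offsets()
    if by_region:
        if region_labels is None:
            spec = library.metadata.get("spec")
            if spec is None:
                raise ParameterError(
                    "region offsets need region_labels or a spec-tagged library"
                )
            region_labels = region_labels_for(spec, library)
        vlabels = _vertex_regions(library, region_labels)
        for region, off in by_region.items():
            offset_um[vlabels == region] += off
    v = v + normals * (offset_um[:, None] / 1000.0)
    v = _laplacian_smooth(
        v, library.faces, model.smoothing_iterations, lam=model.smoothing_lambda
    )
    if model.surface_noise_sd_um > 0:
        noise = rng.normal(0.0, model.surface_noise_sd_um / 1000.0, len(v))
        v = v + normals * noise[:, None]

    rotvec_deg = rng.normal(0.0, model.rigid_jitter_rotation_sd_deg, 3)
    t_mm = rng.normal(0.0, model.rigid_jitter_translation_sd_um / 1000.0, 3)
    rot = Rotation.from_rotvec(rotvec_deg, degrees=True).as_matrix()
    centroid = v.mean(axis=0)
    jitter = RigidTransform(rot, centroid - rot @ centroid + t_mm)
    v = jitter.apply(v)

    scan = TriangleMesh(v, library.faces.copy(), name="scan")
    scan.metadata.update(
        applied_transform=jitter,
        error_model=model,
        seed=seed,
    )
    return scan


# ---------------------------------------------------------------------------
# arch layout and full-study generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchPose:
    label: str
    origin: tuple[float, float, float]
    axis: tuple[float, float, float]

    def transform(self) -> RigidTransform:
        """Rigid pose placing a z-axis-aligned scanbody at this position."""
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        z = np.array([0.0, 0.0, 1.0])
        cross = np.cross(z, axis)
        dot = float(np.clip(z @ axis, -1.0, 1.0))
        if np.linalg.norm(cross) < 1e-12:
            rot = np.eye(3) if dot > 0 else Rotation.from_rotvec([np.pi, 0, 0]).as_matrix()
        else:
            angle = np.arccos(dot)
            rot = Rotation.from_rotvec(angle * cross / np.linalg.norm(cross)).as_matrix()
        return RigidTransform(rot, np.asarray(self.origin, dtype=float))


@dataclass(frozen=True)
class ArchLayout:
    """Six labelled scanbody poses on a maxillary arch, near-parallel axes."""

    poses: tuple[ArchPose, ...]

    def __post_init__(self) -> None:
        if len(self.poses) != 6:
            raise ParameterError("an arch layout has exactly six scanbody poses")
        origins = np.asarray([p.origin for p in self.poses])
        if len(np.unique(np.round(origins, 6), axis=0)) != 6:
            raise ParameterError("scanbody positions must be pairwise distinct")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(p.label for p in self.poses)


def default_arch_layout(arch_radius: float = 25.0, tilt_deg: float = 3.0) -> ArchLayout:
    """Six positions spread over a semicircular maxillary arch (first molar
    to first molar), with small alternating axis tilts so the posts are
    fairly parallel but not identical."""
    angles_deg = (15.0, 50.0, 80.0, 100.0, 130.0, 165.0)
    poses = []
    for i, (label, ang) in enumerate(zip(SB_LABELS, angles_deg)):
        th = np.radians(ang)
        origin = (arch_radius * np.cos(th), arch_radius * np.sin(th), 0.0)
        tilt = np.radians(tilt_deg) * (1 if i % 2 == 0 else -1)
        axis = (np.sin(tilt) * np.cos(th), np.sin(tilt) * np.sin(th), np.cos(tilt))
        poses.append(ArchPose(label, origin, axis))
    return ArchLayout(tuple(poses))


def landmark_points(spec: ScanbodySpec) -> np.ndarray:
    """Three well-separated, non-collinear reference points on the library
    surface (two on the flat face, one on the back of the shaft), emulating
    the three points an operator picks for the rough alignment."""
    d = spec.flat_offset
    w = spec.flat_face_width
    h = spec.height
    return np.array(
        [
            [d, w / 4, 0.2 * h],
            [d, -w / 4, 0.75 * h],
            [-spec.shaft_radius, 0.0, 0.5 * h],
        ]
    )


@dataclass
class StudyDataset:
    """A full synthetic study: one library mesh plus labelled scan meshes."""

    library: TriangleMesh
    scans: dict[tuple[str, int, str], TriangleMesh]
    manifest: pd.DataFrame
    spec: ScanbodySpec
    layout: ArchLayout
    region_labels: np.ndarray


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(
    spec: ScanbodySpec,
    layout: ArchLayout,
    scanner_profiles: dict[str, ErrorModel],
    n_models: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> StudyDataset:
    """Generate ``n_profiles x n_models x 6`` scan meshes plus the library.

    The six manufacturing offsets (one per physical scanbody, uniform within
    the +/-20 um tolerance) are drawn once from the master seed and shared
    across scanners and models, as in a real study where every scanner scans
    the same six posts.  Fully reproducible from ``seed``.
    """
    if n_models < 1:
        raise ParameterError("n_models must be >= 1")
    if not scanner_profiles:
        raise ParameterError("need at least one scanner profile")
    library = build_library_mesh(spec)
    region_labels = region_labels_for(spec, library)
    rng_m = np.random.default_rng(_child_seed(seed, 999_983))
    manufacturing = rng_m.uniform(
        -MANUFACTURING_TOL_UM, MANUFACTURING_TOL_UM, len(layout.poses)
    )

    scans: dict[tuple[str, int, str], TriangleMesh] = {}
    rows = []
    for i, (scanner, profile) in enumerate(scanner_profiles.items()):
        for j in range(1, n_models + 1):
            for k, pose in enumerate(layout.poses):
                child = _child_seed(seed, i, j, k)
                model = replace(profile, manufacturing_offset_um=manufacturing[k])
                scan = simulate_scan(library, model, seed=child, region_labels=region_labels)
                pose_t = pose.transform()
                total = pose_t.compose(scan.metadata["applied_transform"])
                scan = scan.transformed(pose_t.rotation, pose_t.translation)
                scan.metadata.update(
                    applied_transform=total,
                    error_model=model,
                    seed=child,
                    scanner=scanner,
                    model_index=j,
                    sb=pose.label,
                )
                scan.name = f"{scanner}_m{j}_{pose.label}"
                scans[(scanner, j, pose.label)] = scan
                rows.append(
                    {
                        "scanner": scanner,
                        "model": j,
                        "sb": pose.label,
                        "seed": child,
                        "true_offset_um": profile.normal_offset_mean_um,
                        "manufacturing_um": manufacturing[k],
                    }
                )
    manifest = pd.DataFrame(rows)
    dataset = StudyDataset(library, scans, manifest, spec, layout, region_labels)
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: StudyDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mesh(dataset.library, out_dir / "library.stl", format="stl")
    for (scanner, model, sb), mesh in dataset.scans.items():
        d = out_dir / scanner / f"model_{model:02d}"
        d.mkdir(parents=True, exist_ok=True)
        write_mesh(mesh, d / f"{sb}.stl", format="stl")
    dataset.manifest.to_csv(out_dir / "manifest.csv", index=False)


# ---------------------------------------------------------------------------
# mesh-free table simulator (for statistical calibration studies)
# ---------------------------------------------------------------------------


def simulate_deviation_table(
    scanner_means_um: dict[str, float],
    n_models: int,
    rng: np.random.Generator,
    sb_effect_sd_um: float = 5.0,
    within_sd_um: float = 4.0,
) -> pd.DataFrame:
    """Draw a study-shaped deviation table directly at the observation level.

    Scanbody effects are drawn once and shared across scanners (the six
    physical posts are common to all scanners); replicate noise is i.i.d.
    Gaussian.  Used for calibration experiments (e.g. null-distribution
    checks) where simulating meshes would add nothing.
    """
    sb_effects = rng.normal(0.0, sb_effect_sd_um, len(SB_LABELS))
    rows = []
    for scanner, mu in scanner_means_um.items():
        for k, sb in enumerate(SB_LABELS):
            vals = mu + sb_effects[k] + rng.normal(0.0, within_sd_um, n_models)
            for j, v in enumerate(vals, start=1):
                rows.append(
                    {"scanner": scanner, "sb": sb, "model": j, "mean_abs_dev_um": max(v, 0.1)}
                )
    return pd.DataFrame(rows)
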