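"""Signed deviation fields, congruence summaries, and colorimetric classes.

After registration the scan is mapped into the reference frame and each
sample point is assigned its exact distance to the reference surface,
signed by the side of the nearest reference triangle it falls on: positive
outside (outward excess), negative inside (inward defect).  Distances are
reported in micrometres; mesh coordinates stay in millimetres.

The colorimetric classification mirrors the inspection convention of
reverse-engineering software: a +/-50 um display scale with a green
"no deviation" band at +/-1 um; blues are inward, yellow/red outward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyMeshError, InsufficientDataError, ParameterError
from .mesh_io import TriangleMesh
from .registration import RigidTransform, SurfaceIndex, sample_surface
from .synthetic_scanbody import ScanbodySpec, region_labels_for

CLASS_INWARD = "inward"
CLASS_NONE = "none"
CLASS_OUTWARD = "outward"

LABEL_INWARD = "inward deviation"
LABEL_NONE = "no deviation"
LABEL_OUTWARD = "outward deviation"

_CLASS_TO_LABEL = {
    CLASS_INWARD: LABEL_INWARD,
    CLASS_NONE: LABEL_NONE,
    CLASS_OUTWARD: LABEL_OUTWARD,
}


@dataclass
class ColorBinSpec:
    """Display scale (um) and the central green band of the colour map."""

    scale_max: float = 50.0
    green_band: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.green_band < self.scale_max:
            raise ParameterError("need 0 < green_band < scale_max")


@dataclass
class DeviationField:
    """Signed point-to-surface deviations of one registered scan.

    ``positions`` are the sample points in the reference frame (mm),
    ``signed_um`` the signed distances (um), ``regions`` the label of the
    nearest reference region for each sample.
    """

    positions: np.ndarray
    signed_um: np.ndarray
    regions: np.ndarray
    reference: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.signed_um = np.asarray(self.signed_um, dtype=float).reshape(-1)
        self.regions = np.asarray(self.regions, dtype=object).reshape(-1)

    @property
    def n_samples(self) -> int:
        return len(self.signed_um)


@dataclass
class RegionPartition:
    """Exhaustive assignment of reference faces to named regions."""

    face_labels: np.ndarray

    def __post_init__(self) -> None:
        self.face_labels = np.asarray(self.face_labels, dtype=object)


@dataclass
class CongruenceSummary:
    """Descriptive statistics of one scan-reference superimposition (um).

    ``mean_abs``/``sd_abs`` summarise the absolute deviations (the headline
    congruence statistic); ``mean_signed`` retains directionality.  Median,
    quartiles and range are over the absolute deviations; the 95% CI is a
    normal approximation around ``mean_abs``.
    """

    mean_abs: float
    sd_abs: float
    mean_signed: float
    median: float
    q1_q3: tuple[float, float]
    range: tuple[float, float]
    ci95: tuple[float, float]
    n_samples: int

    def as_mean_sd(self, ndigits: int = 0) -> str:
        """Format as the conventional ``mean ± SD μm`` report string."""
        return f"{round(self.mean_abs, ndigits):g} ± {round(self.sd_abs, ndigits):g} μm"


def label_regions(
    reference: TriangleMesh,
    spec: ScanbodySpec | None = None,
    face_labels: np.ndarray | None = None,
) -> RegionPartition:
    """Partition reference faces into flat_central / flat_lateral / back.

    With a :class:`ScanbodySpec` the labels are derived geometrically (the
    central band is the middle third of the flat-face width); alternatively
    user-supplied per-face labels may be given directly.
    """
    if face_labels is not None:
        face_labels = np.asarray(face_labels, dtype=object)
        if len(face_labels) != reference.n_faces:
            raise ParameterError("face_labels length must match reference faces")
        return RegionPartition(face_labels)
    if spec is None:
        spec = reference.metadata.get("spec")
    if spec is None:
        raise ParameterError("need a ScanbodySpec or explicit face labels")
    return RegionPartition(region_labels_for(spec, reference))


def signed_deviation(
    scan: TriangleMesh,
    reference: TriangleMesh,
    transform: RigidTransform | None = None,
    partition: RegionPartition | None = None,
    index: SurfaceIndex | None = None,
    sample_count: int | None = None,
    seed: int = 0,
) -> DeviationField:
    """Signed deviation field of ``scan`` against ``reference``.

    ``transform`` maps the scan into the reference frame (identity when
    omitted).  By default every scan vertex is a sample; passing
    ``sample_count`` switches to seeded area-weighted surface sampling (the
    same sampler ICP uses, so the two can share a point set).  The sign is
    positive when a sample lies on the outward-normal side of its nearest
    reference triangle.
    """
    if scan.n_faces == 0 or reference.n_faces == 0:
        raise EmptyMeshError("scan and reference must be non-empty")
    if index is None:
        index = SurfaceIndex(reference)
    if sample_count is None:
        points = scan.vertices
    else:
        points = sample_surface(scan, sample_count, np.random.default_rng(seed))
    if transform is not None:
        points = transform.apply(points)
    corr = index.query(points)
    side = np.sign(
        np.einsum("ij,ij->i", points - corr.target_points, corr.target_normals)
    )
    side[side == 0] = 1.0
    signed_um = 1000.0 * corr.distances * side
    if partition is not None:
        regions = partition.face_labels[corr.face_indices]
    else:
        regions = np.full(len(points), "all", dtype=object)
    return DeviationField(points, signed_um, regions, reference=reference.name)


def summarize(field: DeviationField) -> CongruenceSummary:
    """Quantitative congruence summary of a deviation field."""
    d = field.signed_um
    if len(d) < 2:
        raise InsufficientDataError("need at least 2 samples to summarise")
    a = np.abs(d)
    mean_abs = float(a.mean())
    sd_abs = float(a.std(ddof=1))
    q1, med, q3 = np.percentile(a, [25, 50, 75])  # linear interpolation
    half = 1.96 * sd_abs / np.sqrt(len(a))
    return CongruenceSummary(
        mean_abs=mean_abs,
        sd_abs=sd_abs,
        mean_signed=float(d.mean()),
        median=float(med),
        q1_q3=(float(q1), float(q3)),
        range=(float(a.min()), float(a.max())),
        ci95=(mean_abs - half, mean_abs + half),
        n_samples=len(a),
    )


def classify_bins(
    field: DeviationField, bins: ColorBinSpec | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Classify each sample as inward / none / outward and tabulate
    per-region class fractions.

    Values beyond ``scale_max`` saturate on a rendered map but classify the
    same as any out-of-band value.  Fractions sum to 1 in every region.
    """
    bins = bins or ColorBinSpec()
    d = field.signed_um
    classes = np.full(len(d), CLASS_NONE, dtype=object)
    classes[d > bins.green_band] = CLASS_OUTWARD
    classes[d < -bins.green_band] = CLASS_INWARD
    df = pd.DataFrame({"region": field.regions, "cls": classes})
    frac = (
        df.groupby("region")["cls"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=[CLASS_INWARD, CLASS_NONE, CLASS_OUTWARD], fill_value=0.0)
    )
    return classes, frac


def direction_label(
    field: DeviationField, bins: ColorBinSpec | None = None, region: str | None = None
) -> str:
    """Majority colorimetric direction of a region (or the whole field).

    Returns 'outward deviation', 'no deviation' or 'inward deviation'; any
    tie for the majority is resolved to 'no deviation'.
    """
    bins = bins or ColorBinSpec()
    mask = np.ones(field.n_samples, dtype=bool)
    if region is not None:
        mask = field.regions == region
        if not mask.any():
            raise InsufficientDataError(f"region {region!r} has no samples")
    d = field.signed_um[mask]
    counts = {
        CLASS_INWARD: int((d < -bins.green_band).sum()),
        CLASS_NONE: int((np.abs(d) <= bins.green_band).sum()),
        CLASS_OUTWARD: int((d > bins.green_band).sum()),
    }
    top = max(counts.values())
    winners = [c for c, v in counts.items() if v == top]
    cls = winners[0] if len(winners) == 1 else CLASS_NONE
    return _CLASS_TO_LABEL[cls]


def export_field_ply(field: DeviationField, path) -> None:
    """Write the samples as an ascii PLY point cloud with a ``signed_um``
    per-vertex scalar, for external rendering of the colour map."""
    n = field.n_samples
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {n}",
        "property float x",
        "property float y",
        "property float z",
        "property float signed_um",
        "end_header",
    ]
    for p, d in zip(field.positions, field.signed_um):
        lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {d:.3f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_field_csv(field: DeviationField, path) -> None:
    """Write the field as (x, y, z, signed_um, region, class) CSV."""
    classes, _ = classify_bins(field)
    pd.DataFrame(
        {
            "x_mm": field.positions[:, 0],
            "y_mm": field.positions[:, 1],
            "z_mm": field.positions[:, 2],
            "signed_um": field.signed_um,
            "region": field.regions,
            "class": classes,
        }
    ).to_csv(path, index=False)
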