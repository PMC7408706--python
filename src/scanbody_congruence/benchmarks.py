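"""Self-contained evaluation experiments for the pipeline.

Each function runs one verification study end to end and returns plain
numbers: the balanced reanalysis of the bundled five-scanner benchmark
cells, registration recovery of a known rigid perturbation, mean-deviation
recovery across imposed offsets, the null-calibration of the Tukey scanner
comparison, and the full-scale synthetic study.  The analysis drivers and
the acceptance script are thin wrappers over these.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import study_stats
from .datasets import load_ios_study_cells
from .deviation import label_regions, signed_deviation, summarize, direction_label
from .pipeline import StudyConfig, register_scan, run_stats, run_study
from .registration import (
    ICPConfig,
    RigidTransform,
    SurfaceIndex,
    brute_force_closest,
    icp_point_to_plane,
)
from .synthetic_scanbody import (
    ErrorModel,
    ScanbodySpec,
    build_library_mesh,
    simulate_deviation_table,
    simulate_scan,
)


def _child(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# balanced reanalysis of the bundled benchmark cells
# ---------------------------------------------------------------------------


def balanced_reference_reanalysis() -> dict[str, float]:
    """Scanner means and Tukey contrast estimates from the bundled cell
    table, under the balanced two-level identity.  Values in um, rounded
    half-up to the report precision (0.1 for means, 0.01 for contrasts)."""
    cells = load_ios_study_cells()
    est = study_stats.scanner_estimates(cells).set_index("scanner")["estimate_um"]
    con = study_stats.scanner_contrasts(cells).set_index("pair")["estimate_um"]
    sbc = study_stats.sb_contrasts(cells).set_index(["scanner", "pair"])["estimate_um"]
    r1 = lambda x: study_stats.round_half_up(x, 1)  # noqa: E731
    r2 = lambda x: study_stats.round_half_up(x, 2)  # noqa: E731
    return {
        "primescan_mean_um": r1(est["PRIMESCAN"]),
        "emerald_mean_um": r1(est["EMERALD_S"]),
        "contrast_primescan_cs3700_um": r2(con["PRIMESCAN - CS3700"]),
        "contrast_primescan_medit_um": r2(con["PRIMESCAN - MEDIT_I500"]),
        "contrast_primescan_emerald_um": r2(con["PRIMESCAN - EMERALD_S"]),
        "contrast_cs3700_medit_um": r2(con["CS3700 - MEDIT_I500"]),
        "contrast_cs3700_emerald_um": r2(con["CS3700 - EMERALD_S"]),
        "contrast_medit_emerald_um": r2(con["MEDIT_I500 - EMERALD_S"]),
        "sb_contrast_primescan_s3_s2_um": r2(sbc[("PRIMESCAN", "S3 - S2")]),
        "sb_contrast_emerald_s4_s2_um": r2(sbc[("EMERALD_S", "S4 - S2")]),
    }


# ---------------------------------------------------------------------------
# registration recovery on a fine mesh
# ---------------------------------------------------------------------------


def icp_recovery_benchmark(
    seed: int,
    mesh_edge_length: float = 0.1,
    rotation_deg: float = 2.0,
    translation_um: float = 50.0,
    n_query_points: int = 1000,
) -> dict[str, float]:
    """Recover a known (rotation, translation) perturbation of a finely
    tessellated (~20k vertex) scanbody, and verify the accelerated
    nearest-point query against the all-triangles brute force."""
    spec = ScanbodySpec(mesh_edge_length=mesh_edge_length)
    library = build_library_mesh(spec)
    index = SurfaceIndex(library)
    rng = np.random.default_rng(_child(seed, 1))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    t_dir = rng.normal(size=3)
    t_dir /= np.linalg.norm(t_dir)
    truth = RigidTransform.from_rotvec_deg(
        rotation_deg * axis, (translation_um / 1000.0) * t_dir
    )
    source = library.transformed(truth.rotation, truth.translation)
    cfg = ICPConfig(
        min_iterations=100, max_iterations=120, sample_count=4000, seed=_child(seed, 2)
    )
    recovered, trace = icp_point_to_plane(source, library, config=cfg, index=index)
    err = recovered.compose(truth)

    pts = rng.uniform(-6, 16, (n_query_points, 3))
    fast = index.query(pts).distances
    oracle = brute_force_closest(pts, library)
    return {
        "rotation_error_deg": err.rotation_angle_deg(),
        "translation_error_um": 1000.0 * float(np.linalg.norm(err.translation)),
        "nearest_query_max_error_um": 1000.0 * float(np.abs(fast - oracle).max()),
        "n_vertices": library.n_vertices,
        "n_iterations": len(trace),
    }


# ---------------------------------------------------------------------------
# offset recovery through the full pipeline
# ---------------------------------------------------------------------------


def offset_recovery_benchmark(
    seed: int,
    offsets_um: tuple[float, ...] = (-40.0, -20.0, -10.0, 10.0, 20.0, 40.0),
    n_seeds: int = 10,
    noise_sd_um: float = 5.0,
) -> pd.DataFrame:
    """simulate -> landmark align -> robust ICP -> deviation, for each
    imposed offset and replicate seed.  Returns one row per run with the
    recovered mean absolute deviation and majority direction label."""
    spec = ScanbodySpec()
    library = build_library_mesh(spec)
    index = SurfaceIndex(library)
    partition = label_regions(library, spec=spec)
    icp_cfg = ICPConfig(min_iterations=30, max_iterations=40, sample_count=400)
    rows = []
    for offset in offsets_um:
        for rep in range(n_seeds):
            run_seed = _child(seed, 10_000 + 100 * rep + int(offset) % 97)
            model = ErrorModel(
                normal_offset_mean_um=offset,
                surface_noise_sd_um=noise_sd_um,
                rigid_jitter_rotation_sd_deg=1.0,
                rigid_jitter_translation_sd_um=200.0,
            )
            scan = simulate_scan(library, model, seed=run_seed)
            rng = np.random.default_rng(run_seed + 1)
            transform, _ = register_scan(
                scan, library, spec,
                dataclasses.replace(icp_cfg, seed=run_seed), index, rng,
            )
            fld = signed_deviation(
                scan, library, transform=transform, partition=partition, index=index
            )
            summary = summarize(fld)
            rows.append(
                {
                    "offset_um": offset,
                    "replicate": rep,
                    "mean_abs_um": summary.mean_abs,
                    "mean_signed_um": summary.mean_signed,
                    "direction": direction_label(fld),
                }
            )
    return pd.DataFrame(rows)


def summarize_offset_recovery(runs: pd.DataFrame) -> dict[str, float]:
    """Largest relative error of the seed-averaged |offset| recovery, and
    the fraction of runs whose majority direction matches the offset sign."""
    rel_errors = []
    for offset, sub in runs.groupby("offset_um"):
        avg = sub["mean_abs_um"].mean()
        rel_errors.append(abs(avg - abs(offset)) / abs(offset))
    expected = np.where(runs["offset_um"] > 0, "outward deviation", "inward deviation")
    agreement = float((runs["direction"] == expected).mean())
    return {
        "max_relative_error": float(max(rel_errors)),
        "direction_agreement_rate": agreement,
        "n_runs": len(runs),
    }


# ---------------------------------------------------------------------------
# null calibration of the scanner comparison
# ---------------------------------------------------------------------------


def null_tukey_rate(
    seed: int,
    n_studies: int = 500,
    n_scanners: int = 3,
    n_models: int = 5,
    alpha: float = study_stats.ALPHA,
) -> dict[str, float]:
    """Fraction of Tukey-significant scanner pairs when every scanner has
    the same true mean (scanbody effects shared, replicate noise i.i.d.)."""
    rng = np.random.default_rng(_child(seed, 3))
    means = {f"scanner_{i}": 30.0 for i in range(n_scanners)}
    n_sig = 0
    n_pairs = 0
    for _ in range(n_studies):
        table = simulate_deviation_table(means, n_models, rng)
        con = study_stats.scanner_contrasts(
            study_stats.describe_cells(table), alpha=alpha
        )
        n_sig += int(con["significant"].sum())
        n_pairs += len(con)
    return {
        "significant_pair_rate": n_sig / n_pairs,
        "n_studies": n_studies,
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# full-scale synthetic study
# ---------------------------------------------------------------------------


def full_study_config(seed: int) -> StudyConfig:
    """The reference full-scale run: five shipped scanner profiles, 10 model
    replicates, six scanbodies (300 superimpositions), 100 ICP iterations at
    reduced sampling (600 points) so a single CPU completes in minutes."""
    cfg = StudyConfig(seed=seed)
    cfg.icp = dataclasses.replace(
        cfg.icp, min_iterations=100, max_iterations=110, sample_count=600
    )
    return cfg


def run_full_study(seed: int):
    """Execute the full-scale study and its statistical battery."""
    result = run_study(full_study_config(seed))
    stats_bundle = run_stats(result.deviation_table)
    return result, stats_bundle
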