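# scanbody-congruence

Mesh-congruence metrology for dental implant scanbodies.

When prosthetic CAD modelling starts, the scanned mesh (ME) of each
implant scanbody is replaced by the manufacturer's exact CAD model — the
library file (LF) — through a best-fit superimposition.  If ME and LF are
not dimensionally congruent, the implant's virtual position is wrong and
the error propagates into the fit of the restoration.  This package
measures that congruence and analyses it at study scale, for researchers
in digital dentistry and 3D surface metrology:

* **synthetic scanbody scans** — a parametric 13 mm flat-faced cylindrical
  scanbody reference plus simulated scans with controlled error
  signatures (manufacturing tolerance within ±20 µm, outward/inward/mixed
  scanner offsets, smoothing, Gaussian noise, rigid jitter);
* **registration** — three-point landmark alignment (orthogonal
  Procrustes) followed by robust point-to-plane ICP with ≥ 100 iterations
  and exact accelerated nearest-point queries;
* **deviation analysis** — signed point-to-surface deviations in µm,
  congruence summaries (mean ± SD, median, quartiles, range, 95% CI of
  the absolute deviations), and the colorimetric inward/none/outward
  classification (±50 µm scale, ±1 µm green band) per scanbody region
  (flat central / flat lateral / back);
* **study statistics** — balanced scanner estimates and Tukey-adjusted
  pairwise contrasts, within-scanner scanbody contrasts, Friedman rank
  tests across replicates with Holm adjustment, agglomerative
  biclustering of the scanner × scanbody matrix (α = 0.01 throughout).

The core registration model: the scan is moved onto the reference by the
rigid transform minimising the robustly weighted point-to-plane energy

    E(R, t) = Σᵢ wᵢ [ nᵢ · (R pᵢ + t − qᵢ) ]²

where qᵢ is the exact nearest point on the reference surface to the
transformed sample pᵢ and nᵢ its outward normal.  Congruence is then
summarised as the mean absolute signed point-to-surface deviation, with
the sign (+ outside / − inside the reference) carrying the direction of
the scanner's error.

## Worked example

The package bundles the cell-level summary of a five-scanner benchmark
(mean absolute ME–LF deviation per scanner × scanbody position over 10
replicate scans).  Because the design is balanced, scanner-level results
are exact functions of the cell means:

```
$ python analysis/01_reference_reanalysis.py
Scanner estimates (balanced means of six cell means, um):
   scanner  estimate_um  sd_total_um  ci95_low  ci95_high  n_cells
 PRIMESCAN        25.50         5.01     21.76      29.24        6
    CS3700        27.08         4.33     24.44      29.73        6
MEDIT_I500        29.87         4.90     24.89      34.84        6
  ITERO_5D        35.27         9.38     29.25      41.29        6
 EMERALD_S        38.30         7.89     29.69      46.91        6
```

PRIMESCAN shows the highest congruence (25.5 µm mean absolute deviation)
and Emerald S the lowest (38.3 µm); the PRIMESCAN − CS3700 difference is
−1.58 µm (Tukey-adjusted, not significant at α = 0.01), while
PRIMESCAN − EMERALD_S is −12.80 µm (significant).  The scanbody columns
S3 and S4 cluster apart from the rest — they carry the largest deviations
for four of the five scanners, consistent with per-post manufacturing
tolerance.

A full synthetic study (5 error profiles × 10 replicate models × 6 arch
positions = 300 superimpositions) runs end to end with:

```
$ python analysis/02_run_synthetic_study.py
300 superimpositions in 359 s
```

and emits the deviation table, registration logs, report-shaped CSV
tables and a markdown report (including the qualitative
direction-predominance table in +/++/+++ notation) under
`results/synthetic_study/`.  `analysis/03_calibration_checks.py` verifies
the chain against ground truth: a known (2°, 50 µm) perturbation of a
~20k-vertex scanbody is recovered to ≈ 1e-15 degree / 1e-12 µm, imposed
offsets of −40..+40 µm come back within 10% with the correct direction
label, and under a null study Tukey-significant scanner pairs occur at a
rate of ~0.005 ≤ α.

Library usage mirrors the scripts:

```python
from scanbody_congruence import (
    ScanbodySpec, ErrorModel, build_library_mesh, simulate_scan,
    icp_point_to_plane, signed_deviation, summarize,
)

library = build_library_mesh(ScanbodySpec())
scan = simulate_scan(library, ErrorModel(normal_offset_mean_um=-30,
                                         surface_noise_sd_um=10), seed=7)
transform, trace = icp_point_to_plane(scan, library)
field = summarize(signed_deviation(scan, library, transform=transform))
print(field.as_mean_sd())   # "29 ± 10 μm"
```

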