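"""Hierarchical statistics for a scanner x scanbody deviation study.

The input is a long-format table of per-superimposition mean absolute
deviations (um): one row per (scanner, scanbody position, model replicate).
The battery mirrors a standard metrology analysis of such a design:

* per-cell descriptives (mean, SD, median, quartiles);
* scanner-level estimates under the balanced two-level identity — for a
  balanced design the scanner mean equals the unweighted average of its six
  scanbody cell means, which makes point estimates exact without a full
  REML fit;
* Tukey-adjusted pairwise scanner contrasts (studentized-range adjustment,
  tested against the scanner x scanbody interaction mean square, since the
  six physical scanbodies are shared by all scanners);
* Tukey-adjusted scanbody contrasts within each scanner (two-way layout,
  pooled within-cell error);
* Friedman rank tests comparing model replicates within each scanner
  (scanbody as the blocking variable), Holm-adjusted across scanners;
* agglomerative hierarchical biclustering of the scanner x scanbody matrix
  of cell means or cell SDs.

The working significance level throughout is alpha = 0.01.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .errors import IncompleteBlocksError, InsufficientDataError, ParameterError

ALPHA = 0.01

VALUE_COL = "mean_abs_dev_um"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report-table convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# table handling
# ---------------------------------------------------------------------------


def validate_deviation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format study table: unique (scanner, sb, model) keys
    and positive deviations."""
    required = {"scanner", "sb", "model", VALUE_COL}
    missing = required - set(table.columns)
    if missing:
        raise ParameterError(f"deviation table lacks columns: {sorted(missing)}")
    if table.duplicated(["scanner", "sb", "model"]).any():
        raise ParameterError("duplicate (scanner, sb, model) rows")
    if (table[VALUE_COL] <= 0).any():
        raise ParameterError("deviations must be positive (um)")
    return table


def _is_cells(df: pd.DataFrame) -> bool:
    return "mean" in df.columns and VALUE_COL not in df.columns


def describe_cells(table: pd.DataFrame, min_n: int = 2) -> pd.DataFrame:
    """Per (scanner, sb) descriptives: n, mean, SD, median, Q1, Q3.

    Cells with fewer than ``min_n`` replicates are reported as absent (they
    cannot carry an SD), never imputed.
    """
    validate_deviation_table(table)
    g = table.groupby(["scanner", "sb"])[VALUE_COL]
    cells = g.agg(
        n="count",
        mean="mean",
        sd=lambda s: s.std(ddof=1),
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
    ).reset_index()
    return cells[cells["n"] >= min_n].reset_index(drop=True)


def format_cell(mean: float, sd: float, median: float, q1: float, q3: float) -> str:
    """Render one cell as ``mean (SD); median; (Q1–Q3)`` at 0.1 um."""
    r = lambda v: f"{round_half_up(v, 1):.1f}"  # noqa: E731
    return f"{r(mean)} ({r(sd)}); {r(median)}; ({r(q1)}–{r(q3)})"


def flag_outliers(
    table: pd.DataFrame,
    rule: str = "robust_z",
    threshold: float = 3.0,
    manual: list[tuple[str, str, int]] | None = None,
) -> pd.Series:
    """Boolean mask of outlying observations (True = flagged).

    ``robust_z`` (default) flags values whose modified z-score within the
    cell, ``(x - median) / (1.4826 MAD)``, exceeds ``threshold``; when the
    MAD collapses to zero the leave-one-out z-score is used instead.  (A
    plain within-cell z-score cannot exceed ``(n-1)/sqrt(n)`` ~ 2.85 at
    n = 10, so it could never flag anything at a threshold of 3.)
    Flagged rows are meant to be excluded from the parametric estimates
    only; rank tests and descriptives keep the full data.
    """
    validate_deviation_table(table)
    flags = pd.Series(False, index=table.index)
    if rule == "none":
        return flags
    if rule == "manual":
        manual = manual or []
        for scanner, sb, model in manual:
            hit = (
                (table["scanner"] == scanner)
                & (table["sb"] == sb)
                & (table["model"] == model)
            )
            flags |= hit
        return flags
    if rule != "robust_z":
        raise ParameterError(f"unknown outlier rule {rule!r}")
    for _, idx in table.groupby(["scanner", "sb"]).groups.items():
        x = table.loc[idx, VALUE_COL].to_numpy(dtype=float)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad > 0:
            z = (x - med) / (1.4826 * mad)
        else:
            z = np.zeros_like(x)
            for i in range(len(x)):
                rest = np.delete(x, i)
                s = rest.std(ddof=1)
                z[i] = (x[i] - rest.mean()) / s if s > 0 else 0.0
        flags.loc[np.asarray(idx)[np.abs(z) > threshold]] = True
    return flags


# ---------------------------------------------------------------------------
# scanner-level estimation and contrasts
# ---------------------------------------------------------------------------


def _cells_from(data: pd.DataFrame) -> pd.DataFrame:
    if _is_cells(data):
        if not {"scanner", "sb", "mean"} <= set(data.columns):
            raise ParameterError("cells need scanner, sb, mean columns")
        return data.copy()
    return describe_cells(data)


def scanner_estimates(data: pd.DataFrame) -> pd.DataFrame:
    """Per-scanner mean absolute deviation with 95% CI.

    Accepts either the long table or a cell-summary frame.  Under the
    balanced design the estimate is the unweighted mean of the scanner's
    scanbody cell means; the CI uses the between-scanbody spread of those
    cell means (t, 5 df).  When cell SDs and counts are available the total
    observation-level SD (within + between cells) is also reported.
    """
    cells = _cells_from(data)
    rows = []
    for scanner, sub in cells.groupby("scanner", sort=False):
        m = sub["mean"].to_numpy(dtype=float)
        if len(m) < 2:
            raise InsufficientDataError(f"scanner {scanner!r} has <2 scanbody cells")
        est = m.mean()
        se = m.std(ddof=1) / np.sqrt(len(m))
        tcrit = stats.t.ppf(0.975, len(m) - 1)
        sd_total = np.nan
        if {"sd", "n"} <= set(sub.columns) and sub["sd"].notna().all():
            n_i = sub["n"].to_numpy(dtype=float)
            s_i = sub["sd"].to_numpy(dtype=float)
            grand = np.sum(n_i * m) / n_i.sum()
            ss = np.sum((n_i - 1) * s_i**2) + np.sum(n_i * (m - grand) ** 2)
            sd_total = float(np.sqrt(ss / (n_i.sum() - 1)))
        rows.append(
            {
                "scanner": scanner,
                "estimate_um": est,
                "sd_total_um": sd_total,
                "ci95_low": est - tcrit * se,
                "ci95_high": est + tcrit * se,
                "n_cells": len(m),
            }
        )
    return pd.DataFrame(rows)


def _cell_mean_matrix(cells: pd.DataFrame) -> pd.DataFrame:
    mat = cells.pivot(index="scanner", columns="sb", values="mean")
    if mat.isna().any().any():
        raise IncompleteBlocksError("scanner x sb cell-mean matrix has holes")
    # preserve first-appearance order of scanners
    order = cells["scanner"].drop_duplicates().tolist()
    return mat.loc[order]


def scanner_contrasts(data: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """All pairwise scanner differences, Tukey-adjusted.

    Point estimates are differences of balanced scanner means.  The error
    term is the scanner x scanbody interaction mean square of the cell-mean
    layout (df = (k-1)(b-1)), appropriate when the scanbody positions are a
    shared blocking factor.  p-values and 95% confidence limits come from
    the studentized-range distribution; ``significant`` applies ``alpha``.
    """
    cells = _cells_from(data)
    mat = _cell_mean_matrix(cells)
    k, b = mat.shape
    if k < 2:
        raise InsufficientDataError("need at least two scanners")
    x = mat.to_numpy(dtype=float)
    rowm = x.mean(axis=1, keepdims=True)
    colm = x.mean(axis=0, keepdims=True)
    grand = x.mean()
    ss_int = float(((x - rowm - colm + grand) ** 2).sum())
    df_err = (k - 1) * (b - 1)
    s2 = ss_int / df_err
    se_mean = np.sqrt(s2 / b)
    qcrit = stats.studentized_range.ppf(0.95, k, df_err)
    means = dict(zip(mat.index, x.mean(axis=1)))
    rows = []
    for a, c in itertools.combinations(mat.index, 2):
        diff = means[a] - means[c]
        q_obs = abs(diff) / se_mean if se_mean > 0 else np.inf
        p_adj = float(stats.studentized_range.sf(q_obs, k, df_err)) if se_mean > 0 else 0.0
        if diff == 0:
            p_adj = 1.0
        t_obs = abs(diff) / (se_mean * np.sqrt(2)) if se_mean > 0 else np.inf
        p_raw = float(2 * stats.t.sf(t_obs, df_err)) if diff != 0 else 1.0
        rows.append(
            {
                "pair": f"{a} - {c}",
                "estimate_um": diff,
                "ci95_low": diff - qcrit * se_mean,
                "ci95_high": diff + qcrit * se_mean,
                "p_unadjusted": min(p_raw, 1.0),
                "p_adjusted": min(p_adj, 1.0),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def sb_contrasts(data: pd.DataFrame, alpha: float = ALPHA) -> pd.DataFrame:
    """All 15 scanbody-pair contrasts within each scanner, Tukey-adjusted.

    Estimates are differences of cell means (the two-way-with-interaction
    fit reproduces them exactly in a balanced design).  The error term is
    the within-cell mean square pooled over the whole table; the Tukey
    family is the 15 pairs within one scanner (6 groups).
    """
    cells = _cells_from(data)
    mat = _cell_mean_matrix(cells)
    have_inference = {"sd", "n"} <= set(cells.columns) and cells["sd"].notna().all()
    if have_inference:
        n_i = cells["n"].to_numpy(dtype=float)
        s_i = cells["sd"].to_numpy(dtype=float)
        df_err = int(np.sum(n_i - 1))
        s2p = float(np.sum((n_i - 1) * s_i**2) / np.sum(n_i - 1))
        n_rep = float(stats.hmean(n_i))
        se_mean = np.sqrt(s2p / n_rep)
        qcrit = stats.studentized_range.ppf(0.95, mat.shape[1], df_err)
    rows = []
    sbs = sorted(mat.columns)
    for scanner in mat.index:
        for hi, lo in itertools.combinations(reversed(sbs), 2):
            diff = float(mat.loc[scanner, hi] - mat.loc[scanner, lo])
            row = {"scanner": scanner, "pair": f"{hi} - {lo}", "estimate_um": diff}
            if have_inference:
                q_obs = abs(diff) / se_mean if se_mean > 0 else np.inf
                p = float(stats.studentized_range.sf(q_obs, mat.shape[1], df_err))
                if diff == 0:
                    p = 1.0
                row.update(
                    ci95_low=diff - qcrit * se_mean,
                    ci95_high=diff + qcrit * se_mean,
                    p_adjusted=min(p, 1.0),
                    significant=p < alpha,
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Friedman rank tests across model replicates
# ---------------------------------------------------------------------------


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def friedman_statistic(blocks: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square for a (b blocks x k treatments) matrix.

    Average ranks within each block, with the standard tie correction
    ``1 - sum(t^3 - t) / (b k (k^2 - 1))``; the p-value is the chi-square
    approximation with k - 1 df.  Closed form, so it also covers the
    two-treatment case that library implementations often refuse.
    """
    x = np.asarray(blocks, dtype=float)
    b, k = x.shape
    if k < 2 or b < 2:
        raise InsufficientDataError("need >= 2 treatments and >= 2 blocks")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    r_j = ranks.sum(axis=0)
    stat = 12.0 / (b * k * (k + 1)) * np.sum(r_j**2) - 3.0 * b * (k + 1)
    tie_sum = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (b * k * (k**2 - 1))
    if correction <= 0:  # every block fully tied
        return 0.0, 1.0
    stat /= correction
    return float(stat), float(stats.chi2.sf(stat, k - 1))


def friedman_by_scanner(table: pd.DataFrame) -> pd.DataFrame:
    """Friedman rank test of model replicates within each scanner, with the
    scanbody position as the blocking variable; Holm adjustment across the
    scanner family.  Requires complete blocks (every model on every sb)."""
    validate_deviation_table(table)
    results = []
    for scanner, sub in table.groupby("scanner", sort=False):
        pivot = sub.pivot(index="sb", columns="model", values=VALUE_COL)
        if pivot.isna().any().any():
            missing = [
                (scanner, pivot.index[i], int(pivot.columns[j]))
                for i, j in zip(*np.where(pivot.isna().to_numpy()))
            ]
            raise IncompleteBlocksError(f"incomplete blocks, missing cells: {missing}")
        stat, p = friedman_statistic(pivot.to_numpy())
        results.append({"scanner": scanner, "statistic": float(stat), "p_raw": float(p)})
    out = pd.DataFrame(results)
    out["p_adjusted"] = holm_adjust(out["p_raw"])
    return out


# ---------------------------------------------------------------------------
# biclustering
# ---------------------------------------------------------------------------


@dataclass
class BiclusterResult:
    """Independent agglomerative clustering of rows and columns."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray


def bicluster(
    matrix: pd.DataFrame, linkage: str = "average", metric: str = "euclidean"
) -> BiclusterResult:
    """Cluster the scanner x scanbody matrix rows and columns independently.

    Average linkage on Euclidean distances by default (common heatmap
    convention); both configurable.  SciPy's pairwise merge order is
    deterministic for a fixed input, so results are reproducible.
    """
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ParameterError("biclustering needs a complete finite matrix")
    row_z = hierarchy.linkage(pdist(x, metric=metric), method=linkage)
    col_z = hierarchy.linkage(pdist(x.T, metric=metric), method=linkage)
    return BiclusterResult(
        row_order=[matrix.index[i] for i in hierarchy.leaves_list(row_z)],
        col_order=[matrix.columns[i] for i in hierarchy.leaves_list(col_z)],
        row_linkage=row_z,
        col_linkage=col_z,
    )


def cell_matrix(cells: pd.DataFrame, value: str = "mean") -> pd.DataFrame:
    """Pivot a cell-summary frame into a scanner x sb matrix of ``value``."""
    mat = cells.pivot(index="scanner", columns="sb", values=value)
    order = cells["scanner"].drop_duplicates().tolist()
    return mat.loc[order]
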