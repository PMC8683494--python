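"""Group comparisons across implant classes (S, S+G, S+G+D, D).

Coverage distributions are skewed and small-sample, so group differences
use the rank-based Kruskal-Wallis test (chi-squared approximation, tie
corrected) with Bonferroni correction over each family of pairwise
contrasts; Dice-coefficient distributions are compared with Pearson's
chi-squared on binned values. Non-parametric tests get non-parametric
summaries: medians with interquartile ranges.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .coverage import NAMED_RADII_MM, CoverageCurve, RegionCoverage

log = logging.getLogger(__name__)


@dataclass
class PatientCoverageRecord:
    """One patient's coverage results, the unit of the cohort analysis."""

    patient_id: str
    implant_class: str
    curve: CoverageCurve
    regions: RegionCoverage | None = None  # at the 5 mm reference radius
    inclusion: dict[str, bool] = field(default_factory=dict)
    dice: pd.DataFrame | None = None  # per contact x radius, if FEM ran


# ---------------------------------------------------------------------------
# Test primitives
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p-value.

    Convention: if every value in every group is identical there is no rank
    information at all; returns (H=0, p=1).
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def bonferroni(p_values: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p * m)."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return np.minimum(1.0, np.asarray(p_values, dtype=float) * m)


def pearson_chi2(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson's chi-squared statistic, p-value and df for a contingency
    table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p), int(dof)


# ---------------------------------------------------------------------------
# Modality comparisons
# ---------------------------------------------------------------------------


def _per_contact_values(
    records: list[PatientCoverageRecord], radius_mm: float, tissue: str
) -> dict[str, np.ndarray]:
    by_class: dict[str, list[float]] = {}
    for rec in records:
        by_class.setdefault(rec.implant_class, []).append(
            rec.curve.value(radius_mm, tissue, "per_contact")
        )
    return {k: np.asarray(v) for k, v in by_class.items()}


def compare_modalities(
    records: list[PatientCoverageRecord],
    radius_mm: float,
    tissue: str = "gm",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise implant-class comparisons of per-contact coverage at one
    radius, Bonferroni-corrected over the pair count. Classes with fewer
    than 2 patients are excluded (and logged)."""
    groups = _per_contact_values(records, radius_mm, tissue)
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(usable))
    if dropped:
        log.warning("classes %s have < 2 patients; excluded from testing", dropped)
    if len(usable) < 2:
        raise ValueError("need >= 2 implant classes with >= 2 patients each")
    pairs = list(itertools.combinations(sorted(usable), 2))
    rows = []
    for a, b in pairs:
        h, p = kruskal_wallis([usable[a], usable[b]])
        rows.append(
            {
                "radius_mm": radius_mm,
                "tissue": tissue,
                "group_a": a,
                "group_b": b,
                "median_a": float(np.median(usable[a])),
                "median_b": float(np.median(usable[b])),
                "H": h,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bonferroni(out.p_raw.values, len(pairs))
    out["significant"] = out.p_adj < alpha
    return out


def _bin_dice(
    groups: dict[str, np.ndarray], n_bins: int, min_expected: float
) -> np.ndarray:
    pooled = np.concatenate(list(groups.values()))
    edges = np.unique(np.quantile(pooled, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise ValueError("Dice values too degenerate to bin")
    edges[0], edges[-1] = -np.inf, np.inf
    table = np.array(
        [np.histogram(v, bins=edges)[0] for v in groups.values()], dtype=float
    )
    # pool adjacent bins until every expected count reaches the floor
    while table.shape[1] > 2:
        colsum = table.sum(axis=0)
        expected = np.outer(table.sum(axis=1), colsum) / table.sum()
        if expected.min() >= min_expected:
            break
        j = expected.min(axis=0).argmin()
        k = j + 1 if j + 1 < table.shape[1] else j - 1
        table[:, min(j, k)] += table[:, max(j, k)]
        table = np.delete(table, max(j, k), axis=1)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < min_expected:
        raise ValueError("insufficient counts after pooling bins")
    return table


def dice_group_test(
    dice_by_group: dict[str, np.ndarray],
    n_bins: int = 10,
    min_expected: float = 5.0,
    method: str = "chi2",
) -> dict:
    """Compare Dice distributions across modality groups.

    Default is Pearson's chi-squared on decile-binned values (bins pooled to
    an expected count >= 5 per cell); ``method='kruskal'`` is the rank-test
    alternative reading.
    """
    if len(dice_by_group) < 2:
        raise ValueError("need >= 2 groups")
    groups = {k: np.asarray(v, dtype=float) for k, v in dice_by_group.items()}
    if method == "kruskal":
        h, p = kruskal_wallis(list(groups.values()))
        return {"method": "kruskal", "stat": h, "p": p, "df": len(groups) - 1}
    table = _bin_dice(groups, n_bins, min_expected)
    stat, p, dof = pearson_chi2(table)
    return {"method": "chi2", "stat": stat, "p": p, "df": dof, "table": table}


# ---------------------------------------------------------------------------
# Crossover radius
# ---------------------------------------------------------------------------


def mean_curve_by_class(
    records: list[PatientCoverageRecord], tissue: str = "gm", scope: str = "per_contact"
) -> pd.DataFrame:
    """Mean coverage curve per implant class (rows: radius, cols: class)."""
    cols = {}
    for rec in records:
        s = rec.curve.series(tissue, scope)
        cols.setdefault(rec.implant_class, []).append(s)
    return pd.DataFrame(
        {cls: pd.concat(series, axis=1).mean(axis=1) for cls, series in cols.items()}
    )


def crossover_radius(
    curves_by_class: pd.DataFrame, class_a: str, class_b: str
) -> float | None:
    """Smallest swept radius at which the sign of mean(A) - mean(B) flips
    relative to its initial sign; None if the ordering never reverses."""
    diff = (curves_by_class[class_a] - curves_by_class[class_b]).values
    radii = curves_by_class.index.values
    sign0 = 0
    for d, r in zip(diff, radii):
        s = int(np.sign(d))
        if sign0 == 0:
            sign0 = s
            continue
        if s != 0 and s != sign0:
            return float(r)
    return None


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------


def summarize(records: list[PatientCoverageRecord]) -> dict[str, pd.DataFrame]:
    """Tidy cohort tables: coverage curves per class (median, IQR, mean),
    region coverage with inclusion counts, and Dice summaries."""
    if not records:
        raise ValueError("no patient records")
    curve_rows = []
    for rec in records:
        t = rec.curve.table.copy()
        t["patient_id"] = rec.patient_id
        t["implant_class"] = rec.implant_class
        curve_rows.append(t)
    curves = pd.concat(curve_rows, ignore_index=True)
    curve_summary = (
        curves.groupby(["implant_class", "tissue", "scope", "radius_mm"])
        .volume_mm3.agg(
            median="median",
            q1=lambda v: v.quantile(0.25),
            q3=lambda v: v.quantile(0.75),
            mean="mean",
            n="count",
        )
        .reset_index()
    )

    region_rows = []
    for rec in records:
        if rec.regions is None:
            continue
        for r in rec.regions.table.itertuples():
            region_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "implant_class": rec.implant_class,
                    "region": r.region,
                    "volume_mm3": r.volume_mm3,
                    "included": rec.inclusion.get(str(r.region), r.volume_mm3 > 0),
                }
            )
    if region_rows:
        regions = pd.DataFrame(region_rows)
        incl = regions[regions.included]
        region_summary = (
            incl.groupby(["implant_class", "region"])
            .volume_mm3.agg(median="median", q1=lambda v: v.quantile(0.25),
                            q3=lambda v: v.quantile(0.75), n="count")
            .reset_index()
        )
        counts = (
            regions.groupby(["implant_class", "region"])
            .included.agg(n_included="sum", n_total="count")
            .reset_index()
        )
        region_summary = counts.merge(
            region_summary, on=["implant_class", "region"], how="left"
        )
    else:
        regions = pd.DataFrame()
        region_summary = pd.DataFrame()

    dice_rows = [rec.dice for rec in records if rec.dice is not None]
    if dice_rows:
        dice_all = pd.concat(dice_rows, ignore_index=True)
        dice_summary = (
            dice_all.groupby(["implant_class", "radius_mm"])
            .dice.agg(median="median", q1=lambda v: v.quantile(0.25),
                      q3=lambda v: v.quantile(0.75), n="count")
            .reset_index()
        )
    else:
        dice_summary = pd.DataFrame()

    return {
        "curves": curves,
        "curve_summary": curve_summary,
        "regions": regions,
        "region_summary": region_summary,
        "dice_summary": dice_summary,
    }


def named_radius_comparisons(
    records: list[PatientCoverageRecord],
    radii_mm: tuple = NAMED_RADII_MM,
    tissues: tuple = ("gm", "wm"),
) -> pd.DataFrame:
    """Pairwise class comparisons at the named radii for each tissue."""
    frames = []
    for tissue in tissues:
        for r in radii_mm:
            try:
                frames.append(compare_modalities(records, r, tissue))
            except (ValueError, KeyError):
                continue  # class too small, or radius not in the sweep
    if not frames:
        raise ValueError("no comparable classes at any named radius")
    return pd.concat(frames, ignore_index=True)
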