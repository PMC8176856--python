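"""Volumetric-agreement statistics for threshold-grid sweeps.

Evaluates each segmentation family over its threshold grid against the
known reference volume of every case: correlation (Pearson after a
Shapiro-Wilk normality gate on both variables, otherwise Spearman),
coefficient of variation, Bland-Altman mean difference and limits of
agreement, Kruskal-Wallis group comparison, per-family ranking, and the
summary of the per-lesion backwards-thresholding experiment (mean/sd/CoV
of the individually solved thresholds, and the agreement obtained when the
single cohort-mean threshold is re-applied to every lesion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .delineation import (
    BackwardsThresholdResult,
    DelineationResult,
    backwards_threshold,
    roi_mean,
    segment_fixed,
)
from .image_model import rasterize
from .phantom import PhantomCase

__all__ = [
    "MethodGrid",
    "AgreementSummary",
    "BackwardsSummary",
    "default_grids",
    "choose_correlation_type",
    "correlate",
    "coefficient_of_variation",
    "bland_altman",
    "kruskal_wallis",
    "sweep",
    "delineate_cases",
    "summarize",
    "results_frame",
    "summaries_frame",
    "rank_methods",
    "solve_backwards",
    "backwards_summary",
    "backwards_summary_from_volumes",
]

ALPHA = 0.05  # two-sided significance level / normality-gate level


@dataclass(frozen=True)
class MethodGrid:
    """One segmentation family and its threshold grid (strictly increasing)."""

    family: str
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise ValueError("grid must contain at least one level")
        if any(b <= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError(f"levels must be strictly increasing, got {self.levels}")


def default_grids() -> list[MethodGrid]:
    """The study's threshold grids for the five families.

    Fixed thresholds in absolute SUV; all other levels as fractions of the
    per-case SUVmax (isocontour) or reference-tissue SUVmean.
    """
    return [
        MethodGrid("fixed", (2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 7.5, 10.0, 15.0)),
        MethodGrid(
            "isocontour",
            tuple(
                p / 100
                for p in (10, 15, 20, 25, 30, 35, 40, 42, 44, 45, 50, 55, 60, 65, 70, 75)
            ),
        ),
        MethodGrid("liver_rel", tuple(p / 100 for p in (45, 50, 55, 60, 70, 75))),
        MethodGrid("parotis_rel", tuple(p / 100 for p in (60, 70, 75, 80, 85, 90))),
        MethodGrid("spleen_rel", tuple(p / 100 for p in (40, 50, 55, 60, 65, 70))),
    ]


@dataclass(frozen=True)
class AgreementSummary:
    """Agreement of one family/level's volumes with the reference volumes."""

    method: str
    level: float
    correlation_type: str  # 'pearson' | 'spearman'
    r: float
    r_squared: float
    p_value: float
    bland_altman_mean_diff: float  # ml, PET - reference
    bland_altman_loa: tuple[float, float]  # ml, mean_diff -/+ 1.96 sd
    n: int


@dataclass(frozen=True)
class BackwardsSummary:
    """Cohort summary of the per-lesion inverse-threshold experiment."""

    mean_threshold: float
    sd_threshold: float
    cov_percent: float
    reapplied_agreement: AgreementSummary | None
    error: str | None = None


def choose_correlation_type(
    x: Sequence[float], y: Sequence[float], alpha: float = ALPHA
) -> str:
    """'pearson' iff both samples pass the Shapiro-Wilk test at ``alpha``.

    Deterministic given the data; constant input is rejected because the
    normality test is undefined there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError(f"need n >= 4 for the normality gate, got n={x.size}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    for name, v in (("x", x), ("y", y)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; normality test undefined")
    p_x = stats.shapiro(x).pvalue
    p_y = stats.shapiro(y).pvalue
    return "pearson" if (p_x > alpha and p_y > alpha) else "spearman"


def correlate(
    volumes_pet: Sequence[float], volumes_ref: Sequence[float]
) -> tuple[str, float, float, float]:
    """(type, r, r^2, two-sided p) between PET and reference volumes.

    The coefficient is Pearson's r when both samples pass the normality
    gate, Spearman's rho otherwise; r^2 is always the square of the
    reported coefficient.
    """
    x = np.asarray(volumes_pet, dtype=float)
    y = np.asarray(volumes_ref, dtype=float)
    kind = choose_correlation_type(x, y)
    if kind == "pearson":
        res = stats.pearsonr(x, y)
    else:
        res = stats.spearmanr(x, y)
    r = float(res.statistic)
    return kind, r, r * r, float(res.pvalue)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CoV in percent: 100 x sample sd (n-1 denominator) / mean; mean must be > 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"CoV undefined for non-positive mean {mean}")
    return float(100.0 * v.std(ddof=1) / mean)


def bland_altman(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, tuple[float, float]]:
    """Mean difference and limits of agreement mean(d) -/+ 1.96 sd(d), d = a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd)


def kruskal_wallis(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Rank-based H with tie correction and chi-square p-value.

    Degenerate all-identical data (tie correction denominator zero) is
    reported as H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 1 for g in groups):
        raise ValueError("each group needs at least 1 value")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def _agreement(
    pet_vols: Sequence[float],
    ref_vols: Sequence[float],
    method: str,
    level: float,
) -> AgreementSummary:
    kind, r, r2, p = correlate(pet_vols, ref_vols)
    mean_diff, loa = bland_altman(pet_vols, ref_vols)
    return AgreementSummary(
        method=method,
        level=level,
        correlation_type=kind,
        r=r,
        r_squared=r2,
        p_value=p,
        bland_altman_mean_diff=mean_diff,
        bland_altman_loa=loa,
        n=len(pet_vols),
    )


def delineate_cases(
    cases: Sequence[PhantomCase], grids: Sequence[MethodGrid]
) -> list[DelineationResult]:
    """One :class:`DelineationResult` per case x family x level.

    Isocontour levels use the per-case SUVmax inside the VOI; background
    families use the per-case mean SUV measured in the corresponding
    reference ROI (not the generative truth).
    """
    if not cases:
        raise ValueError("no cases")
    if not grids:
        raise ValueError("no grids")
    results: list[DelineationResult] = []
    for case in cases:
        vals = case.pet.values[rasterize(case.pet, case.voi)]
        vv = case.pet.voxel_volume_ml
        suvmax = float(vals.max())
        bg = {tissue: roi_mean(case.pet, roi) for tissue, roi in case.rois.items()}
        for grid in grids:
            for level in grid.levels:
                if grid.family == "fixed":
                    thr = level
                elif grid.family == "isocontour":
                    thr = level * suvmax
                elif grid.family.endswith("_rel"):
                    thr = level * bg[grid.family.removesuffix("_rel")]
                else:
                    raise ValueError(f"unknown family {grid.family!r}")
                n = int((vals >= thr).sum())
                results.append(
                    DelineationResult(
                        case_id=case.case_id,
                        method=grid.family,
                        level=float(level),
                        threshold_suv=float(thr),
                        n_voxels=n,
                        volume_ml=n * vv,
                    )
                )
    return results


def summarize(
    frame: pd.DataFrame, ref_volumes: dict[str, float]
) -> list[AgreementSummary]:
    """One :class:`AgreementSummary` per (method, level) in a results table.

    ``frame`` is a long-form results table as produced by
    :func:`results_frame`; ``ref_volumes`` maps case_id to the reference
    volume in ml.  Raises on case ids missing from ``ref_volumes``.
    """
    missing = set(frame["case_id"]) - set(ref_volumes)
    if missing:
        raise ValueError(f"case ids without reference volume: {sorted(missing)[:5]}")
    summaries = []
    for (method, level), sub in frame.groupby(["method", "level"], sort=True):
        pet_vols = sub["volume_ml"].to_numpy()
        ref_vols = np.array([ref_volumes[cid] for cid in sub["case_id"]])
        summaries.append(_agreement(pet_vols, ref_vols, str(method), float(level)))
    return summaries


def sweep(
    cases: Sequence[PhantomCase], grids: Sequence[MethodGrid]
) -> tuple[list[DelineationResult], list[AgreementSummary]]:
    """Delineate every case at every family/level and summarize agreement
    against each case's reference volume."""
    results = delineate_cases(cases, grids)
    ref = {c.case_id: c.ct_reference_volume_ml for c in cases}
    summaries = summarize(results_frame(results), ref)
    return results, summaries


def results_frame(results: Sequence[DelineationResult]) -> pd.DataFrame:
    """Long-form results table (one row per case x family x level)."""
    return pd.DataFrame(
        {
            "case_id": [r.case_id for r in results],
            "method": [r.method for r in results],
            "level": [r.level for r in results],
            "threshold_suv": [r.threshold_suv for r in results],
            "n_voxels": [r.n_voxels for r in results],
            "volume_ml": [r.volume_ml for r in results],
        }
    )


def summaries_frame(summaries: Sequence[AgreementSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [s.method for s in summaries],
            "level": [s.level for s in summaries],
            "correlation_type": [s.correlation_type for s in summaries],
            "r": [s.r for s in summaries],
            "r_squared": [s.r_squared for s in summaries],
            "p_value": [s.p_value for s in summaries],
            "ba_mean_diff_ml": [s.bland_altman_mean_diff for s in summaries],
            "ba_loa_low_ml": [s.bland_altman_loa[0] for s in summaries],
            "ba_loa_high_ml": [s.bland_altman_loa[1] for s in summaries],
            "n": [s.n for s in summaries],
        }
    )


def rank_methods(
    summaries: Sequence[AgreementSummary],
) -> dict[str, AgreementSummary]:
    """Best level (argmax r) within each family plus the overall best.

    Ties are broken toward the lower level.  Returned dict maps each family
    to its best summary, with key ``"overall"`` for the cross-family winner.
    """
    if not summaries:
        raise ValueError("no summaries")
    best: dict[str, AgreementSummary] = {}
    for s in sorted(summaries, key=lambda s: (s.method, s.level)):
        cur = best.get(s.method)
        if cur is None or s.r > cur.r:
            best[s.method] = s
    overall = max(
        (best[m] for m in sorted(best)), key=lambda s: s.r
    )
    out = dict(best)
    out["overall"] = overall
    return out


def solve_backwards(cases: Sequence[PhantomCase]) -> list[BackwardsThresholdResult]:
    """Per-case inverse solve targeting each case's reference volume."""
    return [
        backwards_threshold(
            c.pet, c.voi, c.ct_reference_volume_ml, case_id=c.case_id
        )
        for c in cases
    ]


def backwards_summary_from_volumes(
    thresholds: Sequence[float],
    reapplied_volumes_ml: Sequence[float],
    ref_volumes_ml: Sequence[float],
) -> BackwardsSummary:
    """Summarize inverse thresholds and the re-applied single-threshold agreement."""
    t = np.asarray(thresholds, dtype=float)
    if t.size == 0:
        raise ValueError("no thresholds")
    mean = float(t.mean())
    sd = float(t.std(ddof=1)) if t.size > 1 else 0.0
    cov = coefficient_of_variation(t) if t.size > 1 else 0.0
    try:
        agreement = _agreement(
            reapplied_volumes_ml, ref_volumes_ml, "backwards_mean", mean
        )
        error = None
    except ValueError as exc:
        agreement = None
        error = f"reapplied correlation undefined: {exc}"
    return BackwardsSummary(
        mean_threshold=mean,
        sd_threshold=sd,
        cov_percent=cov,
        reapplied_agreement=agreement,
        error=error,
    )


def backwards_summary(
    cases: Sequence[PhantomCase],
    results: Sequence[BackwardsThresholdResult],
) -> BackwardsSummary:
    """Mean/sd/CoV of per-case thresholds, then re-apply the mean threshold
    to every case and correlate the volumes against the reference."""
    if len(results) != len(cases):
        raise ValueError("need exactly one backwards result per case")
    by_id = {r.case_id: r for r in results}
    if set(by_id) != {c.case_id for c in cases}:
        raise ValueError("case ids of results do not match cases")
    thresholds = [by_id[c.case_id].threshold_suv for c in cases]
    mean_t = float(np.mean(thresholds))
    reapplied = [
        segment_fixed(c.pet, c.voi, mean_t, case_id=c.case_id).volume_ml for c in cases
    ]
    ref = [c.ct_reference_volume_ml for c in cases]
    return backwards_summary_from_volumes(thresholds, reapplied, ref)
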