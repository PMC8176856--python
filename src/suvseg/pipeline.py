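"""Reproducible simulate -> delineate -> evaluate pipeline on disk.

Stages communicate only through files: NIfTI volumes plus plain CSV tables
(comma-separated, '.' decimal, UTF-8, header row).  Every CSV starts with a
comment line recording the cohort seed and a hash of the resolved
configuration, so outputs are traceable and two runs with the same
configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .delineation import segment_fixed
from .evaluation import (
    MethodGrid,
    default_grids,
    delineate_cases,
    rank_methods,
    results_frame,
    backwards_summary_from_volumes,
    solve_backwards,
    summaries_frame,
    summarize,
)
from .image_model import BoxROI, DiscROI, EllipsoidVOI, read_volume, write_volume
from .phantom import (
    BackgroundModel,
    CohortConfig,
    LesionSpec,
    PhantomCase,
    cohort_truth_table,
    generate_cohort,
)

__all__ = [
    "RunConfig",
    "load_run_config",
    "config_hash",
    "simulate",
    "load_cohort",
    "delineate",
    "evaluate",
]

log = logging.getLogger("suvseg")

FAMILIES = ("fixed", "isocontour", "liver_rel", "parotis_rel", "spleen_rel")


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs: cohort sampling, grids, options."""

    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    families: tuple[str, ...] = FAMILIES
    plots: bool = False

    def grids(self) -> list[MethodGrid]:
        grids = [g for g in default_grids() if g.family in self.families]
        if not grids:
            raise ValueError(f"no known families in {self.families}")
        return grids


def _config_dict(config: RunConfig) -> dict:
    cohort = config.cohort
    return {
        "seed": cohort.seed,
        "n_cases": cohort.n_cases,
        "spacing_mm": cohort.spacing_mm,
        "voi_margin_mm": cohort.voi_margin_mm,
        "volume_median_ml": cohort.volume_median_ml,
        "volume_log_sd": cohort.volume_log_sd,
        "volume_range_ml": list(cohort.volume_range_ml),
        "aspect_range": list(cohort.aspect_range),
        "peak_suv_range": list(cohort.peak_suv_range),
        "noise_sd": cohort.background.noise_sd,
        "psf_fwhm_mm": cohort.background.psf_fwhm_mm,
        "families": list(config.families),
        "plots": config.plots,
    }


def _config_from_dict(d: dict) -> RunConfig:
    background = BackgroundModel(
        noise_sd=d.get("noise_sd", 0.3), psf_fwhm_mm=d.get("psf_fwhm_mm", 2.0)
    )
    defaults = CohortConfig()
    cohort = CohortConfig(
        n_cases=d.get("n_cases", defaults.n_cases),
        volume_median_ml=d.get("volume_median_ml", defaults.volume_median_ml),
        volume_log_sd=d.get("volume_log_sd", defaults.volume_log_sd),
        volume_range_ml=tuple(d.get("volume_range_ml", defaults.volume_range_ml)),
        aspect_range=tuple(d.get("aspect_range", defaults.aspect_range)),
        peak_suv_range=tuple(d.get("peak_suv_range", defaults.peak_suv_range)),
        background=background,
        spacing_mm=d.get("spacing_mm", defaults.spacing_mm),
        voi_margin_mm=d.get("voi_margin_mm", defaults.voi_margin_mm),
        seed=d.get("seed", defaults.seed),
    )
    return RunConfig(
        cohort=cohort,
        families=tuple(d.get("families", FAMILIES)),
        plots=bool(d.get("plots", False)),
    )


def load_run_config(
    path: str | Path | None = None, **overrides
) -> RunConfig:
    """Load a YAML run configuration; keyword overrides win over file values."""
    d: dict = {}
    if path is not None:
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
    d.update({k: v for k, v in overrides.items() if v is not None})
    return _config_from_dict(d)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved configuration."""
    canon = yaml.safe_dump(_config_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _write_csv(frame: pd.DataFrame, path: Path, seed: int, chash: str) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={seed} config_hash={chash}\n")
        frame.to_csv(fh, index=False)


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Generate the cohort and write volumes, truth and geometry to ``outdir``."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    (outdir / "cases").mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    cases = generate_cohort(config.cohort)
    for case in cases:
        write_volume(case.pet, outdir / "cases" / f"{case.case_id}.nii.gz")
    _write_csv(
        cohort_truth_table(cases), outdir / "ground_truth.csv", config.cohort.seed, chash
    )
    geometry = pd.DataFrame(
        {
            "case_id": [c.case_id for c in cases],
            "cx": [c.voi.center[0] for c in cases],
            "cy": [c.voi.center[1] for c in cases],
            "cz": [c.voi.center[2] for c in cases],
            "ax": [c.voi.semi_axes[0] for c in cases],
            "ay": [c.voi.semi_axes[1] for c in cases],
            "az": [c.voi.semi_axes[2] for c in cases],
        }
    )
    _write_csv(geometry, outdir / "geometry.csv", config.cohort.seed, chash)
    roi_rows = []
    for c in cases:
        for tissue, roi in sorted(c.rois.items()):
            if isinstance(roi, DiscROI):
                kind, p = "disc", (roi.diameter, 0.0, 0.0)
            else:
                kind, p = "box", roi.edge_lengths
            roi_rows.append(
                (c.case_id, tissue, kind, *roi.center, *p)
            )
    rois = pd.DataFrame(
        roi_rows, columns=["case_id", "tissue", "kind", "cx", "cy", "cz", "p1", "p2", "p3"]
    )
    _write_csv(rois, outdir / "rois.csv", config.cohort.seed, chash)
    with open(outdir / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)
    log.info(
        "simulate: %d cases -> %s (%.1f s)",
        len(cases),
        outdir,
        time.monotonic() - t0,
    )
    return outdir


def load_cohort(cohort_dir: str | Path) -> tuple[list[PhantomCase], RunConfig]:
    """Reload a simulated cohort (volumes, VOIs, ROIs, truth) from disk."""
    cohort_dir = Path(cohort_dir)
    if not (cohort_dir / "ground_truth.csv").exists():
        raise FileNotFoundError(f"no simulated cohort in {cohort_dir}")
    with open(cohort_dir / "config_resolved.yaml") as fh:
        config = _config_from_dict(yaml.safe_load(fh))
    truth = _read_csv(cohort_dir / "ground_truth.csv").set_index("case_id")
    geometry = _read_csv(cohort_dir / "geometry.csv").set_index("case_id")
    rois_frame = _read_csv(cohort_dir / "rois.csv")
    margin = config.cohort.voi_margin_mm
    cases = []
    for case_id, g in geometry.iterrows():
        pet = read_volume(cohort_dir / "cases" / f"{case_id}.nii.gz")
        voi = EllipsoidVOI((g.cx, g.cy, g.cz), (g.ax, g.ay, g.az))
        rois: dict[str, BoxROI | DiscROI] = {}
        for row in rois_frame[rois_frame["case_id"] == case_id].itertuples():
            center = (row.cx, row.cy, row.cz)
            rois[row.tissue] = (
                DiscROI(center, row.p1)
                if row.kind == "disc"
                else BoxROI(center, (row.p1, row.p2, row.p3))
            )
        t = truth.loc[case_id]
        lesion = LesionSpec(
            center=(g.cx, g.cy, g.cz),
            semi_axes=(g.ax - margin, g.ay - margin, g.az - margin),
            peak_suv=t.peak_suv,
        )
        cases.append(
            PhantomCase(
                case_id=str(case_id),
                pet=pet,
                voi=voi,
                ct_reference_volume_ml=float(t.ct_reference_volume_ml),
                background_suvs={
                    "liver": float(t.suv_liver),
                    "parotis": float(t.suv_parotis),
                    "spleen": float(t.suv_spleen),
                },
                rois=rois,
                lesion=lesion,
            )
        )
    return cases, config


def delineate(
    cohort_dir: str | Path,
    outdir: str | Path | None = None,
    families: Sequence[str] | None = None,
) -> tuple[Path, Path]:
    """Run all segmentation families plus the per-case inverse solve.

    Writes ``results.csv`` (case x family x level) and ``backwards.csv``
    (per-case inverse threshold, its achieved volume, and the volume at the
    cohort-mean threshold, ready for the evaluation stage).
    """
    t0 = time.monotonic()
    cohort_dir = Path(cohort_dir)
    outdir = Path(outdir) if outdir is not None else cohort_dir
    outdir.mkdir(parents=True, exist_ok=True)
    cases, config = load_cohort(cohort_dir)
    if families is not None:
        config = dataclasses.replace(config, families=tuple(families))
    chash = config_hash(config)
    seed = config.cohort.seed

    results = delineate_cases(cases, config.grids())
    _write_csv(results_frame(results), outdir / "results.csv", seed, chash)

    bw = solve_backwards(cases)
    mean_t = float(np.mean([r.threshold_suv for r in bw]))
    reapplied = {
        c.case_id: segment_fixed(c.pet, c.voi, mean_t, case_id=c.case_id).volume_ml
        for c in cases
    }
    bw_frame = pd.DataFrame(
        {
            "case_id": [r.case_id for r in bw],
            "threshold_suv": [r.threshold_suv for r in bw],
            "achieved_volume_ml": [r.achieved_volume_ml for r in bw],
            "target_volume_ml": [r.target_volume_ml for r in bw],
            "volume_at_mean_threshold_ml": [reapplied[r.case_id] for r in bw],
        }
    )
    _write_csv(bw_frame, outdir / "backwards.csv", seed, chash)
    log.info(
        "delineate: %d rows, %d backwards solves (%.1f s)",
        len(results),
        len(bw),
        time.monotonic() - t0,
    )
    return outdir / "results.csv", outdir / "backwards.csv"


def _read_header_meta(path: Path) -> dict[str, str]:
    with open(path) as fh:
        first = fh.readline()
    meta = {}
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    return meta


def evaluate(
    results_csv: str | Path,
    truth_csv: str | Path,
    outdir: str | Path,
    backwards_csv: str | Path | None = None,
    plots: bool = False,
) -> Path:
    """Summarize agreement, rank methods and write the markdown report.

    Requires the case ids of the results and truth tables to match exactly.
    """
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = _read_csv(results_csv)
    truth = _read_csv(truth_csv)
    if set(results["case_id"]) != set(truth["case_id"]):
        raise ValueError("case ids in results and ground truth do not match")
    meta = _read_header_meta(Path(results_csv))
    seed = int(meta.get("seed", -1))
    chash = meta.get("config_hash", "unknown")

    ref = dict(zip(truth["case_id"], truth["ct_reference_volume_ml"]))
    summaries = summarize(results, ref)
    ranking = rank_methods(summaries)
    _write_csv(summaries_frame(summaries), outdir / "agreement.csv", seed, chash)
    rank_rows = pd.DataFrame(
        {
            "family": list(ranking),
            "method": [ranking[k].method for k in ranking],
            "level": [ranking[k].level for k in ranking],
            "r": [ranking[k].r for k in ranking],
            "r_squared": [ranking[k].r_squared for k in ranking],
        }
    )
    _write_csv(rank_rows, outdir / "ranking.csv", seed, chash)

    backwards = None
    if backwards_csv is not None:
        bw = _read_csv(backwards_csv)
        if set(bw["case_id"]) != set(truth["case_id"]):
            raise ValueError("case ids in backwards table do not match ground truth")
        bw = bw.set_index("case_id").loc[truth["case_id"]]
        backwards = backwards_summary_from_volumes(
            bw["threshold_suv"].to_numpy(),
            bw["volume_at_mean_threshold_ml"].to_numpy(),
            truth["ct_reference_volume_ml"].to_numpy(),
        )
        bw_summary = pd.DataFrame(
            {
                "mean_threshold_suv": [backwards.mean_threshold],
                "sd_threshold_suv": [backwards.sd_threshold],
                "cov_percent": [backwards.cov_percent],
                "reapplied_r": [
                    backwards.reapplied_agreement.r
                    if backwards.reapplied_agreement
                    else float("nan")
                ],
                "reapplied_r_squared": [
                    backwards.reapplied_agreement.r_squared
                    if backwards.reapplied_agreement
                    else float("nan")
                ],
            }
        )
        _write_csv(bw_summary, outdir / "backwards_summary.csv", seed, chash)

    from .report import build_report

    report = build_report(summaries, ranking, backwards, seed=seed, config_hash=chash)
    (outdir / "report.md").write_text(report, encoding="utf-8")

    if plots:
        from .report import save_agreement_plots

        truth_sorted = truth.set_index("case_id")
        by_family = {}
        for fam, best in ranking.items():
            if fam == "overall":
                continue
            sub = results[
                (results["method"] == best.method) & (results["level"] == best.level)
            ].set_index("case_id")
            ids = list(sub.index)
            by_family[fam] = (sub["volume_ml"].to_numpy(), best.level)
            ref_vols = truth_sorted.loc[ids, "ct_reference_volume_ml"].to_numpy()
        save_agreement_plots(by_family, ref_vols, outdir / "plots")

    log.info("evaluate: %d summaries -> %s (%.1f s)", len(summaries), outdir,
             time.monotonic() - t0)
    return outdir / "report.md"
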