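"""Markdown report assembly and optional agreement plots.

Report tables follow the field's usual layout: one row per threshold level
with r, r^2 and the significance level; r and r^2 are rounded to three
decimals, volumes to one decimal ml, and p-values below 0.001 are printed
as "p<0.001".
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .evaluation import AgreementSummary, BackwardsSummary

_FAMILY_TITLES = {
    "fixed": "Fixed SUV thresholds",
    "isocontour": "Isocontour relative to SUVmax",
    "liver_rel": "Thresholds relative to SUVliver",
    "parotis_rel": "Thresholds relative to SUVparotis",
    "spleen_rel": "Thresholds relative to SUVspleen",
}


def format_level(method: str, level: float) -> str:
    if method == "fixed":
        return f"SUV {level:g}"
    if method == "isocontour":
        return f"Iso {round(level * 100):g}%"
    if method.endswith("_rel"):
        tissue = method.removesuffix("_rel")
        return f"{round(level * 100):g}% SUV_{tissue}"
    return f"{method} {level:g}"


def format_p(p: float) -> str:
    return "p<0.001" if p < 0.001 else f"p={p:.3f}"


def agreement_table(summaries: Sequence[AgreementSummary]) -> str:
    lines = [
        "| Parameter | type | r | r² | significance |",
        "| --- | --- | --- | --- | --- |",
    ]
    for s in summaries:
        lines.append(
            f"| {format_level(s.method, s.level)} | {s.correlation_type} "
            f"| {s.r:.3f} | {s.r_squared:.3f} | {format_p(s.p_value)} |"
        )
    return "\n".join(lines)


def build_report(
    summaries: Sequence[AgreementSummary],
    ranking: dict[str, AgreementSummary],
    backwards: BackwardsSummary | None,
    *,
    seed: int | None = None,
    config_hash: str | None = None,
) -> str:
    """Assemble the full evaluation report as markdown text."""
    parts = ["# Volumetric agreement report", ""]
    if seed is not None or config_hash is not None:
        parts.append(f"_seed={seed} config_hash={config_hash}_")
        parts.append("")
    families = sorted({s.method for s in summaries})
    for fam in families:
        fam_summaries = sorted(
            (s for s in summaries if s.method == fam),
            key=lambda s: s.level,
            reverse=(fam == "fixed"),
        )
        parts.append(f"## {_FAMILY_TITLES.get(fam, fam)}")
        parts.append("")
        parts.append(agreement_table(fam_summaries))
        parts.append("")
    parts.append("## Best level per family")
    parts.append("")
    for fam in families:
        s = ranking[fam]
        parts.append(
            f"- {fam}: {format_level(s.method, s.level)} "
            f"(r={s.r:.3f}, r²={s.r_squared:.3f}, {format_p(s.p_value)})"
        )
    overall = ranking["overall"]
    parts.append(
        f"- **overall**: {format_level(overall.method, overall.level)} "
        f"(r={overall.r:.3f})"
    )
    parts.append("")
    if backwards is not None:
        parts.append("## Individual backwards thresholding")
        parts.append("")
        parts.append(
            f"- Mean ± sd threshold: SUV {backwards.mean_threshold:.1f} "
            f"± {backwards.sd_threshold:.1f}"
        )
        parts.append(f"- Coefficient of variation: {backwards.cov_percent:.1f}%")
        if backwards.reapplied_agreement is not None:
            ra = backwards.reapplied_agreement
            parts.append(
                f"- Re-applied mean threshold (SUV {backwards.mean_threshold:.1f}): "
                f"r={ra.r:.3f}, r²={ra.r_squared:.3f}, {format_p(ra.p_value)}"
            )
        else:
            parts.append(f"- Re-applied agreement: {backwards.error}")
        parts.append("")
    return "\n".join(parts)


def save_agreement_plots(
    pet_volumes_by_family: dict[str, tuple[Sequence[float], float]],
    ref_volumes: Sequence[float],
    outdir: str | Path,
) -> list[Path]:
    """Scatter + Bland-Altman plot per family at its best level (axes in ml)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    ref = np.asarray(ref_volumes, dtype=float)
    for fam, (pet_vols, level) in pet_volumes_by_family.items():
        pet = np.asarray(pet_vols, dtype=float)
        d = pet - ref
        mean_d, sd_d = d.mean(), d.std(ddof=1)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.scatter(ref, pet, s=18)
        lim = max(ref.max(), pet.max()) * 1.05
        ax1.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax1.set_xlabel("reference volume (ml)")
        ax1.set_ylabel("PET volume (ml)")
        ax1.set_title(format_level(fam, level))
        ax2.scatter((pet + ref) / 2, d, s=18)
        ax2.axhline(mean_d, color="red")
        for y in (mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d):
            ax2.axhline(y, color="green", ls="--")
        ax2.set_xlabel("mean of measures (ml)")
        ax2.set_ylabel("difference PET - reference (ml)")
        ax2.set_title("Bland-Altman")
        fig.tight_layout()
        path = outdir / f"agreement_{fam}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
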