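"""Static report rendering: per-patient timelines and the accuracy table.

Charts show the time course of each parameter with its normal bounds
and shade detected dysfunction episodes, so a clinician can retrace why
an alarm fired (duration, parameter type, start and end time). Output
is static files; there is no interactive interface.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

from matplotlib.figure import Figure

from .evaluation import AccuracyResult
from .rules import specify_norm
from .types import Analyte, ODEpisode, PatientRecord, ReferenceEpisode, RuleConfig


def render_patient_timeline(
    patient: PatientRecord,
    episodes: Sequence[ODEpisode],
    out_path: str | Path,
    config: Optional[RuleConfig] = None,
    reference: Sequence[ReferenceEpisode] = (),
) -> Path:
    """Render one patient's platelet/INR course with episode shading."""
    config = config or RuleConfig()
    fig = Figure(figsize=(10, 6))
    axes = fig.subplots(2, 1, sharex=True)
    for ax, analyte, label in (
        (axes[0], Analyte.PLT, "Platelets (/mm³)"),
        (axes[1], Analyte.INR, "INR"),
    ):
        obs = [o for o in patient.observations if o.analyte is analyte]
        norm = specify_norm(analyte, config)
        if obs:
            ax.plot([o.timestamp for o in obs], [o.value for o in obs], "o-", ms=3, lw=1)
        bound = norm.minimum if analyte is Analyte.PLT else norm.maximum
        ax.axhline(bound, color="tab:red", ls="--", lw=1, label=f"threshold {bound:g}")
        for ep in episodes:
            ax.axvspan(ep.start, ep.end, color="tab:red", alpha=0.15)
        for ep in reference:
            ax.axvspan(ep.start, ep.end, color="tab:green", alpha=0.10)
        ax.set_ylabel(label)
        ax.legend(loc="upper right", fontsize=8)
    axes[1].set_xlabel("time")
    fig.suptitle(f"Patient {patient.patient_id}: detected episodes (red), reference (green)")
    fig.autofmt_xdate()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=110)
    return out_path


def render_accuracy_table(result: AccuracyResult, out_path: str | Path) -> Path:
    """Write the 2x2 block cross-tabulation and estimates as markdown."""
    t = result.table

    def fmt(v, ci):
        if v is None:
            return "undefined"
        return f"{v:.3f} (95% CI: {ci[0]:.3f}-{ci[1]:.3f})"

    lines = [
        "# Diagnostic accuracy (block-based)",
        "",
        "| CDSS \\ Reference | Positive | Negative | Total |",
        "|---|---|---|---|",
        f"| Alarm | {t.tp} | {t.fp} | {t.tp + t.fp} |",
        f"| No alarm | {t.fn} | {t.tn} | {t.fn + t.tn} |",
        f"| Total | {t.tp + t.fn} | {t.fp + t.tn} | {t.total} |",
        "",
        f"- Sensitivity: {fmt(result.sensitivity, result.se_ci)}",
        f"- Specificity: {fmt(result.specificity, result.sp_ci)}",
        f"- Patients (clusters): {result.n_patients}",
    ]
    lines.extend(f"- Note: {n}" for n in result.notes)
    out_path = Path(out_path)
    out_path.write_text("\n".join(lines) + "\n")
    return out_path


__all__ = ["render_patient_timeline", "render_accuracy_table"]
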