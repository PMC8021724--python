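"""End-to-end pipeline: simulate -> score -> label -> evaluate -> compare.

Everything is deterministic given the seed; ``summary.json`` is written with
sorted keys and fixed float formatting so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .compare import summaries_to_frame, summarize_groups
from .diagnostics import auc_significance, empirical_roc, sens_spec_at, youden_optimal
from .echo import EchoAssessment, label_infant
from .io import write_scores
from .scoring import MAX_TOTAL, SCHEDULE_HOURS, InfantRecord, ScoreBreakdown, TimepointObservation, score_trajectory

__all__ = ["PipelineConfig", "score_cohort", "evaluate_scores", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: Path = Path("simple_pda_out")
    cohort: CohortConfig = None  # defaults to CohortConfig(seed=seed)
    confidence_level: float = 0.95
    make_plots: bool = False

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)
        if not 0 < self.confidence_level < 1:
            raise ValueError(f"confidence_level must be in (0,1), got {self.confidence_level}")

    def digest(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "level": self.confidence_level,
             "n_total": self.cohort.n_total, "n_cases": self.cohort.n_cases},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def score_cohort(infants: Sequence[InfantRecord],
                 observations: Sequence[TimepointObservation]) -> list[ScoreBreakdown]:
    """Score every infant's trajectory from the raw tables."""
    by_infant: dict[str, list[TimepointObservation]] = defaultdict(list)
    for o in observations:
        by_infant[o.infant_id].append(o)
    out: list[ScoreBreakdown] = []
    for rec in infants:
        obs = sorted(by_infant.get(rec.infant_id, []), key=lambda o: o.hour)
        if obs:
            out.extend(score_trajectory(rec, obs))
    return out


def evaluate_scores(scores_df: pd.DataFrame, labels: Mapping[str, str],
                    level: float = 0.95) -> dict:
    """Per-hour ROC evaluation of total scores against case/control labels."""
    per_hour = {}
    for hour in sorted(scores_df["hour"].unique()):
        sub = scores_df[scores_df["hour"] == hour]
        y = np.array([labels[i] == "case" for i in sub["infant_id"]])
        s = sub["total"].to_numpy(dtype=float)
        roc = empirical_roc(s, y, hour=int(hour), level=level)
        cutoff = youden_optimal(roc)
        (sens, sci), (spec, pci) = sens_spec_at(s, y, cutoff, level=level)
        per_hour[int(hour)] = {
            "n_cases": roc.n_cases,
            "n_controls": roc.n_controls,
            "auc": round(roc.auc, 4),
            "auc_p_value": float(f"{auc_significance(roc):.3e}"),
            "optimal_cutoff": cutoff,
            "sensitivity_pct": round(100 * sens, 2),
            "sensitivity_ci_pct": [round(100 * sci[0], 1), round(100 * sci[1], 1)],
            "specificity_pct": round(100 * spec, 2),
            "specificity_ci_pct": [round(100 * pci[0], 1), round(100 * pci[1], 1)],
        }
    return per_hour


def _roc_points_frame(scores_df: pd.DataFrame, labels: Mapping[str, str],
                      level: float) -> pd.DataFrame:
    frames = []
    for hour in sorted(scores_df["hour"].unique()):
        sub = scores_df[scores_df["hour"] == hour]
        y = np.array([labels[i] == "case" for i in sub["infant_id"]])
        roc = empirical_roc(sub["total"].to_numpy(dtype=float), y, hour=int(hour), level=level)
        frames.append(pd.DataFrame({
            "hour": int(hour),
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "sens_ci_low": roc.sens_ci[:, 0], "sens_ci_high": roc.sens_ci[:, 1],
            "spec_ci_low": roc.spec_ci[:, 0], "spec_ci_high": roc.spec_ci[:, 1],
        }))
    return pd.concat(frames, ignore_index=True)


def _echo_label_frame(echoes: Sequence[EchoAssessment]) -> pd.DataFrame:
    by_infant: dict[str, list[EchoAssessment]] = defaultdict(list)
    for e in echoes:
        by_infant[e.infant_id].append(e)
    rows = []
    for iid in sorted(by_infant):
        flag, hour = label_infant(by_infant[iid])
        rows.append({"infant_id": iid, "echo_hspda": int(flag),
                     "deciding_hour": hour if hour is not None else ""})
    return pd.DataFrame(rows)


def _report_text(cohort: SyntheticCohort, per_hour: dict, group_rows,
                 config: PipelineConfig) -> str:
    tf = cohort.totals_frame()
    lines = [
        "SIMPLE score pipeline report",
        f"  seed: {config.seed}   config: {config.digest()}   version: {__version__}",
        f"  cohort: {len(cohort.infants)} infants "
        f"({sum(1 for v in cohort.labels.values() if v == 'case')} hsPDA cases, "
        f"{sum(1 for v in cohort.labels.values() if v == 'control')} controls)",
        f"  generator acceptance rate: {cohort.acceptance_rate:.3f}",
        f"  maximum attainable score: {MAX_TOTAL}",
        "",
        "Score totals by group, median (range):",
    ]
    for hour in SCHEDULE_HOURS:
        sub = tf[tf.hour == hour]
        parts = []
        for lab in ("case", "control"):
            t = sub[sub.label == lab]["total"]
            parts.append(f"{lab} {t.median():.0f} ({t.min():.0f}-{t.max():.0f})")
        lines.append(f"  {hour:>3} h   " + "   ".join(parts))
    lines.append("")
    lines.append("ROC evaluation per time point:")
    for hour, d in per_hour.items():
        lines.append(
            f"  {hour:>3} h   AUC {d['auc']:.3f} (p {d['auc_p_value']:.1e})   "
            f"cut-off > {d['optimal_cutoff']:g}   "
            f"sens {d['sensitivity_pct']:.2f}% "
            f"({d['sensitivity_ci_pct'][0]:.1f}-{d['sensitivity_ci_pct'][1]:.1f})   "
            f"spec {d['specificity_pct']:.2f}% "
            f"({d['specificity_ci_pct'][0]:.1f}-{d['specificity_ci_pct'][1]:.1f})")
    lines.append("")
    lines.append("Group comparisons:")
    for r in group_rows:
        lines.append(f"  {r.variable:<22} {r.group_a:>18} vs {r.group_b:>18}   "
                     f"p = {r.p_value:.3g} ({r.test})")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> score -> label -> evaluate -> compare; write artifacts.

    Writes infants/observations/echo/labels CSVs, scores.csv, roc.csv,
    summary.json, group_summary.csv and report.txt into ``config.out_dir``.
    Returns the summary dict.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = generate_cohort(config.cohort)
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc

    inf_df, obs_df, echo_df, lab_df = cohort.to_frames()
    inf_df.to_csv(out / "infants.csv", index=False)
    obs_df.to_csv(out / "observations.csv", index=False)
    echo_df.to_csv(out / "echo.csv", index=False)
    lab_df.to_csv(out / "labels.csv", index=False)

    try:
        breakdowns = score_cohort(cohort.infants, cohort.observations)
        scores_df = write_scores(breakdowns, out / "scores.csv")
    except Exception as exc:
        raise RuntimeError(f"[score] {exc}") from exc

    try:
        echo_labels = _echo_label_frame(cohort.echoes)
        echo_labels.to_csv(out / "echo_labels.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[label] {exc}") from exc

    try:
        per_hour = evaluate_scores(scores_df, cohort.labels, config.confidence_level)
        _roc_points_frame(scores_df, cohort.labels, config.confidence_level).to_csv(
            out / "roc.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[evaluate] {exc}") from exc

    try:
        tf = cohort.totals_frame()
        t48 = tf[tf.hour == 48].set_index("infant_id")["total"]
        frame = pd.DataFrame({
            "infant_id": [r.infant_id for r in cohort.infants],
            "label": [cohort.labels[r.infant_id] for r in cohort.infants],
            "gestational_age": [r.gestational_age for r in cohort.infants],
            "birth_weight": [r.birth_weight for r in cohort.infants],
            "chorioamnionitis": [r.chorioamnionitis for r in cohort.infants],
            "no_antenatal_steroid": [not r.antenatal_steroid_complete for r in cohort.infants],
            "mortality": [cohort.outcomes[r.infant_id]["mortality"] for r in cohort.infants],
            "ivh_grade3": [cohort.outcomes[r.infant_id]["ivh_grade3"] for r in cohort.infants],
            "total_48h": [t48.get(r.infant_id, np.nan) for r in cohort.infants],
        })
        group_rows = summarize_groups(frame, {
            "gestational_age": "continuous",
            "birth_weight": "continuous",
            "total_48h": "continuous",
            "chorioamnionitis": "binary",
            "no_antenatal_steroid": "binary",
            "mortality": "binary",
            "ivh_grade3": "binary",
        })
        summaries_to_frame(group_rows).to_csv(out / "group_summary.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"[compare] {exc}") from exc

    summary = {
        "provenance": {"seed": config.seed, "config_digest": config.digest(),
                       "version": __version__},
        "max_attainable_score": MAX_TOTAL,
        "n_infants": len(cohort.infants),
        "n_cases": sum(1 for v in cohort.labels.values() if v == "case"),
        "acceptance_rate": round(cohort.acceptance_rate, 4),
        "roc_per_hour": per_hour,
    }
    (out / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")

    report = _report_text(cohort, per_hour, group_rows, config)
    (out / "report.txt").write_text(report)

    if config.make_plots:
        _plot_rocs(scores_df, cohort.labels, out)
    return summary


def _plot_rocs(scores_df: pd.DataFrame, labels: Mapping[str, str], out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for hour in sorted(scores_df["hour"].unique()):
        sub = scores_df[scores_df["hour"] == hour]
        y = np.array([labels[i] == "case" for i in sub["infant_id"]])
        roc = empirical_roc(sub["total"].to_numpy(dtype=float), y, hour=int(hour))
        fpr = 1 - roc.specificity
        order = np.argsort(fpr)
        ax.plot(fpr[order], roc.sensitivity[order], label=f"{hour} h (AUC {roc.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "roc.png", dpi=150)
    plt.close(fig)
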