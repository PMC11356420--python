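"""TSV report writers and the CV-AUC summary figure."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .evaluation import StudyReport

__all__ = ["cv_report_frame", "selection_frame", "write_reports", "plot_cv_auc"]


def cv_report_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for (outcome, feature_set, platform, proc), r in report.cv_reports.items():
        rows.append(
            {
                "outcome": outcome,
                "feature_set": feature_set,
                "platform": platform or "",
                "procedure": proc,
                "cv_auc": r.mean,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "reps": len(r.aucs),
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def selection_frame(report: StudyReport) -> pd.DataFrame:
    """Selection table mirroring the variable / platform / frequency layout."""
    rows = []
    for (outcome, platform, proc), table in report.stability.items():
        pev = report.pev.get(outcome)
        for var, freq in table.frequency.items():
            if freq == 0:
                continue
            direction = ""
            pev_val = ""
            if pev is not None and var in pev.direction.index:
                direction = pev.direction[var]
            if pev is not None and var in pev.per_variable.index:
                pev_val = f"{pev.per_variable[var]:.3f}"
            rows.append(
                {
                    "outcome": outcome,
                    "platform": platform,
                    "procedure": proc,
                    "variable": var,
                    "frequency": freq,
                    "final": bool(table.final[var]),
                    "pev": pev_val,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def write_reports(report: StudyReport, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    paths = []
    p = outdir / "cv_auc.tsv"
    cv_report_frame(report).to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = outdir / "selection.tsv"
    selection_frame(report).to_csv(p, sep="\t", index=False)
    paths.append(p)
    qc_rows = [
        {"platform": plat, "median_cv_pct_pre": pre.median_cv_pct,
         "median_cv_pct_post": post.median_cv_pct}
        for plat, (pre, post) in report.qc.items()
    ]
    p = outdir / "qc_summary.tsv"
    pd.DataFrame(qc_rows).to_csv(p, sep="\t", index=False)
    paths.append(p)
    try:
        paths.append(plot_cv_auc(report, outdir / "cv_auc.png"))
    except Exception:  # plotting is best-effort
        pass
    return paths


def plot_cv_auc(report: StudyReport, path: str | Path) -> Path:
    """Dot-and-interval CV-AUC plot, one panel per outcome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = cv_report_frame(report)
    outcomes = sorted(frame["outcome"].unique())
    fig, axes = plt.subplots(
        1, len(outcomes), figsize=(5 * len(outcomes), 4), squeeze=False, sharey=True
    )
    markers = {"covariates_only": "o", "metabolites_base": "^", "metabolites_all": "s"}
    for ax, outcome in zip(axes[0], outcomes):
        sub = frame[frame["outcome"] == outcome]
        procs = list(dict.fromkeys(sub["procedure"]))
        for fs, gr in sub.groupby("feature_set"):
            x = [procs.index(p) for p in gr["procedure"]]
            ax.errorbar(
                x, gr["cv_auc"],
                yerr=[gr["cv_auc"] - gr["ci_low"], gr["ci_high"] - gr["cv_auc"]],
                fmt=markers.get(fs, "o"), capsize=3, label=fs, alpha=0.8, ls="none",
            )
        ax.axhline(0.5, color="grey", lw=0.8, ls="--")
        ax.set_xticks(range(len(procs)), procs, rotation=45, ha="right")
        ax.set_title(f"outcome {outcome}")
        ax.set_ylabel("CV-AUC")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
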