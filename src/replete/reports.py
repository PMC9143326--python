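"""Figure generation from serialized run artifacts.

Plots read only the report files a pipeline run wrote (never raw data or
models), so re-rendering figures never recomputes anything.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_pre_post(report_path: str | Path, out_path: str | Path) -> Path:
    """Histograms of pre- vs post-repletion levels with the target band."""
    rep = json.loads(Path(report_path).read_text())
    pre = np.array(rep["pre_levels"], dtype=float)
    post = np.array(rep["post_levels"], dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = 30
    ax.hist(pre[np.isfinite(pre)], bins=bins, alpha=0.6, color="tab:red", label="pre-repletion")
    ax.hist(post[np.isfinite(post)], bins=bins, alpha=0.6, color="tab:green", label="post-repletion")
    ax.set_xlabel("electrolyte level")
    ax.set_ylabel("repletion events")
    ax.legend()
    ax.set_title(f"within-or-above-range fraction: {rep['frac_within_or_above']:.2f}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_frequency(report_path: str | Path, out_path: str | Path) -> Path:
    """Historical vs recommended dosage-frequency bars."""
    rep = json.loads(Path(report_path).read_text())
    per = pd.DataFrame(rep["per_action"])
    x = np.arange(len(per))
    fig, ax = plt.subplots(figsize=(max(6, len(per) * 0.35), 4))
    ax.bar(x - 0.2, per["historical"], width=0.4, label="historical")
    ax.bar(x + 0.2, per["policy"], width=0.4, label="learned policy")
    ax.set_xticks(x)
    ax.set_xticklabels(per["label"], rotation=90, fontsize=7)
    ax.set_ylabel("decision points")
    change = rep["repletion_change_pct"]
    if change is not None:
        ax.set_title(f"repletion events: {change:+.1f}% vs history")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_trajectory(overlay_path: str | Path, out_path: str | Path,
                    reference_range: tuple[float, float] | None = None) -> Path:
    """Single-visit overlay: measured levels, historical and recommended
    repletions, IV infusion spans."""
    df = pd.read_csv(overlay_path)
    fig, axes = plt.subplots(3, 1, figsize=(8, 6), sharex=True)
    axes[0].plot(df["hour_start"], df["imputed_level"], color="lightgray", lw=1)
    axes[0].plot(df["hour_start"], df["measured_level"], "o-", ms=3, color="tab:blue")
    if reference_range:
        axes[0].axhspan(*reference_range, color="gray", alpha=0.2)
    axes[0].set_ylabel("level")
    for ax, col, spans, color, label in (
        (axes[1], "historical_action", ("historical_iv_start", "historical_iv_end"),
         "tab:orange", "historical"),
        (axes[2], "policy_action", ("policy_iv_start", "policy_iv_end"),
         "tab:green", "recommended"),
    ):
        acted = df[df[col] != ""].dropna(subset=[col])
        ax.scatter(acted["hour_start"], np.ones(len(acted)), marker="|", s=200, color=color)
        for _, row in df.dropna(subset=[spans[0]]).iterrows():
            ax.axvspan(row[spans[0]], row[spans[1]], color=color, alpha=0.3)
        ax.set_yticks([])
        ax.set_ylabel(label, fontsize=8)
    axes[2].set_xlabel("hours into admission")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def plot_q_distributions(report_path: str | Path, out_path: str | Path) -> Path:
    """Mean Q-value comparison of learned vs historical policy."""
    rep = json.loads(Path(report_path).read_text())
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(["historical", "learned"], [rep["behavior_mean_q"], rep["learned_mean_q"]],
           color=["tab:red", "tab:green"])
    ax.set_ylabel("mean estimated Q-value (test pairs)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)


def render_all(run_dir: str | Path, reference_range=None) -> list[Path]:
    run_dir = Path(run_dir)
    figures = run_dir / "figures"
    figures.mkdir(exist_ok=True)
    out = []
    pairs = [
        (run_dir / "pre_post_report.json", plot_pre_post, figures / "pre_post.png"),
        (run_dir / "frequency_report.json", plot_frequency, figures / "frequency.png"),
        (run_dir / "fqe_report.json", plot_q_distributions, figures / "q_values.png"),
    ]
    for src, fn, dst in pairs:
        if src.exists():
            out.append(fn(src, dst))
    overlay = run_dir / "trajectory_overlay.csv"
    if overlay.exists():
        out.append(plot_trajectory(overlay, figures / "trajectory.png", reference_range))
    return out
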