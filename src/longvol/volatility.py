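"""Control-chart ("volatility") statistics and plot specifications.

A volatility chart combines a control chart and a spaghetti plot: a
horizontal band at the global mean with warning limits at +/-2 SD and
control limits at +/-3 SD (both computed across ALL samples, not per
group), per-(group, state) mean +/- SD lines, and faded per-subject
trajectories.  Samples beyond the warning or control limits are flagged;
such observations can indicate disturbance, disease or contamination.

The plot is emitted both as a declarative JSON specification (a layered
chart document retaining the metric/group fields an interactive viewer
would need) and as a static matplotlib figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import SampleMetadata

SPEC_SCHEMA = "longvol/volatility-chart/v1"


@dataclass
class SubjectTrajectory:
    subject_id: str
    states: np.ndarray
    values: np.ndarray
    sample_ids: list[str]


@dataclass
class VolatilityStats:
    """Global control-chart limits plus per-group aggregates and spaghetti.

    Limits use the sample (n-1) standard deviation over all samples.
    ``aggregates`` has one row per (group, state): mean, sd, n.
    ``outliers`` has one row per sample with beyond-warning/control flags.
    """

    metric: str
    group_column: str | None
    global_mean: float
    global_sd: float
    warning_limits: tuple[float, float]
    control_limits: tuple[float, float]
    aggregates: pd.DataFrame
    trajectories: list[SubjectTrajectory]
    outliers: pd.DataFrame


def volatility_stats(
    metadata: SampleMetadata,
    metric: str,
    group_column: str | None = None,
) -> VolatilityStats:
    """Compute control-chart statistics for one numeric metric."""
    if not metadata.is_numeric(metric):
        raise ValueError(f"metric column {metric!r} is not numeric")
    df = metadata.longitudinal_frame(extra_required=[metric])
    values = df[metric].astype(float)
    if len(values) < 2:
        raise ValueError("need at least 2 samples to compute a standard deviation")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    warning = (mean - 2 * sd, mean + 2 * sd)
    control = (mean - 3 * sd, mean + 3 * sd)

    group = (
        df[group_column].astype(str)
        if group_column is not None
        else pd.Series("all", index=df.index)
    )
    states = df[metadata.state_column].astype(float)
    agg = (
        pd.DataFrame({"group": group, "state": states, "value": values})
        .groupby(["group", "state"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    agg["sd"] = agg["sd"].fillna(0.0)

    trajectories = []
    for subject, sub in df.groupby(metadata.subject_column, sort=True):
        order = sub[metadata.state_column].astype(float).sort_values(kind="mergesort")
        trajectories.append(
            SubjectTrajectory(
                str(subject),
                order.to_numpy(),
                values.loc[order.index].to_numpy(),
                list(order.index),
            )
        )

    dev = (values - mean).abs()
    outliers = pd.DataFrame(
        {
            "sample-id": df.index,
            "value": values.to_numpy(),
            "beyond_warning": (dev > 2 * sd).to_numpy(),
            "beyond_control": (dev > 3 * sd).to_numpy(),
        }
    )
    return VolatilityStats(
        metric, group_column, mean, sd, warning, control, agg, trajectories, outliers
    )


def volatility_plot_spec(stats: VolatilityStats, title: str | None = None,
                         error_bars: str = "sd") -> dict:
    """Declarative layered-chart document for a volatility chart.

    Layers, in order: one mean line (+/- SD or SEM error bars) per group,
    one faded spaghetti line per subject, and five horizontal rules
    (mean solid; warning limits dotted; control limits dashed).
    """
    if error_bars not in ("sd", "sem"):
        raise ValueError("error_bars must be 'sd' or 'sem'")
    layers: list[dict] = []
    for grp, sub in stats.aggregates.groupby("group", sort=True):
        err = sub["sd"] if error_bars == "sd" else sub["sd"] / np.sqrt(sub["n"])
        layers.append(
            {
                "mark": "line",
                "role": "group-mean",
                "group": str(grp),
                "error_bars": error_bars,
                "points": [
                    {"state": float(s), "mean": float(m), "error": float(e), "n": int(n)}
                    for s, m, e, n in zip(sub["state"], sub["mean"], err, sub["n"])
                ],
            }
        )
    for traj in stats.trajectories:
        layers.append(
            {
                "mark": "line",
                "role": "spaghetti",
                "subject": traj.subject_id,
                "opacity": 0.25,
                "points": [
                    {"state": float(s), "value": float(v), "sample": sid}
                    for s, v, sid in zip(traj.states, traj.values, traj.sample_ids)
                ],
            }
        )
    rules = [
        {"mark": "rule", "role": "global-mean", "stroke": "solid", "y": stats.global_mean},
        {"mark": "rule", "role": "warning-limit", "stroke": "dotted", "y": stats.warning_limits[0]},
        {"mark": "rule", "role": "warning-limit", "stroke": "dotted", "y": stats.warning_limits[1]},
        {"mark": "rule", "role": "control-limit", "stroke": "dashed", "y": stats.control_limits[0]},
        {"mark": "rule", "role": "control-limit", "stroke": "dashed", "y": stats.control_limits[1]},
    ]
    return {
        "$schema": SPEC_SCHEMA,
        "title": title if title is not None else f"Volatility of {stats.metric}",
        "metric": stats.metric,
        "group_column": stats.group_column,
        "global": {
            "mean": stats.global_mean,
            "sd": stats.global_sd,
            "warning_limits": list(stats.warning_limits),
            "control_limits": list(stats.control_limits),
        },
        "layers": layers + rules,
    }


def write_plot_spec(spec: dict, path: str | Path) -> None:
    """Serialize a plot spec deterministically (sorted keys, fixed layout)."""
    text = json.dumps(spec, sort_keys=True, indent=2, ensure_ascii=False)
    Path(path).write_text(text + "\n", encoding="utf-8")


def render_volatility(stats: VolatilityStats, path: str | Path,
                      title: str | None = None, error_bars: str = "sd") -> None:
    """Render the chart to a static image (format from the file suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    for traj in stats.trajectories:
        ax.plot(traj.states, traj.values, color="gray", alpha=0.25, lw=0.8, zorder=1)
    for grp, sub in stats.aggregates.groupby("group", sort=True):
        err = sub["sd"] if error_bars == "sd" else sub["sd"] / np.sqrt(sub["n"])
        ax.errorbar(sub["state"], sub["mean"], yerr=err, lw=2, capsize=3,
                    label=str(grp), zorder=3)
    ax.axhline(stats.global_mean, color="black", ls="-", lw=1)
    for y in stats.warning_limits:
        ax.axhline(y, color="black", ls=":", lw=1)
    for y in stats.control_limits:
        ax.axhline(y, color="black", ls="--", lw=1)
    ax.set_xlabel("state")
    ax.set_ylabel(stats.metric)
    ax.set_title(title or f"Volatility of {stats.metric}")
    if stats.group_column is not None:
        ax.legend(title=stats.group_column, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
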