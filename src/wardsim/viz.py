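"""Trajectory maps and per-policy score box plots.

Trajectory panels draw each patient's recorded path on the floor plan,
segment-colored by orientation state (blue = oriented, red = disoriented by
default; configurable for accessibility).  Score plots are grouped Tukey box
plots (1.5 IQR whiskers), x = policy, one color per value model, with the
score polarity stated in the legend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from matplotlib.collections import LineCollection
from matplotlib.lines import Line2D

from .ecq import ECQResult
from .errors import EmptySampleError, PlanMismatchError
from .protocol import ORI_CODE, RunProtocol
from .world import FloorPlan

TRAJECTORY = "trajectory"
SCORE_BOXPLOT = "score_boxplot"


@dataclass
class PlotSpec:
    """Styling and output choices shared by the plotting entry points."""

    kind: str = TRAJECTORY
    out_path: str = "plot.png"
    color_oriented: str = "tab:blue"
    color_disoriented: str = "tab:red"
    policy_order: list[str] | None = None
    panel_titles: list[str] | None = None
    dpi: int = 150


def _draw_plan(ax, plan: FloorPlan) -> None:
    img = np.where(plan.walkable, 1.0, 0.35)
    ax.imshow(
        img,
        cmap="gray",
        vmin=0.0,
        vmax=1.0,
        origin="upper",
        extent=(0, plan.width, plan.height, 0),
        interpolation="nearest",
    )
    for name, (r, c) in plan.destinations.items():
        ax.plot(c + 0.5, r + 0.5, marker="s", ms=4, color="tab:green", zorder=3)
    for r, c in plan.nurse_stations:
        ax.plot(c + 0.5, r + 0.5, marker="P", ms=6, color="tab:orange", zorder=3)
    ax.set_xticks([])
    ax.set_yticks([])


def plot_trajectories(
    protocols: list[RunProtocol],
    plan: FloorPlan,
    spec: PlotSpec | None = None,
    out_path: str | None = None,
) -> str:
    """Render one panel per protocol: patient paths colored by orientation.

    Every protocol must have been produced on ``plan`` (checked against the
    floor-plan digest).  Returns the path of the written image.
    """
    spec = spec or PlotSpec(kind=TRAJECTORY)
    out = out_path or spec.out_path
    if not protocols:
        raise EmptySampleError("no protocols to plot")
    digest = plan.digest()
    for p in protocols:
        if p.floorplan_digest != digest:
            raise PlanMismatchError(
                f"protocol (seed {p.seed}) was not produced on this floor plan"
            )
    n = len(protocols)
    fig, axes = plt.subplots(
        1, n, figsize=(min(4.2 * n, 20), 3.2), squeeze=False, constrained_layout=True
    )
    for k, (ax, protocol) in enumerate(zip(axes[0], protocols)):
        _draw_plan(ax, plan)
        for pid in protocol.patient_ids:
            mask = protocol.agent_mask(pid)
            xs = protocol.states["x"][mask]
            ys = protocol.states["y"][mask]
            ori = protocol.states["ori"][mask]
            pts = np.column_stack([xs, ys])
            segs = np.stack([pts[:-1], pts[1:]], axis=1)
            colors = np.where(
                ori[:-1] == ORI_CODE["D"], spec.color_disoriented, spec.color_oriented
            )
            ax.add_collection(LineCollection(segs, colors=colors, lw=0.8, alpha=0.85))
        if spec.panel_titles and k < len(spec.panel_titles):
            ax.set_title(spec.panel_titles[k], fontsize=9)
    handles = [
        Line2D([], [], color=spec.color_oriented, label="oriented"),
        Line2D([], [], color=spec.color_disoriented, label="disoriented"),
    ]
    fig.legend(handles=handles, loc="lower center", ncol=2, fontsize=8, frameon=False)
    fig.savefig(out, dpi=spec.dpi)
    plt.close(fig)
    return out


def plot_score_boxplots(
    result: ECQResult | pd.DataFrame,
    spec: PlotSpec | None = None,
    out_path: str | None = None,
) -> str:
    """Grouped box plots of value scores per policy.

    Accepts an ECQResult or an equivalent long-form frame with columns
    policy/seed/value/score/polarity.  Policies appear in ``spec.policy_order``
    when given, otherwise in result order.  Returns the written image path.
    """
    spec = spec or PlotSpec(kind=SCORE_BOXPLOT)
    out = out_path or spec.out_path
    if isinstance(result, ECQResult):
        if not result.scores:
            raise EmptySampleError("empty ECQ result, nothing to plot")
        frame = result.to_long_frame()
    else:
        frame = result
    if frame.empty:
        raise EmptySampleError("empty score table, nothing to plot")
    order = spec.policy_order or list(dict.fromkeys(frame["policy"]))
    polarity = dict(zip(frame["value"], frame["polarity"]))
    fig, ax = plt.subplots(figsize=(1.6 + 1.3 * len(order), 4.0), constrained_layout=True)
    sns.boxplot(
        data=frame,
        x="policy",
        y="score",
        hue="value",
        order=order,
        whis=1.5,
        fliersize=2,
        ax=ax,
    )
    ax.set_ylabel("value score")
    ax.set_xlabel("assistive policy")
    ax.set_ylim(-0.02, 1.02)
    handles, labels = ax.get_legend_handles_labels()
    labels = [
        f"{lab} ({'0 = compliant' if polarity.get(lab) == 'violation' else '1 = optimal'})"
        for lab in labels
    ]
    ax.legend(handles, labels, fontsize=8, title=None)
    fig.savefig(out, dpi=spec.dpi)
    plt.close(fig)
    return out
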