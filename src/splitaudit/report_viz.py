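"""Static renderings of the phase / instrument / supplementary views.

Renderers are split into *model builders* (pure functions that lay out every
number to be drawn) and thin matplotlib drawing code, so tests can assert on
the rendering model instead of pixels.  All numbers in a model are taken
verbatim from the aggregate structures; the only arithmetic performed here
is monotone scaling (arc widths, donut fractions, bar normalization).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import networkx as nx
from matplotlib.patches import Arc as MplArc

from splitaudit.config import END, START, DatasetConfig, SetLabel, SplitAssignment, Surgery
from splitaudit.instrument_stats import (
    CombinationCounts,
    InstrumentCounts,
    classify_frame,
    combination_label,
)
from splitaudit.split_audit import AuditReport, SetTotals
from splitaudit.workflow_stats import (
    Direction,
    DurationStats,
    PhaseCounts,
    Transition,
    TransitionCounts,
)

__all__ = [
    "ViewStyle",
    "phase_view_model",
    "render_phase_view",
    "instrument_view_model",
    "render_instrument_view",
    "supplementary_model",
    "render_supplementary",
    "write_report",
    "filter_surgeries",
]


@dataclass(frozen=True)
class ViewStyle:
    """Shared styling: the set->color mapping is fixed across all views."""

    set_colors: Mapping[SetLabel, str] = field(
        default_factory=lambda: {
            SetLabel.TRAIN: "tab:red",
            SetLabel.VAL: "tab:green",
            SetLabel.TEST: "tab:blue",
        }
    )
    min_arc_width: float = 0.6
    max_arc_width: float = 6.0
    node_radius: float = 0.32

    def color(self, set_label: SetLabel) -> str:
        return self.set_colors[set_label]


def _arc_width(count: int, max_count: int, style: ViewStyle) -> float:
    """Linear occurrence->stroke-width scale with a minimum width."""
    if max_count <= 0:
        return style.min_arc_width
    return style.min_arc_width + (count / max_count) * (
        style.max_arc_width - style.min_arc_width
    )


def _set_fractions(counts: Mapping[SetLabel, int]) -> dict[SetLabel, float]:
    total = sum(counts.values())
    if total == 0:
        return {s: 0.0 for s in counts}
    return {s: c / total for s, c in counts.items()}


# ---------------------------------------------------------------------------
# Phase view


def phase_view_model(
    phase_counts: PhaseCounts,
    transition_counts: TransitionCounts,
    phase_instrument_counts: Mapping[tuple[str, str, SetLabel], int],
    config: DatasetConfig,
    style: ViewStyle | None = None,
) -> dict:
    """Layout model of the phase view.

    Nodes sit left to right in conceptual order; each carries its per-set
    donut fractions and surgery count.  Forward arcs go in the upper half
    (y_sign +1), backward arcs in the lower half (y_sign -1); sentinel arcs
    enter from the left edge / leave at the right edge.
    """
    style = style or ViewStyle()
    phases = phase_counts.phases
    x_of = {p: float(i) for i, p in enumerate(phases)}
    x_start = -1.0
    x_end = float(len(phases))

    nodes = []
    for p in phases:
        counts = {s: phase_counts.frame_count(p, s) for s in SetLabel}
        nodes.append(
            {
                "phase": p,
                "x": x_of[p],
                "surgery_count": phase_counts.surgery_count(p),
                "total_frames": phase_counts.total(p),
                "donut": _set_fractions(counts),
                "counts": counts,
            }
        )

    per_transition: dict[Transition, dict[SetLabel, int]] = {}
    for (t, s), n in transition_counts.occurrences.items():
        per_transition.setdefault(t, {s2: 0 for s2 in SetLabel})[s] = n
    max_count = max(
        (sum(c.values()) for c in per_transition.values()), default=0
    )

    arcs = []
    for t in sorted(per_transition, key=lambda t: (t.source, t.target)):
        counts = per_transition[t]
        total = sum(counts.values())
        x0 = x_start if t.source == START else x_of[t.source]
        x1 = x_end if t.target == END else x_of[t.target]
        y_sign = {
            Direction.FORWARD: 1,
            Direction.BACKWARD: -1,
            Direction.BOUNDARY: 1,
        }[t.direction]
        arcs.append(
            {
                "source": t.source,
                "target": t.target,
                "direction": t.direction.value,
                "x0": x0,
                "x1": x1,
                "y_sign": y_sign,
                "counts": counts,
                "total": total,
                "width": _arc_width(total, max_count, style),
                "pie": _set_fractions(counts),
            }
        )

    instrument_bars = {
        (phase, instr): {
            s: phase_instrument_counts.get((phase, instr, s), 0) for s in SetLabel
        }
        for phase in phases
        for instr in config.instruments
    }
    return {
        "phases": list(phases),
        "nodes": nodes,
        "arcs": arcs,
        "totals_bar": {p: phase_counts.total(p) for p in phases},
        "instrument_bars": instrument_bars,
        "x_start": x_start,
        "x_end": x_end,
    }


def render_phase_view(
    phase_counts: PhaseCounts,
    transition_counts: TransitionCounts,
    phase_instrument_counts: Mapping[tuple[str, str, SetLabel], int],
    config: DatasetConfig,
    out: str | Path,
    style: ViewStyle | None = None,
    arc_pies: bool = False,
) -> dict:
    """Render the phase view to an SVG/PNG file; returns the model drawn."""
    style = style or ViewStyle()
    model = phase_view_model(
        phase_counts, transition_counts, phase_instrument_counts, config, style
    )
    if not model["nodes"]:
        raise ValueError("cannot render a phase view of an empty dataset")

    n_instruments = len(config.instruments)
    fig, (ax, ax_bar, ax_instr) = plt.subplots(
        3,
        1,
        figsize=(max(8, 1.8 * len(model["phases"])), 10),
        height_ratios=[3, 1, max(1, 0.25 * n_instruments)],
    )

    for arc in model["arcs"]:
        x0, x1 = arc["x0"], arc["x1"]
        center = ((x0 + x1) / 2.0, 0.0)
        width = abs(x1 - x0)
        height = 0.8 * width
        theta = (0, 180) if arc["y_sign"] > 0 else (180, 360)
        ax.add_patch(
            MplArc(
                center,
                width,
                height,
                theta1=theta[0],
                theta2=theta[1],
                lw=arc["width"],
                color="0.55",
                zorder=1,
            )
        )
        if arc_pies and arc["total"] > 0:
            apex = (center[0], arc["y_sign"] * height / 2.0)
            _draw_pie(ax, apex, 0.12, arc["pie"], style)

    for node in model["nodes"]:
        _draw_pie(
            ax,
            (node["x"], 0.0),
            style.node_radius,
            node["donut"],
            style,
            donut=True,
        )
        ax.text(
            node["x"], 0, str(node["surgery_count"]),
            ha="center", va="center", fontsize=9, zorder=5,
        )
        ax.annotate(
            node["phase"], (node["x"], -0.45), ha="center", va="top",
            fontsize=8, rotation=20,
        )
    ax.set_xlim(model["x_start"] - 0.5, model["x_end"] + 0.5)
    span = max(1.0, (model["x_end"] - model["x_start"]) * 0.45)
    ax.set_ylim(-span, span)
    ax.set_aspect("equal")
    ax.axis("off")

    phases = model["phases"]
    ax_bar.bar(range(len(phases)), [model["totals_bar"][p] for p in phases], color="0.6")
    ax_bar.set_xticks(range(len(phases)), phases, rotation=20, fontsize=8)
    ax_bar.set_ylabel("frames")

    width = 0.8 / max(1, len(SetLabel))
    for k, s in enumerate(SetLabel):
        for i, instr in enumerate(config.instruments):
            vals = [
                model["instrument_bars"][(p, instr)][s] for p in phases
            ]
            ax_instr.bar(
                [x + (k - 1) * width for x in range(len(phases))],
                vals,
                width=width,
                bottom=[i * 1.0 for _ in phases],  # visual grouping row per instrument
                color=style.color(s),
                alpha=0.7,
                label=s.value if i == 0 else None,
            )
    ax_instr.set_xticks(range(len(phases)), phases, rotation=20, fontsize=8)
    ax_instr.set_yticks([])
    ax_instr.set_ylabel("instruments / phase")
    ax_instr.legend(loc="upper right", fontsize=7)

    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return model


def _draw_pie(
    ax,
    center: tuple[float, float],
    radius: float,
    fractions: Mapping[SetLabel, float],
    style: ViewStyle,
    donut: bool = False,
) -> None:
    start = 90.0
    total = sum(fractions.values())
    if total == 0:
        ax.add_patch(plt.Circle(center, radius, color="0.85", zorder=3))
        return
    from matplotlib.patches import Wedge

    width = radius * 0.45 if donut else None
    for s in SetLabel:
        frac = fractions.get(s, 0.0)
        if frac <= 0:
            continue
        sweep = 360.0 * frac / total
        ax.add_patch(
            Wedge(
                center, radius, start, start + sweep,
                width=width, color=style.color(s), zorder=3,
            )
        )
        start += sweep


# ---------------------------------------------------------------------------
# Instrument view


def instrument_view_model(
    instrument_counts: InstrumentCounts,
    combination_counts: CombinationCounts,
    config: DatasetConfig,
    style: ViewStyle | None = None,
    normalize_bars: bool = False,
    layout_seed: int = 0,
) -> dict:
    """Layout model of the instrument view.

    Instruments (plus the idle bar) sit on a circle; combination nodes are
    placed by a seeded force-directed layout anchored at their member
    instruments and drawn as per-set pies.  ``normalize_bars`` scales each
    instrument's radial bars by that instrument's own maximum, for
    visibility when totals differ by orders of magnitude.
    """
    style = style or ViewStyle()
    instruments = list(config.instruments)
    n = len(instruments) + 1  # + idle bar
    anchor_pos: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(instruments + ["(idle)"]):
        angle = 2 * math.pi * i / n
        anchor_pos[name] = (math.cos(angle), math.sin(angle))

    bars = []
    for name in instruments:
        counts = {s: instrument_counts.frame_count(name, s) for s in SetLabel}
        scale = max(counts.values()) if normalize_bars else None
        bars.append(
            {
                "instrument": name,
                "pos": anchor_pos[name],
                "counts": counts,
                "scaled": {
                    s: (c / scale if scale else c) for s, c in counts.items()
                },
            }
        )
    idle = {s: instrument_counts.idle.get(s, 0) for s in SetLabel}

    combos = combination_counts.observed_combinations()
    graph = nx.Graph()
    for name in instruments:
        graph.add_node(("instrument", name))
    for combo in combos:
        node = ("combo", combo)
        graph.add_node(node)
        for i in combo:
            graph.add_edge(node, ("instrument", instruments[i]))
    fixed = [("instrument", name) for name in instruments]
    init = {("instrument", name): anchor_pos[name] for name in instruments}
    for combo in combos:
        xs = [anchor_pos[instruments[i]][0] for i in combo]
        ys = [anchor_pos[instruments[i]][1] for i in combo]
        init[("combo", combo)] = (sum(xs) / len(xs), sum(ys) / len(ys))
    if combos:
        pos = nx.spring_layout(
            graph, pos=init, fixed=fixed, seed=layout_seed, k=0.3, iterations=50
        )
    else:
        pos = init

    max_total = max((combination_counts.total(c) for c in combos), default=0)
    combo_nodes = []
    for combo in combos:
        counts = {s: combination_counts.count(combo, s) for s in SetLabel}
        total = sum(counts.values())
        combo_nodes.append(
            {
                "combination": combo,
                "label": combination_label(combo, config),
                "pos": tuple(float(v) for v in pos[("combo", combo)]),
                "counts": counts,
                "total": total,
                "pie": _set_fractions(counts),
                "radius": 0.05 + 0.10 * (total / max_total if max_total else 0),
            }
        )
    return {
        "bars": bars,
        "idle": {"pos": anchor_pos["(idle)"], "counts": idle},
        "combos": combo_nodes,
        "normalized": normalize_bars,
        "layout_seed": layout_seed,
    }


def render_instrument_view(
    instrument_counts: InstrumentCounts,
    combination_counts: CombinationCounts,
    config: DatasetConfig,
    out: str | Path,
    style: ViewStyle | None = None,
    normalize_bars: bool = False,
    layout_seed: int = 0,
) -> dict:
    """Render the instrument view to a file; returns the model drawn."""
    style = style or ViewStyle()
    model = instrument_view_model(
        instrument_counts,
        combination_counts,
        config,
        style,
        normalize_bars=normalize_bars,
        layout_seed=layout_seed,
    )
    fig, ax = plt.subplots(figsize=(8, 8))

    global_max = max(
        [max(b["counts"].values(), default=0) for b in model["bars"]]
        + [max(model["idle"]["counts"].values(), default=0), 1]
    )

    def bar_length(entry_counts: Mapping[SetLabel, int], s: SetLabel, normalized: bool) -> float:
        if normalized:
            m = max(entry_counts.values())
            return 0.35 * (entry_counts[s] / m) if m else 0.0
        return 0.35 * (entry_counts[s] / global_max)

    def draw_radial(pos: tuple[float, float], counts: Mapping[SetLabel, int], label: str) -> None:
        ux, uy = pos
        px, py = -uy, ux  # tangential offset for the three set bars
        for k, s in enumerate(SetLabel):
            length = bar_length(counts, s, model["normalized"])
            off = (k - 1) * 0.04
            ax.plot(
                [ux + off * px, ux + off * px + length * ux],
                [uy + off * py, uy + off * py + length * uy],
                color=style.color(s),
                lw=5,
                solid_capstyle="butt",
            )
        ax.annotate(
            label, (1.45 * ux, 1.45 * uy), ha="center", va="center", fontsize=8
        )

    for bar in model["bars"]:
        draw_radial(bar["pos"], bar["counts"], bar["instrument"])
    draw_radial(model["idle"]["pos"], model["idle"]["counts"], "(idle)")

    for combo in model["combos"]:
        _draw_pie(ax, combo["pos"], combo["radius"], combo["pie"], style)
        ax.annotate(
            combo["label"], combo["pos"], xytext=(0, -12),
            textcoords="offset points", ha="center", fontsize=6,
        )

    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.8, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return model


# ---------------------------------------------------------------------------
# Supplementary view


def supplementary_model(
    totals: Mapping[SetLabel, SetTotals],
    durations: DurationStats,
    split: SplitAssignment,
) -> dict:
    """Layout model: mirrored set totals plus per-surgery duration panels.

    Sets with no surgeries are omitted from the panels (an empty VAL draws
    nothing rather than an empty axis).
    """
    sets = [s for s in SetLabel if totals[s].surgeries > 0]
    return {
        "sets": [s.value for s in sets],
        "totals": {
            s.value: {
                "surgeries": totals[s].surgeries,
                "frames": totals[s].frames,
                "mean_duration": totals[s].mean_duration,
            }
            for s in sets
        },
        "panels": {
            s.value: {
                "surgeries": [
                    {"surgery_id": sid, "duration": durations.by_set[s][sid]}
                    for sid in sorted(durations.by_set[s])
                ],
                "mean": durations.means[s],
            }
            for s in sets
        },
    }


def render_supplementary(
    totals: Mapping[SetLabel, SetTotals],
    durations: DurationStats,
    split: SplitAssignment,
    out: str | Path,
    style: ViewStyle | None = None,
) -> dict:
    """Render the supplementary view to a file; returns the model drawn."""
    style = style or ViewStyle()
    model = supplementary_model(totals, durations, split)
    sets = [SetLabel(s) for s in model["sets"]]
    fig, axes = plt.subplots(
        1, 1 + len(sets), figsize=(4 + 3 * len(sets), 4), squeeze=False
    )
    ax0 = axes[0][0]

    y = range(len(sets))
    surg = [model["totals"][s.value]["surgeries"] for s in sets]
    frames = [model["totals"][s.value]["frames"] for s in sets]
    max_frames = max(frames) if frames else 1
    max_surg = max(surg) if surg else 1
    # mirrored: surgeries leftwards, frames rightwards, each on its own scale
    ax0.barh(
        list(y),
        [-v / max_surg for v in surg],
        color=[style.color(s) for s in sets],
        alpha=0.9,
    )
    ax0.barh(
        list(y),
        [v / max_frames for v in frames],
        color=[style.color(s) for s in sets],
        alpha=0.5,
    )
    for i, s in enumerate(sets):
        ax0.text(-1.02, i, str(surg[i]), ha="right", va="center", fontsize=8)
        ax0.text(1.02, i, str(frames[i]), ha="left", va="center", fontsize=8)
    ax0.set_yticks(list(y), [s.value for s in sets])
    ax0.set_xticks([])
    ax0.set_title("surgeries | frames")
    ax0.axvline(0, color="black", lw=0.8)

    for j, s in enumerate(sets, start=1):
        ax = axes[0][j]
        panel = model["panels"][s.value]
        vals = [e["duration"] for e in panel["surgeries"]]
        ax.bar(range(len(vals)), vals, color=style.color(s))
        if panel["mean"] is not None:
            ax.axhline(panel["mean"], ls="--", color="black", lw=1)
        ax.set_title(f"{s.value} (n={len(vals)})", fontsize=9)
        ax.set_xticks([])
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return model


# ---------------------------------------------------------------------------
# Report writers


def write_report(report: AuditReport, path: str | Path, fmt: str | None = None) -> Path:
    """Write an audit report as JSON (lossless), Markdown, or tidy CSV."""
    path = Path(path)
    if fmt is None:
        fmt = {".json": "json", ".md": "markdown", ".csv": "csv"}.get(
            path.suffix, "json"
        )
    if fmt == "json":
        report.to_json(path)
    elif fmt == "markdown":
        path.write_text(_report_markdown(report))
    elif fmt == "csv":
        _report_csv(report, path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


def _report_markdown(report: AuditReport) -> str:
    sets = report.audited_sets
    lines = [f"# Split audit: {report.dataset}", ""]
    lines.append("## Per-set totals")
    lines.append("")
    lines.append("| set | surgeries | frames | mean duration |")
    lines.append("|---|---|---|---|")
    for s in sets:
        t = report.totals[s]
        mean = f"{t.mean_duration:.1f}" if t.mean_duration is not None else "-"
        lines.append(f"| {s.value} | {t.surgeries} | {t.frames} | {mean} |")
    lines.append("")
    lines.append("## Unrepresented attributes per kind and set")
    lines.append("")
    header = "| kind | " + " | ".join(f"absent_in_{s.value}" for s in sets) + " |"
    lines.append(header)
    lines.append("|" + "---|" * (len(sets) + 1))
    summary = report.summary()
    for row, cells in summary.items():
        vals = " | ".join(
            "N/A" if cells[s] is None else str(cells[s]) for s in sets
        )
        lines.append(f"| {row} | {vals} |")
    lines.append("")
    if report.absent_in:
        lines.append("## Flagged attributes")
        lines.append("")
        for key in sorted(report.absent_in, key=lambda k: k._sort_key()):
            absent = ", ".join(sorted(s.value for s in report.absent_in[key]))
            counts = report.attributes[key]
            shown = ", ".join(
                f"{s.value}={counts.get(s, 0)}" for s in sets
            )
            lines.append(
                f"- **{key.kind.value}** `{key.describe()}` absent in: {absent} ({shown})"
            )
        lines.append("")
    return "\n".join(lines)


def _report_csv(report: AuditReport, path: Path) -> None:
    sets = report.audited_sets
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["kind", "attribute"]
            + [s.value for s in sets]
            + ["absent_in"]
        )
        for key in sorted(report.attributes, key=lambda k: k._sort_key()):
            counts = report.attributes[key]
            absent = ";".join(
                sorted(s.value for s in report.absent_in.get(key, frozenset()))
            )
            writer.writerow(
                [key.kind.value, key.describe()]
                + [counts.get(s, 0) for s in sets]
                + [absent]
            )


# ---------------------------------------------------------------------------
# Batch equivalent of the interactive linked filtering


def filter_surgeries(
    surgeries: Iterable[Surgery],
    config: DatasetConfig,
    phases: Sequence[str] | None = None,
    transition: tuple[str, str] | None = None,
    instrument: str | None = None,
    combination: Sequence[str] | None = None,
) -> list[Surgery]:
    """Recompute-and-re-render filtering, mirroring the interactive views.

    ``phases`` keeps only frames labelled with those phases; ``transition``
    keeps whole surgeries containing the (source, target) transition;
    ``instrument`` keeps frames where it is visible; ``combination`` keeps
    frames whose exact visible set equals it.  Surgeries left without frames
    are dropped.
    """
    from splitaudit.workflow_stats import extract_transitions

    out: list[Surgery] = []
    combo_idx = (
        tuple(sorted(config.instrument_index(i) for i in combination))
        if combination
        else None
    )
    instr_idx = config.instrument_index(instrument) if instrument else None
    for s in surgeries:
        if transition is not None:
            if s.phases is None:
                continue
            wanted = transition
            found = any(
                (t.source, t.target) == wanted for t in extract_transitions(s, config)
            )
            if not found:
                continue
        keep = list(range(s.duration))
        if phases is not None:
            if s.phases is None:
                continue
            allowed = set(phases)
            keep = [i for i in keep if s.phases[i] in allowed]
        if instr_idx is not None:
            if s.instruments is None:
                continue
            keep = [i for i in keep if s.instruments[i][instr_idx]]
        if combo_idx is not None:
            if s.instruments is None:
                continue
            keep = [
                i for i in keep if classify_frame(s.instruments[i])[1] == combo_idx
            ]
        if not keep:
            continue
        out.append(
            Surgery(
                surgery_id=s.surgery_id,
                frame_indices=tuple(s.frame_indices[i] for i in keep),
                phases=(
                    tuple(s.phases[i] for i in keep) if s.phases is not None else None
                ),
                instruments=(
                    tuple(s.instruments[i] for i in keep)
                    if s.instruments is not None
                    else None
                ),
            )
        )
    return out
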