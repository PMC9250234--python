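"""Manhattan and region-focus plots.

Plots are rendered with matplotlib to vector output (SVG by default, with
hashed ids and no embedded date so identical inputs yield byte-identical
files).  Every figure is built from an explicit data model (point
coordinates, highlight flags, line positions, track lanes) that is
returned alongside the file so tests can assert on the data layer instead
of pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ._util import chrom_sort_key
from .annotation import GeneFeature

HIGHLIGHT_COLOR = "red"
THRESHOLD_COLOR = "blue"
CHROM_GAP = 1_000_000  # bp of padding between concatenated chromosomes

_SAVEFIG_KW = {"metadata": {"Date": None}}


@dataclass
class VerticalLine:
    """A labelled vertical guide at a genomic coordinate."""

    chromosome: str
    position: int
    style: str = "solid"  # or "dotted"
    label: str = ""

    def __post_init__(self) -> None:
        if self.style not in {"solid", "dotted"}:
            raise ValueError(f"unknown line style {self.style!r}")


@dataclass
class PlotSpec:
    """Styling for Manhattan plots: significant points in ``highlight``,
    the averaged Bonferroni guide in ``threshold_color``, plus optional
    vertical lines and a (chromosome, start, stop) region restriction."""

    highlight: str = HIGHLIGHT_COLOR
    threshold_color: str = THRESHOLD_COLOR
    vertical_lines: list[VerticalLine] = field(default_factory=list)
    region: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        if self.region is not None and not (self.region[1] < self.region[2]):
            raise ValueError("region start must be < stop")


@dataclass
class ManhattanData:
    """Data layer of a rendered Manhattan plot."""

    points: pd.DataFrame  # columns: Marker, Chrom, Pos, x, y, significant
    threshold_y: float | None
    vline_x: list[tuple[float, str, str]]  # (x, style, label)
    chrom_offsets: dict[str, float]


def _cumulative_offsets(table: pd.DataFrame) -> dict[str, float]:
    offsets: dict[str, float] = {}
    running = 0.0
    for c in sorted(table["Chrom"].astype(str).unique(), key=chrom_sort_key):
        offsets[c] = running
        running += float(table.loc[table["Chrom"].astype(str) == c, "Pos"].max()) + CHROM_GAP
    return offsets


def manhattan_plot(
    results,
    significance_report,
    plot_spec: PlotSpec | None = None,
    out_path=None,
    features: list[GeneFeature] | None = None,
) -> ManhattanData:
    """Genome-wide Manhattan plot: -log10 p against cumulative physical
    position, chromosomes concatenated in order with alternating shading.

    Significant markers are drawn in the highlight color; the blue
    horizontal guide sits at the averaged per-chromosome Bonferroni
    y-value carried by the significance report.  Vertical lines may be
    placed at explicit coordinates or, if ``features`` is given and the
    line's label matches a feature name, at that feature's midpoint.
    """
    plot_spec = plot_spec or PlotSpec()
    df = results.table.copy()
    if df.empty:
        raise ValueError("empty GWAS result")
    df["Chrom"] = df["Chrom"].astype(str)
    sig_flags = significance_report.table.set_index("Marker")["Significant"]
    df["significant"] = df["Marker"].map(sig_flags).fillna(False).astype(bool)
    offsets = _cumulative_offsets(df)
    df["x"] = df["Pos"].astype(float) + df["Chrom"].map(offsets)
    df["y"] = -np.log10(df["P"].astype(float))

    feature_mid = {f.name: (f.chromosome, f.midpoint) for f in (features or [])}
    vlines: list[tuple[float, str, str]] = []
    for vl in plot_spec.vertical_lines:
        chrom, pos = vl.chromosome, vl.position
        if vl.label in feature_mid:
            chrom, pos = feature_mid[vl.label]
        if str(chrom) not in offsets:
            raise ValueError(f"vertical line on unknown chromosome {chrom!r}")
        vlines.append((float(pos) + offsets[str(chrom)], vl.style, vl.label))

    data = ManhattanData(
        points=df[["Marker", "Chrom", "Pos", "x", "y", "significant"]],
        threshold_y=significance_report.plot_line_y,
        vline_x=vlines,
        chrom_offsets=offsets,
    )
    if out_path is not None:
        _render_manhattan(data, plot_spec, out_path)
    return data


def _render_manhattan(data: ManhattanData, spec: PlotSpec, out_path) -> None:
    with plt.rc_context({"svg.hashsalt": "locogwas"}):
        fig, ax = plt.subplots(figsize=(10, 4))
        _draw_manhattan_panel(ax, data, spec)
        ax.set_xlabel("physical position (chromosomes concatenated)")
        ax.set_ylabel(r"$-\log_{10}\,p$")
        fig.tight_layout()
        fig.savefig(out_path, **_SAVEFIG_KW)
        plt.close(fig)


def _draw_manhattan_panel(ax, data: ManhattanData, spec: PlotSpec) -> None:
    for i, (c, off) in enumerate(data.chrom_offsets.items()):
        sub = data.points[data.points["Chrom"] == c]
        base = "#444444" if i % 2 == 0 else "#999999"
        plain = sub[~sub["significant"]]
        hot = sub[sub["significant"]]
        ax.scatter(plain["x"], plain["y"], s=6, c=base, linewidths=0)
        if len(hot):
            ax.scatter(hot["x"], hot["y"], s=12, c=spec.highlight, linewidths=0)
    if data.threshold_y is not None:
        ax.axhline(data.threshold_y, color=spec.threshold_color, lw=1)
    for x, style, label in data.vline_x:
        ax.axvline(x, color="black", lw=0.8,
                   linestyle="-" if style == "solid" else ":",
                   label=label or None)


@dataclass(frozen=True)
class SpanPrimitive:
    """One styled span on the architecture track."""

    lane: int
    start: int
    stop: int
    style: str  # "gene", "exon", "ncRNA"
    label: str


def architecture_track(
    features: list[GeneFeature],
    region: tuple[str, int, int],
    exons: dict[str, list[tuple[int, int]]] | None = None,
) -> list[SpanPrimitive]:
    """Drawing primitives for a genome-architecture track.

    Features overlapping the closed region [start, stop] are laid out on
    lanes assigned greedily (a feature takes the lowest lane whose previous
    occupant it does not overlap).  Exon sub-intervals, given per feature
    name, are emitted as "exon" primitives on the parent's lane, clipped to
    the parent's extent; non-coding features get the "ncRNA" style.
    """
    chrom, start, stop = region
    exons = exons or {}
    in_region = [
        f for f in features
        if f.chromosome == str(chrom) and f.stop >= start and f.start <= stop
    ]
    in_region.sort(key=lambda f: (f.start, f.stop, f.name))
    lane_end: list[int] = []
    prims: list[SpanPrimitive] = []
    for f in in_region:
        lane = next((i for i, e in enumerate(lane_end) if f.start > e), None)
        if lane is None:
            lane = len(lane_end)
            lane_end.append(f.stop)
        else:
            lane_end[lane] = f.stop
        style = "gene" if f.feature_class == "gene" else "ncRNA"
        prims.append(SpanPrimitive(lane, f.start, f.stop, style, f.name))
        for es, ee in exons.get(f.name, []):
            prims.append(
                SpanPrimitive(lane, max(es, f.start), min(ee, f.stop), "exon", f.name)
            )
    return prims


@dataclass
class FocusData:
    """Data layer of a dual-density region plot."""

    region: tuple[str, int, int]
    low: pd.DataFrame   # Marker, Pos, y
    high: pd.DataFrame
    track: list[SpanPrimitive]


def focus_plot(
    region: tuple[str, int, int],
    results_low,
    results_high,
    features: list[GeneFeature],
    out_path=None,
    exons: dict[str, list[tuple[int, int]]] | None = None,
) -> FocusData:
    """Three vertically aligned panels over a shared bp x-axis: a
    low-marker-density Manhattan, a high-density Manhattan, and the
    genome-architecture track.  Only markers/features inside the closed
    region are drawn."""
    chrom, start, stop = region
    if start >= stop:
        raise ValueError("empty region")

    def _slice(res) -> pd.DataFrame:
        df = res.table.copy()
        df["Chrom"] = df["Chrom"].astype(str)
        df = df[(df["Chrom"] == str(chrom)) & (df["Pos"] >= start) & (df["Pos"] <= stop)]
        out = df[["Marker", "Pos"]].copy()
        out["y"] = -np.log10(df["P"].astype(float))
        return out.reset_index(drop=True)

    data = FocusData(
        region=region,
        low=_slice(results_low),
        high=_slice(results_high),
        track=architecture_track(features, region, exons),
    )
    if out_path is not None:
        with plt.rc_context({"svg.hashsalt": "locogwas"}):
            fig, axes = plt.subplots(
                3, 1, figsize=(10, 7), sharex=True,
                gridspec_kw={"height_ratios": [3, 3, 1]},
            )
            for ax, panel, title in (
                (axes[0], data.low, "low marker density"),
                (axes[1], data.high, "high marker density"),
            ):
                ax.scatter(panel["Pos"], panel["y"], s=8, c="#444444", linewidths=0)
                ax.set_ylabel(r"$-\log_{10}\,p$")
                ax.set_title(title, fontsize=9)
            for prim in data.track:
                y = -prim.lane
                if prim.style == "exon":
                    axes[2].fill_between([prim.start, prim.stop], y - 0.3, y + 0.3,
                                         color="#333333")
                else:
                    color = "#777777" if prim.style == "gene" else "#cc7722"
                    axes[2].plot([prim.start, prim.stop], [y, y], lw=2, color=color)
            axes[2].set_yticks([])
            axes[2].set_xlabel(f"chromosome {chrom} position (bp)")
            for ax in axes:
                ax.set_xlim(start, stop)
            fig.tight_layout()
            fig.savefig(out_path, **_SAVEFIG_KW)
            plt.close(fig)
    return data
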