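"""Visualization of fragment tables.

Four plot kinds, mirroring the standard exploratory views of locus-centric
fragmentomics: fragment-size distributions (density or histogram), end-motif
bar plots (per-group proportion, raw count, or between-group difference),
pooled base composition at fragment ends, and per-position sequence logos.

Every renderer first computes a plain numeric matrix (a DataFrame) from the
table and then draws it; the matrix is returned alongside the figure so the
numbers can be tested and reused without touching pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.font_manager import FontProperties  # noqa: E402
from matplotlib.patches import PathPatch  # noqa: E402
from matplotlib.textpath import TextPath  # noqa: E402
from matplotlib.transforms import Affine2D  # noqa: E402

from .report import FragmentTable

PLOT_KINDS = ("size_distribution", "motif_barplot", "freq_barplot", "seqlogo")
MOTIF_MODES = ("per_group_proportion", "count", "group_difference")

_BASE_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B",
                "T": "#D62839", "N": "#7F7F7F"}


@dataclass
class PlotRequest:
    kind: str
    group_by: str = "status"
    groups_shown: Optional[Sequence[str]] = None
    mode: str = "per_group_proportion"   # motif_barplot only
    style: str = "density"               # size_distribution: density|histogram
    motif_column: str = "motif5"         # motif_barplot / freq_barplot / seqlogo
    bins: Optional[int] = None

    def __post_init__(self):
        if self.kind not in PLOT_KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}; "
                             f"choose from {PLOT_KINDS}")
        if self.mode not in MOTIF_MODES:
            raise ValueError(f"unknown motif mode {self.mode!r}")


def _grouped(t: FragmentTable, req: PlotRequest) -> pd.DataFrame:
    df = t.df
    if req.group_by not in df.columns:
        raise ValueError(f"group_by column {req.group_by!r} not in table "
                         f"(columns: {list(df.columns)})")
    if req.groups_shown is not None:
        present = set(df[req.group_by].dropna().unique())
        missing = [g for g in req.groups_shown if g not in present]
        if missing:
            raise ValueError(f"requested groups {missing} absent from column "
                             f"{req.group_by!r}")
        df = df[df[req.group_by].isin(list(req.groups_shown))]
    if df.empty:
        raise ValueError("empty selection: no fragments after group filtering")
    return df


def render_plot(t: FragmentTable, req: PlotRequest, out: Optional[str] = None
                ) -> tuple[plt.Figure, pd.DataFrame]:
    """Render one plot; returns (figure, underlying numeric matrix).

    If ``out`` is given the figure is also saved there (format from the
    extension).
    """
    df = _grouped(t, req)
    if req.kind == "size_distribution":
        fig, matrix = _plot_size(df, req)
    elif req.kind == "motif_barplot":
        fig, matrix = _plot_motif_bars(df, req)
    elif req.kind == "freq_barplot":
        fig, matrix = _plot_freq_bars(df, req)
    else:
        fig, matrix = _plot_seqlogo(df, req)
    if out:
        fig.savefig(out, dpi=150, bbox_inches="tight")
    return fig, matrix


# ---------------------------------------------------------------------------

def _size_groups(df: pd.DataFrame, req: PlotRequest):
    groups = {}
    for g, sub in df.groupby(req.group_by, sort=True):
        sizes = sub["size_bp"].dropna().astype(float).to_numpy()
        if len(sizes):
            groups[str(g)] = sizes
    if not groups:
        raise ValueError("no fragments with a defined size in the selection")
    return groups


def _plot_size(df, req):
    from scipy.stats import gaussian_kde

    groups = _size_groups(df, req)
    lo = min(s.min() for s in groups.values()) - 10
    hi = max(s.max() for s in groups.values()) + 10
    fig, ax = plt.subplots(figsize=(6, 4))
    if req.style == "density":
        grid = np.linspace(lo, hi, 512)
        data = {}
        for g, sizes in groups.items():
            if len(np.unique(sizes)) < 2:
                # degenerate group: unit spike rendered as a narrow gaussian
                dens = np.exp(-0.5 * ((grid - sizes[0]) / 1.0) ** 2)
                dens /= np.trapezoid(dens, grid)
            else:
                dens = gaussian_kde(sizes)(grid)
            data[g] = dens
            ax.plot(grid, dens, label=g)
        matrix = pd.DataFrame(data, index=pd.Index(grid, name="size_bp"))
        ax.set_ylabel("density")
    else:
        nbins = req.bins or max(10, int(hi - lo))
        edges = np.linspace(lo, hi, nbins + 1)
        data = {g: np.histogram(sizes, bins=edges)[0]
                for g, sizes in groups.items()}
        matrix = pd.DataFrame(data, index=pd.Index(edges[:-1], name="size_bp"))
        for g, counts in data.items():
            ax.stairs(counts, edges, label=g, fill=False)
        ax.set_ylabel("fragments")
    ax.set_xlabel("fragment size (bp)")
    ax.legend(title=req.group_by)
    return fig, matrix


def _motif_counts(df, req) -> pd.DataFrame:
    sub = df[[req.group_by, req.motif_column]].dropna()
    if sub.empty:
        raise ValueError(f"no defined {req.motif_column} values in selection")
    counts = (sub.groupby([req.motif_column, req.group_by], sort=True)
              .size().unstack(fill_value=0))
    counts.columns = [str(c) for c in counts.columns]
    return counts


def _plot_motif_bars(df, req):
    counts = _motif_counts(df, req)
    if req.mode == "count":
        matrix = counts.astype(float)
        ylabel = "fragments"
    elif req.mode == "per_group_proportion":
        matrix = counts / counts.sum(axis=0)
        ylabel = "proportion of group"
    else:  # group_difference
        if counts.shape[1] != 2:
            raise ValueError("group_difference mode needs exactly two groups "
                             f"(got {list(counts.columns)})")
        props = counts / counts.sum(axis=0)
        a, b = props.columns
        matrix = (props[a] - props[b]).to_frame(f"{a}-{b}")
        ylabel = f"proportion difference ({a} - {b})"
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(matrix)), 4))
    matrix.plot.bar(ax=ax, width=0.8)
    ax.set_ylabel(ylabel)
    ax.set_xlabel(req.motif_column)
    fig.autofmt_xdate(rotation=90)
    return fig, matrix


def _plot_freq_bars(df, req):
    sub = df[[req.group_by, req.motif_column]].dropna()
    if sub.empty:
        raise ValueError(f"no defined {req.motif_column} values in selection")
    data = {}
    for g, s in sub.groupby(req.group_by, sort=True):
        pooled = "".join(s[req.motif_column])
        total = len(pooled)
        data[str(g)] = {b: pooled.count(b) / total for b in "ACGTN"}
    matrix = pd.DataFrame(data).reindex(list("ACGTN")).fillna(0.0)
    matrix = matrix.loc[matrix.sum(axis=1) > 0]
    fig, ax = plt.subplots(figsize=(6, 4))
    matrix.plot.bar(ax=ax, width=0.8)
    ax.set_ylabel("base proportion (all motif positions pooled)")
    ax.set_xlabel("base")
    return fig, matrix


def position_proportions(motifs: Sequence[str]) -> pd.DataFrame:
    """Per-position base-proportion matrix of equal-length motifs; each row
    sums to 1."""
    k = len(motifs[0])
    if any(len(m) != k for m in motifs):
        raise ValueError("motifs have unequal lengths")
    arr = np.array([list(m) for m in motifs])
    rows = []
    for i in range(k):
        col = arr[:, i]
        rows.append({b: float(np.mean(col == b)) for b in "ACGTN"})
    mat = pd.DataFrame(rows, index=pd.RangeIndex(1, k + 1, name="position"))
    return mat.loc[:, (mat != 0).any(axis=0)]


def _plot_seqlogo(df, req):
    sub = df[req.motif_column].dropna()
    if sub.empty:
        raise ValueError(f"no defined {req.motif_column} values in selection")
    matrix = position_proportions(list(sub))
    fig, ax = plt.subplots(figsize=(1.0 * len(matrix) + 1, 3))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for pos_i, (_, row) in enumerate(matrix.iterrows()):
        y = 0.0
        for base, frac in sorted(row.items(), key=lambda kv: kv[1]):
            if frac <= 0:
                continue
            tp = TextPath((0, 0), base, size=1.0, prop=font)
            bb = tp.get_extents()
            transform = (Affine2D()
                         .translate(-bb.x0, -bb.y0)
                         .scale(0.9 / bb.width, frac / bb.height)
                         .translate(pos_i + 0.05, y))
            ax.add_patch(PathPatch(tp, transform=transform + ax.transData,
                                   facecolor=_BASE_COLORS.get(base, "gray"),
                                   edgecolor="none"))
            y += frac
    ax.set_xlim(0, len(matrix))
    ax.set_ylim(0, 1.02)
    ax.set_xticks(np.arange(len(matrix)) + 0.5)
    ax.set_xticklabels(matrix.index)
    ax.set_xlabel("motif position")
    ax.set_ylabel("proportion")
    return fig, matrix
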