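"""Diagnostic plots for codon usage analyses.

Every plot is a pure function of the tidy tables produced by the analysis
modules: no statistics are computed here beyond simple grouping, and no
hidden randomness enters, so identical inputs render identical figures.
:func:`save_plot` writes PNG and SVG alongside the underlying table as TSV
so each figure is independently reproducible.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # noqa: E402  (headless rendering)
matplotlib.rcParams["svg.hashsalt"] = "cubkit"  # deterministic SVG ids

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .composition import NeutralityFit
from .multivariate import ClusterAssignment, HeatmapMatrix, PCAResult

_FIGSIZE = (7.0, 5.0)


def expected_enc(gc3) -> np.ndarray:
    """Expected ENc under codon bias driven solely by GC3.

    ENc*(s) = 2 + s + 29 / (s^2 + (1 - s)^2), capped at 61 for display
    consistency with the index itself.
    """
    s = np.asarray(gc3, dtype=float)
    return np.minimum(2.0 + s + 29.0 / (s ** 2 + (1.0 - s) ** 2), 61.0)


def save_plot(fig: plt.Figure, basepath, data: pd.DataFrame | None = None,
              formats=("png", "svg")) -> list[Path]:
    """Write the figure (PNG/SVG, timestamp-free) and its source table."""
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        target = basepath.with_suffix(f".{fmt}")
        meta = {"Date": None} if fmt == "svg" else {}
        fig.savefig(target, dpi=150, metadata=meta)
        written.append(target)
    if data is not None:
        table = basepath.with_suffix(".tsv")
        out = data.reset_index() if data.index.name or data.index.nlevels > 1 else data
        out.to_csv(table, sep="\t", index=False, float_format="%.10g")
        written.append(table)
    plt.close(fig)
    return written


def plot_qc_boxplot(lengths: pd.DataFrame) -> plt.Figure:
    """CDS length (amino acids) per organism; outliers beyond 1.5 x IQR in red."""
    if lengths.empty:
        raise ValueError("length table is empty")
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    sns.boxplot(
        data=lengths, x="organism", y="aa_length", ax=ax, color="#8ecae6",
        flierprops=dict(marker="o", markerfacecolor="red",
                        markeredgecolor="red", markersize=4),
    )
    ax.set_xlabel("organism")
    ax.set_ylabel("CDS length (amino acids)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    return fig


def plot_gc_boxplot(gc: pd.DataFrame) -> plt.Figure:
    """Grouped boxes per organism for overall GC and GC1/GC2/GC3."""
    long = gc.melt(
        id_vars=["organism", "id"],
        value_vars=["gc_all", "gc1", "gc2", "gc3"],
        var_name="position", value_name="fraction",
    )
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    sns.boxplot(data=long, x="organism", y="fraction", hue="position", ax=ax)
    ax.set_ylabel("GC fraction")
    ax.tick_params(axis="x", rotation=90)
    ax.legend(title="", loc="best", fontsize=8)
    fig.tight_layout()
    return fig


def plot_enc_gc3(enc: pd.DataFrame, gc: pd.DataFrame,
                 group: bool = False) -> plt.Figure:
    """ENc against GC3 with the expected-ENc curve (solid red).

    ``group`` plots one point per organism (means); otherwise one point per
    gene, for one or more organisms distinguished by colour.
    """
    joined = enc.merge(gc[["organism", "id", "gc3"]], on=["organism", "id"])
    joined = joined.dropna(subset=["value", "gc3"])
    if joined.empty:
        raise ValueError("no (organism, id) overlap between ENc and GC tables")
    if group:
        joined = (joined.groupby("organism", sort=False)[["value", "gc3"]]
                  .mean().reset_index())
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    sns.scatterplot(data=joined, x="gc3", y="value", hue="organism",
                    s=30 if group else 12, ax=ax)
    s = np.linspace(1e-3, 1 - 1e-3, 512)
    ax.plot(s, expected_enc(s), color="red", lw=1.5, label="expected ENc")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 62)
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENc")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    return fig


def plot_pr2(points: pd.DataFrame, group: bool = False) -> plt.Figure:
    """PR2 plot: A3/(A3+T3) against G3/(G3+C3) with the parity crosshair."""
    data = points.copy()
    if group:
        data = (data.groupby("organism", sort=False)[["gc_bias", "at_bias"]]
                .mean().reset_index())
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    sns.scatterplot(data=data, x="gc_bias", y="at_bias", hue="organism",
                    s=30 if group else 12, ax=ax)
    ax.axhline(0.5, color="red", lw=1.2)
    ax.axvline(0.5, color="red", lw=1.2)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    return fig


def plot_neutrality(gc: pd.DataFrame, fit: NeutralityFit) -> plt.Figure:
    """Neutrality plot (one organism): GC12 against GC3 with the OLS line.

    The annotation passes the fit through verbatim: slope equation, R, R^2
    and the p-value of the slope.
    """
    organisms = gc["organism"].unique()
    if len(organisms) != 1:
        raise ValueError(
            "the neutrality plot can only be used for one organism at a time"
        )
    fig, ax = plt.subplots(figsize=_FIGSIZE)
    ax.scatter(gc["gc3"], gc["gc12"], s=12, color="#457b9d")
    xs = np.linspace(float(gc["gc3"].min()), float(gc["gc3"].max()), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="red", lw=1.5)
    r = np.sqrt(fit.r2) * np.sign(fit.slope)
    ax.set_title(
        f"{organisms[0]}: GC12 = {fit.slope:.4g}*GC3 + {fit.intercept:.4g}   "
        f"R = {r:.4g}, R$^2$ = {fit.r2:.4g}, p = {fit.pvalue:.3g}",
        fontsize=9,
    )
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    fig.tight_layout()
    return fig


def plot_heatmap(hm: HeatmapMatrix, cmap: str = "vlag") -> plt.Figure:
    """Heatmap honouring the precomputed dendrogram row/column orders."""
    mat = hm.values.loc[hm.row_order, hm.col_order]
    fig, ax = plt.subplots(
        figsize=(max(6.0, 0.22 * mat.shape[1]), max(4.0, 0.3 * mat.shape[0]))
    )
    sns.heatmap(mat, cmap=cmap, center=0 if (mat.values < 0).any() else None,
                ax=ax, cbar_kws={"shrink": 0.7})
    ax.set_xlabel("")
    ax.set_ylabel("")
    fig.tight_layout()
    return fig


def plot_pca(pca: PCAResult,
             assignment: ClusterAssignment | None = None) -> plt.Figure:
    """PC1/PC2 score plot, coloured by cluster, axes labelled with the
    variance explained."""
    scores = pca.scores
    fig, ax = plt.subplots(figsize=(6.0, 5.5))
    if assignment is not None:
        palette = sns.color_palette("deep", assignment.k)
        colors = [palette[int(c)] for c in assignment.labels.loc[scores.index]]
    else:
        colors = None
    ax.scatter(scores["PC1"], scores["PC2"], c=colors, s=40)
    for name, row in scores.iterrows():
        label = name if isinstance(name, str) else name[0]
        ax.annotate(str(label), (row["PC1"], row["PC2"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ve = pca.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({ve[1]:.1f}%)" if len(ve) > 1 else "PC2")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    fig.tight_layout()
    return fig
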