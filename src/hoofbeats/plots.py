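"""Figure generation: interval/ratio densities, ternary plots, lollipop
peak plots, embedding scatters, and ROC curves.

The ternary plot uses a plain barycentric projection of the normalized
triplet proportions with reference markers at the canonical interval
patterns (1:1:1 and the three canter rotations 1:1:2, 1:2:1, 2:1:1).
All functions write a file and return its path; rendering uses the Agg
backend so they are safe headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .rhythm import PeakSet, TripletTable

GAIT_COLORS = {"walk": "#4477aa", "trot": "#ee6677", "canter": "#228833"}
_SQRT3_2 = np.sqrt(3) / 2


def _color(gait):
    return GAIT_COLORS.get(gait, "#888888")


def interval_density(interval_seqs_by_gait: dict, path) -> Path:
    """Kernel density of t_k per gait with annotated peak positions."""
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0.0, 1.0, 512)
    for gait, seqs in interval_seqs_by_gait.items():
        t = np.concatenate([s.t for s in seqs])
        dens = stats.gaussian_kde(t, bw_method="silverman")(grid)
        ax.plot(grid, dens, color=_color(gait), label=gait)
        from scipy.signal import find_peaks

        pk, _ = find_peaks(dens, prominence=0.05 * dens.max())
        for p in pk:
            ax.annotate(f"{grid[p]:.3f}", (grid[p], dens[p]), fontsize=8)
    ax.set_xlabel("inter-onset interval $t_k$ (s)")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ratio_density(ratio_seqs_by_gait: dict, path, references=(1 / 3, 0.5, 2 / 3)) -> Path:
    """Density of r_k per gait with small-integer reference lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(0.01, 0.99, 512)
    for gait, seqs in ratio_seqs_by_gait.items():
        r = np.concatenate([s.r for s in seqs])
        dens = stats.gaussian_kde(r, bw_method="silverman")(grid)
        ax.plot(grid, dens, color=_color(gait), label=gait)
    for ref in references:
        ax.axvline(ref, color="0.7", lw=0.8, ls="--")
    ax.set_xlabel("rhythmic ratio $r_k$")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def lollipop_peaks(peaksets: list[PeakSet], path, references=(1 / 3, 0.5, 2 / 3)) -> Path:
    """Per-individual ratio-density peak positions, one row per individual."""
    gaits = sorted({p.gait for p in peaksets})
    fig, axes = plt.subplots(
        1, len(gaits), figsize=(3.2 * len(gaits), 4), sharey=True, squeeze=False
    )
    for ax, gait in zip(axes[0], gaits):
        sets = [p for p in peaksets if p.gait == gait]
        for row, ps in enumerate(sets):
            for pos in ps.positions:
                ax.plot([pos, pos], [row - 0.3, row + 0.3], color=_color(gait), lw=1.5)
                ax.plot(pos, row, "o", color=_color(gait), ms=3)
        for ref in references:
            ax.axvline(ref, color="0.7", lw=0.8, ls="--")
        ax.set_title(gait)
        ax.set_xlim(0, 1)
        ax.set_xlabel("$r_k$ peak position")
    axes[0][0].set_ylabel("individual")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def _ternary_xy(props: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric (t1, t2, t3) proportions -> 2-D coordinates."""
    s = props.sum(axis=1, keepdims=True)
    a, b, c = (props / s).T
    return b + c / 2, c * _SQRT3_2


def ternary_plot(triplets: TripletTable, path) -> Path:
    """Triplet proportions in a ternary triangle, colored by gait.

    Axis order is fixed (t_k, t_k+1, t_k+2); reference markers sit at
    1:1:1 and the three canter rotations 1:1:2, 1:2:1, 2:1:1.
    """
    fig, ax = plt.subplots(figsize=(5.5, 5))
    tri = np.array([[0, 0], [1, 0], [0.5, _SQRT3_2], [0, 0]])
    ax.plot(tri[:, 0], tri[:, 1], color="0.3", lw=1)
    for gait in sorted(set(triplets.gait)):
        sel = triplets.gait == gait
        x, y = _ternary_xy(triplets.values[sel])
        ax.scatter(x, y, s=3, alpha=0.3, color=_color(gait), label=gait, lw=0)
    for ref, name in [
        ((1, 1, 1), "1:1:1"),
        ((1, 1, 2), "1:1:2"),
        ((1, 2, 1), "1:2:1"),
        ((2, 1, 1), "2:1:1"),
    ]:
        x, y = _ternary_xy(np.array([ref], dtype=float))
        ax.plot(x, y, "k+", ms=8)
        ax.annotate(name, (x[0], y[0]), fontsize=8, xytext=(3, 3),
                    textcoords="offset points")
    for lbl, xy in [("$t_k$", (-0.03, -0.03)), ("$t_{k+1}$", (1.01, -0.03)),
                    ("$t_{k+2}$", (0.5, _SQRT3_2 + 0.02))]:
        ax.annotate(lbl, xy, fontsize=10)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.legend(loc="upper left", markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def embedding_scatter(embedding, path, by: str = "gait") -> Path:
    """UMAP coordinates colored by gait or individual."""
    labels = embedding.gait if by == "gait" else embedding.individual_id
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for lab in sorted(set(labels)):
        sel = labels == lab
        color = _color(lab) if by == "gait" else None
        ax.scatter(
            embedding.coords[sel, 0], embedding.coords[sel, 1],
            s=3, alpha=0.4, label=str(lab), color=color, lw=0,
        )
    ax.set_xlabel("V1")
    ax.set_ylabel("V2")
    if by == "gait":
        ax.legend(markerscale=3)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def roc_plot(curves: dict, path) -> Path:
    """One-vs-rest ROC curves with AUC in the legend."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for cls, c in curves.items():
        ax.plot(c["fpr"], c["tpr"], label=f"{cls} (AUC {c['auc']:.3f})")
    ax.plot([0, 1], [0, 1], color="0.7", ls="--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
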