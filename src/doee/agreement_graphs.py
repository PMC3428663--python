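"""Diagnostic graphs: cumulative detection error and outline error distribution.

The *cumulative detection error* curve answers: how many ROIs were drawn by
only one rater with area strictly greater than a given threshold?  Plotted
per rater and in total, it shows where detection disagreement concentrates
(small lesions) and whether one rater marks more small lesions than the
other.  The *outline error distribution* is the histogram of the signed
relative area difference (|R2| - |R1|) / |R1 ∪ R2| over regions both raters
drew; an ideal distribution is a thin peak at 0, and asymmetry reveals a
systematic outlining bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DomainError
from .region_partition import ConnectedRegion

logger = logging.getLogger(__name__)

__all__ = [
    "CumulativeCurve",
    "OutlineHistogram",
    "cumulative_detection_curve",
    "outline_error_distribution",
    "render_graphs",
]


@dataclass
class CumulativeCurve:
    """Step function: counts of single-rater regions above an area threshold.

    ``thresholds`` holds 0 plus every distinct single-rater region area;
    counts use a strict "greater than", so the curve is right-continuous
    and non-increasing.  When ``normalized`` the counts are per scan.
    """

    thresholds: np.ndarray
    count_total: np.ndarray
    count_r1_only: np.ndarray
    count_r2_only: np.ndarray
    normalized: bool = False
    n_scans: int | None = None
    areas_r1: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    areas_r2: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def evaluate(self, threshold: float, which: str = "total") -> float:
        """Count of regions with area strictly greater than ``threshold``."""
        if which == "total":
            count = (self.areas_r1 > threshold).sum() + (self.areas_r2 > threshold).sum()
        elif which == "r1":
            count = (self.areas_r1 > threshold).sum()
        elif which == "r2":
            count = (self.areas_r2 > threshold).sum()
        else:
            raise DomainError(f"which must be 'total', 'r1' or 'r2', got {which!r}")
        return float(count) / self.n_scans if self.normalized else float(count)

    def to_table(self, path: str | Path | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "threshold": self.thresholds,
                "total": self.count_total,
                "rater1_only": self.count_r1_only,
                "rater2_only": self.count_r2_only,
            }
        )
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


@dataclass
class OutlineHistogram:
    """Histogram of (|R2| - |R1|) / |R1 ∪ R2| over regions drawn by both.

    The statistic always lies in [-1, 1]; negative values mean rater 1
    drew the larger outline.  ``values`` keeps the raw statistics.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    values: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    @property
    def n_regions(self) -> int:
        return int(self.counts.sum())

    def to_table(self, path: str | Path | None = None):
        import pandas as pd

        df = pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def cumulative_detection_curve(
    regions: Sequence[ConnectedRegion],
    per_scan_normalized: bool = False,
    n_scans: int | None = None,
) -> CumulativeCurve:
    """Build the cumulative detection error curve from a region table.

    Region size is the region's union area (the only area a single-rater
    region has).  Regions may span multiple scans; with
    ``per_scan_normalized`` the counts are divided by ``n_scans``.
    """
    if per_scan_normalized and not n_scans:
        raise DomainError("per-scan normalization requires n_scans > 0")
    areas_r1 = np.array([r.area_union for r in regions if r.label == "CR1"], float)
    areas_r2 = np.array([r.area_union for r in regions if r.label == "CR2"], float)
    all_areas = np.concatenate([areas_r1, areas_r2])
    thresholds = np.concatenate([[0.0], np.unique(all_areas)]) if all_areas.size else np.array([0.0])
    count_total = np.array([(all_areas > t).sum() for t in thresholds], float)
    count_r1 = np.array([(areas_r1 > t).sum() for t in thresholds], float)
    count_r2 = np.array([(areas_r2 > t).sum() for t in thresholds], float)
    if per_scan_normalized:
        count_total, count_r1, count_r2 = (
            count_total / n_scans,
            count_r1 / n_scans,
            count_r2 / n_scans,
        )
    return CumulativeCurve(
        thresholds=thresholds,
        count_total=count_total,
        count_r1_only=count_r1,
        count_r2_only=count_r2,
        normalized=per_scan_normalized,
        n_scans=n_scans,
        areas_r1=areas_r1,
        areas_r2=areas_r2,
    )


def outline_error_distribution(
    regions: Sequence[ConnectedRegion], bin_width: float = 0.1
) -> OutlineHistogram:
    """Histogram of the signed relative outline difference over CR12 regions.

    ``bin_width`` must divide the range [-1, 1] into an integer number of
    bins so the edges are symmetric about 0.  Binning is symmetric about 0:
    a positive statistic on a bin edge joins the bin to its left and a
    negative one the bin to its right, so swapping the raters reflects the
    histogram exactly; statistics of exactly 0 (identical outlines) go to
    the bin immediately right of 0.
    """
    n_half = 1.0 / bin_width
    if abs(n_half - round(n_half)) > 1e-9:
        raise DomainError(f"bin width {bin_width} does not divide [-1, 1] evenly")
    n_half = int(round(n_half))
    edges = np.linspace(-1.0, 1.0, 2 * n_half + 1)
    matched = [r for r in regions if r.label == "CR12"]
    if not matched:
        logger.warning("no CR12 regions: outline error distribution is empty")
        return OutlineHistogram(bin_edges=edges, counts=np.zeros(len(edges) - 1, int))
    values = np.array([(r.area_r2 - r.area_r1) / r.area_union for r in matched])
    idx = np.full(len(values), n_half, dtype=int)  # exact zeros
    pos, neg = values > 0, values < 0
    idx[pos] = n_half + np.ceil(values[pos] / bin_width).astype(int) - 1
    idx[neg] = n_half - np.ceil(-values[neg] / bin_width).astype(int)
    counts = np.bincount(np.clip(idx, 0, 2 * n_half - 1), minlength=2 * n_half)
    return OutlineHistogram(bin_edges=edges, counts=counts, values=values)


def _render_curve(curve: CumulativeCurve, ax) -> None:
    kw = dict(where="post")
    ax.step(curve.thresholds, curve.count_total, label="total", color="black", **kw)
    ax.step(curve.thresholds, curve.count_r1_only, label="rater 1 only", color="tab:blue", **kw)
    ax.step(curve.thresholds, curve.count_r2_only, label="rater 2 only", color="tab:red", **kw)
    ax.set_xlabel("area threshold (mm$^2$)")
    ylabel = "detection errors per scan" if curve.normalized else "detection errors"
    ax.set_ylabel(ylabel)
    ax.set_title("Cumulative detection error")
    ax.legend()


def _render_hist(hist: OutlineHistogram, ax) -> None:
    if hist.n_regions == 0:
        ax.text(0.5, 0.5, "no matched regions", ha="center", va="center", transform=ax.transAxes)
        ax.set_xlim(-1, 1)
    else:
        widths = np.diff(hist.bin_edges)
        ax.bar(hist.bin_edges[:-1], hist.counts, width=widths, align="edge", color="tab:gray")
    ax.set_xlabel(r"(|R2| $-$ |R1|) / |R1 $\cup$ R2|" + "\n(negative: rater 1 larger)")
    ax.set_ylabel("matched regions")
    ax.set_title("Outline error distribution")


def render_graphs(obj: CumulativeCurve | OutlineHistogram, path: str | Path) -> Path:
    """Render a curve or histogram to PNG/SVG (by file extension)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4), dpi=100)
    if isinstance(obj, CumulativeCurve):
        _render_curve(obj, ax)
    elif isinstance(obj, OutlineHistogram):
        _render_hist(obj, ax)
    else:
        raise DomainError(f"cannot render object of type {type(obj).__name__}")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, metadata={"Software": "doee"} if path.suffix == ".png" else None)
    plt.close(fig)
    return path
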