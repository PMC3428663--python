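"""Partition the union of two raters' masks into classified connected regions.

Per slice, the union (logical OR) of the two binary masks is labeled into
connected components; each component becomes one region classified by which
rater(s) contributed pixels to it:

* ``CR1`` — only rater 1 drew there (a detection disagreement),
* ``CR2`` — only rater 2 drew there,
* ``CR12`` — both raters drew there (an outline disagreement).

Connectivity is 8-connected within a slice by default, so a thin diagonal
outline cannot split one lesion into several regions; regions never merge
across slices (the analysis is two-dimensional).  A component touched by
both raters is CR12 even when their pixel sets do not overlap (adjacent
outlines merging in the union): its whole area then counts as outline error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from skimage.measure import label as _cc_label

from .errors import ValidationError
from .masks_io import RaterMaskPair

__all__ = ["ConnectedRegion", "partition_regions", "region_counts", "regions_to_table"]

RegionLabel = Literal["CR1", "CR2", "CR12"]


@dataclass(frozen=True)
class ConnectedRegion:
    """One connected component of the union mask, with per-rater areas (mm^2)."""

    scan_id: str
    slice_index: int
    label: RegionLabel
    area_union: float
    area_r1: float
    area_r2: float
    area_intersection: float

    def __post_init__(self) -> None:
        if self.area_union <= 0:
            raise ValidationError("a connected region must have positive union area")
        if self.area_intersection > min(self.area_r1, self.area_r2) + 1e-9:
            raise ValidationError("intersection area exceeds a rater's area")
        if abs(self.area_union - (self.area_r1 + self.area_r2 - self.area_intersection)) > 1e-6 * max(
            1.0, self.area_union
        ):
            raise ValidationError("inclusion-exclusion violated: |u| != |r1| + |r2| - |i|")
        expected = "CR12" if (self.area_r1 > 0 and self.area_r2 > 0) else (
            "CR1" if self.area_r1 > 0 else "CR2"
        )
        if self.label != expected:
            raise ValidationError(f"label {self.label} inconsistent with areas (expected {expected})")


def partition_regions(pair: RaterMaskPair, connectivity: int = 8) -> list[ConnectedRegion]:
    """Enumerate and classify connected regions of the union mask.

    Every foreground pixel of either rater belongs to exactly one region.
    Multiple ROIs of one rater falling in a single union component are
    merged, their areas summed.

    Parameters
    ----------
    pair : RaterMaskPair
        Shape-validated binary stacks plus pixel geometry.
    connectivity : {4, 8}
        Within-slice pixel connectivity (8 connects diagonal neighbours).
    """
    if connectivity not in (4, 8):
        raise ValidationError(f"connectivity must be 4 or 8, got {connectivity}")
    conn = 2 if connectivity == 8 else 1
    px_area = pair.geometry.pixel_area
    regions: list[ConnectedRegion] = []
    for z in range(pair.shape[0]):
        m1 = pair.rater1[z]
        m2 = pair.rater2[z]
        union = m1 | m2
        if not union.any():
            continue
        labels, n = _cc_label(union, connectivity=conn, return_num=True)
        # per-component pixel counts via bincount on the label image
        flat = labels.ravel()
        cnt_union = np.bincount(flat, minlength=n + 1)
        cnt_r1 = np.bincount(flat, weights=m1.ravel(), minlength=n + 1)
        cnt_r2 = np.bincount(flat, weights=m2.ravel(), minlength=n + 1)
        cnt_int = np.bincount(flat, weights=(m1 & m2).ravel(), minlength=n + 1)
        for lab in range(1, n + 1):
            a1 = cnt_r1[lab] * px_area
            a2 = cnt_r2[lab] * px_area
            kind: RegionLabel = "CR12" if (a1 > 0 and a2 > 0) else ("CR1" if a1 > 0 else "CR2")
            regions.append(
                ConnectedRegion(
                    scan_id=pair.scan_id,
                    slice_index=z,
                    label=kind,
                    area_union=cnt_union[lab] * px_area,
                    area_r1=a1,
                    area_r2=a2,
                    area_intersection=cnt_int[lab] * px_area,
                )
            )
    return regions


def region_counts(regions: Iterable[ConnectedRegion]) -> tuple[int, int, int]:
    """Counts of (CR1, CR2, CR12) regions."""
    n1 = n2 = n12 = 0
    for r in regions:
        if r.label == "CR1":
            n1 += 1
        elif r.label == "CR2":
            n2 += 1
        else:
            n12 += 1
    return n1, n2, n12


def regions_to_table(regions: Sequence[ConnectedRegion], path: str | Path | None = None):
    """Region table as a DataFrame; optionally written as TSV (areas at 1 dp)."""
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "scan_id": r.scan_id,
                "slice": r.slice_index,
                "label": r.label,
                "area_union": r.area_union,
                "area_r1": r.area_r1,
                "area_r2": r.area_r2,
                "area_intersection": r.area_intersection,
            }
            for r in regions
        ],
        columns=[
            "scan_id",
            "slice",
            "label",
            "area_union",
            "area_r1",
            "area_r2",
            "area_intersection",
        ],
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.1f")
    return df
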